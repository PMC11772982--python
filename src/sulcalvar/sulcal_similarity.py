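"""Spectral graph-matching similarity between sulcal pattern graphs.

Two sulcal graphs are compared by finding an injective node
correspondence that maximizes summed node similarity, guided by a
pairwise-consistency affinity over candidate assignments (the
spectral relaxation: the principal eigenvector of the assignment
affinity matrix, discretized greedily).  Similarity ranges over [0, 1];
normalization by the larger node count penalizes unmatched nodes and
makes self-similarity exactly 1.

Per-feature similarities (position, depth, area, topology) are reported
for the same correspondence, together with the weighted "total".
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from sulcalvar.config import FeatureWeights
from sulcalvar.sulcal_graph import SulcalGraph

log = logging.getLogger(__name__)

FEATURES = ("position", "depth", "area", "topology")
REGIONS = ("frontal", "temporal", "parietal", "occipital", "hemisphere")
SIDES = ("L", "R")
TRAIT_FEATURES = FEATURES + ("total",)


def trait_columns() -> list[str]:
    """The 50 trait names: ``<side>_<region>_<feature>``."""
    return [f"{side}_{region}_{feature}"
            for side in SIDES for region in REGIONS
            for feature in TRAIT_FEATURES]


@dataclass
class MatchResult:
    """Node correspondence and its similarity scores."""

    correspondence: dict[int, int]  # node id in A -> node id in B
    per_feature: dict[str, float]
    total: float

    def feature_similarity(self, feature: str) -> float:
        if feature == "total":
            return self.total
        if feature not in self.per_feature:
            raise KeyError(f"unknown feature {feature!r}")
        return self.per_feature[feature]


def _feature_arrays(graph: SulcalGraph) -> dict[str, np.ndarray]:
    return {
        "position": graph.positions(),
        "depth": np.array([n.depth for n in graph.nodes]),
        "area": np.array([n.area for n in graph.nodes]),
        "topology": np.array([n.topology for n in graph.nodes]),
    }


def _normalize_pair(pa: np.ndarray, pb: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Center each position cloud and rescale to a common size.

    Both graphs are centered at their node centroid; each is then
    rescaled to the geometric mean of the two root-mean-square node
    radii, which removes global translation and size mismatch while
    keeping distances in mm so the kernel scales stay meaningful.
    """
    ca = pa - pa.mean(axis=0)
    cb = pb - pb.mean(axis=0)
    ra = np.sqrt(np.mean(np.sum(ca ** 2, axis=1)))
    rb = np.sqrt(np.mean(np.sum(cb ** 2, axis=1)))
    if ra > 0 and rb > 0:
        common = np.sqrt(ra * rb)
        ca = ca * (common / ra)
        cb = cb * (common / rb)
    return ca, cb


def node_similarity_matrix(
    ga: SulcalGraph,
    gb: SulcalGraph,
    fw: FeatureWeights,
    normalize: bool = True,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Per-feature and combined similarity for every node pair.

    sim_f(i, j) = exp(-d_f(i, j)^2 / (2 sigma_f^2)); the combined
    similarity is the weight-sum over features.
    """
    fw.validate()
    fa, fb = _feature_arrays(ga), _feature_arrays(gb)
    if normalize:
        fa["position"], fb["position"] = _normalize_pair(
            fa["position"], fb["position"])
    sigmas = {"position": fw.sigma_position, "depth": fw.sigma_depth,
              "area": fw.sigma_area, "topology": fw.sigma_topology}
    weights = {"position": fw.w_position, "depth": fw.w_depth,
               "area": fw.w_area, "topology": fw.w_topology}
    per_feature = {}
    for feature in FEATURES:
        a, b = fa[feature], fb[feature]
        if a.ndim == 1:
            d2 = (a[:, None] - b[None, :]) ** 2
        else:
            diff = a[:, None, :] - b[None, :, :]
            d2 = np.sum(diff ** 2, axis=2)
        per_feature[feature] = np.exp(-d2 / (2.0 * sigmas[feature] ** 2))
    combined = sum(weights[f] * per_feature[f] for f in FEATURES)
    return per_feature, combined


def node_similarity(a, b, fw: FeatureWeights,
                    ) -> tuple[dict[str, float], float]:
    """Similarity of two individual nodes (no coordinate normalization)."""
    fw.validate()
    sims = {}
    sims["position"] = float(np.exp(
        -np.sum((a.position - b.position) ** 2)
        / (2 * fw.sigma_position ** 2)))
    sims["depth"] = float(np.exp(
        -(a.depth - b.depth) ** 2 / (2 * fw.sigma_depth ** 2)))
    sims["area"] = float(np.exp(
        -(a.area - b.area) ** 2 / (2 * fw.sigma_area ** 2)))
    sims["topology"] = float(np.exp(
        -np.sum((a.topology - b.topology) ** 2)
        / (2 * fw.sigma_topology ** 2)))
    combined = (fw.w_position * sims["position"]
                + fw.w_depth * sims["depth"]
                + fw.w_area * sims["area"]
                + fw.w_topology * sims["topology"])
    return sims, float(combined)


def _hop_counts(graph: SulcalGraph) -> np.ndarray:
    """All-pairs shortest-path hop counts; -1 across components."""
    g = graph.to_networkx()
    ids = [n.node_id for n in graph.nodes]
    index = {nid: i for i, nid in enumerate(ids)}
    hops = np.full((len(ids), len(ids)), -1.0)
    for src, lengths in nx.all_pairs_shortest_path_length(g):
        for dst, d in lengths.items():
            hops[index[src], index[dst]] = d
    return hops


def spectral_match(
    ga: SulcalGraph,
    gb: SulcalGraph,
    fw: FeatureWeights | None = None,
    normalize: bool = True,
    max_power_iterations: int = 200,
    refine: bool = True,
) -> MatchResult:
    """Spectral correspondence between two sulcal graphs.

    The affinity matrix over candidate assignments (i, j) has node
    similarity on the diagonal and, for compatible pairs (i != k,
    j != l), a consistency term combining preservation of inter-node
    Euclidean distance and of shortest-path hop count.  Its principal
    eigenvector (power iteration) is discretized greedily by
    descending entry subject to injectivity; an optional local-swap
    refinement then improves the summed node similarity.

    Total similarity = (sum of matched node similarities) /
    max(|V_A|, |V_B|); per-feature similarities use the same
    correspondence and normalization.
    """
    fw = (fw or FeatureWeights()).validate()
    if not ga.nodes or not gb.nodes:
        raise ValueError("cannot match an empty graph")
    if ga.region != gb.region or ga.hemisphere != gb.hemisphere:
        raise ValueError("graphs must share region and hemisphere")
    na, nb = len(ga.nodes), len(gb.nodes)
    per_feature_sim, combined = node_similarity_matrix(ga, gb, fw, normalize)

    pa, pb = _feature_arrays(ga)["position"], _feature_arrays(gb)["position"]
    if normalize:
        pa, pb = _normalize_pair(pa, pb)
    dist_a = np.linalg.norm(pa[:, None] - pa[None, :], axis=2)
    dist_b = np.linalg.norm(pb[:, None] - pb[None, :], axis=2)
    hops_a, hops_b = _hop_counts(ga), _hop_counts(gb)

    n_cand = na * nb
    m = np.zeros((n_cand, n_cand))
    ai, aj = np.divmod(np.arange(n_cand), nb)
    m[np.arange(n_cand), np.arange(n_cand)] = combined[ai, aj]
    geo = np.exp(
        -(dist_a[ai[:, None], ai[None, :]]
          - dist_b[aj[:, None], aj[None, :]]) ** 2
        / (2.0 * fw.sigma_position ** 2))
    ha = hops_a[ai[:, None], ai[None, :]]
    hb = hops_b[aj[:, None], aj[None, :]]
    topo = np.exp(-(ha - hb) ** 2 / (2.0 * fw.sigma_topology ** 2))
    consistency = geo * topo
    # cross-component pairs contribute no consistency
    consistency[(ha < 0) | (hb < 0)] = 0.0
    compatible = (ai[:, None] != ai[None, :]) & (aj[:, None] != aj[None, :])
    off = np.where(compatible, consistency, 0.0)
    np.fill_diagonal(off, 0.0)
    m = m + off
    np.fill_diagonal(m, combined[ai, aj])

    vec = np.full(n_cand, 1.0 / np.sqrt(n_cand))
    for _ in range(max_power_iterations):
        new = m @ vec
        norm = np.linalg.norm(new)
        if norm == 0:
            break
        new /= norm
        if np.linalg.norm(new - vec) < 1e-12:
            vec = new
            break
        vec = new

    correspondence = _greedy_discretize(vec, na, nb)
    if refine:
        correspondence = _refine(correspondence, combined, na, nb)
        # exact assignment on the reported objective; the eigenvector
        # correspondence is kept when it already attains the optimum
        rows, cols = linear_sum_assignment(combined, maximize=True)
        lap = dict(zip(rows.tolist(), cols.tolist()))
        if (sum(combined[i, j] for i, j in lap.items())
                > sum(combined[i, j] for i, j in correspondence.items())
                + 1e-12):
            correspondence = lap

    return _score(correspondence, per_feature_sim, combined, fw, ga, gb)


def _greedy_discretize(vec: np.ndarray, na: int, nb: int) -> dict[int, int]:
    """Assignments by descending eigenvector entry, injectively.

    Ties are broken by (lower A-node index, lower B-node index).
    """
    order = sorted(range(na * nb),
                   key=lambda c: (-vec[c], c // nb, c % nb))
    used_a, used_b = set(), set()
    out: dict[int, int] = {}
    for cand in order:
        i, j = divmod(cand, nb)
        if i in used_a or j in used_b:
            continue
        out[i] = j
        used_a.add(i)
        used_b.add(j)
        if len(out) == min(na, nb):
            break
    return out

def _refine(correspondence: dict[int, int], combined: np.ndarray,
            na: int, nb: int) -> dict[int, int]:
    """Local improvement of summed node similarity: pairwise swaps and
    reassignment to unused partners, iterated to a fixed point."""
    corr = dict(correspondence)
    improved = True
    while improved:
        improved = False
        items = sorted(corr.items())
        free_b = sorted(set(range(nb)) - set(corr.values()))
        for i, j in items:
            best_j, best_gain = j, 0.0
            for j2 in free_b:
                gain = combined[i, j2] - combined[i, j]
                if gain > best_gain + 1e-15:
                    best_j, best_gain = j2, gain
            if best_j != j:
                corr[i] = best_j
                free_b.remove(best_j)
                free_b.append(j)
                free_b.sort()
                improved = True
        items = sorted(corr.items())
        for (i1, j1), (i2, j2) in itertools.combinations(items, 2):
            if corr[i1] != j1 or corr[i2] != j2:
                continue
            gain = (combined[i1, j2] + combined[i2, j1]
                    - combined[i1, j1] - combined[i2, j2])
            if gain > 1e-15:
                corr[i1], corr[i2] = j2, j1
                improved = True
    return corr


def _score(correspondence, per_feature_sim, combined, fw,
           ga: SulcalGraph, gb: SulcalGraph) -> MatchResult:
    denom = max(len(ga.nodes), len(gb.nodes))
    total = sum(combined[i, j] for i, j in correspondence.items()) / denom
    per_feature = {
        f: sum(per_feature_sim[f][i, j]
               for i, j in correspondence.items()) / denom
        for f in FEATURES
    }
    id_a = [n.node_id for n in ga.nodes]
    id_b = [n.node_id for n in gb.nodes]
    mapping = {id_a[i]: id_b[j] for i, j in correspondence.items()}
    return MatchResult(correspondence=mapping,
                       per_feature=per_feature, total=float(total))


def exhaustive_match(
    ga: SulcalGraph,
    gb: SulcalGraph,
    fw: FeatureWeights | None = None,
    normalize: bool = True,
) -> MatchResult:
    """Brute-force optimal matching by enumeration (small graphs only).

    Maximizes the normalized summed node similarity over all injective
    assignments; an independent oracle for :func:`spectral_match`.
    """
    fw = (fw or FeatureWeights()).validate()
    na, nb = len(ga.nodes), len(gb.nodes)
    if na * nb > 64:
        raise ValueError("exhaustive matching is for small graphs only")
    per_feature_sim, combined = node_similarity_matrix(ga, gb, fw, normalize)
    k = min(na, nb)
    best, best_value = {}, -np.inf
    for a_subset in itertools.combinations(range(na), k):
        for b_perm in itertools.permutations(range(nb), k):
            value = sum(combined[i, j] for i, j in zip(a_subset, b_perm))
            if value > best_value:
                best_value = value
                best = dict(zip(a_subset, b_perm))
    return _score(best, per_feature_sim, combined, fw, ga, gb)


def graph_similarity(
    ga: SulcalGraph,
    gb: SulcalGraph,
    fw: FeatureWeights | None = None,
    normalize: bool = True,
) -> MatchResult:
    """Convenience wrapper: spectral matching with default weights."""
    return spectral_match(ga, gb, fw, normalize=normalize)


def mean_similarity_vs_reference(
    subject_graphs: dict[tuple[str, str], SulcalGraph],
    reference: dict[str, dict[tuple[str, str], SulcalGraph]],
    fw: FeatureWeights | None = None,
    subject_id: str | None = None,
    normalize: bool = True,
) -> pd.Series:
    """One participant's trait row: mean similarity to a reference cohort.

    ``subject_graphs`` maps (side, region) to the subject's graph;
    ``reference`` maps participant id to the same structure.  If the
    subject appears in the reference cohort (matched by ``subject_id``)
    it is excluded from its own reference (leave-one-out).  Returns the
    50-trait row indexed by ``<side>_<region>_<feature>``.
    """
    fw = (fw or FeatureWeights()).validate()
    others = [pid for pid in reference if pid != subject_id]
    if not others:
        raise ValueError("reference cohort is empty after exclusion")
    row: dict[str, float] = {}
    for (side, region), graph in subject_graphs.items():
        sums = {f: 0.0 for f in TRAIT_FEATURES}
        count = 0
        for pid in others:
            ref_graph = reference[pid].get((side, region))
            if ref_graph is None:
                continue
            match = spectral_match(graph, ref_graph, fw, normalize=normalize)
            for f in FEATURES:
                sums[f] += match.per_feature[f]
            sums["total"] += match.total
            count += 1
        if count == 0:
            raise ValueError(
                f"no reference graphs for side={side} region={region}")
        for f in TRAIT_FEATURES:
            row[f"{side}_{region}_{f}"] = sums[f] / count
    return pd.Series(row)


def cohort_trait_table(
    graphs: dict[str, dict[tuple[str, str], SulcalGraph]],
    reference_ids: list[str],
    subject_ids: list[str] | None = None,
    fw: FeatureWeights | None = None,
    normalize: bool = True,
) -> pd.DataFrame:
    """Trait table for a set of subjects against a reference cohort.

    Reference participants are compared leave-one-out.  Returns a
    participants x traits frame restricted to the trait columns present
    in the graphs.
    """
    subject_ids = list(graphs) if subject_ids is None else subject_ids
    reference = {pid: graphs[pid] for pid in reference_ids}
    rows = {}
    for pid in subject_ids:
        rows[pid] = mean_similarity_vs_reference(
            graphs[pid], reference, fw, subject_id=pid, normalize=normalize)
    table = pd.DataFrame(rows).T
    table.index.name = "participant"
    return table
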