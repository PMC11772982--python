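"""Synthetic cohorts with planted, recoverable structure.

The generator emulates the statistical structure of a case/control
design in which noncoding de novo variants carry signed functional
scores over annotation tracks and participants carry sulcal pattern
graphs:

* per-participant Poisson variant counts at uniform positions on one
  synthetic chromosome (``chrS``);
* zero-mean Gaussian scores per annotation; "effect" annotations have
  their case-cohort standard deviation multiplied by ``tail_inflation``
  so case scores are stochastically more extreme in both tails;
* planted annotation modules share a participant-level latent factor so
  their per-participant maxima are correlated across participants;
* each participant's sulcal graph is a perturbed copy of a template,
  with feature noise level eps_i linked to the first planted module's
  realized score so that the module score <-> sulcal similarity trait
  correlation approximates ``planted_trait_r``;
* a synthetic TSS map in which an enriched gene set is placed near the
  top-scoring case variants of the first effect annotation.

Nothing here simulates DNA sequence, MRI volumes, or realistic
epigenomic tracks; the generative link between variant impact and
sulcal geometry is a testing device, not a biological model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay

from sulcalvar.config import ConfigurationError, SimulationConfig
from sulcalvar.sulcal_graph import SulcalGraph, SulcalNode, compute_topology
from sulcalvar.sulcal_similarity import REGIONS, SIDES

log = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))

#: offset lifting module-planted scores above the background maxima so a
#: participant's max on a module annotation tracks the latent factor;
#: must clear the expected maximum of the background draws (about 1.9
#: for 20 standard-normal variants) for the planted within-module
#: correlation of maxima to reach its design value of 0.8
MODULE_SCORE_OFFSET = 3.5
#: noise s.d. around the latent factor for module members; with a unit
#: variance factor this gives within-module correlation 1/(1+0.25) = 0.8
MODULE_NOISE_SD = 0.5
#: mild lognormal shaping of eps keeps eps > 0 while staying close
#: enough to linear for Pearson recovery of the planted correlation
EPS_LOG_SD = 0.25


@dataclass
class GroundTruth:
    """Planted structure recorded for downstream recovery tests."""

    effect_annotations: list[str]
    module_membership: pd.Series  # annotation -> module id or "none"
    participant_eps: pd.Series = field(default_factory=pd.Series)
    module_scores: pd.DataFrame | None = None
    enriched_genes: list[str] = field(default_factory=list)
    enriched_set_name: str = "planted_set"


def _participants(cfg: SimulationConfig) -> pd.DataFrame:
    ids = [f"case{i:04d}" for i in range(cfg.n_case)] + \
          [f"ctrl{i:04d}" for i in range(cfg.n_control)]
    cohort = ["case"] * cfg.n_case + ["control"] * cfg.n_control
    return pd.DataFrame({"participant": ids, "cohort": cohort})


def gen_cohort_scores(
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate the variant table, score matrix and ground truth.

    Returns ``(variants, scores, truth)`` where ``variants`` has columns
    chrom, pos, ref, alt, participant, cohort and ``scores`` is a
    variants x annotations frame indexed by ``chrom:pos:ref:alt`` ids.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    participants = _participants(cfg)
    annotations = [f"ann{i:04d}" for i in range(cfg.n_annotations)]

    membership = pd.Series("none", index=annotations, dtype=object)
    start = 0
    for m, size in enumerate(cfg.planted_module_sizes):
        members = annotations[start:start + size]
        membership[members] = f"module{m}"
        start += size
    # effect annotations are disjoint from the planted modules so the
    # case-cohort variance inflation does not disturb module structure
    effect = annotations[start:start + cfg.effect_annotation_count]

    rows = []
    for _, prow in participants.iterrows():
        count = rng.poisson(cfg.variants_per_participant_mean)
        count = max(int(count), 1)  # every participant carries a variant
        pos = rng.integers(1, cfg.chrom_length + 1, size=count)
        ref_idx = rng.integers(0, 4, size=count)
        alt_shift = rng.integers(1, 4, size=count)
        for p, ri, sh in zip(pos, ref_idx, alt_shift):
            rows.append((
                "chrS", int(p), BASES[ri], BASES[(ri + sh) % 4],
                prow["participant"], prow["cohort"],
            ))
    variants = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "participant",
                       "cohort"])
    variants["variant_id"] = (
        variants["chrom"] + ":" + variants["pos"].astype(str)
        + ":" + variants["ref"] + ":" + variants["alt"])
    dup = variants["variant_id"].duplicated(keep="first")
    if dup.any():  # uniform positions can collide at small chrom_length
        variants = variants[~dup].reset_index(drop=True)

    n_var = len(variants)
    scores = rng.standard_normal((n_var, cfg.n_annotations))
    case_rows = (variants["cohort"] == "case").to_numpy()
    effect_cols = [annotations.index(a) for a in effect]
    scores[np.ix_(case_rows, effect_cols)] *= cfg.tail_inflation

    # participant-level latent factor per planted module: one designated
    # variant per participant carries an elevated score tied to the factor
    n_participants = len(participants)
    latent = rng.standard_normal(
        (n_participants, len(cfg.planted_module_sizes)))
    pid_order = participants["participant"].tolist()
    first_var = variants.groupby("participant", sort=False).head(1)
    first_idx = {p: i for p, i in
                 zip(first_var["participant"], first_var.index)}
    for m in range(len(cfg.planted_module_sizes)):
        members = membership.index[membership == f"module{m}"]
        cols = [annotations.index(a) for a in members]
        noise = rng.standard_normal((n_participants, len(cols)))
        planted = (MODULE_SCORE_OFFSET + latent[:, [m]]
                   + MODULE_NOISE_SD * noise)
        for pi, pid in enumerate(pid_order):
            scores[first_idx[pid], cols] = planted[pi]

    score_frame = pd.DataFrame(scores, index=variants["variant_id"],
                               columns=annotations)
    score_frame.index.name = "variant_id"

    module0 = membership.index[membership == "module0"]
    participant_series = variants.set_index("variant_id")["participant"]
    maxima = score_frame[module0].groupby(participant_series).max() \
        if len(module0) else pd.DataFrame(index=pid_order)
    truth = GroundTruth(
        effect_annotations=list(effect),
        module_membership=membership,
        module_scores=maxima,
    )
    return variants.drop(columns="variant_id"), score_frame, truth


def _template_graph(rng: np.random.Generator, n_nodes: int,
                    region: str, side: str) -> SulcalGraph:
    """Template sulcal graph: jittered grid positions on a surface patch,
    log-normal depths and areas, Delaunay-triangulation adjacency."""
    if n_nodes < 3:
        raise ConfigurationError("n_template_nodes must be >= 3")
    grid = int(np.ceil(np.sqrt(n_nodes)))
    xs, ys = np.meshgrid(np.arange(grid), np.arange(grid))
    base = np.column_stack([xs.ravel(), ys.ravel()])[:n_nodes] * 20.0
    xy = base + rng.normal(scale=3.0, size=base.shape)
    z = rng.normal(scale=2.0, size=n_nodes)
    positions = np.column_stack([xy, z])
    depths = rng.lognormal(mean=2.0, sigma=0.3, size=n_nodes)  # ~7-8 mm
    areas = rng.lognormal(mean=5.5, sigma=0.4, size=n_nodes)  # ~250 mm^2
    tri = Delaunay(xy)
    edges = set()
    for simplex in tri.simplices:
        for a, b in ((0, 1), (1, 2), (0, 2)):
            e = (int(min(simplex[a], simplex[b])),
                 int(max(simplex[a], simplex[b])))
            edges.add(e)
    nodes = [SulcalNode(node_id=i, position=positions[i],
                        depth=float(depths[i]), area=float(areas[i]))
             for i in range(n_nodes)]
    graph = SulcalGraph(nodes=nodes, edges=sorted(edges), region=region,
                        hemisphere=side)
    if not graph.edges:
        raise ConfigurationError("degenerate template: no edges")
    compute_topology(graph)
    return graph


def perturb_graph(
    template: SulcalGraph,
    eps: float,
    rng: np.random.Generator,
    sigma_position: float = 15.0,
    sigma_depth: float = 5.0,
    sigma_area: float = 200.0,
    participant: str | None = None,
) -> SulcalGraph:
    """Template copy with feature noise of relative level ``eps``.

    Gaussian noise with standard deviation ``eps * sigma_f`` is added to
    each geometric feature (so ``eps`` is expressed in units of the
    matching kernel scales), and each edge is rewired with probability
    proportional to ``eps``.
    """
    n = len(template.nodes)
    nodes = []
    for node in template.nodes:
        nodes.append(SulcalNode(
            node_id=node.node_id,
            position=node.position
            + rng.normal(scale=eps * sigma_position, size=3),
            depth=float(max(node.depth
                            + rng.normal(scale=eps * sigma_depth), 0.0)),
            area=float(max(node.area
                           + rng.normal(scale=eps * sigma_area), 1e-3)),
        ))
    rewire_p = min(0.5 * eps, 0.9)
    edges = set()
    for a, b in template.edges:
        if rng.random() < rewire_p and n > 2:
            c = int(rng.integers(0, n))
            while c == a:
                c = int(rng.integers(0, n))
            a, b = min(a, c), max(a, c)
        edges.add((min(a, b), max(a, b)))
    graph = SulcalGraph(nodes=nodes, edges=sorted(edges),
                        region=template.region,
                        hemisphere=template.hemisphere,
                        participant=participant)
    compute_topology(graph)
    return graph


def gen_sulcal_cohort(
    cfg: SimulationConfig,
    truth: GroundTruth,
    regions=(("L", "hemisphere"),),
) -> tuple[dict, dict]:
    """Per-participant sulcal graphs as template perturbations.

    Case participants' noise levels eps_i are tied to their planted
    module score so that corr(eps, module score) approximates
    ``-planted_trait_r`` — and hence the downstream module-trait
    correlation (similarity falls as eps grows) approximates
    ``planted_trait_r``; control (reference) participants get
    independent eps around ``perturbation_sd_control``.  Returns
    ``(templates, graphs)`` where ``templates`` maps (side, region) to
    the template graph and ``graphs`` maps participant id to a
    (side, region) -> graph dict.  Updates ``truth.participant_eps``.
    """
    cfg.validate()
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 0x5C1A]))
    templates = {
        (side, region): _template_graph(rng, cfg.n_template_nodes,
                                        region, side)
        for side, region in regions
    }
    participants = _participants(cfg)
    r = cfg.planted_trait_r
    if truth.module_scores is not None and len(truth.module_scores.columns):
        summary = truth.module_scores.mean(axis=1)
    else:
        summary = pd.Series(0.0, index=participants["participant"])
    z_mod = (summary - summary.mean()) / max(summary.std(ddof=0), 1e-12)

    eps_values = {}
    graphs = {}
    for _, prow in participants.iterrows():
        pid = prow["participant"]
        if prow["cohort"] == "case":
            # the sulcal trait (similarity) is monotone DECREASING in
            # eps, so linking eps to the module score with correlation
            # -r makes the module score <-> trait correlation come out
            # at planted_trait_r
            w = rng.standard_normal()
            driver = -r * z_mod.get(pid, 0.0) \
                + np.sqrt(1 - r ** 2) * w
            eps = cfg.perturbation_sd_case * float(
                np.exp(EPS_LOG_SD * driver - EPS_LOG_SD ** 2 / 2))
        else:
            eps = cfg.perturbation_sd_control * float(
                np.exp(EPS_LOG_SD * rng.standard_normal()
                       - EPS_LOG_SD ** 2 / 2))
        eps_values[pid] = eps
        graphs[pid] = {
            key: perturb_graph(tmpl, eps, rng, participant=pid)
            for key, tmpl in templates.items()
        }
    truth.participant_eps = pd.Series(eps_values, name="eps")
    return templates, graphs


def gen_gene_annotation(
    cfg: SimulationConfig,
    variants: pd.DataFrame,
    scores: pd.DataFrame,
    truth: GroundTruth,
    target_annotation: str | None = None,
    placement_fraction: float = 0.8,
    n_decoy_sets: int = 10,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Synthetic TSS map and gene sets with a planted enriched set.

    Genes are spread over the synthetic chromosome; for a fraction of
    case participants' top-scoring variants on ``target_annotation``
    (default: the first effect annotation), an enriched-set gene TSS is
    relocated within 20 kb, cycling through the set so its genes recur.
    Decoy sets are random gene samples.  Returns ``(tss BED-like frame,
    gmt dict)`` and records the enriched genes in ``truth``.
    """
    cfg.validate()
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 0x6E47]))
    spacing = cfg.chrom_length // (cfg.n_genes + 1)
    if spacing < 2:
        raise ConfigurationError("chrom_length too small for n_genes")
    genes = [f"gene{i:04d}" for i in range(cfg.n_genes)]
    tss_pos = (np.arange(1, cfg.n_genes + 1) * spacing
               + rng.integers(-spacing // 4, spacing // 4 + 1,
                              size=cfg.n_genes))
    tss_pos = np.clip(tss_pos, 1, cfg.chrom_length)

    target = target_annotation or truth.effect_annotations[0]
    vid = (variants["chrom"] + ":" + variants["pos"].astype(str)
           + ":" + variants["ref"] + ":" + variants["alt"])
    case = variants[variants["cohort"] == "case"]
    case_vid = vid[case.index]
    col = scores.loc[case_vid, target]
    top = (
        pd.DataFrame({"participant": case["participant"].to_numpy(),
                      "pos": case["pos"].to_numpy(),
                      "score": col.to_numpy()})
        .sort_values(["participant", "score"], ascending=[True, False],
                     kind="mergesort")
        .groupby("participant").first()
    )
    enriched = genes[:cfg.enriched_set_size]
    n_place = int(round(placement_fraction * len(top)))
    placed = top.head(n_place) if n_place else top.iloc[:0]
    for i, (_, row) in enumerate(placed.iterrows()):
        gene_idx = i % cfg.enriched_set_size
        offset = int(rng.integers(-15_000, 15_001))
        tss_pos[gene_idx] = int(
            np.clip(row["pos"] + offset, 1, cfg.chrom_length))

    tss = pd.DataFrame({
        "chrom": "chrS",
        "tss_pos": tss_pos,
        "gene": genes,
        "strand": rng.choice(["+", "-"], size=cfg.n_genes),
    }).sort_values(["chrom", "tss_pos"], kind="mergesort",
                   ignore_index=True)

    gmt = {truth.enriched_set_name: list(enriched)}
    for d in range(n_decoy_sets):
        size = int(rng.integers(cfg.enriched_set_size // 2,
                                2 * cfg.enriched_set_size))
        members = rng.choice(genes[cfg.enriched_set_size:],
                             size=min(size,
                                      cfg.n_genes - cfg.enriched_set_size),
                             replace=False)
        gmt[f"decoy{d:02d}"] = sorted(members)
    truth.enriched_genes = list(enriched)
    return tss, gmt


def tss_to_bed6(tss: pd.DataFrame) -> pd.DataFrame:
    """Convert the 1-based TSS frame to a 0-based BED6 frame."""
    # a TSS occupies one base: [pos-1, pos) in 0-based half-open terms,
    # so start is pos-1 for either strand of a length-1 interval
    start = tss["tss_pos"].to_numpy() - 1
    return pd.DataFrame({
        "chrom": tss["chrom"],
        "start": start,
        "end": start + 1,
        "gene": tss["gene"],
        "score": 0,
        "strand": tss["strand"],
    })


def simulate_study(cfg: SimulationConfig, regions=(("L", "hemisphere"),)):
    """Convenience wrapper generating all synthetic artifacts at once."""
    variants, scores, truth = gen_cohort_scores(cfg)
    templates, graphs = gen_sulcal_cohort(cfg, truth, regions=regions)
    tss, gmt = gen_gene_annotation(cfg, variants, scores, truth)
    return {
        "variants": variants,
        "scores": scores,
        "templates": templates,
        "graphs": graphs,
        "tss": tss,
        "gene_sets": gmt,
        "truth": truth,
    }
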