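"""Weighted correlation network analysis over per-participant score extremes.

Annotations are network nodes; edges are powered positive Pearson
correlations between their per-participant extreme scores (a
"signed-hybrid" network: negative correlations contribute zero).
Modules are detected by average-linkage clustering of the topological
overlap dissimilarity, summarized by eigengenes (first principal
component of the standardized member profiles), merged when eigengenes
are highly correlated, and finally correlated against sulcal traits
with Student asymptotic p-values and Bonferroni control.

This is a self-contained implementation of the procedure; it does not
aim for label-for-label parity with the reference R implementation
(the Dynamic Hybrid deep-split heuristic is replaced by a static
dendrogram cut plus a minimum module size).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from sulcalvar.config import NetworkParams

log = logging.getLogger(__name__)

GREY = "grey"


@dataclass
class Module:
    label: str
    members: list[str]
    eigengene: pd.Series | None = None
    variance_explained: float | None = None


@dataclass
class ModuleNetwork:
    """Result bundle of one network construction."""

    params: NetworkParams
    labels: pd.Series  # per-annotation module label
    modules: dict[str, Module] = field(default_factory=dict)
    removed_outlier: str | None = None


def _corr(profiles: pd.DataFrame) -> pd.DataFrame:
    cor = profiles.corr()  # Pearson, pairwise-complete
    np.fill_diagonal(cor.values, 1.0)
    return cor


def signed_hybrid_adjacency(
    correlation: pd.DataFrame | np.ndarray,
    power: int,
    diagonal: float = 0.0,
) -> np.ndarray:
    """Signed-hybrid adjacency: ``cor^power`` where cor > 0, else 0.

    ``diagonal`` selects the view: 0 for connectivity sums, 1 for
    topological-overlap computation.
    """
    if power < 1:
        raise ValueError("power must be >= 1")
    cor = np.asarray(correlation, dtype=float)
    adj = np.where(cor > 0, cor, 0.0) ** power
    np.fill_diagonal(adj, diagonal)
    return adj


def pick_soft_threshold(
    profiles: pd.DataFrame,
    candidate_powers=range(1, 21),
    r2_target: float = 0.8,
    n_bins: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Choose the soft-thresholding power by the scale-free topology fit.

    For each candidate power the connectivity distribution is binned
    into ``n_bins`` equal-count bins and log10(frequency) is regressed
    on log10(mean connectivity); the signed fit index is R^2 times the
    sign of the negative slope.  The smallest power reaching
    ``r2_target`` is chosen, else the power maximizing the signed fit.
    """
    if profiles.shape[0] < 4 or profiles.shape[1] < 10:
        raise ValueError("need >= 4 participants and >= 10 annotations")
    keep = profiles.columns[profiles.std(ddof=0) > 0]
    dropped = profiles.shape[1] - len(keep)
    if dropped:
        log.warning("pick_soft_threshold: dropped %d constant columns",
                    dropped)
    cor = _corr(profiles[keep]).to_numpy()
    rows = []
    for power in candidate_powers:
        adj = signed_hybrid_adjacency(cor, power, diagonal=0.0)
        k = adj.sum(axis=1)
        rows.append((power, _scale_free_fit(k, n_bins), float(k.mean())))
    table = pd.DataFrame(rows, columns=["power", "signed_r2", "mean_k"])
    qualifying = table[table["signed_r2"] >= r2_target]
    if len(qualifying):
        chosen = int(qualifying["power"].iloc[0])
    else:
        chosen = int(table.loc[table["signed_r2"].idxmax(), "power"])
    return chosen, table


def _scale_free_fit(connectivity: np.ndarray, n_bins: int) -> float:
    k = connectivity[connectivity > 0]
    if k.size < n_bins:
        return -1.0
    order = np.argsort(k)
    bins = np.array_split(order, n_bins)
    mean_k, freq = [], []
    for b in bins:
        if len(b) == 0:
            continue
        mean_k.append(k[b].mean())
        freq.append(len(b) / k.size)
    mean_k, freq = np.asarray(mean_k), np.asarray(freq)
    ok = mean_k > 0
    if ok.sum() < 3 or np.unique(np.log10(mean_k[ok])).size < 2:
        return -1.0
    res = stats.linregress(np.log10(mean_k[ok]), np.log10(freq[ok]))
    return float(res.rvalue ** 2 * np.sign(-res.slope))


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a zero-diagonal adjacency.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    for i != j, and 1 on the diagonal.
    """
    a = np.asarray(adjacency, dtype=float)
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if not np.allclose(np.diag(a), 0.0):
        raise ValueError("adjacency diagonal must be zero")
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + a) / denom
    tom = np.where(denom > 0, tom, 0.0)
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_modules(
    dissimilarity: np.ndarray,
    annotation_ids,
    params: NetworkParams,
) -> pd.Series:
    """Average-linkage clustering of TOM dissimilarity into modules.

    The dendrogram is cut at ``params.cut_height``; clusters with at
    least ``params.min_module_size`` members become modules labeled
    "M1", "M2", ... by decreasing size; everything else is grey.
    """
    ids = list(annotation_ids)
    d = np.asarray(dissimilarity, dtype=float)
    if d.shape[0] != len(ids):
        raise ValueError("dissimilarity size does not match annotation ids")
    if len(ids) < params.min_module_size:
        log.warning("fewer annotations than min_module_size; all grey")
        return pd.Series(GREY, index=ids)
    condensed = squareform(np.clip(d, 0.0, None), checks=False)
    z = linkage(condensed, method="average")
    clusters = fcluster(z, t=params.cut_height, criterion="distance")
    labels = pd.Series(GREY, index=ids, dtype=object)
    sizes = pd.Series(clusters).value_counts()
    big = sizes[sizes >= params.min_module_size]
    # deterministic label order: decreasing size, then first-member position
    order = sorted(
        big.index,
        key=lambda c: (-int(big[c]), int(np.argmax(clusters == c))))
    for rank, cluster_id in enumerate(order, start=1):
        labels.iloc[np.flatnonzero(clusters == cluster_id)] = f"M{rank}"
    return labels


def module_eigengene(
    member_profiles: pd.DataFrame,
) -> tuple[pd.Series, float]:
    """First principal component of the standardized member profiles.

    Returns the unit-norm eigengene (sign oriented so its mean
    correlation with member columns is positive) and the fraction of
    variance it explains.
    """
    if member_profiles.shape[1] < 2:
        raise ValueError("module needs at least 2 members")
    if member_profiles.shape[0] < 3:
        raise ValueError("eigengene needs at least 3 participants")
    x = member_profiles.astype(float)
    sd = x.std(ddof=0)
    constant = sd[sd == 0].index
    if len(constant):
        log.warning("dropping constant member columns: %s",
                    list(constant[:3]))
        x = x.drop(columns=constant)
        sd = sd.drop(constant)
    z = (x - x.mean()) / sd
    u, s, _ = np.linalg.svd(z.to_numpy(), full_matrices=False)
    eig = u[:, 0]
    member_cors = np.array([np.corrcoef(eig, z[c])[0, 1] for c in z.columns])
    if member_cors.mean() < 0:
        eig = -eig
    eigengene = pd.Series(eig / np.linalg.norm(eig), index=x.index,
                          name="eigengene")
    variance_explained = float(s[0] ** 2 / np.sum(s ** 2))
    return eigengene, variance_explained


def merge_modules(
    profiles: pd.DataFrame,
    labels: pd.Series,
    merge_height: float = 0.25,
) -> pd.Series:
    """Merge modules whose eigengenes are highly correlated.

    Modules are clustered (average linkage) on 1 - cor(eigengenes);
    clusters joined below ``merge_height`` are merged, eigengenes
    recomputed, and the step iterated to a fixed point.  Labels are
    re-ranked by size after merging.
    """
    labels = labels.copy()
    while True:
        names = sorted(set(labels) - {GREY})
        if len(names) <= 1:
            break
        eigs = pd.DataFrame({
            m: module_eigengene(profiles[labels.index[labels == m]])[0]
            for m in names})
        diss = 1.0 - eigs.corr().to_numpy()
        np.fill_diagonal(diss, 0.0)
        z = linkage(squareform(np.clip(diss, 0.0, None), checks=False),
                    method="average")
        groups = fcluster(z, t=merge_height, criterion="distance")
        if len(set(groups)) == len(names):
            break
        mapping = {}
        for g in set(groups):
            members = [names[i] for i in np.flatnonzero(groups == g)]
            for m in members:
                mapping[m] = members[0]
        labels = labels.map(lambda m: mapping.get(m, m))
    return _rank_labels(labels)


def _rank_labels(labels: pd.Series) -> pd.Series:
    """Relabel modules M1, M2, ... by decreasing size (grey unchanged)."""
    sizes = labels[labels != GREY].value_counts()
    order = sorted(
        sizes.index,
        key=lambda m: (-int(sizes[m]),
                       int(np.argmax((labels == m).to_numpy()))))
    mapping = {m: f"M{i}" for i, m in enumerate(order, start=1)}
    mapping[GREY] = GREY
    return labels.map(mapping)


def remove_outlier(profiles: pd.DataFrame) -> tuple[pd.DataFrame, str]:
    """Drop the single most outlying participant.

    Participants are clustered (average linkage, Euclidean distance on
    their score profiles); the participant whose singleton joins the
    dendrogram at the greatest height is removed.  Ties go to the
    lowest participant id.
    """
    if profiles.shape[0] < 3:
        raise ValueError("need at least 3 participants")
    x = profiles.to_numpy(dtype=float)
    z = linkage(x, method="average", metric="euclidean")
    n = x.shape[0]
    join_height = np.full(n, -np.inf)
    for a, b, height, _ in z:
        for idx in (int(a), int(b)):
            if idx < n:
                join_height[idx] = height
    top = join_height.max()
    candidates = sorted(profiles.index[np.isclose(join_height, top)])
    if len(candidates) > 1:
        log.info("outlier tie at height %.4g; removing %s", top,
                 candidates[0])
    removed = candidates[0]
    return profiles.drop(index=removed), str(removed)


def build_network(
    profiles: pd.DataFrame,
    params: NetworkParams | None = None,
    label_prefix: str = "",
    drop_outlier: bool = True,
    negate: bool = False,
) -> ModuleNetwork:
    """Full network construction from a participants x annotations matrix.

    ``negate=True`` flips the sign of the profiles before correlation
    (used for the minima network so that "more extreme negative" aligns
    with larger values).  ``label_prefix`` prepends e.g. "Positive" or
    "Negative" to module labels.
    """
    params = (params or NetworkParams()).validate()
    removed = None
    if drop_outlier:
        profiles, removed = remove_outlier(profiles)
    if negate:
        profiles = -profiles
    keep = profiles.columns[profiles.std(ddof=0) > 0]
    if len(keep) < profiles.shape[1]:
        log.warning("dropping %d constant annotations",
                    profiles.shape[1] - len(keep))
    profiles = profiles[keep]
    cor = _corr(profiles).to_numpy()
    adj = signed_hybrid_adjacency(cor, params.power, diagonal=0.0)
    tom = tom_similarity(adj)
    labels = detect_modules(1.0 - tom, profiles.columns, params)
    labels = merge_modules(profiles, labels, params.merge_height)
    if label_prefix:
        labels = labels.map(
            lambda m: m if m == GREY else label_prefix + m.lstrip("M"))
    network = ModuleNetwork(params=params, labels=labels,
                            removed_outlier=removed)
    for name in sorted(set(labels)):
        members = list(labels.index[labels == name])
        module = Module(label=name, members=members)
        if name != GREY and len(members) >= 2:
            module.eigengene, module.variance_explained = \
                module_eigengene(profiles[members])
        elif name == GREY and len(members) >= 2:
            # grey is kept in the trait grid with its own summary profile
            module.eigengene, module.variance_explained = \
                module_eigengene(profiles[members])
        network.modules[name] = module
    return network


def module_trait_correlation(
    network: ModuleNetwork,
    traits: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation of every module eigengene with every trait.

    Student asymptotic two-sided p-values from
    t = r sqrt(n-2)/sqrt(1-r^2); the Bonferroni multiplicity is
    (#modules including grey) x (#traits).
    """
    rows = []
    for name, module in sorted(network.modules.items()):
        if module.eigengene is None:
            continue
        for trait in traits.columns:
            pair = pd.concat(
                [module.eigengene, traits[trait]], axis=1, join="inner"
            ).dropna()
            n = len(pair)
            if n < 4:
                raise ValueError(
                    f"fewer than 4 aligned participants for {name}/{trait}")
            r, p = _pearson_student(pair.iloc[:, 0].to_numpy(),
                                    pair.iloc[:, 1].to_numpy())
            rows.append((name, trait, r, p, n))
    out = pd.DataFrame(rows, columns=["module", "trait", "r", "p", "n"])
    n_tests = len(out)
    threshold = alpha / n_tests if n_tests else np.nan
    out["significant"] = out["p"] < threshold
    out.attrs["bonferroni_threshold"] = threshold
    out.attrs["n_tests"] = n_tests
    return out


def _pearson_student(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n = len(x)
    r = float(np.corrcoef(x, y)[0, 1])
    if np.isnan(r):
        return 0.0, 1.0
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r ** 2)
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return r, p


def partial_correlation(
    x: pd.Series,
    y: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> tuple[float, float]:
    """Pearson correlation of ``x`` and ``y`` after removing covariates.

    Both variables are residualized on the covariates plus an intercept
    by least squares; the p-value uses df = n - 2 - (#covariates).
    With no covariates this reduces to the plain correlation.
    """
    frame = pd.concat([x.rename("x"), y.rename("y")], axis=1, join="inner")
    if covariates is not None and covariates.shape[1] > 0:
        frame = frame.join(covariates, how="inner")
    frame = frame.dropna()
    xv = frame["x"].to_numpy(dtype=float)
    yv = frame["y"].to_numpy(dtype=float)
    n = len(frame)
    n_cov = 0
    if covariates is not None and covariates.shape[1] > 0:
        c = frame[covariates.columns].to_numpy(dtype=float)
        design = np.column_stack([np.ones(n), c])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            ranks = [covariates.columns[j] for j in range(c.shape[1])
                     if np.linalg.matrix_rank(
                         np.column_stack([np.ones(n), np.delete(c, j, 1)]))
                     == np.linalg.matrix_rank(design)]
            raise ValueError(
                f"rank-deficient covariates; collinear columns: {ranks}")
        n_cov = c.shape[1]
        for v in (xv, yv):
            beta, *_ = np.linalg.lstsq(design, v, rcond=None)
            v -= design @ beta
    r = float(np.clip(np.corrcoef(xv, yv)[0, 1], -1.0, 1.0))
    df = n - 2 - n_cov
    if df < 1:
        raise ValueError("not enough observations for the requested model")
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df) / np.sqrt(1.0 - r ** 2)
    return r, float(2.0 * stats.t.sf(abs(t), df=df))
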