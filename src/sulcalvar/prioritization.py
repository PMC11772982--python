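"""Top-variant selection, nearest-TSS target genes, and enrichment.

Candidate target genes of a prioritized noncoding variant are the genes
whose transcription start site (TSS) lies in closest linear proximity to
the variant, within a maximum range of 20 kb.  Over-representation of
gene sets among recurrent target genes is assessed with a one-sided
hypergeometric test against the background of all assigned target
genes, with Benjamini-Hochberg adjustment across sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from sulcalvar.cohort_stats import bh_adjust

log = logging.getLogger(__name__)

MAX_TSS_DISTANCE = 20_000  # bp


@dataclass(frozen=True)
class TargetAssignment:
    variant_id: str
    participant: str
    score: float
    gene: str | None
    distance: int | None  # signed bp, variant pos - TSS pos


def read_tss_bed(path) -> pd.DataFrame:
    """Read a BED6 of transcription start sites.

    The TSS is the interval start for + strand and ``end - 1`` for -
    strand (0-based), converted to 1-based positions.  Duplicate gene
    ids are rejected.
    """
    bed = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "gene", "score", "strand"],
        dtype={"chrom": str, "gene": str},
    )
    pos0 = np.where(bed["strand"] == "-", bed["end"] - 1, bed["start"])
    out = pd.DataFrame({
        "chrom": bed["chrom"],
        "tss_pos": pos0 + 1,  # 1-based
        "gene": bed["gene"],
        "strand": bed["strand"],
    })
    if out["gene"].duplicated().any():
        dupes = out.loc[out["gene"].duplicated(), "gene"].unique()[:3]
        raise ValueError(f"duplicate TSS gene ids: {list(dupes)}")
    return out.sort_values(["chrom", "tss_pos"], kind="mergesort",
                           ignore_index=True)


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets in GMT format (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")


def top_variant_per_participant(
    scores: pd.Series,
    variant_participant: pd.Series,
    direction: str = "max",
) -> pd.DataFrame:
    """Select each participant's most extreme variant on one annotation.

    Ties are broken by lexicographic variant id (logged).  Returns a
    frame indexed by participant with ``variant_id`` and ``score``.
    """
    if direction not in ("max", "min"):
        raise ValueError("direction must be 'max' or 'min'")
    frame = pd.DataFrame({
        "variant_id": scores.index,
        "score": scores.to_numpy(dtype=float),
        "participant": variant_participant.reindex(scores.index).to_numpy(),
    })
    if frame["participant"].isna().any():
        raise ValueError("variants without participant mapping")
    ascending = direction == "min"
    frame = frame.sort_values(
        ["participant", "score", "variant_id"],
        ascending=[True, ascending, True], kind="mergesort")
    picked = frame.groupby("participant", sort=True).first()
    return picked[["variant_id", "score"]]


def assign_nearest_tss(
    chrom: str,
    pos: int,
    tss: pd.DataFrame,
    max_dist: int = MAX_TSS_DISTANCE,
) -> tuple[str | None, int | None]:
    """Nearest TSS within ``max_dist`` bp on the same chromosome.

    Distance is strand-agnostic 1-based position difference.  Ties go
    to the lexicographically lower gene id.  Returns ``(gene, signed
    distance)`` or ``(None, None)``.
    """
    sub = tss[tss["chrom"] == chrom]
    if sub.empty:
        log.info("variant chromosome %s absent from TSS table", chrom)
        return None, None
    positions = sub["tss_pos"].to_numpy()
    dist = np.abs(positions - pos)
    best = dist.min()
    if best > max_dist:
        return None, None
    candidates = sub.loc[sub.index[dist == best]].sort_values("gene")
    row = candidates.iloc[0]
    return str(row["gene"]), int(pos - row["tss_pos"])


def nearest_tss_bulk(
    variants: pd.DataFrame,
    tss: pd.DataFrame,
    max_dist: int = MAX_TSS_DISTANCE,
) -> pd.Series:
    """Vectorized nearest-TSS gene per variant (chrom/pos columns).

    Same contract as :func:`assign_nearest_tss`; returns a gene id (or
    None) per row of ``variants``.
    """
    out = pd.Series([None] * len(variants), index=variants.index,
                    dtype=object)
    for chrom, grp in variants.groupby("chrom"):
        sub = tss[tss["chrom"] == chrom].sort_values(["tss_pos", "gene"])
        if sub.empty:
            continue
        positions = sub["tss_pos"].to_numpy()
        genes = sub["gene"].to_numpy()
        pos = grp["pos"].to_numpy()
        right = np.searchsorted(positions, pos)
        left = np.clip(right - 1, 0, len(positions) - 1)
        right = np.clip(right, 0, len(positions) - 1)
        d_left = np.abs(pos - positions[left])
        d_right = np.abs(pos - positions[right])
        # tie at equal distance: lower gene id wins
        take_left = (d_left < d_right) | (
            (d_left == d_right) & (genes[left] <= genes[right]))
        best = np.where(take_left, left, right)
        dist = np.where(take_left, d_left, d_right)
        chosen = np.where(dist <= max_dist, genes[best], None)
        out.loc[grp.index] = chosen
    return out


def assign_targets(
    top_variants: pd.DataFrame,
    tss: pd.DataFrame,
    max_dist: int = MAX_TSS_DISTANCE,
) -> list[TargetAssignment]:
    """Nearest-TSS assignment for each participant's top variant."""
    out = []
    for participant, row in top_variants.iterrows():
        chrom, pos = row["variant_id"].split(":")[:2]
        gene, dist = assign_nearest_tss(chrom, int(pos), tss, max_dist)
        out.append(TargetAssignment(row["variant_id"], str(participant),
                                    float(row["score"]), gene, dist))
    return out


def recurrent_targets(
    assignments: list[TargetAssignment],
    min_count: int = 2,
) -> pd.DataFrame:
    """Genes hit by at least ``min_count`` distinct variants.

    Sorted by count descending, then gene id.
    """
    hits: dict[str, set[str]] = {}
    for a in assignments:
        if a.gene is not None:
            hits.setdefault(a.gene, set()).add(a.variant_id)
    rows = [(g, len(v)) for g, v in hits.items() if len(v) >= min_count]
    rows.sort(key=lambda t: (-t[1], t[0]))
    return pd.DataFrame(rows, columns=["gene", "n_variants"])


def hypergeometric_enrichment(
    study_genes,
    background_genes,
    gene_sets: dict[str, list[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of each gene set.

    p = P[X >= k] with population the background genes, K the set's
    background overlap, n the study-set size.  Sets with no background
    overlap are skipped; BH adjustment across the tested sets.
    """
    study = set(study_genes)
    background = set(background_genes)
    if not study <= background:
        raise ValueError("study genes must be a subset of the background")
    if not study:
        log.warning("empty study set; no enrichment computed")
        return pd.DataFrame(
            columns=["gene_set", "k", "n", "K", "N", "p", "p_adjusted"])
    n_total = len(background)
    n_study = len(study)
    rows = []
    for name, members in gene_sets.items():
        in_bg = set(members) & background
        if not in_bg:
            continue
        k = len(study & in_bg)
        big_k = len(in_bg)
        p = float(stats.hypergeom.sf(k - 1, n_total, big_k, n_study))
        rows.append((name, k, n_study, big_k, n_total, p))
    out = pd.DataFrame(
        rows, columns=["gene_set", "k", "n", "K", "N", "p"])
    if len(out):
        out["p_adjusted"] = bh_adjust(out["p"])
        out = out.sort_values(["p", "gene_set"], ignore_index=True)
    else:
        out["p_adjusted"] = []
    return out


def interval_overlap(
    variants: pd.DataFrame,
    regions: pd.DataFrame,
) -> tuple[pd.Series, float]:
    """Flag variants falling inside 0-based half-open BED regions.

    A 1-based variant position ``p`` overlaps ``[s, e)`` iff
    ``s < p <= e``.  Returns per-variant flags and the overlapping
    fraction.
    """
    regions = regions.sort_values(["chrom", "start"], kind="mergesort")
    by_chrom = {c: g[["start", "end"]].to_numpy()
                for c, g in regions.groupby("chrom")}
    flags = []
    for _, row in variants.iterrows():
        ivals = by_chrom.get(row["chrom"])
        p = int(row["pos"])
        flags.append(
            ivals is not None
            and bool(np.any((ivals[:, 0] < p) & (p <= ivals[:, 1])))
        )
    flags = pd.Series(flags, index=variants.index, name="overlaps")
    fraction = float(flags.mean()) if len(flags) else 0.0
    return flags, fraction
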