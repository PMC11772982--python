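"""Variant ingestion, filtering and extreme-quartile cohort statistics.

The cohort comparison follows the study protocol for per-annotation
functional scores: pool both cohorts, drop scores in the middle two
quartiles, then run one-sided Mann-Whitney U tests in each tail — the
lower tail asks whether case scores are stochastically smaller than
control scores, the upper tail whether they are stochastically larger —
with Bonferroni control across annotations x tails.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

#: chromosomes retained by default; the synthetic chromosome is included
#: so generated cohorts pass the standard-chromosome filter.
STANDARD_CHROMOSOMES = tuple(
    [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY", "chrS"]
)


@dataclass(frozen=True)
class VariantRecord:
    """A single-nucleotide noncoding de novo variant."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    participant: str
    cohort: str  # "case" or "control"
    allele_frequency: float | None = None

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass(frozen=True)
class MacieScore:
    """Posterior probabilities over the four conservation/regulation states."""

    p00: float
    p10: float
    p01: float
    p11: float

    def __post_init__(self):
        probs = (self.p00, self.p10, self.p01, self.p11)
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("posterior probabilities must lie in [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-6:
            raise ValueError("posterior probabilities must sum to 1")


@dataclass(frozen=True)
class DirectionalTestResult:
    annotation: str
    tail: str  # "lower" or "upper"
    u_statistic: float
    p_value: float
    significant: bool = False
    testable: bool = True


def read_exclusion_bed(path) -> pd.DataFrame:
    """Read a 0-based half-open BED of regions to exclude.

    Raises a ``ValueError`` naming the offending line on malformed input.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}: malformed BED line {lineno}: "
                    "expected at least 3 tab-separated fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed BED line {lineno}: "
                    "non-integer interval bounds") from exc
            if end < start:
                raise ValueError(
                    f"{path}: malformed BED line {lineno}: end < start")
            rows.append((parts[0], start, end))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def filter_variants(
    records: Sequence[VariantRecord],
    exclusion_beds: Iterable[pd.DataFrame] = (),
    af_threshold: float = 0.001,
    standard_chromosomes: Sequence[str] = STANDARD_CHROMOSOMES,
) -> list[VariantRecord]:
    """Apply the study's hard filters to a variant list.

    Removes variants with population allele frequency strictly above
    ``af_threshold`` (missing frequency is retained), variants on
    chromosomes outside ``standard_chromosomes``, and variants whose
    1-based position intersects any 0-based half-open exclusion
    interval.  Order is preserved.
    """
    standard = set(standard_chromosomes)
    exclusions: dict[str, np.ndarray] = {}
    merged = [bed for bed in exclusion_beds if len(bed)]
    if merged:
        allbed = pd.concat(merged, ignore_index=True)
        for chrom, grp in allbed.groupby("chrom"):
            ivals = grp[["start", "end"]].to_numpy()
            exclusions[chrom] = ivals[np.argsort(ivals[:, 0])]

    def excluded(rec: VariantRecord) -> bool:
        ivals = exclusions.get(rec.chrom)
        if ivals is None:
            return False
        pos0 = rec.pos - 1  # 0-based position of the variant base
        return bool(np.any((ivals[:, 0] <= pos0) & (pos0 < ivals[:, 1])))

    retained = []
    for rec in records:
        if rec.allele_frequency is not None and \
                rec.allele_frequency > af_threshold:
            continue
        if rec.chrom not in standard:
            continue
        if excluded(rec):
            continue
        retained.append(rec)
    log.info("filter_variants: retained %d / %d", len(retained), len(records))
    return retained


def macie_class_scores(m: MacieScore) -> tuple[float, float, float]:
    """Combine posterior state probabilities into the three summary classes.

    conserved = p10 + p11; regulatory = p01 + p11;
    any class = p10 + p01 + p11.
    """
    return (m.p10 + m.p11, m.p01 + m.p11, m.p10 + m.p01 + m.p11)


def quartile_extremes(
    scores: pd.Series,
) -> tuple[pd.Series, pd.Series]:
    """Split one annotation's pooled scores into the two extreme quartiles.

    Q1/Q3 are linear-interpolation quantiles over the pooled case and
    control values; the returned subsets are strictly below Q1 and
    strictly above Q3 (the closed interval [Q1, Q3] is discarded).
    """
    if len(scores) < 4:
        raise ValueError("quartile_extremes needs at least 4 values")
    values = scores.to_numpy(dtype=float)
    q1, q3 = np.quantile(values, [0.25, 0.75])  # linear interpolation
    lower = scores[scores < q1]
    upper = scores[scores > q3]
    if lower.empty and upper.empty:
        log.info("quartile_extremes: all values identical, both tails empty")
    return lower, upper


def cohort_compare_directional(
    lower_case: np.ndarray,
    lower_control: np.ndarray,
    upper_case: np.ndarray,
    upper_control: np.ndarray,
    annotation: str = "",
    exact_max_n: int = 20,
) -> tuple[DirectionalTestResult, DirectionalTestResult]:
    """One-sided Mann-Whitney U tests in both score tails.

    Lower tail: alternative "case stochastically less than control";
    upper tail: "case stochastically greater".  The exact null
    distribution is used for combined sample sizes <= ``exact_max_n``
    (falling back to the tie-corrected normal approximation when ties
    are present), otherwise the normal approximation.
    """

    def one(case, control, alternative, tail):
        case = np.asarray(case, dtype=float)
        control = np.asarray(control, dtype=float)
        if case.size == 0 or control.size == 0:
            log.info("annotation %s %s tail untestable (empty cohort)",
                     annotation, tail)
            return DirectionalTestResult(annotation, tail, np.nan, np.nan,
                                         testable=False)
        n = case.size + control.size
        has_ties = np.unique(np.concatenate([case, control])).size < n
        method = "exact" if (n <= exact_max_n and not has_ties) \
            else "asymptotic"
        res = stats.mannwhitneyu(case, control, alternative=alternative,
                                 method=method)
        return DirectionalTestResult(annotation, tail, float(res.statistic),
                                     float(res.pvalue))

    return (one(lower_case, lower_control, "less", "lower"),
            one(upper_case, upper_control, "greater", "upper"))


def cohort_compare_two_sided(
    case: np.ndarray,
    control: np.ndarray,
    annotation: str = "",
) -> DirectionalTestResult:
    """Two-sided Mann-Whitney U comparison of one score column.

    Used for subcohort consistency checks (e.g. imaging subcohort vs
    the rest of the case cohort) where no direction is hypothesized.
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    if case.size == 0 or control.size == 0:
        return DirectionalTestResult(annotation, "two-sided", np.nan,
                                     np.nan, testable=False)
    res = stats.mannwhitneyu(case, control, alternative="two-sided")
    return DirectionalTestResult(annotation, "two-sided",
                                 float(res.statistic), float(res.pvalue))


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold ``alpha / n_tests``."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def score_cohort_tests(
    scores: pd.DataFrame,
    variant_cohort: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run the full per-annotation extreme-quartile directional analysis.

    Parameters
    ----------
    scores
        Variants x annotations signed functional scores.
    variant_cohort
        Cohort label ("case"/"control") per variant id, aligned to
        ``scores.index``.
    alpha
        Family-wise error rate; the Bonferroni threshold divides it by
        the number of testable annotation/tail pairs configured
        (2 tests per annotation).

    Returns a tidy frame with one row per (annotation, tail).
    """
    cohort = variant_cohort.reindex(scores.index)
    if cohort.isna().any():
        missing = scores.index[cohort.isna()][:3].tolist()
        raise ValueError(f"variants without cohort label, e.g. {missing}")
    results = []
    for ann in scores.columns:
        col = scores[ann]
        lower, upper = quartile_extremes(col)
        lo, up = cohort_compare_directional(
            lower[cohort.loc[lower.index] == "case"].to_numpy(),
            lower[cohort.loc[lower.index] == "control"].to_numpy(),
            upper[cohort.loc[upper.index] == "case"].to_numpy(),
            upper[cohort.loc[upper.index] == "control"].to_numpy(),
            annotation=ann,
        )
        results.extend([lo, up])
    n_tests = 2 * scores.shape[1]
    threshold = bonferroni_threshold(alpha, n_tests)
    frame = pd.DataFrame(
        {
            "annotation": [r.annotation for r in results],
            "tail": [r.tail for r in results],
            "U": [r.u_statistic for r in results],
            "p": [r.p_value for r in results],
            "testable": [r.testable for r in results],
        }
    )
    frame["significant"] = frame["testable"] & (frame["p"] < threshold)
    frame.attrs["bonferroni_threshold"] = threshold
    frame.attrs["n_tests"] = n_tests
    return frame


def per_participant_extremes(
    scores: pd.DataFrame,
    variant_participant: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-participant maximum and minimum score over their variants.

    Returns ``(maxima, minima)``, each participants x annotations.
    Participants without variants simply have no row.
    """
    participant = variant_participant.reindex(scores.index)
    if participant.isna().any():
        missing = scores.index[participant.isna()][:3].tolist()
        raise ValueError(f"variants without participant, e.g. {missing}")
    grouped = scores.groupby(participant)
    maxima = grouped.max()
    minima = grouped.min()
    maxima.index.name = minima.index.name = "participant"
    return maxima, minima
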