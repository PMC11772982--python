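"""Cohort-level sulcal trait comparisons and power calculations."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def trait_group_regression(
    traits: pd.DataFrame,
    status: pd.Series,
    field_strength: pd.Series,
) -> pd.DataFrame:
    """Per-trait OLS of trait on case/control status and scanner field.

    ``trait ~ intercept + status + C(field_strength)`` per trait column,
    with two-sided coefficient p-values for the status term and BH
    adjustment across traits.
    """
    status = status.reindex(traits.index).astype(float)
    field = field_strength.reindex(traits.index)
    design = pd.get_dummies(field.astype("category"), drop_first=True,
                            prefix="field", dtype=float)
    design.insert(0, "status", status)
    design = sm.add_constant(design)
    rows = []
    for trait in traits.columns:
        y = traits[trait].astype(float)
        if np.isclose(y.std(ddof=0), 0.0):
            log.info("trait %s constant; coefficient 0, p = 1", trait)
            rows.append((trait, 0.0, 1.0))
            continue
        fit = sm.OLS(y, design).fit()
        rows.append((trait, float(fit.params["status"]),
                     float(fit.pvalues["status"])))
    out = pd.DataFrame(rows, columns=["trait", "status_coef", "p"])
    out["p_adjusted"] = bh_adjust(out["p"])
    return out


def subcohort_ttest(
    traits: pd.DataFrame,
    in_subgroup: pd.Series,
    welch: bool = False,
) -> pd.DataFrame:
    """Two-sided independent t-test per trait between two subgroups.

    Pooled-variance by default; Welch via ``welch=True``.  BH-adjusted
    across traits.
    """
    mask = in_subgroup.reindex(traits.index).astype(bool)
    a = traits.loc[mask]
    b = traits.loc[~mask]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both subgroups need at least 2 participants")
    rows = []
    for trait in traits.columns:
        x, y = a[trait].to_numpy(float), b[trait].to_numpy(float)
        if np.isclose(x.var(ddof=0), 0) and np.isclose(y.var(ddof=0), 0) \
                and np.isclose(x.mean(), y.mean()):
            log.info("trait %s has zero variance in both groups", trait)
            rows.append((trait, 0.0, 1.0))
            continue
        t, p = stats.ttest_ind(x, y, equal_var=not welch)
        rows.append((trait, float(t), float(p)))
    out = pd.DataFrame(rows, columns=["trait", "t", "p"])
    out["p_adjusted"] = bh_adjust(out["p"])
    return out


def correlation_power(r: float, n: int, alpha: float) -> float:
    """Power to detect a correlation of magnitude ``r`` at sample size ``n``.

    Uses the Fisher z transformation: atanh(|r|) is approximately normal
    with standard deviation 1/sqrt(n - 3), so a two-sided level-alpha
    test of zero correlation has power
    Phi(atanh(|r|) sqrt(n-3) - z_{1-alpha/2}) +
    Phi(-atanh(|r|) sqrt(n-3) - z_{1-alpha/2}).
    """
    if abs(r) >= 1:
        raise ValueError("|r| must be < 1")
    if n < 4:
        raise ValueError("n must be >= 4")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    delta = np.arctanh(abs(r)) * np.sqrt(n - 3)
    return float(stats.norm.cdf(delta - z_crit)
                 + stats.norm.cdf(-delta - z_crit))
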