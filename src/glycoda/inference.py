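"""Group-comparison statistics for glycan compositions.

The headline test is a permutation-calibrated max-type two-sample test
for high-dimensional compositional data: the statistic is the largest
squared standardised difference of clr-column means, and its null
distribution is obtained by random relabelling.  Per-coordinate
follow-up uses Mann-Whitney tests on the ilr coordinates with
Benjamini-Hochberg correction, as is standard for exploring which peaks
drive a global difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coda import clr, ilr

__all__ = [
    "TestResult",
    "global_composition_test",
    "mann_whitney",
    "kruskal_wallis",
    "chi_square",
    "bh_adjust",
    "peakwise_comparison",
]


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n1: int
    n2: int
    extra: dict = field(default_factory=dict)


def _max_t2_statistic(a_clr: np.ndarray, b_clr: np.ndarray,
                      keep: np.ndarray) -> float:
    na, nb = a_clr.shape[0], b_clr.shape[0]
    diff = a_clr.mean(axis=0) - b_clr.mean(axis=0)
    va = a_clr.var(axis=0, ddof=1)
    vb = b_clr.var(axis=0, ddof=1)
    denom = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = diff**2 / denom
    t2 = np.where(keep & (denom > 0), t2, -np.inf)
    return float(t2.max())


def global_composition_test(group_a, group_b, n_perm: int = 999,
                            seed: int = 0) -> TestResult:
    """Permutation max-type test of compositional equality of two groups.

    Rows are strictly positive closed compositions.  The statistic is
    M = max_j (mean_A clr_j - mean_B clr_j)^2 / (s_Aj^2/n_A + s_Bj^2/n_B);
    p = (1 + #{M* >= M}) / (n_perm + 1) under random relabelling.
    """
    a = clr(np.atleast_2d(np.asarray(group_a, float)))
    b = clr(np.atleast_2d(np.asarray(group_b, float)))
    na, nb = a.shape[0], b.shape[0]
    if na < 5 or nb < 5:
        raise ValueError("each group needs at least 5 subjects")
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    zero_var = (a.var(axis=0) == 0) & (b.var(axis=0) == 0)
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} clr column(s) constant in both groups; skipped",
            stacklevel=2,
        )
    keep = ~zero_var
    m_obs = _max_t2_statistic(a, b, keep)
    pooled = np.vstack([a, b])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        idx = rng.permutation(na + nb)
        m_star = _max_t2_statistic(pooled[idx[:na]], pooled[idx[na:]], keep)
        if m_star >= m_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return TestResult(m_obs, p, "permutation max-t2 (clr)", na, nb,
                      {"n_perm": n_perm, "skipped_columns": int(zero_var.sum())})


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test with midrank ties.

    Exact enumeration when n1+n2 <= 12 and there are no ties, otherwise
    the tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 values")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        warnings.warn("all values identical in both samples; p = 1", stacklevel=2)
        return TestResult(float(x.size * y.size / 2), 1.0,
                          "Mann-Whitney (degenerate)", x.size, y.size)
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size + y.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return TestResult(float(res.statistic), float(res.pvalue),
                      f"Mann-Whitney ({method})", x.size, y.size)


def kruskal_wallis(*groups) -> TestResult:
    """Kruskal-Wallis H test with tie correction, chi-square p on k-1 df."""
    if len(groups) == 1 and isinstance(groups[0], (list, tuple)):
        groups = tuple(groups[0])
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrs = [np.asarray(g, float) for g in groups]
    if any(a.size < 2 for a in arrs):
        raise ValueError("each group needs at least 2 values")
    if np.unique(np.concatenate(arrs)).size == 1:
        return TestResult(0.0, 1.0, "Kruskal-Wallis (degenerate)",
                          arrs[0].size, arrs[1].size)
    h, p = stats.kruskal(*arrs)
    return TestResult(float(h), float(p), "Kruskal-Wallis",
                      arrs[0].size, arrs[1].size,
                      {"k": len(arrs), "df": len(arrs) - 1})


def chi_square(contingency) -> TestResult:
    """Pearson chi-square test of independence (no continuity correction)."""
    obs = np.asarray(contingency, float)
    if np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
        raise ValueError("contingency table must hold non-negative integers")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("row and column sums must be positive")
    res = stats.chi2_contingency(obs, correction=False)
    extra = {"df": int(res.dof)}
    if np.any(res.expected_freq < 1):
        warnings.warn("expected cell count below 1; chi-square approximation "
                      "unreliable", stacklevel=2)
        extra["low_expected"] = True
    n1 = int(obs[0].sum())
    n2 = int(obs[1].sum()) if obs.shape[0] > 1 else 0
    return TestResult(float(res.statistic), float(res.pvalue),
                      "Pearson chi-square", n1, n2, extra)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def peakwise_comparison(cohort_a, cohort_b, alpha: float = 0.05) -> pd.DataFrame:
    """Coordinate-wise Mann-Whitney tests on ilr coordinates, BH-corrected.

    Parameters are two matrices of closed positive compositions (or
    cohort tables restricted to the GP columns).  Returns one row per
    ilr coordinate with columns (coordinate, statistic, p, p_adj, flag).
    """
    za = ilr(np.atleast_2d(np.asarray(cohort_a, float)))
    zb = ilr(np.atleast_2d(np.asarray(cohort_b, float)))
    rows = []
    for j in range(za.shape[1]):
        r = mann_whitney(za[:, j], zb[:, j])
        rows.append({"coordinate": f"ilr{j + 1}", "statistic": r.statistic,
                     "p": r.p_value})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["p_adj"] < alpha
    return out
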