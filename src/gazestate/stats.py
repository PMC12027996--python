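"""Group-level significance screen.

Mirrors the analysis chain used before range construction: a paired t-test
between the two eyes within each group (Bonferroni-corrected), a
normality-gated two-group comparison between fusion and rivalry units
(independent t when both groups pass Shapiro-Wilk at 0.05, Mann-Whitney U
otherwise), and a Spearman correlation matrix over indicators.

All tests are two-sided.  The Bonferroni family size defaults to 38, which
reproduces the adjusted threshold alpha' = 0.05/38 ~= 0.0013.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .indicators import INDICATOR_NAMES

DEFAULT_BONFERRONI_M = 38


@dataclass
class StatTestResult:
    test: str
    indicator: str
    statistic: float
    p_value: float
    n1: int
    n2: int
    alpha_applied: float
    flag: str = ""

    @property
    def significant(self) -> bool:
        return np.isfinite(self.p_value) and self.p_value < self.alpha_applied


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Family-wise corrected per-test threshold alpha/m."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def paired_t(left, right, indicator: str = "",
             alpha: float = 0.05) -> StatTestResult:
    """Two-sided paired t-test between left- and right-eye values."""
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape or left.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-d arrays")
    if left.size < 3:
        raise ValueError("need at least 3 pairs")
    diff = left - right
    if np.allclose(diff.std(ddof=1), 0.0):
        return StatTestResult("paired_t", indicator, np.nan, np.nan,
                              left.size, left.size, alpha,
                              flag="zero-variance differences")
    t, p = sps.ttest_rel(left, right)
    return StatTestResult("paired_t", indicator, float(t), float(p),
                          left.size, left.size, alpha)


def interocular_screen(trials: pd.DataFrame, alpha: float = 0.05,
                       m: int = DEFAULT_BONFERRONI_M,
                       indicators: Sequence[str] = INDICATOR_NAMES,
                       ) -> list[StatTestResult]:
    """Paired t-test of left vs right eye per indicator, per paradigm.

    Expects the per-trial table with ``left_<name>`` / ``right_<name>``
    columns; rows with a missing eye value are dropped pairwise.
    Significance is judged at the Bonferroni-adjusted threshold.
    """
    adj = bonferroni_alpha(alpha, m)
    out = []
    for paradigm, block in trials.groupby("paradigm"):
        for name in indicators:
            pair = block[[f"left_{name}", f"right_{name}"]].dropna()
            if len(pair) < 3:
                continue
            res = paired_t(pair.iloc[:, 0].to_numpy(),
                           pair.iloc[:, 1].to_numpy(), name, adj)
            res.indicator = f"{paradigm}:{name}"
            out.append(res)
    return out


def two_group_test(fusion, rivalry, indicator: str = "",
                   alpha: float = 0.05, normality_alpha: float = 0.05,
                   force: str | None = None) -> StatTestResult:
    """Normality-gated fusion-vs-rivalry comparison (two-sided).

    Shapiro-Wilk is applied to each group; if both pass, an independent
    samples t-test is used, otherwise a Mann-Whitney U test (exact
    enumeration when the smaller group has <= 8 cases and no ties span the
    groups, normal approximation with continuity and tie correction
    otherwise).
    """
    fusion = np.asarray(fusion, dtype=float)
    rivalry = np.asarray(rivalry, dtype=float)
    fusion = fusion[np.isfinite(fusion)]
    rivalry = rivalry[np.isfinite(rivalry)]
    n1, n2 = fusion.size, rivalry.size
    if min(n1, n2) < 3:
        raise ValueError("need at least 3 cases per group")
    pooled = np.concatenate([fusion, rivalry])
    if np.allclose(pooled, pooled[0]):
        return StatTestResult("degenerate", indicator, np.nan, np.nan,
                              n1, n2, alpha, flag="all values identical")
    if force is None:
        normal = (sps.shapiro(fusion).pvalue > normality_alpha
                  and sps.shapiro(rivalry).pvalue > normality_alpha)
    elif force in ("independent_t", "mann_whitney_u"):
        normal = force == "independent_t"
    else:
        raise ValueError(f"unknown forced test {force!r}")
    if normal:
        t, p = sps.ttest_ind(fusion, rivalry)
        return StatTestResult("independent_t", indicator, float(t), float(p),
                              n1, n2, alpha)
    method = "exact" if min(n1, n2) <= 8 else "asymptotic"
    try:
        u, p = sps.mannwhitneyu(fusion, rivalry, alternative="two-sided",
                                method=method, use_continuity=True)
    except ValueError:  # ties forbid the exact null distribution
        u, p = sps.mannwhitneyu(fusion, rivalry, alternative="two-sided",
                                method="asymptotic", use_continuity=True)
    return StatTestResult("mann_whitney_u", indicator, float(u), float(p),
                          n1, n2, alpha)


def two_group_screen(units: pd.DataFrame, alpha: float = 0.05,
                     m: int = DEFAULT_BONFERRONI_M,
                     indicators: Sequence[str] = INDICATOR_NAMES,
                     ) -> list[StatTestResult]:
    """Run the fusion-vs-rivalry screen for every paradigm x indicator.

    ``units`` is the repetition-averaged table (one row per subject x
    paradigm x group) with a ``state`` column.  Significance is judged at
    the Bonferroni-adjusted threshold.
    """
    adj = bonferroni_alpha(alpha, m)
    out = []
    for paradigm, block in units.groupby("paradigm"):
        fusion = block[block["state"] == "fusion"]
        rivalry = block[block["state"] == "rivalry"]
        for name in indicators:
            f = fusion[name].dropna()
            r = rivalry[name].dropna()
            if min(len(f), len(r)) < 3:
                continue
            res = two_group_test(f.to_numpy(), r.to_numpy(), name, adj)
            res.indicator = f"{paradigm}:{name}"
            out.append(res)
    return out


def spearman_matrix(columns: pd.DataFrame,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rho and p-value matrices across indicator columns.

    Requires >= 5 complete observations; constant columns yield NaN rho.
    Returned frames are symmetric with unit diagonal (zero p).
    """
    data = columns.dropna()
    if len(data) < 5:
        raise ValueError("need at least 5 paired observations")
    cols = list(data.columns)
    k = len(cols)
    rho = np.eye(k)
    pval = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            x, y = data.iloc[:, i], data.iloc[:, j]
            if x.nunique() < 2 or y.nunique() < 2:
                r, p = np.nan, np.nan
            else:
                r, p = sps.spearmanr(x, y)
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    return (pd.DataFrame(rho, index=cols, columns=cols),
            pd.DataFrame(pval, index=cols, columns=cols))


def write_test_table(results: Sequence[StatTestResult],
                     path: str | Path) -> None:
    df = pd.DataFrame([{
        "indicator": r.indicator, "test": r.test, "statistic": r.statistic,
        "p_value": r.p_value, "n1": r.n1, "n2": r.n2,
        "alpha_applied": r.alpha_applied, "significant": r.significant,
        "flag": r.flag} for r in results])
    df.to_csv(path, sep="\t", index=False)
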