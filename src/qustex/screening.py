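"""Per-feature benign-vs-malignant significance screening.

Each group is tested for normality (Shapiro-Wilk at alpha = 0.05); when
both groups pass, an unpaired two-sided t-test is used, otherwise a
two-sided Mann-Whitney U test. No multiple-testing correction is applied.
Significance tiers: ns, * (p < 0.05), ** (p < 0.01), *** (p < 0.001).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

SHAPIRO_ALPHA = 0.05


@dataclass(frozen=True)
class ScreeningResult:
    feature: str
    test: str  # "t-test" | "mann-whitney" | "degenerate"
    p_value: float
    tier: str


def significance_tier(p_value: float) -> str:
    """Threshold map of a p-value onto the star tiers."""
    if not np.isfinite(p_value):
        return "ns"
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return "ns"


def significance_screen(benign, malignant, feature: str = "feature") -> ScreeningResult:
    """Normality-gated two-group test of one feature."""
    x = np.asarray(benign, dtype=float)
    y = np.asarray(malignant, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size < 3 or y.size < 3:
        raise ValueError("need at least 3 observations per group")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        p = 1.0 if x[0] == y[0] else float("nan")
        return ScreeningResult(feature, "degenerate", p, "ns")
    normal = True
    for g in (x, y):
        if np.ptp(g) == 0:  # Shapiro undefined on constant data
            normal = False
            break
        if stats.shapiro(g).pvalue < SHAPIRO_ALPHA:
            normal = False
            break
    if normal:
        p = float(stats.ttest_ind(x, y, equal_var=True).pvalue)
        test = "t-test"
    else:
        method = "exact" if max(x.size, y.size) <= 20 and not _has_ties(x, y) else "asymptotic"
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)
        test = "mann-whitney"
    return ScreeningResult(feature, test, p, significance_tier(p))


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return np.unique(pooled).size < pooled.size


def screen_feature_table(table: pd.DataFrame, label_column: str = "label",
                         positive: str = "malignant") -> pd.DataFrame:
    """Screen every feature column of a cohort table.

    Returns a report frame with feature, test, p and tier columns,
    mirroring the star annotations of a screening figure.
    """
    labels = table[label_column]
    pos = table[labels == positive]
    neg = table[labels != positive]
    rows = []
    for col in table.columns:
        if col == label_column:
            continue
        res = significance_screen(neg[col].to_numpy(), pos[col].to_numpy(), feature=col)
        rows.append((res.feature, res.test, res.p_value, res.tier))
    return pd.DataFrame(rows, columns=["feature", "test", "p", "tier"])
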