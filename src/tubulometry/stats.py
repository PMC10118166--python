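"""Group statistics: Welch tests, five-number summaries, ANOVA + Dunnett.

Welch's unpaired two-tailed t-test is the default two-group comparison
(group sizes are typically unequal — e.g. 4 controls vs 8 treated — and no
variance homogeneity is assumed). Multi-dose designs use one-way ANOVA
followed by Dunnett's many-to-one comparisons against the control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "welch_ttest",
    "five_number_summary",
    "anova_dunnett",
    "benjamini_hochberg",
]


def welch_ttest(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-tailed p-value of Welch's unequal-variance t-test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(sps.ttest_ind(a, b, equal_var=False).pvalue)


def five_number_summary(values: Sequence[float]) -> dict[str, float]:
    """Minimum, first quartile, median, third quartile, maximum — the
    box-and-whisker numbers."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {
        "min": float(v.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(v.max()),
    }


@dataclass
class AnovaDunnettResult:
    anova_p: float
    dunnett_p: dict[str, float]  # treatment name -> adjusted p vs control


def anova_dunnett(
    control: Sequence[float],
    treatments: dict[str, Sequence[float]],
) -> AnovaDunnettResult:
    """One-way ANOVA F-test across all groups, then Dunnett's multi-comparison
    of every treatment against the control."""
    groups = [np.asarray(control, dtype=float)] + [
        np.asarray(v, dtype=float) for v in treatments.values()
    ]
    anova_p = float(sps.f_oneway(*groups).pvalue)
    res = sps.dunnett(*groups[1:], control=groups[0])
    dunnett_p = {name: float(p) for name, p in zip(treatments, res.pvalue)}
    return AnovaDunnettResult(anova_p=anova_p, dunnett_p=dunnett_p)


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (optional across-bin correction)."""
    return sps.false_discovery_control(np.asarray(pvalues, dtype=float), method="bh")
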