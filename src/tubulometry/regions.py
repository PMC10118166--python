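"""Cross-specimen regional analysis on the TP-aligned coordinate.

Profiles from several specimens are aligned on the signed geodesic
coordinate (turning point at 0), split into proximal convoluted (PCT) and
proximal straight (PST) segments at a single split coordinate, averaged in
bins, and compared control vs treated per bin with Welch's t-test. Group
fold changes of whole-tubule length / diameter / volume are summarized the
same way the per-animal box plots are.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import benjamini_hochberg, five_number_summary, welch_ttest

__all__ = [
    "BinnedProfile",
    "RegionComparison",
    "split_regions",
    "bin_profiles",
    "compare_bins",
    "summarize_groups",
    "GroupSummary",
]

ALPHA = 0.05
DEFAULT_BIN_WIDTH_UM = 25.0
DEFAULT_SPLIT_S_UM = 175.0


def split_regions(s: np.ndarray, split_s_um: float = DEFAULT_SPLIT_S_UM) -> np.ndarray:
    """Label each signed coordinate PCT (s < split) or PST (s >= split).

    The PCT contains the glomerulus-to-TP limb and the early post-TP
    segment; everything beyond the split coordinate is PST. The split must
    lie within the coordinate range.
    """
    s = np.asarray(s, dtype=float)
    if s.size and not (s.min() <= split_s_um <= s.max()):
        raise ValueError(
            f"split {split_s_um} μm outside the coordinate range "
            f"[{s.min():.1f}, {s.max():.1f}]"
        )
    return np.where(s < split_s_um, "PCT", "PST")


@dataclass
class BinnedProfile:
    """Per-specimen bin means of one profile metric on the signed coordinate.

    `means` is indexed by specimen with one column per bin center; bins tile
    the pooled coordinate range without overlap (edges anchored at integer
    multiples of the width so bins coincide across specimens). `counts`
    holds the number of profile points behind each mean (0 → no coverage,
    value NaN).
    """

    bin_edges: np.ndarray
    means: pd.DataFrame
    counts: pd.DataFrame
    metric: str
    bin_width_um: float

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def bin_profiles(
    profiles: Mapping[str, pd.DataFrame],
    metric: str = "area_um2",
    bin_width_um: float = DEFAULT_BIN_WIDTH_UM,
    s_column: str = "s_um",
) -> BinnedProfile:
    """Average `metric` per specimen in common bins of the signed coordinate.

    Bin edges are multiples of `bin_width_um` covering the pooled s range;
    a point falls in bin [left, right), except that the final right edge is
    inclusive so the extreme point is not dropped.
    """
    if bin_width_um <= 0:
        raise ValueError("bin width must be positive")
    if not profiles:
        raise ValueError("no profiles given")
    s_min = min(float(p[s_column].min()) for p in profiles.values())
    s_max = max(float(p[s_column].max()) for p in profiles.values())
    lo = np.floor(s_min / bin_width_um)
    hi = np.ceil(s_max / bin_width_um)
    if hi <= lo:
        hi = lo + 1
    edges = np.arange(lo, hi + 1) * bin_width_um
    centers = 0.5 * (edges[:-1] + edges[1:])

    means = pd.DataFrame(index=list(profiles), columns=centers, dtype=float)
    counts = pd.DataFrame(0, index=list(profiles), columns=centers, dtype=int)
    for sid, prof in profiles.items():
        s = prof[s_column].to_numpy(dtype=float)
        v = prof[metric].to_numpy(dtype=float)
        which = np.digitize(s, edges) - 1
        which[s == edges[-1]] = len(centers) - 1
        for b in range(len(centers)):
            sel = which == b
            if sel.any():
                means.iloc[means.index.get_loc(sid), b] = v[sel].mean()
                counts.iloc[counts.index.get_loc(sid), b] = int(sel.sum())
    return BinnedProfile(edges, means, counts, metric, float(bin_width_um))


@dataclass
class RegionComparison:
    """Binwise control-vs-treated comparison plus per-region verdicts."""

    table: pd.DataFrame           # per bin: center, means, p, significant, testable
    region_verdicts: dict[str, bool] = field(default_factory=dict)
    alpha: float = ALPHA


def compare_bins(
    binned: BinnedProfile,
    groups: Mapping[str, str],
    alpha: float = ALPHA,
    split_s_um: float = DEFAULT_SPLIT_S_UM,
    region_majority: float = 0.5,
    correction: str | None = None,
) -> RegionComparison:
    """Welch's unpaired two-tailed t-test per bin, control vs treated.

    Bins with fewer than two specimens per group are marked untestable. A
    region (PCT / PST, split at `split_s_um`) is called significant iff more
    than `region_majority` of its testable bins are. Raw per-bin p-values
    are reported by default; `correction="bh"` applies Benjamini–Hochberg
    across testable bins.
    """
    control_ids = [k for k, g in groups.items() if g == "control"]
    treated_ids = [k for k, g in groups.items() if g == "treated"]
    rows = []
    for center in binned.means.columns:
        c = binned.means.loc[control_ids, center].dropna().to_numpy()
        t = binned.means.loc[treated_ids, center].dropna().to_numpy()
        testable = len(c) >= 2 and len(t) >= 2
        p = welch_ttest(c, t) if testable else np.nan
        rows.append(
            {
                "bin_center_um": float(center),
                "control_mean": c.mean() if len(c) else np.nan,
                "treated_mean": t.mean() if len(t) else np.nan,
                "n_control": len(c),
                "n_treated": len(t),
                "p_value": p,
                "testable": testable,
            }
        )
    table = pd.DataFrame(rows)
    if correction == "bh":
        mask = table["testable"].to_numpy()
        adj = table["p_value"].to_numpy(copy=True)
        adj[mask] = benjamini_hochberg(adj[mask])
        table["p_value"] = adj
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    table["significant"] = table["p_value"] < alpha
    table["region"] = np.where(table["bin_center_um"] < split_s_um, "PCT", "PST")

    verdicts = {}
    for region in ("PCT", "PST"):
        sub = table[(table["region"] == region) & table["testable"]]
        verdicts[region] = bool(len(sub)) and (sub["significant"].mean() > region_majority)
    return RegionComparison(table=table, region_verdicts=verdicts, alpha=alpha)


@dataclass
class GroupSummary:
    """Fold changes vs the control mean plus tests, per whole-tubule metric."""

    per_specimen: pd.DataFrame    # fold columns added per metric
    fold_treated: dict[str, float]
    p_values: dict[str, float]
    five_numbers: dict[str, dict[str, dict[str, float]]]  # metric -> group -> summary


def summarize_groups(
    summaries: pd.DataFrame,
    metrics: Sequence[str] = ("length_um", "mean_diameter_um", "volume_um3"),
) -> GroupSummary:
    """Group-level read-out of whole-tubule metrics.

    For each metric: per-specimen fold change versus the control-group mean,
    the treated-group mean fold, Welch's t-test control vs treated, and the
    five-number (box-plot) summary of each group's folds.
    """
    for col in ("specimen_id", "group"):
        if col not in summaries.columns:
            raise ValueError(f"summaries must have a {col!r} column")
    control = summaries[summaries["group"] == "control"]
    treated = summaries[summaries["group"] == "treated"]
    if control.empty or treated.empty:
        raise ValueError("both control and treated groups must be non-empty")

    out = summaries.copy()
    folds: dict[str, float] = {}
    pvals: dict[str, float] = {}
    fives: dict[str, dict[str, dict[str, float]]] = {}
    for metric in metrics:
        cmean = float(control[metric].mean())
        if cmean == 0:
            raise ZeroDivisionError(f"control mean of {metric} is zero")
        out[f"{metric}_fold"] = out[metric] / cmean
        folds[metric] = float(treated[metric].mean() / cmean)
        pvals[metric] = welch_ttest(control[metric], treated[metric])
        fives[metric] = {
            "control": five_number_summary(out.loc[out["group"] == "control", f"{metric}_fold"]),
            "treated": five_number_summary(out.loc[out["group"] == "treated", f"{metric}_fold"]),
        }
    return GroupSummary(
        per_specimen=out, fold_treated=folds, p_values=pvals, five_numbers=fives
    )
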