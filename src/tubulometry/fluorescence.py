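"""Fluorescence signal-intensity (SI) quantification.

Reimplements the confocal read-out chain: maximum-intensity projection of
the z-stack, mean SI over suprathreshold pixels, threshold-based glomerulus
volume, and fold change normalized to the control-group mean. The
"selected threshold" is either a fixed number or Otsu's method computed on
the control-group MIPs and then held fixed across groups (controls and
treatment groups share acquisition settings, so one shared threshold is the
faithful convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .volume import ImageVolume

__all__ = [
    "SIResult",
    "ThresholdVolumeResult",
    "max_projection",
    "select_threshold",
    "quantify_si",
    "glomerulus_volume",
    "fold_change",
    "quantify_cohort",
]


@dataclass
class SIResult:
    specimen_id: str
    mean_si: float
    suprathreshold_pixel_count: int
    threshold_used: float
    fold_change: float = np.nan
    empty: bool = False  # no pixel passed the threshold


@dataclass
class ThresholdVolumeResult:
    specimen_id: str
    volume_um3: float
    threshold_used: float
    fold_change: float = np.nan
    empty: bool = False


def max_projection(stack: ImageVolume | np.ndarray, axis: int = 0) -> np.ndarray:
    """Maximum-intensity projection along `axis` (default z)."""
    data = stack.data if isinstance(stack, ImageVolume) else np.asarray(stack)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D stack, got {data.ndim} axes")
    return data.max(axis=axis)


def select_threshold(threshold, control_mips: Sequence[np.ndarray] | None = None) -> float:
    """Resolve a threshold spec: a number is passed through; ``"otsu"``
    computes Otsu's threshold on the pooled control-group MIP pixels."""
    if isinstance(threshold, str):
        if threshold.lower() != "otsu":
            raise ValueError(f"unknown threshold method {threshold!r}")
        if not control_mips:
            raise ValueError("otsu thresholding requires control-group MIPs")
        pooled = np.concatenate([np.asarray(m).ravel() for m in control_mips])
        return float(threshold_otsu(pooled))
    return float(threshold)


def quantify_si(
    mip: np.ndarray,
    threshold: float,
    specimen_id: str = "",
    domain: str = "suprathreshold",
) -> SIResult:
    """Mean SI of a MIP over pixels strictly above `threshold`.

    `domain="roi"` averages over the whole image instead (the suprathreshold
    convention is the default read-out). An empty suprathreshold set yields
    mean 0 with the `empty` flag set.
    """
    mip = np.asarray(mip, dtype=float)
    mask = mip > threshold
    count = int(mask.sum())
    if domain == "roi":
        return SIResult(specimen_id, float(mip.mean()), count, float(threshold))
    if domain != "suprathreshold":
        raise ValueError(f"unknown SI domain {domain!r}")
    if count == 0:
        return SIResult(specimen_id, 0.0, 0, float(threshold), empty=True)
    return SIResult(specimen_id, float(mip[mask].mean()), count, float(threshold))


def glomerulus_volume(
    stack: ImageVolume,
    threshold: float,
    specimen_id: str = "",
) -> ThresholdVolumeResult:
    """Threshold-based glomerulus volume in μm³.

    Counts voxels strictly above the threshold inside the largest
    26-connected suprathreshold component (a single structure is being
    measured; stray noise voxels are excluded) and multiplies by the voxel
    volume.
    """
    mask = stack.data > threshold
    if not mask.any():
        return ThresholdVolumeResult(specimen_id, 0.0, float(threshold), empty=True)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    volume = float(mask.sum()) * stack.voxel_volume_um3
    return ThresholdVolumeResult(specimen_id, volume, float(threshold))


def fold_change(values: Mapping[str, float], control_ids: Iterable[str]) -> dict[str, float]:
    """Per-specimen fold change versus the arithmetic mean of the controls.

    By construction the control-group fold changes average exactly 1.
    """
    control_ids = list(control_ids)
    if not control_ids:
        raise ValueError("control group is empty")
    missing = [c for c in control_ids if c not in values]
    if missing:
        raise KeyError(f"control ids missing from values: {missing}")
    control_mean = float(np.mean([values[c] for c in control_ids]))
    if control_mean == 0:
        raise ZeroDivisionError("control mean is zero; fold change undefined")
    return {k: float(v) / control_mean for k, v in values.items()}


def quantify_cohort(
    stacks: Mapping[str, ImageVolume],
    control_ids: Sequence[str],
    threshold="otsu",
    domain: str = "suprathreshold",
) -> list[SIResult]:
    """SI quantification for a whole cohort with one shared threshold.

    The threshold is resolved once (Otsu on the control MIPs by default),
    every stack is projected and quantified with it, and fold changes are
    normalized to the control-group mean SI.
    """
    mips = {k: max_projection(v) for k, v in stacks.items()}
    thr = select_threshold(threshold, [mips[c] for c in control_ids])
    results = {k: quantify_si(m, thr, specimen_id=k, domain=domain) for k, m in mips.items()}
    folds = fold_change({k: r.mean_si for k, r in results.items()}, control_ids)
    for k, r in results.items():
        r.fold_change = folds[k]
    return [results[k] for k in stacks]
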