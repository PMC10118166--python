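"""Synthetic phantoms with exact ground truth.

Three generators mirror the three kinds of measured data:

* :func:`synth_tube` — a hairpin-shaped pronephric-tubule lumen (two limbs
  joined by a bend at the turning point, TP) rasterized as a binary label
  volume, with the analytic centerline, signed geodesic coordinate, TP and
  per-sample radius as ground truth.
* :func:`synth_glomerulus` — a two-compartment glomerulus label volume
  (Bowman's space shell around a cellular core) with exact voxel counts.
* :func:`synth_fluorescence` — an eGFP-like z-stack of flat-top blobs whose
  amplitude scales with a ground-truth expression factor, plus additive
  Gaussian noise.

All generators are pure functions of (spec, seed): the same spec yields the
same volume, bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

from .volume import ImageVolume, LabelVolume

__all__ = [
    "RadiusProfile",
    "TubePhantomSpec",
    "TubeGroundTruth",
    "GlomerulusPhantomSpec",
    "FluorPhantomSpec",
    "hairpin_control_points",
    "synth_tube",
    "synth_glomerulus",
    "synth_fluorescence",
    "synth_dilatation_cohort",
]


# ---------------------------------------------------------------------------
# radius profiles

@dataclass(frozen=True)
class RadiusProfile:
    """Piecewise-linear tubule radius as a function of the signed geodesic
    coordinate s (μm, TP at 0; negative toward the glomerulus neck).

    `knots_s` / `knots_r` define the breakpoints; values outside the knot
    range are held constant (edge clamp).
    """

    knots_s: tuple[float, ...] = (-100.0, 300.0)
    knots_r: tuple[float, ...] = (5.0, 5.0)

    def __post_init__(self) -> None:
        if len(self.knots_s) != len(self.knots_r) or len(self.knots_s) < 1:
            raise ValueError("knots_s and knots_r must be equal-length, non-empty")
        if any(np.diff(self.knots_s) <= 0):
            raise ValueError("knots_s must be strictly increasing")

    def __call__(self, s: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(s, dtype=float), self.knots_s, self.knots_r)

    @staticmethod
    def constant(radius: float) -> "RadiusProfile":
        return RadiusProfile((0.0,), (float(radius),))

    @staticmethod
    def windowed_scale(
        base_radius: float,
        scale: float,
        window: tuple[float, float],
        ramp: float = 10.0,
    ) -> "RadiusProfile":
        """Radius = base everywhere, scaled by `scale` inside `window`, with
        linear ramps of width `ramp` lying *inside* the window edges."""
        lo, hi = window
        if hi - lo <= 2 * ramp:
            raise ValueError("window too narrow for the requested ramp")
        r0, r1 = float(base_radius), float(base_radius * scale)
        return RadiusProfile(
            (lo - 1e-6, lo, lo + ramp, hi - ramp, hi, hi + 1e-6),
            (r0, r0, r1, r1, r0, r0),
        )


# ---------------------------------------------------------------------------
# hairpin path

def hairpin_control_points(
    neck_length: float = 100.0,
    tail_length: float = 300.0,
    limb_separation: float = 30.0,
    z_amplitude: float = 4.0,
    step: float = 12.0,
) -> tuple[np.ndarray, float]:
    """Sample control points along an analytic hairpin path.

    The path runs from the glomerulus neck (arc length 0) along one limb,
    around a half-circle bend of diameter `limb_separation` whose apex is
    the turning point, and down the second limb toward the cloaca. The
    default 100 μm neck-to-TP and 300 μm TP-to-cloaca distances match the
    larval pronephros geometry. A gentle sinusoidal z undulation makes the
    path genuinely three-dimensional.

    Returns (control_points (N,3) world μm in (z,y,x), tp_arc_length).
    """
    bend_r = limb_separation / 2.0
    half_bend = np.pi * bend_r / 2.0  # arc length from limb junction to apex
    neck_straight = neck_length - half_bend
    tail_straight = tail_length - half_bend
    if neck_straight <= 0 or tail_straight <= 0:
        raise ValueError("limbs shorter than the bend half-arc")
    total = neck_straight + 2 * half_bend + tail_straight
    x0 = 80.0  # x of the bend-circle center; arbitrary world offset

    def point_at(s: float) -> tuple[float, float, float]:
        z = z_amplitude * np.sin(2 * np.pi * s / 200.0)
        if s <= neck_straight:  # top limb, heading -x
            return (z, 2 * bend_r, x0 + neck_straight - s)
        if s <= neck_straight + 2 * half_bend:  # bend around (y=bend_r, x=x0)
            theta = np.pi / 2 + (s - neck_straight) / bend_r  # 90° -> 270°
            return (z, bend_r + bend_r * np.sin(theta), x0 + bend_r * np.cos(theta))
        return (z, 0.0, x0 + (s - neck_straight - 2 * half_bend))  # bottom limb

    n = max(int(np.ceil(total / step)) + 1, 8)
    s_samples = np.linspace(0.0, total, n)
    # always include the apex so the spline passes through the true TP
    tp_arc = neck_straight + half_bend
    s_samples = np.sort(np.unique(np.append(s_samples, tp_arc)))
    pts = np.array([point_at(s) for s in s_samples])
    return pts, float(tp_arc)


# ---------------------------------------------------------------------------
# tube phantom

@dataclass
class TubePhantomSpec:
    """Everything needed to rasterize one tubule phantom.

    `radius_profile` gives the clean radius (μm) on the signed TP-centred
    coordinate; `radius_scale` is the global treated-vs-control multiplier;
    `radius_jitter_sd` adds a smooth multiplicative perturbation field
    (knots every `jitter_correlation_um`) emulating biological caliber
    variation along the tubule.
    """

    control_points: np.ndarray | None = None
    tp_arc_length: float | None = None
    radius_profile: RadiusProfile | Callable[[np.ndarray], np.ndarray] = dc_field(
        default_factory=lambda: RadiusProfile.constant(5.0)
    )
    radius_scale: float = 1.0
    radius_jitter_sd: float = 0.0
    jitter_correlation_um: float = 40.0
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    noise_sd: float = 0.0
    lumen_intensity: float = 200.0
    background_intensity: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.control_points is None:
            self.control_points, self.tp_arc_length = hairpin_control_points()
        self.control_points = np.asarray(self.control_points, dtype=float)
        if self.control_points.ndim != 2 or self.control_points.shape[1] != 3:
            raise ValueError("control_points must be (N, 3) world μm (z, y, x)")
        if self.radius_scale <= 0:
            raise ValueError("radius_scale must be positive")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")


@dataclass
class TubeGroundTruth:
    """Analytic truth emitted beside every tube phantom."""

    points: np.ndarray            # (N, 3) world μm, ordered neck -> cloaca
    s_signed: np.ndarray          # signed geodesic coordinate, TP = 0
    tp_index: int
    radius_um: np.ndarray         # rasterization radius at each sample
    length_um: float
    analytic_volume_um3: float    # ∫ π r(s)² ds

    def to_json(self, path: str | Path) -> None:
        payload = {
            "points": self.points.tolist(),
            "s_signed": self.s_signed.tolist(),
            "tp_index": int(self.tp_index),
            "radius_um": self.radius_um.tolist(),
            "length_um": float(self.length_um),
            "analytic_volume_um3": float(self.analytic_volume_um3),
        }
        Path(path).write_text(json.dumps(payload))

    @staticmethod
    def from_json(path: str | Path) -> "TubeGroundTruth":
        d = json.loads(Path(path).read_text())
        return TubeGroundTruth(
            points=np.array(d["points"]),
            s_signed=np.array(d["s_signed"]),
            tp_index=int(d["tp_index"]),
            radius_um=np.array(d["radius_um"]),
            length_um=float(d["length_um"]),
            analytic_volume_um3=float(d["analytic_volume_um3"]),
        )


def _resample_spline(control_points: np.ndarray, step: float) -> np.ndarray:
    """Cubic-spline the control points and resample at ~`step` arc spacing."""
    pts = control_points
    chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    if chord[-1] <= 0:
        raise ValueError("degenerate path (zero length)")
    spline = CubicSpline(chord, pts, axis=0, bc_type="natural")
    # dense pre-sample to get accurate arc length, then uniform resample
    dense_t = np.linspace(0, chord[-1], max(int(chord[-1] / (step / 4)), 16))
    dense = spline(dense_t)
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(dense, axis=0), axis=1))])
    n_out = max(int(np.ceil(arc[-1] / step)) + 1, 2)
    targets = np.linspace(0, arc[-1], n_out)
    t_of_arc = np.interp(targets, arc, dense_t)
    return spline(t_of_arc)


def synth_tube(spec: TubePhantomSpec) -> tuple[LabelVolume, TubeGroundTruth]:
    """Rasterize a tubule-lumen phantom.

    A voxel belongs to the lumen (label 1) iff its center lies within the
    local radius of the spline path, the path being sampled at half-voxel
    steps. Raises if the radius anywhere falls under one voxel, which would
    leave sub-resolution (aliased) lumen.
    """
    spacing = np.asarray(spec.spacing, dtype=float)
    step = 0.5 * float(spacing.min())
    path = _resample_spline(spec.control_points, step)
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])

    if spec.tp_arc_length is None:
        raise ValueError("spec.tp_arc_length is required for custom control points")
    tp_index = int(np.argmin(np.abs(arc - spec.tp_arc_length)))
    s_signed = arc - arc[tp_index]

    radius = np.asarray(spec.radius_profile(s_signed), dtype=float) * spec.radius_scale
    if spec.radius_jitter_sd > 0:
        rng = np.random.default_rng(spec.seed)
        n_knots = max(int(np.ceil((s_signed[-1] - s_signed[0]) / spec.jitter_correlation_um)) + 2, 2)
        knot_s = np.linspace(s_signed[0], s_signed[-1], n_knots)
        knot_f = 1.0 + rng.normal(0.0, spec.radius_jitter_sd, size=n_knots)
        radius = radius * np.interp(s_signed, knot_s, knot_f)

    vox = float(spacing.max())
    if radius.min() < vox:
        raise ValueError(
            f"radius {radius.min():.3g} μm falls under one voxel ({vox:.3g} μm); "
            "increase the radius or refine the spacing"
        )

    pad = radius.max() + 2 * vox
    lo = path.min(axis=0) - pad
    hi = path.max(axis=0) + pad
    origin = np.floor(lo / spacing) * spacing
    shape = np.ceil((hi - origin) / spacing).astype(int) + 1

    zz, yy, xx = np.meshgrid(
        origin[0] + np.arange(shape[0]) * spacing[0],
        origin[1] + np.arange(shape[1]) * spacing[1],
        origin[2] + np.arange(shape[2]) * spacing[2],
        indexing="ij",
    )
    centers = np.column_stack([zz.ravel(), yy.ravel(), xx.ravel()])
    tree = cKDTree(path)
    dist, nearest = tree.query(centers, k=1)
    lumen = dist <= radius[nearest]
    data = lumen.reshape(shape).astype(np.uint8)

    label = LabelVolume(
        data=data,
        spacing=tuple(spacing),
        origin=tuple(origin),
        label_map={1: "lumen"},
    )
    analytic_volume = float(np.trapezoid(np.pi * radius**2, arc))
    truth = TubeGroundTruth(
        points=path,
        s_signed=s_signed,
        tp_index=tp_index,
        radius_um=radius,
        length_um=float(arc[-1]),
        analytic_volume_um3=analytic_volume,
    )
    return label, truth


def render_tube_intensity(label: LabelVolume, spec: TubePhantomSpec) -> ImageVolume:
    """Grayscale rendering of a tube phantom (lumen vs background intensity
    plus additive Gaussian noise), for SI-along-centerline workflows."""
    rng = np.random.default_rng(spec.seed + 1)
    img = np.where(label.data > 0, spec.lumen_intensity, spec.background_intensity).astype(float)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return ImageVolume(data=img, spacing=label.spacing, origin=label.origin)


# ---------------------------------------------------------------------------
# glomerulus phantom

@dataclass
class GlomerulusPhantomSpec:
    """A two-compartment glomerulus: cellular core (mesangial tuft) inside a
    Bowman's capsule; the shell between them is Bowman's space.

    `cellular_fraction` targets cellular / (cellular + space) voxel counts.
    """

    semi_axes_um: tuple[float, float, float] = (20.0, 20.0, 20.0)
    cellular_fraction: float = 0.8
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    center_um: tuple[float, float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.cellular_fraction < 1.0):
            raise ValueError("cellular_fraction must lie strictly between 0 and 1")
        if any(a <= 0 for a in self.semi_axes_um):
            raise ValueError("semi-axes must be positive")
        if any(a < 2 * max(self.spacing) for a in self.semi_axes_um):
            raise ValueError("semi-axes must span at least 2 voxels (degenerate capsule)")


def synth_glomerulus(spec: GlomerulusPhantomSpec) -> tuple[LabelVolume, dict]:
    """Rasterize concentric ellipsoids; the inner (cellular) scale is tuned by
    bisection on actual voxel counts so the realized cellular fraction matches
    the request within 2% (usually much closer).

    Returns (labels {1: bowman_space, 2: cellular}, ground-truth dict with
    exact voxel counts, volumes and the realized ratio).
    """
    spacing = np.asarray(spec.spacing, dtype=float)
    axes = np.asarray(spec.semi_axes_um, dtype=float)
    pad = 2 * spacing.max()
    center = np.asarray(spec.center_um if spec.center_um is not None else axes + pad)
    lo = center - axes - pad
    origin = np.floor(lo / spacing) * spacing
    shape = np.ceil((center + axes + pad - origin) / spacing).astype(int) + 1

    grids = [
        (origin[i] + np.arange(shape[i]) * spacing[i] - center[i]) / axes[i]
        for i in range(3)
    ]
    zz, yy, xx = np.meshgrid(*grids, indexing="ij")
    q = zz**2 + yy**2 + xx**2  # normalized ellipsoidal radius squared
    capsule = q <= 1.0
    n_total = int(capsule.sum())
    if n_total == 0:
        raise ValueError("capsule rasterized to zero voxels")

    def cellular_count(scale: float) -> int:
        return int((q <= scale**2).sum())

    target = spec.cellular_fraction * n_total
    lo_s, hi_s = 0.0, 1.0
    for _ in range(60):
        mid = 0.5 * (lo_s + hi_s)
        if cellular_count(mid) < target:
            lo_s = mid
        else:
            hi_s = mid
    scale = hi_s
    cellular = q <= scale**2
    n_cell = int(cellular.sum())
    realized = n_cell / n_total
    if abs(realized - spec.cellular_fraction) > 0.02:
        raise ValueError(
            f"could not realize cellular fraction {spec.cellular_fraction} "
            f"(got {realized:.4f}); capsule too small for the voxel size"
        )

    data = np.zeros(shape, dtype=np.uint8)
    data[capsule] = 1
    data[cellular] = 2
    label = LabelVolume(
        data=data,
        spacing=tuple(spacing),
        origin=tuple(origin),
        label_map={1: "bowman_space", 2: "cellular"},
    )
    voxvol = float(np.prod(spacing))
    truth = {
        "n_total": n_total,
        "n_cellular": n_cell,
        "n_space": n_total - n_cell,
        "cellular_fraction": realized,
        "total_volume_um3": n_total * voxvol,
        "cellular_volume_um3": n_cell * voxvol,
        "space_volume_um3": (n_total - n_cell) * voxvol,
        "ratio_total_to_cellular": n_total / n_cell,
    }
    return label, truth


# ---------------------------------------------------------------------------
# fluorescence phantom

@dataclass
class FluorPhantomSpec:
    """An eGFP-like z-stack: bright blobs (amplitude = base_amplitude ×
    intensity_scale) on zero background, plus additive Gaussian noise.

    `blob_profile` selects the radial shape. The default ``"ball"`` is a
    uniformly bright sphere of radius `sigma` — the appearance of a
    saturated fluorophore-filled glomerulus, and the shape for which the
    suprathreshold mean SI is exactly linear in `intensity_scale`.
    ``"gaussian"`` / ``"flat-top"`` give exp(-(r²/2σ²)^order) with
    `blob_order` 1 or >1; their soft skirts make the suprathreshold domain
    itself intensity-dependent, as with a diffuse stain. `intensity_scale`
    is the ground-truth expression-level multiplier the SI quantification
    should recover.
    """

    shape: tuple[int, int, int] = (24, 64, 64)
    blob_centers_um: Sequence[tuple[float, float, float]] = ((12.0, 32.0, 32.0),)
    blob_sigmas_um: Sequence[float] = (8.0,)
    base_amplitude: float = 1000.0
    intensity_scale: float = 1.0
    blob_profile: str = "ball"
    blob_order: float = 1.0
    noise_sd: float = 0.0
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.intensity_scale <= 0:
            raise ValueError("intensity_scale must be positive")
        if len(self.blob_centers_um) != len(self.blob_sigmas_um):
            raise ValueError("one sigma per blob center is required")
        if self.blob_profile not in ("ball", "gaussian", "flat-top"):
            raise ValueError(f"unknown blob_profile {self.blob_profile!r}")


def synth_fluorescence(spec: FluorPhantomSpec) -> ImageVolume:
    """Render the fluorescence stack. Noise-free, the suprathreshold mean
    intensity is exactly linear in `intensity_scale`."""
    spacing = np.asarray(spec.spacing, dtype=float)
    coords = [np.arange(n) * spacing[i] for i, n in enumerate(spec.shape)]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    img = np.zeros(spec.shape, dtype=float)
    for center, sigma in zip(spec.blob_centers_um, spec.blob_sigmas_um):
        r2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
        if spec.blob_profile == "ball":
            img += (r2 <= sigma**2).astype(float)
        else:
            order = 1.0 if spec.blob_profile == "gaussian" else spec.blob_order
            img += np.exp(-((r2 / (2.0 * sigma**2)) ** order))
    img = np.clip(img, 0.0, 1.0) * spec.base_amplitude * spec.intensity_scale
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return ImageVolume(data=img, spacing=tuple(spacing))


# ---------------------------------------------------------------------------
# dilatation cohort

def synth_dilatation_cohort(
    n_control: int = 20,
    n_treated: int = 20,
    dilated_fraction: float = 0.75,
    dilation_scale: float = 2.5,
    base_area_um2: float = 78.5,
    jitter_sd: float = 0.08,
    seed: int = 0,
):
    """Per-tubule lumen cross-section areas for dilatation scoring.

    Emulates an observer's table of scored proximal-tubule profiles: control
    areas scatter (lognormally, sd `jitter_sd`) around `base_area_um2`; a
    known `dilated_fraction` of treated tubules is scaled by
    `dilation_scale`. Returns a DataFrame with the ground-truth flag.
    """
    import pandas as pd

    if not (0.0 <= dilated_fraction <= 1.0):
        raise ValueError("dilated_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_dilated = int(round(dilated_fraction * n_treated))
    rows = []
    for i in range(n_control):
        area = base_area_um2 * np.exp(rng.normal(0.0, jitter_sd))
        rows.append({"tubule_id": f"c{i:02d}", "group": "control",
                     "area_um2": area, "truly_dilated": False})
    for i in range(n_treated):
        dilated = i < n_dilated
        area = base_area_um2 * (dilation_scale if dilated else 1.0)
        area *= np.exp(rng.normal(0.0, jitter_sd))
        rows.append({"tubule_id": f"t{i:02d}", "group": "treated",
                     "area_um2": area, "truly_dilated": dilated})
    return pd.DataFrame(rows)
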