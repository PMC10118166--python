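"""Core data carriers and file IO.

Volumes are 3D arrays in ``(z, y, x)`` index order with per-axis voxel
spacing in micrometres. All downstream geometry is computed in world
coordinates (``origin + index * spacing``), so anisotropic voxels are
supported without resampling.

Spacing provenance: NRRD headers carry it natively; TIFF stacks require a
sidecar JSON ``<name>.meta.json`` with key ``"spacing_um": [z, y, x]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from . import _nrrd

__all__ = [
    "ImageVolume",
    "LabelVolume",
    "SpecimenRecord",
    "read_volume",
    "write_volume",
    "compose_slicewise_masks",
    "write_metrics_table",
    "read_metrics_table",
]


@dataclass
class ImageVolume:
    """A 3D scalar image with physical voxel geometry.

    Parameters
    ----------
    data
        3D array, ``(z, y, x)`` indexed; grayscale intensity or labels.
    spacing
        Per-axis voxel size in μm, ``(z, y, x)``.
    origin
        World-coordinate offset of voxel ``(0, 0, 0)`` in μm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"expected 3 axes (z, y, x), got {self.data.ndim} axes"
            )
        if min(self.data.shape) < 1:
            raise ValueError("every axis must have extent >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing))

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        """Map fractional (z, y, x) indices to world μm coordinates."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def index_coordinates(self, world: np.ndarray) -> np.ndarray:
        """Map world μm coordinates to fractional (z, y, x) indices."""
        pts = np.atleast_2d(np.asarray(world, dtype=float))
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)


@dataclass
class LabelVolume(ImageVolume):
    """An integer label image plus a label-id → compartment-name map."""

    label_map: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError(f"label data must be integer, got {self.data.dtype}")
        self.label_map = {int(k): str(v) for k, v in dict(self.label_map).items()}
        present = set(np.unique(self.data).tolist()) - {0}
        missing = present - set(self.label_map)
        if missing:
            raise ValueError(f"labels {sorted(missing)} present in data but not in label_map")

    def mask(self, name: str) -> np.ndarray:
        """Boolean mask of the compartment called `name`."""
        ids = [k for k, v in self.label_map.items() if v == name]
        if not ids:
            raise KeyError(f"no label named {name!r}; have {sorted(self.label_map.values())}")
        return np.isin(self.data, ids)

    def count(self, name: str) -> int:
        return int(self.mask(name).sum())


@dataclass
class SpecimenRecord:
    """One specimen's bookkeeping row: id, experimental group, data path."""

    specimen_id: str
    group: str
    volume_path: str | Path | None = None
    tp_index: int | None = None
    notes: str = ""

    ALLOWED_GROUPS = ("control", "treated")

    def __post_init__(self) -> None:
        if self.group not in self.ALLOWED_GROUPS:
            raise ValueError(
                f"group must be one of {self.ALLOWED_GROUPS}, got {self.group!r}"
            )
        if self.tp_index is not None:
            self.tp_index = int(self.tp_index)
            if self.tp_index < 0:
                raise ValueError("tp_index must be non-negative")


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json") if path.suffix == "" else path.with_suffix(path.suffix + ".meta.json")


def read_volume(path: str | Path, label_map: Mapping[int, str] | None = None) -> ImageVolume:
    """Read a TIFF stack or NRRD volume with spacing metadata.

    NRRD headers are authoritative for spacing. TIFF carries no reliable
    spacing, so a sidecar ``<name>.meta.json`` with ``"spacing_um": [z,y,x]``
    is mandatory. Pass `label_map` to get a :class:`LabelVolume` back.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    origin = (0.0, 0.0, 0.0)
    sidecar_meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        sidecar_meta = json.loads(sidecar.read_text())

    if suffix == ".nrrd":
        data, header = _nrrd.read(path)
        if "spacings" in header:
            spacing = tuple(header["spacings"][::-1])  # fastest-first -> (z,y,x)
        elif "spacing_um" in sidecar_meta:
            spacing = tuple(sidecar_meta["spacing_um"])
        else:
            raise ValueError(
                f"{path}: no spacing in NRRD header and no sidecar "
                f"'{sidecar.name}' with key 'spacing_um': [z, y, x]"
            )
        if "space origin" in header:
            origin = tuple(header["space origin"][::-1])
    elif suffix in (".tif", ".tiff"):
        data = tifffile.imread(path)
        if "spacing_um" not in sidecar_meta:
            raise ValueError(
                f"{path}: TIFF spacing must come from a sidecar JSON "
                f"'{sidecar.name}' with key 'spacing_um': [z, y, x]"
            )
        spacing = tuple(sidecar_meta["spacing_um"])
    else:
        raise ValueError(f"{path}: unsupported format {suffix!r} (use .nrrd or .tif)")

    if "origin_um" in sidecar_meta:
        origin = tuple(sidecar_meta["origin_um"])
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3 axes, got {data.ndim}")

    if label_map is None and "label_map" in sidecar_meta:
        label_map = {int(k): v for k, v in sidecar_meta["label_map"].items()}
    if label_map is not None:
        return LabelVolume(data=data, spacing=spacing, origin=origin, label_map=label_map)
    return ImageVolume(data=data, spacing=spacing, origin=origin)


def write_volume(volume: ImageVolume, path: str | Path) -> None:
    """Write a volume as NRRD (spacing in header) or TIFF (sidecar JSON).

    Label volumes additionally store their label map in the sidecar so a
    save→load round-trip preserves compartment names.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    meta: dict = {"spacing_um": list(volume.spacing), "origin_um": list(volume.origin)}
    if isinstance(volume, LabelVolume):
        meta["label_map"] = {str(k): v for k, v in volume.label_map.items()}
    if suffix == ".nrrd":
        _nrrd.write(path, volume.data, spacings=list(volume.spacing), origin=list(volume.origin))
        if isinstance(volume, LabelVolume):
            _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    elif suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, volume.data)
        _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    else:
        raise ValueError(f"unsupported output format {suffix!r}")


def compose_slicewise_masks(
    xy_masks: np.ndarray,
    yz_masks: np.ndarray | None = None,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    mode: str = "union",
) -> LabelVolume:
    """Stack per-slice 2D segmentations into one 3D lumen volume.

    Manual segmentation is often drawn slice by slice in two orientations:
    `xy_masks` is the (z, y, x) stack of XY-plane masks, `yz_masks` the
    (x, z, y) stack of YZ-plane masks of the same volume. The two are
    combined by `mode` "union" (default — a voxel is lumen if either
    orientation marked it) or "intersection".
    """
    xy = np.asarray(xy_masks) > 0
    if xy.ndim != 3:
        raise ValueError("xy_masks must be a 3D (z, y, x) stack")
    combined = xy
    if yz_masks is not None:
        yz = np.asarray(yz_masks) > 0
        # (x, z, y) slice stack -> (z, y, x) volume
        yz_vol = np.transpose(yz, (1, 2, 0))
        if yz_vol.shape != xy.shape:
            raise ValueError(
                f"orientations disagree on the volume shape: {xy.shape} vs {yz_vol.shape}"
            )
        if mode == "union":
            combined = xy | yz_vol
        elif mode == "intersection":
            combined = xy & yz_vol
        else:
            raise ValueError(f"unknown mode {mode!r} (use 'union' or 'intersection')")
    return LabelVolume(
        data=combined.astype(np.uint8), spacing=spacing, label_map={1: "lumen"}
    )


def write_metrics_table(records: Iterable[Mapping], path: str | Path, columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Write a sequence of homogeneous metric records as CSV.

    Floats are written with 9 significant digits so values round-trip
    beyond the 6-s.f. contract. Records must share one schema.
    """
    records = list(records)
    if records:
        schema = set(records[0].keys())
        for r in records[1:]:
            if set(r.keys()) != schema:
                raise ValueError(
                    f"heterogeneous record schemas: {sorted(schema)} vs {sorted(r.keys())}"
                )
        frame = pd.DataFrame.from_records(records)
    else:
        frame = pd.DataFrame(columns=list(columns or []))
    frame.to_csv(path, index=False, float_format="%.9g")
    return frame


def read_metrics_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
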