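"""Core data containers and NIfTI I/O for 4D DSC-MRI perfusion series.

The canonical in-memory axis order for a perfusion series is
``(w, h, s, f)`` — slice width, slice height, number of slices, number of
frames.  Every module converts to/from this order at its boundary.  Voxel
coordinates are 0-based and live in voxel space; physical quantities are
obtained only through ``voxel_mm``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Literal

import nibabel as nib
import numpy as np
import yaml

__all__ = [
    "PerfusionSeries",
    "VolumeMask",
    "StreamTensor",
    "read_series",
    "write_series",
    "read_volume",
    "write_volume",
    "to_stream",
    "from_stream",
    "DimensionalityError",
    "MetadataError",
]


class DimensionalityError(ValueError):
    """Input array/file does not have the expected number of dimensions."""


class MetadataError(ValueError):
    """Required acquisition metadata (TR/TE) is missing."""


StreamLayout = Literal["spatial", "temporal"]

# axis permutations from canonical (w, h, s, f)
_LAYOUT_PERM = {
    "spatial": (3, 2, 0, 1),   # f x s x w x h
    "temporal": (2, 3, 0, 1),  # s x f x w x h
}


@dataclasses.dataclass
class PerfusionSeries:
    """A 4D perfusion-weighted series with acquisition metadata.

    Parameters
    ----------
    signal
        Non-negative signal tensor of shape ``(w, h, s, f)``.
    tr_s
        Frame repetition interval in seconds.
    te_s
        Echo time in seconds.
    voxel_mm
        Edge lengths of a voxel in mm, ``(dx, dy, dz)``.
    frame_times_s
        Acquisition time of each frame; defaults to ``k * tr_s``.
    """

    signal: np.ndarray
    tr_s: float
    te_s: float
    voxel_mm: np.ndarray
    frame_times_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal)
        if self.signal.ndim != 4:
            raise DimensionalityError(
                f"perfusion series must be 4D (w,h,s,f), got {self.signal.ndim}D"
            )
        if self.signal.shape[3] < 2:
            raise ValueError("a perfusion series needs at least 2 frames")
        if np.any(self.signal < 0):
            raise ValueError("signal values must be non-negative")
        if self.tr_s <= 0 or self.te_s <= 0:
            raise MetadataError("tr_s and te_s must be positive")
        self.voxel_mm = np.asarray(self.voxel_mm, dtype=float)
        if self.voxel_mm.shape != (3,) or np.any(self.voxel_mm <= 0):
            raise ValueError("voxel_mm must be 3 positive edge lengths")
        if self.frame_times_s is None:
            self.frame_times_s = np.arange(self.signal.shape[3]) * self.tr_s
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
        if self.frame_times_s.shape != (self.signal.shape[3],):
            raise ValueError("frame_times_s length must equal frame count")
        if np.any(np.diff(self.frame_times_s) <= 0):
            raise ValueError("frame_times_s must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.signal.shape

    @property
    def n_frames(self) -> int:
        return self.signal.shape[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]


@dataclasses.dataclass
class VolumeMask:
    """A binary 3D mask on the same spatial grid as its parent series."""

    mask: np.ndarray
    voxel_mm: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 3:
            raise DimensionalityError("mask must be 3D (w,h,s)")
        vals = np.unique(self.mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be in {0, 1}")
        self.mask = self.mask.astype(np.uint8)
        self.voxel_mm = np.asarray(self.voxel_mm, dtype=float)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_mm)) / 1000.0


@dataclasses.dataclass
class StreamTensor:
    """A perfusion series rearranged for one network stream.

    ``spatial`` layout is ``(f, s, w, h)`` — frame by frame, then slice by
    slice; ``temporal`` layout is ``(s, f, w, h)`` — slice by slice, then
    frame by frame.
    """

    data: np.ndarray
    layout: StreamLayout

    def __post_init__(self) -> None:
        if self.layout not in _LAYOUT_PERM:
            raise ValueError(f"unknown stream layout {self.layout!r}")
        if self.data.ndim != 4:
            raise DimensionalityError("stream tensor must be 4D")


def to_stream(series_or_array: "PerfusionSeries | np.ndarray", layout: StreamLayout) -> StreamTensor:
    """Rearrange a canonical ``(w,h,s,f)`` tensor into a stream layout.

    Pure axis permutation: no value is changed.
    """
    arr = (
        series_or_array.signal
        if isinstance(series_or_array, PerfusionSeries)
        else np.asarray(series_or_array)
    )
    if arr.ndim != 4:
        raise DimensionalityError("expected a 4D (w,h,s,f) tensor")
    if layout not in _LAYOUT_PERM:
        raise ValueError(f"unknown stream layout {layout!r}")
    return StreamTensor(np.transpose(arr, _LAYOUT_PERM[layout]), layout)


def from_stream(stream: StreamTensor) -> np.ndarray:
    """Invert :func:`to_stream`, returning the canonical ``(w,h,s,f)`` tensor."""
    perm = _LAYOUT_PERM[stream.layout]
    inv = np.argsort(perm)
    return np.transpose(stream.data, inv)


# ---------------------------------------------------------------------------
# NIfTI I/O.  TR is carried in the NIfTI time zoom; TE has no standard slot
# and travels in a small YAML sidecar written next to the image.
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".meta.yaml")
    return path.with_suffix(".meta.yaml")


def write_series(series: PerfusionSeries, path: str | Path) -> None:
    """Write a series as 4D NIfTI-1 plus a ``*.meta.yaml`` sidecar."""
    path = Path(path)
    affine = np.diag(list(series.voxel_mm) + [1.0])
    img = nib.Nifti1Image(series.signal, affine)
    img.header.set_zooms(tuple(series.voxel_mm) + (series.tr_s,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    meta = {
        "tr_s": float(series.tr_s),
        "te_s": float(series.te_s),
        "frame_times_s": [float(t) for t in series.frame_times_s],
    }
    _sidecar_path(path).write_text(yaml.safe_dump(meta))


def read_series(path: str | Path, sidecar: str | Path | None = None) -> PerfusionSeries:
    """Read a 4D NIfTI perfusion series.

    TR/TE are taken from the YAML sidecar when present (either an explicit
    ``sidecar`` path or ``<image>.meta.yaml`` next to the file); TR alone can
    fall back to the NIfTI time zoom.
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 4:
        raise DimensionalityError(f"expected 4D NIfTI, got {data.ndim}D: {path}")
    voxel_mm = np.asarray(img.header.get_zooms()[:3], dtype=float)

    meta: dict = {}
    sc = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    if sc.exists():
        meta = yaml.safe_load(sc.read_text()) or {}

    tr_s = meta.get("tr_s")
    if tr_s is None:
        zooms = img.header.get_zooms()
        tr_s = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else None
    te_s = meta.get("te_s")
    if tr_s is None or te_s is None:
        raise MetadataError(
            f"TR/TE not found in header or sidecar for {path}; "
            "supply a YAML sidecar with tr_s and te_s"
        )
    frame_times = meta.get("frame_times_s")
    return PerfusionSeries(
        signal=data,
        tr_s=float(tr_s),
        te_s=float(te_s),
        voxel_mm=voxel_mm,
        frame_times_s=np.asarray(frame_times, dtype=float) if frame_times else None,
    )


def write_volume(data: np.ndarray, voxel_mm: np.ndarray, path: str | Path) -> None:
    """Write a 3D volume (mask or parameter map) as NIfTI-1."""
    data = np.asarray(data)
    if data.ndim != 3:
        raise DimensionalityError("expected a 3D volume")
    affine = np.diag(list(np.asarray(voxel_mm, dtype=float)) + [1.0])
    nib.save(nib.Nifti1Image(data, affine), str(Path(path)))


def read_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a 3D NIfTI volume; returns ``(data, voxel_mm)``."""
    img = nib.load(str(Path(path)))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise DimensionalityError(f"expected 3D NIfTI, got {data.ndim}D")
    return data, np.asarray(img.header.get_zooms()[:3], dtype=float)
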