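"""Volume and mask I/O with voxel geometry.

Volumes are held as ``(slice, row, col)`` integer arrays (0-based). On disk the
canonical format is NIfTI-1 via nibabel; a plain slice-stack dialect (multi-page
TIFF, or a directory of numbered PNGs) is supported for small fixtures. The
inter-slice gap has no standard NIfTI field, so it is recorded in the header
``descrip`` as ``gap=<mm>`` and parsed back on load.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "VolumeGeometry",
    "GrayVolume",
    "BinaryMask",
    "DEFAULT_GEOMETRY",
    "load_volume",
    "save_volume",
    "load_mask",
    "save_mask",
    "mask_volume_ml",
]


@dataclass(frozen=True)
class VolumeGeometry:
    """In-plane spacing, slice thickness, and inter-slice gap, all in mm.

    The per-voxel volume uses the slice thickness only; the gap is carried for
    transparency but does not enter :meth:`voxel_volume_mm3`.
    """

    in_plane_spacing_mm: tuple[float, float] = (0.4297, 0.4297)
    slice_thickness_mm: float = 5.0
    inter_slice_gap_mm: float = 1.0

    def __post_init__(self) -> None:
        sx, sy = self.in_plane_spacing_mm
        if not (sx > 0 and sy > 0 and self.slice_thickness_mm > 0):
            raise ValueError("spacings and slice thickness must be positive")
        if self.inter_slice_gap_mm < 0:
            raise ValueError("inter-slice gap must be non-negative")

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy = self.in_plane_spacing_mm
        return sx * sy * self.slice_thickness_mm


DEFAULT_GEOMETRY = VolumeGeometry()


@dataclass
class GrayVolume:
    """A stack of grayscale slices with geometry and native dynamic range."""

    voxels: np.ndarray  # (slice, row, col), non-negative integers
    geometry: VolumeGeometry = field(default_factory=VolumeGeometry)
    scale_max: int = 65535

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3 or v.shape[0] < 1:
            raise ValueError("volume must be a 3D (slice, row, col) array")
        if not np.issubdtype(v.dtype, np.integer):
            if np.issubdtype(v.dtype, np.floating) and np.all(v == np.round(v)):
                v = v.astype(np.int64)
            else:
                raise ValueError("volume intensities must be integers")
        if v.min() < 0:
            raise ValueError("volume intensities must be non-negative")
        if v.max() > self.scale_max:
            raise ValueError("intensity exceeds scale_max")
        self.voxels = v

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def slice(self, index: int) -> np.ndarray:
        return self.voxels[index]


@dataclass
class BinaryMask:
    """Boolean voxel mask congruent with an associated :class:`GrayVolume`."""

    voxels: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise ValueError("mask must be a 3D (slice, row, col) array")
        self.voxels = v.astype(bool)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def slice(self, index: int) -> np.ndarray:
        return self.voxels[index]

    def count(self) -> int:
        return int(self.voxels.sum())


def mask_volume_ml(mask: BinaryMask, geometry: VolumeGeometry) -> float:
    """Volume of the true voxels in mL (count x voxel volume / 1000)."""
    return mask.count() * geometry.voxel_volume_mm3 / 1000.0


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_GAP_RE = re.compile(rb"gap=([0-9.]+)")


def _is_nifti(path: Path) -> bool:
    return path.name.endswith((".nii", ".nii.gz"))


def _read_array(path: Path) -> tuple[np.ndarray, VolumeGeometry | None]:
    """Read a (slice, row, col) array plus geometry if the format carries one."""
    import warnings

    if not path.exists():
        raise IOError(f"no such file or directory: {path}")
    if _is_nifti(path):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {data.shape}")
        # stored (row, col, slice); restore (slice, row, col)
        data = np.ascontiguousarray(np.transpose(data, (2, 0, 1)))
        zooms = img.header.get_zooms()[:3]
        gap = DEFAULT_GEOMETRY.inter_slice_gap_mm
        descrip = bytes(img.header["descrip"].tobytes())
        m = _GAP_RE.search(descrip)
        if m:
            gap = float(m.group(1))
        geom = VolumeGeometry((float(zooms[0]), float(zooms[1])), float(zooms[2]), gap)
        return data, geom
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        data = tifffile.imread(str(path))
        if data.ndim == 2:
            data = data[None]
        return np.asarray(data), None
    if path.is_dir():
        import imageio.v3 as iio

        files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".png")
        if not files:
            raise IOError(f"no PNG slices in {path}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            data = np.stack([iio.imread(f) for f in files])
        return data, None
    raise IOError(f"unsupported volume format: {path}")


def load_volume(
    path: str | Path,
    geometry: VolumeGeometry | None = None,
    scale_max: int = 65535,
) -> GrayVolume:
    """Load a grayscale volume; geometry from the header or the supplied default."""
    data, hdr_geom = _read_array(Path(path))
    if not np.issubdtype(data.dtype, np.integer):
        if np.all(data == np.round(data)):
            data = data.astype(np.int64)
        else:
            raise ValueError(f"{path}: non-integer intensities")
    if data.min() < 0:
        raise ValueError(f"{path}: negative intensities")
    geom = geometry or hdr_geom or DEFAULT_GEOMETRY
    return GrayVolume(data.astype(np.int64), geom, scale_max=max(scale_max, int(data.max())))


def _write_array(data: np.ndarray, path: Path, geometry: VolumeGeometry) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    if _is_nifti(path):
        import nibabel as nib

        sx, sy = geometry.in_plane_spacing_mm
        out = np.ascontiguousarray(np.transpose(data, (1, 2, 0)))
        affine = np.diag([sx, sy, geometry.slice_thickness_mm, 1.0])
        img = nib.Nifti1Image(out, affine)
        img.header.set_zooms((sx, sy, geometry.slice_thickness_mm))
        img.header["descrip"] = f"gap={geometry.inter_slice_gap_mm:g}".encode()
        nib.save(img, str(path))
    elif path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(str(path), data, photometric="minisblack")
    else:
        raise IOError(f"unsupported output format: {path}")


def save_volume(volume: GrayVolume, path: str | Path) -> None:
    data = volume.voxels
    dtype = np.uint16 if volume.scale_max <= 65535 else np.int32
    _write_array(data.astype(dtype), Path(path), volume.geometry)


def save_mask(
    mask: BinaryMask, path: str | Path, geometry: VolumeGeometry | None = None
) -> None:
    """Write a mask as {0,1} voxels; round-trips losslessly through load_mask."""
    _write_array(mask.voxels.astype(np.uint8), Path(path), geometry or DEFAULT_GEOMETRY)


def load_mask(path: str | Path) -> BinaryMask:
    data, _ = _read_array(Path(path))
    bad = ~np.isin(data, (0, 1))
    if bad.any():
        raise ValueError(f"{path}: mask values outside {{0,1}}")
    return BinaryMask(data.astype(bool))
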