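"""Reading, writing and canonicalization of binary masks and label volumes.

All volumes are normalized into a canonical LPS voxel frame: array axis 0
increases toward the patient's left (+x), axis 1 toward posterior (+y), axis 2
toward superior (+z).  Downstream geometry is computed in physical
millimetres, with a voxel's position taken at its center:

    position_mm = origin + index * spacing

Supported on-disk formats are NIfTI (.nii/.nii.gz), NRRD (.nrrd/.nhdr) and
MetaImage (.mha/.mhd), all via SimpleITK, whose physical space is LPS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .errors import EmptyMaskError, VolumeFormatError
from .labels import LobeLabel

log = logging.getLogger(__name__)

_SUPPORTED_SUFFIXES = (".nii", ".nii.gz", ".nrrd", ".nhdr", ".mha", ".mhd")


@dataclass
class BinaryVolume:
    """A 3D binary object mask on an anisotropic voxel grid (canonical LPS).

    Attributes
    ----------
    data : ndarray of bool, shape (nx, ny, nz)
        Object/background mask, axes ordered (left, posterior, superior).
    spacing : ndarray of float, shape (3,)
        Voxel edge lengths in mm per axis; strictly positive.
    origin : ndarray of float, shape (3,)
        Physical position (mm) of the center of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-dimensional")
        if not np.all(self.spacing > 0):
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def n_object(self) -> int:
        return int(self.data.sum())

    def object_indices(self) -> np.ndarray:
        """(N, 3) integer indices of the object voxels."""
        return np.argwhere(self.data)

    def indices_to_mm(self, indices: np.ndarray) -> np.ndarray:
        """Map voxel indices to physical voxel-center positions (mm)."""
        return self.origin + np.asarray(indices, dtype=float) * self.spacing

    def mm_to_indices(self, positions: np.ndarray) -> np.ndarray:
        """Map physical positions to the indices of their containing voxels."""
        idx = np.rint((np.asarray(positions, dtype=float) - self.origin) / self.spacing)
        return idx.astype(int)

    def contains_index(self, indices: np.ndarray) -> np.ndarray:
        """Boolean mask: which of the given indices fall inside the grid."""
        idx = np.atleast_2d(indices)
        return np.all((idx >= 0) & (idx < np.array(self.shape)), axis=1)


@dataclass
class LabelVolume:
    """An integer label volume on the same grid as its source mask."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            self.data = self.data.astype(np.int16)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def labels_present(self) -> set[int]:
        return set(np.unique(self.data).tolist())


def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _SUPPORTED_SUFFIXES):
        raise VolumeFormatError(
            f"unsupported volume format: {path.name!r} "
            f"(expected one of {', '.join(_SUPPORTED_SUFFIXES)})"
        )


def _to_canonical(img: sitk.Image) -> sitk.Image:
    """Resample-free reorientation into LPS axis order."""
    return sitk.DICOMOrient(img, "LPS")


def read_mask(path: str | Path) -> BinaryVolume:
    """Read a binary airway mask and canonicalize it to the LPS convention.

    Any nonzero voxel is treated as object.  Raises
    :class:`~airwaylobes.errors.VolumeFormatError` for unreadable files and
    :class:`~airwaylobes.errors.EmptyMaskError` when no object voxel exists.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeFormatError(f"no such file: {path}")
    _check_suffix(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # SimpleITK wraps all reader failures
        raise VolumeFormatError(f"cannot read {path}: {exc}") from exc
    img = _to_canonical(img)
    # SimpleITK arrays are indexed [z, y, x]; transpose into (x, y, z).
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0) != 0
    if not data.any():
        raise EmptyMaskError(f"mask {path} contains no object voxels")
    return BinaryVolume(data, np.array(img.GetSpacing()), np.array(img.GetOrigin()))


def read_labels(path: str | Path) -> LabelVolume:
    """Read an integer label volume (canonical LPS)."""
    path = Path(path)
    if not path.exists():
        raise VolumeFormatError(f"no such file: {path}")
    _check_suffix(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise VolumeFormatError(f"cannot read {path}: {exc}") from exc
    img = _to_canonical(img)
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return LabelVolume(data, np.array(img.GetSpacing()), np.array(img.GetOrigin()))


def _to_sitk(data: np.ndarray, spacing: np.ndarray, origin: np.ndarray) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(data.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


def write_labels(volume: LabelVolume, path: str | Path) -> None:
    """Write a label volume; read-back reproduces data and grid bit-exactly."""
    path = Path(path)
    _check_suffix(path)
    img = _to_sitk(volume.data.astype(np.int16), volume.spacing, volume.origin)
    try:
        sitk.WriteImage(img, str(path), useCompression=path.name.endswith(".gz"))
    except RuntimeError as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc


def write_mask(volume: BinaryVolume, path: str | Path) -> None:
    """Write a binary mask as an 8-bit volume."""
    path = Path(path)
    _check_suffix(path)
    img = _to_sitk(volume.data.astype(np.uint8), volume.spacing, volume.origin)
    try:
        sitk.WriteImage(img, str(path), useCompression=path.name.endswith(".gz"))
    except RuntimeError as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc


def write_lobe_masks(volume: LabelVolume, out_dir: str | Path, stem: str = "lobe") -> list[Path]:
    """Export one binary mask per non-background label present in `volume`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for value in sorted(volume.labels_present() - {0}):
        name = LobeLabel(value).name if value in LobeLabel._value2member_map_ else str(value)
        p = out_dir / f"{stem}_{name}.nii.gz"
        write_mask(
            BinaryVolume(volume.data == value, volume.spacing, volume.origin), p
        )
        written.append(p)
    return written
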