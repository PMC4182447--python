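"""Reading ADC volumes and tumor masks, and assembling the whole-tumor voxel sample.

An ADC (apparent diffusion coefficient) map is a 3-D scalar volume in units of
10⁻⁶ mm²/s. Tumor extent is given by per-slice regions of interest rasterized
to the ADC grid as a boolean *include* mask; definite cystic, necrotic or
hemorrhagic areas may be flagged in a second boolean *exclude* mask. The
analysis operates on the *effective* tumor voxel set ``include & ~exclude``,
pooled over all slices into a single 1-D sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "ADCVolume",
    "TumorMask",
    "VoxelSample",
    "CaseError",
    "MissingFileError",
    "ShapeMismatchError",
    "EmptyTumorError",
    "read_case",
    "write_case",
    "assemble_tumor_voxels",
]


class CaseError(ValueError):
    """Base class for per-case validation failures."""

    code = "case_error"


class MissingFileError(CaseError):
    code = "missing_file"


class ShapeMismatchError(CaseError):
    code = "shape_mismatch"


class EmptyTumorError(CaseError):
    code = "empty_tumor"


@dataclass(frozen=True)
class ADCVolume:
    """3-D ADC map with voxel spacing metadata.

    Parameters
    ----------
    values : ndarray
        3-D float array of ADC values (10⁻⁶ mm²/s).
    spacing : tuple of float
        Voxel edge length per axis, in mm.
    slice_axis : int
        Axis indexing acquisition sections (default: last axis).
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    slice_axis: int = 2

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise ValueError(f"ADC volume must be 3-D, got ndim={v.ndim}")
        if not np.all(np.isfinite(v)):
            raise ValueError("ADC volume contains non-finite values")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        if not -3 <= self.slice_axis <= 2:
            raise ValueError(f"slice_axis out of range: {self.slice_axis}")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "slice_axis", self.slice_axis % 3)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


@dataclass(frozen=True)
class TumorMask:
    """Boolean include/exclude grids; the analysis uses ``include & ~exclude``."""

    include: np.ndarray
    exclude: np.ndarray | None = None

    def __post_init__(self) -> None:
        inc = np.asarray(self.include, dtype=bool)
        exc = self.exclude
        exc = np.zeros_like(inc) if exc is None else np.asarray(exc, dtype=bool)
        if inc.ndim != 3:
            raise ValueError("mask grids must be 3-D")
        if exc.shape != inc.shape:
            raise ShapeMismatchError(
                f"exclude shape {exc.shape} != include shape {inc.shape}"
            )
        object.__setattr__(self, "include", inc)
        object.__setattr__(self, "exclude", exc)

    @property
    def effective(self) -> np.ndarray:
        """Voxels entering the analysis: included and not excluded."""
        return self.include & ~self.exclude

    @property
    def n_effective(self) -> int:
        return int(self.effective.sum())

    @property
    def shape(self) -> tuple[int, ...]:
        return self.include.shape


@dataclass(frozen=True)
class VoxelSample:
    """All effective tumor-voxel ADC values of one case, slices pooled.

    ``values`` follows the fixed slice-major scan order documented in
    :func:`assemble_tumor_voxels`, which makes the pipeline bit-reproducible.
    """

    values: np.ndarray
    source_case: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size < 1:
            raise EmptyTumorError("voxel sample is empty")
        if not np.all(np.isfinite(v)):
            raise ValueError("voxel sample contains non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def n_voxels(self) -> int:
        return int(self.values.size)


def _load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(data), zooms


def read_case(
    volume_path: str | Path,
    mask_path: str | Path,
    exclude_path: str | Path | None = None,
    slice_axis: int = 2,
) -> tuple[ADCVolume, TumorMask]:
    """Load one case (ADC map + include mask + optional exclude mask) from NIfTI.

    Masks are 0/1 integer rasters on the same grid as the volume. Raises
    :class:`MissingFileError`, :class:`ShapeMismatchError` or
    :class:`EmptyTumorError` with distinct error codes on invalid input.
    """
    vol_data, zooms = _load_nifti(volume_path)
    mask_data, _ = _load_nifti(mask_path)
    if mask_data.shape != vol_data.shape:
        raise ShapeMismatchError(
            f"mask shape {mask_data.shape} != volume shape {vol_data.shape}"
        )
    exclude = None
    if exclude_path is not None:
        exc_data, _ = _load_nifti(exclude_path)
        if exc_data.shape != vol_data.shape:
            raise ShapeMismatchError(
                f"exclude-mask shape {exc_data.shape} != volume shape {vol_data.shape}"
            )
        exclude = exc_data > 0
    volume = ADCVolume(vol_data, spacing=zooms, slice_axis=slice_axis)
    mask = TumorMask(mask_data > 0, exclude)
    if mask.n_effective == 0:
        raise EmptyTumorError("effective tumor mask is empty after exclusions")
    return volume, mask


def write_case(
    volume: ADCVolume,
    mask: TumorMask,
    volume_path: str | Path,
    mask_path: str | Path,
    exclude_path: str | Path | None = None,
) -> None:
    """Write a case to NIfTI; the affine encodes voxel spacing on the diagonal."""
    affine = np.diag(list(volume.spacing) + [1.0])
    nib.save(nib.Nifti1Image(volume.values.astype(np.float32), affine), str(volume_path))
    nib.save(
        nib.Nifti1Image(mask.include.astype(np.uint8), affine), str(mask_path)
    )
    if exclude_path is not None:
        nib.save(
            nib.Nifti1Image(mask.exclude.astype(np.uint8), affine), str(exclude_path)
        )


def assemble_tumor_voxels(
    volume: ADCVolume, mask: TumorMask, source_case: str = ""
) -> VoxelSample:
    """Pool the ADC values of all effective tumor voxels into one sample.

    Scan order is slice-major (along ``volume.slice_axis``), then row-major
    within each slice — a fixed, documented order so that identical inputs give
    bit-identical samples.
    """
    if mask.shape != volume.shape:
        raise ShapeMismatchError(
            f"mask shape {mask.shape} != volume shape {volume.shape}"
        )
    eff = mask.effective
    if not eff.any():
        raise EmptyTumorError("effective tumor mask is empty")
    vals = np.moveaxis(volume.values, volume.slice_axis, 0)
    sel = np.moveaxis(eff, volume.slice_axis, 0)
    return VoxelSample(vals[sel], source_case=source_case)
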