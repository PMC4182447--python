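"""Gray-level co-occurrence matrix (GLCM) entropy over the masked tumor.

The GLCM records how often two effective tumor voxels at a fixed in-plane
offset carry quantized gray levels (i, j). Pair counts are accumulated over
all slices and offsets into one matrix, normalized to probabilities P(i, j),
and summarized as entropy −Σ P log P: higher entropy means more heterogeneous
spatial texture. Through-plane offsets are not used — tumor ROIs are drawn
per slice and slice spacing is typically anisotropic.

Two entropy readings are provided: the field-standard joint (Haralick)
entropy over P(i, j), the pipeline default, and the entropy of the marginal
row distribution P_x(i) = Σ_j P(i, j). Both are computed and reported so
either convention is reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .volume_io import ADCVolume, EmptyTumorError, TumorMask

__all__ = [
    "GLCMSpec",
    "GLCMatrix",
    "quantize",
    "accumulate_glcm",
    "glcm_entropy",
    "marginal_entropy",
]

#: distance-1 in-plane offsets at 0°, 45°, 90°, 135° (row, col within a slice)
DEFAULT_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (1, 1), (1, 0), (1, -1))


@dataclass(frozen=True)
class GLCMSpec:
    """Quantization and accumulation parameters.

    G
        Number of gray levels; voxel values are linearly rescaled between the
        per-tumor min and max of the effective voxels, so entropy measures
        *within-tumor* heterogeneity regardless of the tumor's absolute ADC.
    offsets
        In-plane (row, col) displacement vectors; pairs are pooled across all
        offsets and slices into one matrix.
    symmetric
        Count each ordered pair in both directions (P becomes symmetric).
    log_base
        Base of the entropy logarithm (2 → bits).
    """

    G: int = 64
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS
    symmetric: bool = True
    log_base: float = 2.0

    def __post_init__(self) -> None:
        if self.G < 2:
            raise ValueError(f"G must be >= 2, got {self.G}")
        if self.log_base <= 1:
            raise ValueError(f"log_base must be > 1, got {self.log_base}")
        offs = tuple((int(a), int(b)) for a, b in self.offsets)
        if not offs or any(o == (0, 0) for o in offs):
            raise ValueError("offsets must be non-empty and non-zero")
        object.__setattr__(self, "offsets", offs)


@dataclass(frozen=True)
class GLCMatrix:
    """Normalized co-occurrence probabilities with the raw pair count."""

    P: np.ndarray
    n_pairs: int
    symmetric: bool = True

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("P must be a square matrix")
        if np.any(P < 0):
            raise ValueError("P must be non-negative")
        object.__setattr__(self, "P", P)

    @property
    def marginal(self) -> np.ndarray:
        """Row-sum marginal probabilities P_x(i)."""
        return self.P.sum(axis=1)

    def _check_normalized(self) -> None:
        if not math.isclose(float(self.P.sum()), 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError("co-occurrence matrix is not normalized")


def quantize(volume: ADCVolume, mask: TumorMask, spec: GLCMSpec) -> np.ndarray:
    """Map effective tumor voxels to gray levels 0..G−1 by linear min–max.

    level = floor(G (v − min) / (max − min)), clamped to G−1; min and max are
    taken over effective voxels only. A constant region maps to level 0.
    Non-effective voxels are set to −1.
    """
    eff = mask.effective
    if not eff.any():
        raise EmptyTumorError("effective tumor mask is empty")
    v = volume.values[eff]
    vmin, vmax = float(v.min()), float(v.max())
    levels = np.full(volume.shape, -1, dtype=np.int32)
    if vmax == vmin:
        levels[eff] = 0
        return levels
    lv = np.floor(spec.G * (volume.values[eff] - vmin) / (vmax - vmin))
    levels[eff] = np.minimum(lv, spec.G - 1).astype(np.int32)
    return levels


def accumulate_glcm(
    levels: np.ndarray,
    mask: TumorMask,
    spec: GLCMSpec,
    slice_axis: int = 2,
) -> GLCMatrix:
    """Count co-occurring level pairs over all slices and normalize.

    Every ordered pair (voxel, voxel + offset) with both endpoints in the
    effective mask and on the same slice contributes one count; symmetric
    mode adds the reversed pair. Counts from all slices and all offsets are
    pooled into a single matrix before normalization, giving one whole-tumor
    statistic.
    """
    lv = np.moveaxis(np.asarray(levels), slice_axis, 0)
    eff = np.moveaxis(mask.effective, slice_axis, 0)
    G = spec.G
    counts = np.zeros((G, G), dtype=np.int64)
    _, H, W = lv.shape
    for dr, dc in spec.offsets:
        r0, r1 = max(0, -dr), min(H, H - dr)
        c0, c1 = max(0, -dc), min(W, W - dc)
        if r0 >= r1 or c0 >= c1:
            continue
        a = lv[:, r0:r1, c0:c1]
        b = lv[:, r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        ok = eff[:, r0:r1, c0:c1] & eff[:, r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        pair = a[ok].astype(np.int64) * G + b[ok]
        counts += np.bincount(pair, minlength=G * G).reshape(G, G)
    if spec.symmetric:
        counts = counts + counts.T
    n_pairs = int(counts.sum())
    if n_pairs == 0:
        raise EmptyTumorError("no valid voxel pairs in the effective mask")
    return GLCMatrix(counts / n_pairs, n_pairs=n_pairs, symmetric=spec.symmetric)


def _entropy(p: np.ndarray, log_base: float) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() / math.log(log_base))


def glcm_entropy(matrix: GLCMatrix, spec: GLCMSpec | None = None) -> float:
    """Joint (Haralick) entropy −ΣΣ P(i,j) log P(i,j), with 0·log 0 ≡ 0."""
    matrix._check_normalized()
    base = spec.log_base if spec is not None else 2.0
    return _entropy(matrix.P.ravel(), base)


def marginal_entropy(matrix: GLCMatrix, spec: GLCMSpec | None = None) -> float:
    """Entropy −Σ P_x(i) log P_x(i) of the row-marginal distribution."""
    matrix._check_normalized()
    base = spec.log_base if spec is not None else 2.0
    return _entropy(matrix.marginal, base)
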