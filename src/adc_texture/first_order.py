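"""First-order statistics of the whole-tumor ADC voxel sample.

Covers the percentage histogram (bin size 1 × 10⁻⁶ mm²/s by default), its
cumulative form, nearest-rank percentiles (notably the fifth-percentile ADC,
a surrogate for the most cellular tumor subregion), and the sample moments
mean / skewness / excess kurtosis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import stats as sps

from .volume_io import VoxelSample

__all__ = [
    "HistogramSpec",
    "ADCHistogram",
    "FirstOrderFeatures",
    "build_histogram",
    "percentile_adc",
    "first_order_features",
]


@dataclass(frozen=True)
class HistogramSpec:
    """Histogram layout: fixed bin width, edges aligned to multiples of it."""

    bin_size: float = 1.0

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError(f"bin_size must be positive, got {self.bin_size}")


@dataclass(frozen=True)
class ADCHistogram:
    """Percentage-of-lesion-volume histogram with cumulative percentages.

    ``percent[k]`` is 100 × (voxels in bin k) / (total voxels); bin k covers
    ``[bin_edges[k], bin_edges[k] + bin_size)``.
    """

    bin_edges: np.ndarray
    percent: np.ndarray
    cumulative_percent: np.ndarray
    bin_size: float

    def __post_init__(self) -> None:
        if not np.isclose(self.percent.sum(), 100.0, rtol=1e-9):
            raise ValueError("histogram percentages must sum to 100")
        if np.any(np.diff(self.cumulative_percent) < -1e-9):
            raise ValueError("cumulative percentages must be non-decreasing")


class FirstOrderFeatures(NamedTuple):
    mean: float
    skewness: float
    kurtosis: float


def build_histogram(sample: VoxelSample, spec: HistogramSpec | None = None) -> ADCHistogram:
    """Bin the voxel sample and express each bin as percent of lesion volume.

    Every voxel falls in exactly one bin; bin edges sit at integer multiples
    of ``bin_size`` so histograms are comparable across cases.
    """
    spec = spec or HistogramSpec()
    v = sample.values
    idx = np.floor(v / spec.bin_size).astype(np.int64)
    lo, hi = int(idx.min()), int(idx.max())
    counts = np.bincount(idx - lo, minlength=hi - lo + 1).astype(float)
    percent = 100.0 * counts / v.size
    return ADCHistogram(
        bin_edges=np.arange(lo, hi + 1) * spec.bin_size,
        percent=percent,
        cumulative_percent=np.cumsum(percent),
        bin_size=spec.bin_size,
    )


def percentile_adc(sample: VoxelSample, p: float, interpolate: bool = False) -> float:
    """ADC value at percentile ``p`` of the cumulative histogram.

    Default is the nearest-rank (lower) definition: the smallest sample value
    v such that at least p% of voxels are ≤ v — the point at which p% of the
    cumulative histogram lies to the left. Set ``interpolate=True`` for the
    linear-interpolation variant.
    """
    if not 0 < p <= 100:
        raise ValueError(f"percentile must be in (0, 100], got {p}")
    v = sample.values
    if interpolate:
        return float(np.percentile(v, p))
    srt = np.sort(v)
    rank = int(np.ceil(p / 100.0 * v.size))  # 1-based nearest rank
    return float(srt[rank - 1])


def first_order_features(sample: VoxelSample) -> FirstOrderFeatures:
    """Mean, skewness and excess kurtosis of the voxel sample.

    Bias-corrected sample formulas (the convention of desktop statistics
    packages); kurtosis is excess kurtosis, so a normal distribution scores 0.
    A constant sample has undefined shape moments and returns NaN for both.
    """
    v = sample.values
    n = v.size
    if n < 3:
        raise ValueError(f"skewness requires n >= 3, got n={n}")
    if n < 4:
        raise ValueError(f"kurtosis requires n >= 4, got n={n}")
    mean = float(v.mean())
    if np.ptp(v) == 0:  # constant region: shape moments undefined
        return FirstOrderFeatures(mean, float("nan"), float("nan"))
    skew = float(sps.skew(v, bias=False))
    kurt = float(sps.kurtosis(v, fisher=True, bias=False))
    return FirstOrderFeatures(mean, skew, kurt)
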