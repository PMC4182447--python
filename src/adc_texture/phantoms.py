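"""Synthetic 3-D ADC phantoms and graded cohorts.

No patient data accompany this analysis, so every downstream stage is
exercised on simulated tumors with the statistical structure the method
assumes: a spherical tumor whose voxels are drawn from a spatially
correlated mixture of ADC components (texture), plus white noise, embedded
in a uniform background, with an optional contiguous necrosis blob flagged
for exclusion.

The texture model assigns each tumor voxel to a mixture component by
thresholding a Gaussian random field smoothed to a chosen correlation
length. This gives two independent knobs that both move GLCM entropy:
*contrast* (the spread of the component means) and *graininess* (the
correlation length). The cohort generator maps a single per-class
heterogeneity parameter onto both knobs, deepens a low-ADC mixture tail
with class, and keeps the class mean ADC statistically indistinguishable —
the regime in which texture, not mean ADC, carries the grading signal.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
from scipy import ndimage

from .volume_io import ADCVolume, EmptyTumorError, TumorMask, write_case

__all__ = [
    "PhantomSpec",
    "ProliferationLink",
    "CohortSpec",
    "CohortCase",
    "generate_phantom",
    "generate_cohort",
    "write_cohort",
    "GRADE_LABELS",
]

GRADE_LABELS = ("II", "III", "IV")
ADC_RANGE = (200.0, 3500.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a single synthetic tumor volume.

    ADC values are in 10⁻⁶ mm²/s throughout; lengths are in mm.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 20)
    voxel_spacing: tuple[float, float, float] = (1.5, 1.5, 3.0)
    tumor_radius: float = 12.0
    component_means: tuple[float, ...] = (1300.0,)
    component_weights: tuple[float, ...] = (1.0,)
    spatial_correlation_length: float = 4.0
    noise_sd: float = 100.0
    necrosis_fraction: float = 0.0
    background_mean: float = 900.0
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.component_weights, dtype=float)
        m = np.asarray(self.component_means, dtype=float)
        if m.size != w.size or m.size == 0:
            raise ValueError("component_means and component_weights must match and be non-empty")
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("component_weights must be non-negative and sum to 1")
        if np.any(m < ADC_RANGE[0]) or np.any(m > ADC_RANGE[1]):
            raise ValueError(f"component_means must lie within {ADC_RANGE}")
        if not 0 <= self.necrosis_fraction < 1:
            raise ValueError("necrosis_fraction must be in [0, 1)")
        if self.tumor_radius <= 0 or self.noise_sd < 0:
            raise ValueError("tumor_radius must be > 0 and noise_sd >= 0")
        if self.spatial_correlation_length <= 0:
            raise ValueError("spatial_correlation_length must be > 0")
        half_extent = min(
            (n - 1) / 2 * s for n, s in zip(self.grid_shape, self.voxel_spacing)
        )
        if self.tumor_radius > half_extent:
            raise ValueError(
                f"tumor radius {self.tumor_radius} mm does not fit the grid "
                f"(half-extent {half_extent:.1f} mm)"
            )


class ProliferationLink(NamedTuple):
    """Linear link from class heterogeneity to a Ki-67-like index (percent)."""

    intercept: float = -2.0
    slope: float = 8.0
    noise_sd: float = 6.0


@dataclass(frozen=True)
class CohortSpec:
    """A labeled cohort of phantoms in three grade-like classes.

    ``class_heterogeneity`` must be strictly increasing: texture irregularity
    grows with grade. ``class_low_tail_depth`` is the mixture weight of a
    low-ADC component (deepening low-ADC tail with grade, pulling the fifth
    percentile down). The proliferation index is a noisy linear function of
    class heterogeneity, clipped to [0, 100].
    """

    class_sizes: tuple[int, int, int] = (8, 10, 22)
    class_heterogeneity: tuple[float, float, float] = (0.5, 1.0, 2.0)
    class_low_tail_depth: tuple[float, float, float] = (0.02, 0.05, 0.08)
    proliferation_link: ProliferationLink = ProliferationLink()
    base_seed: int = 0
    grid_shape: tuple[int, int, int] = (48, 48, 20)
    voxel_spacing: tuple[float, float, float] = (1.5, 1.5, 3.0)
    tumor_radius: float = 12.0
    noise_sd: float = 120.0
    necrosis_fraction: float = 0.08
    require_ordered: bool = True

    def __post_init__(self) -> None:
        k = len(self.class_sizes)
        if k != len(GRADE_LABELS):
            raise ValueError(f"expected {len(GRADE_LABELS)} classes, got {k}")
        if any(n <= 0 for n in self.class_sizes):
            raise ValueError("class_sizes must be positive")
        if len(self.class_heterogeneity) != k or len(self.class_low_tail_depth) != k:
            raise ValueError("per-class parameter lengths must match class_sizes")
        if self.require_ordered and any(
            b <= a for a, b in zip(self.class_heterogeneity, self.class_heterogeneity[1:])
        ):
            raise ValueError(
                "class_heterogeneity must be strictly increasing; "
                "set require_ordered=False only for explicit null cohorts"
            )


@dataclass(frozen=True)
class CohortCase:
    case_id: str
    volume: ADCVolume
    mask: TumorMask
    who_grade: str
    grade_binary: str  # "low" (II) or "high" (III/IV)
    proliferation_index: float


def _sphere_mask(shape, spacing, radius) -> np.ndarray:
    center = [(n - 1) / 2.0 for n in shape]
    axes = [
        (np.arange(n) - c) * s for n, c, s in zip(shape, center, spacing)
    ]
    d2 = (
        axes[0][:, None, None] ** 2
        + axes[1][None, :, None] ** 2
        + axes[2][None, None, :] ** 2
    )
    return d2 <= radius**2


def generate_phantom(spec: PhantomSpec) -> tuple[ADCVolume, TumorMask]:
    """Deterministically generate one phantom volume and mask from a spec.

    The same spec (including seed) reproduces bit-identical output. The
    necrosis exclusion blob, when requested, is the contiguous set of tumor
    voxels nearest an off-center seed point, sized to ``necrosis_fraction``
    of the tumor.
    """
    rng = np.random.default_rng(spec.seed)
    shape, spacing = spec.grid_shape, spec.voxel_spacing
    tumor = _sphere_mask(shape, spacing, spec.tumor_radius)
    if not tumor.any():
        raise EmptyTumorError("tumor sphere contains no voxels")

    values = np.full(shape, spec.background_mean, dtype=float)

    # spatially correlated component-assignment field
    sigma_vox = [spec.spatial_correlation_length / s for s in spacing]
    texture = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma_vox)
    t_tumor = texture[tumor]
    weights = np.asarray(spec.component_weights, dtype=float)
    means = np.asarray(spec.component_means, dtype=float)
    if means.size == 1:
        assign = np.zeros(t_tumor.size, dtype=np.int64)
    else:
        # empirical quantile thresholds → component proportions match weights
        cuts = np.quantile(t_tumor, np.cumsum(weights)[:-1])
        assign = np.searchsorted(cuts, t_tumor, side="right")
    values[tumor] = means[assign]

    if spec.noise_sd > 0:
        values += rng.standard_normal(shape) * spec.noise_sd

    exclude = np.zeros(shape, dtype=bool)
    if spec.necrosis_fraction > 0:
        n_tumor = int(tumor.sum())
        k = int(round(spec.necrosis_fraction * n_tumor))
        if k > 0:
            idx = np.argwhere(tumor)
            mm = idx * np.asarray(spacing)
            center = np.asarray([(n - 1) / 2.0 * s for n, s in zip(shape, spacing)])
            # seed the blob halfway out along a random direction
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            seed_pt = center + direction * spec.tumor_radius / 2.0
            order = np.argsort(np.linalg.norm(mm - seed_pt, axis=1), kind="stable")
            blob = idx[order[:k]]
            exclude[blob[:, 0], blob[:, 1], blob[:, 2]] = True
    mask = TumorMask(tumor, exclude)
    if mask.n_effective == 0:
        raise EmptyTumorError("tumor fully excluded by necrosis blob")
    return ADCVolume(values, spacing=spacing, slice_axis=2), mask


# Mapping from the scalar heterogeneity knob h to texture-model parameters.
# Entropy is computed after per-tumor min-max quantization, so it responds to
# the *shape* and *graininess* of the voxel field, not its absolute scale:
# finer spatial correlation (∝ 1/h²), more voxel noise and moderately higher
# mixture contrast all raise GLCM entropy monotonically in this regime.
_CENTER_MEAN = 1300.0
_CENTER_SD = 250.0
_H_JITTER_SD = 0.2  # lognormal per-case jitter of h (within-class spread)
_TAIL_JITTER_SD = 0.4  # lognormal per-case jitter of the low-tail weight
_TAIL_MEAN = 700.0
_TAIL_MEAN_SD = 120.0


def _class_phantom_spec(
    h: float, tail_depth: float, seed: int, cohort: CohortSpec, rng: np.random.Generator
) -> PhantomSpec:
    h_case = float(h * rng.lognormal(0.0, _H_JITTER_SD))
    center = float(np.clip(rng.normal(_CENTER_MEAN, _CENTER_SD), 900.0, 2200.0))
    radius = float(cohort.tumor_radius * rng.uniform(0.85, 1.15))
    contrast = 100.0 + 50.0 * h_case
    corr_len = float(np.clip(6.0 / h_case**2, 1.2, 30.0))
    noise_sd = cohort.noise_sd * (0.5 + 0.5 * h_case)
    d = float(np.clip(tail_depth * rng.lognormal(0.0, _TAIL_JITTER_SD), 0.0, 0.5))
    tail_mean = float(np.clip(rng.normal(_TAIL_MEAN, _TAIL_MEAN_SD), 300.0, 1000.0))
    means = (
        float(np.clip(center - contrast, *ADC_RANGE)),
        float(np.clip(center + contrast, *ADC_RANGE)),
        tail_mean,
    )
    weights = ((1 - d) / 2, (1 - d) / 2, d)
    return PhantomSpec(
        grid_shape=cohort.grid_shape,
        voxel_spacing=cohort.voxel_spacing,
        tumor_radius=radius,
        component_means=means,
        component_weights=weights,
        spatial_correlation_length=corr_len,
        noise_sd=noise_sd,
        necrosis_fraction=cohort.necrosis_fraction,
        seed=seed,
    )


def generate_cohort(spec: CohortSpec) -> list[CohortCase]:
    """Generate the full labeled cohort, one phantom per case.

    Per-case seeds derive deterministically from ``base_seed``; the case
    count equals ``sum(class_sizes)``. Grade II is labeled low-grade and
    grades III/IV high-grade.
    """
    rng = np.random.default_rng(spec.base_seed)
    link = spec.proliferation_link
    cases: list[CohortCase] = []
    for ci, (label, n, h, d) in enumerate(
        zip(GRADE_LABELS, spec.class_sizes, spec.class_heterogeneity, spec.class_low_tail_depth)
    ):
        for j in range(n):
            case_seed = int(rng.integers(0, 2**31 - 1))
            pspec = _class_phantom_spec(h, d, case_seed, spec, rng)
            volume, mask = generate_phantom(pspec)
            ki67 = float(
                np.clip(link.intercept + link.slope * h + rng.normal(0, link.noise_sd), 0.0, 100.0)
            )
            cases.append(
                CohortCase(
                    case_id=f"case_{label}_{j:02d}",
                    volume=volume,
                    mask=mask,
                    who_grade=label,
                    grade_binary="low" if ci == 0 else "high",
                    proliferation_index=ki67,
                )
            )
    return cases


def write_cohort(cases: Sequence[CohortCase], out_dir: str | Path) -> Path:
    """Write each case as NIfTI (.nii.gz) plus a cohort manifest CSV.

    Returns the manifest path. Manifest columns: case_id, who_grade,
    grade_binary, proliferation_index, volume, mask, exclude.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["case_id", "who_grade", "grade_binary", "proliferation_index",
             "volume", "mask", "exclude"]
        )
        for case in cases:
            vpath = out_dir / f"{case.case_id}_adc.nii.gz"
            mpath = out_dir / f"{case.case_id}_mask.nii.gz"
            epath = out_dir / f"{case.case_id}_exclude.nii.gz"
            write_case(case.volume, case.mask, vpath, mpath, epath)
            w.writerow(
                [case.case_id, case.who_grade, case.grade_binary,
                 f"{case.proliferation_index:.4f}", vpath.name, mpath.name, epath.name]
            )
    return manifest
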