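"""End-to-end orchestration: cohort in → per-case features → statistics report.

A run takes either a synthetic cohort spec or a manifest of NIfTI volumes and
masks, extracts the per-case feature vector (GLCM joint and marginal entropy,
skewness, excess kurtosis, mean ADC, fifth-percentile ADC), and emits the
report bundle: ``features.csv``, per-case histogram CSVs, four report tables
(group means ± SD with p-values; ROC summaries with AUC, CI, cutoff and
sensitivity/specificity/accuracy; LOOCV accuracies with the McNemar p;
Ki-67 regressions) and ``report.md``. Identical config + seed reproduces a
byte-identical feature table.
"""

from __future__ import annotations

import csv
import dataclasses
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .first_order import HistogramSpec, build_histogram, first_order_features, percentile_adc
from .glcm import GLCMSpec, accumulate_glcm, glcm_entropy, marginal_entropy, quantize
from .phantoms import CohortCase, CohortSpec, ProliferationLink, generate_cohort
from .stats import (
    compare_aucs,
    group_tests,
    loocv_accuracy,
    mcnemar_test,
    pearson_regression,
    roc_analysis,
    youden_cutoff,
)
from .volume_io import ADCVolume, CaseError, TumorMask, assemble_tumor_voxels, read_case

__all__ = [
    "FeatureVector",
    "PipelineConfig",
    "compute_case_features",
    "build_feature_table",
    "load_manifest_cases",
    "run_pipeline",
]

log = logging.getLogger("adc_texture")

FEATURE_COLUMNS = (
    "entropy_joint",
    "entropy_marginal",
    "skewness",
    "kurtosis",
    "mean_adc",
    "p5_adc",
)


class FeatureVector(NamedTuple):
    """Per-case derived values feeding the statistics layer."""

    case_id: str
    entropy_joint: float
    entropy_marginal: float
    skewness: float
    kurtosis: float
    mean_adc: float
    p5_adc: float
    n_voxels: int
    n_excluded: int
    n_pairs: int


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs; serializable to/from YAML."""

    cohort: CohortSpec | None = None
    manifest: str | None = None
    histogram: HistogramSpec = HistogramSpec()
    glcm: GLCMSpec = GLCMSpec()
    welch: bool = False
    posthoc_alpha: float = 0.05
    skip_invalid_cases: bool = False
    out_dir: str = "adc_texture_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.cohort is None) == (self.manifest is None):
            raise ValueError("configure exactly one of cohort (synthetic) or manifest")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        if "cohort" in raw:
            c = dict(raw["cohort"])
            if "proliferation_link" in c:
                c["proliferation_link"] = ProliferationLink(**c["proliferation_link"])
            for key in ("class_sizes", "class_heterogeneity", "class_low_tail_depth",
                        "grid_shape", "voxel_spacing"):
                if key in c:
                    c[key] = tuple(c[key])
            kwargs["cohort"] = CohortSpec(**c)
        if "manifest" in raw:
            kwargs["manifest"] = raw["manifest"]
        if "histogram" in raw:
            kwargs["histogram"] = HistogramSpec(**raw["histogram"])
        if "glcm" in raw:
            g = dict(raw["glcm"])
            if "offsets" in g:
                g["offsets"] = tuple(tuple(o) for o in g["offsets"])
            kwargs["glcm"] = GLCMSpec(**g)
        for key in ("welch", "posthoc_alpha", "skip_invalid_cases", "out_dir", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


def compute_case_features(
    volume: ADCVolume,
    mask: TumorMask,
    case_id: str = "",
    hist_spec: HistogramSpec | None = None,
    glcm_spec: GLCMSpec | None = None,
) -> FeatureVector:
    """Extract the full feature vector for one case.

    Composes the module operations exactly as they are exposed individually,
    so pipeline features carry no hidden state.
    """
    glcm_spec = glcm_spec or GLCMSpec()
    sample = assemble_tumor_voxels(volume, mask, source_case=case_id)
    mean, skew, kurt = first_order_features(sample)
    p5 = percentile_adc(sample, 5.0)
    levels = quantize(volume, mask, glcm_spec)
    matrix = accumulate_glcm(levels, mask, glcm_spec, slice_axis=volume.slice_axis)
    return FeatureVector(
        case_id=case_id,
        entropy_joint=glcm_entropy(matrix, glcm_spec),
        entropy_marginal=marginal_entropy(matrix, glcm_spec),
        skewness=skew,
        kurtosis=kurt,
        mean_adc=mean,
        p5_adc=p5,
        n_voxels=sample.n_voxels,
        n_excluded=int(mask.exclude.sum()),
        n_pairs=matrix.n_pairs,
    )


def load_manifest_cases(manifest_path: str | Path) -> list[CohortCase]:
    """Load a cohort from a manifest CSV (columns as written by write_cohort)."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    base = manifest_path.parent
    cases: list[CohortCase] = []
    with open(manifest_path, newline="") as fh:
        for row in csv.DictReader(fh):
            cid = row["case_id"]
            exclude = row.get("exclude") or None
            try:
                volume, mask = read_case(
                    base / row["volume"],
                    base / row["mask"],
                    base / exclude if exclude else None,
                )
            except CaseError as err:
                raise type(err)(f"case {cid}: {err}") from err
            cases.append(
                CohortCase(
                    case_id=cid,
                    volume=volume,
                    mask=mask,
                    who_grade=row.get("who_grade", ""),
                    grade_binary=row.get("grade_binary", ""),
                    proliferation_index=float(row.get("proliferation_index", "nan")),
                )
            )
    return cases


def build_feature_table(
    cases: Sequence[CohortCase],
    hist_spec: HistogramSpec | None = None,
    glcm_spec: GLCMSpec | None = None,
    skip_invalid: bool = False,
) -> pd.DataFrame:
    """Per-case feature rows plus labels — the grading dataset."""
    rows = []
    for case in cases:
        try:
            fv = compute_case_features(
                case.volume, case.mask, case.case_id, hist_spec, glcm_spec
            )
        except (CaseError, ValueError) as err:
            msg = f"case {case.case_id} failed feature extraction: {err}"
            if skip_invalid:
                log.warning("%s (skipped)", msg)
                continue
            raise type(err)(msg) from err
        log.info(
            "case %s: n_voxels=%d n_excluded=%d n_pairs=%d",
            case.case_id, fv.n_voxels, fv.n_excluded, fv.n_pairs,
        )
        rows.append(
            {**fv._asdict(), "who_grade": case.who_grade,
             "grade_binary": case.grade_binary,
             "proliferation_index": case.proliferation_index}
        )
    if not rows:
        raise ValueError("no valid cases")
    return pd.DataFrame(rows)


def _fmt_mean_sd(v: np.ndarray) -> str:
    return f"{np.mean(v):.3f}±{np.std(v, ddof=1):.3f}"


def _table1(df: pd.DataFrame, welch: bool) -> pd.DataFrame:
    """Low- vs high-grade group means ± SD with unpaired t-test p-values."""
    low = df[df.grade_binary == "low"]
    high = df[df.grade_binary == "high"]
    rows = []
    for feat in FEATURE_COLUMNS:
        gt = group_tests(
            df[feat].to_numpy(), df.grade_binary.to_numpy(), low_classes=("low",),
            welch=welch,
        )
        rows.append(
            {"parameter": feat,
             "low_grade": _fmt_mean_sd(low[feat].to_numpy()),
             "high_grade": _fmt_mean_sd(high[feat].to_numpy()),
             "p_value": gt.t_pvalue}
        )
    return pd.DataFrame(rows)


def _table2(df: pd.DataFrame, posthoc_alpha: float) -> pd.DataFrame:
    """Per-grade means ± SD, overall ANOVA p, and gated Tukey pairwise p's."""
    rows = []
    for feat in FEATURE_COLUMNS:
        gt = group_tests(
            df[feat].to_numpy(), df.who_grade.to_numpy(), low_classes=("II",),
            posthoc_alpha=posthoc_alpha,
        )
        row = {"parameter": feat}
        for g in ("II", "III", "IV"):
            row[f"grade_{g}"] = _fmt_mean_sd(df[df.who_grade == g][feat].to_numpy())
        row["anova_p"] = gt.anova_pvalue
        if gt.posthoc_performed:
            ph = gt.posthoc_pvalues
            row["II_vs_III"] = ph.get(("II", "III"), np.nan)
            row["II_vs_IV"] = ph.get(("II", "IV"), np.nan)
            row["III_vs_IV"] = ph.get(("III", "IV"), np.nan)
            row["posthoc"] = "tukey"
        else:
            row["II_vs_III"] = row["II_vs_IV"] = row["III_vs_IV"] = np.nan
            row["posthoc"] = "not performed (ANOVA n.s.)"
        rows.append(row)
    return pd.DataFrame(rows)


def _roc_row(name, values, labels_bool) -> dict:
    roc = roc_analysis(values, labels_bool)
    ev = youden_cutoff(roc)
    loo = loocv_accuracy(values, labels_bool)
    op = ">" if ev.direction == "higher" else "<="
    return {
        "feature": name,
        "auc": roc.auc,
        "auc_ci_low": roc.auc_ci[0],
        "auc_ci_high": roc.auc_ci[1],
        "p_vs_chance": roc.pvalue_vs_chance,
        "cutoff": f"{op}{ev.cutoff:.4g}",
        "sensitivity_pct": ev.sensitivity,
        "specificity_pct": ev.specificity,
        "accuracy_pct": ev.accuracy,
        "tp": ev.tp, "fn": ev.fn, "tn": ev.tn, "fp": ev.fp,
        "loocv_accuracy_pct": loo.accuracy,
        "_loocv_correct": loo.correct,
    }


def _table3(df: pd.DataFrame) -> pd.DataFrame:
    """ROC of entropy and fifth-percentile ADC for low- vs high-grade, with
    the DeLong curve comparison and LOOCV/McNemar accuracy comparison."""
    y = (df.grade_binary == "high").to_numpy()
    r_ent = _roc_row("entropy_joint", df.entropy_joint.to_numpy(), y)
    r_p5 = _roc_row("p5_adc", df.p5_adc.to_numpy(), y)
    p_delong = compare_aucs(df.entropy_joint.to_numpy(), df.p5_adc.to_numpy(), y)
    p_mcnemar = mcnemar_test(r_ent.pop("_loocv_correct"), r_p5.pop("_loocv_correct"))
    for r in (r_ent, r_p5):
        r["p_auc_comparison"] = p_delong
        r["p_loocv_mcnemar"] = p_mcnemar
    return pd.DataFrame([r_ent, r_p5])


def _table4(df: pd.DataFrame) -> pd.DataFrame:
    """ROC of entropy for grade III vs IV."""
    sub = df[df.who_grade.isin(["III", "IV"])]
    y = (sub.who_grade == "IV").to_numpy()
    row = _roc_row("entropy_joint", sub.entropy_joint.to_numpy(), y)
    row.pop("_loocv_correct")
    return pd.DataFrame([row])


def _regressions(df: pd.DataFrame) -> pd.DataFrame:
    """Pearson regressions of the proliferation index on entropy and p5 ADC."""
    rows = []
    ki = df.proliferation_index.to_numpy()
    for feat in ("entropy_joint", "p5_adc"):
        reg = pearson_regression(df[feat].to_numpy(), ki)
        rows.append(
            {"feature": feat, "slope": reg.slope, "intercept": reg.intercept,
             "r_squared": reg.r_squared, "p_value": reg.pvalue}
        )
    return pd.DataFrame(rows)


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    return obj


def _provenance(config: PipelineConfig) -> str:
    cfg = _listify(dataclasses.asdict(config))
    return yaml.safe_dump(
        {
            "config": cfg,
            "versions": {
                "adc_texture": __version__,
                "python": platform.python_version(),
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        },
        sort_keys=False,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write the report bundle to ``config.out_dir``.

    Returns the bundle in memory: ``features`` DataFrame and the four report
    tables plus regressions.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report_tables").mkdir(exist_ok=True)
    (out / "histograms").mkdir(exist_ok=True)

    if config.cohort is not None:
        cohort = dataclasses.replace(config.cohort, base_seed=config.seed)
        cases = generate_cohort(cohort)
    else:
        cases = load_manifest_cases(config.manifest)

    df = build_feature_table(
        cases, config.histogram, config.glcm, skip_invalid=config.skip_invalid_cases
    )
    # fixed float format → byte-identical feature CSVs for identical config+seed
    df.to_csv(out / "features.csv", index=False, float_format="%.10g")

    for case in cases:
        sample = assemble_tumor_voxels(case.volume, case.mask, case.case_id)
        hist = build_histogram(sample, config.histogram)
        pd.DataFrame(
            {"bin_edge": hist.bin_edges, "percent": hist.percent,
             "cumulative_percent": hist.cumulative_percent}
        ).to_csv(out / "histograms" / f"{case.case_id}.csv", index=False,
                 float_format="%.10g")

    tables = {
        "table1_group_comparison": _table1(df, config.welch),
        "table2_per_grade": _table2(df, config.posthoc_alpha),
        "table3_roc_low_vs_high": _table3(df),
        "table4_roc_III_vs_IV": _table4(df),
        "regressions_ki67": _regressions(df),
    }
    lines = ["# Whole-tumor ADC texture analysis report", "",
             "```yaml", _provenance(config).rstrip(), "```", ""]
    for name, tab in tables.items():
        tab.to_csv(out / "report_tables" / f"{name}.csv", index=False,
                   float_format="%.10g")
        lines += [f"## {name}", "", "```", tab.to_string(index=False), "```", ""]
    (out / "report.md").write_text("\n".join(lines))
    return {"features": df, **tables}
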