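"""End-to-end pipeline: quantify -> normalize -> CV-filter -> MoM -> adjust.

Each stage is a thin orchestration over the corresponding module; the stage
functions return in-memory results and optionally write the canonical CSV /
JSON artifacts so the CLI, the analysis drivers and the tests all share one
code path.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .covariates import CovariateModel, adjust_mom, fit_covariate_model, spearman_screen
from .io_formats import COVARIATE_COLUMNS, Panel, write_annotations, write_matrix, write_panel, write_peak_table
from .mom import build_reference_table, to_mom
from .normalize import (
    ComBat,
    CvProfile,
    CyclicLoessNormalizer,
    QuantileNormalizer,
    RobNorm,
    compare_methods,
    compute_cv_profile,
    control_groups,
    exclude_high_cv,
)
from .quantify import (
    QuantMatrix,
    back_calculate,
    evaluate_batches,
    fit_batch_curves,
    filter_quantifiable,
    quantify_samples,
)
from .simulate import Experiment, SimConfig, simulate_experiment

CONTROL_ROLES = (
    "standard:A",
    "standard:B",
    "standard:C",
    "standard:D",
    "standard:E",
    "standard:F",
    "standard:G",
    "qc:QCA",
    "qc:QCB",
    "qc:QCC",
    "qc:CLP",
)


def control_concentrations(
    peak_table: pd.DataFrame,
    curves,
    panel: Panel,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Back-calculate control rows (standards + QCs) without clamping.

    Returns (conc matrix indexed by control sample_id, group label per row,
    batch label per row). Controls are never clamped: their purpose is to
    measure assay variability, and clamping would censor it.
    """
    ctl = peak_table.loc[peak_table["role"] != "cohort"].copy()
    ctl = ctl.loc[ctl["role"] != "blank"]
    pep_to_prot = {e.peptide_id: e.protein_id for e in panel}
    conc = []
    for _, row in ctl.iterrows():
        curve = curves[(row["peptide"], row["batch"])]
        if not curve.fittable or not np.isfinite(row["ratio"]):
            conc.append(np.nan)
        else:
            conc.append(float(back_calculate(curve, row["ratio"])))
    ctl = ctl.assign(conc=conc, protein=ctl["peptide"].map(pep_to_prot))
    mat = ctl.pivot_table(
        index="sample_id", columns="protein", values="conc", aggfunc="mean"
    )
    meta = ctl.drop_duplicates("sample_id").set_index("sample_id")
    mat = mat.reindex(meta.index)
    groups = control_groups(meta)
    return mat, groups, meta["batch"]


@dataclass
class QuantifyResult:
    curves: dict
    verdicts: dict
    quant: QuantMatrix
    retained: list[str]
    exclusions: list[dict]


def run_quantify(
    peak_table: pd.DataFrame, panel: Panel, config: PipelineConfig | None = None
) -> QuantifyResult:
    config = config or PipelineConfig()
    curves = fit_batch_curves(peak_table, panel, config)
    verdicts = evaluate_batches(curves, peak_table, panel, config)
    quant = quantify_samples(peak_table, curves, panel, config, verdicts)
    retained, exclusions = filter_quantifiable(quant, curves, panel, config)
    return QuantifyResult(curves, verdicts, quant, retained, exclusions)


@dataclass
class NormalizeResult:
    matrices: dict[str, pd.DataFrame]  # cohort matrices by method (incl. raw)
    control_matrices: dict[str, pd.DataFrame]
    profiles: dict[str, CvProfile]
    comparison: pd.DataFrame
    best_method: str
    retained_after_cv: list[str]
    sample_effects: pd.Series | None = None


def run_normalize(
    peak_table: pd.DataFrame,
    panel: Panel,
    qres: QuantifyResult,
    config: PipelineConfig | None = None,
    methods: tuple[str, ...] = ("quantile", "loess", "robnorm", "combat"),
) -> NormalizeResult:
    """Benchmark the normalization methods by control CVs and apply the
    CV >= 20% exclusion on the winning method's profile."""
    config = config or PipelineConfig()
    cohort = qres.quant.conc.loc[:, qres.retained]
    batches = _cohort_batches(peak_table)
    ctl_mat, ctl_groups, ctl_batches = control_concentrations(
        peak_table, qres.curves, panel
    )
    ctl_mat = ctl_mat.loc[:, [c for c in qres.retained if c in ctl_mat.columns]]

    matrices: dict[str, pd.DataFrame] = {"raw": cohort}
    controls: dict[str, pd.DataFrame] = {"raw": ctl_mat}
    sample_effects = None

    if "quantile" in methods:
        qn = QuantileNormalizer().fit(cohort)
        matrices["quantile"] = qn.transform(cohort)
        controls["quantile"] = qn.transform(ctl_mat)
    if "loess" in methods:
        lo = CyclicLoessNormalizer()
        matrices["loess"] = lo.fit_transform(cohort)
        controls["loess"] = lo.transform(ctl_mat)
    if "robnorm" in methods:
        rn = RobNorm().fit(cohort)
        matrices["robnorm"] = rn.normalized(cohort)
        controls["robnorm"] = rn.transform(ctl_mat)
        sample_effects = rn.sample_effects_
    if "combat" in methods:
        cb = ComBat().fit(cohort, batches)
        matrices["combat"] = cb.transform(cohort, batches)
        controls["combat"] = cb.transform(ctl_mat, ctl_batches)

    profiles = {
        m: compute_cv_profile(controls[m], ctl_groups, method=m, config=config)
        for m in matrices
    }
    comparison = compare_methods(profiles)
    best = min(
        (m for m in profiles if m != "raw"),
        key=lambda m: profiles[m].median_mean_cv,
    )
    if profiles[best].median_mean_cv > profiles["raw"].median_mean_cv:
        best = "raw"
    retained = exclude_high_cv(profiles[best], config)
    return NormalizeResult(
        matrices=matrices,
        control_matrices=controls,
        profiles=profiles,
        comparison=comparison,
        best_method=best,
        retained_after_cv=retained,
        sample_effects=sample_effects,
    )


def _cohort_batches(peak_table: pd.DataFrame) -> pd.Series:
    rows = peak_table.loc[peak_table["role"] == "cohort"]
    return rows.drop_duplicates("sample_id").set_index("sample_id")["batch"]


@dataclass
class ReferenceResult:
    mom: pd.DataFrame
    medians: pd.Series
    table: pd.DataFrame
    dynamic_range: float


def run_reference(
    matrix: pd.DataFrame, config: PipelineConfig | None = None
) -> ReferenceResult:
    mom_matrix, medians = to_mom(matrix)
    table, dyn = build_reference_table(mom_matrix, matrix, config)
    return ReferenceResult(mom_matrix, medians, table, dyn)


@dataclass
class AdjustResult:
    associations: pd.DataFrame
    models: dict[str, CovariateModel]
    adjusted: pd.DataFrame
    factors: pd.DataFrame
    table: pd.DataFrame  # reference table on adjusted MoM


def run_adjust(
    mom_matrix: pd.DataFrame,
    raw_matrix: pd.DataFrame,
    annotations: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> AdjustResult:
    config = config or PipelineConfig()
    associations = spearman_screen(mom_matrix, annotations, config=config)
    models = {
        protein: fit_covariate_model(
            mom_matrix[protein], annotations, COVARIATE_COLUMNS, config
        )
        for protein in mom_matrix.columns
    }
    adjusted = adjust_mom(mom_matrix, models, annotations, config)
    table, _ = build_reference_table(adjusted.data, raw_matrix, config)
    return AdjustResult(
        associations=associations,
        models=models,
        adjusted=adjusted.data,
        factors=adjusted.factors,
        table=table,
    )


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------


@dataclass
class PipelineRun:
    experiment: Experiment
    quantify: QuantifyResult
    normalize: NormalizeResult
    reference: ReferenceResult
    adjust: AdjustResult
    report: dict = field(default_factory=dict)


def run_all(
    sim_config: SimConfig | None = None,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
    experiment: Experiment | None = None,
) -> PipelineRun:
    """Run the full pipeline on a simulated (or supplied) experiment and
    optionally write every canonical artifact to ``outdir``."""
    config = config or PipelineConfig()
    if experiment is None:
        experiment = simulate_experiment(sim_config or SimConfig())
    qres = run_quantify(experiment.peak_table, experiment.panel, config)
    nres = run_normalize(experiment.peak_table, experiment.panel, qres, config)
    best = nres.matrices[nres.best_method].loc[:, nres.retained_after_cv]
    rres = run_reference(best, config)
    ares = run_adjust(rres.mom, best, experiment.annotations, config)

    report = {
        "seed": experiment.config.seed,
        "config_hash": config.hash(),
        "versions": {
            "mrmref": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "n_panel": len(experiment.panel),
        "n_quantified": len(qres.retained),
        "n_after_cv_filter": len(nres.retained_after_cv),
        "best_method": nres.best_method,
        "median_mean_cv": {
            m: p.median_mean_cv for m, p in nres.profiles.items()
        },
        "dynamic_range_log10": rres.dynamic_range,
        "batch_verdicts": {
            b: {
                "valid": v.valid,
                "qc_pass_frac": v.qc_pass_frac_observed,
                "curve_pass_frac": v.curve_pass_frac_observed,
            }
            for b, v in qres.verdicts.items()
        },
        "excluded_proteins": qres.exclusions,
        "excluded_samples": qres.quant.excluded_samples,
    }
    run = PipelineRun(experiment, qres, nres, rres, ares, report)
    if outdir is not None:
        write_run(run, outdir)
    return run


def write_run(run: PipelineRun, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exp = run.experiment
    write_peak_table(exp.peak_table, outdir / "peaks.csv")
    write_annotations(exp.annotations, outdir / "annotations.csv")
    write_panel(exp.panel, outdir / "panel.csv")
    exp.ground_truth.save(outdir / "ground_truth")
    write_matrix(run.quantify.quant.conc, outdir / "quant.csv")
    write_matrix(run.quantify.quant.flags, outdir / "quant_flags.csv")
    curves_df = pd.DataFrame(
        [
            {
                "peptide": c.peptide_id,
                "batch": c.batch_id,
                "slope": c.slope,
                "intercept": c.intercept,
                "r2": c.r2,
                "curve_pass": c.curve_pass,
            }
            for c in run.quantify.curves.values()
        ]
    )
    curves_df.to_csv(outdir / "curves.csv", index=False)
    for m, mat in run.normalize.matrices.items():
        write_matrix(mat, outdir / f"normalized_{m}.csv")
    cv_rows = []
    for m, prof in run.normalize.profiles.items():
        df = prof.per_group_cv.copy()
        df["mean_cv"] = prof.mean_cv
        df["method"] = m
        cv_rows.append(df.reset_index(names="protein_id"))
    pd.concat(cv_rows, ignore_index=True).to_csv(outdir / "cv_profiles.csv", index=False)
    run.normalize.comparison.to_csv(outdir / "method_comparison.csv", index=False)
    write_matrix(run.reference.mom, outdir / "mom.csv")
    run.reference.table.to_csv(outdir / "reference_table.csv", index=False)
    run.adjust.associations.to_csv(outdir / "associations.csv", index=False)
    model_rows = []
    for protein, model in run.adjust.models.items():
        if model.is_intercept_only:
            model_rows.append(
                {"protein_id": protein, "predictor": "(intercept)",
                 "beta": model.intercept, "p_value": np.nan}
            )
        for pred, beta in model.coefficients.items():
            model_rows.append(
                {"protein_id": protein, "predictor": pred, "beta": beta,
                 "p_value": model.p_values[pred]}
            )
    pd.DataFrame(model_rows).to_csv(outdir / "covariate_models.csv", index=False)
    write_matrix(run.adjust.adjusted, outdir / "mom_adjusted.csv")
    run.adjust.table.to_csv(outdir / "reference_table_adjusted.csv", index=False)
    with open(outdir / "run_report.json", "w") as fh:
        json.dump(run.report, fh, indent=1, default=str)
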