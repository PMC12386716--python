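"""Absolute quantification from response ratios via weighted calibration.

For each peptide and batch, a 1/x^2-weighted linear regression of the
light/heavy response ratio on nominal concentration is fitted to the
calibration standards. Acceptance gating follows ICH M10-style rules:

* a calibration level passes if its back-calculated accuracy deviation and
  replicate precision CV are both within 20%;
* a curve passes if at least ``min_standards_pass`` levels pass;
* a batch is valid if >= 66% of its surrogate-matrix QC measurements
  back-calculate within 20% of nominal and >= 90% of its curves pass;
* cohort concentrations below the LLOQ (level A) or above the HLOQ (level
  G) are clamped to those limits and flagged;
* a protein is quantifiable only if its curve R^2 exceeds 0.99 in every
  valid batch and no more than 50% of cohort cells are clamped or missing.

The 1/x^2 weighting gives every calibration level comparable relative
leverage, which is why it is the default for assays spanning multiple
decades of concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .io_formats import Panel

FLAG_MEASURED = "measured"
FLAG_LLOQ = "clamped_LLOQ"
FLAG_HLOQ = "clamped_HLOQ"
FLAG_MISSING = "missing"


class QuantificationError(ValueError):
    """Raised for undefined back-calculations (e.g. zero slope)."""


@dataclass
class LevelRecord:
    level: str
    nominal_conc: float
    n_replicates: int
    mean_back_calc: float
    accuracy_dev: float  # |mean back-calc - nominal| / nominal
    precision_cv: float  # CV of replicate back-calculations (NaN if n < 2)
    passed: bool


@dataclass
class CalibrationCurve:
    peptide_id: str
    batch_id: str
    slope: float
    intercept: float
    r2: float
    fittable: bool = True
    levels: list[LevelRecord] = field(default_factory=list)
    curve_pass: bool = False

    def predict(self, conc):
        return self.intercept + self.slope * np.asarray(conc, dtype=float)


@dataclass
class BatchVerdict:
    batch_id: str
    qc_pass_frac_observed: float
    curve_pass_frac_observed: float
    n_qc: int
    n_curves: int
    valid: bool


# ---------------------------------------------------------------------------
# curve fitting
# ---------------------------------------------------------------------------


def fit_calibration_curve(
    points: list[tuple[float, float]],
    peptide_id: str = "",
    batch_id: str = "",
    weight_scheme: str = "1/x^2",
) -> CalibrationCurve:
    """Weighted least-squares line through (nominal_conc, response_ratio).

    Minimizes sum w_i (y_i - a - b x_i)^2 with w_i = 1/x_i^2 (or 1/x, or
    unweighted). R^2 is computed on the weighted fit: 1 - SSR_w / SST_w with
    the weighted mean as reference. Fewer than three distinct usable
    concentrations marks the curve unfittable rather than raising.
    """
    pts = [
        (float(x), float(y))
        for x, y in points
        if np.isfinite(x) and np.isfinite(y) and x > 0
    ]
    if len({x for x, _ in pts}) < 3:
        return CalibrationCurve(
            peptide_id, batch_id, np.nan, np.nan, np.nan, fittable=False
        )
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if weight_scheme == "1/x^2":
        w = 1.0 / x**2
    elif weight_scheme == "1/x":
        w = 1.0 / x
    elif weight_scheme in ("none", "1"):
        w = np.ones_like(x)
    else:
        raise ValueError(f"unknown weight scheme: {weight_scheme!r}")
    # 2x2 weighted normal equations
    sw, swx, swy = w.sum(), (w * x).sum(), (w * y).sum()
    swxx, swxy = (w * x * x).sum(), (w * x * y).sum()
    det = sw * swxx - swx**2
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    resid = y - intercept - slope * x
    ybar_w = swy / sw
    sst = (w * (y - ybar_w) ** 2).sum()
    ssr = (w * resid**2).sum()
    r2 = 1.0 if sst == 0 and ssr == 0 else 1.0 - ssr / sst
    return CalibrationCurve(peptide_id, batch_id, slope, intercept, r2)


def back_calculate(curve: CalibrationCurve, response_ratio: float):
    """Invert the calibration line: (ratio - intercept) / slope."""
    if not curve.fittable or not np.isfinite(curve.slope):
        raise QuantificationError(
            f"curve {curve.peptide_id}/{curve.batch_id} is not fittable"
        )
    if curve.slope == 0:
        raise QuantificationError(
            f"curve {curve.peptide_id}/{curve.batch_id} has zero slope; "
            "concentration undefined"
        )
    return (np.asarray(response_ratio, dtype=float) - curve.intercept) / curve.slope


def gate_standards(
    curve: CalibrationCurve,
    level_ratios: dict[str, tuple[float, list[float]]],
    config: PipelineConfig | None = None,
) -> CalibrationCurve:
    """Fill per-level accuracy/precision records and the curve verdict.

    ``level_ratios`` maps level label -> (nominal_conc, replicate ratios).
    A level passes iff accuracy_dev <= accuracy_tol and (when >= 2
    replicates) precision_cv <= precision_tol. The curve passes iff at least
    ``min_standards_pass`` levels pass.
    """
    config = config or PipelineConfig()
    curve.levels = []
    if not curve.fittable:
        curve.curve_pass = False
        return curve
    for level, (nominal, ratios) in level_ratios.items():
        back = [
            float(back_calculate(curve, r)) for r in ratios if np.isfinite(r)
        ]
        if not back:
            curve.levels.append(
                LevelRecord(level, nominal, 0, math.nan, math.nan, math.nan, False)
            )
            continue
        mean_bc = float(np.mean(back))
        acc = abs(mean_bc - nominal) / nominal
        cv = (
            float(np.std(back, ddof=1) / mean_bc)
            if len(back) >= 2 and mean_bc != 0
            else math.nan
        )
        passed = acc <= config.accuracy_tol and (
            math.isnan(cv) or cv <= config.precision_tol
        )
        curve.levels.append(
            LevelRecord(level, nominal, len(back), mean_bc, acc, cv, passed)
        )
    n_pass = sum(rec.passed for rec in curve.levels)
    curve.curve_pass = n_pass >= config.min_standards_pass
    return curve


def fit_batch_curves(
    peak_table: pd.DataFrame,
    panel: Panel,
    config: PipelineConfig | None = None,
) -> dict[tuple[str, str], CalibrationCurve]:
    """Fit and gate one curve per (peptide, batch) from the standard rows."""
    config = config or PipelineConfig()
    std = peak_table.loc[peak_table["role"].str.startswith("standard:")].copy()
    if std.empty:
        raise QuantificationError("peak table contains no calibration standards")
    std["level"] = std["role"].str.split(":").str[1]
    curves: dict[tuple[str, str], CalibrationCurve] = {}
    for (peptide, batch), grp in std.groupby(["peptide", "batch"], sort=False):
        entry = panel[peptide]
        level_ratios = {}
        points = []
        for level, lgrp in grp.groupby("level", sort=False):
            nominal = entry.level_concs[level]
            ratios = lgrp["ratio"].tolist()
            level_ratios[level] = (nominal, ratios)
            points.extend((nominal, r) for r in ratios)
        curve = fit_calibration_curve(points, peptide, batch)
        # keep levels in panel order
        ordered = {
            lv: level_ratios[lv] for lv in entry.levels if lv in level_ratios
        }
        curves[(peptide, batch)] = gate_standards(curve, ordered, config)
    # every batch must carry a full standard set for every peptide
    batches = sorted(peak_table["batch"].unique())
    for batch in batches:
        for peptide in panel.peptides:
            if (peptide, batch) not in curves:
                raise QuantificationError(
                    f"batch {batch} has no calibration standards for {peptide}"
                )
    return curves


# ---------------------------------------------------------------------------
# batch validity
# ---------------------------------------------------------------------------


def evaluate_batch(
    batch_id: str,
    curves: dict[tuple[str, str], CalibrationCurve],
    peak_table: pd.DataFrame,
    panel: Panel,
    config: PipelineConfig | None = None,
) -> BatchVerdict:
    """Batch verdict from the QC accuracy rule and the curve-pass rule.

    Each surrogate-matrix QC measurement (one peptide in one QC replicate)
    counts as one QC result; it passes iff its back-calculated concentration
    is within ``accuracy_tol`` of nominal. The pooled-serum control has no
    nominal value and does not enter the rule.
    """
    config = config or PipelineConfig()
    qc = peak_table.loc[
        (peak_table["batch"] == batch_id)
        & peak_table["role"].isin(["qc:QCA", "qc:QCB", "qc:QCC"])
    ]
    if qc.empty:
        raise QuantificationError(f"batch {batch_id} has no QC samples")
    n_qc = n_qc_pass = 0
    for _, row in qc.iterrows():
        if not np.isfinite(row["ratio"]):
            continue
        entry = panel[row["peptide"]]
        nominal = entry.qc_concs.get(row["role"].split(":")[1])
        if nominal is None:
            continue
        curve = curves[(row["peptide"], batch_id)]
        if not curve.fittable:
            n_qc += 1
            continue
        conc = float(back_calculate(curve, row["ratio"]))
        n_qc += 1
        if abs(conc - nominal) / nominal <= config.accuracy_tol:
            n_qc_pass += 1
    batch_curves = [c for (pep, b), c in curves.items() if b == batch_id]
    n_curves = len(batch_curves)
    n_curve_pass = sum(c.curve_pass for c in batch_curves)
    qc_frac = n_qc_pass / n_qc if n_qc else 0.0
    curve_frac = n_curve_pass / n_curves if n_curves else 0.0
    return BatchVerdict(
        batch_id=batch_id,
        qc_pass_frac_observed=qc_frac,
        curve_pass_frac_observed=curve_frac,
        n_qc=n_qc,
        n_curves=n_curves,
        valid=qc_frac >= config.qc_pass_frac and curve_frac >= config.curve_pass_frac,
    )


def evaluate_batches(
    curves: dict[tuple[str, str], CalibrationCurve],
    peak_table: pd.DataFrame,
    panel: Panel,
    config: PipelineConfig | None = None,
) -> dict[str, BatchVerdict]:
    batches = sorted({b for _, b in curves})
    return {
        b: evaluate_batch(b, curves, peak_table, panel, config) for b in batches
    }


# ---------------------------------------------------------------------------
# sample quantification
# ---------------------------------------------------------------------------


@dataclass
class QuantMatrix:
    """Samples x proteins concentrations (fmol/uL = nM) with per-cell flags."""

    conc: pd.DataFrame
    flags: pd.DataFrame  # same shape; measured / clamped_LLOQ / clamped_HLOQ / missing
    verdicts: dict[str, BatchVerdict]
    excluded_samples: dict[str, str]  # sample_id -> reason

    def clamp_or_missing_frac(self) -> pd.Series:
        return (self.flags != FLAG_MEASURED).mean(axis=0)


def quantify_samples(
    peak_table: pd.DataFrame,
    curves: dict[tuple[str, str], CalibrationCurve],
    panel: Panel,
    config: PipelineConfig | None = None,
    verdicts: dict[str, BatchVerdict] | None = None,
    roles: tuple[str, ...] = ("cohort",),
) -> QuantMatrix:
    """Back-calculate cohort concentrations and clamp to the LLOQ/HLOQ.

    Technical duplicates are averaged *after* back-calculation so the limit
    clamp applies to the biological estimate. Samples whose batch failed the
    validity rules are excluded with a logged reason.
    """
    config = config or PipelineConfig()
    if verdicts is None:
        verdicts = evaluate_batches(curves, peak_table, panel, config)
    rows = peak_table.loc[peak_table["role"].isin(roles)].copy()
    excluded: dict[str, str] = {}
    invalid = {b for b, v in verdicts.items() if not v.valid}
    for sid in rows.loc[rows["batch"].isin(invalid), "sample_id"].unique():
        batch = rows.loc[rows["sample_id"] == sid, "batch"].iloc[0]
        excluded[sid] = f"batch {batch} failed validity rules"
    rows = rows.loc[~rows["batch"].isin(invalid)]

    pep_to_prot = {e.peptide_id: e.protein_id for e in panel}
    # vectorized back-calculation via per-(peptide,batch) slope/intercept
    key = list(zip(rows["peptide"], rows["batch"]))
    slope = np.array([curves[k].slope for k in key])
    intercept = np.array([curves[k].intercept for k in key])
    fittable = np.array([curves[k].fittable for k in key])
    with np.errstate(invalid="ignore", divide="ignore"):
        conc = (rows["ratio"].to_numpy() - intercept) / slope
    conc[~fittable | (slope == 0)] = np.nan
    rows = rows.assign(conc=conc, protein=rows["peptide"].map(pep_to_prot))

    mean_conc = (
        rows.groupby(["sample_id", "protein"], sort=False)["conc"]
        .mean()  # NaN replicates are skipped; all-NaN -> NaN
        .unstack("protein")
    )
    sample_order = [
        s for s in pd.unique(rows["sample_id"]) if s in mean_conc.index
    ]
    protein_order = [pep_to_prot[p] for p in panel.peptides if pep_to_prot[p] in mean_conc.columns]
    mean_conc = mean_conc.reindex(index=sample_order, columns=protein_order)

    lloq = pd.Series({e.protein_id: e.lloq for e in panel}).reindex(protein_order)
    hloq = pd.Series({e.protein_id: e.hloq for e in panel}).reindex(protein_order)
    flags = pd.DataFrame(
        FLAG_MEASURED, index=mean_conc.index, columns=mean_conc.columns
    )
    flags = flags.mask(mean_conc.isna(), FLAG_MISSING)
    low = mean_conc.lt(lloq, axis=1) & mean_conc.notna()
    high = mean_conc.gt(hloq, axis=1) & mean_conc.notna()
    flags = flags.mask(low, FLAG_LLOQ).mask(high, FLAG_HLOQ)
    clamped = mean_conc.clip(lower=lloq, upper=hloq, axis=1)
    return QuantMatrix(
        conc=clamped, flags=flags, verdicts=verdicts, excluded_samples=excluded
    )


# ---------------------------------------------------------------------------
# quantifiability filter
# ---------------------------------------------------------------------------


def filter_quantifiable(
    quant: QuantMatrix,
    curves: dict[tuple[str, str], CalibrationCurve],
    panel: Panel,
    config: PipelineConfig | None = None,
) -> tuple[list[str], list[dict]]:
    """Retain proteins quantified with R^2 > r2_min in every valid batch and
    clamped/missing in no more than ``detect_frac`` of cohort cells.

    Returns (retained protein ids, exclusion report rows).
    """
    config = config or PipelineConfig()
    valid_batches = [b for b, v in quant.verdicts.items() if v.valid]
    pep_of = {e.protein_id: e.peptide_id for e in panel}
    frac = quant.clamp_or_missing_frac()
    retained, report = [], []
    for protein in quant.conc.columns:
        pep = pep_of[protein]
        bad_r2 = [
            b
            for b in valid_batches
            if not (
                curves[(pep, b)].fittable and curves[(pep, b)].r2 > config.r2_min
            )
        ]
        reasons = []
        if bad_r2:
            r2s = [curves[(pep, b)].r2 for b in bad_r2]
            reasons.append(
                f"curve R^2 <= {config.r2_min} in batch(es) "
                + ", ".join(f"{b} (R^2={r:.4f})" for b, r in zip(bad_r2, r2s))
            )
        if frac[protein] > config.detect_frac:
            reasons.append(
                f"out-of-range or missing in {frac[protein]:.0%} of cohort "
                f"samples (> {config.detect_frac:.0%})"
            )
        if reasons:
            report.append({"protein_id": protein, "reasons": reasons})
        else:
            retained.append(protein)
    return retained, report
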