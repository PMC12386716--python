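"""Covariate association screening and clinically adjusted MoM values.

Two stages mirror clinical-reference practice for first-trimester serum
markers:

1. a Spearman rank-correlation screen of every protein's MoM values against
   the clinical covariates (maternal age, BMI, gestational age at
   collection, parity, uterine myoma, fetal sex, plus any extra numeric
   annotation columns);
2. per protein, an ordinary least-squares model of MoM on the candidate
   covariates refined by backward elimination — while any predictor has
   p >= 0.05, the least significant one is dropped and the model refitted.
   The final model defines the expected MoM for a sample's covariate
   profile; dividing observed by expected MoM yields the clinically
   adjusted value, and the covariate values at which expected MoM = 1 are
   the baseline profile reported with each model.

The screen reports raw p-values (significance at p < 0.05) plus a
Benjamini-Hochberg q-value column, since a ~100-protein x ~6-covariate
screen demands it for any serious reuse.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .io_formats import COVARIATE_COLUMNS


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Spearman screen
# ---------------------------------------------------------------------------


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho with midranks for ties (Pearson correlation of ranks)."""
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.corrcoef(rx, ry)[0, 1])


def _spearman_pvalue(rho: float, x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided p-value: exact permutation enumeration for n <= 9, else the
    t-approximation with n - 2 degrees of freedom."""
    n = x.size
    if not np.isfinite(rho):
        return np.nan
    if n <= 9:
        ry = stats.rankdata(y, method="average")
        rx = stats.rankdata(x, method="average")
        obs = abs(rho)
        count = total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, perm)[0, 1]
            total += 1
            if abs(r) >= obs - 1e-12:
                count += 1
        return count / total
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def spearman_screen(
    mom_matrix: pd.DataFrame,
    annotations: pd.DataFrame,
    clinical_columns: list[str] | None = None,
    config: PipelineConfig | None = None,
    min_n: int = 10,
) -> pd.DataFrame:
    """Rank-correlate every protein with every clinical column.

    Returns one record per protein x covariate with rho, two-sided p, n, a
    significance flag at ``p_enter_exit``, and a Benjamini-Hochberg q-value
    computed over the whole screen.
    """
    config = config or PipelineConfig()
    if clinical_columns is None:
        numeric_extra = [
            c
            for c in annotations.columns
            if c not in COVARIATE_COLUMNS + ["batch"]
            and pd.api.types.is_numeric_dtype(annotations[c])
        ]
        clinical_columns = COVARIATE_COLUMNS + numeric_extra
    ann = annotations.reindex(mom_matrix.index)
    rows = []
    for cov in clinical_columns:
        cvals = pd.to_numeric(ann[cov], errors="coerce")
        for protein in mom_matrix.columns:
            pair = pd.concat([mom_matrix[protein], cvals], axis=1).dropna()
            n = len(pair)
            if n < min_n:
                raise ModelError(
                    f"fewer than {min_n} paired observations for "
                    f"({protein}, {cov})"
                )
            x = pair.iloc[:, 0].to_numpy(float)
            y = pair.iloc[:, 1].to_numpy(float)
            rho = _spearman_rho(x, y)
            if not np.isfinite(rho):
                warnings.warn(f"zero-variance covariate {cov!r}; rho undefined")
                rows.append(
                    {
                        "protein_id": protein,
                        "covariate": cov,
                        "rho": np.nan,
                        "p_value": np.nan,
                        "n": n,
                        "significant": False,
                    }
                )
                continue
            p = _spearman_pvalue(rho, x, y)
            rows.append(
                {
                    "protein_id": protein,
                    "covariate": cov,
                    "rho": rho,
                    "p_value": p,
                    "n": n,
                    "significant": bool(p < config.p_enter_exit),
                }
            )
    out = pd.DataFrame(rows)
    mask = out["p_value"].notna()
    out["q_value"] = np.nan
    if mask.any():
        out.loc[mask, "q_value"] = multipletests(
            out.loc[mask, "p_value"], method="fdr_bh"
        )[1]
    return out


# ---------------------------------------------------------------------------
# backward-elimination regression
# ---------------------------------------------------------------------------


@dataclass
class CovariateModel:
    protein_id: str
    intercept: float
    coefficients: dict[str, float] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)
    r_squared: float = np.nan
    dropped: list[str] = field(default_factory=list)
    baseline: dict[str, float] = field(default_factory=dict)
    baseline_in_range: bool = True

    @property
    def is_intercept_only(self) -> bool:
        return not self.coefficients

    def expected_mom(self, covariates: pd.DataFrame | pd.Series) -> pd.Series:
        """Model-expected MoM for covariate profiles. Intercept-only models
        predict exactly 1 (no adjustment)."""
        if isinstance(covariates, pd.Series):
            covariates = covariates.to_frame().T
        if self.is_intercept_only:
            return pd.Series(1.0, index=covariates.index)
        pred = pd.Series(self.intercept, index=covariates.index, dtype=float)
        for name, beta in self.coefficients.items():
            pred += beta * pd.to_numeric(covariates[name], errors="coerce")
        return pred


def fit_covariate_model(
    mom_values: pd.Series,
    annotations: pd.DataFrame,
    candidates: list[str] | None = None,
    config: PipelineConfig | None = None,
    cond_threshold: float = 1e8,
) -> CovariateModel:
    """OLS of MoM on covariates with one-at-a-time backward elimination.

    While any predictor has p >= ``p_enter_exit``, the largest-p predictor
    is removed and the model refitted; the final model may be
    intercept-only. A collinear design (condition number of the
    standardized design above threshold) raises, naming the predictors.
    """
    config = config or PipelineConfig()
    candidates = list(candidates or COVARIATE_COLUMNS)
    data = pd.concat(
        [mom_values.rename("mom"), annotations[candidates]], axis=1
    ).dropna()
    n = len(data)
    if n <= len(candidates) + 2:
        raise ModelError(
            f"need n > {len(candidates) + 2} complete observations, got {n}"
        )
    xs = data[candidates].astype(float)
    scaled = (xs - xs.mean()) / xs.std().replace(0, 1.0)
    cond = np.linalg.cond(np.column_stack([np.ones(n), scaled.to_numpy()]))
    if cond > cond_threshold:
        raise ModelError(
            f"collinear design (condition number {cond:.3g}) among "
            f"predictors {candidates}"
        )
    retained = list(candidates)
    dropped: list[str] = []
    y = data["mom"].astype(float)
    while True:
        X = sm.add_constant(data[retained].astype(float)) if retained else None
        if retained:
            fit = sm.OLS(y, X).fit()
            pvals = fit.pvalues.drop("const")
            worst = pvals.idxmax()
            if pvals.loc[worst] >= config.p_enter_exit:
                retained.remove(worst)
                dropped.append(worst)
                continue
            model = CovariateModel(
                protein_id=str(mom_values.name or ""),
                intercept=float(fit.params["const"]),
                coefficients={k: float(fit.params[k]) for k in retained},
                p_values={k: float(pvals[k]) for k in retained},
                r_squared=float(fit.rsquared),
                dropped=dropped,
            )
        else:
            fit = sm.OLS(y, np.ones((n, 1))).fit()
            model = CovariateModel(
                protein_id=str(mom_values.name or ""),
                intercept=float(fit.params.iloc[0]),
                r_squared=0.0,
                dropped=dropped,
            )
        break
    baseline_values(model, annotations)
    return model


def baseline_values(
    model: CovariateModel, annotations: pd.DataFrame
) -> dict[str, float]:
    """Covariate profile x0 at which the model-expected MoM equals 1.

    All retained covariates but the last are anchored at their cohort
    medians; the last is solved analytically. If the solved value falls
    outside the observed covariate range the profile is still reported but
    flagged out-of-range; when several orderings are possible the first
    in-range solution (trying the last retained covariate first) wins.
    """
    if model.is_intercept_only:
        model.baseline = {}
        model.baseline_in_range = True
        return {}
    names = list(model.coefficients)
    medians = {c: float(annotations[c].astype(float).median()) for c in names}
    ranges = {
        c: (
            float(annotations[c].astype(float).min()),
            float(annotations[c].astype(float).max()),
        )
        for c in names
    }
    chosen = None
    for free in reversed(names):
        beta = model.coefficients[free]
        if beta == 0:
            continue
        x0 = {c: medians[c] for c in names if c != free}
        residual = 1.0 - model.intercept - sum(
            model.coefficients[c] * x0[c] for c in x0
        )
        x0[free] = residual / beta
        lo, hi = ranges[free]
        in_range = lo <= x0[free] <= hi
        if chosen is None or (in_range and not chosen[1]):
            chosen = (x0, in_range)
        if in_range:
            break
    if chosen is None:  # all betas zero: degenerate, anchor at medians
        chosen = ({c: medians[c] for c in names}, False)
    model.baseline = {k: float(v) for k, v in chosen[0].items()}
    model.baseline_in_range = bool(chosen[1])
    check = float(
        model.expected_mom(pd.Series(model.baseline)).iloc[0]
    )
    if chosen[1] and abs(check - 1.0) > 1e-9:
        raise ModelError(
            f"baseline profile fails expected_mom(x0) = 1 check: {check}"
        )
    return model.baseline


# ---------------------------------------------------------------------------
# MoM adjustment
# ---------------------------------------------------------------------------


@dataclass
class AdjustedMoM:
    data: pd.DataFrame  # samples x proteins corrected MoM
    factors: pd.DataFrame  # expected MoM used per cell (after flooring)
    warnings: list[str] = field(default_factory=list)


def adjust_mom(
    mom_matrix: pd.DataFrame,
    models: dict[str, CovariateModel],
    annotations: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> AdjustedMoM:
    """Corrected MoM = observed / expected MoM given the sample's covariates.

    Intercept-only models pass through unchanged (factor 1). The expected
    MoM is floored at ``expected_mom_floor`` to prevent explosion; each
    corrected column is re-centered so its median is exactly 1.
    """
    config = config or PipelineConfig()
    ann = annotations.reindex(mom_matrix.index)
    factors = pd.DataFrame(
        1.0, index=mom_matrix.index, columns=mom_matrix.columns
    )
    notes: list[str] = []
    for protein in mom_matrix.columns:
        model = models.get(protein)
        if model is None or model.is_intercept_only:
            continue
        expected = model.expected_mom(ann)
        bad = expected.index[expected <= 0]
        if len(bad):
            notes.append(
                f"{protein}: expected MoM <= 0 for samples {bad.tolist()}; floored"
            )
        factors[protein] = expected.clip(lower=config.expected_mom_floor)
    corrected = mom_matrix / factors
    med = corrected.median(axis=0, skipna=True)
    corrected = corrected.div(med, axis=1)
    return AdjustedMoM(data=corrected, factors=factors, warnings=notes)
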