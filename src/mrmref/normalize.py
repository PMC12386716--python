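"""Normalization methods and the control-CV benchmarking that ranks them.

Four approaches are compared on the same footing:

* quantile normalization — each sample's sorted values are replaced by the
  cross-sample mean of order statistics (rank-based, linear scale);
* cyclic LOESS — locally weighted regression of the log-difference M on the
  log-average A, subtracted symmetrically; the default "fast" variant
  normalizes each sample against the mean reference profile, the "pairwise"
  variant cycles over all sample pairs;
* RobNorm — per-sample log shifts estimated by a density-power-weighted
  Gaussian criterion so that majority (non-outlying) proteins dominate;
* ComBat — parametric empirical-Bayes location/scale batch adjustment with
  per-(batch, protein) parameters shrunk toward pooled priors.

All model-based methods (LOESS, RobNorm, ComBat) operate on log10
concentrations and exponentiate back; quantile normalization is rank-based
and applied on the reported concentration scale. Methods are *fit* on cohort
samples and control samples are *transformed* with the fitted parameters, so
the CV criterion measures generalization rather than self-fit.

The benchmarking criterion: per protein, the CV (SD/mean, linear scale) is
computed within each control group — calibration standards pooled per level,
each surrogate-matrix QC level, and the pooled-serum control — then averaged
over groups; the median over proteins of these mean CVs summarizes a method,
and proteins with mean CV >= 20% are excluded from further analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA as _SkPCA
from statsmodels.nonparametric.smoothers_lowess import lowess

from .config import PipelineConfig


class NormalizationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------


class QuantileNormalizer:
    """Map every sample onto the mean-of-order-statistics reference
    distribution; ties receive the mean of their ranks' reference values."""

    def __init__(self) -> None:
        self.reference_: np.ndarray | None = None

    def fit(self, matrix: pd.DataFrame) -> "QuantileNormalizer":
        if len(matrix) < 2:
            warnings.warn("quantile normalization with a single sample is identity")
            self.reference_ = None
            return self
        values = matrix.to_numpy(dtype=float)
        sorted_cols = np.sort(values, axis=1)  # NaN sorts last
        if np.isnan(values).any():
            # build the reference on a common quantile grid over non-missing values
            grid = np.linspace(0, 1, values.shape[1])
            rows = []
            for row in values:
                row = row[np.isfinite(row)]
                rows.append(np.quantile(row, grid))
            self.reference_ = np.mean(rows, axis=0)
        else:
            self.reference_ = sorted_cols.mean(axis=0)
        return self

    def _transform_row(self, row: np.ndarray) -> np.ndarray:
        out = np.full_like(row, np.nan, dtype=float)
        mask = np.isfinite(row)
        vals = row[mask]
        if vals.size == 0:
            return out
        ref = self.reference_
        # average ranks (midranks for ties), mapped onto the reference grid
        ranks = stats.rankdata(vals, method="average") - 1.0
        grid = np.linspace(0, 1, ref.size)
        q = ranks / max(vals.size - 1, 1)
        out[mask] = np.interp(q, grid, ref)
        return out

    def transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        if self.reference_ is None:
            return matrix.copy()
        arr = np.vstack(
            [self._transform_row(r) for r in matrix.to_numpy(dtype=float)]
        )
        return pd.DataFrame(arr, index=matrix.index, columns=matrix.columns)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """One-shot quantile normalization of a samples x proteins matrix."""
    norm = QuantileNormalizer().fit(matrix)
    return norm.transform(matrix)


# ---------------------------------------------------------------------------
# cyclic LOESS
# ---------------------------------------------------------------------------


class CyclicLoessNormalizer:
    """MA-plot LOESS normalization on log10 values.

    ``method="fast"`` regresses each sample's M against the running mean
    reference (one smoother per sample per cycle); ``method="pairwise"``
    cycles over all sample pairs with symmetric half-corrections.
    """

    def __init__(
        self,
        span: float = 0.7,
        max_iter: int = 3,
        tol: float = 1e-4,
        method: str = "fast",
    ) -> None:
        self.span = span
        self.max_iter = max_iter
        self.tol = tol
        self.method = method
        self.reference_: pd.Series | None = None

    @staticmethod
    def _smooth(m: np.ndarray, a: np.ndarray, span: float) -> np.ndarray:
        # delta-interpolation: evaluate the local fits on a coarse grid of
        # A-values; ~50x faster and visually identical for smooth trends
        delta = 0.01 * (a.max() - a.min())
        out = lowess(m, a, frac=span, it=1, delta=delta, return_sorted=False)
        return np.asarray(out, dtype=float)

    def fit_transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        if len(matrix) < 2:
            raise NormalizationError("cyclic LOESS needs >= 2 samples")
        n_window = max(int(np.ceil(self.span * matrix.shape[1])), 3)
        if matrix.shape[1] < max(n_window, 10):
            raise NormalizationError(
                f"too few proteins ({matrix.shape[1]}) for LOESS span {self.span}"
            )
        log = np.log10(matrix.to_numpy(dtype=float))
        n = log.shape[0]
        for _ in range(self.max_iter):
            max_corr = 0.0
            if self.method == "fast":
                ref = np.nanmean(log, axis=0)
                for i in range(n):
                    mask = np.isfinite(log[i]) & np.isfinite(ref)
                    m = log[i, mask] - ref[mask]
                    a = 0.5 * (log[i, mask] + ref[mask])
                    fit = self._smooth(m, a, self.span)
                    log[i, mask] -= fit
                    max_corr = max(max_corr, float(np.mean(np.abs(fit))))
            elif self.method == "pairwise":
                # half-corrections applied pair by pair (Gauss-Seidel style)
                for i in range(n):
                    for j in range(i + 1, n):
                        mask = np.isfinite(log[i]) & np.isfinite(log[j])
                        m = log[i, mask] - log[j, mask]
                        a = 0.5 * (log[i, mask] + log[j, mask])
                        fit = self._smooth(m, a, self.span)
                        log[i, mask] -= fit / 2
                        log[j, mask] += fit / 2
                        max_corr = max(max_corr, float(np.mean(np.abs(fit))))
            else:
                raise ValueError(f"unknown method {self.method!r}")
            if max_corr < self.tol:
                break
        self.reference_ = pd.Series(np.nanmean(log, axis=0), index=matrix.columns)
        return pd.DataFrame(
            10.0**log, index=matrix.index, columns=matrix.columns
        )

    def transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        """Normalize new samples against the stored reference profile."""
        if self.reference_ is None:
            raise NormalizationError("call fit_transform first")
        log = np.log10(matrix.to_numpy(dtype=float))
        ref = self.reference_.to_numpy()
        for _ in range(self.max_iter):
            done = True
            for i in range(log.shape[0]):
                mask = np.isfinite(log[i]) & np.isfinite(ref)
                m = log[i, mask] - ref[mask]
                a = 0.5 * (log[i, mask] + ref[mask])
                fit = self._smooth(m, a, self.span)
                log[i, mask] -= fit
                if np.mean(np.abs(fit)) >= self.tol:
                    done = False
            if done:
                break
        return pd.DataFrame(10.0**log, index=matrix.index, columns=matrix.columns)


def cyclic_loess_normalize(
    matrix: pd.DataFrame, span: float = 0.7, max_iter: int = 3, method: str = "fast"
) -> pd.DataFrame:
    return CyclicLoessNormalizer(span=span, max_iter=max_iter, method=method).fit_transform(
        matrix
    )


# ---------------------------------------------------------------------------
# RobNorm
# ---------------------------------------------------------------------------


class RobNorm:
    """Per-sample effect estimation by density-power-weighted Gaussian
    fitting on log10 values.

    Model: x_sp = mu_p + e_s + eps, eps ~ N(0, sigma_p^2). Each observation
    is weighted by the model density raised to ``density_power`` (gamma), so
    proteins far from their majority distribution — outliers, truly
    differential features — get down-weighted and the estimated sample
    effects track the majority. gamma -> 0 recovers maximum-likelihood
    column means. The per-protein scale uses the density-power fixed point
    sigma^2 = (1 + gamma) * sum(w r^2) / sum(w).
    """

    def __init__(
        self,
        density_power: float = 0.5,
        max_iter: int = 500,
        tol: float = 1e-9,
    ) -> None:
        self.gamma = density_power
        self.max_iter = max_iter
        self.tol = tol
        self.mu_: pd.Series | None = None
        self.sigma_: pd.Series | None = None
        self.sample_effects_: pd.Series | None = None

    def _weights(self, resid: np.ndarray, sigma: np.ndarray) -> np.ndarray:
        if self.gamma == 0:
            return np.ones_like(resid)
        w = np.exp(-self.gamma * resid**2 / (2.0 * sigma[None, :] ** 2))
        return w

    def fit(self, matrix: pd.DataFrame) -> "RobNorm":
        if len(matrix) < 3:
            raise NormalizationError("RobNorm needs >= 3 samples")
        x = np.log10(matrix.to_numpy(dtype=float))
        finite = np.isfinite(x)
        mu = np.nanmedian(np.where(finite, x, np.nan), axis=0)
        e = np.zeros(x.shape[0])
        sigma = np.maximum(np.nanstd(np.where(finite, x, np.nan), axis=0), 1e-6)
        trace = []
        for it in range(self.max_iter):
            resid = np.where(finite, x - mu[None, :] - e[:, None], 0.0)
            w = self._weights(resid, sigma) * finite
            wsum_p = w.sum(axis=0)
            sigma2 = (1.0 + self.gamma) * (w * resid**2).sum(axis=0) / np.maximum(
                wsum_p, 1e-12
            )
            sigma = np.sqrt(np.maximum(sigma2, 1e-12))
            w = self._weights(
                np.where(finite, x - mu[None, :] - e[:, None], 0.0), sigma
            ) * finite
            num = (w * np.where(finite, x - mu[None, :], 0.0)).sum(axis=1)
            den = np.maximum(w.sum(axis=1), 1e-12)
            e_new = num / den
            e_new -= e_new.mean()  # identifiability: effects sum to zero
            num_p = (w * np.where(finite, x - e_new[:, None], 0.0)).sum(axis=0)
            mu = num_p / np.maximum(w.sum(axis=0), 1e-12)
            delta = float(np.max(np.abs(e_new - e)))
            trace.append(delta)
            e = e_new
            if delta < self.tol:
                break
        else:
            raise NormalizationError(
                f"RobNorm did not converge in {self.max_iter} iterations; "
                f"last deltas: {trace[-5:]}"
            )
        self.mu_ = pd.Series(mu, index=matrix.columns)
        self.sigma_ = pd.Series(sigma, index=matrix.columns)
        self.sample_effects_ = pd.Series(e, index=matrix.index)
        return self

    def _estimate_effect(self, row: np.ndarray) -> float:
        """Sample effect for a new observation vector, holding mu/sigma fixed."""
        mu = self.mu_.to_numpy()
        sigma = self.sigma_.to_numpy()
        mask = np.isfinite(row) & np.isfinite(mu)
        resid0 = row[mask] - mu[mask]
        e = float(np.median(resid0))
        for _ in range(100):
            r = resid0 - e
            w = (
                np.exp(-self.gamma * r**2 / (2.0 * sigma[mask] ** 2))
                if self.gamma
                else np.ones_like(r)
            )
            if w.sum() < 1e-9:  # profile far from the cohort model: fall back
                return float(np.median(resid0))
            e_new = float((w * resid0).sum() / w.sum())
            if abs(e_new - e) < 1e-12:
                return e_new
            e = e_new
        return e

    def transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        x = np.log10(matrix.to_numpy(dtype=float))
        effects = np.array([self._estimate_effect(row) for row in x])
        out = 10.0 ** (x - effects[:, None])
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)

    def normalized(self, matrix: pd.DataFrame) -> pd.DataFrame:
        """Remove the fitted per-sample effects from the fit matrix."""
        x = np.log10(matrix.to_numpy(dtype=float))
        out = 10.0 ** (x - self.sample_effects_.to_numpy()[:, None])
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def robnorm(
    matrix: pd.DataFrame, density_power: float = 0.5
) -> tuple[pd.DataFrame, pd.Series]:
    """Fit-and-apply RobNorm; returns (normalized matrix, sample effects)."""
    model = RobNorm(density_power=density_power).fit(matrix)
    return model.normalized(matrix), model.sample_effects_


# ---------------------------------------------------------------------------
# ComBat
# ---------------------------------------------------------------------------


class ComBat:
    """Parametric empirical-Bayes location/scale batch adjustment (log10).

    Data are standardized per protein, per-(batch, protein) location and
    scale estimates are shrunk toward pooled priors (normal prior on
    locations, inverse-gamma on scales, both fitted by moments), the shrunk
    effects are removed, and the data are de-standardized.
    """

    def __init__(self, parametric: bool = True, max_iter: int = 100, tol: float = 1e-8):
        if not parametric:
            raise NotImplementedError("only the parametric prior is implemented")
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, matrix: pd.DataFrame, batches: pd.Series) -> "ComBat":
        batches = batches.reindex(matrix.index)
        counts = batches.value_counts()
        if (counts < 2).any():
            small = counts[counts < 2].index.tolist()
            raise NormalizationError(
                f"batch(es) of size < 2: {small}; variance undefined"
            )
        x = np.log10(matrix.to_numpy(dtype=float))
        n, p = x.shape
        levels = sorted(counts.index)
        design = np.stack(
            [(batches == b).to_numpy(dtype=float) for b in levels], axis=1
        )
        n_b = design.sum(axis=0)
        # pooled (size-weighted) protein means and variances
        batch_means = (design.T @ x) / n_b[:, None]
        grand = (n_b[:, None] * batch_means).sum(axis=0) / n
        resid = x - design @ batch_means
        pooled_var = (resid**2).sum(axis=0) / n
        pooled_sd = np.sqrt(np.maximum(pooled_var, 1e-12))
        z = (x - grand[None, :]) / pooled_sd[None, :]

        gamma_hat = (design.T @ z) / n_b[:, None]  # batches x proteins
        delta_hat = np.empty_like(gamma_hat)
        for i, b in enumerate(levels):
            zb = z[design[:, i] == 1]
            delta_hat[i] = zb.var(axis=0, ddof=1)

        gamma_star = np.empty_like(gamma_hat)
        delta_star = np.empty_like(delta_hat)
        for i in range(len(levels)):
            g, d = gamma_hat[i], delta_hat[i]
            g_bar, t2 = g.mean(), g.var(ddof=1)
            # inverse-gamma prior on delta^2 by moments
            v, s2 = d.mean(), d.var(ddof=1)
            a_prior = (2 * s2 + v**2) / s2 if s2 > 0 else 100.0
            b_prior = (v * s2 + v**3) / s2 if s2 > 0 else v * 99.0
            ni = n_b[i]
            zb = z[design[:, i] == 1]
            g_new, d_new = g.copy(), d.copy()
            for _ in range(self.max_iter):
                g_old, d_old = g_new.copy(), d_new.copy()
                g_new = (ni * t2 * g + d_new * g_bar) / (ni * t2 + d_new)
                sse = ((zb - g_new[None, :]) ** 2).sum(axis=0)
                d_new = (0.5 * sse + b_prior) / (ni / 2.0 + a_prior - 1.0)
                change = max(
                    np.max(np.abs(g_new - g_old)), np.max(np.abs(d_new - d_old))
                )
                if change < self.tol:
                    break
            gamma_star[i] = g_new
            delta_star[i] = d_new

        self.levels_ = levels
        self.grand_ = pd.Series(grand, index=matrix.columns)
        self.pooled_sd_ = pd.Series(pooled_sd, index=matrix.columns)
        self.gamma_star_ = pd.DataFrame(
            gamma_star, index=levels, columns=matrix.columns
        )
        self.delta_star_ = pd.DataFrame(
            delta_star, index=levels, columns=matrix.columns
        )
        return self

    def transform(self, matrix: pd.DataFrame, batches: pd.Series) -> pd.DataFrame:
        batches = batches.reindex(matrix.index)
        x = np.log10(matrix.to_numpy(dtype=float))
        grand = self.grand_.to_numpy()
        sd = self.pooled_sd_.to_numpy()
        z = (x - grand[None, :]) / sd[None, :]
        out = np.empty_like(z)
        for i, b in enumerate(batches):
            if b not in self.levels_:
                raise NormalizationError(f"unknown batch {b!r} at transform time")
            g = self.gamma_star_.loc[b].to_numpy()
            d = np.sqrt(self.delta_star_.loc[b].to_numpy())
            out[i] = (z[i] - g) / d
        adj = out * sd[None, :] + grand[None, :]
        return pd.DataFrame(10.0**adj, index=matrix.index, columns=matrix.columns)


def combat_adjust(
    matrix: pd.DataFrame, batches: pd.Series, parametric: bool = True
) -> pd.DataFrame:
    if batches.reindex(matrix.index).nunique() < 2:
        # nothing to adjust
        return matrix.copy()
    model = ComBat(parametric=parametric).fit(matrix, batches)
    return model.transform(matrix, batches)


# ---------------------------------------------------------------------------
# CV profiling and method comparison
# ---------------------------------------------------------------------------


@dataclass
class CvProfile:
    method: str
    per_group_cv: pd.DataFrame  # proteins x control groups
    mean_cv: pd.Series  # per-protein mean over groups
    median_mean_cv: float
    excluded_proteins: list[str] = field(default_factory=list)


def control_groups(peak_table: pd.DataFrame) -> pd.Series:
    """Group label per control row: standards pooled per level (across
    batches), and each QC role pooled across batches."""
    roles = peak_table["role"]
    labels = pd.Series(pd.NA, index=peak_table.index, dtype=object)
    std = roles.str.startswith("standard:")
    labels[std] = roles[std]
    qc = roles.str.startswith("qc:")
    labels[qc] = roles[qc]
    return labels


def compute_cv_profile(
    control_conc: pd.DataFrame,
    groups: pd.Series,
    method: str = "raw",
    config: PipelineConfig | None = None,
) -> CvProfile:
    """CV = SD/mean per protein within each control group (linear scale),
    averaged over groups; the median over proteins summarizes the method."""
    config = config or PipelineConfig()
    groups = groups.reindex(control_conc.index)
    per_group = {}
    for g, idx in groups.groupby(groups).groups.items():
        sub = control_conc.loc[idx]
        if len(sub) < 2:
            warnings.warn(f"control group {g!r} has < 2 replicates; skipped")
            continue
        mean = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            per_group[g] = (sd / mean).where(mean != 0)
    if not per_group:
        raise NormalizationError("no control group has >= 2 replicates")
    per_group_df = pd.DataFrame(per_group)
    mean_cv = per_group_df.mean(axis=1)
    excluded = mean_cv.index[mean_cv >= config.cv_exclude].tolist()
    return CvProfile(
        method=method,
        per_group_cv=per_group_df,
        mean_cv=mean_cv,
        median_mean_cv=float(mean_cv.median()),
        excluded_proteins=excluded,
    )


def exclude_high_cv(
    profile: CvProfile, config: PipelineConfig | None = None
) -> list[str]:
    """Proteins retained after the mean-CV >= 20% exclusion (strict >=)."""
    config = config or PipelineConfig()
    return profile.mean_cv.index[profile.mean_cv < config.cv_exclude].tolist()


def compare_methods(profiles: dict[str, CvProfile]) -> pd.DataFrame:
    """Pairwise one-sided paired rank tests on per-protein mean CVs.

    For each ordered pair (a, b) the one-sided Wilcoxon signed-rank test
    asks whether method a's per-protein mean CVs are stochastically smaller
    than method b's. Identical profiles give p = 1 by convention.
    """
    names = list(profiles)
    if len(names) < 2:
        raise ValueError("need >= 2 profiles to compare")
    common = profiles[names[0]].mean_cv.index
    for n in names[1:]:
        common = common.intersection(profiles[n].mean_cv.index)
    if len(common) == 0:
        raise ValueError("profiles have disjoint protein sets")
    rows = []
    for a in names:
        for b in names:
            if a == b:
                continue
            da = profiles[a].mean_cv.loc[common]
            db = profiles[b].mean_cv.loc[common]
            diff = (da - db).dropna()
            if np.allclose(diff, 0):
                p = 1.0
            else:
                p = float(
                    stats.wilcoxon(diff, alternative="less").pvalue
                )
            rows.append(
                {
                    "method_a": a,
                    "method_b": b,
                    "median_mean_cv_a": profiles[a].median_mean_cv,
                    "median_mean_cv_b": profiles[b].median_mean_cv,
                    "n_proteins": int(diff.size),
                    "p_a_less_than_b": p,
                }
            )
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["median_mean_cv_a", "median_mean_cv_b"]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# PCA diagnostics
# ---------------------------------------------------------------------------


@dataclass
class PcaResult:
    scores: pd.DataFrame
    explained_variance_ratio: np.ndarray
    separation_ratio: float  # between/within batch distance ratio on PC1-2


def pca_diagnostics(
    matrix: pd.DataFrame, labels: pd.Series, n_components: int | None = None
) -> PcaResult:
    """Autoscaled PCA with a batch-separation statistic on PC1-2."""
    if len(matrix) < 3:
        raise NormalizationError("PCA diagnostics need >= 3 samples")
    x = matrix.to_numpy(dtype=float)
    x = (x - x.mean(axis=0)) / np.where(x.std(axis=0) > 0, x.std(axis=0), 1.0)
    k = n_components or min(x.shape[0] - 1, x.shape[1], 10)
    pca = _SkPCA(n_components=k)
    scores = pca.fit_transform(x)
    scores_df = pd.DataFrame(
        scores, index=matrix.index, columns=[f"PC{i + 1}" for i in range(k)]
    )
    labels = labels.reindex(matrix.index)
    pc12 = scores[:, : min(2, k)]
    centroids = {}
    within = []
    for g, idx in labels.groupby(labels).groups.items():
        pts = pc12[[matrix.index.get_loc(i) for i in idx]]
        c = pts.mean(axis=0)
        centroids[g] = c
        within.extend(np.linalg.norm(pts - c, axis=1))
    cents = list(centroids.values())
    between = [
        np.linalg.norm(cents[i] - cents[j])
        for i in range(len(cents))
        for j in range(i + 1, len(cents))
    ]
    sep = float(np.mean(between) / np.mean(within)) if between and np.mean(within) > 0 else np.nan
    return PcaResult(
        scores=scores_df,
        explained_variance_ratio=pca.explained_variance_ratio_,
        separation_ratio=sep,
    )
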