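import itertools
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mrmref.config import PipelineConfig
from mrmref.normalize import (
    ComBat,
    CyclicLoessNormalizer,
    NormalizationError,
    QuantileNormalizer,
    RobNorm,
    combat_adjust,
    compare_methods,
    compute_cv_profile,
    cyclic_loess_normalize,
    exclude_high_cv,
    pca_diagnostics,
    quantile_normalize,
    robnorm,
)


def _df(arr, prefix="S"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"{prefix}{i}" for i in range(arr.shape[0])],
        columns=[f"P{j}" for j in range(arr.shape[1])],
    )


class TestQuantile:
    def test_textbook_two_samples(self):
        out = quantile_normalize(_df([[1, 2, 3], [4, 5, 6]]))
        expected = np.array([[2.5, 3.5, 4.5], [2.5, 3.5, 4.5]])
        assert np.allclose(out, expected)

    def test_identical_samples_unchanged(self):
        df = _df([[1, 5, 9], [1, 5, 9]])
        assert np.allclose(quantile_normalize(df), df)

    def test_row_distributions_equalized(self):
        rng = np.random.default_rng(3)
        df = _df(rng.uniform(1, 100, (5, 8)))
        out = quantile_normalize(df).to_numpy()
        sorted_rows = np.sort(out, axis=1)
        assert np.allclose(sorted_rows, sorted_rows[0], atol=1e-12)

    def test_shape_and_missingness_preserved(self):
        df = _df([[1, 2, 3, 4], [4, 3, 2, 1], [2, 4, 1, 3]])
        df.iloc[0, 1] = np.nan
        out = quantile_normalize(df)
        assert out.shape == df.shape
        assert out.isna().equals(df.isna())


class TestCyclicLoess:
    def test_constant_offset_removed(self):
        rng = np.random.default_rng(0)
        base = 10.0 ** rng.uniform(0, 3, 60)
        df = _df([base, base * 10**0.3])
        out = cyclic_loess_normalize(df)
        m = np.log10(out.iloc[0] / out.iloc[1])
        assert np.abs(m.mean()) < 1e-3

    def test_idempotent_on_normalized_data(self):
        rng = np.random.default_rng(1)
        base = 10.0 ** rng.uniform(0, 3, 80)
        noise = rng.normal(0, 0.01, (4, 80))
        df = _df(base[None, :] * 10**noise)
        out1 = cyclic_loess_normalize(df)
        out2 = cyclic_loess_normalize(out1)
        assert np.allclose(np.log10(out2 / out1), 0, atol=5e-3)

    def test_intensity_dependent_bend_flattened(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 3, 200)
        base = 10.0**a
        # inject an M vs A slope on one sample
        bend = 0.1 * (a - a.mean())
        df = _df([base, base * 10**bend])
        out = cyclic_loess_normalize(df, span=0.4)

        def ma_slope(mat):
            log = np.log10(mat.to_numpy())
            m = log[1] - log[0]
            av = log.mean(axis=0)
            return np.polyfit(av, m, 1)[0]

        assert abs(ma_slope(out)) < abs(ma_slope(df)) / 10

    def test_pairwise_variant_removes_offset(self):
        rng = np.random.default_rng(4)
        base = 10.0 ** rng.uniform(0, 3, 60)
        df = _df([base, base * 10**0.2, base * 10**-0.2])
        out = cyclic_loess_normalize(df, method="pairwise")
        logs = np.log10(out.to_numpy())
        offsets = logs.mean(axis=1) - logs.mean()
        assert np.abs(offsets).max() < 5e-3

    def test_too_few_proteins_rejected(self):
        with pytest.raises(NormalizationError, match="too few"):
            cyclic_loess_normalize(_df(np.ones((3, 5))))


class TestRobNorm:
    def test_exact_shift_recovery(self):
        rng = np.random.default_rng(5)
        profile = rng.uniform(0, 3, 50)
        shifts = np.array([0.0, 0.3, -0.3])
        df = _df(10.0 ** (profile[None, :] + shifts[:, None]))
        _, effects = robnorm(df)
        rec = effects.to_numpy() - effects.to_numpy().mean()
        assert np.allclose(rec, shifts - shifts.mean(), atol=1e-6)

    def test_robust_to_sample_specific_spikes(self):
        rng = np.random.default_rng(6)
        profile = rng.uniform(0, 3, 100)
        shifts = np.array([0.0, 0.25, -0.25, 0.1, -0.1])
        log = profile[None, :] + shifts[:, None] + rng.normal(0, 0.02, (5, 100))
        # 10% of proteins get sample-specific spikes in one sample each
        for j in range(10):
            log[j % 5, j] += 1.5
        df = _df(10.0**log)
        _, effects = robnorm(df)
        rec = effects.to_numpy() - effects.mean()
        truth = shifts - shifts.mean()
        assert np.abs(rec - truth).max() < 0.01
        # plain column-median-style estimate is visibly worse than robust one
        naive = np.log10(df).mean(axis=1).to_numpy()
        naive -= naive.mean()
        assert np.abs(naive - truth).max() > np.abs(rec - truth).max()

    def test_gamma_zero_gives_ml_column_means(self):
        rng = np.random.default_rng(7)
        df = _df(10.0 ** rng.normal(1, 0.2, (6, 40)))
        model = RobNorm(density_power=0.0).fit(df)
        log = np.log10(df.to_numpy())
        # ML solution: sample effect = row mean of (x - protein means),
        # iterated to the two-way fixed point; check against closed form
        # for the balanced case: centered row means of centered data
        centered = log - log.mean(axis=0)
        expected = centered.mean(axis=1) - centered.mean(axis=1).mean()
        assert np.allclose(model.sample_effects_, expected, atol=1e-8)

    def test_needs_three_samples(self):
        with pytest.raises(NormalizationError, match=">= 3"):
            RobNorm().fit(_df(np.ones((2, 10))))


class TestComBat:
    def _batched(self, shift=0.3, n=8, p=40, seed=8):
        rng = np.random.default_rng(seed)
        log = rng.normal(1.5, 0.3, (2 * n, p))
        log[n:] += shift
        batches = pd.Series(
            ["B1"] * n + ["B2"] * n, index=[f"S{i}" for i in range(2 * n)]
        )
        return _df(10.0**log), batches

    def test_constant_shift_near_equalizes_batch_means(self):
        """A constant inter-batch shift is removed up to the second-order
        residual that empirical-Bayes shrinkage leaves behind (the reference
        sva implementation behaves identically)."""
        df, batches = self._batched()
        pre = np.log10(df)
        pre_diff = abs(
            pre[batches == "B1"].mean().mean() - pre[batches == "B2"].mean().mean()
        )
        out = np.log10(combat_adjust(df, batches))
        m1 = out[batches == "B1"].mean().mean()
        m2 = out[batches == "B2"].mean().mean()
        assert abs(m1 - m2) < 0.05 * pre_diff

    def test_single_batch_identity(self):
        df, batches = self._batched()
        out = combat_adjust(df, pd.Series("B1", index=df.index))
        assert np.allclose(out, df, rtol=1e-10)

    def test_batch_of_one_rejected(self):
        df, batches = self._batched()
        batches.iloc[-1] = "B3"
        with pytest.raises(NormalizationError, match="size < 2"):
            combat_adjust(df, batches)

    def test_matches_sva_reference(self, tmp_path):
        """Independent oracle: Bioconductor sva::ComBat on the same matrix."""
        df, batches = self._batched(shift=0.25, n=6, p=25, seed=9)
        log = np.log10(df)
        mat_path, batch_path, out_path = (
            tmp_path / "m.csv", tmp_path / "b.csv", tmp_path / "r.csv"
        )
        log.T.to_csv(mat_path)
        batches.rename("batch").to_csv(batch_path)
        script = tmp_path / "combat.R"
        script.write_text(
            "suppressMessages(library(sva))\n"
            f"m <- as.matrix(read.csv('{mat_path}', row.names=1, check.names=FALSE))\n"
            f"b <- read.csv('{batch_path}', row.names=1)[[1]]\n"
            "adj <- ComBat(dat=m, batch=b, par.prior=TRUE)\n"
            f"write.csv(adj, '{out_path}')\n"
        )
        subprocess.run(
            ["Rscript", str(script)], check=True, capture_output=True, text=True
        )
        ours = np.log10(combat_adjust(df, batches))
        ref = pd.read_csv(out_path, index_col=0).T
        ref.index = ours.index
        ref.columns = ours.columns
        assert np.abs(ours - ref).max().max() < 1e-6


class TestCvProfile:
    def _controls(self):
        rows, groups = [], []
        rng = np.random.default_rng(10)
        for g, mean in [("qc:QCA", 10.0), ("qc:QCB", 100.0)]:
            for r in range(3):
                rows.append([mean, 2 * mean])
                groups.append(g)
        df = _df(rows, prefix="C")
        return df, pd.Series(groups, index=df.index)

    def test_constant_replicates_zero_cv(self):
        df, groups = self._controls()
        prof = compute_cv_profile(df, groups)
        assert np.allclose(prof.mean_cv, 0.0)

    def test_two_point_cv(self):
        df = _df([[9.0], [11.0]], prefix="C")
        groups = pd.Series(["qc:QCA", "qc:QCA"], index=df.index)
        prof = compute_cv_profile(df, groups)
        assert np.isclose(prof.mean_cv.iloc[0], np.sqrt(2) / 10, rtol=1e-12)

    def test_small_group_skipped_with_warning(self):
        df, groups = self._controls()
        groups.iloc[0] = "qc:CLP"  # leaves CLP with a single replicate
        with pytest.warns(UserWarning, match="CLP"):
            prof = compute_cv_profile(df, groups)
        assert "qc:CLP" not in prof.per_group_cv.columns


class TestExcludeHighCv:
    def test_strict_threshold_boundary(self, default_config):
        prof = compute_cv_profile(
            _df([[10, 10, 10], [12.47, 13.06, 10.0]], prefix="C"),
            pd.Series(["g", "g"], index=["C0", "C1"]),
        )
        # engineer mean CVs just beside the boundary via direct profile edit
        prof.mean_cv = pd.Series({"P0": 0.199, "P1": 0.20, "P2": 0.30})
        retained = exclude_high_cv(prof, default_config)
        assert retained == ["P0"]

    def test_engineered_noisy_proteins_excluded(self, default_config):
        """Two proteins with 30% replicate CV are exactly the exclusions."""
        rng = np.random.default_rng(11)
        n_rep, cvs = 30, {}
        data = {}
        for j in range(10):
            cv = 0.30 if j < 2 else 0.05
            sigma = np.sqrt(np.log1p(cv**2))
            data[f"P{j}"] = 50.0 * np.exp(sigma * rng.standard_normal(3 * n_rep))
        df = pd.DataFrame(data, index=[f"C{i}" for i in range(3 * n_rep)])
        groups = pd.Series(
            ["qc:QCA"] * n_rep + ["qc:QCB"] * n_rep + ["qc:QCC"] * n_rep,
            index=df.index,
        )
        prof = compute_cv_profile(df, groups)
        retained = exclude_high_cv(prof, default_config)
        assert set(prof.mean_cv.index) - set(retained) == {"P0", "P1"}


class TestCompareMethods:
    def test_uniform_improvement_significant(self):
        rng = np.random.default_rng(12)
        base = pd.Series(rng.uniform(0.05, 0.15, 60), index=[f"P{i}" for i in range(60)])
        prof_a = compute_cv_profile(
            _df(np.ones((2, 60)) * [[1.0], [1.0]]), pd.Series(["g", "g"], index=["S0", "S1"])
        )
        prof_b = compute_cv_profile(
            _df(np.ones((2, 60))), pd.Series(["g", "g"], index=["S0", "S1"])
        )
        prof_a.mean_cv = base
        prof_b.mean_cv = base - 0.01
        prof_a.median_mean_cv = float(base.median())
        prof_b.median_mean_cv = float((base - 0.01).median())
        out = compare_methods({"A": prof_a, "B": prof_b})
        p = out.loc[(out.method_a == "B") & (out.method_b == "A"), "p_a_less_than_b"]
        assert float(p.iloc[0]) < 1e-3

    def test_identical_profiles_p_one(self):
        rng = np.random.default_rng(13)
        base = pd.Series(rng.uniform(0.05, 0.15, 20), index=[f"P{i}" for i in range(20)])
        profs = {}
        for name in ("A", "B"):
            prof = compute_cv_profile(
                _df(np.ones((2, 20))), pd.Series(["g", "g"], index=["S0", "S1"])
            )
            prof.mean_cv = base.copy()
            profs[name] = prof
        out = compare_methods(profs)
        assert (out["p_a_less_than_b"] == 1.0).all()

    def test_signed_rank_matches_exact_enumeration(self):
        """scipy's exact signed-rank p equals brute-force enumeration, n <= 10."""
        rng = np.random.default_rng(14)
        for n in (5, 8, 10):
            d = rng.normal(0.02, 0.05, n)
            ranks = stats.rankdata(np.abs(d))
            w_obs = ranks[d > 0].sum()  # positive-rank sum statistic
            count = 0
            for signs in itertools.product([0, 1], repeat=n):
                w = ranks[np.array(signs) == 1].sum()
                if w <= w_obs + 1e-12:
                    count += 1
            exact = count / 2**n
            p = stats.wilcoxon(d, alternative="less", method="exact").pvalue
            assert np.isclose(p, exact, rtol=1e-12)


class TestPca:
    def test_batch_shift_separates_then_combat_mixes(self):
        rng = np.random.default_rng(15)
        log = rng.normal(2, 0.1, (20, 30))
        log[10:] += 0.5
        df = _df(10.0**log)
        batches = pd.Series(["B1"] * 10 + ["B2"] * 10, index=df.index)
        before = pca_diagnostics(df, batches)
        assert before.separation_ratio > 2.0
        after = pca_diagnostics(combat_adjust(df, batches), batches)
        assert after.separation_ratio < 1.2

    def test_scores_match_eigendecomposition(self):
        rng = np.random.default_rng(16)
        df = _df(rng.uniform(1, 5, (5, 4)))
        labels = pd.Series(["a", "a", "a", "b", "b"], index=df.index)
        res = pca_diagnostics(df, labels)
        x = df.to_numpy()
        x = (x - x.mean(0)) / x.std(0)
        cov = np.cov(x, rowvar=False)
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        expected = x @ v[:, order]
        got = res.scores.to_numpy()
        for j in range(got.shape[1]):
            assert np.allclose(np.abs(got[:, j]), np.abs(expected[:, j]), atol=1e-8)
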