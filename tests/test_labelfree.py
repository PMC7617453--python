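"""Normalization, imputation, moderated t-test, BH, Zq standardization."""

import math
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import xenotrace as xt
from xenotrace.labelfree import _fit_prior, log2_with_missing, moderated_test


def _design(n=3):
    samples = [f"A{i}" for i in range(n)] + [f"B{i}" for i in range(n)]
    return pd.Series(["A"] * n + ["B"] * n, index=samples)


def _matrix(arr, n=3):
    arr = np.asarray(arr, float)
    return pd.DataFrame(arr, columns=_design(n).index)


class TestNormalize:
    def test_equal_totals_unchanged(self):
        m = pd.DataFrame({"s1": [1.0, 2.0], "s2": [2.0, 1.0]})
        pd.testing.assert_frame_equal(xt.normalize_counts(m), m)

    def test_closed_form_scale_factors(self):
        m = pd.DataFrame({"s1": [100.0], "s2": [300.0]})
        out = xt.normalize_counts(m)
        assert out.loc[0, "s1"] == pytest.approx(200.0)  # factor 2.0
        assert out.loc[0, "s2"] == pytest.approx(200.0)  # factor 2/3

    def test_column_totals_equal_after(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.poisson(20.0, size=(50, 6)).astype(float))
        totals = xt.normalize_counts(m).sum(axis=0)
        assert np.allclose(totals, totals.iloc[0])

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.poisson(20.0, size=(30, 4)).astype(float))
        once = xt.normalize_counts(m)
        pd.testing.assert_frame_equal(xt.normalize_counts(once), once)

    def test_zeros_preserved_and_all_zero_column_rejected(self):
        m = pd.DataFrame({"s1": [0.0, 10.0], "s2": [5.0, 5.0]})
        assert xt.normalize_counts(m).loc[0, "s1"] == 0.0
        with pytest.raises(ValueError, match="all-zero"):
            xt.normalize_counts(pd.DataFrame({"s1": [0.0], "s2": [1.0]}))


class TestImpute:
    def test_no_missing_is_identity(self):
        m = _matrix(np.arange(12.0).reshape(2, 6) + 1)
        pd.testing.assert_frame_equal(xt.impute_missing(m, seed=0), m)

    def test_seeded_determinism(self):
        m = _matrix(np.arange(24.0).reshape(4, 6) + 1)
        m.iloc[0, 0] = np.nan
        m.iloc[2, 3] = np.nan
        pd.testing.assert_frame_equal(xt.impute_missing(m, seed=5), xt.impute_missing(m, seed=5))

    def test_downshift_monte_carlo(self):
        rng = np.random.default_rng(7)
        obs = rng.normal(10.0, 2.0, size=400)
        col = np.concatenate([obs, np.full(4000, np.nan)])
        m = pd.DataFrame({"s": col})
        with pytest.raises(ValueError):
            xt.impute_missing(pd.DataFrame({"s": [1.0, np.nan, np.nan]}), seed=0)
        out = xt.impute_missing(m, shift=1.8, width=0.3, seed=11)
        imputed = out["s"].iloc[400:]
        mu, sd = obs.mean(), obs.std(ddof=1)
        assert imputed.mean() == pytest.approx(mu - 1.8 * sd, abs=0.05 * sd)
        assert imputed.std(ddof=1) == pytest.approx(0.3 * sd, rel=0.1)


class TestModeratedTest:
    def test_identical_groups_give_zero_log2fc(self):
        half = np.random.default_rng(0).normal(10, 1, size=(40, 3))
        m = _matrix(np.hstack([half, half]))
        res = moderated_test(m, _design(), ("A", "B"))
        assert np.allclose(res.table["log2fc"], 0.0)

    def test_contrast_sign_is_first_minus_second(self):
        m = _matrix(np.array([[10.0, 10, 10, 8, 8, 8]]) + np.random.default_rng(1).normal(0, .01, (1, 6)))
        res = moderated_test(m, _design(), ("A", "B"))
        assert res.table["log2fc"].iloc[0] == pytest.approx(2.0, abs=0.1)
        res_rev = moderated_test(m, _design(), ("B", "A"))
        assert res_rev.table["log2fc"].iloc[0] == pytest.approx(-2.0, abs=0.1)

    def test_unknown_group_rejected(self):
        m = _matrix(np.ones((3, 6)))
        with pytest.raises(ValueError, match="not in design"):
            moderated_test(m, _design(), ("A", "C"))

    def test_row_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        m = _matrix(rng.normal(8, 1, size=(60, 6)))
        res = moderated_test(m, _design(), ("A", "B")).table
        perm = rng.permutation(60)
        res_p = moderated_test(m.iloc[perm], _design(), ("A", "B")).table
        pd.testing.assert_frame_equal(res_p.sort_index(), res.sort_index())

    def test_limits_ordinary_t_and_pooled_z(self):
        """d0 -> 0 recovers the ordinary t; d0 -> inf the pooled-variance z."""
        rng = np.random.default_rng(4)
        x = rng.normal(10, 1, size=(50, 6))
        m = _matrix(x)
        res = moderated_test(m, _design(), ("A", "B"))
        d0, s02 = res.d0, res.s0_sq
        n1 = n2 = 3
        df = n1 + n2 - 2
        fc = x[:, :3].mean(1) - x[:, 3:].mean(1)
        s2 = (x[:, :3].var(1, ddof=1) * 2 + x[:, 3:].var(1, ddof=1) * 2) / df
        se = math.sqrt(1 / n1 + 1 / n2)
        # reconstruct the moderated t with d0 forced to the two limits
        t_ord = fc / (np.sqrt(s2) * se)
        t_lim0 = fc / (np.sqrt((0 * s02 + df * s2) / (0 + df)) * se)
        assert np.allclose(t_lim0, t_ord)
        t_then = fc / (np.sqrt((1e12 * s02 + df * s2) / (1e12 + df)) * se)
        t_z = fc / (math.sqrt(s02) * se)
        assert np.allclose(t_then, t_z, rtol=1e-4)
        # and the fitted moderated t lies between the two in shrinkage
        assert np.isfinite(d0) and d0 > 0

    def test_degenerate_prior_falls_back_to_ordinary_t(self):
        # identical residual variance everywhere -> log-variances underdispersed
        base = np.array([[1.0, 2, 3, 4, 5, 6]])
        m = _matrix(np.repeat(base, 30, axis=0) + np.arange(30)[:, None])
        res = moderated_test(m, _design(), ("A", "B"))
        # constant variances: either infinite-d0 full shrinkage or flagged fallback
        assert math.isinf(res.d0) or res.ordinary_fallback

    def test_bh_equals_brute_force(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=101)
        from statsmodels.stats.multitest import multipletests

        q = multipletests(p, method="fdr_bh")[1]
        # brute force: sorted p * n / rank with running minimum from the top
        order = np.argsort(p)
        n = len(p)
        adj = p[order] * n / (np.arange(n) + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        brute = np.empty(n)
        brute[order] = np.minimum(adj, 1.0)
        assert np.allclose(q, brute)

    def test_matches_limma_on_fixed_matrix(self, tmp_path):
        """Independent oracle: R/limma eBayes on the same small matrix."""
        rng = np.random.default_rng(12)
        x = rng.normal(10, 1, size=(80, 6))
        x[:8, 3:] += 1.5
        m = _matrix(x)
        res = moderated_test(m, _design(), ("B", "A"))
        csv = tmp_path / "m.csv"
        m.to_csv(csv)
        rscript = textwrap.dedent(
            """
            suppressMessages(library(limma))
            m <- as.matrix(read.csv(%r, row.names=1))
            design <- model.matrix(~ c(0,0,0,1,1,1))
            fit <- eBayes(lmFit(m, design))
            out <- data.frame(fc=fit$coefficients[,2], t=fit$t[,2],
                              p=fit$p.value[,2], d0=fit$df.prior, s02=fit$s2.prior)
            write.csv(out, %r)
            """
            % (str(csv), str(tmp_path / "out.csv"))
        )
        try:
            subprocess.run(["Rscript", "-e", rscript], check=True, capture_output=True,
                           timeout=120)
        except (FileNotFoundError, subprocess.CalledProcessError, subprocess.TimeoutExpired):
            pytest.skip("Rscript/limma not available")
        ref = pd.read_csv(tmp_path / "out.csv", index_col=0)
        assert np.allclose(res.table["log2fc"], ref["fc"], atol=1e-8)
        assert res.d0 == pytest.approx(float(ref["d0"].iloc[0]), rel=0.05)
        assert res.s0_sq == pytest.approx(float(ref["s02"].iloc[0]), rel=0.05)
        assert np.allclose(res.table["t"], ref["t"], rtol=0.02, atol=0.02)
        assert np.allclose(res.table["p"], ref["p"], rtol=0.05, atol=1e-4)


class TestWorkflow:
    def test_differential_enrichment_reports_imputation(self):
        counts, design, truth = xt.simulate_counts(xt.SimulationConfig(seed=3, n_proteins=300))
        res = xt.differential_enrichment(counts, design, ("B", "A"), seed=1)
        t = res.table
        assert {"log2fc", "p", "q", "zq", "imputed_fraction_B", "imputed_fraction_A"} <= set(t.columns)
        assert t["q"].between(0, 1).all()
        # q-values are monotone in p-value rank
        srt = t.sort_values("p")
        assert (np.diff(srt["q"]) >= -1e-12).all()

    def test_spiked_proteins_rank_first(self):
        cfg = xt.SimulationConfig(seed=9, n_proteins=400, effect_fraction=0.05)
        counts, design, truth = xt.simulate_counts(cfg)
        res = xt.differential_enrichment(counts, design, ("B", "A"), seed=2)
        top = res.table.nsmallest(10, "q").index
        assert (truth.loc[top, "true_log2fc"] > 0).mean() >= 0.8


class TestZq:
    def test_median_maps_to_zero(self):
        z = xt.zq_standardize(np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert z[2] == 0.0

    def test_symmetric_closed_form(self):
        z = xt.zq_standardize(np.array([-1.0, 0.0, 1.0]))
        assert np.allclose(z, [-1 / 1.4826, 0.0, 1 / 1.4826])

    def test_location_invariance(self):
        x = np.array([0.3, -1.2, 2.0, 0.9, -0.4])
        assert np.allclose(xt.zq_standardize(x + 7.5), xt.zq_standardize(x))

    def test_errors(self):
        with pytest.raises(ValueError, match="MAD"):
            xt.zq_standardize(np.array([1.0, 1.0, 1.0]))
        with pytest.raises(ValueError, match="at least 3"):
            xt.zq_standardize(np.array([1.0, 2.0]))
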