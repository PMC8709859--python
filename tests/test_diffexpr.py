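"""Linear-model fits, variance moderation, FDR, and DE calling."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from cernet import diffexpr
from cernet.synthetic import StudyConfig, blood_study_config, gen_expression_study

from conftest import make_study


def _noiseless_study(log2fc=0.8, n_per_group=5, n_genes=3):
    base = np.full((n_genes, 2 * n_per_group), 6.0)
    base[:, :n_per_group] += log2fc
    return make_study(
        base, conditions=["case"] * n_per_group + ["control"] * n_per_group
    )


class TestLinearFit:
    def test_noiseless_coefficient_exact(self):
        fit = diffexpr.fit_linear_models(_noiseless_study(log2fc=0.8))
        np.testing.assert_allclose(fit.coef.to_numpy(), 0.8)
        np.testing.assert_allclose(fit.s2.to_numpy(), 0.0, atol=1e-20)

    def test_condition_and_covariate_recovered_within_4se(self):
        # numeric covariate with slope 0.1 plus condition effect 2.0
        cfg = blood_study_config(
            seed=21, n_genes=1000, n_lncrnas=100, frac_de=0.2,
        )
        study, truth = gen_expression_study(cfg)
        fit = diffexpr.fit_linear_models(study.to_log2(), covariates=("age", "sex", "race"))
        se = np.sqrt(fit.s2) * fit.stdev_unscaled
        effects = truth.de_genes["LB"]
        assert len(effects) >= 200
        for gene, eff in effects.items():
            assert abs(fit.coef[gene] - eff) < 4 * se[gene]
        null_genes = fit.coef.index.difference(effects)
        cover = (np.abs(fit.coef[null_genes]) < 4 * se[null_genes]).mean()
        assert cover > 0.99

    def test_duplicated_covariate_is_rank_error(self):
        study = _noiseless_study()
        study.sample_meta["x1"] = np.arange(10.0)
        study.sample_meta["x2"] = np.arange(10.0)
        with pytest.raises(ValueError, match="x2"):
            diffexpr.fit_linear_models(study, covariates=("x1", "x2"))


class TestModeration:
    @pytest.fixture
    def noisy_fit(self, rng):
        mat = rng.normal(7.0, 1.0, size=(300, 16))
        study = make_study(mat, conditions=["case"] * 8 + ["control"] * 8)
        return diffexpr.fit_linear_models(study)

    def test_d0_zero_equals_ordinary_t(self, noisy_fit):
        params, table = diffexpr.moderate_and_test(noisy_fit, d0=0.0)
        se = np.sqrt(noisy_fit.s2) * noisy_fit.stdev_unscaled
        np.testing.assert_allclose(table["t"], noisy_fit.coef / se)
        np.testing.assert_allclose(params.s_tilde_sq, noisy_fit.s2)

    def test_d0_infinite_pools_all_variances(self, noisy_fit):
        params, _ = diffexpr.moderate_and_test(noisy_fit, d0=math.inf)
        assert params.s_tilde_sq.nunique() == 1
        assert params.s_tilde_sq.iloc[0] == pytest.approx(params.s0_sq)

    def test_posterior_variance_between_prior_and_sample(self, noisy_fit):
        params, _ = diffexpr.moderate_and_test(noisy_fit)
        assert 0 < params.d0 < math.inf
        lo = np.minimum(params.s_g_sq, params.s0_sq)
        hi = np.maximum(params.s_g_sq, params.s0_sq)
        assert ((params.s_tilde_sq >= lo - 1e-12) & (params.s_tilde_sq <= hi + 1e-12)).all()

    def test_prior_estimate_recovers_known_hyperparameters(self, rng):
        # residual variances drawn from the scaled chi^2 hierarchy
        d0_true, s0_true, df = 8.0, 0.25, 12
        var0 = s0_true * d0_true / rng.chisquare(d0_true, size=5000)
        s2 = var0 * rng.chisquare(df, size=5000) / df
        d0, s0 = diffexpr.estimate_prior(s2, df)
        assert d0 == pytest.approx(d0_true, rel=0.2)
        assert s0 == pytest.approx(s0_true, rel=0.05)

    def test_global_null_pvalues_uniform(self):
        study, _ = gen_expression_study(
            blood_study_config(seed=7, n_genes=1900, n_lncrnas=100, frac_de=0.0)
        )
        table = diffexpr.differential_expression(
            study.to_log2(), covariates=("age", "sex", "race")
        )
        ks = kstest(table["p"].to_numpy(), "uniform").statistic
        assert ks < 0.05

    def test_type_i_error_calibrated(self):
        # nominal per-test alpha=0.05 on global-null data, pooled over seeds
        rejections, total = 0, 0
        for seed in range(10):
            study, _ = gen_expression_study(
                StudyConfig(
                    groups_per_tissue={"LB": (15, 15)},
                    n_genes=1900, n_lncrnas=100, frac_de=0.0, seed=seed,
                )
            )
            fit = diffexpr.fit_linear_models(study.to_log2())
            _, table = diffexpr.moderate_and_test(fit)
            rejections += (table["p"] < 0.05).sum()
            total += len(table)
        assert 0.035 <= rejections / total <= 0.065


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            diffexpr.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(diffexpr.bh_adjust([0.2]), [0.2])

    def test_matches_independent_step_up_oracle(self, rng):
        def brute_bh(p):
            p = np.asarray(p)
            m = len(p)
            order = np.argsort(p)
            adj = np.empty(m)
            running_min = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running_min = min(running_min, p[i] * m / rank)
                adj[i] = running_min
            return adj

        for _ in range(5):
            p = rng.uniform(size=50)
            np.testing.assert_allclose(diffexpr.bh_adjust(p), brute_bh(p))

    def test_adjp_dominates_p_and_is_monotone(self, rng):
        p = rng.uniform(size=100)
        adj = diffexpr.bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            diffexpr.bh_adjust([0.5, 1.2])


class TestCalling:
    def _table(self, log2fc, adj_p):
        return pd.DataFrame(
            {"log2fc": log2fc, "t": 0.0, "p": adj_p, "adj_p": adj_p},
            index=[f"G{i}" for i in range(len(log2fc))],
        )

    def test_thresholds_strict_on_both_axes(self):
        table = diffexpr.call_degs(
            self._table([0.70, 0.69, -0.70, 0.70], [5e-4, 5e-4, 5e-4, 1e-3])
        )
        assert list(table["direction"]) == ["up", "ns", "down", "ns"]

    def test_global_null_yields_no_calls(self):
        study, _ = gen_expression_study(
            blood_study_config(seed=13, n_genes=1900, n_lncrnas=100, frac_de=0.0)
        )
        table = diffexpr.differential_expression(
            study.to_log2(), covariates=("age", "sex", "race")
        )
        assert (table["direction"] != "ns").sum() <= 1

    def test_power_on_planted_effects(self):
        study, truth = gen_expression_study(
            blood_study_config(seed=17, n_genes=1900, n_lncrnas=100, frac_de=0.1)
        )
        table = diffexpr.differential_expression(
            study.to_log2(), covariates=("age", "sex", "race"),
            lncrna_catalog=truth.lncrna_catalog,
        )
        planted = list(truth.de_genes["LB"])
        called = (table.loc[planted, "direction"] != "ns").mean()
        assert called >= 0.95


class TestClassesAndProbes:
    def test_partition_by_catalog_exact_case_sensitive(self):
        table = pd.DataFrame(index=["NEAT1", "VEGFA", "neat1"])
        out = diffexpr.partition_gene_classes(table, {"NEAT1", "XIST"})
        assert out.loc["NEAT1", "gene_class"] == "lncRNA"
        assert out.loc["VEGFA", "gene_class"] == "mRNA"
        assert out.loc["neat1", "gene_class"] == "mRNA"  # case mismatch

    def test_empty_catalog_all_mrna(self):
        out = diffexpr.partition_gene_classes(pd.DataFrame(index=["A", "B"]), set())
        assert (out["gene_class"] == "mRNA").all()

    def test_collapse_keeps_most_variable_probe_per_symbol(self, rng):
        mat = np.vstack([
            np.full(6, 5.0),                      # probe1 -> GA, IQR 0
            rng.normal(5, 2, 6),                  # probe2 -> GA, variable
            rng.normal(7, 1, 6),                  # probe3 -> GB
            rng.normal(3, 1, 6),                  # probe4 -> unmapped
        ])
        study = make_study(mat, genes=["p1", "p2", "p3", "p4"])
        collapsed = diffexpr.collapse_probes(
            study, {"p1": "GA", "p2": "GA", "p3": "GB", "p4": ""}
        )
        assert sorted(collapsed.matrix.index) == ["GA", "GB"]
        np.testing.assert_allclose(collapsed.matrix.loc["GA"], mat[1])
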