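"""Normalization, filtering, QC and batch-removal behavior."""

import numpy as np
import pandas as pd
import pytest

from cernet import preprocess
from cernet.synthetic import blood_study_config, gen_expression_study

from conftest import make_study


class TestQuantileNormalize:
    def test_hand_computed_two_columns(self):
        study = make_study(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]))
        out = preprocess.quantile_normalize(study)
        expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
        np.testing.assert_allclose(out.matrix.to_numpy(), expected)

    def test_permuted_columns_unchanged_as_multisets(self, rng):
        col = rng.normal(size=30)
        mat = np.column_stack([rng.permutation(col) for _ in range(4)])
        out = preprocess.quantile_normalize(make_study(mat))
        np.testing.assert_allclose(out.matrix.to_numpy(), mat)

    def test_idempotent_and_equal_medians(self, rng):
        mat = rng.normal(5, 2, size=(40, 6))
        once = preprocess.quantile_normalize(make_study(mat))
        twice = preprocess.quantile_normalize(once)
        np.testing.assert_allclose(once.matrix.to_numpy(), twice.matrix.to_numpy())
        medians = once.matrix.median(axis=0)
        assert medians.nunique() == 1

    def test_ties_receive_mean_reference_value(self):
        # column 0 has a three-way tie spanning the low reference values
        mat = np.array([[1.0, 10.0], [1.0, 20.0], [1.0, 30.0], [5.0, 40.0]])
        out = preprocess.quantile_normalize(make_study(mat))
        ref = np.sort(mat, axis=0).mean(axis=1)
        assert out.matrix.iloc[0, 0] == pytest.approx(ref[:3].mean())
        assert out.matrix.iloc[3, 0] == pytest.approx(ref[3])
        # tied values stay tied
        assert out.matrix.iloc[0, 0] == out.matrix.iloc[1, 0] == out.matrix.iloc[2, 0]


class TestIQRFilter:
    def test_hand_computed_median_cut(self):
        # per-gene IQRs 1, 2, 3, 4 -> median 2.5 -> two genes survive
        rows = [np.array([0.0, q / 3, 2 * q / 3, q]) for q in [2.0, 4.0, 6.0, 8.0]]
        study = make_study(np.array(rows))
        iqrs = preprocess.gene_iqr(study.matrix)
        np.testing.assert_allclose(sorted(iqrs), [1, 2, 3, 4])
        kept = preprocess.iqr_filter(study)
        assert kept == ["G2", "G3"]

    def test_all_constant_keeps_nothing(self):
        study = make_study(np.ones((5, 4)))
        assert preprocess.iqr_filter(study) == []

    def test_matches_independent_quartile_oracle(self, rng):
        mat = rng.normal(size=(20, 8))
        study = make_study(mat)
        kept = set(preprocess.iqr_filter(study))
        # brute-force oracle with an independent quantile routine
        iqrs = {}
        for i, g in enumerate(study.matrix.index):
            q1 = np.quantile(mat[i], 0.25, method="linear")
            q3 = np.quantile(mat[i], 0.75, method="linear")
            iqrs[g] = q3 - q1
        med = np.median(list(iqrs.values()))
        assert kept == {g for g, v in iqrs.items() if v > med}

    def test_requires_log2_scale(self):
        study = make_study(np.ones((3, 4)) + 1, scale="linear")
        with pytest.raises(ValueError, match="log2"):
            preprocess.iqr_filter(study)


class TestIntensityFilter:
    def test_boundary_quarter_of_arrays_inclusive(self):
        mat = np.full((1, 12), 50.0)
        mat[0, :3] = 150.0  # exactly 25% of arrays above signal
        study = make_study(mat, scale="linear")
        assert preprocess.intensity_filter(study) == ["G0"]

    def test_low_signal_gene_removed(self):
        study = make_study(np.full((2, 8), 1.0), scale="linear")
        assert preprocess.intensity_filter(study) == []

    def test_matches_brute_force_counting(self, rng):
        mat = rng.uniform(1, 500, size=(30, 12))
        study = make_study(mat, scale="linear")
        kept = set(preprocess.intensity_filter(study))
        oracle = {
            g for i, g in enumerate(study.matrix.index)
            if sum(v > 100 for v in mat[i]) / 12 >= 0.25
        }
        assert kept == oracle

    def test_invalid_fraction_rejected(self):
        study = make_study(np.ones((2, 4)), scale="linear")
        with pytest.raises(ValueError, match="min_frac"):
            preprocess.intensity_filter(study, min_frac=1.5)


class TestFilterComposition:
    def test_kept_set_independent_of_row_order(self, rng):
        cfg = blood_study_config(seed=9, n_genes=200, n_lncrnas=20)
        study, _ = gen_expression_study(cfg)

        def run(s):
            normed = preprocess.quantile_normalize(s.to_linear())
            expressed = preprocess.intensity_filter(normed)
            log2 = normed.subset_genes(expressed).to_log2()
            return set(preprocess.iqr_filter(log2))

        shuffled = study.subset_genes(rng.permutation(study.matrix.index))
        assert run(study) == run(shuffled)


class TestQC:
    def test_planted_outlier_is_the_only_flag(self):
        cfg = blood_study_config(
            seed=3, n_genes=800, n_lncrnas=50, outlier=("LB", "case", 10.0)
        )
        study, truth = gen_expression_study(cfg)
        report = preprocess.qc_report(study.to_log2())
        assert preprocess.flag_outliers(report) == [truth.outlier_sample]

    def test_homogeneous_study_unflagged(self):
        # no covariate/batch structure, fixed seed: clean data passes
        study, _ = gen_expression_study(
            blood_study_config(
                seed=0, n_genes=400, n_lncrnas=40, covariates=(), n_batches=1
            )
        )
        report = preprocess.qc_report(study.to_log2())
        assert preprocess.flag_outliers(report) == []

    def test_clean_default_study_rarely_flagged(self):
        # with covariates and batches present, across 20 seeds no study
        # loses more than 10% of its samples to the flag rule
        for seed in range(20):
            study, _ = gen_expression_study(
                blood_study_config(seed=seed, n_genes=300, n_lncrnas=30)
            )
            report = preprocess.qc_report(study.to_log2())
            assert len(preprocess.flag_outliers(report)) <= 0.1 * study.n_samples

    def test_correlation_unit_diagonal_and_pc_fractions(self, rng):
        study = make_study(rng.normal(8, 1, size=(60, 12)))
        report = preprocess.qc_report(study)
        np.testing.assert_allclose(np.diag(report.correlation), 1.0)
        assert np.allclose(report.correlation, report.correlation.T)
        assert all(0 <= f <= 1 for f in report.variance_fractions)
        assert report.cluster_labels.isin([1, 2]).all()

    def test_constant_matrix_is_degenerate(self):
        with pytest.raises(ValueError, match="constant"):
            preprocess.qc_report(make_study(np.ones((5, 6))))


class TestBatchRemoval:
    def _noiseless_study(self, delta=1.0):
        # 2 genes, 8 samples; condition effect 0.5 on gene 0; batch shift delta
        base = np.array([[5.0] * 8, [7.0] * 8])
        cond = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        batch = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        mat = base + 0.5 * cond * np.array([[1.0], [0.0]]) + delta * batch
        return make_study(
            mat,
            conditions=["case"] * 4 + ["control"] * 4,
            batch=[f"b{b}" for b in batch],
        )

    def test_planted_batch_shift_removed_condition_preserved(self):
        study = self._noiseless_study(delta=1.0)
        out = preprocess.remove_batch_effect(study)
        meta = out.sample_meta
        in_b1 = meta["batch"] == "b1"
        batch_diff = out.matrix.loc[:, in_b1.values].mean(axis=1) - out.matrix.loc[
            :, (~in_b1).values
        ].mean(axis=1)
        assert np.abs(batch_diff).max() < 1e-8
        case = meta["condition"] == "case"
        cond_diff = (
            out.matrix.loc["G0", case.values].mean()
            - out.matrix.loc["G0", (~case).values].mean()
        )
        assert cond_diff == pytest.approx(0.5, abs=1e-8)

    def test_single_batch_is_identity(self):
        study = make_study(np.arange(12.0).reshape(3, 4), batch=["b0"] * 4)
        out = preprocess.remove_batch_effect(study)
        np.testing.assert_allclose(out.matrix.to_numpy(), study.matrix.to_numpy())

    def test_identical_batches_change_nothing(self):
        study = self._noiseless_study(delta=0.0)
        out = preprocess.remove_batch_effect(study)
        np.testing.assert_allclose(
            out.matrix.to_numpy(), study.matrix.to_numpy(), atol=1e-10
        )

    def test_confounded_batch_raises(self):
        study = make_study(
            np.ones((2, 6)) + np.arange(6),
            conditions=["case"] * 3 + ["control"] * 3,
            batch=["b0"] * 3 + ["b1"] * 3,
        )
        with pytest.raises(ValueError, match="confounded"):
            preprocess.remove_batch_effect(study)
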