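import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import proteosubtype as pst
from proteosubtype.normalize import bh_adjust, tmm_factors

from .conftest import two_plex_samples
from .oracles import bh_stepup, naive_knn_impute, naive_tmm_factors


def _matrix(values, scale="raw_intensity", kind="protein", prefix="F"):
    arr = np.asarray(values, dtype=float)
    df = pd.DataFrame(arr, index=[f"{prefix}{i}" for i in range(arr.shape[0])],
                      columns=[f"s{j}" for j in range(arr.shape[1])])
    return pst.OmicsMatrix(df, scale, kind)


class TestFilterMissing:
    def test_strictly_below_threshold_dropped(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(1, 10, size=(3, 100))
        X[0, 29:] = np.nan  # 29/100 valid -> dropped
        X[1, 30:] = np.nan  # 30/100 valid -> kept (boundary of the rule)
        m = pst.filter_missing(_matrix(X), 0.30)
        assert m.feature_ids == ["F1", "F2"]

    def test_fully_observed_unchanged(self, toy_matrix):
        out = pst.filter_missing(toy_matrix.to_raw(), 0.30)
        pd.testing.assert_frame_equal(out.data, toy_matrix.to_raw().data)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_invalid_threshold(self, toy_matrix, bad):
        with pytest.raises(ValueError):
            pst.filter_missing(toy_matrix, bad)


class TestKnnImpute:
    def test_complete_matrix_identity(self, toy_matrix):
        out = pst.knn_impute(toy_matrix, k=2)
        pd.testing.assert_frame_equal(out.data, toy_matrix.data)

    def test_k1_copies_nearest_feature(self):
        X = np.array([[1.0, 2.0, np.nan],
                      [1.0, 2.0, 5.0],
                      [9.0, 9.0, 9.0]])
        out = pst.knn_impute(_matrix(X, scale="log2"), k=1)
        assert out.data.loc["F0", "s2"] == 5.0

    def test_observed_values_never_altered(self):
        rng = np.random.default_rng(3)
        X = rng.normal(10, 2, size=(20, 8))
        mask = rng.random(X.shape) < 0.2
        mask[:, 0] = False
        Xm = np.where(mask, np.nan, X)
        out = pst.knn_impute(_matrix(Xm, scale="log2"), k=3)
        obs = ~np.isnan(Xm)
        assert np.array_equal(out.data.to_numpy()[obs], Xm[obs])
        assert not out.data.isna().any().any()

    def test_matches_exhaustive_search_on_toy(self):
        rng = np.random.default_rng(7)
        X = rng.normal(8, 1, size=(6, 4))
        X[0, 1] = X[2, 3] = X[4, 0] = np.nan
        out = pst.knn_impute(_matrix(X, scale="log2"), k=2)
        expected = naive_knn_impute(X, k=2)
        np.testing.assert_allclose(out.data.to_numpy(), expected, rtol=1e-12)

    def test_all_missing_feature_rejected(self):
        X = np.array([[np.nan, np.nan], [1.0, 2.0]])
        with pytest.raises(ValueError, match="zero observed"):
            pst.knn_impute(_matrix(X, scale="log2"), k=1)


class TestSampleLoading:
    def test_equal_sums_unchanged(self):
        X = np.array([[1.0, 2.0], [3.0, 2.0]])  # both columns sum to 4
        out = pst.sample_loading_normalize(_matrix(X))
        np.testing.assert_allclose(out.data.to_numpy(), X)

    def test_factor_arithmetic(self):
        X = np.array([[100.0, 300.0]])
        out = pst.sample_loading_normalize(_matrix(X))
        np.testing.assert_allclose(out.data.to_numpy(), [[200.0, 200.0]])

    def test_column_sums_equalized(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(1, 100, size=(50, 6))
        out = pst.sample_loading_normalize(_matrix(X))
        sums = out.data.sum(axis=0)
        assert (sums.max() - sums.min()) / sums.mean() < 1e-9

    def test_zero_column_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            pst.sample_loading_normalize(_matrix(np.array([[0.0, 1.0]])))


def _named_matrix(values, columns, scale="raw_intensity"):
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    df = pd.DataFrame(arr, index=[f"F{i}" for i in range(arr.shape[0])],
                      columns=columns)
    return pst.OmicsMatrix(df, scale, "protein")


TWO_PLEX_META = pd.DataFrame({
    "sample_id": ["a1", "refA", "b1", "refB"],
    "plex_id": ["A", "A", "B", "B"],
    "is_pooled_reference": [False, True, False, True]})


class TestIrs:
    def test_single_plex_identity(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(10, 100, size=(5, 4))
        ids = ["s0", "s1", "s2", "REF0"]
        m = _named_matrix(X, ids)
        out = pst.irs_correct(m, two_plex_samples(ids, per_plex=4))
        np.testing.assert_allclose(out.data.to_numpy(), X, rtol=1e-12)

    def test_reference_means_equalized_at_geometric_mean(self):
        # feature with reference means 100 (plex A) and 200 (plex B)
        m = _named_matrix([50.0, 100.0, 80.0, 200.0], TWO_PLEX_META["sample_id"])
        out = pst.irs_correct(m, pst.SampleTable(TWO_PLEX_META))
        g = np.sqrt(100.0 * 200.0)
        np.testing.assert_allclose(out.data.to_numpy(),
                                   [[50 * g / 100, g, 80 * g / 200, g]], rtol=1e-12)
        assert np.isclose(out.data.iloc[0, 1], out.data.iloc[0, 3])

    def test_feature_without_plex_reference_becomes_missing(self):
        m = _named_matrix([50.0, 100.0, 80.0, np.nan], TWO_PLEX_META["sample_id"])
        out = pst.irs_correct(m, pst.SampleTable(TWO_PLEX_META))
        assert np.isnan(out.data.loc["F0", "b1"])
        assert not np.isnan(out.data.loc["F0", "a1"])

    def test_batch_variance_removed_on_synthetic_cohort(self):
        cfg = pst.SimulationConfig(
            n_samples=30, samples_per_plex=11, n_proteins=500, n_phosphosites=500,
            n_mrna=400, batch_effect_sd=0.5, missing_rate=0.0, seed=5)
        cohort = pst.simulate_cohort(cfg)
        m = cohort.protein
        refs = cohort.samples.reference_samples()
        sl = pst.sample_loading_normalize(m)
        out = pst.irs_correct(sl, cohort.samples)
        def between_plex_var(mat):
            ref_log = np.log2(mat.data[refs].to_numpy())
            return np.nanvar(ref_log, axis=1).mean()
        assert between_plex_var(out) < 0.01 * between_plex_var(sl)


class TestTmm:
    def test_identical_columns_unit_factors(self):
        X = np.tile(np.linspace(1, 50, 30)[:, None], (1, 4))
        f = tmm_factors(_matrix(X))
        np.testing.assert_allclose(f.to_numpy(), 1.0, rtol=1e-12)

    def test_constant_m_closed_form(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(5, 50, size=200)
        X = np.column_stack([a, 2 * a])  # column B = 2 x column A exactly
        f = tmm_factors(_matrix(X))
        assert abs(f.iloc[1] / f.iloc[0] - 2.0) < 1e-9

    def test_matches_independent_reimplementation(self):
        rng = np.random.default_rng(8)
        X = rng.lognormal(3, 1, size=(500, 8))
        f = tmm_factors(_matrix(X))
        np.testing.assert_allclose(f.to_numpy(), naive_tmm_factors(X), rtol=1e-10)

    def test_idempotent_with_fixed_reference(self):
        rng = np.random.default_rng(9)
        X = rng.lognormal(3, 1, size=(300, 5))
        m = _matrix(X)
        sums = m.data.sum(axis=0)
        ref = (sums - sums.mean()).abs().idxmin()
        normed, _ = pst.tmm_normalize(m)
        f2 = tmm_factors(normed, ref_col=ref)
        np.testing.assert_allclose(f2.to_numpy(), 1.0, atol=1e-9)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            tmm_factors(_matrix(np.array([[0.0, 1.0], [1.0, 1.0]])))


class TestDifferentialAbundance:
    def test_identical_groups_null(self):
        X = np.tile(np.array([[3.0], [5.0]]), (1, 8))
        m = _matrix(X, scale="log2")
        res = pst.differential_abundance(m, [f"s{i}" for i in range(4)],
                                         [f"s{i}" for i in range(4, 8)])
        assert (res["log2FC"] == 0).all()
        assert (res["p"] == 1.0).all()

    def test_bh_arithmetic(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.01, 0.02, 0.04])),
                                   [0.03, 0.03, 0.04])

    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_bh_matches_stepup_recursion(self, pvals):
        np.testing.assert_allclose(bh_adjust(np.array(pvals)), bh_stepup(pvals),
                                   rtol=1e-12)

    def test_power_and_type_i_calibration(self):
        rng = np.random.default_rng(12)
        n_feat, shifted = 1000, 100
        X = rng.normal(0, 1, size=(n_feat, 40))
        X[:shifted, 20:] += 2.0  # 2 pooled SDs
        m = _matrix(X, scale="log2")
        res = pst.differential_abundance(m, [f"s{i}" for i in range(20)],
                                         [f"s{i}" for i in range(20, 40)])
        power = (res["q"][:shifted] < 0.05).mean()
        type_i = (res["p"][shifted:] < 0.05).mean()
        assert power >= 0.95
        assert abs(type_i - 0.05) <= 0.02

    def test_small_group_rejected(self, toy_matrix):
        with pytest.raises(ValueError, match=">= 2"):
            pst.differential_abundance(toy_matrix, ["s1"], ["s2", "s3"])


class TestChain:
    def test_scale_transforms_idempotent(self):
        rng = np.random.default_rng(21)
        X = rng.lognormal(4, 1, size=(100, 6))
        sl1 = pst.sample_loading_normalize(_matrix(X))
        sl2 = pst.sample_loading_normalize(sl1)
        np.testing.assert_allclose(sl1.data.to_numpy(), sl2.data.to_numpy(), rtol=1e-12)

    def test_full_chain_counts_monotone(self, small_cohort):
        normed, report = pst.normalize_pipeline(small_cohort.protein,
                                                small_cohort.samples)
        counts = [s["n_features"] for s in report.stages]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert normed.scale_tag == "log2"
        assert normed.n_missing == 0
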