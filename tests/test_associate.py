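import numpy as np
import pandas as pd
import pytest

import proteosubtype as pst
from proteosubtype.associate import (alteration_frequencies, cis_trans_map,
                                     cooccurrence_fisher, fit_subtype_classifier,
                                     km_logrank, predict_subtypes,
                                     select_transfer_features)
from proteosubtype.io import AlterationMatrix

from .oracles import fisher_two_sided


def omics(arr, index=None, columns=None, scale="log2", kind="mrna"):
    arr = np.asarray(arr, dtype=float)
    df = pd.DataFrame(arr,
                      index=index or [f"g{i}" for i in range(arr.shape[0])],
                      columns=columns or [f"s{j}" for j in range(arr.shape[1])])
    return pst.OmicsMatrix(df, scale, kind)


class TestCisTrans:
    def test_monotone_cis_effect_detected(self):
        rng = np.random.default_rng(0)
        cn = rng.integers(0, 5, size=(3, 20)).astype(float)
        expr = np.exp(cn) + 0.0  # strictly monotone in CN
        cna = omics(cn, kind="cna_gene", scale="raw_intensity")
        mrna = omics(expr)
        records, summary = cis_trans_map(cna, mrna=mrna, fdr=0.1)
        cis = records[records["is_cis"]]
        assert (cis["rho"] > 0.99).all()
        assert summary["n_cis_mrna"] == 3

    def test_spearman_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        cn = rng.normal(0, 1, size=(2, 15))
        expr = cn + rng.normal(0, 0.5, size=cn.shape)
        a, _ = cis_trans_map(omics(cn, kind="cna_gene", scale="log2"),
                             mrna=omics(expr))
        b, _ = cis_trans_map(omics(cn, kind="cna_gene", scale="log2"),
                             mrna=omics(np.exp(expr)))
        np.testing.assert_allclose(a["rho"], b["rho"], rtol=1e-12)

    def test_too_few_shared_samples_rejected(self):
        cna = omics(np.ones((2, 5)), kind="cna_gene", scale="raw_intensity")
        with pytest.raises(ValueError, match=">= 10"):
            cis_trans_map(cna, mrna=omics(np.ones((2, 5))))

    def test_null_false_discovery_controlled(self):
        rng = np.random.default_rng(2)
        n_genes, n_samp = 1000, 40
        cn = rng.integers(0, 5, size=(n_genes, n_samp)).astype(float)
        expr = rng.normal(0, 1, size=(n_genes, n_samp))  # independent of CN
        records, summary = cis_trans_map(
            omics(cn, kind="cna_gene", scale="raw_intensity"),
            mrna=omics(expr), fdr=0.1)
        assert summary["n_cis_mrna"] / n_genes <= 0.15

    def test_planted_cis_recovered(self, small_cohort):
        c = small_cohort
        records, summary = cis_trans_map(c.cna, mrna=c.mrna, fdr=0.1)
        cis_hits = set(records[(records["is_cis"]) & (records["level"] == "mrna")
                               & (records["q"] < 0.1)]["cna_gene"])
        recovered = len(cis_hits & set(c.truth.cis_genes)) / len(c.truth.cis_genes)
        assert recovered >= 0.9


class TestAlterations:
    def alts(self):
        calls = pd.DataFrame("none", index=["G1", "G2", "G3"],
                             columns=[f"s{i}" for i in range(3)])
        calls.loc["G1", ["s0", "s1"]] = "mutation"
        return AlterationMatrix(calls)

    def test_frequency_arithmetic(self):
        freq = alteration_frequencies(self.alts())
        assert freq.loc["G1", "frequency"] == pytest.approx(2 / 3)
        assert freq.loc["G2", "frequency"] == 0.0
        assert list(freq.index)[0] == "G1"  # sorted descending

    def test_fisher_examples(self):
        calls = pd.DataFrame("none", index=["A", "B"],
                             columns=[f"s{i}" for i in range(10)])
        calls.loc["A", [f"s{i}" for i in range(5)]] = "amplification"
        calls.loc["B", [f"s{i}" for i in range(5)]] = "loh"
        table, odds, p = cooccurrence_fisher(AlterationMatrix(calls), "A", "B")
        assert p == pytest.approx(2 / 252, rel=1e-9)
        calls.loc["B"] = "none"
        calls.loc["B", [f"s{i}" for i in [0, 1, 5, 6]]] = "loh"
        _, _, p2 = cooccurrence_fisher(AlterationMatrix(calls), "A", "B")
        assert p2 == pytest.approx(1.0)

    def test_fisher_matches_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(4, 21))
            a = rng.random(n) < 0.5
            b = rng.random(n) < 0.5
            calls = pd.DataFrame("none", index=["A", "B"],
                                 columns=[f"s{i}" for i in range(n)])
            calls.loc["A", a] = "mutation"
            calls.loc["B", b] = "mutation"
            table, _, p = cooccurrence_fisher(AlterationMatrix(calls), "A", "B")
            assert p == pytest.approx(fisher_two_sided(table), rel=1e-6)

    def test_fisher_symmetry(self):
        am = self.alts()
        _, _, p_ab = cooccurrence_fisher(am, "G1", "G2")
        _, _, p_ba = cooccurrence_fisher(am, "G2", "G1")
        assert p_ab == p_ba

    def test_absent_gene_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            cooccurrence_fisher(self.alts(), "G1", "NOPE")


class TestTransfer:
    def separable_data(self, n_per_class=10, seed=0):
        rng = np.random.default_rng(seed)
        n = 3 * n_per_class
        labels = pd.Series(["A", "B", "C"] * n_per_class,
                           index=[f"s{i}" for i in range(n)])
        X = rng.normal(0, 0.3, size=(50, n))
        for k, cls in enumerate(["A", "B", "C"]):
            members = np.flatnonzero((labels == cls).to_numpy())
            X[k * 5:(k + 1) * 5, members] += 4.0
        return omics(X), labels

    def test_planted_features_selected_nulls_excluded(self):
        expr, labels = self.separable_data()
        feats = select_transfer_features(expr, labels, fdr=0.01, min_abs_fc=2)
        planted = {f"g{i}" for i in range(15)}
        assert planted <= set(feats)
        nulls = set(expr.feature_ids) - planted
        assert len(set(feats) & nulls) / len(nulls) <= 0.05

    def test_vacuous_thresholds_return_everything(self):
        expr, labels = self.separable_data(seed=1)
        feats = select_transfer_features(expr, labels, fdr=1.0, min_abs_fc=1.0)
        # a feature is excluded only if its log2FC is exactly 0 in every contrast
        assert len(feats) == len(expr.feature_ids)

    def test_identical_classes_select_nothing(self):
        rng = np.random.default_rng(2)
        X = np.tile(rng.normal(0, 1, size=(20, 1)), (1, 12))
        labels = pd.Series(["A", "B", "C"] * 4,
                           index=[f"s{i}" for i in range(12)])
        assert select_transfer_features(omics(X), labels) == []

    def test_separable_classifier_perfect_f1(self):
        expr, labels = self.separable_data(n_per_class=12, seed=3)
        feats = select_transfer_features(expr, labels)
        model, per_class, macro = fit_subtype_classifier(expr, labels, feats, seed=0)
        assert macro == 1.0
        assert (per_class == 1.0).all()

    def test_same_seed_same_scores(self):
        expr, labels = self.separable_data(n_per_class=8, seed=4)
        feats = select_transfer_features(expr, labels)
        _, _, m1 = fit_subtype_classifier(expr, labels, feats, seed=7)
        _, _, m2 = fit_subtype_classifier(expr, labels, feats, seed=7)
        assert m1 == m2

    def test_null_labels_near_chance(self):
        rng = np.random.default_rng(5)
        scores = []
        for seed in range(10):
            X = rng.normal(0, 1, size=(30, 36))
            labels = pd.Series((["A", "B", "C"] * 12)[:36],
                               index=[f"s{i}" for i in range(36)])
            expr = omics(X)
            from sklearn.ensemble import RandomForestClassifier
            _, _, macro = fit_subtype_classifier(
                expr, labels, expr.feature_ids, seed=seed, n_folds=3,
                model=RandomForestClassifier(n_estimators=100, random_state=seed))
            scores.append(macro)
        assert abs(np.mean(scores) - 1 / 3) <= 0.15

    def test_prediction_uses_only_selected_features(self):
        expr, labels = self.separable_data(n_per_class=10, seed=6)
        feats = select_transfer_features(expr, labels)
        model, _, _ = fit_subtype_classifier(expr, labels, feats, seed=1)
        pred_full = predict_subtypes(model, expr)
        # corrupt every non-selected feature: predictions must not move
        corrupted = expr.data.copy()
        others = [f for f in expr.feature_ids if f not in feats]
        corrupted.loc[others] = 99.0
        pred_corrupted = predict_subtypes(
            model, pst.OmicsMatrix(corrupted, "log2", "mrna"))
        pd.testing.assert_series_equal(pred_full, pred_corrupted)


class TestSurvival:
    def samples_from(self, times, events, groups):
        n = len(times)
        df = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)],
                           "os_time": times, "os_event": events})
        return (pst.SampleTable(df),
                pd.Series(groups, index=[f"s{i}" for i in range(n)]))

    def test_identical_groups_zero_chi2(self):
        times = [1, 2, 3, 4, 5, 1, 2, 3, 4, 5]
        events = [1, 1, 0, 1, 1] * 2
        samples, groups = self.samples_from(times, events, ["a"] * 5 + ["b"] * 5)
        _, chi2, p = km_logrank(samples, groups, "os")
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_product_limit_hand_computation(self):
        # times 1, 2, 3+, 4, 5 (censor at 3): S(4) = (4/5)(3/4)(1/2)
        times = [1, 2, 3, 4, 5] + [10] * 3
        events = [1, 1, 0, 1, 1] + [1] * 3
        samples, groups = self.samples_from(times, events, ["a"] * 5 + ["b"] * 3)
        curves, _, _ = km_logrank(samples, groups, "os")
        surv = curves["a"]
        s_at_4 = surv.loc[4.0].iloc[0]
        assert s_at_4 == pytest.approx((4 / 5) * (3 / 4) * (1 / 2), rel=1e-9)

    def test_hazard_ratio_power(self):
        detected = 0
        n_sim = 60
        for seed in range(n_sim):
            rng = np.random.default_rng(seed)
            t_a = rng.exponential(1.0, 50)
            t_b = rng.exponential(3.0, 50)
            cens = rng.uniform(0, 8, 100)
            times = np.concatenate([t_a, t_b])
            events = (times <= cens).astype(int)
            times = np.minimum(times, cens)
            samples, groups = self.samples_from(times, events,
                                                ["a"] * 50 + ["b"] * 50)
            _, _, p = km_logrank(samples, groups, "os")
            detected += p < 0.05
        assert detected / n_sim >= 0.8

    def test_single_group_rejected(self):
        samples, groups = self.samples_from([1, 2, 3], [1, 1, 1], ["a"] * 3)
        with pytest.raises(ValueError, match="2 groups"):
            km_logrank(samples, groups, "os")

    def test_subtype_stratification_on_cohort(self, small_cohort):
        c = small_cohort
        _, chi2, p = km_logrank(c.samples, c.truth.true_labels, "os")
        assert chi2 > 0
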