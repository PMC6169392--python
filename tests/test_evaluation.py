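"""ROC/AUC machinery, stratified bootstrap, call-matrix analyses, clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import codonlrt as clt
from codonlrt import evaluation


def pair_counting_auc(scores, labels):
    """Mann-Whitney oracle: (#concordant + 0.5 #tied) / (n_pos * n_neg)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos, neg = scores[labels], scores[~labels]
    conc = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return conc / (len(pos) * len(neg))


class TestRocCurve:
    def test_perfect_separation(self):
        curve = clt.roc_curve([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert curve.auc == 1.0

    def test_all_ties_give_half(self):
        curve = clt.roc_curve([0.5] * 10, [1] * 5 + [0] * 5)
        assert curve.auc == pytest.approx(0.5)

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n_pos, n_neg = 5, 7
            scores = rng.integers(0, 6, n_pos + n_neg).astype(float)  # ties likely
            labels = np.array([1] * n_pos + [0] * n_neg)
            curve = clt.roc_curve(scores, labels)
            assert curve.auc == pytest.approx(pair_counting_auc(scores, labels), abs=1e-12)

    def test_orientation_flip(self):
        scores = [0.1, 0.2, 0.9, 0.8]
        labels = [1, 1, 0, 0]
        assert clt.roc_curve(scores, labels, higher_is_deleterious=False).auc == 1.0

    def test_sensitivity_specificity_monotone(self):
        rng = np.random.default_rng(1)
        curve = clt.roc_curve(rng.standard_normal(60), rng.integers(0, 2, 60))
        assert (np.diff(curve.sensitivity) >= -1e-12).all()
        assert (np.diff(curve.specificity) <= 1e-12).all()

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            clt.roc_curve([0.4, 0.5], [1, 1])

    @given(st.integers(min_value=1, max_value=8))
    def test_auc_invariant_to_monotone_transform(self, k):
        rng = np.random.default_rng(k)
        scores = rng.standard_normal(40)
        labels = np.array([1] * 20 + [0] * 20)
        a = clt.roc_curve(scores, labels).auc
        b = clt.roc_curve(np.exp(k * scores), labels).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_rank_auc_equals_curve_auc(self):
        rng = np.random.default_rng(9)
        scores = rng.integers(0, 4, 50).astype(float)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        assert evaluation.rank_auc(scores, labels) == pytest.approx(
            clt.roc_curve(scores, labels).auc, abs=1e-12
        )


class TestThresholdAtSpecificity:
    def test_discrete_specificity_excludes_all_negatives(self):
        # 10 distinct-score negatives: 9/10 = 0.90 < 0.95, so the threshold
        # must exclude every negative
        negatives = np.linspace(0, 0.9, 10)
        positives = np.array([0.95, 0.99])
        scores = np.concatenate([positives, negatives])
        labels = np.array([1] * 2 + [0] * 10)
        curve = clt.roc_curve(scores, labels)
        thr = clt.threshold_at_specificity(curve, 0.95)
        calls = clt.calls_at_threshold(negatives, thr.threshold)
        assert calls.sum() == 0
        assert thr.specificity == 1.0

    def test_target_zero_is_most_permissive(self):
        curve = clt.roc_curve([0.9, 0.1, 0.5, 0.4], [1, 0, 1, 0])
        thr = clt.threshold_at_specificity(curve, 0.0)
        assert thr.sensitivity == 1.0

    def test_calls_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.standard_normal(50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        c1 = clt.threshold_at_specificity(clt.roc_curve(scores, labels))
        calls1 = clt.calls_at_threshold(scores, c1.threshold)
        t = np.exp(scores)  # strictly increasing
        c2 = clt.threshold_at_specificity(clt.roc_curve(t, labels))
        calls2 = clt.calls_at_threshold(t, c2.threshold)
        np.testing.assert_array_equal(calls1, calls2)


class TestBootstrap:
    def test_perfect_separation_interval_is_degenerate(self):
        scores = np.array([1.0, 0.9, 0.8, 0.1, 0.2, 0.3])
        labels = np.array([1, 1, 1, 0, 0, 0])
        lo, hi = clt.bootstrap_auc_ci(scores, labels, n_reps=100, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_replicates_preserve_class_counts(self, monkeypatch):
        from codonlrt.evaluation import _stratified_resample_auc
        from scipy.stats import rankdata

        seen = []
        rng = np.random.default_rng(0)
        scores = np.concatenate([rng.normal(1, 1, 13), rng.normal(0, 1, 29)])
        labels = np.array([1] * 13 + [0] * 29)

        orig = rankdata

        def spy(arr, *a, **k):
            seen.append(len(arr))
            return orig(arr, *a, **k)

        monkeypatch.setattr(evaluation, "rankdata", spy)
        clt.bootstrap_auc_ci(scores, labels, n_reps=50, seed=1)
        # every replicate ranks exactly n_pos + n_neg resampled scores
        assert set(seen) == {42}

    def test_reproducible(self):
        rng = np.random.default_rng(4)
        scores = rng.standard_normal(60)
        labels = np.array([1] * 30 + [0] * 30)
        assert clt.bootstrap_auc_ci(scores, labels, 200, seed=9) == clt.bootstrap_auc_ci(
            scores, labels, 200, seed=9
        )

    def test_interval_contains_point_estimate_typically(self):
        rng = np.random.default_rng(5)
        scores = np.concatenate([rng.normal(1.2, 1, 150), rng.normal(0, 1, 150)])
        labels = np.array([1] * 150 + [0] * 150)
        auc = evaluation.rank_auc(scores, labels)
        lo, hi = clt.bootstrap_auc_ci(scores, labels, n_reps=500, seed=2)
        assert lo <= auc <= hi


class TestAucDifference:
    def test_identical_scores_give_zero_delta(self):
        rng = np.random.default_rng(0)
        scores = rng.standard_normal(60)
        labels = np.array([1] * 30 + [0] * 30)
        delta, (lo, hi) = clt.auc_difference_test(scores, scores, labels, n_reps=100, seed=0)
        assert delta == 0.0 and lo == 0.0 and hi == 0.0

    def test_antisymmetric(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(80)
        b = rng.standard_normal(80)
        labels = np.array([1] * 40 + [0] * 40)
        d_ab, _ = clt.auc_difference_test(a, b, labels, n_reps=50, seed=3)
        d_ba, _ = clt.auc_difference_test(b, a, labels, n_reps=50, seed=3)
        assert d_ab == pytest.approx(-d_ba, abs=1e-12)

    def test_separating_vs_random_excludes_zero(self):
        rng = np.random.default_rng(2)
        labels = np.array([1] * 200 + [0] * 200)
        good = labels + rng.normal(0, 0.05, 400)
        noise = rng.standard_normal(400)
        delta, (lo, hi) = clt.auc_difference_test(good, noise, labels, n_reps=500, seed=1)
        assert lo > 0

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            clt.auc_difference_test([1, 2], [1, 2, 3], [0, 1], n_reps=10)


class TestCallMatrixAnalyses:
    @pytest.fixture
    def toy_calls(self):
        frame = pd.DataFrame(
            {
                "A": [1, 1, 0, 0, 1, np.nan],
                "B": [1, 0, 0, 1, 1, 1],
                "C": [0, 1, 0, 1, 1, 0],
            }
        )
        return clt.CallMatrix(frame)

    def test_all_deleterious_gives_ones(self):
        calls = clt.CallMatrix(pd.DataFrame({"A": [1, 1], "B": [1, 1]}))
        out = clt.proportion_deleterious_by_class(calls, [1, 9])
        assert (out.to_numpy() == 1.0).all() or np.isnan(out.to_numpy()).any()

    def test_printed_class_edges(self):
        macs = [1, 2, 3, 4, 5, 8, 9]
        calls = clt.CallMatrix(pd.DataFrame({"A": [1, 0, 1, 0, 1, 0, 1]}))
        out = clt.proportion_deleterious_by_class(calls, macs)
        assert list(out.columns) == ["1", "2", "3-4", "5-8", ">8"]
        assert out.loc["A", "1"] == 1.0
        assert out.loc["A", "2"] == 0.0
        assert out.loc["A", "3-4"] == 0.5
        assert out.loc["A", "5-8"] == 0.5
        assert out.loc["A", ">8"] == 1.0

    def test_brute_force_recount_on_toy_matrix(self, toy_calls):
        rng = np.random.default_rng(7)
        frame = pd.DataFrame(rng.integers(0, 2, (20, 3)).astype(float), columns=list("XYZ"))
        macs = rng.integers(1, 15, 20)
        out = clt.proportion_deleterious_by_class(clt.CallMatrix(frame), macs)
        for col, (lo, hi) in zip(out.columns, evaluation.DEFAULT_FREQUENCY_CLASSES):
            members = (macs >= lo) & (macs <= hi)
            for a in "XYZ":
                if members.sum():
                    assert out.loc[a, col] == pytest.approx(frame.loc[members, a].mean())

    def test_zero_count_rejected(self, toy_calls):
        with pytest.raises(ValueError):
            clt.proportion_deleterious_by_class(toy_calls, [0, 1, 2, 3, 4, 5])

    def test_agreement_identical_columns_all_or_none(self):
        frame = pd.DataFrame({"A": [1, 0, 1], "B": [1, 0, 1], "C": [1, 0, 1]})
        out = clt.call_agreement_summary(clt.CallMatrix(frame))
        assert out[1] == out[2] == out[3] == pytest.approx(2 / 3)

    def test_agreement_complementary_columns(self):
        frame = pd.DataFrame({"A": [1] * 100, "B": [0] * 100})
        out = clt.call_agreement_summary(clt.CallMatrix(frame))
        assert out[1] == 1.0 and out[2] == 0.0

    def test_agreement_toy_matches_hand_count(self, toy_calls):
        out = clt.call_agreement_summary(toy_calls)
        # complete rows: first five; called-by counts 2,2,0,2,3
        assert out[1] == pytest.approx(4 / 5)
        assert out[2] == pytest.approx(4 / 5)
        assert out[3] == pytest.approx(1 / 5)

    def test_distance_identical_and_complementary(self):
        frame = pd.DataFrame({"A": [1, 0] * 50, "B": [1, 0] * 50, "C": [0, 1] * 50})
        D = clt.disagreement_distance(clt.CallMatrix(frame))
        assert D.loc["A", "B"] == 0
        assert D.loc["A", "C"] == 100
        assert (np.diag(D.to_numpy()) == 0).all()

    def test_distance_matches_double_loop(self):
        rng = np.random.default_rng(8)
        raw = rng.integers(0, 2, (30, 4)).astype(float)
        raw[rng.random((30, 4)) < 0.1] = np.nan
        frame = pd.DataFrame(raw, columns=list("ABCD"))
        D = clt.disagreement_distance(clt.CallMatrix(frame))
        for i, a in enumerate("ABCD"):
            for j, b in enumerate("ABCD"):
                expected = sum(
                    1
                    for r in range(30)
                    if not np.isnan(raw[r, i]) and not np.isnan(raw[r, j])
                    and raw[r, i] != raw[r, j]
                )
                assert D.iloc[i, j] == expected

    def test_distance_symmetry_and_identity(self, toy_calls):
        D = clt.disagreement_distance(toy_calls).to_numpy()
        np.testing.assert_array_equal(D, D.T)
        assert (np.diag(D) == 0).all()


class TestClusterApproaches:
    def test_identical_pair_clusters_with_full_support(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 2, 200).astype(float)
        frame = pd.DataFrame({"A": col, "B": col, "C": 1 - col})
        result = clt.cluster_approaches(clt.CallMatrix(frame), n_boot=100, seed=0)
        assert result.support[frozenset({"A", "B"})] == pytest.approx(1.0)

    def test_supports_are_probabilities(self):
        rng = np.random.default_rng(1)
        frame = pd.DataFrame(
            rng.integers(0, 2, (100, 4)).astype(float), columns=list("ABCD")
        )
        result = clt.cluster_approaches(clt.CallMatrix(frame), n_boot=50, seed=0)
        for v in result.support.values():
            assert 0.0 <= v <= 1.0

    def test_planted_pairs_recovered(self):
        rng = np.random.default_rng(2)
        base1 = rng.integers(0, 2, 300).astype(float)
        base2 = rng.integers(0, 2, 300).astype(float)
        noisy = lambda b: np.where(rng.random(300) < 0.05, 1 - b, b)
        frame = pd.DataFrame(
            {"A1": noisy(base1), "A2": noisy(base1), "B1": noisy(base2), "B2": noisy(base2)}
        )
        result = clt.cluster_approaches(clt.CallMatrix(frame), n_boot=50, seed=0)
        clades = set(result.support)
        assert frozenset({"A1", "A2"}) in clades
        assert frozenset({"B1", "B2"}) in clades

    def test_newick_contains_all_approaches_and_supports(self):
        rng = np.random.default_rng(3)
        frame = pd.DataFrame(
            rng.integers(0, 2, (50, 3)).astype(float), columns=["X", "Y", "Z"]
        )
        result = clt.cluster_approaches(clt.CallMatrix(frame), n_boot=20, seed=0)
        for name in "XYZ":
            assert name in result.newick

    def test_too_few_approaches_rejected(self):
        frame = pd.DataFrame({"A": [1.0, 0.0], "B": [0.0, 1.0]})
        with pytest.raises(ValueError):
            clt.cluster_approaches(clt.CallMatrix(frame), n_boot=10, seed=0)
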