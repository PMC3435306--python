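import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from maldiforest.classify import (
    RFETrace,
    below_median_mask,
    confusion_metrics,
    elimination_schedule,
    fit_forest,
    major_vote,
    nested_performance,
    repeated_cv,
    rfe,
    roc_points,
    vote_auc,
)
from maldiforest.peaks import FeatureMatrix


def brute_force_auc(fractions, labels):
    """Oracle: all-pairs concordance count with half credit for ties."""
    fractions = np.asarray(fractions, float)
    labels = np.asarray(labels)
    cases = fractions[labels == "case"]
    controls = fractions[labels == "control"]
    total = 0.0
    for c in cases:
        for k in controls:
            total += 1.0 if c > k else (0.5 if c == k else 0.0)
    return total / (cases.size * controls.size)


def make_features(X, y, seed_ids=None):
    X = np.asarray(X, float)
    labels = np.array(["case" if v else "control" for v in y], dtype=object)
    return FeatureMatrix(
        values=X,
        sample_ids=[f"s{i}" for i in range(X.shape[0])],
        labels=labels,
        peak_ids=seed_ids or [f"f{j}" for j in range(X.shape[1])],
    )


def separated_features(n_per_class=20, n_noise=0, gap=5.0, seed=0):
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    y = np.r_[np.ones(n_per_class), np.zeros(n_per_class)].astype(int)
    signal = (y * gap + rng.normal(0, 1.0, n))[:, None]
    if n_noise:
        X = np.hstack([signal, rng.normal(0, 1.0, (n, n_noise))])
    else:
        X = signal
    return make_features(X, y)


class TestMajorVote:
    def test_strictly_above_half_is_case(self):
        assert major_vote(0.51) == "case"

    def test_exactly_half_is_control(self):
        assert major_vote(0.5) == "control"

    def test_zero_is_control(self):
        assert major_vote(0.0) == "control"

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            major_vote(1.2)


class TestVoteAuc:
    def test_perfect_separation(self):
        assert vote_auc([0.9, 0.8, 0.2, 0.1], ["case", "case", "control", "control"]) == 1.0

    def test_three_of_four_pairs_concordant(self):
        assert vote_auc([0.9, 0.4, 0.6, 0.1], ["case", "case", "control", "control"]) == 0.75

    def test_all_ties_is_half(self):
        assert vote_auc([0.5, 0.5], ["case", "control"]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            vote_auc([0.5, 0.6], ["case", "case"])

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        st.lists(st.integers(0, 10), min_size=1, max_size=30),
        st.lists(st.integers(0, 10), min_size=1, max_size=30),
    )
    def test_matches_brute_force_pair_count(self, case_scores, control_scores):
        fractions = np.array(case_scores + control_scores) / 10.0
        labels = ["case"] * len(case_scores) + ["control"] * len(control_scores)
        assert vote_auc(fractions, labels) == pytest.approx(
            brute_force_auc(fractions, labels), abs=1e-12
        )


class TestConfusionMetrics:
    def test_printed_percentage_triples(self):
        """273/350 cases and 175/230 controls pool to 448/580 = 77.2%."""
        preds = np.array(
            ["case"] * 273 + ["control"] * 77 + ["control"] * 175 + ["case"] * 55
        )
        labels = np.array(["case"] * 350 + ["control"] * 230)
        m = confusion_metrics(preds, labels)
        assert m.sensitivity == 78.0
        assert m.specificity == 76.1
        assert m.accuracy == 77.2
        assert (m.n_correct, m.n_total) == (448, 580)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(np.array(["case"]), np.array(["case", "control"]))


class TestFitForest:
    def test_separable_data_has_tiny_oob_error(self):
        errors = [
            fit_forest(separated_features(seed=s), n_trees=100, seed=s,
                       compute_importance=False).oob_error
            for s in range(10)
        ]
        assert all(e <= 0.05 for e in errors)

    def test_permuted_labels_oob_error_near_half(self):
        errors = []
        for s in range(10):
            fm = separated_features(seed=s)
            rng = np.random.default_rng(s)
            shuffled = rng.permutation(fm.labels)
            fm_null = make_features(fm.values, shuffled == "case")
            errors.append(
                fit_forest(fm_null, n_trees=100, seed=s, compute_importance=False).oob_error
            )
        assert 0.35 <= np.mean(errors) <= 0.65

    def test_noise_feature_ranks_below_marker(self):
        wins = 0
        for s in range(10):
            fm = separated_features(n_noise=1, gap=3.0, seed=s)
            model = fit_forest(fm, n_trees=200, seed=s)
            wins += model.mda_z[0] > model.mda_z[1]
        assert wins >= 9

    def test_single_class_rejected(self):
        fm = make_features(np.ones((4, 2)), [1, 1, 1, 1])
        with pytest.raises(ValueError):
            fit_forest(fm, n_trees=10)

    def test_deterministic_given_seed(self):
        fm = separated_features(n_noise=3)
        a = fit_forest(fm, n_trees=50, seed=11)
        b = fit_forest(fm, n_trees=50, seed=11)
        np.testing.assert_array_equal(a.oob_votes, b.oob_votes)
        np.testing.assert_array_equal(a.mda_z, b.mda_z)

    def test_vote_fractions_within_unit_interval(self):
        fm = separated_features(n_noise=2)
        model = fit_forest(fm, n_trees=50, seed=0, compute_importance=False)
        assert np.all((model.oob_votes >= 0) & (model.oob_votes <= 1))


class TestRepeatedCV:
    def test_pooled_prediction_bookkeeping(self):
        fm = separated_features(n_per_class=15, n_noise=2)
        cv = repeated_cv(fm, n_folds=5, n_repetitions=3, n_trees=30, seed=0)
        assert cv.n_predictions == 30 * 3
        assert cv.metrics.n_cases == 15 * 3 and cv.metrics.n_controls == 15 * 3
        per_rep = cv.predictions.groupby("repetition")["sample_id"].nunique()
        assert (per_rep == 30).all()

    def test_separable_cohort_auc_near_one(self):
        fm = separated_features(n_per_class=20, n_noise=2)
        cv = repeated_cv(fm, n_folds=5, n_repetitions=3, n_trees=50, seed=1)
        assert cv.auc >= 0.99

    def test_permuted_labels_auc_near_half(self):
        aucs = []
        for s in range(6):
            rng = np.random.default_rng(s)
            fm = make_features(rng.normal(size=(30, 5)), rng.integers(0, 2, 30))
            try:
                cv = repeated_cv(fm, n_folds=5, n_repetitions=2, n_trees=40, seed=s)
            except ValueError:  # a draw without two samples per class
                continue
            aucs.append(cv.auc)
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_all_features_selector_equals_no_selector(self):
        fm = separated_features(n_per_class=12, n_noise=3)
        plain = repeated_cv(fm, n_folds=4, n_repetitions=2, n_trees=40, seed=3)
        identity = repeated_cv(
            fm, n_folds=4, n_repetitions=2, n_trees=40, seed=3,
            selector=lambda train, fold_seed: list(train.peak_ids),
        )
        np.testing.assert_array_equal(
            plain.predictions["vote_fraction"].to_numpy(),
            identity.predictions["vote_fraction"].to_numpy(),
        )
        assert plain.auc == identity.auc


class TestRFE:
    def test_strict_below_median_schedule_from_153(self):
        """Distinct importances follow 153 -> 77 -> 39 -> 20 -> 10 -> 5 -> 3 -> 2."""
        rng = np.random.default_rng(0)
        sizes = [153]
        mda = rng.permutation(np.linspace(0, 1, 153))
        while True:
            keep = below_median_mask(mda)
            if keep.sum() < 2 or keep.sum() == mda.size:
                break
            mda = mda[keep]
            sizes.append(mda.size)
        assert sizes == [153, 77, 39, 20, 10, 5, 3, 2]

    def test_features_at_median_survive(self):
        keep = below_median_mask(np.array([1.0, 2.0, 2.0, 3.0]))
        assert list(keep) == [False, True, True, True]

    def test_two_features_give_single_set_trace(self):
        fm = separated_features(n_per_class=10, n_noise=1)
        sets = elimination_schedule(fm, seed=0, n_trees=30)
        trace = rfe(fm, seed=0, n_trees_importance=30, n_trees_cv=30,
                    n_folds=4, n_repetitions=1)
        assert trace.sizes[0] == 2
        assert len(sets) == len(trace.sizes)

    def test_trace_sizes_strictly_decrease_and_start_full(self, small_pipeline):
        fm = small_pipeline["features"]
        sets = elimination_schedule(fm, seed=0, n_trees=60)
        sizes = [len(s) for s in sets]
        assert sizes[0] == fm.n_features
        assert all(b < a for a, b in zip(sizes, sizes[1:]))
        assert sizes[-1] >= 2

    def test_auc_tie_breaks_toward_smaller_set(self):
        from maldiforest.classify import CVResult, ConfusionMetrics
        import pandas as pd

        def fake_cv(auc):
            preds = pd.DataFrame(
                {
                    "repetition": [0, 0],
                    "sample_id": ["a", "b"],
                    "label": ["case", "control"],
                    "vote_fraction": [0.9, 0.1],
                    "prediction": ["case", "control"],
                }
            )
            return CVResult(
                predictions=preds, auc=auc,
                metrics=ConfusionMetrics(100.0, 100.0, 100.0, 2, 2, 1, 1, 1, 1),
                n_folds=2, n_repetitions=1,
            )

        trace = RFETrace(
            feature_sets=[["a", "b", "c"], ["a", "b"]],
            cv_results=[fake_cv(0.9), fake_cv(0.9)],
        )
        assert trace.selected_set == ["a", "b"]


class TestNested:
    def test_null_cohort_nested_auc_near_half(self):
        aucs = []
        for s in range(3):
            rng = np.random.default_rng(100 + s)
            y = np.r_[np.ones(15), np.zeros(15)].astype(int)
            fm = make_features(rng.normal(size=(30, 12)), y)
            cv = nested_performance(
                fm, seed=s, selected_fraction=0.25,
                n_trees_importance=40, n_trees_cv=40, n_folds=5, n_repetitions=2,
            )
            aucs.append(cv.auc)
        assert 0.35 <= np.mean(aucs) <= 0.65


class TestRocPoints:
    def test_endpoints_and_perfect_separation(self):
        pts = roc_points([0.9, 0.8, 0.2, 0.1], ["case", "case", "control", "control"])
        assert (pts.iloc[0].fpr, pts.iloc[0].tpr) == (0.0, 0.0)
        assert (pts.iloc[-1].fpr, pts.iloc[-1].tpr) == (1.0, 1.0)
        assert ((pts.fpr == 0.0) & (pts.tpr == 1.0)).any()

    def test_all_identical_fractions(self):
        pts = roc_points([0.4, 0.4, 0.4], ["case", "control", "case"])
        area = np.trapezoid(pts.tpr, pts.fpr)
        assert area == pytest.approx(0.5, abs=1e-12)

    def test_trapezoid_area_equals_vote_auc(self):
        rng = np.random.default_rng(2)
        fractions = rng.integers(0, 20, 50) / 20.0
        labels = np.where(rng.random(50) < 0.5, "case", "control")
        if len(set(labels)) < 2:
            labels[0], labels[1] = "case", "control"
        pts = roc_points(fractions, labels)
        area = np.trapezoid(pts.tpr, pts.fpr)
        assert area == pytest.approx(vote_auc(fractions, labels), abs=1e-12)

    def test_cutoffs_descend_beyond_score_range(self):
        pts = roc_points([0.2, 0.7], ["control", "case"])
        cutoffs = pts.cutoff.to_numpy()
        assert np.all(np.diff(cutoffs) < 0)
        assert cutoffs[0] > 0.7 and cutoffs[-1] < 0.2
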