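import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from xrdtissue.classify import (
    FoldAssignment,
    aggregate_to_patients,
    grouped_stratified_folds,
    oof_probabilities,
    roc_ap_metrics,
    youden_point,
)


def brute_force_auc(y, s):
    """Concordant-pair fraction with half-credit for score ties."""
    y = np.asarray(y, dtype=bool)
    s = np.asarray(s, dtype=float)
    pos, neg = s[y], s[~y]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def _gauss_features(rng, n_patients_pos, n_patients_neg, frames, d, gap):
    rows, recs = [], []
    for p in range(n_patients_pos + n_patients_neg):
        positive = p < n_patients_pos
        label = "cancer" if positive else "fibroadenoma"
        mu = gap / 2 if positive else -gap / 2
        pid = f"P{p:02d}"
        patient_shift = rng.normal(0, 0.2, d)
        for m in range(frames):
            rows.append(rng.normal(mu, 1.0, d) + patient_shift)
            recs.append({"frame_id": f"{pid}_{m}", "patient_id": pid, "label": label})
    return np.vstack(rows), pd.DataFrame(recs)


class TestGroupedFolds:
    def test_partition_and_grouping(self):
        records = []
        for p in range(36):
            label = "cancer" if p < 24 else "fibroadenoma"
            for m in range(8):
                records.append(
                    {"frame_id": f"{p}_{m}", "patient_id": f"P{p}", "label": label}
                )
        meta = pd.DataFrame(records)
        folds = grouped_stratified_folds(meta, k=5, seed=0)
        a = folds.assignments
        # disjoint test-patient sets covering all patients
        by_fold = a.groupby("fold")["patient_id"].apply(set)
        union = set().union(*by_fold)
        assert union == set(meta["patient_id"])
        assert sum(len(s) for s in by_fold) == 36
        # each patient in exactly one fold
        assert (a.groupby("patient_id")["fold"].nunique() == 1).all()
        # training fraction of frames within [0.7, 0.9] per fold
        for fold_id, test_set in by_fold.items():
            frac_train = 1 - a[a["fold"] == fold_id].shape[0] / len(a)
            assert 0.7 <= frac_train <= 0.9

    def test_deterministic_given_seed(self, small_metadata):
        a = grouped_stratified_folds(small_metadata, k=3, seed=42).assignments
        b = grouped_stratified_folds(small_metadata, k=3, seed=42).assignments
        assert a.equals(b)

    def test_k_exceeding_patients_rejected(self, small_metadata):
        with pytest.raises(ValueError, match="exceed"):
            grouped_stratified_folds(small_metadata, k=40)

    def test_single_class_rejected(self, small_metadata):
        meta = small_metadata.assign(label="cancer")
        with pytest.raises(ValueError, match="both classes"):
            grouped_stratified_folds(meta, k=3)

    def test_split_patient_assignment_rejected(self, small_metadata):
        bad = small_metadata.copy()
        bad["fold"] = np.arange(len(bad)) % 3  # splits patients
        with pytest.raises(ValueError, match="split across folds"):
            FoldAssignment(assignments=bad, k=3)


class TestOofProbabilities:
    def test_separated_classes_score_high_auc(self):
        rng = np.random.default_rng(0)
        X, meta = _gauss_features(rng, 8, 4, 4, 30, gap=2.0)
        folds = grouped_stratified_folds(meta, k=4, seed=0)
        scores = oof_probabilities(X, meta, folds, n_components=5, seed=0)
        assert scores["score"].between(0, 1).all()
        assert not scores["score"].isna().any()
        assert roc_ap_metrics(scores).auc >= 0.9

    def test_no_patient_leaks_between_train_and_test(self):
        rng = np.random.default_rng(1)
        X, meta = _gauss_features(rng, 8, 4, 3, 10, gap=1.0)
        folds = grouped_stratified_folds(meta, k=4, seed=1)
        a = folds.assignments
        for fold_id in a["fold"].unique():
            test_patients = set(a.loc[a["fold"] == fold_id, "patient_id"])
            train_patients = set(a.loc[a["fold"] != fold_id, "patient_id"])
            assert not (test_patients & train_patients)

    def test_duplicated_feature_columns_leave_scores_unchanged(self):
        rng = np.random.default_rng(2)
        X, meta = _gauss_features(rng, 8, 4, 4, 30, gap=1.0)
        folds = grouped_stratified_folds(meta, k=4, seed=0)
        s1 = oof_probabilities(X, meta, folds, n_components=5, seed=0)["score"]
        s2 = oof_probabilities(np.hstack([X, X]), meta, folds, n_components=5, seed=0)["score"]
        assert np.allclose(s1, s2, atol=1e-9)

    def test_component_cap_warns(self):
        rng = np.random.default_rng(3)
        X, meta = _gauss_features(rng, 4, 4, 2, 6, gap=1.0)
        folds = grouped_stratified_folds(meta, k=2, seed=0)
        with pytest.warns(UserWarning, match="capped"):
            oof_probabilities(X, meta, folds, n_components=50, seed=0)

    def test_single_class_training_fold_rejected(self):
        rng = np.random.default_rng(4)
        X, meta = _gauss_features(rng, 6, 2, 2, 5, gap=1.0)
        bad = meta[["frame_id", "patient_id", "label"]].copy()
        # hand-build folds putting every fibroadenoma patient in fold 0's
        # training complement -> fold 1 trains on cancer only
        bad["fold"] = np.where(bad["label"] == "cancer", 1, 0)
        folds = FoldAssignment(assignments=bad, k=2)
        with pytest.raises(ValueError, match="single class"):
            oof_probabilities(X, meta, folds, n_components=2, seed=0)

    def test_random_forest_variant_same_contract(self):
        rng = np.random.default_rng(5)
        X, meta = _gauss_features(rng, 8, 4, 3, 10, gap=2.0)
        folds = grouped_stratified_folds(meta, k=3, seed=0)
        scores = oof_probabilities(
            X, meta, folds, n_components=5, classifier="random_forest", seed=0
        )
        assert scores["score"].between(0, 1).all()
        assert roc_ap_metrics(scores).auc >= 0.8


class TestAggregateToPatients:
    def test_mean_of_frame_probabilities(self):
        scores = pd.DataFrame(
            {
                "frame_id": ["a", "b", "c", "d"],
                "patient_id": ["P1", "P1", "P1", "P2"],
                "label": ["cancer"] * 3 + ["fibroadenoma"],
                "score": [0.2, 0.4, 0.6, 0.9],
            }
        )
        out = aggregate_to_patients(scores)
        assert out.set_index("patient_id").loc["P1", "score"] == pytest.approx(0.4)
        assert out.set_index("patient_id").loc["P2", "score"] == pytest.approx(0.9)

    def test_patient_count(self, small_metadata):
        scores = small_metadata.assign(score=0.5)
        assert len(aggregate_to_patients(scores)) == 12

    def test_conflicting_labels_rejected(self):
        scores = pd.DataFrame(
            {
                "frame_id": ["a", "b"],
                "patient_id": ["P1", "P1"],
                "label": ["cancer", "fibroadenoma"],
                "score": [0.5, 0.5],
            }
        )
        with pytest.raises(ValueError, match="conflicting"):
            aggregate_to_patients(scores)


def _table(scores, labels):
    return pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(len(scores))],
            "score": scores,
            "label": ["cancer" if l else "fibroadenoma" for l in labels],
        }
    )


class TestRocApMetrics:
    def test_worked_auc_example(self):
        roc = roc_ap_metrics(_table([0.9, 0.6, 0.4, 0.2], [1, 0, 1, 0]))
        assert roc.auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        roc = roc_ap_metrics(_table([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]))
        assert roc.auc == 1.0 and roc.ap == 1.0

    def test_worked_ap_example(self):
        roc = roc_ap_metrics(_table([0.9, 0.8, 0.3], [1, 0, 1]))
        assert roc.ap == pytest.approx(0.5 * 1.0 + 0.5 * 2 / 3)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_ap_metrics(_table([0.4, 0.6], [1, 1]))

    @settings(deadline=None, max_examples=50)
    @given(
        data=st.lists(
            st.tuples(st.integers(0, 4), st.booleans()), min_size=4, max_size=30
        )
    )
    def test_auc_equals_brute_force_with_ties(self, data):
        labels = [l for _, l in data]
        if not (any(labels) and not all(labels)):
            return
        scores = [s / 4 for s, _ in data]
        roc = roc_ap_metrics(_table(scores, labels))
        assert roc.auc == pytest.approx(brute_force_auc(labels, scores), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(0, 1, 20)
        labels = rng.random(20) < 0.5
        labels[:2] = [True, False]
        base = roc_ap_metrics(_table(scores, labels))
        warped = roc_ap_metrics(_table(1 / (1 + np.exp(-5 * scores)), labels))
        assert warped.auc == pytest.approx(base.auc, abs=1e-12)
        assert warped.ap == pytest.approx(base.ap, abs=1e-12)
        t0, se0, sp0 = youden_point(base)
        t1, se1, sp1 = youden_point(warped)
        assert (se1, sp1) == (se0, sp0)


class TestYoudenPoint:
    def test_perfect_classifier(self):
        roc = roc_ap_metrics(_table([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]))
        _, sens, spec = youden_point(roc)
        assert sens == 1.0 and spec == 1.0

    def test_worked_example_tied_maximum(self):
        # J = 0.5 both at threshold 0.9 (sens 0.5, spec 1.0) and at
        # threshold 0.4 (sens 1.0, spec 0.5); the tie-break takes the
        # higher, more conservative threshold
        roc = roc_ap_metrics(_table([0.9, 0.6, 0.4, 0.2], [1, 0, 1, 0]))
        thr, sens, spec = youden_point(roc)
        assert sens + spec - 1 == pytest.approx(0.5)
        assert thr == pytest.approx(0.9)
        assert (sens, spec) == (0.5, 1.0)

    def test_uninformative_scores_warn(self):
        roc = roc_ap_metrics(_table([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]))
        with pytest.warns(UserWarning, match="uninformative"):
            _, sens, spec = youden_point(roc)
        assert sens + spec - 1 == pytest.approx(0.0)
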