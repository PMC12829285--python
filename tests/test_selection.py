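import numpy as np
import pytest

from methmark import (
    BetaMatrix,
    PipelineConfig,
    evaluate_classifier,
    fit_enet,
    stratified_split,
    substream,
)
from methmark._enet import enet_path, lambda_max, objective
from methmark.selection import (
    ConsensusError,
    EnetModelRecord,
    SplitSpec,
    consensus_from_records,
)


class TestStratifiedSplit:
    def test_exact_proportionality(self):
        labels = np.repeat([2, 3, 5, 6], 10)
        ids = [f"s{i}" for i in range(40)]
        split = stratified_split(ids, labels, 0.7, substream(0, "sp"))
        lut = dict(zip(ids, labels))
        for c in (2, 3, 5, 6):
            assert sum(lut[s] == c for s in split.train_ids) == 7
            assert sum(lut[s] == c for s in split.test_ids) == 3

    def test_study_sized_cohort_train_count(self):
        labels = np.repeat([2, 3, 5, 6], [50, 42, 45, 50])
        ids = [f"s{i}" for i in range(187)]
        split = stratified_split(ids, labels, 0.70, substream(1, "sp"))
        # round(0.7 * 187) = 131; the study reports 132 (rounding convention)
        assert len(split.train_ids) in (131, 132)
        assert len(split.train_ids) + len(split.test_ids) == 187
        assert not set(split.train_ids) & set(split.test_ids)

    def test_fixed_stream_is_deterministic(self):
        labels = np.repeat([2, 3], [6, 8])
        ids = [f"s{i}" for i in range(14)]
        a = stratified_split(ids, labels, 0.7, substream(9, "sp"))
        b = stratified_split(ids, labels, 0.7, substream(9, "sp"))
        assert a == b

    def test_tiny_cluster_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            stratified_split(["a", "b", "c"], np.array([1, 1, 2]), 0.7, substream(0, "sp"))


class TestEvaluateClassifier:
    def test_confusion_arithmetic(self):
        truth = np.array([0] * 10 + [1] * 10)
        pred = np.array([0] * 8 + [1] * 2 + [0] * 4 + [1] * 6)
        m = evaluate_classifier(pred, truth)
        assert m["accuracy"] == pytest.approx(0.70)
        assert m["balanced_accuracy"] == pytest.approx((0.8 + 0.6) / 2)

    def test_f1_from_counts(self):
        # TP=8, FP=4, FN=2 -> precision 2/3, recall 0.8, F1 0.7273
        truth = np.array([1] * 10 + [0] * 10)
        pred = np.array([1] * 8 + [0] * 2 + [1] * 4 + [0] * 6)
        m = evaluate_classifier(pred, truth)
        assert m["per_class"][1]["f1"] == pytest.approx(0.7273, abs=1e-4)
        assert m["per_class"][1]["sensitivity"] == pytest.approx(0.8)

    def test_perfect_prediction(self):
        truth = np.array([1, 2, 3, 1, 2, 3])
        m = evaluate_classifier(truth, truth)
        assert m["accuracy"] == 1.0
        assert m["balanced_accuracy"] == 1.0
        assert all(v["f1"] == 1.0 for v in m["per_class"].values())

    def test_absent_class_excluded_from_balanced_mean(self):
        truth = np.array([1, 1, 2, 2])
        pred = np.array([1, 1, 2, 3])
        m = evaluate_classifier(pred, truth, classes=[1, 2, 3])
        assert m["balanced_accuracy"] == pytest.approx((1.0 + 0.5) / 2)
        assert np.isnan(m["per_class"][3]["sensitivity"])


def _record(split_id, selected, accuracy=0.9, gate=0.8):
    sel = frozenset(selected)
    return EnetModelRecord(
        split_id=split_id,
        alpha=0.5,
        lam=0.1,
        selected_cpgs_overall=sel,
        selected_cpgs_per_class={2: sel},
        accuracy=accuracy,
        balanced_accuracy=accuracy,
        per_class={},
        successful=accuracy > gate,
    )


class TestConsensus:
    def test_frequency_counting(self):
        records = [_record(0, {"A", "B"}), _record(1, {"A"}), _record(2, {"A", "C"})]
        cons = consensus_from_records(records, 0.10)
        assert cons.frequencies_overall == {"A": 1.0, "B": 1 / 3, "C": 1 / 3}
        assert cons.retained == {"A", "B", "C"}

    def test_higher_threshold_shrinks_retained(self):
        records = [_record(0, {"A", "B"}), _record(1, {"A"}), _record(2, {"A", "C"})]
        cons = consensus_from_records(records, 0.5)
        assert cons.retained == {"A"}

    def test_record_order_invariance(self):
        records = [_record(0, {"A", "B"}), _record(1, {"A"}), _record(2, {"A", "C"})]
        a = consensus_from_records(records, 0.10)
        b = consensus_from_records(records[::-1], 0.10)
        assert a == b

    def test_failed_models_excluded_from_denominator(self):
        records = [_record(0, {"A"}), _record(1, {"B"}, accuracy=0.5)]
        cons = consensus_from_records(records, 0.10)
        assert cons.n_successful == 1
        assert "B" not in cons.frequencies_overall

    def test_no_successful_model_raises(self):
        with pytest.raises(ConsensusError):
            consensus_from_records([_record(0, {"A"}, accuracy=0.2)], 0.10)

    def test_gate_monotonicity(self):
        accs = [0.7, 0.85, 0.9, 0.95]
        n_success = [
            sum(a > gate for a in accs) for gate in (0.6, 0.8, 0.92)
        ]
        assert n_success == sorted(n_success, reverse=True)


class TestEnetSolver:
    def test_lambda_max_zeroes_everything(self):
        rng = np.random.default_rng(0)
        X = np.ascontiguousarray(rng.normal(size=(40, 15)))
        y = rng.integers(0, 3, 40).astype(np.int64)
        lam = lambda_max(X, y, 3, 0.5)
        B0, B = enet_path(X, y, 3, np.array([lam * 1.001]), 0.5, 1e-8, 50, 200)
        assert np.all(B[0] == 0.0)

    def test_informative_feature_sign_matches_group_difference(self):
        rng = np.random.default_rng(1)
        n = 60
        y = np.array([0] * 30 + [1] * 30, dtype=np.int64)
        X = rng.normal(size=(n, 3))
        X[y == 1, 0] += 2.0  # class 1 mean higher on feature 0
        X = np.ascontiguousarray((X - X.mean(0)) / X.std(0))
        lam = lambda_max(X, y, 2, 1.0)
        path = np.geomspace(lam, lam * 0.05, 10)
        B0, B = enet_path(X, y, 2, path, 1.0, 1e-8, 50, 200)
        b = B[-1]
        assert b[1, 0] > 0 and b[0, 0] < 0
        assert np.abs(b[:, 1:]).max() < np.abs(b[:, 0]).min()

    @pytest.mark.parametrize("alpha", [0.2, 1.0])
    def test_objective_matches_saga_reference(self, alpha):
        """Independent oracle: sklearn's saga solver on the same penalty."""
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(42)
        n, p, K = 60, 20, 3
        X = np.ascontiguousarray(rng.normal(size=(n, p)))
        beta = np.zeros((K, p))
        beta[:, :4] = rng.normal(scale=1.5, size=(K, 4))
        probs = np.exp(X @ beta.T)
        probs /= probs.sum(1, keepdims=True)
        y = np.array([rng.choice(K, p=pi) for pi in probs]).astype(np.int64)
        lam_hi = lambda_max(X, y, K, alpha)
        path = np.geomspace(lam_hi, lam_hi * 0.02, 12)
        B0, B = enet_path(X, y, K, path, alpha, 1e-8, 100, 300)
        for j in (4, 11):
            lam = path[j]
            sk = LogisticRegression(
                l1_ratio=alpha, C=1.0 / (lam * n), tol=1e-8, max_iter=50000,
                solver="saga",
            ).fit(X, y)
            mine = objective(X, y, B0[j], B[j], lam, alpha)
            theirs = objective(X, y, sk.intercept_, sk.coef_, lam, alpha)
            assert mine <= theirs + 1e-6


class TestFitEnet:
    def test_strong_signal_split_is_accurate_and_selective(self, small_pair, small_labels):
        _, disc, _, _, truth = small_pair
        info = sorted(truth.informative_cpgs)[:25]
        noise = [g for g in disc.cpg_ids if g not in truth.informative_cpgs][:75]
        sub = disc.select_cpgs(info + noise)
        split = stratified_split(
            sub.sample_ids, small_labels, 0.7, substream(0, "sp")
        )
        rec = fit_enet(
            sub, small_labels, split, (0.5, 1.0), 5, substream(0, "cv"), n_lambda=20
        )
        assert rec.accuracy > 0.8
        assert rec.successful
        selected_info = len(set(rec.selected_cpgs_overall) & set(info))
        assert selected_info >= 15
        assert rec.selected_cpgs_overall == frozenset().union(
            *rec.selected_cpgs_per_class.values()
        )
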