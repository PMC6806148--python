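import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from adlfusion.alignment import (
    AlignmentError,
    compute_offsets,
    detect_motion_start,
    detect_vision_activity_start,
    match_all,
    match_windows,
    trim_to_common_span,
)
from adlfusion.fusion import (
    EarlyFusionClassifier,
    LateFusionClassifier,
    early_fuse,
    late_fuse_train,
    predict,
    stack_features,
)
from adlfusion.inertial import make_window_grid
from adlfusion.types import (
    FusedInstance,
    InertialStream,
    Modality,
    TemporalWindow,
    WristPosition,
)


def still_then_step(step_at_ms=5000, total_ms=10000, noise_sd=0.05, seed=0,
                    step=(2.0, 0.0, 0.0)):
    rng = np.random.default_rng(seed)
    t = np.arange(0, total_ms, 20).astype(np.int64)
    a = np.tile([0.0, 0.0, 9.81], (t.size, 1)) + rng.normal(0, noise_sd, (t.size, 3))
    a[t >= step_at_ms] += step
    return InertialStream("dev", WristPosition.LEFT_WRIST, t, a)


class TestMotionStart:
    def test_step_detected_within_one_sample_period(self):
        stream = still_then_step(5000)
        assert abs(detect_motion_start(stream, 0.5, 1000) - 5000) <= 20

    def test_all_still_stream_errors(self):
        stream = still_then_step(10**9, total_ms=8000)  # never steps
        with pytest.raises(AlignmentError):
            detect_motion_start(stream, 0.5, 1000)

    def test_zero_threshold_returns_first_sample_after_prefix(self):
        stream = still_then_step(5000, noise_sd=0.0)
        t = detect_motion_start(stream, 0.0, 1000, consecutive=1)
        assert t == 1000

    def test_motion_during_prefix_errors(self):
        stream = still_then_step(200)
        with pytest.raises(AlignmentError):
            detect_motion_start(stream, 0.5, 1000)

    def test_orthogonal_motion_detected(self):
        # a step in the x-axis leaves the magnitude nearly unchanged only if
        # tiny; the vector criterion sees it regardless of direction
        stream = still_then_step(4000, step=(1.5, 0.0, 0.0))
        assert abs(detect_motion_start(stream, 0.5, 1000) - 4000) <= 20

    def test_vision_onset_from_object_detections(self):
        from adlfusion.types import BoundingBox, FrameDetections

        frames = []
        for i in range(100):
            boxes = [BoundingBox("person", 0.9, 0, 0, 10, 10)]
            if i >= 60:
                boxes.append(BoundingBox("cup", 0.9, 5, 0, 15, 10))
            frames.append(FrameDetections(i * 40, i, boxes))
        assert detect_vision_activity_start(frames) == 2400

    def test_compute_offsets_reference_zero(self):
        off = compute_offsets({"a": 5000, "b": 5500, "vision": 5200}, "vision")
        assert off.offsets_ms == {"a": 200, "b": -300, "vision": 0}


class TestTrim:
    def test_nested_spans(self):
        assert trim_to_common_span({"a": (0, 100), "b": (10, 90)}) == (10, 90)

    def test_identical_spans_unchanged(self):
        assert trim_to_common_span({"a": (5, 50), "b": (5, 50)}) == (5, 50)

    def test_disjoint_spans_error(self):
        with pytest.raises(AlignmentError, match="no temporal overlap"):
            trim_to_common_span({"a": (0, 10), "b": (20, 30)})


class TestMatching:
    def grid(self, starts, length=1000):
        return [TemporalWindow(s, s + length, i, Modality.IMU)
                for i, s in enumerate(starts)]

    def vw(self, start):
        return TemporalWindow(start, start + 400, 0, Modality.VISION)

    def test_exact_start_match(self):
        m = match_windows(self.vw(1000), self.grid([750, 1000, 1250]))
        assert m.start_ms == 1000

    def test_next_later_start(self):
        m = match_windows(self.vw(1100), self.grid([750, 1000, 1250]))
        assert m.start_ms == 1250

    def test_no_later_window_absent(self):
        assert match_windows(self.vw(2000), self.grid([750, 1000, 1250])) is None

    def test_matched_pairs_within_one_step(self, rng):
        imu = make_window_grid(0, 60000, 1000, 0.75)  # step 250
        for _ in range(200):
            ts = int(rng.integers(0, 58000))
            m = match_windows(self.vw(ts), imu)
            if m is None:
                assert ts > imu[-1].start_ms
            else:
                assert 0 <= m.start_ms - ts < 250

    def test_match_all_idempotent_and_order_independent(self, rng):
        imu = make_window_grid(0, 20000, 1000, 0.5)
        vws = [self.vw(int(rng.integers(0, 19000))) for _ in range(30)]
        pairs1 = match_all(vws, imu)
        pairs2 = match_all(vws, imu)
        assert pairs1 == pairs2
        perm = list(rng.permutation(len(vws)))
        permuted = match_all([vws[i] for i in perm], imu)
        assert {(perm[a], b) for a, b in permuted} == set(pairs1)


def make_instances(n_per_class=30, n_imu=84, n_vis=14, seed=0, classes=("a", "b")):
    """Linearly separable synthetic instances with both blocks."""
    rng = np.random.default_rng(seed)
    out = []
    for ci, cls in enumerate(classes):
        for k in range(n_per_class):
            imu = rng.normal(3 * ci, 0.3, n_imu)
            vis = rng.normal(-2 * ci, 0.3, n_vis)
            out.append(FusedInstance(
                subject="s0", session="s",
                window=TemporalWindow(k * 100, k * 100 + 50, k, Modality.VISION),
                label=cls, imu_features=imu, vision_features=vis))
    return out


class TestEarlyFusion:
    def test_dimension_arithmetic(self):
        inst = make_instances(3)
        X, kept = early_fuse(inst)
        assert X.shape == (6, 98)
        assert len(kept) == 6

    def test_empty_input_keeps_column_count(self):
        X, kept = early_fuse([], n_imu=84, n_vision=14)
        assert X.shape == (0, 98) and kept == []

    def test_missing_block_dropped(self):
        inst = make_instances(2)
        inst[0].vision_features = None
        X, kept = early_fuse(inst)
        assert X.shape[0] == 3

    def test_row_order_follows_instance_order(self):
        inst = make_instances(5)
        X1, _ = early_fuse(inst)
        X2, _ = early_fuse(inst[::-1])
        np.testing.assert_array_equal(X1, X2[::-1])

    def test_estimator_fits_separable_data(self):
        inst = make_instances(20)
        X, y = stack_features(inst)
        clf = EarlyFusionClassifier(random_state=0).fit(X, y)
        assert (clf.predict(X) == y).all()


class TestLateFusion:
    def test_meta_input_dimension(self):
        # 84 imu + C probs + 14 vision + C probs, C = 7
        classes = tuple("abcdefg")
        inst = make_instances(8, classes=classes)
        model = late_fuse_train(inst, random_state=0)
        assert model.meta_input_dim_ == 84 + 7 + 14 + 7 == 112

    def test_separable_data_perfect_training_f1(self):
        inst = make_instances(25)
        model = late_fuse_train(inst, random_state=0)
        labels, probs = predict(model, inst)
        assert (labels == np.array([i.label for i in inst])).all()

    def test_probabilities_normalized_through_stacking(self):
        inst = make_instances(15, classes=("a", "b", "c"))
        model = late_fuse_train(inst, random_state=0)
        _, probs = predict(model, inst)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_deterministic_refit(self):
        inst = make_instances(15)
        X, y = stack_features(inst)
        m1 = LateFusionClassifier(n_imu_features=84, random_state=7).fit(X, y)
        m2 = LateFusionClassifier(n_imu_features=84, random_state=7).fit(X, y)
        np.testing.assert_array_equal(m1.predict_proba(X), m2.predict_proba(X))

    def test_single_class_training_error(self):
        inst = make_instances(10, classes=("a",))
        with pytest.raises(ValueError, match="class"):
            late_fuse_train(inst)

    def test_dimension_mismatch_error_names_layout(self):
        inst = make_instances(10)
        model = late_fuse_train(inst, random_state=0)
        with pytest.raises(ValueError, match="imu 84"):
            model.predict(np.zeros((2, 90)))

    def test_in_sample_stacking_beats_or_ties_base_learners_on_train(self, rng):
        # noisy, overlapping classes so nobody is perfect
        n, n_imu, n_vis = 120, 10, 4
        X = rng.normal(0, 1.0, (n, n_imu + n_vis))
        y = np.array(["a", "b"] * (n // 2))
        X[y == "b", 0] += 1.0
        X[y == "b", n_imu] += 1.0
        model = LateFusionClassifier(
            imu_estimator=LogisticRegression(max_iter=500),
            vision_estimator=LogisticRegression(max_iter=500),
            meta_estimator=LogisticRegression(max_iter=500),
            n_imu_features=n_imu, prob_mode="in_sample", random_state=0,
        ).fit(X, y)
        acc_fused = (model.predict(X) == y).mean()
        acc_imu = (model.imu_estimator_.predict(X[:, :n_imu]) == y).mean()
        acc_vis = (model.vision_estimator_.predict(X[:, n_imu:]) == y).mean()
        assert acc_fused >= max(acc_imu, acc_vis) - 1e-12

    def test_out_of_fold_mode_fits_and_predicts(self):
        inst = make_instances(20)
        model = late_fuse_train(inst, prob_mode="out_of_fold", random_state=0)
        labels, probs = predict(model, inst)
        assert labels.shape == (40,)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_empty_prediction(self):
        inst = make_instances(10)
        model = late_fuse_train(inst, random_state=0)
        labels, probs = predict(model, [])
        assert labels.size == 0

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        model = LateFusionClassifier(n_imu_features=84, random_state=3)
        cloned = clone(model)
        assert cloned.get_params()["random_state"] == 3
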