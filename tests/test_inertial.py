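import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import _oracles as orc
from adlfusion.inertial import (
    FEATURE_NAMES,
    assign_samples,
    extract_imu_features,
    feature_frame,
    frequency_domain_features,
    make_window_grid,
    time_domain_features,
    window_features,
)
from adlfusion.types import InertialStream, TemporalWindow, Modality, WristPosition


def make_stream(t, a, position=WristPosition.LEFT_WRIST, rate=50.0):
    return InertialStream("dev", position, np.asarray(t), np.asarray(a), rate)


def ideal_stream(duration_ms, rate_hz=50.0, value=(0.0, 0.0, 9.81)):
    t = np.arange(0, duration_ms, 1000.0 / rate_hz).astype(np.int64)
    return make_stream(t, np.tile(value, (t.size, 1)), rate=rate_hz)


class TestWindowGrid:
    @pytest.mark.parametrize(
        "span,length,overlap,expected_count,expected_step",
        [
            ((0, 10000), 1000, 0.5, 19, 500),
            ((0, 10000), 1000, 0.75, 37, 250),
            ((0, 900), 1000, 0.5, 0, None),
        ],
    )
    def test_grid_counts(self, span, length, overlap, expected_count, expected_step):
        grid = make_window_grid(span[0], span[1], length, overlap)
        assert len(grid) == expected_count
        if expected_count:
            starts = [w.start_ms for w in grid]
            assert starts[0] == span[0]
            assert all(b - a == expected_step for a, b in zip(starts, starts[1:]))
            assert grid[-1].end_ms <= span[1]

    def test_grid_never_past_span_end(self):
        grid = make_window_grid(0, 10000, 1000, 0.5)
        assert grid[-1].end_ms == 10000

    @pytest.mark.parametrize("kwargs", [
        dict(length_ms=0, overlap_frac=0.5),
        dict(length_ms=1000, overlap_frac=1.0),
        dict(length_ms=-5, overlap_frac=0.0),
    ])
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ValueError):
            make_window_grid(0, 10000, **kwargs)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        span=st.integers(100, 60000),
        length=st.integers(50, 5000),
        overlap=st.sampled_from([0.0, 0.25, 0.5, 0.75, 0.9]),
    )
    def test_count_formula_and_step_property(self, span, length, overlap):
        grid = make_window_grid(0, span, length, overlap)
        step = length * (1 - overlap)
        expected = int(np.floor((span - length) / step)) + 1 if span >= length else 0
        assert len(grid) == expected
        for a, b in zip(grid, grid[1:]):
            assert b.start_ms - a.start_ms == round((b.index) * step) - round(a.index * step)
        for w in grid:
            assert w.end_ms <= span
            assert w.length_ms == length


class TestAssignSamples:
    def test_half_open_boundary(self):
        stream = make_stream([0, 500, 1000], np.zeros((3, 3)))
        w = TemporalWindow(0, 1000, 0, Modality.IMU)
        t, a = assign_samples(w, stream)
        assert list(t) == [0, 500]

    def test_empty_stream_allowed_by_selection(self):
        stream = make_stream([5000], np.zeros((1, 3)))
        w = TemporalWindow(0, 1000, 0, Modality.IMU)
        t, _ = assign_samples(w, stream)
        assert t.size == 0

    def test_ideal_50hz_window_has_50_samples(self):
        stream = ideal_stream(10000)
        w = TemporalWindow(2000, 3000, 0, Modality.IMU)
        t, _ = assign_samples(w, stream)
        assert t.size == 50


class TestTimeDomain:
    def test_constant_signal_degeneracies(self):
        a = np.tile([1.0, 2.0, 3.0], (50, 1))
        f = time_domain_features(a)
        assert f["x_mean"] == 1 and f["y_mean"] == 2 and f["z_mean"] == 3
        for ax in "xyz":
            assert f[f"{ax}_variance"] == 0
            assert f[f"{ax}_iqr"] == 0
            assert f[f"{ax}_mad"] == 0
            assert f[f"{ax}_kurtosis"] == 0
            assert f[f"{ax}_entropy_time"] == 0
        assert f["corr_xy"] == f["corr_xz"] == f["corr_yz"] == 0
        np.testing.assert_allclose(
            [f["gravity_x"], f["gravity_y"], f["gravity_z"]], [1, 2, 3])

    def test_hand_computed_order_statistics(self):
        a = np.zeros((4, 3))
        a[:, 0] = [1.0, 2.0, 3.0, 4.0]
        f = time_domain_features(a)
        assert f["x_mean"] == 2.5
        assert f["x_median"] == 2.5
        assert f["x_variance"] == 1.25
        assert f["x_iqr"] == 1.5
        assert f["x_mad"] == 1.0

    def test_perfect_linear_dependence(self, rng):
        x = rng.normal(size=60)
        a = np.column_stack([x, 2 * x + 1, rng.normal(size=60)])
        f = time_domain_features(a)
        assert f["corr_xy"] == pytest.approx(1.0, abs=1e-12)

    def test_too_few_samples_flagged_invalid(self):
        assert time_domain_features(np.zeros((3, 3))) is None
        assert frequency_domain_features(np.zeros((2, 3))) is None

    def test_matches_brute_force_oracle_on_random_windows(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 80))
            a = rng.normal(0, 3, (n, 3)) + rng.uniform(-10, 10, 3)
            f = time_domain_features(a)
            for i, ax in enumerate("xyz"):
                v = list(a[:, i])
                assert f[f"{ax}_mean"] == pytest.approx(orc.mean(v), rel=1e-9)
                assert f[f"{ax}_median"] == pytest.approx(orc.median(v), rel=1e-9)
                assert f[f"{ax}_variance"] == pytest.approx(orc.variance_pop(v), rel=1e-9)
                assert f[f"{ax}_std"] == pytest.approx(orc.std_pop(v), rel=1e-9)
                assert f[f"{ax}_iqr"] == pytest.approx(orc.iqr(v), rel=1e-9, abs=1e-12)
                assert f[f"{ax}_mad"] == pytest.approx(orc.mad(v), rel=1e-9, abs=1e-12)
                assert f[f"{ax}_kurtosis"] == pytest.approx(
                    orc.kurtosis_excess(v), rel=1e-9, abs=1e-12)
                assert f[f"{ax}_entropy_time"] == pytest.approx(
                    orc.entropy_time(v), rel=1e-9, abs=1e-12)
            assert f["corr_xy"] == pytest.approx(
                orc.pearson(a[:, 0], a[:, 1]), rel=1e-9, abs=1e-12)
            g = orc.gravity_lowpass([list(r) for r in a])
            np.testing.assert_allclose(
                [f["gravity_x"], f["gravity_y"], f["gravity_z"]], g, rtol=1e-9)
            np.testing.assert_allclose(
                [f["orientation_x"], f["orientation_y"], f["orientation_z"]],
                orc.orientation(g), rtol=1e-9, atol=1e-12)

    def test_invariant_ranges(self, rng):
        for _ in range(50):
            a = rng.normal(0, 2, (int(rng.integers(4, 60)), 3))
            f = time_domain_features(a)
            for ax in "xyz":
                assert f[f"{ax}_variance"] >= 0
                assert f[f"{ax}_std"] == pytest.approx(
                    np.sqrt(f[f"{ax}_variance"]))
                assert f[f"{ax}_iqr"] >= 0 and f[f"{ax}_mad"] >= 0
                assert f[f"{ax}_entropy_time"] >= 0
                assert 0 <= f[f"orientation_{ax}"] <= np.pi
            for pair in ("xy", "xz", "yz"):
                assert -1 <= f[f"corr_{pair}"] <= 1


class TestFrequencyDomain:
    def test_zero_signal(self):
        f = frequency_domain_features(np.zeros((32, 3)))
        for ax in "xyz":
            assert f[f"{ax}_energy"] == 0
            assert f[f"{ax}_entropy_freq"] == 0
            assert f[f"{ax}_mean_dc"] == 0

    def test_constant_signal_power_all_in_dc(self):
        a = np.full((25, 3), 7.5)
        f = frequency_domain_features(a)
        for ax in "xyz":
            assert f[f"{ax}_energy"] == pytest.approx(0, abs=1e-9)
            assert f[f"{ax}_mean_dc"] == pytest.approx(7.5)

    def test_pure_sinusoid_entropy_ln2_and_energy_vs_direct_dft(self):
        n = 50
        t = np.arange(n)
        v = np.sin(2 * np.pi * 5 * t / n)  # 5 full periods in the window
        a = np.column_stack([v, v, v])
        f = frequency_domain_features(a)
        assert f["x_entropy_freq"] == pytest.approx(np.log(2), abs=1e-9)
        _, energy, ent = orc.spectral_features(list(v))
        assert f["x_energy"] == pytest.approx(energy, abs=1e-6)
        assert f["x_entropy_freq"] == pytest.approx(ent, abs=1e-9)

    def test_matches_direct_dft_oracle_on_random_windows(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 40))
            a = rng.normal(0, 2, (n, 3))
            f = frequency_domain_features(a)
            for i, ax in enumerate("xyz"):
                dc, energy, ent = orc.spectral_features(list(a[:, i]))
                assert f[f"{ax}_mean_dc"] == pytest.approx(dc, abs=1e-6)
                assert f[f"{ax}_energy"] == pytest.approx(energy, rel=1e-6)
                assert f[f"{ax}_entropy_freq"] == pytest.approx(ent, abs=1e-6)

    def test_parseval_identity(self, rng):
        # sum_t a_t^2 = N*mean_dc^2 + energy under the DC-excluded convention
        for _ in range(50):
            n = int(rng.integers(4, 64))
            a = rng.normal(0, 3, (n, 3))
            f = frequency_domain_features(a)
            for i, ax in enumerate("xyz"):
                lhs = float(np.sum(a[:, i] ** 2))
                rhs = n * f[f"{ax}_mean_dc"] ** 2 + f[f"{ax}_energy"]
                assert lhs == pytest.approx(rhs, rel=1e-6)


class TestExtract:
    def test_identical_streams_give_symmetric_blocks(self, rng):
        t = np.arange(0, 5000, 20).astype(np.int64)
        a = rng.normal(0, 1, (t.size, 3)) + [0, 0, 9.81]
        left = make_stream(t, a)
        right = make_stream(t, a.copy(), WristPosition.RIGHT_WRIST)
        grid = make_window_grid(0, 5000, 1000, 0.5)
        X, windows = extract_imu_features(left, right, grid)
        assert X.shape == (len(grid), 84)
        np.testing.assert_array_equal(X[:, :42], X[:, 42:])

    def test_60s_session_at_75_percent_overlap_yields_237_rows(self):
        left = ideal_stream(60000)
        right = ideal_stream(60000, value=(1.0, 0.0, 9.0))
        grid = make_window_grid(0, 60000, 1000, 0.75)
        X, windows = extract_imu_features(left, right, grid)
        assert X.shape[0] == 237
        assert len(grid) == 237

    def test_gap_windows_dropped(self):
        t = np.concatenate([np.arange(0, 5000, 20), np.arange(10000, 15000, 20)])
        a = np.tile([0.0, 0.0, 9.81], (t.size, 1))
        s = make_stream(t.astype(np.int64), a)
        grid = make_window_grid(0, 15000, 1000, 0.5)
        X, windows = extract_imu_features(s, s, grid)
        kept_starts = {w.start_ms for w in windows}
        assert 6000 not in kept_starts and 7000 not in kept_starts
        assert X.shape[0] == len(windows) < len(grid)

    def test_determinism_bit_identical(self, rng):
        t = np.arange(0, 8000, 20).astype(np.int64)
        a = rng.normal(0, 1, (t.size, 3))
        s1 = make_stream(t, a)
        s2 = make_stream(t, a.copy(), WristPosition.RIGHT_WRIST)
        grid = make_window_grid(0, 8000, 1000, 0.75)
        X1, _ = extract_imu_features(s1, s2, grid)
        X2, _ = extract_imu_features(s1, s2, grid)
        assert np.array_equal(X1, X2)

    def test_feature_frame_layout(self):
        left = ideal_stream(3000)
        grid = make_window_grid(0, 3000, 1000, 0.5)
        X, windows = extract_imu_features(left, left, grid)
        df = feature_frame(X, windows)
        assert list(df.columns[:3]) == ["window_index", "start_ms", "end_ms"]
        assert df.shape[1] == 3 + 84
        assert list(df.columns[3:45]) == [f"left_{n}" for n in FEATURE_NAMES]
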