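"""Activity quantification, flow metrics and the .flo container."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from farrowcast.flow import (FlowField, epe, estimate_flow, fl_all,
                             mean_displacement, normalize_series, read_flo,
                             segment_activity, smooth_series, write_flo)
from farrowcast.synth import generate_flow_pair


def const_field(u, v, shape=(4, 4)):
    return FlowField(u=np.full(shape, float(u)), v=np.full(shape, float(v)))


class TestMeanDisplacement:
    def test_zero_field_gives_zero_activity(self):
        assert mean_displacement(const_field(0, 0)) == 0.0

    def test_three_four_five_triangle(self):
        assert mean_displacement(const_field(3, 4)) == pytest.approx(5.0)

    def test_half_moving_half_still(self):
        u = np.zeros((2, 4))
        u[:, :2] = 1.0
        assert mean_displacement(FlowField(u=u, v=np.zeros((2, 4)))) == pytest.approx(0.5)

    def test_permutation_invariance_and_linearity(self, rng):
        u, v = rng.normal(size=(2, 6, 6))
        f = FlowField(u=u, v=v)
        perm = rng.permutation(36)
        fp = FlowField(u=u.ravel()[perm].reshape(6, 6), v=v.ravel()[perm].reshape(6, 6))
        assert mean_displacement(fp) == pytest.approx(mean_displacement(f))
        fc = FlowField(u=-2.5 * u, v=-2.5 * v)
        assert mean_displacement(fc) == pytest.approx(2.5 * mean_displacement(f))

    def test_rejects_mismatched_or_empty(self):
        with pytest.raises(ValueError):
            FlowField(u=np.zeros((2, 2)), v=np.zeros((2, 3)))
        with pytest.raises(ValueError):
            FlowField(u=np.zeros((0, 2)), v=np.zeros((0, 2)))


class TestSegmentActivity:
    def test_canonical_600_frame_segment(self):
        # 2 fps over 5 minutes: 600 frame-level values
        assert segment_activity(np.ones(600)) == pytest.approx(600.0)

    @pytest.mark.parametrize("vals,total", [([2.5], 2.5), ([1, 2, 3], 6.0)])
    def test_simple_sums(self, vals, total):
        assert segment_activity(vals) == pytest.approx(total)

    def test_negative_magnitude_rejected(self):
        with pytest.raises(ValueError):
            segment_activity([1.0, -0.1])
        with pytest.raises(ValueError):
            segment_activity([])


class TestNormalizeSeries:
    def test_reference_endpoints_map_to_0_and_100(self):
        assert normalize_series([3.0], 3.0, 9.0)[0] == 0.0
        assert normalize_series([9.0], 3.0, 9.0)[0] == 100.0

    def test_hand_computed_midpoints(self):
        out = normalize_series([0.0, 5.0, 10.0], 0.0, 10.0)
        assert out == pytest.approx([0.0, 50.0, 100.0])

    def test_out_of_range_clipped(self):
        out = normalize_series([-5.0, 15.0], 0.0, 10.0)
        assert out.tolist() == [0.0, 100.0]

    def test_degenerate_range(self):
        assert normalize_series([2.0, 2.0], 2.0, 2.0).tolist() == [0.0, 0.0]
        with pytest.raises(ValueError):
            normalize_series([1.0, 2.0], 2.0, 2.0)

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=30))
    def test_round_trip_recovers_input(self, vals):
        vals = np.asarray(vals)
        lo, hi = vals.min() - 1.0, vals.max() + 1.0
        norm = normalize_series(vals, lo, hi)
        back = norm / 100.0 * (hi - lo) + lo
        assert np.allclose(back, vals, atol=1e-9)


class TestSmoothSeries:
    def test_window_one_is_identity(self, rng):
        x = rng.normal(size=20)
        assert np.array_equal(smooth_series(x, 1), x)

    def test_constant_series_unchanged(self):
        assert np.allclose(smooth_series(np.full(10, 3.3), 5), 3.3)

    def test_truncated_edges_hand_example(self):
        assert smooth_series([0.0, 3.0, 0.0], 3).tolist() == [1.5, 1.0, 1.5]

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_series([1.0, 2.0, 3.0], 2)


class TestFlowErrors:
    def test_epe_identical_fields_zero(self, rng):
        u, v = rng.normal(size=(2, 5, 5))
        f = FlowField(u=u, v=v)
        assert epe(f, f) == 0.0

    def test_epe_345_offset(self):
        assert epe(const_field(3, 4), const_field(0, 0)) == pytest.approx(5.0)

    def test_epe_matches_bruteforce_loop(self, rng):
        a = FlowField(*rng.normal(size=(2, 16, 16)))
        b = FlowField(*rng.normal(size=(2, 16, 16)))
        acc = 0.0
        for i in range(16):
            for j in range(16):
                acc += np.sqrt((a.u[i, j] - b.u[i, j]) ** 2 + (a.v[i, j] - b.v[i, j]) ** 2)
        assert epe(a, b) == pytest.approx(acc / 256)
        assert epe(b, a) == pytest.approx(epe(a, b))

    def test_fl_all_trivial_extremes(self):
        f = const_field(1, 1)
        assert fl_all(f, f, 3.0) == 0.0
        assert fl_all(const_field(3, 4), const_field(0, 0), 3.0) == 100.0

    def test_fl_all_half_counting(self):
        u = np.zeros((2, 4))
        u[0, :] = 5.0
        pred = FlowField(u=u, v=np.zeros((2, 4)))
        assert fl_all(pred, const_field(0, 0, (2, 4)), 3.0) == pytest.approx(50.0)

    @given(st.integers(0, 2**31 - 1))
    def test_fl_all_nonincreasing_in_delta(self, seed):
        r = np.random.default_rng(seed)
        pred = FlowField(*r.normal(scale=3, size=(2, 8, 8)))
        truth = FlowField(*r.normal(scale=3, size=(2, 8, 8)))
        vals = [fl_all(pred, truth, d) for d in (0.5, 1.0, 2.0, 4.0, 8.0)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            epe(const_field(0, 0, (2, 2)), const_field(0, 0, (3, 3)))


class TestFloFormat:
    def test_round_trip_bit_exact(self, tmp_path, rng):
        f = FlowField(*rng.normal(size=(2, 5, 7)).astype(np.float32).astype(np.float64))
        path = tmp_path / "field.flo"
        write_flo(path, f)
        back = read_flo(path)
        assert np.array_equal(back.u, f.u) and np.array_equal(back.v, f.v)

    def test_bad_magic_rejected(self, tmp_path):
        p = tmp_path / "bad.flo"
        p.write_bytes(b"\x00" * 32)
        with pytest.raises(ValueError, match="magic"):
            read_flo(p)


class TestEstimateFlow:
    def test_recovers_integer_displacement_on_interior(self):
        (fa, fb), truth = generate_flow_pair(40, 40, displacement=(2, 1), seed=0)
        est = estimate_flow(fa, fb, search_radius=3)
        interior = np.s_[8:32, 8:32]
        assert np.allclose(est.u[interior], 2.0)
        assert np.allclose(est.v[interior], 1.0)
        assert fl_all(est, truth, 3.0) <= 25.0  # only wrap-around border blocks may miss

    def test_identical_frames_give_zero_field(self, rng):
        frame = rng.normal(size=(16, 16))
        est = estimate_flow(frame, frame.copy(), search_radius=2)
        assert np.allclose(est.u, 0) and np.allclose(est.v, 0)

    def test_unknown_backend_lists_registered(self):
        with pytest.raises(KeyError, match="block_matching"):
            estimate_flow(np.zeros((8, 8)), np.zeros((8, 8)), backend="nonexistent")
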