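"""Stream decoding and natural-neighbor gridding, with brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial import Delaunay

from virthist import phantom, scan_recon as sr
from virthist.encode import DualChannelImage


class TestDecodeEncoder:
    def test_static_states_give_zero_displacement(self):
        a = np.zeros(100, dtype=int)
        b = np.zeros(100, dtype=int)
        assert np.all(sr.decode_encoder(a, b) == 0)

    def test_full_forward_cycle_is_four_counts(self):
        # 00 -> 01 -> 11 -> 10 -> 00
        a = np.array([0, 0, 1, 1, 0])
        b = np.array([0, 1, 1, 0, 0])
        counts = sr.decode_encoder(a, b)
        assert counts[-1] == 4

    def test_reverse_cycle_is_minus_four_counts(self):
        a = np.array([0, 1, 1, 0, 0])
        b = np.array([0, 0, 1, 1, 0])
        assert sr.decode_encoder(a, b)[-1] == -4

    def test_counts_per_um_scaling(self):
        a = np.array([0, 0, 1, 1, 0])
        b = np.array([0, 1, 1, 0, 0])
        um = sr.decode_encoder(a, b, counts_per_um=8.0)
        assert um[-1] == pytest.approx(0.5)

    def test_double_bit_flip_raises_glitch_with_index(self):
        a = np.array([0, 0, 1])
        b = np.array([0, 0, 1])  # 00 -> 11 both bits flip
        with pytest.raises(sr.EncoderGlitchError) as exc:
            sr.decode_encoder(a, b)
        assert exc.value.index == 2

    @given(st.lists(st.integers(-1, 1), min_size=1, max_size=200))
    @settings(max_examples=50, deadline=None)
    def test_quadrature_roundtrip_recovers_any_walk(self, steps):
        """Encoding a random ±1 walk and decoding returns the walk."""
        counts = np.concatenate([[0], np.cumsum(steps)])
        order = np.array(sr._QUAD_ORDER)
        phase = np.mod(counts, 4)
        decoded = sr.decode_encoder(order[phase, 0], order[phase, 1])
        assert np.array_equal(decoded, counts)

    def test_phantom_trajectory_positions_within_one_count(self):
        dual = DualChannelImage(np.full((16, 16), 0.5), np.full((16, 16), 0.5))
        traj = phantom.TrajectorySpec(duration=0.05)
        stream = phantom.make_scan_stream(dual, traj, seed=0)
        x = sr.decode_encoder(stream.encoder_x_a, stream.encoder_x_b,
                              stream.counts_per_um)
        extent = 15 * 0.25
        t = np.arange(len(stream)) / traj.sample_rate
        x_true = extent / 2 * (1 - np.cos(2 * np.pi * traj.fast_freq * t))
        assert np.max(np.abs(x - x_true)) <= 1.0 / traj.counts_per_um + 1e-9


class TestExtractSamples:
    def _stream(self, pars, scat, markers, n=None):
        n = n or len(pars)
        zeros = np.zeros(n, dtype=int)
        return sr.ScanStream(markers, pars, scat, zeros, zeros, zeros, zeros,
                             sample_rate=1e5)

    def test_triangular_pulse_apex_extracted(self):
        pars = np.zeros(20)
        pars[5:8] = [0.4, 0.9, 0.3]
        stream = self._stream(pars, np.zeros(20), [4])
        pts = sr.extract_samples(stream, window=5)
        assert pts.pars_value[0] == pytest.approx(0.9)

    def test_zero_traces_give_zero_values(self):
        stream = self._stream(np.zeros(30), np.zeros(30), [2, 12, 22])
        pts = sr.extract_samples(stream, window=5)
        assert np.all(pts.pars_value == 0)
        assert len(pts) == 3

    def test_truncated_event_dropped_with_warning(self):
        stream = self._stream(np.ones(20), np.ones(20), [2, 18])
        with pytest.warns(UserWarning, match="truncated"):
            pts = sr.extract_samples(stream, window=5)
        assert len(pts) == 1

    def test_output_length_equals_accepted_events(self):
        stream = self._stream(np.ones(100), np.ones(100), [0, 10, 20, 30])
        assert len(sr.extract_samples(stream, window=5)) == 4

    def test_phantom_roundtrip_values_match_image(self, small_phantom):
        _, dual, _ = small_phantom
        traj = phantom.TrajectorySpec(duration=0.2)
        stream = phantom.make_scan_stream(dual, traj, seed=0)
        pts = sr.extract_samples(stream, traj.pulse_window)
        # spot check: sampled values must lie within the image value range
        assert pts.pars_value.min() >= 0
        assert pts.pars_value.max() <= dual.pars.max() + 1e-9


def _oracle_sibson_weights(pts, q, res=1200):
    """Brute-force Sibson weights by pixel counting of stolen Voronoi area."""
    lo = pts.min(0) - 1
    hi = pts.max(0) + 1
    xs = np.linspace(lo[0], hi[0], res)
    ys = np.linspace(lo[1], hi[1], res)
    gx, gy = np.meshgrid(xs, ys)
    p = np.stack([gx.ravel(), gy.ravel()], 1)
    d_old = ((p[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    near_old = d_old.argmin(1)
    stolen = ((p - q) ** 2).sum(-1) < d_old.min(1)
    w = np.bincount(near_old[stolen], minlength=len(pts)).astype(float)
    return w / w.sum()


class TestGridInterpolate:
    def test_values_reproduced_at_sites(self, rng):
        pts = np.array([[0, 0], [4, 0], [0, 4], [4, 4], [2, 2], [1, 3], [3, 1]],
                       dtype=float)
        vals = rng.normal(size=7)
        sp = sr.SamplePoints(pts[:, 0], pts[:, 1], vals, vals)
        grid = sr.GridSpec(0, 0, 5, 5, 1.0)
        out = sr.grid_interpolate(sp, grid, "pars", method="sibson", fill=np.nan)
        assert out[2, 2] == vals[4]
        assert out[0, 0] == vals[0]
        assert out[3, 1] == vals[5]

    def test_partition_of_unity_constant_field(self, rng):
        pts = rng.uniform(0, 10, size=(60, 2))
        vals = np.full(60, 5.5)
        sp = sr.SamplePoints(pts[:, 0], pts[:, 1], vals, vals)
        grid = sr.GridSpec(2, 2, 20, 20, 0.3)
        out = sr.grid_interpolate(sp, grid, "pars", method="sibson", fill=np.nan)
        assert np.nanmax(np.abs(out - 5.5)) < 1e-12

    def test_affine_field_exact_within_hull(self, rng):
        pts = rng.uniform(0, 10, size=(80, 2))
        a, b, c = 0.3, -0.7, 2.0
        vals = a * pts[:, 0] + b * pts[:, 1] + c
        sp = sr.SamplePoints(pts[:, 0], pts[:, 1], vals, vals)
        grid = sr.GridSpec(2, 2, 25, 25, 0.25)
        out = sr.grid_interpolate(sp, grid, "pars", method="sibson", fill=np.nan)
        xs, ys = grid.node_coords()
        gx, gy = np.meshgrid(xs, ys)
        expected = a * gx + b * gy + c
        scale = np.abs(expected).max()
        assert np.nanmax(np.abs(out - expected)) / scale < 1e-6

    def test_sibson_weights_match_area_stealing_oracle(self, rng):
        pts = rng.uniform(0, 10, size=(30, 2))
        tri = Delaunay(pts)
        centers, r2 = sr._circumcenters(pts, tri.simplices)
        for q in ([5.0, 5.0], [3.3, 6.1], [6.8, 2.9]):
            q = np.array(q)
            nbrs, w = sr.sibson_weights(tri, centers, r2, q)
            wfull = np.zeros(len(pts))
            wfull[nbrs] = w
            oracle = _oracle_sibson_weights(pts, q)
            assert np.abs(wfull - oracle).max() < 5e-3

    def test_outside_hull_uses_fill_value(self, rng):
        pts = rng.uniform(4, 6, size=(20, 2))
        vals = rng.normal(size=20)
        sp = sr.SamplePoints(pts[:, 0], pts[:, 1], vals, vals)
        grid = sr.GridSpec(0, 0, 3, 3, 1.0)  # entirely outside the hull
        out = sr.grid_interpolate(sp, grid, "pars", method="sibson", fill=-7.0)
        assert np.all(out == -7.0)

    def test_collinear_points_raise_degenerate_error(self):
        x = np.arange(5, dtype=float)
        sp = sr.SamplePoints(x, x, x, x)
        grid = sr.GridSpec(0, 0, 4, 4, 1.0)
        with pytest.raises(sr.DegenerateGeometryError):
            sr.grid_interpolate(sp, grid, "pars")

    def test_duplicate_positions_averaged(self):
        x = np.array([0, 0, 4, 0, 4.0])
        y = np.array([0, 0, 0, 4, 4.0])
        v = np.array([1.0, 3.0, 5.0, 5.0, 5.0])  # duplicates at origin -> 2.0
        sp = sr.SamplePoints(x, y, v, v)
        grid = sr.GridSpec(0, 0, 2, 2, 1.0)
        out = sr.grid_interpolate(sp, grid, "pars", method="sibson", fill=np.nan)
        assert out[0, 0] == pytest.approx(2.0)

    def test_linear_fallback_agrees_on_affine_field(self, rng):
        pts = rng.uniform(0, 10, size=(50, 2))
        vals = 1.1 * pts[:, 0] - 0.4 * pts[:, 1]
        sp = sr.SamplePoints(pts[:, 0], pts[:, 1], vals, vals)
        grid = sr.GridSpec(3, 3, 10, 10, 0.4)
        o1 = sr.grid_interpolate(sp, grid, "pars", method="sibson", fill=np.nan)
        o2 = sr.grid_interpolate(sp, grid, "pars", method="linear", fill=np.nan)
        assert np.nanmax(np.abs(o1 - o2)) < 1e-9

    def test_ramp_roundtrip_through_scan_stream(self):
        """make_scan_stream -> extract -> grid recovers a smooth ramp."""
        h = w = 32
        yy, xx = np.mgrid[0:h, 0:w]
        ramp = (0.3 * xx + 0.5 * yy) / (0.8 * max(h, w))
        dual = DualChannelImage(ramp, ramp, 250.0)
        traj = phantom.TrajectorySpec(fast_freq=20, prr=20000,
                                      sample_rate=400000, duration=1.0,
                                      counts_per_um=40)
        stream = phantom.make_scan_stream(dual, traj, seed=0)
        pts = sr.extract_samples(stream, traj.pulse_window)
        grid = sr.GridSpec(0, 0, w, h, 0.25)
        rec = sr.grid_interpolate(pts, grid, "pars", method="linear", fill=np.nan)
        mask = ~np.isnan(rec)
        assert mask.mean() > 0.9
        assert np.abs(rec - ramp)[mask].max() < 1e-6
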