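"""Honeycomb removal: core means, Delaunay-linear interpolation,
percentile subtraction."""

import numpy as np
import pytest

import fiberscope as fs
from fiberscope.io import GridTransform
from fiberscope.reconstruction import CoreInterpolator


def small_coremap():
    labels = np.zeros((6, 9), np.int64)
    labels[1:3, 1:3] = 1
    labels[1:3, 5:7] = 2
    labels[4, 4] = 3
    centers = np.array([[1.5, 1.5], [1.5, 5.5], [4.0, 4.0]])
    return fs.CoreMap(labels, centers, labels > 0, 3)


class TestExtractCoreMeans:
    def test_constant_frame_gives_constant_means(self):
        cm = small_coremap()
        stack = fs.RawStack(frames=np.full((2, 6, 9), 7, np.uint16))
        m = fs.extract_core_means(stack, cm)
        assert np.all(m.values == 7)

    def test_region_mean_is_arithmetic(self):
        cm = small_coremap()
        frame = np.zeros((6, 9), np.uint16)
        frame[1, 1], frame[1, 2], frame[2, 1], frame[2, 2] = 2, 4, 6, 4
        stack = fs.RawStack(frames=frame[None])
        m = fs.extract_core_means(stack, cm)
        assert m.values[0, 0] == pytest.approx(4.0)

    def test_geometry_mismatch_raises(self):
        cm = small_coremap()
        with pytest.raises(ValueError):
            fs.extract_core_means(
                fs.RawStack(frames=np.zeros((1, 5, 5), np.uint16)), cm
            )

    def test_one_cell_movie_core_means_track_transient(self, noise_free):
        cfg, stack, truth, ref, coremap = noise_free
        m = fs.extract_core_means(stack, coremap)
        assert m.values.shape == (cfg.n_frames, coremap.n_cores)
        assert np.isfinite(m.values).all()


class TestInterpolation:
    def test_affine_field_exact(self):
        """Barycentric-linear interpolation reproduces f = 1 + x + 2y."""
        centers = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0]])  # (y, x)
        values = np.array([1.0, 2.0, 3.0])  # 1 + x + 2y at the nodes
        grid = GridTransform(origin=(-0.005, -0.005), scale=0.01, n_grid=100)
        frame, mask = fs.interpolate_frame(values, centers, grid)
        # grid index (24, 24) has raw coordinate (0.24+0.005-0.005) = 0.24...
        yy = (np.arange(100) + 0.5) * 0.01 - 0.005
        expect = 1.0 + yy[None, :] + 2.0 * yy[:, None]
        assert np.allclose(frame[mask], expect[mask], atol=1e-12)
        # the specific point (0.25, 0.25) -> 1.75
        i = np.argmin(np.abs(yy - 0.25))
        assert frame[i, i] == pytest.approx(1.75, abs=1e-9)

    def test_constant_values_fill_hull(self, noise_free):
        *_, coremap = noise_free
        grid = fs.grid_from_coremap(coremap)
        interp = CoreInterpolator(coremap.centers_px, grid)
        frame = interp(np.full(coremap.n_cores, 42.0))
        assert np.allclose(frame[interp.valid_mask], 42.0, atol=1e-9)
        assert np.all(frame[~interp.valid_mask] == 0.0)

    def test_node_interpolation_matches_core_values(self, noise_free):
        """Evaluated at a core center, the interpolant returns that core's
        value (linear interpolation is nodal)."""
        *_, coremap = noise_free
        from scipy.interpolate import LinearNDInterpolator
        from scipy.spatial import Delaunay

        rng = np.random.default_rng(0)
        values = rng.uniform(10, 100, coremap.n_cores)
        tri = Delaunay(coremap.centers_px)
        f = LinearNDInterpolator(tri, values)
        at_nodes = f(coremap.centers_px)
        assert np.allclose(at_nodes, values, atol=1e-8)

    def test_impulse_fwhm_equals_lattice_spacing(self, unjittered):
        """A single bright core reconstructs as a tent of FWHM one lattice
        spacing — the sampling-limited effective resolution."""
        cfg, truth, ref, coremap = unjittered
        grid = fs.grid_from_coremap(coremap)
        interp = CoreInterpolator(coremap.centers_px, grid)
        i = np.argmin(
            np.abs(coremap.centers_px - coremap.centers_px.mean(0)).sum(1)
        )
        values = np.zeros(coremap.n_cores)
        values[i] = 1.0
        frame = interp(values)
        peak = np.unravel_index(np.argmax(frame), frame.shape)
        profile = frame[peak[0], :]
        w_grid = fs.fwhm(profile, pixel_size_um=1.0)
        spacing_grid = cfg.lattice_spacing_um / cfg.raw_pixel_um / grid.scale
        assert w_grid == pytest.approx(spacing_grid, abs=1.0)

    def test_too_few_or_collinear_centers_raise(self):
        grid = GridTransform((0, 0), 1.0, 8)
        with pytest.raises(ValueError):
            fs.interpolate_frame(np.ones(2), np.array([[0, 0], [1, 1]]), grid)
        collinear = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        with pytest.raises(ValueError):
            fs.interpolate_frame(np.ones(4), collinear, grid)


class TestSubtractPercentile:
    def make_recon(self, frames, mask=None):
        frames = np.asarray(frames, np.float32)
        if mask is None:
            mask = np.ones(frames.shape[1:], bool)
        return fs.ReconStack(frames=frames, valid_mask=mask)

    def test_constant_frame_becomes_zero(self):
        recon = self.make_recon(np.full((2, 4, 4), 5.0))
        out = fs.subtract_percentile(recon)
        assert np.allclose(out.frames, 0.0)
        assert out.background_subtracted

    def test_linear_interpolation_percentile_convention(self):
        frame = np.array([[1.0, 2.0], [3.0, 4.0]])
        out = fs.subtract_percentile(self.make_recon(frame[None]), p=25)
        # 25th percentile of {1,2,3,4} by linear interpolation is 1.75
        assert np.allclose(out.frames[0], frame - 1.75)

    def test_per_frame_offsets_cancel_exactly(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(0, 100, (8, 8)).astype(np.float32)
        offsets = np.array([0.0, 5.0, -3.0, 11.0], np.float32)
        frames = base[None] + offsets[:, None, None]
        out = fs.subtract_percentile(self.make_recon(frames))
        for t in range(1, 4):
            assert np.allclose(out.frames[t], out.frames[0], atol=1e-4)

    def test_zeroes_the_in_mask_percentile_of_every_frame(self, insitu_recon):
        *_, recon = insitu_recon
        for t in range(0, recon.n_frames, 37):
            q = np.percentile(recon.frames[t][recon.valid_mask], 25)
            assert q == pytest.approx(0.0, abs=0.01)

    def test_double_subtraction_rejected(self):
        out = fs.subtract_percentile(self.make_recon(np.ones((1, 4, 4))))
        with pytest.raises(ValueError, match="already"):
            fs.subtract_percentile(out)

    def test_negatives_retained_outside_mask_untouched(self):
        mask = np.zeros((4, 4), bool)
        mask[1:3, 1:3] = True
        frames = np.arange(16, dtype=np.float32).reshape(1, 4, 4)
        out = fs.subtract_percentile(self.make_recon(frames.copy(), mask))
        assert (out.frames[0][mask] < 0).any()
        assert np.array_equal(out.frames[0][~mask], frames[0][~mask])

    def test_flicker_cv_lower_with_per_frame_subtraction(self):
        """For a gain-flickered static background movie, per-frame
        percentile subtraction beats a single fixed baseline: the remaining
        ROI-trace variation is strictly smaller."""
        rng = np.random.default_rng(2)
        base = rng.uniform(80, 120, (16, 16)).astype(np.float64)
        gains = 1.0 + 0.05 * rng.standard_normal(40)
        frames = gains[:, None, None] * base[None]
        recon = self.make_recon(frames)
        roi = np.zeros((16, 16), bool)
        roi[4:10, 4:10] = True

        per_frame = fs.subtract_percentile(recon).frames
        fixed = frames - np.percentile(frames[0], 25)
        trace_pf = per_frame[:, roi].mean(axis=1)
        trace_fx = fixed[:, roi].mean(axis=1)
        assert trace_pf.std() < trace_fx.std()
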