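"""Generator correctness: lattice geometry, transient shape, rendering."""

import numpy as np
import pytest

import fiberscope as fs
from fiberscope.synthetic import (
    CellSpec,
    MotionSpec,
    NoiseSpec,
    SyntheticConfig,
    cell_transient,
    default_insitu_config,
    generate_lattice,
    render_movie,
)


def brute_force_hex_count(spacing, diameter):
    """Independent enumeration of hex-lattice points inside the circle."""
    r = diameter / 2.0
    row = spacing * np.sqrt(3.0) / 2.0
    n = 0
    i = -int(np.ceil(r / row)) - 2
    while i <= int(np.ceil(r / row)) + 2:
        y = i * row
        off = spacing / 2.0 if i % 2 else 0.0
        j = -int(np.ceil(r / spacing)) - 2
        while j <= int(np.ceil(r / spacing)) + 2:
            x = j * spacing + off
            if y * y + x * x <= r * r:
                n += 1
            j += 1
        i += 1
    return n


class TestLattice:
    def test_count_matches_brute_force_enumeration(self):
        cfg = default_insitu_config(
            lattice_spacing_um=3.676, fov_diameter_um=147.5, jitter_sd_um=0.0
        )
        centers = generate_lattice(cfg)
        assert len(centers) == brute_force_hex_count(3.676, 147.5)
        assert 1400 <= len(centers) <= 1520  # ideal packing predicts ~1460

    def test_unjittered_min_nn_distance_equals_spacing(self):
        cfg = default_insitu_config(jitter_sd_um=0.0)
        centers = generate_lattice(cfg)
        from scipy.spatial import cKDTree

        d, _ = cKDTree(centers).query(centers, k=2)
        assert d[:, 1].min() == pytest.approx(cfg.lattice_spacing_um, abs=1e-9)

    def test_degenerate_spacing_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            generate_lattice(
                default_insitu_config(fov_diameter_um=10.0, lattice_spacing_um=20.0)
            )

    def test_jitter_is_seed_deterministic(self):
        cfg = default_insitu_config(jitter_sd_um=0.1, seed=3)
        assert np.array_equal(generate_lattice(cfg), generate_lattice(cfg))


class TestTransient:
    CELL = CellSpec(
        center_um=(0, 0), radius_um=5, baseline=100, amplitude_rel=0.6,
        onset_s=10.0, rise_s=2.0, plateau_s=4.0, decay_s=20.0,
    )

    @pytest.mark.parametrize(
        "t,expected",
        [
            (0.0, 1.0),
            (9.99, 1.0),  # baseline before onset
            (12.0, 1.6),  # top of the rise (the in-situ 1.6-fold response)
            (14.0, 1.6),  # still on the plateau
        ],
    )
    def test_piecewise_values(self, t, expected):
        assert cell_transient(self.CELL, t) == pytest.approx(expected)

    def test_decay_reaches_one_over_e_at_tau(self):
        cell = CellSpec(
            center_um=(0, 0), radius_um=5, baseline=100, amplitude_rel=1.0,
            onset_s=5.0, rise_s=1.0, plateau_s=2.0, decay_s=7.0,
        )
        t = 5.0 + 1.0 + 2.0 + 7.0
        assert cell_transient(cell, t) == pytest.approx(1.0 + np.exp(-1.0))

    def test_optional_dip_only_when_enabled(self):
        dip = CellSpec(
            center_um=(0, 0), radius_um=5, baseline=100, amplitude_rel=0.5,
            onset_s=10.0, rise_s=2.0, dip_s=4.0, dip_amplitude_rel=0.2,
        )
        assert cell_transient(dip, 8.0) == pytest.approx(0.8)
        assert cell_transient(self.CELL, 8.0) == 1.0


class TestRender:
    def test_static_scene_frames_identical_per_channel(self):
        cfg = default_insitu_config(
            n_frames=6, cells=(), flicker_sd=0.0, noise=NoiseSpec(0, 0),
            channel_sequence=("395", "475"),
            autofluorescence_per_channel={"395": 400.0, "475": 150.0},
        )
        stack, _ = render_movie(cfg)
        for c in (0, 1):
            ch = stack.frames[c::2]
            assert all(np.array_equal(ch[0], f) for f in ch[1:])
        assert not np.array_equal(stack.frames[0], stack.frames[1])

    def test_channel_cycling_starts_at_frame_zero(self):
        cfg = default_insitu_config(
            n_frames=10,
            channel_sequence=("475", "555"),
            autofluorescence_per_channel={"475": 150.0, "555": 90.0},
        )
        stack, _ = render_movie(cfg)
        assert stack.frame_channels() == ["475", "555"] * 5

    def test_fixed_seed_reproduces_byte_identical_movie(self, tmp_path):
        cfg = default_insitu_config(n_frames=4)
        s1, t1 = render_movie(cfg)
        s2, t2 = render_movie(cfg)
        assert np.array_equal(s1.frames, s2.frames)
        assert np.array_equal(t1.per_frame_shift_px, t2.per_frame_shift_px)
        p1, p2 = tmp_path / "a.tif", tmp_path / "b.tif"
        fs.write_stack(s1, p1)
        fs.write_stack(s2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_saturation_raises_not_clips(self):
        cfg = default_insitu_config(
            n_frames=2, cells=(),
            autofluorescence_per_channel={"475": 70000.0},
        )
        with pytest.raises(fs.synthetic.SaturationError, match="saturation"):
            render_movie(cfg)

    def test_ground_truth_invariants(self, invivo_motion):
        _, truth, _ = invivo_motion
        assert tuple(truth.per_frame_shift_px[0]) == (0, 0)
        t_before = truth.config.frame_times_s < min(
            c.onset_s for c in truth.config.cells if c.amplitude_rel > 0
        )
        responding = [
            i for i, c in enumerate(truth.config.cells) if c.amplitude_rel > 0
        ]
        assert np.allclose(truth.cell_traces[responding][:, t_before], 1.0)

    def test_core_trace_proportional_to_transient_times_gain(self):
        """One cell, one channel, no noise/motion: the mean trace over cores
        under the cell follows baseline x transient x gain."""
        cell = CellSpec(
            center_um=(0.0, 0.0), radius_um=10.0, baseline=300.0,
            amplitude_rel=0.6, onset_s=3.0, rise_s=2.0, plateau_s=3.0,
            decay_s=10.0,
        )
        cfg = default_insitu_config(
            n_frames=80, cells=(cell,), noise=NoiseSpec(0, 0), flicker_sd=0.02
        )
        stack, truth = render_movie(cfg)
        coremap = fs.segment_cores(fs.build_reference(stack))
        matrix = fs.extract_core_means(stack, coremap)
        d = np.hypot(
            coremap.centers_px[:, 0] - 255.5, coremap.centers_px[:, 1] - 255.5
        )
        under = d < 0.5 * cell.radius_um / cfg.raw_pixel_um
        trace = matrix.values[:, under].mean(axis=1)
        af = cfg.autofluorescence_per_channel["475"]
        model = (af + cell.baseline * truth.cell_traces[0]) * truth.gains
        trace_n = trace / trace[0]
        model_n = model / model[0]
        assert np.allclose(trace_n, model_n, rtol=0.01)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(core_fwhm_um=5.0, lattice_spacing_um=3.7)
        with pytest.raises(ValueError):
            SyntheticConfig(n_frames=0)
        with pytest.raises(ValueError):
            SyntheticConfig(channel_sequence=())
        with pytest.raises(ValueError):
            CellSpec(center_um=(0, 0), radius_um=1, baseline=-5,
                     amplitude_rel=0.5, onset_s=1, rise_s=1)


def test_motion_spec_zero_at_frame_zero_and_quantized():
    spec = MotionSpec(amplitude_px=16.0, period_s=2.5, quantum_px=4)
    t = np.arange(50) / 7.6
    s = spec.shifts(t)
    assert tuple(s[0]) == (0, 0)
    assert np.all(s % 4 == 0)
    assert np.abs(s).max() >= 12  # actually moves
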