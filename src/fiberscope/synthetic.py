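"""Synthetic fiber-bundle microendoscope movies with known ground truth.

A multicore imaging fiber relays the sample plane through ~1500 individually
guiding cores arranged in a (slightly imperfect) hexagonal lattice inside a
circular image field.  The raw camera frame therefore shows a honeycomb of
bright core spots on dark cladding, superimposed on every artifact the
processing pipeline exists to remove: channel-dependent core
autofluorescence, per-frame multiplicative gain flicker, rigid
breathing-like motion, and shot/read noise.  This module renders such movies
from first principles so that segmentation, reconstruction, registration and
trace extraction can be validated against exact ground truth.

The scene model is deliberately simple: sparse disk-shaped cells whose
relative brightness follows a piecewise transient (linear rise, optional
plateau, exponential decay).  Each core integrates the scene through a
Gaussian aperture whose FWHM equals the core diameter, and is painted onto
the raw frame as a Gaussian spot at its (sub-pixel) position.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "CellSpec",
    "MotionSpec",
    "NoiseSpec",
    "SyntheticConfig",
    "GroundTruth",
    "SaturationError",
    "generate_lattice",
    "cell_transient",
    "render_movie",
    "default_insitu_config",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # sigma = FWHM / 2.355


class SaturationError(ValueError):
    """Scene exceeds the 16-bit camera range beyond the allowed tolerance."""


@dataclass(frozen=True)
class CellSpec:
    """One fluorescent cell: a disk with a calcium-transient time course.

    ``center_um`` is (y, x) in the sample plane relative to the center of the
    field of view.  ``channel_response`` scales the cell's brightness per
    excitation channel (all 1.0 for a single-channel indicator; asymmetric
    for ratiometric sensors such as roGFP2).  The optional pre-rise dip
    (``dip_s``/``dip_amplitude_rel``) models the brief signal decline seen in
    some in-situ recordings; it is off by default.
    """

    center_um: tuple[float, float]
    radius_um: float
    baseline: float
    amplitude_rel: float
    onset_s: float
    rise_s: float
    plateau_s: float = 0.0
    decay_s: float = 20.0
    channel_response: Mapping[str, float] = field(default_factory=dict)
    dip_s: float = 0.0
    dip_amplitude_rel: float = 0.0
    edge_sigma_um: float = 0.0  # soft-edge width; 0 = sharp disk

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        if self.rise_s <= 0 or self.decay_s <= 0:
            raise ValueError("rise_s and decay_s must be positive")
        if self.amplitude_rel < 0:
            raise ValueError("amplitude_rel must be non-negative")

    def response(self, channel: str) -> float:
        return float(self.channel_response.get(channel, 1.0))


@dataclass(frozen=True)
class MotionSpec:
    """Rigid sinusoidal in-plane motion of the sample relative to the fiber.

    Shifts are integer raw pixels: ``quantum_px`` rounds the sinusoid to
    multiples of that many pixels (set it to the reconstruction downsample
    factor to generate motion the grid-level registration can recover
    exactly).  Frame 0 always has zero shift.
    """

    amplitude_px: float
    period_s: float
    quantum_px: int = 1

    def shifts(self, times_s: np.ndarray) -> np.ndarray:
        """(T, 2) integer (dy, dx) scene displacement per frame."""
        w = 2.0 * np.pi / self.period_s
        dy = self.amplitude_px * np.sin(w * times_s)
        dx = 0.5 * self.amplitude_px * np.sin(2.0 * w * times_s)
        q = max(int(self.quantum_px), 1)
        out = np.stack([dy, dx], axis=1)
        return (q * np.round(out / q)).astype(int)


@dataclass(frozen=True)
class NoiseSpec:
    """Photon shot noise plus Gaussian read noise.

    ``photons_per_count`` scales counts to photons before Poisson sampling
    (0 disables shot noise); ``read_noise_sd`` is in camera counts.
    """

    photons_per_count: float = 1.0
    read_noise_sd: float = 2.0

    @property
    def enabled(self) -> bool:
        return self.photons_per_count > 0 or self.read_noise_sd > 0


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of a synthetic recording session."""

    fov_diameter_um: float = 147.5
    lattice_spacing_um: float = 3.71
    jitter_sd_um: float = 0.10
    core_fwhm_um: float = 2.34
    raw_pixel_um: float = 0.2883
    frame_shape: tuple[int, int] = (512, 512)
    n_frames: int = 258
    frame_rate_fps: float = 4.3
    channel_sequence: tuple[str, ...] = ("475",)
    autofluorescence_per_channel: Mapping[str, float] = field(
        default_factory=lambda: {"475": 150.0}
    )
    flicker_sd: float = 0.01
    motion: MotionSpec | None = None
    cells: tuple[CellSpec, ...] = ()
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    clip_tolerance: float = 0.0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.fov_diameter_um <= 0 or self.lattice_spacing_um <= 0:
            raise ValueError("FOV diameter and lattice spacing must be positive")
        if not self.core_fwhm_um < self.lattice_spacing_um:
            raise ValueError("core FWHM must be smaller than the lattice spacing")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not self.channel_sequence:
            raise ValueError("channel_sequence must be non-empty")
        for ch in self.channel_sequence:
            if ch not in self.autofluorescence_per_channel:
                raise ValueError(f"no autofluorescence level for channel {ch!r}")

    @property
    def frame_times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_fps

    def frame_channels(self) -> list[str]:
        p = len(self.channel_sequence)
        return [self.channel_sequence[k % p] for k in range(self.n_frames)]


@dataclass
class GroundTruth:
    """What the generator actually drew, for downstream validation."""

    core_centers_um: np.ndarray  # (N, 2) (y, x) relative to FOV center
    core_centers_px: np.ndarray  # (N, 2) (row, col) on the raw frame
    per_frame_shift_px: np.ndarray  # (T, 2) integer scene displacement (dy, dx)
    cell_traces: np.ndarray  # (n_cells, T) ideal relative intensity
    gains: np.ndarray  # (T,) multiplicative flicker gain
    config: SyntheticConfig


def generate_lattice(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Jittered hexagonal lattice of core centers inside the circular FOV.

    Returns (N, 2) centers in micrometres, (y, x) relative to the FOV
    center.  Row pitch is ``spacing * sqrt(3)/2`` with alternate rows offset
    by half a spacing; each center is then displaced by isotropic Gaussian
    jitter of SD ``jitter_sd_um`` per axis.
    """
    d = config.lattice_spacing_um
    radius = config.fov_diameter_um / 2.0
    if d >= config.fov_diameter_um:
        raise ValueError("degenerate lattice: spacing >= FOV diameter")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    row_pitch = d * np.sqrt(3.0) / 2.0
    n_rows = int(np.ceil(radius / row_pitch)) + 1
    n_cols = int(np.ceil(radius / d)) + 1
    centers = []
    for i in range(-n_rows, n_rows + 1):
        y = i * row_pitch
        x_off = (d / 2.0) if (i % 2) else 0.0
        for j in range(-n_cols, n_cols + 1):
            x = j * d + x_off
            if y * y + x * x <= radius * radius:
                centers.append((y, x))
    out = np.array(sorted(centers), dtype=float)
    if config.jitter_sd_um > 0:
        out = out + rng.normal(0.0, config.jitter_sd_um, size=out.shape)
    return out


def cell_transient(spec: CellSpec, t: float | np.ndarray) -> np.ndarray | float:
    """Relative intensity of a cell at time ``t`` (1 = baseline).

    Baseline 1 before onset (optionally a brief dip just before), linear
    rise to ``1 + amplitude_rel`` over ``rise_s``, flat plateau for
    ``plateau_s``, then exponential decay with time constant ``decay_s``.
    """
    t = np.asarray(t, dtype=float)
    out = np.ones_like(t)
    a = spec.amplitude_rel
    t0, tr, tp = spec.onset_s, spec.rise_s, spec.plateau_s

    if spec.dip_s > 0 and spec.dip_amplitude_rel > 0:
        in_dip = (t >= t0 - spec.dip_s) & (t < t0)
        phase = (t - (t0 - spec.dip_s)) / spec.dip_s
        out = np.where(
            in_dip, 1.0 - spec.dip_amplitude_rel * np.sin(np.pi * phase), out
        )

    rising = (t >= t0) & (t < t0 + tr)
    out = np.where(rising, 1.0 + a * (t - t0) / tr, out)
    plateau = (t >= t0 + tr) & (t < t0 + tr + tp)
    out = np.where(plateau, 1.0 + a, out)
    decaying = t >= t0 + tr + tp
    out = np.where(
        decaying, 1.0 + a * np.exp(-(t - (t0 + tr + tp)) / spec.decay_s), out
    )
    return out if out.ndim else float(out)


def _spot_matrix(
    centers_px: np.ndarray, shape: tuple[int, int], sigma_px: float
):
    """Sparse (H*W, N) matrix of unit-peak Gaussian core spots."""
    from scipy import sparse

    h, w = shape
    half = max(int(np.ceil(3.0 * sigma_px)), 2)
    rows, cols, vals = [], [], []
    for j, (cy, cx) in enumerate(centers_px):
        iy0 = max(int(np.floor(cy)) - half, 0)
        iy1 = min(int(np.floor(cy)) + half + 1, h)
        ix0 = max(int(np.floor(cx)) - half, 0)
        ix1 = min(int(np.floor(cx)) + half + 1, w)
        if iy0 >= iy1 or ix0 >= ix1:
            continue
        yy = np.arange(iy0, iy1)[:, None] - cy
        xx = np.arange(ix0, ix1)[None, :] - cx
        patch = np.exp(-(yy * yy + xx * xx) / (2.0 * sigma_px * sigma_px))
        pr, pc = np.nonzero(patch > 1e-6)
        rows.append((pr + iy0) * w + (pc + ix0))
        cols.append(np.full(pr.size, j))
        vals.append(patch[pr, pc])
    mat = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(h * w, len(centers_px)),
    )
    return mat.tocsr()


def _cell_aperture_fields(
    config: SyntheticConfig, shape: tuple[int, int]
) -> list[np.ndarray]:
    """Per-cell aperture response on the raw grid: disk indicator smoothed by
    the Gaussian core aperture (FWHM = core diameter)."""
    h, w = shape
    px = config.raw_pixel_um
    cy0, cx0 = (h - 1) / 2.0, (w - 1) / 2.0
    sigma_ap = config.core_fwhm_um * FWHM_TO_SIGMA / px
    yy, xx = np.mgrid[0:h, 0:w]
    fields = []
    for cell in config.cells:
        cy = cy0 + cell.center_um[0] / px
        cx = cx0 + cell.center_um[1] / px
        r_px = cell.radius_um / px
        disk = ((yy - cy) ** 2 + (xx - cx) ** 2 <= r_px * r_px).astype(float)
        sigma = np.hypot(sigma_ap, cell.edge_sigma_um / px)
        fields.append(ndi.gaussian_filter(disk, sigma, mode="constant"))
    return fields


def render_movie(config: SyntheticConfig):
    """Render a raw movie and its ground truth.

    Per frame: each core's value is the channel's autofluorescence plus the
    aperture-weighted scene intensity at the core's (motion-shifted) sample
    position; cores are painted as Gaussian spots of FWHM ``core_fwhm_um``;
    the frame is scaled by a per-frame gain ~ Normal(1, flicker_sd), noise is
    added, and the result is quantized to 16-bit.

    Returns ``(RawStack, GroundTruth)``.
    """
    from .io import RawStack

    rng = np.random.default_rng(config.seed)
    centers_um = generate_lattice(config, rng)
    h, w = config.frame_shape
    px = config.raw_pixel_um
    centers_px = np.column_stack(
        [(h - 1) / 2.0 + centers_um[:, 0] / px, (w - 1) / 2.0 + centers_um[:, 1] / px]
    )
    inside = (
        (centers_px[:, 0] > 1)
        & (centers_px[:, 0] < h - 2)
        & (centers_px[:, 1] > 1)
        & (centers_px[:, 1] < w - 2)
    )
    centers_um, centers_px = centers_um[inside], centers_px[inside]

    sigma_spot = config.core_fwhm_um * FWHM_TO_SIGMA / px
    spots = _spot_matrix(centers_px, (h, w), sigma_spot)
    cell_fields = _cell_aperture_fields(config, (h, w))

    times = config.frame_times_s
    channels = config.frame_channels()
    if config.motion is not None:
        shifts = config.motion.shifts(times)
        shifts[0] = 0
    else:
        shifts = np.zeros((config.n_frames, 2), dtype=int)

    transients = (
        np.array([cell_transient(c, times) for c in config.cells])
        if config.cells
        else np.zeros((0, config.n_frames))
    )
    gains = (
        rng.normal(1.0, config.flicker_sd, size=config.n_frames)
        if config.flicker_sd > 0
        else np.ones(config.n_frames)
    )

    # Aperture samples per cell per unique shift (scene moves by +s, so the
    # core at c samples the unshifted scene at c - s).
    sample_cache: dict[tuple[int, int], np.ndarray] = {}

    def cell_samples(shift: tuple[int, int]) -> np.ndarray:
        if shift not in sample_cache:
            coords = (centers_px - np.asarray(shift)).T  # (2, N)
            sample_cache[shift] = np.array(
                [
                    ndi.map_coordinates(f, coords, order=1, mode="constant")
                    for f in cell_fields
                ]
            ).reshape(len(cell_fields), -1)
        return sample_cache[shift]

    frames = np.empty((config.n_frames, h, w), dtype=np.uint16)
    max_count = float(np.iinfo(np.uint16).max)
    for t in range(config.n_frames):
        ch = channels[t]
        v = np.full(
            len(centers_px), float(config.autofluorescence_per_channel[ch])
        )
        if config.cells:
            samp = cell_samples(tuple(shifts[t]))
            amps = np.array(
                [
                    c.baseline * c.response(ch) * transients[i, t]
                    for i, c in enumerate(config.cells)
                ]
            )
            v = v + amps @ samp
        frame = (spots @ v).reshape(h, w) * gains[t]
        if config.noise.photons_per_count > 0:
            ppc = config.noise.photons_per_count
            frame = rng.poisson(frame * ppc) / ppc
        if config.noise.read_noise_sd > 0:
            frame = frame + rng.normal(0.0, config.noise.read_noise_sd, frame.shape)
        over = np.count_nonzero(frame > max_count)
        if over > config.clip_tolerance * frame.size:
            raise SaturationError(
                f"saturation: {over} pixels exceed the 16-bit range in frame {t}"
            )
        frames[t] = np.clip(np.round(frame), 0, max_count).astype(np.uint16)

    stack = RawStack(
        frames=frames,
        frame_rate_fps=config.frame_rate_fps,
        channel_sequence=tuple(config.channel_sequence),
    )
    truth = GroundTruth(
        core_centers_um=centers_um,
        core_centers_px=centers_px,
        per_frame_shift_px=shifts,
        cell_traces=transients,
        gains=gains,
        config=config,
    )
    return stack, truth


def default_insitu_config(**overrides) -> SyntheticConfig:
    """The default in-situ recording: 60 s at 4.3 fps, three sparse cells
    with 0.6 peak dF/F (the 1.6-fold response typical of tracheal tuft
    cells), staggered onsets, shot + read noise and 2% gain flicker."""
    cells = tuple(
        CellSpec(
            center_um=c,
            radius_um=8.0,
            baseline=300.0,
            amplitude_rel=0.6,
            onset_s=t0,
            rise_s=2.0,
            plateau_s=5.0,
            decay_s=18.0,
        )
        for c, t0 in [((-30.0, 20.0), 14.0), ((25.0, -28.0), 17.0), ((18.0, 35.0), 20.0)]
    )
    cfg = dict(cells=cells)
    cfg.update(overrides)
    return SyntheticConfig(**cfg)


def scatter_background_cells(
    n: int,
    fov_diameter_um: float = 147.5,
    baseline: float = 60.0,
    radius_um: float = 10.0,
    seed: int = 7,
) -> tuple[CellSpec, ...]:
    """Dim non-responding fluorescent structures scattered over the FOV.

    Moving tissue carries fluorescence everywhere, not just in responding
    cells; these static-amplitude disks give the scene the spatial texture
    that cross-correlation registration locks onto in real recordings.
    """
    rng = np.random.default_rng(seed)
    r_max = 0.42 * fov_diameter_um
    out = []
    for _ in range(n):
        rr = r_max * np.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * np.pi)
        out.append(
            CellSpec(
                center_um=(rr * np.sin(th), rr * np.cos(th)),
                radius_um=radius_um * rng.uniform(0.6, 1.4),
                baseline=baseline * rng.uniform(0.5, 1.5),
                amplitude_rel=0.0,
                onset_s=0.0,
                rise_s=1.0,
                # band-limit above the core pitch: structure finer than the
                # lattice cannot translate faithfully through it
                edge_sigma_um=6.0,
            )
        )
    return tuple(out)


def default_invivo_config(**overrides) -> SyntheticConfig:
    """The default in-vivo recording: 7.6 fps with breathing-like rigid
    motion, weak responses (~15% peak dF/F, as tracheal tuft cells show in
    the living animal) on a textured tissue background."""
    cells = tuple(
        CellSpec(
            center_um=c,
            radius_um=8.0,
            baseline=300.0,
            amplitude_rel=0.15,
            onset_s=t0,
            rise_s=4.0,
            plateau_s=0.0,
            decay_s=12.0,
        )
        for c, t0 in [((-28.0, 18.0), 12.0), ((22.0, -30.0), 15.0)]
    ) + scatter_background_cells(120)
    cfg = dict(
        cells=cells,
        frame_rate_fps=7.6,
        n_frames=456,
        motion=MotionSpec(amplitude_px=16.0, period_s=2.5, quantum_px=4),
    )
    cfg.update(overrides)
    return SyntheticConfig(**cfg)


def replace(config: SyntheticConfig, **changes) -> SyntheticConfig:
    """Convenience wrapper around :func:`dataclasses.replace`."""
    return dataclasses.replace(config, **changes)
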