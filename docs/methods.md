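# Methods

## The imaging model

A multicore imaging fiber samples the object plane at ~1460 discrete
points arranged in an imperfect hexagonal lattice inside a circular field
of view (FOV). Each core guides the fluorescence collected through its own
aperture and appears on the camera as a bright spot on dark cladding. The
movie model handled by this package is, per raw frame *t* and core *j*:

    I_t(x) = g_t · Σ_j  S_j( a_j(ch_t) + w_j · scene(c_j − s_t, ch_t) ) + noise

where `a_j(ch)` is the channel-dependent core autofluorescence, `w_j` the
core's aperture weighting of the scene, `c_j` its position, `s_t` a rigid
scene displacement (breathing), `g_t ~ N(1, σ_flicker)` a global gain, and
`S_j` the painted core spot. The pipeline inverts this model stage by
stage: segmentation recovers `c_j` and the core regions; per-core
averaging and scattered-data interpolation remove the honeycomb carrier
`S_j`; per-frame percentile subtraction removes `g_t · a`; masked
cross-correlation recovers `s_t`; ROI statistics recover the scene's cell
transients.

## Synthetic scenes (what they emulate, and what they do not)

The generator reproduces every artifact the pipeline corrects, with
defaults set to the instrument's working point:

| parameter | default | meaning |
|---|---|---|
| `fov_diameter_um` | 147.5 | bundle image circle |
| `lattice_spacing_um` | 3.71 | core pitch |
| `jitter_sd_um` | 0.10 | per-axis lattice disorder; calibrated so the measured nearest-neighbour spacing SD is ≈0.08 µm |
| `core_fwhm_um` | 2.34 | painted spot and aperture FWHM |
| `raw_pixel_um` | 0.2883 | sample-plane pixel (512 × 512 frames) |
| `frame_rate_fps` | 4.3 (in situ) / 7.6 (in vivo) | acquisition rate |
| `flicker_sd` | 0.01 | per-frame multiplicative gain SD, the stability of a TTL-switched LED engine + CCD |
| `noise` | shot noise at 1 photon/count + 2-count read noise | camera model |
| cell transients | linear rise 1–3 s, optional plateau < 10 s, exponential decay 12–50 s, amplitudes 0.15–0.6 ΔF/F | calcium-indicator kinetics of podocytes / tuft cells |

Cells are soft disks; each core integrates the scene through a Gaussian
aperture with FWHM equal to the core diameter, which makes a 1 µm bead
fall on a single core, as observed. Motion is an integer-pixel sinusoid
(`MotionSpec`); its `quantum_px` field generates displacement in multiples
of the reconstruction downsample factor (4 raw px = 1 grid px by default)
so that grid-level registration can be checked for *exact* recovery.

Two physical facts shaped the in-vivo default scene and deserve note
because they apply to real data as well:

* **Lattice-sampled scenes are band-limited.** Structure finer than the
  core pitch cannot be transported by the bundle; when such structure
  moves, its lattice samples change in a quasi-static moiré pattern rather
  than translating. The in-vivo scene therefore carries a background
  texture of soft-edged blobs (`edge_sigma_um = 6`), emulating diffuse
  tissue fluorescence at the scales the fiber can actually convey.
* **A static, featureless background cannot anchor registration.** Only
  scene structure that moves with the tissue correlates across frames;
  the generator's textured background plays that role, as real tissue
  autofluorescence does.

Not modelled: optical PSF physics and cross-talk between cores,
photobleaching, non-rigid deformation, and sub-pixel motion (off by
default). Passing tests on these scenes therefore validate the inverse
pipeline against the stated forward model, not against optical effects
the model omits — in particular the measured 4.6 µm bead FWHM of the real
instrument includes optical blur that the generator does not simulate;
the synthetic analogue is the tent-function impulse response whose FWHM
equals the lattice spacing.

## Segmentation

The reference image (time average, single frame, or the 395 nm
autofluorescence channel's average) is smoothed with a Gaussian of
`smoothing_sigma_px = 1` raw px (≈ half the core radius: merges intra-core
noise without merging neighbours), inverted, and watershed-flooded with
8-connected topology so each local maximum of the original image seeds one
region. Regions whose peak smoothed intensity is below the image's 25th
percentile are dropped as background (dark corners). Regions are capped at
0.6 lattice spacings from their center: interior basins are bounded by
their neighbours anyway, but the outermost ring's basins would otherwise
spill into the dark corners and depress those cores' means, which imprints
a static dark annulus on every reconstructed frame.

Because the spots are wide relative to their pitch (FWHM/pitch ≈ 0.63),
every core sits on its neighbours' tails. Centers and spot widths are
therefore measured on **neighbour-subtracted patches**: the bundle is
modelled locally as common-width Gaussian spots, each neighbour's tail
(amplitude read at its center) is subtracted, and the center
(squared-intensity weighted centroid inside half a pitch) or the radial
FWHM is taken from the residual single-spot profile; the width estimate
and the subtraction are iterated to a fixed point. Without this
correction the naive ring-average FWHM reads ~18% high and centroid bias
pushes the nearest-neighbour spacing more than 1% low. All intensities
are referenced to the dark level measured outside the bundle's convex
hull, which also makes segmentation invariant to affine intensity
changes a·I + b.

Reported core diameter is the FWHM of the *smoothed* spot, deliberately
not deconvolved for the 1-px kernel (a ~3% inflation at the defaults);
the convention is stated here because diameter definitions vary.

## Reconstruction

Core means are interpolated onto a 128 × 128 grid whose square spans the
bundle footprint, with the raw-to-grid scale rounded up to a whole number
of raw pixels (4 at the defaults) — an integer downsampling keeps rigid
raw-pixel motion commensurate with the grid. Interpolation is
barycentric-linear on the Delaunay triangulation of the core centers:
exact on affine fields, nodal (a core's grid value equals its mean), with
fill value 0 and a validity mask outside the convex hull. A single-core
impulse reconstructs as a tent of FWHM one lattice spacing — the
sampling-limited effective resolution of the instrument.

Per frame, the 25th percentile (linear-interpolation convention) of the
in-mask pixels is subtracted. Negative values are retained so the in-mask
percentile of every frame is exactly zero; clipping would break that
invariant and bias ΔF/F baselines. The 25th percentile tracks the
autofluorescence pedestal, so a multiplicative gain `g_t` acting on the
pedestal is removed per frame — a single fixed baseline cannot do this,
and the coefficient of variation of a background ROI trace is strictly
lower under per-frame subtraction (tested).

## Registration

Each frame is compared to frame 0 by **masked normalized
cross-correlation**: for every integer lag within ±25% of the grid size,
the Pearson correlation of the two frames over the overlap of the FOV
mask with its lag-shifted copy, computed for all lags at once from six FFT
cross-correlations of the masked images, their squares, and the mask.
This is the exact masked form of the usual NCC: the dark corners never
enter, and per-overlap mean subtraction absorbs intensity offsets. (A
global correlation after filling the corners with the in-mask mean — the
textbook shortcut — is biased toward zero lag on sparse scenes by the
static step between the background level and the fill level, and by
overlap dilution; the masked form has neither problem and recovers all
synthetic shifts exactly.) Ties are broken toward the smallest
displacement, then row-major. Peaks on the search-window boundary, and
zero-variance frames, yield displacement (0, 0) with a logged warning.
Frames are realigned by the negated displacement; vacated pixels are
filled with the in-mask mean and marked invalid in a per-frame mask that
all downstream ROI statistics honour.

Registration accepts only reconstructed stacks: on raw frames the static
honeycomb dominates any correlation and pins the peak at zero. It runs
after percentile subtraction (flicker removal benefits the correlation);
whether to run it at all is the user's call (`registration` flag), since
in-situ preparations are typically still.

## Channels and ratios

Frame *k* of an interleaved recording belongs to channel `k mod period`
(frame 0 = first label, matching the acquisition convention that odd
1-based frames carry the first excitation). Per-channel rate is the raw
rate divided by the period — 4.3 fps two-channel recordings yield
2.15 fps per channel — and de-interleave/re-interleave round-trips
exactly, including odd lengths. Ratio traces pair samples by
within-channel index (frames ~230 ms apart treated as simultaneous),
divide, and normalize to the mean of the first 50 ratio values; shorter
traces normalize by all available values with a warning. The ratio is
invariant to any common rescaling of both channels, which is the point of
ratiometric sensing. By default ratios are formed on percentile-subtracted
stacks (flag to disable), since the subtraction removes the channel's
autofluorescence pedestal that would otherwise compress the ratio.

## Traces

ΔF/F uses the minimum of the *unfiltered* ROI-mean trace as baseline
(F/min(F) − 1), so the output minimum is exactly zero and the measure is
scale-invariant. The minimum is noise-biased: under gain flicker the
baseline catches min(g_t) ≈ 1 − 2.3·σ_flicker over a typical recording,
inflating peak ΔF/F by ≈ (1 + A)·2.3·σ_flicker (~4% at the 1% default
flicker). A percentile-baseline option exists for noisier data (off by
default, to keep the literal min-normalization convention). The median
filter is centered, truncated at the ends, with an even window *w*
covering [t − w/2, t + w/2 − 1] and even-count medians averaging the two
central order statistics; defaults are 30 frames (in situ) and 53 frames
(in vivo). Onset is the first sample at or above a fraction of the trace
maximum (0.8 in situ, 0.96 for the weaker in-vivo responses), computed on
the filtered trace so alignment does not jitter with noise. Ensembles
align member traces at their onsets, crop to the maximal common window,
and report per-timepoint mean and *population* SD (N in the denominator —
stable for the N = 3–4 cells typical here).

## Optics

`theoretical_magnification` is f_tube/f_objective × |GRIN magnification|;
`magnification_from_shift` inverts a calibrated stage displacement
(image shift in camera pixels × pixel pitch / stage shift).
`hex_spacing(N, D)` assumes one core per (√3/2)·d² of hexagonal packing:
d = √(2·π(D/2)² / (√3·N)). The diffraction limit uses the Rayleigh
criterion 0.61·λ/NA (the printed ≈720 nm at 475 nm/NA 0.4 is consistent
with Rayleigh, not Abbe). Rounding follows reporting conventions: two
decimals for magnification and spacing, three significant figures for
areas, one decimal for area-per-core, nearest 10 nm for the diffraction
limit. `fwhm` interpolates the half-maximum crossings linearly between
samples on both sides of a strict interior peak.

## Numerical and design notes

* All randomness flows from one `numpy` Generator seeded by the config;
  fixed seed ⇒ byte-identical TIFF output.
* Watershed plateau ties are resolved by scikit-image's deterministic
  scan order; relabelling is row-major by centroid, so label maps are
  reproducible.
* The saturation check raises rather than silently clipping when more
  than `clip_tolerance` of a frame's pixels exceed the 16-bit range.
* Stack metadata (frame rate, channel sequence, grid transform,
  subtraction state) travels in a YAML sidecar next to each TIFF rather
  than in private TIFF tags, for dialect portability.
* Problem sizes in the test suite: full-bundle fixtures use the complete
  512 × 512 / ~1420-core geometry; time axes are 258 frames (60 s in situ)
  for end-to-end recovery and 60 frames for motion fixtures, chosen as the
  shortest windows that contain a full transient or several breathing
  cycles.

## Known limitations

* Integer-pixel registration only; sub-pixel motion aliases into the
  nearest grid pixel.
* Dead or broken cores are not detected or gap-filled; a missing core
  leaves a tent-shaped dent in its Delaunay cell.
* The min-baseline ΔF/F bias described above grows with flicker and trace
  length; use the percentile baseline for long, noisy recordings.
* Ratio traces assume strict channel periodicity; acquisition-side
  sequence resets must be handled upstream (a mismatch raises rather than
  guesses).
* The pre-stimulus dip seen in some in-situ recordings is available in
  the generator (`dip_s`, `dip_amplitude_rel`) but its mechanism is not
  modelled; it defaults to off.
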