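"""Fiber-core segmentation and lattice statistics.

The raw honeycomb image is a field of bright core spots.  A reference image
(time average, single frame, or the autofluorescence channel's average) is
Gaussian-smoothed, inverted, and watershed-segmented so that every basin of
the inverted image — i.e. every local intensity maximum of the original —
becomes one core region.  Dim basins in the dark corners outside the bundle
are discarded by a background threshold.

Core spots are wide relative to their spacing (FWHM/pitch ≈ 0.6), so the
tails of neighbouring cores overlap every core's surroundings.  Centers and
spot widths are therefore estimated on neighbour-subtracted patches: the
bundle is modelled locally as a lattice of Gaussian spots of common width,
each neighbour's tail is subtracted using its measured amplitude, and the
center (intensity-weighted centroid) and radial FWHM are read from the
residual single-spot profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.morphology import convex_hull_image
from skimage.segmentation import watershed

from .io import RawStack

__all__ = [
    "ReferenceImage",
    "CoreMap",
    "LatticeStats",
    "build_reference",
    "segment_cores",
    "lattice_stats",
]

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ≈ 2.355


@dataclass
class ReferenceImage:
    pixels: np.ndarray
    source_mode: str = "time-average"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise ValueError("reference image must be finite and non-negative")


@dataclass
class CoreMap:
    label_image: np.ndarray  # 0 = background
    centers_px: np.ndarray  # (N, 2) sub-pixel (row, col)
    fov_mask: np.ndarray
    n_cores: int


@dataclass
class LatticeStats:
    n_cores: int
    mean_nn_spacing_um: float
    sd_nn_spacing_um: float
    mean_core_diameter_um: float
    sd_core_diameter_um: float
    pixel_size_um: float


def build_reference(
    stack: RawStack,
    mode: str = "time-average",
    frame_index: int = 0,
    channel: str | None = None,
) -> ReferenceImage:
    """Build the core-detection reference image from a movie.

    ``time-average``: per-pixel mean over all frames.  ``single-frame``: the
    designated frame.  ``autofluorescence-channel``: mean over the frames of
    one excitation channel only (strong 395 nm autofluorescence makes cores
    visible without a sample).
    """
    if stack.n_frames == 0:
        raise ValueError("empty stack")
    if mode == "time-average":
        ref = stack.frames.mean(axis=0)
    elif mode == "single-frame":
        ref = stack.frames[frame_index].astype(float)
    elif mode == "autofluorescence-channel":
        if channel is None or channel not in stack.channel_sequence:
            raise ValueError(f"channel {channel!r} not in the stack's sequence")
        sel = [k for k, c in enumerate(stack.frame_channels()) if c == channel]
        ref = stack.frames[sel].mean(axis=0)
    else:
        raise ValueError(f"unknown reference mode {mode!r}")
    return ReferenceImage(pixels=ref, source_mode=mode)


# ---------------------------------------------------------------------------
# local spot model: common-width Gaussian lattice, used for neighbour-tail
# subtraction in both center refinement and diameter measurement


def _dark_level(smoothed: np.ndarray, centers: np.ndarray) -> float:
    """Dark level of the image: median outside the bundle's convex hull.

    Inside the bundle the overlapping spot tails never return to the true
    dark level, so the in-FOV minimum would overestimate the background.
    Falls back to the image minimum when the hull covers the whole frame.
    """
    seeds = np.zeros(smoothed.shape, dtype=bool)
    rr = np.clip(np.round(centers[:, 0]).astype(int), 0, smoothed.shape[0] - 1)
    cc = np.clip(np.round(centers[:, 1]).astype(int), 0, smoothed.shape[1] - 1)
    seeds[rr, cc] = True
    outside = ~convex_hull_image(seeds)
    if outside.any():
        return float(np.median(smoothed[outside]))
    return float(smoothed.min())


def _neighbor_subtracted_patch(
    sm0: np.ndarray,
    centers: np.ndarray,
    amps: np.ndarray,
    tree: cKDTree,
    i: int,
    radius_px: int,
    sigma_px: float,
):
    """Patch around core ``i`` with neighbouring spots' tails removed.

    Returns ``(patch, yy, xx)`` or None when the patch would leave the
    image.  ``sm0`` is the smoothed image above the dark level.
    """
    h, w = sm0.shape
    c = centers[i]
    iy, ix = int(round(c[0])), int(round(c[1]))
    if (
        iy - radius_px < 0
        or ix - radius_px < 0
        or iy + radius_px + 1 > h
        or ix + radius_px + 1 > w
    ):
        return None
    yy = np.arange(iy - radius_px, iy + radius_px + 1)[:, None]
    xx = np.arange(ix - radius_px, ix + radius_px + 1)[None, :]
    patch = sm0[iy - radius_px : iy + radius_px + 1,
                ix - radius_px : ix + radius_px + 1].astype(float).copy()
    k = min(8, len(centers))
    _, nb = tree.query(c, k=k)
    for j in np.atleast_1d(nb):
        if j == i or j >= len(centers):
            continue
        cj = centers[j]
        patch -= amps[j] * np.exp(
            -((yy - cj[0]) ** 2 + (xx - cj[1]) ** 2) / (2.0 * sigma_px**2)
        )
    return patch, yy, xx


def _fit_sigma_inner(
    sm0: np.ndarray, centers: np.ndarray, r_fit_px: float
) -> float:
    """Common spot width from a Gaussian fit to the inner radial profile
    (inside ~0.3 lattice spacings, where neighbour tails are negligible)."""
    h, w = sm0.shape
    step = max(len(centers) // 200, 1)
    sigmas = []
    r_int = int(np.ceil(r_fit_px))
    for c in centers[::step]:
        iy, ix = int(round(c[0])), int(round(c[1]))
        if iy - r_int < 0 or ix - r_int < 0 or iy + r_int + 1 > h or ix + r_int + 1 > w:
            continue
        yy = np.arange(iy - r_int, iy + r_int + 1)[:, None] - c[0]
        xx = np.arange(ix - r_int, ix + r_int + 1)[None, :] - c[1]
        patch = sm0[iy - r_int : iy + r_int + 1, ix - r_int : ix + r_int + 1]
        r = np.hypot(yy, xx).ravel()
        v = patch.ravel()
        sel = (r <= r_fit_px) & (v > 0)
        if sel.sum() < 6:
            continue
        slope = np.polyfit(r[sel] ** 2, np.log(v[sel]), 1)[0]
        if slope < 0:
            sigmas.append(np.sqrt(-0.5 / slope))
    if not sigmas:
        raise ValueError("could not estimate a core spot width")
    return float(np.median(sigmas))


def _refine_centers(
    sm0: np.ndarray, centers: np.ndarray, nn_px: float, sigma_px: float
) -> np.ndarray:
    """Intensity-weighted centroids on neighbour-subtracted circular
    patches (squared weights, which suppress residual tail leverage)."""
    tree = cKDTree(centers)
    amps = np.array(
        [sm0[int(round(c[0])), int(round(c[1]))] for c in centers]
    )
    radius = int(np.ceil(nn_px / 2.0)) + 1
    out = centers.copy()
    for i in range(len(centers)):
        res = _neighbor_subtracted_patch(
            sm0, centers, amps, tree, i, radius, sigma_px
        )
        if res is None:
            continue
        patch, yy, xx = res
        c = centers[i]
        r2 = (yy - c[0]) ** 2 + (xx - c[1]) ** 2
        wgt = np.where(r2 <= (nn_px / 2.0) ** 2, np.clip(patch, 0, None), 0.0) ** 2
        s = wgt.sum()
        if s > 0:
            out[i] = ((wgt * yy).sum() / s, (wgt * xx).sum() / s)
    return out


def segment_cores(ref: ReferenceImage, smoothing_sigma_px: float = 1.0) -> CoreMap:
    """Watershed segmentation of individual fiber cores.

    The reference is smoothed with a 2-D Gaussian, inverted, and flooded
    from its regional minima (the original image's maxima) with 8-connected
    watershed.  Regions whose peak smoothed intensity falls below the 25th
    percentile of the smoothed reference are treated as background (dark
    corners) and dropped.  Region centroids are then refined on
    neighbour-subtracted patches for sub-pixel accuracy.  The FOV mask is
    the filled convex hull of the surviving centers.

    All intensities are referenced to the smoothed image's 25th-percentile
    dark level, making the result invariant to affine intensity changes
    a*I + b (a > 0).
    """
    img = ref.pixels
    if img.max() == img.min():
        raise ValueError("no cores found: constant reference image")
    smoothed = ndi.gaussian_filter(img, smoothing_sigma_px)
    labels = watershed(-smoothed, connectivity=2)

    threshold = np.percentile(smoothed, 25)
    idx = np.arange(1, labels.max() + 1)
    peaks = ndi.maximum(smoothed, labels=labels, index=idx)
    keep = idx[peaks > threshold]
    if keep.size == 0:
        raise ValueError("no cores found: all regions below background")

    # relabel 1..N in deterministic (row-major centroid) order
    coms = np.array(
        ndi.center_of_mass(
            np.clip(smoothed - threshold, 0, None), labels=labels, index=keep
        )
    )
    order = np.lexsort((coms[:, 1], coms[:, 0]))
    remap = np.zeros(labels.max() + 1, dtype=np.int64)
    remap[keep[order]] = np.arange(1, keep.size + 1)
    label_image = remap[labels]
    centers = coms[order]

    sm0 = smoothed - _dark_level(smoothed, centers)
    if keep.size >= 2:
        tree = cKDTree(centers)
        nn_px = float(np.median(tree.query(centers, k=2)[0][:, 1]))
        try:
            sigma_px = _fit_sigma_inner(sm0, centers, 0.28 * nn_px)
            centers = _refine_centers(sm0, centers, nn_px, sigma_px)
        except ValueError:
            pass  # keep plain centroids for tiny/degenerate bundles
        # Cap each region at 0.6 lattice spacings from its center: interior
        # basins are bounded by their neighbours anyway, but the outermost
        # ring's basins would otherwise spill into the dark corners and
        # systematically depress those cores' mean intensities.
        yy, xx = np.nonzero(label_image)
        lab = label_image[yy, xx]
        d2 = (yy - centers[lab - 1, 0]) ** 2 + (xx - centers[lab - 1, 1]) ** 2
        far = d2 > (0.6 * nn_px) ** 2
        label_image[yy[far], xx[far]] = 0

    fov_mask = convex_hull_image(label_image > 0)
    return CoreMap(
        label_image=label_image,
        centers_px=centers,
        fov_mask=fov_mask,
        n_cores=keep.size,
    )


def _radial_fwhm_px(patch, yy, xx, center, r_max_px, bin_px=0.25) -> float | None:
    """FWHM (px) of the ring-averaged radial profile of one spot patch."""
    r = np.hypot(yy - center[0], xx - center[1]).ravel()
    v = patch.ravel()
    sel = r <= r_max_px
    r, v = r[sel], v[sel]
    bins = np.floor(r / bin_px).astype(int)
    counts = np.bincount(bins)
    sums = np.bincount(bins, weights=v)
    occupied = counts > 0
    prof = sums[occupied] / counts[occupied]
    r_bin = ((np.arange(len(counts)) + 0.5) * bin_px)[occupied]
    if prof.size < 3:
        return None
    peak_idx = int(np.argmax(prof))
    half = prof[peak_idx] / 2.0
    below = np.nonzero(prof[peak_idx:] < half)[0]
    if below.size == 0:
        return None
    k = peak_idx + below[0]
    frac = (prof[k - 1] - half) / (prof[k - 1] - prof[k])
    return 2.0 * float(r_bin[k - 1] + frac * (r_bin[k] - r_bin[k - 1]))


def lattice_stats(
    coremap: CoreMap,
    ref: ReferenceImage,
    pixel_size_um: float,
    smoothing_sigma_px: float = 1.0,
) -> LatticeStats:
    """Nearest-neighbour core spacing and core diameter (radial FWHM).

    Spacing is each core's distance to its nearest neighbour, scaled to the
    sample plane.  Diameter is the FWHM of the smoothed radial intensity
    profile of each core spot, measured on neighbour-subtracted patches:
    the tails of surrounding cores are estimated from the common-width
    Gaussian spot model and removed before the half-maximum crossing is
    read (the spot-width estimate and subtraction are iterated to a fixed
    point).  Cores without a clean half-maximum crossing are skipped.
    """
    if coremap.n_cores < 2:
        raise ValueError("need at least 2 cores for lattice statistics")
    centers = coremap.centers_px
    tree = cKDTree(centers)
    dists, _ = tree.query(centers, k=2)
    nn_um = dists[:, 1] * pixel_size_um
    nn_px = float(dists[:, 1].mean())

    smoothed = ndi.gaussian_filter(ref.pixels, smoothing_sigma_px)
    outside = ~coremap.fov_mask
    dark = float(np.median(smoothed[outside])) if outside.any() else float(
        smoothed.min()
    )
    sm0 = smoothed - dark
    amps = np.array([sm0[int(round(c[0])), int(round(c[1]))] for c in centers])
    radius = int(np.ceil(nn_px / 2.0)) + 1

    try:
        sigma_px = _fit_sigma_inner(sm0, centers, 0.28 * nn_px)
    except ValueError:
        sigma_px = nn_px / 4.0
    fwhms_px: list[float] = []
    for _ in range(3):  # iterate the spot model to a fixed point
        fwhms_px = []
        for i in range(len(centers)):
            res = _neighbor_subtracted_patch(
                sm0, centers, amps, tree, i, radius, sigma_px
            )
            if res is None:
                continue
            patch, yy, xx = res
            f = _radial_fwhm_px(patch, yy, xx, centers[i], nn_px / 2.0 + 1.0)
            if f is not None:
                fwhms_px.append(f)
        if not fwhms_px:
            break
        sigma_px = float(np.mean(fwhms_px)) / FWHM_PER_SIGMA

    if not fwhms_px:
        warnings.warn("no core yielded a radial FWHM; diameter set to nan")
        mean_d, sd_d = float("nan"), float("nan")
    else:
        f_um = np.asarray(fwhms_px) * pixel_size_um
        mean_d, sd_d = float(f_um.mean()), float(f_um.std())
    return LatticeStats(
        n_cores=coremap.n_cores,
        mean_nn_spacing_um=float(nn_um.mean()),
        sd_nn_spacing_um=float(nn_um.std()),
        mean_core_diameter_um=mean_d,
        sd_core_diameter_um=sd_d,
        pixel_size_um=pixel_size_um,
    )
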