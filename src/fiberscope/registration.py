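"""Rigid motion correction by normalized cross-correlation.

Each reconstructed frame is compared to the first frame of the movie with
masked normalized cross-correlation: for every candidate integer lag, the
Pearson correlation of the two frames is evaluated over the overlap of the
FOV mask with its shifted copy (computed for all lags at once with FFT
cross-correlations of the masked images, their squares, and the mask).
Restricting to the mask overlap means the dark corners outside the round
fiber bundle never enter the correlation, and the per-overlap mean
subtraction makes the measure insensitive to per-frame intensity offsets.
The integer lag with the highest correlation is the measured displacement;
the frame is then shifted back by it, with vacated pixels filled by the
in-mask mean and marked invalid.

Registration operates on reconstructed (honeycomb-free) stacks only: on raw
frames the static core lattice dominates the correlation and pins the peak
at zero regardless of sample motion.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .io import ReconStack

__all__ = ["ShiftTable", "register_stack"]

log = logging.getLogger(__name__)


@dataclass
class ShiftTable:
    """Measured per-frame displacement (dy, dx) relative to frame 0.

    A frame whose content moved by +d is realigned by shifting it by -d.
    """

    displacement_px: np.ndarray  # (T, 2) integers
    reference_index: int = 0

    @property
    def correction_px(self) -> np.ndarray:
        """The shift applied to realign each frame (negated displacement)."""
        return -self.displacement_px


def _xcorr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Full cross-correlation: result[(H-1)+dy, (W-1)+dx] = sum a(x) b(x-d)."""
    return fftconvolve(a, b[::-1, ::-1], mode="full")


class _MaskedNCC:
    """Masked normalized cross-correlation against a fixed reference.

    Precomputes the reference-side and mask-side correlation maps; each
    frame then needs three FFT correlations.  The correlation at lag d is
    the Pearson r of the frame and the d-shifted reference over the overlap
    of the mask with its own d-shifted copy.
    """

    def __init__(self, ref: np.ndarray, mask: np.ndarray, max_shift: int):
        self.mask = mask.astype(np.float64)
        self.max_shift = max_shift
        self.g = np.where(mask, ref, 0.0).astype(np.float64)
        self.n = _xcorr(self.mask, self.mask)
        self.s_g = _xcorr(self.mask, self.g)
        self.s_gg = _xcorr(self.mask, self.g * self.g)
        self.center = (ref.shape[0] - 1, ref.shape[1] - 1)
        # require a healthy overlap so tiny-overlap lags cannot win
        self.valid = self.n >= 0.5 * self.n.max()
        cy, cx = self.center
        window = np.zeros_like(self.valid)
        window[
            cy - max_shift : cy + max_shift + 1,
            cx - max_shift : cx + max_shift + 1,
        ] = True
        self.valid &= window

    def response(self, frame: np.ndarray) -> np.ndarray:
        f = np.where(self.mask > 0, frame, 0.0).astype(np.float64)
        s_fg = _xcorr(f, self.g)
        s_f = _xcorr(f, self.mask)
        s_ff = _xcorr(f * f, self.mask)
        n = np.maximum(self.n, 1.0)
        cov = s_fg - s_f * self.s_g / n
        var_f = s_ff - s_f * s_f / n
        var_g = self.s_gg - self.s_g * self.s_g / n
        denom = np.sqrt(np.clip(var_f, 0, None) * np.clip(var_g, 0, None))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 1e-12 * n, cov / np.maximum(denom, 1e-300), -2.0)
        return np.where(self.valid, r, -2.0)


def _peak_displacement(response: np.ndarray, center: tuple[int, int]) -> np.ndarray:
    peaks = np.argwhere(response == response.max())
    disp = peaks - np.asarray(center)
    # smallest displacement magnitude first, then row-major order
    order = np.lexsort((disp[:, 1], disp[:, 0], (disp ** 2).sum(axis=1)))
    return disp[order[0]]


def _shift_with_fill(
    frame: np.ndarray, shift: np.ndarray, fill: float
) -> tuple[np.ndarray, np.ndarray]:
    """Integer-shift a frame; returns (shifted, vacated_mask)."""
    out = np.full_like(frame, fill)
    vac = np.ones(frame.shape, dtype=bool)
    h, w = frame.shape
    dy, dx = int(shift[0]), int(shift[1])
    ys = slice(max(dy, 0), min(h + dy, h))
    xs = slice(max(dx, 0), min(w + dx, w))
    yo = slice(max(-dy, 0), min(h - dy, h))
    xo = slice(max(-dx, 0), min(w - dx, w))
    out[ys, xs] = frame[yo, xo]
    vac[ys, xs] = False
    return out, vac


def register_stack(
    recon: ReconStack, max_shift_frac: float = 0.25
) -> tuple[ReconStack, ShiftTable]:
    """Register every frame of a reconstructed stack to its first frame.

    Displacements larger than ``max_shift_frac`` of the grid size are
    treated as correlation failures: the frame is left unshifted and a
    warning is logged.  Zero-variance frames likewise get displacement
    (0, 0).
    """
    if not isinstance(recon, ReconStack):
        raise TypeError(
            "register_stack requires a reconstructed (honeycomb-free) stack; "
            "on raw frames the static core pattern dominates the correlation"
        )
    if recon.n_frames < 1:
        raise ValueError("empty stack")
    mask = recon.valid_mask
    h, w = recon.frames.shape[1:]
    max_shift = int(max_shift_frac * max(h, w))

    ref = recon.frames[0].astype(np.float64)
    ref_std = ref[mask].std()
    ncc = _MaskedNCC(ref, mask, max_shift)
    displacements = np.zeros((recon.n_frames, 2), dtype=int)
    frames = np.empty_like(recon.frames)
    frame_valid = np.empty((recon.n_frames, h, w), dtype=bool)
    frames[0] = recon.frames[0]
    frame_valid[0] = mask

    for t in range(1, recon.n_frames):
        cur = recon.frames[t].astype(np.float64)
        if ref_std == 0 or cur[mask].std() == 0:
            log.warning("frame %d: zero variance, correlation undefined; shift (0,0)", t)
            disp = np.zeros(2, dtype=int)
        else:
            response = ncc.response(cur)
            disp = _peak_displacement(response, ncc.center)
            # a peak on the search-window boundary is a failed correlation
            if np.abs(disp).max() >= max_shift:
                log.warning(
                    "frame %d: displacement %s exceeds %d px limit; rejected",
                    t, tuple(disp), max_shift,
                )
                disp = np.zeros(2, dtype=int)
        displacements[t] = disp
        fill = recon.frames[t][mask].mean()
        shifted, vacated = _shift_with_fill(recon.frames[t], -disp, fill)
        frames[t] = shifted
        base_mask, _ = _shift_with_fill(
            mask.astype(np.float32), -disp, 0.0
        )
        frame_valid[t] = base_mask.astype(bool) & ~vacated & mask

    registered = dataclasses.replace(
        recon, frames=frames, frame_valid=frame_valid
    )
    table = ShiftTable(displacement_px=displacements, reference_index=0)
    return registered, table
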