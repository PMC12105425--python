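"""Frame-interleaved channel handling and ratiometric traces.

The light engine alternates excitation wavelengths on successive camera
frames (e.g. 475 nm / 555 nm for a GCaMP6f + mKate2 pair, or 395 nm /
475 nm for the redox sensor roGFP2-Orp1), so one monochrome camera records
several channels quasi-simultaneously.  De-interleaving splits the movie by
``frame index mod period``; a two-channel movie recorded at 4.3 fps yields
two series at an effective 2.15 fps each.

For ratiometric sensors the two per-ROI traces are divided sample-by-sample
and the result normalized to the mean of its first 50 values, making the
readout insensitive to expression level and common-mode intensity changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import RawStack, ReconStack

__all__ = [
    "ChannelSequence",
    "ChannelSet",
    "RatioTrace",
    "deinterleave",
    "interleave",
    "ratio_trace",
]


@dataclass(frozen=True)
class ChannelSequence:
    """Ordered excitation labels; frame k carries ``labels[k % period]``."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        if not self.labels:
            raise ValueError("channel sequence must be non-empty")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")

    @property
    def period(self) -> int:
        return len(self.labels)

    def channel_of(self, frame_index: int) -> str:
        return self.labels[frame_index % self.period]


@dataclass
class ChannelSet:
    """Per-channel stacks with per-channel timestamps."""

    stacks: dict[str, RawStack | ReconStack]
    timestamps_s: dict[str, np.ndarray]
    sequence: ChannelSequence = field(
        default_factory=lambda: ChannelSequence(("0",))
    )

    def __getitem__(self, label: str):
        return self.stacks[label]


def deinterleave(stack, seq: ChannelSequence) -> ChannelSet:
    """Split an interleaved stack into one stack per excitation channel.

    Channel c receives frames c, c+period, c+2*period, ... at an effective
    frame rate of ``raw_rate / period``; timestamps keep each frame's
    original acquisition time.
    """
    period = seq.period
    rate = stack.frame_rate_fps / period
    stacks: dict[str, RawStack | ReconStack] = {}
    times: dict[str, np.ndarray] = {}
    for c, label in enumerate(seq.labels):
        frames = stack.frames[c::period]
        if isinstance(stack, ReconStack):
            sub = ReconStack(
                frames=frames,
                valid_mask=stack.valid_mask,
                grid=stack.grid,
                frame_rate_fps=rate,
                channel_sequence=(label,),
                background_subtracted=stack.background_subtracted,
                percentile_p=stack.percentile_p,
                frame_valid=None
                if stack.frame_valid is None
                else stack.frame_valid[c::period],
            )
        else:
            sub = RawStack(
                frames=frames, frame_rate_fps=rate, channel_sequence=(label,)
            )
        stacks[label] = sub
        times[label] = (
            np.arange(frames.shape[0]) * period + c
        ) / stack.frame_rate_fps
    return ChannelSet(stacks=stacks, timestamps_s=times, sequence=seq)


def interleave(channels: ChannelSet):
    """Inverse of :func:`deinterleave`: re-weave channel stacks in sequence
    order (channel lengths may differ by at most one frame)."""
    seq = channels.sequence
    subs = [channels.stacks[label] for label in seq.labels]
    lengths = [s.frames.shape[0] for s in subs]
    if max(lengths) - min(lengths) > 1:
        raise ValueError("channel lengths differ by more than one frame")
    total = sum(lengths)
    first = subs[0]
    frames = np.empty((total,) + first.frames.shape[1:], dtype=first.frames.dtype)
    for c, sub in enumerate(subs):
        frames[c :: seq.period] = sub.frames
    rate = first.frame_rate_fps * seq.period
    if isinstance(first, ReconStack):
        return ReconStack(
            frames=frames,
            valid_mask=first.valid_mask,
            grid=first.grid,
            frame_rate_fps=rate,
            channel_sequence=seq.labels,
            background_subtracted=first.background_subtracted,
            percentile_p=first.percentile_p,
        )
    return RawStack(frames=frames, frame_rate_fps=rate, channel_sequence=seq.labels)


@dataclass
class RatioTrace:
    """Normalized two-channel ratio: mean of the first ``n_norm`` samples
    is 1 by construction."""

    values: np.ndarray
    numerator: str
    denominator: str
    n_norm: int = 50
    frame_rate_fps: float = 1.0

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.frame_rate_fps


def ratio_trace(
    cha: np.ndarray,
    chb: np.ndarray,
    n_norm: int = 50,
    numerator: str = "A",
    denominator: str = "B",
    frame_rate_fps: float = 1.0,
) -> RatioTrace:
    """Sample-wise ratio of two channel traces, normalized to the mean of
    the initial ``n_norm`` ratio values.

    Frames are paired by within-channel index (interleaved frames acquired
    a fraction of a second apart are treated as simultaneous); the longer
    trace is trimmed to the shorter.  If fewer than ``n_norm`` samples
    exist, all of them are used for normalization (with a warning).
    """
    a = np.asarray(cha, dtype=float).ravel()
    b = np.asarray(chb, dtype=float).ravel()
    n = min(len(a), len(b))
    if n < 2:
        raise ValueError("need at least 2 paired samples")
    a, b = a[:n], b[:n]
    if np.any(b <= 0):
        raise ValueError("invalid denominator: non-positive values in channel B")
    r = a / b
    k = min(n_norm, n)
    if k < n_norm:
        warnings.warn(
            f"only {n} samples available; normalizing by all of them "
            f"instead of the first {n_norm}"
        )
    return RatioTrace(
        values=r / r[:k].mean(),
        numerator=numerator,
        denominator=denominator,
        n_norm=k,
        frame_rate_fps=frame_rate_fps,
    )
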