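"""Data containers and file I/O.

Movies travel as multipage grayscale TIFF (16-bit integer raw, 32-bit float
reconstructed) with a YAML sidecar (``<stem>.meta.yaml``) carrying the frame
rate and excitation-channel sequence, so both dialects round-trip without
relying on private TIFF tags.  Tables (core centers, lattice statistics,
shifts, traces, ensembles) are CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "RawStack",
    "ReconStack",
    "GridTransform",
    "read_stack",
    "write_stack",
    "read_coremap",
    "write_coremap",
    "write_table",
]


@dataclass
class RawStack:
    """T x H x W camera frames as captured through the fiber."""

    frames: np.ndarray
    frame_rate_fps: float = 1.0
    channel_sequence: tuple[str, ...] = ("0",)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("RawStack frames must be a T x H x W array")
        self.channel_sequence = tuple(str(c) for c in self.channel_sequence)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def frame_channels(self) -> list[str]:
        p = len(self.channel_sequence)
        return [self.channel_sequence[k % p] for k in range(self.n_frames)]


@dataclass(frozen=True)
class GridTransform:
    """Mapping between the reconstruction grid and raw-frame pixels.

    Grid pixel (gy, gx) samples raw coordinate
    ``origin + (g + 0.5) * scale`` (pixel-center convention).
    """

    origin: tuple[float, float]  # raw (row, col) of the grid's corner
    scale: float  # raw px per grid px
    n_grid: int = 128

    def grid_points_raw(self) -> np.ndarray:
        """(n*n, 2) raw (row, col) coordinates of all grid pixel centers."""
        g = (np.arange(self.n_grid) + 0.5) * self.scale
        yy, xx = np.meshgrid(g + self.origin[0], g + self.origin[1], indexing="ij")
        return np.column_stack([yy.ravel(), xx.ravel()])


@dataclass
class ReconStack:
    """T x n x n honeycomb-free frames on the interpolation grid.

    ``valid_mask`` marks grid pixels inside the convex hull of the fiber
    cores; pixels outside carry the fill value 0 and are excluded from all
    statistics.  ``frame_valid`` (optional, T x n x n) additionally marks
    pixels vacated by registration shifts.
    """

    frames: np.ndarray
    valid_mask: np.ndarray
    grid: GridTransform | None = None
    frame_rate_fps: float = 1.0
    channel_sequence: tuple[str, ...] = ("0",)
    background_subtracted: bool = False
    percentile_p: float | None = None
    frame_valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 3:
            raise ValueError("ReconStack frames must be a T x H x W array")
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        self.channel_sequence = tuple(str(c) for c in self.channel_sequence)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def mask_for(self, t: int) -> np.ndarray:
        if self.frame_valid is not None:
            return self.frame_valid[t]
        return self.valid_mask


def _sidecar(path: Path) -> Path:
    return path.with_name(path.stem + ".meta.yaml")


def write_stack(stack, path) -> Path:
    """Write a stack as multipage grayscale TIFF plus a YAML metadata sidecar."""
    path = Path(path)
    frames = stack.frames
    if isinstance(stack, ReconStack):
        frames = frames.astype(np.float32)
    tifffile.imwrite(path, frames, photometric="minisblack")
    meta = {
        "frame_rate_fps": float(stack.frame_rate_fps),
        "channel_sequence": list(stack.channel_sequence),
        "kind": "recon" if isinstance(stack, ReconStack) else "raw",
    }
    if isinstance(stack, ReconStack):
        meta["background_subtracted"] = bool(stack.background_subtracted)
        meta["percentile_p"] = stack.percentile_p
        tifffile.imwrite(
            path.with_name(path.stem + ".mask.tif"),
            stack.valid_mask.astype(np.uint8),
            photometric="minisblack",
        )
        if stack.grid is not None:
            meta["grid"] = {
                "origin": [float(v) for v in stack.grid.origin],
                "scale": float(stack.grid.scale),
                "n_grid": int(stack.grid.n_grid),
            }
    _sidecar(path).write_text(yaml.safe_dump(meta, sort_keys=True))
    return path


def read_stack(path):
    """Read a stack written by :func:`write_stack`.

    Raises ``ValueError`` for non-grayscale images or inconsistent page
    shapes.
    """
    path = Path(path)
    try:
        frames = tifffile.imread(path)
    except Exception as exc:  # corrupt file
        raise ValueError(f"cannot read TIFF stack {path}: {exc}") from exc
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ValueError("stack must be grayscale (one channel per page)")
    if frames.shape[-1] in (3, 4) and frames.shape[-1] < min(frames.shape[:-1]):
        raise ValueError("stack must be grayscale, not RGB(A)")

    meta = {}
    if _sidecar(path).exists():
        meta = yaml.safe_load(_sidecar(path).read_text()) or {}
    rate = float(meta.get("frame_rate_fps", 1.0))
    seq = tuple(str(c) for c in meta.get("channel_sequence", ["0"]))
    if meta.get("kind") == "recon":
        mask_path = path.with_name(path.stem + ".mask.tif")
        mask = (
            tifffile.imread(mask_path).astype(bool)
            if mask_path.exists()
            else np.ones(frames.shape[1:], dtype=bool)
        )
        grid = None
        if "grid" in meta:
            g = meta["grid"]
            grid = GridTransform(tuple(g["origin"]), g["scale"], g["n_grid"])
        return ReconStack(
            frames=frames,
            valid_mask=mask,
            grid=grid,
            frame_rate_fps=rate,
            channel_sequence=seq,
            background_subtracted=bool(meta.get("background_subtracted", False)),
            percentile_p=meta.get("percentile_p"),
        )
    return RawStack(frames=frames, frame_rate_fps=rate, channel_sequence=seq)


def write_coremap(coremap, path_prefix) -> tuple[Path, Path]:
    """Write a CoreMap as a label TIFF plus a centers CSV."""
    prefix = Path(path_prefix)
    label_path = prefix.with_name(prefix.name + ".labels.tif")
    tifffile.imwrite(
        label_path, coremap.label_image.astype(np.int32), photometric="minisblack"
    )
    centers_path = prefix.with_name(prefix.name + ".centers.csv")
    pd.DataFrame(
        {
            "core": np.arange(1, coremap.n_cores + 1),
            "row_px": coremap.centers_px[:, 0],
            "col_px": coremap.centers_px[:, 1],
        }
    ).to_csv(centers_path, index=False)
    return label_path, centers_path


def read_coremap(path_prefix):
    from .segmentation import CoreMap

    prefix = Path(path_prefix)
    labels = tifffile.imread(prefix.with_name(prefix.name + ".labels.tif"))
    centers = pd.read_csv(prefix.with_name(prefix.name + ".centers.csv"))
    return CoreMap(
        label_image=labels.astype(np.int64),
        centers_px=centers[["row_px", "col_px"]].to_numpy(),
        fov_mask=labels > 0,
        n_cores=len(centers),
    )


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path
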