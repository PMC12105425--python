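"""Pipeline configuration and end-to-end orchestration.

``run_pipeline`` chains the stages in acquisition order — segment cores,
extract per-core means, interpolate to the 128 x 128 grid, subtract the
per-frame percentile, optionally register, optionally de-interleave, then
extract per-ROI dF/F or ratio traces — writing every intermediate to the
output directory along with the echoed configuration and a plain-text log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .channels import ChannelSequence, deinterleave, ratio_trace
from .io import (
    RawStack,
    read_stack,
    write_coremap,
    write_stack,
    write_table,
)
from .reconstruction import (
    extract_core_means,
    reconstruct_stack,
    subtract_percentile,
)
from .registration import register_stack
from .segmentation import build_reference, lattice_stats, segment_cores
from .traces import ROI, align_and_average, dff, median_filter, roi_mean_trace

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    input_stack: str = ""
    output_dir: str = "fiberscope_out"
    channel_sequence: tuple[str, ...] = ()
    reference_mode: str = "time-average"
    reference_channel: str | None = None
    smoothing_sigma_px: float = 1.0
    percentile_p: float = 25.0
    registration: bool = False
    median_window: int = 30
    onset_fraction: float = 0.8
    n_norm: int = 50
    pixel_size_um: float = 0.2883
    n_grid: int = 128
    seed: int = 0
    rois: list[dict] = field(default_factory=list)
    ratio_channels: tuple[str, str] | None = None
    ratio_on_subtracted: bool = True

    def echo(self, path: Path) -> None:
        d = dataclasses.asdict(self)
        d["channel_sequence"] = list(self.channel_sequence)
        if self.ratio_channels is not None:
            d["ratio_channels"] = list(self.ratio_channels)
        path.write_text(yaml.safe_dump(d, sort_keys=True))


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline config, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "channel_sequence" in raw:
        raw["channel_sequence"] = tuple(str(c) for c in raw["channel_sequence"])
    if raw.get("ratio_channels") is not None:
        raw["ratio_channels"] = tuple(str(c) for c in raw["ratio_channels"])
    return PipelineConfig(**raw)


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc
        log.info("stage %-12s %.2f s", name, time.perf_counter() - t0)
        return out

    return wrap


def _roi_from_spec(spec: dict, shape) -> ROI:
    label = str(spec.get("label", ""))
    if "polygon" in spec:
        return ROI.from_polygon(spec["polygon"], shape, label=label)
    if "disk" in spec:
        c = spec["disk"]
        return ROI.disk((c["row"], c["col"]), c["radius"], shape, label=label)
    if "mask_tiff" in spec:
        import tifffile

        mask = np.asarray(tifffile.imread(spec["mask_tiff"])) > 0
        if mask.shape != tuple(shape):
            raise ValueError("ROI mask shape does not match the grid")
        return ROI(mask=mask, label=label)
    raise ValueError(f"ROI spec needs 'polygon', 'disk' or 'mask_tiff': {spec}")


def run_pipeline(config: PipelineConfig, stack: RawStack | None = None) -> dict:
    """Execute the full processing chain; returns a dict of result objects.

    ``stack`` may be supplied directly (e.g. fresh from the synthetic
    generator); otherwise it is read from ``config.input_stack``.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("fiberscope")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    config.echo(out_dir / "config_echo.yaml")
    log.info("fiberscope %s, seed %d", __version__, config.seed)
    results: dict = {}
    try:
        if stack is None:
            stack = _stage("read")(read_stack, config.input_stack)
            if not isinstance(stack, RawStack):
                raise PipelineError("read", "input must be a raw stack")
        if config.channel_sequence:
            stack.channel_sequence = tuple(config.channel_sequence)

        ref = _stage("reference")(
            build_reference,
            stack,
            config.reference_mode,
            channel=config.reference_channel,
        )
        coremap = _stage("segment")(
            segment_cores, ref, config.smoothing_sigma_px
        )
        write_coremap(coremap, out_dir / "coremap")
        stats = _stage("stats")(
            lattice_stats, coremap, ref, config.pixel_size_um,
            config.smoothing_sigma_px,
        )
        write_table(
            pd.DataFrame([dataclasses.asdict(stats)]), out_dir / "lattice_stats.csv"
        )
        results.update(coremap=coremap, lattice_stats=stats)

        matrix = _stage("extract")(extract_core_means, stack, coremap)
        write_table(
            pd.DataFrame(
                matrix.values,
                columns=[f"core_{i}" for i in range(1, matrix.n_cores + 1)],
            ),
            out_dir / "core_means.csv",
        )
        recon = _stage("interpolate")(
            reconstruct_stack, matrix, coremap, config.n_grid
        )
        recon = _stage("subtract")(subtract_percentile, recon, config.percentile_p)

        if config.registration:
            recon, shifts = _stage("register")(register_stack, recon)
            write_table(
                pd.DataFrame(
                    {
                        "frame": np.arange(recon.n_frames),
                        "dy_px": shifts.displacement_px[:, 0],
                        "dx_px": shifts.displacement_px[:, 1],
                    }
                ),
                out_dir / "shifts.csv",
            )
            results["shifts"] = shifts
        write_stack(recon, out_dir / "recon.tif")
        results["recon"] = recon

        seq = ChannelSequence(stack.channel_sequence)
        channel_set = None
        if seq.period > 1:
            channel_set = _stage("deinterleave")(deinterleave, recon, seq)
            for label, sub in channel_set.stacks.items():
                write_stack(sub, out_dir / f"channel_{label}.tif")
            results["channels"] = channel_set

        if config.rois:
            rois = [
                _roi_from_spec(s, recon.frames.shape[1:]) for s in config.rois
            ]
            if config.ratio_channels and channel_set is not None:
                num, den = config.ratio_channels
                rows = []
                for roi in rois:
                    ta = roi_mean_trace(channel_set[num], roi)
                    tb = roi_mean_trace(channel_set[den], roi)
                    rt = _stage("ratio")(
                        ratio_trace,
                        ta.values,
                        tb.values,
                        config.n_norm,
                        numerator=num,
                        denominator=den,
                        frame_rate_fps=channel_set[num].frame_rate_fps,
                    )
                    rows.append((roi.label, rt))
                for label, rt in rows:
                    write_table(
                        pd.DataFrame({"time_s": rt.times_s, "ratio": rt.values}),
                        out_dir / f"ratio_{label or 'roi'}.csv",
                    )
                results["ratios"] = dict(rows)
            else:
                filtered = []
                for roi in rois:
                    tr = _stage("trace")(roi_mean_trace, recon, roi)
                    tr = dff(tr)
                    tr = median_filter(tr, config.median_window)
                    filtered.append(tr)
                    write_table(
                        pd.DataFrame({"time_s": tr.times_s, "dff": tr.values}),
                        out_dir / f"trace_{roi.label or 'roi'}.csv",
                    )
                results["traces"] = filtered
                if len(filtered) >= 2:
                    ens = _stage("align")(
                        align_and_average, filtered, config.onset_fraction
                    )
                    write_table(
                        pd.DataFrame(
                            {
                                "time_s": np.arange(ens.aligned.shape[1])
                                / ens.frame_rate_fps,
                                "mean": ens.mean,
                                "sd": ens.sd,
                                "n": ens.n,
                            }
                        ),
                        out_dir / "ensemble.csv",
                    )
                    results["ensemble"] = ens
        (out_dir / "manifest.json").write_text(
            json.dumps(sorted(p.name for p in out_dir.iterdir()), indent=2)
        )
        return results
    finally:
        root.removeHandler(handler)
        handler.close()
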