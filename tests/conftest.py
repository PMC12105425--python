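"""Shared synthetic fixtures.

Heavy renders are session-scoped; everything is generated at run time from
the synthetic-scene module, so the suite carries no binary data.
"""

from __future__ import annotations

import numpy as np
import pytest

import fiberscope as fs
from fiberscope.synthetic import default_insitu_config, default_invivo_config


@pytest.fixture(scope="session")
def insitu():
    """Default noisy in-situ movie (258 frames, 4.3 fps, three 0.6-dF/F
    cells) with its ground truth."""
    cfg = default_insitu_config()
    stack, truth = fs.render_movie(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def insitu_recon(insitu):
    """Segmented, reconstructed, percentile-subtracted in-situ movie."""
    cfg, stack, truth = insitu
    ref = fs.build_reference(stack)
    coremap = fs.segment_cores(ref)
    recon = fs.subtract_percentile(
        fs.reconstruct_stack(fs.extract_core_means(stack, coremap), coremap)
    )
    return cfg, truth, ref, coremap, recon


@pytest.fixture(scope="session")
def noise_free():
    """Default scene rendered without noise or flicker (short)."""
    cfg = default_insitu_config(
        n_frames=6, noise=fs.NoiseSpec(0, 0), flicker_sd=0.0
    )
    stack, truth = fs.render_movie(cfg)
    ref = fs.build_reference(stack)
    coremap = fs.segment_cores(ref)
    return cfg, stack, truth, ref, coremap


@pytest.fixture(scope="session")
def unjittered():
    """Perfect hexagonal lattice, no cells, no noise: parameter-recovery
    ground for the spacing and diameter estimators."""
    cfg = default_insitu_config(
        n_frames=4, jitter_sd_um=0.0, cells=(),
        noise=fs.NoiseSpec(0, 0), flicker_sd=0.0,
    )
    stack, truth = fs.render_movie(cfg)
    ref = fs.build_reference(stack)
    coremap = fs.segment_cores(ref)
    return cfg, truth, ref, coremap


@pytest.fixture(scope="session")
def mini_bundle():
    """Seven-core bundle (center + hexagonal ring), noise-free."""
    cfg = fs.SyntheticConfig(
        fov_diameter_um=2.4 * 3.71,
        lattice_spacing_um=3.71,
        jitter_sd_um=0.0,
        frame_shape=(64, 64),
        n_frames=3,
        noise=fs.NoiseSpec(0, 0),
        flicker_sd=0.0,
    )
    stack, truth = fs.render_movie(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def invivo_motion():
    """In-vivo style movie with breathing-like grid-commensurate motion,
    noise-free variant for exact shift recovery."""
    cfg = default_invivo_config(
        n_frames=60, noise=fs.NoiseSpec(0, 0), flicker_sd=0.0
    )
    stack, truth = fs.render_movie(cfg)
    coremap = fs.segment_cores(fs.build_reference(stack))
    recon = fs.subtract_percentile(
        fs.reconstruct_stack(fs.extract_core_means(stack, coremap), coremap)
    )
    return cfg, truth, recon


def cell_roi(cfg, cell, grid, shape=(128, 128), scale_r=1.0) -> fs.ROI:
    """Disk ROI on the reconstruction grid covering a generated cell."""
    h, w = cfg.frame_shape
    cy = (h - 1) / 2.0 + cell.center_um[0] / cfg.raw_pixel_um
    cx = (w - 1) / 2.0 + cell.center_um[1] / cfg.raw_pixel_um
    gy = (cy - grid.origin[0]) / grid.scale - 0.5
    gx = (cx - grid.origin[1]) / grid.scale - 0.5
    r = scale_r * cell.radius_um / cfg.raw_pixel_um / grid.scale
    return fs.ROI.disk((gy, gx), r, shape)
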