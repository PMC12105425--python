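# fiberscope

Processing for **multicore-fiber (fiber-bundle) microendoscope** movies.

A flexible microendoscope relays the sample plane through a GRIN lens onto
a bundle of ~1500 individually guiding fiber cores, each core sampling one
image point. The raw camera frames therefore show a honeycomb of bright
core spots on dark cladding, overlaid with core autofluorescence,
frame-to-frame gain flicker, and (in vivo) breathing-induced rigid motion.
`fiberscope` turns such recordings into quantitative single-cell traces:

1. **Core segmentation** — Gaussian-smooth a reference image, invert it,
   and watershed so every basin is one fiber core; sub-pixel centers come
   from neighbour-tail-corrected intensity centroids.
2. **Honeycomb removal** — average each core's pixels, then interpolate
   the scattered per-core values onto a 128 × 128 grid with
   Delaunay-triangulation-based linear interpolation.
3. **Background correction** — subtract each frame's 25th intensity
   percentile (computed inside the bundle footprint only), which cancels
   the autofluorescence pedestal together with multiplicative gain flicker
   acting on it.
4. **Motion correction** — masked normalized cross-correlation of every
   frame against the first; integer-pixel realignment.
5. **Channels** — de-interleave frame-alternated excitation (e.g.
   475/555 nm for GCaMP6f + mKate2, or 395/475 nm for the redox sensor
   roGFP2-Orp1) and form ratio traces normalized to the mean of their
   first 50 samples.
6. **Traces** — per-ROI means, ΔF/F = F/min(F) − 1, moving-median
   denoising, onset alignment (first crossing of a fixed fraction of the
   maximum), and ensemble mean ± SD.

The package also implements the optical-characterization arithmetic
(magnification, field-of-view geometry, ideal hexagonal core spacing,
Rayleigh limit, FWHM measurement) and a **synthetic movie generator** that
renders a jittered hexagonal bundle with every artifact above plus cells
with known transients, so the whole pipeline is testable against exact
ground truth without hardware.

## Worked example

Render the default synthetic in-situ recording (60 s at 4.3 fps, three
cells with 0.6 peak ΔF/F — i.e. the ~1.6-fold responses typical of
tracheal tuft cells), run the full pipeline, and read off the results:

```python
import fiberscope as fs
from fiberscope.pipeline import PipelineConfig, run_pipeline

cfg = fs.synthetic.default_insitu_config()
stack, truth = fs.render_movie(cfg)
fs.write_stack(stack, "demo_raw.tif")

pc = PipelineConfig(
    input_stack="demo_raw.tif", output_dir="demo_out", median_window=30,
    rois=[{"disk": {"row": 38, "col": 81, "radius": 7}, "label": "cell1"},
          {"disk": {"row": 86, "col": 40, "radius": 7}, "label": "cell2"},
          {"disk": {"row": 80, "col": 94, "radius": 7}, "label": "cell3"}],
)
res = run_pipeline(pc)
st = res["lattice_stats"]
print(st.n_cores, st.mean_nn_spacing_um, st.mean_core_diameter_um)
print([float(t.values.max()) for t in res["traces"]])
```

Output (seed 42):

```
n_cores 1417  spacing 3.55±0.08 µm  core diameter 2.41±0.02 µm
cell1 peak dF/F 0.627   cell2 peak dF/F 0.621   cell3 peak dF/F 0.631
ensemble peak 0.626 (n = 3)
```

The segmentation finds all 1417 generated cores; the nearest-neighbour
spacing and core-diameter estimates recover the generator's lattice
(3.71 µm pitch with 0.1 µm jitter, 2.34 µm core FWHM measured through the
1-px smoothing kernel), and the median-filtered peak ΔF/F lands within a
few percent of the generated 0.6 amplitude — the residual upward bias is
the min-baseline convention reacting to gain flicker (see
`docs/methods.md`).

The same stages are available from the shell:

```bash
fiberscope simulate --out raw.tif --n-frames 258
fiberscope segment raw.tif --out-prefix coremap
fiberscope reconstruct raw.tif --coremap-prefix coremap --out recon.tif --register
fiberscope trace recon.tif --roi 38,81,7 --out trace.csv
fiberscope calibrate
```

`fiberscope calibrate` prints the instrument constants derived from the
optical design (f = 3.6 mm objective, f = 200 mm tube lens, 16 µm camera
pixels, NA 0.4, λ = 475 nm):

```
     magnification: 55.56
     pixel_size_um: 0.287977
      fov_area_um2: 17100
      um2_per_core: 11.7
    hex_spacing_um: 3.68
 rayleigh_limit_nm: 720
```

## Layout

```
src/fiberscope/
  synthetic.py       synthetic bundle movies + ground truth
  segmentation.py    watershed core segmentation, lattice statistics
  reconstruction.py  core means, Delaunay interpolation, percentile subtraction
  registration.py    masked-NCC rigid motion correction
  channels.py        de-interleaving, ratio traces
  traces.py          ROI traces, dF/F, median filter, onset alignment
  optics.py          optical characterization calculations
  io.py              TIFF/CSV/YAML I/O and data containers
  pipeline.py        configuration + end-to-end driver
  cli.py             command-line interface
```
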