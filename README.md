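# cyanosight

Quantitative tools for studying how a single cyanobacterial cell
(*Synechocystis* sp., a ~3 µm sphere) perceives the direction of light.
The biological claim under test is that the cell body acts as a
microscopic lens: incoming light is focused into an intense spot at the
membrane *opposite* the light source (a photonic nanojet), the cell reads
the spot position, and steers its twitching motility toward the light.
Shading by the cell's own pigments, the competing hypothesis, is too weak
— a single cell absorbs only ~20% of photons even at peak wavelengths.

The package implements the full measurement chain around that claim, and
a synthetic-data generator so every stage can be validated end-to-end
with known ground truth:

- **`cyanosight.synthetic`** — renders time-lapse stacks of blob-like
  motile cells (1 frame / 3 s, speeds 0.05–0.4 µm/s, direction switching
  ~1 min after light onset), fluorescent periplasmic ring images with a
  configurable focal spot, and labelled track fixtures.
- **`cyanosight.tracking`** — scale-normalized Laplacian-of-Gaussian blob
  detection (scale σ = R/√2, sub-pixel quadratic refinement) and
  mutual-nearest-neighbour linking with an 8 µm displacement gate.
- **`cyanosight.motility`** — the track quality filters (≥25 consecutive
  frames, mean speed in [0.05, 0.4) µm/s, no step ≥ 8 µm), displacement
  orientations, and circular statistics: mean resultant length
  r = ‖Σ(cos θᵢ, sin θᵢ)‖/n and the Rayleigh test of circular uniformity
  with the standard finite-n series correction.
- **`cyanosight.lens`** — intensity profiles around the cell
  circumference (3 px line width), peak/front ratio and FWHM of the
  focal spot, Gaussian quadrature PSF correction
  FWHM_true = √(FWHM_obs² − FWHM_psf²), and angular resolution
  θ = FWHM_true/(d/2) · 180/π.
- **`cyanosight.transmission`** — single-cell Beer–Lambert model: the
  thylakoid region as a hollow sphere (inner/outer diameter 1/2 µm),
  effective pigment concentrations from per-cell molecule counts,
  A = Σ εᵢ cᵢ L along the 1 µm central chord, T = 10^(−A).
- **`cyanosight.optics`** — a 2-D FDTD Maxwell solver (Yee grid, 10 nm
  spacing, TF/SF plane-wave injection, split-field PML, TM and TE) for
  the d = 3 µm, n = 1.4 model cell at λ = 365 nm, cross-validated
  against an exact Mie-series solution for the infinite dielectric
  cylinder, plus photonic-nanojet metrics (focal position, peak
  enhancement, transverse FWHM).

## Worked example

Simulate a phototaxis movie, track the cells, and measure how strongly
their displacements cluster toward the light:

```bash
cyanosight simulate --out stack.tif --tracks-out truth.csv \
    --n-cells 12 --n-frames 120 --light-onset-frame 20 --seed 11
cyanosight track --stack stack.tif --out tracks.csv \
    --min-response 50 --n-patches 32
cyanosight stats --tracks tracks.csv --out stats.json \
    --light-dir 0 --onset-frame 20
```

`stats.json` then contains

```json
{
  "n_tracks_in": 12,
  "n_tracks_kept": 12,
  "reject_reasons": { "valid": 12 },
  "n": 12,
  "r": 0.90877701311365,
  "mean_direction_deg": 7.059968658004143,
  "rayleigh_p": 0.0
}
```

All 12 rendered cells were recovered and pass the quality filters; their
net displacements over the 5 min window starting 1 min after light onset
cluster tightly around the light direction (r = 0.91, mean direction 7°
from the light axis, Rayleigh p ≈ 0 — decisively non-uniform).

The lens measurements run from Python:

```python
>>> from cyanosight.lens import deconvolve_fwhm, angular_resolution
>>> deconvolve_fwhm(609.0, 270.0)       # observed spot, microscope PSF
545.8672...                              # true spot ≈ 550 nm
>>> angular_resolution(545.87, 3.0)      # on a 3 µm cell
20.85...                                 # ≈ 21° angular resolution
```

and the micro-optics simulation from the CLI
(`cyanosight fdtd --config examples/fdtd_smoke.json --out field.tif
--metrics-out metrics.json`) or the library (`cyanosight.optics.run_fdtd`).

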