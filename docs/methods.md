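# Methods

This note records the models behind each module, the defaults and why
they were chosen, and what the synthetic data do and do not emulate.

## Angle and image conventions

All angles are in degrees, anticlockwise from +x, in a y-up mathematical
frame. In-memory images are `[y, x]` arrays with y increasing upward;
the IO layer flips raster files (stored y-down) on read and write, so no
other module ever reasons about raster orientation. Pixel `i` is centred
at `(i + 0.5) * pixel_size`.

## Synthetic motility scenes

The generator emulates surface-motility time-lapse microscopy: cells are
radially symmetric 2-D Gaussian blobs (σ = cell_radius/2 — matching the
blob model the LoG detector assumes, and free of disc-edge aliasing) on
a flat background, imaged at 1 frame / 3 s with Poisson noise by default
(photon-limited fluorescence/scatter imaging). Defaults: 3 µm cell
diameter, 0.2 µm pixels, mean speed 0.2 µm/s within the observed
0.05–0.4 µm/s range.

Three heading models are provided:

- **direct_steering** — persistent random walk (per-step Gaussian heading
  noise, default sd 10°) until light onset plus a switch delay (default
  60 s, matching the observed ~1 min switching); afterwards the heading
  relaxes exponentially toward the light direction with a 30 s time
  constant while keeping its noise. The published behaviour constrains
  only the ~1 min aggregate switch time; the delay + relaxation split and
  the heading noise are tunable, not fitted.
- **biased_random_walk** — the run-and-tumble null model: Poisson tumbles
  (default 0.05 s⁻¹); after onset a tumble re-draws the heading from a
  mixture of uniform (weight 1 − bias) and light-centred von Mises(κ=2)
  (weight bias). With bias 0 displacements are isotropic.
- **immotile** — static cells.

Cells are solid bodies: initial placement is hard-core (centres at least
one cell diameter apart; if a crowded field makes that impossible the
draw is accepted anyway and a density warning is logged), and a step
that would overlap another cell is rejected for that interval. Both
position and heading reflect at the boundary, which is placed one cell
diameter inside the image edge — the field of view is treated as an
interior crop of a larger dish, so rendered cells are never truncated by
the image border. Per-cell speeds are drawn once (truncated normal) and
held fixed; real cells vary speed over time, which the generator does
not emulate. There is no photobleaching, focus drift, or cell division —
passing the tracking tests therefore demonstrates correctness of
detection/linking on well-behaved data, not robustness to those real
artifacts.

## Ring images (periplasmic reporter with a focal spot)

The intrinsic circumference profile is a uniform ring plus a von
Mises-shaped bump, rescaled to be exactly 0 at the antipode and 1 at the
peak, so the configured peak/front ratio is exact pre-blur; the bump
concentration κ is solved numerically from the requested arc-length
FWHM. The 2-D image sweeps that angular profile around a radial Gaussian
ring (default radial FWHM 0.3 µm) and convolves with a Gaussian PSF.
For spots much narrower than the ring circumference the von Mises bump
is locally Gaussian, so the blurred arc FWHM follows the quadrature rule
√(FWHM² + PSF²); a dense 1-D convolution oracle in the tests confirms
this to better than 2%.

## Cell tracking

Detection computes the scale-normalized LoG response `-σ²·∇²(G_σ * I)`
at the single scale σ = R/√2 (the standard blob-radius relation), keeps
strict 8-neighbour maxima — at most one per tile of an n×n image
partition, the "patch" control of the original tracking approach — above
a response threshold, and refines each to sub-pixel position with a
separable 3-point quadratic fit. scipy's truncated Gaussian kernels pass
a small DC gain, so flat image regions respond at gain × intensity; the
detection floor is held above twice that leak, which also makes the
detection count invariant under constant intensity offsets.

Linking joins mutually-nearest detections in consecutive frames within a
displacement gate (default 8 µm per 3 s interval), greedy by increasing
distance with lowest-index tie-break; unmatched detections open new
tracks and a missed detection closes a track (no gap closing, since the
downstream filters require consecutive frames). Tests verify equivalence
with optimal bipartite assignment on small instances and symmetry under
time reversal. No appearance model or motion prediction is used — the
method is distance-only by design.

## Motility statistics

A track enters the directional analysis iff it spans ≥ 25 consecutive
frames, every step is < 8 µm, and its mean speed (path length / elapsed
time) lies in [0.05, 0.4) µm/s; slower cells are labelled immotile,
the boundary value itself counting as motile (with a 1e-9 relative
tolerance so exact-boundary fixtures classify deterministically).

Circular statistics use the mean resultant length
r = ‖Σ(cos θ, sin θ)‖ / n and the Rayleigh statistic Z = n r², with the
finite-n series correction
p = e^(−Z)[1 + (2Z − Z²)/(4n) − (24Z − 132Z² + 76Z³ − 9Z⁴)/(288n²)]
clipped to [0, 1]. The independent `pingouin` implementation is used in
tests as a cross-check (it applies a different finite-n approximation;
the two agree to ~1e-3).

The directionality time course slides a window (default 60 frames = 5
min, stride 1 frame; the stride is not specified by the source method
and is exposed as a parameter) over the filtered tracks; each track
covering a window contributes the angle of its net displacement relative
to the light direction, wrapped to (−180°, 180°]. Direction switching
around a stimulus event compares net-displacement orientations over
132 s windows before and after the event.

## Circumference profiling and spot metrics

Profiles sample a true circle (centre and radius are explicit inputs —
hand-fitted spline contours are not reproducible and are deliberately
not emulated) at ≥ 2 samples per pixel of arc, averaging bilinear
interpolants over a 3 px line width. The arc origin sits at the point
nearest the light source ("front"), increasing anticlockwise.

Spot metrics: front intensity is the mean over a 3-sample window at the
arc origin; the FWHM is measured at half height above the profile
minimum (the ring background — profiles never fall to zero), with
linear interpolation on both flanks; a profile whose global maximum sits
inside the front window is flagged rather than measured. PSF correction
is quadrature subtraction (valid for Gaussian spot and PSF); because
blurring conserves the bump area, the intrinsic peak/front ratio is
recovered as 1 + (observed − 1)·FWHM_obs/FWHM_true. Angular resolution
treats the FWHM as arc length on the circumference (small-angle
equivalent of the chord). Closure of the whole chain
(generate → profile → metrics → deconvolve) is verified to within 5%
across ratio ∈ [1.5, 8], FWHM ∈ [400, 900] nm, PSF ∈ [200, 350] nm at
25 nm sampling, where pixelization no longer dominates; at coarser
sampling the pixel grid adds its own quadrature-like blur.

## Single-cell transmission

The pigmented thylakoid region is modelled as a hollow sphere (defaults:
inner diameter 1 µm, outer 2 µm, shell volume 3.665 µm³), pigments
uniformly distributed; a narrow central beam crosses 1 µm of pigmented
path. Per-cell molecule counts convert to molar concentrations via
Avogadro's number and the shell volume in litres; absorbance follows
Beer–Lambert with centralised unit conversions (µm→cm, mM→M), and the
suspension spectrum — scattering-baselined at 750 nm, negatives clipped
with a logged count — is rescaled so its value at the reference peak
(620 nm) equals the computed single-cell absorbance, then converted to
transmission T = 10^(−A). Molar extinction spectra are user-supplied
configuration (the bundled example bases are synthetic placeholders,
labelled as such); pigment unmixing onto supplied bases uses
non-negative least squares. Computed quantities are reported as
computed — e.g. the default counts (2.94×10⁷ chlorophylls) in the
default shell give 13.3 mM — and nothing re-states externally quoted
concentrations. Refraction and interference are deliberately outside
this module: it is a pure absorption bound along a straight ray.

## 2-D FDTD and the Mie oracle

The solver treats the cell as a homogeneous dielectric disc — the 2-D
(infinite-cylinder) cross-section of the spherical model cell (n = 1.4,
d = 3 µm, vacuum background by default to match the lithography-in-air
geometry; 1.33 is available via config). 2-D was chosen because it
admits an exact analytic counterpart (cylindrical-harmonic Mie series)
as an independent oracle and runs at desk scale; 3-D is a non-goal.
Material boundaries use 4×4 sub-pixel permittivity averaging.

Numerics: Yee grid at 10 nm default spacing (validation requires ≥ 10
cells per in-medium wavelength); the time step is Courant-limited,
dt = 0.99·dx/(c√2) ≈ 2.3×10⁻¹⁷ s at 10 nm, snapped so one optical
period is an integer number of steps. A continuous plane wave (raised-
cosine ramp over 3 periods) enters through a total-field/scattered-field
rectangle driven by a 1-D auxiliary grid stepped with the same dx and dt
— the 1-D dispersion relation then equals the 2-D on-axis branch
exactly, making injection leak-free to machine precision. Berenger
split-field PMLs (30 cells, cubic grading, 10⁻⁶ reflection target)
absorb outgoing waves; the TF/SF corrections are accumulated in the
x-curl split so they persist in the field state. The run continues until
the per-period-averaged field energy changes by < 1% between successive
periods (with a floor of ramp + one domain crossing, to avoid declaring
convergence before the wave arrives), then intensity is averaged over
two further periods.

Intensity is the period-averaged magnitude of the instantaneous
Poynting vector ⟨|S(t)|⟩ at field nodes (E time-centred, H spatially and
temporally interpolated), normalized by the same quantity measured on
the 1-D incident grid with the identical interpolation — cancelling the
small systematic attenuation the interpolation introduces. The Mie
oracle computes the same observable analytically: exact incident plane
wave plus a scattered/interior series (coefficients from a per-order
2×2 continuity system solved numerically), fields converted to
S(t) = A + Re(B e^(−2iωt)) and |S| averaged over the beat phase. Series
truncation follows x + 4x^(1/3) + 10 on the interior size parameter with
an explicit tail check. Both TM (out-of-plane E, the default) and TE are
implemented in solver and oracle.

At the production configuration the two routes agree to 2.3% relative
L2 over the total-field region; the nanojet focus sits ~0.5 µm outside
the distal surface with ~10× peak enhancement and a 226 nm transverse
FWHM (subwavelength). The distal/proximal surface ratio is sampled half
a wavelength outside the poles because the surface points themselves can
sit on interference nodes.

The published description of this simulation prints a time step of
10⁻⁸ s, which violates the Courant bound at 10 nm spacing by ~9 orders
of magnitude and is presumably a typo; this implementation always uses
the stable Courant-limited step.

## Problem sizes and tolerances in the test suite

Routine tests use coarse smoke grids (15–20 nm FDTD spacing, where
discretization error ~10% dominates the FDTD–Mie comparison) and
moderate ensembles (200 tracks, 2000 angles); the acceptance suite runs
the 10 nm production grid once and shares it across checks. Tracking
recovery is scored by assigning each recovered point to the nearest
ground-truth cell per frame: tracks mapping to a single cell for ≥ 25
frames with sub-half-pixel mean error count as recovered; long tracks
mapping to multiple cells count as identity swaps. Stochastic
assertions (von Mises r, null-ensemble r, recovery fraction) hold with
margin across seeds; hypothesis-based property tests run derandomized.
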