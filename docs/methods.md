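# Methods

This note documents the models and numerical choices behind
`hyperplume`, what the synthetic scene generator does and does not
emulate, and the package's known limitations.

## Data model and I/O

A hyperspectral cube is held in memory as a `(line, sample, band)` array
with a strictly increasing band-center wavelength vector in nm, no
matter which ENVI interleave (`bil`, `bip`, `bsq`) the file uses;
conversion happens only at the I/O boundary. Pixel coordinates are
0-based `(row=line, col=sample)` throughout. The reader supports the
common ENVI numeric types (uint8/16/32, int16/32, float32/64) and
promotes to float on ingestion; the writer defaults to float32, which
round-trips losslessly. Negative sensor values are clamped to zero on
read — reflectance and radiance are physically non-negative — with the
clamp count logged rather than silently propagated as NaN. Headers
declaring micrometer wavelength units are converted to nm.

## Calibration

Push-broom geometry means the illumination field varies across the
sensor line (samples/columns) but is constant along the scan direction
(lines). The flat-field therefore averages the bright cube over its
lines to one reference spectrum per column and divides the scene by it.
Zero entries in the reference (dead bands) become NaN ("missing") with a
logged count.

Spectral calibration divides by the per-band **median** spectrum of the
standard's pixels — the median resists specular glints and dust on the
standard. The nominal reflectance of the standard defaults to 1.0
(i.e., plain division by a 99% Spectralon panel, the conventional
arithmetic); passing 0.99 applies the physically exact correction.
Calibrated values above 1 are legitimate (specular highlights) and are
flagged above a configurable cap, never clipped. Dark-current
subtraction is out of scope: the supported correction chain is bright
division plus standard division.

## Sampling

Sampling a lattice rather than every pixel controls cost and reduces
redundancy from spatial autocorrelation. The lattice spacing starts at
`floor(sqrt(mask_area / target))` and walks ±1 until the in-mask count
is within ±10% of the target or the target is bracketed; the count
closest to the target wins, with ties resolved toward the smaller
spacing (more samples). The lattice origin is anchored at the mask
bounding-box corner offset by half a spacing — fully deterministic, no
randomness. A target of 1 degenerates to the mask pixel nearest the
centroid.

Each sample is the per-band median of a 10 × 10 window centred on the
lattice point; windows are truncated (not discarded) at image edges,
because discarding would bias sampling away from patch boundaries.
Locations falling inside the standard's mask are excluded. The default
target of 1,000 samples per patch per specimen reflects the scale at
which patch-level color distributions stabilise without overwhelming
downstream embeddings. An iridescent breast-style patch can be
restricted to views flagged "angled", where its color is actually
directed at the camera.

## Spectral preprocessing

1. **Interpolation** — piecewise linear onto the integer-nm grid
   325–700 (376 points), the reliable range of the emulated instrument
   class; no extrapolation at this stage.
2. **Smoothing** — Savitzky–Golay, 45 nm window and polynomial order 2.
   On a 1 nm grid the nm window maps directly to 45 filter points (odd).
   Edges are refit on the truncated window (`mode='interp'`), so
   constants survive exactly and quadratics survive at interior points.
   This is deliberately heavy smoothing: its purpose is to stabilise the
   short-wavelength extrapolation, where small noise near 325 nm would
   otherwise produce large extrapolated differences. Appropriate
   smoothing levels for other applications are a user decision.
3. **UV extrapolation** — a monotone cubic Hermite interpolant (PCHIP)
   is fitted to the smoothed 325–700 nm curve and its leftmost cubic
   segment evaluated on 300–324 nm. "Cubic monotone spline" admits
   several readings; PCHIP was chosen because it is shape-preserving,
   deterministic, and extends the curve without inventing oscillations.
   Extrapolated values are clamped to `[0, 1.5 × max(observed)]` to stay
   physical (the clamp bound is a package choice). The fit uses the full
   325–700 nm range; the final grid is exactly 300–700 nm (401 points)
   with the extrapolated region flagged.

Avian spectral sensitivity below 325 nm is low for violet-sensitive
systems, so visual-model outputs should be (and are measured to be)
nearly indifferent to the extrapolated segment: replacing it with a
constant shifts dS by well under 0.1 JND for the synthetic patch spectra.

## Visual-system-independent embedding

"Brightness removal" subtracts each spectrum's own scalar mean
reflectance, so the embedding responds to spectral shape; this is the
default reading of mean-subtraction, with the alternative
(dataset-mean-spectrum centring, which retains brightness) available via
`brightness_removal='dataset_mean'`. PCA (scikit-learn, full SVD) keeps
20 components; one PCA per plumage patch is the intended usage, since
patch spaces are not comparable. UMAP (n_neighbors 15, min_dist 0.1,
fixed default seed 42, all configurable) reduces the 20 scores to a 2-D
plane; with a fixed `random_state` the embedding is bit-reproducible.
All-identical inputs collapse to co-located points rather than crashing.

Kernel densities use `scipy.stats.gaussian_kde` with Scott's-rule
bandwidth per group, evaluated on a 256 × 256 grid over the pooled
bounding box padded 10% per side and renormalised to unit mass on the
grid. The contour level for mass m is found by sorting grid densities
and accumulating cell mass until m is reached — the highest-density
region. Mode = grid argmax; "mode spectra" are the k = 50 samples
nearest the mode in the 2-D plane, summarised by per-band median and
median absolute deviation. Zero-variance groups get a jittered
bandwidth floor with a warning.

KDE smoothing inflates the apparent spread slightly: on 20,000
standard-normal draws the measured 80% region covers ≈ 0.81 of points
and its area-equivalent radius is ≈ 2% above the closed form
√(−2 ln 0.2). This is inherent to fixed-bandwidth KDE, not an error.

## Avian visual model

Receptor sensitivities for an "average violet-sensitive bird" are
generated from the Govardovskii et al. (2000) A1 pigment nomogram
(alpha + beta band, peak-normalised) at λmax = 417/478/542/607 nm for
VS/SWS/MWS/LWS. These are template approximations — the package does
not ship digitised measured curves — and every λmax is configurable;
the template itself is exposed for arbitrary systems. An optional
double cone can be generated at any λmax; when absent, the LWS curve
serves as the luminance proxy.

Quantum catches assume a flat (ideal) illuminant with von-Kries
normalisation to an ideal white background, making Q dimensionless and
Q ≡ 1 for a perfect white. Tetrahedral coordinates follow the standard
convention with the achromatic point at the origin and vertices at
radius 0.75:

    x = ((1 − 2s − m − u)/2)·√(3/2),  y = (−1 + 3m + u)/(2√2),  z = u − 1/4.

Receptor-noise contrasts use cone ratios (1,1,1,2) and a chromatic
Weber fraction w = 0.1 **anchored to the most abundant cone class**
(LWS), giving e = (0.1√2, 0.1√2, 0.1√2, 0.1) — the convention of the
standard implementations; both w and the anchoring are configurable.
dS uses the tetrachromatic receptor-noise formula (cross-checked in the
test suite against an independent brute-force transcription); dL =
|ln(Q_D^A/Q_D^B)|/w_D with w_D = 0.1. A floor of 1e−9 is applied to
catches before logs so synthetic black pixels do not produce −∞; floor
applications are logged. The discriminability call is inclusive:
contrast ≥ 3 counts as discriminable. Pairwise specimen contrasts use
the median spectrum per patch per specimen — a deliberate
single-spectrum simplification; the full sample distribution remains
available for distribution-level analyses.

Per-pixel cone-catch images run every pixel spectrum through the same
preprocessing chain (vectorised; a constant UV extension is available
as a cheaper option) and refuse cubes that do not carry a calibration
flag unless forced.

## 3-D registration

The imager is fixed-height over a translation stage, so the camera is
modelled as orthographic with one global scale. Pose estimation fits
image = s·(R·X)₀₁ + t by least squares: with ≥ 4 non-coplanar landmark
pairs, an affine 2×3 fit is projected onto the nearest scaled rotation
via SVD (exact for exactly-similar data); coplanar configurations,
including the 3-point minimum, use an in-plane 2-D similarity fit where
out-of-plane tilt is unobservable. Collinear landmarks are rejected as
degenerate.

Rasterisation is an orthographic depth buffer at the hyperspectral
image's resolution. Angle conventions (camera x → image right, y →
image down, z → toward camera): roll = atan2(−n_x, n_z) is positive
when the surface faces left of the camera; pitch = atan2(−n_y, n_z) is
positive facing up; both in [−π, π]. Background pixels are flagged
invalid, never zero. Face normals are the default; barycentric
vertex-normal interpolation (`use_vertex_normals=True`) is markedly more
accurate on curved surfaces — flat face normals on a subdivision-4
icosphere deviate from the true sphere normal by up to ~2° purely from
tessellation, while interpolated vertex normals stay within ~0.4°.

Pitch binning attaches to each sample the normal at its window centre
(nearest pixel), drops samples without a valid normal (logged), and
reports per-bin per-band median ± MAD. When regressing recovered peak
wavelengths on pitch, use the samples' median pitch per bin rather than
the bin centre: pitch is non-uniformly distributed over a curved
surface, and bin centres bias the slope toward zero.

## Synthetic scenes

The generator emulates: a white-standard rectangle (nominal 0.99), four
body patches with parametric spectra, a linear column-wise illumination
gradient (directional lighting makes surfaces nearer the source
brighter), additive Gaussian sensor noise on radiance, and the
instrument-style wavelength grid (294 bands, 274–812 nm, ≈ 1.83 nm
spacing) so interpolation arithmetic matches real headers. Default
patch spectra are broad, as natural plumage curves are: a structural
green Gaussian peak (σ = 50 nm), carotenoid-like sigmoid steps (scale
25–28 nm), flat white, and a brown ramp. Default noise sd is 0.01 on
unit-scale radiance and the default gradient amplitude 0.2 (±20% across
the field). The 3-D variant uses an analytic ellipsoid whose coat peak
shifts linearly with surface pitch (default 100 nm/rad) plus five exact
landmark correspondences. Everything is reproducible from the seed.

What the generator does **not** emulate: wavelength-dependent
illuminant shape, shot (signal-dependent) noise, specular highlights,
feather microstructure and true BRDFs, fluorescence, spatial texture
within patches, and registration error between image and mesh. Passing
tests therefore demonstrate correctness of the pipeline's arithmetic
and its recovery of known ground truth under realistic noise — not
robustness to every artefact of real museum-specimen imaging.

## Problem sizes

Default verification scenes are 160 × 220 pixels with 294 bands and
~200 samples per patch, and density calibration uses 20,000 draws on a
256² grid — sizes at which every ground-truth recovery above is stable
while the full suite runs in about a minute.

## Known limitations

- Patch masks are user-supplied; no automatic segmentation.
- Only the bright-division + standard-division calibration chain is
  implemented (no dark reference).
- The orthographic camera ignores perspective; fine for fixed-height
  stage acquisition, wrong for close-range free photography.
- Receptor curves are nomogram templates, not species measurements, and
  the ideal-illuminant assumption ignores real lighting spectra.
- The receptor-noise model assumes discrimination at the physiological
  limit under ideal conditions; the ≥ 3 threshold is a deliberately
  conservative convention, and conclusions can be sensitive to the
  assumed cone ratios and Weber fraction.
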