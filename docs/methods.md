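# Methods

This note documents the physical model, the numerical choices and the
limits of validity of the `tilesheet` simulator. It is the place where
design decisions that the code cannot explain by itself are argued.

## Optical model

All propagation is **scalar** Fourier optics. The excitation pupil is
sampled in absolute numerical-aperture coordinates (`na = n·sinθ`, medium
index included — water, n = 1.33, throughout), and fields reach the focal
region by the angular spectrum of plane waves with the exact (non-paraxial)
axial wavevector `k_x = (2π/λ)√(n² − na²)`; evanescent components are
excluded. Scalar theory is accurate to a few percent at the excitation NAs
used here (≤ 0.5) and degrades to ~10% errors at the 0.8 NA detection
objective; tolerances on detection-side quantities are set accordingly.
Polarization, aberrations and scattering are out of scope.

The FFT pairs pupil and image planes on a common grid: with N transverse
samples of pitch Δy, the pupil NA step is `Δna = λ/(N·Δy)`. The default
excitation grid (512 × 512, Δy = 0.135 µm) satisfies the Nyquist condition
`Δy ≤ λ/(4·NA_max)` for every aperture simulated, and a circular stop at
the inscribed pupil circle represents the relay aperture (it also keeps the
sampled band alias-free). Simulated SLM grids are laid on the same pixels,
with the origin at index `n//2` so designed maps align exactly with the FFT
origin; the map-to-NA scaling is a single linear calibration constant
(`na_per_px`), the one free parameter a simulator needs where hardware has
fixed relay magnifications.

## Binary phase maps

The SLM carries two phase levels, 0 and π. Continuous designs (defocus,
defocus + Dammann, carrier) are wrapped to [0, 2π) and binarized by the
rule *[0, π) → 0, [π, 2π) → π*. Binarization of a defocus map creates a
conjugate order pair focused at ±d with ~40% efficiency each. A pure
binary defocus cannot be separated by a slit — the two orders are coaxial —
so the designed phase includes a **lateral carrier tilt** (default 20 µm
image-plane offset along the dither axis): the orders then land at ±20 µm
in the slit plane, the rectangular passband (a config parameter; the
hardware width is not published) transmits one, and the tilt is removed
after the slit, which is what the scan galvo does in hardware. The
abandon-area grating (2 px period, exactly 50% duty so its 0th-order
amplitude is analytically zero) diffracts unwanted light to the edge of the
simulated window, where the slit blocks it.

## Dammann design

Order amplitudes of a binary grating are closed-form in its transition
points, and a real ±1 transmittance makes ±m orders identical, so an
N-beam design solves for `2·int[(N−1)/4]+2` transitions equalizing orders
0…(N−1)/2. The optimizer is multi-start trust-region least squares
(seeded, deterministic) with a small efficiency reward (weight 0.05) and
rejection of collapsed-transition solutions, followed by quantization to
the SLM pixel grid; the design is accepted only if the quantized orders
stay within 5% relative spread (default periods: 128 px for N ≤ 9, 1024 px
above). With the minimal transition count the optimizer reaches ≤ 5%
spread for N ∈ {3,5,7,9,13,…,21} but stalls near 8% at N = 11; that size
appears to need more transitions than the minimal formula provides, and
`design_dammann` raises for it unless the caller relaxes the bound.

## Sheet metrics

* **Thickness** — FWHM of the central lobe of the swept profile I(x₀, z)
  at the focal plane, by linear interpolation between samples; the lobe is
  found by walking uphill from z = 0, so Bessel side lobes are excluded.
* **Length** — FWHM along x of the beam's **on-axis intensity**
  I(x, 0, 0), the standard beam-length definition for Bessel/Gaussian
  beams. An alternative span — the contiguous range over which the
  central-lobe FWHM stays within √2 of its minimum — is also computed
  (`uniform_range`); it runs ~15–25% longer than the on-axis FWHM for the
  annuli studied here, and the on-axis definition is the one that matches
  the dimensions quoted for both reference sheets (≈11 vs ∼10 µm and
  ≈30 vs ∼30 µm), so it is the primary `length`.
* **Confinement** — fraction of the focal-plane profile I(x₀, z) inside
  the detection depth of focus `n·λ_em/NA_det²` (≈1.06 µm for 0.8 NA at
  510 nm; overridable). Emission defaults: 0.510 µm (GFP) and 0.590 µm
  (mCherry).

## Image formation

During a z-stack the sheet moves with the detection focal plane, so for a
static object each tile is a single 3D convolution with the **system PSF**
— the widefield detection PSF weighted along z by the sheet's waist
profile — while the sheet's axial envelope I(x, z≈0) multiplies the object
in sample space. This factorization uses the waist z-profile for the whole
tile and therefore ignores sheet thickening towards tile edges; that
approximation is precisely why reconstruction keeps only tile centres. The
camera model is sCMOS-like: linear photon scaling, optional Poisson shot
noise, Gaussian read noise, constant offset; the noiseless mode is
bit-deterministic. The z-stack step defaults to 0.2 µm and is independent
of the optics grid; resampling is explicit. PSF kernels are generated with
odd pixel counts so centred convolutions are exact.

## Reconstruction

Tiles are first divided by their known illumination envelope (flat-field
correction — the envelope is part of the acquisition metadata), then fused
with per-tile weights that are 1 over the central half-spacing, cross-fade
linearly over a margin of 10% of the spacing, and are normalized to sum to
one everywhere; uniform phantoms stitch flat to ≤5% and boundary objects
keep single-tile flux. Richardson–Lucy runs 20 unregularized iterations by
default (circular FFT convolutions with the PSF embedded at the grid
origin; a ratio floor of 1e-9 × max guards empty regions), initialized
from the data mean. On noiseless data it conserves flux to ≪1% and its
Poisson log-likelihood is non-decreasing. The final step zeroes all
frequencies where the system OTF magnitude is below 1e-3 of its peak
(hard cutoff; apodization is deliberately not applied, matching the
simple low-pass described for the original analysis chain). This step
matters quantitatively: RL on noiseless point data sharpens indefinitely
(≈0.30 µm axial after 20 iterations), and the OTF cut restores the
band-limited ≈0.37 µm that the full chain delivers. Bead widths are
measured on cubic-interpolated axial/lateral line profiles through each
refined bead centre; beads closer than 5× the expected FWHM are excluded.

## Synthetic data

Bead phantoms place sub-diffraction impulses (ground-truth centres
recorded) with a minimum separation (default 2.5 µm) and an edge margin;
shell phantoms emulate membrane/nucleus double labelling with spherical
shells plus nuclear spots. The default end-to-end study uses 12 beads in a
28.8 × 9.6 × 14.4 µm³ volume at (0.2, 0.1, 0.1) µm voxels, imaged in three
tiles at 10 µm spacing — an embryo-scale plan at desk-scale cost. What the
phantoms do **not** emulate: realistic morphology, scattering, aberration,
photobleaching, or background autofluorescence; passing tests therefore
demonstrate the correctness of the optics/reconstruction chain, not
robustness on real tissue.

## Tiling planner

`n = 1 + ceil((FOV − sheet_length)/spacing)` (one tile when the sheet
covers the FOV), positions centred on the FOV, spacing larger than the
sheet length rejected as a coverage gap. For a 30 µm FOV with a 10 µm
sheet at 10 µm spacing this gives the three-position embryo plan; for a
200 µm FOV with a 30 µm sheet it yields eight positions at 25 µm (nine
positions correspond to the same plan at the ~21 µm spacing implied by
nine tiles spanning 200 µm — "∼25 µm" in the source).

## Known limitations

Scalar theory at NA 0.8; periodic-window wrap in FFT convolutions (keep
structures off the volume faces); the factorized tile PSF; no subpixel
tile registration (translations are assumed known exactly); lattice
patterns are binarized without amplitude weighting, so their focal fields
match ideal coherent arrays only approximately (correlation ≈ 0.84 for a
single beam on the default grid).
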