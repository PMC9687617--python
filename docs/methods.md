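# Methods

## Physical model and conventions

The imaging problem is two-dimensional and TM-polarized: z-oriented line
sources on a measurement circle Gamma (default 30 antennas, radius 12 cm)
illuminate a 15 cm x 15 cm imaging domain at a single frequency (default
1 GHz). The package adopts the `exp(+j w t)` time convention, so the
relative complex permittivity is `eps_r = eps' - j sigma / (w eps0)`, a
passive medium has `Im(eps) <= 0`, outgoing waves carry the Hankel
function of the second kind, and the 2D background Green function is
`g = (-j/4) H0^(2)(k_b |rho - rho'|)` with `k_b = (w/c) sqrt(eps_b)`
(principal branch, which decays correctly for lossy backgrounds).

The background medium is a homogeneous coupling liquid; its permittivity
is configurable with default `eps_b = 20 - j0`, a typical lossless
value for matching liquids at these frequencies. The line sources have
unit amplitude by default: the inverter normalizes its inputs, so only
consistency between dataset generation and inference matters.

## Forward solver

The state equation `E_t = E_i + A_i(chi E_t)` is discretized by the method
of moments with Richmond's rule: each square pixel is replaced by the
equal-area circle (radius `a = pixel / sqrt(pi)`), over which the Green
function integrates in closed form,

    off-cell   (-j pi k a / 2) J1(k a) H0^(2)(k R)
    self-cell  (-j pi k a / 2) H1^(2)(k a) - 1.

Because cell coupling depends only on center offsets, the operator is
block-Toeplitz with Toeplitz blocks; one application is a 2D convolution
with a `(2n-1)^2` kernel evaluated by FFT in `O(n^2 log n)`, verified
against the dense matrix to ~1e-15 relative on small grids. The linear
system `(I - G X) E_t = E_i` is complex non-Hermitian and is solved with
BiCGStab (default tolerance 1e-6 on the relative residual, 1000
iterations max; an LSQR-based normal-equations fallback is provided).
Receiver sampling uses the same Richmond radiation coefficients; with
coincident transmit/receive positions the noiseless scattering matrix is
symmetric, which the tests assert to 1e-6.

Validation is against an independent analytic oracle: the exact
line-source solution for a homogeneous circular cylinder via
cylindrical-harmonic expansion, with adaptive truncation (increase by 5
orders until the result is stable to 1e-10 relative) and an energy
cross-check (for a lossless cylinder the modal coefficients satisfy
`|a_m|^2 = -Re a_m`, the coefficient form of the optical theorem, met to
1e-16). A 3 cm cylinder of `eps = 25` off-center in `eps_b = 20` agrees
with the solver to 0.96% relative RMS on the 64-pixel grid and 4.2% on
the 32-pixel grid; the residual is staircase discretization error
(center-in-cell rasterization), which halves roughly linearly with pixel
size, so no sub-pixel averaging is applied.

Measurement noise is i.i.d. circular complex Gaussian per matrix entry
with variance `mean(|S|^2) / 10^(SNR/10)`; the Monte-Carlo calibration
over 10,000 draws reproduces a requested 30 dB to better than 0.01 dB.

## Phantom generator

Each phantom is drawn as follows (all through one seeded generator):

1. **Geometry** — ellipse axis lengths (full diameters) uniform in
   [6.5, 12] cm independently; center uniform in a 1 cm-radius disc;
   orientation uniform on [0, 2 pi); skin thickness uniform in
   [1.5, 2.5] mm. Axis lengths are read as diameters so the breast always
   fits the 15 cm domain. Geometry is resampled (up to 100 times) if the
   ellipse would leave the domain, which cannot occur with defaults.
2. **Interior texture** — a scale-invariant random field from spectral
   synthesis (isotropic power-law spectrum, exponent beta = 3 in power)
   followed by pointwise exponentiation, a log-normal surrogate of a
   multiplicative cascade that introduces intermittency; standardized to
   zero mean, unit variance. The field serves purely as a segmentation
   substrate.
3. **Segmentation** — the interior (inside the skin annulus) is cut at
   empirical quantiles of the field into adipose (lowest values),
   transitional, and fibroglandular (highest) so pixel fractions match
   class-conditional targets: fibroglandular and transitional percentages
   are drawn uniformly in the class ranges (A: 5-20/5-15, B: 20-30/10-20,
   C: 30-40/15-20, D: 40-65/20-25) and adipose takes the remainder to
   100%, which the table's construction keeps inside its own range. The
   tissue-to-quantile ordering is fixed for determinism. The skin is the
   band between the ellipse and its inward offset by the sampled
   thickness, closed with a one-pixel boundary layer so the annulus never
   breaks on coarse grids (on a 32-pixel grid the 4.7 mm pixels exceed
   the physical 1.5-2.5 mm thickness).
4. **Dielectrics** — per-pixel `eps'` and `sigma` from per-tissue
   truncated normals (`eps' >= 1`, `sigma >= 0`) with 1 GHz defaults
   consistent with published large-scale measurements of excised breast
   tissue: adipose N(5.5, 1.0)/N(0.08, 0.03) S/m, transitional
   N(28, 5)/N(0.45, 0.10), fibroglandular N(49, 6)/N(0.90, 0.15), skin
   N(40, 3)/N(0.90, 0.10). These are configurable and should be
   recalibrated by users targeting a specific tissue database.
5. **Spatial correlation** — within-tissue Gaussian smoothing
   (normalized masked convolution, default length 2 pixels) emulates the
   spatial coherence of real tissue maps without bleeding across tissue
   boundaries.

Skin thickness is measured on the raster as skin area divided by the
Ramanujan ellipse perimeter; across the 108-pixel grid this agrees with
the sampled thickness to within one pixel.

What the generator does **not** emulate: anatomically curved
fibroglandular structures (texture is statistically isotropic), tumors or
any malignant-tissue insertion, 3D out-of-plane effects, frequency
dispersion of the tissue properties, and antenna/hardware nonidealities.
Passing tests therefore demonstrate correctness of the pipeline and the
learnability of this phantom family, not clinical performance.

## Database and inverter

The database pairs the vectorized scattering matrix (real parts row-major
then imaginary parts; `2 x 30^2 = 1800` inputs) with the vectorized maps
(`eps'` block then `sigma` block row-major; `2 x 108^2 = 23,328` outputs
at full scale). The split is 85/10/5 train/validation/test, stratified by
class with a seeded shuffle (largest-remainder rounding keeps counts
exact: 120,000 profiles split into 102,000/12,000/6,000). Normalization
statistics — per-feature input standardization, per-block (eps'/sigma)
target standardization so both channels weigh comparably in the loss —
are fitted on the training split only and stored with the model. One
AWGN realization (default 30 dB) is stored per sample alongside the
noiseless matrix, enabling re-noising robustness studies.

The inverter is a fully-connected stack — default three hidden layers of
2000 rectifier units and a linear regression output — trained with Adam
(full-scale defaults: initial rate 5e-5, 30 epochs, batch 64, MSE loss),
implemented directly in NumPy with seeded Glorot-uniform initialization
so training is bit-reproducible. The best validation epoch is
checkpointed and restored by default, in addition to the fixed-epoch
schedule. Activation, depth, width and schedule are configurable;
architecture sweeps retrain with identical seeds and data and report
held-out MSE/NRMSE plus the radial spectrum per topology.

### Desk-scale conditions

Full-scale training (120,000 profiles, 58.3M parameters) is a multi-hour
GPU-class job; the package's test and reproduction scale runs on one CPU
in minutes: 32-pixel grid, 80 phantoms per class, a 3 x 256 network, 10
epochs at Adam rate 1e-3 (the standard Adam default; the full-scale 5e-5
rate is tied to the 102,000-sample regime) with batch 32. At this scale
the trained model beats the constant mean-image baseline by ~15% test
NRMSE; the margin is data-limited (a validation-selected ridge regression
on the same 272 training samples reaches ~19%, and raising the budget to
200 phantoms per class lifts the network above 21%), while the
label-oracle floor is NRMSE ~0.02, far below both. Capacity ordering
(2000-node vs 50-node sweep) and noise robustness ordering (worse at 5 dB
than at 30 dB) are reproduced at this scale.

## Metrics

* **SSIM** — Gaussian-windowed (11 x 11, sigma 1.5, reflect padding,
  K1 = 0.01, K2 = 0.03, edge-cropped mean), dynamic range taken from the
  reference map per channel; cross-checked against scikit-image to 1e-6.
* **NRMSE** — `||est - ref|| / ||ref||` (0 perfect, 1 for a zero
  estimate); range normalization available by flag.
* **CORR** — Pearson correlation of the flattened maps, reported in
  amplitude.
* **Radial spectrum** — `T(nu, theta)` is the mean over profiles of the
  squared magnitude of the centered 2D DFT of the retrieved complex
  permittivity map (reassembled as `eps' - j sigma / (w eps0)`; an
  eps'-only flag exists); `S(nu)` averages `T` over annular bins one
  frequency sample wide (Cartesian bins assigned by rounding their radial
  frequency), a discrete surrogate of the angular integral. Verified
  against closed forms for constant, impulse and Gaussian inputs (the
  Gaussian against its analytic Fourier pair to 2% RMS under identical
  binning).

Degenerate inputs are rejected loudly: SSIM on a zero-range reference
requires an explicit dynamic range, NRMSE rejects a zero reference, CORR
rejects constant maps.

## Known limitations

* 2D scalar model only; no 3D, near-field antenna models, mutual
  coupling or matching-medium design.
* The tissue dielectric distributions are configurable placeholders, not
  a fit to a specific published database.
* Single-frequency data; no frequency-hopping or multi-frequency
  inversion.
* The MoM solver's staircase rasterization limits cylinder-oracle
  agreement to ~1% at 64 pixels; finer grids reduce this linearly.
* Desk-scale accuracy figures are bounded by the small training budget,
  as quantified above; they demonstrate pipeline correctness and
  qualitative orderings, not attainable image quality.
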