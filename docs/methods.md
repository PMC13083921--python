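# Methods

## Instrument forward model

The simulated polarimeter is the Mueller chain

    I_det(t) = [ M_pol(β) · M_ret(δ₂(t), 0) · M_ret(δ₁(t), α) · S_in ]₀

with PEM retardances δ_k(t) = A_k sin(2π f_k t). PEM2's optic axis defines
the x-axis; PEM1 sits at α (default 45°) and the analyser at β (default
23°). The linear-retarder matrix uses the sign convention in which
right-circular light acquires U′ = sin δ at axis angle 0; this one choice
fixes every downstream sign and is locked in by the round-trip tests.

Defaults: A₁ = A₂ = 2.405 rad — the first zero of J₀, standard dual-PEM
practice, so the retardance terms contribute nothing to the DC level —
and f₁ = 50, f₂ = 42 in arbitrary reciprocal time units, mirroring the
50/42 kHz optical heads of the physical instrument. Only the frequency
ratio matters: the common period is p/f₁ where f₁/f₂ = p/q in lowest
terms, and the simulation requires that ratio to be a small-denominator
rational (q ≤ 1000); truly incommensurate pairs have no usable common
period and are rejected.

### Two demodulation routes

1. **Numerical lock-in**: the detector series is sampled uniformly over an
   integer number of common periods (endpoint excluded, so discrete sums
   are exact Fourier projections) and multiplied against cos(2·2πf₁t),
   cos(2·2πf₂t) and sin(2πf₁t) references; in-phase amplitudes are twice
   the product means. A series shorter than 20 samples per cycle of the
   fastest relevant harmonic (2·max(f₁,f₂)) is rejected.
2. **Bessel series**: the intensity is a degree-≤1 polynomial in each of
   cos δ₁, sin δ₁, cos δ₂, sin δ₂, so its nine tensor-basis coefficients
   are recovered exactly from a 3×3 grid of static retardances; the
   Jacobi–Anger expansion (cos(A sin ωt) = J₀ + 2ΣJ₂ₖcos 2kωt,
   sin(A sin ωt) = 2ΣJ₂ₖ₊₁sin(2k+1)ωt, truncated at order 8) turns each
   basis function into a line spectrum whose products are collected by the
   trigonometric product identities.

The two routes are independent derivations and agree to better than 1e−6
relative in the tests (in practice to machine precision, since both are
exact up to Bessel truncation and sampling aliasing of order ≳ 16
harmonics, negligible at A ≈ 2.4).

At the default geometry the induced signal←Stokes map is near-diagonal:
S_DC = I/2, S_QU1 ∝ Q, S_QU2 ∝ U, S_v ∝ −V. Deviations from α = 45°
populate the (k4 k5; k6 k7) block, which the K pattern accommodates.

## Calibration

Given known generator states and measured signals, each Stokes row of K
depends on its own signal subset, so the default solver is row-wise linear
least squares — exact, with per-row condition numbers reported.
A nonlinear option refines the generator ellipse parameters (ellipticity,
azimuth per state) jointly with k₁…k₈, absorbing generator imperfections;
it is seeded by the linear solution. Six Poincaré-axis states (H, V, ±45°,
RCP, LCP) are the default generator set. Identifiability is diagnosed
explicitly: a state set that never excites V, for example, fails naming k₈.

The sparsity validation fits an *unconstrained* 4×4 from ≥ 16 states and
reports the worst leakage into the structural zero positions relative to
the largest element; the dual-PEM forward model leaves those positions
empty to machine precision.

## Sample model and inversion

The uniaxial sample matrix is applied to Ip-normalised Stokes vectors.
The depolarisation factor σ = P⁻¹ scales the intensity row exactly as the
model states it, so (q′, u′, v′) keep unit norm and σ shows up only in the
degree of polarisation: P′ = 1/σ for fully polarised input, hence
D_p = √(1 − σ⁻²). Estimated σ is clipped below at 1 (noise can push the
raw ratio marginally under unity).

Retardation from circular illumination is δ_s = arccos(clamp(v′)), which
confines δ_s to its principal range [0, π]: an arccos cannot distinguish
δ from 2π−δ, and thin (5 µm) histology sections sit far below π.
Clamping events are counted and reported. The optic axis
γ = ½ atan2(−q′, u′) is reduced to [0, π) and masked where
|(q′, u′)| < 1e−6 · max‖(q′, u′)‖ (sin δ_s ≈ 0 leaves it undefined).

The joint inversion solves the three propagation equations per pixel for
(δ_s, γ) by Levenberg–Marquardt, seeded by the circular-approximation
estimates. The sample matrix satisfies M(−δ, γ) = M(δ, γ + π/2), so the
solver roams an unconstrained smooth landscape and the branch is folded
back afterwards. Pixels that fail to converge (not observed in testing)
retain their seed values and are counted. The per-pixel loop is intended
for profile sweeps and modest fields, not megapixel maps — circular-mode
inversion is fully vectorised and is the default.

With the source's 41° ellipticity, the direct estimator's bias at
δ_s = 1 rad peaks at ≈ 0.14 rad near γ = π/4 + kπ/2, where the residual
linear component projects fully onto v′; the error envelope recurs every
π/2. The joint inversion is exact there, and the error-sweep tool reports
the simulation's own profile rather than asserting any instrument-specific
percentage, which would fold in calibration effects a simulation cannot
reproduce.

Background correction subtracts a baseline estimated either from a
user-supplied no-tissue region (default, mean) or as the modal value
(median within the fullest of 256 histogram bins). Negative corrected
values are retained deliberately: they mark regions whose optic axis is
rotated 90° relative to the baseline.

## Phantoms

Phantom geometry is procedural, not image-realistic — concentric annuli
with tangential axis for placental villi, oriented Gaussian bands with
small orientation dispersion for dermis, a smoothed random lesion mask
with a spatially correlated chaotic axis field for keloid — which is
sufficient to exercise every estimator but does not emulate histological
texture, stain chemistry or out-of-plane fibre tilt. Magnitudes default
to the tissue values the technique reports, so simulated experiments read
against familiar numbers: substrate baseline retardation 0.11 rad;
structure peaks 0.04 / 1.00 / 1.40 rad *above* baseline for
placenta / dermis / keloid (profiles are normalised so the peak is exact);
substrate D_p 0.44 (mid-range of the reported 0.40–0.48 band), tissue
0.37, keloid lesion maximum 0.96. All are overridable, and identical
seeds give bit-identical phantoms.

The noise model is an implementer's stand-in (no camera noise model is
published for the instrument): Gaussian read noise added to the four
demodulated planes, optionally Poisson resampling of the DC plane with a
matching √(S_DC/scale) shot-noise floor on the harmonic planes — an
idealised transfer of photon statistics through the lock-in.
`tune_read_noise` finds the read-noise level producing a chosen
retardation noise floor (default 0.005 rad) by a seeded pilot render on a
flat substrate-baseline phantom and linear rescaling (the δ-noise/
signal-noise map is linear away from δ = 0; a second pass corrects
residual curvature). What passing phantom tests shows is that the
*estimators* are correct and noise-calibrated; it says nothing about
stain-dependent contrast or specimen variability in real acquisitions.

## ROI statistics

ROIs are squares specified by centre and side (µm converted through the
pixel size with round-to-nearest, so the canonical 48.6 µm side at
0.617 px/µm gives a 30 px = 900-pixel ROI; the module takes side and
pixel size explicitly rather than guessing a magnification). Masked
pixels are excluded and counted. Summaries use the n−1 standard
deviation.

The two-group comparison is gated: both groups passing Shapiro–Wilk at
α = 0.05 selects the two-tailed unpaired t-test, otherwise the two-sided
Mann–Whitney U — the conventional reading of "t-test, or Mann–Whitney
where appropriate". Welch's t is the default (equal variances are not
guaranteed between lesion and substrate ROIs); a pooled option exists.
The U test uses the exact null distribution for tie-free groups of ≤ 8,
the tie-corrected normal approximation otherwise. Zero-variance groups
are a documented special case (p = 1 if equal, 0 if not) since no
distributional test applies. Raw p-values are reported with significance
at p ≤ 0.05; Holm adjustment is available but off by default. The gated
procedure's empirical size is ≈ 0.05 under both Normal and exponential
nulls (checked at 2000 replicates).

## Numerical and design choices

- Ip-normalisation masks pixels with I_p ≤ 1e−12·max|I| (masked arrays,
  never silent NaN), keeping ROI statistics well-defined downstream.
- P > 1 from noise is clamped to 1 before D_p and counted.
- The azimuth uses the two-argument arctangent (range (−π/2, π/2]); the
  single-argument U/Q form is quadrant-ambiguous.
- Angles are radians internally, degrees at every file/CLI boundary.
- Interchange is 32-bit float multi-page TIFF (page orders documented in
  `stokespol.io`), metadata as JSON in the description tag, masked pixels
  as NaN; all writes are atomic (temp file + rename).
- Problem sizes: the full-scale end-to-end checks run 512² phantoms
  (circular-mode, fully vectorised); the joint per-pixel inversion is
  exercised on orientation sweeps and small fields.

## Known limitations

- Single uniaxial layer with in-plane axis; no biaxial samples, layer
  stacking, or out-of-plane tilt, and Stokes (not full Mueller) imaging.
- δ_s principal-value ambiguity above π; irrelevant for thin sections.
- Ideal PEM waveforms and a linear detector; no wavelength dispersion of
  retardance, no frame-rate or synchronisation modelling.
- The nonlinear calibration refinement assumes fully polarised generator
  states.
- Phantoms validate algorithms, not biology: no claim about specific
  tissue contrasts transfers from simulation to specimens.
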