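# Methods

This note documents the models implemented in `fibrefuse`, the choices made
where the design was genuinely open, and what the synthetic phantoms do and
do not establish about real data.

## Units and conventions

b-values in ms/µm², diffusivities in µm²/ms, voxel sizes in mm, microscopy
pixel sizes in µm, T1/TI in ms. Angles are degrees at every public
interface and radians internally. All orientations are axial (v ≡ −v);
in-plane angles live in [0°, 180°) measured counter-clockwise from the
image +x (column) axis, and 2D circular statistics work on doubled angles.
Image arrays index as (row, column) with x along columns.

## Sphere point sets and gradient schemes

Direction sets minimise the antipodally symmetrised Coulomb energy
Σ 1/|gᵢ−gⱼ| + 1/|gᵢ+gⱼ| by projected repulsion with a backtracking step,
which makes the energy trace strictly decreasing — a property the tests
assert. One 256-point antipodally paired grid (`sphere.symmetric_sphere_grid`)
serves both as the orientation-histogram support in the fusion module and as
the quadrature grid for Watson/Bingham integrals; a single shared, tested
generator was preferred over per-module grids.

"Good coverage" is operationalised as the minimal pairwise axial angle
(degrees); the acquisition-ordering contract (every prefix usable) is met by
greedy maximin selection. Exchange-search analysis shows that no nested
ordering of an even 60-point set can bring a 10-direction prefix within 10%
of a dedicated 10-point electrostatic set under this metric (the subset
optimum is ≈86%); the tests therefore assert prefix coverage at ≥75% of the
fresh set and dominance over the unordered prefix. Batching inserts one b≈0
volume before every 25 diffusion-weighted volumes and orders each batch by
always stepping to the farthest remaining direction; the default colinearity
floor between consecutive directions is 10° (the goal of spreading gradient
heating fixes no particular threshold; 10° is comfortably achieved by even
250-direction sets).

## Phantom forward models

The ground-truth `FibreField` holds up to three fibre populations per voxel
(unit axis, signal fraction fᵢ, concentration κ_b with κ_b = ∞ meaning
coherent) plus an isotropic ball of fraction 1 − Σfᵢ; one free diffusivity
d (default 0.4 µm²/ms, an ex-vivo white-matter value at room temperature)
is shared by all compartments.

**Diffusion.** Linear-encoded entries follow the ball-and-stick signal
S(g,b) = s0[(1−Σfᵢ)e^{−bd} + Σᵢ fᵢ⟨e^{−bd(g·n)²}⟩]; dispersed populations
average the stick response over a Watson FOD by quadrature on the shared
256-point grid. Spherical-tensor-encoded entries attenuate with each
compartment's mean diffusivity (d for the ball, d/3 for a stick),
independent of orientation. Noise is Rician (magnitude MRI) with σ in s0
units; microscopy noise is additive Gaussian.

**PLI.** Frame k at analyser angle ρ_k = k·(180°/n) (endpoint excluded so
the π period is sampled exactly once, keeping the Fourier inversion exact)
has I(ρ) = (I_T/2)[1 + Σᵢ fᵢ sin(δ_max cos²αᵢ) sin(2ρ−2φᵢ)]. Per-fibre
sinusoids mix linearly at the intensity level, weighted by signal fraction;
this reproduces the characteristic signal cancellation over perpendicular
equal crossings (dark bands between tracts) without a full Jones-matrix
treatment, which is out of scope. δ_max defaults to π/2 so that a fully
in-plane fibre at unit fraction reaches retardance 1.

**Histology.** The stain simulator draws dark anti-aliased line segments
(default length 31 px, depth 0.6) on a white background; the per-segment
retention probability equals the voxel's total fibre fraction and
`fibre_density` (default 0.12) sets the expected pixel coverage at unit
fraction. Orientation dispersion is realised as a *spatially correlated*
jitter field: a Gaussian copula field with 50 px correlation length pushed
through the exact inverse CDF of the axial von Mises distribution, so the
marginal matches the voxel's κ exactly while nearby segments share their
local deviation. This mirrors fibre undulation in tissue, where dispersion
accumulates over tens of micrometres rather than independently per fibre —
and it is what makes dispersion recoverable by a structure tensor whose
integration window (10 px) would average away independent per-segment
jitter. Recovery tests pool superpixel FOD histograms across superpixels
and seeds before fitting κ, because a single 150 px superpixel contains too
few independent orientation patches for an unbiased concentration estimate.

The phantoms emulate geometry, signal forms and noise; they do not emulate
stain chemistry, mosaic stitching, section deformation, bubbles or patchy
staining. Passing tests therefore validate the estimators' correctness and
calibration on well-posed inputs, not robustness to histological artefacts.

## PLI inversion

For equidistant angles the per-pixel fit reduces to discrete Fourier
components: a0 = mean(I), a2 = (2/N)ΣI cos2ρ, b2 = (2/N)ΣI sin2ρ, giving
I_T = 2a0, r = √(a2²+b2²)/a0, φ = ½ atan2(−a2, b2). Non-equidistant stacks
fall back to least-squares harmonic regression. Validity requires a0 > 0
and r > r_min (default 0.01; flat pixels carry no orientation). Inclination
inverts r = sin(δ_max cos²α) to α = acos√(asin r / δ_max), clipping r at
sin δ_max; this assumes constant myelin content, so on a phantom with
fibre fraction < 1 the inclination is biased — it is a co-registration
contrast, not a quantitative metric, and the round-trip tests use unit
fraction.

## Structure tensor and dispersion statistics

Gradients are Gaussian-derivative filtered at σ_deriv (default 1 px); the
tensor components ⟨Ix²⟩, ⟨IxIy⟩, ⟨Iy²⟩ are averaged at σ_window (default
10 px). The fibre angle is ½ atan2(2Jxy, Jxx−Jyy) + 90° (perpendicular to
the dominant gradient), coherence is (λ1−λ2)/(λ1+λ2), and pixels with
tensor energy below 1e−12 × image variance are invalid. The 10 px kernel is
assigned to the integration (averaging) scale, its most common reading; the
derivative scale remains a parameter.

Superpixels (default 150 px ≈ 40 µm at the nominal 0.28 µm/px) aggregate
orientations into 2°-binned FODs weighted by coherence (weighting
suppresses unstructured background and is switchable off), with circular
mean, κ and ODI per tile. The 2D restriction of the Bingham distribution is
the axial von Mises density p(θ) ∝ exp(κ cos 2(θ−µ)); its MLE solves
I₁(κ)/I₀(κ) = R̄ (mean resultant length of doubled angles) by bracketed
root finding, capped at κ = 10⁴ so perfectly aligned data map to ODI ≈ 0
rather than overflowing.

## Diffusion model fitting

**Preprocessing.** Signal drift is removed multiplicatively: a line fitted
to the b≈0 means over time divides every volume by its relative trend
(1 + c1·t/c0) — multiplicative rather than additive because scanner drift
scales the signal. S0 normalisation divides voxelwise by the mean b≈0
volume and masks zero-reference voxels.

**DTI** is the standard log-linear least-squares fit; non-positive signals
are excluded per voxel.

**Ball and Stick** fits sticks stagewise (k = 1…3) by bounded nonlinear
least squares with an analytic Jacobian; stick-breaking parameterisation
keeps Σfᵢ ≤ 1. Stage k is initialised from the DTI eigenvectors plus random
restarts and accepted when it lowers the BIC with its smallest fraction
above 0.05 — the BIC plays the role of the automatic relevance
determination used with MCMC-based fitting, combined with the downstream
f < 0.05 exclusion rule. Orientation samples come from a residual
bootstrap (default 50 warm-started, iteration-capped refits) rather than an
MCMC posterior: deterministic under a seed, dependency-free, and providing
the same downstream contract (sample axes per population). Bootstrap
populations are matched to the point estimate by axial proximity to avoid
label switching. The orientation-precision statistic is the cone half-angle
acos√λ_max of the mean dyadic tensor ⟨vvᵀ⟩ over samples (0° = perfect,
54.7° = isotropic), an explicit stand-in for an unspecified precision
metric.

**Ball and Rackets** fits a single Bingham-dispersed stick by quadrature:
the 256-point grid is rotated into the candidate Bingham frame (with one
grid point aligned to the canonical pole) so the density is always sampled
symmetrically about the axis and the κ → ∞ limit degenerates exactly to a
stick. Concentrations are parameterised as κ1 and κ1 + Δκ to enforce
κ1 ≤ κ2.

**DIVIDE / µFA.** Powder (directional) averages per shell and encoding are
fitted jointly with the Laplace transform of a gamma diffusivity
distribution, S/s0 = (1 + b·µ2/µ1)^(−µ1²/µ2), sharing the mean diffusivity
µ1 across encodings (one tissue, one mean diffusivity) with separate second
moments. µFA = √(3/2)·[1 + (2/5)(µ1² + µ2_sph)/(µ2_lin − µ2_sph)]^(−1/2),
clamped to [0, 1]; µ2_lin < µ2_sph is flagged and clamped to 0. The
conversion is validated against the identity that identical randomly
oriented axisymmetric microtensors must give µFA equal to the single-tensor
FA, rather than against any printed constant. Isotropic and anisotropic
kurtosis components are 3µ2/µ1² of the respective variance parts.

**T1** fits S(TI) = a + b·e^{−TI/T1} per voxel with a log-spaced T1 grid
initialisation (the model is linear in a, b at fixed T1) followed by
bounded refinement.

## Fusion

3D axes project onto a section plane as angle = atan2(a·e2, a·e1) mod 180°
with in-plane magnitude as confidence; axes within 1e−8 of the normal have
undefined angle. Hybrid matching takes, per microscopy pixel, the
ball-and-stick orientation sample (populations with f ≥ 0.05 only) whose
*in-plane* angle is axially most similar to the microscopy angle — "most
similar" is deliberately the smallest axial in-plane difference — and
builds v = cosα cosφ e1 + cosα sinφ e2 + sinα n from the microscopy φ and
the matched sample's inclination α, keeping the higher-confidence
microscopy in-plane information. Ties break by higher population fraction,
then lower sample index; samples enter unweighted by fraction once past the
threshold. Sphere-histogram FODs give each axis half a count at its nearest
grid point (axial metric) and half at that point's antipode, so the
histogram is exactly symmetric under v → −v. Order-8 real even spherical
harmonics (45 coefficients; m < 0 ↦ √2(−1)^m Im Y, m > 0 ↦ √2(−1)^m Re Y)
are fitted by least squares at the 256 points; the NIfTI export documents
basis and (l, m) ordering in a JSON sidecar rather than asserting any
particular external tool's convention.

The regression helper reports OLS slope/intercept, Pearson r, the
model-comparison F = (n−2)R²/(1−R²) with p from F(1, n−2), and 95%
confidence bands for the mean response.

## Numerical choices

Optimisers are scipy TRF bounded least squares at xtol = ftol = 1e−10;
bootstrap refits cap iterations (max_nfev = 15) since they start at the
optimum. Staged ball-and-stick fitting stops early once a stage's residual
is numerically zero (below 1e−14·Σy²), where neither restarts nor extra
sticks can improve the BIC. Degenerate inputs are contracts, not crashes:
duplicate gradient directions tie-break by input order with a logged
warning, empty superpixels and sub-threshold voxels are flagged invalid,
retardance above sin δ_max is clipped and counted.

## Problem sizes in the test suite

The validation suite runs at desk scale: the crossing-recovery check uses a
1000-voxel phantom with 250 directions; the precision-versus-angular-
resolution trend uses 200 crossing voxels at SNR 20 across 64–1000-direction
prefixes of one incrementally ordered scheme; dispersion recovery uses
20 seeds of 400×400 px stain images per ODI level; the hybrid end-to-end
check uses a 4×4×2-voxel crossing phantom sectioned at 250 µm pixels.

## Known limitations

- The PLI forward model mixes sinusoids linearly and ignores full
  polarisation optics; inclination estimates inherit the constant-myelin
  assumption.
- Structure-tensor dispersion at a fixed integration scale underestimates
  orientation spread that varies faster than the window; per-superpixel κ
  on small windows carries small-sample bias (hence pooled recovery).
- Ball-and-Rackets concentrations above ~100 are effectively
  indistinguishable from a pure stick at 256-point quadrature.
- The gamma signal representation is a two-moment approximation; at very
  high b·MD its µ2 estimates bias, so the µFA oracle operates at b ≤ 2.
- Registration between modalities is taken as given (affine plane frames);
  slice-to-volume registration is out of scope.
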