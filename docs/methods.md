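# Methods

## Signal model and units

All generators produce magnitude MR signals. Diffusivities D are carried in
μm²/ms (≡ 10⁻³ mm²/s) and b-values in s/mm², so a monoexponential component
attenuates as exp(−b·D/1000). This unit choice is the only one numerically
consistent with the values the package defaults to (≈0.7 μm²/ms for brain
tissue diffusion, 2.9–3.1 for free water); some of the literature prints
"μm²/s" for the same numbers, which we read as μm²/ms.

Three generators are provided: multi-exponential mixtures
S0·Σ_p a_p·exp(−b·D_p/1000) with 1–3 components (fractions sum to 1,
diffusivities distinct), the bi-exponential IVIM model
S0·[(1−f)·exp(−bD/1000) + f·exp(−bD*/1000)] with D ≤ D*, and a
cumulant-expansion kurtosis signal S0·exp(−bD/1000 + (bD/1000)²·K/6) used
only to place non-monoexponential decays in phasor plots. The kurtosis form
warns when its quadratic term makes the signal rise inside the sampled
b-range (b·D·K/1000 > 3 at b_max), where the expansion is unreliable.

## Rician noise

Noise is added to the real and imaginary channels of the complex signal
(std σ each) and the magnitude taken, giving Rician-distributed data with
the characteristic noise floor σ·√(π/2) at zero signal. σ is defined from
the noise-free b = 0 signal of the curve being corrupted: σ = S(0)/SNR, so
"SNR 30" means mean-over-std of 30 in the b = 0 image at phantom scale.
SNR = ∞ returns the input unchanged.

Seed policy: every study takes one master seed; per-condition and per-repeat
streams are spawned from a counter-based `numpy.random.SeedSequence`, so
repeats are independent, order-insensitive, and any study reruns
bit-identically from its configuration.

## Phasor transform and reference curve

The transform is the index-based positive-exponent DFT at harmonic n = 1,
normalized by the signal sum: P = Σ_u S_u·e^{2πj·n·u/U} / Σ_u S_u. Sample
positions enter only through the signal values (sort by b, then transform);
this is deliberate — irregular b-spacing is absorbed entirely into the
numerically computed monoexponential reference curve, never into the data
transform, so noisy data need no resampling. With this sign convention
decaying signals map to the upper half-plane: D → 0 approaches (0, 0),
D → ∞ approaches (1, 0). For equidistant schemes the transform of a sampled
exponential has the closed form (e^{T/(Uτ)} − 1)/(e^{T/(Uτ)} − e^{2πj·n/U})
(τ = 1000/D, T = U·Δb), which the tests verify to 1e-12; the continuous-
sampling limit is the Lorentz point 1/(1 + jωτ) on the ideal semicircle.

The reference curve is evaluated on a log-spaced diffusivity grid, default
2000 points spanning [1e-3, 50] μm²/ms, and cached per scheme. Decay-rate
estimation finds the nearest grid point to a phasor coordinate and refines
it by bounded 1-D minimization of the Euclidean distance over the
neighbouring grid interval (xatol 1e-9), giving noise-free round-trip
accuracy better than 1e-4 relative across 0.05 ≤ D·b_max/1000 ≤ 10. A point
mapping to the end of the grid is returned at the boundary value.

## Unmixing

Three-component unmixing solves the barycentric system — real balance,
imaginary balance, Σα = 1 — in closed form (Cramer's rule) for the phasor
fractions α, then converts to signal fractions via a_p ∝ α_p/E_p with
E_p = Σ_u e^{−b_u·D_p/1000}, normalized so Σa = 1 by construction
(a₃ = 1 − a₁ − a₂). The two-component case sets α₃ = 0. Collinear (or
coincident) vertices are rejected as singular.

Linear unmixing solves the decay model directly: the U×P design
exp(−b_u·D_p/1000) against the signal normalized by its measured b = 0
value, by unconstrained ordinary least squares. It is exact for noise-free
input. No non-negativity constraint, no clipping, and no renormalization of
Σa: out-of-range fractions and Σa ≠ 1 under noise are diagnostic signal, and
the structural Σa = 1 of the phasor route vs. the free sum of the linear
route is an intentional asymmetry between the methods. Without a b = 0
sample the normalization would need S0 as a nuisance column; the phantom
studies always include b = 0, and the volume reader requires it in practice.

The error metric everywhere is estimate − truth; "bias" is the mean error
pooled over all fraction combinations and noise repeats (the median is
reported alongside, since either aggregation is defensible).

## IVIM fitters

**Nonlinear (nlls).** Bounded trust-region-reflective least squares on
(S0, f, D, D*) with analytic Jacobian. Initialization: S0 at the measured
b = 0 value (the three published companion inits are f = 0.5, D = 0.1,
D* = 15 μm²/ms); bounds D ≥ 0, D* ≥ 2.5 μm²/ms, 0 ≤ f ≤ 1 (the f bound is
removable via `constrain_f=False`). If the solver returns D > D* the roles
are exchanged and f ← 1 − f, with a `swapped` flag. Tolerances 1e-10,
max 400 evaluations.

**Segmented.** Stage 1: ordinary least squares on (b, ln S) strictly above
the 300 s/mm² threshold (with the 15-b-value clinical scheme that is
{400, 600, 800, 1000}); D = −slope·1000. Stage 2: f = (S(0) − e^intercept)/S(0).
Stage 3: the stage-1 monoexponential is subtracted from the full curve and a
log-linear fit on residuals exceeding 1e-12·S(0) gives D*. Nothing is
constrained: negative D (pathological tails) and negative D* (a well-known
noise failure mode of this estimator) propagate unclipped; fewer than two
positive residuals flags D* undefined.

**Phasor projection.** One free parameter, D*, optimized by bounded
trust-region least squares (init 15, bound ≥ 0). Per candidate: the D*
vertex and the measured signal's phasor point define a chord; its
intersections with the reference curve are located by sign changes of the
signed perpendicular distance along the discretized curve and refined by
bisection in D to ~1e-10; the intersection beyond the data point (as seen
from the D* vertex) and nearest to it is taken as the D vertex. Restricting
the intersection search to D ∈ [1e-3, D*] makes D ≤ D* structural. f follows
by two-component unmixing, and the candidate is scored against the
b=0-normalized signal with penalty λ·f·(1 − L/L0)² added while the data
point lies within L0 of the curve (L, the point's distance to the curve, is
fixed per voxel; λ = L0 = 0.05 by default; L0 is a dimensionless
phasor-space distance, roughly the distance a perfusion fraction of 0.05
displaces a point off the curve for clinical schemes). The penalty is
applied for positive f only — a term rewarding negative fractions would
invert its purpose. L is measured against the *sampled* reference curve,
not the ideal semicircle, because the sampled curve is the true
monoexponential locus under the scheme.

If no far-side intersection exists (the point lies above the curve, in
negative-kurtosis territory, or outside the representable triangle) the
candidate is evaluated as a monoexponential: f = 0, D the direct decay-rate
estimate capped at D*. This keeps the objective finite and continuous so the
outer optimizer can recover, and the final fit is flagged when it rests on
the fallback. Consequences worth knowing: under noise at very low true f,
roughly half the phasor points land above the curve and the fit returns
exactly f = 0 — a spike at zero in the f distribution — and the one-
parameter cost is flat in D* wherever the fallback is active.

The regularizer deliberately biases f toward zero for points within L0 of
the curve: with λ = 0.05 a noise-free f = 0.1 curve (D = 0.7, D* = 10)
refits at f ≈ 0.095. Exactness tests of the projection geometry therefore
run with λ = 0; the regularizer's shrinkage and its suppression of the
spurious high-f local optimum are asserted separately.

## Phantom studies

*Unmixing phantom:* components at 2.9/0.85/0.18 μm²/ms mixed on the 0.1-step
simplex grid (66 unique combinations), 21 equidistant b-values 0–2500 s/mm²,
S0 = 1, SNR levels {30, 50, 100, ∞}, 10 000 repeats per combination
(noise-free conditions collapse to one repeat). The displacement study
unmixes data generated with the true diffusivities using one diffusivity
scaled by 0.75–1.25 (step 0.05) at a time; the b-value-count study repeats
the noise analysis on equidistant schemes of 3–99 b-values (spacing rule:
equidistant including both endpoints, a choice this package fixes since
nothing else is specified) at SNR 30.

*IVIM sweep:* truth D = 0.7, D* = 10 μm²/ms, 101 fractions f ∈ [0, 1], SNR
30, 5000 repeats per fraction, 15 b-values {0, 10, 20, 30, 40, 60, 100, 150,
200, 250, 300, 400, 600, 800, 1000} s/mm²; a 6-b-value subset
{0, 30, 100, 250, 600, 1000} is supported for reduced-sampling comparisons.
Failed fits are excluded from quantiles but counted. Error quantiles use
linear interpolation between order statistics (differences between quantile
definitions are far below the Monte-Carlo noise at these sample sizes);
kernel densities of parameter estimates use a Gaussian kernel with
Silverman's bandwidth, renormalized to unit area on the evaluation grid.

The acceptance script runs the studies at full published size (66 × 10 000
unmixing; 5000 IVIM repeats at f = 0.05); the test suite uses 200–2000
repeats per condition to keep its runtime modest, at correspondingly widened
Monte-Carlo tolerances.

What the phantom does *not* emulate: partial voluming and physiological
variation within tissue masks, more than three tissue components
(free water is absent from the IVIM sweep), gradient-direction effects
(in-vivo data are geometrically averaged over directions before analysis,
which the reader supports), spatially correlated noise, and motion/eddy/EPI
distortion. Passing the phantom studies therefore demonstrates correctness
of the estimators under the stated noise model, not in-vivo parameter-map
quality.

## Visualization and gating

Phasor histograms use origin-anchored square bins of width 1/300 with
half-open binning [k·w, (k+1)·w) on both axes (points on an edge
deterministically land in the higher bin) and render as log(1 + count) with
the ideal semicircle and the scheme's sampled curve overlaid. The bin-area
unit is treated as dimensionless phasor area; the default rendering extent
is whatever covers the data. Polygon gates are simple polygons in (g, s);
containment uses an even-odd test with boundary points counted inside
(delegated to shapely's `covers`), self-intersecting polygons are rejected,
and gates serialize as CSV vertex lists so one subject's gate can be
reapplied to another's phasor space.

## Known limitations

- The nonlinear IVIM fitter's susceptibility to the high-f/low-D local
  minimum depends on the optimizer implementation; bounded trust-region
  solvers from different libraries visit that basin at very different rates,
  so spread statistics of nlls f estimates are not portable across
  implementations (the segmented and phasor fitters are essentially
  implementation-independent).
- Harmonics above n = 1 are accepted by the transform but the unmixing and
  IVIM geometry are only validated at n = 1 (the reference curve can
  self-intersect at higher harmonics).
- The phasor IVIM fit assumes a b = 0 sample for normalization and anchor.
- No Bayesian or spatially regularized IVIM variants, no T2/TE correction of
  f, no kurtosis-IVIM hybrid fitting, no estimation of the fixed unmixing
  diffusivities themselves.
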