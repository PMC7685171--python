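# dwiphasor

Phasor-space analysis of diffusion-weighted MRI decay signals: multi-component
unmixing with fixed diffusivities, intravoxel incoherent motion (IVIM) model
fitting, and the Monte-Carlo digital-phantom studies that benchmark them.

## The idea

A diffusion-weighted acquisition measures, per voxel, a decay curve S(b) over
a set of b-values (s/mm²). The **phasor transform** maps that curve to a
single normalized Fourier coefficient

    P = Σ_u S_u · exp(2πj·n·u/U) / Σ_u S_u ,

plotted as a point (g, s) = (Re P, Im P) in the complex plane (harmonic
n = 1, U samples). Under continuous sampling every monoexponential
exp(−b·D) lands on the semicircle of radius ½ centred at (½, 0); under
discrete (and especially non-equidistant) sampling the monoexponential locus
deforms into a scheme-specific curve that this package computes numerically.
Because the transform is linear in the signal, a P-component mixture
Σ_p a_p·exp(−b·D_p) lands inside the polygon spanned by its pure-component
vertices, with barycentric weights α_p = a_p·E_p / Σ a_p'·E_p', where
E_p = Σ_u exp(−b_u·D_p) is the component sum over the scheme. This turns
decay-curve decomposition into plane geometry:

- **Unmixing** (2–3 components, fixed D_p): invert the barycentric
  coordinates of the voxel's phasor point and convert α → a through the E_p.
  A linear least-squares solve of the decay model is provided as the
  benchmark; both return out-of-range fractions unclipped.
- **IVIM fitting**: S(b) = S0·[(1−f)·e^{−bD} + f·e^{−bD*}] is bi-exponential,
  so its phasor point lies on the chord between the D and D* vertices. With
  D* as the only free parameter, D follows by projecting the chord back onto
  the monoexponential curve and f by two-component unmixing — a
  one-parameter fit, regularized by λ·f·(1 − L/L0)² for points within
  distance L0 of the curve (near-monoexponential voxels should get f ≈ 0).
  Classical four-parameter bounded nonlinear least squares and two-stage
  segmented fitting (D from b > 300 s/mm², f from the b = 0 gap, D* from the
  residual) are included for comparison.
- **Visualization/gating**: 2D phasor histograms (1/300-wide bins,
  log color scale) and polygon gates that select voxel populations by decay
  signature, with NIfTI + FSL `.bval` I/O.

Diffusivities are carried in μm²/ms (0.7 ≈ brain tissue, ~3 ≈ free water);
b-values in s/mm², so exponents are −b·D/1000.

## Worked example

```python
import numpy as np
from dwiphasor import (ComponentBasis, IVIMParams, MixtureSpec, NoiseSpec,
                       PHANTOM_DIFFUSIVITIES, SamplingScheme, IVIM_BVALUES,
                       add_rician_noise, fit_phasor, fit_segmented, fit_nlls,
                       ivim_signal, make_equidistant_scheme, multiexp_signal,
                       phasor_transform, phasor_unmix3)

# three-component phantom voxel (40/40/20 mix), SNR 30, 21 b-values 0-2500
scheme = make_equidistant_scheme(21, 2500)
mix = MixtureSpec(PHANTOM_DIFFUSIVITIES, (0.4, 0.4, 0.2))
noisy = add_rician_noise(multiexp_signal(scheme, mix), NoiseSpec(snr=30, seed=42))
basis = ComponentBasis.for_scheme(scheme, PHANTOM_DIFFUSIVITIES)
point = phasor_transform(noisy, scheme)
est = phasor_unmix3(point, basis)
print(f"phasor point: g={point.g:.4f}, s={point.s:.4f}")
print("fractions:", np.round(est.a, 3))

# IVIM fitting of one noisy voxel (true f=0.1, D=0.7, D*=10)
ivim = SamplingScheme(IVIM_BVALUES)
truth = IVIMParams(S0=1.0, f=0.1, D=0.7, D_star=10.0)
y = add_rician_noise(ivim_signal(ivim, truth), NoiseSpec(snr=30, seed=7))
for fit in (fit_nlls(y, ivim), fit_segmented(y, ivim), fit_phasor(y, ivim)):
    print(f"{fit.method:10s} f={fit.f:+.3f}  D={fit.D:.3f}  D*={fit.D_star:7.3f}")
```

prints

```
phasor point: g=0.1713, s=0.2087
fractions: [0.411 0.354 0.236]
nlls       f=+0.069  D=0.777  D*= 38.718
segmented  f=+0.057  D=0.779  D*=  1.296
phasor     f=+0.069  D=0.761  D*= 25.598
```

The unmixed fractions sit within a few percent of the 0.40/0.40/0.20 truth
at SNR 30. All three IVIM fitters recover D well; f is noisier; D* at low f
is poorly determined for every method — the expected behavior at this noise
level.

A command-line interface mirrors the library for shell use:
`dwiphasor unmix`, `dwiphasor ivim-fit`, `dwiphasor experiment`,
`dwiphasor plot-phasor`, `dwiphasor gate` (see `--help` on each).

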