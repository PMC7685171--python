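"""Phasor transform of decay curves and the sampling-deformed reference curve.

The phasor transform maps a decay curve to a single complex Fourier
coefficient normalized by the signal sum,

    S = Σ_u s_u · exp(+2πj · n · u / U) / Σ_u s_u ,

plotted as coordinates (g, s) = (Re S, Im S).  Under continuous sampling every
monoexponential lands on the semicircle of radius 1/2 centred at (1/2, 0)
(the Lorentz locus); under discrete — and especially non-equidistant —
sampling the monoexponential locus deforms into a scheme-specific curve that
has to be computed numerically.  The transform itself is *index-based*: sample
positions enter only through the signal values, so irregular b-spacing is
absorbed entirely into the reference curve, never into the data transform.

Sign convention: positive-exponent DFT at harmonic n=1, which places decaying
signals in the upper half-plane (fast decays near (1,0), slow decays near the
origin).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize_scalar

from .signals import DecayCurve, MixtureSpec, SamplingScheme

__all__ = [
    "PhasorPoint",
    "ReferenceCurve",
    "PhasorWeights",
    "phasor_transform",
    "transform_many",
    "lorentz_point",
    "reference_curve",
    "estimate_decay_rate",
    "phasor_weights",
    "component_sum",
]


@dataclass(frozen=True)
class PhasorPoint:
    """Coordinates (g, s) of a transformed curve; ``valid`` is False for
    degenerate (zero-sum) inputs."""

    g: float
    s: float
    valid: bool = True

    @property
    def complex(self) -> complex:
        return complex(self.g, self.s)

    def as_array(self) -> np.ndarray:
        return np.array([self.g, self.s])


@dataclass(frozen=True)
class PhasorWeights:
    """Phasor-space fractions α_p of a mixture (sum to 1; entries may lie
    outside [0, 1])."""

    alpha: tuple[float, ...]


def _dft_kernel(n_samples: int, harmonic: int) -> np.ndarray:
    u = np.arange(n_samples)
    return np.exp(2j * np.pi * harmonic * u / n_samples)


def phasor_transform(curve: DecayCurve | np.ndarray, scheme: SamplingScheme) -> PhasorPoint:
    """Transform one decay curve into phasor space at the scheme's harmonic."""
    values = curve.values if isinstance(curve, DecayCurve) else np.asarray(curve, float)
    if values.shape[-1] != scheme.n_b:
        raise ValueError("curve length does not match scheme")
    total = values.sum()
    if total == 0:
        return PhasorPoint(np.nan, np.nan, valid=False)
    coeff = (values @ _dft_kernel(scheme.n_b, scheme.harmonic)) / total
    return PhasorPoint(float(coeff.real), float(coeff.imag))


def transform_many(values: np.ndarray, scheme: SamplingScheme) -> np.ndarray:
    """Vectorized phasor transform of an (..., U) stack of curves.

    Returns a complex array of shape (...); zero-sum rows come out NaN.
    """
    values = np.asarray(values, dtype=float)
    total = values.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (values @ _dft_kernel(scheme.n_b, scheme.harmonic)) / total
    return np.where(total == 0, np.nan + 0j, out)


def lorentz_point(d: float, omega_tau: float | None = None) -> PhasorPoint:
    """Continuous-sampling ideal position 1/(1+jωτ) of a monoexponential.

    ``omega_tau`` is the dimensionless product ωτ; when omitted it is taken
    as ``1/d`` with ω=1.  Used only for the ideal-semicircle overlay.
    """
    wt = (1.0 / d) if omega_tau is None else omega_tau
    denom = 1.0 + wt * wt
    return PhasorPoint(1.0 / denom, wt / denom)


def equidistant_closed_form(
    tau: float, n_samples: int, total_duration: float, harmonic: int = 1
) -> complex:
    """Closed-form phasor of exp(−t/τ) sampled at t = u·T/U, u = 0..U−1:
    (e^{T/(Uτ)} − 1) / (e^{T/(Uτ)} − e^{2πj·n/U}).

    Serves as an analytic cross-check of the index-based transform on
    equidistant schemes.
    """
    x = np.exp(total_duration / (n_samples * tau))
    return (x - 1.0) / (x - np.exp(2j * np.pi * harmonic / n_samples))


@dataclass(frozen=True)
class ReferenceCurve:
    """Sampled monoexponential locus in phasor space for one scheme.

    ``d_grid`` is a strictly increasing diffusivity grid (μm²/ms) and
    ``points`` the complex phasor coordinates of the corresponding noise-free
    monoexponential curves.
    """

    d_grid: np.ndarray
    points: np.ndarray
    scheme: SamplingScheme

    def point_at(self, d: float) -> PhasorPoint:
        """Exact (non-interpolated) phasor position of diffusivity ``d``."""
        z = _single_exp_phasor(self.scheme, float(d))
        return PhasorPoint(z.real, z.imag)


def _single_exp_phasor(scheme: SamplingScheme, d: float | np.ndarray) -> complex | np.ndarray:
    b = scheme.b_array
    decay = np.exp(-np.multiply.outer(np.asarray(d, float), b) / 1000.0)
    out = (decay @ _dft_kernel(scheme.n_b, scheme.harmonic)) / decay.sum(axis=-1)
    return out if np.ndim(d) else complex(out)


@lru_cache(maxsize=32)
def _cached_reference(scheme: SamplingScheme, d_min: float, d_max: float, n_grid: int):
    d_grid = np.geomspace(d_min, d_max, n_grid)
    points = _single_exp_phasor(scheme, d_grid)
    return d_grid, points


def reference_curve(
    scheme: SamplingScheme,
    d_min: float = 1e-3,
    d_max: float = 50.0,
    n_grid: int = 2000,
) -> ReferenceCurve:
    """Numerically computed monoexponential locus on a log-spaced D grid.

    Cached per (scheme, grid) so repeated fits share one curve.
    """
    if not 0 < d_min < d_max:
        raise ValueError("need 0 < d_min < d_max")
    if n_grid < 100:
        raise ValueError("n_grid must be at least 100")
    d_grid, points = _cached_reference(scheme, float(d_min), float(d_max), int(n_grid))
    return ReferenceCurve(d_grid, points, scheme)


def estimate_decay_rate(
    point: PhasorPoint, ref: ReferenceCurve, return_distance: bool = False
):
    """Diffusivity whose reference-curve position is nearest the given point.

    A coarse pass over the grid picks the best bin; a bounded 1-D golden/
    parabolic search over the neighbouring grid interval refines the estimate
    to ~1e-6 relative.  A point mapping to the end of the grid is returned at
    the boundary value (callers may treat that as out of range).
    """
    z = point.complex
    dist = np.abs(ref.points - z)
    i = int(np.argmin(dist))
    lo = ref.d_grid[max(i - 1, 0)]
    hi = ref.d_grid[min(i + 1, len(ref.d_grid) - 1)]
    if lo == hi:
        d_best = float(lo)
    else:
        res = minimize_scalar(
            lambda d: abs(_single_exp_phasor(ref.scheme, d) - z),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-9},
        )
        d_best = float(res.x)
        if abs(_single_exp_phasor(ref.scheme, d_best) - z) > dist[i]:
            d_best = float(ref.d_grid[i])
    if return_distance:
        return d_best, float(abs(_single_exp_phasor(ref.scheme, d_best) - z))
    return d_best


def component_sum(scheme: SamplingScheme, d: float) -> float:
    """Σ_u exp(−b_u·d/1000): the per-component normalization that links
    signal fractions to phasor fractions under discrete sampling."""
    if d <= 0:
        raise ValueError("d must be positive")
    return float(np.exp(-scheme.b_array * d / 1000.0).sum())


def phasor_weights(mixture: MixtureSpec, scheme: SamplingScheme) -> PhasorWeights:
    """Phasor-space weights α_p = a_p·E_p / Σ_p' a_p'·E_p' of a mixture.

    With E_p the per-component sum over the scheme; the mixture's transform
    equals the α-weighted combination of the pure-component transforms.
    """
    a = np.asarray(mixture.fractions)
    e = np.array([component_sum(scheme, d) for d in mixture.diffusivities])
    w = a * e
    return PhasorWeights(tuple((w / w.sum()).tolist()))
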