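"""Ground-truth diffusion decay signals and Rician noise.

Diffusivities are carried in μm²/ms (equivalently 10⁻³ mm²/s) and b-values in
s/mm², so a monoexponential attenuation is ``exp(-b * D / 1000)``.  Brain-like
values on this scale are ~0.7 μm²/ms for tissue diffusion and ~3 μm²/ms for
free water.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SamplingScheme",
    "MixtureSpec",
    "IVIMParams",
    "KurtosisParams",
    "NoiseSpec",
    "make_equidistant_scheme",
    "multiexp_signal",
    "ivim_signal",
    "kurtosis_signal",
    "add_rician_noise",
    "read_bval",
    "write_bval",
]

#: Diffusivities (μm²/ms) of the three-component digital phantom:
#: free-water-like, tissue-like and slow/restricted components.
PHANTOM_DIFFUSIVITIES = (2.9, 0.85, 0.18)

#: b-values (s/mm²) of the 15-point IVIM acquisition scheme.
IVIM_BVALUES = (0, 10, 20, 30, 40, 60, 100, 150, 200, 250, 300, 400, 600, 800, 1000)

#: Six-b-value subset used for reduced-sampling IVIM analyses.
IVIM_BVALUES_6 = (0, 30, 100, 250, 600, 1000)


@dataclass(frozen=True)
class SamplingScheme:
    """An ordered set of diffusion weightings plus the analysis harmonic.

    Parameters
    ----------
    b_values : tuple of float
        Strictly increasing b-values in s/mm²; the first entry is usually 0.
    harmonic : int
        Harmonic number ``n`` used by the phasor transform (lowest nonzero
        frequency by default).
    """

    b_values: tuple[float, ...]
    harmonic: int = 1

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        if b.ndim != 1 or b.size < 3:
            raise ValueError("a sampling scheme needs at least 3 b-values")
        if not np.all(np.isfinite(b)):
            raise ValueError("b-values must be finite")
        if b[0] < 0:
            raise ValueError("b-values must be non-negative")
        if not np.all(np.diff(b) > 0):
            raise ValueError("b-values must be strictly increasing")
        if not (isinstance(self.harmonic, (int, np.integer)) and self.harmonic >= 1):
            raise ValueError("harmonic must be a positive integer")
        if self.harmonic >= b.size / 2:
            raise ValueError("harmonic must be below half the number of samples")
        object.__setattr__(self, "b_values", tuple(float(x) for x in b))

    @property
    def n_b(self) -> int:
        return len(self.b_values)

    @property
    def b_max(self) -> float:
        return self.b_values[-1]

    @property
    def b_array(self) -> np.ndarray:
        return np.asarray(self.b_values, dtype=float)

    def subset(self, b_max: float) -> "SamplingScheme":
        """Scheme restricted to b-values ≤ ``b_max`` (s/mm²)."""
        kept = tuple(b for b in self.b_values if b <= b_max)
        return SamplingScheme(kept, self.harmonic)


@dataclass(frozen=True)
class MixtureSpec:
    """Generative parameters of a 1–3 component multi-exponential mixture."""

    diffusivities: tuple[float, ...]
    fractions: tuple[float, ...]

    def __post_init__(self) -> None:
        d = np.asarray(self.diffusivities, dtype=float)
        a = np.asarray(self.fractions, dtype=float)
        if d.size != a.size or d.size not in (1, 2, 3):
            raise ValueError("mixture must have 1-3 matched diffusivities/fractions")
        if np.any(d <= 0):
            raise ValueError("diffusivities must be positive")
        if len(set(d.tolist())) != d.size:
            raise ValueError("diffusivities must be distinct")
        if abs(a.sum() - 1.0) > 1e-12:
            raise ValueError("fractions must sum to 1")
        object.__setattr__(self, "diffusivities", tuple(d.tolist()))
        object.__setattr__(self, "fractions", tuple(a.tolist()))


@dataclass(frozen=True)
class IVIMParams:
    """Bi-exponential IVIM parameters: baseline S0, perfusion fraction f,
    tissue diffusivity D and pseudo-diffusivity D* (both μm²/ms)."""

    S0: float
    f: float
    D: float
    D_star: float

    def __post_init__(self) -> None:
        if self.S0 <= 0:
            raise ValueError("S0 must be positive")
        if not 0 <= self.f <= 1:
            raise ValueError("generative f must lie in [0, 1]")
        if self.D > self.D_star:
            raise ValueError("D must not exceed D*")


@dataclass(frozen=True)
class KurtosisParams:
    """Cumulant-expansion kurtosis signal parameters."""

    D: float
    K: float

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError("D must be positive")
        if not math.isfinite(self.K):
            raise ValueError("K must be finite")


@dataclass(frozen=True)
class NoiseSpec:
    """Rician noise level.  ``snr`` is mean-over-std of the b=0 image;
    ``math.inf`` disables noise."""

    snr: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.snr > 0:
            raise ValueError("snr must be positive")


@dataclass
class DecayCurve:
    """Signal values aligned with a :class:`SamplingScheme`."""

    values: np.ndarray
    scheme: SamplingScheme = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape[-1] != self.scheme.n_b:
            raise ValueError("curve length does not match scheme")
        if not np.all(np.isfinite(v)):
            raise ValueError("curve values must be finite")
        self.values = v


def make_equidistant_scheme(n_b: int, b_max: float, harmonic: int = 1) -> SamplingScheme:
    """Equally spaced b-values from 0 to ``b_max`` inclusive."""
    if n_b < 3:
        raise ValueError("need at least 3 b-values")
    if b_max <= 0:
        raise ValueError("b_max must be positive")
    return SamplingScheme(tuple(np.linspace(0.0, float(b_max), int(n_b))), harmonic)


def _attenuation(b: np.ndarray, d: float | np.ndarray) -> np.ndarray:
    return np.exp(-np.multiply.outer(np.asarray(d, dtype=float), b) / 1000.0)


def multiexp_signal(scheme: SamplingScheme, mixture: MixtureSpec, S0: float = 1.0) -> DecayCurve:
    """Noise-free mixture of monoexponential decays, S0·Σ_p a_p·exp(−b·D_p/1000)."""
    b = scheme.b_array
    a = np.asarray(mixture.fractions)
    basis = _attenuation(b, mixture.diffusivities)  # (P, U)
    return DecayCurve(S0 * a @ basis, scheme)


def ivim_signal(scheme: SamplingScheme, params: IVIMParams) -> DecayCurve:
    """Bi-exponential IVIM signal S0·[(1−f)e^{−bD/1000} + f·e^{−bD*/1000}]."""
    b = scheme.b_array
    v = params.S0 * (
        (1 - params.f) * np.exp(-b * params.D / 1000.0)
        + params.f * np.exp(-b * params.D_star / 1000.0)
    )
    return DecayCurve(v, scheme)


def kurtosis_signal(scheme: SamplingScheme, params: KurtosisParams, S0: float = 1.0) -> DecayCurve:
    """Cumulant-expansion signal S0·exp(−bD/1000 + (bD/1000)²·K/6).

    Used for phasor-space visualization of non-monoexponential decays; warns
    when the quadratic term makes the signal rise within the scheme's b range
    (the expansion is only valid at moderate b·D·K).
    """
    b = scheme.b_array
    bd = b * params.D / 1000.0
    v = S0 * np.exp(-bd + bd**2 * params.K / 6.0)
    if params.K > 0 and bd[-1] * params.K > 3.0:
        warnings.warn(
            "kurtosis signal is non-monotone within the sampled b range "
            "(b·D·K/3000 exceeds 1); the cumulant expansion is unreliable here",
            RuntimeWarning,
            stacklevel=2,
        )
    return DecayCurve(v, scheme)


def add_rician_noise(
    curve: DecayCurve,
    noise: NoiseSpec,
    reference_b0: float | None = None,
    rng: np.random.Generator | None = None,
) -> DecayCurve:
    """Corrupt a curve with Rician noise at the stated SNR.

    Gaussian noise of standard deviation ``σ = reference_b0 / snr`` is added
    to the real and imaginary channels and the magnitude is taken, so the
    result follows a Rician distribution.  ``reference_b0`` defaults to the
    curve's noise-free b=0 value; ``snr = inf`` returns the input unchanged.
    """
    if math.isinf(noise.snr):
        return DecayCurve(curve.values.copy(), curve.scheme)
    if reference_b0 is None:
        reference_b0 = float(curve.values[..., 0])
    sigma = reference_b0 / noise.snr
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    g1 = rng.normal(0.0, sigma, size=curve.values.shape)
    g2 = rng.normal(0.0, sigma, size=curve.values.shape)
    return DecayCurve(np.hypot(curve.values + g1, g2), curve.scheme)


def rician_magnitude(values: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Vectorized Rician corruption of an array of noise-free magnitudes."""
    if sigma == 0:
        return np.array(values, dtype=float, copy=True)
    g1 = rng.normal(0.0, sigma, size=values.shape)
    g2 = rng.normal(0.0, sigma, size=values.shape)
    return np.hypot(values + g1, g2)


def read_bval(path) -> SamplingScheme:
    """Read an FSL-style `.bval` text file (single whitespace-separated line)."""
    b = np.loadtxt(path, ndmin=1)
    return SamplingScheme(tuple(float(x) for x in b))


def write_bval(path, scheme: SamplingScheme) -> None:
    """Write a `.bval` file; integer b-values round-trip bit-identically."""
    parts = []
    for b in scheme.b_values:
        parts.append(str(int(b)) if float(b).is_integer() else repr(b))
    with open(path, "w") as fh:
        fh.write(" ".join(parts) + "\n")
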