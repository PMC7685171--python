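"""Fixed-diffusivity unmixing of 2–3 component decay signals.

Two routes to the same fractions:

* **phasor unmixing** — barycentric inversion in phasor space.  The mixture's
  phasor point is expressed in the basis of the pure-component vertices,
  giving phasor fractions α_p (sum constrained to 1, entries unconstrained),
  which are converted to signal fractions a_p through the per-component sums
  E_p = Σ_u exp(−b_u·D_p/1000).
* **linear unmixing** — ordinary least squares on the decay model itself,
  solving exp(−b_u·D_p/1000)·a_p ≈ s_u/s_0 without constraints.

Neither route clips: out-of-range fractions are returned as-is, which is the
behaviour a practitioner needs to see to judge noise sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phasor import (
    PhasorPoint,
    _single_exp_phasor,
    component_sum,
    phasor_transform,
    transform_many,
)
from .signals import DecayCurve, SamplingScheme

__all__ = [
    "ComponentBasis",
    "FractionEstimate",
    "phasor_unmix3",
    "phasor_unmix2",
    "linear_unmix",
    "unmix_volume",
]

_COLLINEAR_TOL = 1e-12


@dataclass(frozen=True)
class ComponentBasis:
    """Fixed diffusivities with their phasor vertices and component sums for
    one sampling scheme."""

    diffusivities: tuple[float, ...]
    vertices: tuple[PhasorPoint, ...]
    sums: tuple[float, ...]
    scheme: SamplingScheme

    @classmethod
    def for_scheme(cls, scheme: SamplingScheme, diffusivities) -> "ComponentBasis":
        d = tuple(float(x) for x in diffusivities)
        if len(set(d)) != len(d):
            raise ValueError("diffusivities must be distinct")
        if len(d) not in (2, 3):
            raise ValueError("basis supports 2 or 3 components")
        verts = []
        for di in d:
            z = _single_exp_phasor(scheme, di)
            verts.append(PhasorPoint(z.real, z.imag))
        sums = tuple(component_sum(scheme, di) for di in d)
        basis = cls(d, tuple(verts), sums, scheme)
        if len(d) == 3 and abs(basis._signed_area2()) <= _COLLINEAR_TOL:
            raise ValueError("component vertices are collinear; unmixing is singular")
        return basis

    def _signed_area2(self) -> float:
        (g1, s1), (g2, s2), (g3, s3) = [(v.g, v.s) for v in self.vertices]
        return (g2 - g1) * (s3 - s1) - (g3 - g1) * (s2 - s1)


@dataclass(frozen=True)
class FractionEstimate:
    """Signal fractions a (and phasor fractions α where applicable).

    Both sum to 1 by construction; individual entries may lie outside [0, 1]
    under noise or mis-specified diffusivities.
    """

    a: tuple[float, ...]
    alpha: tuple[float, ...] | None
    method: str
    valid: bool = True


def _alpha3(g: np.ndarray, s: np.ndarray, basis: ComponentBasis) -> tuple[np.ndarray, np.ndarray]:
    """Barycentric phasor fractions of points (g, s) in the vertex triangle.

    Closed-form (Cramer) solution of the 3x3 system: real/imaginary balance
    plus Σα = 1.
    """
    (g1, s1), (g2, s2), (g3, s3) = [(v.g, v.s) for v in basis.vertices]
    det = (g2 - g1) * (s3 - s1) - (g3 - g1) * (s2 - s1)
    a1 = ((g2 - g) * (s3 - s) - (g3 - g) * (s2 - s)) / det
    a2 = ((g3 - g) * (s1 - s) - (g1 - g) * (s3 - s)) / det
    return a1, a2


def _alpha_to_a3(a1: np.ndarray, a2: np.ndarray, sums) -> tuple[np.ndarray, np.ndarray]:
    """Convert phasor fractions to signal fractions: a_p ∝ α_p / E_p,
    normalized so Σa = 1 (a_3 = 1 − a_1 − a_2)."""
    e1, e2, e3 = sums
    a3 = 1.0 - a1 - a2
    denom = a1 * e2 * e3 + a2 * e1 * e3 + a3 * e1 * e2
    return a1 * e2 * e3 / denom, a2 * e1 * e3 / denom


def phasor_unmix3(point: PhasorPoint, basis: ComponentBasis) -> FractionEstimate:
    """Three-component phasor unmixing of one phasor point."""
    if len(basis.diffusivities) != 3:
        raise ValueError("phasor_unmix3 needs a 3-component basis")
    if not point.valid:
        return FractionEstimate((np.nan,) * 3, None, "phasor", valid=False)
    al1, al2 = _alpha3(np.float64(point.g), np.float64(point.s), basis)
    a1, a2 = _alpha_to_a3(al1, al2, basis.sums)
    return FractionEstimate(
        (float(a1), float(a2), float(1 - a1 - a2)),
        (float(al1), float(al2), float(1 - al1 - al2)),
        "phasor",
    )


def _alpha2(g, s, basis: ComponentBasis):
    """Two-component phasor fraction of component 1: the oblique projection
    α1 = (Im S2·Re M − Im M·Re S2) / (Im S2·Re S1 − Im S1·Re S2)."""
    v1, v2 = basis.vertices[0], basis.vertices[1]
    denom = v2.s * v1.g - v1.s * v2.g
    return (v2.s * g - s * v2.g) / denom


def phasor_unmix2(point: PhasorPoint, basis: ComponentBasis) -> FractionEstimate:
    """Two-component phasor unmixing (the IVIM special case α_3 = 0)."""
    if len(basis.diffusivities) != 2:
        raise ValueError("phasor_unmix2 needs a 2-component basis")
    v1, v2 = basis.vertices
    if abs(v1.g - v2.g) < 1e-14 and abs(v1.s - v2.s) < 1e-14:
        return FractionEstimate((np.nan, np.nan), None, "phasor", valid=False)
    if not point.valid:
        return FractionEstimate((np.nan, np.nan), None, "phasor", valid=False)
    al1 = float(_alpha2(point.g, point.s, basis))
    e1, e2 = basis.sums
    a1 = al1 * e2 / (e1 + al1 * (e2 - e1))
    return FractionEstimate((float(a1), float(1 - a1)), (al1, 1 - al1), "phasor")


def _design(scheme: SamplingScheme, diffusivities) -> np.ndarray:
    b = scheme.b_array
    return np.exp(-np.multiply.outer(b, np.asarray(diffusivities, float)) / 1000.0)


def linear_unmix(
    curve: DecayCurve | np.ndarray,
    scheme: SamplingScheme,
    diffusivities,
) -> FractionEstimate:
    """Unconstrained least-squares solution of the decay model for the signal
    fractions, on the curve normalized by its b=0 value.

    Exact for noise-free input; noisy solutions may fall outside [0, 1] and
    their sum is not forced to 1 (that asymmetry with the phasor route is a
    diagnostic, not a defect).
    """
    values = curve.values if isinstance(curve, DecayCurve) else np.asarray(curve, float)
    d = tuple(float(x) for x in diffusivities)
    if len(set(d)) != len(d):
        raise ValueError("duplicate diffusivities make the design rank-deficient")
    if values[0] == 0:
        return FractionEstimate((np.nan,) * len(d), None, "linear", valid=False)
    y = values / values[0]
    a, *_ = np.linalg.lstsq(_design(scheme, d), y, rcond=None)
    return FractionEstimate(tuple(float(x) for x in a), None, "linear")


def _unmix_stack_phasor(values: np.ndarray, basis: ComponentBasis) -> np.ndarray:
    """Vectorized phasor unmixing of an (..., U) stack; returns (..., P)."""
    z = transform_many(values, basis.scheme)
    g, s = z.real, z.imag
    if len(basis.diffusivities) == 3:
        al1, al2 = _alpha3(g, s, basis)
        a1, a2 = _alpha_to_a3(al1, al2, basis.sums)
        return np.stack([a1, a2, 1.0 - a1 - a2], axis=-1)
    al1 = _alpha2(g, s, basis)
    e1, e2 = basis.sums
    a1 = al1 * e2 / (e1 + al1 * (e2 - e1))
    return np.stack([a1, 1.0 - a1], axis=-1)


def _unmix_stack_linear(values: np.ndarray, scheme: SamplingScheme, diffusivities) -> np.ndarray:
    """Vectorized least-squares unmixing via the design pseudo-inverse."""
    pinv = np.linalg.pinv(_design(scheme, diffusivities))  # (P, U)
    b0 = values[..., 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        y = values / b0[..., None]
    out = y @ pinv.T
    return np.where((b0 == 0)[..., None], np.nan, out)


def unmix_volume(
    volume4d: np.ndarray,
    scheme: SamplingScheme,
    diffusivities,
    method: str = "phasor",
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel unmixing of a 4D (x, y, z, b) volume.

    Returns ``(fractions, valid)`` where ``fractions`` has shape
    (x, y, z, P) and ``valid`` flags voxels that were inside the mask and had
    a usable (nonzero) signal.  Invalid voxels hold NaN fractions.
    """
    volume4d = np.asarray(volume4d, dtype=float)
    if volume4d.ndim != 4 or volume4d.shape[-1] != scheme.n_b:
        raise ValueError("volume must be 4D with last axis matching the scheme")
    if method == "phasor":
        basis = ComponentBasis.for_scheme(scheme, diffusivities)
        fr = _unmix_stack_phasor(volume4d, basis)
    elif method == "linear":
        fr = _unmix_stack_linear(volume4d, scheme, diffusivities)
    else:
        raise ValueError(f"unknown method {method!r}")
    valid = np.isfinite(fr).all(axis=-1)
    if mask is not None:
        valid &= np.asarray(mask, bool)
        fr = np.where(valid[..., None], fr, np.nan)
    return fr, valid
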