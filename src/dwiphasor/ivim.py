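"""IVIM (intravoxel incoherent motion) model fitting.

The bi-exponential IVIM model

    S(b) = S0 · [(1 − f) · exp(−b·D/1000) + f · exp(−b·D*/1000)]

splits the diffusion-weighted decay into tissue diffusion (D, μm²/ms) and a
perfusion-driven pseudo-diffusion pool (D*, fraction f).  Three estimation
strategies are provided:

* :func:`fit_nlls` — bounded trust-region nonlinear least squares on all four
  parameters.
* :func:`fit_segmented` — the classical two-stage log-linear approach: D from
  the high-b tail (b > 300 s/mm²), f from the b=0 gap, D* from the residual.
* :func:`fit_phasor` — a one-parameter fit exploiting the geometry of phasor
  space: bi-exponential signals lie on the chord between their two pure
  components on the monoexponential reference curve, so a candidate D* fixes
  D (by projecting the chord back onto the curve) and f (by two-component
  unmixing).  A penalty proportional to f, active only for points within a
  cutoff distance L0 of the reference curve, discourages spurious perfusion
  fractions for (near-)monoexponential voxels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .phasor import (
    PhasorPoint,
    ReferenceCurve,
    _single_exp_phasor,
    estimate_decay_rate,
    phasor_transform,
    reference_curve,
)
from .signals import DecayCurve, SamplingScheme

__all__ = [
    "IVIMFit",
    "PhasorFitConfig",
    "fit_nlls",
    "fit_segmented",
    "fit_phasor",
    "project_through_point",
    "fit_volume",
]


@dataclass(frozen=True)
class IVIMFit:
    """Result of one voxel-level IVIM fit.

    Fields are plain floats because fitted values may violate the generative
    parameter ranges (negative f or D* from the segmented method, for
    instance) and are intentionally never clipped.
    """

    S0: float
    f: float
    D: float
    D_star: float
    method: str
    converged: bool = True
    swapped: bool = False
    cost: float = np.nan
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class PhasorFitConfig:
    """Tunables of the phasor-projection IVIM fit.

    ``lam`` scales the low-f penalty; ``l0`` is the phasor-space distance to
    the reference curve below which the penalty is active (both dimensionless,
    default 0.05 — a distance of 0.05 from the curve corresponds roughly to
    f = 0.05 for typical clinical schemes).  ``dstar_init`` (μm²/ms) seeds the
    one-dimensional search; D* is bounded below by ``dstar_min`` (0: only
    non-negativity).
    """

    lam: float = 0.05
    l0: float = 0.05
    dstar_init: float = 15.0
    dstar_min: float = 0.0
    d_min: float = 1e-3
    max_nfev: int = 400

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be non-negative")
        if self.l0 <= 0:
            raise ValueError("l0 must be positive")


_TRF_TOL = dict(xtol=1e-10, ftol=1e-10, gtol=1e-10)


# ---------------------------------------------------------------------------
# Nonlinear least squares
# ---------------------------------------------------------------------------

def _ivim_model(b: np.ndarray, s0, f, d, dstar) -> np.ndarray:
    return s0 * ((1 - f) * np.exp(-b * d / 1000.0) + f * np.exp(-b * dstar / 1000.0))


def fit_nlls(
    curve: DecayCurve | np.ndarray,
    scheme: SamplingScheme,
    constrain_f: bool = True,
) -> IVIMFit:
    """Bounded trust-region least squares on (S0, f, D, D*).

    Initialization: S0 at the measured b=0 value, f = 0.5, D = 0.1,
    D* = 15 μm²/ms.  Bounds: D ≥ 0, D* ≥ 2.5 μm²/ms, 0 ≤ f ≤ 1 (the f bound
    is lifted when ``constrain_f`` is False).  If the solver returns D > D*,
    the two roles are exchanged and f ← 1 − f, with the ``swapped`` flag set.
    """
    y = curve.values if isinstance(curve, DecayCurve) else np.asarray(curve, float)
    b = scheme.b_array
    if scheme.n_b < 5 or b[0] != 0:
        raise ValueError("nlls fit needs at least 5 samples including b=0")
    y0 = float(y[0])
    if y0 <= 0:
        return IVIMFit(np.nan, np.nan, np.nan, np.nan, "nlls", converged=False,
                       flags=("nonpositive_b0",))

    f_lo, f_hi = (0.0, 1.0) if constrain_f else (-np.inf, np.inf)
    f0 = 0.5

    def resid(x):
        return _ivim_model(b, *x) - y

    def jac(x):
        s0, f, d, dstar = x
        e_d = np.exp(-b * d / 1000.0)
        e_ds = np.exp(-b * dstar / 1000.0)
        return np.column_stack([
            (1 - f) * e_d + f * e_ds,
            s0 * (e_ds - e_d),
            -s0 * (1 - f) * b / 1000.0 * e_d,
            -s0 * f * b / 1000.0 * e_ds,
        ])

    try:
        res = least_squares(
            resid,
            x0=[y0, f0, 0.1, 15.0],
            jac=jac,
            bounds=([0.0, f_lo, 0.0, 2.5], [np.inf, f_hi, np.inf, np.inf]),
            method="trf",
            max_nfev=400,
            **_TRF_TOL,
        )
    except Exception:
        return IVIMFit(np.nan, np.nan, np.nan, np.nan, "nlls", converged=False,
                       flags=("solver_error",))
    s0, f, d, dstar = res.x
    swapped = False
    if d > dstar:
        d, dstar, f, swapped = dstar, d, 1 - f, True
    method = "nlls" if constrain_f else "nlls_unconstrained_f"
    return IVIMFit(float(s0), float(f), float(d), float(dstar), method,
                   converged=bool(res.success), swapped=swapped,
                   cost=float(2 * res.cost))


# ---------------------------------------------------------------------------
# Segmented fitting
# ---------------------------------------------------------------------------

def fit_segmented(
    curve: DecayCurve | np.ndarray,
    scheme: SamplingScheme,
    threshold: float = 300.0,
) -> IVIMFit:
    """Two-stage log-linear IVIM fit.

    Stage 1 fits a line to ln S over b strictly above ``threshold`` (s/mm²),
    where perfusion is assumed negligible, giving D and the extrapolated
    intercept.  Stage 2 reads f off the gap between the measured b=0 signal
    and that intercept.  Stage 3 subtracts the extrapolated monoexponential
    from the full curve and fits a line to the log of the positive residuals,
    giving D*.  Nothing is constrained: negative D* (a well-known failure
    mode of this estimator under noise) is reported as-is.
    """
    y = curve.values if isinstance(curve, DecayCurve) else np.asarray(curve, float)
    b = scheme.b_array
    if b[0] != 0:
        raise ValueError("segmented fit needs a b=0 sample")
    flags: list[str] = []

    tail = b > threshold
    if tail.sum() < 2:
        raise ValueError("need at least 2 b-values above the threshold")
    y_tail, b_tail = y[tail], b[tail]
    pos = y_tail > 0
    if pos.sum() < 2:
        return IVIMFit(np.nan, np.nan, np.nan, np.nan, "segmented",
                       converged=False, flags=("tail_nonpositive",))
    if not pos.all():
        flags.append("tail_samples_dropped")
    slope, intercept = np.polyfit(b_tail[pos], np.log(y_tail[pos]), 1)
    d = -slope * 1000.0
    s_mono0 = math.exp(intercept)
    f = (y[0] - s_mono0) / y[0]

    resid = y - s_mono0 * np.exp(slope * b)
    keep = resid > 1e-12 * y[0]
    if keep.sum() < 2:
        return IVIMFit(float(y[0]), float(f), float(d), np.nan, "segmented",
                       converged=True, flags=(*flags, "dstar_undefined"))
    slope2, _ = np.polyfit(b[keep], np.log(resid[keep]), 1)
    dstar = -slope2 * 1000.0
    return IVIMFit(float(y[0]), float(f), float(d), float(dstar), "segmented",
                   converged=True, flags=tuple(flags))


# ---------------------------------------------------------------------------
# Phasor-projection fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Projection:
    """Result of projecting a phasor point through a curve vertex."""

    point: PhasorPoint
    d: float
    ok: bool


def project_through_point(
    l_s: PhasorPoint,
    l_dstar: PhasorPoint,
    ref: ReferenceCurve,
    d_max: float | None = None,
    dstar_for_anchor: float | None = None,
) -> Projection:
    """Intersect the line through ``l_s`` and ``l_dstar`` with the reference
    curve on the far side of ``l_s``.

    The signed perpendicular distance of the discretized curve to the line
    changes sign at each crossing; each bracketing grid interval is refined by
    bisection in D (on the exact forward transform) to ~1e-10.  Among the
    crossings, the one *beyond* ``l_s`` as seen from ``l_dstar`` and nearest
    to it is returned.  When ``d_max`` is given the search is restricted to
    curve diffusivities at or below it, which structurally enforces D ≤ D*.
    """
    scheme = ref.scheme
    p0 = np.array([l_dstar.g, l_dstar.s])
    p1 = np.array([l_s.g, l_s.s])
    direction = p1 - p0
    norm2 = float(direction @ direction)
    if norm2 < 1e-28:
        # l_s coincides with the D* vertex: pure pseudo-diffusion signal.
        return Projection(l_dstar, dstar_for_anchor if dstar_for_anchor else np.nan, True)

    d_grid, pts = ref.d_grid, ref.points
    if d_max is not None:
        hi = int(np.searchsorted(d_grid, d_max, side="right"))
        if hi < 2:
            return Projection(l_s, np.nan, False)
        d_grid, pts = d_grid[:hi], pts[:hi]

    # signed perpendicular distance (cross product with the line direction)
    gx, gs = pts.real, pts.imag
    signed = (gx - p0[0]) * direction[1] - (gs - p0[1]) * direction[0]
    crossings = np.nonzero(np.signbit(signed[:-1]) != np.signbit(signed[1:]))[0]

    best_t, best_d, best_pt = None, None, None
    for i in crossings:
        lo_d, hi_d = d_grid[i], d_grid[i + 1]
        s_lo = signed[i]
        for _ in range(80):
            mid = 0.5 * (lo_d + hi_d)
            z = _single_exp_phasor(scheme, mid)
            s_mid = (z.real - p0[0]) * direction[1] - (z.imag - p0[1]) * direction[0]
            if np.signbit(s_mid) == np.signbit(s_lo):
                lo_d, s_lo = mid, s_mid
            else:
                hi_d = mid
            if hi_d - lo_d < 1e-10 * max(1.0, lo_d):
                break
        d_cross = 0.5 * (lo_d + hi_d)
        z = _single_exp_phasor(scheme, d_cross)
        t = ((z.real - p0[0]) * direction[0] + (z.imag - p0[1]) * direction[1]) / norm2
        if t >= 1.0 - 1e-6 and (best_t is None or t < best_t):
            best_t, best_d = t, float(d_cross)
            best_pt = PhasorPoint(float(z.real), float(z.imag))
    if best_t is None:
        return Projection(l_s, np.nan, False)
    return Projection(best_pt, best_d, True)


def fit_phasor(
    curve: DecayCurve | np.ndarray,
    scheme: SamplingScheme,
    config: PhasorFitConfig | None = None,
    ref: ReferenceCurve | None = None,
) -> IVIMFit:
    """Phasor-projection IVIM fit with a single free parameter D*.

    For each candidate D*, the D* vertex on the reference curve and the
    measured signal's phasor point define a chord; its far-side intersection
    with the curve yields D, and two-component phasor unmixing yields f.  The
    candidate is scored against the b=0-normalized signal, with the penalty
    λ·f·(1 − L/L0)² added while the measured point lies within L0 of the
    reference curve (L is the point's distance to the curve and does not
    depend on the candidate).  The projection's search range [d_min, D*]
    makes D ≤ D* structural.
    """
    cfg = config or PhasorFitConfig()
    y_raw = curve.values if isinstance(curve, DecayCurve) else np.asarray(curve, float)
    b = scheme.b_array
    if b[0] != 0:
        raise ValueError("phasor fit needs a b=0 sample for normalization")
    y0 = float(y_raw[0])
    if y0 <= 0:
        return IVIMFit(np.nan, np.nan, np.nan, np.nan, "phasor", converged=False,
                       flags=("nonpositive_b0",))
    y = y_raw / y0
    if ref is None:
        ref = reference_curve(scheme, d_min=cfg.d_min)

    l_s = phasor_transform(y, scheme)
    if not l_s.valid:
        return IVIMFit(np.nan, np.nan, np.nan, np.nan, "phasor", converged=False,
                       flags=("zero_sum",))
    d_nearest, dist_l = estimate_decay_rate(l_s, ref, return_distance=True)
    pen_coeff = cfg.lam * (1.0 - dist_l / cfg.l0) ** 2 if dist_l <= cfg.l0 else 0.0

    exp_b = lambda d: np.exp(-b * d / 1000.0)  # noqa: E731

    def evaluate(dstar: float):
        """(f, D, fallback) for one candidate D*."""
        z_star = _single_exp_phasor(scheme, dstar) if dstar > 0 else 0j
        l_dstar = PhasorPoint(float(np.real(z_star)), float(np.imag(z_star)))
        proj = project_through_point(l_s, l_dstar, ref, d_max=dstar,
                                     dstar_for_anchor=dstar)
        if proj.ok and np.isfinite(proj.d):
            e1 = float(exp_b(dstar).sum())
            e2 = float(exp_b(proj.d).sum())
            denom = l_dstar.g * proj.point.s - l_dstar.s * proj.point.g
            if abs(denom) > 1e-30:
                # two-vertex unmixing with S1 = L_D*, S2 = L_D, M = L_S
                alpha1 = (l_s.g * proj.point.s - l_s.s * proj.point.g) / denom
                f = alpha1 * e2 / (e1 + alpha1 * (e2 - e1))
                return float(f), float(proj.d), False
        # fallback: treat as monoexponential at the nearest curve diffusivity
        return 0.0, min(d_nearest, dstar) if dstar > 0 else d_nearest, True

    def residuals(x):
        dstar = float(x[0])
        f, d, _ = evaluate(dstar)
        yhat = (1 - f) * exp_b(d) + f * exp_b(dstar)
        pen = math.sqrt(pen_coeff * f) if (pen_coeff > 0 and f > 0) else 0.0
        return np.append(yhat - y, pen)

    try:
        res = least_squares(
            residuals,
            x0=[cfg.dstar_init],
            bounds=([cfg.dstar_min], [np.inf]),
            method="trf",
            max_nfev=cfg.max_nfev,
            diff_step=1e-4,
            **_TRF_TOL,
        )
    except Exception:
        return IVIMFit(np.nan, np.nan, np.nan, np.nan, "phasor", converged=False,
                       flags=("solver_error",))
    dstar = float(res.x[0])
    f, d, fell_back = evaluate(dstar)
    flags = ("projection_fallback",) if fell_back else ()
    return IVIMFit(y0, float(f), float(d), dstar, "phasor",
                   converged=bool(res.success), cost=float(2 * res.cost),
                   flags=flags)


# ---------------------------------------------------------------------------
# Volume-level driver
# ---------------------------------------------------------------------------

_FITTERS = {
    "nlls": lambda y, scheme, **kw: fit_nlls(y, scheme, **kw),
    "segmented": lambda y, scheme, **kw: fit_segmented(y, scheme, **kw),
    "phasor": lambda y, scheme, **kw: fit_phasor(y, scheme, **kw),
}


def fit_volume(
    volume4d: np.ndarray,
    scheme: SamplingScheme,
    method: str = "phasor",
    mask: np.ndarray | None = None,
    b_max: float | None = None,
    **kwargs,
) -> dict[str, np.ndarray]:
    """Voxel-wise IVIM fitting of a 4D (x, y, z, b) volume.

    ``b_max`` restricts the analysis to b-values at or below it (IVIM is
    customarily fitted on b ≤ 1000 s/mm²).  Returns maps ``S0``, ``f``, ``D``,
    ``Dstar`` plus ``failed`` (no solution) and ``negative`` (physically
    implausible negative f, D or D*) flag maps.
    """
    volume4d = np.asarray(volume4d, dtype=float)
    if volume4d.ndim != 4 or volume4d.shape[-1] != scheme.n_b:
        raise ValueError("volume must be 4D with last axis matching the scheme")
    if b_max is not None:
        keep = scheme.b_array <= b_max
        volume4d = volume4d[..., keep]
        scheme = scheme.subset(b_max)
    if method not in _FITTERS:
        raise ValueError(f"unknown method {method!r}")
    if method == "phasor" and "ref" not in kwargs:
        kwargs["ref"] = reference_curve(scheme)

    shape = volume4d.shape[:3]
    maps = {k: np.full(shape, np.nan) for k in ("S0", "f", "D", "Dstar")}
    failed = np.zeros(shape, dtype=bool)
    negative = np.zeros(shape, dtype=bool)
    mask_arr = np.ones(shape, bool) if mask is None else np.asarray(mask, bool)

    fitter = _FITTERS[method]
    for idx in np.ndindex(shape):
        if not mask_arr[idx]:
            continue
        y = volume4d[idx]
        if not np.any(y):
            failed[idx] = True
            continue
        try:
            fit = fitter(y, scheme, **kwargs)
        except ValueError:
            failed[idx] = True
            continue
        if not fit.converged and not np.isfinite(fit.f):
            failed[idx] = True
            continue
        maps["S0"][idx] = fit.S0
        maps["f"][idx] = fit.f
        maps["D"][idx] = fit.D
        maps["Dstar"][idx] = fit.D_star
        vals = (fit.f, fit.D, fit.D_star)
        negative[idx] = any(np.isfinite(v) and v < 0 for v in vals)
    maps["failed"] = failed
    maps["negative"] = negative
    return maps
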