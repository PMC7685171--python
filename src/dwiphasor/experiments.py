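"""Monte-Carlo digital-phantom studies of unmixing and IVIM fitting.

Study conditions (the defaults throughout this module):

* **Unmixing phantom** — three components with diffusivities 2.9, 0.85 and
  0.18 μm²/ms (free-water-like, tissue-like, slow), mixed on a 0.1-step
  simplex grid (66 unique fraction combinations), sampled on 21 equidistant
  b-values 0–2500 s/mm², 10 000 Rician noise repeats per combination at SNR
  levels 30, 50, 100 and ∞.
* **IVIM sweep** — D = 0.7, D* = 10 μm²/ms, 101 perfusion fractions f on
  [0, 1], 5000 Rician repeats at SNR 30, fitted on the 15-b-value clinical
  scheme (0–1000 s/mm²).

Errors are always estimate − truth; "bias" is the mean error pooled over all
combinations and repeats (the median is reported alongside).  Quantiles use
linear interpolation between order statistics.  Every study is deterministic
given its seed: per-repeat random streams are derived by spawning counter-
based child sequences from one master `numpy.random.SeedSequence`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .ivim import PhasorFitConfig, fit_nlls, fit_phasor, fit_segmented
from .phasor import reference_curve
from .signals import (
    IVIM_BVALUES,
    PHANTOM_DIFFUSIVITIES,
    IVIMParams,
    SamplingScheme,
    ivim_signal,
    make_equidistant_scheme,
    rician_magnitude,
)
from .unmix import _unmix_stack_linear, _unmix_stack_phasor, ComponentBasis

__all__ = [
    "FractionGrid",
    "ErrorSummary",
    "StudyConfig",
    "run_unmix_noise_study",
    "run_displacement_study",
    "run_bcount_study",
    "run_ivim_sweep",
    "kde_pdf",
    "summarize_errors",
]


@dataclass(frozen=True)
class FractionGrid:
    """All fraction triples on the 0.1-step simplex (66 combinations)."""

    step: float = 0.1

    @property
    def combinations(self) -> np.ndarray:
        n = round(1.0 / self.step)
        combos = [
            (i / n, j / n, (n - i - j) / n)
            for i, j in itertools.product(range(n + 1), repeat=2)
            if i + j <= n
        ]
        return np.array(combos)

    def __len__(self) -> int:
        return len(self.combinations)


@dataclass(frozen=True)
class ErrorSummary:
    """Location and spread of an error sample (estimate − truth)."""

    mean: float
    median: float
    q05: float
    q25: float
    q75: float
    q95: float
    n: int

    @property
    def iqr(self) -> float:
        return self.q75 - self.q25


def summarize_errors(errors) -> ErrorSummary:
    """Mean, median and 5/25/75/95% quantiles (linear interpolation)."""
    e = np.asarray(errors, dtype=float).ravel()
    if e.size == 0:
        raise ValueError("cannot summarize an empty error sample")
    q05, q25, med, q75, q95 = np.quantile(e, [0.05, 0.25, 0.5, 0.75, 0.95])
    return ErrorSummary(float(e.mean()), float(med), float(q05), float(q25),
                        float(q75), float(q95), int(e.size))


@dataclass(frozen=True)
class StudyConfig:
    """Shared configuration of the phantom studies."""

    diffusivities: tuple[float, ...] = PHANTOM_DIFFUSIVITIES
    n_b: int = 21
    b_max: float = 2500.0
    snr_levels: tuple[float, ...] = (30.0, 50.0, 100.0, math.inf)
    n_repeats: int = 10_000
    seed: int = 0
    displacement_factors: tuple[float, ...] = tuple(
        np.round(np.arange(0.75, 1.2501, 0.05), 2)
    )
    b_counts: tuple[int, ...] = tuple(range(3, 100))
    ivim_b_values: tuple[float, ...] = IVIM_BVALUES
    ivim_D: float = 0.7
    ivim_D_star: float = 10.0
    ivim_f_values: tuple[float, ...] = tuple(np.round(np.linspace(0, 1, 101), 2))
    ivim_n_repeats: int = 5000

    @property
    def scheme(self) -> SamplingScheme:
        return make_equidistant_scheme(self.n_b, self.b_max)

    @property
    def ivim_scheme(self) -> SamplingScheme:
        return SamplingScheme(self.ivim_b_values)


def _phantom_curves(scheme: SamplingScheme, diffusivities, fractions: np.ndarray) -> np.ndarray:
    """Noise-free curves (n_combo, U) of all fraction combinations, S0 = 1."""
    b = scheme.b_array
    basis = np.exp(-np.multiply.outer(np.asarray(diffusivities, float), b) / 1000.0)
    return fractions @ basis


def _unmix_errors(
    scheme: SamplingScheme,
    gen_diffusivities,
    fit_diffusivities,
    snr: float,
    n_repeats: int,
    seed_seq: np.random.SeedSequence,
) -> dict[str, np.ndarray]:
    """Pooled fraction errors (n_combo·n_repeats, 3) per unmixing method.

    Data are generated with ``gen_diffusivities`` and unmixed with
    ``fit_diffusivities`` (identical unless a displacement is under study).
    Noise-free runs collapse to a single repeat.
    """
    grid = FractionGrid().combinations
    clean = _phantom_curves(scheme, gen_diffusivities, grid)
    basis = ComponentBasis.for_scheme(scheme, fit_diffusivities)
    if math.isinf(snr):
        noisy = clean[:, None, :]  # one noise-free "repeat"
        n_repeats = 1
    else:
        sigma = 1.0 / snr  # S0 = 1 for every combination
        rng = np.random.default_rng(seed_seq)
        noisy = rician_magnitude(
            np.broadcast_to(clean[:, None, :], (len(grid), n_repeats, scheme.n_b)),
            sigma,
            rng,
        )
    truth = grid[:, None, :]
    err_phasor = _unmix_stack_phasor(noisy, basis) - truth
    err_linear = _unmix_stack_linear(noisy, scheme, fit_diffusivities) - truth
    return {
        "phasor": err_phasor.reshape(-1, 3),
        "linear": err_linear.reshape(-1, 3),
    }


def run_unmix_noise_study(config: StudyConfig | None = None) -> pd.DataFrame:
    """Noise dependence of fixed-diffusivity unmixing with true diffusivities.

    Returns one row per (snr, method, component) with the pooled mean error
    (the noise-induced bias), median error and quantiles over all 66
    combinations × repeats.
    """
    cfg = config or StudyConfig()
    scheme = cfg.scheme
    master = np.random.SeedSequence(cfg.seed)
    rows = []
    for snr, child in zip(cfg.snr_levels, master.spawn(len(cfg.snr_levels))):
        errors = _unmix_errors(scheme, cfg.diffusivities, cfg.diffusivities,
                               snr, cfg.n_repeats, child)
        for method, err in errors.items():
            for comp in range(3):
                s = summarize_errors(err[:, comp])
                rows.append({"snr": snr, "method": method, "component": comp + 1,
                             "bias": s.mean, "median": s.median, "q05": s.q05,
                             "q25": s.q25, "q75": s.q75, "q95": s.q95,
                             "iqr": s.iqr, "n": s.n})
    return pd.DataFrame(rows)


def run_displacement_study(
    config: StudyConfig | None = None,
    snr_levels: tuple[float, ...] = (math.inf, 30.0),
    factors: tuple[float, ...] | None = None,
) -> pd.DataFrame:
    """Sensitivity of unmixing to mis-specified component diffusivities.

    Data are generated with the true diffusivities while each component's
    unmixing diffusivity is scaled in turn by every displacement factor; one
    row per (snr, factor, displaced component, estimated component, method).
    """
    cfg = config or StudyConfig()
    scheme = cfg.scheme
    facs = cfg.displacement_factors if factors is None else factors
    master = np.random.SeedSequence(cfg.seed)
    rows = []
    cells = [(snr, fac, disp) for snr in snr_levels for fac in facs
             for disp in range(3)]
    for (snr, fac, disp), child in zip(cells, master.spawn(len(cells))):
        fit_d = list(cfg.diffusivities)
        fit_d[disp] *= fac
        errors = _unmix_errors(scheme, cfg.diffusivities, tuple(fit_d),
                               snr, cfg.n_repeats, child)
        for method, err in errors.items():
            for comp in range(3):
                s = summarize_errors(err[:, comp])
                rows.append({"snr": snr, "factor": fac, "displaced": disp + 1,
                             "component": comp + 1, "method": method,
                             "bias": s.mean, "median": s.median, "q05": s.q05,
                             "q25": s.q25, "q75": s.q75, "q95": s.q95,
                             "iqr": s.iqr, "n": s.n})
    return pd.DataFrame(rows)


def run_bcount_study(
    config: StudyConfig | None = None,
    snr: float = 30.0,
) -> pd.DataFrame:
    """Precision of unmixing as a function of the number of b-values.

    Equidistant schemes 0–b_max with 3 to 99 samples, true diffusivities,
    evaluated at a single SNR (30 by default, the clinically realistic level).
    """
    cfg = config or StudyConfig()
    master = np.random.SeedSequence(cfg.seed)
    rows = []
    for n_b, child in zip(cfg.b_counts, master.spawn(len(cfg.b_counts))):
        scheme = make_equidistant_scheme(n_b, cfg.b_max)
        errors = _unmix_errors(scheme, cfg.diffusivities, cfg.diffusivities,
                               snr, cfg.n_repeats, child)
        for method, err in errors.items():
            for comp in range(3):
                s = summarize_errors(err[:, comp])
                rows.append({"n_b": n_b, "snr": snr, "method": method,
                             "component": comp + 1, "bias": s.mean,
                             "median": s.median, "q05": s.q05, "q25": s.q25,
                             "q75": s.q75, "q95": s.q95, "iqr": s.iqr, "n": s.n})
    return pd.DataFrame(rows)


def _ivim_estimates_one_f(
    scheme: SamplingScheme,
    truth: IVIMParams,
    snr: float,
    n_repeats: int,
    methods: tuple[str, ...],
    seed_seq: np.random.SeedSequence,
    phasor_config: PhasorFitConfig | None = None,
) -> dict[str, dict[str, np.ndarray]]:
    """Parameter estimates (with NaN for failures) per method at one true f."""
    clean = ivim_signal(scheme, truth).values
    if math.isinf(snr):
        noisy = np.broadcast_to(clean, (n_repeats, scheme.n_b)).copy()
    else:
        rng = np.random.default_rng(seed_seq)
        noisy = rician_magnitude(
            np.broadcast_to(clean, (n_repeats, scheme.n_b)), truth.S0 / snr, rng
        )
    ref = reference_curve(scheme)
    cfg = phasor_config or PhasorFitConfig()
    out = {m: {"f": np.full(n_repeats, np.nan),
               "D": np.full(n_repeats, np.nan),
               "Dstar": np.full(n_repeats, np.nan)} for m in methods}
    for i in range(n_repeats):
        y = noisy[i]
        for m in methods:
            if m == "nlls":
                fit = fit_nlls(y, scheme)
            elif m == "segmented":
                fit = fit_segmented(y, scheme)
            elif m == "phasor":
                fit = fit_phasor(y, scheme, config=cfg, ref=ref)
            else:
                raise ValueError(f"unknown method {m!r}")
            out[m]["f"][i] = fit.f
            out[m]["D"][i] = fit.D
            out[m]["Dstar"][i] = fit.D_star
    return out


def run_ivim_sweep(
    config: StudyConfig | None = None,
    snr: float = 30.0,
    methods: tuple[str, ...] = ("nlls", "segmented", "phasor"),
    f_values: tuple[float, ...] | None = None,
    n_repeats: int | None = None,
) -> pd.DataFrame:
    """Accuracy and precision of the three IVIM fitters across true f.

    For each true perfusion fraction, ``n_repeats`` noisy realizations are
    fitted by every method; one row per (f, method, parameter) carries the
    error quantiles and the failure count (failed fits are excluded from the
    quantiles but reported).
    """
    cfg = config or StudyConfig()
    scheme = cfg.ivim_scheme
    fvals = cfg.ivim_f_values if f_values is None else f_values
    nrep = cfg.ivim_n_repeats if n_repeats is None else n_repeats
    master = np.random.SeedSequence(cfg.seed)
    rows = []
    for f_true, child in zip(fvals, master.spawn(len(fvals))):
        truth = IVIMParams(S0=1.0, f=float(f_true), D=cfg.ivim_D,
                           D_star=cfg.ivim_D_star)
        est = _ivim_estimates_one_f(scheme, truth, snr, nrep, methods, child)
        true_vals = {"f": truth.f, "D": truth.D, "Dstar": truth.D_star}
        for m in methods:
            for param, tv in true_vals.items():
                vals = est[m][param]
                ok = np.isfinite(vals)
                s = summarize_errors(vals[ok] - tv)
                rows.append({"f_true": float(f_true), "method": m,
                             "parameter": param, "mean": s.mean,
                             "median": s.median, "q05": s.q05, "q25": s.q25,
                             "q75": s.q75, "q95": s.q95, "iqr": s.iqr,
                             "n": s.n, "n_failed": int((~ok).sum())})
    return pd.DataFrame(rows)


def kde_pdf(estimates, grid) -> np.ndarray:
    """Gaussian kernel density (Silverman bandwidth) on a grid, renormalized
    to integrate to 1 over that grid.

    Degenerate zero-variance input raises, since a kernel density is not
    defined for a point mass.
    """
    e = np.asarray(estimates, dtype=float).ravel()
    grid = np.asarray(grid, dtype=float)
    if e.size < 50:
        raise ValueError("need at least 50 estimates for a stable density")
    if np.std(e) == 0:
        raise ValueError("zero-variance sample: density is a point mass")
    kde = gaussian_kde(e, bw_method="silverman")
    pdf = kde(grid)
    area = np.trapezoid(pdf, grid)
    return pdf / area
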