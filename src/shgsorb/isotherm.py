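"""Adsorption-isotherm assembly, modified-Langmuir fitting and derived reports.

Time-zero SHG intensities at a grid of total dye concentrations are fit to
the depletion-corrected Langmuir observation model with the incoherent
slope ``alpha`` and the baseline ``B`` held fixed at their calibrated
values, leaving three free parameters: the saturation intensity ``A``, the
site concentration ``Nmax`` and the equilibrium constant ``K``.  ``K`` is
fitted on a log10 scale to tame its seven-decade disparity with the other
parameters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .constants import DEFAULT_TEMPERATURE_K, R_KCAL_PER_MOL_K, WATER_MOLARITY_UM
from .core_models import (
    LangmuirParams,
    SampleComposition,
    TransportFit,
    adsorption_free_energy,
    isotherm_intensity,
    lipids_per_site,
    signal_per_coverage,
)
from .exceptions import FitError, InsufficientDataError, InvalidInputError
from .kinetics import time_zero_intensity

__all__ = [
    "IsothermPoint",
    "AdsorptionIsotherm",
    "IsothermFitResult",
    "DerivedReport",
    "assemble_isotherm",
    "fit_modified_langmuir",
    "bootstrap_uncertainties",
    "derived_report",
]

log = logging.getLogger(__name__)

LOG10K_BOUNDS = (3.0, 12.0)  # box constraint on log10 of the equilibrium constant
NMAX_BOUND_FACTOR = 10.0  # Nmax upper bound, in units of max(C)


@dataclass(frozen=True)
class IsothermPoint:
    C_total: float  # uM
    I0: float  # counts, extrapolated time-zero intensity
    I0_sigma: float = 0.0

    def __post_init__(self):
        if not (self.C_total > 0):
            raise InvalidInputError(f"C_total must be > 0, got {self.C_total!r}")
        if self.I0_sigma < 0:
            raise InvalidInputError("I0_sigma must be >= 0")


@dataclass
class AdsorptionIsotherm:
    """Time-zero intensity vs total dye concentration for one sample."""

    points: list[IsothermPoint]
    sample: SampleComposition
    alpha: float  # counts/uM, fixed from HRS calibration
    B: float  # counts, fixed from dye-free baseline

    def __post_init__(self):
        if len(self.points) < 4:
            raise InsufficientDataError(f"need >= 4 isotherm points, got {len(self.points)}")
        conc = [p.C_total for p in self.points]
        if len(set(conc)) != len(conc):
            raise InvalidInputError("isotherm concentrations must be distinct")
        self.points = sorted(self.points, key=lambda p: p.C_total)

    @property
    def C(self) -> np.ndarray:
        return np.array([p.C_total for p in self.points])

    @property
    def I0(self) -> np.ndarray:
        return np.array([p.I0 for p in self.points])

    @property
    def I0_sigma(self) -> np.ndarray:
        return np.array([p.I0_sigma for p in self.points])


@dataclass
class IsothermFitResult:
    """Fitted modified-Langmuir parameters with uncertainties."""

    params: LangmuirParams
    param_stderr: dict  # keys "A", "Nmax", "K"
    param_cov: np.ndarray  # 3x3 covariance of (A, Nmax, K), linear scale
    rss: float = 0.0
    saturation_unidentified: bool = False
    hrs_mode: str = "free"
    bootstrap_draws: np.ndarray | None = None  # (n_boot, 3) of (A, Nmax, K)
    bootstrap_intervals: dict | None = None  # 68% percentile intervals


@dataclass(frozen=True)
class DerivedReport:
    """Thermodynamic and geometric quantities derived from a Langmuir fit."""

    delta_g: float  # kcal/mol
    delta_g_err: float
    lipids_per_site: float
    lipids_per_site_err: float
    signal_per_coverage: float  # counts uM^-2
    signal_per_coverage_err: float
    T: float  # K
    sample: SampleComposition


def assemble_isotherm(
    fits: list[tuple[float, TransportFit]],
    sample: SampleComposition,
    alpha: float,
    B: float,
) -> AdsorptionIsotherm:
    """Build an isotherm from time-zero extrapolations of transport fits.

    Duplicate concentrations are mean-aggregated (combined sigma) and
    logged.  Requires >= 4 distinct concentrations.
    """
    by_conc: dict[float, list[tuple[float, float]]] = {}
    for c, fit in fits:
        i0, sig = time_zero_intensity(fit, with_sigma=True)
        by_conc.setdefault(float(c), []).append((i0, sig))
    points = []
    for c, vals in by_conc.items():
        if len(vals) > 1:
            log.info("aggregating %d duplicate isotherm points at %g uM", len(vals), c)
        i0 = float(np.mean([v[0] for v in vals]))
        sig = float(np.sqrt(np.sum([v[1] ** 2 for v in vals])) / len(vals))
        points.append(IsothermPoint(C_total=c, I0=i0, I0_sigma=sig))
    return AdsorptionIsotherm(points=points, sample=sample, alpha=alpha, B=B)


def _coverage_like(c, nmax, k):
    from .core_models import langmuir_coverage

    return langmuir_coverage(float(c), nmax, k).N_adsorbed


def _model(C, A, Nmax, K, alpha, B, hrs_mode):
    p = LangmuirParams(A=A, Nmax=Nmax, K=K, alpha=alpha, B=B)
    return isotherm_intensity(C, p, hrs_mode=hrs_mode)


def _default_init(iso: AdsorptionIsotherm) -> tuple[float, float, float]:
    """Heuristic start: A from the plateau, Nmax = maxC/2, K at half depletion."""
    c_max = float(iso.C.max())
    a0 = max(float(iso.I0.max()) - iso.B, 1e-6)
    nmax0 = c_max / 2.0
    k0 = WATER_MOLARITY_UM / c_max
    return a0, nmax0, k0


def fit_modified_langmuir(
    iso: AdsorptionIsotherm,
    init: tuple[float, float, float] | None = None,
    hrs_mode: str = "free",
    n_restarts: int = 5,
    seed: int = 0,
    log_k: bool = True,
) -> IsothermFitResult:
    """Weighted least squares of the isotherm model over (A, Nmax, K).

    Weights are ``1/I0_sigma**2`` when sigmas are present (uniform
    otherwise).  ``K`` is fitted as log10(K) inside a [1e3, 1e12] box by
    default; ``log_k=False`` fits K on the linear scale (used only to
    verify reparameterization invariance).  Five seeded, jittered restarts
    are attempted before declaring non-convergence.
    """
    C, I0, sig = iso.C, iso.I0, iso.I0_sigma
    use_w = np.all(sig > 0)
    w = 1.0 / sig if use_w else np.ones_like(I0)
    c_max = float(C.max())
    nmax_hi = NMAX_BOUND_FACTOR * c_max

    a0, nmax0, k0 = init if init is not None else _default_init(iso)

    def pack(a, nmax, k):
        return np.array([a, nmax, np.log10(k) if log_k else k])

    def unpack(x):
        return x[0], x[1], 10.0 ** x[2] if log_k else x[2]

    if log_k:
        lb = [1e-12, 1e-9, LOG10K_BOUNDS[0]]
        ub = [np.inf, nmax_hi, LOG10K_BOUNDS[1]]
    else:
        lb = [1e-12, 1e-9, 10.0 ** LOG10K_BOUNDS[0]]
        ub = [np.inf, nmax_hi, 10.0 ** LOG10K_BOUNDS[1]]

    def residuals(x):
        a, nmax, k = unpack(x)
        return (_model(C, a, nmax, k, iso.alpha, iso.B, hrs_mode) - I0) * w

    rng = np.random.default_rng(seed)
    starts = [pack(a0, nmax0, k0)]
    for _ in range(n_restarts):
        jit = rng.uniform(0.5, 1.5, size=3)
        starts.append(pack(a0 * jit[0], min(nmax0 * jit[1], 0.9 * nmax_hi),
                           np.clip(k0 * jit[2], 10.0 ** (LOG10K_BOUNDS[0] + 0.1),
                                   10.0 ** (LOG10K_BOUNDS[1] - 0.1))))

    best = None
    diagnostics = []
    for x0 in starts:
        x0 = np.clip(x0, lb, ub)
        try:
            sol = least_squares(residuals, x0, bounds=(lb, ub), method="trf",
                                xtol=1e-15, ftol=1e-15, gtol=1e-15,
                                x_scale="jac", max_nfev=20000)
        except Exception as exc:  # pathological start
            diagnostics.append(str(exc))
            continue
        if np.isfinite(sol.cost) and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitError("modified-Langmuir fit failed from all starts",
                       diagnostics={"errors": diagnostics})

    a, nmax, k = unpack(best.x)
    rss = float(2.0 * best.cost)
    dof = max(C.size - 3, 1)
    jtj = best.jac.T @ best.jac
    cov_x = np.linalg.pinv(jtj) * (rss / dof)
    # transform covariance to linear (A, Nmax, K)
    jac_t = np.diag([1.0, 1.0, k * np.log(10.0) if log_k else 1.0])
    cov = jac_t @ cov_x @ jac_t
    stderr = {name: float(np.sqrt(max(cov[i, i], 0.0)))
              for i, name in enumerate(("A", "Nmax", "K"))}

    a, nmax, k = float(a), float(nmax), float(k)
    saturated = bool(nmax > 0.999 * nmax_hi)
    if saturated:
        warnings.warn("Nmax hit its upper bound; saturation not identified", stacklevel=2)
    # fitted coherent contribution at the largest concentration
    coh_max = a * (_coverage_like(c_max, nmax, k) / nmax) ** 2
    if coh_max < 1e-6 * max(float(I0.max()), 1.0):
        warnings.warn("fitted coherent signal is ~0 (degenerate isotherm)", stacklevel=2)
        a = max(a, 1e-12)

    params = LangmuirParams(A=a, Nmax=nmax, K=k, alpha=iso.alpha, B=iso.B)
    return IsothermFitResult(params=params, param_stderr=stderr, param_cov=cov,
                             rss=rss, saturation_unidentified=saturated,
                             hrs_mode=hrs_mode)


def bootstrap_uncertainties(
    iso: AdsorptionIsotherm,
    result: IsothermFitResult,
    n_boot: int = 500,
    seed: int = 0,
) -> IsothermFitResult:
    """Residual-resampling bootstrap around the base fit.

    Each replicate resamples the fitted residuals with replacement, adds
    them back onto the fitted curve, and refits warm-started from the base
    solution.  Reports 68% percentile intervals alongside the
    covariance-based standard errors; deterministic under ``seed``.
    """
    if n_boot < 100:
        raise InvalidInputError(f"n_boot must be >= 100, got {n_boot}")
    C, I0 = iso.C, iso.I0
    p = result.params
    fitted = _model(C, p.A, p.Nmax, p.K, iso.alpha, iso.B, result.hrs_mode)
    resid = I0 - fitted
    rng = np.random.default_rng(seed)
    draws = []
    failures = 0
    base_init = (p.A, p.Nmax, p.K)
    for _ in range(n_boot):
        idx = rng.integers(0, resid.size, size=resid.size)
        boot_points = [
            IsothermPoint(C_total=float(c), I0=float(f + r), I0_sigma=float(s))
            for c, f, r, s in zip(C, fitted, resid[idx], iso.I0_sigma)
        ]
        boot_iso = AdsorptionIsotherm(points=boot_points, sample=iso.sample,
                                      alpha=iso.alpha, B=iso.B)
        try:
            rep = fit_modified_langmuir(boot_iso, init=base_init,
                                        hrs_mode=result.hrs_mode, n_restarts=0)
            draws.append([rep.params.A, rep.params.Nmax, rep.params.K])
        except FitError:
            failures += 1
    if failures > 0.2 * n_boot:
        warnings.warn(f"bootstrap unstable: {failures}/{n_boot} replicates failed",
                      stacklevel=2)
    draws_arr = np.array(draws) if draws else np.empty((0, 3))
    intervals = {}
    if draws_arr.size:
        for i, name in enumerate(("A", "Nmax", "K")):
            lo, hi = np.percentile(draws_arr[:, i], [16.0, 84.0])
            intervals[name] = (float(lo), float(hi))
    return replace(result, bootstrap_draws=draws_arr, bootstrap_intervals=intervals)


def derived_report(
    result: IsothermFitResult,
    sample: SampleComposition,
    T: float = DEFAULT_TEMPERATURE_K,
) -> DerivedReport:
    """Table-style derived quantities with first-order error propagation.

    delta_g = -RT ln K with sigma = RT * sigma_K / K; lipids per site =
    lipid_conc / Nmax; signal per coverage = A / Nmax**2.
    """
    p = result.params
    s_a = result.param_stderr.get("A", 0.0)
    s_n = result.param_stderr.get("Nmax", 0.0)
    s_k = result.param_stderr.get("K", 0.0)

    dg = adsorption_free_energy(p.K, T).delta_g
    dg_err = R_KCAL_PER_MOL_K * T * s_k / p.K

    lps = lipids_per_site(sample.lipid_conc, p.Nmax)
    lps_err = sample.lipid_conc / p.Nmax**2 * s_n

    spc = signal_per_coverage(p.A, p.Nmax)
    spc_err = float(np.sqrt((s_a / p.Nmax**2) ** 2 + (2.0 * p.A * s_n / p.Nmax**3) ** 2))

    return DerivedReport(delta_g=dg, delta_g_err=dg_err,
                         lipids_per_site=lps, lipids_per_site_err=lps_err,
                         signal_per_coverage=spc, signal_per_coverage_err=spc_err,
                         T=T, sample=sample)
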