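"""Pure model functions for SHG adsorption and transport analysis.

This module houses the physical observation models as side-effect-free
functions: the coherent two-leaflet field model, the depletion-corrected
Langmuir coverage solver (closed form plus an independent bisection
oracle), the SHG isotherm observation model, the exponential field decay,
and thermodynamic derivations.

Unit conventions
----------------
Concentrations are in uM.  The equilibrium constant ``K`` is dimensionless,
referenced to the 55.5 M molarity of water (:data:`shgsorb.constants.WATER_MOLARITY_UM`).
Free energies are in kcal/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_TEMPERATURE_K, R_KCAL_PER_MOL_K, WATER_MOLARITY_UM
from .exceptions import BracketError, InternalConsistencyError, InvalidInputError

__all__ = [
    "InterfacePopulations",
    "SampleComposition",
    "LangmuirParams",
    "CoverageResult",
    "TransportFit",
    "ThermoResult",
    "coherent_field",
    "shg_intensity",
    "langmuir_coverage",
    "langmuir_coverage_oracle",
    "isotherm_intensity",
    "field_decay",
    "adsorption_free_energy",
    "lipids_per_site",
    "signal_per_coverage",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InterfacePopulations:
    """Adsorbate populations on the two bilayer leaflets.

    Attributes
    ----------
    n_outer, n_inner : float
        Surface populations (uM equivalents) on the outer / inner leaflet.
    e_omega : float
        Incident optical field amplitude (arbitrary field units).
    """

    n_outer: float
    n_inner: float
    e_omega: float = 1.0

    def __post_init__(self):
        for name in ("n_outer", "n_inner", "e_omega"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise InvalidInputError(f"{name} must be finite, got {v!r}")
            if v < 0:
                raise InvalidInputError(f"{name} must be >= 0, got {v!r}")


@dataclass(frozen=True)
class SampleComposition:
    """Composition of one liposome sample."""

    lipid_conc: float  # uM
    apap_conc: float = 0.0  # uM
    label: str = ""

    def __post_init__(self):
        if not (self.lipid_conc > 0):
            raise InvalidInputError(f"lipid_conc must be > 0, got {self.lipid_conc!r}")
        if self.apap_conc < 0:
            raise InvalidInputError(f"apap_conc must be >= 0, got {self.apap_conc!r}")


@dataclass(frozen=True)
class LangmuirParams:
    """Parameters of the depletion-corrected Langmuir observation model.

    Attributes
    ----------
    A : float
        SHG intensity at adsorbate saturation (counts).
    Nmax : float
        Maximum adsorption site concentration (uM).
    K : float
        Dimensionless adsorption equilibrium constant (referenced to
        55.5 M water).
    alpha : float
        Incoherent (hyper-Rayleigh) slope, counts per uM free dye.
    B : float
        Baseline offset (counts) from the dye-free sample.
    """

    A: float
    Nmax: float
    K: float
    alpha: float = 0.0
    B: float = 0.0

    def __post_init__(self):
        if not (self.A > 0):
            raise InvalidInputError(f"A must be > 0, got {self.A!r}")
        if not (self.Nmax > 0):
            raise InvalidInputError(f"Nmax must be > 0, got {self.Nmax!r}")
        if not (self.K > 0):
            raise InvalidInputError(f"K must be > 0, got {self.K!r}")
        if self.alpha < 0:
            raise InvalidInputError(f"alpha must be >= 0, got {self.alpha!r}")
        if self.B < 0:
            raise InvalidInputError(f"B must be >= 0, got {self.B!r}")


@dataclass(frozen=True)
class CoverageResult:
    """Equilibrium partition of added dye between surface and solution.

    Mass balance ``N_adsorbed + M_free == C_total`` holds exactly as stored.
    """

    N_adsorbed: float  # uM
    M_free: float  # uM
    C_total: float  # uM


@dataclass
class TransportFit:
    """Result of fitting the exponential field decay E(t) = A0 + A1*exp(-t/tau).

    ``background`` is an optional constant intensity offset (counts) under
    the squared coherent field; it is zero for a pure field-domain
    exponential and is fitted when the trace carries an incoherent
    (HRS + baseline) pedestal.
    """

    A0: float
    A1: float
    tau: float  # s
    param_cov: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    rss: float = 0.0
    background: float = 0.0
    background_stderr: float = 0.0
    clamp_count: int = 0
    unresolved_decay: bool = False

    def __post_init__(self):
        if not (self.tau > 0):
            raise InvalidInputError(f"tau must be > 0, got {self.tau!r}")
        cov = np.asarray(self.param_cov, dtype=float)
        if cov.shape != (3, 3):
            raise InvalidInputError(f"param_cov must be 3x3, got shape {cov.shape}")
        self.param_cov = cov

    @property
    def stderr(self) -> np.ndarray:
        """Standard errors of (A0, A1, tau) from the covariance diagonal."""
        return np.sqrt(np.clip(np.diag(self.param_cov), 0.0, None))


@dataclass(frozen=True)
class ThermoResult:
    """Adsorption free energy derived from an equilibrium constant."""

    delta_g: float  # kcal/mol
    K: float
    T: float  # K


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def coherent_field(pop: InterfacePopulations, prefactor: float = 1.0) -> float:
    """Coherent second-harmonic field from the leaflet population difference.

    Oppositely oriented adsorbates on the two leaflets radiate with
    opposite phase, so the net field is proportional to the population
    difference: ``prefactor * (n_outer - n_inner) * e_omega**2``.  The sign
    is preserved (negative when the inner population dominates).
    """
    if not math.isfinite(prefactor) or prefactor <= 0:
        raise InvalidInputError(f"prefactor must be a positive finite real, got {prefactor!r}")
    return prefactor * (pop.n_outer - pop.n_inner) * pop.e_omega**2


def shg_intensity(field: float) -> float:
    """SHG intensity is the square of the second-harmonic field."""
    if not math.isfinite(field):
        raise InvalidInputError(f"field must be finite, got {field!r}")
    return field * field


def _coverage_n(C, Nmax: float, K: float):
    """Vectorized physical root of the depletion quadratic.

    N solves ``N/(Nmax - N) = (K/W) * (C - N)`` i.e.
    ``N^2 - (C + Nmax + W/K) N + C*Nmax = 0``; the smaller root is the
    physical one.  Computed as ``2*C*Nmax / (s + sqrt(disc))`` with the
    discriminant expanded in a cancellation-free form
    ``(C - Nmax)^2 + 2*(C + Nmax)*(W/K) + (W/K)^2`` (all terms >= 0).
    """
    C = np.asarray(C, dtype=float)
    wk = WATER_MOLARITY_UM / K
    s = C + Nmax + wk
    disc = (C - Nmax) ** 2 + 2.0 * (C + Nmax) * wk + wk * wk
    if np.any(disc < 0):
        raise InternalConsistencyError("negative discriminant in depletion quadratic")
    return 2.0 * C * Nmax / (s + np.sqrt(disc))


def langmuir_coverage(C_total: float, Nmax: float, K: float) -> CoverageResult:
    """Solve the depletion-corrected Langmuir equilibrium for the coverage.

    Parameters
    ----------
    C_total : float
        Total added dye concentration (uM).
    Nmax : float
        Maximum adsorption site concentration (uM).
    K : float
        Dimensionless equilibrium constant (referenced to 55.5 M water).

    Returns
    -------
    CoverageResult
        Adsorbed concentration ``N``, free concentration ``M = C - N`` and
        the total; ``N`` satisfies ``N/(Nmax-N) = (K/W)(C-N)`` to relative
        residual <= 1e-9 and lies in ``[0, min(C, Nmax)]``.
    """
    for name, v in (("C_total", C_total), ("Nmax", Nmax), ("K", K)):
        if not math.isfinite(v):
            raise InvalidInputError(f"{name} must be finite, got {v!r}")
    if C_total < 0:
        raise InvalidInputError(f"C_total must be >= 0, got {C_total!r}")
    if Nmax <= 0 or K <= 0:
        raise InvalidInputError("Nmax and K must be > 0")
    n = float(_coverage_n(C_total, Nmax, K))
    n = min(n, C_total, Nmax)  # guard fp drift at the saturating limits
    m = C_total - n
    for _ in range(5):  # nudge within 1 ulp so mass balance holds exactly as stored
        if n + m == C_total:
            break
        n = C_total - m
        m = C_total - n
    return CoverageResult(N_adsorbed=n, M_free=m, C_total=C_total)


def langmuir_coverage_oracle(C_total: float, Nmax: float, K: float, tol: float = 1e-12) -> float:
    """Independent bracketed-bisection solution of the coverage equilibrium.

    Finds the root of ``f(N) = N*W - K*(C-N)*(Nmax-N)`` on
    ``[0, min(C, Nmax)]``.  Exists purely to cross-check
    :func:`langmuir_coverage`; shares no code with the closed form.
    """
    if C_total < 0 or Nmax <= 0 or K <= 0:
        raise InvalidInputError("inputs must satisfy C_total >= 0, Nmax > 0, K > 0")
    if C_total == 0:
        return 0.0
    hi = min(C_total, Nmax)

    def f(n):
        return n * WATER_MOLARITY_UM - K * (C_total - n) * (Nmax - n)

    lo, f_lo = 0.0, f(0.0)
    f_hi = f(hi)
    if f_lo == 0.0:
        return 0.0
    if f_hi == 0.0:
        return hi
    if f_lo * f_hi > 0:
        raise BracketError(f"no sign change on [0, {hi}]: f(0)={f_lo}, f(hi)={f_hi}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if mid <= lo or mid >= hi:  # hit float resolution
            break
        if f_lo * f(mid) <= 0:
            hi = mid
        else:
            lo, f_lo = mid, f(mid)
    return 0.5 * (lo + hi)


def isotherm_intensity(C_total, params: LangmuirParams, hrs_mode: str = "free"):
    """SHG isotherm observation model.

    ``I(C) = A * (N/Nmax)**2 + alpha * M_hrs + B`` where ``N`` is the
    depletion-corrected Langmuir coverage and ``M_hrs`` is the free dye
    concentration ``C - N`` (``hrs_mode="free"``, default, attributing the
    hyper-Rayleigh term to free dye in solution) or the total ``C``
    (``hrs_mode="total"``, for sensitivity checks).

    Accepts a scalar or array ``C_total`` and returns a matching shape.
    """
    if hrs_mode not in ("free", "total"):
        raise InvalidInputError(f"hrs_mode must be 'free' or 'total', got {hrs_mode!r}")
    C = np.asarray(C_total, dtype=float)
    if np.any(~np.isfinite(C)) or np.any(C < 0):
        raise InvalidInputError("C_total must be finite and >= 0")
    n = _coverage_n(C, params.Nmax, params.K)
    m_hrs = C if hrs_mode == "total" else C - n
    out = params.A * (n / params.Nmax) ** 2 + params.alpha * m_hrs + params.B
    if np.isscalar(C_total) or np.ndim(C_total) == 0:
        return float(out)
    return out


def field_decay(t, fit: TransportFit):
    """Exponential decay of the SHG field, ``E(t) = A0 + A1 * exp(-t/tau)``."""
    if not (fit.tau > 0):
        raise InvalidInputError(f"tau must be > 0, got {fit.tau!r}")
    t_arr = np.asarray(t, dtype=float)
    out = fit.A0 + fit.A1 * np.exp(-t_arr / fit.tau)
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(out)
    return out


def adsorption_free_energy(K: float, T: float = DEFAULT_TEMPERATURE_K) -> ThermoResult:
    """Adsorption free energy ``delta_g = -R*T*ln(K)`` in kcal/mol."""
    if not (K > 0) or not math.isfinite(K):
        raise InvalidInputError(f"K must be a positive finite real, got {K!r}")
    if not (T > 0):
        raise InvalidInputError(f"T must be > 0, got {T!r}")
    return ThermoResult(delta_g=-R_KCAL_PER_MOL_K * T * math.log(K), K=K, T=T)


def lipids_per_site(lipid_conc: float, Nmax: float) -> float:
    """Number of lipid molecules per adsorption site: ``lipid_conc / Nmax``."""
    if not (Nmax > 0):
        raise InvalidInputError(f"Nmax must be > 0, got {Nmax!r}")
    if not (lipid_conc > 0):
        raise InvalidInputError(f"lipid_conc must be > 0, got {lipid_conc!r}")
    return lipid_conc / Nmax


def signal_per_coverage(A: float, Nmax: float) -> float:
    """SHG signal per squared surface coverage, ``A / Nmax**2`` (counts uM^-2)."""
    if not (Nmax > 0):
        raise InvalidInputError(f"Nmax must be > 0, got {Nmax!r}")
    return A / Nmax**2
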