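"""Synthetic SHG experiment generator with sealed ground truth.

Generates complete virtual experiments — dye-only calibration series,
dye-free baselines, emission spectra and time traces over a concentration
grid for two liposome compositions — from a known :class:`ExperimentTruth`,
so that every pipeline stage can be tested with no external data.

Generative model
----------------
Adsorption is treated as instantaneous: the total adsorbed population is
at its depletion-corrected Langmuir value from t = 0+.  A fraction ``f``
of the adsorbed dye then migrates to the inner leaflet with time constant
tau, where its opposite orientation cancels coherently:

    N_inner(t) = f * N_total * (1 - exp(-t/tau))
    N_outer(t) = N_total - N_inner(t)

giving a coherent field of single-exponential form.  Measured intensity is
the squared field plus an incoherent hyper-Rayleigh term linear in the
free dye concentration plus the dye-free baseline, with multiplicative
then additive Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core_models import (
    InterfacePopulations,
    LangmuirParams,
    SampleComposition,
    coherent_field,
    langmuir_coverage,
)
from .exceptions import ConfigError, InvalidInputError
from .kinetics import TimeTrace
from .spectral import Spectrum

__all__ = [
    "ExperimentTruth",
    "SyntheticDataset",
    "default_truth",
    "leaflet_populations",
    "simulate_trace",
    "simulate_spectrum",
    "simulate_experiment",
    "PURE_LABEL",
    "APAP_LABEL",
]

PURE_LABEL = "pure_dopc"
APAP_LABEL = "dopc_apap"

# magnitudes used as generating defaults (saturation counts, site conc uM,
# dimensionless equilibrium constant) for the two sample compositions
_DEFAULT_LANGMUIR = {
    PURE_LABEL: dict(A=174.0, Nmax=2.9, K=5e7),
    APAP_LABEL: dict(A=241.0, Nmax=3.6, K=9e7),
}
_DEFAULT_ALPHA = 5.0  # counts per uM free dye (HRS slope)
_DEFAULT_B = 2.0  # counts, dye-free liposome baseline

#: Below this dye concentration the two samples share the same transport
#: time; above it the additive-containing sample is slower.
TAU_SPLIT_UM = 3.0
_TAU_BASE_S = 250.0
_TAU_APAP_FACTOR = 1.5


@dataclass
class ExperimentTruth:
    """Sealed generating truth for one virtual experiment.

    ``tau_s`` maps sample label -> {C_total: tau}; ``partition_fraction``
    is the equilibrium fraction of adsorbed dye on the inner leaflet
    (f in [0, 0.5]; f = 0.5 means full coherent cancellation at long times).
    """

    langmuir: dict[str, LangmuirParams]
    samples: dict[str, SampleComposition]
    tau_s: dict[str, dict[float, float]]
    partition_fraction: float = 0.3
    peak_center_nm: float = 400.0
    peak_fwhm_nm: float = 4.7
    spectrum_background: float = 1.0  # flat counts floor per wavelength bin
    noise_multiplicative: float = 0.05
    noise_additive: float = 0.5  # counts
    conc_grid: tuple = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 5.0, 6.0, 7.0, 8.0)
    time_grid: tuple = tuple(np.arange(0.0, 2001.0, 10.0))
    wavelength_grid: tuple = tuple(np.round(np.arange(380.0, 420.0001, 0.1), 4))
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.partition_fraction <= 0.5):
            raise InvalidInputError("partition_fraction must be in [0, 0.5]")
        if self.noise_multiplicative < 0 or self.noise_additive < 0:
            raise InvalidInputError("noise parameters must be >= 0")
        for name in ("conc_grid", "time_grid", "wavelength_grid"):
            g = np.asarray(getattr(self, name), dtype=float)
            if np.any(np.diff(g) <= 0):
                raise InvalidInputError(f"{name} must be strictly increasing")

    def tau(self, sample: str, C_total: float) -> float:
        try:
            return self.tau_s[sample][float(C_total)]
        except KeyError as exc:
            raise ConfigError(f"no tau for sample {sample!r} at C={C_total}") from exc


@dataclass
class SyntheticDataset:
    """One complete virtual experiment with its sealed truth.

    ``truth`` is carried for verification only; fitting stages must never
    read it.
    """

    traces: list[TimeTrace]
    dye_only: list[tuple[float, Spectrum]]  # (C_uM, spectrum) HRS calibration
    dye_free: dict[str, list[Spectrum]]  # sample label -> baseline spectra
    spectra: list[Spectrum]  # representative dye-present spectra
    truth: ExperimentTruth


def default_truth(seed: int = 0, noise_multiplicative: float | None = None,
                  noise_additive: float | None = None,
                  partition_fraction: float = 0.3) -> ExperimentTruth:
    """Documented default truth at the magnitudes of the studied system.

    The parameters themselves are deterministic; ``seed`` controls only
    the noise stream of the simulators.
    """
    langmuir = {
        label: LangmuirParams(alpha=_DEFAULT_ALPHA, B=_DEFAULT_B, **kw)
        for label, kw in _DEFAULT_LANGMUIR.items()
    }
    samples = {
        PURE_LABEL: SampleComposition(lipid_conc=75.0, apap_conc=0.0, label=PURE_LABEL),
        APAP_LABEL: SampleComposition(lipid_conc=75.0, apap_conc=25.0, label=APAP_LABEL),
    }
    truth = ExperimentTruth(langmuir=langmuir, samples=samples, tau_s={}, seed=seed,
                            partition_fraction=partition_fraction)
    tau_s: dict[str, dict[float, float]] = {PURE_LABEL: {}, APAP_LABEL: {}}
    for c in truth.conc_grid:
        tau_s[PURE_LABEL][float(c)] = _TAU_BASE_S
        slow = c > TAU_SPLIT_UM
        tau_s[APAP_LABEL][float(c)] = _TAU_BASE_S * (_TAU_APAP_FACTOR if slow else 1.0)
    truth.tau_s = tau_s
    if noise_multiplicative is not None:
        truth.noise_multiplicative = noise_multiplicative
    if noise_additive is not None:
        truth.noise_additive = noise_additive
    return truth


def leaflet_populations(t: float, C_total: float, truth: ExperimentTruth,
                        sample: str) -> InterfacePopulations:
    """Outer/inner leaflet populations at time t for the two-leaflet model."""
    if t < 0:
        raise InvalidInputError(f"t must be >= 0, got {t!r}")
    p = truth.langmuir[sample]
    n_total = langmuir_coverage(C_total, p.Nmax, p.K).N_adsorbed
    tau = truth.tau(sample, C_total)
    f = truth.partition_fraction
    n_inner = f * n_total * (1.0 - math.exp(-t / tau))
    return InterfacePopulations(n_outer=n_total - n_inner, n_inner=n_inner)


def _field_prefactor(p: LangmuirParams) -> float:
    # normalization: intensity at full outer coverage (N_total = Nmax,
    # N_inner = 0) equals the saturation intensity A
    return math.sqrt(p.A) / p.Nmax


def _apply_noise(values: np.ndarray, truth: ExperimentTruth,
                 rng: np.random.Generator) -> np.ndarray:
    out = values * (1.0 + truth.noise_multiplicative * rng.standard_normal(values.shape))
    out = out + truth.noise_additive * rng.standard_normal(values.shape)
    return out


def simulate_trace(C_total: float, sample: str, truth: ExperimentTruth,
                   rng: np.random.Generator | None = None) -> TimeTrace:
    """Simulate one SHG time trace at a grid concentration.

    Zero-noise traces satisfy, by construction,
    ``I(t) = (A0 + A1 exp(-t/tau))**2 + alpha*M_free + B`` with
    ``(A0 + A1)**2 + alpha*M_free + B`` equal to the isotherm observation
    model at ``C_total``.
    """
    if float(C_total) not in {float(c) for c in truth.conc_grid}:
        raise ConfigError(f"C_total={C_total} not in truth.conc_grid")
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    p = truth.langmuir[sample]
    cov = langmuir_coverage(C_total, p.Nmax, p.K)
    k = _field_prefactor(p)
    t = np.asarray(truth.time_grid, dtype=float)
    tau = truth.tau(sample, C_total)
    f = truth.partition_fraction
    n_total = cov.N_adsorbed
    # field(t) = k * (N_outer - N_inner) = k*n_total*(1 - 2f) + k*n_total*2f*exp(-t/tau)
    e_field = np.array([
        coherent_field(
            InterfacePopulations(
                n_outer=n_total - f * n_total * (1.0 - np.exp(-ti / tau)),
                n_inner=f * n_total * (1.0 - np.exp(-ti / tau)),
            ),
            prefactor=k,
        )
        for ti in t
    ]) if n_total > 0 else np.zeros_like(t)
    intensity = e_field**2 + p.alpha * cov.M_free + p.B
    intensity = _apply_noise(intensity, truth, rng)
    return TimeTrace(times=t, intensity=intensity, C_total=float(C_total),
                     sample=truth.samples[sample])


def simulate_spectrum(total_intensity: float, truth: ExperimentTruth,
                      rng: np.random.Generator | None = None,
                      meta: dict | None = None) -> Spectrum:
    """Gaussian emission peak whose integrated area equals ``total_intensity``.

    A flat background floor and the truth's noise model are added on top;
    :func:`shgsorb.spectral.integrate_peak` recovers ``total_intensity``
    to within the noise.
    """
    if total_intensity < 0:
        raise InvalidInputError("total_intensity must be >= 0")
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    lam = np.asarray(truth.wavelength_grid, dtype=float)
    sigma = truth.peak_fwhm_nm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    peak = (total_intensity / (sigma * math.sqrt(2.0 * math.pi))) * np.exp(
        -0.5 * ((lam - truth.peak_center_nm) / sigma) ** 2
    )
    counts = _apply_noise(peak + truth.spectrum_background, truth, rng)
    return Spectrum(wavelengths=lam, counts=counts, meta=dict(meta or {}))


def simulate_experiment(truth: ExperimentTruth) -> SyntheticDataset:
    """Generate the full virtual experiment; deterministic under truth.seed.

    Produces a time trace for every (sample, concentration) pair, a
    dye-only hyper-Rayleigh calibration series over the grid, dye-free
    baseline spectra per sample, and representative dye-present spectra.
    """
    rng = np.random.default_rng(truth.seed)
    traces = [
        simulate_trace(c, label, truth, rng)
        for label in sorted(truth.langmuir)
        for c in truth.conc_grid
    ]
    alpha = next(iter(truth.langmuir.values())).alpha
    dye_only = [
        (float(c), simulate_spectrum(alpha * float(c), truth, rng,
                                     meta={"sample": "dye_only", "dye_uM": float(c)}))
        for c in truth.conc_grid
    ]
    dye_free = {
        label: [
            simulate_spectrum(truth.langmuir[label].B, truth, rng,
                              meta={"sample": label, "dye_uM": 0.0, "replicate": i})
            for i in range(3)
        ]
        for label in sorted(truth.langmuir)
    }
    # representative dye-present spectra at the largest grid concentration
    c_rep = float(truth.conc_grid[-1])
    spectra = []
    for label in sorted(truth.langmuir):
        p = truth.langmuir[label]
        cov = langmuir_coverage(c_rep, p.Nmax, p.K)
        i0 = p.A * (cov.N_adsorbed / p.Nmax) ** 2 + p.alpha * cov.M_free + p.B
        spectra.append(simulate_spectrum(i0, truth, rng,
                                         meta={"sample": label, "dye_uM": c_rep,
                                               "time_s": 0.0}))
    return SyntheticDataset(traces=traces, dye_only=dye_only, dye_free=dye_free,
                            spectra=spectra, truth=truth)
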