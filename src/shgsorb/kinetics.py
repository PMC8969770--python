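"""Transport-kinetics fitting of SHG time traces.

Time traces are fit in the field domain (square root of intensity) to a
single-exponential decay ``E(t) = A0 + A1 * exp(-t / tau)`` to extract the
membrane transport time ``tau`` and the extrapolated time-zero intensity
used to assemble adsorption isotherms.

When the measured intensity carries a constant incoherent pedestal (the
hyper-Rayleigh term plus the dye-free baseline) under the squared coherent
field, the fitted model becomes ``sqrt((A0 + A1 e^{-t/tau})^2 + bg)``; the
pedestal ``bg`` can be fixed or co-fitted (``background="fit"``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .core_models import SampleComposition, TransportFit
from .exceptions import FitError, InsufficientDataError, InvalidInputError

__all__ = [
    "TimeTrace",
    "FieldTrace",
    "intensity_to_field",
    "fit_transport",
    "time_zero_intensity",
    "transport_table",
]

log = logging.getLogger(__name__)

TRANSPORT_TABLE_COLUMNS = ["sample", "C_total_uM", "tau_s", "tau_stderr_s"]


@dataclass
class TimeTrace:
    """Intensity vs time after dye addition at a known total dye concentration."""

    times: np.ndarray  # s, strictly increasing, t=0 at dye addition
    intensity: np.ndarray  # counts
    C_total: float  # uM
    sample: SampleComposition

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        if t.ndim != 1 or i.ndim != 1 or t.size != i.size:
            raise InvalidInputError("times and intensity must be 1-D of equal length")
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if not np.all(np.isfinite(i)):
            raise InvalidInputError("intensity must be finite")
        if not (self.C_total > 0):
            raise InvalidInputError(f"C_total must be > 0, got {self.C_total!r}")
        self.times = t
        self.intensity = i


@dataclass
class FieldTrace:
    """Square-root (field-domain) transform of a time trace."""

    times: np.ndarray
    field: np.ndarray
    clamp_count: int = 0


def intensity_to_field(trace: TimeTrace) -> FieldTrace:
    """Pointwise ``sqrt(max(intensity, 0))``; counts clamped points."""
    neg = trace.intensity < 0
    return FieldTrace(
        times=trace.times,
        field=np.sqrt(np.clip(trace.intensity, 0.0, None)),
        clamp_count=int(neg.sum()),
    )


def _init_exponential(t: np.ndarray, f: np.ndarray) -> tuple[float, float, float]:
    """Initial (A0, A1, tau): tail mean, first-point excess, 1/e crossing time."""
    n_tail = max(1, t.size // 10)
    a0 = float(np.mean(f[-n_tail:]))
    a1 = float(f[0] - a0)
    target = a0 + a1 / np.e
    tau0 = None
    if abs(a1) > 0:
        # first crossing of the 1/e level, linear interpolation
        sign = np.sign(a1)
        below = sign * (f - target) <= 0
        idx = np.nonzero(below)[0]
        if idx.size and idx[0] > 0:
            k = idx[0]
            f0, f1 = f[k - 1], f[k]
            if f1 != f0:
                frac = (target - f0) / (f1 - f0)
                tau0 = float(t[k - 1] + frac * (t[k] - t[k - 1]))
    if tau0 is None or tau0 <= 0:
        tau0 = float((t[-1] - t[0]) / 3.0) or 1.0
    return a0, a1, tau0


def fit_transport(
    trace: TimeTrace,
    weighting: str = "uniform",
    background: float | str = 0.0,
    domain: str = "field",
) -> TransportFit:
    """Nonlinear least-squares fit of the exponential field decay.

    Parameters
    ----------
    trace : TimeTrace
        Measured intensity trace (>= 6 points).
    weighting : {"uniform", "poisson"}
        ``uniform`` weights all points equally.  ``poisson`` weights
        intensity-domain residuals by ``1/sqrt(max(I, 1))``; in the field
        domain the square-root transform already variance-stabilizes shot
        noise, so ``poisson`` only differs for ``domain="intensity"``.
    background : float or "fit"
        Constant intensity pedestal under the squared field.  A float is
        held fixed (default 0, the pure exponential); ``"fit"`` co-fits it
        with a non-negativity bound.
    domain : {"field", "intensity"}
        Residual domain.  Default fits ``sqrt(I)``; ``intensity`` fits the
        squared model to raw counts (sensitivity-analysis option).

    Returns
    -------
    TransportFit
        With ``param_cov`` the 3x3 covariance of (A0, A1, tau) and an
        ``unresolved_decay`` flag when the decay is not resolved by the
        trace (near-zero amplitude or tau >> trace span).
    """
    if weighting not in ("uniform", "poisson"):
        raise InvalidInputError(f"unknown weighting {weighting!r}")
    if domain not in ("field", "intensity"):
        raise InvalidInputError(f"unknown domain {domain!r}")
    if trace.times.size < 6:
        raise InsufficientDataError(f"need >= 6 points, got {trace.times.size}")

    fit_bg = background == "fit"
    if not fit_bg:
        bg_fixed = float(background)
        if bg_fixed < 0:
            raise InvalidInputError("fixed background must be >= 0")

    ft = intensity_to_field(trace)
    t, f_meas = ft.times, ft.field
    span = float(t[-1] - t[0])

    a0_init, a1_init, tau_init = _init_exponential(t, f_meas)
    if fit_bg:
        x0 = np.array([a0_init, a1_init, tau_init, 0.0])
        lb = [-np.inf, -np.inf, 1e-9, 0.0]
        ub = [np.inf, np.inf, np.inf, np.inf]
    else:
        x0 = np.array([a0_init, a1_init, tau_init])
        lb = [-np.inf, -np.inf, 1e-9]
        ub = [np.inf, np.inf, np.inf]

    if weighting == "poisson" and domain == "intensity":
        sigma = np.sqrt(np.clip(trace.intensity, 1.0, None))
    else:
        sigma = np.ones_like(f_meas)

    def residuals(x):
        a0, a1, tau = x[0], x[1], x[2]
        bg = x[3] if fit_bg else bg_fixed
        e = a0 + a1 * np.exp(-t / tau)
        model_i = e * e + bg
        if domain == "intensity":
            return (model_i - trace.intensity) / sigma
        return (np.sqrt(np.clip(model_i, 0.0, None)) - f_meas) / sigma

    try:
        sol = least_squares(residuals, x0, bounds=(lb, ub), method="trf",
                            xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=20000)
    except Exception as exc:
        raise FitError(f"transport fit failed: {exc}",
                       diagnostics={"x0": list(x0)}) from exc
    if not sol.success and not np.isfinite(sol.cost):
        raise FitError("transport fit did not converge",
                       diagnostics={"status": sol.status, "message": sol.message})

    x = sol.x
    a0, a1, tau = (float(v) for v in x[:3])
    bg = float(x[3]) if fit_bg else bg_fixed
    rss = float(2.0 * sol.cost)
    n, p = t.size, x.size
    dof = max(n - p, 1)
    jtj = sol.jac.T @ sol.jac
    cov_full = np.linalg.pinv(jtj) * (rss / dof)
    cov3 = cov_full[:3, :3]
    bg_stderr = float(np.sqrt(max(cov_full[3, 3], 0.0))) if fit_bg else 0.0

    field_scale = max(abs(a0), abs(a0 + a1), 1e-12)
    unresolved = tau > 100.0 * span or abs(a1) < 1e-6 * field_scale
    if unresolved:
        log.debug("unresolved decay: tau=%.3g span=%.3g A1=%.3g", tau, span, a1)

    return TransportFit(A0=a0, A1=a1, tau=tau, param_cov=cov3, rss=rss,
                        background=bg, background_stderr=bg_stderr,
                        clamp_count=ft.clamp_count, unresolved_decay=unresolved)


def time_zero_intensity(fit: TransportFit, with_sigma: bool = False):
    """Extrapolated intensity at t=0: ``(A0 + A1)**2 + background``.

    With ``with_sigma=True`` returns ``(I0, sigma)`` where sigma is a
    first-order delta-method propagation through the (A0, A1) covariance
    block plus the independent background variance.
    """
    s = fit.A0 + fit.A1
    i0 = s * s + fit.background
    if not with_sigma:
        return float(i0)
    g = np.array([2.0 * s, 2.0 * s, 0.0])
    var = float(g @ fit.param_cov @ g) + fit.background_stderr**2
    return float(i0), float(np.sqrt(max(var, 0.0)))


def transport_table(traces: list[TimeTrace], **fit_kwargs) -> pd.DataFrame:
    """Fit every trace and tabulate tau per (sample, concentration).

    Duplicate (sample, C_total) pairs are aggregated by the mean with a
    combined standard error; rows are sorted by (sample, C_total).
    """
    rows = []
    for trace in traces:
        fit = fit_transport(trace, **fit_kwargs)
        tau_err = float(np.sqrt(max(fit.param_cov[2, 2], 0.0)))
        rows.append({"sample": trace.sample.label, "C_total_uM": trace.C_total,
                     "tau_s": fit.tau, "tau_stderr_s": tau_err})
    df = pd.DataFrame(rows, columns=TRANSPORT_TABLE_COLUMNS)
    if df.empty:
        return df
    grouped = df.groupby(["sample", "C_total_uM"], sort=True)
    for key, n in grouped.size().items():
        if n > 1:
            log.info("aggregating %d duplicate traces for %s", n, key)
    out = grouped.agg(
        tau_s=("tau_s", "mean"),
        tau_stderr_s=("tau_stderr_s",
                      lambda s: float(np.sqrt(np.sum(s.to_numpy() ** 2))) / s.size),
    ).reset_index()
    return out[TRANSPORT_TABLE_COLUMNS]
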