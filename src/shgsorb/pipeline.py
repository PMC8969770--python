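"""Config-driven orchestration: simulate/ingest -> calibrate -> kinetics -> isotherm -> report.

The pipeline runs the stages in a fixed order, persists every intermediate
under the output directory, and produces a machine-readable report whose
derived quantities re-derive exactly from the stored fit parameters.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .constants import DEFAULT_TEMPERATURE_K
from .core_models import TransportFit
from .exceptions import ConfigError, InsufficientDataError, StageError
from .io import read_dataset, write_dataset, write_json
from .isotherm import (
    DerivedReport,
    IsothermFitResult,
    assemble_isotherm,
    bootstrap_uncertainties,
    derived_report,
    fit_modified_langmuir,
)
from .kinetics import fit_transport, transport_table
from .spectral import baseline_offset, hrs_calibration
from .synthetic import SyntheticDataset, default_truth, simulate_experiment

__all__ = ["RunConfig", "RunReport", "run_pipeline", "compare_samples",
           "report_to_dict", "report_table"]

log = logging.getLogger(__name__)

TABLE_COLUMNS = [
    "sample", "A", "A_err", "K", "K_err", "Nmax_uM", "Nmax_err",
    "lipid_per_site", "lipid_per_site_err", "deltaG_kcal_mol", "deltaG_err", "T_K",
]


@dataclass
class RunConfig:
    """Run configuration; CLI flags override file values override defaults."""

    mode: str = "simulate"  # or "analyze"
    input_dir: str | None = None  # required for analyze
    out_dir: str | None = None
    seed: int = 0
    temperature_k: float = DEFAULT_TEMPERATURE_K
    peak_center_nm: float = 400.0
    half_window_nm: float = 10.0
    weighting: str = "uniform"
    hrs_mode: str = "free"
    bootstrap: int = 0  # n_boot; 0 disables the bootstrap stage
    noise_multiplicative: float | None = None  # simulate-mode truth overrides
    noise_additive: float | None = None
    partition_fraction: float = 0.3

    def __post_init__(self):
        if self.mode not in ("simulate", "analyze"):
            raise ConfigError(f"mode must be 'simulate' or 'analyze', got {self.mode!r}")
        if self.mode == "analyze" and not self.input_dir:
            raise ConfigError("analyze mode requires input_dir")
        if not (self.temperature_k > 0):
            raise ConfigError("temperature_k must be > 0")
        if self.hrs_mode not in ("free", "total"):
            raise ConfigError(f"hrs_mode must be 'free' or 'total', got {self.hrs_mode!r}")

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "RunConfig":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Per-sample fits and derived quantities plus run provenance."""

    calibration: dict  # alpha, intercept, r_squared, B per sample
    transport: pd.DataFrame
    fits: dict  # sample label -> IsothermFitResult
    derived: dict  # sample label -> DerivedReport
    provenance: dict = field(default_factory=dict)


def _stage(name: str, out_dir: Path | None):
    """Decorator-free stage guard: wraps exceptions into StageError."""

    class _Guard:
        def __enter__(self):
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is None:
                log.info("stage %s: ok", name)
                return False
            if isinstance(exc, StageError):
                return False
            if out_dir is not None:
                out_dir.mkdir(parents=True, exist_ok=True)
                write_json({"failed_stage": name, "error": str(exc)},
                           out_dir / "failure.json")
            raise StageError(name, str(exc)) from exc

    return _Guard()


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages in order and return the final report.

    Idempotent under identical config and seed; all intermediates are
    persisted when ``config.out_dir`` is set.  Any stage failure raises
    :class:`StageError` naming the stage; partial outputs are retained
    next to a ``failure.json`` marker.
    """
    out = Path(config.out_dir) if config.out_dir else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    with _stage("ingest", out):
        if config.mode == "simulate":
            truth = default_truth(
                seed=config.seed,
                noise_multiplicative=config.noise_multiplicative,
                noise_additive=config.noise_additive,
                partition_fraction=config.partition_fraction,
            )
            ds = simulate_experiment(truth)
            if out is not None:
                write_dataset(ds, out / "dataset")
        else:
            ds = read_dataset(config.input_dir)

    report = analyze_dataset(ds, config)
    report.provenance["mode"] = config.mode
    if out is not None:
        persist_report(report, out)
    return report


def analyze_dataset(ds: SyntheticDataset, config: RunConfig) -> RunReport:
    """Run calibration, kinetics, isotherm and report stages on a dataset."""
    out = Path(config.out_dir) if config.out_dir else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    with _stage("calibration", out):
        if not ds.dye_only:
            raise InsufficientDataError("dataset has no dye-only calibration series")
        cal = hrs_calibration(ds.dye_only, config.peak_center_nm, config.half_window_nm)
        b_per_sample = {
            label: baseline_offset(specs, config.peak_center_nm, config.half_window_nm)
            for label, specs in sorted(ds.dye_free.items())
        }
        calibration = {"alpha": cal.alpha, "intercept": cal.intercept,
                       "r_squared": cal.r_squared, "B": b_per_sample}
        if out is not None:
            write_json(calibration, out / "calibration.json")

    with _stage("kinetics", out):
        fits_by_sample: dict[str, list[tuple[float, TransportFit]]] = {}
        for trace in ds.traces:
            fit = fit_transport(trace, weighting=config.weighting, background="fit")
            fits_by_sample.setdefault(trace.sample.label, []).append((trace.C_total, fit))
        ttable = transport_table(ds.traces, weighting=config.weighting,
                                 background="fit")
        if out is not None:
            ttable.to_csv(out / "transport_table.csv", index=False)

    with _stage("isotherm", out):
        sample_by_label = {t.sample.label: t.sample for t in ds.traces}
        fits: dict[str, IsothermFitResult] = {}
        derived: dict[str, DerivedReport] = {}
        for label, cfits in sorted(fits_by_sample.items()):
            sample = sample_by_label[label]
            iso = assemble_isotherm(cfits, sample, alpha=calibration["alpha"],
                                    B=b_per_sample.get(label, 0.0))
            res = fit_modified_langmuir(iso, hrs_mode=config.hrs_mode,
                                        seed=config.seed)
            if config.bootstrap:
                res = bootstrap_uncertainties(iso, res, n_boot=config.bootstrap,
                                              seed=config.seed)
            fits[label] = res
            derived[label] = derived_report(res, sample, T=config.temperature_k)
            if out is not None:
                write_json(_fit_to_dict(res), out / f"isotherm_{label}.json")

    report = RunReport(
        calibration=calibration, transport=ttable, fits=fits, derived=derived,
        provenance={"config": config.to_dict(), "config_hash": config.digest(),
                    "seed": config.seed, "version": __version__},
    )
    return report


def _fit_to_dict(res: IsothermFitResult) -> dict:
    d = {
        "params": asdict(res.params),
        "param_stderr": res.param_stderr,
        "param_cov": np.asarray(res.param_cov).tolist(),
        "rss": res.rss,
        "saturation_unidentified": res.saturation_unidentified,
        "hrs_mode": res.hrs_mode,
    }
    if res.bootstrap_intervals:
        d["bootstrap_intervals"] = {k: list(v) for k, v in res.bootstrap_intervals.items()}
    return d


def report_to_dict(report: RunReport) -> dict:
    """JSON-ready view of a run report (deterministic key order when dumped)."""
    samples = {}
    for label in sorted(report.fits):
        res = report.fits[label]
        der = report.derived[label]
        samples[label] = {
            "fit": _fit_to_dict(res),
            "derived": {
                "deltaG_kcal_mol": der.delta_g, "deltaG_err": der.delta_g_err,
                "lipid_per_site": der.lipids_per_site,
                "lipid_per_site_err": der.lipids_per_site_err,
                "signal_per_coverage_uM-2": der.signal_per_coverage,
                "signal_per_coverage_err": der.signal_per_coverage_err,
                "T_K": der.T,
            },
        }
    return {
        "calibration": report.calibration,
        "transport_table": report.transport.to_dict(orient="records"),
        "samples": samples,
        "provenance": report.provenance,
    }


def report_table(report: RunReport) -> pd.DataFrame:
    """Flat per-sample parameter table (one row per sample)."""
    rows = []
    for label in sorted(report.fits):
        res, der = report.fits[label], report.derived[label]
        p, se = res.params, res.param_stderr
        rows.append({
            "sample": label,
            "A": p.A, "A_err": se["A"],
            "K": p.K, "K_err": se["K"],
            "Nmax_uM": p.Nmax, "Nmax_err": se["Nmax"],
            "lipid_per_site": der.lipids_per_site,
            "lipid_per_site_err": der.lipids_per_site_err,
            "deltaG_kcal_mol": der.delta_g, "deltaG_err": der.delta_g_err,
            "T_K": der.T,
        })
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def persist_report(report: RunReport, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_json(report_to_dict(report), out / "report.json")
    report_table(report).to_csv(out / "report_table.csv", index=False)
    comparison = compare_samples(report) if len(report.fits) >= 2 else None
    if comparison is not None:
        write_json(comparison, out / "comparison.json")


def compare_samples(report: RunReport) -> dict:
    """Pairwise differences of K, Nmax, deltaG and tau-by-concentration.

    Differences exceeding one combined standard deviation are flagged.
    """
    labels = sorted(report.fits)
    if len(labels) < 2:
        raise InsufficientDataError("need >= 2 samples to compare")
    pairs = {}
    for a, b in itertools.combinations(labels, 2):
        ra, rb = report.fits[a], report.fits[b]
        da, db = report.derived[a], report.derived[b]
        entry = {}
        for name, (va, sa_), (vb, sb_) in (
            ("K", (ra.params.K, ra.param_stderr["K"]), (rb.params.K, rb.param_stderr["K"])),
            ("Nmax", (ra.params.Nmax, ra.param_stderr["Nmax"]),
             (rb.params.Nmax, rb.param_stderr["Nmax"])),
            ("deltaG", (da.delta_g, da.delta_g_err), (db.delta_g, db.delta_g_err)),
        ):
            diff = vb - va
            sigma = float(np.sqrt(sa_**2 + sb_**2))
            entry[name] = {"difference": diff, "sigma": sigma,
                           "significant": bool(abs(diff) > sigma)}
        # tau comparison on shared concentrations
        tt = report.transport
        ta = tt[tt["sample"] == a].set_index("C_total_uM")
        tb = tt[tt["sample"] == b].set_index("C_total_uM")
        shared = sorted(set(ta.index) & set(tb.index))
        tau_rows = []
        for c in shared:
            diff = float(tb.loc[c, "tau_s"] - ta.loc[c, "tau_s"])
            sigma = float(np.sqrt(ta.loc[c, "tau_stderr_s"] ** 2
                                  + tb.loc[c, "tau_stderr_s"] ** 2))
            tau_rows.append({"C_total_uM": float(c), "difference_s": diff,
                             "sigma_s": sigma,
                             "significant": bool(abs(diff) > sigma)})
        entry["tau_by_concentration"] = tau_rows
        pairs[f"{a}__vs__{b}"] = entry
    return pairs
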