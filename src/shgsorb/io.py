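"""Plain-text I/O for spectra, time traces, synthetic datasets and reports.

File dialects
-------------
Spectrum: two-column CSV ``wavelength_nm,counts`` with metadata either as
embedded ``# key=value`` comment lines or a ``<name>.json`` sidecar (both
read; the comment dialect is written).

Time trace: two-column CSV ``time_s,intensity_counts`` with ``# sample=``,
``# dye_uM=``, ``# lipid_uM=``, ``# apap_uM=`` comment headers.

Synthetic dataset: a directory with ``traces/``, ``spectra/``,
``calibration/``, ``truth.json`` and ``manifest.json``.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .core_models import LangmuirParams, SampleComposition
from .exceptions import InvalidInputError
from .kinetics import TimeTrace
from .spectral import Spectrum
from .synthetic import ExperimentTruth, SyntheticDataset

__all__ = [
    "write_spectrum", "read_spectrum",
    "write_trace", "read_trace",
    "truth_to_dict", "truth_from_dict",
    "write_dataset", "read_dataset",
    "write_json", "read_json",
]

_FLOAT_FMT = "%.17g"  # lossless round trip for doubles
SCHEMA_VERSION = 1


def _parse_meta_value(v: str):
    try:
        return json.loads(v)
    except (json.JSONDecodeError, ValueError):
        return v


def _write_two_column(path: Path, header: str, col1, col2, meta: dict):
    lines = [f"# {k}={json.dumps(v) if not isinstance(v, str) else v}"
             for k, v in sorted(meta.items())]
    lines.append(header)
    for a, b in zip(col1, col2):
        lines.append(f"{_FLOAT_FMT % a},{_FLOAT_FMT % b}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _read_two_column(path: Path, expected_header: str):
    meta: dict = {}
    rows = []
    header_seen = False
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                k, _, v = body.partition("=")
                meta[k.strip()] = _parse_meta_value(v.strip())
            continue
        if not header_seen:
            if line.replace(" ", "") != expected_header:
                raise InvalidInputError(
                    f"{path}: expected header {expected_header!r}, got {line!r}")
            header_seen = True
            continue
        a, _, b = line.partition(",")
        rows.append((float(a), float(b)))
    if not rows:
        raise InvalidInputError(f"{path}: no data rows")
    arr = np.array(rows, dtype=float)
    return arr[:, 0], arr[:, 1], meta


def write_spectrum(s: Spectrum, path: str | Path) -> None:
    _write_two_column(Path(path), "wavelength_nm,counts",
                      s.wavelengths, s.counts, s.meta)


def read_spectrum(path: str | Path) -> Spectrum:
    path = Path(path)
    w, c, meta = _read_two_column(path, "wavelength_nm,counts")
    sidecar = path.with_suffix(".json")
    if sidecar.exists() and sidecar != path:
        meta = {**json.loads(sidecar.read_text(encoding="utf-8")), **meta}
    return Spectrum(wavelengths=w, counts=c, meta=meta)


def write_trace(trace: TimeTrace, path: str | Path) -> None:
    meta = {
        "sample": trace.sample.label,
        "dye_uM": trace.C_total,
        "lipid_uM": trace.sample.lipid_conc,
        "apap_uM": trace.sample.apap_conc,
    }
    _write_two_column(Path(path), "time_s,intensity_counts",
                      trace.times, trace.intensity, meta)


def read_trace(path: str | Path) -> TimeTrace:
    t, i, meta = _read_two_column(Path(path), "time_s,intensity_counts")
    for key in ("sample", "dye_uM", "lipid_uM"):
        if key not in meta:
            raise InvalidInputError(f"{path}: missing required header '# {key}='")
    sample = SampleComposition(lipid_conc=float(meta["lipid_uM"]),
                               apap_conc=float(meta.get("apap_uM", 0.0)),
                               label=str(meta["sample"]))
    return TimeTrace(times=t, intensity=i, C_total=float(meta["dye_uM"]), sample=sample)


# ---------------------------------------------------------------------------
# Truth / dataset serialization
# ---------------------------------------------------------------------------


def truth_to_dict(truth: ExperimentTruth) -> dict:
    d = {
        "schema_version": SCHEMA_VERSION,
        "langmuir": {k: asdict(v) for k, v in sorted(truth.langmuir.items())},
        "samples": {k: asdict(v) for k, v in sorted(truth.samples.items())},
        "tau_s": {k: {_FLOAT_FMT % c: tau for c, tau in sorted(v.items())}
                  for k, v in sorted(truth.tau_s.items())},
        "partition_fraction": truth.partition_fraction,
        "peak_center_nm": truth.peak_center_nm,
        "peak_fwhm_nm": truth.peak_fwhm_nm,
        "spectrum_background": truth.spectrum_background,
        "noise_multiplicative": truth.noise_multiplicative,
        "noise_additive": truth.noise_additive,
        "conc_grid": [float(c) for c in truth.conc_grid],
        "time_grid": [float(t) for t in truth.time_grid],
        "wavelength_grid": [float(w) for w in truth.wavelength_grid],
        "seed": truth.seed,
    }
    return d


def truth_from_dict(d: dict) -> ExperimentTruth:
    return ExperimentTruth(
        langmuir={k: LangmuirParams(**v) for k, v in d["langmuir"].items()},
        samples={k: SampleComposition(**v) for k, v in d["samples"].items()},
        tau_s={k: {float(c): float(tau) for c, tau in v.items()}
               for k, v in d["tau_s"].items()},
        partition_fraction=d["partition_fraction"],
        peak_center_nm=d["peak_center_nm"],
        peak_fwhm_nm=d["peak_fwhm_nm"],
        spectrum_background=d["spectrum_background"],
        noise_multiplicative=d["noise_multiplicative"],
        noise_additive=d["noise_additive"],
        conc_grid=tuple(d["conc_grid"]),
        time_grid=tuple(d["time_grid"]),
        wavelength_grid=tuple(d["wavelength_grid"]),
        seed=int(d["seed"]),
    )


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text(encoding="utf-8"))


def _conc_tag(c: float) -> str:
    return ("%g" % c).replace(".", "p")


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> None:
    """Write a synthetic dataset as a directory of plain-text files."""
    out = Path(out_dir)
    (out / "traces").mkdir(parents=True, exist_ok=True)
    (out / "spectra").mkdir(exist_ok=True)
    (out / "calibration").mkdir(exist_ok=True)
    manifest = {"schema_version": SCHEMA_VERSION, "seed": ds.truth.seed,
                "traces": [], "spectra": [], "dye_only": [], "dye_free": []}
    for trace in ds.traces:
        name = f"traces/{trace.sample.label}_C{_conc_tag(trace.C_total)}.csv"
        write_trace(trace, out / name)
        manifest["traces"].append(name)
    for c, spec in ds.dye_only:
        name = f"calibration/dye_only_C{_conc_tag(c)}.csv"
        write_spectrum(spec, out / name)
        manifest["dye_only"].append(name)
    for label, specs in sorted(ds.dye_free.items()):
        for i, spec in enumerate(specs):
            name = f"calibration/dye_free_{label}_{i}.csv"
            write_spectrum(spec, out / name)
            manifest["dye_free"].append(name)
    for i, spec in enumerate(ds.spectra):
        name = f"spectra/spectrum_{i}_{spec.meta.get('sample', 'unknown')}.csv"
        write_spectrum(spec, out / name)
        manifest["spectra"].append(name)
    write_json(truth_to_dict(ds.truth), out / "truth.json")
    write_json(manifest, out / "manifest.json")


def read_dataset(in_dir: str | Path) -> SyntheticDataset:
    """Read a dataset directory written by :func:`write_dataset`."""
    src = Path(in_dir)
    manifest = read_json(src / "manifest.json")
    truth = truth_from_dict(read_json(src / "truth.json"))
    traces = [read_trace(src / name) for name in manifest["traces"]]
    dye_only = []
    for name in manifest["dye_only"]:
        spec = read_spectrum(src / name)
        dye_only.append((float(spec.meta["dye_uM"]), spec))
    dye_free: dict[str, list[Spectrum]] = {}
    for name in manifest["dye_free"]:
        spec = read_spectrum(src / name)
        dye_free.setdefault(str(spec.meta["sample"]), []).append(spec)
    spectra = [read_spectrum(src / name) for name in manifest["spectra"]]
    return SyntheticDataset(traces=traces, dye_only=dye_only, dye_free=dye_free,
                            spectra=spectra, truth=truth)
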