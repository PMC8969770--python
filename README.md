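# shgsorb

Analysis pipeline for second-harmonic-generation (SHG) spectroscopy of dye
adsorption and translocation at colloidal liposome surfaces:

- **Depletion-corrected Langmuir isotherm fitting.** Time-zero SHG
  intensities vs total dye concentration are fit to an observation model
  `I(C) = A (N/Nmax)^2 + alpha (C - N) + B`, where the coverage `N` solves
  the Langmuir equilibrium with explicit bulk depletion (referenced to the
  55.5 M molarity of water), `alpha` is the hyper-Rayleigh (HRS) slope
  calibrated from dye-only controls, and `B` the dye-free baseline.
- **Transport kinetics.** Time traces are fit in the field domain
  (square root of intensity) to `E(t) = A0 + A1 exp(-t/tau)` to extract
  membrane transport times and extrapolated time-zero intensities.
- **Derived thermodynamics.** `deltaG = -RT ln K`, lipids per adsorption
  site (`lipid/Nmax`), and SHG signal per squared coverage (`A/Nmax^2`),
  with covariance-based and bootstrap uncertainties.
- **Synthetic experiment generator.** A seeded two-leaflet generative
  model (instantaneous adsorption, exponential outer-to-inner migration
  with coherent cancellation) produces complete virtual experiments —
  spectra, calibration series, time traces — with sealed ground truth, so
  every stage is testable end to end with no external data.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (identity checks
against reference parameter values, round-trip parameter recovery at
realistic noise, property suites).

## CLI

```sh
# full pipeline: simulate a virtual experiment, analyze, report
shgsorb run --seed 1 --out results/run1

# stage by stage
shgsorb simulate --seed 1 --out work
shgsorb calibrate    --data work/dataset --out work/stages
shgsorb fit-kinetics --data work/dataset --out work/stages
shgsorb fit-isotherm --intermediates work/stages
shgsorb report       --data work/dataset --out work/report
```

Flags: `--config PATH` (JSON run config), `--seed INT`,
`--temperature-k FLOAT` (default 293), `--bootstrap INT`,
`--hrs-mode {free|total}` (HRS term uses free `C - N` or total `C` dye).
Outputs are JSON plus a flat CSV parameter table
(`sample, A, A_err, K, K_err, Nmax_uM, Nmax_err, lipid_per_site, ...`).

Data formats are plain text: spectra as `wavelength_nm,counts` CSV and
time traces as `time_s,intensity_counts` CSV, both with `# key=value`
metadata headers; datasets are directories with a `manifest.json` and a
sealed `truth.json` (simulated data only).

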