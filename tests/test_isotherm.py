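"""Tests for isotherm assembly, modified-Langmuir fitting and derived reports."""

import numpy as np
import pytest

from shgsorb import (
    LangmuirParams,
    SampleComposition,
    TransportFit,
    adsorption_free_energy,
    isotherm_intensity,
    lipids_per_site,
    signal_per_coverage,
)
from shgsorb.exceptions import InsufficientDataError, InvalidInputError
from shgsorb.isotherm import (
    AdsorptionIsotherm,
    IsothermPoint,
    assemble_isotherm,
    bootstrap_uncertainties,
    derived_report,
    fit_modified_langmuir,
)

PURE = SampleComposition(lipid_conc=75.0, label="pure")
C_GRID = np.array([0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 5.0, 6.0, 7.0, 8.0])
TRUTH_PURE = LangmuirParams(A=174.0, Nmax=2.9, K=5e7, alpha=5.0, B=2.0)
TRUTH_APAP = LangmuirParams(A=241.0, Nmax=3.6, K=9e7, alpha=5.0, B=2.0)


def make_isotherm(truth, c_grid=C_GRID, noise=0.0, rng=None, sigma=0.0,
                  sample=PURE):
    i0 = isotherm_intensity(c_grid, truth)
    if noise and rng is not None:
        i0 = i0 * (1 + noise * rng.standard_normal(i0.size))
    points = [IsothermPoint(float(c), float(v), sigma) for c, v in zip(c_grid, i0)]
    return AdsorptionIsotherm(points=points, sample=sample,
                              alpha=truth.alpha, B=truth.B)


class TestAssembleIsotherm:
    @staticmethod
    def _fit(i0_field):
        return TransportFit(A0=i0_field * 0.6, A1=i0_field * 0.4, tau=300.0)

    def test_sorted_points(self):
        fits = [(c, self._fit(np.sqrt(c + 1))) for c in [6, 1, 3, 2, 4, 5, 2.5]]
        iso = assemble_isotherm(fits, PURE, alpha=1.0, B=0.0)
        assert [p.C_total for p in iso.points] == sorted(f[0] for f in fits)

    def test_duplicate_aggregated(self):
        fits = [(1.0, self._fit(1.0)), (1.0, self._fit(2.0)),
                (2.0, self._fit(1.5)), (3.0, self._fit(2.0)), (4.0, self._fit(2.5))]
        iso = assemble_isotherm(fits, PURE, alpha=1.0, B=0.0)
        assert len(iso.points) == 4
        expected = np.mean([1.0**2, 2.0**2])
        assert iso.points[0].I0 == pytest.approx(expected)

    def test_insufficient_points(self):
        fits = [(c, self._fit(1.0)) for c in [1.0, 2.0, 3.0]]
        with pytest.raises(InsufficientDataError):
            assemble_isotherm(fits, PURE, alpha=1.0, B=0.0)

    def test_noiseless_points_on_model(self):
        # time-zero of a decomposed field fit lands exactly on the isotherm
        truth = TRUTH_PURE
        fits = []
        for c in C_GRID:
            i_coh = isotherm_intensity(float(c), truth) - truth.B \
                - truth.alpha * (c - _coverage(c, truth))
            e0 = np.sqrt(i_coh)
            fits.append((float(c), TransportFit(
                A0=0.4 * e0, A1=0.6 * e0, tau=250.0,
                background=truth.alpha * (c - _coverage(c, truth)) + truth.B)))
        iso = assemble_isotherm(fits, PURE, alpha=truth.alpha, B=truth.B)
        expected = isotherm_intensity(iso.C, truth)
        np.testing.assert_allclose(iso.I0, expected, rtol=1e-12)


def _coverage(c, p):
    from shgsorb import langmuir_coverage

    return langmuir_coverage(float(c), p.Nmax, p.K).N_adsorbed


class TestFitModifiedLangmuir:
    @pytest.mark.parametrize("truth", [TRUTH_PURE, TRUTH_APAP],
                             ids=["pure", "apap"])
    def test_noiseless_round_trip(self, truth):
        res = fit_modified_langmuir(make_isotherm(truth))
        assert res.params.A == pytest.approx(truth.A, rel=1e-4)
        assert res.params.Nmax == pytest.approx(truth.Nmax, rel=1e-4)
        assert res.params.K == pytest.approx(truth.K, rel=1e-4)

    @pytest.mark.parametrize("nmax", [1.0, 3.0, 6.0])
    @pytest.mark.parametrize("k", [1e6, 5e7, 1e9])
    def test_identifiability_grid(self, nmax, k):
        truth = LangmuirParams(A=200.0, Nmax=nmax, K=k, alpha=4.0, B=1.0)
        c = np.linspace(0.25 * nmax, 3.0 * nmax, 10)
        res = fit_modified_langmuir(make_isotherm(truth, c_grid=c))
        assert res.params.A == pytest.approx(truth.A, rel=1e-4)
        assert res.params.Nmax == pytest.approx(nmax, rel=1e-4)
        assert res.params.K == pytest.approx(k, rel=1e-4)

    def test_reparameterization_invariance(self):
        iso = make_isotherm(TRUTH_PURE)
        res_log = fit_modified_langmuir(iso, log_k=True)
        res_lin = fit_modified_langmuir(iso, log_k=False)
        assert res_lin.params.K == pytest.approx(res_log.params.K, rel=1e-6)
        assert res_lin.params.Nmax == pytest.approx(res_log.params.Nmax, rel=1e-6)
        assert res_lin.params.A == pytest.approx(res_log.params.A, rel=1e-6)

    def test_degenerate_flat_isotherm(self):
        points = [IsothermPoint(float(c), 2.0) for c in [1.0, 2.0, 3.0, 4.0, 5.0]]
        iso = AdsorptionIsotherm(points=points, sample=PURE, alpha=0.0, B=2.0)
        with pytest.warns(UserWarning):
            res = fit_modified_langmuir(iso)
        assert res.params.A < 1e-3

    def test_bias_control_5pct_noise(self):
        # 5% multiplicative measurement noise, triplicate measurements per
        # concentration aggregated to isotherm points, sigma-weighted fit
        rng = np.random.default_rng(17)
        i_true = isotherm_intensity(C_GRID, TRUTH_PURE)
        errs = {"A": [], "Nmax": [], "K": []}
        for _ in range(100):
            meas = i_true[:, None] * (1 + 0.05 * rng.standard_normal((i_true.size, 3)))
            points = [IsothermPoint(float(c), float(m.mean()),
                                    float(0.05 * v / np.sqrt(3)))
                      for c, m, v in zip(C_GRID, meas, i_true)]
            iso = AdsorptionIsotherm(points=points, sample=PURE,
                                     alpha=TRUTH_PURE.alpha, B=TRUTH_PURE.B)
            res = fit_modified_langmuir(iso, n_restarts=0)
            errs["A"].append(abs(res.params.A - TRUTH_PURE.A) / TRUTH_PURE.A)
            errs["Nmax"].append(abs(res.params.Nmax - TRUTH_PURE.Nmax) / TRUTH_PURE.Nmax)
            errs["K"].append(abs(res.params.K - TRUTH_PURE.K) / TRUTH_PURE.K)
        for name, e in errs.items():
            assert np.median(e) <= 0.10, f"median relative error of {name} too large"

    def test_weighted_fit_uses_sigmas(self):
        iso = make_isotherm(TRUTH_PURE, sigma=2.0)
        res = fit_modified_langmuir(iso)
        assert res.params.Nmax == pytest.approx(2.9, rel=1e-4)


class TestBootstrap:
    def test_seed_determinism(self):
        rng = np.random.default_rng(1)
        iso = make_isotherm(TRUTH_PURE, noise=0.03, rng=rng)
        base = fit_modified_langmuir(iso)
        b1 = bootstrap_uncertainties(iso, base, n_boot=100, seed=9)
        b2 = bootstrap_uncertainties(iso, base, n_boot=100, seed=9)
        np.testing.assert_array_equal(b1.bootstrap_draws, b2.bootstrap_draws)

    def test_noiseless_interval_widths_vanish(self):
        iso = make_isotherm(TRUTH_PURE)
        base = fit_modified_langmuir(iso)
        b = bootstrap_uncertainties(iso, base, n_boot=100, seed=0)
        lo, hi = b.bootstrap_intervals["Nmax"]
        assert hi - lo < 1e-4

    def test_n_boot_validation(self):
        iso = make_isotherm(TRUTH_PURE)
        base = fit_modified_langmuir(iso)
        with pytest.raises(InvalidInputError):
            bootstrap_uncertainties(iso, base, n_boot=50)

    def test_interval_spans_truth_in_nested_replicates(self):
        # scaled-down nested calibration: the 68% K interval should span the
        # generating K in well over half of the outer replicates
        rng = np.random.default_rng(23)
        hits = 0
        n_outer = 20
        for i in range(n_outer):
            iso = make_isotherm(TRUTH_PURE, noise=0.05, rng=rng)
            base = fit_modified_langmuir(iso, n_restarts=0)
            b = bootstrap_uncertainties(iso, base, n_boot=100, seed=100 + i)
            lo, hi = b.bootstrap_intervals["K"]
            if lo <= TRUTH_PURE.K <= hi:
                hits += 1
        assert hits / n_outer >= 0.6


class TestDerivedReport:
    def _result(self, A, Nmax, K, se_frac=0.0):
        p = LangmuirParams(A=A, Nmax=Nmax, K=K, alpha=5.0, B=2.0)
        stderr = {"A": se_frac * A, "Nmax": se_frac * Nmax, "K": se_frac * K}
        from shgsorb.isotherm import IsothermFitResult

        return IsothermFitResult(params=p, param_stderr=stderr,
                                 param_cov=np.zeros((3, 3)))

    def test_pure_sample_values(self):
        rep = derived_report(self._result(174.0, 2.9, 5e7), PURE, T=293.0)
        assert rep.delta_g == pytest.approx(-10.3, abs=0.1)
        assert rep.lipids_per_site == pytest.approx(25.9, abs=0.05)
        assert rep.signal_per_coverage == pytest.approx(21, abs=0.5)

    def test_apap_sample_values(self):
        apap = SampleComposition(lipid_conc=75.0, apap_conc=25.0, label="apap")
        rep = derived_report(self._result(241.0, 3.6, 9e7), apap, T=293.0)
        assert rep.delta_g == pytest.approx(-10.6, abs=0.1)
        assert rep.lipids_per_site == pytest.approx(20.8, abs=0.05)
        assert rep.signal_per_coverage == pytest.approx(19, abs=0.5)

    def test_k_of_one_gives_zero(self):
        rep = derived_report(self._result(10.0, 1.0, 1.0), PURE, T=293.0)
        assert rep.delta_g == 0.0

    def test_identities_match_core_models_exactly(self):
        res = self._result(174.0, 2.9, 5e7, se_frac=0.2)
        rep = derived_report(res, PURE, T=293.0)
        assert rep.delta_g == adsorption_free_energy(5e7, 293.0).delta_g
        assert rep.lipids_per_site == lipids_per_site(75.0, 2.9)
        assert rep.signal_per_coverage == signal_per_coverage(174.0, 2.9)

    def test_delta_g_error_magnitude(self):
        # sigma_K/K = 0.2 propagates to ~0.1 kcal/mol
        rep = derived_report(self._result(174.0, 2.9, 5e7, se_frac=0.2), PURE)
        assert rep.delta_g_err == pytest.approx(0.116, abs=0.01)
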