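"""Unit and property tests for the pure model functions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shgsorb import (
    InterfacePopulations,
    LangmuirParams,
    TransportFit,
    adsorption_free_energy,
    coherent_field,
    field_decay,
    isotherm_intensity,
    langmuir_coverage,
    langmuir_coverage_oracle,
    lipids_per_site,
    shg_intensity,
    signal_per_coverage,
)
from shgsorb.constants import WATER_MOLARITY_UM
from shgsorb.exceptions import InvalidInputError


class TestCoherentField:
    def test_equal_populations_cancel(self):
        pop = InterfacePopulations(n_outer=5, n_inner=5, e_omega=1)
        assert coherent_field(pop, prefactor=1) == 0

    def test_outer_only(self):
        pop = InterfacePopulations(n_outer=3, n_inner=0, e_omega=2)
        assert coherent_field(pop, prefactor=1) == 12

    def test_sign_flips_when_inner_exceeds_outer(self):
        pop = InterfacePopulations(n_outer=2, n_inner=3, e_omega=1)
        assert coherent_field(pop, prefactor=1) == -1

    def test_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            InterfacePopulations(n_outer=float("nan"), n_inner=0)
        with pytest.raises(InvalidInputError):
            InterfacePopulations(n_outer=-1, n_inner=0)
        with pytest.raises(InvalidInputError):
            coherent_field(InterfacePopulations(1, 0), prefactor=0)

    @given(n_o=st.floats(0, 1e3), n_i=st.floats(0, 1e3),
           pref=st.floats(1e-3, 1e3), e=st.floats(0, 10))
    def test_antisymmetry(self, n_o, n_i, pref, e):
        a = coherent_field(InterfacePopulations(n_o, n_i, e), pref)
        b = coherent_field(InterfacePopulations(n_i, n_o, e), pref)
        assert a == -b


class TestShgIntensity:
    @pytest.mark.parametrize("field,expected", [(0, 0), (-4, 16), (3, 9)])
    def test_square(self, field, expected):
        assert shg_intensity(field) == expected

    def test_nonfinite(self):
        with pytest.raises(InvalidInputError):
            shg_intensity(float("inf"))


class TestLangmuirCoverage:
    def test_zero_concentration(self):
        assert langmuir_coverage(0, 2.9, 5e7).N_adsorbed == 0

    def test_infinite_affinity_saturates(self):
        n = langmuir_coverage(10, 2.9, 1e15).N_adsorbed
        assert n == pytest.approx(2.9, abs=1e-6)

    def test_derived_value_against_oracle(self):
        # frozen value computed independently by the bisection oracle
        oracle = langmuir_coverage_oracle(6, 2.9, 5e7, tol=1e-12)
        assert oracle == pytest.approx(2.2391321434, abs=1e-8)
        assert langmuir_coverage(6, 2.9, 5e7).N_adsorbed == pytest.approx(oracle, abs=1e-9)
        assert langmuir_coverage(6, 2.9, 5e7).N_adsorbed == pytest.approx(2.24, abs=5e-3)

    def test_equilibrium_residual(self):
        cov = langmuir_coverage(6, 2.9, 5e7)
        n = cov.N_adsorbed
        lhs = n / (2.9 - n)
        rhs = (5e7 / WATER_MOLARITY_UM) * (6 - n)
        assert abs(lhs - rhs) <= 1e-9 * max(abs(lhs), abs(rhs))

    def test_mass_balance_exact(self):
        cov = langmuir_coverage(6.3, 2.9, 5e7)
        assert cov.N_adsorbed + cov.M_free == cov.C_total

    def test_errors(self):
        with pytest.raises(InvalidInputError):
            langmuir_coverage(-1, 2.9, 5e7)
        with pytest.raises(InvalidInputError):
            langmuir_coverage(1, 0, 5e7)
        with pytest.raises(InvalidInputError):
            langmuir_coverage(1, 2.9, 0)
        with pytest.raises(InvalidInputError):
            langmuir_coverage(float("nan"), 2.9, 5e7)

    def test_solver_oracle_equivalence_1000_tuples(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            c = rng.uniform(0, 20)
            nmax = rng.uniform(0.5, 10)
            k = 10 ** rng.uniform(5, 10)
            closed = langmuir_coverage(c, nmax, k).N_adsorbed
            oracle = langmuir_coverage_oracle(c, nmax, k, tol=1e-13)
            assert abs(closed - oracle) <= 1e-9 * nmax

    @given(c=st.floats(0, 50), nmax=st.floats(0.1, 20),
           logk=st.floats(3, 12))
    @settings(max_examples=200)
    def test_coverage_bounds(self, c, nmax, logk):
        n = langmuir_coverage(c, nmax, 10**logk).N_adsorbed
        assert 0 <= n <= min(c, nmax) + 1e-12

    def test_strictly_increasing_in_C_K_Nmax(self):
        cs = np.linspace(0.1, 20, 40)
        ns = [langmuir_coverage(c, 2.9, 5e7).N_adsorbed for c in cs]
        assert np.all(np.diff(ns) > 0)
        ks = np.logspace(5, 10, 40)
        ns = [langmuir_coverage(6, 2.9, k).N_adsorbed for k in ks]
        assert np.all(np.diff(ns) > 0)
        nmaxes = np.linspace(0.5, 10, 40)
        ns = [langmuir_coverage(6, m, 5e7).N_adsorbed for m in nmaxes]
        assert np.all(np.diff(ns) > 0)

    def test_dilute_limit(self):
        # K*C/W = 1e-4 with C << Nmax and K*Nmax/W << 1
        nmax = 2.9
        k = 5e-3 / nmax * WATER_MOLARITY_UM  # K*Nmax/W = 5e-3
        c = 1e-4 * WATER_MOLARITY_UM / k
        n = langmuir_coverage(c, nmax, k).N_adsorbed
        linear = nmax * k * c / WATER_MOLARITY_UM
        assert n / linear == pytest.approx(1.0, abs=0.01)


class TestOracle:
    def test_zero(self):
        assert langmuir_coverage_oracle(0, 2.9, 5e7) == 0

    def test_strictly_below_bounds(self):
        n = langmuir_coverage_oracle(1, 3.6, 9e7, tol=1e-12)
        assert 0 < n < min(1, 3.6)

    def test_invalid(self):
        with pytest.raises(InvalidInputError):
            langmuir_coverage_oracle(1, -1, 5e7)


class TestIsothermIntensity:
    def test_baseline_only_at_zero(self):
        p = LangmuirParams(A=174, Nmax=2.9, K=5e7, alpha=3, B=7)
        assert isotherm_intensity(0, p) == pytest.approx(7)

    def test_saturation_limit(self):
        p = LangmuirParams(A=174, Nmax=2.9, K=5e7, alpha=0, B=0)
        assert isotherm_intensity(1e6, p) == pytest.approx(174, rel=1e-3)

    def test_compose_with_coverage_oracle(self):
        p = LangmuirParams(A=174, Nmax=2.9, K=5e7, alpha=0, B=0)
        n = langmuir_coverage_oracle(6, 2.9, 5e7, tol=1e-13)
        assert isotherm_intensity(6, p) == pytest.approx(174 * (n / 2.9) ** 2, rel=1e-9)

    def test_non_decreasing(self):
        p = LangmuirParams(A=174, Nmax=2.9, K=5e7, alpha=5, B=2)
        c = np.linspace(0, 20, 100)
        i = isotherm_intensity(c, p)
        assert np.all(np.diff(i) >= 0)

    def test_hrs_modes_differ_by_alpha_N(self):
        p = LangmuirParams(A=174, Nmax=2.9, K=5e7, alpha=5, B=2)
        n = langmuir_coverage(6, 2.9, 5e7).N_adsorbed
        free = isotherm_intensity(6, p, hrs_mode="free")
        total = isotherm_intensity(6, p, hrs_mode="total")
        assert total - free == pytest.approx(5 * n, rel=1e-9)

    def test_bad_mode(self):
        p = LangmuirParams(A=1, Nmax=1, K=1e6)
        with pytest.raises(InvalidInputError):
            isotherm_intensity(1, p, hrs_mode="bogus")


class TestFieldDecay:
    def test_time_zero(self):
        fit = TransportFit(A0=2, A1=3, tau=100)
        assert field_decay(0, fit) == pytest.approx(5)

    def test_asymptote(self):
        fit = TransportFit(A0=2, A1=3, tau=100)
        assert field_decay(1e9, fit) == pytest.approx(2)

    def test_one_tau(self):
        fit = TransportFit(A0=0, A1=1, tau=50)
        assert field_decay(50, fit) == pytest.approx(math.exp(-1), rel=1e-12)

    def test_invalid_tau(self):
        with pytest.raises(InvalidInputError):
            TransportFit(A0=0, A1=1, tau=0)


class TestThermo:
    def test_ln1_is_zero(self):
        assert adsorption_free_energy(1, 293).delta_g == 0

    def test_table_values(self):
        # printed free energies for the two equilibrium constants, T = 293 K
        assert adsorption_free_energy(5e7, 293).delta_g == pytest.approx(-10.3, abs=0.1)
        assert adsorption_free_energy(9e7, 293).delta_g == pytest.approx(-10.6, abs=0.1)

    def test_domain_error(self):
        with pytest.raises(InvalidInputError):
            adsorption_free_energy(0)
        with pytest.raises(InvalidInputError):
            adsorption_free_energy(1e7, T=-1)

    @given(logk=st.floats(1, 12), t=st.floats(100, 500))
    def test_identities(self, logk, t):
        k = 10**logk
        dg = adsorption_free_energy(k, t)
        # strictly decreasing in K at fixed T
        dg2 = adsorption_free_energy(k * 2, t)
        assert dg2.delta_g < dg.delta_g
        # delta_g / T independent of T at fixed K
        other = adsorption_free_energy(k, 2 * t)
        assert other.delta_g / (2 * t) == pytest.approx(dg.delta_g / t, rel=1e-12)


class TestRatios:
    def test_lipids_per_site_table(self):
        assert round(lipids_per_site(75, 2.9), 1) == 25.9
        assert round(lipids_per_site(75, 3.6), 1) == 20.8
        assert lipids_per_site(10, 10) == 1

    def test_signal_per_coverage_table(self):
        assert signal_per_coverage(174, 2.9) == pytest.approx(21, abs=0.5)
        assert signal_per_coverage(241, 3.6) == pytest.approx(19, abs=0.5)
        assert signal_per_coverage(100, 10) == 1

    def test_division_errors(self):
        with pytest.raises(InvalidInputError):
            lipids_per_site(75, 0)
        with pytest.raises(InvalidInputError):
            signal_per_coverage(174, 0)
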