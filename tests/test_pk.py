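"""Dosing regimens and compartmental PK simulation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad, solve_ivp

import xenoscale as xs
from xenoscale.pk import ConcentrationProfile, cumulative_exposure


class TestBuildRegimen:
    def test_gemcitabine_induction_has_seven_weekly_infusions(self):
        reg = xs.build_regimen("gemcitabine_standard", 8 * 7.0, bsa_m2=1.8)
        assert len(reg.events) == 7
        assert [e.time for e in reg.events] == [7.0 * w for w in range(7)]
        assert all(e.duration == pytest.approx(0.5 / 24) for e in reg.events)

    def test_gemcitabine_dose_scales_with_bsa(self):
        reg = xs.build_regimen("gemcitabine_standard", 14.0, bsa_m2=1.8)
        assert reg.events[0].amount == pytest.approx(1800.0)

    def test_gemcitabine_cycles_three_on_one_off(self):
        reg = xs.build_regimen("gemcitabine_standard", 16 * 7.0, bsa_m2=1.8)
        times = [e.time for e in reg.events]
        # induction weeks 0-6, rest week 7, then weeks 8,9,10 and 12,13,14
        assert times == [0, 7, 14, 21, 28, 35, 42, 56, 63, 70, 84, 91, 98]

    def test_sorafenib_twice_daily(self):
        reg = xs.build_regimen("sorafenib_standard", 7.0)
        assert len(reg.events) == 14
        assert sum(e.amount for e in reg.events) == pytest.approx(14 * 400.0)

    def test_missing_bsa_raises(self):
        with pytest.raises(ValueError, match="bsa"):
            xs.build_regimen("gemcitabine_standard", 56.0)

    def test_short_horizon_warns(self):
        with pytest.warns(UserWarning, match="truncated"):
            xs.build_regimen("gemcitabine_standard", 14.0, bsa_m2=1.8)


class TestSimulatePK:
    def test_one_compartment_bolus_analytic(self):
        spec = xs.PKModelSpec(v_central=10.0, k_elim=0.1, time_unit="day")
        reg = xs.DoseRegimen((xs.DoseEvent(0.0, 100.0),), horizon=50.0)
        prof = xs.simulate_pk(spec, reg, np.linspace(0, 50, 101))
        expected = 10.0 * np.exp(-0.1 * prof.times)
        assert prof.conc[0] == pytest.approx(10.0)
        assert np.allclose(prof.conc, expected, rtol=1e-8)

    def test_two_compartment_infusion_vs_ode_oracle(self):
        spec = xs.PKModelSpec(
            v_central=5.0, k_elim=0.3, n_compartments=2, k12=0.4, k21=0.2,
            time_unit="day",
        )
        reg = xs.DoseRegimen(
            (xs.DoseEvent(0.0, 240.0, "iv", duration=2.0),), horizon=20.0
        )
        prof = xs.simulate_pk(spec, reg, np.linspace(0, 20, 81))

        def rhs(t, y):
            inp = 120.0 if t < 2.0 else 0.0
            return [
                inp - (0.3 + 0.4) * y[0] + 0.2 * y[1],
                0.4 * y[0] - 0.2 * y[1],
            ]

        sol = solve_ivp(
            rhs, (0, 20), [0.0, 0.0], t_eval=prof.times, rtol=1e-11,
            atol=1e-12, max_step=0.5,
        )
        ref = sol.y[0] / 5.0
        scale = ref.max()
        assert np.max(np.abs(prof.conc - ref)) / scale < 1e-3

    def test_transit_chain_matches_erlang_convolution(self):
        """A 4-stage transit chain delivers an Erlang(4, ktr)-shaped input;
        the central profile must match its analytic convolution with the
        one-compartment impulse response."""
        n, ktr, k, v, dose = 4, 2.0, 0.5, 10.0, 100.0
        spec = xs.PKModelSpec(
            v_central=v, k_elim=k, absorption="transit", transit_n=n, ktr=ktr,
            time_unit="day",
        )
        reg = xs.DoseRegimen((xs.DoseEvent(0.0, dose, "oral"),), horizon=15.0)
        prof = xs.simulate_pk(spec, reg, np.linspace(0, 15, 61))

        def erlang_input(s):
            return ktr**n * s ** (n - 1) * math.exp(-ktr * s) / math.factorial(n - 1)

        def conc_ref(t):
            val, _ = quad(
                lambda s: erlang_input(s) * math.exp(-k * (t - s)), 0.0, t,
                limit=200,
            )
            return dose * val / v

        check_t = np.array([0.5, 1.0, 2.0, 3.0, 5.0, 8.0, 12.0])
        ref = np.array([conc_ref(t) for t in check_t])
        got = np.interp(check_t, prof.times, prof.conc)
        assert np.max(np.abs(got - ref)) / ref.max() < 5e-3

    def test_non_physical_spec_rejected(self):
        with pytest.raises(ValueError):
            xs.PKModelSpec(v_central=1.0, k_elim=-1.0)
        with pytest.raises(ValueError):
            xs.PKModelSpec(v_central=1.0, k_elim=1.0, n_compartments=2, k12=0.0, k21=1.0)

    def test_unit_mismatch_raises(self):
        spec = xs.PKModelSpec(v_central=1.0, k_elim=1.0, time_unit="hour")
        reg = xs.DoseRegimen((xs.DoseEvent(0.0, 1.0),), horizon=10.0, time_unit="day")
        with pytest.raises(ValueError, match="hour"):
            xs.simulate_pk(spec, reg)


class TestCumulativeExposure:
    def test_rectangle(self):
        t = np.linspace(0.0, 5.0, 11)
        prof = cumulative_exposure(
            ConcentrationProfile(t, np.full_like(t, 2.0), time_unit="hour")
        )
        assert prof.cauc[-1] == pytest.approx(10.0)
        assert prof.cauc[0] == 0.0

    def test_bolus_terminal_auc_is_dose_over_clearance(self):
        spec = xs.PKModelSpec(v_central=10.0, k_elim=0.1, time_unit="day")
        reg = xs.DoseRegimen((xs.DoseEvent(0.0, 100.0),), horizon=150.0)
        prof = xs.simulate_pk(spec, reg)
        assert prof.cauc[-1] == pytest.approx(100.0, rel=1e-3)

    def test_matches_quadrature_oracle(self):
        t = np.sort(np.concatenate([[0.0, 12.0], np.random.default_rng(3).uniform(0, 12, 400)]))
        c = np.exp(-0.3 * t) * (1 + 0.5 * np.sin(t))
        prof = cumulative_exposure(ConcentrationProfile(t, c, time_unit="day"))

        def interp_c(x):
            return np.interp(x, t, c)

        ref, _ = quad(interp_c, 0.0, 12.0, limit=500)
        assert prof.cauc[-1] == pytest.approx(ref, rel=1e-3)

    def test_unsorted_grid_rejected(self):
        with pytest.raises(ValueError):
            ConcentrationProfile(np.array([0.0, 2.0, 1.0]), np.ones(3))


class TestLinearity:
    @settings(derandomize=True, deadline=None, max_examples=15)
    @given(
        doses=st.lists(st.floats(1.0, 50.0), min_size=1, max_size=4),
        times=st.lists(st.floats(0.0, 20.0), min_size=1, max_size=4),
        factor=st.floats(1.5, 5.0),
    )
    def test_dose_proportionality(self, doses, times, factor):
        """Doubling every dose doubles concentration and exposure."""
        n = min(len(doses), len(times))
        events = tuple(
            xs.DoseEvent(t, d)
            for t, d in zip(np.sort(np.unique(np.round(times[:n], 3))), doses[:n])
        )
        if not events:
            return
        spec = xs.PKModelSpec(v_central=3.0, k_elim=0.4, time_unit="day")
        reg = xs.DoseRegimen(events, horizon=30.0)
        base = xs.simulate_pk(spec, reg, np.linspace(0, 30, 61))
        scaled = xs.simulate_pk(spec, reg.scaled(factor), np.linspace(0, 30, 61))
        assert np.allclose(scaled.conc, factor * base.conc, rtol=1e-9, atol=1e-12)
        assert np.allclose(scaled.cauc, factor * base.cauc, rtol=1e-9, atol=1e-12)

    def test_superposition_of_shifted_doses(self):
        """Multi-dose profile equals the sum of single-dose profiles."""
        spec = xs.PKModelSpec(
            v_central=2.0, k_elim=0.5, n_compartments=2, k12=0.3, k21=0.6,
            time_unit="day",
        )
        grid = np.linspace(0.0, 24.0, 97)
        multi = xs.simulate_pk(
            spec,
            xs.DoseRegimen(
                (xs.DoseEvent(0.0, 10.0), xs.DoseEvent(6.0, 25.0)), horizon=24.0
            ),
            grid,
        )
        total = np.zeros_like(grid)
        for t0, d in [(0.0, 10.0), (6.0, 25.0)]:
            single = xs.simulate_pk(
                spec, xs.DoseRegimen((xs.DoseEvent(t0, d),), horizon=24.0), grid
            )
            total += np.interp(grid, single.times, single.conc)
        got = np.interp(grid, multi.times, multi.conc)
        assert np.allclose(got, total, rtol=1e-6, atol=1e-9)

    def test_auc_conservation_two_compartment(self):
        """Terminal exposure equals absorbed amount / clearance for any
        linear spec."""
        spec = xs.PKModelSpec(
            v_central=4.0, k_elim=0.8, n_compartments=2, k12=0.2, k21=0.1,
            absorption="first_order", ka=1.5, bioavailability=0.7,
            time_unit="day",
        )
        reg = xs.DoseRegimen(
            (xs.DoseEvent(0.0, 50.0, "oral"), xs.DoseEvent(5.0, 50.0, "oral")),
            horizon=120.0,
        )
        prof = xs.simulate_pk(spec, reg)
        expected = 0.7 * 100.0 / (4.0 * 0.8)
        assert prof.cauc[-1] == pytest.approx(expected, rel=2e-3)
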