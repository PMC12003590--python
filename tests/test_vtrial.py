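"""Virtual trials: cohort sampling, progression times, Kaplan-Meier,
Monte Carlo aggregation and TTP reconstruction."""

import math

import numpy as np
import pytest
from lifelines import KaplanMeierFitter

import xenoscale as xs
from xenoscale.pk import ConcentrationProfile, cumulative_exposure
from xenoscale.vtrial import SurvivalCurve


def _pop(lambda0=0.2, k2=0.0, omega=None):
    om = np.zeros((2, 2)) if omega is None else np.asarray(omega, dtype=float)
    return xs.HumanPopulation(lambda0_pop=lambda0, k2_pop=k2, omega=om)


def _flat_conc(level, horizon=14.0):
    t = np.linspace(0.0, horizon, 400)
    return cumulative_exposure(
        ConcentrationProfile(t, np.full_like(t, level), time_unit="month")
    )


class TestSamplePatients:
    def test_mean_matches_population(self):
        om = np.array([[0.25, 0.1], [0.1, 0.16]])
        pats = xs.sample_patients(_pop(0.2, 0.5, om), 100_000, seed=4)
        lam = np.log([p.lambda0_human for p in pats])
        se = math.sqrt(0.25 / len(pats))
        assert abs(lam.mean() - math.log(0.2)) < 3 * se

    def test_degenerate_distribution(self):
        pats = xs.sample_patients(_pop(0.2, 0.5), 10, seed=0)
        assert all(p.lambda0_human == pytest.approx(0.2) for p in pats)
        assert all(p.k2_human == pytest.approx(0.5) for p in pats)
        assert all(p.tv0 == 1.0 for p in pats)

    def test_seed_determinism(self):
        om = np.array([[0.2, 0.0], [0.0, 0.2]])
        a = xs.sample_patients(_pop(0.2, 0.5, om), 50, seed=9)
        b = xs.sample_patients(_pop(0.2, 0.5, om), 50, seed=9)
        assert all(
            pa.lambda0_human == pb.lambda0_human and pa.k2_human == pb.k2_human
            for pa, pb in zip(a, b)
        )

    def test_lognormal_baseline(self):
        spec = xs.BaselineSpec(kind="lognormal", tv0_typical=115.3, omega_tv0_sq=0.16)
        pats = xs.sample_patients(_pop(), 50_000, baseline=spec, seed=2)
        logs = np.log([p.tv0 for p in pats])
        assert logs.mean() == pytest.approx(math.log(115.3), abs=0.02)
        assert logs.var() == pytest.approx(0.16, rel=0.05)


class TestTimeToProgression:
    def test_untreated_closed_form(self):
        """No drug, baseline reference: the 20% diameter threshold is hit
        exactly at 3 ln(1.2) / lambda0."""
        pat = xs.VirtualPatient(0, 0.2, 0.0, 1.0)
        rule = xs.ProgressionRule(reference="baseline", horizon=14.0)
        t, event = xs.time_to_progression(pat, None, rule)
        assert event
        assert t == pytest.approx(3.0 * math.log(1.2) / 0.2, abs=1e-9)
        assert t == pytest.approx(math.log(1.728) / 0.2, abs=1e-9)

    def test_tv0_invariance(self):
        """Event times do not depend on baseline tumor volume."""
        rule = xs.ProgressionRule(reference="nadir", horizon=14.0)
        conc = _flat_conc(0.3)
        times = [
            xs.time_to_progression(
                xs.VirtualPatient(0, 0.25, 0.4, tv0), conc, rule
            )[0]
            for tv0 in (0.01, 1.0, 115.3, 900.0)
        ]
        assert all(t == pytest.approx(times[0], abs=1e-12) for t in times)

    def test_monotone_shrinkage_is_censored(self):
        """Kill rate above growth under constant infusion: never progresses."""
        pat = xs.VirtualPatient(0, 0.2, 1.0, 1.0)
        t, event = xs.time_to_progression(
            pat, _flat_conc(0.5), xs.ProgressionRule(horizon=14.0)
        )
        assert not event
        assert t == 14.0

    def test_nadir_reference_matches_dense_scan(self, gem_conc_month):
        """Pulsed regimen with decline then regrowth: the located crossing
        agrees with a brute-force scan of the log-gain at 1e-4 month."""
        pat = xs.VirtualPatient(0, 0.35, 1.4, 1.0)
        rule = xs.ProgressionRule(reference="nadir", horizon=14.0)
        t, event = xs.time_to_progression(pat, gem_conc_month, rule)
        assert event
        scan_t = np.arange(0.0, 14.0, 1e-4)
        g = pat.lambda0_human * scan_t - pat.k2_human * gem_conc_month.cauc_at(scan_t)
        h = g - np.minimum.accumulate(g)
        crossed = h >= 3.0 * math.log(1.2)
        t_scan = scan_t[np.argmax(crossed)]
        assert t == pytest.approx(t_scan, abs=1e-3)

    def test_baseline_vs_nadir_ordering(self, gem_conc_month):
        """Under a shrinking-then-regrowing course the nadir reference
        triggers progression no later than... never earlier than baseline
        would on the way up from below baseline."""
        pat = xs.VirtualPatient(0, 0.3, 1.2, 1.0)
        t_base, _ = xs.time_to_progression(
            pat, gem_conc_month, xs.ProgressionRule(reference="baseline", horizon=14.0)
        )
        t_nadir, _ = xs.time_to_progression(
            pat, gem_conc_month, xs.ProgressionRule(reference="nadir", horizon=14.0)
        )
        assert t_nadir <= t_base + 1e-12


class TestKaplanMeier:
    def test_no_censoring(self):
        curve = xs.km_estimate([1.0, 2.0, 3.0], [True, True, True])
        assert np.allclose(curve.survival, [2 / 3, 1 / 3, 0.0])

    def test_with_censoring_hand_computation(self):
        curve = xs.km_estimate([1.0, 2.0, 3.0], [True, False, True])
        assert curve.survival_at(1.0) == pytest.approx(2 / 3)
        assert curve.survival_at(2.5) == pytest.approx(2 / 3)
        assert curve.survival_at(3.0) == pytest.approx(0.0)

    def test_all_censored(self):
        curve = xs.km_estimate([5.0, 5.0, 5.0], [False] * 3)
        assert np.all(curve.survival == 1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            xs.km_estimate([], [])

    def test_matches_lifelines_on_random_data(self):
        """Product-limit estimator equals the reference implementation to
        1e-12 on 100 random censored datasets."""
        rng = np.random.default_rng(17)
        kmf = KaplanMeierFitter()
        for _ in range(100):
            n = rng.integers(3, 60)
            times = np.round(rng.exponential(5.0, n), 2)
            events = rng.random(n) < 0.7
            curve = xs.km_estimate(times, events)
            kmf.fit(times, events)
            ref = kmf.survival_function_at_times(curve.times).to_numpy()
            assert np.max(np.abs(curve.survival - ref)) < 1e-12


class TestCurveMedian:
    def test_first_crossing(self):
        c = SurvivalCurve(
            np.array([2.0, 5.0]), np.array([0.6, 0.4]),
            np.zeros(2), np.zeros(2), np.zeros(2),
        )
        assert xs.curve_median(c) == 5.0

    def test_exact_half_plateau(self):
        c = SurvivalCurve(
            np.array([4.0, 6.0]), np.array([0.5, 0.2]),
            np.zeros(2), np.zeros(2), np.zeros(2),
        )
        assert xs.curve_median(c) == 4.0

    def test_never_reached(self):
        c = SurvivalCurve(
            np.array([10.0]), np.array([0.7]), np.zeros(1), np.zeros(1), np.zeros(1)
        )
        assert xs.curve_median(c) is None


class TestRunVirtualTrials:
    def test_fully_degenerate_trial(self):
        """omega = 0 and no drug: every replicate is identical, bands have
        zero width and all patients progress at 3 ln(1.2) / lambda0."""
        summary = xs.run_virtual_trials(
            _pop(0.25, 0.0), None,
            rule=xs.ProgressionRule(reference="baseline", horizon=14.0),
            n_patients=50, n_replicates=20, seed=3,
        )
        t_star = 3.0 * math.log(1.2) / 0.25
        assert summary.median_ttp == pytest.approx(t_star, abs=0.01)
        lo, hi = summary.median_ttp_pi90
        assert hi - lo < 1e-9
        assert not summary.median_ttp_censored.any()

    def test_overwhelming_effect_all_censored(self):
        summary = xs.run_virtual_trials(
            _pop(0.2, 50.0), _flat_conc(1.0),
            rule=xs.ProgressionRule(horizon=14.0),
            n_patients=30, n_replicates=10, seed=1,
        )
        assert summary.median_ttp_censored.all()
        assert summary.median_ttp == 14.0
        assert summary.band_touches_horizon

    def test_increasing_potency_never_shortens_ttp(self, gem_conc_month):
        om = np.array([[0.2, 0.05], [0.05, 0.2]])
        rule = xs.ProgressionRule(horizon=14.0)
        meds = []
        for k2 in (0.2, 0.6, 1.2):
            s = xs.run_virtual_trials(
                _pop(0.25, k2, om), gem_conc_month, rule=rule,
                n_patients=100, n_replicates=20, seed=11,
            )
            meds.append(s.median_ttp)
        assert meds[0] <= meds[1] <= meds[2]

    def test_replicates_stable_under_extension(self, gem_conc_month):
        """Counter-based substreams: replicate r is identical whether 10
        or 30 replicates are requested."""
        om = np.array([[0.2, 0.0], [0.0, 0.2]])
        kwargs = dict(
            rule=xs.ProgressionRule(horizon=14.0), n_patients=40, seed=23
        )
        a = xs.run_virtual_trials(
            _pop(0.25, 0.5, om), gem_conc_month, n_replicates=10, **kwargs
        )
        b = xs.run_virtual_trials(
            _pop(0.25, 0.5, om), gem_conc_month, n_replicates=30, **kwargs
        )
        assert np.allclose(a.median_ttps, b.median_ttps[:10])

    def test_band_ordering(self, gem_conc_month):
        om = np.array([[0.25, 0.1], [0.1, 0.25]])
        s = xs.run_virtual_trials(
            _pop(0.25, 0.8, om), gem_conc_month,
            rule=xs.ProgressionRule(horizon=14.0),
            n_patients=50, n_replicates=30, seed=2,
        )
        assert np.all(s.ttp_bands[0] <= s.ttp_bands[1] + 1e-12)
        assert np.all(s.ttp_bands[1] <= s.ttp_bands[2] + 1e-12)
        assert np.all(s.td_bands[0] <= s.td_bands[2] + 1e-12)


def _step(times, survival):
    times = np.asarray(times, dtype=float)
    z = np.zeros_like(times)
    return SurvivalCurve(times, np.asarray(survival, dtype=float), z, z, z)


class TestReconstructTTP:
    def test_no_deaths_gives_pfs(self):
        pfs = _step([1.0, 2.0, 4.0], [0.8, 0.5, 0.2])
        os_curve = _step([5.0], [1.0])
        ttp = xs.reconstruct_ttp(pfs, os_curve)
        assert np.allclose(ttp.survival_at([1.0, 2.0, 4.0]), [0.8, 0.5, 0.2])

    def test_hand_ratio(self):
        pfs = _step([2.0], [0.5])
        os_curve = _step([2.0], [0.8])
        ttp = xs.reconstruct_ttp(pfs, os_curve)
        assert ttp.survival_at(2.0) == pytest.approx(0.625)

    def test_all_events_are_deaths(self):
        t = [1.0, 3.0, 6.0]
        s = [0.7, 0.4, 0.1]
        ttp = xs.reconstruct_ttp(_step(t, s), _step(t, s))
        assert np.allclose(ttp.survival_at(t), 1.0)

    def test_small_violations_clipped(self):
        pfs = _step([1.0, 2.0], [0.81, 0.5])
        os_curve = _step([1.0, 2.0], [0.80, 0.6])
        ttp = xs.reconstruct_ttp(pfs, os_curve)
        assert ttp.survival_at(1.0) == pytest.approx(1.0)

    def test_large_violations_rejected(self):
        pfs = _step([1.0], [0.9])
        os_curve = _step([1.0], [0.6])
        with pytest.raises(ValueError, match="inconsistent"):
            xs.reconstruct_ttp(pfs, os_curve)

    def test_monotone_output(self):
        pfs = _step([1.0, 2.0, 3.0], [0.9, 0.6, 0.3])
        os_curve = _step([1.0, 2.0, 3.0], [0.95, 0.65, 0.6])
        ttp = xs.reconstruct_ttp(pfs, os_curve)
        assert np.all(np.diff(ttp.survival) <= 1e-12)
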