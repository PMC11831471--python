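"""Experiment schedules, DRC classification, EC50 fits, populations, loss fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bpmsim import (
    ConcentrationProfile,
    DoseResponseCurve,
    ExperimentDesign,
    PopulationSpec,
    RateConstants,
    TransducerConfig,
    build_profile,
    classify_shape,
    default_ladder,
    estimate_loss_rate,
    fit_ec50,
    heterogeneity_summary,
    particle_drc,
    sample_population,
    simulate,
)
from bpmsim.dose_response import run_experiment
from bpmsim.reaction_model import oracle_ec50


class TestDesignAndProfile:
    def test_default_protocol_spans_25_hours(self):
        design = ExperimentDesign()
        profile = build_profile(design)
        observed = profile.observed_windows()
        assert len(observed) == 80
        assert profile.end_time == pytest.approx(25 * 3600.0)
        assert design.series_duration_s == pytest.approx(2.5 * 3600.0)
        # last observed window ends 15 min into the last application
        assert observed[-1][1] == pytest.approx(25 * 3600.0 - 225.0)

    def test_small_design_times(self):
        d = ExperimentDesign(n_series=1, n_applications=2, obs_duration_s=60,
                             dead_time_s=10, ladder=(1e-7, 0.0))
        prof = build_profile(d)
        assert prof.observed_windows() == [(0.0, 60.0, 1e-7), (70.0, 130.0, 0.0)]

    @given(n_series=st.integers(1, 4), n_app=st.integers(1, 5))
    @settings(max_examples=15)
    def test_matches_brute_force_schedule(self, n_series, n_app):
        ladder = tuple(np.linspace(1e-6, 0.0, n_app))
        d = ExperimentDesign(n_series=n_series, n_applications=n_app,
                             obs_duration_s=100.0, dead_time_s=20.0, ladder=ladder)
        got = build_profile(d).observed_windows()
        brute = []
        t = 0.0
        for _ in range(n_series):
            for c in ladder:
                brute.append((t, t + 100.0, c))
                t += 120.0
        assert len(got) == len(brute)
        for g, b in zip(got, brute):
            assert g == pytest.approx(b)

    def test_increasing_ladder_rejected(self):
        with pytest.raises(ValueError, match="high to low"):
            ExperimentDesign(n_applications=2, ladder=(0.0, 1e-7))

    def test_default_ladder_shape(self):
        lad = default_ladder(kd=1e-7)
        assert len(lad) == 8 and lad[-1] == 0.0
        assert lad[0] == pytest.approx(1e-5) and lad[-2] == pytest.approx(1e-9)
        assert all(x >= y for x, y in zip(lad, lad[1:]))


class TestClassification:
    def test_strictly_decreasing_is_sigmoidal(self):
        drc = DoseResponseCurve(0, 0, default_ladder(), np.linspace(2, 30, 8))
        assert classify_shape(drc) == "sigmoidal"

    def test_all_zero_is_non_responsive(self):
        drc = DoseResponseCurve(0, 0, default_ladder(), np.zeros(8))
        assert classify_shape(drc) == "non-responsive"

    def test_interior_maximum_with_low_blank_is_bell(self):
        act = np.array([1.0, 5.0, 20.0, 30.0, 25.0, 15.0, 8.0, 5.0])
        drc = DoseResponseCurve(0, 0, default_ladder(), act)
        assert classify_shape(drc) == "bell"

    def test_interior_maximum_with_high_blank_stays_sigmoidal(self):
        act = np.array([1.0, 5.0, 20.0, 30.0, 28.0, 27.0, 27.5, 29.0])
        drc = DoseResponseCurve(0, 0, default_ladder(), act)
        assert classify_shape(drc, bell_ratio=0.8) == "sigmoidal"


class TestEc50:
    def test_recovers_generating_parameters(self):
        lad = np.asarray(default_ladder(kd=1e-7))
        ec50 = 3e-7
        act = 1.0 + (28.0 - 1.0) / (1.0 + (lad / ec50) ** 1.3)
        fit = fit_ec50(DoseResponseCurve(0, 0, lad, act))
        assert fit.converged
        assert fit.ec50 == pytest.approx(ec50, rel=0.01)
        assert fit.hill == pytest.approx(1.3, rel=0.05)

    def test_bell_curve_rejected(self):
        drc = DoseResponseCurve(0, 0, default_ladder(), np.zeros(8))
        drc.shape_class = "bell"
        with pytest.raises(ValueError, match="sigmoidal"):
            fit_ec50(drc)

    def test_too_few_points_rejected(self):
        drc = DoseResponseCurve(0, 0, [1e-6, 1e-7, 0.0], [1.0, 5.0, 9.0])
        with pytest.raises(ValueError, match="4"):
            fit_ec50(drc)

    def test_monovalent_oracle_curve_half_activity_point(self):
        """The 4PL EC50 of the exact monovalent DRC matches the dense
        half-activity crossing: competition shifts it above the analyte KD."""
        cfg = TransducerConfig(1, 3)
        lad = np.asarray(default_ladder(cfg.rates.kd_analyte))
        from bpmsim import stationary_drc

        fit = fit_ec50(DoseResponseCurve(0, 0, lad, stationary_drc(cfg, lad)))
        dense = oracle_ec50(cfg, 1e-10, 1e-4)
        assert fit.converged
        assert fit.ec50 == pytest.approx(dense, rel=0.05)
        # closed form: EC50 = KD * (1 + k_on_star * n_ssb / k_off_bond)
        closed = cfg.rates.kd_analyte * (1 + cfg.rates.k_on_star * 3 / cfg.rates.k_off_bond)
        assert fit.ec50 == pytest.approx(closed, rel=0.05)


class TestPopulation:
    def test_reproducible_and_poisson_moments(self):
        spec = PopulationSpec(n_particles=10_000, mean_n_psb=3.0, mean_n_ssb=8.0, master_seed=4)
        pop = sample_population(spec)
        again = sample_population(spec)
        assert [c.n_psb for c in pop] == [c.n_psb for c in again]
        n_psb = np.array([c.n_psb for c in pop])
        n_ssb = np.array([c.n_ssb for c in pop])
        assert n_psb.mean() == pytest.approx(3.0, rel=0.05)
        assert n_psb.var() == pytest.approx(3.0, rel=0.05)
        assert n_ssb.mean() == pytest.approx(8.0, rel=0.05)

    def test_zero_mean_gives_empty_transducers(self):
        spec = PopulationSpec(n_particles=50, mean_n_psb=0.0, mean_n_ssb=0.0)
        assert all(c.n_psb == 0 and c.n_ssb == 0 for c in sample_population(spec))


class TestParticleDrc:
    DESIGN = ExperimentDesign(
        n_series=2, n_applications=3, obs_duration_s=300.0, dead_time_s=60.0,
        ladder=(1e-6, 1e-8, 0.0),
    )

    def test_zero_event_trace_is_non_responsive(self):
        cfg = TransducerConfig(0, 3)
        tr = simulate(cfg, build_profile(self.DESIGN), seed=1, record="bonds")
        per_series, avg = particle_drc(tr, self.DESIGN)
        assert np.all(avg.activities == 0.0)
        assert classify_shape(avg) == "non-responsive"
        assert len(per_series) == 2

    def test_single_series_average_equals_series_with_zero_sd(self):
        d = ExperimentDesign(n_series=1, n_applications=3, obs_duration_s=300.0,
                             dead_time_s=60.0, ladder=(1e-6, 1e-8, 0.0))
        cfg = TransducerConfig(2, 3)
        tr = simulate(cfg, build_profile(d), seed=2, record="bonds")
        per_series, avg = particle_drc(tr, d)
        assert np.array_equal(per_series[0].activities, avg.activities)
        assert np.all(avg.sd == 0.0)

    def test_short_trace_rejected(self):
        cfg = TransducerConfig(1, 1)
        tr = simulate(cfg, ConcentrationProfile.constant(0.0, 100.0), seed=3)
        with pytest.raises(ValueError, match="horizon"):
            particle_drc(tr, self.DESIGN)


class TestHeterogeneity:
    def _curves(self):
        lad = default_ladder()
        rng = np.random.default_rng(0)
        curves = []
        for i in range(30):
            kind = i % 3
            if kind == 0:
                act = np.linspace(1, 25, 8) + rng.normal(0, 0.3, 8)
            elif kind == 1:
                act = np.array([1, 4, 15, 28, 22, 12, 6, 4.0]) + rng.normal(0, 0.3, 8)
            else:
                act = np.abs(rng.normal(0, 0.2, 8))
            curves.append(DoseResponseCurve(i, "time-averaged", lad, act))
        return curves

    def test_counts_match_brute_force_reclassification(self):
        curves = self._curves()
        summ = heterogeneity_summary(curves)
        brute = {"sigmoidal": 0, "bell": 0, "non-responsive": 0}
        for c in curves:
            brute[classify_shape(c)] += 1
        assert summ.class_counts == brute
        assert sum(summ.class_counts.values()) == summ.n_particles == 30

    def test_ensemble_curve_is_unweighted_mean(self):
        curves = self._curves()
        summ = heterogeneity_summary(curves)
        manual = np.mean([c.activities for c in curves], axis=0)
        assert np.allclose(summ.ensemble_curve.activities, manual)


class TestLossRateFit:
    TIMES = np.linspace(1.0, 24.0, 10)

    def test_constant_activity_zero_rate(self):
        fit = estimate_loss_rate(np.full(10, 20.0), self.TIMES)
        assert fit.rate_pct_per_h == pytest.approx(0.0, abs=1e-9)

    def test_exact_linear_decay_recovered_exactly(self):
        act = 30.0 * (1.0 - 0.02 * self.TIMES)
        fit = estimate_loss_rate(act, self.TIMES)
        assert fit.rate_pct_per_h == pytest.approx(2.0, abs=1e-9)
        assert fit.se_pct_per_h == pytest.approx(0.0, abs=1e-9)

    def test_guards(self):
        with pytest.raises(ValueError, match="3 blank"):
            estimate_loss_rate([1.0, 2.0], [0.0, 5.0])
        with pytest.raises(ValueError, match="2 hours"):
            estimate_loss_rate([1.0, 2.0, 3.0], [0.0, 0.5, 1.0])
        bad = estimate_loss_rate([-1.0, -2.0, -3.0, -4.0], [0.0, 2.0, 4.0, 6.0])
        assert not bad.ok and "intercept" in bad.message

    def test_recovers_generating_decay_in_simulated_experiment(self):
        """Parameter recovery on a short monovalent population with binder loss."""
        lam = 0.02 / 3600.0  # 2 %/h per binder type -> 4 %/h product decay
        spec = PopulationSpec(
            n_particles=150, mean_n_psb=1.0, mean_n_ssb=1.0,
            rates=RateConstants(),
            loss_rate_psb=lam, loss_rate_ssb=lam, master_seed=3,
        )
        result = run_experiment(spec, ExperimentDesign())
        t, acts = result.blank_activity_series()
        fit = estimate_loss_rate(acts, t)
        assert fit.ok
        # independent expectation: the same linear estimator applied to the
        # exact exponential product decay (the estimator linearizes, so its
        # expected value is below the generating 4 %/h on a 25-h horizon)
        expected = estimate_loss_rate(np.exp(-0.04 * t), t).rate_pct_per_h
        assert expected < 4.0
        assert abs(fit.rate_pct_per_h - expected) <= 3 * fit.se_pct_per_h
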