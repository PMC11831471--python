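"""Kinetic model and exact CTMC oracle."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bpmsim import (
    RateConstants,
    SystemState,
    TransducerConfig,
    enumerate_states,
    propensities,
    stationary_distribution,
    stationary_single_bound_fraction,
    stationary_switching_activity,
)
from bpmsim.reaction_model import generator_matrix


def props(state, config, conc):
    return dict(propensities(state, config, conc))


class TestPropensities:
    def test_single_free_pair_no_analyte(self):
        r = RateConstants(k_on_star=0.01)
        cfg = TransducerConfig(1, 1, r)
        p = props(SystemState(0, 0, 1, 1), cfg, 0.0)
        assert p["bond_form"] == pytest.approx(0.01)
        assert all(v == 0.0 for k, v in p.items() if k != "bond_form")

    def test_empty_transducer_is_inert(self):
        cfg = TransducerConfig(0, 5)
        p = props(SystemState(0, 0, 0, 5), cfg, 1e-6)
        assert p["analyte_capture"] == 0.0
        assert p["bond_form"] == 0.0
        assert p["analyte_release"] == 0.0 and p["bond_break"] == 0.0

    def test_free_binder_combinatorics_hand_count(self):
        # a=2, b=3 out of 10x10: 5 free PSBs, 7 free SSBs -> 35 pairs
        cfg = TransducerConfig(10, 10)
        st_ = SystemState(2, 3, 10, 10)
        p = props(st_, cfg, 0.0)
        # independent combinatorial enumeration of labeled free binder pairs
        free_psb = [i for i in range(10) if i >= 2 + 3]
        free_ssb = [j for j in range(10) if j >= 3]
        n_pairs = sum(1 for _ in free_psb for _ in free_ssb)
        assert n_pairs == 35
        assert p["bond_form"] == pytest.approx(cfg.rates.k_on_star * n_pairs)
        assert p["analyte_release"] == pytest.approx(cfg.rates.k_off_analyte * 2)
        assert p["bond_break"] == pytest.approx(cfg.rates.k_off_bond * 3)

    def test_bond_rate_variant_independent_of_ssb_count(self):
        cfg = TransducerConfig(4, 9, bond_rate_scales_with_ssb=False)
        p = props(SystemState(1, 1, 4, 9), cfg, 0.0)
        assert p["bond_form"] == pytest.approx(cfg.rates.k_on_star * 2)  # f=2, no s factor
        # with no free SSB left the bond cannot form under either variant
        cfg1 = TransducerConfig(4, 1, bond_rate_scales_with_ssb=False)
        assert props(SystemState(0, 1, 4, 1), cfg1, 0.0)["bond_form"] == 0.0

    def test_loss_propensities_cover_unbonded_binders_only(self):
        cfg = TransducerConfig(5, 4, loss_rate_psb=0.1, loss_rate_ssb=0.2)
        p = props(SystemState(1, 2, 5, 4), cfg, 0.0)
        assert p["psb_loss"] == pytest.approx(0.1 * (2 + 1))  # f=2 free + a=1 occupied
        assert p["ssb_loss"] == pytest.approx(0.2 * 2)  # s=2 free
        sever = TransducerConfig(5, 4, loss_rate_psb=0.1, loss_rate_ssb=0.2, loss_severs_bonds=True)
        p = props(SystemState(1, 2, 5, 4), sever, 0.0)
        assert p["psb_loss"] == pytest.approx(0.1 * 5)
        assert p["ssb_loss"] == pytest.approx(0.2 * 4)

    def test_invariant_violations_named(self):
        cfg = TransducerConfig(2, 2)
        with pytest.raises(ValueError, match="n_psb_current"):
            propensities(SystemState(2, 1, 2, 2), cfg, 0.0)
        with pytest.raises(ValueError, match="b >= 0"):
            propensities(SystemState(0, -1, 2, 2), cfg, 0.0)
        with pytest.raises(ValueError, match="concentration"):
            propensities(SystemState(0, 0, 2, 2), cfg, -1e-9)

    @given(
        n_psb=st.integers(0, 6),
        n_ssb=st.integers(0, 6),
        a=st.integers(0, 6),
        b=st.integers(0, 6),
    )
    def test_all_propensities_nonnegative(self, n_psb, n_ssb, a, b):
        if a + b > n_psb or b > n_ssb:
            return
        cfg = TransducerConfig(n_psb, n_ssb, loss_rate_psb=1e-5, loss_rate_ssb=1e-5)
        p = propensities(SystemState(a, b, n_psb, n_ssb), cfg, 1e-7)
        assert len(p) == 6
        assert all(v >= 0 for _, v in p)


class TestEnumeration:
    def test_hand_enumerations(self):
        assert enumerate_states(TransducerConfig(1, 1)) == [(0, 0), (1, 0), (0, 1)]
        assert enumerate_states(TransducerConfig(0, 5)) == [(0, 0)]
        assert enumerate_states(TransducerConfig(2, 1)) == [
            (0, 0), (1, 0), (2, 0), (0, 1), (1, 1),
        ]

    @given(n_psb=st.integers(0, 8), n_ssb=st.integers(0, 8))
    def test_matches_brute_force_double_loop(self, n_psb, n_ssb):
        brute = {
            (a, b)
            for a in range(n_psb + 1)
            for b in range(n_ssb + 1)
            if a + b <= n_psb and b <= n_ssb
        }
        got = enumerate_states(TransducerConfig(n_psb, n_ssb))
        assert set(got) == brute
        assert len(got) == len(brute)  # each exactly once

    def test_cap_refusal_mentions_state_space(self):
        with pytest.raises(ValueError, match="state"):
            enumerate_states(TransducerConfig(40, 40))
        # but an explicit higher cap is honored
        assert len(enumerate_states(TransducerConfig(14, 1), cap=14)) == 29

    def test_lossy_config_refused(self):
        with pytest.raises(ValueError, match="loss"):
            enumerate_states(TransducerConfig(1, 1, loss_rate_psb=1e-5))


class TestStationary:
    def test_symmetric_two_state(self):
        r = RateConstants(k_on_star=0.01, k_off_bond=0.01)
        pi = stationary_distribution(TransducerConfig(1, 1, r), 0.0)
        assert pi[(0, 0)] == pytest.approx(0.5)
        assert pi[(0, 1)] == pytest.approx(0.5)

    def test_detailed_balance_two_state(self):
        r = RateConstants(k_on_star=0.01, k_off_bond=0.03)
        pi = stationary_distribution(TransducerConfig(1, 1, r), 0.0)
        assert pi[(0, 1)] == pytest.approx(0.25)

    @given(
        n_psb=st.integers(1, 5),
        n_ssb=st.integers(1, 5),
        conc_x=st.sampled_from([0.0, 0.3, 1.0, 10.0]),
    )
    def test_global_balance_and_normalization(self, n_psb, n_ssb, conc_x):
        cfg = TransducerConfig(n_psb, n_ssb)
        conc = conc_x * cfg.rates.kd_analyte
        states, q = generator_matrix(cfg, conc)
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)
        pi = stationary_distribution(cfg, conc)
        vec = np.array([pi[s] for s in states])
        assert vec.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.abs(vec @ q).max() < 1e-10 * max(1.0, np.abs(q).max())

    def test_switching_activity_closed_form(self):
        r = RateConstants(k_on_star=0.01, k_off_bond=0.01)
        act = stationary_switching_activity(TransducerConfig(1, 1, r), 0.0)
        assert act == pytest.approx(36.0)  # 0.01/s expressed per hour
        r2 = RateConstants(k_on_star=0.01, k_off_bond=0.03)
        act2 = stationary_switching_activity(TransducerConfig(1, 1, r2), 0.0)
        assert act2 == pytest.approx(2 * 0.01 * 0.03 / 0.04 * 3600)

    def test_degenerate_configs_always_unbound(self):
        assert stationary_switching_activity(TransducerConfig(5, 0), 0.0) == 0.0
        assert stationary_single_bound_fraction(TransducerConfig(0, 5), 0.0) == 0.0

    def test_activity_vanishes_at_saturating_analyte(self):
        cfg = TransducerConfig(2, 2)
        assert stationary_switching_activity(cfg, 1.0) < 1e-3  # 10^7 x KD

    def test_activity_monotone_decreasing_in_conc_monovalent(self):
        cfg = TransducerConfig(1, 3)
        concs = np.logspace(-9, -5, 12)
        acts = [stationary_switching_activity(cfg, c) for c in concs]
        assert all(x > y for x, y in zip(acts, acts[1:]))

    def test_single_bound_fraction_examples(self):
        r = RateConstants(k_on_star=0.01, k_off_bond=0.03)
        assert stationary_single_bound_fraction(
            TransducerConfig(1, 1, r), 0.0
        ) == pytest.approx(0.25)
        # multivalent states steal probability mass from the single-bond state
        low = stationary_single_bound_fraction(TransducerConfig(1, 10), 0.0)
        high = stationary_single_bound_fraction(TransducerConfig(10, 10), 0.0)
        assert high < low

    def test_single_bound_fraction_rises_then_falls_with_psb(self):
        # at fixed n_ssb = 10 the fraction peaks at an interior binder number
        fracs = [
            stationary_single_bound_fraction(TransducerConfig(n, 10), 0.0)
            for n in (1, 2, 3, 5, 10)
        ]
        peak = int(np.argmax(fracs))
        assert 0 < peak < len(fracs) - 1 or fracs[1] > fracs[0]
        assert fracs[-1] < fracs[0]

    def test_single_bound_fraction_increases_with_ssb_at_low_psb(self):
        fracs = [
            stationary_single_bound_fraction(TransducerConfig(1, n), 0.0)
            for n in (1, 2, 5, 10)
        ]
        assert all(x < y for x, y in zip(fracs, fracs[1:]))
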