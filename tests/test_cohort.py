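import numpy as np
import pytest

from sfgsim import (
    FULL_BAN,
    STATUS_QUO,
    CohortSpec,
    Gender,
    PolicySpec,
    RunOptions,
    build_calibrated,
    effective_start,
    premature_death_fraction,
    run_cohort,
    step,
)
from sfgsim.cohort import OUTCOME_FIELDS

from conftest import build_flat_ps
from microsim import microsim_shares


class TestStep:
    def test_identity_when_nothing_happens(self):
        occ = np.array([1000.0, 0.0, 0.0, 0.0])
        new, deaths = step(occ, np.zeros(3), 0.0, 0.1, 0.1)
        np.testing.assert_array_equal(new, occ)
        assert deaths.sum() == 0.0

    def test_single_transition(self):
        new, _ = step(np.array([1000.0, 0, 0, 0]), np.zeros(3), 0.1, 0.0, 0.0)
        np.testing.assert_allclose(new, [900.0, 100.0, 0.0, 0.0])

    def test_death_then_transition_hand_arithmetic(self):
        # 1000 current smokers: 2% die, then 10% of the 980 survivors quit
        new, deaths = step(
            np.array([0.0, 1000.0, 0.0, 0.0]), np.array([0.0, 0.02, 0.0]), 0.0, 0.1, 0.0
        )
        assert deaths[1] == pytest.approx(20.0)
        np.testing.assert_allclose(new, [0.0, 882.0, 98.0, 20.0])

    def test_conservation_is_exact(self):
        occ = np.array([321.5, 123.4, 55.1, 10.0])
        new, _ = step(occ, np.array([0.01, 0.05, 0.02]), 0.03, 0.11, 0.07)
        assert new.sum() == pytest.approx(occ.sum(), rel=1e-15)

    def test_step_matches_stochastic_microsim(self):
        """Expected-value update agrees with Bernoulli micro-simulation."""
        ps = build_flat_ps(start=0.05, quit=0.1, relapse=0.02, death=0.01, max_age=40)
        cal = build_calibrated(ps)
        n = 200_000
        shares = microsim_shares(ps, cal, Gender.MALE, n, 20, seed=7)
        spec = CohortSpec(2010, Gender.MALE, 1.0)
        traj, _ = run_cohort(spec, STATUS_QUO, ps, cal)
        for k in (5, 10, 20):
            for s in range(4):
                p = traj.occupancy[k, s]
                se = np.sqrt(max(p * (1 - p), 1e-12) / n)
                assert abs(shares[k, s] - p) < 3 * se + 1e-9


class TestEffectiveStart:
    def test_status_quo_never_changes(self):
        assert effective_start(0.05, STATUS_QUO, 2010, 2030) == 0.05

    def test_full_ban_zeroes_banned_cohort(self):
        assert effective_start(0.05, FULL_BAN, 2010, 2025) == 0.0

    def test_pre_cutoff_cohort_unaffected(self):
        assert effective_start(0.05, FULL_BAN, 2009, 2030) == 0.05

    def test_ninety_percent_effectiveness(self):
        pol = PolicySpec("sfg", effectiveness=0.9)
        assert effective_start(0.05, pol, 2012, 2030) == pytest.approx(0.005)

    def test_lag_window_delays_effect(self):
        pol = PolicySpec("sfg", effectiveness=1.0, lag_years=5)
        # born 2010: inside the lag window; no effect until 2030
        assert effective_start(0.05, pol, 2010, 2029) == 0.05
        assert effective_start(0.05, pol, 2010, 2030) == 0.0
        # born after the window: banned from entry
        assert effective_start(0.05, pol, 2016, 2031) == 0.0

    def test_status_quo_forces_zero_effectiveness(self):
        assert PolicySpec("status_quo", effectiveness=0.7).effectiveness == 0.0


class TestRunCohort:
    def test_zero_size_cohort_gives_zero_ledger(self, flat_ps):
        cal = build_calibrated(flat_ps)
        spec = CohortSpec(2010, Gender.MALE, 0.0)
        traj, led = run_cohort(spec, STATUS_QUO, flat_ps, cal)
        assert traj.occupancy.sum() == 0.0
        for f in OUTCOME_FIELDS:
            assert np.all(led.undiscounted[f] == 0.0)

    def test_full_ban_cohort_never_smokes(self, flat_ps):
        cal = build_calibrated(flat_ps)
        traj, _ = run_cohort(CohortSpec(2010, Gender.FEMALE, 1000.0), FULL_BAN, flat_ps, cal)
        assert np.all(traj.occupancy[:, 1] == 0.0)
        assert np.all(traj.occupancy[:, 2] == 0.0)

    def test_conservation_and_monotone_dead(self, synth_ps, synth_cal):
        spec = CohortSpec(2010, Gender.MALE, 123_456.0)
        traj, _ = run_cohort(spec, STATUS_QUO, synth_ps, synth_cal)
        np.testing.assert_allclose(traj.occupancy.sum(axis=1), spec.size, rtol=1e-9)
        assert np.all(np.diff(traj.occupancy[:, 3]) >= -1e-9)

    def test_deterministic_bit_identical(self, synth_ps, synth_cal):
        spec = CohortSpec(2012, Gender.FEMALE, 50_000.0)
        t1, l1 = run_cohort(spec, FULL_BAN, synth_ps, synth_cal)
        t2, l2 = run_cohort(spec, FULL_BAN, synth_ps, synth_cal)
        np.testing.assert_array_equal(t1.occupancy, t2.occupancy)
        for f in OUTCOME_FIELDS:
            np.testing.assert_array_equal(l1.discounted[f], l2.discounted[f])

    def test_tax_and_gdp_per_surviving_smoker_cycle(self):
        # deathless world where everyone starts smoking in the first cycle
        ps = build_flat_ps(start=1.0, quit=0.0, relapse=0.0, death=0.0, max_age=20)
        cal = build_calibrated(ps)
        _, led = run_cohort(CohortSpec(2010, Gender.MALE, 1.0), STATUS_QUO, ps, cal)
        assert led.undiscounted["tax"][0] == pytest.approx(842.50)
        assert led.undiscounted["gdp"][0] == pytest.approx(355.625)

    def test_discount_factor_closed_form(self):
        ps = build_flat_ps(death=0.0, start=0.0, max_age=40, discount=0.015)
        cal = build_calibrated(ps)
        _, led = run_cohort(CohortSpec(2010, Gender.MALE, 1.0), STATUS_QUO, ps, cal)
        ratio = led.discounted["life_years"][0] / led.undiscounted["life_years"][0]
        assert ratio == pytest.approx(1.015 ** -0.25, rel=1e-12)
        # twenty cycles apart = exactly ten years of extra discounting
        r20 = (led.discounted["life_years"][20] / led.undiscounted["life_years"][20]) / ratio
        assert r20 == pytest.approx(1.015 ** -10, rel=1e-12)
        assert 1.015 ** -10 == pytest.approx(0.861667, abs=5e-7)

    def test_unrelated_costs_only_when_flagged(self, flat_ps):
        cal = build_calibrated(flat_ps)
        spec = CohortSpec(2010, Gender.MALE, 1000.0)
        _, l_off = run_cohort(spec, STATUS_QUO, flat_ps, cal)
        _, l_on = run_cohort(
            spec, STATUS_QUO, flat_ps, cal, RunOptions(include_unrelated_costs=True)
        )
        assert np.all(l_off.undiscounted["unrelated_cost"] == 0.0)
        assert l_on.undiscounted["unrelated_cost"].sum() > 0.0

    def test_effectiveness_interpolates_between_arms(self, synth_ps, synth_cal):
        spec = CohortSpec(2011, Gender.MALE, 100_000.0)
        res = {}
        for name, pol in (
            ("sq", STATUS_QUO),
            ("mid", PolicySpec("sfg", effectiveness=0.9)),
            ("ban", FULL_BAN),
        ):
            _, led = run_cohort(spec, pol, synth_ps, synth_cal)
            res[name] = {f: led.undiscounted[f].sum() for f in ("qalys", "tax", "gdp")}
        for f in ("qalys", "tax", "gdp"):
            lo, hi = sorted((res["sq"][f], res["ban"][f]))
            assert lo - 1e-9 <= res["mid"][f] <= hi + 1e-9

    def test_policy_noop_when_start_is_zero(self):
        ps = build_flat_ps(start=0.0)
        cal = build_calibrated(ps)
        spec = CohortSpec(2010, Gender.MALE, 10_000.0)
        _, sq = run_cohort(spec, STATUS_QUO, ps, cal)
        _, ban = run_cohort(spec, FULL_BAN, ps, cal)
        for f in OUTCOME_FIELDS:
            np.testing.assert_array_equal(sq.discounted[f], ban.discounted[f])

    def test_full_ban_dominates_qalys_when_premises_hold(self, synth_ps, synth_cal):
        # utilities: never >= former >= current; death RRs >= 1 in the generator
        spec = CohortSpec(2010, Gender.FEMALE, 100_000.0)
        _, sq = run_cohort(spec, STATUS_QUO, synth_ps, synth_cal)
        _, ban = run_cohort(spec, FULL_BAN, synth_ps, synth_cal)
        assert ban.undiscounted["qalys"].sum() >= sq.undiscounted["qalys"].sum()


class TestPrematureDeath:
    def test_zero_mortality_before_75(self):
        ps = build_flat_ps(death=0.0)
        cal = build_calibrated(ps)
        traj, _ = run_cohort(CohortSpec(2010, Gender.MALE, 100.0), STATUS_QUO, ps, cal)
        assert premature_death_fraction(traj) == 0.0

    def test_constant_hazard_closed_form(self):
        q = 0.004
        ps = build_flat_ps(death=q, rr_death=(1.0, 1.0))
        cal = build_calibrated(ps)
        traj, _ = run_cohort(CohortSpec(2010, Gender.MALE, 1.0), STATUS_QUO, ps, cal)
        n_cycles_before_75 = 2 * (75 - 15)
        assert premature_death_fraction(traj) == pytest.approx(
            1.0 - (1.0 - q) ** n_cycles_before_75, rel=1e-10
        )

    def test_short_trajectory_rejected(self):
        ps = build_flat_ps(max_age=60)
        cal = build_calibrated(ps)
        traj, _ = run_cohort(CohortSpec(2010, Gender.MALE, 1.0), STATUS_QUO, ps, cal)
        with pytest.raises(ValueError, match="age 75"):
            premature_death_fraction(traj)
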