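import numpy as np
import pytest

from sfgsim import (
    FULL_BAN,
    STATUS_QUO,
    CohortSpec,
    Gender,
    HorizonSummary,
    PolicySpec,
    build_calibrated,
    generate,
    generate_standing_population,
    project_prevalence,
    rollup,
    run_all_cohorts,
    run_cohort,
    threshold_qaly,
)
from sfgsim.population import NET_FIELDS, StandingPopulation, UndefinedThresholdError
from sfgsim.synthetic import SynthConfig
from sfgsim.uncertainty import Scenario, evaluate_scenario

from conftest import build_flat_ps


def mk_summary(qalys=1.0, hc=0.0, unrel=0.0, tax=0.0, gdp=0.0, horizon=50):
    return HorizonSummary(
        horizon=horizon,
        life_years_gained=0.0,
        qalys_gained=qalys,
        hc_costs_averted=hc,
        unrelated_costs_averted=unrel,
        tax_foregone=tax,
        gdp_foregone=gdp,
        cases_prevented_COPD=0.0,
        cases_prevented_CHD=0.0,
        cases_prevented_stroke=0.0,
        cases_prevented_lung_cancer=0.0,
    )


class TestRollup:
    def test_single_cohort_first_year_matches_cohort_ledger(self, flat_ps):
        ps = flat_ps.copy()
        ps.cohorts = [CohortSpec(2010, Gender.MALE, 1000.0)]
        cal = build_calibrated(ps)
        sq = run_all_cohorts(ps, cal, STATUS_QUO)
        po = run_all_cohorts(ps, cal, FULL_BAN)
        cl = rollup(sq, po)
        _, led = run_cohort(CohortSpec(2010, Gender.MALE, 1000.0), STATUS_QUO, ps, cal)
        expected = led.undiscounted["qalys"][:2].sum()  # two cycles of 2025
        assert cl.status_quo.loc[2025, "qalys"] == pytest.approx(expected, rel=1e-12)

    def test_identical_policies_give_zero_net(self, flat_ps):
        cal = build_calibrated(flat_ps)
        sq = run_all_cohorts(flat_ps, cal, STATUS_QUO)
        cl = rollup(sq, sq)
        assert np.all(cl.net.to_numpy() == 0.0)

    def test_two_identical_cohorts_double_the_ledger(self, flat_ps):
        base = flat_ps.copy()
        base.cohorts = [CohortSpec(2010, Gender.MALE, 1000.0)]
        doubled = flat_ps.copy()
        doubled.cohorts = [CohortSpec(2010, Gender.MALE, 1000.0)] * 2
        cal = build_calibrated(base)
        cl1 = rollup(
            run_all_cohorts(base, cal, STATUS_QUO), run_all_cohorts(base, cal, FULL_BAN)
        )
        cl2 = rollup(
            run_all_cohorts(doubled, cal, STATUS_QUO), run_all_cohorts(doubled, cal, FULL_BAN)
        )
        np.testing.assert_allclose(2 * cl1.net.to_numpy(), cl2.net.to_numpy(), rtol=1e-9, atol=1e-6)

    def test_linearity_in_cohort_size(self, flat_ps):
        small = flat_ps.copy()
        small.cohorts = [CohortSpec(2010, Gender.FEMALE, 1000.0)]
        big = flat_ps.copy()
        big.cohorts = [CohortSpec(2010, Gender.FEMALE, 3000.0)]
        cal = build_calibrated(small)
        cl_s = rollup(run_all_cohorts(small, cal, STATUS_QUO), run_all_cohorts(small, cal, FULL_BAN))
        cl_b = rollup(run_all_cohorts(big, cal, STATUS_QUO), run_all_cohorts(big, cal, FULL_BAN))
        np.testing.assert_allclose(3 * cl_s.net.to_numpy(), cl_b.net.to_numpy(), rtol=1e-9, atol=1e-6)

    def test_mismatched_cohort_sets_rejected(self, flat_ps):
        ps1 = flat_ps.copy()
        ps1.cohorts = [CohortSpec(2010, Gender.MALE, 1000.0)]
        ps2 = flat_ps.copy()
        ps2.cohorts = [CohortSpec(2011, Gender.MALE, 1000.0)]
        cal = build_calibrated(ps1)
        with pytest.raises(ValueError, match="differ"):
            rollup(run_all_cohorts(ps1, cal, STATUS_QUO), run_all_cohorts(ps2, cal, FULL_BAN))

    def test_net_zero_before_first_affected_cohort_is_active(self, synth_ps, synth_cal):
        cl = rollup(
            run_all_cohorts(synth_ps, synth_cal, STATUS_QUO),
            run_all_cohorts(synth_ps, synth_cal, FULL_BAN),
        )
        assert int(cl.net.index[0]) == 2025  # first cohort (born 2010) turns 15

    def test_cached_rollup_matches_individual_cohort_runs(self, synth_ps, synth_cal):
        """Stationarity caching must be an exact optimization, not an approximation."""
        ledgers = run_all_cohorts(synth_ps, synth_cal, STATUS_QUO)
        spec = synth_ps.cohorts[7]
        _, direct = run_cohort(spec, STATUS_QUO, synth_ps, synth_cal)
        cached = ledgers[7]
        np.testing.assert_allclose(
            cached.discounted["qalys"], direct.discounted["qalys"], rtol=1e-12
        )

    def test_horizon_prefix_property(self, synth_ps):
        cl = evaluate_scenario(synth_ps, Scenario("base"))
        cum = cl.cumulative_net()
        h10 = cl.horizon_summary(10)
        h25 = cl.horizon_summary(25)
        assert cum.loc[2034, "qalys_gained_disc"] == pytest.approx(h10.qalys_gained, rel=1e-12)
        assert h25.qalys_gained >= h10.qalys_gained

    def test_gender_decomposition_sums_to_total(self, flat_ps):
        ps = flat_ps.copy()
        ps.cohorts = [CohortSpec(2010, Gender.MALE, 1000.0), CohortSpec(2010, Gender.FEMALE, 900.0)]
        males = flat_ps.copy()
        males.cohorts = ps.cohorts[:1]
        females = flat_ps.copy()
        females.cohorts = ps.cohorts[1:]
        cal = build_calibrated(ps)

        def net(p):
            return rollup(
                run_all_cohorts(p, cal, STATUS_QUO), run_all_cohorts(p, cal, FULL_BAN)
            ).net.to_numpy()

        np.testing.assert_allclose(net(males) + net(females), net(ps), rtol=1e-10, atol=1e-9)


class TestThresholdQaly:
    def test_direct_formula(self):
        assert threshold_qaly(mk_summary(qalys=1.0, tax=10.0, gdp=5.0)) == pytest.approx(15.0)

    def test_break_even_when_savings_equal_offsets(self):
        assert threshold_qaly(mk_summary(qalys=2.0, hc=15.0, tax=10.0, gdp=5.0)) == pytest.approx(0.0)

    def test_negative_when_savings_exceed_offsets(self):
        assert threshold_qaly(mk_summary(qalys=1.0, hc=20.0, tax=10.0, gdp=5.0)) < 0.0

    def test_undefined_without_qaly_gain(self):
        with pytest.raises(UndefinedThresholdError):
            threshold_qaly(mk_summary(qalys=0.0, tax=10.0))


class TestPrevalenceProjection:
    def test_no_smokers_and_no_uptake_stays_at_zero(self):
        ps = build_flat_ps(start=0.0, w=(1.0, 0.0, 0.0), max_age=40)
        cal = build_calibrated(ps)
        counts = np.zeros((2, ps.n_ages, 3))
        counts[:, :, 0] = 1000.0
        standing = StandingPopulation(15, 40, counts)
        table, first = project_prevalence(standing, ps, cal, STATUS_QUO, n_years=10)
        assert np.all(table["prevalence"] == 0.0)
        assert first[0.05] == 2025

    def test_full_ban_weakly_below_status_quo_every_year(self, synth_ps, synth_cal):
        standing = generate_standing_population(SynthConfig(seed=0), synth_ps)
        sq, _ = project_prevalence(standing, synth_ps, synth_cal, STATUS_QUO, n_years=40)
        ban, _ = project_prevalence(standing, synth_ps, synth_cal, FULL_BAN, n_years=40)
        assert np.all(ban["prevalence"] <= sq["prevalence"] + 1e-12)

    def test_target_year_monotone_in_effectiveness(self, synth_ps, synth_cal):
        standing = generate_standing_population(SynthConfig(seed=0), synth_ps)
        years = []
        for eff in (0.0, 0.5, 1.0):
            pol = STATUS_QUO if eff == 0.0 else PolicySpec("sfg", effectiveness=eff)
            _, first = project_prevalence(
                standing, synth_ps, synth_cal, pol, n_years=80, targets=(0.05,)
            )
            years.append(first[0.05] if first[0.05] is not None else np.inf)
        assert years[0] >= years[1] >= years[2]


def test_annual_savings_eventually_cross_tax_plus_gdp_losses(synth_ps):
    """Qualitative long-run shape: the annual undiscounted health-care costs
    averted eventually exceed the annual tax revenue plus GDP foregone."""
    cl = evaluate_scenario(synth_ps, Scenario("base"))
    hc = cl.net["hc_costs_averted"]
    offsets = cl.net["tax_foregone"] + cl.net["gdp_foregone"]
    crossed = (hc > offsets) & (hc > 0)
    assert crossed.any()
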