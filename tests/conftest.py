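import numpy as np
import pytest

from sfgsim import (
    AgeSchedule,
    CohortSpec,
    DiseaseInputs,
    EconParams,
    Gender,
    MortalityInputs,
    ParameterSet,
    SmokingState,
    SynthConfig,
    TransitionInputs,
    UtilityInputs,
    build_calibrated,
    canadian_parameter_set,
    generate,
)
from sfgsim.parameters import DISEASES, GENDERS, validate_parameters


def build_flat_ps(
    *,
    start=0.01,
    quit=0.02,
    relapse=0.005,
    death=0.002,
    rr_death=(2.0, 1.3),
    w=(0.8, 0.1, 0.1),
    utilities=(0.9, 0.85, 0.88),
    disease_prev=0.02,
    disease_rr=(2.0, 1.5),
    cost=1000.0,
    tax=1685.0,
    gdp=711.25,
    discount=0.015,
    max_age=100,
    cohorts=((2010, 200_000.0, 190_000.0),),
) -> ParameterSet:
    """Hand-sized parameter set with age-constant schedules (exact arithmetic)."""
    n = max_age - 15 + 1

    def sched(v):
        return {g: AgeSchedule(15, np.full(n, float(v))) for g in GENDERS}

    diseases = {
        d: DiseaseInputs(
            d,
            disease_rr[0],
            disease_rr[1],
            cost,
            marginal_prevalence=sched(disease_prev),
        )
        for d in DISEASES
    }
    by_status = {
        g: {
            SmokingState.NEVER: AgeSchedule(15, np.full(n, utilities[0])),
            SmokingState.CURRENT: AgeSchedule(15, np.full(n, utilities[1])),
            SmokingState.FORMER: AgeSchedule(15, np.full(n, utilities[2])),
        }
        for g in GENDERS
    }
    ps = ParameterSet(
        transitions=TransitionInputs(sched(start), sched(quit), sched(relapse)),
        mortality=MortalityInputs(
            marginal_death=sched(death),
            rr_current=rr_death[0],
            rr_former=rr_death[1],
            prev_never=sched(w[0]),
            prev_current=sched(w[1]),
            prev_former=sched(w[2]),
        ),
        diseases=diseases,
        utilities=UtilityInputs(by_status),
        econ=EconParams(
            tax_per_smoker_year=tax,
            gdp_per_smoker_year=gdp,
            discount_rate_annual=discount,
            unrelated_cost_survivor=sched(500.0),
            unrelated_cost_decedent=sched(20000.0),
        ),
        cohorts=[
            c
            for by, m, f in cohorts
            for c in (CohortSpec(by, Gender.MALE, m), CohortSpec(by, Gender.FEMALE, f))
        ],
        max_age=max_age,
    )
    validate_parameters(ps)
    return ps


@pytest.fixture(scope="session")
def flat_ps():
    return build_flat_ps()


@pytest.fixture(scope="session")
def synth_ps():
    """Default synthetic set, shrunk to 5 birth-year cohorts for speed."""
    return generate(SynthConfig(seed=0, n_birth_years=5))


@pytest.fixture(scope="session")
def synth_cal(synth_ps):
    return build_calibrated(synth_ps)


@pytest.fixture(scope="session")
def canada_ps():
    return canadian_parameter_set()


@pytest.fixture(scope="session")
def canada_cal(canada_ps):
    return build_calibrated(canada_ps)
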