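"""Synthetic reconstruction of the Canadian model input table.

The published analysis this package re-implements stratifies its inputs in
a dense table that is not machine-readable; this module is a SYNTHETIC
stand-in, not a transcription.  It anchors every panel to figures that are
public: Gompertz–Makeham all-cause mortality fitted to Canadian life-table
survival (male ~0.735 and female ~0.84 survival from age 15 to 75),
survey-scale smoking-status prevalence for the standing adult population,
start schedules that reproduce the reported daily-smoking shares at age 18
(7.5% of males, 4.6% of females), literature-scale relative risks, 2023-CAD
disease costs, status-specific utilities, the per-smoker tobacco tax
($1685/year) and tobacco-industry GDP ($711.25/year), and a 1.5% annual
discount rate.  Cohort sizes are census-scale: 201,000 males and 191,000
females turning 15 in 2025.

Results computed from this reconstruction follow the published analysis in
structure and magnitude but are not expected to match its totals exactly.
"""

from __future__ import annotations

import numpy as np

from .parameters import (
    GENDERS,
    AgeSchedule,
    CohortSpec,
    DiseaseInputs,
    EconParams,
    Gender,
    MortalityInputs,
    ParameterSet,
    SmokingState,
    TransitionInputs,
    UtilityInputs,
    validate_parameters,
)

__all__ = ["canadian_parameter_set", "COHORT_SIZES"]

START_AGE, MAX_AGE = 15, 100

#: persons turning 15 in 2025 (census-scale synthetic figures)
COHORT_SIZES = {Gender.MALE: 201_000.0, Gender.FEMALE: 191_000.0}

# Gompertz–Makeham annual hazard a*exp(b*age) + c per gender, fitted once to
# life-table survival anchors (see module docstring)
_GOMPERTZ = {
    Gender.MALE: (2.44e-5, 0.094, 4.0e-4),
    Gender.FEMALE: (1.15e-5, 0.097, 2.0e-4),
}

_RR_DEATH = (2.8, 1.3)  # current, former vs never


def _ages() -> np.ndarray:
    return np.arange(START_AGE, MAX_AGE + 1, dtype=float)


def _interp(points: dict) -> np.ndarray:
    """Piecewise-linear curve through {age: value} control points."""
    ages = _ages()
    xs = sorted(points)
    return np.interp(ages, xs, [points[x] for x in xs])


def _marginal_death(g: Gender) -> np.ndarray:
    a, b, c = _GOMPERTZ[g]
    hazard = a * np.exp(b * _ages()) + c
    return 1.0 - np.exp(-hazard / 2.0)


def _transitions() -> TransitionInputs:
    ages = _ages()
    # 6-month start probability: concentrated at 15-18 so that the share
    # ever starting by age 18 is ~7.5% (male) / ~4.6% (female)
    start_m = _interp({15: 0.0095, 18: 0.0095, 21: 0.004, 25: 0.0015, 30: 0.0003, 35: 0.0})
    start_f = 0.60 * start_m
    quit_ = _interp({15: 0.015, 25: 0.018, 45: 0.028, 65: 0.042, 85: 0.055, 100: 0.06})
    relapse = _interp({15: 0.007, 35: 0.004, 55: 0.0025, 100: 0.0015})
    return TransitionInputs(
        start={Gender.MALE: AgeSchedule(START_AGE, start_m), Gender.FEMALE: AgeSchedule(START_AGE, start_f)},
        quit={g: AgeSchedule(START_AGE, quit_.copy()) for g in GENDERS},
        relapse={g: AgeSchedule(START_AGE, relapse.copy()) for g in GENDERS},
    )


def _status_prevalence() -> tuple[dict, dict, dict]:
    # survey-scale smoking-status mix of the standing population (older
    # generations smoked more than cohorts entering now)
    cur = {
        Gender.MALE: _interp({15: 0.02, 20: 0.10, 30: 0.14, 55: 0.13, 70: 0.07, 80: 0.045, 100: 0.02}),
        Gender.FEMALE: _interp({15: 0.015, 20: 0.07, 30: 0.10, 55: 0.10, 70: 0.055, 80: 0.035, 100: 0.015}),
    }
    fmr = {
        Gender.MALE: _interp({15: 0.01, 20: 0.04, 30: 0.12, 50: 0.28, 70: 0.44, 85: 0.47, 100: 0.47}),
        Gender.FEMALE: _interp({15: 0.008, 20: 0.03, 30: 0.09, 50: 0.22, 70: 0.34, 85: 0.36, 100: 0.36}),
    }
    prev_never, prev_current, prev_former = {}, {}, {}
    for g in GENDERS:
        prev_current[g] = AgeSchedule(START_AGE, cur[g])
        prev_former[g] = AgeSchedule(START_AGE, fmr[g])
        prev_never[g] = AgeSchedule(START_AGE, 1.0 - cur[g] - fmr[g])
    return prev_never, prev_current, prev_former


def _diseases() -> dict:
    # prevalence curves at population scale; relative risks at literature scale
    copd = {
        Gender.MALE: _interp({15: 0.001, 40: 0.02, 55: 0.05, 65: 0.09, 75: 0.12, 90: 0.13, 100: 0.13}),
        Gender.FEMALE: _interp({15: 0.001, 40: 0.02, 55: 0.05, 65: 0.085, 75: 0.11, 90: 0.12, 100: 0.12}),
    }
    chd = {
        Gender.MALE: _interp({15: 0.001, 40: 0.015, 55: 0.06, 65: 0.11, 75: 0.17, 90: 0.22, 100: 0.22}),
        Gender.FEMALE: _interp({15: 0.001, 40: 0.008, 55: 0.035, 65: 0.07, 75: 0.12, 90: 0.17, 100: 0.17}),
    }
    stroke = {
        Gender.MALE: _interp({15: 0.0005, 45: 0.008, 60: 0.025, 75: 0.06, 90: 0.09, 100: 0.09}),
        Gender.FEMALE: _interp({15: 0.0005, 45: 0.006, 60: 0.02, 75: 0.05, 90: 0.085, 100: 0.085}),
    }
    lc_inc = {  # annual lung-cancer incidence
        Gender.MALE: _interp({15: 0.0, 40: 0.0001, 55: 0.0008, 65: 0.002, 75: 0.003, 85: 0.0025, 100: 0.0015}),
        Gender.FEMALE: _interp({15: 0.0, 40: 0.0001, 55: 0.0007, 65: 0.0017, 75: 0.0026, 85: 0.0022, 100: 0.0013}),
    }
    mk = lambda d: {g: AgeSchedule(START_AGE, d[g]) for g in GENDERS}
    return {
        "COPD": DiseaseInputs("COPD", 12.0, 7.0, 2000.0, marginal_prevalence=mk(copd)),
        "CHD": DiseaseInputs("CHD", 2.5, 1.3, 2500.0, marginal_prevalence=mk(chd)),
        "stroke": DiseaseInputs("stroke", 2.0, 1.3, 5000.0, marginal_prevalence=mk(stroke)),
        "lung_cancer": DiseaseInputs(
            "lung_cancer", 20.0, 8.0, 20000.0, incidence=mk(lc_inc), mean_survival_years=2.0
        ),
    }


def _utilities() -> UtilityInputs:
    ages = _ages()
    by_status = {}
    for g in GENDERS:
        base = _interp({15: 0.92, 40: 0.88, 60: 0.84, 75: 0.79, 90: 0.72, 100: 0.65})
        if g is Gender.FEMALE:
            base = base - 0.005
        by_status[g] = {
            SmokingState.NEVER: AgeSchedule(START_AGE, np.clip(base, 0, 1)),
            SmokingState.CURRENT: AgeSchedule(START_AGE, np.clip(base - 0.04, 0, 1)),
            SmokingState.FORMER: AgeSchedule(START_AGE, np.clip(base - 0.02, 0, 1)),
        }
    return UtilityInputs(by_status)


def _econ() -> EconParams:
    ages = _ages()
    surv = {
        g: AgeSchedule(START_AGE, _interp({15: 900, 40: 1500, 60: 3200, 75: 6000, 85: 9000, 100: 12000}))
        for g in GENDERS
    }
    dec = {
        g: AgeSchedule(START_AGE, _interp({15: 32000, 50: 28000, 70: 22000, 85: 16000, 100: 12000}))
        for g in GENDERS
    }
    return EconParams(
        tax_per_smoker_year=1685.0,
        gdp_per_smoker_year=711.25,
        discount_rate_annual=0.015,
        unrelated_cost_survivor=surv,
        unrelated_cost_decedent=dec,
    )


def canadian_parameter_set(n_birth_years: int = 90) -> ParameterSet:
    """The full synthetic Canadian parameter set (see module docstring).

    ``n_birth_years`` policy-affected cohorts are listed, born 2010 onward,
    all at the 2025 census-scale sizes (stable entering cohorts).
    """
    prev_never, prev_current, prev_former = _status_prevalence()
    cohorts = [
        CohortSpec(by, g, COHORT_SIZES[g])
        for by in range(2010, 2010 + n_birth_years)
        for g in GENDERS
    ]
    ps = ParameterSet(
        transitions=_transitions(),
        mortality=MortalityInputs(
            marginal_death={g: AgeSchedule(START_AGE, _marginal_death(g)) for g in GENDERS},
            rr_current=_RR_DEATH[0],
            rr_former=_RR_DEATH[1],
            prev_never=prev_never,
            prev_current=prev_current,
            prev_former=prev_former,
        ),
        diseases=_diseases(),
        utilities=_utilities(),
        econ=_econ(),
        cohorts=cohorts,
        start_age=START_AGE,
        max_age=MAX_AGE,
    )
    validate_parameters(ps)
    return ps
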