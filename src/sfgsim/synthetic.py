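"""Synthetic parameter-set generator.

Produces complete, internally consistent model inputs with the statistical
structure the analysis assumes: smoking uptake concentrated in the late
teens and near zero after age 30, quit probability rising with age,
Gompertz–Makeham all-cause mortality, smoking-status prevalence consistent
with the long-run equilibrium of the generated start/quit/relapse
schedules, four smoking-related diseases with age-increasing prevalence,
status-specific utilities and per-smoker economic constants.  Everything is
deterministic in the seed, so every module is testable without any
external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .parameters import (
    DISEASES,
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
from .population import StandingPopulation

__all__ = ["SynthConfig", "generate", "generate_standing_population"]


@dataclass(frozen=True)
class SynthConfig:
    seed: int = 0
    #: persons per gender per birth-year cohort
    cohort_size_scale: float = 200_000.0
    n_birth_years: int = 90
    first_birth_year: int = 2010
    start_age: int = 15
    max_age: int = 100
    # smoking uptake: 6-month probability, bump centred on the late teens
    start_peak_age: float = 17.0
    start_peak_level: dict = field(
        default_factory=lambda: {Gender.MALE: 0.011, Gender.FEMALE: 0.007}
    )
    start_width_years: float = 3.0
    # quitting rises with age, relapse declines
    quit_base: float = 0.016
    quit_slope_per_year: float = 0.0005
    relapse_base: float = 0.008
    # Gompertz–Makeham annual hazard: a * exp(b * age) + c
    gompertz: dict = field(
        default_factory=lambda: {
            Gender.MALE: (2.3e-5, 0.094, 4.0e-4),
            Gender.FEMALE: (1.15e-5, 0.097, 2.0e-4),
        }
    )
    rr_death_current: float = 2.8
    rr_death_former: float = 1.3
    # disease -> (rr_current, rr_former, cost_6mo CAD)
    disease_rr_cost: dict = field(
        default_factory=lambda: {
            "COPD": (11.0, 7.0, 2200.0),
            "CHD": (2.3, 1.4, 3100.0),
            "stroke": (2.0, 1.3, 4600.0),
            "lung_cancer": (15.0, 5.0, 17500.0),
        }
    )
    lung_cancer_mean_survival: float = 2.5
    utility_at_15: float = 0.95
    utility_slope_per_year: float = 0.0022
    utility_decrement_current: float = 0.04
    utility_decrement_former: float = 0.015
    tax_per_smoker_year: float = 1685.0
    gdp_per_smoker_year: float = 711.25
    discount_rate_annual: float = 0.015
    #: relative jitter applied to level parameters per seed
    jitter_sd: float = 0.03
    #: default PSA dispersion shipped with the set (SE as fraction of mean)
    psa_dispersion: float = 0.1


def _ages(cfg: SynthConfig) -> np.ndarray:
    return np.arange(cfg.start_age, cfg.max_age + 1, dtype=float)


def _marginal_death(cfg: SynthConfig, g: Gender, jit: float) -> np.ndarray:
    a, b, c = cfg.gompertz[g]
    hazard = (a * jit) * np.exp(b * _ages(cfg)) + c
    return 1.0 - np.exp(-hazard / 2.0)  # 6-month probability


def _start_sched(cfg: SynthConfig, g: Gender, jit: float) -> np.ndarray:
    ages = _ages(cfg)
    bump = np.exp(-0.5 * ((ages - cfg.start_peak_age) / cfg.start_width_years) ** 2)
    vals = cfg.start_peak_level[g] * jit * bump
    vals[ages > 35] = 0.0
    return vals


def _equilibrium_shares(
    start: np.ndarray,
    quit_: np.ndarray,
    relapse: np.ndarray,
    death: np.ndarray,
    rr_current: float = 1.0,
    rr_former: float = 1.0,
    n_iter: int = 4,
) -> np.ndarray:
    """Status shares by age consistent with the transition schedules.

    ``death`` is the marginal schedule; the returned shares are the fixed
    point of (calibrate status-specific mortality from the shares) ->
    (propagate a cohort with those status-specific deaths) -> (read off the
    shares), so that simulating the full calibrated model reproduces them.
    """
    n = start.size
    shares = np.tile(np.array([1.0, 0.0, 0.0]), (n, 1))
    for _ in range(n_iter):
        denom = shares[:, 0] + shares[:, 1] * rr_current + shares[:, 2] * rr_former
        p_never = death / denom
        death_by_status = np.stack([p_never, rr_current * p_never, rr_former * p_never], axis=1)
        new = np.zeros((n, 3))
        occ = np.array([1.0, 0.0, 0.0])
        for i in range(n):
            for _half in range(2):  # two half-year cycles per year of age
                surv = occ * (1.0 - death_by_status[i])
                s, q, r = surv[0] * start[i], surv[1] * quit_[i], surv[2] * relapse[i]
                occ = np.array([surv[0] - s, surv[1] + s - q + r, surv[2] + q - r])
            tot = occ.sum()
            new[i] = occ / tot if tot > 0 else np.array([1.0, 0.0, 0.0])
        shares = new
    return shares


def generate(cfg: SynthConfig = SynthConfig()) -> ParameterSet:
    """Generate a complete validated ParameterSet, deterministic in the seed."""
    rng = np.random.default_rng(cfg.seed)
    ages = _ages(cfg)
    a0, a1 = cfg.start_age, cfg.max_age

    def jit() -> float:
        return float(np.exp(rng.normal(0.0, cfg.jitter_sd)))

    start, quit_, relapse, death = {}, {}, {}, {}
    for g in GENDERS:
        start[g] = AgeSchedule(a0, _start_sched(cfg, g, jit()))
        quit_[g] = AgeSchedule(
            a0, np.clip(cfg.quit_base * jit() + cfg.quit_slope_per_year * (ages - a0), 0, 0.12)
        )
        relapse[g] = AgeSchedule(a0, cfg.relapse_base * jit() * np.exp(-(ages - a0) / 30.0))
        death[g] = AgeSchedule(a0, _marginal_death(cfg, g, jit()))

    prev_never, prev_current, prev_former = {}, {}, {}
    for g in GENDERS:
        sh = _equilibrium_shares(
            start[g].values,
            quit_[g].values,
            relapse[g].values,
            death[g].values,
            cfg.rr_death_current,
            cfg.rr_death_former,
        )
        prev_never[g] = AgeSchedule(a0, sh[:, 0])
        prev_current[g] = AgeSchedule(a0, sh[:, 1])
        prev_former[g] = AgeSchedule(a0, sh[:, 2])

    diseases = {}
    shapes = {
        "COPD": (0.11, 67.0, 7.0),
        "CHD": (0.16, 70.0, 8.0),
        "stroke": (0.07, 72.0, 8.0),
    }
    for name, (rr_c, rr_f, cost) in cfg.disease_rr_cost.items():
        if name == "lung_cancer":
            inc = {}
            for g in GENDERS:
                level = 0.002 * jit()
                inc[g] = AgeSchedule(a0, level * np.exp(-0.5 * ((ages - 72.0) / 10.0) ** 2))
            diseases[name] = DiseaseInputs(
                name=name,
                rr_current=rr_c,
                rr_former=rr_f,
                cost_6mo=cost,
                incidence=inc,
                mean_survival_years=cfg.lung_cancer_mean_survival,
            )
        else:
            level, mid, width = shapes[name]
            prev = {}
            for g in GENDERS:
                lv = level * jit() * (1.0 if g is Gender.MALE else 0.85)
                prev[g] = AgeSchedule(a0, lv / (1.0 + np.exp(-(ages - mid) / width)))
            diseases[name] = DiseaseInputs(
                name=name, rr_current=rr_c, rr_former=rr_f, cost_6mo=cost, marginal_prevalence=prev
            )

    base_u = np.clip(cfg.utility_at_15 - cfg.utility_slope_per_year * (ages - a0), 0.0, 1.0)
    by_status = {}
    for g in GENDERS:
        shift = 0.0 if g is Gender.MALE else 0.005
        by_status[g] = {
            SmokingState.NEVER: AgeSchedule(a0, np.clip(base_u + shift, 0, 1)),
            SmokingState.CURRENT: AgeSchedule(
                a0, np.clip(base_u + shift - cfg.utility_decrement_current, 0, 1)
            ),
            SmokingState.FORMER: AgeSchedule(
                a0, np.clip(base_u + shift - cfg.utility_decrement_former, 0, 1)
            ),
        }

    surv_cost = {
        g: AgeSchedule(a0, 1200.0 * np.exp(0.033 * (ages - a0))) for g in GENDERS
    }
    dec_cost = {
        g: AgeSchedule(a0, np.maximum(32000.0 - 180.0 * (ages - a0), 12000.0)) for g in GENDERS
    }
    econ = EconParams(
        tax_per_smoker_year=cfg.tax_per_smoker_year,
        gdp_per_smoker_year=cfg.gdp_per_smoker_year,
        discount_rate_annual=cfg.discount_rate_annual,
        unrelated_cost_survivor=surv_cost,
        unrelated_cost_decedent=dec_cost,
    )

    cohorts = []
    for by in range(cfg.first_birth_year, cfg.first_birth_year + cfg.n_birth_years):
        for g in GENDERS:
            scale = 1.0 if g is Gender.MALE else 0.95
            cohorts.append(CohortSpec(by, g, cfg.cohort_size_scale * scale))

    ps = ParameterSet(
        transitions=TransitionInputs(start=start, quit=quit_, relapse=relapse),
        mortality=MortalityInputs(
            marginal_death=death,
            rr_current=cfg.rr_death_current,
            rr_former=cfg.rr_death_former,
            prev_never=prev_never,
            prev_current=prev_current,
            prev_former=prev_former,
        ),
        diseases=diseases,
        utilities=UtilityInputs(by_status),
        econ=econ,
        cohorts=cohorts,
        start_age=a0,
        max_age=a1,
    )
    validate_parameters(ps)
    return ps


def generate_standing_population(cfg: SynthConfig, ps: ParameterSet) -> StandingPopulation:
    """Standing population at 1 January 2025 built from the parameter set.

    The age pyramid scales the cohort size by survival implied by the
    marginal mortality schedule (a monotone-decreasing elderly tail); the
    status mix at each age equals the parameter set's status prevalence.
    """
    a0, a1 = ps.start_age, ps.max_age
    n_ages = a1 - a0 + 1
    counts = np.zeros((2, n_ages, 3))
    for gi, g in enumerate(GENDERS):
        q = ps.mortality.marginal_death[g].array(a0, a1)
        # survival from age 15 to each age (two cycles per year)
        surv = np.concatenate([[1.0], np.cumprod((1.0 - q) ** 2)[:-1]])
        size = cfg.cohort_size_scale * (1.0 if g is Gender.MALE else 0.95)
        pyramid = size * surv
        shares = np.stack(
            [
                ps.mortality.prev_never[g].array(a0, a1),
                ps.mortality.prev_current[g].array(a0, a1),
                ps.mortality.prev_former[g].array(a0, a1),
            ],
            axis=1,
        )
        counts[gi] = pyramid[:, None] * shares
    return StandingPopulation(start_age=a0, max_age=a1, counts=counts)
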