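"""Markov cohort engine: one birth-year x gender cohort from age 15 to death.

States are never / current / former smoker and dead.  Each 6-month cycle
applies (1) status-specific death, then (2) behaviour transitions among the
survivors: never->current ("start", the probability the policy acts on),
current->former ("quit") and former->current ("relapse").  Outcomes —
life-years, QALYs, smoking-related disease costs, smoking-unrelated health
care costs, tobacco tax and tobacco-industry GDP, incident disease cases —
accrue per cycle, discounted to a single reference date.

Accrual uses the midpoint convention: a person dying within a cycle
contributes half a cycle of life-years, QALYs and monetary flows at the
state they died from; discounting uses cycle-midpoint times.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .calibration import CalibratedSchedules
from .parameters import (
    DISEASES,
    GENDERS,
    CohortSpec,
    Gender,
    ParameterSet,
    SmokingState,
)

__all__ = [
    "PolicySpec",
    "STATUS_QUO",
    "FULL_BAN",
    "RunOptions",
    "CohortTrajectory",
    "CohortLedger",
    "step",
    "effective_start",
    "start_multipliers",
    "run_cohort",
    "premature_death_fraction",
    "OUTCOME_FIELDS",
]

#: ledger field names, fixed order
OUTCOME_FIELDS = (
    "life_years",
    "qalys",
    "disease_cost",
    "unrelated_cost",
    "tax",
    "gdp",
) + tuple(f"incident_{d}" for d in DISEASES) + tuple(f"prevalent_{d}" for d in DISEASES)


@dataclass(frozen=True)
class PolicySpec:
    """Smoke-free-generation policy arm.

    ``effectiveness`` is the fractional reduction of the start probability
    for banned cohorts (1.0 = complete ban, the base analysis).  During the
    first ``lag_years`` after policy start, cohorts born within the lag
    window (birth years in (cutoff, cutoff + lag]) can still obtain tobacco
    and their start probability is unchanged until the lag has elapsed.
    """

    kind: str = "status_quo"  # "status_quo" | "sfg"
    effectiveness: float = 0.0
    lag_years: int = 0

    def __post_init__(self):
        if self.kind not in ("status_quo", "sfg"):
            raise ValueError(f"unknown policy kind {self.kind!r}")
        if self.kind == "status_quo" and self.effectiveness != 0.0:
            object.__setattr__(self, "effectiveness", 0.0)
        if not 0.0 <= self.effectiveness <= 1.0:
            raise ValueError("effectiveness must be in [0, 1]")
        if self.lag_years < 0:
            raise ValueError("lag_years must be >= 0")


STATUS_QUO = PolicySpec("status_quo")
FULL_BAN = PolicySpec("sfg", effectiveness=1.0)


def effective_start(
    start: float,
    policy: PolicySpec,
    birth_year: int,
    calendar_year: int,
    policy_start_year: int = 2025,
    first_banned_birth_year: int = 2009,
) -> float:
    """Start probability after applying the policy to one cohort-year."""
    if policy.kind == "status_quo" or birth_year <= first_banned_birth_year:
        return start
    if calendar_year < policy_start_year:
        return start
    in_lag_window = birth_year <= first_banned_birth_year + policy.lag_years
    if in_lag_window and calendar_year < policy_start_year + policy.lag_years:
        return start
    return start * (1.0 - policy.effectiveness)


def start_multipliers(
    policy: PolicySpec,
    birth_year: int,
    calendar_years: np.ndarray,
    policy_start_year: int = 2025,
    first_banned_birth_year: int = 2009,
) -> np.ndarray:
    """Per-cycle multiplicative factor on the start probability."""
    return np.array(
        [
            effective_start(1.0, policy, birth_year, int(y), policy_start_year, first_banned_birth_year)
            for y in calendar_years
        ]
    )


def step(
    occ: np.ndarray,
    death_probs: np.ndarray,
    start: float,
    quit: float,
    relapse: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance one cycle. ``occ`` is (never, current, former, dead).

    Death (status-specific) acts first; survivors then make behaviour
    transitions.  Returns (new occupancy, deaths by living state).
    Conservation is exact: transitions only move mass between states.
    """
    living = occ[:3]
    deaths = living * death_probs
    surv = living - deaths
    started = surv[0] * start
    quitted = surv[1] * quit
    relapsed = surv[2] * relapse
    new = np.empty(4)
    new[0] = surv[0] - started
    new[1] = surv[1] + started - quitted + relapsed
    new[2] = surv[2] + quitted - relapsed
    new[3] = occ[3] + deaths.sum()
    return new, deaths


@dataclass(frozen=True)
class RunOptions:
    include_unrelated_costs: bool = False
    #: calendar year whose 1 January is discounting time-zero; None puts
    #: time-zero at the cohort's own entry
    discount_to: Optional[int] = 2025
    #: override the parameter file's annual discount rate (scenario analyses)
    discount_rate: Optional[float] = None


@dataclass
class CohortTrajectory:
    spec: CohortSpec
    occupancy: np.ndarray  # (n_cycles + 1, 4); row 0 = entry
    deaths_by_state: np.ndarray  # (n_cycles, 3)
    age_at_cycle: np.ndarray  # (n_cycles,) integer age during the cycle
    calendar_year_at_cycle: np.ndarray  # (n_cycles,)

    @property
    def n_cycles(self) -> int:
        return self.deaths_by_state.shape[0]

    @property
    def deaths_in_cycle(self) -> np.ndarray:
        return self.deaths_by_state.sum(axis=1)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "cycle": np.arange(self.n_cycles),
                "age": self.age_at_cycle,
                "calendar_year": self.calendar_year_at_cycle,
                "never": self.occupancy[1:, 0],
                "current": self.occupancy[1:, 1],
                "former": self.occupancy[1:, 2],
                "dead": self.occupancy[1:, 3],
                "deaths_in_cycle": self.deaths_in_cycle,
            }
        )


@dataclass
class CohortLedger:
    """Per-cycle accrued outcomes, undiscounted and discounted."""

    spec: CohortSpec
    calendar_year_at_cycle: np.ndarray
    undiscounted: dict  # field -> (n_cycles,) array
    discounted: dict

    def to_frame(self):
        import pandas as pd

        data = {"cycle": np.arange(len(self.calendar_year_at_cycle)),
                "calendar_year": self.calendar_year_at_cycle}
        for f in OUTCOME_FIELDS:
            data[f] = self.undiscounted[f]
            data[f + "_disc"] = self.discounted[f]
        return pd.DataFrame(data)

    def annual(self):
        """Sum cycles into calendar years (two cycles per year)."""
        return self.to_frame().drop(columns="cycle").groupby("calendar_year").sum()


def _accrue(
    traj: CohortTrajectory,
    gender: Gender,
    ps: ParameterSet,
    cal: CalibratedSchedules,
    options: RunOptions,
) -> CohortLedger:
    a0 = ps.start_age
    ages_idx = traj.age_at_cycle - a0
    occ_after = traj.occupancy[1:, :3]  # (N, 3)
    deaths = traj.deaths_by_state  # (N, 3)
    # midpoint convention: decedents count half a cycle at their prior state
    eff = occ_after + 0.5 * deaths

    u = np.stack(
        [
            ps.utilities.by_status[gender][st].array(a0, ps.max_age)
            for st in (SmokingState.NEVER, SmokingState.CURRENT, SmokingState.FORMER)
        ],
        axis=0,
    )  # (3, n_ages)
    u_cycle = u[:, ages_idx].T  # (N, 3)

    und = {}
    und["life_years"] = 0.5 * eff.sum(axis=1)
    und["qalys"] = 0.5 * (eff * u_cycle).sum(axis=1)
    und["tax"] = eff[:, 1] * ps.econ.tax_per_smoker_year / 2.0
    und["gdp"] = eff[:, 1] * ps.econ.gdp_per_smoker_year / 2.0

    disease_cost = np.zeros(traj.n_cycles)
    entry_occ = traj.occupancy[0, :3]
    alive_after = occ_after.sum(axis=1)
    alive_prev = np.concatenate([[entry_occ.sum()], alive_after[:-1]])
    for name in ps.diseases:
        p = cal.disease[name][gender]  # (3, n_ages)
        p_cycle = p[:, ages_idx].T  # (N, 3)
        prevalent = (occ_after * p_cycle).sum(axis=1)
        cases_mid = (eff * p_cycle).sum(axis=1)
        disease_cost += cases_mid * ps.diseases[name].cost_6mo
        prev0 = float(entry_occ @ p[:, ages_idx[0]])
        prev_last = np.concatenate([[prev0], prevalent[:-1]])
        with np.errstate(invalid="ignore", divide="ignore"):
            surv_frac = np.where(alive_prev > 0, alive_after / np.maximum(alive_prev, 1e-300), 0.0)
        und[f"incident_{name}"] = np.maximum(0.0, prevalent - prev_last * surv_frac)
        und[f"prevalent_{name}"] = prevalent
    und["disease_cost"] = disease_cost

    if options.include_unrelated_costs:
        cs = ps.econ.unrelated_cost_survivor[gender].array(a0, ps.max_age)[ages_idx]
        cd = ps.econ.unrelated_cost_decedent[gender].array(a0, ps.max_age)[ages_idx]
        und["unrelated_cost"] = alive_after * cs + deaths.sum(axis=1) * cd
    else:
        und["unrelated_cost"] = np.zeros(traj.n_cycles)

    r = options.discount_rate if options.discount_rate is not None else ps.econ.discount_rate_annual
    entry_year = traj.calendar_year_at_cycle[0]
    ref = options.discount_to if options.discount_to is not None else entry_year
    k = np.arange(traj.n_cycles)
    t_mid = (entry_year - ref) + 0.25 + 0.5 * k
    df = (1.0 + r) ** (-t_mid)
    disc = {f: v * df for f, v in und.items()}
    return CohortLedger(
        spec=traj.spec,
        calendar_year_at_cycle=traj.calendar_year_at_cycle,
        undiscounted=und,
        discounted=disc,
    )


def run_cohort(
    spec: CohortSpec,
    policy: PolicySpec,
    ps: ParameterSet,
    cal: CalibratedSchedules,
    options: RunOptions = RunOptions(),
) -> tuple[CohortTrajectory, CohortLedger]:
    """Simulate one cohort from entry at age 15 to forced absorption.

    The cohort enters 100% never smokers at age ``ps.start_age`` in calendar
    year ``birth_year + start_age``; it is stepped through two 6-month
    cycles per single year of age up to ``max_age``, after which any
    survivors are absorbed into dead (no outcomes accrue past ``max_age``).
    """
    gender = spec.gender
    a0 = ps.start_age
    n_ages = ps.n_ages
    n_cycles = 2 * n_ages
    ages = a0 + np.arange(n_cycles) // 2
    entry_year = spec.birth_year + a0
    years = entry_year + np.arange(n_cycles) // 2

    start_arr = ps.transitions.start[gender].array(a0, ps.max_age)
    quit_arr = ps.transitions.quit[gender].array(a0, ps.max_age)
    rel_arr = ps.transitions.relapse[gender].array(a0, ps.max_age)
    death = cal.death[gender]  # (3, n_ages)
    mult = start_multipliers(
        policy, spec.birth_year, years, ps.policy_start_year, ps.first_banned_birth_year
    )

    occupancy = np.zeros((n_cycles + 1, 4))
    deaths_by_state = np.zeros((n_cycles, 3))
    occupancy[0, 0] = spec.size
    occ = occupancy[0].copy()
    for kk in range(n_cycles):
        a = (ages[kk] - a0)
        occ, d = step(
            occ,
            death[:, a],
            start_arr[a] * mult[kk],
            quit_arr[a],
            rel_arr[a],
        )
        occupancy[kk + 1] = occ
        deaths_by_state[kk] = d

    traj = CohortTrajectory(
        spec=spec,
        occupancy=occupancy,
        deaths_by_state=deaths_by_state,
        age_at_cycle=ages,
        calendar_year_at_cycle=years,
    )
    ledger = _accrue(traj, gender, ps, cal, options)
    return traj, ledger


def premature_death_fraction(traj: CohortTrajectory, age_limit: int = 75) -> float:
    """Fraction of the entering cohort that dies before ``age_limit``."""
    if traj.age_at_cycle[-1] + 1 < age_limit:
        raise ValueError(f"trajectory ends before age {age_limit}")
    size = traj.occupancy[0, :3].sum()
    if size == 0:
        return 0.0
    mask = traj.age_at_cycle < age_limit
    return float(traj.deaths_by_state[mask].sum() / size)
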