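"""Multi-cohort rollup, horizon summaries, threshold-QALY and prevalence
projection.

Each birth-year cohort affected by the policy (born after the cutoff, i.e.
2010 onward) enters the model the year it turns 15; calendar-year ledgers
sum the two half-year cycles of every active cohort.  Net impact is
policy minus status quo with reporting sign conventions: QALYs and life
years as gains, health-care costs as amounts averted, taxes and GDP as
amounts foregone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Optional

import numpy as np
import pandas as pd

from .calibration import CalibratedSchedules
from .cohort import (
    OUTCOME_FIELDS,
    CohortLedger,
    CohortSpec,
    PolicySpec,
    RunOptions,
    STATUS_QUO,
    run_cohort,
    start_multipliers,
)
from .parameters import DISEASES, GENDERS, Gender, ParameterSet

__all__ = [
    "HORIZONS",
    "CalendarLedger",
    "HorizonSummary",
    "StandingPopulation",
    "UndefinedThresholdError",
    "run_all_cohorts",
    "rollup",
    "threshold_qaly",
    "project_prevalence",
]

HORIZONS = (10, 25, 50, 90)

#: net-impact column names (reporting sign conventions)
NET_FIELDS = (
    "life_years_gained",
    "qalys_gained",
    "hc_costs_averted",
    "unrelated_costs_averted",
    "tax_foregone",
    "gdp_foregone",
) + tuple(f"cases_prevented_{d}" for d in DISEASES)

# mapping net field -> (raw field, sign of policy-minus-status-quo difference)
_NET_MAP = {
    "life_years_gained": ("life_years", +1),
    "qalys_gained": ("qalys", +1),
    "hc_costs_averted": ("disease_cost", -1),
    "unrelated_costs_averted": ("unrelated_cost", -1),
    "tax_foregone": ("tax", -1),
    "gdp_foregone": ("gdp", -1),
    **{f"cases_prevented_{d}": (f"incident_{d}", -1) for d in DISEASES},
}


class UndefinedThresholdError(ValueError):
    """Threshold QALY value is undefined when net QALYs are not positive."""


def run_all_cohorts(
    ps: ParameterSet,
    cal: CalibratedSchedules,
    policy: PolicySpec,
    options: RunOptions = RunOptions(),
) -> dict:
    """Run every cohort in ``ps.cohorts``; returns {position: ledger}.

    With stationary parameters, cohorts that face the same per-cycle policy
    profile share one unit-size trajectory; the unit run is cached and each
    cohort's ledger is rebuilt by linear scaling and re-discounting.  The
    result is identical to running each cohort individually.
    """
    a0 = ps.start_age
    n_cycles = 2 * ps.n_ages
    r = options.discount_rate if options.discount_rate is not None else ps.econ.discount_rate_annual
    cache: dict = {}
    out: dict = {}
    for pos, spec in enumerate(ps.cohorts):
        entry_year = spec.birth_year + a0
        years = entry_year + np.arange(n_cycles) // 2
        mult = start_multipliers(
            policy, spec.birth_year, years, ps.policy_start_year, ps.first_banned_birth_year
        )
        key = (spec.gender, mult.tobytes())
        if key not in cache:
            unit_spec = CohortSpec(spec.birth_year, spec.gender, 1.0)
            _, unit_ledger = run_cohort(unit_spec, policy, ps, cal, options)
            cache[key] = unit_ledger
        unit = cache[key]
        ref = options.discount_to if options.discount_to is not None else entry_year
        t_mid = (entry_year - ref) + 0.25 + 0.5 * np.arange(n_cycles)
        df = (1.0 + r) ** (-t_mid)
        und = {f: unit.undiscounted[f] * spec.size for f in OUTCOME_FIELDS}
        out[pos] = CohortLedger(
            spec=spec,
            calendar_year_at_cycle=years,
            undiscounted=und,
            discounted={f: v * df for f, v in und.items()},
        )
    return out


def _annual_table(ledgers: Mapping, years_index: np.ndarray) -> pd.DataFrame:
    cols = {}
    for f in OUTCOME_FIELDS:
        cols[f] = np.zeros(len(years_index))
        cols[f + "_disc"] = np.zeros(len(years_index))
    y0 = int(years_index[0])
    for led in ledgers.values():
        idx = led.calendar_year_at_cycle - y0
        ok = (idx >= 0) & (idx < len(years_index))
        for f in OUTCOME_FIELDS:
            np.add.at(cols[f], idx[ok], led.undiscounted[f][ok])
            np.add.at(cols[f + "_disc"], idx[ok], led.discounted[f][ok])
    return pd.DataFrame(cols, index=pd.Index(years_index, name="calendar_year"))


@dataclass
class CalendarLedger:
    """Per-calendar-year outcome totals for both arms and their net impact."""

    status_quo: pd.DataFrame
    policy: pd.DataFrame
    net: pd.DataFrame  # NET_FIELDS columns, plus "_disc" variants

    @property
    def years(self) -> np.ndarray:
        return self.net.index.to_numpy()

    def horizon_summary(self, horizon: int, discounted: bool = True) -> "HorizonSummary":
        y0 = int(self.net.index[0])
        sub = self.net.loc[: y0 + horizon - 1]
        suffix = "_disc" if discounted else ""
        vals = {f: float(sub[f + suffix].sum()) for f in NET_FIELDS}
        return HorizonSummary(horizon=horizon, discounted=discounted, **vals)

    def cumulative_net(self, discounted: bool = True) -> pd.DataFrame:
        suffix = "_disc" if discounted else ""
        return self.net[[f + suffix for f in NET_FIELDS]].cumsum()


@dataclass(frozen=True)
class HorizonSummary:
    horizon: int
    life_years_gained: float
    qalys_gained: float
    hc_costs_averted: float
    unrelated_costs_averted: float
    tax_foregone: float
    gdp_foregone: float
    cases_prevented_COPD: float
    cases_prevented_CHD: float
    cases_prevented_stroke: float
    cases_prevented_lung_cancer: float
    discounted: bool = True

    def as_dict(self) -> dict:
        return {f: getattr(self, f) for f in NET_FIELDS}

    @property
    def total_costs_averted(self) -> float:
        return self.hc_costs_averted + self.unrelated_costs_averted


def rollup(
    ledgers_status_quo: Mapping,
    ledgers_policy: Mapping,
    start_year: Optional[int] = None,
    n_years: int = 90,
) -> CalendarLedger:
    """Aggregate cohort ledgers of both arms into calendar-year totals.

    Both arms must contain the same cohorts run with identical parameters;
    a mismatch raises.  ``start_year`` defaults to the earliest entry year.
    """
    if set(ledgers_status_quo) != set(ledgers_policy) or any(
        ledgers_status_quo[k].spec != ledgers_policy[k].spec for k in ledgers_status_quo
    ):
        raise ValueError("cohort sets differ between the two policy arms")
    if not ledgers_status_quo:
        raise ValueError("no cohorts supplied")
    if start_year is None:
        start_year = min(int(l.calendar_year_at_cycle[0]) for l in ledgers_status_quo.values())
    years = np.arange(start_year, start_year + n_years)
    sq = _annual_table(ledgers_status_quo, years)
    po = _annual_table(ledgers_policy, years)
    net = pd.DataFrame(index=sq.index)
    for nf, (raw, sign) in _NET_MAP.items():
        net[nf] = sign * (po[raw] - sq[raw])
        net[nf + "_disc"] = sign * (po[raw + "_disc"] - sq[raw + "_disc"])
    return CalendarLedger(status_quo=sq, policy=po, net=net)


def threshold_qaly(h: HorizonSummary) -> float:
    """Monetary value per QALY at which the policy's monetized benefits
    (QALYs at the threshold plus health-care costs averted) exactly offset
    tax revenue foregone plus the tobacco-industry GDP decline.

    May be negative when cost savings alone exceed the offsets.
    """
    if h.qalys_gained <= 0:
        raise UndefinedThresholdError("net QALYs must be positive for a threshold value")
    return (h.tax_foregone + h.gdp_foregone - h.total_costs_averted) / h.qalys_gained


# ---------------------------------------------------------------------------
# population-wide prevalence projection


@dataclass
class StandingPopulation:
    """Persons by gender, age and smoking status at 1 January 2025."""

    start_age: int
    max_age: int
    counts: np.ndarray  # (2, n_ages, 3): never / current / former

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (2, self.max_age - self.start_age + 1, 3):
            raise ValueError("counts must have shape (2, n_ages, 3)")
        if np.any(self.counts < 0):
            raise ValueError("negative standing-population count")

    @property
    def alive(self) -> float:
        return float(self.counts.sum())

    def smoking_prevalence(self) -> float:
        tot = self.counts.sum()
        return float(self.counts[:, :, 1].sum() / tot) if tot > 0 else 0.0


def _age_start_multiplier(
    ages: np.ndarray,
    year: int,
    policy: PolicySpec,
    policy_start_year: int,
    cutoff: int,
) -> np.ndarray:
    birth = year - ages
    banned = birth > cutoff
    if policy.kind == "status_quo" or year < policy_start_year:
        return np.ones_like(ages, dtype=float)
    in_lag = banned & (birth <= cutoff + policy.lag_years) & (year < policy_start_year + policy.lag_years)
    mult = np.ones_like(ages, dtype=float)
    mult[banned & ~in_lag] = 1.0 - policy.effectiveness
    return mult


def project_prevalence(
    standing: StandingPopulation,
    ps: ParameterSet,
    cal: CalibratedSchedules,
    policy: PolicySpec,
    n_years: int = 90,
    entrant_sizes: Optional[Callable[[int, Gender], float]] = None,
    targets: tuple = (0.05, 0.025),
) -> tuple[pd.DataFrame, dict]:
    """Project population smoking prevalence from 2025 onward.

    The standing population (born on or before the cutoff) always follows
    status-quo transitions; each year a new age-15 cohort (born after the
    cutoff) enters and follows the policy.  Cohort sizes come from
    ``ps.cohorts`` unless ``entrant_sizes(year, gender)`` is given; years
    beyond the listed cohorts reuse the latest listed size.

    Returns a per-year table (alive, current smokers, prevalence at year
    end) and, for each target, the first calendar year with prevalence
    strictly below it (None if never reached).
    """
    a0, a1 = ps.start_age, ps.max_age
    n_ages = a1 - a0 + 1
    ages = np.arange(a0, a1 + 1)
    year0 = ps.policy_start_year

    by_gender_sizes = {g: {} for g in GENDERS}
    for c in ps.cohorts:
        by_gender_sizes[c.gender][c.birth_year + a0] = c.size

    def entrants(year: int, g: Gender) -> float:
        if entrant_sizes is not None:
            return float(entrant_sizes(year, g))
        sizes = by_gender_sizes[g]
        if not sizes:
            return 0.0
        if year in sizes:
            return sizes[year]
        latest = max(y for y in sizes if y <= year) if any(y <= year for y in sizes) else min(sizes)
        return sizes[latest]

    P = standing.counts.copy()  # (2, n_ages, 3)
    start = np.stack([ps.transitions.start[g].array(a0, a1) for g in GENDERS])
    quit_ = np.stack([ps.transitions.quit[g].array(a0, a1) for g in GENDERS])
    relapse = np.stack([ps.transitions.relapse[g].array(a0, a1) for g in GENDERS])
    death = np.stack([cal.death[g] for g in GENDERS])  # (2, 3, n_ages)

    records = []
    first_below = {t: None for t in targets}
    for step_year in range(n_years):
        year = year0 + step_year
        for gi, g in enumerate(GENDERS):
            P[gi, 0, 0] += entrants(year, g)
        mult = np.stack(
            [
                _age_start_multiplier(ages, year, policy, ps.policy_start_year, ps.first_banned_birth_year)
                for _ in GENDERS
            ]
        )
        for _half in range(2):
            d = P * np.transpose(death, (0, 2, 1))  # (2, n_ages, 3)
            surv = P - d
            started = surv[:, :, 0] * start * mult
            quitted = surv[:, :, 1] * quit_
            relapsed = surv[:, :, 2] * relapse
            P = np.stack(
                [
                    surv[:, :, 0] - started,
                    surv[:, :, 1] + started - quitted + relapsed,
                    surv[:, :, 2] + quitted - relapsed,
                ],
                axis=2,
            )
        alive = float(P.sum())
        current = float(P[:, :, 1].sum())
        prev = current / alive if alive > 0 else 0.0
        records.append({"year": year, "alive": alive, "current_smokers": current, "prevalence": prev})
        for t in targets:
            if first_below[t] is None and prev < t:
                first_below[t] = year
        # birthday: everyone ages one year; survivors past max_age die
        P = np.concatenate([np.zeros((2, 1, 3)), P[:, :-1, :]], axis=1)
    table = pd.DataFrame(records).set_index("year")
    return table, first_below
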