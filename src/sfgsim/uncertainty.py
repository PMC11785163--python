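"""Probabilistic sensitivity analysis and the scenario grid.

Parameter uncertainty follows the conventional health-economic families:
probabilities, prevalences and utilities ~ Beta; costs (and other
non-negative amounts) ~ Gamma; relative risks ~ Lognormal.  Each value is
matched by method of moments to its mean and a standard error equal to a
stated fraction of the mean (default 10%) when no SE is supplied.  Draws
are reproducible from (seed, replicate index); structural constants (cycle
length, cohort sizes, discount rate) are not sampled.  Sampling happens
before calibration, which is re-run per replicate.
"""

from __future__ import annotations

import copy
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .calibration import build_calibrated
from .cohort import FULL_BAN, STATUS_QUO, PolicySpec, RunOptions
from .parameters import GENDERS, AgeSchedule, ParameterSet
from .population import (
    HORIZONS,
    NET_FIELDS,
    CalendarLedger,
    UndefinedThresholdError,
    rollup,
    run_all_cohorts,
    threshold_qaly,
)

__all__ = [
    "PsaConfig",
    "Scenario",
    "default_scenario_grid",
    "sample_parameters",
    "evaluate_scenario",
    "run_psa",
    "PsaResult",
    "run_scenario_suite",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PsaConfig:
    n_replications: int = 5000
    seed: int = 0
    #: standard error as a fraction of the mean when no SE is supplied
    dispersion: float = 0.1

    def __post_init__(self):
        if self.n_replications < 1:
            raise ValueError("n_replications must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


@dataclass(frozen=True)
class Scenario:
    """A fully specified run: policy arm, discount rate, cost scope."""

    name: str
    policy: PolicySpec = FULL_BAN
    discount_rate: Optional[float] = None  # None = parameter file's rate
    include_unrelated_costs: bool = False

    @property
    def options(self) -> RunOptions:
        return RunOptions(
            include_unrelated_costs=self.include_unrelated_costs,
            discount_rate=self.discount_rate,
        )


def default_scenario_grid() -> dict:
    """The published scenario set: base case plus the six variations."""
    return {
        "base": Scenario("base"),
        "effectiveness_90": Scenario("effectiveness_90", PolicySpec("sfg", effectiveness=0.9)),
        "lag_5y": Scenario("lag_5y", PolicySpec("sfg", effectiveness=1.0, lag_years=5)),
        "discount_0": Scenario("discount_0", discount_rate=0.0),
        "discount_3": Scenario("discount_3", discount_rate=0.03),
        "discount_5": Scenario("discount_5", discount_rate=0.05),
        "unrelated_costs_included": Scenario(
            "unrelated_costs_included", include_unrelated_costs=True
        ),
    }


# ---------------------------------------------------------------------------
# sampling


def _beta_draw(rng: np.random.Generator, mean: np.ndarray, disp: float) -> np.ndarray:
    """Beta draw matched to (mean, disp*mean); degenerate at 0/1; clipped
    normal fallback where the moment match is infeasible."""
    m = np.asarray(mean, dtype=float)
    out = m.copy()
    sd = disp * m
    interior = (m > 0) & (m < 1) & (sd > 0)
    feasible = interior & (sd**2 < m * (1 - m))
    if np.any(feasible):
        mm, ss = m[feasible], sd[feasible]
        nu = mm * (1 - mm) / ss**2 - 1.0
        out[feasible] = rng.beta(mm * nu, (1 - mm) * nu)
    infeasible = interior & ~feasible
    if np.any(infeasible):
        warnings.warn("Beta moment match infeasible; clipped-normal fallback")
        out[infeasible] = np.clip(rng.normal(m[infeasible], sd[infeasible]), 0.0, 1.0)
    return out


def _gamma_draw(rng: np.random.Generator, mean, disp: float):
    m = np.asarray(mean, dtype=float)
    out = m.copy()
    pos = m > 0
    if np.any(pos):
        shape = 1.0 / disp**2
        out[pos] = rng.gamma(shape, m[pos] * disp**2)
    return out if out.ndim else float(out)


def _lognormal_draw(rng: np.random.Generator, mean: float, disp: float) -> float:
    if mean <= 0:
        return mean
    sigma2 = np.log1p(disp**2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def _sample_sched(rng, sched: AgeSchedule, draw, disp) -> AgeSchedule:
    return AgeSchedule(sched.start_age, draw(rng, sched.values, disp))


def sample_parameters(ps: ParameterSet, cfg: PsaConfig, replicate: int) -> ParameterSet:
    """One Monte-Carlo draw of the uncertain parameters.

    Probabilities/prevalences/utilities ~ Beta, costs ~ Gamma, relative
    risks ~ Lognormal; status-prevalence shares are renormalized to sum to
    one after sampling.  ``dispersion == 0`` returns the input set.
    """
    out = copy.deepcopy(ps)
    if cfg.dispersion == 0:
        return out
    rng = np.random.default_rng([int(cfg.seed), int(replicate)])
    d = cfg.dispersion

    for g in GENDERS:
        out.transitions.start[g] = _sample_sched(rng, ps.transitions.start[g], _beta_draw, d)
        out.transitions.quit[g] = _sample_sched(rng, ps.transitions.quit[g], _beta_draw, d)
        out.transitions.relapse[g] = _sample_sched(rng, ps.transitions.relapse[g], _beta_draw, d)
        out.mortality.marginal_death[g] = _sample_sched(
            rng, ps.mortality.marginal_death[g], _beta_draw, d
        )
        wc = _beta_draw(rng, ps.mortality.prev_current[g].values, d)
        wf = _beta_draw(rng, ps.mortality.prev_former[g].values, d)
        wn = ps.mortality.prev_never[g].values.copy()
        tot = wn + wc + wf
        a0 = ps.mortality.prev_never[g].start_age
        out.mortality.prev_never[g] = AgeSchedule(a0, wn / tot)
        out.mortality.prev_current[g] = AgeSchedule(a0, wc / tot)
        out.mortality.prev_former[g] = AgeSchedule(a0, wf / tot)
    out.mortality.rr_current = _lognormal_draw(rng, ps.mortality.rr_current, d)
    out.mortality.rr_former = _lognormal_draw(rng, ps.mortality.rr_former, d)

    for name, di in ps.diseases.items():
        o = out.diseases[name]
        o.rr_current = _lognormal_draw(rng, di.rr_current, d)
        o.rr_former = _lognormal_draw(rng, di.rr_former, d)
        o.cost_6mo = float(_gamma_draw(rng, np.array(di.cost_6mo), d))
        if di.marginal_prevalence is not None:
            for g in GENDERS:
                o.marginal_prevalence[g] = _sample_sched(
                    rng, di.marginal_prevalence[g], _beta_draw, d
                )
        if di.incidence is not None:
            for g in GENDERS:
                o.incidence[g] = _sample_sched(rng, di.incidence[g], _gamma_draw, d)
            o.mean_survival_years = float(_gamma_draw(rng, np.array(di.mean_survival_years), d))

    for g in GENDERS:
        for st, sched in ps.utilities.by_status[g].items():
            out.utilities.by_status[g][st] = _sample_sched(rng, sched, _beta_draw, d)

    out.econ.tax_per_smoker_year = float(_gamma_draw(rng, np.array(ps.econ.tax_per_smoker_year), d))
    out.econ.gdp_per_smoker_year = float(_gamma_draw(rng, np.array(ps.econ.gdp_per_smoker_year), d))
    for g in GENDERS:
        out.econ.unrelated_cost_survivor[g] = _sample_sched(
            rng, ps.econ.unrelated_cost_survivor[g], _gamma_draw, d
        )
        out.econ.unrelated_cost_decedent[g] = _sample_sched(
            rng, ps.econ.unrelated_cost_decedent[g], _gamma_draw, d
        )
    return out


# ---------------------------------------------------------------------------
# deterministic scenario evaluation


def evaluate_scenario(ps: ParameterSet, scenario: Scenario, n_years: int = 90) -> CalendarLedger:
    """Full pipeline for one scenario: calibrate, run both arms, roll up."""
    cal = build_calibrated(ps)
    opts = scenario.options
    sq = run_all_cohorts(ps, cal, STATUS_QUO, opts)
    po = run_all_cohorts(ps, cal, scenario.policy, opts)
    return rollup(sq, po, n_years=n_years)


def run_scenario_suite(
    ps: ParameterSet,
    grid: Optional[Mapping[str, Scenario]] = None,
    horizon: int = 50,
    n_years: int = 90,
) -> pd.DataFrame:
    """One row per scenario: cumulative discounted net outcomes at the
    horizon plus the threshold QALY value."""
    grid = dict(grid) if grid is not None else default_scenario_grid()
    rows = []
    for name, sc in grid.items():
        cl = evaluate_scenario(ps, sc, n_years=max(n_years, horizon))
        h = cl.horizon_summary(horizon)
        row = {"scenario": name, **h.as_dict()}
        try:
            row["threshold_qaly"] = threshold_qaly(h)
        except UndefinedThresholdError:
            row["threshold_qaly"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("scenario")


# ---------------------------------------------------------------------------
# PSA


@dataclass
class PsaResult:
    """Replicate-level outcomes and order-independent summaries."""

    replicates: pd.DataFrame  # index replicate, columns (horizon, field)
    summary: pd.DataFrame  # index (horizon, field), columns mean/sd/q025/q975
    n_failed: int
    failures: list = field(default_factory=list)


def run_psa(
    ps: ParameterSet,
    cfg: PsaConfig,
    scenario: Optional[Scenario] = None,
    horizons: tuple = HORIZONS,
    n_years: int = 90,
) -> PsaResult:
    """Monte-Carlo propagation of parameter uncertainty.

    Each replicate samples a parameter set, re-runs calibration and both
    policy arms, and records every horizon summary plus the threshold QALY
    value.  Failed replicates are recorded and excluded; more than 1%
    failing raises.
    """
    scenario = scenario or Scenario("base")
    rows = {}
    failures = []
    for rep in range(cfg.n_replications):
        try:
            sampled = sample_parameters(ps, cfg, rep)
            cl = evaluate_scenario(sampled, scenario, n_years=n_years)
            row = {}
            for h in horizons:
                hs = cl.horizon_summary(h)
                for f in NET_FIELDS:
                    row[(h, f)] = getattr(hs, f)
                try:
                    row[(h, "threshold_qaly")] = threshold_qaly(hs)
                except UndefinedThresholdError:
                    row[(h, "threshold_qaly")] = np.nan
            rows[rep] = row
        except Exception as exc:  # noqa: BLE001 - replicate isolation
            log.warning("replicate %d failed: %s", rep, exc)
            failures.append((rep, repr(exc)))
    if len(failures) > 0.01 * cfg.n_replications:
        raise RuntimeError(f"{len(failures)} of {cfg.n_replications} PSA replicates failed")
    reps = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    reps.columns = pd.MultiIndex.from_tuples(reps.columns, names=["horizon", "field"])
    summary = pd.DataFrame(
        {
            "mean": reps.mean(),
            "sd": reps.std(ddof=1) if len(reps) > 1 else reps.std(ddof=0),
            "q025": reps.quantile(0.025),
            "q975": reps.quantile(0.975),
        }
    )
    summary.index.names = ["horizon", "field"]
    return PsaResult(replicates=reps, summary=summary, n_failed=len(failures), failures=failures)
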