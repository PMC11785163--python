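"""Model parameter set: domain types, validation, file I/O.

The parameter file mirrors the published input table of a gender-stratified
Markov cohort model of smoking behaviour: age–gender schedules of start /
quit / relapse probabilities, all-cause mortality, smoking-status prevalence,
prevalence / incidence and costs for four smoking-related diseases (COPD,
CHD, stroke, lung cancer), utility values by smoking status, and economic
constants (tobacco tax and tobacco-industry GDP per smoker, discount rate,
smoking-unrelated health-care costs).

All probabilities are stored as 6-month (per-cycle) probabilities at
single-year age resolution; a file may declare ``basis: annual`` to have
transition and mortality probabilities converted on load.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "Gender",
    "SmokingState",
    "DISEASES",
    "AgeSchedule",
    "TransitionInputs",
    "MortalityInputs",
    "DiseaseInputs",
    "UtilityInputs",
    "EconParams",
    "CohortSpec",
    "ParameterSet",
    "ParameterError",
    "SchemaError",
    "ValidationError",
    "annual_to_cycle_probability",
    "load_parameters",
    "save_parameters",
    "export_csv",
    "import_csv",
]


class ParameterError(ValueError):
    """Base class for parameter-file problems."""


class SchemaError(ParameterError):
    """A required stratum / block is missing or malformed."""


class ValidationError(ParameterError):
    """A value is outside its admissible range."""


class Gender(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


GENDERS: tuple[Gender, Gender] = (Gender.MALE, Gender.FEMALE)


class SmokingState(str, enum.Enum):
    NEVER = "never"
    CURRENT = "current"
    FORMER = "former"
    DEAD = "dead"


#: living states, in the engine's canonical order
LIVING_STATES = (SmokingState.NEVER, SmokingState.CURRENT, SmokingState.FORMER)

DISEASES: tuple[str, ...] = ("COPD", "CHD", "stroke", "lung_cancer")


def annual_to_cycle_probability(p_annual: float) -> float:
    """Convert an annual probability to the equivalent 6-month probability.

    Uses the constant-hazard identity ``1 - (1 - p)**0.5`` so that two
    consecutive cycles reproduce the annual probability exactly.
    """
    p = float(p_annual)
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"annual probability {p!r} outside [0, 1]")
    return 1.0 - (1.0 - p) ** 0.5


@dataclass
class AgeSchedule:
    """One real value per single year of age, from ``start_age`` upward.

    Lookups below ``start_age`` return the first value and lookups beyond
    the last listed age return the last value (age capping).
    """

    start_age: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.start_age = int(self.start_age)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise SchemaError("AgeSchedule needs a 1-d sequence of length >= 1")

    @classmethod
    def from_points(
        cls, points: Mapping[int, float], start_age: int, max_age: int
    ) -> "AgeSchedule":
        """Densify sparse ``{age: value}`` points to single-year resolution.

        Values are piecewise-constant: each age takes the value of the
        nearest specified age at or below it (the first specified value
        before that).  Supports coarser stratifications such as 5-year bands.
        """
        if not points:
            raise SchemaError("empty points mapping for AgeSchedule")
        ages = np.array(sorted(int(a) for a in points))
        vals = np.array([float(points[a]) for a in ages])
        grid = np.arange(start_age, max_age + 1)
        idx = np.clip(np.searchsorted(ages, grid, side="right") - 1, 0, len(ages) - 1)
        return cls(start_age, vals[idx])

    @property
    def max_listed_age(self) -> int:
        return self.start_age + self.values.size - 1

    def at(self, age: int) -> float:
        idx = int(np.clip(int(age) - self.start_age, 0, self.values.size - 1))
        return float(self.values[idx])

    def array(self, start_age: int, max_age: int) -> np.ndarray:
        """Values for every age in ``start_age..max_age`` inclusive, capped."""
        ages = np.arange(start_age, max_age + 1)
        idx = np.clip(ages - self.start_age, 0, self.values.size - 1)
        return self.values[idx]

    def map(self, fn) -> "AgeSchedule":
        return AgeSchedule(self.start_age, np.array([fn(v) for v in self.values]))

    def __eq__(self, other) -> bool:  # value equality, for round-trip tests
        return (
            isinstance(other, AgeSchedule)
            and self.start_age == other.start_age
            and self.values.shape == other.values.shape
            and bool(np.all(self.values == other.values))
        )


GenderSchedules = dict  # Gender -> AgeSchedule


@dataclass
class TransitionInputs:
    """6-month smoking-behaviour transition probabilities, by gender."""

    start: GenderSchedules
    quit: GenderSchedules
    relapse: GenderSchedules


@dataclass
class MortalityInputs:
    """Marginal all-cause 6-month death probability, status prevalence and
    the relative risks of death for current/former vs never smokers."""

    marginal_death: GenderSchedules
    rr_current: float
    rr_former: float
    prev_never: GenderSchedules
    prev_current: GenderSchedules
    prev_former: GenderSchedules


@dataclass
class DiseaseInputs:
    """One smoking-related disease: prevalence (or incidence for lung
    cancer), relative risks of disease vs never smokers, 6-month cost per
    prevalent case (2023 CAD)."""

    name: str
    rr_current: float
    rr_former: float
    cost_6mo: float
    marginal_prevalence: GenderSchedules | None = None
    incidence: GenderSchedules | None = None  # annual incidence (lung cancer)
    mean_survival_years: float | None = None


@dataclass
class UtilityInputs:
    """Utility by age, gender and smoking status; dead has utility 0.

    Smoking-status utilities already embody disease burden, so no separate
    disease disutilities exist (double-counting guard).
    """

    by_status: dict  # Gender -> {SmokingState(living): AgeSchedule}


@dataclass
class EconParams:
    tax_per_smoker_year: float
    gdp_per_smoker_year: float
    discount_rate_annual: float
    unrelated_cost_survivor: GenderSchedules
    unrelated_cost_decedent: GenderSchedules


@dataclass(frozen=True)
class CohortSpec:
    birth_year: int
    gender: Gender
    size: float


@dataclass
class ParameterSet:
    transitions: TransitionInputs
    mortality: MortalityInputs
    diseases: dict  # name -> DiseaseInputs
    utilities: UtilityInputs
    econ: EconParams
    cohorts: list = field(default_factory=list)
    start_age: int = 15
    max_age: int = 100
    cycle_length: float = 0.5
    policy_start_year: int = 2025
    first_banned_birth_year: int = 2009  # exclusive: born AFTER this is banned

    @property
    def n_ages(self) -> int:
        return self.max_age - self.start_age + 1

    def copy(self) -> "ParameterSet":
        import copy as _copy

        return _copy.deepcopy(self)

    def validate(self) -> None:
        validate_parameters(self)


# ---------------------------------------------------------------------------
# validation


def _check_prob_schedule(sched: AgeSchedule, where: str) -> None:
    bad = np.where((sched.values < 0) | (sched.values > 1))[0]
    if bad.size:
        age = sched.start_age + int(bad[0])
        raise ValidationError(
            f"probability {sched.values[bad[0]]!r} outside [0, 1] at {where}/{age}"
        )


def _check_nonneg_schedule(sched: AgeSchedule, where: str) -> None:
    bad = np.where(sched.values < 0)[0]
    if bad.size:
        age = sched.start_age + int(bad[0])
        raise ValidationError(f"negative value at {where}/{age}")


def _require_genders(mapping: Mapping, where: str) -> None:
    for g in GENDERS:
        if g not in mapping:
            raise SchemaError(f"missing gender {g.value!r} in {where}")


def validate_parameters(ps: ParameterSet) -> None:
    """Check every structural and range invariant; raise with the location."""
    if ps.cycle_length != 0.5:
        raise ValidationError("cycle_length is fixed at 0.5 years")
    for name, sch in (
        ("start", ps.transitions.start),
        ("quit", ps.transitions.quit),
        ("relapse", ps.transitions.relapse),
    ):
        _require_genders(sch, f"transitions/{name}")
        for g in GENDERS:
            _check_prob_schedule(sch[g], f"{name}/{g.value}")

    _require_genders(ps.mortality.marginal_death, "mortality/marginal_death")
    for g in GENDERS:
        _check_prob_schedule(ps.mortality.marginal_death[g], f"marginal_death/{g.value}")
    if ps.mortality.rr_current < 1 or ps.mortality.rr_former < 1:
        warnings.warn(
            "mortality relative risk below 1 (current %.3g, former %.3g)"
            % (ps.mortality.rr_current, ps.mortality.rr_former)
        )
    for g in GENDERS:
        wn = ps.mortality.prev_never[g].array(ps.start_age, ps.max_age)
        wc = ps.mortality.prev_current[g].array(ps.start_age, ps.max_age)
        wf = ps.mortality.prev_former[g].array(ps.start_age, ps.max_age)
        for nm, w in (("never", wn), ("current", wc), ("former", wf)):
            if np.any((w < 0) | (w > 1)):
                age = ps.start_age + int(np.where((w < 0) | (w > 1))[0][0])
                raise ValidationError(
                    f"status share outside [0, 1] at status_prevalence/{g.value}/{nm}/{age}"
                )
        s = wn + wc + wf
        if np.any(np.abs(s - 1.0) > 1e-9):
            age = ps.start_age + int(np.argmax(np.abs(s - 1.0)))
            raise ValidationError(
                f"status shares sum to {s[age - ps.start_age]:.12g} != 1 at "
                f"status_prevalence/{g.value}/{age}"
            )

    for d in DISEASES:
        if d not in ps.diseases:
            raise SchemaError(f"missing disease block {d!r}")
        di = ps.diseases[d]
        if di.cost_6mo < 0:
            raise ValidationError(f"negative cost at diseases/{d}/cost_6mo")
        if di.rr_current <= 0 or di.rr_former <= 0:
            raise ValidationError(f"non-positive relative risk at diseases/{d}")
        if di.marginal_prevalence is not None:
            _require_genders(di.marginal_prevalence, f"diseases/{d}/prevalence")
            for g in GENDERS:
                _check_prob_schedule(di.marginal_prevalence[g], f"{d}/prevalence/{g.value}")
        elif di.incidence is not None:
            _require_genders(di.incidence, f"diseases/{d}/incidence")
            for g in GENDERS:
                _check_nonneg_schedule(di.incidence[g], f"{d}/incidence/{g.value}")
            if not di.mean_survival_years or di.mean_survival_years <= 0:
                raise ValidationError(
                    f"diseases/{d}: mean_survival_years must be > 0 when incidence is given"
                )
        else:
            raise SchemaError(f"diseases/{d}: need marginal_prevalence or incidence")

    _require_genders(ps.utilities.by_status, "utilities")
    for g in GENDERS:
        for st in LIVING_STATES:
            if st not in ps.utilities.by_status[g]:
                raise SchemaError(f"missing utilities/{g.value}/{st.value}")
            _check_prob_schedule(
                ps.utilities.by_status[g][st], f"utilities/{g.value}/{st.value}"
            )

    ec = ps.econ
    if ec.tax_per_smoker_year < 0 or ec.gdp_per_smoker_year < 0:
        raise ValidationError("negative economic constant in econ block")
    if not 0 <= ec.discount_rate_annual < 1:
        raise ValidationError(
            f"discount_rate_annual {ec.discount_rate_annual!r} outside [0, 1)"
        )
    for nm, sch in (
        ("unrelated_cost_survivor", ec.unrelated_cost_survivor),
        ("unrelated_cost_decedent", ec.unrelated_cost_decedent),
    ):
        _require_genders(sch, f"econ/{nm}")
        for g in GENDERS:
            _check_nonneg_schedule(sch[g], f"econ/{nm}/{g.value}")

    for c in ps.cohorts:
        if c.size < 0:
            raise ValidationError(f"cohorts: negative size for {c.birth_year}/{c.gender.value}")


# ---------------------------------------------------------------------------
# YAML serialization


def _sched_to_yaml(s: AgeSchedule) -> dict:
    return {"start_age": s.start_age, "values": [float(v) for v in s.values]}


def _sched_from_yaml(node, where: str, ps_start: int, ps_max: int) -> AgeSchedule:
    if not isinstance(node, Mapping):
        raise SchemaError(f"schedule at {where} must be a mapping")
    if "values" in node:
        return AgeSchedule(int(node.get("start_age", ps_start)), node["values"])
    if "points" in node:
        return AgeSchedule.from_points(node["points"], ps_start, ps_max)
    raise SchemaError(f"schedule at {where} needs 'values' or 'points'")


def _gender_scheds_to_yaml(d: GenderSchedules) -> dict:
    return {g.value: _sched_to_yaml(d[g]) for g in GENDERS}


def _gender_scheds_from_yaml(node, where, start, max_age, convert=False) -> GenderSchedules:
    if not isinstance(node, Mapping):
        raise SchemaError(f"block {where} must map gender to schedule")
    out = {}
    for g in GENDERS:
        if g.value not in node:
            raise SchemaError(f"missing gender {g.value!r} in {where}")
        s = _sched_from_yaml(node[g.value], f"{where}/{g.value}", start, max_age)
        if convert:
            s = s.map(annual_to_cycle_probability)
        out[g] = s
    return out


def save_parameters(ps: ParameterSet, path) -> None:
    """Write a ParameterSet to a YAML parameter file (one block per panel)."""
    doc = {
        "meta": {
            "start_age": ps.start_age,
            "max_age": ps.max_age,
            "cycle_length": ps.cycle_length,
            "policy_start_year": ps.policy_start_year,
            "first_banned_birth_year": ps.first_banned_birth_year,
            "basis": "semiannual",
        },
        "transitions": {
            "start": _gender_scheds_to_yaml(ps.transitions.start),
            "quit": _gender_scheds_to_yaml(ps.transitions.quit),
            "relapse": _gender_scheds_to_yaml(ps.transitions.relapse),
        },
        "mortality": {
            "rr_current": float(ps.mortality.rr_current),
            "rr_former": float(ps.mortality.rr_former),
            "marginal_death": _gender_scheds_to_yaml(ps.mortality.marginal_death),
        },
        "status_prevalence": {
            "never": _gender_scheds_to_yaml(ps.mortality.prev_never),
            "current": _gender_scheds_to_yaml(ps.mortality.prev_current),
            "former": _gender_scheds_to_yaml(ps.mortality.prev_former),
        },
        "diseases": {},
        "utilities": {
            g.value: {
                st.value: _sched_to_yaml(ps.utilities.by_status[g][st])
                for st in LIVING_STATES
            }
            for g in GENDERS
        },
        "econ": {
            "tax_per_smoker_year": float(ps.econ.tax_per_smoker_year),
            "gdp_per_smoker_year": float(ps.econ.gdp_per_smoker_year),
            "discount_rate_annual": float(ps.econ.discount_rate_annual),
            "unrelated_cost_survivor": _gender_scheds_to_yaml(ps.econ.unrelated_cost_survivor),
            "unrelated_cost_decedent": _gender_scheds_to_yaml(ps.econ.unrelated_cost_decedent),
        },
        "cohorts": [
            {"birth_year": c.birth_year, "gender": c.gender.value, "size": float(c.size)}
            for c in ps.cohorts
        ],
    }
    for name, di in ps.diseases.items():
        blk: dict = {
            "rr_current": float(di.rr_current),
            "rr_former": float(di.rr_former),
            "cost_6mo": float(di.cost_6mo),
        }
        if di.marginal_prevalence is not None:
            blk["prevalence"] = _gender_scheds_to_yaml(di.marginal_prevalence)
        if di.incidence is not None:
            blk["incidence"] = _gender_scheds_to_yaml(di.incidence)
            blk["mean_survival_years"] = float(di.mean_survival_years)
        doc["diseases"][name] = blk
    text = yaml.safe_dump(doc, sort_keys=False, default_flow_style=None, width=100)
    Path(path).write_text(text)


def load_parameters(path) -> ParameterSet:
    """Read and validate a YAML parameter file; densify all age schedules."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(path)
    doc = yaml.safe_load(p.read_text())
    if not isinstance(doc, Mapping):
        raise SchemaError("parameter file must be a YAML mapping")
    meta = doc.get("meta", {})
    start_age = int(meta.get("start_age", 15))
    max_age = int(meta.get("max_age", 100))
    annual = meta.get("basis", "semiannual") == "annual"

    for blk in ("transitions", "mortality", "status_prevalence", "diseases", "utilities", "econ"):
        if blk not in doc:
            raise SchemaError(f"missing block {blk!r}")

    tr = doc["transitions"]
    transitions = TransitionInputs(
        start=_gender_scheds_from_yaml(tr.get("start"), "transitions/start", start_age, max_age, annual),
        quit=_gender_scheds_from_yaml(tr.get("quit"), "transitions/quit", start_age, max_age, annual),
        relapse=_gender_scheds_from_yaml(tr.get("relapse"), "transitions/relapse", start_age, max_age, annual),
    )
    mo, sp = doc["mortality"], doc["status_prevalence"]
    mortality = MortalityInputs(
        marginal_death=_gender_scheds_from_yaml(
            mo.get("marginal_death"), "mortality/marginal_death", start_age, max_age, annual
        ),
        rr_current=float(mo["rr_current"]),
        rr_former=float(mo["rr_former"]),
        prev_never=_gender_scheds_from_yaml(sp.get("never"), "status_prevalence/never", start_age, max_age),
        prev_current=_gender_scheds_from_yaml(sp.get("current"), "status_prevalence/current", start_age, max_age),
        prev_former=_gender_scheds_from_yaml(sp.get("former"), "status_prevalence/former", start_age, max_age),
    )
    diseases = {}
    for name, blk in doc["diseases"].items():
        diseases[name] = DiseaseInputs(
            name=name,
            rr_current=float(blk["rr_current"]),
            rr_former=float(blk["rr_former"]),
            cost_6mo=float(blk["cost_6mo"]),
            marginal_prevalence=(
                _gender_scheds_from_yaml(blk["prevalence"], f"diseases/{name}/prevalence", start_age, max_age)
                if "prevalence" in blk
                else None
            ),
            incidence=(
                _gender_scheds_from_yaml(blk["incidence"], f"diseases/{name}/incidence", start_age, max_age)
                if "incidence" in blk
                else None
            ),
            mean_survival_years=(
                float(blk["mean_survival_years"]) if "mean_survival_years" in blk else None
            ),
        )
    ut = doc["utilities"]
    by_status = {}
    for g in GENDERS:
        if g.value not in ut:
            raise SchemaError(f"missing gender {g.value!r} in utilities")
        by_status[g] = {}
        for st in LIVING_STATES:
            if st.value not in ut[g.value]:
                raise SchemaError(f"missing utilities/{g.value}/{st.value}")
            by_status[g][st] = _sched_from_yaml(
                ut[g.value][st.value], f"utilities/{g.value}/{st.value}", start_age, max_age
            )
    ec = doc["econ"]
    econ = EconParams(
        tax_per_smoker_year=float(ec["tax_per_smoker_year"]),
        gdp_per_smoker_year=float(ec["gdp_per_smoker_year"]),
        discount_rate_annual=float(ec["discount_rate_annual"]),
        unrelated_cost_survivor=_gender_scheds_from_yaml(
            ec.get("unrelated_cost_survivor"), "econ/unrelated_cost_survivor", start_age, max_age
        ),
        unrelated_cost_decedent=_gender_scheds_from_yaml(
            ec.get("unrelated_cost_decedent"), "econ/unrelated_cost_decedent", start_age, max_age
        ),
    )
    cohorts = [
        CohortSpec(int(c["birth_year"]), Gender(c["gender"]), float(c["size"]))
        for c in doc.get("cohorts", [])
    ]
    ps = ParameterSet(
        transitions=transitions,
        mortality=mortality,
        diseases=diseases,
        utilities=UtilityInputs(by_status),
        econ=econ,
        cohorts=cohorts,
        start_age=start_age,
        max_age=max_age,
        cycle_length=float(meta.get("cycle_length", 0.5)),
        policy_start_year=int(meta.get("policy_start_year", 2025)),
        first_banned_birth_year=int(meta.get("first_banned_birth_year", 2009)),
    )
    validate_parameters(ps)
    return ps


# ---------------------------------------------------------------------------
# flat CSV export / import (one table per panel)


#: full-precision CSV export so import reproduces every float bit-exactly
_CSV_KW = {"index": False, "float_format": "%.17g"}


def export_csv(ps: ParameterSet, directory) -> None:
    import pandas as pd

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    ages = np.arange(ps.start_age, ps.max_age + 1)

    def long(scheds: GenderSchedules, col: str) -> "pd.DataFrame":
        rows = []
        for g in GENDERS:
            rows.append(
                pd.DataFrame(
                    {"gender": g.value, "age": ages, col: scheds[g].array(ps.start_age, ps.max_age)}
                )
            )
        return pd.concat(rows, ignore_index=True)

    tr = long(ps.transitions.start, "start")
    tr["quit"] = long(ps.transitions.quit, "quit")["quit"]
    tr["relapse"] = long(ps.transitions.relapse, "relapse")["relapse"]
    tr.to_csv(d / "transitions.csv", **_CSV_KW)

    mo = long(ps.mortality.marginal_death, "marginal_death")
    mo.to_csv(d / "mortality.csv", **_CSV_KW)
    sp = long(ps.mortality.prev_never, "never")
    sp["current"] = long(ps.mortality.prev_current, "current")["current"]
    sp["former"] = long(ps.mortality.prev_former, "former")["former"]
    sp.to_csv(d / "status_prevalence.csv", **_CSV_KW)

    drows, dmeta = [], []
    for name, di in ps.diseases.items():
        dmeta.append(
            {
                "disease": name,
                "rr_current": di.rr_current,
                "rr_former": di.rr_former,
                "cost_6mo": di.cost_6mo,
                "mean_survival_years": di.mean_survival_years,
            }
        )
        for g in GENDERS:
            row = {"disease": name, "gender": g.value}
            df = pd.DataFrame({"age": ages, **row})
            if di.marginal_prevalence is not None:
                df["prevalence"] = di.marginal_prevalence[g].array(ps.start_age, ps.max_age)
            if di.incidence is not None:
                df["incidence"] = di.incidence[g].array(ps.start_age, ps.max_age)
            drows.append(df)
    pd.concat(drows, ignore_index=True).to_csv(d / "diseases.csv", **_CSV_KW)
    pd.DataFrame(dmeta).to_csv(d / "diseases_meta.csv", **_CSV_KW)

    urows = []
    for g in GENDERS:
        for st in LIVING_STATES:
            urows.append(
                pd.DataFrame(
                    {
                        "gender": g.value,
                        "status": st.value,
                        "age": ages,
                        "utility": ps.utilities.by_status[g][st].array(ps.start_age, ps.max_age),
                    }
                )
            )
    pd.concat(urows, ignore_index=True).to_csv(d / "utilities.csv", **_CSV_KW)

    ec = long(ps.econ.unrelated_cost_survivor, "unrelated_cost_survivor")
    ec["unrelated_cost_decedent"] = long(ps.econ.unrelated_cost_decedent, "x")["x"]
    ec.to_csv(d / "unrelated_costs.csv", **_CSV_KW)
    pd.DataFrame(
        [
            {
                "tax_per_smoker_year": ps.econ.tax_per_smoker_year,
                "gdp_per_smoker_year": ps.econ.gdp_per_smoker_year,
                "discount_rate_annual": ps.econ.discount_rate_annual,
                "rr_death_current": ps.mortality.rr_current,
                "rr_death_former": ps.mortality.rr_former,
                "start_age": ps.start_age,
                "max_age": ps.max_age,
                "policy_start_year": ps.policy_start_year,
                "first_banned_birth_year": ps.first_banned_birth_year,
            }
        ]
    ).to_csv(d / "econ.csv", **_CSV_KW)
    pd.DataFrame(
        [{"birth_year": c.birth_year, "gender": c.gender.value, "size": c.size} for c in ps.cohorts]
    ).to_csv(d / "cohorts.csv", **_CSV_KW)


def import_csv(directory) -> ParameterSet:
    import functools

    import pandas as pd

    # exact float parsing so export/import is a bit-exact round trip
    read_csv = functools.partial(pd.read_csv, float_precision="round_trip")
    d = Path(directory)
    econ_row = read_csv(d / "econ.csv").iloc[0]
    start_age, max_age = int(econ_row["start_age"]), int(econ_row["max_age"])

    def scheds(df: "pd.DataFrame", col: str) -> GenderSchedules:
        out = {}
        for g in GENDERS:
            sub = df[df["gender"] == g.value].sort_values("age")
            if sub.empty:
                raise SchemaError(f"missing gender {g.value!r} for column {col!r}")
            out[g] = AgeSchedule(int(sub["age"].iloc[0]), sub[col].to_numpy(float))
        return out

    tr = read_csv(d / "transitions.csv")
    mo = read_csv(d / "mortality.csv")
    sp = read_csv(d / "status_prevalence.csv")
    transitions = TransitionInputs(scheds(tr, "start"), scheds(tr, "quit"), scheds(tr, "relapse"))
    mortality = MortalityInputs(
        marginal_death=scheds(mo, "marginal_death"),
        rr_current=float(econ_row["rr_death_current"]),
        rr_former=float(econ_row["rr_death_former"]),
        prev_never=scheds(sp, "never"),
        prev_current=scheds(sp, "current"),
        prev_former=scheds(sp, "former"),
    )
    dmeta = read_csv(d / "diseases_meta.csv").set_index("disease")
    ddf = read_csv(d / "diseases.csv")
    diseases = {}
    for name, meta in dmeta.iterrows():
        sub = ddf[ddf["disease"] == name]
        has_prev = "prevalence" in sub.columns and sub["prevalence"].notna().all()
        has_inc = "incidence" in sub.columns and sub["incidence"].notna().all()
        diseases[name] = DiseaseInputs(
            name=name,
            rr_current=float(meta["rr_current"]),
            rr_former=float(meta["rr_former"]),
            cost_6mo=float(meta["cost_6mo"]),
            marginal_prevalence=scheds(sub, "prevalence") if has_prev else None,
            incidence=scheds(sub, "incidence") if has_inc else None,
            mean_survival_years=(
                float(meta["mean_survival_years"]) if pd.notna(meta["mean_survival_years"]) else None
            ),
        )
    udf = read_csv(d / "utilities.csv")
    by_status = {
        g: {
            st: AgeSchedule(
                start_age,
                udf[(udf["gender"] == g.value) & (udf["status"] == st.value)]
                .sort_values("age")["utility"]
                .to_numpy(float),
            )
            for st in LIVING_STATES
        }
        for g in GENDERS
    }
    uc = read_csv(d / "unrelated_costs.csv")
    econ = EconParams(
        tax_per_smoker_year=float(econ_row["tax_per_smoker_year"]),
        gdp_per_smoker_year=float(econ_row["gdp_per_smoker_year"]),
        discount_rate_annual=float(econ_row["discount_rate_annual"]),
        unrelated_cost_survivor=scheds(uc, "unrelated_cost_survivor"),
        unrelated_cost_decedent=scheds(uc, "unrelated_cost_decedent"),
    )
    cdf = read_csv(d / "cohorts.csv")
    cohorts = [
        CohortSpec(int(r["birth_year"]), Gender(r["gender"]), float(r["size"]))
        for _, r in cdf.iterrows()
    ]
    ps = ParameterSet(
        transitions=transitions,
        mortality=mortality,
        diseases=diseases,
        utilities=UtilityInputs(by_status),
        econ=econ,
        cohorts=cohorts,
        start_age=start_age,
        max_age=max_age,
        policy_start_year=int(econ_row["policy_start_year"]),
        first_banned_birth_year=int(econ_row["first_banned_birth_year"]),
    )
    validate_parameters(ps)
    return ps
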