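"""Calibration of status-specific probabilities from marginal rates.

Survey data give the *marginal* probability of death (or of having a
smoking-related disease) at each age and gender, the smoking-status mix of
that stratum, and relative risks for current and former smokers versus never
smokers.  The unique status-specific probabilities consistent with those
three ingredients solve the prevalence-weighted constraint

    w_never * p_never + w_current * p_current + w_former * p_former = marginal
    p_current = rr_current * p_never,   p_former = rr_former * p_never

giving the closed form ``p_never = marginal / (w_n + w_c*rr_c + w_f*rr_f)``.

Lung-cancer prevalence is not observed directly and is constructed from
annual incidence and mean survival as the steady-state stock
``prevalence = incidence * mean_survival_years`` (capped at 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .parameters import (
    DISEASES,
    GENDERS,
    AgeSchedule,
    Gender,
    ParameterSet,
)

__all__ = [
    "CalibratedSchedules",
    "DegenerateStratumError",
    "calibrate_by_status",
    "lung_cancer_prevalence",
    "build_calibrated",
]


class DegenerateStratumError(ValueError):
    """All status shares (weighted by relative risk) vanish in a stratum."""


def calibrate_by_status(
    marginal: float,
    shares: tuple[float, float, float],
    rr_current: float,
    rr_former: float,
) -> tuple[float, float, float]:
    """Solve for (p_never, p_current, p_former) from a marginal probability.

    The weighted identity ``w_n*p_n + w_c*p_c + w_f*p_f = marginal`` holds
    exactly before clamping; outputs are clamped to [0, 1] with a warning
    when the relative risks push a status-specific probability past 1.
    """
    w_n, w_c, w_f = (float(w) for w in shares)
    denom = w_n + w_c * rr_current + w_f * rr_former
    if denom <= 0:
        raise DegenerateStratumError(
            f"degenerate stratum: shares {shares} with rr ({rr_current}, {rr_former})"
        )
    p_never = float(marginal) / denom
    out = (p_never, rr_current * p_never, rr_former * p_never)
    if any(p < 0 or p > 1 for p in out):
        warnings.warn(
            "calibrated probability outside [0, 1] clamped "
            f"(marginal={marginal}, rr=({rr_current}, {rr_former}))"
        )
        out = tuple(min(1.0, max(0.0, p)) for p in out)
    return out


def _calibrate_arrays(
    marginal: np.ndarray,
    w_n: np.ndarray,
    w_c: np.ndarray,
    w_f: np.ndarray,
    rr_c: float,
    rr_f: float,
    where: str,
) -> np.ndarray:
    """Vectorized calibration over an age axis; returns shape (3, n_ages)."""
    denom = w_n + w_c * rr_c + w_f * rr_f
    if np.any(denom <= 0):
        age_idx = int(np.argmax(denom <= 0))
        raise DegenerateStratumError(f"degenerate stratum at {where}, age index {age_idx}")
    p_never = marginal / denom
    out = np.stack([p_never, rr_c * p_never, rr_f * p_never])
    if np.any(out > 1.0) or np.any(out < 0.0):
        warnings.warn(f"clamped calibrated probabilities at {where}")
        out = np.clip(out, 0.0, 1.0)
    return out


def lung_cancer_prevalence(
    incidence: AgeSchedule,
    mean_survival_years: float,
    mode: str = "steady_state",
) -> AgeSchedule:
    """Construct a prevalence schedule from annual incidence and survival.

    ``steady_state`` (default): prevalence = incidence * mean survival, the
    equilibrium stock of a birth-death process with the given inflow and
    mean dwell time.  ``literal_divide`` divides incidence by the survival
    duration instead; it is kept only as an explicit alternative reading of
    the construction and is not the default.  Values are capped at 1.
    """
    if mean_survival_years <= 0:
        raise ValueError("mean_survival_years must be > 0")
    if mode == "steady_state":
        vals = incidence.values * mean_survival_years
    elif mode == "literal_divide":
        vals = incidence.values / mean_survival_years
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if np.any(vals > 1.0):
        warnings.warn("lung-cancer prevalence capped at 1")
        vals = np.minimum(vals, 1.0)
    return AgeSchedule(incidence.start_age, vals)


@dataclass
class CalibratedSchedules:
    """Status-specific 6-month probabilities on the dense age grid.

    ``death[gender]`` has shape (3, n_ages): rows never/current/former.
    ``disease[name][gender]`` likewise holds the probability of being a
    prevalent case of that disease, by smoking status.
    """

    start_age: int
    max_age: int
    death: dict  # Gender -> ndarray (3, n_ages)
    disease: dict  # name -> Gender -> ndarray (3, n_ages)

    @property
    def n_ages(self) -> int:
        return self.max_age - self.start_age + 1

    def to_frame(self):
        """Long-format DataFrame of all calibrated values (for inspection)."""
        import pandas as pd

        ages = np.arange(self.start_age, self.max_age + 1)
        rows = []
        statuses = ("never", "current", "former")
        for g in GENDERS:
            for i, st in enumerate(statuses):
                rows.append(
                    pd.DataFrame(
                        {
                            "quantity": "death",
                            "gender": g.value,
                            "status": st,
                            "age": ages,
                            "probability": self.death[g][i],
                        }
                    )
                )
                for name, per_gender in self.disease.items():
                    rows.append(
                        pd.DataFrame(
                            {
                                "quantity": name,
                                "gender": g.value,
                                "status": st,
                                "age": ages,
                                "probability": per_gender[g][i],
                            }
                        )
                    )
        return pd.concat(rows, ignore_index=True)


def build_calibrated(ps: ParameterSet, lung_cancer_mode: str = "steady_state") -> CalibratedSchedules:
    """Calibrate death and disease probabilities for every stratum.

    Applies :func:`calibrate_by_status` independently at each age–gender
    stratum, using the model-input status prevalence as fixed weights.  A
    lung-cancer marginal given as incidence is first converted through
    :func:`lung_cancer_prevalence`.
    """
    a0, a1 = ps.start_age, ps.max_age
    death = {}
    shares = {}
    for g in GENDERS:
        w_n = ps.mortality.prev_never[g].array(a0, a1)
        w_c = ps.mortality.prev_current[g].array(a0, a1)
        w_f = ps.mortality.prev_former[g].array(a0, a1)
        shares[g] = (w_n, w_c, w_f)
        death[g] = _calibrate_arrays(
            ps.mortality.marginal_death[g].array(a0, a1),
            w_n,
            w_c,
            w_f,
            ps.mortality.rr_current,
            ps.mortality.rr_former,
            f"death/{g.value}",
        )
    disease = {}
    for name, di in ps.diseases.items():
        per_gender = {}
        for g in GENDERS:
            if di.marginal_prevalence is not None:
                marg = di.marginal_prevalence[g].array(a0, a1)
            else:
                prev = lung_cancer_prevalence(
                    AgeSchedule(a0, di.incidence[g].array(a0, a1)),
                    di.mean_survival_years,
                    mode=lung_cancer_mode,
                )
                marg = prev.values
            w_n, w_c, w_f = shares[g]
            per_gender[g] = _calibrate_arrays(
                marg, w_n, w_c, w_f, di.rr_current, di.rr_former, f"{name}/{g.value}"
            )
        disease[name] = per_gender
    return CalibratedSchedules(start_age=a0, max_age=a1, death=death, disease=disease)
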