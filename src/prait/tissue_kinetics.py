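"""Whole-body and organ-level kinetics of the radiolabeled hapten.

Whole-body activity (decay-corrected) is modeled as the sum of the central
and distribution compartments of a two-compartment system whose elimination
rate follows the molar-ratio power law, k_el = A_WB * MR^B_WB.

Organ activity is modeled as a fraction of the central-compartment activity
(an apparent fast-equilibrating volume, in L/kg of tissue) plus a
tissue-specific distribution compartment D exchanging with the central
compartment at first-order rates:

    A_organ(t) = fraction * tissue_mass * C_central(t) + D(t)
    dD/dt      = k_on * A_central(t) - k_off * D(t),  D(0) = 0

where C_central = A_central / V_central.  The uptake term does not deplete
the central compartment: each organ sees the whole-body input function, as
in the published population analysis of regional activities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

from .pk_models import InfusionRecord, linear_infusion_solution

__all__ = [
    "WholeBodyParams",
    "TissueParams",
    "TissueRecord",
    "TissueFit",
    "predict_wholebody",
    "predict_tissue",
    "fit_tissue",
]


@dataclass(frozen=True)
class WholeBodyParams:
    """Whole-body two-compartment parameters with MR-driven elimination."""

    k_pc: float   # distribution -> central (1/h)
    k_cp: float   # central -> distribution (1/h)
    a_wb: float   # power-law coefficient (1/h)
    b_wb: float   # power-law exponent (dimensionless)

    def __post_init__(self) -> None:
        if self.k_pc < 0 or self.k_cp < 0:
            raise ValueError("exchange rates must be >= 0")
        if self.a_wb <= 0:
            raise ValueError("a_wb must be > 0")

    def k_el(self, mr: float) -> float:
        if mr <= 0:
            raise ValueError("mr must be > 0")
        return self.a_wb * mr**self.b_wb


@dataclass(frozen=True)
class TissueParams:
    """Organ uptake parameters: exchange rates and fast-equilibrium fraction."""

    k_on: float          # central -> tissue compartment (1/h)
    k_off: float         # tissue compartment -> central (1/h)
    fraction: float      # apparent fractional volume (L/kg)
    tissue_mass: float   # kg

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "fraction", "tissue_mass"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _wb_matrix(params: WholeBodyParams, mr: float) -> np.ndarray:
    kel = params.k_el(mr)
    return np.array(
        [
            [-(kel + params.k_cp), params.k_pc],
            [params.k_cp, -params.k_pc],
        ]
    )


def predict_wholebody(
    params: WholeBodyParams,
    mr: float,
    infusions: Sequence[InfusionRecord] | InfusionRecord,
    times: np.ndarray,
) -> np.ndarray:
    """Decay-corrected whole-body activity: central + distribution amounts (MBq)."""
    if isinstance(infusions, InfusionRecord):
        infusions = [infusions]
    x = linear_infusion_solution(_wb_matrix(params, mr), 0, infusions, times)
    return x[0] + x[1]


def central_activity(
    params: WholeBodyParams,
    mr: float,
    infusions: Sequence[InfusionRecord] | InfusionRecord,
    times: np.ndarray,
) -> np.ndarray:
    """Central-compartment activity of the whole-body model (MBq)."""
    if isinstance(infusions, InfusionRecord):
        infusions = [infusions]
    x = linear_infusion_solution(_wb_matrix(params, mr), 0, infusions, times)
    return x[0]


def predict_tissue(
    wb: WholeBodyParams,
    mr: float,
    infusions: Sequence[InfusionRecord] | InfusionRecord,
    tp: TissueParams,
    times: np.ndarray,
    central_volume: float,
) -> np.ndarray:
    """Organ activity (MBq): fraction-of-central term plus trap compartment.

    Solved in closed form by extending the whole-body system with the organ
    distribution compartment (driven by the central amount, non-depleting).
    """
    if isinstance(infusions, InfusionRecord):
        infusions = [infusions]
    if central_volume <= 0:
        raise ValueError("central_volume must be > 0")
    m2 = _wb_matrix(wb, mr)
    m = np.zeros((3, 3))
    m[:2, :2] = m2
    m[2, 0] = tp.k_on
    m[2, 2] = -tp.k_off
    x = linear_infusion_solution(m, 0, infusions, times)
    frac_term = tp.fraction * tp.tissue_mass * x[0] / central_volume
    return frac_term + x[2]


def fit_wholebody(
    times: np.ndarray,
    activities: np.ndarray,
    infusions: Sequence[InfusionRecord] | InfusionRecord,
) -> dict:
    """Per-record whole-body fit of (k_pc, k_cp, k_el) to decay-corrected WB activity.

    The molar-ratio power law (A_WB, B_WB) is obtained afterwards by the
    log-log regression of the per-record ``k_el`` estimates on MR (see
    :func:`prait.covariates.fit_power_law`).
    """
    if isinstance(infusions, InfusionRecord):
        infusions = [infusions]
    times = np.asarray(times, dtype=float)
    activities = np.asarray(activities, dtype=float)
    if times.size < 3:
        raise ValueError("need >= 3 whole-body points")

    def resid(theta):
        k_pc, k_cp, k_el = np.exp(theta)
        m = np.array([[-(k_el + k_cp), k_pc], [k_cp, -k_pc]])
        x = linear_infusion_solution(m, 0, infusions, times)
        pred = np.clip(x[0] + x[1], 1e-300, None)
        pos = activities > 0
        return np.log(pred[pos]) - np.log(activities[pos])

    sol = optimize.least_squares(
        resid, np.log([0.0096, 0.0163, 0.15]), method="lm",
        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=5000,
    )
    k_pc, k_cp, k_el = np.exp(sol.x)
    return {
        "k_pc": float(k_pc),
        "k_cp": float(k_cp),
        "k_el": float(k_el),
        "converged": sol.status > 0,
        "cost": float(sol.cost),
    }


@dataclass
class TissueRecord:
    """One organ time-activity curve with its whole-body input function."""

    organ: str
    patient_id: str
    times: np.ndarray
    activities: np.ndarray
    tissue_mass: float
    wb: WholeBodyParams
    mr: float
    infusions: Sequence[InfusionRecord]
    central_volume: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.activities = np.asarray(self.activities, dtype=float)
        if self.times.size < 3:
            raise ValueError("need >= 3 time points per organ curve")
        if np.any(self.activities < 0):
            raise ValueError("activities must be >= 0")


@dataclass
class TissueFit:
    organ: str
    params: TissueParams
    converged: bool
    cost: float
    n_records: int
    message: str = ""


def _tissue_residuals(theta: np.ndarray, recs: list[TissueRecord]) -> np.ndarray:
    k_on, k_off, fraction = np.exp(theta)
    out = []
    for r in recs:
        tp = TissueParams(k_on=k_on, k_off=k_off, fraction=fraction, tissue_mass=r.tissue_mass)
        pred = predict_tissue(r.wb, r.mr, r.infusions, tp, r.times, r.central_volume)
        pos = r.activities > 0
        out.append(np.log(np.clip(pred[pos], 1e-300, None)) - np.log(r.activities[pos]))
    return np.concatenate(out) if out else np.empty(0)


def fit_tissue(
    records: Sequence[TissueRecord],
    mode: str = "population",
) -> dict[str, TissueFit] | list[TissueFit]:
    """Estimate (k_on, k_off, fraction) per organ from time-activity curves.

    ``mode="population"`` fits one shared parameter set per organ across all
    records (the default, used for normal organs); ``mode="individual"`` fits
    each record separately (required for tumors, whose uptake is too variable
    for a population structure).  Curves that are identically zero yield
    k_on = fraction = 0 directly.
    """
    if mode not in ("population", "individual"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "individual":
        return [_fit_group([r], r.organ) for r in records]
    groups: dict[str, list[TissueRecord]] = {}
    for r in records:
        groups.setdefault(r.organ, []).append(r)
    return {organ: _fit_group(recs, organ) for organ, recs in groups.items()}


def _fit_group(recs: list[TissueRecord], organ: str) -> TissueFit:
    if all(np.all(r.activities == 0) for r in recs):
        return TissueFit(
            organ=organ,
            params=TissueParams(0.0, 0.0, 0.0, recs[0].tissue_mass),
            converged=True,
            cost=0.0,
            n_records=len(recs),
            message="all-zero curve",
        )
    x0 = np.log([1.5e-3, 1.2e-2, 3.0e-2])
    sol = optimize.least_squares(
        _tissue_residuals, x0, args=(recs,), method="lm",
        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=6000,
    )
    k_on, k_off, fraction = np.exp(sol.x)
    return TissueFit(
        organ=organ,
        params=TissueParams(k_on, k_off, fraction, recs[0].tissue_mass),
        converged=sol.status > 0,
        cost=float(sol.cost),
        n_records=len(recs),
        message=str(sol.message),
    )
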