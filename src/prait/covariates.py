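"""Covariate laws linking hapten kinetics to the pretargeting conditions.

The clearance of the radiolabeled hapten depends on how much bispecific
antibody is still circulating when the hapten is injected: circulating
antibody binds the hapten and slows its elimination.  The covariate that
captures this is the molar ratio MR = (injected hapten, nmol) / (circulating
antibody, nmol), the denominator being the antibody concentration
extrapolated to the hapten injection time multiplied by the antibody central
volume.  Clearance then follows a power law CL = A * MR^B, and k_el = CL/Vc.

The power law is fitted by ordinary least squares on the natural-log scale;
R^2 is reported on that same scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .pk_models import InfusionRecord, TwoCompartmentParams, predict_concentration

__all__ = [
    "MolarRatioContext",
    "PowerLawFit",
    "compute_mr",
    "clearance_power_law",
    "fit_power_law",
]


@dataclass(frozen=True)
class MolarRatioContext:
    """Inputs and result of a molar-ratio computation."""

    n_hapten: float          # injected hapten (nmol)
    tf2_conc_at_inj: float   # antibody concentration at hapten injection (nmol/L)
    tf2_vc: float            # antibody central volume (L)
    mr: float                # derived ratio (dimensionless)

    def __post_init__(self) -> None:
        expected = self.n_hapten / (self.tf2_conc_at_inj * self.tf2_vc)
        if not np.isclose(self.mr, expected, rtol=1e-9):
            raise ValueError("mr inconsistent with n_hapten/(conc*Vc)")
        if self.mr <= 0:
            raise ValueError("mr must be > 0")


@dataclass(frozen=True)
class PowerLawFit:
    """Result of a log-log OLS fit response = A * covariate^B."""

    coefficient: float  # A, units of the response
    exponent: float     # B, dimensionless
    r_squared: float    # on the log scale
    n: int = 0

    def __post_init__(self) -> None:
        if self.coefficient <= 0:
            raise ValueError("coefficient A must be > 0")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")

    def __call__(self, covariate: float | np.ndarray) -> float | np.ndarray:
        return clearance_power_law(self.coefficient, self.exponent, covariate)

    def to_dict(self, analyte: str = "") -> dict:
        return {
            "analyte": analyte,
            "A": self.coefficient,
            "B": self.exponent,
            "r_squared": self.r_squared,
            "n": self.n,
        }


def compute_mr(
    n_hapten: float,
    tf2_params: TwoCompartmentParams,
    tf2_infusions: Sequence[InfusionRecord],
    t_inj: float,
    bsa: float,
) -> MolarRatioContext:
    """Molar ratio of injected hapten to circulating antibody at ``t_inj``.

    The antibody concentration is evaluated from its fitted kinetic model at
    the hapten injection time; multiplying by Vc gives the circulating molar
    amount.
    """
    if n_hapten <= 0:
        raise ValueError("n_hapten must be > 0")
    for inf in tf2_infusions:
        if t_inj < inf.t_end:
            raise ValueError("t_inj must be after the end of the antibody infusion")
    conc = float(predict_concentration(tf2_params, bsa, tf2_infusions, np.array([t_inj]))[0])
    if conc <= 0:
        raise ValueError("predicted antibody concentration <= 0: molar ratio undefined")
    vc = tf2_params.central_volume(bsa)
    mr = n_hapten / (conc * vc)
    return MolarRatioContext(n_hapten=n_hapten, tf2_conc_at_inj=conc, tf2_vc=vc, mr=mr)


def clearance_power_law(a: float, b: float, mr: float | np.ndarray) -> float | np.ndarray:
    """Evaluate CL = A * MR^B (L/h for clearance, 1/h when A is a rate)."""
    if a <= 0:
        raise ValueError("A must be > 0")
    mr_arr = np.asarray(mr, dtype=float)
    if np.any(mr_arr <= 0):
        raise ValueError("mr must be > 0")
    out = a * mr_arr ** b
    return float(out) if np.isscalar(mr) or out.ndim == 0 else out


def fit_power_law(pairs: Sequence[tuple[float, float]]) -> PowerLawFit:
    """OLS on (ln covariate, ln response): A = exp(intercept), B = slope."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (covariate, response) pairs")
    if np.any(arr <= 0):
        raise ValueError("all covariates and responses must be > 0")
    x, y = np.log(arr[:, 0]), np.log(arr[:, 1])
    if np.ptp(x) == 0:
        raise ValueError("all covariate values identical: exponent undefined")
    res = stats.linregress(x, y)
    return PowerLawFit(
        coefficient=float(np.exp(res.intercept)),
        exponent=float(res.slope),
        r_squared=float(res.rvalue**2),
        n=arr.shape[0],
    )
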