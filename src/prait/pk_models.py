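"""Closed-form two-compartment kinetics with zero-order infusion input.

The serum kinetics of both the bispecific antibody (TF2) and the radiolabeled
hapten (IMP288) are described by a linear two-compartment model: a central
(serum) compartment exchanging with a peripheral compartment at first-order
rates, with first-order elimination from the central compartment.  The central
volume is proportional to body surface area, ``Vc = vol_per_m2 * bsa``.

Rate-constant naming is unambiguous here: ``k_pc`` moves material from the
peripheral compartment into the central one, ``k_cp`` the other way round.
Published tables that print ``k_2,1``/``k_1,2`` are mapped onto these names by
the fixture loaders in :mod:`prait.io`.

For a dose ``D`` infused at constant rate over ``[t0, t0+T]`` the central
concentration is a superposition of exponential unit-step responses obtained
from the eigendecomposition of the 2x2 rate matrix; multiple infusions add
linearly because the model is linear.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TwoCompartmentParams",
    "InfusionRecord",
    "ConcentrationSeries",
    "predict_concentration",
    "compartment_amounts",
    "halflives",
    "eigenrates",
    "clearance",
    "linear_infusion_solution",
]

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class TwoCompartmentParams:
    """Kinetic parameter set of the two-compartment serum model.

    Parameters
    ----------
    k_pc : float
        Transfer rate peripheral -> central (1/h).
    k_cp : float
        Transfer rate central -> peripheral (1/h).
    k_el : float
        Elimination rate from the central compartment (1/h).
    vol_per_m2 : float
        Central volume per body-surface-area unit (L/m^2).
    """

    k_pc: float
    k_cp: float
    k_el: float
    vol_per_m2: float

    def __post_init__(self) -> None:
        for name in ("k_pc", "k_cp", "k_el"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.vol_per_m2 <= 0:
            raise ValueError(f"vol_per_m2 must be > 0, got {self.vol_per_m2}")

    def central_volume(self, bsa: float) -> float:
        """Central compartment volume Vc = vol_per_m2 * bsa (L)."""
        if bsa <= 0:
            raise ValueError(f"bsa must be > 0, got {bsa}")
        return self.vol_per_m2 * bsa


@dataclass(frozen=True)
class InfusionRecord:
    """A zero-order i.v. infusion of drug or activity.

    ``dose`` is in nmol for molar series and MBq for activity series; times in
    hours.  Default duration is 0.5 h (infusions are given over 30-60 min).
    """

    dose: float
    t_start: float = 0.0
    duration: float = 0.5
    session: str = "S1"
    analyte: str = "TF2"

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError(f"dose must be >= 0, got {self.dose}")
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")

    @property
    def rate(self) -> float:
        return self.dose / self.duration

    @property
    def t_end(self) -> float:
        return self.t_start + self.duration


@dataclass
class ConcentrationSeries:
    """Timestamped serum measurements with per-point censoring flags."""

    times: np.ndarray
    values: np.ndarray
    below_limit: np.ndarray = field(default=None)  # type: ignore[assignment]
    analyte: str = "TF2"
    session: str = "S1"
    unit: str = "nmol/L"
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.below_limit is None:
            self.below_limit = np.zeros_like(self.times, dtype=bool)
        self.below_limit = np.asarray(self.below_limit, dtype=bool)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same shape")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        observed = ~self.below_limit
        if np.any(self.values[observed] < 0):
            raise ValueError("observed concentrations must be >= 0")

    def __len__(self) -> int:
        return self.times.size


def _step_response(mu: np.ndarray, a: float, b: float, t: np.ndarray) -> np.ndarray:
    """integral_a^b exp(mu*(t - tau)) dtau for t >= b, eigenvalue-wise.

    Stable for mu -> 0 via expm1; mu has shape (k,), t shape (n,); returns
    (n, k).
    """
    mu = np.asarray(mu, dtype=float)[None, :]
    t = np.asarray(t, dtype=float)[:, None]
    width = b - a
    out = np.empty(np.broadcast_shapes(t.shape, mu.shape), dtype=float)
    small = np.abs(mu) * width < 1e-12
    # exp(mu (t-b)) * expm1(mu (b-a)) / mu ; limit mu->0 : (b-a)
    with np.errstate(divide="ignore", invalid="ignore"):
        full = np.exp(mu * (t - b)) * np.expm1(mu * width) / mu
    lim = np.exp(mu * (t - b)) * width
    out = np.where(np.broadcast_to(small, out.shape), lim, full)
    return out


def linear_infusion_solution(
    matrix: np.ndarray,
    input_index: int,
    infusions: Sequence[InfusionRecord],
    times: np.ndarray,
) -> np.ndarray:
    """State trajectory of dx/dt = M x + r(t) e_i under zero-order infusions.

    Analytic solution through the eigendecomposition of ``matrix``; each
    infusion contributes its convolution integral in closed form.  Returns an
    array of shape ``(n_states, n_times)``.  Falls back to a tightly tolerated
    Runge-Kutta integration if the eigenbasis is numerically defective.
    """
    matrix = np.asarray(matrix, dtype=float)
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    n = matrix.shape[0]
    mu, vecs = np.linalg.eig(matrix)
    defective = (
        np.any(np.abs(mu.imag) > 1e-9 * (np.abs(mu.real) + 1e-30))
        or np.linalg.cond(vecs) > 1e8
    )
    if defective:
        return _ode_fallback(matrix, input_index, infusions, times)
    mu = mu.real
    vecs = vecs.real
    vinv = np.linalg.inv(vecs)
    x = np.zeros((n, times.size))
    e_in = np.zeros(n)
    e_in[input_index] = 1.0
    w = vinv @ e_in  # modal weights of the input direction
    for inf in infusions:
        if inf.dose == 0:
            continue
        a, b_end = inf.t_start, inf.t_end
        active = times > a
        if not np.any(active):
            continue
        t_act = times[active]
        b_eff = np.minimum(t_act, b_end)
        # per-time, per-mode step responses; b varies with t during infusion
        resp = np.empty((t_act.size, n))
        for j, muj in enumerate(mu):
            width = b_eff - a
            arg = muj * width
            with np.errstate(divide="ignore", invalid="ignore"):
                val = np.exp(muj * (t_act - b_eff)) * np.expm1(arg) / muj
            lim = np.exp(muj * (t_act - b_eff)) * width
            resp[:, j] = np.where(np.abs(arg) < 1e-12, lim, val)
        x[:, active] += inf.rate * (vecs @ (w[:, None] * resp.T))
    return x


def _ode_fallback(matrix, input_index, infusions, times):
    """Piecewise Runge-Kutta integration between infusion breakpoints.

    Used only when the rate matrix is numerically defective (near-repeated
    eigenvalues); integrating phase by phase keeps infusion on/off switches
    at phase boundaries so no step can skip a short infusion.
    """
    from scipy.integrate import solve_ivp

    n = matrix.shape[0]
    t_max = float(times.max()) if times.size else 0.0
    breaks = sorted(
        {0.0, t_max}
        | {inf.t_start for inf in infusions if inf.t_start < t_max}
        | {inf.t_end for inf in infusions if inf.t_end < t_max}
    )
    out = np.zeros((n, times.size))
    state = np.zeros(n)
    for a, b in zip(breaks[:-1], breaks[1:]):
        rate = sum(
            inf.rate for inf in infusions
            if inf.dose > 0 and inf.t_start <= a and b <= inf.t_end
        )
        forcing = np.zeros(n)
        forcing[input_index] = rate
        inside = (times > a) & (times <= b)
        eval_pts = np.unique(np.concatenate([times[inside], [b]]))
        sol = solve_ivp(
            lambda t, x: matrix @ x + forcing, (a, b), state,
            t_eval=eval_pts, rtol=1e-11, atol=1e-16, method="DOP853",
        )
        if not sol.success:  # pragma: no cover
            raise RuntimeError(f"ODE fallback failed: {sol.message}")
        lookup = {t: sol.y[:, j] for j, t in enumerate(eval_pts)}
        for j in np.nonzero(inside)[0]:
            out[:, j] = lookup[times[j]]
        state = sol.y[:, -1]
    return out


def _rate_matrix(params: TwoCompartmentParams, with_eliminated: bool = False) -> np.ndarray:
    m = np.array(
        [
            [-(params.k_el + params.k_cp), params.k_pc],
            [params.k_cp, -params.k_pc],
        ]
    )
    if not with_eliminated:
        return m
    m3 = np.zeros((3, 3))
    m3[:2, :2] = m
    m3[2, 0] = params.k_el  # cumulative eliminated amount
    return m3


def compartment_amounts(
    params: TwoCompartmentParams,
    infusions: Sequence[InfusionRecord],
    times: np.ndarray,
) -> dict[str, np.ndarray]:
    """Central, peripheral and cumulatively eliminated amounts over time.

    Amounts carry the unit of the infused dose (nmol or MBq).  The three
    trajectories satisfy mass balance against the cumulative infused amount.
    """
    x = linear_infusion_solution(_rate_matrix(params, with_eliminated=True), 0, infusions, times)
    return {"central": x[0], "peripheral": x[1], "eliminated": x[2]}


def cumulative_infused(infusions: Sequence[InfusionRecord], times: np.ndarray) -> np.ndarray:
    """Total amount delivered by ``times`` under the zero-order schedules."""
    times = np.atleast_1d(np.asarray(times, dtype=float))
    total = np.zeros_like(times)
    for inf in infusions:
        frac = np.clip((times - inf.t_start) / inf.duration, 0.0, 1.0)
        total += inf.dose * frac
    return total


def predict_concentration(
    params: TwoCompartmentParams,
    bsa: float,
    infusions: Sequence[InfusionRecord],
    times: np.ndarray,
) -> np.ndarray:
    """Central-compartment concentration C(t) under superposed infusions.

    Returns nmol/L (or MBq/L for activity doses): central amount divided by
    Vc = vol_per_m2 * bsa.
    """
    vc = params.central_volume(bsa)
    x = linear_infusion_solution(_rate_matrix(params), 0, infusions, times)
    return x[0] / vc


def eigenrates(params: TwoCompartmentParams) -> tuple[float, float]:
    """Hybrid rate constants (lambda_alpha, lambda_beta), alpha >= beta.

    lambda_{a,b} = [(k_el + k_cp + k_pc) +/- sqrt((k_el + k_cp + k_pc)^2
    - 4 k_el k_pc)] / 2.
    """
    s = params.k_el + params.k_cp + params.k_pc
    disc = s * s - 4.0 * params.k_el * params.k_pc
    root = np.sqrt(max(disc, 0.0))
    return (s + root) / 2.0, (s - root) / 2.0


def halflives(params: TwoCompartmentParams) -> tuple[float, float]:
    """Distribution (alpha) and terminal (beta) half-lives in hours.

    In the degenerate one-compartment limit (both exchange rates zero) the
    concentration curve is a single exponential with rate ``k_el``; both
    half-lives then equal ln2/k_el.  If the slow eigenvalue vanishes for any
    other reason (``k_el == 0`` or ``k_pc == 0``) the terminal phase does not
    decay and the beta half-life is undefined.
    """
    if params.k_cp == 0 and params.k_pc == 0:
        if params.k_el == 0:
            raise ValueError("all rates zero: no decay, half-lives undefined")
        t = LN2 / params.k_el
        return t, t
    lam_a, lam_b = eigenrates(params)
    if lam_b <= 0:
        raise ValueError(
            "terminal eigenvalue is zero (k_el*k_pc == 0): beta half-life undefined"
        )
    return LN2 / lam_a, LN2 / lam_b


def clearance(params: TwoCompartmentParams, bsa: float) -> float:
    """Serum clearance Vc * k_el (L/h)."""
    return params.central_volume(bsa) * params.k_el
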