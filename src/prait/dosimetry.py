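"""MIRD-style dosimetry from fitted organ time-activity curves.

Decay-corrected organ curves are condensed into mono- or biexponential
functions (mono when fewer than four points are available), integrated
analytically with the physical decay constant re-applied to obtain cumulated
activities, and multiplied by S factors scaled to the patient's organ masses
to give absorbed doses.  Pretherapeutic (In-111) estimates are translated to
the therapy radionuclide (Lu-177) by re-integrating the same biological fit
with the other physical half-life — valid because the hapten kinetics is the
same for the two labels.

Session and cohort comparisons use nonparametric statistics: Spearman rank
correlation with an exact permutation p-value for n <= 8, the Wilcoxon test
for paired dose vectors and the Kruskal-Wallis test across cohorts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "IsotopeSpec",
    "IN111",
    "LU177",
    "TimeActivityCurve",
    "ExponentialFit",
    "SFactorTable",
    "DoseReport",
    "fit_time_activity",
    "cumulated_activity",
    "translate_isotope",
    "absorbed_dose",
    "spearman_exact",
    "compare_sessions",
    "compare_cohorts",
]

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class IsotopeSpec:
    """Radionuclide physical constants."""

    name: str
    half_life_h: float

    def __post_init__(self) -> None:
        if self.half_life_h <= 0:
            raise ValueError("half_life_h must be > 0")

    @property
    def decay_constant(self) -> float:
        """lambda_phys = ln2 / t_half (1/h)."""
        return LN2 / self.half_life_h


# Default constants; replaceable by configuration.
IN111 = IsotopeSpec("In-111", 67.32)
LU177 = IsotopeSpec("Lu-177", 159.53)


@dataclass(frozen=True)
class ExponentialFit:
    """Sum-of-exponentials fit of a decay-corrected time-activity curve."""

    form: str                      # "mono" | "bi"
    coefficients: tuple[float, ...]  # MBq
    rates: tuple[float, ...]         # biological rates (1/h)
    degenerate: bool = False

    def __post_init__(self) -> None:
        n = {"mono": 1, "bi": 2}.get(self.form)
        if n is None:
            raise ValueError(f"unknown form {self.form!r}")
        if len(self.coefficients) != n or len(self.rates) != n:
            raise ValueError("number of terms must match form")
        if any(r <= 0 for r in self.rates):
            raise ValueError("rates must be > 0")
        if any(c < 0 for c in self.coefficients):
            raise ValueError("coefficients must be >= 0")

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return sum(
            c * np.exp(-lam * t) for c, lam in zip(self.coefficients, self.rates)
        )


@dataclass
class TimeActivityCurve:
    """Timestamped decay-corrected organ activities with an isotope tag."""

    times: np.ndarray
    activities: np.ndarray
    organ: str = ""
    isotope: str = ""
    patient_id: str = ""
    session: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.activities = np.asarray(self.activities, dtype=float)
        if self.times.shape != self.activities.shape:
            raise ValueError("times and activities must have the same shape")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


def _loglinear_init(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    pos = y > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
        lam = max(-slope, 1e-6)
        c = float(np.exp(intercept))
    else:
        lam, c = 1e-2, max(float(y.max()), 1e-6)
    return c, lam


def fit_time_activity(
    times: np.ndarray | TimeActivityCurve, activities: np.ndarray | None = None
) -> ExponentialFit:
    """Mono- (< 4 points) or biexponential (>= 4) nonnegative fit.

    The threshold of four points makes the biexponential (four unknowns)
    identifiable.  A fit whose optimizer did not converge, or that collapses
    to coincident rates, is flagged ``degenerate`` rather than rejected.
    """
    if isinstance(times, TimeActivityCurve):
        times, activities = times.times, times.activities
    t = np.asarray(times, dtype=float)
    y = np.asarray(activities, dtype=float)
    if t.size != y.size:
        raise ValueError("times and activities must have equal length")
    if t.size < 2:
        raise ValueError("need >= 2 points to fit a time-activity curve")
    if np.any(y < 0):
        raise ValueError("activities must be >= 0")
    c0, lam0 = _loglinear_init(t, y)
    if t.size < 4:
        def resid_m(p):
            return np.exp(p[0]) * np.exp(-np.exp(p[1]) * t) - y

        sol = optimize.least_squares(
            resid_m, np.log([max(c0, 1e-9), lam0]), method="lm", xtol=1e-14, ftol=1e-14
        )
        c, lam = np.exp(sol.x)
        return ExponentialFit("mono", (float(c),), (float(lam),), degenerate=sol.status <= 0)

    def resid_b(p):
        c1, l1, c2, l2 = np.exp(p)
        return c1 * np.exp(-l1 * t) + c2 * np.exp(-l2 * t) - y

    x0 = np.log([max(0.6 * c0, 1e-9), lam0 * 3.0, max(0.4 * c0, 1e-9), lam0])
    sol = optimize.least_squares(resid_b, x0, method="lm", xtol=1e-14, ftol=1e-14,
                                 max_nfev=5000)
    c1, l1, c2, l2 = np.exp(sol.x)
    if l1 < l2:
        c1, l1, c2, l2 = c2, l2, c1, l1
    degenerate = sol.status <= 0 or abs(l1 - l2) < 1e-8 * max(l1, l2)
    return ExponentialFit(
        "bi", (float(c1), float(c2)), (float(l1), float(l2)), degenerate=degenerate
    )


def cumulated_activity(fit: ExponentialFit, isotope: IsotopeSpec) -> float:
    """Cumulated activity (MBq*h): sum_i c_i / (lambda_i + lambda_phys).

    The fit describes decay-corrected biology; the physical decay constant
    re-enters here, and the fitted function is integrated from 0 to infinity.
    """
    lam_p = isotope.decay_constant
    total = 0.0
    for c, lam in zip(fit.coefficients, fit.rates):
        denom = lam + lam_p
        if denom <= 0:
            raise ValueError(f"nonpositive effective rate {denom}")
        total += c / denom
    return total


def translate_isotope(
    fit: ExponentialFit, from_isotope: IsotopeSpec, to_isotope: IsotopeSpec
) -> float:
    """Cumulated activity the same biology would give with another label.

    The biological rates are label-independent, so translation is simply
    re-integration with the target physical decay constant.
    """
    del from_isotope  # biological fit does not depend on the original label
    return cumulated_activity(fit, to_isotope)


@dataclass
class SFactorTable:
    """(source, target) -> S value (mGy per MBq*h) at reference organ masses."""

    entries: dict[tuple[str, str], float]
    reference_masses: dict[str, float]

    def __post_init__(self) -> None:
        for organ, m in self.reference_masses.items():
            if m <= 0:
                raise ValueError(f"reference mass for {organ} must be > 0")
        targets = {t for (_, t) in self.entries}
        for organ in targets:
            if (organ, organ) not in self.entries:
                raise ValueError(f"missing self-dose S entry for {organ}")

    def s_value(self, source: str, target: str) -> float:
        try:
            return self.entries[(source, target)]
        except KeyError:
            raise KeyError(f"no S factor for pair (source={source!r}, target={target!r})")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SFactorTable":
        entries = {
            (r.source, r.target): float(r.S_mGy_per_MBq_h) for r in df.itertuples()
        }
        masses = {r.target: float(r.ref_mass_kg) for r in df.itertuples()}
        return cls(entries=entries, reference_masses=masses)


@dataclass
class DoseReport:
    """Per-organ cumulated activities and absorbed doses for one session."""

    table: pd.DataFrame  # organ, cumulated_MBq_h, dose_mGy, dose_mGy_per_MBq
    session: str = ""
    cohort: str = ""
    administered_MBq: float = float("nan")

    def doses(self, organs: Sequence[str] | None = None) -> np.ndarray:
        df = self.table.set_index("organ")
        organs = list(organs) if organs is not None else list(df.index)
        return df.loc[organs, "dose_mGy_per_MBq"].to_numpy()


def absorbed_dose(
    cumulated: Mapping[str, float],
    s_table: SFactorTable,
    organ_masses: Mapping[str, float],
    administered_MBq: float,
    session: str = "",
    cohort: str = "",
) -> DoseReport:
    """MIRD absorbed doses with self-dose S scaled by patient organ mass.

    D(target) = sum_source A~(source) * S(target<-source) * scale, where
    self-dose S values scale by (reference mass / patient mass) — local
    electron dose scales inversely with the mass absorbing it — and photon
    cross-dose terms are left at their reference values.
    """
    if administered_MBq <= 0:
        raise ValueError("administered_MBq must be > 0")
    rows = []
    for target in cumulated:
        mass = organ_masses.get(target)
        if mass is None or mass <= 0:
            raise ValueError(f"missing or nonpositive mass for organ {target!r}")
        dose = 0.0
        for source, a_tilde in cumulated.items():
            if a_tilde < 0:
                raise ValueError(f"negative cumulated activity for {source!r}")
            s = s_table.s_value(source, target)
            if source == target:
                s *= s_table.reference_masses[target] / mass
            dose += a_tilde * s
        rows.append(
            {
                "organ": target,
                "cumulated_MBq_h": cumulated[target],
                "dose_mGy": dose,
                "dose_mGy_per_MBq": dose / administered_MBq,
            }
        )
    return DoseReport(
        table=pd.DataFrame(rows),
        session=session,
        cohort=cohort,
        administered_MBq=administered_MBq,
    )


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        raise ValueError("constant vector: rank correlation undefined")
    return float(rx @ ry) / denom


def spearman_exact(
    x: Sequence[float], y: Sequence[float], exact_n_max: int = 8
) -> tuple[float, float]:
    """Spearman rho with a two-sided permutation p-value.

    For n <= ``exact_n_max`` all n! permutations are enumerated (mid-ranks
    for ties); beyond that the large-sample t approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    rx, ry = _midranks(x), _midranks(y)
    rho = _rank_corr(rx, ry)
    n = x.size
    if n <= exact_n_max:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = _rank_corr(rx, ry[list(perm)])
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        p = count / total
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p


def compare_sessions(
    report_s1: DoseReport, report_s2: DoseReport
) -> dict[str, float]:
    """Predictivity statistics of session-1 doses for session-2 doses.

    Requires matched organ sets; returns Spearman rho with its permutation
    p-value and the paired Wilcoxon signed-rank statistic and p-value on the
    normalized doses.
    """
    o1 = list(report_s1.table["organ"])
    o2 = set(report_s2.table["organ"])
    if set(o1) != o2:
        raise ValueError(
            f"organ sets differ: only_in_s1={sorted(set(o1) - o2)}, "
            f"only_in_s2={sorted(o2 - set(o1))}"
        )
    d1 = report_s1.doses(o1)
    d2 = report_s2.doses(o1)
    rho, p_rho = spearman_exact(d1, d2)
    if np.allclose(d1, d2):
        w_stat, w_p = 0.0, 1.0
    else:
        w = stats.wilcoxon(d1, d2)
        w_stat, w_p = float(w.statistic), float(w.pvalue)
    return {
        "spearman_rho": rho,
        "spearman_p": p_rho,
        "wilcoxon_stat": w_stat,
        "wilcoxon_p": w_p,
        "n_organs": float(len(o1)),
    }


def compare_cohorts(doses_by_cohort: Mapping[str, Sequence[float]]) -> dict[str, float]:
    """Kruskal-Wallis test of dose distributions across dosing cohorts."""
    groups = [np.asarray(v, dtype=float) for v in doses_by_cohort.values()]
    if len(groups) < 2:
        raise ValueError("need >= 2 cohorts")
    res = stats.kruskal(*groups)
    return {"kruskal_stat": float(res.statistic), "kruskal_p": float(res.pvalue)}
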