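"""Recompute the published summary quantities from the packaged fixtures.

Every value here is derived at run time by applying the package's closed-form
operations (eigenvalue half-lives, clearance identities, log-log covariate
regression) to the transcribed individual parameter rows; nothing is looked
up.
"""

from __future__ import annotations

import numpy as np

from . import io
from .covariates import fit_power_law
from .pk_models import halflives
from .population_fit import summarize_individuals

__all__ = ["halflife_summary", "clearance_summary", "covariate_summary", "fixture_report"]


def _mean_halflives(df) -> tuple[float, float]:
    hl = np.array([halflives(io.params_from_serum_row(r)) for _, r in df.iterrows()])
    return float(hl[:, 0].mean()), float(hl[:, 1].mean())


def halflife_summary() -> dict[str, float]:
    """Cohort-mean alpha/beta half-lives of the three kinetic tables (h)."""
    a4, b4 = _mean_halflives(io.load_table4())
    a5, b5 = _mean_halflives(io.load_table5())
    a6, b6 = _mean_halflives(io.load_table6())
    return {
        "tf2_alpha_h": a4,
        "tf2_beta_h": b4,
        "hapten_alpha_h": a5,
        "hapten_beta_h": b5,
        "wholebody_alpha_h": a6,
        "wholebody_beta_h": b6,
    }


def clearance_summary() -> dict[str, float]:
    """Clearance identities of the antibody table: Vc*k_el per patient."""
    df = io.load_table4()
    cl = df["vc_L"].to_numpy() * df["k_el"].to_numpy()
    cl_per_m2 = df["vol_per_m2_L"].to_numpy() * df["k_el"].to_numpy()
    summ = summarize_individuals(
        [{"clearance": c} for c in cl]
    )
    return {
        "patient_1_clearance_L_per_h": float(cl[0]),
        "mean_clearance_L_per_h": float(summ.loc["mean", "clearance"]),
        "sd_clearance_L_per_h": float(summ.loc["sd", "clearance"]),
        "mean_clearance_L_per_h_per_m2": float(cl_per_m2.mean()),
    }


def covariate_summary() -> dict[str, float]:
    """Power-law regressions of clearance and whole-body k_el on molar ratio."""
    t5 = io.load_table5()
    serum = fit_power_law(list(zip(t5["MR"], t5["clearance_L_per_h"])))
    t6 = io.load_table6()
    wb = fit_power_law(list(zip(t6["MR"], t6["k_el"])))
    return {
        "serum_A": serum.coefficient,
        "serum_B": serum.exponent,
        "serum_r_squared": serum.r_squared,
        "wholebody_A": wb.coefficient,
        "wholebody_B": wb.exponent,
        "wholebody_r_squared": wb.r_squared,
    }


# (computed value key, published value, absolute tolerance)
_PUBLISHED = [
    ("tf2_alpha_h", 3.7, 0.1),
    ("tf2_beta_h", 21.3, 0.2),
    ("hapten_alpha_h", 3.4, 0.1),
    ("hapten_beta_h", 28.9, 0.3),
    ("wholebody_alpha_h", 4.3, 0.1),
    ("wholebody_beta_h", 80.0, 0.5),
    ("patient_1_clearance_L_per_h", 0.78, 0.005),
    ("mean_clearance_L_per_h", 0.64, 0.005),
    ("mean_clearance_L_per_h_per_m2", 0.33, 0.005),
    ("serum_A", 1.33, 0.005),
    ("serum_B", 0.18, 0.005),
    ("serum_r_squared", 0.66, 0.005),
    ("wholebody_B", 0.15, 0.005),
]


def fixture_report() -> tuple[str, bool]:
    """Plain-text pass/fail report of all fixture-derived checks."""
    values = {**halflife_summary(), **clearance_summary(), **covariate_summary()}
    lines = []
    all_ok = True
    for key, published, tol in _PUBLISHED:
        got = values[key]
        ok = abs(got - published) <= tol
        all_ok &= ok
        lines.append(
            f"{'PASS' if ok else 'FAIL'}  {key:34s} computed={got:10.4f} "
            f"published={published:8.3f} tol={tol}"
        )
    lines.append(f"overall: {'PASS' if all_ok else 'FAIL'}")
    return "\n".join(lines), all_ok
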