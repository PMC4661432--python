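"""File formats and packaged fixture tables.

All exchange formats are plain CSV with dot decimal separators and explicit
unit columns; fit results serialize to JSON.  The packaged fixtures transcribe
the published parameter tables of the trial (antibody serum kinetics, hapten
serum kinetics, whole-body kinetics, organ uptake, dosing schemes) plus a
small synthetic S-factor table.

Rate-direction convention: the published serum tables print ``k_2,1`` for the
transfer into the central compartment, so the serum loaders map
``k21 -> k_pc`` and ``k12 -> k_cp``.  The whole-body table uses the opposite
printed convention (this is the mapping that reproduces the published
whole-body half-lives of 4.3 h and 80 h), so its loader maps
``k21 -> k_cp`` and ``k12 -> k_pc``.  Each loaded frame records the mapping
applied in ``df.attrs["rate_mapping"]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .pk_models import ConcentrationSeries, TwoCompartmentParams
from .dosimetry import SFactorTable, TimeActivityCurve

__all__ = [
    "SchemaError",
    "load_table4",
    "load_table5",
    "load_table6",
    "load_table7",
    "load_dosing_table",
    "load_sfactor_table",
    "params_from_serum_row",
    "read_concentration_csv",
    "write_concentration_csv",
    "read_activity_csv",
    "write_activity_csv",
    "RunConfig",
]

SERUM_COLUMNS = ["patient_id", "session", "analyte", "time_h", "value", "unit", "censored"]
ACTIVITY_COLUMNS = ["patient_id", "session", "organ", "time_h", "activity_MBq", "isotope"]


class SchemaError(ValueError):
    """A CSV did not match the expected column schema."""


def _data_path(name: str):
    return resources.files("prait.data").joinpath(name)


def _load_fixture(name: str) -> pd.DataFrame:
    with resources.as_file(_data_path(name)) as p:
        return pd.read_csv(p)


def _individual_rows(df: pd.DataFrame) -> pd.DataFrame:
    return df[~df["record"].str.startswith("population")].reset_index(drop=True)


def load_table4(individuals_only: bool = True) -> pd.DataFrame:
    """Antibody serum kinetics table; serum rate mapping (k21 -> k_pc)."""
    df = _load_fixture("table4_tf2_serum.csv")
    df = _individual_rows(df) if individuals_only else df
    df = df.rename(columns={"k21_per_h": "k_pc", "k12_per_h": "k_cp", "kel_per_h": "k_el"})
    df.attrs["rate_mapping"] = "k21->k_pc (serum convention)"
    return df


def load_table5(individuals_only: bool = True) -> pd.DataFrame:
    """Hapten serum kinetics table; serum rate mapping (k21 -> k_pc)."""
    df = _load_fixture("table5_hapten_serum.csv")
    df = _individual_rows(df) if individuals_only else df
    df = df.rename(columns={"k21_per_h": "k_pc", "k12_per_h": "k_cp", "kel_per_h": "k_el"})
    df.attrs["rate_mapping"] = "k21->k_pc (serum convention)"
    return df


def load_table6(individuals_only: bool = True) -> pd.DataFrame:
    """Whole-body kinetics table; swapped rate mapping (k21 -> k_cp)."""
    df = _load_fixture("table6_wholebody.csv")
    df = _individual_rows(df) if individuals_only else df
    df = df.rename(columns={"k21_per_h": "k_cp", "k12_per_h": "k_pc", "kel_per_h": "k_el"})
    df.attrs["rate_mapping"] = "k21->k_cp (whole-body convention)"
    return df


def load_table7() -> pd.DataFrame:
    """Organ uptake parameters (k_on, k_off, fraction) with their SDs."""
    return _load_fixture("table7_tissue.csv")


def load_dosing_table() -> pd.DataFrame:
    """The three cohort dosing schemes."""
    return _load_fixture("table1_dosing.csv")


def load_sfactor_table() -> SFactorTable:
    """Synthetic literature-style adult S-factor table (replaceable)."""
    return SFactorTable.from_frame(_load_fixture("sfactors_synthetic.csv"))


def params_from_serum_row(row) -> TwoCompartmentParams:
    """Build kinetic parameters from a loaded serum-table row."""
    return TwoCompartmentParams(
        k_pc=float(row["k_pc"]),
        k_cp=float(row["k_cp"]),
        k_el=float(row["k_el"]),
        vol_per_m2=float(row.get("vol_per_m2_L", 1.0) or 1.0),
    )


def _check_columns(df: pd.DataFrame, expected: Sequence[str], path) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_concentration_csv(path) -> list[ConcentrationSeries]:
    """Read serum series; one series per (patient_id, session, analyte)."""
    df = pd.read_csv(path)
    _check_columns(df, SERUM_COLUMNS, path)
    out = []
    for (pid, session, analyte), grp in df.groupby(
        ["patient_id", "session", "analyte"], sort=True
    ):
        grp = grp.sort_values("time_h")
        out.append(
            ConcentrationSeries(
                times=grp["time_h"].to_numpy(float),
                values=grp["value"].to_numpy(float),
                below_limit=grp["censored"].to_numpy(int).astype(bool),
                analyte=str(analyte),
                session=str(session),
                unit=str(grp["unit"].iloc[0]),
                patient_id=str(pid),
            )
        )
    return out


def write_concentration_csv(series: Sequence[ConcentrationSeries], path) -> None:
    rows = []
    for s in series:
        for t, v, c in zip(s.times, s.values, s.below_limit):
            rows.append(
                {
                    "patient_id": s.patient_id,
                    "session": s.session,
                    "analyte": s.analyte,
                    "time_h": float(t),
                    "value": float(v),
                    "unit": s.unit,
                    "censored": int(c),
                }
            )
    pd.DataFrame(rows, columns=SERUM_COLUMNS).to_csv(path, index=False)


def read_activity_csv(path) -> list[TimeActivityCurve]:
    """Read organ time-activity curves; one per (patient_id, session, organ)."""
    df = pd.read_csv(path)
    _check_columns(df, ACTIVITY_COLUMNS, path)
    out = []
    for (pid, session, organ), grp in df.groupby(
        ["patient_id", "session", "organ"], sort=True
    ):
        grp = grp.sort_values("time_h")
        out.append(
            TimeActivityCurve(
                times=grp["time_h"].to_numpy(float),
                activities=grp["activity_MBq"].to_numpy(float),
                organ=str(organ),
                isotope=str(grp["isotope"].iloc[0]),
                patient_id=str(pid),
                session=str(session),
            )
        )
    return out


def write_activity_csv(curves: Sequence[TimeActivityCurve], path) -> None:
    rows = []
    for c in curves:
        for t, a in zip(c.times, c.activities):
            rows.append(
                {
                    "patient_id": c.patient_id,
                    "session": c.session,
                    "organ": c.organ,
                    "time_h": float(t),
                    "activity_MBq": float(a),
                    "isotope": c.isotope,
                }
            )
    pd.DataFrame(rows, columns=ACTIVITY_COLUMNS).to_csv(path, index=False)


@dataclass
class RunConfig:
    """Configuration of a pipeline run; the seed is mandatory."""

    seed: int
    cohort: str = "I"
    n_patients: int = 3
    output_dir: str = "prait_out"
    isotope_half_lives_h: dict = field(
        default_factory=lambda: {"In-111": 67.32, "Lu-177": 159.53}
    )
    sfactor_path: str | None = None
    serum_sigma: float = 0.10
    imaging_sigma: float = 0.15
    tf2_loq: float = 0.1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise SchemaError(f"{path}: missing required key 'seed'")
        return cls(**raw)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")
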