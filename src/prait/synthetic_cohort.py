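"""Seeded virtual-patient generator for the pretargeting trial design.

The generator emulates the optimization trial this package analyses: three
dosing cohorts (differing in bispecific-antibody molar dose and pretargeting
delay), a dense serum sampling schedule over seven days, and three to five
quantitative imaging points between 1 h and 7 days.  True kinetic parameters
are drawn as lognormal random effects around the published population values
of the antibody, hapten, whole-body and organ models, so that every pipeline
stage (individual fits, population fits, covariate regression, dosimetry)
can be exercised and validated by parameter recovery without any patient
data.

Within a simulated session the antibody is infused at t = 0 and the hapten
at t = delay; hapten series are reported on a clock starting at the hapten
infusion.  The hapten elimination rate is derived from the patient's true
molar ratio through the clearance power law, which is what makes cohorts
with larger antibody doses (lower MR) clear the hapten more slowly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.stats import truncnorm

from .pk_models import (
    ConcentrationSeries,
    InfusionRecord,
    TwoCompartmentParams,
    predict_concentration,
)
from .covariates import clearance_power_law
from .tissue_kinetics import (
    TissueParams,
    WholeBodyParams,
    predict_tissue,
    predict_wholebody,
)

__all__ = [
    "DosingScheme",
    "DOSING_SCHEMES",
    "PopulationConfig",
    "NoiseConfig",
    "VirtualPatient",
    "SyntheticTrial",
    "sample_patient",
    "simulate_trial",
]

# Serum sampling schedule (h, relative to each infusion start): 5 min before
# the end of a 30-min infusion, 5 min after it, 1 h, 2-4 h (realised as 3 h),
# 24 h, then four more times over 7 days.
SERUM_SCHEDULE = (0.417, 0.583, 1.5, 3.0, 24.0, 48.0, 96.0, 120.0, 168.0)
# Imaging points between 1 h and 7 d after hapten injection.
IMAGING_SCHEDULE = (1.0, 24.0, 48.0, 120.0, 168.0)

REFERENCE_ORGAN_MASSES = {
    "wholebody": 73.0,
    "lungs": 1.0,
    "liver": 1.8,
    "kidneys": 0.31,
    "spleen": 0.18,
    "heart": 0.33,
}


@dataclass(frozen=True)
class DosingScheme:
    """One cohort row of the trial's dosing table."""

    cohort: str
    s1_tf2_dose: float      # nmol/m^2
    s2_tf2_dose: float      # nmol/m^2
    s1_hapten_dose: float   # nmol/m^2
    s2_hapten_dose: float   # nmol/m^2
    delay: float            # h between antibody and hapten infusions
    s1_activity: float      # MBq (fixed)
    s2_activity: float      # MBq/m^2 (scaled by BSA)

    def __post_init__(self) -> None:
        if self.delay not in (24.0, 48.0):
            raise ValueError("pretargeting delay must be 24 or 48 h")


DOSING_SCHEMES: dict[str, DosingScheme] = {
    "I": DosingScheme("I", 44.0, 240.0, 4.4, 24.0, 48.0, 185.0, 1100.0),
    "II": DosingScheme("II", 88.0, 480.0, 4.4, 24.0, 48.0, 185.0, 1100.0),
    "III": DosingScheme("III", 88.0, 480.0, 4.4, 24.0, 24.0, 185.0, 1100.0),
}


def _lognormal_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv**2)))


@dataclass(frozen=True)
class PopulationConfig:
    """Population means and between-subject CVs the generator draws from.

    Defaults are the published population estimates of the antibody, hapten,
    whole-body and organ models; CVs are the between-subject coefficients of
    variation of the corresponding individual estimates.  Tumor dispersion is
    deliberately a free knob (the trial reported only that tumor kinetics was
    too variable for a population analysis).
    """

    tf2_mean: tuple[float, float, float, float] = (0.034, 0.0075, 0.182, 1.86)
    tf2_cv: tuple[float, float, float, float] = (0.055, 0.145, 0.090, 0.040)
    # hapten serum: k_pc, k_cp, A_S (L/h), B_S, vol_per_m2
    hapten_mean: tuple[float, float, float, float, float] = (0.027, 0.019, 1.42, 0.182, 6.38)
    hapten_cv: tuple[float, float, float, float, float] = (0.045, 0.143, 0.115, 0.086, 0.041)
    # whole body: k_pc, k_cp, A_WB (1/h), B_WB
    wb_mean: tuple[float, float, float, float] = (0.0096, 0.0163, 0.105, 0.14)
    wb_cv: tuple[float, float, float, float] = (0.058, 0.139, 0.152, 0.116)
    # organ name -> (k_on 1/h, k_off 1/h, fraction L/kg)
    organ_mean: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "lungs": (1.06e-3, 1.17e-2, 3.38e-2),
            "liver": (1.45e-3, 1.14e-2, 2.33e-2),
            "kidneys": (4.35e-3, 2.22e-2, 5.91e-2),
            "spleen": (1.48e-3, 1.30e-2, 2.21e-2),
            "heart": (0.45e-3, 0.94e-2, 3.08e-2),
        }
    )
    organ_cv: float = 0.08
    tumor_mean: tuple[float, float, float] = (2.0e-3, 1.5e-2, 2.70e-2)
    tumor_cv: float = 0.8
    tumor_mass_kg: float = 0.02
    bsa_mean: float = 1.9
    bsa_sd: float = 0.2
    bsa_bounds: tuple[float, float] = (1.4, 2.4)
    organ_mass_cv: float = 0.10


@dataclass(frozen=True)
class NoiseConfig:
    """Measurement-noise and censoring configuration."""

    serum_sigma: float = 0.10     # multiplicative lognormal SD, serum samples
    imaging_sigma: float = 0.15   # multiplicative lognormal SD, imaging points
    tf2_loq: float = 0.005        # nmol/L (~0.8 ng/mL ELISA limit for a 157 kDa protein)
    hapten_loq: float = 0.0       # MBq/L (gamma counting; effectively none)

    def __post_init__(self) -> None:
        if self.serum_sigma < 0 or self.imaging_sigma < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclass
class VirtualPatient:
    id: str
    bsa: float
    organ_masses: dict[str, float]
    cohort: str
    seed: int
    tf2: TwoCompartmentParams
    hapten_exchange: tuple[float, float]      # k_pc, k_cp
    hapten_power_law: tuple[float, float]     # A_S, B_S (individual)
    hapten_vol_per_m2: float
    wb: WholeBodyParams
    organs: dict[str, TissueParams]
    tumor: TissueParams

    def hapten_params(self, mr: float) -> TwoCompartmentParams:
        """Hapten two-compartment parameters at a given molar ratio."""
        a_s, b_s = self.hapten_power_law
        cl = clearance_power_law(a_s, b_s, mr)
        vc = self.hapten_vol_per_m2 * self.bsa
        return TwoCompartmentParams(
            k_pc=self.hapten_exchange[0],
            k_cp=self.hapten_exchange[1],
            k_el=cl / vc,
            vol_per_m2=self.hapten_vol_per_m2,
        )


def sample_patient(
    seed: int,
    cohort: str = "I",
    config: PopulationConfig | None = None,
    patient_id: str | None = None,
) -> VirtualPatient:
    """Draw one virtual patient; deterministic in ``seed``."""
    if cohort not in DOSING_SCHEMES:
        raise ValueError(f"unknown cohort {cohort!r}; presets are I, II, III")
    cfg = config or PopulationConfig()
    rng = np.random.default_rng(seed)
    bsa = float(
        truncnorm.rvs(
            (cfg.bsa_bounds[0] - cfg.bsa_mean) / cfg.bsa_sd,
            (cfg.bsa_bounds[1] - cfg.bsa_mean) / cfg.bsa_sd,
            loc=cfg.bsa_mean,
            scale=cfg.bsa_sd,
            random_state=rng,
        )
    )

    def draw(means, cvs):
        means = np.asarray(means, dtype=float)
        sig = np.array([_lognormal_sigma(c) for c in np.broadcast_to(cvs, means.shape)])
        return means * np.exp(sig * rng.standard_normal(means.size))

    tf2 = TwoCompartmentParams(*draw(cfg.tf2_mean, cfg.tf2_cv))
    hp = draw(cfg.hapten_mean, cfg.hapten_cv)
    wb = WholeBodyParams(*draw(cfg.wb_mean, cfg.wb_cv))
    masses = {
        organ: float(m * np.exp(_lognormal_sigma(cfg.organ_mass_cv) * rng.standard_normal()))
        for organ, m in REFERENCE_ORGAN_MASSES.items()
    }
    organs = {
        name: TissueParams(*draw(mean, cfg.organ_cv), tissue_mass=masses[name])
        for name, mean in cfg.organ_mean.items()
    }
    tumor = TissueParams(*draw(cfg.tumor_mean, cfg.tumor_cv), tissue_mass=cfg.tumor_mass_kg)
    return VirtualPatient(
        id=patient_id or f"vp{seed}",
        bsa=bsa,
        organ_masses=masses,
        cohort=cohort,
        seed=seed,
        tf2=tf2,
        hapten_exchange=(float(hp[0]), float(hp[1])),
        hapten_power_law=(float(hp[2]), float(hp[3])),
        hapten_vol_per_m2=float(hp[4]),
        wb=wb,
        organs=organs,
        tumor=tumor,
    )


@dataclass
class SessionData:
    """All simulated measurements of one session (S1 or S2)."""

    session: str
    isotope: str
    tf2_series: ConcentrationSeries
    tf2_infusion: InfusionRecord
    hapten_series: ConcentrationSeries      # clock starts at hapten infusion
    hapten_infusion: InfusionRecord
    wb_times: np.ndarray
    wb_activity: np.ndarray
    organ_curves: dict[str, tuple[np.ndarray, np.ndarray]]
    tumor_curve: tuple[np.ndarray, np.ndarray]
    administered_MBq: float
    true_mr: float
    true_hapten: TwoCompartmentParams


@dataclass
class SyntheticTrial:
    patient: VirtualPatient
    scheme: DosingScheme
    sessions: dict[str, SessionData]


def _noisy(rng: np.random.Generator, values: np.ndarray, sigma: float) -> np.ndarray:
    if sigma == 0:
        return values.copy()
    return values * np.exp(sigma * rng.standard_normal(values.size))


def _censor(series_values: np.ndarray, loq: float) -> np.ndarray:
    return series_values < loq if loq > 0 else np.zeros_like(series_values, dtype=bool)


def simulate_trial(
    patient: VirtualPatient,
    scheme: DosingScheme | None = None,
    noise: NoiseConfig | None = None,
    seed: int = 0,
    serum_schedule=SERUM_SCHEDULE,
    imaging_schedule=IMAGING_SCHEDULE,
) -> SyntheticTrial:
    """Simulate both trial sessions for one patient.

    Serum samples follow the trial's blood-draw schedule with multiplicative
    lognormal noise and quantification-limit censoring; imaging points carry
    their own (larger) noise.  All activities are decay-corrected, as in the
    measured data the analysis chain expects.
    """
    scheme = scheme or DOSING_SCHEMES[patient.cohort]
    noise = noise or NoiseConfig()
    rng = np.random.default_rng(seed)
    if not (3 <= len(imaging_schedule) <= 5):
        raise ValueError("imaging schedule must have 3-5 points")
    sessions = {}
    for session, tf2_dose_m2, hapten_dose_m2, isotope in (
        ("S1", scheme.s1_tf2_dose, scheme.s1_hapten_dose, "In-111"),
        ("S2", scheme.s2_tf2_dose, scheme.s2_hapten_dose, "Lu-177"),
    ):
        tf2_dose = tf2_dose_m2 * patient.bsa
        tf2_inf = InfusionRecord(dose=tf2_dose, t_start=0.0, duration=0.5,
                                 session=session, analyte="TF2")
        t_serum = np.asarray(serum_schedule, dtype=float)
        tf2_clean = predict_concentration(patient.tf2, patient.bsa, [tf2_inf], t_serum)
        tf2_noisy = _noisy(rng, tf2_clean, noise.serum_sigma)
        tf2_cens = _censor(tf2_noisy, noise.tf2_loq)
        tf2_series = ConcentrationSeries(
            times=t_serum, values=tf2_noisy, below_limit=tf2_cens,
            analyte="TF2", session=session, unit="nmol/L", patient_id=patient.id,
        )

        # true molar ratio from the noise-free antibody curve
        n_hapten = hapten_dose_m2 * patient.bsa
        t_inj = scheme.delay
        conc_at_inj = float(
            predict_concentration(patient.tf2, patient.bsa, [tf2_inf], np.array([t_inj]))[0]
        )
        vc_tf2 = patient.tf2.central_volume(patient.bsa)
        mr = n_hapten / (conc_at_inj * vc_tf2)

        hp = patient.hapten_params(mr)
        activity = (
            scheme.s1_activity if session == "S1" else scheme.s2_activity * patient.bsa
        )
        hap_inf = InfusionRecord(dose=activity, t_start=0.0, duration=0.5,
                                 session=session, analyte=f"IMP288-{isotope}")
        hap_clean = predict_concentration(hp, patient.bsa, [hap_inf], t_serum)
        hap_noisy = _noisy(rng, hap_clean, noise.serum_sigma)
        hap_series = ConcentrationSeries(
            times=t_serum, values=hap_noisy,
            below_limit=_censor(hap_noisy, noise.hapten_loq),
            analyte=f"IMP288-{isotope}", session=session, unit="MBq/L",
            patient_id=patient.id,
        )

        t_img = np.asarray(imaging_schedule, dtype=float)
        wb_clean = predict_wholebody(patient.wb, mr, hap_inf, t_img)
        wb_noisy = _noisy(rng, wb_clean, noise.imaging_sigma)
        vc_hapten = hp.central_volume(patient.bsa)
        organ_curves = {}
        for organ, tp in patient.organs.items():
            clean = predict_tissue(patient.wb, mr, hap_inf, tp, t_img, vc_hapten)
            organ_curves[organ] = (t_img, _noisy(rng, clean, noise.imaging_sigma))
        tum_clean = predict_tissue(
            patient.wb, mr, hap_inf, patient.tumor, t_img, vc_hapten
        )
        tumor_curve = (t_img, _noisy(rng, tum_clean, noise.imaging_sigma))

        sessions[session] = SessionData(
            session=session,
            isotope=isotope,
            tf2_series=tf2_series,
            tf2_infusion=tf2_inf,
            hapten_series=hap_series,
            hapten_infusion=hap_inf,
            wb_times=t_img,
            wb_activity=wb_noisy,
            organ_curves=organ_curves,
            tumor_curve=tumor_curve,
            administered_MBq=activity,
            true_mr=mr,
            true_hapten=hp,
        )
    return SyntheticTrial(patient=patient, scheme=scheme, sessions=sessions)
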