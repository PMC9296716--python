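"""Synthetic patient cohorts with a known MFI → outcome relationship.

Each patient carries a selected MFI value, a Goutallier category derived
from the MFI through a calibrated fat-fraction mapping, covariates (age,
sex, BMI, smoking) and five patient-reported outcomes (ODI, NRS back/leg
pain, ZCQ pain/disability) generated from a linear model with Gaussian
noise and clamped to their scale ranges.  Defaults emulate a surgical
lumbar-spinal-stenosis cohort: 243 patients, age 66.6 ± 8.5 years, 49%
female, BMI 27.8 ± 4.0, 23% smokers, MFI ≈ 0.53 ± 0.18.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .phantom import fat_fraction_to_gcs
from .scoring import trichotomize

OUTCOME_NAMES = ("odi", "nrs_back", "nrs_leg", "zcq_pain", "zcq_disability")

#: outcome scale ranges: ODI 0–100, NRS 0–10, ZCQ 1–5
SCALE_RANGES = {
    "odi": (0.0, 100.0),
    "nrs_back": (0.0, 10.0),
    "nrs_leg": (0.0, 10.0),
    "zcq_pain": (1.0, 5.0),
    "zcq_disability": (1.0, 5.0),
}


@dataclass(frozen=True)
class OutcomeModel:
    """Linear data-generating model for one patient-reported outcome."""

    name: str
    intercept: float
    beta_mfi: float
    beta_age: float = 0.0
    beta_sex: float = 0.0
    beta_bmi: float = 0.0
    beta_smoking: float = 0.0
    residual_sd: float = 1.0

    def __post_init__(self):
        if self.name not in SCALE_RANGES:
            raise ValueError(f"unknown outcome {self.name!r}")
        if self.residual_sd < 0:
            raise ValueError(f"residual_sd must be >= 0, got {self.residual_sd}")

    def linear_predictor(self, mfi, age, sex, bmi, smoking):
        return (
            self.intercept
            + self.beta_mfi * mfi
            + self.beta_age * age
            + self.beta_sex * sex
            + self.beta_bmi * bmi
            + self.beta_smoking * smoking
        )


def _default_outcomes() -> dict[str, OutcomeModel]:
    # Effect sizes and dispersions sized to a symptomatic surgical LSS
    # cohort; intercepts chosen so that at the mean MFI of 0.53 each outcome
    # sits at its typical cohort mean (ODI 40.7, NRS ~6.3, ZCQ ~3.4/2.6).
    defaults = {
        "odi": (-6.90, 40.66, 14.57),
        "nrs_back": (-0.41, 6.28, 2.19),
        "nrs_leg": (-1.58, 6.38, 2.10),
        "zcq_pain": (-0.30, 3.38, 0.55),
        "zcq_disability": (-0.25, 2.58, 0.52),
    }
    return {
        name: OutcomeModel(
            name=name,
            beta_mfi=beta,
            intercept=mean - beta * 0.53,
            residual_sd=sd,
        )
        for name, (beta, mean, sd) in defaults.items()
    }


@dataclass(frozen=True)
class CohortParams:
    """Data-generating parameters for a synthetic cohort."""

    n_patients: int = 243
    outcomes: dict = field(default_factory=_default_outcomes)
    age_mean: float = 66.6
    age_sd: float = 8.5
    female_proportion: float = 0.49
    bmi_mean: float = 27.8
    bmi_sd: float = 4.0
    smoking_proportion: float = 0.23
    # MFI ~ Beta(a, b) rescaled to (0, 1]; defaults give mean ~0.53, sd ~0.18
    mfi_beta_a: float = 3.55
    mfi_beta_b: float = 3.14
    gcs_misclass_prob: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError(f"n_patients must be >= 1, got {self.n_patients}")
        for name in ("female_proportion", "smoking_proportion", "gcs_misclass_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.age_sd < 0 or self.bmi_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.mfi_beta_a <= 0 or self.mfi_beta_b <= 0:
            raise ValueError("Beta shape parameters must be positive")

    def with_outcome(self, name: str, **changes) -> "CohortParams":
        """Copy with one outcome's generating model altered."""
        outcomes = dict(self.outcomes)
        outcomes[name] = replace(outcomes[name], **changes)
        return replace(self, outcomes=outcomes)


# Piecewise-linear inversion from measured MFI to an implied paraspinal fat
# fraction.  Anchors are calibrated so that the fat-fraction grade edges
# (0.05, 0.20, 0.45, 0.55) fall at MFI values matching the observed
# grade-wise MFI means in LSS patients (grade 0 ≈ 0.61 … grade 4 ≈ 0.29):
# an MFI of 1.0 implies no infiltration and MFI below ~0.3 implies a
# fat-dominated paraspinal compartment.
_MFI_ANCHORS = np.array([1.0, 0.515, 0.385, 0.325, 0.295, 0.05])
_FAT_ANCHORS = np.array([0.0, 0.05, 0.20, 0.45, 0.55, 1.0])


def mfi_to_fat_fraction(mfi) -> np.ndarray:
    """Implied paraspinal fat fraction for a measured MFI (monotone ↓)."""
    m = np.clip(np.asarray(mfi, dtype=float), 0.0, 1.0)
    # np.interp needs increasing x: flip both anchor arrays
    return np.interp(m, _MFI_ANCHORS[::-1], _FAT_ANCHORS[::-1])


def generate_cohort(params: CohortParams) -> pd.DataFrame:
    """Draw one synthetic cohort table (one row per patient).

    Columns: patient_id, mfi_selected, gcs_grade, gcs_category, age, sex
    (1 = female), bmi, smoking (1 = yes), and the five outcomes.  The GCS
    grade is the fat-fraction grade implied by the MFI, optionally misread
    by ±1 with probability ``gcs_misclass_prob`` before trichotomisation.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_patients

    eps = 1e-6
    mfi = np.clip(rng.beta(params.mfi_beta_a, params.mfi_beta_b, size=n), eps, 1.0)
    age = rng.normal(params.age_mean, params.age_sd, size=n)
    sex = (rng.random(n) < params.female_proportion).astype(int)
    bmi = rng.normal(params.bmi_mean, params.bmi_sd, size=n)
    smoking = (rng.random(n) < params.smoking_proportion).astype(int)

    fat = mfi_to_fat_fraction(mfi)
    grades = np.array([fat_fraction_to_gcs(f) for f in fat])
    if params.gcs_misclass_prob > 0:
        flip = rng.random(n) < params.gcs_misclass_prob
        step = np.where(rng.random(n) < 0.5, 1, -1)
        shifted = grades + step
        shifted = np.where((shifted < 0) | (shifted > 4), grades - step, shifted)
        grades = np.where(flip, shifted, grades)

    table = pd.DataFrame(
        {
            "patient_id": np.arange(1, n + 1),
            "mfi_selected": mfi,
            "gcs_grade": grades,
            "gcs_category": [trichotomize(g) for g in grades],
            "age": age,
            "sex": sex,
            "bmi": bmi,
            "smoking": smoking,
        }
    )
    for name, model in params.outcomes.items():
        lin = model.linear_predictor(mfi, age, sex, bmi, smoking)
        if model.residual_sd > 0:
            lin = lin + rng.normal(0.0, model.residual_sd, size=n)
        lo, hi = SCALE_RANGES[name]
        table[name] = np.clip(lin, lo, hi)
    return table
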