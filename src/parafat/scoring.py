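"""Muscle fat index (MFI) computation and Goutallier grade handling.

The simplified MFI is the ratio of the mean T2 signal intensity of the psoas
major (PM) to that of the combined multifidus + erector spinae on the same
axial slice and side.  Because the PM serves as an internal low-fat
reference, values near 1.0 indicate little paraspinal fatty infiltration and
values near 0 indicate severe infiltration.  Ratios above 1.0 (bright PM
relative to paraspinal muscle without apparent PM infiltration) are clipped
to 1.0 and flagged, never silently altered.

The Goutallier classification system (GCS) is the companion 5-level ordinal
visual grading (0 = no fatty streaks … 4 = more fat than muscle).  For
regression analyses grades are trichotomised into category 0 (grade 0),
category I (grade 1) and category II (grades 2–4).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .roi import MeanSignal, RegionLabel

#: vertebral levels, upper-endplate convention: "L2L3" is the slice at the
#: upper endplate of L3
LEVELS = ("L2L3", "L3L4", "L4L5")
SIDES = ("left", "right")

#: trichotomisation: grade 0 → category 0, grade 1 → I, grades 2–4 → II
_CATEGORY_OF_GRADE = {0: "0", 1: "I", 2: "II", 3: "II", 4: "II"}


@dataclass(frozen=True)
class MfiValue:
    """One MFI measurement, with its clipping audit trail."""

    raw: float
    clipped: float
    was_clipped: bool
    patient_id: str | int | None = None
    level: str | None = None
    side: str | None = None


def compute_mfi(
    si_pm: MeanSignal | float,
    si_para: MeanSignal | float,
    patient_id=None,
    level: str | None = None,
    side: str | None = None,
) -> MfiValue:
    """MFI = mean PM signal / mean paraspinal signal, clipped at 1.0.

    Accepts either :class:`~parafat.roi.MeanSignal` objects (whose sides
    must match) or bare floats.  The ratio is scale-invariant: multiplying
    both signals by any c > 0 leaves the MFI unchanged, which is what makes
    the index robust to global scanner-brightness differences.
    """
    if isinstance(si_pm, MeanSignal) and isinstance(si_para, MeanSignal):
        if si_pm.side != si_para.side:
            raise ValueError(
                f"side mismatch: PM is {si_pm.side!r}, paraspinal is {si_para.side!r}"
            )
        side = side or si_pm.side
        pm_value, para_value = si_pm.value, si_para.value
    else:
        pm_value = si_pm.value if isinstance(si_pm, MeanSignal) else float(si_pm)
        para_value = si_para.value if isinstance(si_para, MeanSignal) else float(si_para)

    if para_value <= 0:
        raise ValueError(f"paraspinal mean signal must be positive, got {para_value}")
    raw = pm_value / para_value
    return MfiValue(
        raw=raw,
        clipped=min(raw, 1.0),
        was_clipped=raw > 1.0,
        patient_id=patient_id,
        level=level,
        side=side,
    )


def clip_mfi(raw: float) -> float:
    """Clipping rule applied to raw MFI values (idempotent)."""
    return min(float(raw), 1.0)


def validate_grade(grade) -> int:
    g = int(grade)
    if not 0 <= g <= 4:
        raise ValueError(f"Goutallier grade must be in 0..4, got {grade}")
    return g


def trichotomize(grade) -> str:
    """Map a Goutallier grade (0–4) to category '0', 'I' or 'II'."""
    return _CATEGORY_OF_GRADE[validate_grade(grade)]


def select_for_regression(records: pd.DataFrame) -> pd.Series:
    """Per-patient selection rule: the side with the highest infiltration.

    Given one patient's measurements at a single level (one row per side
    with columns ``mfi`` and ``gcs``), returns the minimum clipped MFI and
    the maximum GCS grade across sides — the side-wise worst case.  A
    single-side input is returned as-is with a warning.  Ties in MFI record
    the left side as source, for determinism.
    """
    if len(records) == 0:
        return pd.Series({"mfi_selected": np.nan, "gcs_selected": np.nan,
                          "mfi_source_side": None})
    mfi = records["mfi"].map(clip_mfi)
    if len(records) == 1:
        warnings.warn(
            "only one side available; selected values come from a single measurement",
            stacklevel=2,
        )
    order = {"left": 0, "right": 1}
    idx = sorted(records.index, key=lambda i: (mfi[i], order.get(records.loc[i, "side"], 2)))
    best = idx[0]
    return pd.Series(
        {
            "mfi_selected": float(mfi[best]),
            "gcs_selected": int(records["gcs"].max()),
            "mfi_source_side": records.loc[best, "side"],
        }
    )


def select_cohort_values(measurements: pd.DataFrame, level: str = "L2L3") -> pd.DataFrame:
    """Apply the selection rule patient-by-patient at one vertebral level."""
    at_level = measurements[measurements["level"] == level]
    if at_level.empty:
        raise ValueError(f"no measurements at level {level!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = at_level.groupby("patient_id", sort=True).apply(
            select_for_regression, include_groups=False
        )
    out["gcs_category"] = out["gcs_selected"].map(trichotomize)
    return out.reset_index()


def summarize_mfi_by_grade(measurements: pd.DataFrame, confidence: float = 0.95) -> pd.DataFrame:
    """Mean clipped MFI per Goutallier grade with a two-sided t-based CI.

    One row per observed grade: grade, n, mean MFI, CI bounds.  A grade with
    fewer than two observations gets NaN CI bounds rather than being
    dropped.
    """
    df = measurements[["gcs", "mfi"]].dropna().copy()
    df["gcs"] = df["gcs"].map(validate_grade)
    df["mfi"] = df["mfi"].map(clip_mfi)

    rows = []
    for grade, group in df.groupby("gcs", sort=True):
        vals = group["mfi"].to_numpy()
        n = len(vals)
        mean = float(vals.mean())
        if n >= 2:
            sem = vals.std(ddof=1) / np.sqrt(n)
            tcrit = stats.t.ppf(0.5 + confidence / 2, df=n - 1)
            lo, hi = mean - tcrit * sem, mean + tcrit * sem
        else:
            lo = hi = np.nan
        rows.append({"grade": int(grade), "n": n, "mean_mfi": mean,
                     "ci_low": float(lo), "ci_high": float(hi)})
    return pd.DataFrame(rows)
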