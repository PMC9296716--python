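"""Imperfect-observer simulation on phantom slices.

A simulated observer re-delineates each muscle ROI with random morphological
jitter (erosion or dilation by a random radius), may wrongly include the
epimuscular fat rim in the paraspinal ROI, and misreads the Goutallier grade
with a configurable probability (a ±1 shift, reflected inward at the scale
ends).  With all three noise sources at zero the observer reproduces the
phantom ground truth exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.morphology import dilation, disk, erosion

from .phantom import PhantomParams, PhantomTruth, generate_phantom
from .roi import RegionLabel, extract_mean_signal
from .scoring import compute_mfi

_MAX_JITTER_RETRIES = 10


@dataclass(frozen=True)
class ObserverProfile:
    """Noise parameters of one simulated observer."""

    roi_jitter_px: int = 0
    epimuscular_inclusion_prob: float = 0.0
    grade_misclass_prob: float = 0.0
    min_mask_pixels: int = 25
    seed: int = 0

    def __post_init__(self):
        if self.roi_jitter_px < 0:
            raise ValueError(f"roi_jitter_px must be >= 0, got {self.roi_jitter_px}")
        for name in ("epimuscular_inclusion_prob", "grade_misclass_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")


def _jitter_mask(mask: np.ndarray, max_px: int, min_pixels: int, rng) -> np.ndarray:
    """Randomly erode or dilate a mask; never return one below min_pixels."""
    if max_px == 0:
        return mask
    for _ in range(_MAX_JITTER_RETRIES):
        radius = int(rng.integers(-max_px, max_px + 1))
        if radius == 0:
            return mask
        footprint = disk(abs(radius))
        out = dilation(mask, footprint) if radius > 0 else erosion(mask, footprint)
        if out.sum() >= min_pixels:
            return out
    raise RuntimeError(
        f"ROI jitter emptied a mask of {int(mask.sum())} pixels after "
        f"{_MAX_JITTER_RETRIES} retries (jitter {max_px} px)"
    )


def perturb_grade(grade: int, prob: float, rng) -> int:
    """Shift a Goutallier grade by ±1 with the given probability.

    The shift direction is uniform; a shift that would leave the 0–4 scale
    is reflected inward, so a certain misread of a grade-0 muscle yields
    grade 1.
    """
    if prob > 0 and rng.random() < prob:
        step = 1 if rng.random() < 0.5 else -1
        shifted = grade + step
        if not 0 <= shifted <= 4:
            shifted = grade - step
        return shifted
    return grade


def simulate_observer(
    image: np.ndarray,
    masks: dict[RegionLabel, np.ndarray],
    truth: PhantomTruth,
    profile: ObserverProfile,
    rng: np.random.Generator | None = None,
    **keys,
) -> pd.DataFrame:
    """One observer's reading of one slice: per-side MFI and GCS grade.

    Returns a two-row frame (one per side) with columns mfi, mfi_raw, gcs
    plus any identifying keyword columns (patient_id, level, observer,
    session, ...).  With a dedicated ``rng`` the profile seed is ignored,
    which lets a study simulator drive many readings from one seed stream.
    """
    if rng is None:
        rng = np.random.default_rng(profile.seed)

    region_pairs = {
        "left": (RegionLabel.PM_LEFT, RegionLabel.PARA_LEFT),
        "right": (RegionLabel.PM_RIGHT, RegionLabel.PARA_RIGHT),
    }
    rim = masks.get(RegionLabel.EPIMUSCULAR_FAT)
    rows = []
    for side, (pm_label, para_label) in region_pairs.items():
        pm_mask = _jitter_mask(masks[pm_label], profile.roi_jitter_px,
                               profile.min_mask_pixels, rng)
        para_mask = _jitter_mask(masks[para_label], profile.roi_jitter_px,
                                 profile.min_mask_pixels, rng)

        observed = {pm_label: pm_mask, para_label: para_mask}
        if rim is not None:
            if profile.epimuscular_inclusion_prob > 0 and (
                rng.random() < profile.epimuscular_inclusion_prob
            ):
                # the observer violates the exclusion rule: fat rim pixels
                # enter the paraspinal ROI and no rim label is declared
                observed[para_label] = para_mask | rim
            else:
                observed[RegionLabel.EPIMUSCULAR_FAT] = rim

        si_pm = extract_mean_signal(image, observed, pm_label)
        si_para = extract_mean_signal(image, observed, para_label)
        mfi = compute_mfi(si_pm, si_para, side=side)
        grade = perturb_grade(truth.true_gcs[side], profile.grade_misclass_prob, rng)
        rows.append({**keys, "side": side, "mfi": mfi.clipped, "mfi_raw": mfi.raw,
                     "was_clipped": mfi.was_clipped, "gcs": grade})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Whole-study simulation


def simulate_reliability_study(
    n_patients: int = 102,
    observer_profiles: list[ObserverProfile] | None = None,
    n_sessions: int = 2,
    levels: tuple[str, ...] = ("L2L3",),
    phantom_params: PhantomParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a multi-observer test-retest reading study on phantoms.

    One phantom is generated per (patient, level) with patient-specific fat
    fractions — paraspinal fat drawn uniformly over [0.02, 0.80] with a
    small left-right asymmetry and psoas fat uniform over [0, 0.10] — and
    every observer reads each slice in every session.  Returns long-format
    measurement records (patient_id, level, side, observer, session, mfi,
    gcs, ...).
    """
    if observer_profiles is None:
        observer_profiles = [ObserverProfile() for _ in range(3)]
    base = phantom_params or PhantomParams()
    master = np.random.SeedSequence(seed)
    phantom_seeds, observer_seed = master.spawn(2)
    obs_rng = np.random.default_rng(observer_seed)
    draw = np.random.default_rng(phantom_seeds)

    frames = []
    for p in range(n_patients):
        f_para = float(draw.uniform(0.02, 0.80))
        for level in levels:
            asym = float(draw.normal(0.0, 0.03))
            params_kwargs = dict(
                fat_fraction_pm_left=float(draw.uniform(0.0, 0.10)),
                fat_fraction_pm_right=float(draw.uniform(0.0, 0.10)),
                fat_fraction_para_left=float(np.clip(f_para - asym, 0.0, 1.0)),
                fat_fraction_para_right=float(np.clip(f_para + asym, 0.0, 1.0)),
                seed=int(draw.integers(2**31 - 1)),
            )
            params = PhantomParams(
                **{
                    **{k: getattr(base, k) for k in (
                        "image_height", "image_width", "mu_muscle", "mu_fat",
                        "noise_sd", "epimuscular_rim_px", "background_signal",
                    )},
                    **params_kwargs,
                }
            )
            image, masks, truth = generate_phantom(params)
            for obs_idx, profile in enumerate(observer_profiles, start=1):
                for session in range(1, n_sessions + 1):
                    frames.append(
                        simulate_observer(
                            image, masks, truth, profile, rng=obs_rng,
                            patient_id=p + 1, level=level,
                            observer=obs_idx, session=session,
                        )
                    )
    return pd.concat(frames, ignore_index=True)
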