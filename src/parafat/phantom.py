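"""Synthetic axial-slice phantoms with known fat content.

Each phantom is a 2D image holding four elliptical muscle regions — psoas
major (PM) left/right anteriorly, combined multifidus + erector spinae
("paraspinal") left/right posteriorly — plus an optional epimuscular fat rim
around each paraspinal region.  The signal model is a linear two-compartment
mixture: a region with fat fraction f has mean intensity

    (1 − f) · mu_muscle + f · mu_fat

with additive Gaussian noise.  This is deliberately the simplest model that
admits an analytic ground truth; no MRI physics (bias fields, coil shading)
is simulated.  The ground-truth MFI per side is the PM mean over the
paraspinal mean, and the ground-truth Goutallier grade follows a fixed
monotone mapping from paraspinal fat fraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .roi import RegionLabel

#: fat-fraction → Goutallier grade: anchored so that a region with equal
#: amounts of fat and muscle (f ≈ 0.5) is grade 3 and fat-dominated regions
#: are grade 4
GCS_FAT_FRACTION_EDGES = (0.05, 0.20, 0.45, 0.55)


def fat_fraction_to_gcs(f: float) -> int:
    """Goutallier grade implied by a fat fraction.

    f < 0.05 → 0; [0.05, 0.20) → 1; [0.20, 0.45) → 2; [0.45, 0.55] → 3;
    > 0.55 → 4.  Monotone non-decreasing in f.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"fat fraction must lie in [0, 1], got {f}")
    if f < 0.05:
        return 0
    if f < 0.20:
        return 1
    if f < 0.45:
        return 2
    if f <= 0.55:
        return 3
    return 4


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, signal and noise parameters of one synthetic slice."""

    image_height: int = 128
    image_width: int = 128
    mu_muscle: float = 400.0
    mu_fat: float = 1000.0
    noise_sd: float = 20.0
    fat_fraction_pm_left: float = 0.05
    fat_fraction_pm_right: float = 0.05
    fat_fraction_para_left: float = 0.30
    fat_fraction_para_right: float = 0.30
    epimuscular_rim_px: int = 2
    background_signal: float = 60.0
    seed: int = 0

    def __post_init__(self):
        for name in (
            "fat_fraction_pm_left",
            "fat_fraction_pm_right",
            "fat_fraction_para_left",
            "fat_fraction_para_right",
        ):
            f = getattr(self, name)
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {f}")
        if not self.mu_fat > self.mu_muscle > 0:
            raise ValueError(
                f"need mu_fat > mu_muscle > 0, got mu_fat={self.mu_fat}, "
                f"mu_muscle={self.mu_muscle}"
            )
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.epimuscular_rim_px < 0:
            raise ValueError(f"epimuscular_rim_px must be >= 0, got {self.epimuscular_rim_px}")
        if self.image_height < 32 or self.image_width < 32:
            raise ValueError("image must be at least 32 x 32 pixels")

    @property
    def fat_fractions(self) -> dict[RegionLabel, float]:
        return {
            RegionLabel.PM_LEFT: self.fat_fraction_pm_left,
            RegionLabel.PM_RIGHT: self.fat_fraction_pm_right,
            RegionLabel.PARA_LEFT: self.fat_fraction_para_left,
            RegionLabel.PARA_RIGHT: self.fat_fraction_para_right,
        }


@dataclass(frozen=True)
class PhantomTruth:
    """Analytic ground truth for one phantom slice."""

    true_mean_signal: dict = field(default_factory=dict)  # RegionLabel.name -> signal
    true_mfi_left: float = float("nan")
    true_mfi_right: float = float("nan")
    true_gcs: dict = field(default_factory=dict)          # "left"/"right" -> grade

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def mixture_signal(f: float, mu_muscle: float, mu_fat: float) -> float:
    """Mean signal of a two-compartment muscle/fat mixture."""
    return (1.0 - f) * mu_muscle + f * mu_fat


def _ellipse_mask(shape, center, semiaxes) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    r0, c0 = center
    ra, ca = semiaxes
    return ((rr - r0) / ra) ** 2 + ((cc - c0) / ca) ** 2 <= 1.0


def _default_geometry(h: int, w: int) -> dict[RegionLabel, tuple]:
    """Ellipse centres and semiaxes, as fractions of the slice size.

    PM pair sits anteriorly (upper rows), the larger paraspinal pair
    posteriorly, mirrored across the midline like the muscle layout on a
    lumbar axial slice.
    """
    return {
        RegionLabel.PM_LEFT: ((0.33 * h, 0.30 * w), (0.110 * h, 0.095 * w)),
        RegionLabel.PM_RIGHT: ((0.33 * h, 0.70 * w), (0.110 * h, 0.095 * w)),
        RegionLabel.PARA_LEFT: ((0.72 * h, 0.32 * w), (0.145 * h, 0.115 * w)),
        RegionLabel.PARA_RIGHT: ((0.72 * h, 0.68 * w), (0.145 * h, 0.115 * w)),
    }


def generate_phantom(
    params: PhantomParams,
) -> tuple[np.ndarray, dict[RegionLabel, np.ndarray], PhantomTruth]:
    """Render one phantom slice.

    Returns the image, a dict of boolean region masks (including the
    epimuscular-fat rim when ``epimuscular_rim_px`` > 0), and the analytic
    :class:`PhantomTruth`.  Raises ``ValueError`` naming the offending
    region if the geometry would overlap or leave the image bounds.
    """
    h, w = params.image_height, params.image_width
    geometry = _default_geometry(h, w)

    masks: dict[RegionLabel, np.ndarray] = {}
    for label, (center, semiaxes) in geometry.items():
        r0, c0 = center
        ra, ca = semiaxes
        if r0 - ra < 0 or r0 + ra >= h or c0 - ca < 0 or c0 + ca >= w:
            raise ValueError(f"region {label.name} leaves the image bounds")
        masks[label] = _ellipse_mask((h, w), center, semiaxes)

    if params.epimuscular_rim_px > 0:
        from skimage.morphology import dilation, disk

        footprint = disk(params.epimuscular_rim_px)
        rim = np.zeros((h, w), dtype=bool)
        for label in (RegionLabel.PARA_LEFT, RegionLabel.PARA_RIGHT):
            rim |= dilation(masks[label], footprint) & ~masks[label]
        masks[RegionLabel.EPIMUSCULAR_FAT] = rim

    labels = list(masks)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            if (masks[a] & masks[b]).any():
                raise ValueError(f"regions {a.name} and {b.name} overlap")

    true_mean = {
        label.name: mixture_signal(f, params.mu_muscle, params.mu_fat)
        for label, f in params.fat_fractions.items()
    }
    rng = np.random.default_rng(params.seed)
    image = np.full((h, w), params.background_signal, dtype=float)
    for label in (
        RegionLabel.PM_LEFT,
        RegionLabel.PM_RIGHT,
        RegionLabel.PARA_LEFT,
        RegionLabel.PARA_RIGHT,
    ):
        image[masks[label]] = true_mean[label.name]
    if RegionLabel.EPIMUSCULAR_FAT in masks:
        image[masks[RegionLabel.EPIMUSCULAR_FAT]] = params.mu_fat
    if params.noise_sd > 0:
        image += rng.normal(0.0, params.noise_sd, size=(h, w))

    truth = PhantomTruth(
        true_mean_signal=true_mean,
        true_mfi_left=true_mean["PM_LEFT"] / true_mean["PARA_LEFT"],
        true_mfi_right=true_mean["PM_RIGHT"] / true_mean["PARA_RIGHT"],
        true_gcs={
            "left": fat_fraction_to_gcs(params.fat_fraction_para_left),
            "right": fat_fraction_to_gcs(params.fat_fraction_para_right),
        },
    )
    return image, masks, truth


def masks_to_label_array(masks: dict[RegionLabel, np.ndarray]) -> np.ndarray:
    """Flatten a dict of boolean masks into one integer label array."""
    shape = next(iter(masks.values())).shape
    out = np.zeros(shape, dtype=np.int16)
    for label in sorted(masks, key=int):
        out[masks[label]] = int(label)
    return out
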