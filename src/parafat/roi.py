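"""Region-of-interest signal extraction from axial image slices.

The raw material of the muscle fat index is the mean T2 signal intensity
inside manually (or synthetically) delineated muscle regions: psoas major
(PM) left/right and the combined multifidus + erector spinae ("paraspinal")
left/right.  Epimuscular fat — fat outside the muscle fascia — carries its
own label and is always excluded from the paraspinal mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

#: smallest region size accepted by default; guards against degenerate masks
DEFAULT_MINIMUM_ROI_PIXELS = 25


class RegionLabel(IntEnum):
    """Integer labels used in mask volumes (0 = background)."""

    PM_LEFT = 1
    PM_RIGHT = 2
    PARA_LEFT = 3
    PARA_RIGHT = 4
    EPIMUSCULAR_FAT = 5


MUSCLE_LABELS = (
    RegionLabel.PM_LEFT,
    RegionLabel.PM_RIGHT,
    RegionLabel.PARA_LEFT,
    RegionLabel.PARA_RIGHT,
)

#: region → side, for bookkeeping in MeanSignal rows
REGION_SIDE = {
    RegionLabel.PM_LEFT: "left",
    RegionLabel.PM_RIGHT: "right",
    RegionLabel.PARA_LEFT: "left",
    RegionLabel.PARA_RIGHT: "right",
    RegionLabel.EPIMUSCULAR_FAT: "both",
}


@dataclass(frozen=True)
class MeanSignal:
    """Arithmetic mean signal intensity over one labelled region."""

    region: RegionLabel
    side: str
    value: float
    pixel_count: int


class MaskValidationError(ValueError):
    """Raised when a mask set violates the labelling contract."""


def _masks_to_dict(masks) -> dict[RegionLabel, np.ndarray]:
    """Normalise a mask input to a dict of boolean arrays.

    Accepts either an integer label array (labels per RegionLabel, 0 =
    background) or a mapping RegionLabel → boolean array.  An integer array
    is disjoint by construction; a dict may overlap and is checked by
    :func:`validate_mask_set`.
    """
    if isinstance(masks, dict):
        return {RegionLabel(k): np.asarray(v, dtype=bool) for k, v in masks.items()}
    arr = np.asarray(masks)
    if not np.issubdtype(arr.dtype, np.integer):
        raise MaskValidationError(
            f"label mask must be integer-valued, got dtype {arr.dtype}"
        )
    out: dict[RegionLabel, np.ndarray] = {}
    for label in RegionLabel:
        m = arr == int(label)
        if m.any():
            out[label] = m
    return out


def validate_mask_set(
    masks,
    image_shape: tuple[int, ...] | None = None,
    minimum_roi_pixels: int = DEFAULT_MINIMUM_ROI_PIXELS,
) -> dict[RegionLabel, np.ndarray]:
    """Check a mask set and return it as a dict of boolean arrays.

    Requires all four muscle labels present, pairwise disjoint, and each at
    least ``minimum_roi_pixels`` in size.  The epimuscular-fat label is
    optional.  Raises :class:`MaskValidationError` naming the offending
    region (and, for overlaps, example pixel coordinates).
    """
    mask_dict = _masks_to_dict(masks)

    shapes = {m.shape for m in mask_dict.values()}
    if len(shapes) > 1:
        raise MaskValidationError(f"masks have inconsistent shapes: {shapes}")
    if image_shape is not None and shapes and shapes != {tuple(image_shape)}:
        raise MaskValidationError(
            f"mask shape {shapes.pop()} does not match image shape {tuple(image_shape)}"
        )

    for label in MUSCLE_LABELS:
        if label not in mask_dict or not mask_dict[label].any():
            raise MaskValidationError(f"missing region {label.name}")

    labels = sorted(mask_dict, key=int)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            overlap = mask_dict[a] & mask_dict[b]
            if overlap.any():
                coords = np.argwhere(overlap)[:5].tolist()
                raise MaskValidationError(
                    f"regions {a.name} and {b.name} overlap at pixels {coords}"
                )

    for label in MUSCLE_LABELS:
        n = int(mask_dict[label].sum())
        if n < minimum_roi_pixels:
            raise MaskValidationError(
                f"region {label.name} has {n} pixels, below the minimum of "
                f"{minimum_roi_pixels}"
            )

    return mask_dict


def extract_mean_signal(
    image: np.ndarray,
    masks,
    region: RegionLabel,
) -> MeanSignal:
    """Mean signal intensity of one labelled region.

    For the paraspinal regions any pixel also carrying the epimuscular-fat
    label is excluded before averaging, enforcing the ROI rule that the fat
    outside the muscle fascia never contributes to the muscle mean.
    """
    image = np.asarray(image, dtype=float)
    mask_dict = _masks_to_dict(masks)
    if region not in mask_dict:
        raise MaskValidationError(f"missing region {region.name}")

    mask = mask_dict[region].copy()
    if region in (RegionLabel.PARA_LEFT, RegionLabel.PARA_RIGHT):
        rim = mask_dict.get(RegionLabel.EPIMUSCULAR_FAT)
        if rim is not None:
            mask &= ~rim

    n = int(mask.sum())
    if n == 0:
        raise MaskValidationError(
            f"region {region.name} is empty after epimuscular-fat exclusion"
        )
    return MeanSignal(
        region=region,
        side=REGION_SIDE[region],
        value=float(image[mask].mean()),
        pixel_count=n,
    )


def extract_all_means(image: np.ndarray, masks) -> dict[RegionLabel, MeanSignal]:
    """Mean signal for each of the four muscle regions."""
    return {label: extract_mean_signal(image, masks, label) for label in MUSCLE_LABELS}


# ---------------------------------------------------------------------------
# NIfTI / CSV interfaces


def load_slice_pair(image_path, mask_path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI image/label-mask pair as 2D arrays.

    Singleton trailing dimensions are squeezed so that single-slice volumes
    round-trip to 2D arrays.  Masks must already be in image space.
    """
    img = np.asarray(nib.load(str(image_path)).dataobj, dtype=float)
    msk = np.asarray(nib.load(str(mask_path)).dataobj)
    img, msk = np.squeeze(img), np.squeeze(msk)
    if img.shape != msk.shape:
        raise MaskValidationError(
            f"image shape {img.shape} does not match mask shape {msk.shape}"
        )
    return img, np.rint(msk).astype(np.int16)


def save_slice_pair(image: np.ndarray, label_mask: np.ndarray, image_path, mask_path) -> None:
    """Write an image slice and integer label mask as NIfTI files."""
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(image, dtype=np.float32), affine), str(image_path))
    nib.save(nib.Nifti1Image(np.asarray(label_mask, dtype=np.int16), affine), str(mask_path))


def means_to_frame(means: dict[RegionLabel, MeanSignal], **keys) -> pd.DataFrame:
    """Tabulate MeanSignal rows; extra keyword columns identify the slice."""
    rows = [
        {**keys, "region": m.region.name, "side": m.side, "mean_signal": m.value,
         "pixel_count": m.pixel_count}
        for m in means.values()
    ]
    return pd.DataFrame(rows)


def write_means_csv(frame: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
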