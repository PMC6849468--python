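"""Plant segmentation and pixel-sum digital traits.

The processing chain mirrors a conveyor-platform image pipeline: crop to the
region of interest, classify pixels by hue/saturation into plant vs blue-cage
vs background, suppress dark shadow pixels with a grey-level threshold, drop
the cage class, remove small connected components, and optionally close small
gaps.  The surviving foreground is the *digital plant object*; its pixel
count, summed over the three side views and the top view and divided by
1000, is the estimated shoot biomass EB in kilopixels (kPix).  The top view
alone gives the top-view area TVA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.color import rgb2gray, rgb2hsv
from skimage.measure import label as cc_label
from skimage.morphology import binary_closing, disk

from .synthetic import VIEWS

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationConfig",
    "DigitalObject",
    "segment_plant",
    "estimated_biomass",
    "top_view_area",
    "extract_trait_table",
]

KPIX = 1000  # one kilopixel is exactly 1000 pixels


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable parameters of the segmentation chain.

    Hue windows are in degrees on the 0-360 colour wheel and must not
    overlap; ``min_saturation`` separates coloured (plant/cage) pixels from
    the near-white background; ``grey_threshold`` (on [0, 1] grey intensity)
    suppresses shadow pixels; components smaller than ``min_component_area``
    pixels are treated as noise; ``morphology_radius`` > 0 applies a binary
    closing with a disc of that radius (0 disables it, keeping pixel counts
    exact on clean scenes).
    """

    roi: tuple[int, int, int, int] | None = None  # (row0, col0, row1, col1)
    grey_threshold: float = 0.08
    plant_hue_window: tuple[float, float] = (60.0, 180.0)
    cage_hue_window: tuple[float, float] = (200.0, 260.0)
    min_saturation: float = 0.25
    min_component_area: int = 5
    morphology_radius: int = 0

    def __post_init__(self) -> None:
        p0, p1 = self.plant_hue_window
        c0, c1 = self.cage_hue_window
        if not (0 <= p0 < p1 <= 360 and 0 <= c0 < c1 <= 360):
            raise ValueError("hue windows must be ordered and within [0, 360]")
        if max(p0, c0) < min(p1, c1):
            raise ValueError("plant and cage hue windows must be disjoint")
        if not 0.0 <= self.grey_threshold <= 1.0:
            raise ValueError("grey_threshold must lie in [0, 1]")
        if self.min_component_area < 1:
            raise ValueError("min_component_area must be >= 1")
        if self.morphology_radius < 0:
            raise ValueError("morphology_radius must be >= 0")
        if self.roi is not None:
            r0, c0_, r1, c1_ = self.roi
            if r1 <= r0 or c1_ <= c0_:
                raise ValueError("roi is empty (end coordinates must exceed start)")


@dataclass(frozen=True)
class DigitalObject:
    """Binary plant mask for one view plus identifying metadata."""

    mask: np.ndarray
    pixel_count: int
    view: str
    das: float | None = None
    pot_id: str | None = None
    variety: str | None = None
    n_level: str | None = None

    def __post_init__(self) -> None:
        if self.pixel_count != int(self.mask.sum()):
            raise ValueError("pixel_count does not match the mask")


def segment_plant(
    image: np.ndarray,
    config: SegmentationConfig = SegmentationConfig(),
    *,
    view: str = "side_0",
    das: float | None = None,
    pot_id: str | None = None,
    variety: str | None = None,
    n_level: str | None = None,
) -> DigitalObject:
    """Segment the plant from one RGB view and count its pixels.

    Steps, in order: ROI crop; hue/saturation classification into plant and
    cage; grey-threshold shadow suppression; cage removal; small-component
    removal (8-connectivity); optional morphological closing.  The returned
    mask has the dimensions of the *input* image (the ROI crop is re-embedded
    so pixel coordinates remain comparable across views).
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] < 3:
        raise ValueError("segment_plant expects an RGB image (H, W, 3)")
    full_shape = image.shape[:2]
    if config.roi is not None:
        r0, c0, r1, c1 = config.roi
        r1 = min(r1, full_shape[0])
        c1 = min(c1, full_shape[1])
        if r1 <= r0 or c1 <= c0:
            raise ValueError("roi does not intersect the image")
        sub = image[r0:r1, c0:c1, :3]
    else:
        r0 = c0 = 0
        sub = image[..., :3]

    hsv = rgb2hsv(sub)
    hue_deg = hsv[..., 0] * 360.0
    sat = hsv[..., 1]
    grey = rgb2gray(sub)

    p0, p1 = config.plant_hue_window
    plant = (hue_deg >= p0) & (hue_deg <= p1) & (sat >= config.min_saturation)
    cg0, cg1 = config.cage_hue_window
    cage = (hue_deg >= cg0) & (hue_deg <= cg1) & (sat >= config.min_saturation)

    plant &= grey >= config.grey_threshold  # drop shadow pixels
    plant &= ~cage

    if plant.any() and config.min_component_area > 1:
        cc = cc_label(plant, connectivity=2)
        sizes = np.bincount(cc.ravel())
        keep = sizes >= config.min_component_area
        keep[0] = False  # background label
        plant = keep[cc]
    if config.morphology_radius > 0:
        plant = binary_closing(plant, disk(config.morphology_radius))
        plant &= ~cage

    mask = np.zeros(full_shape, dtype=bool)
    mask[r0 : r0 + plant.shape[0], c0 : c0 + plant.shape[1]] = plant
    return DigitalObject(
        mask=mask,
        pixel_count=int(mask.sum()),
        view=view,
        das=das,
        pot_id=pot_id,
        variety=variety,
        n_level=n_level,
    )


def estimated_biomass(objects: Sequence[DigitalObject]) -> float:
    """EB in kilopixels: pixel sum over the three side views plus the top view.

    Exactly one object per view is required; a missing or duplicated view is
    an error because EB is defined on the complete four-view set of one plant
    on one imaging day.
    """
    present = sorted(o.view for o in objects)
    if present != sorted(VIEWS):
        raise ValueError(
            f"estimated_biomass needs exactly one object per view {VIEWS}; got {present}"
        )
    return sum(o.pixel_count for o in objects) / KPIX


def top_view_area(obj: DigitalObject) -> float:
    """TVA in kilopixels: pixel sum of the segmented top view."""
    if obj.view != "top":
        raise ValueError(f"top_view_area expects the top view, got {obj.view!r}")
    return obj.pixel_count / KPIX


MANIFEST_COLUMNS = ("pot_id", "variety", "n_level", "das", "view", "path")


def extract_trait_table(
    manifest: pd.DataFrame,
    config: SegmentationConfig = SegmentationConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segment every image listed in a manifest and build the trait table.

    ``manifest`` has one row per image with columns
    ``pot_id, variety, n_level, das, view, path``.  Returns
    ``(traits, skipped)``: one trait row per pot x imaging day with
    ``eb_kpix`` and ``tva_kpix``, and a report of pot x day groups skipped
    because their four-view set was incomplete or an image failed to read.
    Unreadable files are logged and treated as missing views; processing
    continues.
    """
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest is missing columns: {missing}")

    trait_rows = []
    skip_rows = []
    for (pot_id, das), group in manifest.groupby(["pot_id", "das"], sort=True):
        objects = {}
        failures = []
        for rec in group.itertuples():
            try:
                image = iio.imread(rec.path)
            except (OSError, ValueError) as exc:
                logger.error("failed to read %s: %s", rec.path, exc)
                failures.append(str(rec.path))
                continue
            objects[rec.view] = segment_plant(
                image,
                config,
                view=rec.view,
                das=float(das),
                pot_id=str(pot_id),
                variety=str(rec.variety),
                n_level=str(rec.n_level),
            )
        if sorted(objects) != sorted(VIEWS):
            skip_rows.append(
                {
                    "pot_id": pot_id,
                    "das": das,
                    "views_present": ",".join(sorted(objects)),
                    "unreadable": ",".join(failures),
                }
            )
            continue
        first = group.iloc[0]
        trait_rows.append(
            {
                "pot_id": pot_id,
                "variety": first["variety"],
                "n_level": first["n_level"],
                "das": float(das),
                "eb_kpix": estimated_biomass(list(objects.values())),
                "tva_kpix": top_view_area(objects["top"]),
            }
        )
    traits = pd.DataFrame(
        trait_rows, columns=["pot_id", "variety", "n_level", "das", "eb_kpix", "tva_kpix"]
    )
    skipped = pd.DataFrame(
        skip_rows, columns=["pot_id", "das", "views_present", "unreadable"]
    )
    return traits, skipped
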