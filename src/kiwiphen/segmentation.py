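"""Colour-rule segmentation of plant pixels in RGB views.

Plants are imaged against a high-contrast achromatic background, tied to
a support stick painted blue precisely so that colour rules can separate
plant from stick.  A pixel is classified as plant iff

* its hue lies inside the configured plant window (default 40-190 deg,
  chosen to bracket the 60-180 deg analysis bands with margin),
* its saturation and value exceed minimums (rejecting the grey/black
  background), and
* its hue is NOT inside the blue-exclusion window (default 200-260 deg,
  the stick).

An optional connected-component minimum-size filter removes speckle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from skimage.morphology import remove_small_objects

from .colorimetry import hsv_channels
from .errors import FormatError

log = logging.getLogger(__name__)

VIEWS = ("TV", "SV0", "SV90")


@dataclass(frozen=True)
class SegmentationParams:
    """Thresholds for the HSV colour rule (hue in degrees)."""

    hue_min: float = 40.0
    hue_max: float = 190.0
    s_min: float = 0.15
    v_min: float = 0.10
    blue_hue_min: float = 200.0
    blue_hue_max: float = 260.0
    #: connected components smaller than this are dropped; 0 disables.
    min_component_px: int = 20

    def without_cleanup(self) -> "SegmentationParams":
        return replace(self, min_component_px=0)


@dataclass
class PlantMask:
    """Binary plant-pixel map for one view."""

    view: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.view not in VIEWS:
            raise ValueError(f"view must be one of {VIEWS}, got {self.view!r}")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise FormatError("mask must be a 2-D raster")

    @property
    def plant_pixel_count(self) -> int:
        return int(self.mask.sum())


def segment_plant(
    image: np.ndarray,
    params: SegmentationParams | None = None,
    view: str = "SV0",
) -> PlantMask:
    """Segment plant pixels from one RGB view by the HSV colour rule.

    A zero-pixel result is a valid empty mask (logged, not an error);
    non-3-channel input raises :class:`FormatError`.
    """
    params = params or SegmentationParams()
    hue, sat, val = hsv_channels(image)  # raises FormatError if not RGB
    plant = (
        (hue >= params.hue_min)
        & (hue <= params.hue_max)
        & (sat >= params.s_min)
        & (val >= params.v_min)
        & ~((hue >= params.blue_hue_min) & (hue <= params.blue_hue_max))
    )
    if params.min_component_px > 0:
        try:
            # skimage >= 0.26: max_size removes components <= threshold
            plant = remove_small_objects(plant, max_size=params.min_component_px - 1)
        except TypeError:  # older releases: min_size removes components < threshold
            plant = remove_small_objects(plant, min_size=params.min_component_px)
    if not plant.any():
        log.info("segmentation produced an empty mask for view %s", view)
    return PlantMask(view=view, mask=plant)


def segment_views(
    images: dict[str, np.ndarray], params: SegmentationParams | None = None
) -> dict[str, PlantMask]:
    """Segment every provided view, keyed by view name."""
    return {v: segment_plant(img, params, view=v) for v, img in images.items()}
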