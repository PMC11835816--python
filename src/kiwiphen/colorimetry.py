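"""Hue-histogram colorimetry of segmented plant pixels.

Plant colour is summarised from the hue channel of the HSV colour space,
with hue expressed as an angle in degrees on [0, 360).  Healthy leaf
tissue sits near 120 deg (green); chlorotic, yellowing tissue drifts
toward 60 deg.  Three indices are derived from the hue histogram of the
plant pixels:

* ``HUE`` - the weighted mean hue of the plant, a single-number colour
  summary;
* ``GAS`` / ``GerAS`` - the "green" and "greener" pixel areas, i.e. the
  number of plant pixels whose hue falls in the 60-180 deg and 80-180 deg
  bands respectively (inclusive bounds, so GerAS is nested in GAS);
* ``SI`` - the senescence index ``(GAS - GerAS) / GAS``, the fraction of
  green-band pixels that sit in the yellowing 60-80 deg sub-band.  0 means
  every green-band pixel is "greener" (healthy), 1 means the whole green
  band is in the yellow sub-band.

Histograms use 360 one-degree bins centred on integer degrees: bin ``k``
collects hues in ``[k - 0.5, k + 0.5)`` (mod 360), so a pixel at exactly
120 deg contributes to bin 120 and the weighted mean of a single-hue
image is that hue.  Band membership is decided at bin resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2hsv

from .errors import FormatError, UndefinedResult

N_BINS = 360

#: Inclusive hue bands (degrees) for the green and greener areas.
GREEN_BAND = (60, 180)
GREENER_BAND = (80, 180)


def hsv_channels(image: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (hue_deg, saturation, value) float arrays for an RGB raster.

    Hue is in degrees [0, 360); saturation and value in [0, 1].
    """
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise FormatError(f"expected a 3-channel RGB raster, got shape {arr.shape}")
    hsv = rgb2hsv(arr)
    return hsv[..., 0] * 360.0, hsv[..., 1], hsv[..., 2]


def hue_to_bin(hue_deg: np.ndarray) -> np.ndarray:
    """Map hue angles (degrees) to integer bins 0..359, nearest-degree."""
    return np.rint(np.asarray(hue_deg)).astype(np.int64) % N_BINS


@dataclass
class HueHistogram:
    """Hue histogram of the plant pixels of one view (or pooled views)."""

    counts: np.ndarray
    view: str = "SV0"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_BINS,):
            raise FormatError(f"hue histogram must have {N_BINS} bins")
        if (self.counts < 0).any():
            raise FormatError("hue histogram counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "HueHistogram") -> "HueHistogram":
        return HueHistogram(self.counts + other.counts, view=f"{self.view}+{other.view}")


def hue_histogram(image: np.ndarray, mask, view: str = "SV0") -> HueHistogram:
    """Histogram the hue of the masked (plant) pixels of an RGB raster."""
    mask_arr = np.asarray(getattr(mask, "mask", mask), dtype=bool)
    arr = np.asarray(image)
    if arr.shape[:2] != mask_arr.shape:
        raise FormatError(
            f"image {arr.shape[:2]} and mask {mask_arr.shape} dimensions differ"
        )
    if not mask_arr.any():
        return HueHistogram(np.zeros(N_BINS, dtype=np.int64), view=view)
    hue_deg, _, _ = hsv_channels(arr)
    bins = hue_to_bin(hue_deg[mask_arr])
    return HueHistogram(np.bincount(bins, minlength=N_BINS), view=view)


def weighted_mean_hue(hist: HueHistogram) -> float:
    """Weighted mean hue in degrees: sum(bin * count) / total.

    Linear (non-circular) mean on bin representatives; adequate while the
    plant hue mass stays away from the 0/360 wrap, which segmentation
    guarantees by excluding blues and the achromatic background.
    """
    if hist.total == 0:
        raise UndefinedResult("weighted mean hue is undefined for an empty histogram")
    bins = np.arange(N_BINS, dtype=float)
    return float((bins * hist.counts).sum() / hist.total)


def green_fractions(
    hist: HueHistogram,
    green_band: tuple[int, int] = GREEN_BAND,
    greener_band: tuple[int, int] = GREENER_BAND,
) -> tuple[int, int]:
    """Return (GAS, GerAS): pixel counts in the green and greener hue bands.

    Bounds are inclusive on both ends; a pixel at exactly 80 deg counts in
    both bands.  GerAS <= GAS holds whenever the greener band is nested in
    the green band, which the defaults guarantee.
    """
    lo, hi = green_band
    glo, ghi = greener_band
    if not (lo <= glo and ghi <= hi):
        raise ValueError("greener band must be nested inside the green band")
    gas = int(hist.counts[lo : hi + 1].sum())
    geras = int(hist.counts[glo : ghi + 1].sum())
    return gas, geras


def senescence_index(gas: int, geras: int) -> float:
    """SI = (GAS - GerAS) / GAS, in [0, 1]."""
    if gas < 0 or geras < 0 or geras > gas:
        raise ValueError(f"need 0 <= GerAS <= GAS, got GAS={gas}, GerAS={geras}")
    if gas == 0:
        raise UndefinedResult("senescence index is undefined when GAS = 0")
    return (gas - geras) / gas


@dataclass
class ColorResult:
    """Per-plant colour indices pooled over the two side views.

    GAS/GerAS and SI are defined on side-view images; HUE is the weighted
    mean of the pooled side-view histogram.
    """

    hue_weighted_mean_deg: float
    green_area_px: int
    greener_area_px: int
    si: float
    histogram: HueHistogram = field(repr=False)


def color_result(
    images: dict[str, np.ndarray],
    masks: dict[str, "np.ndarray | object"],
    green_band: tuple[int, int] = GREEN_BAND,
    greener_band: tuple[int, int] = GREENER_BAND,
) -> ColorResult:
    """Compute HUE, GAS, GerAS and SI from the side views of one plant.

    ``images``/``masks`` map view names to rasters; only ``SV0`` and
    ``SV90`` enter the colour indices.  Raises :class:`UndefinedResult`
    when the plant has no side-view pixels at all (empty histogram).
    """
    pooled = HueHistogram(np.zeros(N_BINS, dtype=np.int64), view="SV")
    for view in ("SV0", "SV90"):
        if view in images:
            pooled = pooled + hue_histogram(images[view], masks[view], view=view)
    hue = weighted_mean_hue(pooled)  # raises on empty plant
    gas, geras = green_fractions(pooled, green_band, greener_band)
    si = senescence_index(gas, geras) if gas > 0 else float("nan")
    return ColorResult(hue, gas, geras, si, pooled)
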