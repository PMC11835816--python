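"""Near-infrared intensity as a tissue water-content proxy.

NIR reflectance around the 1,450 nm water-absorption band drops as
tissue water content rises: well-hydrated tissue absorbs more and
reflects less, so *high water content -> low NIR intensity*.  The proxy
reported per plant is simply the arithmetic mean of the side-view NIR
raster over the plant pixels, on the raw 8-bit scale (no reflectance
calibration; the useful dynamic range in practice is roughly 150-200).

The plant mask comes from the co-acquired RGB side view; rasters are
assumed co-aligned and same-size (any real-data registration is a
config-level rescale upstream of this module).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FormatError, UndefinedResult


@dataclass
class NirResult:
    mean_intensity: float
    pixel_count: int
    view: str = "SV0"


def nir_intensity(nir: np.ndarray, mask, view: str = "SV0") -> NirResult:
    """Mean NIR intensity over the masked plant pixels.

    Raises :class:`UndefinedResult` for an empty mask and
    :class:`FormatError` on a dimension mismatch.  Pixels outside the
    mask never influence the result.
    """
    arr = np.asarray(nir)
    if arr.ndim != 2:
        raise FormatError(f"NIR raster must be single-channel 2-D, got shape {arr.shape}")
    mask_arr = np.asarray(getattr(mask, "mask", mask), dtype=bool)
    if arr.shape != mask_arr.shape:
        raise FormatError(
            f"NIR raster {arr.shape} and mask {mask_arr.shape} dimensions differ"
        )
    n = int(mask_arr.sum())
    if n == 0:
        raise UndefinedResult("NIR intensity is undefined for an empty mask")
    return NirResult(
        mean_intensity=float(arr[mask_arr].mean()), pixel_count=n, view=view
    )
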