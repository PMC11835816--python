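"""Morphometric traits from binary plant masks.

Two traits are computed:

* **Projected shoot area (PSA)** - the plant pixel areas of the top view
  and the two orthogonal side views are summed,

      PSA = Area(TV) + Area(0 deg SV) + Area(90 deg SV),

  and converted to cm^2 with a camera calibration factor (cm^2 per
  pixel).  The three-view sum averages out leaf overlap seen from any
  single direction.

* **Solidity (S)** - the ratio of the plant pixel area to the pixel area
  of the filled convex hull containing all plant pixels, in (0, 1].  A
  compact, dense canopy scores near 1; a sprawling or defoliated one
  scores low.

Hull convention: the hull is the convex hull of the plant *pixel
centres* (integer grid coordinates), and the hull pixel area counts the
raster pixels whose centre lies inside or on that polygon.  Because all
vertices are lattice points, inclusion is decided with exact integer
half-plane tests - no floating-point boundary ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .errors import DesignError, UndefinedResult
from .segmentation import VIEWS, PlantMask


def _segment_lattice_count(coords: np.ndarray, v: np.ndarray) -> int:
    """Lattice points on the hull of collinear points (a segment)."""
    if not v.any():  # all points identical
        return 1
    t = coords @ v
    vmin, vmax = coords[int(np.argmin(t))], coords[int(np.argmax(t))]
    step = np.gcd(abs(int(vmax[0] - vmin[0])), abs(int(vmax[1] - vmin[1])))
    return int(step) + 1


def hull_pixel_area(mask: np.ndarray | PlantMask) -> int:
    """Pixel count of the filled convex hull of the mask's plant pixels."""
    arr = np.asarray(getattr(mask, "mask", mask), dtype=bool)
    coords = np.argwhere(arr)  # (row, col) integer centres
    n = len(coords)
    if n == 0:
        raise UndefinedResult("convex hull of an empty mask is undefined")
    if n == 1:
        return 1
    try:
        hull = ConvexHull(coords)
    except QhullError:
        return _segment_lattice_count(coords, coords[-1] - coords[0])
    verts = coords[hull.vertices]  # consistent winding order
    # orient counter-clockwise in (row, col) axes via the signed area
    r, c = verts[:, 0], verts[:, 1]
    signed2 = int(np.sum(r * np.roll(c, -1) - np.roll(r, -1) * c))
    if signed2 < 0:
        verts = verts[::-1]
    rmin, cmin = coords.min(axis=0)
    rmax, cmax = coords.max(axis=0)
    rr, cc = np.meshgrid(
        np.arange(rmin, rmax + 1, dtype=np.int64),
        np.arange(cmin, cmax + 1, dtype=np.int64),
        indexing="ij",
    )
    inside = np.ones(rr.shape, dtype=bool)
    for (r0, c0), (r1, c1) in zip(verts, np.roll(verts, -1, axis=0)):
        # integer cross product: >= 0 keeps points on/left of the edge
        cross = (int(r1) - int(r0)) * (cc - int(c0)) - (int(c1) - int(c0)) * (rr - int(r0))
        inside &= cross >= 0
    return int(inside.sum())


def solidity(mask: np.ndarray | PlantMask) -> float:
    """Plant pixel area / filled convex hull pixel area, in (0, 1]."""
    arr = np.asarray(getattr(mask, "mask", mask), dtype=bool)
    plant = int(arr.sum())
    if plant == 0:
        raise UndefinedResult("solidity of an empty mask is undefined")
    return plant / hull_pixel_area(arr)


def projected_shoot_area(
    masks: dict[str, PlantMask], calibration_cm2_per_px: float
) -> float:
    """PSA in cm^2 from exactly one mask per view (TV, SV0, SV90)."""
    if calibration_cm2_per_px <= 0:
        raise ValueError(
            f"calibration must be positive, got {calibration_cm2_per_px}"
        )
    missing = [v for v in VIEWS if v not in masks]
    if missing:
        raise DesignError(f"missing view(s) for PSA: {', '.join(missing)}")
    total_px = sum(masks[v].plant_pixel_count for v in VIEWS)
    return total_px * calibration_cm2_per_px


def plant_solidity(masks: dict[str, PlantMask], include_top: bool = False) -> float:
    """Per-plant solidity: mean over the two side views (optionally + TV).

    Views with an empty mask are excluded; if every included view is
    empty the result is undefined.
    """
    views = ("TV", "SV0", "SV90") if include_top else ("SV0", "SV90")
    vals = [
        solidity(masks[v])
        for v in views
        if v in masks and masks[v].plant_pixel_count > 0
    ]
    if not vals:
        raise UndefinedResult("solidity undefined: all included views are empty")
    return float(np.mean(vals))


@dataclass
class MorphometryResult:
    """PSA and solidity for one plant-day."""

    area_tv_px: int
    area_sv0_px: int
    area_sv90_px: int
    psa_cm2: float
    calibration_cm2_per_px: float
    solidity: float  # NaN when undefined (empty plant)
    hull_area_px: int  # pooled over the views entering solidity


def compute_morphometry(
    masks: dict[str, PlantMask],
    calibration_cm2_per_px: float,
    include_top_in_solidity: bool = False,
) -> MorphometryResult:
    psa = projected_shoot_area(masks, calibration_cm2_per_px)
    try:
        sol = plant_solidity(masks, include_top=include_top_in_solidity)
    except UndefinedResult:
        sol = float("nan")
    views = ("TV", "SV0", "SV90") if include_top_in_solidity else ("SV0", "SV90")
    hull_total = sum(
        hull_pixel_area(masks[v])
        for v in views
        if v in masks and masks[v].plant_pixel_count > 0
    )
    return MorphometryResult(
        area_tv_px=masks["TV"].plant_pixel_count,
        area_sv0_px=masks["SV0"].plant_pixel_count,
        area_sv90_px=masks["SV90"].plant_pixel_count,
        psa_cm2=psa,
        calibration_cm2_per_px=calibration_cm2_per_px,
        solidity=sol,
        hull_area_px=hull_total,
    )
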