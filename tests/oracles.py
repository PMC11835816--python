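"""Independent brute-force oracles used to validate the fast paths.

Deliberately naive: per-pixel Python loops with ``colorsys`` for colour
and shapely geometry for hulls, sharing no code with the package.
"""

import colorsys

import numpy as np
from shapely.geometry import MultiPoint, Point


def pixel_hues_deg(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Hue (degrees) of every masked pixel via colorsys, one at a time."""
    hues = []
    for r, c in np.argwhere(mask):
        rr, gg, bb = (float(v) / 255.0 for v in image[r, c])
        h, _, _ = colorsys.rgb_to_hsv(rr, gg, bb)
        hues.append(h * 360.0)
    return np.asarray(hues)


def classify_plant_pixels(image: np.ndarray) -> np.ndarray:
    """Plant = saturated pixel with hue outside the blue band.

    Rendered scenes contain only an achromatic background, a pure-blue
    stick and fully saturated leaf pixels, so this scan is exact.
    """
    h, w, _ = image.shape
    mask = np.zeros((h, w), dtype=bool)
    for r in range(h):
        for c in range(w):
            rr, gg, bb = (float(v) / 255.0 for v in image[r, c])
            hh, ss, vv = colorsys.rgb_to_hsv(rr, gg, bb)
            if ss > 0.5 and vv > 0.5 and not (200.0 <= hh * 360.0 <= 260.0):
                mask[r, c] = True
    return mask


def hull_pixel_area_bruteforce(mask: np.ndarray) -> int:
    """Count raster pixels whose centre lies in/on the convex hull of the
    plant pixel centres, via shapely point-in-polygon tests."""
    coords = np.argwhere(mask)
    hull = MultiPoint([tuple(p) for p in coords]).convex_hull
    rmin, cmin = coords.min(axis=0)
    rmax, cmax = coords.max(axis=0)
    count = 0
    for r in range(rmin, rmax + 1):
        for c in range(cmin, cmax + 1):
            if hull.covers(Point(r, c)):
                count += 1
    return count


def balanced_two_way_anova(values: np.ndarray) -> dict:
    """Classical two-way ANOVA with interaction on a balanced design.

    ``values`` has shape (a, b, n): factor A levels x factor B levels x
    replicates.  Textbook sums-of-squares formulas; returns F and p per
    term.
    """
    from scipy.stats import f as fdist

    a, b, n = values.shape
    grand = values.mean()
    mean_a = values.mean(axis=(1, 2))
    mean_b = values.mean(axis=(0, 2))
    mean_ab = values.mean(axis=2)
    ss_a = b * n * ((mean_a - grand) ** 2).sum()
    ss_b = a * n * ((mean_b - grand) ** 2).sum()
    ss_ab = n * ((mean_ab - mean_a[:, None] - mean_b[None, :] + grand) ** 2).sum()
    ss_err = ((values - mean_ab[..., None]) ** 2).sum()
    df_a, df_b, df_ab, df_err = a - 1, b - 1, (a - 1) * (b - 1), a * b * (n - 1)
    out = {}
    for name, ss, df in (("A", ss_a, df_a), ("B", ss_b, df_b), ("AB", ss_ab, df_ab)):
        F = (ss / df) / (ss_err / df_err)
        out[name] = (F, float(fdist.sf(F, df, df_err)))
    return out
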