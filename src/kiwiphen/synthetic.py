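"""Synthetic plant image sets and physiology tables with known ground truth.

The generator emulates the structure of a greenhouse waterlogging trial
on kiwifruit as seen by a conveyor phenotyping platform:

* per plant and day, three RGB views (top view TV, two orthogonal side
  views SV0/SV90) of a leafy silhouette on an achromatic mid-grey
  background, tied to a blue support stick, plus one side-view NIR
  raster;
* a long-format gas-exchange table (gs, E, A, Ci, Tleaf) with the
  cultivar x treatment (WW/WL) x day-after-waterlogging (DAW) design and
  effect sizes taken from the published group means.

Rendering choices that make ground truth exact:

* Leaves are filled discs; the union silhouette is the plant.  Each
  plant pixel is assigned an integer-degree hue - a ``chlorosis_fraction``
  of them uniformly from the yellowing band (62-78 deg), the rest from
  the green band (85-175 deg) - and painted at full saturation and
  value.  At S = V = 1 two RGB channels are exactly 0/255, so the uint8
  round trip perturbs hue by at most ~0.12 deg and every pixel lands
  back in its assigned one-degree bin.
* The stick is pure blue (220 deg), the background achromatic grey, so
  colour-rule segmentation can be pixel-perfect.
* NIR plant pixels take the single value
  ``round(I_max - water_content * (I_max - I_min))`` on the 8-bit scale
  (defaults I_min=100, I_max=220, bracketing the realistic 150-200
  range), making mean NIR intensity an exact, strictly decreasing
  function of water content.

Ground truth records what was *rendered* (post-clipping, post-overlap),
never what was requested.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.color import hsv2rgb
from skimage.draw import disk

from .colorimetry import N_BINS, GREEN_BAND, GREENER_BAND
from .errors import DesignError

CULTIVARS = ("B", "D", "H", "Z/B", "Z/D", "Z/H")
TREATMENTS = ("WW", "WL")
VIEWS = ("TV", "SV0", "SV90")
PHYSIO_VARIABLES = ("gs", "E", "A", "Ci", "Tleaf")

#: filesystem-safe cultivar codes used in plant ids and directory names
CULTIVAR_SLUGS = {"B": "B", "D": "D", "H": "H", "Z/B": "ZB", "Z/D": "ZD", "Z/H": "ZH"}
SLUG_CULTIVARS = {v: k for k, v in CULTIVAR_SLUGS.items()}

#: integer-degree hue pools for plant pixels (inside the 60-80 / 80-180 bands
#: with >=2 deg margin so quantisation can never cross a band boundary)
CHLOROTIC_HUES = (62, 78)
GREEN_HUES = (85, 175)
STICK_HUE = 220
BACKGROUND_GREY = 128
NIR_BACKGROUND = 10


def hues_to_rgb_u8(hues_deg: np.ndarray) -> np.ndarray:
    """Fully saturated, full-value RGB (uint8) for an array of hues."""
    h = np.asarray(hues_deg, dtype=float) / 360.0
    hsv = np.stack([h, np.ones_like(h), np.ones_like(h)], axis=-1)
    return np.rint(hsv2rgb(hsv) * 255.0).astype(np.uint8)


@dataclass(frozen=True)
class PlantSpec:
    """Everything needed to render one plant-day deterministically."""

    plant_id: str
    cultivar: str = "H"
    treatment: str = "WW"
    daw: int = 1
    leaf_count: int = 10
    leaf_radius_px: int = 40
    chlorosis_fraction: float = 0.0
    stick: bool = True
    water_content: float = 0.5
    seed: int = 0
    image_shape: tuple[int, int] = (600, 800)  # (height, width)
    nir_min: int = 100
    nir_max: int = 220
    stick_width_px: int = 12

    def __post_init__(self) -> None:
        if self.cultivar not in CULTIVARS:
            raise ValueError(f"unknown cultivar {self.cultivar!r}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.daw < 1:
            raise ValueError("daw must be >= 1")
        if self.leaf_count < 0 or self.leaf_radius_px <= 0:
            raise ValueError("need leaf_count >= 0 and leaf_radius_px > 0")
        if not 0.0 <= self.chlorosis_fraction <= 1.0:
            raise ValueError("chlorosis_fraction must be in [0, 1]")
        if not 0.0 <= self.water_content <= 1.0:
            raise ValueError("water_content must be in [0, 1]")
        if not 0 <= self.nir_min < self.nir_max <= 255:
            raise ValueError("need 0 <= nir_min < nir_max <= 255")


@dataclass
class GroundTruth:
    """Rendered-pixel truth for one plant-day (side-view colour pooling)."""

    true_plant_pixels_per_view: tuple[int, int, int]  # (TV, SV0, SV90)
    true_hue_histogram: np.ndarray  # 360 bins, pooled over SV0+SV90
    true_green_pixels: int
    true_greener_pixels: int
    true_si: float  # NaN when the green band is empty
    true_mean_nir: float  # NaN when the NIR view has no plant pixels

    def to_json(self) -> str:
        d = asdict(self)
        d["true_hue_histogram"] = self.true_hue_histogram.tolist()
        d["true_plant_pixels_per_view"] = list(self.true_plant_pixels_per_view)
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            true_plant_pixels_per_view=tuple(d["true_plant_pixels_per_view"]),
            true_hue_histogram=np.asarray(d["true_hue_histogram"], dtype=np.int64),
            true_green_pixels=d["true_green_pixels"],
            true_greener_pixels=d["true_greener_pixels"],
            true_si=d["true_si"],
            true_mean_nir=d["true_mean_nir"],
        )


@dataclass
class PlantImageSet:
    """The three RGB views plus the side-view NIR raster for one plant-day."""

    rgb: dict[str, np.ndarray]
    nir: np.ndarray
    nir_view: str = "SV0"
    spec: PlantSpec | None = field(default=None, repr=False)


def _render_view(rng: np.random.Generator, spec: PlantSpec, view: str):
    """Render one RGB view; returns (image, silhouette, assigned hues)."""
    h, w = spec.image_shape
    img = np.full((h, w, 3), BACKGROUND_GREY, dtype=np.uint8)
    if spec.stick:
        blue = hues_to_rgb_u8(np.array([STICK_HUE]))[0]
        if view == "TV":  # stick seen end-on: a small disc at centre
            rr, cc = disk((h // 2, w // 2), max(spec.stick_width_px, 2), shape=(h, w))
            img[rr, cc] = blue
        else:  # vertical stick spanning the image height
            c0 = w // 2 - spec.stick_width_px // 2
            img[:, c0 : c0 + spec.stick_width_px] = blue
    silhouette = np.zeros((h, w), dtype=bool)
    for _ in range(spec.leaf_count):
        radius = spec.leaf_radius_px * rng.uniform(0.7, 1.3)
        if view == "TV":
            centre = (
                rng.uniform(0.25 * h, 0.75 * h),
                rng.uniform(0.25 * w, 0.75 * w),
            )
        else:
            centre = (
                rng.uniform(0.15 * h, 0.85 * h),
                rng.uniform(0.30 * w, 0.70 * w),
            )
        rr, cc = disk(centre, radius, shape=(h, w))  # clipped at the border
        silhouette[rr, cc] = True
    coords = np.argwhere(silhouette)
    n = len(coords)
    hues = np.empty(n, dtype=np.int64)
    if n:
        n_chl = int(round(spec.chlorosis_fraction * n))
        order = rng.permutation(n)
        chl, grn = order[:n_chl], order[n_chl:]
        hues[chl] = rng.integers(CHLOROTIC_HUES[0], CHLOROTIC_HUES[1] + 1, len(chl))
        hues[grn] = rng.integers(GREEN_HUES[0], GREEN_HUES[1] + 1, len(grn))
        img[coords[:, 0], coords[:, 1]] = hues_to_rgb_u8(hues)
    return img, silhouette, hues


def generate_plant_images(spec: PlantSpec) -> tuple[PlantImageSet, GroundTruth]:
    """Render the three RGB views and the NIR raster for one plant-day.

    Deterministic for a fixed spec (including seed).  Ground truth counts
    rendered pixels per view and pools the side-view hue histogram, the
    green/greener areas and the senescence index exactly as the analysis
    side defines them.
    """
    rng = np.random.default_rng(spec.seed)
    rgb: dict[str, np.ndarray] = {}
    silhouettes: dict[str, np.ndarray] = {}
    hist = np.zeros(N_BINS, dtype=np.int64)
    for view in VIEWS:
        img, sil, hues = _render_view(rng, spec, view)
        rgb[view] = img
        silhouettes[view] = sil
        if view != "TV":
            hist += np.bincount(hues, minlength=N_BINS)
    green = int(hist[GREEN_BAND[0] : GREEN_BAND[1] + 1].sum())
    greener = int(hist[GREENER_BAND[0] : GREENER_BAND[1] + 1].sum())
    si = (green - greener) / green if green > 0 else float("nan")

    nir_sil = silhouettes["SV0"]
    h, w = spec.image_shape
    nir = np.full((h, w), NIR_BACKGROUND, dtype=np.uint8)
    intensity = int(round(spec.nir_max - spec.water_content * (spec.nir_max - spec.nir_min)))
    nir[nir_sil] = intensity
    mean_nir = float(intensity) if nir_sil.any() else float("nan")

    truth = GroundTruth(
        true_plant_pixels_per_view=tuple(int(silhouettes[v].sum()) for v in VIEWS),
        true_hue_histogram=hist,
        true_green_pixels=green,
        true_greener_pixels=greener,
        true_si=si,
        true_mean_nir=mean_nir,
    )
    return PlantImageSet(rgb=rgb, nir=nir, spec=spec), truth


# ---------------------------------------------------------------------------
# disk layout: <root>/<plant_id>/<daw>/{tv,sv0,sv90,nir}.png + ground_truth.json

_FILE_NAMES = {"TV": "tv.png", "SV0": "sv0.png", "SV90": "sv90.png"}


def write_image_set(directory: Path, images: PlantImageSet,
                    truth: GroundTruth | None = None) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for view, fname in _FILE_NAMES.items():
        iio.imwrite(directory / fname, images.rgb[view])
    if images.nir is not None:
        iio.imwrite(directory / "nir.png", images.nir)
    if truth is not None:
        (directory / "ground_truth.json").write_text(truth.to_json())


def read_image_set(directory: Path, require_nir: bool = False) -> PlantImageSet:
    directory = Path(directory)
    rgb = {}
    for view, fname in _FILE_NAMES.items():
        path = directory / fname
        if not path.exists():
            raise FileNotFoundError(f"missing {view} image: {path}")
        rgb[view] = iio.imread(path)
    nir_path = directory / "nir.png"
    nir = iio.imread(nir_path) if nir_path.exists() else None
    if require_nir and nir is None:
        raise FileNotFoundError(f"missing NIR image: {nir_path}")
    return PlantImageSet(rgb=rgb, nir=nir)


# ---------------------------------------------------------------------------
# experiment-level image simulation

#: how strongly each cultivar responds to waterlogging in the imaging
#: indices (0 = unaffected).  The tolerant B rootstock barely responds;
#: D and its graft respond most, mirroring the study's ranking.
WATERLOGGING_SUSCEPTIBILITY = {
    "B": 0.1, "D": 1.0, "H": 0.8, "Z/B": 0.3, "Z/D": 1.2, "Z/H": 0.9,
}

#: relative canopy size per cultivar (B is much smaller than D/H)
LEAF_RADIUS_FACTOR = {
    "B": 0.7, "D": 1.2, "H": 1.05, "Z/B": 0.95, "Z/D": 1.1, "Z/H": 1.15,
}

IMAGING_DAWS = (1, 2, 3, 4, 7, 9)
NIR_DAWS = (2, 3, 9)


def condition_for(cultivar: str, treatment: str, daw: int) -> dict:
    """Chlorosis fraction, water content and canopy size for one cell.

    Well-watered plants keep a small basal chlorosis (0.05), a water
    content of 0.75 and grow slowly (+2% leaf radius per day).
    Waterlogged plants yellow, dehydrate and lose canopy area linearly
    with DAW at a cultivar-specific susceptibility; at full
    susceptibility the canopy radius halves by DAW 9 (roughly a 70%
    projected-area loss, the magnitude seen in the most sensitive
    graft).  ``size_factor`` multiplies the leaf radius.
    """
    susc = WATERLOGGING_SUSCEPTIBILITY[cultivar]
    growth = 1.0 + 0.02 * daw
    if treatment == "WW":
        return {"chlorosis_fraction": 0.05, "water_content": 0.75,
                "size_factor": growth}
    return {
        "chlorosis_fraction": min(0.05 + 0.04 * susc * daw, 0.85),
        "water_content": max(0.75 - 0.05 * susc * daw, 0.10),
        "size_factor": growth * max(1.0 - 0.055 * susc * daw, 0.30),
    }


def plant_id_for(cultivar: str, treatment: str, index: int) -> str:
    return f"{CULTIVAR_SLUGS[cultivar]}-{treatment}-{index:02d}"


def parse_plant_id(plant_id: str) -> tuple[str, str, int]:
    """Decode ``<cultivar-slug>-<treatment>-<index>``; hard error if malformed."""
    parts = plant_id.split("-")
    if (
        len(parts) != 3
        or parts[0] not in SLUG_CULTIVARS
        or parts[1] not in TREATMENTS
        or not parts[2].isdigit()
    ):
        raise DesignError(f"malformed plant id {plant_id!r}")
    return SLUG_CULTIVARS[parts[0]], parts[1], int(parts[2])


def simulate_experiment_images(
    root: Path,
    cultivars: tuple[str, ...] = CULTIVARS,
    n_plants: int = 5,
    daws: tuple[int, ...] = IMAGING_DAWS,
    nir_daws: tuple[int, ...] = NIR_DAWS,
    image_shape: tuple[int, int] = (600, 800),
    leaf_count: int = 10,
    seed: int = 0,
) -> int:
    """Write a full synthetic imaging experiment to ``root``.

    Layout: ``<root>/<plant_id>/<daw>/{tv,sv0,sv90[,nir]}.png`` with a
    ground-truth JSON sidecar per plant-day.  NIR rasters are written
    only on ``nir_daws``, matching an acquisition schedule where the NIR
    chamber ran on a subset of days.  Returns the number of plant-days
    written.  Deterministic per (seed, design).
    """
    root = Path(root)
    base_radius = max(image_shape[1] // 16, 4)
    written = 0
    for ci, cultivar in enumerate(cultivars):
        for ti, treatment in enumerate(TREATMENTS):
            for idx in range(1, n_plants + 1):
                pid = plant_id_for(cultivar, treatment, idx)
                for daw in daws:
                    cond = condition_for(cultivar, treatment, daw)
                    size = cond.pop("size_factor")
                    radius = max(
                        int(round(base_radius * LEAF_RADIUS_FACTOR[cultivar] * size)),
                        3,
                    )
                    spec = PlantSpec(
                        plant_id=pid,
                        cultivar=cultivar,
                        treatment=treatment,
                        daw=daw,
                        leaf_count=leaf_count,
                        leaf_radius_px=radius,
                        seed=(seed * 1_000_003 + ci * 10_000 + ti * 1_000
                              + idx * 10 + daw) % 2**31,
                        image_shape=image_shape,
                        **cond,
                    )
                    images, truth = generate_plant_images(spec)
                    if daw not in nir_daws:
                        images.nir = None
                    write_image_set(root / pid / str(daw), images, truth)
                    written += 1
    return written


# ---------------------------------------------------------------------------
# physiology tables

@dataclass
class PhysioEffectModel:
    """Generative model for the gas-exchange table.

    ``baselines`` maps ``(variable, cultivar, daw)`` (or, as a fallback,
    ``(variable, cultivar)``) to the well-watered group mean;
    ``treatment_effect`` maps ``(variable, cultivar, daw)`` to the
    multiplicative waterlogging effect (WL mean = baseline x effect).
    ``noise_sd`` is the per-variable residual standard deviation among
    replicate vines.  A missing effect entry for a requested cell is a
    hard error - the design must be explicit.
    """

    baselines: dict
    treatment_effect: dict
    noise_sd: dict
    cultivars: tuple[str, ...]
    n_replicates: int = 4
    seed: int = 0
    default_hour: str = "11:00"

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("need n_replicates >= 2 for variance estimation")
        for key, value in self.baselines.items():
            if key[0] in ("gs", "E", "A") and value <= 0:
                raise ValueError(f"baseline for {key} must be positive")

    def baseline(self, variable: str, cultivar: str, daw: int) -> float:
        try:
            return self.baselines[(variable, cultivar, daw)]
        except KeyError:
            try:
                return self.baselines[(variable, cultivar)]
            except KeyError:
                raise DesignError(
                    f"no baseline for {variable}/{cultivar} (DAW {daw})"
                ) from None

    def effect(self, variable: str, cultivar: str, daw: int) -> float:
        try:
            return self.treatment_effect[(variable, cultivar, daw)]
        except KeyError:
            raise DesignError(
                f"no treatment effect for {variable}/{cultivar}/DAW {daw}"
            ) from None


def generate_physio_dataset(
    model: PhysioEffectModel,
    daws: list[int],
    hours: list[str] | None = None,
    hour_factors: dict[str, float] | None = None,
):
    """Balanced long gas-exchange table: one row per replicate x cultivar
    x treatment x DAW x hour.

    WL cell means are ``baseline x treatment_effect``; replicate noise is
    additive Gaussian per variable.  ``hour_factors`` optionally scales
    the flux variables (gs, E, A) per hour to shape a diurnal course.
    Bit-identical output for a fixed model seed.
    """
    import pandas as pd

    hours = hours or [model.default_hour]
    rng = np.random.default_rng(model.seed)
    rows = []
    for daw in daws:
        for cultivar in model.cultivars:
            for treatment in TREATMENTS:
                for rep in range(1, model.n_replicates + 1):
                    pid = plant_id_for(cultivar, treatment, rep)
                    for hour in hours:
                        hf = (hour_factors or {}).get(hour, 1.0)
                        row = {
                            "plant_id": pid,
                            "cultivar": cultivar,
                            "treatment": treatment,
                            "daw": daw,
                            "hour": hour,
                        }
                        for variable in PHYSIO_VARIABLES:
                            mu = model.baseline(variable, cultivar, daw)
                            if treatment == "WL":
                                mu = mu * model.effect(variable, cultivar, daw)
                            if variable in ("gs", "E", "A"):
                                mu = mu * hf
                            sd = model.noise_sd.get(variable, 0.0)
                            noise = rng.normal(0.0, sd) if sd > 0 else 0.0
                            value = mu + noise
                            # conductance and transpiration are physically
                            # positive; truncate rare negative noise draws
                            if variable == "gs":
                                value = max(value, 1e-3)
                            elif variable == "E":
                                value = max(value, 1e-2)
                            row[variable] = value
                        rows.append(row)
    return pd.DataFrame(rows)


def default_effect_model(which: str = "rootstock", seed: int = 0,
                         n_replicates: int = 4) -> PhysioEffectModel:
    """Effect model matching the published group means.

    Baselines are the printed well-watered cell means per DAW (gs backed
    out as A/WUEi); waterlogging effects are the printed WL/WW ratios;
    replicate noise is the median printed SE x sqrt(n) per variable.
    Transpiration E, not tabulated, gets cultivar-level baselines in the
    reported 2.3-4.6 mmol m-2 s-1 range and follows the gs effect, since
    E tracks stomatal closure.
    """
    from .reference_data import load_reference_means, reconstruct_gs

    means = load_reference_means(which)
    gs_tbl = reconstruct_gs(means)
    cultivars = tuple(sorted(means.cultivar.unique()))

    baselines: dict = {}
    effects: dict = {}
    for cultivar in cultivars:
        for daw in sorted(means.daw.unique()):
            for variable in ("A", "Ci", "Tleaf"):
                ww = means.query(
                    "cultivar == @cultivar and daw == @daw and treatment == 'WW' "
                    "and variable == @variable"
                )["mean"].item()
                wl = means.query(
                    "cultivar == @cultivar and daw == @daw and treatment == 'WL' "
                    "and variable == @variable"
                )["mean"].item()
                baselines[(variable, cultivar, daw)] = ww
                effects[(variable, cultivar, daw)] = wl / ww
            gs_ww = gs_tbl.query(
                "cultivar == @cultivar and daw == @daw and treatment == 'WW'"
            )["gs"].item()
            gs_wl = gs_tbl.query(
                "cultivar == @cultivar and daw == @daw and treatment == 'WL'"
            )["gs"].item()
            baselines[("gs", cultivar, daw)] = gs_ww
            effects[("gs", cultivar, daw)] = gs_wl / gs_ww
            effects[("E", cultivar, daw)] = gs_wl / gs_ww

    e_baseline = {"B": 4.0, "D": 2.8, "H": 3.0, "Z/B": 4.2, "Z/D": 3.2, "Z/H": 3.4}
    for cultivar in cultivars:
        baselines[("E", cultivar)] = e_baseline[cultivar]

    def _median_sd(variable: str) -> float:
        sub = means[means.variable == variable]
        return float(np.median(sub.se * np.sqrt(sub.n)))

    gs_med = float(np.median(gs_tbl.gs))
    noise_sd = {
        "A": _median_sd("A"),
        "Ci": _median_sd("Ci"),
        "Tleaf": _median_sd("Tleaf"),
        "gs": 0.15 * gs_med,
        "E": 0.4,
    }
    return PhysioEffectModel(
        baselines=baselines,
        treatment_effect=effects,
        noise_sd=noise_sd,
        cultivars=cultivars,
        n_replicates=n_replicates,
        seed=seed,
        default_hour="11:00" if which == "rootstock" else "10:00",
    )
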