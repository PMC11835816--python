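"""Batch orchestration: config, dataset walking, index extraction, reports.

The imaging dataset is laid out on disk as

    <image_root>/<plant_id>/<daw>/{tv,sv0,sv90[,nir]}.png

where ``plant_id`` encodes cultivar and treatment
(``<cultivar-slug>-<WW|WL>-<index>``, e.g. ``ZD-WL-03``).  The pipeline
segments each view, computes the morphometric (PSA, solidity),
colorimetric (HUE, GAS, GerAS, SI) and NIR indices per plant-day, and
assembles per-DAW ANOVA/Tukey summary tables.  Plant-days with a
missing RGB view are skipped with a log entry; a missing NIR raster is
allowed (the NIR chamber runs on a subset of days) and flagged.

Everything is deterministic for a fixed config and input tree; results
are written as CSV with a stable row order and float format, so reruns
are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .colorimetry import color_result
from .errors import DesignError, UndefinedResult
from .morphometry import compute_morphometry
from .nir import nir_intensity
from .physiology import summarize_groups
from .segmentation import SegmentationParams, segment_views
from .stats import ALPHA, anova_pvalue_table, one_way_anova, tukey_hsd
from .synthetic import parse_plant_id, read_image_set

log = logging.getLogger(__name__)

IMAGE_COLUMNS = [
    "plant_id", "cultivar", "treatment", "daw",
    "area_tv_px", "area_sv0_px", "area_sv90_px", "psa_cm2", "solidity",
    "hue_weighted_mean_deg", "green_area_px", "greener_area_px", "si",
    "nir_mean_intensity", "qc_flags",
]


@dataclass
class ExperimentConfig:
    """Run configuration; calibration has no default and must be given."""

    image_root: Path
    calibration_cm2_per_px: float
    output_dir: Path = Path("results")
    physio_table: Path | None = None
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    green_band: tuple[int, int] = (60, 180)
    greener_band: tuple[int, int] = (80, 180)
    nir_bounds: tuple[int, int] = (0, 255)
    alpha: float = ALPHA
    seed: int = 0
    include_top_in_solidity: bool = False

    def __post_init__(self) -> None:
        self.image_root = Path(self.image_root)
        self.output_dir = Path(self.output_dir)
        if self.calibration_cm2_per_px <= 0:
            raise ValueError("calibration_cm2_per_px must be positive")
        lo, hi = self.green_band
        glo, ghi = self.greener_band
        if not (lo < glo <= ghi <= hi):
            raise ValueError("need green lower < greener lower and nested bands")

    @classmethod
    def from_yaml(cls, path: Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        seg = SegmentationParams(**raw.pop("segmentation", {}))
        for key in ("green_band", "greener_band", "nir_bounds"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(segmentation=seg, **raw)

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload = json.dumps(payload, default=str, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ResultsBundle:
    records: pd.DataFrame  # one row per processed plant-day
    processed: int
    skipped: list[str]
    config: ExperimentConfig


def _discover(image_root: Path):
    """Yield (plant_id, daw, directory) sorted for determinism."""
    for plant_dir in sorted(p for p in image_root.iterdir() if p.is_dir()):
        for daw_dir in sorted(
            (d for d in plant_dir.iterdir() if d.is_dir() and d.name.isdigit()),
            key=lambda d: int(d.name),
        ):
            yield plant_dir.name, int(daw_dir.name), daw_dir


def analyze_plant_day(directory: Path, config: ExperimentConfig) -> dict:
    """All image indices for one plant-day directory."""
    images = read_image_set(directory)  # FileNotFoundError on a missing view
    masks = segment_views(images.rgb, config.segmentation)
    qc = []
    morpho = compute_morphometry(
        masks, config.calibration_cm2_per_px,
        include_top_in_solidity=config.include_top_in_solidity,
    )
    if all(m.plant_pixel_count == 0 for m in masks.values()):
        qc.append("empty_mask")
    try:
        color = color_result(images.rgb, masks, config.green_band, config.greener_band)
        hue, gas, geras, si = (color.hue_weighted_mean_deg, color.green_area_px,
                               color.greener_area_px, color.si)
        if np.isnan(si):
            qc.append("undefined_si")
    except UndefinedResult:
        hue, gas, geras, si = np.nan, 0, 0, np.nan
        qc.append("undefined_si")
    if images.nir is None:
        nir_mean = np.nan
        qc.append("missing_nir")
    else:
        try:
            nir_mean = nir_intensity(images.nir, masks["SV0"]).mean_intensity
        except UndefinedResult:
            nir_mean = np.nan
            qc.append("undefined_nir")
    return {
        "area_tv_px": morpho.area_tv_px,
        "area_sv0_px": morpho.area_sv0_px,
        "area_sv90_px": morpho.area_sv90_px,
        "psa_cm2": morpho.psa_cm2,
        "solidity": morpho.solidity,
        "hue_weighted_mean_deg": hue,
        "green_area_px": gas,
        "greener_area_px": geras,
        "si": si,
        "nir_mean_intensity": nir_mean,
        "qc_flags": ";".join(qc),
    }


def run_pipeline(config: ExperimentConfig) -> ResultsBundle:
    """Process every discovered plant-day under the image root.

    Raises :class:`DesignError` on a malformed plant id; a plant-day
    with a missing view is skipped and logged, never silently dropped.
    Every discovered plant-day is either processed or listed in
    ``skipped``.
    """
    if not config.image_root.is_dir():
        raise FileNotFoundError(f"image root {config.image_root} does not exist")
    rows, skipped = [], []
    for plant_id, daw, directory in _discover(config.image_root):
        cultivar, treatment, _ = parse_plant_id(plant_id)  # DesignError if malformed
        try:
            indices = analyze_plant_day(directory, config)
        except FileNotFoundError as exc:
            log.warning("skipping %s DAW %d: %s", plant_id, daw, exc)
            skipped.append(f"{plant_id}/{daw}")
            continue
        rows.append(
            {"plant_id": plant_id, "cultivar": cultivar,
             "treatment": treatment, "daw": daw} | indices
        )
    records = pd.DataFrame(rows, columns=IMAGE_COLUMNS)
    return ResultsBundle(records=records, processed=len(rows),
                         skipped=skipped, config=config)


def write_bundle(bundle: ResultsBundle) -> Path:
    """Write the per-plant-day CSV and a run log; returns the CSV path."""
    out = bundle.config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / "plant_day_indices.csv"
    bundle.records.to_csv(csv_path, index=False, float_format="%.6f")
    run_log = {
        "package_version": __version__,
        "config_hash": bundle.config.config_hash(),
        "seed": bundle.config.seed,
        "processed": bundle.processed,
        "skipped": bundle.skipped,
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2, sort_keys=True))
    return csv_path


IMAGE_VARIABLES = ["psa_cm2", "solidity", "hue_weighted_mean_deg", "si",
                   "nir_mean_intensity"]


def make_report(records: pd.DataFrame,
                variables: list[str] | None = None,
                alpha: float = ALPHA) -> dict[str, pd.DataFrame]:
    """Summary tables: group means +/- SE with Tukey letters, and the
    per-DAW two-way ANOVA p-value table.

    ``records`` is any long table with cultivar/treatment/daw columns
    plus the requested variables (image indices or physiology).  For
    each variable and DAW, lowercase letters group the cultivar and the
    treatment main effects and uppercase letters the treatment x
    cultivar cells, provided the design supports the comparison.
    Variables with no data on a DAW (e.g. NIR on non-NIR days) simply do
    not appear for that DAW.
    """
    variables = variables or IMAGE_VARIABLES
    summary_rows = []
    anova_rows = []
    for variable in variables:
        for daw in sorted(records.daw.unique()):
            day = records[records.daw == daw].dropna(subset=[variable])
            if day.empty:
                continue
            summary = summarize_groups(day, [variable])
            letters_cell: dict[str, str] = {}
            letters_cult: dict[str, str] = {}
            letters_trt: dict[str, str] = {}
            try:
                day = day.assign(cell=day.treatment + ":" + day.cultivar)
                letters_cell = tukey_hsd(day, variable, "cell",
                                         alpha=alpha, uppercase=True).letters
                letters_cult = tukey_hsd(day, variable, "cultivar",
                                         alpha=alpha).letters
                letters_trt = tukey_hsd(day, variable, "treatment",
                                        alpha=alpha).letters
            except DesignError as exc:
                log.info("no Tukey letters for %s DAW %s: %s", variable, daw, exc)
            for _, row in summary.iterrows():
                cell = f"{row.treatment}:{row.cultivar}"
                summary_rows.append({
                    "variable": variable, "daw": daw,
                    "cultivar": row.cultivar, "treatment": row.treatment,
                    "mean": row["mean"], "se": row.se, "n": row.n,
                    "letters_interaction": letters_cell.get(cell, ""),
                    "letters_cultivar": letters_cult.get(row.cultivar, ""),
                    "letters_treatment": letters_trt.get(row.treatment, ""),
                })
            try:
                anova_rows.append(
                    anova_pvalue_table(day, [variable], daws=[daw]).iloc[0].to_dict()
                )
            except DesignError as exc:
                log.info("no two-way ANOVA for %s DAW %s: %s", variable, daw, exc)
    report = {
        "group_summary": pd.DataFrame(summary_rows),
        "anova_pvalues": pd.DataFrame(anova_rows),
    }
    return report


def one_way_table(records: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """WW-vs-WL one-way ANOVA p per cultivar x DAW x variable."""
    rows = []
    for variable in variables:
        for daw in sorted(records.daw.unique()):
            day = records[records.daw == daw].dropna(subset=[variable])
            for cultivar in sorted(day.cultivar.unique()):
                try:
                    p = one_way_anova(day, variable, cultivar=cultivar)
                except DesignError:
                    continue
                rows.append({"variable": variable, "daw": daw,
                             "cultivar": cultivar, "p_treatment": p})
    return pd.DataFrame(rows)
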