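"""The generator's ground truth must describe what was actually rendered."""

import numpy as np
import pandas as pd
import pytest

from kiwiphen.errors import DesignError
from kiwiphen.physiology import percent_change, round_percent
from kiwiphen.synthetic import (
    PhysioEffectModel,
    PlantSpec,
    generate_physio_dataset,
    generate_plant_images,
    parse_plant_id,
    plant_id_for,
)
from oracles import classify_plant_pixels, pixel_hues_deg


def test_rendering_is_deterministic_for_fixed_seed():
    spec = PlantSpec(plant_id="B-WW-01", cultivar="B", seed=42,
                     leaf_count=4, leaf_radius_px=18, image_shape=(120, 150))
    a, ta = generate_plant_images(spec)
    b, tb = generate_plant_images(spec)
    for view in a.rgb:
        assert np.array_equal(a.rgb[view], b.rgb[view])
    assert np.array_equal(a.nir, b.nir)
    assert ta.true_plant_pixels_per_view == tb.true_plant_pixels_per_view
    assert np.array_equal(ta.true_hue_histogram, tb.true_hue_histogram)


def test_empty_plant_has_no_pixels_anywhere():
    spec = PlantSpec(plant_id="B-WW-01", cultivar="B", leaf_count=0,
                     leaf_radius_px=10, image_shape=(80, 100))
    _, truth = generate_plant_images(spec)
    assert truth.true_plant_pixels_per_view == (0, 0, 0)
    assert truth.true_hue_histogram.sum() == 0
    assert np.isnan(truth.true_si)


def test_zero_chlorosis_gives_zero_senescence_index():
    spec = PlantSpec(plant_id="H-WW-01", cultivar="H", chlorosis_fraction=0.0,
                     leaf_count=5, leaf_radius_px=20, image_shape=(120, 150))
    _, truth = generate_plant_images(spec)
    assert truth.true_green_pixels > 0
    assert truth.true_si == 0.0


def test_half_chlorotic_si_verified_by_per_pixel_scan(half_chlorotic):
    """chlorosis_fraction=0.5 over >10k pixels: SI within 0.02 of 0.5,
    recomputed by classifying every rendered side-view pixel's hue."""
    _, images, truth, _ = half_chlorotic
    assert sum(truth.true_plant_pixels_per_view[1:]) > 10_000
    yellow = green = 0
    for view in ("SV0", "SV90"):
        mask = classify_plant_pixels(images.rgb[view])
        hues = pixel_hues_deg(images.rgb[view], mask)
        yellow += int(((hues >= 60) & (hues < 80)).sum())
        green += int(((hues >= 60) & (hues <= 180)).sum())
    si_oracle = yellow / green
    assert abs(truth.true_si - 0.5) <= 0.02
    assert truth.true_si == pytest.approx(si_oracle, abs=1e-9)


def test_ground_truth_matches_exhaustive_recount(half_chlorotic):
    """Pixel counts and the pooled hue histogram equal a brute-force
    per-pixel recount of the rendered rasters."""
    _, images, truth, _ = half_chlorotic
    counts = []
    hist = np.zeros(360, dtype=int)
    for view in ("TV", "SV0", "SV90"):
        mask = classify_plant_pixels(images.rgb[view])
        counts.append(int(mask.sum()))
        if view != "TV":
            hues = pixel_hues_deg(images.rgb[view], mask)
            hist += np.bincount(np.rint(hues).astype(int) % 360, minlength=360)
    assert tuple(counts) == truth.true_plant_pixels_per_view
    assert np.array_equal(hist, truth.true_hue_histogram)
    assert truth.true_greener_pixels <= truth.true_green_pixels


def test_si_monotone_in_chlorosis_fraction(chlorosis_ladder):
    sis = [truth.true_si for _, _, truth in chlorosis_ladder]
    assert all(b >= a for a, b in zip(sis, sis[1:]))
    assert sis[0] == 0.0 and sis[-1] == 1.0


def test_mean_nir_strictly_decreasing_in_water_content():
    values = []
    for w in (0.0, 0.25, 0.5, 0.75, 1.0):
        spec = PlantSpec(plant_id="D-WW-01", cultivar="D", water_content=w,
                         leaf_count=4, leaf_radius_px=16, seed=3,
                         image_shape=(100, 120))
        _, truth = generate_plant_images(spec)
        values.append(truth.true_mean_nir)
    assert all(b < a for a, b in zip(values, values[1:]))


def test_plant_id_roundtrip_and_malformed_error():
    assert parse_plant_id(plant_id_for("Z/D", "WL", 3)) == ("Z/D", "WL", 3)
    for bad in ("ZD_WL_03", "QQ-WL-03", "ZD-XX-03", "ZD-WL-three"):
        with pytest.raises(DesignError):
            parse_plant_id(bad)


# ---------------------------------------------------------------------------
# physiology generator


def _tiny_model(effect=1.0, noise=0.0, seed=0):
    cultivars = ("B", "D")
    baselines = {}
    for c in cultivars:
        baselines.update({("gs", c): 0.1, ("E", c): 3.0, ("A", c): 10.0,
                          ("Ci", c): 260.0, ("Tleaf", c): 32.5})
    effects = {(v, c, d): effect for v in ("gs", "E", "A", "Ci", "Tleaf")
               for c in cultivars for d in (1, 2)}
    noise_sd = {v: noise for v in ("gs", "E", "A", "Ci", "Tleaf")}
    return PhysioEffectModel(baselines=baselines, treatment_effect=effects,
                             noise_sd=noise_sd, cultivars=cultivars,
                             n_replicates=4, seed=seed)


def test_null_model_gives_identical_group_means():
    df = generate_physio_dataset(_tiny_model(effect=1.0, noise=0.0), daws=[1, 2])
    means = df.groupby("treatment")[["gs", "A", "Ci"]].mean()
    pd.testing.assert_frame_equal(means.loc[["WW"]].reset_index(drop=True),
                                  means.loc[["WL"]].reset_index(drop=True))
    # and WW means equal the configured baselines exactly
    assert df.query("treatment == 'WW'")["A"].unique().tolist() == [10.0]


def test_published_effect_cell_recovers_63_percent_reduction():
    model = _tiny_model(noise=0.0)
    model.baselines[("A", "D")] = 8.58
    model.treatment_effect[("A", "D", 1)] = 3.16 / 8.58
    df = generate_physio_dataset(model, daws=[1])
    ww = df.query("cultivar == 'D' and treatment == 'WW'")["A"].mean()
    wl = df.query("cultivar == 'D' and treatment == 'WL'")["A"].mean()
    assert round_percent(percent_change(ww, wl)) == 63


def test_table_generation_is_bit_identical_under_fixed_seed():
    a = generate_physio_dataset(_tiny_model(noise=0.5, seed=9), daws=[1, 2])
    b = generate_physio_dataset(_tiny_model(noise=0.5, seed=9), daws=[1, 2])
    pd.testing.assert_frame_equal(a, b)


def test_missing_effect_entry_is_a_hard_error():
    model = _tiny_model()
    del model.treatment_effect[("Ci", "D", 2)]
    with pytest.raises(DesignError, match="Ci/D/DAW 2"):
        generate_physio_dataset(model, daws=[1, 2])


def test_balanced_table_shape():
    df = generate_physio_dataset(_tiny_model(), daws=[1, 2])
    # 2 daws x 2 cultivars x 2 treatments x 4 replicates
    assert len(df) == 32
    assert df.groupby(["daw", "cultivar", "treatment"]).size().eq(4).all()
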