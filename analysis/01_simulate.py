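#!/usr/bin/env python
"""Generate the synthetic experiment: image sets and gas-exchange tables.

Emulates the trial design - 6 cultivars (3 rootstocks B/D/H, 3 graft
combinations Z/B, Z/D, Z/H) x 2 irrigation treatments (WW/WL), imaged at
DAW 1, 2, 3, 4, 7 and 9 with NIR on DAW 2, 3 and 9 - with waterlogged
susceptible cultivars progressively yellowing and drying.  Images (binary
PNG) go under scratch/; tables (text) under results/.
"""

from pathlib import Path

import pandas as pd

from kiwiphen.physiology import PHYSIO_COLUMNS
from kiwiphen.synthetic import (
    default_effect_model,
    generate_physio_dataset,
    simulate_experiment_images,
)

REPO = Path(__file__).resolve().parents[1]
IMAGE_ROOT = REPO / "scratch" / "synthetic_images"
RESULTS = REPO / "results"
SEED = 20230710  # the trial started on 10 July 2023

N_PLANTS = 3          # imaged vines per cultivar x treatment
IMAGE_SHAPE = (150, 200)  # kept small; indices are resolution-free ratios/sums


def main() -> None:
    n = simulate_experiment_images(IMAGE_ROOT, n_plants=N_PLANTS, seed=SEED,
                                   image_shape=IMAGE_SHAPE, leaf_count=8)
    print(f"rendered {n} plant-days (6 cultivars x 2 treatments x "
          f"{N_PLANTS} plants x 6 DAWs) under {IMAGE_ROOT}")

    frames = []
    for which in ("rootstock", "graft"):
        model = default_effect_model(which, seed=SEED)
        frames.append(generate_physio_dataset(model, daws=[1, 2, 3, 4]))
    table = pd.concat(frames, ignore_index=True)[PHYSIO_COLUMNS]
    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "synthetic_gas_exchange.csv"
    table.to_csv(out, index=False, float_format="%.6f")
    print(f"wrote {len(table)} gas-exchange records "
          f"(baselines and effects from the published group means) to {out}")


if __name__ == "__main__":
    main()
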