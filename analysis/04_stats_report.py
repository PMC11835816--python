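#!/usr/bin/env python
"""Per-DAW factorial statistics and the mean +/- SE report tables.

Runs the two-way (treatment x cultivar) and one-way (WW vs WL within
cultivar) ANOVAs per DAW on the image indices and the gas-exchange
records, and assembles group-summary tables with Tukey HSD compact
letter displays (lowercase = main effects, uppercase = interaction).
"""

from pathlib import Path

import pandas as pd

from kiwiphen.pipeline import IMAGE_VARIABLES, make_report, one_way_table

REPO = Path(__file__).resolve().parents[1]
RESULTS = REPO / "results"

PHYSIO_VARIABLES = ["gs", "E", "A", "Ci", "Tleaf", "WUEi"]


def _analyse(name: str, records: pd.DataFrame, variables: list[str]) -> None:
    report = make_report(records, variables=variables)
    for table_name, frame in report.items():
        out = RESULTS / f"{name}_{table_name}.csv"
        frame.to_csv(out, index=False, float_format="%.6g")
    ow = one_way_table(records, variables)
    ow.to_csv(RESULTS / f"{name}_anova_one_way.csv", index=False,
              float_format="%.6g")
    pv = report["anova_pvalues"]
    sig = pv[(pv.p_T < 0.05)]
    print(f"{name}: {len(pv)} variable x DAW two-way ANOVAs, "
          f"{len(sig)} with a significant treatment effect at alpha=0.05")


def main() -> None:
    images = pd.read_csv(RESULTS / "plant_day_indices.csv")
    _analyse("image", images, IMAGE_VARIABLES)

    physio = pd.read_csv(RESULTS / "gas_exchange_records.csv")
    # rootstocks and graft combinations are separate experiments
    for which, cultivars in (("rootstock", ("B", "D", "H")),
                             ("graft", ("Z/B", "Z/D", "Z/H"))):
        sub = physio[physio.cultivar.isin(cultivars)]
        _analyse(f"physio_{which}", sub, PHYSIO_VARIABLES)

    daw4 = physio[(physio.cultivar.isin(("B", "D", "H"))) & (physio.daw == 4)]
    from kiwiphen.stats import two_way_anova

    res = two_way_anova(daw4, "A", daw=4)
    print(f"rootstock A at DAW 4: p_T={res.p_treatment:.4g}, "
          f"p_C={res.p_cultivar:.4g}, p_TxC={res.p_interaction:.4g}")


if __name__ == "__main__":
    main()
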