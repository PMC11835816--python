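"""Published gas-exchange group means bundled with the package.

The underlying waterlogging study reports leaf gas-exchange responses of
kiwifruit as group means with standard errors (n = 4 vines) for each
cultivar x irrigation treatment x day-after-waterlogging (DAW) cell:

* ``rootstock`` - the self-rooted rootstocks B ('Bounty 71',
  *A. macrosperma*), D ('D1') and H ('Hayward') (both *A. chinensis*
  var. *deliciosa*), measured at 11:00 h;
* ``graft`` - the scion-rootstock combinations Z/B, Z/D, Z/H ('Zesy 002'
  grafted on each rootstock), measured at 10:00 h.

Variables: net photosynthesis ``A`` (umol m-2 s-1), intrinsic water-use
efficiency ``WUEi`` = A/gs (umol CO2 mol-1 H2O), intercellular CO2
``Ci`` (umol mol-1) and leaf temperature ``Tleaf`` (degC), at DAW 1-4.

These printed summaries serve two roles: validation inputs (percent
changes and WUEi round-trips recompute directly from them) and the
effect-size source for the synthetic physiology generator.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

ROOTSTOCK_CULTIVARS = ("B", "D", "H")
GRAFT_CULTIVARS = ("Z/B", "Z/D", "Z/H")
VARIABLES = ("A", "WUEi", "Ci", "Tleaf")

_FILES = {
    "rootstock": "rootstock_gas_exchange_means.csv",
    "graft": "graft_gas_exchange_means.csv",
}


def load_reference_means(which: str = "rootstock") -> pd.DataFrame:
    """Load one bundled means table (``rootstock`` or ``graft``).

    Columns: cultivar, treatment (WW/WL), daw, variable, mean, se, n.
    """
    if which not in _FILES:
        raise ValueError(f"which must be one of {sorted(_FILES)}, got {which!r}")
    with resources.files("kiwiphen.data").joinpath(_FILES[which]).open() as fh:
        return pd.read_csv(fh)


def reference_cell(df: pd.DataFrame, cultivar: str, treatment: str, daw: int,
                   variable: str) -> pd.Series:
    """One (cultivar, treatment, daw, variable) row of a means table."""
    sel = df[
        (df.cultivar == cultivar)
        & (df.treatment == treatment)
        & (df.daw == daw)
        & (df.variable == variable)
    ]
    if len(sel) != 1:
        raise KeyError(
            f"expected one row for {cultivar}/{treatment}/DAW{daw}/{variable}, "
            f"found {len(sel)}"
        )
    return sel.iloc[0]


def reconstruct_gs(df: pd.DataFrame) -> pd.DataFrame:
    """Back out stomatal conductance gs = A / WUEi for each group cell.

    WUEi is defined as A/gs, so the printed A and WUEi means pin down the
    implied gs (mol m-2 s-1) of each cell exactly.
    """
    wide = df.pivot_table(
        index=["cultivar", "treatment", "daw"], columns="variable", values="mean"
    )
    out = wide.reset_index()[["cultivar", "treatment", "daw"]].copy()
    out["gs"] = (wide["A"] / wide["WUEi"]).to_numpy()
    return out


def synthesize_replicates(mean: float, se: float, n: int) -> np.ndarray:
    """Deterministic replicate values with exactly the given mean and SE.

    A fixed symmetric score pattern is scaled so that the sample mean is
    ``mean`` and the sample standard error (ddof=1) is ``se``.  Used to
    rebuild per-vine observations from printed group summaries, e.g. to
    re-run ANOVA on a published cell.
    """
    if n < 2:
        raise ValueError("need n >= 2 replicates to encode a standard error")
    base = np.linspace(-1.0, 1.0, n)
    base = base / base.std(ddof=1)
    return mean + base * (se * np.sqrt(n))
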