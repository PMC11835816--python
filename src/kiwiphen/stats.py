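"""Factorial comparison layer: ANOVA, Tukey HSD and letter displays.

The experimental questions are answered day by day: at each DAW a
two-way ANOVA (irrigation treatment x cultivar, always including the
interaction) tests the main and interaction effects on each variable,
one-way ANOVAs compare WW vs WL within each cultivar, and Tukey's HSD
groups the means.  Letter displays follow the agronomy convention:
lowercase letters for main-effect groups, uppercase for interaction
cells; groups sharing no letter differ at the chosen alpha.

Normality (Shapiro-Wilk) and variance homogeneity (Levene) checks are
advisory: they are reported but do not gate the ANOVA, and each DAW is
tested independently with no multiplicity correction across days or
variables (a deliberate, documented caveat).

Sums of squares are Type II, which coincides with classical ANOVA on
the balanced designs generated here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.formula.api import ols
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import DesignError

log = logging.getLogger(__name__)

ALPHA = 0.05


# ---------------------------------------------------------------------------
# assumption checks

@dataclass
class AssumptionReport:
    shapiro: dict  # group -> (statistic, p) or a skip reason string
    levene: "tuple[float, float] | str"

    @property
    def all_normal(self) -> bool:
        ps = [v[1] for v in self.shapiro.values() if isinstance(v, tuple)]
        return all(p >= ALPHA for p in ps) if ps else True


def check_assumptions(groups: dict[str, np.ndarray]) -> AssumptionReport:
    """Shapiro-Wilk per group and Levene across groups, advisory only.

    Groups with < 3 observations or zero variance are skipped with a
    recorded reason rather than producing a spurious p-value.
    """
    shapiro: dict = {}
    for name, values in groups.items():
        values = np.asarray(values, dtype=float)
        if len(values) < 3:
            shapiro[name] = "skipped: n < 3"
            log.info("Shapiro-Wilk skipped for %s (n=%d)", name, len(values))
        elif np.ptp(values) == 0:
            shapiro[name] = "skipped: zero variance"
            log.info("Shapiro-Wilk skipped for %s (constant data)", name)
        else:
            stat, p = sps.shapiro(values)
            shapiro[name] = (float(stat), float(p))
    usable = [np.asarray(v, float) for v in groups.values() if len(v) >= 3]
    if len(usable) < 2:
        levene = "skipped: < 2 groups with n >= 3"
    elif all(np.ptp(v) == 0 for v in usable):
        levene = "skipped: zero variance"
    else:
        stat, p = sps.levene(*usable)
        levene = (float(stat), float(p))
    return AssumptionReport(shapiro=shapiro, levene=levene)


# ---------------------------------------------------------------------------
# ANOVA

@dataclass
class AnovaResult:
    daw: int | None
    variable: str
    p_treatment: float
    p_cultivar: float
    p_interaction: float
    alpha: float = ALPHA
    table: pd.DataFrame = field(default=None, repr=False)

    @property
    def significant(self) -> dict[str, bool]:
        return {
            "treatment": self.p_treatment < self.alpha,
            "cultivar": self.p_cultivar < self.alpha,
            "interaction": self.p_interaction < self.alpha,
        }


def _check_cells(df: pd.DataFrame, variable: str) -> None:
    counts = df.groupby(["treatment", "cultivar"], sort=True)[variable].count()
    full = pd.MultiIndex.from_product(
        [sorted(df.treatment.unique()), sorted(df.cultivar.unique())],
        names=["treatment", "cultivar"],
    )
    counts = counts.reindex(full, fill_value=0)
    empty = counts[counts == 0]
    if len(empty):
        cell = empty.index[0]
        raise DesignError(f"empty design cell treatment={cell[0]}, cultivar={cell[1]}")
    if (counts < 2).any():
        raise DesignError("every cell needs >= 2 replicates for the interaction term")


def two_way_anova(records: pd.DataFrame, variable: str,
                  daw: int | None = None, alpha: float = ALPHA) -> AnovaResult:
    """Treatment x cultivar ANOVA (Type II SS, interaction included)."""
    df = records if daw is None else records[records.daw == daw]
    df = df.dropna(subset=[variable])
    if df.treatment.nunique() < 2 or df.cultivar.nunique() < 2:
        raise DesignError("two-way ANOVA needs >= 2 levels per factor")
    _check_cells(df, variable)
    model = ols(f"Q('{variable}') ~ C(treatment) * C(cultivar)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    return AnovaResult(
        daw=daw,
        variable=variable,
        p_treatment=float(table.loc["C(treatment)", "PR(>F)"]),
        p_cultivar=float(table.loc["C(cultivar)", "PR(>F)"]),
        p_interaction=float(table.loc["C(treatment):C(cultivar)", "PR(>F)"]),
        alpha=alpha,
        table=table,
    )


def one_way_anova(records: pd.DataFrame, variable: str,
                  cultivar: str | None = None, daw: int | None = None) -> float:
    """WW-vs-WL one-way ANOVA p-value (within one cultivar at one DAW)."""
    df = records
    if cultivar is not None:
        df = df[df.cultivar == cultivar]
    if daw is not None:
        df = df[df.daw == daw]
    df = df.dropna(subset=[variable])
    groups = [g[variable].to_numpy(dtype=float)
              for _, g in df.groupby("treatment", sort=True)]
    if len(groups) < 2:
        raise DesignError("one-way ANOVA needs >= 2 treatment groups")
    if any(len(g) < 2 for g in groups):
        raise DesignError("each treatment group needs >= 2 observations")
    _, p = sps.f_oneway(*groups)
    return float(p)


def anova_pvalue_table(records: pd.DataFrame, variables: list[str],
                       daws: list[int] | None = None) -> pd.DataFrame:
    """Per-DAW two-way ANOVA p-values, rows = DAW, columns = T, C, TxC."""
    daws = daws if daws is not None else sorted(records.daw.unique())
    rows = []
    for variable in variables:
        for daw in daws:
            res = two_way_anova(records, variable, daw=daw)
            rows.append({
                "variable": variable, "daw": daw,
                "p_T": res.p_treatment, "p_C": res.p_cultivar,
                "p_TxC": res.p_interaction,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Tukey HSD and compact letter displays

@dataclass
class TukeyGrouping:
    groups: list[str]  # ordered by descending mean
    means: dict[str, float]
    letters: dict[str, str]
    p_adjusted: dict[frozenset, float]
    alpha: float = ALPHA


def _maximal_cliques(nodes: list[str], adj: dict[str, set]) -> list[set]:
    """Bron-Kerbosch (with pivoting) over a small undirected graph."""
    cliques: list[set] = []

    def bk(r: set, p: set, x: set) -> None:
        if not p and not x:
            cliques.append(r)
            return
        pivot = max(p | x, key=lambda u: len(adj[u] & p))
        for v in list(p - adj[pivot]):
            bk(r | {v}, p & adj[v], x & adj[v])
            p.remove(v)
            x.add(v)

    bk(set(), set(nodes), set())
    return cliques


def compact_letter_display(
    means: dict[str, float],
    p_adjusted: dict[frozenset, float],
    alpha: float = ALPHA,
    uppercase: bool = False,
) -> dict[str, str]:
    """Letter classes = maximal cliques of the non-significance graph.

    Two groups are connected when their adjusted p is >= alpha; each
    maximal clique of that graph becomes one letter, assigned in order
    of descending within-clique mean.  By construction two groups share
    a letter iff they are pairwise non-significant, the validity
    condition of a compact letter display.  Group labels affect only the
    letter naming, never the class structure.
    """
    names = sorted(means, key=lambda g: (-means[g], g))
    if len(names) == 1:
        return {names[0]: "A" if uppercase else "a"}
    adj = {
        g: {
            h
            for h in names
            if h != g and p_adjusted[frozenset((g, h))] >= alpha
        }
        for g in names
    }
    cliques = _maximal_cliques(names, adj)
    cliques.sort(key=lambda c: (min(names.index(g) for g in c),
                                sorted(names.index(g) for g in c)))
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ" if uppercase else \
               "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in names}
    for i, cls in enumerate(cliques):
        ch = alphabet[i % 26] * (1 + i // 26)
        for g in names:
            if g in cls:
                letters[g] += ch
    return letters


def tukey_hsd(records: pd.DataFrame, value: str, group: str,
              alpha: float = ALPHA, uppercase: bool = False) -> TukeyGrouping:
    """All-pairs Tukey HSD with a compact letter display.

    ``group`` is a column naming the groups to compare (a main-effect
    factor, or a precomputed interaction-cell label).  Every group needs
    n >= 2.
    """
    df = records.dropna(subset=[value])
    sizes = df.groupby(group, sort=True)[value].count()
    if len(sizes) < 2:
        raise DesignError("Tukey HSD needs >= 2 groups")
    small = sizes[sizes < 2]
    if len(small):
        raise DesignError(f"group(s) with n < 2: {', '.join(map(str, small.index))}")
    with np.errstate(divide="ignore", invalid="ignore"):
        # zero pooled variance (constant data) yields p = 0 for unequal
        # means and p = 1 for ties, which is the sensible degenerate limit
        res = pairwise_tukeyhsd(df[value].to_numpy(dtype=float),
                                df[group].astype(str).to_numpy(), alpha=alpha)
    names = [str(n) for n in res.groupsunique]
    p_adj = {}
    for (i, j), p in zip(combinations(range(len(names)), 2), res.pvalues):
        # 0/0 studentized range (tied means, zero variance) -> no difference
        p_adj[frozenset((names[i], names[j]))] = 1.0 if np.isnan(p) else float(p)
    means = {str(k): float(v) for k, v in df.groupby(group)[value].mean().items()}
    letters = compact_letter_display(means, p_adj, alpha=alpha, uppercase=uppercase)
    ordered = sorted(names, key=means.get, reverse=True)
    return TukeyGrouping(groups=ordered, means=means, letters=letters,
                         p_adjusted=p_adj, alpha=alpha)
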