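"""Family trait assignment and the three-factor type-II ANOVA.

The response is each family's median Ka/Ks; the factors are reproduction
(HD/DD), lifestyle (free-living FL / parasite-parasitoid PP) and locomotion
(winged WW / flightless females FF).  Families inherit each trait from the
level held by more than half of their member species (BINs); exact ties
fall back to the ancestral/common default (DD, FL, WW) with a logged flag.

The linear model contains the three main effects and the three two-way
interactions (no three-way term), coded with sum-to-zero contrasts, and is
fit by ordinary least squares; term sums of squares are type II (each term
tested against the model containing all terms that do not include it,
respecting marginality), with type III available as a sensitivity option.
Fitting and the SS decomposition are delegated to statsmodels.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

FACTORS = ("reproduction", "lifestyle", "locomotion")
DEFAULT_LEVEL = {"reproduction": "DD", "lifestyle": "FL", "locomotion": "WW"}
LEVELS = {
    "reproduction": ("DD", "HD"),
    "lifestyle": ("FL", "PP"),
    "locomotion": ("WW", "FF"),
}


@dataclass
class TraitCall:
    level: str
    provenance: float  # fraction of member species supporting the call
    tie: bool = False


@dataclass
class TraitTable:
    calls: dict[str, dict[str, TraitCall]]  # family -> factor -> call
    ties: list[tuple[str, str]] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        rows = {
            fam: {fac: call.level for fac, call in by_factor.items()}
            for fam, by_factor in self.calls.items()
        }
        return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def assign_traits(species_traits: pd.DataFrame, family_col: str = "family") -> TraitTable:
    """Majority-rule family trait assignment from per-species records.

    `species_traits` needs a family column plus the three factor columns
    with values from the closed vocabularies.  A level is assigned when it
    is held by >50% of the family's species; an exact 50/50 split takes the
    default level (DD/FL/WW) and is flagged.
    """
    for col in (family_col, *FACTORS):
        if col not in species_traits.columns:
            raise ValueError(f"species table lacks column {col!r}")
    calls: dict[str, dict[str, TraitCall]] = {}
    ties: list[tuple[str, str]] = []
    for fam, grp in species_traits.groupby(family_col, sort=True):
        if len(grp) == 0:
            raise ValueError(f"family {fam}: no species records")
        calls[fam] = {}
        for factor in FACTORS:
            values = grp[factor]
            bad = set(values) - set(LEVELS[factor])
            if bad:
                raise ValueError(f"family {fam}, factor {factor}: illegal levels {bad}")
            counts = values.value_counts()
            top = counts.max()
            frac = top / len(values)
            if frac > 0.5:
                level = counts.idxmax()
                calls[fam][factor] = TraitCall(level=level, provenance=float(frac))
            else:  # exact tie (two levels, so frac == 0.5)
                calls[fam][factor] = TraitCall(
                    level=DEFAULT_LEVEL[factor], provenance=float(frac), tie=True
                )
                ties.append((fam, factor))
    return TraitTable(calls=calls, ties=ties)


TERMS = [
    "reproduction",
    "lifestyle",
    "locomotion",
    "reproduction:lifestyle",
    "reproduction:locomotion",
    "lifestyle:locomotion",
]


def _estimable_terms(data: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Interaction terms are inestimable when a factor-level cell is empty."""
    keep, dropped = list(TERMS[:3]), []
    for a, b in itertools.combinations(FACTORS, 2):
        cells = data.groupby([a, b], observed=True).size()
        n_cells = len(LEVELS[a]) * len(LEVELS[b])
        term = f"{a}:{b}"
        if len(cells) < n_cells:
            dropped.append(term)
        else:
            keep.append(term)
    return keep, dropped


def type2_anova(
    data: pd.DataFrame,
    response: str = "median_omega",
    include_interactions: bool = True,
    ss_type: int = 2,
) -> pd.DataFrame:
    """Factorial ANOVA of the family response against the three traits.

    Returns a table with one row per term plus a residual row (columns:
    sum_sq, df, mean_sq, F, PR(>F)).  Sum-to-zero contrasts make the
    type-II decomposition valid under unbalance; terms made inestimable by
    empty cells are dropped with a warning.
    """
    if ss_type not in (2, 3):
        raise ValueError("ss_type must be 2 or 3")
    data = data.copy()
    for factor in FACTORS:
        if data[factor].nunique() < 2:
            raise ValueError(f"factor {factor!r} has fewer than 2 observed levels")
        data[factor] = pd.Categorical(data[factor], categories=LEVELS[factor])
    if include_interactions:
        terms, dropped = _estimable_terms(data)
        for term in dropped:
            warnings.warn(f"dropping inestimable interaction {term} (empty cell)")
    else:
        terms, dropped = list(TERMS[:3]), []
    rhs = " + ".join(
        ":".join(f"C({f}, Sum)" for f in t.split(":")) for t in terms
    )
    n_params = 1 + len(terms)  # two-level factors: 1 df per term
    if len(data) <= n_params:
        raise ValueError(
            f"n = {len(data)} families does not exceed model df = {n_params}"
        )
    model = smf.ols(f"{response} ~ {rhs}", data=data).fit()
    table = sm.stats.anova_lm(model, typ=ss_type)
    if ss_type == 3:
        table = table.drop(index="Intercept")
    rename = {
        ":".join(f"C({f}, Sum)" for f in t.split(":")): t for t in terms
    }
    table = table.rename(index=rename)
    table["mean_sq"] = table["sum_sq"] / table["df"]
    table = table[["sum_sq", "df", "mean_sq", "F", "PR(>F)"]]
    table.attrs["dropped_terms"] = dropped
    table.attrs["ss_type"] = ss_type
    return table
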