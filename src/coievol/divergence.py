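"""Amino-acid divergence metrics and quartile classification.

p-distance is the proportion of differing comparable columns (both states
unambiguous amino acids); the Poisson-corrected distance -ln(1 - p)
accounts for multiple hits.  Families are classed by the quartiles of their
outgroup substitution counts (strictly above Q3 = "high", strictly below
Q1 = "low"); concordance between the two outgroup comparisons is the
squared Pearson correlation of the per-family counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .consensus import _AA20


def p_distance(aa_a: str, aa_b: str) -> float:
    """Proportion of differing columns among comparable ones.

    Comparable means both states are one of the 20 amino acids; X, '-' and
    '*' columns are excluded before the ratio.  Raises if no column is
    comparable.
    """
    if len(aa_a) != len(aa_b):
        raise ValueError(f"aligned lengths differ: {len(aa_a)} vs {len(aa_b)}")
    comparable = diffs = 0
    for x, y in zip(aa_a, aa_b):
        if x in _AA20 and y in _AA20:
            comparable += 1
            if x != y:
                diffs += 1
    if comparable == 0:
        raise ValueError("no comparable columns: p-distance undefined")
    return diffs / comparable


def poisson_distance(p: float) -> float:
    """Multiple-hit corrected distance d = -ln(1 - p); requires 0 <= p < 1."""
    if not 0.0 <= p < 1.0:
        raise ValueError(f"p-distance {p} outside [0, 1): Poisson distance undefined")
    return -math.log1p(-p)


def outgroup_concordance(counts1: Sequence[float], counts2: Sequence[float]) -> float:
    """Squared Pearson correlation between two per-family count vectors."""
    x = np.asarray(counts1, dtype=float)
    y = np.asarray(counts2, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length vectors with >= 3 families")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r = stats.pearsonr(x, y).statistic
    return float(r * r)


@dataclass
class QuartileClasses:
    q1: float
    q3: float
    labels: dict[str, str]  # family -> low | mid | high
    method: str = "linear interpolation (type 7)"


def quartile_classes(
    counts: dict[str, float],
    thresholds: tuple[float, float] | None = None,
) -> QuartileClasses:
    """Label families by the quartiles of their substitution counts.

    high: count strictly above Q3; low: strictly below Q1; else mid.
    Quartiles use linear interpolation (numpy's default, R type 7), stated
    in the output because the convention is not standardised.  Explicit
    (q1, q3) thresholds can be injected to reuse dataset-specific cutoffs.
    """
    if len(counts) < 4 and thresholds is None:
        raise ValueError("need >= 4 families to estimate quartiles")
    values = np.array([counts[f] for f in sorted(counts)], dtype=float)
    if thresholds is None:
        q1, q3 = np.quantile(values, [0.25, 0.75])
        method = "linear interpolation (type 7)"
    else:
        q1, q3 = thresholds
        method = "injected thresholds"
    labels = {
        fam: "high" if c > q3 else ("low" if c < q1 else "mid")
        for fam, c in counts.items()
    }
    return QuartileClasses(q1=float(q1), q3=float(q3), labels=labels, method=method)


@dataclass
class PairDistance:
    family_a: str
    family_b: str
    p: float
    d_poisson: float


def pairwise_distances(
    aa_by_family: dict[str, str], families: Sequence[str] | None = None
) -> list[PairDistance]:
    """Long-format p / Poisson distances for all family pairs (within one
    order, typically)."""
    fams = sorted(aa_by_family) if families is None else list(families)
    out = []
    for i, a in enumerate(fams):
        for b in fams[i + 1 :]:
            p = p_distance(aa_by_family[a], aa_by_family[b])
            out.append(PairDistance(a, b, p, poisson_distance(p)))
    return out
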