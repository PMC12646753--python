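"""Nei–Gojobori-style Ka/Ks estimation under the invertebrate mitochondrial code.

The estimator is deliberately the transparent counting one: per-codon
synonymous/nonsynonymous site fractions from single-nucleotide mutant
enumeration (mutations to stop codons are excluded from the opportunity at
that position), pathway-averaged difference counts for codon pairs, and a
Jukes–Cantor multiple-hit correction of the pooled proportions:

    pS = sum(Sd) / sum(S_sites),     Ks = -(3/4) * ln(1 - (4/3) * pS)

and likewise for Ka.  omega = Ka/Ks.  Family-level summaries take the median
omega over all usable within-family pairs; class-level (HD vs DD) contrasts
pool the raw counts over pairs before correcting, which is robust to the
small per-pair synonymous counts typical of closely related barcodes.

All tables are precomputed at import for the 64 codons, so pairwise
computation is a table lookup.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import codons
from .codons import GAP

AMBIGUOUS = -2  # codon containing N or a partial gap; skipped pairwise


def _site_fractions(codon: str) -> tuple[float, float]:
    """NG86 synonymous/nonsynonymous site counts for one sense codon.

    At each position the fraction of synonymous changes is taken over the
    non-stop single-nucleotide mutants only, so the two fractions sum to one
    per position and S + N = 3 for every codon.
    """
    aa = codons.aa_of(codon)
    s = 0.0
    for pos in range(3):
        syn = 0
        non_stop = 0
        for base in codons.BASES:
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1 :]
            if mut in codons.STOP_CODONS:
                continue
            non_stop += 1
            if codons.aa_of(mut) == aa:
                syn += 1
        if non_stop:
            s += syn / non_stop
    return s, 3.0 - s


def _pathway_differences(a: str, b: str) -> tuple[float, float]:
    """Pathway-averaged (Sd, Nd) between two sense codons.

    All orderings of the differing positions are enumerated; orderings that
    pass through a stop codon are excluded.  If every ordering is blocked
    (cannot happen between sense codons under table 5, but kept as a guard)
    the average falls back to all orderings.
    """
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    allowed: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in itertools.permutations(diff):
        cur = a
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in codons.STOP_CODONS and nxt != b:
                ok = False
            if codons.translate_codon(cur) == codons.translate_codon(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        (allowed if ok else blocked).append((sd, nd))
    paths = allowed or blocked
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def _build_tables():
    s_sites = np.full(64, np.nan)
    n_sites = np.full(64, np.nan)
    for i, codon in enumerate(codons.ALL_CODONS):
        if not codons.IS_STOP[i]:
            s_sites[i], n_sites[i] = _site_fractions(codon)
    sd = np.full((64, 64), np.nan)
    nd = np.full((64, 64), np.nan)
    for i in codons.SENSE_INDICES:
        for j in codons.SENSE_INDICES:
            sd[i, j], nd[i, j] = _pathway_differences(
                codons.ALL_CODONS[i], codons.ALL_CODONS[j]
            )
    return s_sites, n_sites, sd, nd


S_SITES, N_SITES, SD_TABLE, ND_TABLE = _build_tables()


def count_sites(codon: str) -> tuple[float, float]:
    """(S_sites, N_sites) for one codon; raises for stops, None-skips for N."""
    if any(b not in "ACGT" for b in codon):
        raise ValueError(f"ambiguous codon {codon!r}: skip it, do not count it")
    idx = codons.codon_index(codon)
    if codons.IS_STOP[idx]:
        raise ValueError(f"stop codon {codon!r} has no defined site counts")
    return float(S_SITES[idx]), float(N_SITES[idx])


def count_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (Sd, Nd) between two sense codons."""
    ia, ib = codons.codon_index(codon_a), codons.codon_index(codon_b)
    if codons.IS_STOP[ia] or codons.IS_STOP[ib]:
        raise ValueError("stop codons are not comparable")
    return float(SD_TABLE[ia, ib]), float(ND_TABLE[ia, ib])


def jc_correct(p: float) -> float | None:
    """Jukes–Cantor correction -(3/4)ln(1-4p/3); None outside its domain."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def encode_for_kaks(seq) -> np.ndarray:
    """Encode an aligned nucleotide string (or pass through an index array)
    to codon indices with GAP for '---' and AMBIGUOUS for anything else
    unresolvable."""
    if isinstance(seq, np.ndarray):
        return seq
    if len(seq) % 3:
        raise ValueError(f"aligned length {len(seq)} not a multiple of 3")
    out = np.empty(len(seq) // 3, dtype=np.int64)
    for k in range(0, len(seq), 3):
        codon = seq[k : k + 3]
        if codon == "---":
            out[k // 3] = GAP
        elif any(b not in "ACGT" for b in codon):
            out[k // 3] = AMBIGUOUS
        else:
            out[k // 3] = codons.codon_index(codon)
    return out


@dataclass
class KaKsResult:
    """Pairwise NG86 decomposition for one aligned BIN pair."""

    pair: tuple[str, str]
    s_sites: float = 0.0
    n_sites: float = 0.0
    sd: float = 0.0
    nd: float = 0.0
    n_codons_used: int = 0
    n_codons_skipped: int = 0
    ps: float | None = None
    pn: float | None = None
    ks: float | None = None
    ka: float | None = None
    omega: float | None = None
    usable: bool = False
    reason: str = ""


def kaks_pair(seq_a, seq_b, pair: tuple[str, str] = ("a", "b")) -> KaKsResult:
    """NG86 Ka/Ks for one aligned pair of in-frame nucleotide sequences.

    Codons with a gap, an ambiguity, or a stop in either sequence are
    skipped pairwise.  Site totals are the average of the two sequences'
    sums, as in the original counting scheme.
    """
    a = encode_for_kaks(seq_a)
    b = encode_for_kaks(seq_b)
    if len(a) != len(b):
        raise ValueError(f"codon counts differ: {len(a)} vs {len(b)}")
    res = KaKsResult(pair=pair)
    ok = (a >= 0) & (b >= 0) & ~codons.IS_STOP[np.clip(a, 0, 63)] & ~codons.IS_STOP[
        np.clip(b, 0, 63)
    ]
    ai, bi = a[ok], b[ok]
    res.n_codons_used = int(ok.sum())
    res.n_codons_skipped = len(a) - res.n_codons_used
    if res.n_codons_used == 0:
        res.reason = "no comparable codons"
        return res
    res.s_sites = float((S_SITES[ai].sum() + S_SITES[bi].sum()) / 2.0)
    res.n_sites = float((N_SITES[ai].sum() + N_SITES[bi].sum()) / 2.0)
    res.sd = float(SD_TABLE[ai, bi].sum())
    res.nd = float(ND_TABLE[ai, bi].sum())
    res.ps = res.sd / res.s_sites if res.s_sites > 0 else None
    res.pn = res.nd / res.n_sites if res.n_sites > 0 else None
    if res.ps is None or res.pn is None:
        res.reason = "zero site total"
        return res
    res.ks = jc_correct(res.ps)
    res.ka = jc_correct(res.pn)
    if res.ks is None or res.ka is None:
        res.reason = "JC correction out of domain (p >= 3/4)"
        return res
    if res.ks == 0.0:
        res.reason = "Ks = 0: omega undefined"
        return res
    res.omega = res.ka / res.ks
    res.usable = True
    return res


@dataclass
class FamilyKaKs:
    family: str
    median_omega: float | None
    n_pairs: int
    n_usable: int
    skip_reasons: dict[str, int] = field(default_factory=dict)
    results: list[KaKsResult] = field(default_factory=list)


def family_median_kaks(
    family: str, seqs: Mapping[str, object], keep_results: bool = True
) -> FamilyKaKs:
    """Median omega over all C(n,2) BIN pairs of one family.

    Pairs with undefined omega (Ks = 0, out-of-domain correction, no
    comparable codons) are excluded from the median and tallied by reason.
    """
    bins = sorted(seqs)
    encoded = {b: encode_for_kaks(seqs[b]) for b in bins}
    results = []
    for x, y in itertools.combinations(bins, 2):
        results.append(kaks_pair(encoded[x], encoded[y], pair=(x, y)))
    usable = [r.omega for r in results if r.usable]
    reasons: dict[str, int] = {}
    for r in results:
        if not r.usable:
            reasons[r.reason] = reasons.get(r.reason, 0) + 1
    return FamilyKaKs(
        family=family,
        median_omega=median(usable) if usable else None,
        n_pairs=len(results),
        n_usable=len(usable),
        skip_reasons=reasons,
        results=results if keep_results else [],
    )


@dataclass
class ClassOmega:
    """Pooled counting-based omega per branch class and their ratio."""

    omega_by_class: dict[str, float | None]
    n_pairs_by_class: dict[str, int]
    pooled: dict[str, dict[str, float]]

    @property
    def omega_hd(self) -> float | None:
        return self.omega_by_class.get("HD")

    @property
    def omega_dd(self) -> float | None:
        return self.omega_by_class.get("DD")

    @property
    def ratio(self) -> float | None:
        hd, dd = self.omega_hd, self.omega_dd
        if hd is None or dd is None or dd <= 0:
            return None
        return hd / dd


def pool_pairs(results: Iterable[KaKsResult]) -> dict[str, float]:
    """Sum raw NG86 counts over pairs (pairs with no comparable codons drop out)."""
    tot = {"sd": 0.0, "nd": 0.0, "s_sites": 0.0, "n_sites": 0.0, "n_pairs": 0}
    for r in results:
        if r.n_codons_used == 0:
            continue
        tot["sd"] += r.sd
        tot["nd"] += r.nd
        tot["s_sites"] += r.s_sites
        tot["n_sites"] += r.n_sites
        tot["n_pairs"] += 1
    return tot


def _pooled_omega(tot: dict[str, float]) -> float | None:
    if tot["s_sites"] <= 0 or tot["n_sites"] <= 0:
        return None
    ks = jc_correct(tot["sd"] / tot["s_sites"])
    ka = jc_correct(tot["nd"] / tot["n_sites"])
    if ks is None or ka is None or ks == 0:
        return None
    return ka / ks


def pooled_class_omega(
    family_results: Mapping[str, Sequence[KaKsResult]] | Mapping[str, FamilyKaKs],
    class_by_family: Mapping[str, str],
) -> ClassOmega:
    """Site-weighted pooled omega per class (e.g. HD vs DD) and the HD:DD ratio.

    Raw synonymous/nonsynonymous differences and sites are summed over all
    within-family pairs of each class before the Jukes–Cantor correction, so
    every codon site carries equal weight and pairs with Sd = 0 contribute
    rather than being dropped.
    """
    by_class: dict[str, list[KaKsResult]] = {}
    for fam, res in family_results.items():
        cls = class_by_family.get(fam)
        if cls is None:
            raise KeyError(f"family {fam!r} has no class label")
        pair_list = res.results if isinstance(res, FamilyKaKs) else res
        by_class.setdefault(cls, []).extend(pair_list)
    if len(by_class) < 1 or not any(by_class.values()):
        raise ValueError("no class has any pairwise results")
    omega: dict[str, float | None] = {}
    n_pairs: dict[str, int] = {}
    pooled: dict[str, dict[str, float]] = {}
    for cls, res in sorted(by_class.items()):
        tot = pool_pairs(res)
        pooled[cls] = tot
        n_pairs[cls] = int(tot["n_pairs"])
        omega[cls] = _pooled_omega(tot)
    return ClassOmega(omega_by_class=omega, n_pairs_by_class=n_pairs, pooled=pooled)
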