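"""Family consensus building and invertebrate-mitochondrial translation.

A family's consensus nucleotide sequence is the column-wise modal state of
its aligned members ("most common base"): N never competes, a gap wins a
column only on a strict majority over every residue, and residue ties break
by the fixed priority A > C > G > T so the call is deterministic.  The
consensus is translated codon-wise under translation table 5; the
consensus-of-family-consensuses (each family weighted equally) serves as
the overall insect reference, and outgroup consensuses are built by the
same operations.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

from . import codons

_RESIDUE_PRIORITY = {b: i for i, b in enumerate("ACGT")}


@dataclass
class FamilyAlignment:
    """Aligned nucleotide rows (over A,C,G,T,N,-) for one family."""

    family: str
    rows: dict[str, str]  # record_id -> aligned nt
    frame_offset: int = 0

    def __post_init__(self):
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"family {self.family}: unequal row lengths {lengths}")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))


@dataclass
class ConsensusProfile:
    family: str
    nt_consensus: str
    aa_consensus: str  # aligned: gap codons as '-'
    column_support: list[int]


def consensus_column(states: Sequence[str]) -> tuple[str, int]:
    """Modal state of one column.

    N is excluded from the tally (an all-N column yields N with support 0);
    '-' competes but only wins on a strict majority over the best residue;
    residue ties break A > C > G > T.
    """
    counts = Counter(s for s in states if s != "N")
    if not counts:
        return "N", 0
    gap_count = counts.pop("-", 0)
    if counts:
        best = min(counts, key=lambda b: (-counts[b], _RESIDUE_PRIORITY[b]))
        if gap_count > counts[best]:
            return "-", gap_count
        return best, counts[best]
    return "-", gap_count


def build_consensus(alignment: FamilyAlignment) -> ConsensusProfile:
    """'Most common base' consensus of a family alignment, with codon-wise
    translation of the result."""
    if not alignment.rows:
        raise ValueError(f"family {alignment.family}: no rows to build consensus from")
    rows = [alignment.rows[k] for k in sorted(alignment.rows)]
    nt_chars, support = [], []
    for col in range(alignment.n_columns):
        state, n = consensus_column([row[col] for row in rows])
        nt_chars.append(state)
        support.append(n)
    nt = "".join(nt_chars)
    aa = translate_mt_invertebrate(nt, alignment.frame_offset)
    return ConsensusProfile(
        family=alignment.family, nt_consensus=nt, aa_consensus=aa, column_support=support
    )


def translate_mt_invertebrate(nt: str, frame_offset: int = 0) -> str:
    """Codon-wise translation under the invertebrate mitochondrial code.

    Gap runs must be codon-length multiples (else a frameshift error is
    raised); '---' codons translate to '-', codons containing N (or a
    partial gap) to 'X', and a trailing partial codon is dropped.
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    body = nt[frame_offset:]
    run = 0
    for ch in body.rstrip("-"):
        if ch == "-":
            run += 1
        else:
            if run % 3:
                raise ValueError(
                    f"internal gap run of length {run} is not a multiple of 3"
                )
            run = 0
    out = []
    for i in range(0, len(body) - len(body) % 3, 3):
        out.append(codons.translate_codon(body[i : i + 3]))
    return "".join(out)


_AA20 = set("ACDEFGHIKLMNPQRSTVWY")


def count_aa_substitutions(aa_a: str, aa_b: str) -> int:
    """Differing columns where both states are unambiguous amino acids;
    columns containing X, '-' or '*' in either sequence are excluded."""
    if len(aa_a) != len(aa_b):
        raise ValueError(f"aligned lengths differ: {len(aa_a)} vs {len(aa_b)}")
    return sum(
        1 for x, y in zip(aa_a, aa_b) if x in _AA20 and y in _AA20 and x != y
    )


def overall_consensus(
    profiles: Mapping[str, ConsensusProfile], name: str = "insect"
) -> ConsensusProfile:
    """Consensus of family consensuses, each family weighted equally."""
    rows = {fam: p.nt_consensus for fam, p in profiles.items()}
    return build_consensus(FamilyAlignment(family=name, rows=rows))
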