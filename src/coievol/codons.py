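"""Invertebrate mitochondrial codon machinery (NCBI translation table 5).

The COI barcode is a mitochondrial protein-coding fragment, so all codon
arithmetic in this package runs under the invertebrate mitochondrial code:
AGA/AGG encode Ser (not Arg/stop), ATA encodes Met, TGA encodes Trp, and the
only stop codons are TAA and TAG.  Codons are frequently handled as integer
indices ``16*b1 + 4*b2 + b3`` with A,C,G,T = 0..3, which keeps the
substitution simulator and the site-counting tables fast.
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

TABLE_ID = 5
BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_TABLE = CodonTable.unambiguous_dna_by_id[TABLE_ID]
STOP_CODONS = frozenset(_TABLE.stop_codons)  # {'TAA', 'TAG'}

#: purine<->purine / pyrimidine<->pyrimidine substitutions
_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}

ALL_CODONS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)
SENSE_CODONS = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)

#: amino acid for every codon index; '*' marks a stop
AA_BY_INDEX = np.array(
    [_TABLE.forward_table.get(c, "*") for c in ALL_CODONS], dtype="U1"
)
IS_STOP = np.array([c in STOP_CODONS for c in ALL_CODONS], dtype=bool)
SENSE_INDICES = np.flatnonzero(~IS_STOP)

GAP = -1  # sentinel for a gap codon in integer-encoded alignments


def codon_index(codon: str) -> int:
    """Map a 3-mer over ACGT to its 0..63 index."""
    try:
        return (
            16 * _BASE_INDEX[codon[0]]
            + 4 * _BASE_INDEX[codon[1]]
            + _BASE_INDEX[codon[2]]
        )
    except KeyError as exc:
        raise ValueError(f"codon {codon!r} contains a non-ACGT base") from exc


def index_to_codon(idx: int) -> str:
    return ALL_CODONS[idx]


def aa_of(codon: str) -> str:
    """Translate one resolved codon; '*' for stop."""
    return _TABLE.forward_table.get(codon, "*") if codon not in STOP_CODONS else "*"


def translate_codon(codon: str) -> str:
    """Translate a codon that may contain N or gaps.

    '---' -> '-';  any N (or partial gap) -> 'X';  stops -> '*'.
    """
    if codon == "---":
        return "-"
    if any(b not in _BASE_INDEX for b in codon):
        return "X"
    return aa_of(codon)


def is_transition(a: str, b: str) -> bool:
    """True if a->b is a transition (A<->G or C<->T)."""
    if a == b:
        raise ValueError("identical bases have no substitution type")
    return (a in _PURINES) == (b in _PURINES)


def single_nt_mutants(codon: str):
    """Yield (position, new_base, mutant_codon) for the 9 single-nt neighbours."""
    for pos in range(3):
        for base in BASES:
            if base != codon[pos]:
                yield pos, base, codon[:pos] + base + codon[pos + 1 :]


def encode_codons(nt: str) -> np.ndarray:
    """Encode an in-frame, length-divisible-by-3 nucleotide string to codon
    indices, with '---' runs as GAP.  Raises on partially gapped codons."""
    if len(nt) % 3:
        raise ValueError(f"length {len(nt)} is not a multiple of 3")
    out = np.empty(len(nt) // 3, dtype=np.int64)
    for i in range(0, len(nt), 3):
        codon = nt[i : i + 3]
        if codon == "---":
            out[i // 3] = GAP
        else:
            out[i // 3] = codon_index(codon)
    return out


def decode_codons(indices) -> str:
    """Inverse of :func:`encode_codons` ('---' for GAP cells)."""
    return "".join("---" if i == GAP else ALL_CODONS[i] for i in indices)
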