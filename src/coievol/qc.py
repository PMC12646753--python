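"""Record-level quality control and taxonomically stratified sampling.

Mirrors the preparation of a barcode corpus for comparative analysis:

1. length window — keep records whose ungapped length covers the full
   barcode amplicon (643–661 bp);
2. one sequence per BIN (the species proxy), chosen uniformly at random;
3. reading-frame screen — the frame (0/1/2) minimising internal stop codons
   under the invertebrate mitochondrial code; any internal stop, or an
   internal alignment gap whose length is not a multiple of three, fails the
   record (NUMT / sequencing-error suspects);
4. stratified downsampling — families with <100 BINs keep everything,
   100–1000 keep a random 100, and families above 1000 BINs are capped at
   100 BINs per large subfamily;
5. exclusion of families with fewer than three BINs.

Random choices are made by ranking order-independent digests of
(seed, group, bin), so selections do not depend on input ordering.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from . import codons

LENGTH_MIN = 643
LENGTH_MAX = 661
LEGAL_CHARS = set("ACGTN-")


@dataclass
class SequenceRecord:
    """One barcode record with its BIN label, taxonomy and binary traits."""

    record_id: str
    bin_id: str
    family: str
    nt: str
    order: str = ""
    subfamily: str = ""
    tribe: str = ""
    traits: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.bin_id:
            raise ValueError(f"record {self.record_id}: empty bin_id")
        if not self.nt:
            raise ValueError(f"record {self.record_id}: empty sequence")

    @property
    def ungapped(self) -> str:
        return self.nt.replace("-", "")

    @property
    def ungapped_length(self) -> int:
        return len(self.ungapped)


@dataclass
class QCReport:
    record_id: str
    ungapped_length: int
    best_frame: int
    stop_codons_in_best_frame: int
    frameshift_flag: bool
    verdict: str  # "pass" | "fail"
    reason: str = ""


def _rank(seed: int, *parts: str) -> bytes:
    h = hashlib.blake2b(digest_size=16)
    h.update(repr((seed,) + parts).encode())
    return h.digest()


def filter_length(
    records: Iterable[SequenceRecord],
    min_len: int = LENGTH_MIN,
    max_len: int = LENGTH_MAX,
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Partition records by the amplicon length window (gaps stripped)."""
    kept, dropped = [], []
    for rec in records:
        (kept if min_len <= rec.ungapped_length <= max_len else dropped).append(rec)
    return kept, dropped


def one_per_bin(records: Sequence[SequenceRecord], seed: int) -> list[SequenceRecord]:
    """Keep exactly one record per BIN, uniformly at random under `seed`.

    The survivor is the record with the smallest digest of
    (seed, bin_id, record_id), which is a uniform choice independent of the
    input order.
    """
    best: dict[str, tuple[bytes, SequenceRecord]] = {}
    for rec in records:
        key = _rank(seed, "one_per_bin", rec.bin_id, rec.record_id)
        if rec.bin_id not in best or key < best[rec.bin_id][0]:
            best[rec.bin_id] = (key, rec)
    return [best[b][1] for b in sorted(best)]


def _internal_gap_runs(nt: str) -> list[int]:
    """Lengths of gap runs strictly between the first and last non-gap char."""
    first = len(nt) - len(nt.lstrip("-"))
    last = len(nt.rstrip("-"))
    runs, current = [], 0
    for ch in nt[first:last]:
        if ch == "-":
            current += 1
        elif current:
            runs.append(current)
            current = 0
    return runs


def screen_reading_frame(record: SequenceRecord) -> QCReport:
    """Frame/stop screen for NUMT or sequencing-error suspects.

    The best frame minimises internal stop codons (the final complete codon
    is not counted as internal); ties resolve to the smallest offset.  The
    record fails if any internal stop remains in the best frame or if an
    internal gap run breaks the codon structure.
    """
    for pos, ch in enumerate(record.nt):
        if ch not in LEGAL_CHARS:
            raise ValueError(
                f"record {record.record_id}: illegal character {ch!r} at position {pos}"
            )
    seq = record.ungapped
    stops_by_frame = []
    for frame in range(3):
        n_stops = 0
        limit = len(seq) - 3  # exclude the final (possibly terminal-stop) codon
        for i in range(frame, limit - ((limit - frame) % 3), 3):
            codon = seq[i : i + 3]
            if codon in codons.STOP_CODONS:
                n_stops += 1
        stops_by_frame.append(n_stops)
    best_frame = min(range(3), key=lambda f: (stops_by_frame[f], f))
    n_stops = stops_by_frame[best_frame]
    frameshift = any(run % 3 for run in _internal_gap_runs(record.nt))
    reasons = []
    if n_stops > 0:
        reasons.append(f"{n_stops} internal stop codon(s) in best frame")
    if frameshift:
        reasons.append("internal gap run not a multiple of 3 (frameshift)")
    return QCReport(
        record_id=record.record_id,
        ungapped_length=record.ungapped_length,
        best_frame=best_frame,
        stop_codons_in_best_frame=n_stops,
        frameshift_flag=frameshift,
        verdict="fail" if reasons else "pass",
        reason="; ".join(reasons),
    )


def screen_records(
    records: Iterable[SequenceRecord],
) -> tuple[list[SequenceRecord], list[SequenceRecord], list[QCReport]]:
    kept, dropped, reports = [], [], []
    for rec in records:
        rep = screen_reading_frame(rec)
        reports.append(rep)
        (kept if rep.verdict == "pass" else dropped).append(rec)
    return kept, dropped, reports


UNPLACED = "unplaced"


def _cap(group: Sequence[SequenceRecord], cap: int, seed: int, label: str
         ) -> list[SequenceRecord]:
    if len(group) <= cap:
        return list(group)
    ranked = sorted(group, key=lambda r: _rank(seed, "stratified", label, r.bin_id))
    return ranked[:cap]


def stratified_sample(
    records: Sequence[SequenceRecord],
    per_family_cap: int = 100,
    subfamily_cap: int = 100,
    large_family_threshold: int = 1000,
    seed: int = 0,
    log: list[str] | None = None,
) -> list[SequenceRecord]:
    """Taxonomically stratified downsampling (assumes one record per BIN).

    <100 BINs: keep all.  100–1000: keep exactly `per_family_cap`.
    >1000: keep at most `subfamily_cap` per subfamily (all of small ones);
    records of large families lacking a subfamily label are pooled into an
    "unplaced" pseudo-subfamily and logged.
    """
    by_family: dict[str, list[SequenceRecord]] = {}
    for rec in records:
        by_family.setdefault(rec.family, []).append(rec)
    selected: list[SequenceRecord] = []
    for fam in sorted(by_family):
        group = by_family[fam]
        n = len(group)
        if n <= large_family_threshold:
            if n < per_family_cap:
                selected.extend(group)
            else:
                selected.extend(_cap(group, per_family_cap, seed, fam))
        else:
            by_sub: dict[str, list[SequenceRecord]] = {}
            for rec in group:
                sub = rec.subfamily or UNPLACED
                by_sub.setdefault(sub, []).append(rec)
            if UNPLACED in by_sub and log is not None:
                log.append(
                    f"family {fam}: {len(by_sub[UNPLACED])} records without a "
                    f"subfamily label routed to '{UNPLACED}'"
                )
            for sub in sorted(by_sub):
                selected.extend(
                    _cap(by_sub[sub], subfamily_cap, seed, f"{fam}/{sub}")
                )
    order = {id(r): i for i, r in enumerate(records)}
    selected.sort(key=lambda r: order[id(r)])
    return selected


def exclude_small_families(
    records: Sequence[SequenceRecord], min_bins: int = 3
) -> tuple[list[SequenceRecord], list[str]]:
    """Drop families represented by fewer than `min_bins` BINs."""
    bins_by_family: dict[str, set[str]] = {}
    for rec in records:
        bins_by_family.setdefault(rec.family, set()).add(rec.bin_id)
    small = {f for f, bins in bins_by_family.items() if len(bins) < min_bins}
    return [r for r in records if r.family not in small], sorted(small)


@dataclass
class QCOutcome:
    records: list[SequenceRecord]
    reports: list[QCReport]
    attrition: dict[str, int]
    dropped_families: list[str]
    log: list[str]


def run_qc(
    records: Sequence[SequenceRecord],
    seed: int = 0,
    per_family_cap: int = 100,
    subfamily_cap: int = 100,
    min_bins: int = 3,
) -> QCOutcome:
    """The fixed QC pipeline: length → one-per-BIN → frame screen →
    stratified sample → small-family exclusion.  Each stage only shrinks
    the record set; the attrition table accounts for every drop."""
    log: list[str] = []
    attrition = {"input": len(records)}
    kept, dropped_len = filter_length(records)
    attrition["length_window"] = len(kept)
    kept = one_per_bin(kept, seed)
    attrition["one_per_bin"] = len(kept)
    kept, dropped_frame, reports = screen_records(kept)
    attrition["frame_screen"] = len(kept)
    kept = stratified_sample(
        kept, per_family_cap, subfamily_cap, seed=seed, log=log
    )
    attrition["stratified_sample"] = len(kept)
    kept, small = exclude_small_families(kept, min_bins)
    attrition["small_family_exclusion"] = len(kept)
    for rec in dropped_len:
        log.append(
            f"drop {rec.record_id}: length {rec.ungapped_length} outside "
            f"[{LENGTH_MIN}, {LENGTH_MAX}]"
        )
    for rep in reports:
        if rep.verdict == "fail":
            log.append(f"drop {rep.record_id}: {rep.reason}")
    for fam in small:
        log.append(f"drop family {fam}: fewer than {min_bins} BINs")
    return QCOutcome(
        records=kept,
        reports=reports,
        attrition=attrition,
        dropped_families=small,
        log=log,
    )
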