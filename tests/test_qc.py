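"""Record QC and the stratified sampling contract."""

import numpy as np
import pytest

from coievol import qc
from coievol.consensus import translate_mt_invertebrate


def make(record_id="r1", bin_id="b1", family="Fam", nt="ATT" * 217, **kw):
    return qc.SequenceRecord(record_id=record_id, bin_id=bin_id, family=family,
                             nt=nt, **kw)


# ------------------------------------------------------------- length window

def test_length_window_boundaries():
    recs = [make(record_id=f"r{n}", nt="A" * n) for n in (642, 643, 661, 662)]
    kept, dropped = qc.filter_length(recs)
    assert sorted(r.ungapped_length for r in kept) == [643, 661]
    assert sorted(r.ungapped_length for r in dropped) == [642, 662]


def test_length_window_ignores_gaps_and_content():
    rec = make(nt="N" * 650)  # all-N but in-window: length filter keeps it
    assert qc.filter_length([rec])[0] == [rec]
    gapped = make(nt="A" * 650 + "-" * 20)
    assert qc.filter_length([gapped])[0] == [gapped]
    assert qc.filter_length([]) == ([], [])


# ------------------------------------------------------------- one per BIN

def test_one_per_bin_cardinality_and_determinism():
    recs = [make(record_id=f"r{i}", bin_id="b1") for i in range(3)] + [
        make(record_id="r9", bin_id="b2")
    ]
    out = qc.one_per_bin(recs, seed=1)
    assert len(out) == 2 and {r.bin_id for r in out} == {"b1", "b2"}
    assert [r.record_id for r in qc.one_per_bin(recs, seed=1)] == [
        r.record_id for r in out
    ]
    # input order must not matter
    assert [r.record_id for r in qc.one_per_bin(recs[::-1], seed=1)] == [
        r.record_id for r in out
    ]
    distinct = [make(record_id=f"r{i}", bin_id=f"b{i}") for i in range(4)]
    assert len(qc.one_per_bin(distinct, seed=0)) == 4


# ------------------------------------------------------------- frame screen

def test_clean_sequence_passes():
    rep = qc.screen_reading_frame(make())
    assert rep.verdict == "pass" and rep.stop_codons_in_best_frame == 0
    assert rep.best_frame == 0 and not rep.frameshift_flag


def test_inframe_stop_fails_with_reason(rng):
    from coievol import codons

    # random coding sequence (aperiodic, so shifted frames have stops of
    # their own) with one planted in-frame TAA
    body = "".join(str(c) for c in rng.choice(list(codons.SENSE_CODONS), size=100))
    nt = body[:150] + "TAA" + body[153:]
    rep = qc.screen_reading_frame(make(nt=nt))
    assert rep.verdict == "fail" and "stop" in rep.reason


def test_frameshift_gap_run():
    nt = "ATT" * 30 + "----" + "ATT" * 30
    rep = qc.screen_reading_frame(make(nt=nt))
    assert rep.frameshift_flag and rep.verdict == "fail"
    ok = qc.screen_reading_frame(make(nt="ATT" * 30 + "---" + "ATT" * 30))
    assert not ok.frameshift_flag and ok.verdict == "pass"


def test_best_frame_detection():
    # stop-free in frame 1 only: prepend one base to an in-frame sequence
    nt = "G" + "ATTATA" * 40
    rep = qc.screen_reading_frame(make(nt=nt))
    assert rep.best_frame in (0, 1) and rep.stop_codons_in_best_frame == 0


def test_illegal_character_names_position():
    with pytest.raises(ValueError, match="position 3"):
        qc.screen_reading_frame(make(nt="ATTZTT"))


def test_n_is_never_a_stop():
    rep = qc.screen_reading_frame(make(nt="ATT" + "TNA" * 20 + "ATT"))
    assert rep.stop_codons_in_best_frame == 0


def test_screen_detects_all_planted_defects(small_cohort, rng):
    """Clean simulator output passes; planted stops / frameshifts are all
    caught."""
    records = [
        qc.SequenceRecord(r.record_id, r.bin_id, r.family, nt=r.nt)
        for r in small_cohort.records
    ]
    _, dropped, _ = qc.screen_records(records)
    assert dropped == []
    broken = []
    for rec in records[:50]:
        s = list(rec.nt)
        if rng.random() < 0.5:  # plant an in-frame stop
            pos = 3 * int(rng.integers(5, 100))
            s[pos : pos + 3] = "TAA"
        else:  # break the frame with a 4-nt internal gap
            pos = 3 * int(rng.integers(5, 100))
            s[pos : pos + 4] = "----"
        broken.append(qc.SequenceRecord(rec.record_id, rec.bin_id, rec.family,
                                        nt="".join(s)))
    kept, dropped, _ = qc.screen_records(broken)
    # a single in-frame TAA can be dodged by shifting frame only at the cost
    # of new stops elsewhere, so all planted defects must be detected
    assert kept == [] and len(dropped) == 50


# ------------------------------------------------------------- stratified

def _family(n, fam="F", subfams=None):
    recs = []
    for i in range(n):
        sub = ""
        if subfams:
            # deterministic assignment proportional to subfamily sizes
            acc = 0
            for name, size in subfams.items():
                acc += size
                if i < acc:
                    sub = name
                    break
        recs.append(make(record_id=f"{fam}r{i}", bin_id=f"{fam}b{i}", family=fam,
                         subfamily=sub, nt="ATT"))
    return recs


@pytest.mark.parametrize("n,expected", [(37, 37), (99, 99), (100, 100), (250, 100)])
def test_family_caps(n, expected):
    assert len(qc.stratified_sample(_family(n), seed=1)) == expected


def test_large_family_subfamily_caps():
    recs = _family(1200, subfams={"S1": 900, "S2": 300})
    out = qc.stratified_sample(recs, seed=1)
    by_sub = {}
    for r in out:
        by_sub[r.subfamily] = by_sub.get(r.subfamily, 0) + 1
    assert by_sub == {"S1": 100, "S2": 100}


def test_large_family_missing_subfamily_routed_to_unplaced():
    recs = _family(1100, subfams={"S1": 600})  # 500 records lack a subfamily
    log = []
    out = qc.stratified_sample(recs, seed=1, log=log)
    assert len(out) == 200  # 100 from S1 + 100 from 'unplaced'
    assert any("unplaced" in line for line in log)


def test_sampler_contract_brute_force():
    """Randomised verification of all the stratified-sampling rules plus the
    <3-BIN exclusion over 1000 cohorts."""
    rng = np.random.default_rng(2024)
    for case in range(1000):
        fams = {}
        records = []
        for f in range(int(rng.integers(1, 5))):
            fam = f"F{f}"
            regime = rng.integers(0, 3)
            n = int(
                [rng.integers(1, 100), rng.integers(100, 400),
                 rng.integers(1001, 1400)][regime]
            )
            if regime < 2:
                subfams = None
            else:
                sizes = []
                left = n
                while left > 0:
                    s = int(min(left, rng.integers(20, 400)))
                    sizes.append(s)
                    left -= s
                subfams = {f"S{j}": s for j, s in enumerate(sizes)}
            group = _family(n, fam=fam, subfams=subfams)
            fams[fam] = (n, subfams)
            records.extend(group)
        out = qc.stratified_sample(records, seed=case)
        assert {id(r) for r in out} <= {id(r) for r in records}  # subset
        by_fam = {}
        for r in out:
            by_fam.setdefault(r.family, []).append(r)
        for fam, (n, subfams) in fams.items():
            got = by_fam.get(fam, [])
            if n < 100:
                assert len(got) == n
            elif n <= 1000:
                assert len(got) == 100
            else:
                by_sub = {}
                for r in got:
                    by_sub[r.subfamily] = by_sub.get(r.subfamily, 0) + 1
                for sub, size in subfams.items():
                    assert by_sub.get(sub, 0) == min(size, 100)
        survivors, dropped = qc.exclude_small_families(out, min_bins=3)
        for r in survivors:
            assert len({x.bin_id for x in by_fam[r.family]}) >= 3


# ------------------------------------------------------------- exclusion

def test_exclude_small_families_boundary():
    recs = [make(record_id=f"a{i}", bin_id=f"a{i}", family="A") for i in range(2)]
    recs += [make(record_id=f"b{i}", bin_id=f"b{i}", family="B") for i in range(3)]
    kept, dropped = qc.exclude_small_families(recs)
    assert {r.family for r in kept} == {"B"} and dropped == ["A"]
    assert qc.exclude_small_families([]) == ([], [])


# ------------------------------------------------------------- pipeline order

def test_run_qc_attrition_monotone(small_cohort):
    records = [
        qc.SequenceRecord(r.record_id, r.bin_id, r.family, order=r.order,
                          subfamily=r.subfamily, nt=r.nt)
        for r in small_cohort.records
    ]
    outcome = qc.run_qc(records, seed=0)
    counts = list(outcome.attrition.values())
    assert all(a >= b for a, b in zip(counts, counts[1:]))
    assert outcome.attrition["input"] == len(records)
    # simulated records are clean and families are >= 3 BINs
    assert outcome.attrition["small_family_exclusion"] == len(records)
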