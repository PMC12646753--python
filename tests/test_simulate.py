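"""Synthetic cohort generator: determinism, frame safety, planted structure."""

import json

import dendropy
import numpy as np
import pytest

from coievol import codons
from coievol.consensus import translate_mt_invertebrate
from coievol.simulate import (
    DD,
    HD,
    BinCountDistribution,
    RateModel,
    SimConfig,
    evolve_branch,
    evolve_codon_sequences,
    generate_cohort,
    plant_indels,
    random_root_codons,
    simulate_family_tree,
    tree_to_newick,
)


# ---------------------------------------------------------------- tree

def test_two_families_half_hd():
    tree = simulate_family_tree(2, depth=0.2, hd_fraction=0.5, seed=1)
    classes = sorted(l.branch_class for l in tree.leaf_node_iter())
    assert classes == [DD, HD]


def test_zero_hd_fraction_labels_everything_dd():
    tree = simulate_family_tree(10, depth=0.2, hd_fraction=0.0, seed=1)
    assert all(l.branch_class == DD for l in tree.leaf_node_iter())


def test_tree_is_deterministic_and_ultrametric():
    s1 = tree_to_newick(simulate_family_tree(12, 0.3, 0.5, seed=9))
    s2 = tree_to_newick(simulate_family_tree(12, 0.3, 0.5, seed=9))
    assert s1 == s2
    tree = simulate_family_tree(12, 0.3, 0.5, seed=9)
    assert all(e.length > 0 for e in tree.preorder_edge_iter() if e.length is not None)
    depths = [l.distance_from_root() for l in tree.leaf_node_iter()]
    assert np.allclose(depths, 0.3)


def test_hd_leaves_form_a_clade():
    tree = simulate_family_tree(20, 0.3, 0.35, seed=3)
    hd = {l.taxon.label for l in tree.leaf_node_iter() if l.branch_class == HD}
    assert len(hd) == 7  # round(0.35 * 20)
    mrca = tree.mrca(taxon_labels=sorted(hd))
    assert {l.taxon.label for l in mrca.leaf_iter()} == hd


def test_tree_rejects_tiny_or_invalid_input():
    with pytest.raises(ValueError):
        simulate_family_tree(1, 0.3, 0.5, seed=0)
    with pytest.raises(ValueError):
        simulate_family_tree(5, 0.3, 1.5, seed=0)


# ---------------------------------------------------------------- evolution

def _two_leaf_tree(length_a: float, length_b: float) -> dendropy.Tree:
    tree = dendropy.Tree()
    ns = tree.taxon_namespace
    for label, ln, cls in (("A", length_a, HD), ("B", length_b, DD)):
        child = tree.seed_node.new_child(edge_length=ln)
        child.taxon = ns.require_taxon(label)
        child.branch_class = cls
    tree.is_rooted = True
    return tree


def test_zero_branch_lengths_leave_sequences_unchanged(rng):
    root = random_root_codons(100, rng)
    leaves = evolve_codon_sequences(
        _two_leaf_tree(0.0, 0.0), root, {HD: 0.1, DD: 0.1}, kappa=1.0, seed=4
    )
    assert np.array_equal(leaves["A"], root) and np.array_equal(leaves["B"], root)


def test_omega_zero_forbids_nonsynonymous_change(rng):
    root = random_root_codons(150, rng)
    leaves = evolve_codon_sequences(
        _two_leaf_tree(0.5, 0.5), root, {HD: 0.0, DD: 0.0}, kappa=2.0, seed=4
    )
    root_aa = translate_mt_invertebrate(codons.decode_codons(root))
    for seq in leaves.values():
        assert (seq != root).any()  # substitutions did happen
        assert translate_mt_invertebrate(codons.decode_codons(seq)) == root_aa


def test_root_with_stop_rejected():
    bad = np.array([codons.codon_index("TAA")] * 10)
    with pytest.raises(ValueError):
        evolve_codon_sequences(_two_leaf_tree(0.1, 0.1), bad, {HD: 1, DD: 1}, 1.0, 0)


def test_evolution_never_introduces_stops(rng):
    """Frame safety asserted over >= 10^4 simulated sequences."""
    total = 0
    for seed in range(10):
        cfg = SimConfig(
            n_families=110,
            bins_per_family=BinCountDistribution(8, 12, 0.5),
            tree_depth=0.4,
            indel_rate=0.2,
            seed=1000 + seed,
        )
        cohort = generate_cohort(cfg)
        for rec in cohort.records:
            aa = translate_mt_invertebrate(rec.nt)
            assert "*" not in aa, rec.record_id
        total += len(cohort.records)
    assert total >= 10_000


def test_branch_length_calibration(rng):
    """At omega=1, kappa=1 the realised substitutions per site approximate
    the branch length (stop rejection removes only a small fraction)."""
    model = RateModel(omega=1.0, kappa=1.0)
    root = random_root_codons(2000, rng)
    t = 0.05
    evolved = evolve_branch(root, t, model, rng)
    frac = (evolved != root).mean()  # codon-level change fraction ~ 3t at small t
    assert 0.8 * 3 * t < frac < 1.1 * 3 * t


# ---------------------------------------------------------------- indels

def _toy_alignment(rng, n_fams=6, n_codons=220):
    return {
        f"F{i:02d}": rng.choice(codons.SENSE_INDICES, size=n_codons)
        for i in range(n_fams)
    }


def test_plant_indels_rate_zero_is_identity(rng):
    aln = _toy_alignment(rng)
    out, events, trims = plant_indels(aln, rate=0.0, seed=1)
    assert events == [] and trims == {}
    for fam in aln:
        assert np.array_equal(out[fam], aln[fam])


def test_single_deletion_arithmetic(rng):
    aln = _toy_alignment(rng)
    out, events, trims = plant_indels(aln, rate=0.25, deletion_fraction=1.0, seed=3)
    assert events and all(e.type == "deletion" for e in events)
    deleted = {}
    for e in events:
        deleted[e.family] = deleted.get(e.family, 0) + e.length
    for fam, arr in out.items():
        expect = 220 - deleted.get(fam, 0)
        assert int((arr != codons.GAP).sum()) == expect


def test_deletion_insertion_ratio_binomial(rng):
    """deletion_fraction=2/3 over ~60 events: realised deletion count within
    the central 99.9% binomial band."""
    from scipy import stats

    aln = _toy_alignment(rng, n_fams=60)
    out, events, _ = plant_indels(aln, rate=1.0, deletion_fraction=2 / 3, seed=11)
    n = len(events)
    dels = sum(1 for e in events if e.type == "deletion")
    lo, hi = stats.binom.ppf([0.0005, 0.9995], n, 2 / 3)
    assert lo <= dels <= hi
    assert n >= 40


def test_plant_indels_refuses_excessive_rate(rng):
    with pytest.raises(ValueError, match="length bounds"):
        plant_indels(_toy_alignment(rng), rate=5.0, seed=0)
    with pytest.raises(ValueError):
        plant_indels(_toy_alignment(rng), rate=0.5, length_set=(3,), seed=0)


def test_planted_gaps_are_codon_aligned_and_explained(indel_cohort):
    """Every internal gap in the emitted alignment is explained by exactly
    one truth event (terminal trims accounted separately)."""
    truth = indel_cohort.truth
    events = truth["events"]
    by_family: dict[str, list] = {}
    for e in events:
        by_family.setdefault(e["family"], []).append(e)
    # one representative record per family shares the family gap pattern
    rep = {}
    for rec in indel_cohort.records:
        rep.setdefault(rec.family, rec.nt)
    for fam, nt in rep.items():
        cells = [nt[i : i + 3] for i in range(0, len(nt), 3)]
        assert all(c == "---" or "-" not in c for c in cells)  # codon-aligned
        n = len(cells)
        first = next(i for i, c in enumerate(cells) if c != "---")
        last = n - next(i for i, c in enumerate(reversed(cells)) if c != "---")
        internal_gaps = {i for i in range(first, last) if cells[i] == "---"}
        explained = set()
        for e in by_family.get(fam, []):
            if e["type"] == "deletion":
                span = range(e["position"] - 1, e["position"] - 1 + e["length"])
                assert explained.isdisjoint(span)
                explained.update(span)
        # gaps not explained by own deletions must be other families' insertions
        ins_cols = set()
        for e in events:
            if e["type"] == "insertion" and e["family"] != fam:
                ins_cols.update(range(e["position"] - 1, e["position"] - 1 + e["length"]))
        assert internal_gaps - ins_cols == explained & internal_gaps
        assert explained <= internal_gaps


# ---------------------------------------------------------------- cohort

def test_cohort_counts_and_lengths(small_cohort):
    assert len(small_cohort.records) == 20 * 5
    assert len(small_cohort.outgroups) == 2
    for rec in small_cohort.records:
        assert 643 <= len(rec.nt.replace("-", "")) <= 661


def test_cohort_reproduction_matches_tree_classes(small_cohort):
    cls = small_cohort.truth["class_by_family"]
    for rec in small_cohort.records:
        assert rec.reproduction == cls[rec.family]


def test_generate_cohort_is_byte_identical(tmp_path):
    cfg = SimConfig(n_families=5, bins_per_family=BinCountDistribution(3, 4, 0.0),
                    indel_rate=0.3, seed=17)
    a, b = tmp_path / "a", tmp_path / "b"
    generate_cohort(cfg, outdir=a)
    generate_cohort(cfg, outdir=b)
    for name in ("records.fasta", "outgroups.fasta", "taxonomy.tsv", "tree.nwk",
                 "truth.json"):
        assert (a / name).read_bytes() == (b / name).read_bytes()


def test_truth_json_roundtrip(tmp_path, small_cohort):
    path = tmp_path / "truth.json"
    path.write_text(json.dumps(small_cohort.truth, sort_keys=True))
    assert json.loads(path.read_text()) == json.loads(
        json.dumps(small_cohort.truth, sort_keys=True)
    )


def test_distant_outgroups_exceed_ingroup_divergence():
    """With outgroup branches 3x the tree depth, every family is farther
    from the outgroup than from any other family."""
    cfg = SimConfig(
        n_families=10,
        bins_per_family=BinCountDistribution(3, 3, 0.0),
        tree_depth=0.1,
        outgroup_branch_length=0.6,  # + depth -> ~2x any ingroup path
        indel_rate=0.0,
        seed=23,
    )
    cohort = generate_cohort(cfg)
    rep = {}
    for rec in cohort.records:
        rep.setdefault(rec.family, rec.nt)
    og = next(iter(cohort.outgroups.values()))

    def diffs(x, y):
        return sum(a != b for a, b in zip(x, y) if a != "-" and b != "-")

    fams = sorted(rep)
    max_ingroup = max(
        diffs(rep[a], rep[b]) for i, a in enumerate(fams) for b in fams[i + 1 :]
    )
    for fam in fams:
        assert diffs(rep[fam], og) > max_ingroup
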