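"""Amino-acid indel calling and parsimony-minimal event counting.

Indels are called per family by comparing the family's aligned amino-acid
consensus with the overall insect consensus: a maximal run where the family
is gapped but the reference has residues is a deletion; residues opposite
reference gaps are an insertion.  Terminal gap runs are treated as missing
coverage, not deletions.  Two families share an *event key* only when start
position, length and type all coincide (a deliberately conservative
identity).  For each key, presence/absence across the leaves of the family
tree is a binary character whose minimal number of origins is computed by
small-parsimony dynamic programming with the root fixed to "absent" (the
reference state); a gains-only Dollo variant is available.

Coordinates are 1-based codon columns of the shared alignment (identical to
positions in the insect-consensus frame wherever no insertion column
precedes the call).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy

from .consensus import _AA20

INSERTION = "insertion"
DELETION = "deletion"
CANONICAL_LENGTHS = (1, 2)


@dataclass(frozen=True)
class IndelKey:
    position: int  # 1-based codon column of the first affected column
    length: int  # codons
    type: str  # insertion | deletion


@dataclass
class IndelEvent:
    key: IndelKey
    carriers: set[str] = field(default_factory=set)
    inferred_events: int | None = None

    @property
    def canonical(self) -> bool:
        return self.key.length in CANONICAL_LENGTHS


def call_indels(family_aa: str, reference_aa: str) -> list[IndelKey]:
    """Indel calls for one family consensus against the reference consensus.

    Both sequences must share one alignment coordinate system.  Deletion
    runs may be interrupted by columns where the reference is also gapped
    (insertion columns of other families); those columns are ignored, and
    only reference-residue columns count toward the deletion length.
    Leading and trailing family gap runs are never called.
    """
    if len(family_aa) != len(reference_aa):
        raise ValueError(
            f"aligned lengths differ: {len(family_aa)} vs {len(reference_aa)}"
        )
    n = len(family_aa)
    first = n - len(family_aa.lstrip("-"))
    last = len(family_aa.rstrip("-"))  # exclusive
    calls: list[IndelKey] = []

    # deletions: maximal family-gap runs within [first, last)
    i = first
    while i < last:
        if family_aa[i] == "-":
            j = i
            while j < last and family_aa[j] == "-":
                j += 1
            ref_cols = [k for k in range(i, j) if reference_aa[k] != "-"]
            if ref_cols:
                calls.append(IndelKey(ref_cols[0] + 1, len(ref_cols), DELETION))
            i = j
        else:
            i += 1

    # insertions: maximal runs where the family has residues and the
    # reference is gapped
    i = 0
    while i < n:
        if reference_aa[i] == "-" and family_aa[i] != "-":
            j = i
            while j < n and reference_aa[j] == "-" and family_aa[j] != "-":
                j += 1
            calls.append(IndelKey(i + 1, j - i, INSERTION))
            i = j
        else:
            i += 1
    calls.sort(key=lambda k: (k.position, k.type))
    return calls


def collect_events(
    calls_by_family: Mapping[str, Sequence[IndelKey]]
) -> list[IndelEvent]:
    """Group per-family calls into shared events by exact key identity."""
    events: dict[IndelKey, IndelEvent] = {}
    for family, calls in calls_by_family.items():
        for key in calls:
            events.setdefault(key, IndelEvent(key=key)).carriers.add(family)
    return sorted(
        events.values(), key=lambda e: (e.key.position, e.key.type, e.key.length)
    )


def classify_indels(
    events: Iterable[IndelEvent],
    class_by_family: Mapping[str, str] | None = None,
    order_by_family: Mapping[str, str] | None = None,
) -> dict:
    """Summary counts by type and length, with optional per-class (HD/DD)
    and per-order roll-ups of family-level indel carriage."""
    events = list(events)
    by_type = Counter(e.key.type for e in events)
    by_length = Counter(e.key.length for e in events)
    summary = {
        "total": len(events),
        "insertion": by_type.get(INSERTION, 0),
        "deletion": by_type.get(DELETION, 0),
        "by_length": {str(k): by_length[k] for k in sorted(by_length)},
        "non_canonical": sum(1 for e in events if not e.canonical),
    }
    if class_by_family is not None:
        per_class: Counter = Counter()
        for e in events:
            for fam in e.carriers:
                per_class[class_by_family.get(fam, "?")] += 1
        summary["carriage_by_class"] = dict(sorted(per_class.items()))
    if order_by_family is not None:
        per_order: Counter = Counter()
        for e in events:
            for fam in e.carriers:
                per_order[order_by_family.get(fam, "?")] += 1
        summary["carriage_by_order"] = dict(sorted(per_order.items()))
    return summary


def _min_changes(
    tree: dendropy.Tree,
    present: set[str],
    root_state: int | None = 0,
    gain_only: bool = False,
) -> int:
    """Small-parsimony cost of a binary presence/absence character.

    Dynamic programming over the rooted tree (Sankoff): cost[v][s] is the
    minimal number of state changes in the subtree of v given state s at v.
    root_state=0 fixes absence at the root; gain_only forbids 1->0 changes
    (Dollo-style, gains only).
    """
    INF = float("inf")
    leaf_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = present - leaf_labels
    if missing:
        raise KeyError(f"carrier families absent from the tree: {sorted(missing)}")

    cost: dict[int, tuple[float, float]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            state = 1 if node.taxon.label in present else 0
            cost[id(node)] = (0.0 if state == 0 else INF, 0.0 if state == 1 else INF)
        else:
            c0 = c1 = 0.0
            for child in node.child_nodes():
                k0, k1 = cost[id(child)]
                # transition costs: stay free, change costs 1; 1->0 forbidden
                # under gain_only
                c0 += min(k0, k1 + 1.0)
                c1 += min(k1, k0 + (INF if gain_only else 1.0))
            cost[id(node)] = (c0, c1)
    r0, r1 = cost[id(tree.seed_node)]
    if root_state is None:
        best = min(r0, r1)
    else:
        best = (r0, r1)[root_state]
    if best == INF:
        raise ValueError("character has no admissible history under the constraints")
    return int(best)


def min_event_count(
    events: Iterable[IndelEvent],
    tree: dendropy.Tree,
    class_by_family: Mapping[str, str] | None = None,
    gain_only: bool = False,
) -> dict:
    """Parsimony-minimal event counts per indel key and overall.

    Each key's carriers form a binary character; the minimal number of
    changes on the tree (absence ancestral) is its event count.  When class
    labels are supplied, per-class minima are computed on each class's
    carrier subset so the HD/DD split sums to interpretable totals.
    """
    events = list(events)
    per_key = {}
    total = 0
    by_class: Counter = Counter()
    for e in events:
        n = _min_changes(tree, e.carriers, root_state=0, gain_only=gain_only)
        e.inferred_events = n
        per_key[e.key] = n
        total += n
        if class_by_family is not None:
            carriers_by_class: dict[str, set[str]] = {}
            for fam in e.carriers:
                carriers_by_class.setdefault(class_by_family.get(fam, "?"), set()).add(fam)
            for cls, carriers in carriers_by_class.items():
                by_class[cls] += _min_changes(
                    tree, carriers, root_state=0, gain_only=gain_only
                )
    out = {"per_key": per_key, "total": total}
    if class_by_family is not None:
        out["by_class"] = dict(sorted(by_class.items()))
    return out
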