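"""Germline-rooted lineage trees from V-region mutation sets.

Each distinct mutation set among a clone's unique sequences becomes a
populated node; unpopulated ancestors are inferred at set intersections
where the containment order requires them.  Every root-to-node path is a
strictly increasing chain of mutation sets, with the empty set (germline)
at the root.  Nodes carry a tissue-label multiset with one entry per
observed instance of the genotype.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterator, Mapping

from clonotrack.airr_io import Tissue
from clonotrack.clonal import Clone

_MUTATION_RE = re.compile(r"^(\d+)([A-Za-z])>([A-Za-z])$")


def parse_mutation(identifier: str) -> tuple[int, str, str]:
    """Split an identifier like ``"45A>G"`` into (position, germline, observed)."""
    m = _MUTATION_RE.match(identifier)
    if not m:
        raise ValueError(f"malformed mutation identifier {identifier!r}")
    return int(m.group(1)), m.group(2), m.group(3)


@dataclass
class LineageNode:
    node_id: int
    mutation_set: frozenset[str]
    populated: bool
    labels: Counter = field(default_factory=Counter)
    children: list["LineageNode"] = field(default_factory=list)

    def walk(self) -> Iterator["LineageNode"]:
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class LineageTree:
    clone_id: int
    root: LineageNode

    def nodes(self) -> list[LineageNode]:
        return list(self.root.walk())


def _check_consistent(mutation_set: frozenset[str], owner: str) -> None:
    positions: dict[int, str] = {}
    for mut in mutation_set:
        pos, _, _ = parse_mutation(mut)
        if pos in positions and positions[pos] != mut:
            raise ValueError(
                f"{owner}: conflicting mutation identifiers at position {pos}: "
                f"{positions[pos]!r} vs {mut!r}"
            )
        positions[pos] = mut


def _set_key(s: frozenset[str]) -> tuple[str, ...]:
    return tuple(sorted(s))


def build_lineage(
    clone: Clone, sample_tissue: Mapping[str, Tissue] | None = None
) -> LineageTree:
    """Build the mutation-containment lineage tree of a clone.

    Unique sequences with identical mutation sets share one populated node
    and pool their labels (one label per (sequence, sample) instance, from
    ``sample_tissue``; omitted instances carry no label).  Inferred ancestors
    are the intersections needed to keep the containment relation a tree:
    the family of sets is closed under pairwise intersection, each node's
    parent is its largest strict subset in the family (ties broken
    lexicographically), and unpopulated non-root nodes with fewer than two
    children are spliced out.  The construction is invariant under member
    permutation; children are ordered by mutation-set lexicographic order.
    """
    # genotype -> labels; each member row is one instance
    genotype_labels: dict[frozenset[str], Counter] = {}
    seen_instances: set[tuple[str, str]] = set()
    for m in clone.members:
        if m.v_mutation_set is None:
            raise ValueError(
                f"clone {clone.clone_id}: member {m.sequence_id} lacks a mutation set"
            )
        _check_consistent(m.v_mutation_set, f"clone {clone.clone_id}/{m.sequence_id}")
        key = (m.sequence_id, m.sample_id)
        if key in seen_instances:
            continue
        seen_instances.add(key)
        labels = genotype_labels.setdefault(m.v_mutation_set, Counter())
        if sample_tissue is not None and m.sample_id in sample_tissue:
            labels[sample_tissue[m.sample_id]] += 1

    observed = set(genotype_labels)
    family: set[frozenset[str]] = set(observed)
    family.add(frozenset())
    # close under pairwise intersection (fixpoint; clones are small)
    changed = True
    while changed:
        changed = False
        current = sorted(family, key=_set_key)
        for i in range(len(current)):
            for j in range(i + 1, len(current)):
                inter = current[i] & current[j]
                if inter not in family:
                    family.add(inter)
                    changed = True

    # parent = largest strict subset in the family, lexicographic tie-break
    ordered = sorted(family, key=lambda s: (len(s), _set_key(s)))
    parent_of: dict[frozenset[str], frozenset[str]] = {}
    for s in ordered:
        if not s:
            continue
        candidates = [t for t in family if t < s]
        best_len = max(len(t) for t in candidates)
        parent_of[s] = min((t for t in candidates if len(t) == best_len), key=_set_key)

    children_of: dict[frozenset[str], list[frozenset[str]]] = {s: [] for s in family}
    for s, p in parent_of.items():
        children_of[p].append(s)

    # splice unpopulated internal nodes with a single child; drop childless
    # unpopulated non-root nodes (intersection artifacts)
    def prune() -> bool:
        for s in list(children_of):
            if not s or s in observed or s not in children_of:
                continue
            kids = children_of[s]
            parent = parent_of[s]
            if len(kids) <= 1:
                children_of[parent].remove(s)
                for kid in kids:
                    parent_of[kid] = parent
                    children_of[parent].append(kid)
                del children_of[s]
                del parent_of[s]
                return True
        return False

    while prune():
        pass

    def build(s: frozenset[str], counter: Iterator[int]) -> LineageNode:
        node = LineageNode(
            node_id=next(counter),
            mutation_set=s,
            populated=s in observed,
            labels=Counter(genotype_labels.get(s, Counter())),
        )
        for child_set in sorted(children_of.get(s, []), key=_set_key):
            node.children.append(build(child_set, counter))
        return node

    root = build(frozenset(), iter(range(len(children_of) + 1)))
    return LineageTree(clone_id=clone.clone_id, root=root)


def populated_node_count(tree: LineageTree) -> int:
    """Number of nodes populated by at least one observed unique sequence."""
    return sum(1 for node in tree.root.walk() if node.populated)


def to_newick(tree: LineageTree) -> str:
    """Serialize as Newick with node comments carrying the populated flag and
    tissue-label multiset, e.g. ``n3[&populated=1,labels=blood:2|ileum:1]``."""

    def comment(node: LineageNode) -> str:
        labels = "|".join(
            f"{t.value}:{n}" for t, n in sorted(node.labels.items(), key=lambda kv: kv[0].value)
        )
        return f"[&populated={int(node.populated)},labels={labels}]"

    def render(node: LineageNode) -> str:
        name = f"n{node.node_id}{comment(node)}"
        if not node.children:
            return name
        inner = ",".join(render(c) for c in node.children)
        return f"({inner}){name}"

    return render(tree.root) + ";"


def lineage_nodes_table(tree: LineageTree) -> list[dict]:
    """Flat per-node rows (for the nodes TSV report)."""
    rows = []
    parent_ids = {}
    for node in tree.root.walk():
        for child in node.children:
            parent_ids[child.node_id] = node.node_id
    for node in tree.root.walk():
        rows.append(
            {
                "clone_id": tree.clone_id,
                "node_id": node.node_id,
                "parent_id": parent_ids.get(node.node_id, ""),
                "n_mutations": len(node.mutation_set),
                "mutations": ",".join(sorted(node.mutation_set)),
                "populated": int(node.populated),
                "labels": "|".join(
                    f"{t.value}:{n}"
                    for t, n in sorted(node.labels.items(), key=lambda kv: kv[0].value)
                ),
            }
        )
    return rows
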