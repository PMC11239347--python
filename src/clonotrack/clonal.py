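"""Clonal grouping and per-clone filters and classifications.

Sequences sharing V gene, J gene and CDR3 length are clustered by
single-linkage on CDR3 amino-acid identity with a join threshold of 85%.
On top of the resulting clones this module provides the published filters:
detectability (a productive member with copy number >= 2 in a tissue),
per-bracket clone size in unique instances, the >2% mutated-clone
classification, trunk-clone detection (>= 5 mutations shared by >= 85% of
unique sequences), and the >= k unique-sequences / both-tissues filter used
for lineage-mixing analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

from clonotrack.airr_io import SampleMeta, SequenceRecord, Tissue
from clonotrack.stats import Bracket, assign_bracket

logger = logging.getLogger(__name__)

#: Published clone-definition and filter defaults.
DEFAULT_IDENTITY_THRESHOLD = 0.85
DEFAULT_MIN_COPY_NUMBER = 2
DEFAULT_MUTATED_CUTOFF = 0.02
DEFAULT_TRUNK_MIN_MUTATIONS = 5
DEFAULT_TRUNK_MIN_SHARE = 0.85
DEFAULT_MIN_UNIQUE_SEQUENCES = 3


@dataclass(frozen=True)
class Clone:
    """A set of rearrangements presumed descended from one ancestor."""

    clone_id: int
    v_gene: str
    j_gene: str
    cdr3_length: int
    members: tuple[SequenceRecord, ...]

    def unique_sequence_ids(self) -> set[str]:
        """Distinct unique (nucleotide-collapsed) sequences in the clone."""
        return {m.sequence_id for m in self.members}

    def instances(self) -> set[tuple[str, str]]:
        """Distinct (sequence_id, sample_id) occurrences — the size unit."""
        return {(m.sequence_id, m.sample_id) for m in self.members}

    def tissues_detected(self, sample_tissue: Mapping[str, Tissue]) -> set[Tissue]:
        return {sample_tissue[m.sample_id] for m in self.members if m.sample_id in sample_tissue}


@dataclass(frozen=True)
class CloneBracketSize:
    """Clone size (unique instances) within one patient/tissue/time bracket."""

    clone_id: int
    patient_id: str
    tissue: Tissue
    bracket: Bracket
    size: int


def cdr3_identity(a: str, b: str) -> float:
    """Fraction of matching positions between two equal-length CDR3s."""
    if len(a) != len(b):
        raise ValueError("CDR3 identity requires equal lengths")
    if not a:
        raise ValueError("empty CDR3")
    return sum(x == y for x, y in zip(a, b)) / len(a)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def group_clones(
    records: Sequence[SequenceRecord], threshold: float = DEFAULT_IDENTITY_THRESHOLD
) -> list[Clone]:
    """Partition records into clones.

    Records are bucketed by (V gene, J gene, CDR3 length); within a bucket,
    single-linkage clustering joins two sequences when their CDR3 amino-acid
    identity is >= ``threshold``.  The partition, member ordering and clone
    ids are independent of the input order.  Records with an empty CDR3 are
    excluded with a logged tally.
    """
    usable = []
    n_excluded = 0
    for r in records:
        if not r.cdr3_aa:
            n_excluded += 1
            continue
        usable.append(r)
    if n_excluded:
        logger.warning("excluded %d records with empty CDR3 from clone grouping", n_excluded)

    buckets: dict[tuple[str, str, int], list[SequenceRecord]] = {}
    for r in usable:
        buckets.setdefault((r.v_call, r.j_call, r.cdr3_length), []).append(r)

    raw_clones: list[tuple[tuple, list[SequenceRecord]]] = []
    for (v, j, length), bucket in buckets.items():
        # sort for order-independence of the union-find tie-breaking
        bucket = sorted(bucket, key=lambda r: (r.sequence_id, r.sample_id))
        uf = _UnionFind(len(bucket))
        # distinct CDR3 strings only: identical CDR3s always co-cluster
        for i in range(len(bucket)):
            for k in range(i + 1, len(bucket)):
                if cdr3_identity(bucket[i].cdr3_aa, bucket[k].cdr3_aa) >= threshold:
                    uf.union(i, k)
        groups: dict[int, list[SequenceRecord]] = {}
        for idx, r in enumerate(bucket):
            groups.setdefault(uf.find(idx), []).append(r)
        for members in groups.values():
            key = (v, j, length, members[0].sequence_id, members[0].sample_id)
            raw_clones.append((key, members))

    raw_clones.sort(key=lambda kv: kv[0])
    clones = []
    for clone_id, ((v, j, length, _, _), members) in enumerate(raw_clones, start=1):
        clones.append(
            Clone(
                clone_id=clone_id,
                v_gene=v,
                j_gene=j,
                cdr3_length=length,
                members=tuple(members),
            )
        )
    return clones


def mutation_fraction(record: SequenceRecord) -> float:
    """V-gene mutation frequency: mutation count over sequenced V length."""
    if record.v_sequenced_length <= 0:
        raise ValueError(f"{record.sequence_id}: v_sequenced_length must be positive")
    return record.v_mutation_count / record.v_sequenced_length


def clone_mutation_fraction(clone: Clone) -> float:
    """Unweighted mean mutation fraction over the clone's unique instances.

    Each distinct (sequence, sample) occurrence contributes once; copy
    numbers do not weight the average.
    """
    seen: set[tuple[str, str]] = set()
    fractions = []
    for m in clone.members:
        key = (m.sequence_id, m.sample_id)
        if key in seen:
            continue
        seen.add(key)
        fractions.append(mutation_fraction(m))
    if not fractions:
        raise ValueError(f"clone {clone.clone_id} has no members")
    return sum(fractions) / len(fractions)


def is_mutated_clone(clone: Clone, cutoff: float = DEFAULT_MUTATED_CUTOFF) -> bool:
    """True iff the clone's average V mutation frequency strictly exceeds 2%."""
    return clone_mutation_fraction(clone) > cutoff


def is_detectable(
    clone: Clone,
    tissue: Tissue,
    sample_tissue: Mapping[str, Tissue],
    min_copies: int = DEFAULT_MIN_COPY_NUMBER,
) -> bool:
    """True iff the clone has a functional sequence with copy number >= 2 there.

    "Functional" means the productive flag is set.  ``sample_tissue`` maps
    sample ids to tissues (see :func:`clonotrack.airr_io.sample_tissue_map`).
    """
    for m in clone.members:
        if (
            sample_tissue.get(m.sample_id) == tissue
            and m.productive
            and m.copy_number >= min_copies
        ):
            return True
    return False


def clone_bracket_sizes(
    clones: Iterable[Clone],
    metadata: Sequence[SampleMeta],
    bracket_fn: Callable[[int], Bracket] = assign_bracket,
) -> list[CloneBracketSize]:
    """Clone sizes per (patient, tissue, time bracket).

    Size is the number of distinct (sequence_id, sample_id) instances of the
    clone among all samples of that patient/tissue falling in the bracket.
    Empty cells are omitted.  An instance whose sample id is not in
    ``metadata`` is a hard error.
    """
    meta_by_id = {m.sample_id: m for m in metadata}
    rows: list[CloneBracketSize] = []
    for clone in clones:
        cells: dict[tuple[str, Tissue, Bracket], set[tuple[str, str]]] = {}
        for seq_id, sample_id in clone.instances():
            meta = meta_by_id.get(sample_id)
            if meta is None:
                raise ValueError(
                    f"clone {clone.clone_id}: sample_id {sample_id!r} not found in metadata"
                )
            key = (meta.patient_id, meta.tissue, bracket_fn(meta.pod))
            cells.setdefault(key, set()).add((seq_id, sample_id))
        for (patient, tissue, bracket), instances in sorted(
            cells.items(), key=lambda kv: (kv[0][0], kv[0][1].value, kv[0][2].value)
        ):
            rows.append(
                CloneBracketSize(
                    clone_id=clone.clone_id,
                    patient_id=patient,
                    tissue=tissue,
                    bracket=bracket,
                    size=len(instances),
                )
            )
    return rows


def is_trunk_clone(
    clone: Clone,
    min_mutations: int = DEFAULT_TRUNK_MIN_MUTATIONS,
    min_share: float = DEFAULT_TRUNK_MIN_SHARE,
) -> bool:
    """True iff >= 5 distinct mutations are each shared by >= 85% of the
    clone's unique sequences (evidence of a common mutated ancestor)."""
    seq_sets: dict[str, frozenset[str]] = {}
    for m in clone.members:
        if m.v_mutation_set is None:
            raise ValueError(
                f"clone {clone.clone_id}: member {m.sequence_id} lacks a mutation set"
            )
        seq_sets.setdefault(m.sequence_id, m.v_mutation_set)
    n_seqs = len(seq_sets)
    counts: dict[str, int] = {}
    for mutset in seq_sets.values():
        for mut in mutset:
            counts[mut] = counts.get(mut, 0) + 1
    n_shared = sum(1 for c in counts.values() if c / n_seqs >= min_share)
    return n_shared >= min_mutations


def min_unique_sequences_filter(
    clones: Iterable[Clone],
    k: int = DEFAULT_MIN_UNIQUE_SEQUENCES,
    tissues: tuple[Tissue, Tissue] | None = None,
    sample_tissue: Mapping[str, Tissue] | None = None,
) -> list[Clone]:
    """Keep clones with >= k unique sequences, sampled in both given tissues.

    When ``tissues`` is provided, ``sample_tissue`` must map every member's
    sample to its tissue and the clone must have at least one unique sequence
    in each of the two tissues.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if tissues is not None and sample_tissue is None:
        raise ValueError("sample_tissue mapping required when tissues are given")
    kept = []
    for clone in clones:
        if len(clone.unique_sequence_ids()) < k:
            continue
        if tissues is not None:
            present = clone.tissues_detected(sample_tissue)
            if not (tissues[0] in present and tissues[1] in present):
                continue
        kept.append(clone)
    return kept
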