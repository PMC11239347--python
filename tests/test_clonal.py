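import random

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonotrack.airr_io import Tissue
from clonotrack.clonal import (
    cdr3_identity,
    clone_bracket_sizes,
    clone_mutation_fraction,
    group_clones,
    is_detectable,
    is_mutated_clone,
    is_trunk_clone,
    min_unique_sequences_filter,
    mutation_fraction,
)
from clonotrack.stats import Bracket

from .conftest import make_clone, make_meta, make_record

AA = "ACDEFGHIKLMNPQRSTVWY"


def mutate(cdr3, positions, to="W"):
    chars = list(cdr3)
    for p in positions:
        chars[p] = to if chars[p] != to else "Y"
    return "".join(chars)


def brute_force_partition(records, threshold):
    """Independent oracle: connected components of the pairwise >=threshold graph."""
    g = nx.Graph()
    g.add_nodes_from(range(len(records)))
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            a, b = records[i], records[j]
            if (a.v_call, a.j_call, a.cdr3_length) != (b.v_call, b.j_call, b.cdr3_length):
                continue
            ident = sum(x == y for x, y in zip(a.cdr3_aa, b.cdr3_aa)) / a.cdr3_length
            if ident >= threshold:
                g.add_edge(i, j)
    return {
        frozenset((records[i].sequence_id, records[i].sample_id) for i in comp)
        for comp in nx.connected_components(g)
    }


def partition_keys(clones):
    return {frozenset((m.sequence_id, m.sample_id) for m in c.members) for c in clones}


class TestGroupClones:
    def test_identical_cdr3_one_clone(self):
        records = [
            make_record(sequence_id="S1", cdr3_aa="CARDYWGQGTLVT"),
            make_record(sequence_id="S2", cdr3_aa="CARDYWGQGTLVT"),
        ]
        assert len(group_clones(records)) == 1

    def test_85_percent_boundary(self):
        base = "CARDYWGQGTLVTVSSAAAA"  # 20 aa
        three = mutate(base, [5, 10, 15])  # 17/20 = 85%
        four = mutate(base, [5, 10, 15, 18])  # 16/20 = 80%
        r0 = make_record(sequence_id="S1", cdr3_aa=base)
        assert len(group_clones([r0, make_record(sequence_id="S2", cdr3_aa=three)])) == 1
        assert len(group_clones([r0, make_record(sequence_id="S2", cdr3_aa=four)])) == 2

    def test_different_j_gene_splits(self):
        records = [
            make_record(sequence_id="S1", j_call="IGHJ4"),
            make_record(sequence_id="S2", j_call="IGHJ6"),
        ]
        assert len(group_clones(records)) == 2

    def test_matches_brute_force_oracle_random_buckets(self):
        rng = random.Random(42)
        for _ in range(30):
            base = "".join(rng.choice(AA) for _ in range(16))
            records = []
            for i in range(rng.randint(2, 20)):
                n_mut = rng.randint(0, 6)
                cdr3 = mutate(base, rng.sample(range(16), n_mut), to=rng.choice(AA))
                records.append(make_record(sequence_id=f"S{i}", cdr3_aa=cdr3))
            clones = group_clones(records)
            assert partition_keys(clones) == brute_force_partition(records, 0.85)

    def test_is_partition(self):
        rng = random.Random(0)
        records = [
            make_record(
                sequence_id=f"S{i}",
                cdr3_aa="".join(rng.choice(AA) for _ in range(13)),
                j_call=rng.choice(["IGHJ4", "IGHJ6"]),
            )
            for i in range(40)
        ]
        clones = group_clones(records)
        assert sum(len(c.members) for c in clones) == len(records)
        assert len({m for c in clones for m in c.members}) == len(records)

    @given(st.randoms(use_true_random=False))
    @settings(max_examples=25, deadline=None)
    def test_permutation_invariant(self, rnd):
        base = "CARDYWGQGTLVTVSS"
        records = [
            make_record(sequence_id=f"S{i}", cdr3_aa=mutate(base, list(range(i % 5))))
            for i in range(12)
        ]
        shuffled = records[:]
        rnd.shuffle(shuffled)
        assert partition_keys(group_clones(records)) == partition_keys(group_clones(shuffled))

    def test_threshold_monotone_refinement(self):
        rng = random.Random(7)
        base = "CARDYWGQGTLVTVSS"
        records = [
            make_record(sequence_id=f"S{i}", cdr3_aa=mutate(base, rng.sample(range(16), rng.randint(0, 5)), to=rng.choice(AA)))
            for i in range(15)
        ]
        loose = partition_keys(group_clones(records, threshold=0.75))
        strict = partition_keys(group_clones(records, threshold=0.90))
        # raising the threshold only refines: every strict clone fits in one loose clone
        for s in strict:
            assert any(s <= l for l in loose)

    def test_empty_cdr3_excluded(self, caplog):
        records = [make_record(sequence_id="S1"), make_record(sequence_id="S2", cdr3_aa="")]
        with caplog.at_level("WARNING"):
            clones = group_clones(records)
        assert sum(len(c.members) for c in clones) == 1


class TestMutationFraction:
    def test_arithmetic(self):
        assert mutation_fraction(make_record(v_mutation_count=6, v_sequenced_length=300)) == 0.02

    def test_zero(self):
        assert mutation_fraction(make_record(v_mutation_count=0)) == 0.0

    def test_upper_bound(self):
        r = make_record(v_mutation_count=300, v_sequenced_length=300)
        assert mutation_fraction(r) == 1.0

    def test_clone_average(self):
        clone = make_clone(
            [
                make_record(sequence_id="S1", v_mutation_count=3, v_sequenced_length=300),
                make_record(sequence_id="S2", v_mutation_count=9, v_sequenced_length=300),
            ]
        )
        assert clone_mutation_fraction(clone) == pytest.approx(0.02)

    def test_single_instance(self):
        clone = make_clone([make_record(v_mutation_count=15, v_sequenced_length=300)])
        assert clone_mutation_fraction(clone) == pytest.approx(0.05)

    def test_clone_average_matches_brute_force(self):
        rng = random.Random(3)
        members = [
            make_record(sequence_id=f"S{i}", v_mutation_count=rng.randint(0, 30))
            for i in range(10)
        ]
        clone = make_clone(members)
        expected = sum(m.v_mutation_count / 270 for m in members) / 10
        assert clone_mutation_fraction(clone) == pytest.approx(expected)

    def test_copy_number_does_not_weight(self):
        clone = make_clone(
            [
                make_record(sequence_id="S1", copy_number=100, v_mutation_count=0),
                make_record(sequence_id="S2", copy_number=1, v_mutation_count=27),
            ]
        )
        assert clone_mutation_fraction(clone) == pytest.approx(13.5 / 270)


class TestIsMutated:
    @pytest.mark.parametrize(
        "muts,expected", [(21, True), (20, False), (0, False)]
    )
    def test_strict_two_percent_boundary(self, muts, expected):
        clone = make_clone([make_record(v_mutation_count=muts, v_sequenced_length=1000)])
        assert is_mutated_clone(clone) is expected


class TestIsDetectable:
    def setup_method(self):
        self.sample_tissue = {"A": Tissue.ILEUM}

    def test_copy_one_not_detectable(self):
        clone = make_clone([make_record(copy_number=1)])
        assert not is_detectable(clone, Tissue.ILEUM, self.sample_tissue)

    def test_copy_two_detectable(self):
        clone = make_clone([make_record(copy_number=2)])
        assert is_detectable(clone, Tissue.ILEUM, self.sample_tissue)

    def test_unproductive_not_detectable(self):
        clone = make_clone([make_record(copy_number=5, productive=False)])
        assert not is_detectable(clone, Tissue.ILEUM, self.sample_tissue)

    def test_wrong_tissue(self):
        clone = make_clone([make_record(copy_number=5)])
        assert not is_detectable(clone, Tissue.BLOOD, self.sample_tissue)


class TestCloneBracketSizes:
    def test_counts_instances_in_bracket(self):
        metas = [
            make_meta(sample_id="A", pod=10),
            make_meta(sample_id="B", pod=50),
        ]
        clone = make_clone(
            [
                make_record(sequence_id="S1", sample_id="A"),
                make_record(sequence_id="S2", sample_id="A"),
                make_record(sequence_id="S3", sample_id="B"),
            ]
        )
        rows = clone_bracket_sizes([clone], metas)
        assert len(rows) == 1
        assert rows[0].bracket == Bracket.EARLY
        assert rows[0].size == 3

    def test_same_sequence_two_samples_counts_twice(self):
        # an instance is (sequence, sample): manual enumeration gives 2
        metas = [make_meta(sample_id="A", pod=10), make_meta(sample_id="B", pod=20)]
        clone = make_clone(
            [
                make_record(sequence_id="S1", sample_id="A"),
                make_record(sequence_id="S1", sample_id="B"),
            ]
        )
        rows = clone_bracket_sizes([clone], metas)
        assert rows[0].size == 2

    def test_unresolvable_sample_errors(self):
        clone = make_clone([make_record(sample_id="GHOST")])
        with pytest.raises(ValueError, match="GHOST"):
            clone_bracket_sizes([clone], [make_meta(sample_id="A")])

    def test_empty_cells_omitted(self):
        metas = [make_meta(sample_id="A", pod=10)]
        clone = make_clone([make_record(sample_id="A")])
        rows = clone_bracket_sizes([clone], metas)
        assert {r.bracket for r in rows} == {Bracket.EARLY}


def trunk_clone(n_sharing, shared, n_total=10):
    members = []
    for i in range(n_total):
        muts = {f"{p}A>G" for p in range(1, shared + 1)} if i < n_sharing else {f"{90 + i}C>T"}
        members.append(make_record(sequence_id=f"S{i}", v_mutation_set=muts))
    return make_clone(members)


class TestTrunkClone:
    def test_nine_of_ten_share_five(self):
        assert is_trunk_clone(trunk_clone(9, 5)) is True

    def test_only_four_shared(self):
        assert is_trunk_clone(trunk_clone(9, 4)) is False

    def test_eighty_percent_share(self):
        assert is_trunk_clone(trunk_clone(8, 5)) is False

    def test_missing_mutation_sets_error(self):
        clone = make_clone([make_record()])
        with pytest.raises(ValueError, match="mutation set"):
            is_trunk_clone(clone)


class TestMinUniqueSequencesFilter:
    def make(self, n_seqs, samples):
        members = [
            make_record(sequence_id=f"S{i}", sample_id=samples[i % len(samples)])
            for i in range(n_seqs)
        ]
        return make_clone(members)

    def setup_method(self):
        self.tissue_of = {"A": Tissue.BLOOD, "B": Tissue.ILEUM}
        self.pair = (Tissue.BLOOD, Tissue.ILEUM)

    def test_three_seqs_both_tissues_retained(self):
        clone = self.make(3, ["A", "B"])
        assert min_unique_sequences_filter([clone], 3, self.pair, self.tissue_of) == [clone]

    def test_two_seqs_dropped(self):
        clone = self.make(2, ["A", "B"])
        assert min_unique_sequences_filter([clone], 3, self.pair, self.tissue_of) == []

    def test_single_tissue_dropped(self):
        clone = self.make(5, ["A"])
        assert min_unique_sequences_filter([clone], 3, self.pair, self.tissue_of) == []


def test_cdr3_identity_rejects_unequal_lengths():
    with pytest.raises(ValueError):
        cdr3_identity("CAR", "CARD")
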