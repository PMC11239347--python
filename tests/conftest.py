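from collections import Counter

import pytest

from clonotrack.airr_io import RejectionStatus, SampleMeta, SequenceRecord, Tissue
from clonotrack.clonal import Clone
from clonotrack.lineage import LineageNode, LineageTree


def make_record(
    sequence_id="S1",
    sample_id="A",
    v_call="IGHV1-8",
    j_call="IGHJ4",
    cdr3_aa="CARDYWGQGTLVT",
    productive=True,
    copy_number=2,
    v_mutation_count=0,
    v_sequenced_length=270,
    v_mutation_set=None,
):
    if v_mutation_set is not None:
        v_mutation_set = frozenset(v_mutation_set)
        v_mutation_count = len(v_mutation_set)
    return SequenceRecord(
        sequence_id=sequence_id,
        sample_id=sample_id,
        v_call=v_call,
        j_call=j_call,
        cdr3_aa=cdr3_aa,
        productive=productive,
        copy_number=copy_number,
        v_mutation_count=v_mutation_count,
        v_sequenced_length=v_sequenced_length,
        v_mutation_set=v_mutation_set,
    )


def make_meta(
    sample_id="A",
    patient_id="P1",
    tissue=Tissue.BLOOD,
    allograft=False,
    pod=30,
    rejection_status=RejectionStatus.NONE,
    parent_gate_count=100,
    chimerism_pct=None,
):
    return SampleMeta(
        sample_id=sample_id,
        patient_id=patient_id,
        tissue=tissue,
        allograft=allograft,
        pod=pod,
        rejection_status=rejection_status,
        parent_gate_count=parent_gate_count,
        chimerism_pct=chimerism_pct,
    )


def make_clone(members, clone_id=1):
    first = members[0]
    return Clone(
        clone_id=clone_id,
        v_gene=first.v_call,
        j_gene=first.j_call,
        cdr3_length=first.cdr3_length,
        members=tuple(members),
    )


def node(node_id, mutations=(), populated=False, labels=None, children=()):
    """Hand-build a lineage node for clumpiness tests."""
    return LineageNode(
        node_id=node_id,
        mutation_set=frozenset(mutations),
        populated=populated,
        labels=Counter(labels or {}),
        children=list(children),
    )


def tree(root, clone_id=1):
    return LineageTree(clone_id=clone_id, root=root)


@pytest.fixture
def blood():
    return Tissue.BLOOD


@pytest.fixture
def ileum():
    return Tissue.ILEUM
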