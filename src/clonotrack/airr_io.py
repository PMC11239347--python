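"""Read, validate and write annotated rearrangement tables and sample metadata.

The canonical on-disk dialect is the AIRR-C rearrangement TSV (tab-separated,
UTF-8, header row).  An ImmuneDB-style column mapping is provided for tables
emitted by that stack.  Rows violating record invariants are dropped and
tallied rather than aborting the whole read; missing mandatory columns are a
hard error naming the column.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)


class Tissue(str, enum.Enum):
    """Tissue compartments a sample can come from."""

    BLOOD = "blood"
    ILEUM = "ileum"
    COLON = "colon"
    NATIVE_COLON = "native_colon"
    DUODENUM = "duodenum"


class RejectionStatus(str, enum.Enum):
    """Histological rejection grade of a sample."""

    NONE = "none"
    INDETERMINATE = "indeterminate"
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"
    AMR = "amr"


#: Grades treated as quiescent; indeterminate is contrasted with
#: "mild or greater" rejection and therefore kept.
QUIESCENT_GRADES = frozenset({RejectionStatus.NONE, RejectionStatus.INDETERMINATE})


def strip_allele(call: str) -> str:
    """Collapse an allele-level gene call to gene level.

    ``IGHV1-2*02`` -> ``IGHV1-2``.  Grouping operates at gene level; allele
    designators after ``*`` are removed, surrounding whitespace stripped.
    """
    return call.split("*", 1)[0].strip()


@dataclass(frozen=True)
class SequenceRecord:
    """One annotated unique rearrangement observed in one sample.

    ``v_call``/``j_call`` are stored gene-level (allele suffix stripped).
    ``v_mutation_set`` is an optional frozenset of mutation identifiers of the
    form ``"<position><germline>><observed>"`` (e.g. ``"45A>G"``).
    """

    sequence_id: str
    sample_id: str
    v_call: str
    j_call: str
    cdr3_aa: str
    productive: bool
    copy_number: int
    v_mutation_count: int
    v_sequenced_length: int
    v_mutation_set: frozenset[str] | None = None

    @property
    def cdr3_length(self) -> int:
        return len(self.cdr3_aa)

    def validate(self) -> None:
        """Raise ``ValueError`` on any invariant violation."""
        if self.copy_number < 1:
            raise ValueError(f"{self.sequence_id}: copy_number must be >= 1")
        if self.v_mutation_count < 0:
            raise ValueError(f"{self.sequence_id}: negative v_mutation_count")
        if self.v_sequenced_length < 1:
            raise ValueError(f"{self.sequence_id}: v_sequenced_length must be >= 1")
        if self.v_mutation_count > self.v_sequenced_length:
            raise ValueError(
                f"{self.sequence_id}: v_mutation_count exceeds v_sequenced_length"
            )
        if not self.cdr3_aa:
            raise ValueError(f"{self.sequence_id}: empty CDR3")
        if self.v_mutation_set is not None and len(self.v_mutation_set) != self.v_mutation_count:
            raise ValueError(
                f"{self.sequence_id}: v_mutation_set cardinality "
                f"{len(self.v_mutation_set)} != v_mutation_count {self.v_mutation_count}"
            )


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata: provenance, timing, rejection grade, cytometry."""

    sample_id: str
    patient_id: str
    tissue: Tissue
    allograft: bool
    pod: int
    rejection_status: RejectionStatus
    parent_gate_count: int | None = None
    chimerism_pct: float | None = None

    def validate(self) -> None:
        if self.pod < 0:
            raise ValueError(f"{self.sample_id}: pod must be >= 0")
        if self.chimerism_pct is not None and not (0.0 <= self.chimerism_pct <= 100.0):
            raise ValueError(f"{self.sample_id}: chimerism_pct outside [0, 100]")
        if self.parent_gate_count is not None and self.parent_gate_count < 0:
            raise ValueError(f"{self.sample_id}: negative parent_gate_count")


# Column names of the canonical AIRR-C dialect, and the ImmuneDB-style
# synonyms mapped onto them.
_AIRR_COLUMNS = {
    "sequence_id": "sequence_id",
    "sample_id": "sample_id",
    "v_call": "v_call",
    "j_call": "j_call",
    "junction_aa": "cdr3_aa",
    "productive": "productive",
    "duplicate_count": "copy_number",
    "v_mutation_count": "v_mutation_count",
    "v_sequenced_length": "v_sequenced_length",
}
_IMMUNEDB_COLUMNS = {
    "seq_id": "sequence_id",
    "sample_id": "sample_id",
    "v_gene": "v_call",
    "j_gene": "j_call",
    "cdr3_aa": "cdr3_aa",
    "functional": "productive",
    "copy_number": "copy_number",
    "v_mutations": "v_mutation_count",
    "v_length": "v_sequenced_length",
}
_DIALECTS = {"airr": _AIRR_COLUMNS, "immunedb": _IMMUNEDB_COLUMNS}
#: Optional column (either dialect) carrying a comma-separated mutation set.
_MUTATION_SET_COLUMN = "v_mutation_set"

_TRUE_STRINGS = {"t", "true", "1", "yes", "y"}
_FALSE_STRINGS = {"f", "false", "0", "no", "n"}


def _parse_bool(value: str) -> bool:
    v = value.strip().lower()
    if v in _TRUE_STRINGS:
        return True
    if v in _FALSE_STRINGS:
        return False
    raise ValueError(f"cannot parse boolean from {value!r}")


def _parse_mutation_set(value: str) -> frozenset[str] | None:
    v = value.strip()
    if not v:
        return None
    return frozenset(m.strip() for m in v.split(",") if m.strip())


def read_rearrangements(
    path: str | Path, dialect: str = "airr"
) -> tuple[list[SequenceRecord], int]:
    """Read an annotated rearrangement TSV.

    Returns ``(records, n_rejected)`` where ``n_rejected`` counts rows that
    failed to parse or violated a :class:`SequenceRecord` invariant; those
    rows are dropped and logged.  V and J calls are normalized to gene level.

    Raises
    ------
    ValueError
        If a mandatory column of the declared dialect is missing (the message
        names the column), or the dialect is unknown.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECTS)}")
    columns = _DIALECTS[dialect]
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in columns:
        if col not in df.columns:
            raise ValueError(f"missing mandatory column: {col!r} (dialect {dialect!r})")
    has_mutset = _MUTATION_SET_COLUMN in df.columns

    records: list[SequenceRecord] = []
    n_rejected = 0
    for row in df.itertuples(index=False):
        raw = {field: getattr(row, col) for col, field in columns.items()}
        try:
            record = SequenceRecord(
                sequence_id=raw["sequence_id"],
                sample_id=raw["sample_id"],
                v_call=strip_allele(raw["v_call"]),
                j_call=strip_allele(raw["j_call"]),
                cdr3_aa=raw["cdr3_aa"].strip(),
                productive=_parse_bool(raw["productive"]),
                copy_number=int(raw["copy_number"]),
                v_mutation_count=int(raw["v_mutation_count"]),
                v_sequenced_length=int(raw["v_sequenced_length"]),
                v_mutation_set=(
                    _parse_mutation_set(getattr(row, _MUTATION_SET_COLUMN))
                    if has_mutset
                    else None
                ),
            )
            record.validate()
        except (ValueError, TypeError) as exc:
            n_rejected += 1
            logger.warning("rejected rearrangement row: %s", exc)
            continue
        records.append(record)
    if n_rejected:
        logger.info("read %d records, rejected %d rows", len(records), n_rejected)
    return records, n_rejected


def write_rearrangements(
    records: Iterable[SequenceRecord], path: str | Path, dialect: str = "airr"
) -> None:
    """Write records as TSV in the given dialect (round-trips bit-exactly)."""
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    columns = _DIALECTS[dialect]
    field_to_col = {field: col for col, field in columns.items()}
    rows = []
    for r in records:
        row = {
            field_to_col["sequence_id"]: r.sequence_id,
            field_to_col["sample_id"]: r.sample_id,
            field_to_col["v_call"]: r.v_call,
            field_to_col["j_call"]: r.j_call,
            field_to_col["cdr3_aa"]: r.cdr3_aa,
            field_to_col["productive"]: "T" if r.productive else "F",
            field_to_col["copy_number"]: r.copy_number,
            field_to_col["v_mutation_count"]: r.v_mutation_count,
            field_to_col["v_sequenced_length"]: r.v_sequenced_length,
            _MUTATION_SET_COLUMN: (
                ",".join(sorted(r.v_mutation_set)) if r.v_mutation_set is not None else ""
            ),
        }
        rows.append(row)
    cols = list(columns) + [_MUTATION_SET_COLUMN]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


_META_COLUMNS = [
    "sample_id",
    "patient_id",
    "tissue",
    "allograft",
    "pod",
    "rejection_status",
    "parent_gate_count",
    "chimerism_pct",
]


def read_metadata(path: str | Path) -> list[SampleMeta]:
    """Read the sample-metadata TSV.

    Unknown tissue or rejection labels and duplicate sample ids are hard
    errors naming the offending value; rows violating numeric invariants
    (e.g. negative POD) are dropped with a logged message.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _META_COLUMNS[:6]:
        if col not in df.columns:
            raise ValueError(f"missing mandatory metadata column: {col!r}")
    seen: set[str] = set()
    metas: list[SampleMeta] = []
    for row in df.itertuples(index=False):
        sample_id = row.sample_id
        if sample_id in seen:
            raise ValueError(f"duplicate sample_id: {sample_id!r}")
        seen.add(sample_id)
        try:
            tissue = Tissue(row.tissue)
        except ValueError:
            raise ValueError(f"unknown tissue label {row.tissue!r} for sample {sample_id!r}")
        try:
            status = RejectionStatus(row.rejection_status)
        except ValueError:
            raise ValueError(
                f"unknown rejection_status {row.rejection_status!r} for sample {sample_id!r}"
            )
        gate = getattr(row, "parent_gate_count", "")
        chim = getattr(row, "chimerism_pct", "")
        try:
            meta = SampleMeta(
                sample_id=sample_id,
                patient_id=row.patient_id,
                tissue=tissue,
                allograft=_parse_bool(row.allograft),
                pod=int(row.pod),
                rejection_status=status,
                parent_gate_count=int(gate) if str(gate).strip() else None,
                chimerism_pct=float(chim) if str(chim).strip() else None,
            )
            meta.validate()
        except (ValueError, TypeError) as exc:
            logger.warning("rejected metadata row for sample %r: %s", sample_id, exc)
            continue
        metas.append(meta)
    return metas


def write_metadata(metas: Iterable[SampleMeta], path: str | Path) -> None:
    rows = []
    for m in metas:
        rows.append(
            {
                "sample_id": m.sample_id,
                "patient_id": m.patient_id,
                "tissue": m.tissue.value,
                "allograft": "T" if m.allograft else "F",
                "pod": m.pod,
                "rejection_status": m.rejection_status.value,
                "parent_gate_count": "" if m.parent_gate_count is None else m.parent_gate_count,
                "chimerism_pct": "" if m.chimerism_pct is None else m.chimerism_pct,
            }
        )
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path, sep="\t", index=False)


def filter_quiescent(metas: Sequence[SampleMeta]) -> list[SampleMeta]:
    """Keep only samples without rejection (grades none/indeterminate).

    Order-preserving and idempotent.
    """
    return [m for m in metas if m.rejection_status in QUIESCENT_GRADES]


def sample_tissue_map(metas: Iterable[SampleMeta]) -> dict[str, Tissue]:
    """Convenience ``sample_id -> tissue`` lookup."""
    return {m.sample_id: m.tissue for m in metas}
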