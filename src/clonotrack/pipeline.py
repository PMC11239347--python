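"""End-to-end report generation from annotated tables to analysis TSVs.

``run_report`` composes the stage modules into the per-patient figure-style
outputs: mutated-clone fractions by tissue and bracket, evenness by bracket,
sign tests between consecutive brackets, per-clone and per-individual median
clumpiness by tissue pair, cosine similarities between tissue pairs, and
normalized chimerism AUC by bracket.  A manifest records every threshold
and a digest of the inputs; identical inputs and config produce
byte-identical reports.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from clonotrack import clonal
from clonotrack.airr_io import (
    SampleMeta,
    SequenceRecord,
    Tissue,
    filter_quiescent,
    read_metadata,
    read_rearrangements,
    sample_tissue_map,
)
from clonotrack.clumpiness import DEFAULT_MIN_CLONES as MEDIAN_MIN_CLONES
from clonotrack.clumpiness import clumpiness, median_clumpiness
from clonotrack.lineage import build_lineage, lineage_nodes_table, to_newick
from clonotrack.metrics import (
    DEFAULT_MIN_CLONES,
    RepertoireSlice,
    cosine_similarity,
    evenness,
    hill_diversity,
    min_clone_filter,
    slices_from_bracket_sizes,
)
from clonotrack.stats import (
    BRACKET_ORDER,
    Bracket,
    ChimerismSeries,
    chimerism_auc_normalized,
    parent_gate_filter,
    sign_test_clone_sizes,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Paths and thresholds of one report run (defaults are the published ones)."""

    rearrangements: str
    metadata: str
    out_dir: str
    dialect: str = "airr"
    identity_threshold: float = clonal.DEFAULT_IDENTITY_THRESHOLD
    min_copy_number: int = clonal.DEFAULT_MIN_COPY_NUMBER
    mutated_cutoff: float = clonal.DEFAULT_MUTATED_CUTOFF
    trunk_min_mutations: int = clonal.DEFAULT_TRUNK_MIN_MUTATIONS
    trunk_min_share: float = clonal.DEFAULT_TRUNK_MIN_SHARE
    min_clones: int = DEFAULT_MIN_CLONES
    min_unique_sequences: int = clonal.DEFAULT_MIN_UNIQUE_SEQUENCES
    median_min_clones: int = MEDIAN_MIN_CLONES
    parent_gate_min: int = 40
    quiescent_only: bool = True
    clumpiness_pairs: tuple[tuple[str, str], ...] = (("blood", "ileum"),)
    write_lineages: bool = False


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, out_dir: Path, name: str) -> None:
    df.to_csv(out_dir / name, sep="\t", index=False, float_format="%.10g")


def _group_clones_per_patient(
    records: list[SequenceRecord],
    metas: list[SampleMeta],
    threshold: float,
) -> dict[str, list[clonal.Clone]]:
    """Clone grouping on pooled per-patient data with globally unique ids."""
    patient_of = {m.sample_id: m.patient_id for m in metas}
    by_patient: dict[str, list[SequenceRecord]] = {}
    for r in records:
        if r.sample_id not in patient_of:
            raise ValueError(f"sample_id {r.sample_id!r} missing from metadata")
        by_patient.setdefault(patient_of[r.sample_id], []).append(r)
    out: dict[str, list[clonal.Clone]] = {}
    offset = 0
    for patient in sorted(by_patient):
        clones = clonal.group_clones(by_patient[patient], threshold=threshold)
        out[patient] = [
            clonal.Clone(
                clone_id=c.clone_id + offset,
                v_gene=c.v_gene,
                j_gene=c.j_gene,
                cdr3_length=c.cdr3_length,
                members=c.members,
            )
            for c in clones
        ]
        offset += len(clones)
    return out


def run_report(config: RunConfig) -> Path:
    """Run the whole analysis; returns the output directory.

    Each stage failure is re-raised with the stage name prefixed so the CLI
    can surface the offending context.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    stage = "read_inputs"
    try:
        records, n_rejected = read_rearrangements(config.rearrangements, dialect=config.dialect)
        metas = read_metadata(config.metadata)
        if config.quiescent_only:
            metas_used = filter_quiescent(metas)
        else:
            metas_used = list(metas)
        kept_samples = {m.sample_id for m in metas_used}
        records = [r for r in records if r.sample_id in kept_samples]
        tissue_of = sample_tissue_map(metas_used)

        stage = "clonal_inference"
        clones_by_patient = _group_clones_per_patient(
            records, metas_used, config.identity_threshold
        )
        all_clones = [c for cs in clones_by_patient.values() for c in cs]
        patient_of_clone = {
            c.clone_id: p for p, cs in clones_by_patient.items() for c in cs
        }
        have_mutsets = all(
            m.v_mutation_set is not None for c in all_clones for m in c.members
        )

        clone_rows = []
        for c in all_clones:
            tissues = sorted(t.value for t in c.tissues_detected(tissue_of))
            clone_rows.append(
                {
                    "clone_id": c.clone_id,
                    "patient_id": patient_of_clone[c.clone_id],
                    "v_gene": c.v_gene,
                    "j_gene": c.j_gene,
                    "cdr3_length": c.cdr3_length,
                    "n_unique_seqs": len(c.unique_sequence_ids()),
                    "n_instances": len(c.instances()),
                    "avg_v_mutation_fraction": clonal.clone_mutation_fraction(c),
                    "is_mutated": int(clonal.is_mutated_clone(c, config.mutated_cutoff)),
                    "is_trunk": (
                        int(
                            clonal.is_trunk_clone(
                                c, config.trunk_min_mutations, config.trunk_min_share
                            )
                        )
                        if have_mutsets
                        else ""
                    ),
                    "tissues": ",".join(tissues),
                }
            )
        _write(pd.DataFrame(clone_rows), out_dir, "clones.tsv")

        stage = "bracket_sizes"
        size_rows = clonal.clone_bracket_sizes(all_clones, metas_used)
        slices = slices_from_bracket_sizes(size_rows)
        mutated_by_clone = {r["clone_id"]: r["is_mutated"] for r in clone_rows}

        stage = "mutated_fractions"
        mut_rows = []
        for s in min_clone_filter(slices, config.min_clones):
            flags = [mutated_by_clone[cid] for cid in s.sizes]
            mut_rows.append(
                {
                    "patient_id": s.patient_id,
                    "tissue": s.tissue.value,
                    "bracket": s.bracket.value,
                    "n_clones": s.richness,
                    "mutated_fraction": sum(flags) / len(flags),
                }
            )
        _write(pd.DataFrame(mut_rows), out_dir, "mutated_fractions.tsv")

        stage = "diversity"
        div_rows = []
        for s in slices:
            div_rows.append(
                {
                    "patient_id": s.patient_id,
                    "tissue": s.tissue.value,
                    "bracket": s.bracket.value,
                    "richness": s.richness,
                    "d0": hill_diversity(s, 0.0),
                    "d1": hill_diversity(s, 1.0),
                    "evenness": evenness(s),
                    "passes_min_clones": int(s.richness > config.min_clones),
                }
            )
        _write(pd.DataFrame(div_rows), out_dir, "evenness.tsv")

        stage = "sign_tests"
        slice_by_key = {(s.patient_id, s.tissue, s.bracket): s for s in slices}
        sign_rows = []
        for patient in sorted({s.patient_id for s in slices}):
            for tissue in sorted({s.tissue for s in slices}, key=lambda t: t.value):
                for b1, b2 in itertools.pairwise(BRACKET_ORDER):
                    s1 = slice_by_key.get((patient, tissue, b1))
                    s2 = slice_by_key.get((patient, tissue, b2))
                    if s1 is None or s2 is None:
                        continue
                    try:
                        res = sign_test_clone_sizes(s1.sizes, s2.sizes)
                    except ValueError:
                        continue
                    sign_rows.append(
                        {
                            "patient_id": patient,
                            "tissue": tissue.value,
                            "bracket_from": b1.value,
                            "bracket_to": b2.value,
                            "n_plus": res.n_plus,
                            "n_minus": res.n_minus,
                            "p_value": res.p_value,
                        }
                    )
        _write(pd.DataFrame(sign_rows), out_dir, "sign_tests.tsv")

        stage = "clumpiness"
        clump_rows = []
        for pair_names in config.clumpiness_pairs:
            pair = (Tissue(pair_names[0]), Tissue(pair_names[1]))
            eligible = clonal.min_unique_sequences_filter(
                all_clones, config.min_unique_sequences, pair, tissue_of
            )
            for c in eligible:
                tree = build_lineage(c, tissue_of)
                value = clumpiness(tree, pair[0], pair[1])
                if value is None:
                    continue
                clump_rows.append(
                    {
                        "patient_id": patient_of_clone[c.clone_id],
                        "clone_id": c.clone_id,
                        "tissue_a": pair[0].value,
                        "tissue_b": pair[1].value,
                        "clumpiness": value,
                    }
                )
        _write(pd.DataFrame(clump_rows), out_dir, "clumpiness.tsv")
        medians = median_clumpiness(
            [
                (r["patient_id"], (r["tissue_a"], r["tissue_b"]), r["clumpiness"])
                for r in clump_rows
            ],
            min_clones=config.median_min_clones,
        )
        median_rows = [
            {
                "patient_id": patient,
                "tissue_a": pair[0],
                "tissue_b": pair[1],
                "median_clumpiness": value,
            }
            for (patient, pair), value in sorted(medians.items())
        ]
        _write(pd.DataFrame(median_rows), out_dir, "clumpiness_medians.tsv")

        if config.write_lineages:
            stage = "lineages"
            newicks = []
            node_rows = []
            for c in all_clones:
                if any(m.v_mutation_set is None for m in c.members):
                    continue
                tree = build_lineage(c, tissue_of)
                newicks.append(to_newick(tree))
                node_rows.extend(lineage_nodes_table(tree))
            (out_dir / "lineages.nwk").write_text("\n".join(newicks) + "\n")
            _write(pd.DataFrame(node_rows), out_dir, "lineage_nodes.tsv")

        stage = "cosine"
        cos_rows = []
        by_pb: dict[tuple[str, Bracket], list[RepertoireSlice]] = {}
        for s in slices:
            by_pb.setdefault((s.patient_id, s.bracket), []).append(s)
        for (patient, bracket), group in sorted(
            by_pb.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
        ):
            group = sorted(group, key=lambda s: s.tissue.value)
            for sa, sb in itertools.combinations(group, 2):
                cos_rows.append(
                    {
                        "patient_id": patient,
                        "bracket": bracket.value,
                        "tissue_a": sa.tissue.value,
                        "tissue_b": sb.tissue.value,
                        "cosine_similarity": cosine_similarity(sa, sb),
                    }
                )
        _write(pd.DataFrame(cos_rows), out_dir, "cosine.tsv")

        stage = "chimerism_auc"
        auc_rows = []
        by_pt: dict[tuple[str, Tissue], list[SampleMeta]] = {}
        for m in metas_used:
            if m.chimerism_pct is not None:
                by_pt.setdefault((m.patient_id, m.tissue), []).append(m)
        for (patient, tissue), group in sorted(
            by_pt.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
        ):
            group = sorted(group, key=lambda m: m.pod)
            pods = [m.pod for m in group]
            if len(set(pods)) != len(pods):
                logger.warning("%s/%s: duplicate PODs in chimerism series, skipped", patient, tissue.value)
                continue
            series = ChimerismSeries(
                patient_id=patient,
                compartment="graft_recipient" if tissue != Tissue.BLOOD else "pbmc_donor",
                points=tuple((m.pod, m.chimerism_pct, m.parent_gate_count) for m in group),
            )
            series = parent_gate_filter(series, config.parent_gate_min)
            for bracket in (Bracket.EARLY, Bracket.MID, Bracket.LATE):
                try:
                    auc = chimerism_auc_normalized(series, bracket)
                except ValueError:
                    continue
                auc_rows.append(
                    {
                        "patient_id": patient,
                        "tissue": tissue.value,
                        "bracket": bracket.value,
                        "auc_normalized": auc,
                    }
                )
        _write(pd.DataFrame(auc_rows), out_dir, "chimerism_auc.tsv")

        stage = "manifest"
        manifest = {
            "inputs": {
                "rearrangements": {
                    "path": str(config.rearrangements),
                    "sha256": _sha256(config.rearrangements),
                    "n_records": len(records),
                    "n_rejected_rows": n_rejected,
                },
                "metadata": {
                    "path": str(config.metadata),
                    "sha256": _sha256(config.metadata),
                    "n_samples": len(metas),
                    "n_samples_used": len(metas_used),
                },
            },
            "thresholds": {
                "identity_threshold": config.identity_threshold,
                "min_copy_number": config.min_copy_number,
                "mutated_cutoff": config.mutated_cutoff,
                "trunk_min_mutations": config.trunk_min_mutations,
                "trunk_min_share": config.trunk_min_share,
                "min_clones": config.min_clones,
                "min_unique_sequences": config.min_unique_sequences,
                "median_min_clones": config.median_min_clones,
                "parent_gate_min": config.parent_gate_min,
                "quiescent_only": config.quiescent_only,
            },
            "n_clones": len(all_clones),
            "samples_used": sorted(kept_samples),
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    except Exception as exc:
        raise RuntimeError(f"report stage {stage!r} failed: {exc}") from exc
    return out_dir
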