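"""Deterministic synthetic rearrangement and chimerism data.

Clones are grown as germline-founded lineages: two founder clades per clone
accumulate distinct V mutations (sampled without replacement from V
positions, so mutation sets along a branch are strictly nested and never
collide).  Unique sequences are assigned to per-tissue samples with a
mixing parameter pi: at pi=0 each clade is sampled in exactly one tissue
(tissue-pure split at the germline), at pi=1 every unique sequence is
sampled in both tissues.  Clone sizes follow a configurable power-law skew
and drift across time brackets with a growth bias, so the downstream
clumpiness, evenness and sign-test machinery has known ground truth.

All randomness flows from a single integer seed through
``numpy.random.default_rng``; identical configs produce byte-identical
tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from clonotrack.airr_io import RejectionStatus, SampleMeta, SequenceRecord, Tissue
from clonotrack.stats import Bracket, ChimerismSeries, assign_bracket

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_BASES = "ACGT"
_V_GENES = (
    "IGHV1-8",
    "IGHV1-18",
    "IGHV3-23",
    "IGHV3-30",
    "IGHV4-34",
    "IGHV4-59",
    "IGHV5-51",
    "IGHV6-1",
)
_J_GENES = ("IGHJ1", "IGHJ2", "IGHJ3", "IGHJ4", "IGHJ5", "IGHJ6")

#: (pod, tissue, rejection grade, parent-gate count) sampling plan used when
#: a config does not override it: paired blood/ileum samples at transplant
#: and through the early, mid and late brackets.
DEFAULT_POD_SCHEDULE: tuple[tuple[int, Tissue, RejectionStatus, int], ...] = tuple(
    (pod, tissue, RejectionStatus.NONE, 200)
    for pod in (0, 30, 60, 180, 300, 500, 700)
    for tissue in (Tissue.BLOOD, Tissue.ILEUM)
)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic repertoire generator; seed determines all."""

    seed: int = 0
    n_patients: int = 5
    n_clones: int = 200
    clone_size_exponent: float = 0.6  # 0 = equal clone sizes; larger = heavier tail
    shm_rate: float = 1.5  # expected new V mutations per branching step
    branching_depth: int = 4
    tissue_mix: float = 0.5  # pi: probability a unique sequence is sampled in both tissues
    copy_number_mean: float = 2.0
    pod_schedule: tuple[tuple[int, Tissue, RejectionStatus, int], ...] = DEFAULT_POD_SCHEDULE
    growth_bias: float = 0.5  # probability a clone grows between consecutive brackets
    growth_factor: float = 1.7
    chimerism_curve: tuple[float, float, float] = (60.0, 0.05, 90.0)  # midpoint, steepness, asymptote
    chimerism_noise: float = 0.0
    v_sequenced_length: int = 270
    base_clone_genotypes: int = 6
    max_clone_genotypes: int = 48
    tissues: tuple[Tissue, Tissue] = (Tissue.BLOOD, Tissue.ILEUM)

    def validate(self) -> None:
        if self.n_patients < 1 or self.n_clones < 1:
            raise ValueError("n_patients and n_clones must be >= 1")
        if not (0.0 <= self.tissue_mix <= 1.0):
            raise ValueError("tissue_mix must be in [0, 1]")
        if not (0.0 <= self.growth_bias <= 1.0):
            raise ValueError("growth_bias must be in [0, 1]")
        if self.clone_size_exponent < 0:
            raise ValueError("clone_size_exponent must be >= 0")
        if self.shm_rate <= 0:
            raise ValueError("shm_rate must be positive")
        if self.copy_number_mean < 1:
            raise ValueError("copy_number_mean must be >= 1")
        if self.branching_depth < 1:
            raise ValueError("branching_depth must be >= 1")
        if self.growth_factor <= 1:
            raise ValueError("growth_factor must be > 1")
        if not self.pod_schedule:
            raise ValueError("pod_schedule must be non-empty")
        if self.tissues[0] == self.tissues[1]:
            raise ValueError("the two simulated tissues must differ")
        for pod, _, _, gate in self.pod_schedule:
            if pod < 0 or gate < 0:
                raise ValueError("pod and parent_gate_count must be non-negative")


def _sample_id(patient: str, pod: int, tissue: Tissue) -> str:
    return f"{patient}_d{pod:04d}_{tissue.value}"


def _make_metadata(config: SimulationConfig, patient: str, rng: np.random.Generator) -> list[SampleMeta]:
    midpoint, steepness, asymptote = config.chimerism_curve
    metas = []
    for pod, tissue, rejection, gate in config.pod_schedule:
        chim = asymptote / (1.0 + np.exp(-steepness * (pod - midpoint)))
        if config.chimerism_noise > 0:
            chim += rng.uniform(-config.chimerism_noise, config.chimerism_noise)
        metas.append(
            SampleMeta(
                sample_id=_sample_id(patient, pod, tissue),
                patient_id=patient,
                tissue=tissue,
                allograft=tissue not in (Tissue.BLOOD, Tissue.NATIVE_COLON),
                pod=pod,
                rejection_status=rejection,
                parent_gate_count=gate,
                chimerism_pct=round(float(np.clip(chim, 0.0, 100.0)), 4),
            )
        )
    return metas


def _grow_genotypes(
    config: SimulationConfig, rng: np.random.Generator, n_target: int
) -> list[tuple[frozenset[str], int]]:
    """Branching process yielding ``(mutation_set, clade)`` pairs.

    Two mutated founders sit directly under the germline; descendants add
    fresh mutations drawn without replacement from V positions, so sets are
    strictly nested along branches and disjoint between clades.
    """
    positions = rng.permutation(np.arange(1, config.v_sequenced_length + 1)).tolist()

    def new_mutations(k: int) -> frozenset[str]:
        muts = []
        for _ in range(min(k, len(positions))):
            pos = positions.pop()
            germ, obs = rng.choice(list(_BASES), size=2, replace=False)
            muts.append(f"{pos}{germ}>{obs}")
        return frozenset(muts)

    genotypes: list[tuple[frozenset[str], int, int]] = []  # (set, clade, depth)
    for clade in (0, 1):
        founder = new_mutations(max(1, int(rng.poisson(config.shm_rate))))
        genotypes.append((founder, clade, 1))
    while len(genotypes) < n_target and positions:
        eligible = [g for g in genotypes if g[2] < config.branching_depth]
        if not eligible:
            break
        parent_set, clade, depth = eligible[int(rng.integers(len(eligible)))]
        child = parent_set | new_mutations(max(1, int(rng.poisson(config.shm_rate))))
        if child == parent_set:  # ran out of positions
            break
        genotypes.append((child, clade, depth + 1))
    return [(s, clade) for s, clade, _ in genotypes]


def _bracket_samples(
    config: SimulationConfig, patient: str
) -> dict[Bracket, dict[Tissue, list[str]]]:
    out: dict[Bracket, dict[Tissue, list[str]]] = {}
    for pod, tissue, _, _ in config.pod_schedule:
        out.setdefault(assign_bracket(pod), {}).setdefault(tissue, []).append(
            _sample_id(patient, pod, tissue)
        )
    return out


def simulate_repertoire(
    config: SimulationConfig,
) -> tuple[list[SequenceRecord], list[SampleMeta]]:
    """Generate annotated rearrangements plus matching sample metadata.

    Output passes :mod:`clonotrack.airr_io` validation and reassembles into
    the simulated clones under default clone grouping.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    records: list[SequenceRecord] = []
    metas: list[SampleMeta] = []
    tissue_a, tissue_b = config.tissues

    for p in range(config.n_patients):
        patient = f"P{p + 1:03d}"
        metas.extend(_make_metadata(config, patient, rng))
        by_bracket = _bracket_samples(config, patient)
        brackets = [b for b in (Bracket.PRE, Bracket.EARLY, Bracket.MID, Bracket.LATE) if b in by_bracket]

        for c in range(config.n_clones):
            v_gene = _V_GENES[int(rng.integers(len(_V_GENES)))]
            j_gene = _J_GENES[int(rng.integers(len(_J_GENES)))]
            cdr3_len = int(rng.integers(12, 21))
            cdr3 = "".join(rng.choice(list(_AMINO_ACIDS), size=cdr3_len))

            # power-law clone size (number of unique sequences)
            u = rng.random()
            n_target = int(
                np.clip(
                    round(config.base_clone_genotypes * (1.0 - u) ** (-config.clone_size_exponent)),
                    2,
                    config.max_clone_genotypes,
                )
            )
            genotypes = _grow_genotypes(config, rng, n_target)

            # per-genotype tissue eligibility under the mixing parameter
            eligibility: list[tuple[frozenset[str], tuple[Tissue, ...]]] = []
            for mutation_set, clade in genotypes:
                home = tissue_a if clade == 0 else tissue_b
                both = rng.random() < config.tissue_mix
                eligibility.append((mutation_set, (tissue_a, tissue_b) if both else (home,)))

            # per-bracket inclusion probability drifting with the growth bias
            incl = 0.55
            incl_by_bracket = {}
            for i, bracket in enumerate(brackets):
                if i > 0:
                    if rng.random() < config.growth_bias:
                        incl *= config.growth_factor
                    else:
                        incl /= config.growth_factor
                incl_by_bracket[bracket] = float(np.clip(incl, 0.05, 0.95))

            for g, (mutation_set, eligible) in enumerate(eligibility):
                chosen = [b for b in brackets if rng.random() < incl_by_bracket[b]]
                if not chosen:  # every genotype is observed at least once
                    chosen = [brackets[int(rng.integers(len(brackets)))]]
                seq_id = f"{patient}_c{c + 1:04d}_g{g + 1:03d}"
                for bracket in chosen:
                    for tissue in eligible:
                        samples = by_bracket[bracket].get(tissue)
                        if not samples:
                            continue
                        sample = samples[int(rng.integers(len(samples)))]
                        records.append(
                            SequenceRecord(
                                sequence_id=seq_id,
                                sample_id=sample,
                                v_call=v_gene,
                                j_call=j_gene,
                                cdr3_aa=cdr3,
                                productive=bool(rng.random() < 0.97),
                                copy_number=int(rng.geometric(1.0 / config.copy_number_mean)),
                                v_mutation_count=len(mutation_set),
                                v_sequenced_length=config.v_sequenced_length,
                                v_mutation_set=mutation_set,
                            )
                        )
    for r in records:
        r.validate()
    return records, metas


def simulate_chimerism(config: SimulationConfig) -> list[ChimerismSeries]:
    """Logistic chimerism trajectories per patient and compartment.

    ``graft_recipient`` rises toward the asymptote; ``pbmc_donor`` is its
    mirror (donor cells replaced in blood).  Additive bounded noise is
    clipped to [0, 100]; parent-gate counts come from the sampling plan.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    midpoint, steepness, asymptote = config.chimerism_curve
    series = []
    for p in range(config.n_patients):
        patient = f"P{p + 1:03d}"
        pods = sorted({pod for pod, _, _, _ in config.pod_schedule})
        gates = {pod: gate for pod, _, _, gate in config.pod_schedule}
        for compartment in ("pbmc_donor", "graft_recipient"):
            points = []
            for pod in pods:
                rising = asymptote / (1.0 + np.exp(-steepness * (pod - midpoint)))
                pct = rising if compartment == "graft_recipient" else asymptote - rising
                if config.chimerism_noise > 0:
                    pct += rng.uniform(-config.chimerism_noise, config.chimerism_noise)
                points.append((pod, float(np.clip(pct, 0.0, 100.0)), gates[pod]))
            series.append(ChimerismSeries(patient, compartment, tuple(points)))
    return series
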