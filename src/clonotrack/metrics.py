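"""Diversity, evenness and cosine similarity on clone-size distributions.

Diversity follows the Hill-number framework: at order 0 it equals richness,
and higher orders weight large clones more.  Evenness is order-1 diversity
normalized by richness.  Cosine similarity compares two repertoires' clone
size vectors over the union of their clones, so disjoint repertoires score
0 and proportional ones score 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from clonotrack.airr_io import Tissue
from clonotrack.clonal import CloneBracketSize
from clonotrack.stats import Bracket

#: Slices need strictly more than this many clones for per-bracket plots.
DEFAULT_MIN_CLONES = 5


@dataclass(frozen=True)
class RepertoireSlice:
    """Clone -> size mapping for one (patient, tissue, time bracket) cell."""

    patient_id: str
    tissue: Tissue
    bracket: Bracket
    sizes: Mapping[int, int]

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.sizes.values()):
            raise ValueError("all clone sizes must be >= 1")

    @property
    def richness(self) -> int:
        return len(self.sizes)


def slices_from_bracket_sizes(rows: Iterable[CloneBracketSize]) -> list[RepertoireSlice]:
    """Group per-clone bracket sizes into repertoire slices."""
    cells: dict[tuple[str, Tissue, Bracket], dict[int, int]] = {}
    for row in rows:
        cells.setdefault((row.patient_id, row.tissue, row.bracket), {})[row.clone_id] = row.size
    return [
        RepertoireSlice(patient_id=p, tissue=t, bracket=b, sizes=sizes)
        for (p, t, b), sizes in sorted(
            cells.items(), key=lambda kv: (kv[0][0], kv[0][1].value, kv[0][2].value)
        )
    ]


def hill_diversity(slice_: RepertoireSlice, q: float) -> float:
    """Hill number of order ``q`` over the slice's clone-size proportions.

    ``(sum p_i**q)**(1/(1-q))`` for q != 1; the continuous limit
    ``exp(-sum p_i ln p_i)`` at q == 1.
    """
    if q < 0:
        raise ValueError("order q must be >= 0")
    if not slice_.sizes:
        raise ValueError("diversity undefined on an empty slice")
    sizes = np.array(list(slice_.sizes.values()), dtype=float)
    p = sizes / sizes.sum()
    if math.isclose(q, 1.0, rel_tol=0.0, abs_tol=1e-12):
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def evenness(slice_: RepertoireSlice) -> float:
    """Order-1 diversity divided by richness, in (0, 1]; 1 means equal sizes."""
    if not slice_.sizes:
        raise ValueError("evenness undefined on an empty slice")
    return hill_diversity(slice_, 1.0) / slice_.richness


def cosine_similarity(a: RepertoireSlice, b: RepertoireSlice) -> float:
    """Cosine of the two clone-size vectors over the union of clone ids.

    Clones absent from one repertoire contribute zero, so disjoint
    repertoires score 0 and identical (or proportional) ones score 1.
    """
    if not a.sizes or not b.sizes:
        raise ValueError("cosine similarity undefined on an empty slice")
    clone_ids = sorted(set(a.sizes) | set(b.sizes))
    va = np.array([a.sizes.get(c, 0) for c in clone_ids], dtype=float)
    vb = np.array([b.sizes.get(c, 0) for c in clone_ids], dtype=float)
    return float(va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb)))


def min_clone_filter(
    slices: Iterable[RepertoireSlice], k: int = DEFAULT_MIN_CLONES
) -> list[RepertoireSlice]:
    """Keep slices with strictly more than ``k`` clones."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return [s for s in slices if s.richness > k]
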