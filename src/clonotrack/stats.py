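"""Time-bracket binning and longitudinal statistics.

Clone-size sign test, two-sided Mann-Whitney U, trapezoidal chimerism AUC
normalized by days of measurement, parent-gate filtering, and the MFI-based
donor-specific-antibody (DSA) positivity call.  Everything here is
deterministic and randomless.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)


class Bracket(str, enum.Enum):
    """Post-operative-day time brackets: 0, 1-90, 91-365, >365."""

    PRE = "pre"
    EARLY = "early"
    MID = "mid"
    LATE = "late"


#: Canonical temporal ordering of brackets.
BRACKET_ORDER = (Bracket.PRE, Bracket.EARLY, Bracket.MID, Bracket.LATE)


def assign_bracket(pod: int) -> Bracket:
    """Bin a post-operative day into its time bracket.

    0 -> pre, 1-90 -> early, 91-365 -> mid, >365 -> late.
    """
    if pod < 0:
        raise ValueError(f"pod must be non-negative, got {pod}")
    if pod == 0:
        return Bracket.PRE
    if pod <= 90:
        return Bracket.EARLY
    if pod <= 365:
        return Bracket.MID
    return Bracket.LATE


@dataclass(frozen=True)
class SignTestResult:
    """Counts of growing/shrinking clones and the exact binomial p-value."""

    n_plus: int
    n_minus: int
    p_value: float


def sign_test_clone_sizes(
    sizes_t1: Mapping[object, int], sizes_t2: Mapping[object, int]
) -> SignTestResult:
    """Sign test on clone-size changes between two time points.

    Clones present in both mappings are scored ``+`` if larger at the later
    time point and ``-`` if smaller; unchanged clones are excluded.  The
    p-value is the exact two-sided binomial test at success probability 1/2
    (doubled smaller tail, capped at 1).

    Raises
    ------
    ValueError
        If no clone is shared or every shared clone is unchanged.
    """
    shared = set(sizes_t1) & set(sizes_t2)
    n_plus = sum(1 for c in shared if sizes_t2[c] > sizes_t1[c])
    n_minus = sum(1 for c in shared if sizes_t2[c] < sizes_t1[c])
    n = n_plus + n_minus
    if n == 0:
        raise ValueError("sign test undefined: no clone changed size between time points")
    p = sps.binomtest(n_plus, n, p=0.5, alternative="two-sided").pvalue
    return SignTestResult(n_plus=n_plus, n_minus=n_minus, p_value=float(min(p, 1.0)))


def rank_sum_compare(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value between two independent samples.

    Uses the exact null distribution when the combined sample size is <= 20
    and there are no ties, otherwise the normal approximation with tie
    correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(res.pvalue)
    if not np.isfinite(p):  # degenerate tie-corrected variance
        return 1.0
    return min(p, 1.0)


@dataclass(frozen=True)
class ChimerismSeries:
    """Per-patient chimerism time series.

    ``points`` is a sequence of ``(pod, percent, parent_gate_count)`` with
    strictly increasing PODs; ``parent_gate_count`` may be None when the
    cytometry event count was not recorded.
    """

    patient_id: str
    compartment: str  # "pbmc_donor" or "graft_recipient"
    points: tuple[tuple[int, float, int | None], ...]

    def __post_init__(self) -> None:
        pods = [p[0] for p in self.points]
        if any(b <= a for a, b in zip(pods, pods[1:])):
            raise ValueError(f"{self.patient_id}: PODs must be strictly increasing")
        for pod, pct, _ in self.points:
            if not (0.0 <= pct <= 100.0):
                raise ValueError(f"{self.patient_id}: percent {pct} outside [0, 100]")


def parent_gate_filter(series: ChimerismSeries, min_events: int = 40) -> ChimerismSeries:
    """Drop points with fewer than ``min_events`` cells in the parent gate.

    Points with a missing count cannot be verified and are dropped with a
    warning.
    """
    kept = []
    for pod, pct, gate in series.points:
        if gate is None:
            logger.warning(
                "%s POD %d: missing parent-gate count, point dropped", series.patient_id, pod
            )
            continue
        if gate >= min_events:
            kept.append((pod, pct, gate))
    return ChimerismSeries(series.patient_id, series.compartment, tuple(kept))


def chimerism_auc_normalized(
    series: ChimerismSeries, bracket: Bracket | None = None
) -> float:
    """Trapezoidal AUC of chimerism over a bracket, normalized by the span.

    The area under the (pod, percent) curve is divided by
    ``pod_last - pod_first`` so the result is a time-averaged percentage in
    [0, 100].  With ``bracket=None`` all points are used.

    Raises
    ------
    ValueError
        With a named condition if fewer than 2 points fall in the bracket,
        or if the points span zero days.
    """
    pts = [
        (pod, pct)
        for pod, pct, _ in series.points
        if bracket is None or assign_bracket(pod) == bracket
    ]
    if len(pts) < 2:
        raise ValueError(
            f"undefined: fewer than 2 points in bracket "
            f"{'all' if bracket is None else bracket.value} for {series.patient_id}"
        )
    pods = np.array([p[0] for p in pts], dtype=float)
    pcts = np.array([p[1] for p in pts], dtype=float)
    span = pods[-1] - pods[0]
    if span == 0:
        raise ValueError(f"{series.patient_id}: pod_last == pod_first, cannot normalize")
    return float(np.trapezoid(pcts, pods) / span)


#: MFI increments over baseline at which a single-antigen bead is called
#: DSA-positive, by specimen type.
DSA_THRESHOLDS = {"serum": 2000.0, "supernatant": 500.0}


def call_dsa_positive(mfi: float, baseline: float, specimen: str) -> bool:
    """Call a single-antigen bead DSA-positive from its MFI reading.

    Positive when the reading exceeds the baseline by at least 2,000 MFI for
    serum or 500 MFI for concentrated culture supernatants (inclusive at the
    printed increment).
    """
    if specimen not in DSA_THRESHOLDS:
        raise ValueError(f"unknown specimen {specimen!r}; expected serum or supernatant")
    if mfi < 0 or baseline < 0:
        raise ValueError("MFI values must be non-negative")
    return (mfi - baseline) >= DSA_THRESHOLDS[specimen]
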