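"""Tissue-label mixing ("clumpiness") within a clonal lineage tree.

For a pair of labels, every label instance scores 2**(-d) where d is the
edge distance from its node to the nearest populated node carrying the
other label; paths passing through the germline root score zero, so two
label-pure clades meeting only at the root give 0, while a tree whose every
populated node carries both labels gives 1.  The clumpiness value is the
mean score over all instances of both labels.
"""

from __future__ import annotations

from collections import deque
from statistics import median
from typing import Hashable, Iterable, Mapping

from clonotrack.lineage import LineageNode, LineageTree

#: Individuals need strictly more than this many contributing clones for
#: their median to be reported.
DEFAULT_MIN_CLONES = 6


def _distances_from(
    source: LineageNode,
    adjacency: Mapping[int, list[LineageNode]],
    root_id: int,
) -> dict[int, int]:
    """BFS edge distances from ``source``, never expanding through the root.

    The root may be reached as an endpoint but acts as a barrier between its
    clades (unless the source is the root itself).
    """
    dist = {source.node_id: 0}
    queue = deque([source])
    while queue:
        node = queue.popleft()
        if node.node_id == root_id and source.node_id != root_id:
            continue  # root is a barrier, not a through-station
        for neigh in adjacency[node.node_id]:
            if neigh.node_id not in dist:
                dist[neigh.node_id] = dist[node.node_id] + 1
                queue.append(neigh)
    return dist


def clumpiness(tree: LineageTree, label_a: Hashable, label_b: Hashable) -> float | None:
    """Mixing of two labels within a lineage, on a 0-1 scale.

    Returns ``None`` (undefined, distinct from 0) when either label is
    absent from the tree's populated nodes.  Symmetric in the two labels and
    insensitive to instances of any other label.
    """
    if label_a == label_b:
        raise ValueError("labels must differ")
    nodes = tree.nodes()
    adjacency: dict[int, list[LineageNode]] = {n.node_id: [] for n in nodes}
    for node in nodes:
        for child in node.children:
            adjacency[node.node_id].append(child)
            adjacency[child.node_id].append(node)
    root_id = tree.root.node_id

    carriers = {
        label: [n for n in nodes if n.populated and n.labels.get(label, 0) > 0]
        for label in (label_a, label_b)
    }
    if not carriers[label_a] or not carriers[label_b]:
        return None

    total_score = 0.0
    total_instances = 0
    for here, there in ((label_a, label_b), (label_b, label_a)):
        targets = {n.node_id for n in carriers[there]}
        for node in carriers[here]:
            count = node.labels[here]
            total_instances += count
            if node.node_id in targets:
                total_score += count * 1.0  # d = 0
                continue
            dist = _distances_from(node, adjacency, root_id)
            reachable = [dist[t] for t in targets if t in dist]
            if reachable:
                total_score += count * 2.0 ** (-min(reachable))
            # else: every path crosses the germline root -> score 0
    return total_score / total_instances


def median_clumpiness(
    results: Iterable[tuple[str, tuple[Hashable, Hashable], float]],
    min_clones: int = DEFAULT_MIN_CLONES,
) -> dict[tuple[str, tuple[Hashable, Hashable]], float]:
    """Per-individual median of per-clone clumpiness values.

    ``results`` holds (individual, label_pair, value) triples; label pairs
    are canonicalized by sorting.  Individuals contributing fewer than
    ``min_clones`` clones for a pair (i.e. not strictly more than 5 at the
    default) are dropped.
    """
    grouped: dict[tuple[str, tuple[Hashable, Hashable]], list[float]] = {}
    for individual, pair, value in results:
        key = (individual, tuple(sorted(pair, key=str)))
        grouped.setdefault(key, []).append(value)
    return {
        key: median(values)
        for key, values in grouped.items()
        if len(values) >= min_clones
    }
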