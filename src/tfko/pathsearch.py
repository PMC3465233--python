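"""Shortest regulatory paths from a knocked-out TF to its knockout targets.

The search is a modified breadth-first search (mBFS): a first-visit BFS
with per-node path bookkeeping that tolerates cycles and self-loops and
terminates early the moment the destination appears as a successor.  A
knockout target is classified by the outcome:

* ``direct`` — shortest path of length 1 (the TF binds the target's promoter);
* ``indirect`` — shortest path of length > 1 (a transcriptional regulatory
  chain through intermediate TFs);
* ``false_positive`` — no path exists in the network.

Targets with a path are the biologically interpretable "signals"; the rest
are "noises".
"""

from __future__ import annotations

import logging
from collections import deque
from collections.abc import Iterable, Mapping
from dataclasses import dataclass
from enum import Enum

from .network import RegulatoryNetwork, eligible_tfs

logger = logging.getLogger(__name__)

__all__ = [
    "PathResult",
    "TargetClassification",
    "RefinedSet",
    "PathConfidence",
    "CoveragePrecision",
    "mbfs_shortest_path",
    "classify_target",
    "refine_targets",
    "path_confidence",
    "coverage_precision",
]


class TargetClassification(str, Enum):
    DIRECT = "direct"
    INDIRECT = "indirect"
    FALSE_POSITIVE = "false_positive"


@dataclass(frozen=True)
class PathResult:
    """Outcome of one mBFS query.

    ``nodes`` runs from the start TF to the destination; ``length`` is the
    edge count.  Both are ``None`` when no path exists.
    """

    found: bool
    nodes: tuple[str, ...] | None = None

    @property
    def length(self) -> int | None:
        return None if self.nodes is None else len(self.nodes) - 1

    @property
    def status(self) -> str:
        return "found" if self.found else "no_path"


def mbfs_shortest_path(
    network: RegulatoryNetwork, start: str, destination: str
) -> PathResult:
    """Find a shortest path from *start* to *destination* by first-visit BFS.

    Successors are expanded in lexicographic order, which makes the single
    reported path canonical when several shortest paths exist.  The
    destination test applies to successors only, so a path from a node to
    itself is found only through a cycle (length >= 1).  A destination
    absent from the network simply yields "no path".

    Raises ``ValueError`` if *start* is not a node of the network.
    """
    if not network.has_node(start):
        raise ValueError(f"start node {start!r} is not in the network")
    waiting: deque[str] = deque([start])
    # First-visit semantics: a node's path is fixed at discovery (enqueue)
    # time, which preserves BFS level order on cyclic graphs.
    discovered: set[str] = {start}
    path: dict[str, tuple[str, ...]] = {start: (start,)}
    while waiting:
        v = waiting.popleft()
        for u in network.successors(v):
            if u == destination:
                return PathResult(found=True, nodes=path[v] + (u,))
            if u not in discovered:
                discovered.add(u)
                path[u] = path[v] + (u,)
                waiting.append(u)
    return PathResult(found=False)


def classify_target(result: PathResult) -> TargetClassification:
    """Map a path-search outcome to the three-way target classification."""
    if not result.found:
        return TargetClassification.FALSE_POSITIVE
    if result.length == 1:
        return TargetClassification.DIRECT
    return TargetClassification.INDIRECT


@dataclass(frozen=True)
class RefinedSet:
    """Per-TF partition of the original knockout targets.

    ``signals`` maps each interpretable target to its path; ``noises`` holds
    the targets with no path.  Together they cover the original target set
    disjointly.
    """

    tf: str
    signals: Mapping[str, PathResult]
    noises: frozenset[str]
    classifications: Mapping[str, TargetClassification]

    @property
    def targets(self) -> frozenset[str]:
        return frozenset(self.signals) | self.noises

    @property
    def interpretable_ratio(self) -> float | None:
        """|signals| / |targets|, or None for an empty target list."""
        n = len(self.signals) + len(self.noises)
        return None if n == 0 else len(self.signals) / n


def refine_targets(
    network: RegulatoryNetwork,
    knockout_sets: Mapping[str, Iterable[str]],
) -> dict[str, RefinedSet]:
    """Run one mBFS query per (TF, target) pair and partition each TF's
    targets into signals and noises.

    TFs without outgoing edges in the network (not analysable) are skipped
    with a warning.  Target lists are deduplicated.
    """
    eligible = eligible_tfs(network, knockout_sets)
    refined: dict[str, RefinedSet] = {}
    for tf in sorted(knockout_sets):
        if tf not in eligible:
            logger.warning(
                "skipping TF %s: no outgoing binding edges in the network", tf
            )
            continue
        targets = sorted(set(knockout_sets[tf]))
        signals: dict[str, PathResult] = {}
        noises: set[str] = set()
        classes: dict[str, TargetClassification] = {}
        for target in targets:
            result = mbfs_shortest_path(network, tf, target)
            classes[target] = classify_target(result)
            if result.found:
                signals[target] = result
            else:
                noises.add(target)
        refined[tf] = RefinedSet(
            tf=tf,
            signals=signals,
            noises=frozenset(noises),
            classifications=classes,
        )
        ratio = refined[tf].interpretable_ratio
        logger.info(
            "TF %s: %d/%d targets interpretable (%s)",
            tf,
            len(signals),
            len(targets),
            "n/a" if ratio is None else f"{ratio:.3f}",
        )
    return refined


@dataclass(frozen=True)
class PathConfidence:
    """Fraction of path edges that carry literature evidence of TF regulation."""

    supported_edges: int
    total_edges: int

    @property
    def score(self) -> float:
        return self.supported_edges / self.total_edges


def path_confidence(result: PathResult, network: RegulatoryNetwork) -> PathConfidence:
    """Confidence of a found path: the ratio of its TF->gene steps that have
    regulation evidence (along the direction of the path)."""
    if not result.found or result.nodes is None:
        raise ValueError("path confidence is defined only for found paths")
    supported = 0
    edges = list(zip(result.nodes[:-1], result.nodes[1:]))
    for tf, target in edges:
        if network.regulation_supported(tf, target):
            supported += 1
    return PathConfidence(supported_edges=supported, total_edges=len(edges))


@dataclass(frozen=True)
class CoveragePrecision:
    """Coverage: fraction of original targets that are interpretable, pooled
    over TFs.  Precision: unweighted mean path-confidence score over all
    found paths (None when no path was found)."""

    coverage: float
    precision: float | None


def coverage_precision(
    refined: Mapping[str, RefinedSet], network: RegulatoryNetwork
) -> CoveragePrecision:
    """Pool the coverage/precision tradeoff over a refined collection."""
    n_signals = sum(len(r.signals) for r in refined.values())
    n_total = sum(len(r.signals) + len(r.noises) for r in refined.values())
    if n_total == 0:
        raise ValueError("coverage is undefined for an empty target collection")
    scores = [
        path_confidence(res, network).score
        for r in refined.values()
        for res in r.signals.values()
    ]
    precision = sum(scores) / len(scores) if scores else None
    if precision is None:
        logger.warning("no found paths; precision reported as missing")
    return CoveragePrecision(coverage=n_signals / n_total, precision=precision)
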