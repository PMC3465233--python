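"""Directed TF binding / regulatory network: data model and TSV I/O.

A node is a gene; a directed edge TF -> gene records ChIP-chip binding
evidence for the TF at that gene's promoter, optionally reinforced by
literature evidence of actual regulation.  Two network flavours are used:
the *binding* network keeps every edge with binding evidence, while the
stricter *binding_and_regulation* network keeps only edges supported by
both kinds of evidence.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import NamedTuple

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SupportMode",
    "EdgeRecord",
    "RegulatoryNetwork",
    "normalize_gene_id",
    "load_alias_map",
    "load_edges",
    "write_edges",
    "build_network",
    "eligible_tfs",
]


class SupportMode(str, Enum):
    """Evidence requirement for keeping an edge in the network."""

    BINDING = "binding"
    BINDING_AND_REGULATION = "binding_and_regulation"


def normalize_gene_id(name: str, alias_map: Mapping[str, str] | None = None) -> str:
    """Normalize a gene identifier: strip surrounding whitespace, uppercase,
    then resolve through an optional alias->canonical map.

    Normalization is idempotent provided the alias map is transitively
    resolved (see :func:`load_alias_map`).
    """
    token = str(name).strip().upper()
    if not token:
        raise ValueError(f"empty gene identifier after normalization: {name!r}")
    if any(c.isspace() for c in token):
        raise ValueError(f"gene identifier contains internal whitespace: {name!r}")
    if alias_map is not None:
        token = alias_map.get(token, token)
    return token


def load_alias_map(path: str | Path) -> dict[str, str]:
    """Read a two-column alias->canonical TSV and transitively resolve it.

    Chains (a->b, b->c) collapse to a->c so that normalization with the
    returned map is idempotent; cycles raise an error.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["alias", "canonical"], dtype=str)
    raw = {
        normalize_gene_id(a): normalize_gene_id(c)
        for a, c in zip(df["alias"], df["canonical"])
    }
    resolved: dict[str, str] = {}
    for alias in raw:
        seen = [alias]
        cur = alias
        while cur in raw:
            cur = raw[cur]
            if cur in seen:
                raise ValueError(f"alias cycle detected: {' -> '.join(seen + [cur])}")
            seen.append(cur)
        resolved[alias] = cur
    return resolved


class EdgeRecord(NamedTuple):
    """One directed TF -> target edge with its evidence flags."""

    tf: str
    target: str
    binding: bool
    regulation: bool

    def validate(self) -> "EdgeRecord":
        if not (self.binding or self.regulation):
            raise ValueError(
                f"edge {self.tf}->{self.target} carries no evidence flag"
            )
        return self


# Accepted column names for the two TSV dialects.
_DEFAULT_DIALECT = {
    "tf": "tf",
    "target": "target",
    "evidence": "evidence",
    "binding": "binding",
    "regulation": "regulation",
}


def load_edges(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    alias_map: Mapping[str, str] | None = None,
) -> list[EdgeRecord]:
    """Read an edge-list TSV into :class:`EdgeRecord` rows.

    Two dialects are recognised: a single ``evidence`` column holding a
    comma-separated subset of ``{binding, regulation}``, or two 0/1 flag
    columns ``binding`` and ``regulation``.  Column names may be remapped
    through *dialect*.  Duplicate (tf, target) rows are merged by OR-ing
    their evidence flags; the merge count is logged.
    """
    names = dict(_DEFAULT_DIALECT)
    if dialect:
        names.update(dialect)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (names["tf"], names["target"]):
        if col not in df.columns:
            raise ValueError(f"edge file {path} is missing required column {col!r}")
    has_evidence = names["evidence"] in df.columns
    has_flags = names["binding"] in df.columns and names["regulation"] in df.columns
    if not has_evidence and not has_flags:
        raise ValueError(
            f"edge file {path} is missing evidence columns: expected "
            f"{names['evidence']!r} or {names['binding']!r}/{names['regulation']!r}"
        )
    if df.empty:
        logger.warning("edge file %s contains a header only; no edges loaded", path)
        return []

    merged: dict[tuple[str, str], tuple[bool, bool]] = {}
    order: list[tuple[str, str]] = []
    n_merged = 0
    for _, row in df.iterrows():
        tf = normalize_gene_id(row[names["tf"]], alias_map)
        target = normalize_gene_id(row[names["target"]], alias_map)
        if has_evidence:
            tokens = {
                t.strip().lower()
                for t in str(row[names["evidence"]]).split(",")
                if t.strip()
            }
            unknown = tokens - {"binding", "regulation"}
            if unknown:
                raise ValueError(
                    f"unknown evidence token(s) {sorted(unknown)} in {path}"
                )
            binding = "binding" in tokens
            regulation = "regulation" in tokens
        else:
            binding = str(row[names["binding"]]).strip() in {"1", "true", "True"}
            regulation = str(row[names["regulation"]]).strip() in {"1", "true", "True"}
        key = (tf, target)
        if key in merged:
            b0, r0 = merged[key]
            merged[key] = (b0 or binding, r0 or regulation)
            n_merged += 1
        else:
            merged[key] = (binding, regulation)
            order.append(key)
    if n_merged:
        logger.info("merged %d duplicate edge rows in %s", n_merged, path)
    return [
        EdgeRecord(tf, target, *merged[(tf, target)]).validate() for tf, target in order
    ]


def write_edges(edges: Iterable[EdgeRecord], path: str | Path) -> None:
    """Write edges as a TSV in the ``evidence`` dialect, sorted by (tf, target)
    so that identical edge multisets serialize byte-identically."""
    rows = []
    for e in sorted(set(edges)):
        tokens = [name for name, flag in
                  (("binding", e.binding), ("regulation", e.regulation)) if flag]
        rows.append((e.tf, e.target, ",".join(tokens)))
    pd.DataFrame(rows, columns=["tf", "target", "evidence"]).to_csv(
        path, sep="\t", index=False
    )


@dataclass(frozen=True)
class RegulatoryNetwork:
    """Immutable directed network over gene identifiers.

    ``adjacency`` maps each source gene to its successors in lexicographic
    order (the determinism contract for path search); ``edge_evidence``
    keeps the (binding, regulation) flags of every retained edge.
    """

    support_mode: SupportMode
    adjacency: Mapping[str, tuple[str, ...]]
    edge_evidence: Mapping[tuple[str, str], tuple[bool, bool]]
    nodes: frozenset[str] = field(default_factory=frozenset)

    def has_node(self, gene: str) -> bool:
        return gene in self.nodes

    def successors(self, gene: str) -> tuple[str, ...]:
        return self.adjacency.get(gene, ())

    def has_edge(self, tf: str, target: str) -> bool:
        return (tf, target) in self.edge_evidence

    def regulation_supported(self, tf: str, target: str) -> bool:
        """Whether the edge carries literature evidence of TF regulation."""
        return self.edge_evidence[(tf, target)][1]

    @property
    def source_nodes(self) -> frozenset[str]:
        """Genes with at least one outgoing edge (the TF side of the network)."""
        return frozenset(g for g, succ in self.adjacency.items() if succ)

    @property
    def n_edges(self) -> int:
        return len(self.edge_evidence)

    def to_edge_records(self) -> list[EdgeRecord]:
        return [
            EdgeRecord(tf, tgt, b, r)
            for (tf, tgt), (b, r) in sorted(self.edge_evidence.items())
        ]


def build_network(
    edges: Sequence[EdgeRecord], mode: SupportMode = SupportMode.BINDING
) -> RegulatoryNetwork:
    """Assemble a :class:`RegulatoryNetwork`, dropping edges that fail the
    mode's evidence requirement.

    Under ``binding`` mode an edge needs binding evidence; under
    ``binding_and_regulation`` it needs both flags.  Self-loops are kept (a
    TF may bind its own promoter).  The result is independent of input
    order: successors are sorted and evidence flags of duplicates OR-ed.
    """
    mode = SupportMode(mode)
    evidence: dict[tuple[str, str], tuple[bool, bool]] = {}
    for e in edges:
        e.validate()
        key = (e.tf, e.target)
        b, r = evidence.get(key, (False, False))
        evidence[key] = (b or e.binding, r or e.regulation)
    if mode is SupportMode.BINDING:
        kept = {k: v for k, v in evidence.items() if v[0]}
    else:
        kept = {k: v for k, v in evidence.items() if v[0] and v[1]}
    adjacency: dict[str, list[str]] = {}
    nodes: set[str] = set()
    for tf, target in kept:
        adjacency.setdefault(tf, []).append(target)
        nodes.add(tf)
        nodes.add(target)
    adj = {tf: tuple(sorted(succ)) for tf, succ in sorted(adjacency.items())}
    return RegulatoryNetwork(
        support_mode=mode,
        adjacency=adj,
        edge_evidence=dict(sorted(kept.items())),
        nodes=frozenset(nodes),
    )


def eligible_tfs(network: RegulatoryNetwork, knockout_tfs: Iterable[str]) -> set[str]:
    """Knockout TFs with enough binding data to analyse, proxied as having at
    least one outgoing edge in the constructed network."""
    sources = network.source_nodes
    return {tf for tf in knockout_tfs if tf in sources}
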