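"""Readers and writers for the flat-text formats the pipeline exchanges.

Everything is plain TSV/GMT/JSON: knockout-target lists (tf/target pairs),
refined-target tables with the identified path, expression matrices (first
column gene id, remaining columns numeric conditions, ``NA`` for missing),
two-column undirected PPI edge lists, and GMT annotation files.
"""

from __future__ import annotations

import json
from collections.abc import Iterable, Mapping, Set as AbstractSet
from pathlib import Path

import numpy as np
import pandas as pd

from .network import RegulatoryNetwork, normalize_gene_id
from .pathsearch import RefinedSet, path_confidence

__all__ = [
    "read_targets",
    "write_targets",
    "read_expression",
    "write_expression",
    "read_ppi_edges",
    "write_ppi_edges",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "write_gene_list",
    "write_refined",
    "read_refined_sets",
]


def read_targets(
    path: str | Path, alias_map: Mapping[str, str] | None = None
) -> dict[str, list[str]]:
    """Read a knockout-target TSV with columns ``tf`` and ``target`` into an
    ordered mapping TF -> deduplicated sorted target list."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("tf", "target"):
        if col not in df.columns:
            raise ValueError(f"target file {path} is missing column {col!r}")
    sets: dict[str, set[str]] = {}
    for tf, target in zip(df["tf"], df["target"]):
        sets.setdefault(normalize_gene_id(tf, alias_map), set()).add(
            normalize_gene_id(target, alias_map)
        )
    return {tf: sorted(targets) for tf, targets in sorted(sets.items())}


def write_targets(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    rows = [(tf, t) for tf in sorted(sets) for t in sorted(set(sets[tf]))]
    pd.DataFrame(rows, columns=["tf", "target"]).to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Expression TSV: first column the gene id, remaining columns numeric
    condition values (``NA`` allowed)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.index = df.index.map(normalize_gene_id)
    return df.astype(float)


def write_expression(expression: pd.DataFrame, path: str | Path) -> None:
    expression.to_csv(path, sep="\t", index_label="gene", na_rep="NA", float_format="%.6g")


def read_ppi_edges(path: str | Path) -> list[tuple[str, str]]:
    """Two-column TSV of undirected gene pairs; self-pairs are dropped."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns[:2])
    pairs = []
    for a, b in zip(df[cols[0]], df[cols[1]]):
        a, b = normalize_gene_id(a), normalize_gene_id(b)
        if a != b:
            pairs.append((min(a, b), max(a, b)))
    return sorted(set(pairs))


def write_ppi_edges(edges: Iterable[tuple[str, str]], path: str | Path) -> None:
    rows = sorted({(min(a, b), max(a, b)) for a, b in edges if a != b})
    pd.DataFrame(rows, columns=["gene_a", "gene_b"]).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, frozenset[str]]:
    """GMT: one term per line — term id, description, then member genes,
    tab-separated."""
    terms: dict[str, frozenset[str]] = {}
    with open(path) as handle:
        for line in handle:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not fields[0]:
                continue
            terms[fields[0]] = frozenset(
                normalize_gene_id(g) for g in fields[2:] if g.strip()
            )
    return terms


def write_gmt(
    terms: Mapping[str, AbstractSet[str]],
    path: str | Path,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    with open(path, "w") as handle:
        for term_id in sorted(terms):
            desc = (descriptions or {}).get(term_id, "na")
            genes = "\t".join(sorted(terms[term_id]))
            handle.write(f"{term_id}\t{desc}\t{genes}\n")


def read_gene_list(path: str | Path) -> frozenset[str]:
    """One gene per line (used for an explicit universe file)."""
    with open(path) as handle:
        return frozenset(
            normalize_gene_id(line) for line in handle if line.strip()
        )


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as handle:
        for g in sorted(set(genes)):
            handle.write(g + "\n")


def write_refined(
    refined: Mapping[str, RefinedSet],
    network: RegulatoryNetwork,
    path: str | Path,
) -> None:
    """Refined-target table: one row per (tf, target) with the
    classification, the identified path (nodes joined by ``->``), its
    length, and its confidence score."""
    rows = []
    for tf in sorted(refined):
        r = refined[tf]
        for target in sorted(r.targets):
            cls = r.classifications[target]
            if target in r.signals:
                result = r.signals[target]
                conf = path_confidence(result, network).score
                rows.append(
                    (
                        tf,
                        target,
                        cls.value,
                        "->".join(result.nodes),
                        result.length,
                        f"{conf:.6g}",
                    )
                )
            else:
                rows.append((tf, target, cls.value, "", "", ""))
    pd.DataFrame(
        rows,
        columns=["tf", "target", "classification", "path", "path_length", "confidence"],
    ).to_csv(path, sep="\t", index=False)


def read_refined_sets(path: str | Path, signals_only: bool = True) -> dict[str, frozenset[str]]:
    """Load a refined-target table back as TF -> gene set (by default only
    the interpretable targets, i.e. the refined collection)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if signals_only:
        df = df[df["classification"] != "false_positive"]
    out: dict[str, set[str]] = {}
    for tf, target in zip(df["tf"], df["target"]):
        out.setdefault(tf, set()).add(target)
    return {tf: frozenset(v) for tf, v in sorted(out.items())}


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as handle:
        json.dump(obj, handle, indent=2, sort_keys=True, default=default)
        handle.write("\n")
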