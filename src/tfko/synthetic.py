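"""Synthetic data with planted ground truth for the whole pipeline.

The generator emulates the five inputs the method consumes — a TF binding
network (ChIP-chip style), per-TF knockout-target lists, an expression
compendium, a physical PPI network, and annotation term sets — and records
the planted truth for every one of them:

* each (TF, target) pair's category (direct / indirect / unreachable) and,
  for reachable targets, the minimal path length, verified at generation
  time with an independent breadth-first reachability pass (networkx);
* which genes share a coherent expression block, and with what factor
  loading;
* which gene sets received a planted PPI module;
* which annotation terms were planted as enriched.

Unreachable targets are guaranteed by construction: a reserved fraction of
genes receives no incoming edges at all.  Reachability truth is still
recomputed exhaustively so the truth can never drift from the emitted
network.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence, Set as AbstractSet
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd

from .network import EdgeRecord, RegulatoryNetwork, SupportMode, build_network
from .pathsearch import TargetClassification

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate_network",
    "generate_knockout_sets",
    "generate_expression",
    "generate_ppi",
    "generate_annotations",
    "generate_dataset",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters.

    Defaults emulate the regime observed on the real yeast data: per TF,
    ~6% of knockout targets directly bound, ~84% reachable through a
    regulatory chain, ~10% unreachable, and ~18% of binding edges backed by
    literature regulation evidence.  Problem sizes (gene count, TF count,
    condition count) are desk-scale stand-ins for the genome-wide inputs.
    """

    n_genes: int = 3000
    n_tfs: int = 50
    out_degree_mean: float = 60.0
    targets_per_tf: int = 100
    planted_fractions: tuple[float, float, float] = (0.06, 0.84, 0.10)
    regulation_flag_density: float = 0.18
    unreachable_fraction: float = 0.10
    n_conditions: int = 50
    coherence_loading: float = 0.7
    ppi_module_density: float = 0.9
    ppi_background_density: float = 0.01
    n_terms: int = 80
    term_size_range: tuple[int, int] = (15, 40)
    term_enrichment_strength: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.planted_fractions) - 1.0) > 1e-9:
            raise ValueError("planted_fractions must sum to 1")
        if min(self.planted_fractions) < 0:
            raise ValueError("planted_fractions must be nonnegative")
        for name in ("n_genes", "targets_per_tf", "n_conditions", "n_terms"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_tfs < 0 or self.n_tfs > self.n_genes:
            raise ValueError("n_tfs must lie in [0, n_genes]")
        if not (0.0 <= self.coherence_loading <= 1.0):
            raise ValueError("coherence_loading must lie in [0, 1]")
        for name in (
            "regulation_flag_density",
            "ppi_module_density",
            "ppi_background_density",
            "term_enrichment_strength",
        ):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def target_counts(self) -> tuple[int, int, int]:
        """Planted (direct, indirect, unreachable) counts per TF."""
        n = self.targets_per_tf
        n_direct = round(self.planted_fractions[0] * n)
        n_unreachable = round(self.planted_fractions[2] * n)
        n_indirect = n - n_direct - n_unreachable
        if n_indirect < 0:
            raise ValueError("planted fractions round to more targets than requested")
        return n_direct, n_indirect, n_unreachable

    @property
    def min_out_degree(self) -> int:
        # Every TF needs enough out-neighbours to host its planted direct
        # targets; one spare avoids forcing every neighbour into the list.
        return max(1, self.target_counts[0] + 1)


@dataclass
class SyntheticTruth:
    """Planted ground truth accumulated as the dataset is generated."""

    distances: dict[str, dict[str, int]] = field(default_factory=dict)
    unreachable_pool: frozenset[str] = frozenset()
    categories: dict[str, dict[str, TargetClassification]] = field(default_factory=dict)
    planted_path_length: dict[str, dict[str, int]] = field(default_factory=dict)
    block_loading: float = 0.0
    block_membership: dict[str, tuple[str, ...]] = field(default_factory=dict)
    module_sets: dict[str, frozenset[str]] = field(default_factory=dict)
    planted_terms: dict[str, str] = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["unreachable_pool"] = sorted(self.unreachable_pool)
        d["categories"] = {
            tf: {g: c.value for g, c in m.items()} for tf, m in self.categories.items()
        }
        d["block_membership"] = {
            g: list(b) for g, b in self.block_membership.items()
        }
        d["module_sets"] = {k: sorted(v) for k, v in self.module_sets.items()}
        return d


def _gene_names(config: SyntheticConfig) -> tuple[list[str], list[str], list[str]]:
    """(tf_genes, regular_genes, unreachable_pool) covering n_genes names."""
    tfs = [f"TF{i:03d}" for i in range(config.n_tfs)]
    n_other = config.n_genes - config.n_tfs
    others = [f"G{i:04d}" for i in range(n_other)]
    pool_size = min(n_other, round(config.unreachable_fraction * config.n_genes))
    # The pool receives no incoming edges, so its genes are unreachable
    # from every TF by construction.
    pool = others[n_other - pool_size:]
    regular = others[: n_other - pool_size]
    return tfs, regular, pool


def generate_network(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[RegulatoryNetwork, SyntheticTruth]:
    """Emit a binding network with Poisson out-degrees on the TF genes.

    A deterministic cycle over the TFs keeps the TF subgraph strongly
    connected, so every TF has a deep reachable set for planting indirect
    targets.  Regulation flags are drawn i.i.d. at
    ``regulation_flag_density``.  Exhaustive per-TF shortest-path lengths
    (networkx BFS) are stored as reachability truth.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    tfs, regular, pool = _gene_names(config)
    candidates = tfs + regular  # pool genes never receive edges
    edges: list[EdgeRecord] = []
    for i, tf in enumerate(tfs):
        succ: set[str] = set()
        if len(tfs) > 1:
            succ.add(tfs[(i + 1) % len(tfs)])
        available = [g for g in candidates if g != tf and g not in succ]
        k = int(rng.poisson(config.out_degree_mean))
        k = min(max(k, config.min_out_degree) - len(succ), len(available))
        if k > 0:
            picks = rng.choice(len(available), size=k, replace=False)
            succ.update(available[j] for j in sorted(picks.tolist()))
        for target in sorted(succ):
            regulation = bool(rng.random() < config.regulation_flag_density)
            edges.append(EdgeRecord(tf, target, binding=True, regulation=regulation))
    network = build_network(edges, SupportMode.BINDING)

    digraph = nx.DiGraph()
    digraph.add_nodes_from(tfs + regular + pool)
    digraph.add_edges_from((e.tf, e.target) for e in edges)
    distances = {
        tf: dict(nx.single_source_shortest_path_length(digraph, tf)) for tf in tfs
    }
    truth = SyntheticTruth(distances=distances, unreachable_pool=frozenset(pool))
    # Generation-time verification: the reserved pool must be unreachable.
    for tf, dist in distances.items():
        leaked = truth.unreachable_pool & set(dist)
        if leaked:
            raise RuntimeError(
                f"generator invariant violated: {sorted(leaked)} reachable from {tf}"
            )
    return network, truth


def generate_knockout_sets(
    network: RegulatoryNetwork,
    truth: SyntheticTruth,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, list[str]]:
    """Sample per-TF knockout-target lists hitting the planted fractions.

    Direct targets come from the TF's out-neighbours (distance 1), indirect
    targets from genes reachable at distance >= 2, unreachable targets from
    genes with no path from the TF.  Exact categories and minimal path
    lengths are recorded in *truth*.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    n_direct, n_indirect, n_unreachable = config.target_counts
    all_genes = sorted(network.nodes | truth.unreachable_pool)
    knockout_sets: dict[str, list[str]] = {}
    for tf in sorted(truth.distances):
        dist = truth.distances[tf]
        direct_pool = sorted(g for g, d in dist.items() if d == 1)
        indirect_pool = sorted(g for g, d in dist.items() if d >= 2)
        unreachable_pool = sorted(set(all_genes) - set(dist) - {tf})
        for name, pool, need in (
            ("direct", direct_pool, n_direct),
            ("indirect", indirect_pool, n_indirect),
            ("unreachable", unreachable_pool, n_unreachable),
        ):
            if len(pool) < need:
                raise ValueError(
                    f"TF {tf}: only {len(pool)} candidate(s) for planted "
                    f"category {name!r}, need {need}"
                )
        chosen: dict[str, TargetClassification] = {}
        lengths: dict[str, int] = {}
        for pool, need, category in (
            (direct_pool, n_direct, TargetClassification.DIRECT),
            (indirect_pool, n_indirect, TargetClassification.INDIRECT),
            (unreachable_pool, n_unreachable, TargetClassification.FALSE_POSITIVE),
        ):
            picks = rng.choice(len(pool), size=need, replace=False)
            for j in sorted(picks.tolist()):
                gene = pool[j]
                chosen[gene] = category
                if category is not TargetClassification.FALSE_POSITIVE:
                    lengths[gene] = dist[gene]
        truth.categories[tf] = chosen
        truth.planted_path_length[tf] = lengths
        knockout_sets[tf] = sorted(chosen)
    return knockout_sets


def signal_noise_split(
    truth: SyntheticTruth,
) -> tuple[dict[str, frozenset[str]], dict[str, frozenset[str]]]:
    """Planted signal (direct + indirect) and noise sets per TF."""
    signals = {
        tf: frozenset(
            g
            for g, c in cats.items()
            if c is not TargetClassification.FALSE_POSITIVE
        )
        for tf, cats in truth.categories.items()
    }
    noises = {
        tf: frozenset(
            g for g, c in cats.items() if c is TargetClassification.FALSE_POSITIVE
        )
        for tf, cats in truth.categories.items()
    }
    return signals, noises


def generate_expression(
    gene_sets: Mapping[str, AbstractSet[str]],
    universe: Sequence[str],
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    truth: SyntheticTruth | None = None,
) -> pd.DataFrame:
    """Latent-factor expression matrix (genes x conditions).

    Each gene set is a coherent block with its own standard-normal factor
    f_b per condition.  A gene in blocks B follows

        x = lambda * sum_{b in B} f_b / sqrt(|B|) + sqrt(1 - lambda^2) * eps,

    with loading lambda = ``coherence_loading`` and independent
    standard-normal noise eps; genes in no block are pure noise.  For
    disjoint blocks this is the classic one-factor model with within-block
    pairwise correlation lambda^2; overlapping blocks share proportionally
    less.
    """
    if config.n_conditions < 3:
        raise ValueError("need at least 3 conditions")
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    lam = config.coherence_loading
    universe = sorted(universe)
    membership: dict[str, list[str]] = {}
    factors: dict[str, np.ndarray] = {}
    for name in sorted(gene_sets):
        factors[name] = rng.standard_normal(config.n_conditions)
        for g in sorted(gene_sets[name]):
            membership.setdefault(g, []).append(name)
    data = rng.standard_normal((len(universe), config.n_conditions))
    data *= math.sqrt(1.0 - lam * lam)
    for i, g in enumerate(universe):
        blocks = membership.get(g)
        if blocks:
            shared = np.sum([factors[b] for b in blocks], axis=0)
            data[i] += lam * shared / math.sqrt(len(blocks))
    if truth is not None:
        truth.block_loading = lam
        truth.block_membership = {g: tuple(b) for g, b in membership.items()}
    columns = [f"C{j:04d}" for j in range(config.n_conditions)]
    return pd.DataFrame(data, index=universe, columns=columns)


def generate_ppi(
    gene_sets: Mapping[str, AbstractSet[str]],
    universe: Sequence[str],
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    truth: SyntheticTruth | None = None,
) -> list[tuple[str, str]]:
    """Undirected PPI edges: Erdos–Renyi background over the universe at
    ``ppi_background_density``, with pairs internal to a planted gene set
    wired instead at ``ppi_module_density``.

    Equal densities therefore collapse to a pure Erdos–Renyi graph.
    """
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    universe = sorted(universe)
    index = {g: i for i, g in enumerate(universe)}
    within: set[tuple[int, int]] = set()
    for name in sorted(gene_sets):
        members = sorted(index[g] for g in gene_sets[name] if g in index)
        for a_pos, a in enumerate(members):
            for b in members[a_pos + 1:]:
                within.add((a, b))
    edges: list[tuple[str, str]] = []
    for a, b in sorted(within):
        if rng.random() < config.ppi_module_density:
            edges.append((universe[a], universe[b]))
    n = len(universe)
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(iu.size) < config.ppi_background_density
    for a, b in zip(iu[mask].tolist(), ju[mask].tolist()):
        if (a, b) not in within:
            edges.append((universe[a], universe[b]))
    if truth is not None:
        truth.module_sets = {
            name: frozenset(gene_sets[name]) for name in sorted(gene_sets)
        }
    return sorted(edges)


def generate_annotations(
    gene_sets: Mapping[str, AbstractSet[str]],
    universe: Sequence[str],
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    truth: SyntheticTruth | None = None,
) -> dict[str, frozenset[str]]:
    """Annotation term sets in the spirit of pre-propagated GO slims.

    One planted term per gene set oversamples that set: each of its genes
    is drawn from the set with probability ``term_enrichment_strength`` and
    from the whole universe otherwise.  ``n_terms`` background terms sample
    the universe uniformly.
    """
    rng = np.random.default_rng(config.seed + 4) if rng is None else rng
    universe = sorted(universe)
    lo, hi = config.term_size_range
    terms: dict[str, frozenset[str]] = {}
    planted: dict[str, str] = {}
    for name in sorted(gene_sets):
        members = sorted(gene_sets[name])
        size = int(rng.integers(lo, hi + 1))
        n_from_set = min(len(members), int(rng.binomial(size, config.term_enrichment_strength)))
        picked: set[str] = set()
        if n_from_set:
            idx = rng.choice(len(members), size=n_from_set, replace=False)
            picked.update(members[i] for i in sorted(idx.tolist()))
        remaining = sorted(set(universe) - picked)
        n_fill = min(size - len(picked), len(remaining))
        if n_fill > 0:
            idx = rng.choice(len(remaining), size=n_fill, replace=False)
            picked.update(remaining[i] for i in sorted(idx.tolist()))
        term_id = f"TERM_{name}"
        terms[term_id] = frozenset(picked)
        planted[term_id] = name
    for i in range(config.n_terms):
        size = int(rng.integers(10, 61))
        idx = rng.choice(len(universe), size=min(size, len(universe)), replace=False)
        terms[f"BG{i:03d}"] = frozenset(universe[j] for j in sorted(idx.tolist()))
    if truth is not None:
        truth.planted_terms = planted
    return terms


@dataclass
class SyntheticDataset:
    """Everything one pipeline run needs, plus the planted truth."""

    config: SyntheticConfig
    network: RegulatoryNetwork
    truth: SyntheticTruth
    knockout_sets: dict[str, list[str]]
    signal_sets: dict[str, frozenset[str]]
    noise_sets: dict[str, frozenset[str]]
    expression: pd.DataFrame
    ppi_edges: list[tuple[str, str]]
    annotations: dict[str, frozenset[str]]

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(self.expression.index)


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate all five inputs from one seed, with independent sub-streams
    per stage so regenerating one stage never perturbs another."""
    children = np.random.SeedSequence(config.seed).spawn(5)
    rngs = [np.random.default_rng(c) for c in children]
    network, truth = generate_network(config, rngs[0])
    knockout_sets = generate_knockout_sets(network, truth, config, rngs[1])
    signals, noises = signal_noise_split(truth)
    universe = sorted(network.nodes | truth.unreachable_pool)
    expression = generate_expression(signals, universe, config, rngs[2], truth)
    ppi_edges = generate_ppi(signals, universe, config, rngs[3], truth)
    annotations = generate_annotations(signals, universe, config, rngs[4], truth)
    return SyntheticDataset(
        config=config,
        network=network,
        truth=truth,
        knockout_sets=knockout_sets,
        signal_sets=signals,
        noise_sets=noises,
        expression=expression,
        ppi_edges=ppi_edges,
        annotations=annotations,
    )
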