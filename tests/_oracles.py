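"""Independent brute-force oracles used only by the test suite.

Each oracle takes a deliberately different computational route from the
implementation it checks: shortest paths via boolean matrix powers and via
exhaustive simple-path enumeration, the hypergeometric tail via exact
factorial rationals, the one-sided rank-sum via full permutation
enumeration, and the PPI module via a literal double loop over the
definition.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb, factorial

import networkx as nx
import numpy as np


def shortest_lengths_matrix_power(adjacency: np.ndarray) -> np.ndarray:
    """All-pairs shortest walk lengths by boolean matrix powers.

    Entry (i, j) is the smallest k >= 1 with (A^k)[i, j] > 0, or 0 when no
    walk exists (note: the diagonal answers "shortest cycle through i").
    A shortest walk never repeats a node, so this equals the shortest
    simple-path (or simple-cycle) length.
    """
    a = adjacency.astype(bool)
    n = a.shape[0]
    lengths = np.zeros((n, n), dtype=int)
    power = a.copy()
    for k in range(1, n + 1):
        newly = power & (lengths == 0)
        lengths[newly] = k
        power = (power.astype(int) @ a.astype(int)) > 0
    return lengths


def shortest_length_enumeration(graph: nx.DiGraph, s, t) -> int | None:
    """Shortest s->t length by exhaustive simple-path (or, for s == t,
    simple-cycle) enumeration; None when no path exists."""
    if s == t:
        best = None
        for u in graph.successors(s):
            if u == s:
                return 1
            for path in nx.all_simple_paths(graph, u, s):
                length = len(path)  # edge s->u adds one step
                if best is None or length < best:
                    best = length
        return best
    best = None
    if t in graph:
        for path in nx.all_simple_paths(graph, s, t):
            length = len(path) - 1
            if best is None or length < best:
                best = length
    return best


def hypergeom_tail_exact(v: int, s: int, t: int, g: int) -> Fraction:
    """Upper-tail hypergeometric probability as an exact rational, computed
    from factorials."""

    def c(n: int, k: int) -> int:
        if k < 0 or k > n:
            return 0
        return factorial(n) // (factorial(k) * factorial(n - k))

    total = sum(c(s, x) * c(g - s, t - x) for x in range(v, min(s, t) + 1))
    return Fraction(total, c(g, t))


def hypergeom_pmf_mass(s: int, t: int, g: int) -> Fraction:
    """Total probability mass of the hypergeometric pmf over its support."""
    def c(n: int, k: int) -> int:
        if k < 0 or k > n:
            return 0
        return factorial(n) // (factorial(k) * factorial(n - k))

    lo = max(0, s + t - g)
    return Fraction(
        sum(c(s, x) * c(g - s, t - x) for x in range(lo, min(s, t) + 1)), c(g, t)
    )


def ranksum_greater_exact(a, b) -> Fraction:
    """Exact one-sided rank-sum p-value P(W >= w_obs) under the permutation
    null, by enumerating every assignment of pooled ranks to the first
    sample.  Requires tie-free data."""
    pooled = sorted(list(a) + list(b))
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = {value: i + 1 for i, value in enumerate(pooled)}
    w_obs = sum(ranks[x] for x in a)
    n, m = len(a), len(b)
    hits = 0
    total = comb(n + m, n)
    for assignment in combinations(range(1, n + m + 1), n):
        if sum(assignment) >= w_obs:
            hits += 1
    return Fraction(hits, total)


def ppi_module_bruteforce(gene_set, edges):
    """Literal double-loop evaluation of the core/neighborhood definition."""
    gene_set = set(gene_set)
    undirected = {frozenset(e) for e in edges if e[0] != e[1]}

    def interacts(x, y) -> bool:
        return frozenset((x, y)) in undirected

    everyone = {g for e in undirected for g in e} | gene_set
    core = {
        g
        for g in gene_set
        if any(interacts(g, h) for h in gene_set if h != g)
    }
    neighborhood = {
        h
        for h in everyone - gene_set
        if any(interacts(h, c) for c in core)
    }
    return core, neighborhood


def random_digraph(rng: np.random.Generator, n_nodes: int, edge_prob: float):
    """Random directed graph (self-loops allowed) as an adjacency matrix and
    the matching RegulatoryNetwork edge list."""
    return rng.random((n_nodes, n_nodes)) < edge_prob
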