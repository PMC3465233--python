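"""Validation statistics for TF target-set collections.

Three measures of biological meaningfulness, applicable to any mapping of
TF -> gene set:

1. *Functional enrichment* — per-set hypergeometric term enrichment against
   pre-propagated annotation sets, summarised per TF as the sum of
   |log10 p| over terms significant at an FDR cutoff, and over a collection
   as the sum of the per-TF scores.
2. *Expression coherence* — the distribution of absolute pairwise Pearson
   correlations within a set; two sets are compared by a one-sided Wilcoxon
   rank-sum test of stochastic superiority.
3. *PPI-module membership* — Reimand-style module (core genes: in the set
   with a physical interaction partner inside the set; neighborhood genes:
   outside the set with a partner in the core) tested with the upper-tail
   hypergeometric p-value for the set/module overlap in the gene universe.

Multiple testing across TFs (or across terms) is controlled with the
Benjamini–Hochberg step-up procedure.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Mapping, Sequence, Set as AbstractSet
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichedTerm",
    "EnrichmentScore",
    "CoherenceResult",
    "PPIModule",
    "ValidationResources",
    "ValidationReport",
    "hypergeometric_upper_tail",
    "ppi_adjacency",
    "build_ppi_module",
    "ppi_module_test",
    "term_enrichment",
    "enrichment_score",
    "aggregate_enrichment",
    "pairwise_abs_correlation",
    "coherence_test",
    "bh_fdr",
    "validate_collection",
]


def hypergeometric_upper_tail(
    overlap: int, set_size: int, module_size: int, universe_size: int
) -> float:
    """P(X >= overlap) for X ~ Hypergeometric(universe, set, module).

    This is the p-value for rejecting "the gene set is not enriched for
    membership in the module": with a universe of G genes, a set S and a
    module T, the chance that a random T-sized draw overlaps S in at least
    V genes,

        p = sum_{x=V}^{min(S,T)} C(S,x) C(G-S, T-x) / C(G,T).

    Computed in exact integer arithmetic (one rational division at the
    end), so it is stable for universes up to ~1e5 genes.
    """
    v, s, t, g = overlap, set_size, module_size, universe_size
    if not (0 <= s <= g and 0 <= t <= g and 0 <= v <= min(s, t)):
        raise ValueError(
            f"invalid hypergeometric input: V={v}, S={s}, T={t}, G={g}"
        )
    support_lo = max(0, s + t - g)
    if v <= support_lo:
        return 1.0  # tail covers the whole support
    # term(x) = C(S,x) C(G-S,T-x); recurrences keep the arithmetic exact.
    num = math.comb(s, v) * math.comb(g - s, t - v)
    total = num
    for x in range(v, min(s, t)):
        num = num * (s - x) // (x + 1)
        num = num * (t - x) // (g - s - t + x + 1)
        total += num
    return float(Fraction(total, math.comb(g, t)))


def ppi_adjacency(edges: Iterable[tuple[str, str]]) -> dict[str, set[str]]:
    """Build an undirected adjacency map from gene pairs; self-pairs are
    dropped (a protein interacting with itself carries no module signal)."""
    adj: dict[str, set[str]] = {}
    for a, b in edges:
        if a == b:
            continue
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    return adj


@dataclass(frozen=True)
class PPIModule:
    """Core genes (in the set, interacting with the set) plus neighborhood
    genes (outside the set, interacting with the core)."""

    core: frozenset[str]
    neighborhood: frozenset[str]

    @property
    def genes(self) -> frozenset[str]:
        return self.core | self.neighborhood

    @property
    def size(self) -> int:
        return len(self.core) + len(self.neighborhood)


def _as_adjacency(
    ppi: Mapping[str, AbstractSet[str]] | Iterable[tuple[str, str]],
) -> Mapping[str, AbstractSet[str]]:
    if isinstance(ppi, Mapping):
        return ppi
    return ppi_adjacency(ppi)


def build_ppi_module(
    gene_set: AbstractSet[str],
    ppi: Mapping[str, AbstractSet[str]] | Iterable[tuple[str, str]],
) -> PPIModule:
    """Construct the PPI module of a gene set.

    Core genes are members of the set with at least one physical
    interaction partner inside the set; neighborhood genes are non-members
    with at least one partner among the core genes.
    """
    adj = _as_adjacency(ppi)
    gene_set = set(gene_set)
    core = {g for g in gene_set if adj.get(g, frozenset()) & gene_set}
    neighborhood: set[str] = set()
    for g in core:
        neighborhood |= adj[g]
    neighborhood -= gene_set
    return PPIModule(core=frozenset(core), neighborhood=frozenset(neighborhood))


def ppi_module_test(
    gene_set: AbstractSet[str],
    ppi: Mapping[str, AbstractSet[str]] | Iterable[tuple[str, str]],
    universe: AbstractSet[str],
) -> float:
    """Upper-tail hypergeometric p-value for the gene set being in a PPI
    module: V = |set ∩ module| (= the core), S = |set|, T = |module|,
    G = |universe|.  Genes outside the universe are dropped with a warning.
    """
    if not universe:
        raise ValueError("empty gene universe")
    gene_set = set(gene_set)
    outside = gene_set - set(universe)
    if outside:
        logger.warning(
            "dropping %d gene(s) outside the universe from the PPI test", len(outside)
        )
        gene_set -= outside
    module = build_ppi_module(gene_set, ppi)
    return hypergeometric_upper_tail(
        overlap=len(module.core),
        set_size=len(gene_set),
        module_size=module.size,
        universe_size=len(universe),
    )


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values, order-aligned with the
    input.  NaN entries (untestable hypotheses) are passed through and do
    not count toward the number of tests."""
    p = np.asarray(p_values, dtype=float)
    mask = ~np.isnan(p)
    if ((p[mask] <= 0) | (p[mask] > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    q = np.full_like(p, np.nan)
    pv = p[mask]
    m = pv.size
    if m:
        order = np.argsort(pv, kind="stable")
        ranked = pv[order] * m / np.arange(1, m + 1)
        adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(adjusted, 1.0)
        q[mask] = out
    return q


@dataclass(frozen=True)
class EnrichedTerm:
    term_id: str
    p_value: float
    q_value: float
    enriched: bool
    overlap: int


def term_enrichment(
    gene_set: AbstractSet[str],
    annotations: Mapping[str, AbstractSet[str]],
    universe: AbstractSet[str],
    fdr: float = 0.05,
) -> list[EnrichedTerm]:
    """Hypergeometric term enrichment of a gene set against annotation sets.

    Annotation sets are intersected with the universe; terms with no genes
    in the universe are skipped.  BH correction is applied across all
    tested terms, and a term is flagged enriched when q <= *fdr*.
    """
    universe = set(universe)
    gene_set = set(gene_set) & universe
    g = len(universe)
    rows: list[tuple[str, int, float]] = []
    for term_id in sorted(annotations):
        term_genes = set(annotations[term_id]) & universe
        if not term_genes:
            continue
        v = len(gene_set & term_genes)
        p = hypergeometric_upper_tail(v, len(gene_set), len(term_genes), g)
        rows.append((term_id, v, p))
    if not rows:
        logger.warning("no annotation terms overlap the universe")
        return []
    q_values = bh_fdr([p for _, _, p in rows])
    return [
        EnrichedTerm(term_id, p, q, bool(q <= fdr), v)
        for (term_id, v, p), q in zip(rows, q_values)
    ]


@dataclass(frozen=True)
class EnrichmentScore:
    tf: str
    score: float
    n_enriched: int


# Smallest positive double; p-values of 0 are clamped here before the log.
_P_FLOOR = float(np.nextafter(0, 1))


def enrichment_score(
    terms: Sequence[EnrichedTerm], tf: str = "", log_base: float = 10.0
) -> EnrichmentScore:
    """Sum of |log p| over the enriched terms (log10 by default).

    Zero when nothing is enriched; additive over terms, hence invariant to
    their order.
    """
    contributions = []
    for term in terms:
        if not term.enriched:
            continue
        p = term.p_value
        if p <= 0.0:
            logger.warning("clamping p=0 for term %s before log", term.term_id)
            p = _P_FLOOR
        contributions.append(abs(math.log(p, log_base)))
    # summing in sorted order makes the float result permutation-invariant
    return EnrichmentScore(
        tf=tf, score=math.fsum(sorted(contributions)), n_enriched=len(contributions)
    )


def aggregate_enrichment(scores: Iterable[EnrichmentScore]) -> float:
    """Aggregate enrichment score of a collection: the sum over TFs."""
    return float(sum(s.score for s in scores))


def pairwise_abs_correlation(
    expression: pd.DataFrame, gene_set: AbstractSet[str]
) -> np.ndarray:
    """Absolute Pearson correlation for every unordered pair of set genes
    present in the expression matrix (genes x conditions).

    Correlations use pairwise-complete observations, so missing entries are
    tolerated.  Pairs where either profile has zero variance are skipped
    (their correlation is undefined); the skip count is logged.
    """
    present = sorted(set(gene_set) & set(expression.index))
    if len(present) < 2:
        logger.warning(
            "fewer than two set genes present in the expression matrix"
        )
        return np.empty(0)
    sub = expression.loc[present].astype(float)
    corr = sub.T.corr(min_periods=2).to_numpy()
    iu = np.triu_indices(len(present), k=1)
    values = corr[iu]
    n_skipped = int(np.isnan(values).sum())
    if n_skipped:
        logger.info("skipped %d gene pair(s) with undefined correlation", n_skipped)
    return np.abs(values[~np.isnan(values)])


@dataclass(frozen=True)
class CoherenceResult:
    tf: str
    n_pairs_a: int
    n_pairs_b: int
    p_value: float
    significant_after_fdr: bool


def coherence_test(dist_a: Sequence[float], dist_b: Sequence[float]) -> float:
    """One-sided Wilcoxon rank-sum p-value for "dist_a is stochastically
    greater than dist_b".

    The exact null distribution is used when both samples have at most 12
    values and the pooled data are tie-free; otherwise the normal
    approximation with tie and continuity corrections.
    """
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("coherence test requires two non-empty samples")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0.0:
        return 1.0  # every ranking tied: no evidence of superiority
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size <= 12 and b.size <= 12 and no_ties) else "asymptotic"
    result = stats.mannwhitneyu(a, b, alternative="greater", method=method)
    return float(result.pvalue)


@dataclass(frozen=True)
class ValidationResources:
    """External evidence used by the three validation measures."""

    expression: pd.DataFrame
    ppi: Mapping[str, AbstractSet[str]]
    annotations: Mapping[str, AbstractSet[str]]
    universe: frozenset[str]

    @classmethod
    def build(
        cls,
        expression: pd.DataFrame,
        ppi: Mapping[str, AbstractSet[str]] | Iterable[tuple[str, str]],
        annotations: Mapping[str, AbstractSet[str]],
        universe: Iterable[str],
    ) -> "ValidationResources":
        return cls(
            expression=expression,
            ppi=_as_adjacency(ppi),
            annotations=annotations,
            universe=frozenset(universe),
        )


@dataclass
class ValidationReport:
    """Per-TF statistics and collection-level summary of an A-vs-B comparison."""

    per_tf: pd.DataFrame
    summary: dict = field(default_factory=dict)


def validate_collection(
    sets_a: Mapping[str, AbstractSet[str]],
    sets_b: Mapping[str, AbstractSet[str]],
    resources: ValidationResources,
    fdr: float = 0.05,
    label_a: str = "a",
    label_b: str = "b",
) -> ValidationReport:
    """Compare two target-set collections with the three validation measures.

    For every TF present on both sides: enrichment scores for both sets;
    one-sided coherence tests in both directions, BH-corrected across TFs
    per direction; PPI-module tests for both sets, BH-corrected across TFs
    per side.  The summary reports, per measure, how many TFs each side
    wins (equal-or-higher / strictly higher enrichment score, significantly
    higher coherence, enriched module membership and strictly smaller
    module p-value).
    """
    if not (0 < fdr < 1):
        raise ValueError("fdr threshold must lie in (0, 1)")
    for name, value in (
        ("expression", resources.expression),
        ("ppi", resources.ppi),
        ("annotations", resources.annotations),
        ("universe", resources.universe),
    ):
        if value is None or (name == "universe" and not value):
            raise ValueError(f"missing validation resource: {name}")
    common = sorted(set(sets_a) & set(sets_b))
    dropped = (set(sets_a) | set(sets_b)) - set(common)
    if dropped:
        logger.warning(
            "dropping %d TF(s) present on only one side: %s",
            len(dropped),
            ", ".join(sorted(dropped)),
        )
    if not common:
        raise ValueError("no TFs shared between the two collections")

    rows = []
    for tf in common:
        set_a = set(sets_a[tf])
        set_b = set(sets_b[tf])
        score_a = enrichment_score(
            term_enrichment(set_a, resources.annotations, resources.universe, fdr), tf
        )
        score_b = enrichment_score(
            term_enrichment(set_b, resources.annotations, resources.universe, fdr), tf
        )
        dist_a = pairwise_abs_correlation(resources.expression, set_a)
        dist_b = pairwise_abs_correlation(resources.expression, set_b)
        if dist_a.size and dist_b.size:
            p_a_gt_b = coherence_test(dist_a, dist_b)
            p_b_gt_a = coherence_test(dist_b, dist_a)
        else:
            logger.warning("TF %s: coherence untestable (too few expression pairs)", tf)
            p_a_gt_b = p_b_gt_a = np.nan
        ppi_p_a = ppi_module_test(set_a, resources.ppi, resources.universe)
        ppi_p_b = ppi_module_test(set_b, resources.ppi, resources.universe)
        rows.append(
            {
                "tf": tf,
                "enrichment_score_a": score_a.score,
                "enrichment_score_b": score_b.score,
                "n_pairs_a": int(dist_a.size),
                "n_pairs_b": int(dist_b.size),
                "coherence_p_a_gt_b": p_a_gt_b,
                "coherence_p_b_gt_a": p_b_gt_a,
                "ppi_p_a": ppi_p_a,
                "ppi_p_b": ppi_p_b,
            }
        )
    per_tf = pd.DataFrame(rows)
    per_tf["coherence_q_a_gt_b"] = bh_fdr(per_tf["coherence_p_a_gt_b"])
    per_tf["coherence_q_b_gt_a"] = bh_fdr(per_tf["coherence_p_b_gt_a"])
    per_tf["ppi_q_a"] = bh_fdr(per_tf["ppi_p_a"])
    per_tf["ppi_q_b"] = bh_fdr(per_tf["ppi_p_b"])

    sig_a = (per_tf["coherence_q_a_gt_b"] <= fdr).sum()
    sig_b = (per_tf["coherence_q_b_gt_a"] <= fdr).sum()
    summary = {
        "label_a": label_a,
        "label_b": label_b,
        "n_tfs": len(per_tf),
        "fdr": fdr,
        "aggregate_enrichment_a": float(per_tf["enrichment_score_a"].sum()),
        "aggregate_enrichment_b": float(per_tf["enrichment_score_b"].sum()),
        "enrichment_a_ge_b": int(
            (per_tf["enrichment_score_a"] >= per_tf["enrichment_score_b"]).sum()
        ),
        "enrichment_a_gt_b": int(
            (per_tf["enrichment_score_a"] > per_tf["enrichment_score_b"]).sum()
        ),
        "enrichment_b_gt_a": int(
            (per_tf["enrichment_score_b"] > per_tf["enrichment_score_a"]).sum()
        ),
        "coherence_sig_a": int(sig_a),
        "coherence_sig_b": int(sig_b),
        "ppi_enriched_a": int((per_tf["ppi_q_a"] <= fdr).sum()),
        "ppi_enriched_b": int((per_tf["ppi_q_b"] <= fdr).sum()),
        "ppi_smaller_p_a": int((per_tf["ppi_p_a"] < per_tf["ppi_p_b"]).sum()),
        "ppi_smaller_p_b": int((per_tf["ppi_p_b"] < per_tf["ppi_p_a"]).sum()),
    }
    return ValidationReport(per_tf=per_tf, summary=summary)
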