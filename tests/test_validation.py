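"""Hypergeometric enrichment, coherence testing, PPI modules and FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from _oracles import (
    hypergeom_pmf_mass,
    hypergeom_tail_exact,
    ppi_module_bruteforce,
    ranksum_greater_exact,
)
from tfko.validation import (
    ValidationResources,
    aggregate_enrichment,
    bh_fdr,
    build_ppi_module,
    coherence_test,
    enrichment_score,
    hypergeometric_upper_tail,
    pairwise_abs_correlation,
    ppi_module_test,
    term_enrichment,
    validate_collection,
)


class TestHypergeometricUpperTail:
    def test_zero_overlap_sums_full_mass(self):
        assert hypergeometric_upper_tail(0, 5, 6, 20) == 1.0

    def test_set_equal_to_universe_is_degenerate(self):
        # every draw lies in the set, so the overlap is always T
        assert hypergeometric_upper_tail(6, 20, 6, 20) == 1.0

    def test_matches_exact_rational_oracle(self):
        value = hypergeometric_upper_tail(4, 5, 6, 20)
        exact = float(hypergeom_tail_exact(4, 5, 6, 20))
        assert value == pytest.approx(exact, rel=1e-12)

    def test_matches_scipy_survival_function(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            g = int(rng.integers(2, 2000))
            s = int(rng.integers(1, g + 1))
            t = int(rng.integers(1, g + 1))
            v = int(rng.integers(max(0, s + t - g), min(s, t) + 1))
            ours = hypergeometric_upper_tail(v, s, t, g)
            ref = stats.hypergeom.sf(v - 1, g, s, t)
            assert ours == pytest.approx(ref, rel=1e-9, abs=1e-300)

    def test_monotone_nonincreasing_in_overlap(self):
        g, s, t = 100, 20, 30
        tails = [hypergeometric_upper_tail(v, s, t, g) for v in range(0, 21)]
        assert all(a >= b for a, b in zip(tails, tails[1:]))

    def test_pmf_mass_conserved(self):
        # the tail at the bottom of the support is the whole pmf
        for g, s, t in [(10, 3, 7), (25, 12, 20), (30, 30, 15)]:
            lo = max(0, s + t - g)
            assert hypergeometric_upper_tail(lo, s, t, g) == 1.0
            assert hypergeom_pmf_mass(s, t, g) == 1

    def test_large_universe_stable(self):
        p = hypergeometric_upper_tail(40, 200, 500, 100_000)
        assert 0.0 < p < 1e-30  # deep tail, no under/overflow to 0 or nan

    @pytest.mark.parametrize("v,s,t,g", [(6, 5, 6, 20), (1, 25, 6, 20), (-1, 5, 6, 20)])
    def test_invalid_inputs_rejected(self, v, s, t, g):
        with pytest.raises(ValueError):
            hypergeometric_upper_tail(v, s, t, g)


class TestPPIModule:
    def test_definition_example(self):
        module = build_ppi_module({"A", "B", "C"}, [("A", "B"), ("B", "X")])
        assert module.core == {"A", "B"}
        assert module.neighborhood == {"X"}

    def test_no_internal_interactions_gives_empty_module(self):
        module = build_ppi_module({"A", "B"}, [("A", "X"), ("B", "Y")])
        assert module.core == frozenset() and module.neighborhood == frozenset()

    def test_matches_bruteforce_definition_on_random_instances(self):
        rng = np.random.default_rng(11)
        genes = [f"G{i:02d}" for i in range(30)]
        for _ in range(50):
            edges = [
                (genes[i], genes[j])
                for i in range(30)
                for j in range(i + 1, 30)
                if rng.random() < 0.08
            ]
            gene_set = set(rng.choice(genes, size=8, replace=False).tolist())
            module = build_ppi_module(gene_set, edges)
            core, neighborhood = ppi_module_bruteforce(gene_set, edges)
            assert module.core == core
            assert module.neighborhood == neighborhood
            assert module.core <= gene_set
            assert not (module.neighborhood & gene_set)

    def test_empty_module_gives_p_one(self):
        universe = {f"G{i}" for i in range(50)}
        assert ppi_module_test({"G1", "G2"}, [], universe) == 1.0

    def test_fully_connected_universe_degenerates_gracefully(self):
        genes = [f"G{i}" for i in range(12)]
        edges = [(a, b) for i, a in enumerate(genes) for b in genes[i + 1:]]
        p = ppi_module_test(set(genes[:4]), edges, set(genes))
        assert 0.0 < p <= 1.0

    def test_genes_outside_universe_dropped(self, caplog):
        universe = {"A", "B", "C", "D"}
        with caplog.at_level("WARNING"):
            p = ppi_module_test({"A", "B", "ZZ"}, [("A", "B")], universe)
        assert "outside the universe" in caplog.text
        assert p == hypergeometric_upper_tail(2, 2, 2, 4)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            ppi_module_test({"A"}, [], set())


class TestTermEnrichment:
    def test_set_identical_to_term_is_enriched(self):
        universe = {f"G{i}" for i in range(100)}
        term_genes = frozenset(list(sorted(universe))[:10])
        result = term_enrichment(term_genes, {"T1": term_genes}, universe)
        assert len(result) == 1 and result[0].enriched

    def test_term_covering_whole_universe_never_enriched(self):
        universe = {f"G{i}" for i in range(50)}
        annotations = {"T1": frozenset(universe), "T2": frozenset(universe)}
        result = term_enrichment(set(list(universe)[:5]), annotations, universe)
        assert all(t.p_value == 1.0 and not t.enriched for t in result)

    def test_no_overlapping_terms_warns_and_returns_empty(self, caplog):
        with caplog.at_level("WARNING"):
            result = term_enrichment({"A"}, {"T1": {"ZZ"}}, {"A", "B"})
        assert result == []


class TestEnrichmentScore:
    def _terms(self, pairs):
        from tfko.validation import EnrichedTerm

        return [
            EnrichedTerm(f"T{i}", p, p, enriched, 1)
            for i, (p, enriched) in enumerate(pairs)
        ]

    def test_no_enriched_terms_scores_zero(self):
        assert enrichment_score(self._terms([(0.5, False)])).score == 0.0

    def test_sum_of_absolute_log10_p(self):
        terms = self._terms([(0.01, True), (0.001, True), (0.2, False)])
        assert enrichment_score(terms).score == pytest.approx(5.0)

    def test_permutation_invariant(self):
        terms = self._terms([(0.01, True), (0.001, True), (0.04, True)])
        assert (
            enrichment_score(terms).score
            == enrichment_score(terms[::-1]).score
        )

    def test_zero_p_clamped_not_infinite(self, caplog):
        with caplog.at_level("WARNING"):
            score = enrichment_score(self._terms([(0.0, True)])).score
        assert np.isfinite(score) and score > 300

    def test_aggregate_is_a_plain_sum(self):
        from tfko.validation import EnrichmentScore

        scores = [EnrichmentScore("A", 5.0, 1), EnrichmentScore("B", 2.0, 1)]
        assert aggregate_enrichment(scores) == 7.0
        assert aggregate_enrichment(scores[::-1]) == 7.0
        assert aggregate_enrichment([]) == 0.0


class TestPairwiseAbsCorrelation:
    def test_identical_rows_correlate_perfectly(self):
        expr = pd.DataFrame(
            [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]], index=["A", "B"]
        )
        assert pairwise_abs_correlation(expr, {"A", "B"}) == pytest.approx([1.0])

    def test_anticorrelation_counts_as_coherence(self):
        expr = pd.DataFrame([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]], index=["A", "B"])
        assert pairwise_abs_correlation(expr, {"A", "B"}) == pytest.approx([1.0])

    def test_orthogonal_centered_rows_give_zero(self):
        expr = pd.DataFrame(
            [[-1.0, 1.0, -1.0, 1.0], [-1.0, 1.0, 1.0, -1.0]], index=["A", "B"]
        )
        assert pairwise_abs_correlation(expr, {"A", "B"}) == pytest.approx([0.0])

    def test_pair_count_is_m_choose_2(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.standard_normal((6, 10)),
                            index=[f"G{i}" for i in range(6)])
        values = pairwise_abs_correlation(expr, {f"G{i}" for i in range(5)})
        assert values.size == 10  # C(5,2); G5 ignored, absent genes too

    def test_zero_variance_rows_skipped(self):
        expr = pd.DataFrame(
            [[1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [2.0, 4.0, 6.0]],
            index=["FLAT", "A", "B"],
        )
        values = pairwise_abs_correlation(expr, {"FLAT", "A", "B"})
        assert values == pytest.approx([1.0])  # only the A-B pair survives

    def test_missing_values_use_pairwise_complete_columns(self):
        expr = pd.DataFrame(
            [[1.0, 2.0, 3.0, np.nan], [1.0, 2.0, 3.0, 100.0]], index=["A", "B"]
        )
        assert pairwise_abs_correlation(expr, {"A", "B"}) == pytest.approx([1.0])

    def test_fewer_than_two_present_genes_yields_empty(self):
        expr = pd.DataFrame([[1.0, 2.0]], index=["A"])
        assert pairwise_abs_correlation(expr, {"A", "MISSING"}).size == 0


class TestCoherenceTest:
    def test_exact_p_matches_permutation_oracle(self):
        a = [0.9, 0.95, 0.99]
        b = [0.1, 0.15, 0.2]
        assert coherence_test(a, b) == pytest.approx(
            float(ranksum_greater_exact(a, b))
        )
        # swapping sides gives the complementary tail of the same null
        assert coherence_test(b, a) == pytest.approx(
            float(ranksum_greater_exact(b, a))
        )

    @given(
        st.lists(st.integers(0, 10_000), min_size=2, max_size=6, unique=True),
        st.lists(st.integers(10_001, 20_000), min_size=2, max_size=6, unique=True),
    )
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_exact_route_agrees_with_enumeration(self, a_raw, b_raw):
        a = [x / 20_000 for x in a_raw]
        b = [x / 20_000 for x in b_raw]
        assert coherence_test(a, b) == pytest.approx(
            float(ranksum_greater_exact(a, b))
        )

    def test_identical_samples_give_no_evidence(self):
        values = [0.2, 0.4, 0.6, 0.8]
        assert coherence_test(values, values) >= 0.5
        assert coherence_test([1.0] * 5, [1.0] * 5) == 1.0

    def test_large_samples_use_tie_corrected_normal_approximation(self):
        rng = np.random.default_rng(5)
        a = rng.choice([0.1, 0.2, 0.3, 0.9], size=50).tolist()
        b = rng.choice([0.1, 0.2, 0.3], size=60).tolist()
        p = coherence_test(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="greater", method="asymptotic")
        assert p == pytest.approx(float(ref.pvalue))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            coherence_test([], [0.1])


class TestBHFDR:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_stepup_hand_example(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_identical_ps_unchanged(self):
        assert bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_matches_statsmodels_reference(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(17)
        for _ in range(200):
            p = rng.uniform(1e-12, 1.0, size=int(rng.integers(1, 40)))
            ours = bh_fdr(p)
            ref = multipletests(p, method="fdr_bh")[1]
            assert ours == pytest.approx(ref, rel=1e-12)
            assert (ours >= p - 1e-15).all()

    def test_nan_passthrough_excluded_from_m(self):
        q = bh_fdr([0.01, np.nan, 0.02])
        assert np.isnan(q[1])
        assert q[[0, 2]] == pytest.approx(bh_fdr([0.01, 0.02]))

    @pytest.mark.parametrize("bad", [[0.0, 0.1], [-0.1], [1.5]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            bh_fdr(bad)


def _tiny_resources(rng, genes):
    expr = pd.DataFrame(
        rng.standard_normal((len(genes), 12)), index=sorted(genes)
    )
    edges = [("G00", "G01"), ("G01", "G02"), ("G05", "G06")]
    annotations = {"T1": frozenset(sorted(genes)[:6])}
    return ValidationResources.build(expr, edges, annotations, genes)


class TestValidateCollection:
    GENES = frozenset(f"G{i:02d}" for i in range(20))

    def test_self_comparison_is_symmetric_and_silent(self):
        rng = np.random.default_rng(0)
        resources = _tiny_resources(rng, self.GENES)
        sets = {"TF1": frozenset(["G00", "G01", "G02", "G03"]),
                "TF2": frozenset(["G05", "G06", "G07"])}
        report = validate_collection(sets, sets, resources)
        assert report.summary["coherence_sig_a"] == 0
        assert report.summary["coherence_sig_b"] == 0
        assert (
            report.per_tf["enrichment_score_a"].tolist()
            == report.per_tf["enrichment_score_b"].tolist()
        )
        assert report.summary["ppi_smaller_p_a"] == 0

    def test_single_tf_collection_produces_one_row(self):
        rng = np.random.default_rng(1)
        resources = _tiny_resources(rng, self.GENES)
        sets = {"TF1": frozenset(["G00", "G01", "G02"])}
        report = validate_collection(sets, sets, resources)
        assert len(report.per_tf) == 1
        q = report.per_tf["coherence_q_a_gt_b"]
        assert ((q.dropna() > 0) & (q.dropna() <= 1)).all()

    def test_asymmetric_tf_keys_dropped_with_warning(self, caplog):
        rng = np.random.default_rng(2)
        resources = _tiny_resources(rng, self.GENES)
        a = {"TF1": frozenset(["G00", "G01"]), "ONLYA": frozenset(["G02", "G03"])}
        b = {"TF1": frozenset(["G00", "G01"])}
        with caplog.at_level("WARNING"):
            report = validate_collection(a, b, resources)
        assert report.summary["n_tfs"] == 1
        assert "ONLYA" in caplog.text

    def test_missing_resource_named_in_error(self):
        rng = np.random.default_rng(3)
        resources = _tiny_resources(rng, self.GENES)
        broken = ValidationResources(
            expression=resources.expression,
            ppi=resources.ppi,
            annotations=resources.annotations,
            universe=frozenset(),
        )
        with pytest.raises(ValueError, match="universe"):
            validate_collection(
                {"TF1": frozenset(["G00"])}, {"TF1": frozenset(["G00"])}, broken
            )
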