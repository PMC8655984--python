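"""Permutation Z-score, linkage score, and enrichment-score screening."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rwrscreen import (
    CandidateSet,
    ConfigError,
    EmptyInputError,
    EnrichmentVector,
    GeneSet,
    MissingNodeError,
    PermutationNull,
    RWRScreenError,
    apply_filters,
    build_network,
    cosine_similarity,
    enrichment_score,
    enrichment_vector,
    enrichment_vectors,
    hypergeom_tail_score,
    max_enrichment_score,
    max_linkage_score,
    permutation_test,
    read_gmt,
    rwr,
    select_candidates,
    z_score,
)
from rwrscreen.io import AnnotationMap
from conftest import random_connected_net


def exact_tail_score(N, M, n, m):
    """Exhaustive hypergeometric upper tail by exact rational enumeration."""
    tail = sum(
        Fraction(math.comb(M, k) * math.comb(N - M, n - k), math.comb(N, n))
        for k in range(m, min(n, M) + 1)
    )
    return -math.log10(tail)


class TestZScore:
    @pytest.mark.parametrize(
        "pro,prom,prostd,expected",
        [
            (0.5, 0.3, 0.1, 2.0),
            (0.3, 0.3, 0.1, 0.0),
            (0.2, 0.1, 0.0, float("inf")),
            (0.1, 0.2, 0.0, float("-inf")),
            (0.1, 0.1, 0.0, 0.0),
        ],
    )
    def test_values_including_degenerate_std(self, pro, prom, prostd, expected):
        assert z_score(pro, prom, prostd) == expected

    def test_negative_std_rejected(self):
        with pytest.raises(ConfigError):
            z_score(0.1, 0.1, -1e-9)


class TestMaxLinkageScore:
    def test_takes_maximum_over_validated(self):
        net = build_network(
            [("c", "v1", 300), ("c", "v2", 950), ("c", "v3", 10), ("c", "x", 999)]
        )
        validated = GeneSet(identifiers=("v1", "v2", "v3"))
        assert max_linkage_score(net, "c", validated) == 950

    def test_no_adjacency_gives_zero(self):
        net = build_network([("c", "x", 999), ("v1", "x", 999)])
        assert max_linkage_score(net, "c", GeneSet(identifiers=("v1",))) == 0

    def test_exact_900_passes_inclusive_cut(self):
        net = build_network([("c", "v1", 900)])
        mls = max_linkage_score(net, "c", GeneSet(identifiers=("v1",)))
        assert mls == 900 and mls >= 900

    def test_empty_validated_errors(self):
        net = build_network([("c", "v1", 900)])
        with pytest.raises(EmptyInputError):
            max_linkage_score(net, "c", GeneSet(identifiers=()))

    def test_invariant_to_validated_order(self):
        net = build_network([("c", "v1", 300), ("c", "v2", 950)])
        a = max_linkage_score(net, "c", GeneSet(identifiers=("v1", "v2")))
        b = max_linkage_score(net, "c", GeneSet(identifiers=("v2", "v1")))
        assert a == b


@pytest.fixture
def micro_enrichment():
    """Gene g with 4 neighbors; two terms with overlaps 4 and 2; N = 10."""
    net = build_network(
        [("g", "a", 10), ("g", "b", 20), ("g", "c", 30), ("g", "d", 40)]
    )
    ann = AnnotationMap(
        genes_by_term={
            "T_full": frozenset({"a", "b", "c", "d", "e"}),
            "T_half": frozenset({"a", "b", "x", "y", "z"}),
            "T_none": frozenset({"q", "r"}),
        }
    )
    return net, ann


class TestEnrichmentScore:
    def test_hand_computed_overlap_four(self, micro_enrichment):
        net, ann = micro_enrichment
        # single surviving term k=4: C(5,4)C(5,0)/C(10,4) = 5/210
        score = enrichment_score("g", "T_full", ann, net, N=10)
        assert abs(score - (-math.log10(5 / 210))) < 1e-10

    def test_hand_computed_overlap_two(self, micro_enrichment):
        net, ann = micro_enrichment
        # k=2,3,4: (100+50+5)/210
        score = enrichment_score("g", "T_half", ann, net, N=10)
        assert abs(score - (-math.log10(155 / 210))) < 1e-10

    def test_zero_overlap_scores_zero(self, micro_enrichment):
        net, ann = micro_enrichment
        assert enrichment_score("g", "T_none", ann, net, N=10) == 0.0

    def test_impossible_overlap_rejected(self):
        with pytest.raises(RWRScreenError):
            hypergeom_tail_score(10, 5, 4, 5)

    def test_sample_exceeding_population_rejected(self):
        with pytest.raises(ConfigError):
            hypergeom_tail_score(5, 3, 8, 2)

    def test_matches_exact_enumeration_small(self):
        for N in range(1, 13):
            for M in range(N + 1):
                for n in range(N + 1):
                    lo = max(0, n - (N - M))
                    for m in range(min(n, M) + 1):
                        got = hypergeom_tail_score(N, M, n, m)
                        want = exact_tail_score(N, M, n, m)
                        assert abs(got - want) < 1e-10, (N, M, n, m)


class TestEnrichmentVector:
    def test_zero_neighbor_gene_gives_zero_vector(self, micro_enrichment, caplog):
        _, ann = micro_enrichment
        net = build_network([("g", "a", 10), ("iso", "iso", 5)])
        with caplog.at_level("WARNING"):
            v = enrichment_vector("iso", ann, net, N=10)
        assert np.all(v.scores == 0)
        assert "no network neighbors" in caplog.text

    def test_identical_neighbor_sets_give_identical_vectors(self, micro_enrichment):
        _, ann = micro_enrichment
        net = build_network(
            [("g1", "a", 10), ("g1", "b", 20), ("g2", "a", 30), ("g2", "b", 40)]
        )
        v1 = enrichment_vector("g1", ann, net, N=10)
        v2 = enrichment_vector("g2", ann, net, N=10)
        assert np.array_equal(v1.scores, v2.scores)

    def test_single_term_vector_equals_scalar_score(self, micro_enrichment):
        net, _ = micro_enrichment
        ann1 = AnnotationMap(genes_by_term={"T": frozenset({"a", "b", "c", "d", "e"})})
        v = enrichment_vector("g", ann1, net, N=10)
        assert len(v) == 1
        assert v.scores[0] == enrichment_score("g", "T", ann1, net, N=10)

    def test_shared_term_ordering(self, micro_enrichment):
        net, ann = micro_enrichment
        v = enrichment_vector("g", ann, net, N=10)
        assert v.terms == ann.terms


def _ev(name, scores):
    return EnrichmentVector(gene=name, terms=tuple(f"t{i}" for i in range(len(scores))),
                            scores=np.asarray(scores, dtype=float))


class TestCosineSimilarity:
    def test_parallel_vectors(self):
        v = _ev("a", [1.0, 2.0, 3.0])
        w = _ev("b", [2.0, 4.0, 6.0])
        assert abs(cosine_similarity(v, w) - 1.0) < 1e-12

    def test_orthogonal_vectors(self):
        assert cosine_similarity(_ev("a", [1, 0]), _ev("b", [0, 1])) == 0.0

    def test_half_overlap(self):
        assert abs(cosine_similarity(_ev("a", [1, 1, 0]), _ev("b", [1, 0, 1])) - 0.5) < 1e-12

    def test_zero_norm_defined_as_zero(self):
        assert cosine_similarity(_ev("a", [0, 0]), _ev("b", [1, 1])) == 0.0

    def test_length_mismatch_errors(self):
        with pytest.raises(ConfigError):
            cosine_similarity(_ev("a", [1, 0]), _ev("b", [1, 0, 0]))

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(0, 100, allow_nan=False), min_size=2, max_size=8),
        st.lists(st.floats(0, 100, allow_nan=False), min_size=2, max_size=8),
    )
    def test_bounded_on_nonnegative_vectors(self, xs, ys):
        k = min(len(xs), len(ys))
        sim = cosine_similarity(_ev("a", xs[:k]), _ev("b", ys[:k]))
        assert -1e-12 <= sim <= 1.0 + 1e-12


class TestMaxEnrichmentScore:
    def test_identical_vector_gives_one(self):
        vectors = {"c": _ev("c", [1, 2]), "v1": _ev("v1", [2, 4]), "v2": _ev("v2", [1, 0])}
        mes = max_enrichment_score("c", GeneSet(identifiers=("v1", "v2")), vectors)
        assert abs(mes - 1.0) < 1e-12

    def test_orthogonal_to_all_gives_zero(self):
        vectors = {"c": _ev("c", [1, 0]), "v1": _ev("v1", [0, 1])}
        assert max_enrichment_score("c", GeneSet(identifiers=("v1",)), vectors) == 0.0

    def test_takes_maximum_and_order_invariant(self):
        # similarities to v1 / v2 are ~0.3162 and ~0.9487; max must win
        vectors = {
            "c": _ev("c", [1.0, 3.0]),
            "v1": _ev("v1", [1.0, 0.0]),
            "v2": _ev("v2", [0.0, 1.0]),
        }
        a = max_enrichment_score("c", GeneSet(identifiers=("v1", "v2")), vectors)
        b = max_enrichment_score("c", GeneSet(identifiers=("v2", "v1")), vectors)
        assert a == b
        assert abs(a - 3.0 / math.sqrt(10.0)) < 1e-12

    def test_missing_vector_names_gene(self):
        vectors = {"c": _ev("c", [1, 0])}
        with pytest.raises(MissingNodeError, match="v1"):
            max_enrichment_score("c", GeneSet(identifiers=("v1",)), vectors)


class TestPermutationTest:
    def _k4(self):
        nodes = ["a", "b", "c", "d"]
        return build_network(
            [(u, v, 100) for i, u in enumerate(nodes) for v in nodes[i + 1:]]
        )

    def test_symmetric_null_has_zero_std(self):
        # on a complete graph with equal weights every non-self draw gives the
        # candidate the same probability up to summation order
        net = self._k4()
        cands = CandidateSet(items=(("c", 0.1),))
        null = permutation_test(
            net, GeneSet(identifiers=("a",)), cands, n_perm=12, rng_seed=3
        )
        assert null.std[0] <= 1e-15
        assert null.mean[0] > 0

    def test_fixed_seed_is_bit_identical(self):
        net = random_connected_net(20, 5)
        seeds = GeneSet(identifiers=net.nodes[:3])
        p = rwr(net, seeds)
        cands = select_candidates(p, seeds, threshold=1e-4)
        n1 = permutation_test(net, seeds, cands, n_perm=20, rng_seed=7)
        n2 = permutation_test(net, seeds, cands, n_perm=20, rng_seed=7)
        assert np.array_equal(n1.mean, n2.mean)
        assert np.array_equal(n1.std, n2.std)

    def test_too_few_permutations_rejected(self):
        net = self._k4()
        with pytest.raises(ConfigError):
            permutation_test(
                net, GeneSet(identifiers=("a",)),
                CandidateSet(items=(("c", 0.1),)), n_perm=1,
            )

    def test_mean_matches_high_rep_reference(self):
        """Monte-Carlo oracle: a 300-permutation null reproduces the mean of a
        10,000-permutation reference within 3 standard errors per candidate."""
        net = random_connected_net(30, 7)
        seeds = GeneSet(identifiers=net.nodes[:5])
        p = rwr(net, seeds)
        cands = select_candidates(p, seeds, threshold=1e-4)
        assert len(cands) > 5
        small = permutation_test(net, seeds, cands, n_perm=300, rng_seed=1)
        ref = permutation_test(net, seeds, cands, n_perm=10_000, rng_seed=2)
        se = ref.std / np.sqrt(np.maximum(small.n_used, 1))
        assert np.all(np.abs(small.mean - ref.mean) <= 3 * se + 1e-15)


class TestApplyFilters:
    def _scenario(self):
        net = build_network(
            [
                ("c_good", "v1", 998),
                ("c_weak", "v1", 500),
                ("c_good", "v2", 120),
                ("c_weak", "v2", 130),
                ("v1", "v2", 900),
            ]
        )
        validated = GeneSet(identifiers=("v1", "v2"))
        ann = AnnotationMap(
            genes_by_term={
                "T1": frozenset({"v1", "v2", "c_good"}),
                "T2": frozenset({"c_weak", "x"}),
            }
        )
        vectors = enrichment_vectors(net.nodes, ann, net, N=50)
        return net, validated, vectors

    def _null(self, genes, mean, std):
        return PermutationNull(
            genes=tuple(genes), mean=np.asarray(mean, dtype=float),
            std=np.asarray(std, dtype=float), n_perm=100, rng_seed=0,
        )

    def test_all_filters_passing_marks_inferred(self):
        net, validated, vectors = self._scenario()
        cands = CandidateSet(items=(("c_good", 9.7e-5),))
        null = self._null(["c_good"], [1e-5], [1e-5])  # z ~ 8.7
        recs = apply_filters(cands, null, net, validated, vectors,
                             z_cut=1.96, mls_cut=900, mes_cut=0.5)
        (rec,) = recs
        assert rec.z_score > 1.96 and rec.mls == 998
        assert rec.inferred

    def test_z_boundary_is_strict(self):
        net, validated, vectors = self._scenario()
        cands = CandidateSet(items=(("c_good", 1.96),))
        null = self._null(["c_good"], [0.0], [1.0])  # z == 1.96 exactly
        (rec,) = apply_filters(cands, null, net, validated, vectors, mes_cut=0.0)
        assert rec.z_score == 1.96
        assert not rec.pass_permutation and not rec.inferred

    def test_mls_and_mes_boundaries_are_inclusive(self):
        net, validated, vectors = self._scenario()
        cands = CandidateSet(items=(("c_good", 0.5),))
        null = self._null(["c_good"], [0.0], [0.01])
        mes = max_enrichment_score("c_good", validated, vectors)
        recs = apply_filters(cands, null, net, validated, vectors,
                             z_cut=1.96, mls_cut=998, mes_cut=mes)
        (rec,) = recs
        assert rec.pass_linkage and rec.mls == 998
        assert rec.pass_enrichment and rec.mes == mes

    def test_lazy_skips_downstream_scores(self):
        net, validated, vectors = self._scenario()
        cands = CandidateSet(items=(("c_good", 0.0), ("c_weak", 0.5)))
        null = self._null(["c_good", "c_weak"], [0.0, 0.0], [1.0, 0.01])
        recs = apply_filters(cands, null, net, validated, vectors, lazy=True,
                             z_cut=1.96, mls_cut=900, mes_cut=0.98)
        by_gene = {r.gene: r for r in recs}
        assert by_gene["c_good"].mls is None and by_gene["c_good"].mes is None
        assert by_gene["c_weak"].mls == 500 and by_gene["c_weak"].mes is None
        assert not any(r.inferred for r in recs)

    def test_invalid_cuts_rejected(self):
        net, validated, vectors = self._scenario()
        cands = CandidateSet(items=(("c_good", 0.5),))
        null = self._null(["c_good"], [0.0], [1.0])
        for kw in ({"mls_cut": 1500}, {"mes_cut": 1.5}, {"z_cut": float("nan")}):
            with pytest.raises(ConfigError):
                apply_filters(cands, null, net, validated, vectors, **kw)

    def test_candidate_missing_from_null_rejected(self):
        net, validated, vectors = self._scenario()
        cands = CandidateSet(items=(("c_good", 0.5),))
        null = self._null(["c_weak"], [0.0], [1.0])
        with pytest.raises(ConfigError):
            apply_filters(cands, null, net, validated, vectors)
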