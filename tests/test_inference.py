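"""Weighted voting, Gibbs sweeps, rank vectors and rank aggregation."""

from __future__ import annotations

import numpy as np
import pytest

from ppigibbs.containers import (
    AnnotationSet,
    EnrichedNetwork,
    ExplicitNetwork,
)
from ppigibbs.inference import (
    GibbsConfig,
    aggregate_ranks,
    bootstrap,
    gibbs_predict,
    rank_vector,
    sample_assignment,
    weighted_vote,
)

from conftest import random_fixture


def _labels(ann: AnnotationSet) -> dict:
    return {p: ann.functions_of(p) for p in ann.proteins}


class TestWeightedVote:
    def test_worked_two_channel_example(self, vote_fixture):
        enriched, ann = vote_fixture
        d = weighted_vote(
            "X", enriched, _labels(ann), GibbsConfig(lam=0.5), terms=ann.terms
        )
        np.testing.assert_allclose(d.probs, [0.75, 0.25], atol=1e-12)
        assert not d.is_fallback

    def test_unanimous_neighbours_give_point_mass(self):
        net = ExplicitNetwork.from_edges([("X", "A", 1.0), ("X", "B", 2.0)])
        en = EnrichedNetwork(net, {"X": (("A", 7.0),)}, 1)
        labels = {"A": {"F1"}, "B": {"F1"}}
        d = weighted_vote("X", en, labels, GibbsConfig(lam=0.4), terms=("F1", "F2"))
        np.testing.assert_allclose(d.probs, [1.0, 0.0], atol=1e-12)

    def test_empty_implicit_channel_renormalizes_to_explicit(self):
        net = ExplicitNetwork.from_edges([("X", "A", 3.0)])
        en = EnrichedNetwork(net, {"X": ()}, 0)
        d = weighted_vote(
            "X", en, {"A": {"F2"}}, GibbsConfig(lam=0.3), terms=("F1", "F2")
        )
        np.testing.assert_allclose(d.probs, [0.0, 1.0], atol=1e-12)
        assert not d.is_fallback

    def test_multilabel_neighbour_votes_for_all_its_functions(self):
        net = ExplicitNetwork.from_edges([("X", "A", 1.0), ("X", "B", 1.0)])
        en = EnrichedNetwork(net, {"X": ()}, 0)
        d = weighted_vote(
            "X", en, {"A": {"F1", "F2"}, "B": {"F1"}},
            GibbsConfig(lam=0.3), terms=("F1", "F2"),
        )
        np.testing.assert_allclose(d.probs, [2 / 3, 1 / 3], atol=1e-12)

    def test_no_evidence_yields_flagged_fallback_prior(self):
        net = ExplicitNetwork.from_edges([("X", "U", 1.0)])  # U unlabeled
        en = EnrichedNetwork(net, {"X": ()}, 0)
        d = weighted_vote(
            "X", en, {"L1": {"F1"}, "L2": {"F1"}, "L3": {"F2"}},
            GibbsConfig(lam=0.3), terms=("F1", "F2"),
        )
        assert d.is_fallback
        np.testing.assert_allclose(d.probs, [2 / 3, 1 / 3], atol=1e-12)
        d_uni = weighted_vote(
            "X", en, {"L1": {"F1"}, "L2": {"F1"}, "L3": {"F2"}},
            GibbsConfig(lam=0.3, fallback_prior="uniform"), terms=("F1", "F2"),
        )
        np.testing.assert_allclose(d_uni.probs, [0.5, 0.5], atol=1e-12)

    def test_soft_fractional_labels_accepted(self):
        net = ExplicitNetwork.from_edges([("X", "A", 1.0)])
        en = EnrichedNetwork(net, {"X": ()}, 0)
        d = weighted_vote(
            "X", en, {"A": {"F1": 0.25, "F2": 0.75}},
            GibbsConfig(lam=0.3), terms=("F1", "F2"),
        )
        np.testing.assert_allclose(d.probs, [0.25, 0.75], atol=1e-12)


class TestBootstrap:
    def test_matches_weighted_vote_on_fixture(self):
        """Six-node fixture: bootstrap equals weighted_vote restricted to
        labeled proteins."""
        net = ExplicitNetwork.from_edges(
            [("Q", "A", 1.0), ("Q", "B", 2.0), ("Q", "U", 9.0), ("A", "B", 1.0)]
        )
        en = EnrichedNetwork(net, {"Q": (("C", 5.0), ("U2", 3.0))}, 2)
        ann = AnnotationSet.from_mapping(
            {"A": {"F1"}, "B": {"F2"}, "C": {"F1", "F3"}}
        )
        cfg = GibbsConfig(lam=0.3)
        got = bootstrap(en, ann, ["Q"], cfg)["Q"]
        want = weighted_vote("Q", en, _labels(ann), cfg, terms=ann.terms)
        np.testing.assert_array_equal(got.probs, want.probs)

    def test_only_unlabeled_neighbours_fallback_flagged(self):
        net = ExplicitNetwork.from_edges([("Q", "U", 1.0)])
        en = EnrichedNetwork(net, {p: () for p in net.proteins}, 0)
        ann = AnnotationSet.from_mapping({"L": {"F1"}})
        d = bootstrap(en, ann, ["Q"], GibbsConfig())["Q"]
        assert d.is_fallback

    def test_single_labeled_neighbour_point_mass(self):
        net = ExplicitNetwork.from_edges([("Q", "A", 1.0)])
        en = EnrichedNetwork(net, {p: () for p in net.proteins}, 0)
        ann = AnnotationSet.from_mapping({"A": {"F3"}, "B": {"F1"}, "C": {"F2"}})
        d = bootstrap(en, ann, ["Q"], GibbsConfig())["Q"]
        assert d.argmax_term() == "F3"
        assert d.probs[list(ann.terms).index("F3")] == 1.0

    def test_annotated_query_rejected(self):
        net = ExplicitNetwork.from_edges([("A", "B", 1.0)])
        en = EnrichedNetwork(net, {p: () for p in net.proteins}, 0)
        ann = AnnotationSet.from_mapping({"A": {"F1"}, "B": {"F2"}})
        with pytest.raises(ValueError, match="annotated"):
            bootstrap(en, ann, ["A"], GibbsConfig())


class TestSampling:
    def test_degenerate_distribution_always_first(self):
        rng = np.random.default_rng(0)
        assert all(sample_assignment([1.0, 0.0], rng) == 0 for _ in range(50))

    def test_empirical_frequency_matches_probabilities(self):
        rng = np.random.default_rng(123)
        draws = [sample_assignment([0.5, 0.5], rng) for _ in range(10_000)]
        freq = np.mean(np.array(draws) == 0)
        assert 0.47 <= freq <= 0.53

    def test_same_seed_identical_sequence(self):
        r1 = np.random.default_rng(9)
        r2 = np.random.default_rng(9)
        s1 = [sample_assignment([0.3, 0.2, 0.5], r1) for _ in range(100)]
        s2 = [sample_assignment([0.3, 0.2, 0.5], r2) for _ in range(100)]
        assert s1 == s2

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            sample_assignment([0.0, 0.0], np.random.default_rng(0))


class TestRankVector:
    def test_descending_argsort(self):
        b = rank_vector(np.array([0.2, 0.5, 0.3]), np.random.default_rng(0))
        assert list(b) == [1, 2, 0]

    def test_ties_permuted_uniformly(self):
        rng = np.random.default_rng(7)
        first = [rank_vector(np.array([0.5, 0.5]), rng)[0] for _ in range(1000)]
        share = np.mean(np.array(first) == 0)
        assert 0.45 <= share <= 0.55

    def test_single_function(self):
        assert list(rank_vector(np.array([1.0]), np.random.default_rng(0))) == [0]

    def test_is_permutation(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            m = int(rng.integers(1, 8))
            p = rng.dirichlet(np.ones(m))
            assert sorted(rank_vector(p, rng)) == list(range(m))


class TestAggregateRanks:
    def test_column_mode_with_exclusion(self):
        pred = aggregate_ranks([[0, 1], [0, 1], [1, 0]], ("F1", "F2"))
        assert pred.terms == ("F1", "F2")
        np.testing.assert_allclose(pred.supports, [2 / 3, 2 / 3])

    def test_single_row_identity(self):
        pred = aggregate_ranks([[2, 0, 1]], ("F1", "F2", "F3"))
        assert pred.terms == ("F3", "F1", "F2")
        assert pred.supports == (1.0, 1.0, 1.0)

    def test_all_rows_identical(self):
        pred = aggregate_ranks([[1, 0]] * 5, ("F1", "F2"))
        assert pred.terms == ("F2", "F1")
        assert pred.supports == (1.0, 1.0)

    def test_tie_and_exclusion_rules(self):
        # column 1 ties {F1, F2} -> F1 by index; column 2 excludes F1 -> F2
        pred = aggregate_ranks([[0, 1], [1, 0]], ("F1", "F2"))
        assert pred.terms == ("F1", "F2")

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            aggregate_ranks(np.zeros((0, 2), dtype=int), ("F1", "F2"))


class TestGibbsPredict:
    def test_unanimity_propagates(self):
        # clique of F1-labeled proteins plus one attached query
        edges = [("A", "B"), ("A", "C"), ("B", "C"), ("Q", "A")]
        net = ExplicitNetwork.from_edges(edges)
        # separate labeled clique with F2 so m=2
        net.graph.add_edge("D", "E", weight=1.0)
        en = EnrichedNetwork(net, {p: () for p in net.proteins}, 0)
        ann = AnnotationSet.from_mapping(
            {"A": {"F1"}, "B": {"F1"}, "C": {"F1"}, "D": {"F2"}, "E": {"F2"}}
        )
        pred = gibbs_predict(en, ann, ["Q"], GibbsConfig(seed=5))["Q"]
        assert pred.terms[0] == "F1"
        assert pred.supports[0] == 1.0

    def test_isolated_query_gets_flagged_prior_ranking(self):
        net = ExplicitNetwork.from_edges([("A", "B", 1.0)])
        net.graph.add_node("Q")
        en = EnrichedNetwork(net, {p: () for p in net.proteins}, 0)
        ann = AnnotationSet.from_mapping(
            {"A": {"F1"}, "B": {"F1"}, "C": {"F2"}}
        )
        pred = gibbs_predict(en, ann, ["Q"], GibbsConfig(seed=1))["Q"]
        assert pred.is_fallback
        assert pred.terms[0] == "F1"  # frequency prior favours F1 (2 vs 1)

    def test_bit_reproducible_under_seed(self):
        rng = np.random.default_rng(17)
        en, ann, queries = random_fixture(rng, n=12, m=4)
        cfg = GibbsConfig(lam=0.4, burn_in=3, samples=10, seed=99)
        p1 = gibbs_predict(en, ann, queries, cfg)
        p2 = gibbs_predict(en, ann, queries, cfg)
        assert p1 == p2

    def test_soft_mode_runs_and_ranks(self):
        rng = np.random.default_rng(4)
        en, ann, queries = random_fixture(rng, n=10, m=3)
        cfg = GibbsConfig(burn_in=2, samples=5, seed=3, update_mode="soft")
        preds = gibbs_predict(en, ann, queries, cfg)
        for pred in preds.values():
            assert sorted(pred.terms) == sorted(ann.terms)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            GibbsConfig(lam=0.0)
        with pytest.raises(ValueError):
            GibbsConfig(lam=1.0)
        with pytest.raises(ValueError):
            GibbsConfig(samples=0)
        with pytest.raises(ValueError):
            GibbsConfig(burn_in=-1)
        with pytest.raises(ValueError):
            GibbsConfig(update_mode="annealed")


class TestLambdaBoundaries:
    def _two_channel_fixture(self):
        net = ExplicitNetwork.from_edges([("X", "A", 1.0)])
        en = EnrichedNetwork(net, {"X": (("B", 10.0),)}, 1)
        ann = AnnotationSet.from_mapping({"A": {"F1"}, "B": {"F2"}})
        return en, ann

    def test_lambda_to_zero_is_explicit_only(self):
        en, ann = self._two_channel_fixture()
        d = bootstrap(en, ann, ["X"], GibbsConfig(lam=1e-6))["X"]
        np.testing.assert_allclose(d.probs, [1.0, 0.0], atol=1e-5)

    def test_lambda_to_one_is_implicit_only(self):
        en, ann = self._two_channel_fixture()
        d = bootstrap(en, ann, ["X"], GibbsConfig(lam=1 - 1e-6))["X"]
        np.testing.assert_allclose(d.probs, [0.0, 1.0], atol=1e-5)


def test_stationary_agreement_with_bootstrap_argmax():
    """When every query's neighbours are labeled the chain is stationary:
    the rank-1 Gibbs call matches the bootstrap argmax for nearly all
    queries at large S (disagreement only at near-ties)."""
    rng = np.random.default_rng(42)
    agree = 0
    total = 0
    while total < 100:
        edges = []
        labeled = {}
        terms = ["F1", "F2", "F3"]
        q = f"Q{total}"
        for i in range(int(rng.integers(2, 6))):
            nbr = f"L{total}_{i}"
            edges.append((q, nbr, float(rng.uniform(0.5, 2.0))))
            labeled[nbr] = {terms[int(rng.integers(0, 3))]}
        net = ExplicitNetwork.from_edges(edges)
        en = EnrichedNetwork(net, {p: () for p in net.proteins}, 0)
        ann = AnnotationSet.from_mapping(labeled, terms=terms)
        d = bootstrap(en, ann, [q], GibbsConfig(seed=1))[q]
        pred = gibbs_predict(en, ann, [q], GibbsConfig(seed=1, samples=500))[q]
        top = np.flatnonzero(d.probs == d.probs.max())
        if len(top) == 1:  # unambiguous argmax only
            total += 1
            agree += pred.terms[0] == d.argmax_term()
    assert agree >= 95
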