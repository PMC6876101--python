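"""Restart-walk mechanics and the two-round pipeline."""

import numpy as np
import pandas as pd
import pytest

from oncowalk.assembly import ComplexCatalog, HeterogeneousNetwork, LayeredNodeIndex
from oncowalk.transition import row_normalize
from oncowalk.walk import (
    ConvergenceError,
    SeedSet,
    WalkParams,
    build_second_round_network,
    build_transition,
    combine_scores,
    first_round,
    initial_probability,
    rwr,
    second_round,
    two_round_prioritize,
)

EMPTY = ComplexCatalog(())


def _index(genes=(), mirnas=(), lncrnas=(), cancers=()):
    return LayeredNodeIndex(tuple(genes), tuple(mirnas), tuple(lncrnas), tuple(cancers))


class TestInitialProbability:
    def test_uniform_within_layers(self):
        index = _index(["g1", "g2", "g3", "g4"], ["m1"], ["l1"], ["c1"])
        seeds = SeedSet(("g1", "g2", "g3", "g4"), ("m1",), ("l1",), ("c1",))
        p = initial_probability(index, seeds, (0.25, 0.25, 0.25, 0.25)).p
        assert p[:4].sum() == pytest.approx(0.25)
        assert p[4] == pytest.approx(0.25)
        assert p.sum() == pytest.approx(1.0)

    def test_unseeded_layer_mass_redistributed(self):
        index = _index(["g1", "g2"], ["m1"], ["l1"], ["c1"])
        seeds = SeedSet(gene_seeds=("g1", "g2"), cancer_seeds=("c1",))
        p = initial_probability(index, seeds, (0.25, 0.25, 0.25, 0.25)).p
        # gene and cancer layers split the full mass equally
        assert p[0] == pytest.approx(0.25)
        assert p[1] == pytest.approx(0.25)
        assert p[-1] == pytest.approx(0.5)

    def test_single_layer_eta(self):
        index = _index(["g1", "g2", "g3", "g4"])
        seeds = SeedSet(gene_seeds=("g1", "g2", "g3", "g4"))
        p = initial_probability(index, seeds, (1.0, 0.0, 0.0, 0.0)).p
        np.testing.assert_allclose(p, 0.25)

    def test_empty_seed_set_rejected(self):
        index = _index(["g1"])
        with pytest.raises(ValueError):
            initial_probability(index, SeedSet(), (0.25, 0.25, 0.25, 0.25))


class TestRwr:
    def test_full_restart_returns_p0(self, rng):
        W = row_normalize(rng.random((5, 5)))
        p0 = np.full(5, 0.2)
        np.testing.assert_array_equal(rwr(W, p0, gamma=1.0), p0)

    def test_matches_linear_solve_on_chain(self):
        adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        W = row_normalize(adj)
        p0 = np.array([1.0, 0.0, 0.0])
        gamma = 0.5
        iterative = rwr(W, p0, gamma, tol=1e-10)
        direct = np.linalg.solve(np.eye(3) - (1 - gamma) * W.T, gamma * p0)
        np.testing.assert_allclose(iterative, direct, atol=1e-6)

    def test_probability_conserved_on_dangling_free_operator(self, rng):
        adj = rng.random((8, 8)) + 0.05  # strictly positive, no dangling rows
        np.fill_diagonal(adj, 0)
        W = row_normalize(adj)
        p0 = np.zeros(8)
        p0[0] = 1.0
        result = rwr(W, p0, gamma=0.4, tol=1e-10)
        assert result.sum() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("gamma", [0.9, 0.99, 0.999])
    def test_high_restart_pins_walk_to_seeds(self, rng, gamma):
        adj = rng.random((10, 10))
        np.fill_diagonal(adj, 0)
        W = row_normalize(adj)
        p0 = np.zeros(10)
        p0[3] = 1.0
        drift = np.linalg.norm(rwr(W, p0, gamma, tol=1e-12) - p0)
        assert drift <= (1 - gamma) * 2 + 1e-9

    def test_monotone_restart_convergence_to_seed(self, rng):
        adj = rng.random((10, 10))
        np.fill_diagonal(adj, 0)
        W = row_normalize(adj)
        p0 = np.zeros(10)
        p0[0] = 1.0
        drifts = [np.linalg.norm(rwr(W, p0, g, tol=1e-12) - p0) for g in (0.9, 0.99, 0.999)]
        assert drifts[0] > drifts[1] > drifts[2]

    def test_nonconvergence_raises_with_residual(self, rng):
        W = row_normalize(rng.random((6, 6)))
        p0 = np.full(6, 1 / 6)
        with pytest.raises(ConvergenceError) as err:
            rwr(W, p0, gamma=0.01, tol=1e-16, max_iter=3)
        assert err.value.residual > 0


class TestFirstRound:
    def test_sigma_one_keeps_all_genes(self, small_net, default_params):
        net, complexes = small_net
        import dataclasses

        params = dataclasses.replace(default_params, sigma=1.0)
        result = first_round(net, complexes, params)
        assert set(result.topk_genes) == set(net.index.gene_ids)

    def test_topk_matches_sorted_scores(self, small_net, default_params):
        import dataclasses

        net, complexes = small_net
        params = dataclasses.replace(default_params, sigma=0.5)
        result = first_round(net, complexes, params)
        scores = result.scores.as_series("gene")
        k = len(result.topk_genes)
        assert k == round(0.5 * len(net.index.gene_ids))
        cutoff = min(scores[g] for g in result.topk_genes)
        outside = scores.drop(list(result.topk_genes))
        assert (outside <= cutoff + 1e-15).all()

    def test_planted_genes_enriched_in_topk(self, small_bundle, small_net, default_params):
        import dataclasses

        net, complexes = small_net
        params = dataclasses.replace(default_params, sigma=0.3)
        result = first_round(net, complexes, params)
        planted = {g for g, _ in small_bundle.truth}
        k = len(result.topk_genes)
        hits = len(planted & set(result.topk_genes))
        # planted modules cover 1/3 of genes; enrichment means well above the
        # hypergeometric expectation k * |planted| / n
        expected = k * len(planted) / len(net.index.gene_ids)
        assert hits > 2 * expected


class TestSecondRound:
    def test_full_subnet_all_seeds_reduces_to_first_round(self, small_net):
        net, complexes = small_net
        params = WalkParams(sigma=1.0)
        result = first_round(net, complexes, params)
        subnet = build_second_round_network(net, result.topk_genes)
        # seeding round two with every cancer's entities reproduces round one
        p2_sum = np.zeros(net.index.total)
        seeds = SeedSet(
            gene_seeds=net.cancer_associated("gene"),
            mirna_seeds=net.cancer_associated("mirna"),
            lncrna_seeds=net.cancer_associated("lncrna"),
            cancer_seeds=net.index.cancer_ids,
        )
        W = build_transition(subnet, complexes, result.cancer_genes, params.delta)
        p0 = initial_probability(subnet.index, seeds, params.eta)
        p2 = rwr(W, p0, params.gamma, params.tol, params.max_iter)
        np.testing.assert_allclose(p2, result.scores.p, atol=1e-12)

    def test_restriction_matches_brute_force_filtering(self, small_net, default_params):
        net, complexes = small_net
        keep = set(net.index.gene_ids[::2])
        subnet = build_second_round_network(net, keep)
        dropped = set(net.index.gene_ids) - keep
        assert dropped.isdisjoint(subnet.index.gene_ids)
        expected_edges = {
            (a, b)
            for i, a in enumerate(net.index.gene_ids)
            for j, b in enumerate(net.index.gene_ids)
            if i < j and net.G[i, j] > 0 and a in keep and b in keep
        }
        got_edges = {
            (subnet.index.gene_ids[i], subnet.index.gene_ids[j])
            for i, j in zip(*np.nonzero(np.triu(subnet.G)))
        }
        assert got_edges == expected_edges

    def test_empty_topk_rejected(self, small_net):
        net, _ = small_net
        with pytest.raises(ValueError):
            build_second_round_network(net, set())

    def test_runs_with_only_rna_seeds(self, small_net, default_params):
        net, complexes = small_net
        disease = net.index.cancer_ids[0]
        exclude = frozenset(net.cancer_associated("gene", disease))
        p2 = second_round(net, complexes, disease, default_params, frozenset(), exclude_genes=exclude)
        assert p2.p.sum() == pytest.approx(1.0, abs=1e-6)


class TestCombineScores:
    def test_alpha_limits(self):
        p1 = pd.Series([0.1, 0.2, 0.3], index=["a", "b", "c"])
        p2 = pd.Series([0.5], index=["b"])
        np.testing.assert_allclose(combine_scores(p1, p2, 1.0), p1)
        zeroed = combine_scores(p1, p2, 0.0)
        np.testing.assert_allclose(zeroed, [0.0, 0.5, 0.0])

    def test_weighted_mixture_value(self):
        p1 = pd.Series([0.02], index=["g"])
        p2 = pd.Series([0.1], index=["g"])
        assert combine_scores(p1, p2, 0.9)["g"] == pytest.approx(0.028)

    def test_alpha_out_of_range_rejected(self):
        p1 = pd.Series([0.1], index=["g"])
        with pytest.raises(ValueError):
            combine_scores(p1, p1, 1.2)


class TestTwoRoundPrioritize:
    def test_deterministic_across_runs(self, small_net, default_params):
        net, complexes = small_net
        disease = net.index.cancer_ids[0]
        a = two_round_prioritize(net, complexes, disease, default_params)
        b = two_round_prioritize(net, complexes, disease, default_params)
        np.testing.assert_array_equal(a.score, b.score)

    def test_score_conservation_with_full_sigma(self, small_net):
        net, complexes = small_net
        params = WalkParams(sigma=1.0)
        disease = net.index.cancer_ids[0]
        result = two_round_prioritize(net, complexes, disease, params)
        expected = params.alpha * result.p1.sum() + (1 - params.alpha) * result.p2.sum()
        assert result.score.sum() == pytest.approx(expected, abs=1e-12)

    def test_ejected_genes_score_by_round_one_only(self, small_net):
        net, complexes = small_net
        params = WalkParams(sigma=0.4)
        disease = net.index.cancer_ids[0]
        result = two_round_prioritize(net, complexes, disease, params)
        outside = [g for g in result.gene_ids if g not in set(result.topk_genes)]
        assert outside
        idx = [result.gene_ids.index(g) for g in outside]
        np.testing.assert_allclose(result.score[idx], params.alpha * result.p1[idx])

    def test_unknown_disease_rejected(self, small_net, default_params):
        net, complexes = small_net
        with pytest.raises(KeyError):
            two_round_prioritize(net, complexes, "nope", default_params)


class TestWalkParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"gamma": 1.5},
            {"eta": (0.5, 0.5, 0.5, 0.5)},
            {"eta": (1.0, 0.0, 0.0)},
            {"tol": 0.0},
            {"sigma": -0.1},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            WalkParams(**kwargs)
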