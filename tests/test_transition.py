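"""Gene-layer evidence fusion and the global transition operator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oncowalk.assembly import ComplexCatalog
from oncowalk.simulate import FixtureConfig, generate
from oncowalk.transition import (
    GeneTransitionInputs,
    complex_ratios,
    complex_weight,
    gene_transition,
    global_transition,
    membership_count,
    row_normalize,
    single_network_transition,
)

EMPTY = ComplexCatalog(())


class TestRowNormalize:
    def test_zero_rows_preserved(self):
        out = row_normalize(np.array([[2.0, 2.0], [0.0, 0.0]]))
        np.testing.assert_array_equal(out, [[0.5, 0.5], [0.0, 0.0]])

    def test_identity_fixed_point(self):
        np.testing.assert_array_equal(row_normalize(np.eye(3)), np.eye(3))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_rows_sum_to_one_or_zero(self, seed):
        rng = np.random.default_rng(seed)
        matrix = rng.uniform(0, 1, (5, 5)) * (rng.random((5, 5)) < 0.5)
        sums = row_normalize(matrix).sum(axis=1)
        assert all(abs(s - 1) < 1e-12 or s == 0 for s in sums)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            row_normalize(np.array([[1.0, -0.1]]))


class TestSingleNetworkTransition:
    def test_path_graph_splits_middle_row(self):
        adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        out = single_network_transition(adj)
        np.testing.assert_allclose(out[1], [0.5, 0, 0.5])

    def test_isolated_node_row_is_zero(self):
        adj = np.zeros((2, 2))
        adj[0, 1] = adj[1, 0] = 0  # fully isolated pair
        assert single_network_transition(adj).sum() == 0

    def test_star_center_uniform(self):
        adj = np.zeros((5, 5))
        adj[0, 1:] = adj[1:, 0] = 1
        out = single_network_transition(adj)
        np.testing.assert_allclose(out[0, 1:], 0.25)


class TestMembershipCount:
    def test_counts_zero_one_two(self):
        ppi = np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0]], dtype=float)
        path = np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0]], dtype=float)
        path[2, 2] = 0
        counts = membership_count(ppi, path)
        np.testing.assert_array_equal(counts, [2, 2, 0])
        path[:2] = 0
        path[:, :2] = 0
        np.testing.assert_array_equal(membership_count(ppi, path), [1, 1, 0])


def _inputs(gene_ids, ppi, path, complexes=EMPTY, cancer=frozenset()):
    return GeneTransitionInputs(tuple(gene_ids), ppi, path, complexes, frozenset(cancer))


class TestComplexWeight:
    def test_ratio_on_neighbours(self):
        # complex {g1..g4} with two cancer members; g1 also borders g5
        ids = ["g1", "g2", "g3", "g4", "g5"]
        adj = np.zeros((5, 5))
        adj[0, 4] = adj[4, 0] = 1
        catalog = ComplexCatalog.from_memberships([["g1", "g2", "g3", "g4"]])
        w = complex_weight(_inputs(ids, adj, np.zeros((5, 5)), catalog, {"g1", "g2"}))
        assert w[0, 4] == pytest.approx(0.5)
        assert w[4, 0] == 0.0  # g5 belongs to no complex

    def test_gene_in_no_complex_gets_zero_row(self):
        ids = ["a", "b"]
        adj = np.array([[0, 1], [1, 0]], dtype=float)
        w = complex_weight(_inputs(ids, adj, np.zeros((2, 2)), EMPTY, {"a"}))
        assert w.sum() == 0

    def test_maximum_ratio_across_complexes(self):
        ids = [f"g{i}" for i in range(6)]
        catalog = ComplexCatalog.from_memberships(
            [["g0", "g1", "g2", "g3"], ["g0", "g4"]]  # ratios 0.25 and 0.5 for g0
        )
        ratios = complex_ratios(catalog, ids, {"g0"})
        assert ratios[0] == pytest.approx(0.5)

    def test_empty_cancer_set_gives_zero_feedback(self, small_net):
        net, complexes = small_net
        inputs = GeneTransitionInputs(
            net.index.gene_ids, net.gene_ppi, net.gene_pathway, complexes, frozenset()
        )
        assert complex_weight(inputs).sum() == 0

    def test_ratios_bounded(self, small_net):
        net, complexes = small_net
        cancer = frozenset(net.cancer_associated("gene"))
        ratios = complex_ratios(complexes, net.index.gene_ids, cancer)
        assert ratios.min() >= 0 and ratios.max() <= 1


class TestGeneTransition:
    def test_ppi_only_gene_keeps_ppi_row(self):
        ids = ["a", "b", "c"]
        ppi = np.array([[0, 1, 1], [1, 0, 0], [1, 0, 0]], dtype=float)
        path = np.zeros((3, 3))
        out = gene_transition(_inputs(ids, ppi, path))
        np.testing.assert_allclose(out, single_network_transition(ppi))

    def test_both_networks_average_then_normalize(self):
        # hand computation: a-b in PPI, a-c in pathway => row a = (0.5, 0.25, 0.25)*2
        ids = ["a", "b", "c", "d"]
        ppi = np.zeros((4, 4))
        ppi[0, 1] = ppi[1, 0] = 1
        path = np.zeros((4, 4))
        path[0, 2] = path[2, 0] = 1
        out = gene_transition(_inputs(ids, ppi, path))
        np.testing.assert_allclose(out[0], [0, 0.5, 0.5, 0])

    def test_reduces_to_plain_transition_for_identical_networks(self, rng):
        base = (rng.random((6, 6)) < 0.4).astype(float)
        adj = np.triu(base, 1)
        adj = adj + adj.T
        out = gene_transition(_inputs([f"g{i}" for i in range(6)], adj, adj))
        np.testing.assert_array_equal(out, single_network_transition(adj))

    def test_cancer_complex_shifts_mass_toward_members(self):
        # g0 borders g1 (co-complex with cancer genes) and g2 (background):
        # feedback must increase the g0->g1 share over the complex-free walk
        ids = ["g0", "g1", "g2", "g3"]
        ppi = np.zeros((4, 4))
        for i, j in [(0, 1), (0, 2), (1, 3)]:
            ppi[i, j] = ppi[j, i] = 1
        path = np.zeros((4, 4))
        path[0, 1] = path[1, 0] = 1
        catalog = ComplexCatalog.from_memberships([["g1", "g3"]])
        without = gene_transition(_inputs(ids, ppi, path, EMPTY, frozenset()))
        with_fb = gene_transition(_inputs(ids, ppi, path, catalog, {"g3"}))
        assert with_fb[1, 3] > without[1, 3]


class TestGlobalTransition:
    @pytest.mark.parametrize("delta", [0.0, 0.25, 0.5, 1.0])
    def test_rows_stochastic_or_dangling(self, small_net, delta):
        net, complexes = small_net
        inputs = GeneTransitionInputs(
            net.index.gene_ids, net.gene_ppi, net.gene_pathway, complexes,
            frozenset(net.cancer_associated("gene")),
        )
        tm = global_transition(net, gene_transition(inputs), delta)
        sums = tm.row_sums()
        assert np.all((np.abs(sums - 1) < 1e-12) | (sums == 0))

    def test_delta_zero_is_block_diagonal(self, small_net):
        net, _ = small_net
        from oncowalk.transition import row_normalize as rn

        tm = global_transition(net, rn(net.G), 0.0)
        gs = net.index.layer_slice("gene")
        ms = net.index.layer_slice("mirna")
        assert tm.W[gs, ms].sum() == 0
        np.testing.assert_allclose(tm.W[gs, gs], rn(net.G))

    def test_missing_couplings_reallocate_to_intra(self):
        # gene g2 has intra edges but no inter-layer partner: full mass in-layer
        bundle = generate(FixtureConfig(
            n_genes=12, n_mirnas=4, n_lncrnas=4, n_cancers=2, n_modules=2,
            module_size=3, noise=0.0, seed=3,
        ))
        net, complexes = bundle.to_network()
        inputs = GeneTransitionInputs(
            net.index.gene_ids, net.gene_ppi, net.gene_pathway, complexes,
            frozenset(net.cancer_associated("gene")),
        )
        gene_W = gene_transition(inputs)
        tm = global_transition(net, gene_W, 0.5)
        gs = net.index.layer_slice("gene")
        inter = net.GM.sum(axis=1) + net.GL.sum(axis=1) + net.GC.sum(axis=1)
        intra = gene_W.sum(axis=1)
        lonely = (inter == 0) & (intra > 0)
        if lonely.any():
            i = int(np.nonzero(lonely)[0][0])
            np.testing.assert_allclose(tm.W[gs, gs][i], gene_W[i])

    def test_full_coupling_row_uses_delta_thirds(self):
        bundle = generate(FixtureConfig(
            n_genes=8, n_mirnas=4, n_lncrnas=4, n_cancers=2, n_modules=2,
            module_size=3, signal=1.0, noise=0.5, seed=5,
        ))
        net, complexes = bundle.to_network()
        inputs = GeneTransitionInputs(
            net.index.gene_ids, net.gene_ppi, net.gene_pathway, complexes,
            frozenset(net.cancer_associated("gene")),
        )
        gene_W = gene_transition(inputs)
        delta = 0.3
        tm = global_transition(net, gene_W, delta)
        gs = net.index.layer_slice("gene")
        coupled = (
            (net.GM.sum(axis=1) > 0) & (net.GL.sum(axis=1) > 0)
            & (net.GC.sum(axis=1) > 0) & (gene_W.sum(axis=1) > 0)
        )
        assert coupled.any()
        i = int(np.nonzero(coupled)[0][0])
        assert tm.W[gs, gs][i].sum() == pytest.approx(1 - delta)
        assert tm.W[gs, net.index.layer_slice("mirna")][i].sum() == pytest.approx(delta / 3)

    def test_delta_out_of_range_rejected(self, small_net):
        net, _ = small_net
        from oncowalk.transition import row_normalize as rn

        with pytest.raises(ValueError):
            global_transition(net, rn(net.G), 1.5)
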