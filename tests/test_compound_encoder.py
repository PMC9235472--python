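"""Compound encoder layers against explicit brute-force loop oracles, plus
attention and permutation-invariance properties."""

import numpy as np
import pytest

from mlpathway import autodiff as ad
from mlpathway.compound_encoder import (GatParams, GcnParams, encode_compound,
                                        gat_layer, gcn_layer, readout)
from mlpathway.mol_graph import MoleculeGraph, smiles_to_graph


def random_graph(rng, n_atoms, n_feats=6):
    """Random connected-ish undirected graph with random binary features."""
    adj = np.zeros((n_atoms, n_atoms))
    bonds = []
    for i in range(1, n_atoms):  # spanning tree keeps it molecule-like
        j = int(rng.integers(i))
        adj[i, j] = adj[j, i] = 1
        bonds.append((j, i))
    for _ in range(n_atoms // 2):  # extra edges
        i, j = rng.integers(n_atoms, size=2)
        if i != j and adj[i, j] == 0:
            adj[min(i, j), max(i, j)] = adj[max(i, j), min(i, j)] = 1
            adj[i, j] = adj[j, i] = 1
            bonds.append((min(i, j), max(i, j)))
    feats = (rng.random((n_atoms, n_feats)) > 0.5).astype(float)
    return MoleculeGraph(n_atoms=n_atoms, atom_features=feats, adjacency=adj,
                         bond_list=sorted(set(bonds)), smiles="")


def leaky(x, slope):
    return np.where(x > 0, x, slope * x)


def gat_bruteforce(graph, params):
    """Explicit double loop over atom pairs: scores, neighbourhood softmax,
    weighted aggregation, ReLU, head concatenation."""
    X = graph.atom_features
    n = graph.n_atoms
    head_outs, head_alphas = [], []
    for head in params.heads:
        W = head["W"].data
        a_src = head["a_src"].data[:, 0]
        a_dst = head["a_dst"].data[:, 0]
        Wh = X @ W
        out = np.zeros((n, W.shape[1]))
        alpha_full = np.zeros((n, n))
        for i in range(n):
            nbrs = [j for j in range(n) if graph.adjacency[i, j] or j == i]
            e = np.array([leaky(a_src @ Wh[i] + a_dst @ Wh[j],
                                params.leaky_slope) for j in nbrs])
            ex = np.exp(e - e.max())
            alpha = ex / ex.sum()
            for w, j in zip(alpha, nbrs):
                alpha_full[i, j] = w
                out[i] += w * Wh[j]
        head_outs.append(np.maximum(out, 0))
        head_alphas.append(alpha_full)
    return np.concatenate(head_outs, axis=1), head_alphas


def gcn_bruteforce(H, adj, W):
    n = adj.shape[0]
    a_tilde = adj + np.eye(n)
    d = a_tilde.sum(axis=1)
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            S[i, j] = a_tilde[i, j] / np.sqrt(d[i] * d[j])
    return np.maximum(S @ H @ W, 0)


class TestGatLayer:
    @pytest.mark.parametrize("seed", range(4))
    def test_matches_bruteforce_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        graph = random_graph(rng, n_atoms=int(rng.integers(2, 7)))
        params = GatParams.init(rng, in_dim=6, head_dim=5, n_heads=3)
        out, attn = gat_layer(graph, params)
        expected, expected_alphas = gat_bruteforce(graph, params)
        np.testing.assert_allclose(out.data, expected, atol=1e-5)
        for got, want in zip(attn.head_alphas, expected_alphas):
            np.testing.assert_allclose(got, want, atol=1e-5)

    def test_identical_atoms_share_attention_equally(self):
        graph = smiles_to_graph("CC")  # two identical bonded carbons
        rng = np.random.default_rng(0)
        params = GatParams.init(rng, in_dim=78, head_dim=4, n_heads=2)
        _, attn = gat_layer(graph, params)
        for alpha in attn.head_alphas:
            np.testing.assert_allclose(alpha, 0.5)

    def test_isolated_atom_attends_to_itself(self):
        graph = smiles_to_graph("C")
        rng = np.random.default_rng(1)
        params = GatParams.init(rng, in_dim=78, head_dim=4, n_heads=2)
        out, attn = gat_layer(graph, params)
        for alpha in attn.head_alphas:
            assert alpha[0, 0] == pytest.approx(1.0)
        Wh = graph.atom_features @ params.heads[0]["W"].data
        np.testing.assert_allclose(out.data[0, :4], np.maximum(Wh[0], 0),
                                   atol=1e-12)

    def test_attention_rows_sum_to_one(self):
        rng = np.random.default_rng(2)
        graph = random_graph(rng, 6)
        params = GatParams.init(rng, 6, 4, 3)
        _, attn = gat_layer(graph, params)
        for alpha in attn.head_alphas:
            np.testing.assert_allclose(alpha.sum(axis=1), 1.0)


class TestGcnLayer:
    def test_single_atom_identity_normalisation(self):
        graph = smiles_to_graph("C")
        rng = np.random.default_rng(3)
        params = GcnParams.init(rng, 78, 5)
        h = ad.constant(graph.atom_features)
        out = gcn_layer(h, graph, params)
        np.testing.assert_allclose(
            out.data, np.maximum(graph.atom_features @ params.W.data, 0))

    def test_identical_rows_stay_identical(self):
        graph = smiles_to_graph("CC")
        rng = np.random.default_rng(4)
        params = GcnParams.init(rng, 3, 4)
        h = ad.constant(np.tile([1.0, 2.0, 3.0], (2, 1)))
        out = gcn_layer(h, graph, params).data
        np.testing.assert_allclose(out[0], out[1])

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed + 10)
        graph = random_graph(rng, 5)
        params = GcnParams.init(rng, 6, 4)
        h_data = rng.standard_normal((5, 6))
        out = gcn_layer(ad.constant(h_data), graph, params)
        np.testing.assert_allclose(
            out.data, gcn_bruteforce(h_data, graph.adjacency, params.W.data),
            atol=1e-5)


class TestReadout:
    def test_hand_example(self):
        out = readout(ad.constant([[1.0, 2.0], [3.0, 0.0]]))
        np.testing.assert_array_equal(out.data, [[3, 2, 2, 1]])

    def test_single_atom_max_equals_mean(self):
        v = np.array([[0.5, -1.0, 2.0]])
        out = readout(ad.constant(v))
        np.testing.assert_array_equal(out.data, np.hstack([v, v]))

    def test_permutation_invariant(self):
        rng = np.random.default_rng(5)
        h = rng.standard_normal((6, 4))
        a = readout(ad.constant(h)).data
        b = readout(ad.constant(h[rng.permutation(6)])).data
        np.testing.assert_allclose(a, b)


class TestEncodeCompound:
    def test_composition_equals_sequential_application(self):
        rng = np.random.default_rng(6)
        graph = smiles_to_graph("CCO")
        gat = GatParams.init(rng, 78, 4, 2)
        gcn = GcnParams.init(rng, 8, 5)
        z, _ = encode_compound(graph, gat, gcn)
        h, _ = gat_layer(graph, gat)
        expected = readout(gcn_layer(h, graph, gcn)).data
        np.testing.assert_allclose(z.data, expected)

    def test_default_dimensions_give_1560(self):
        rng = np.random.default_rng(7)
        graph = smiles_to_graph("CCO")
        gat = GatParams.init(rng, 78, 78, 10)
        gcn = GcnParams.init(rng, 780, 780)
        z, _ = encode_compound(graph, gat, gcn)
        assert z.shape == (1, 1560)

    def test_embedding_invariant_to_smiles_spelling(self):
        rng = np.random.default_rng(8)
        gat = GatParams.init(rng, 78, 4, 2)
        gcn = GcnParams.init(rng, 8, 5)
        za, _ = encode_compound(smiles_to_graph("OCC"), gat, gcn)
        zb, _ = encode_compound(smiles_to_graph("CCO"), gat, gcn)
        np.testing.assert_allclose(za.data, zb.data, atol=1e-5)

    def test_zero_weights_give_zero_embedding(self):
        graph = smiles_to_graph("CCO")
        gat = GatParams(heads=[{"W": ad.parameter(np.zeros((78, 4))),
                                "a_src": ad.parameter(np.zeros((4, 1))),
                                "a_dst": ad.parameter(np.zeros((4, 1)))}])
        gcn = GcnParams(W=ad.parameter(np.zeros((4, 3))))
        z, _ = encode_compound(graph, gat, gcn)
        np.testing.assert_array_equal(z.data, 0.0)
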