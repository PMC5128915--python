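import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone
from sklearn.metrics import adjusted_rand_score

from coexmod.extract import (GeneModule, THDConfig,
                             ThresholdDecrementExtractor, extract_modules,
                             grow_module, mark_border, select_core)
from coexmod.similarity import build_network, similarity_matrix
from coexmod.simulate import (SyntheticSpec, generate_expression,
                              planted_recovery_ari)


def net_from_edges(n, edges, delta=0.9):
    S = np.zeros((n, n))
    np.fill_diagonal(S, 1.0)
    for i, j in edges:
        S[i, j] = S[j, i] = 0.95
    names = [f"g{i:02d}" for i in range(n)]
    return build_network(pd.DataFrame(S, index=names, columns=names), delta)


def bfs_component(adj, start):
    """Independent BFS oracle for module growth."""
    seen, queue = {start}, [start]
    while queue:
        u = queue.pop(0)
        for v in np.flatnonzero(adj[u]):
            if v not in seen:
                seen.add(v)
                queue.append(v)
    return seen


def random_net(seed, max_n=30, p=0.25):
    rng = np.random.default_rng(seed)
    n = rng.integers(4, max_n + 1)
    A = rng.random((n, n)) < p
    A = np.triu(A, 1)
    edges = list(zip(*np.nonzero(A)))
    return net_from_edges(n, edges)


class TestSelectCore:
    def test_star_hub_selected(self):
        net = net_from_edges(5, [(0, 1), (0, 2), (0, 3), (0, 4)])
        assert select_core(net, set(net.gene_ids), rho=3) == "g00"

    def test_path_graph_has_no_core(self):
        net = net_from_edges(4, [(0, 1), (1, 2), (2, 3)])
        assert select_core(net, set(net.gene_ids), rho=3) is None

    def test_empty_unassigned(self):
        net = net_from_edges(3, [(0, 1)])
        assert select_core(net, set(), rho=1) is None

    def test_tie_breaks_lexicographically(self):
        # two disjoint triangles with a pendant each: equal max degree
        net = net_from_edges(8, [(0, 1), (1, 2), (0, 2), (0, 3),
                                 (4, 5), (5, 6), (4, 6), (4, 7)])
        assert select_core(net, set(net.gene_ids), rho=3) == "g00"

    def test_degree_restricted_to_unassigned(self):
        # hub's neighbors all assigned away -> hub no longer qualifies
        net = net_from_edges(6, [(0, 1), (0, 2), (0, 3),
                                 (4, 1), (4, 2), (4, 5), (4, 3)])
        unassigned = {"g00", "g04", "g05"}
        # within {g00,g04,g05}: only edge g04-g05
        assert select_core(net, unassigned, rho=1) == "g04"
        assert select_core(net, unassigned, rho=3) is None

    @given(st.integers(0, 10 ** 6))
    @settings(max_examples=50)
    def test_matches_exhaustive_degree_oracle(self, seed):
        net = random_net(seed, max_n=12)
        genes = net.gene_ids
        rng = np.random.default_rng(seed + 1)
        unassigned = {g for g in genes if rng.random() < 0.7}
        got = select_core(net, unassigned, rho=2)
        idx = {g: i for i, g in enumerate(genes)}
        degs = {g: sum(1 for h in unassigned
                       if h != g and net.adjacency[idx[g], idx[h]])
                for g in unassigned}
        qualified = {g: d for g, d in degs.items() if d >= 2}
        if not qualified:
            assert got is None
        else:
            best = max(qualified.values())
            assert got == min(g for g, d in qualified.items() if d == best)


class TestGrowModule:
    def test_disconnected_clique(self):
        net = net_from_edges(6, [(0, 1), (1, 2), (0, 2), (3, 4)])
        assert grow_module(net, "g00", set(net.gene_ids)) == {"g00", "g01", "g02"}

    def test_chain_is_multi_hop(self):
        net = net_from_edges(4, [(0, 1), (1, 2)])
        assert grow_module(net, "g00", set(net.gene_ids)) == {"g00", "g01", "g02"}

    def test_core_must_be_unassigned(self):
        net = net_from_edges(3, [(0, 1)])
        with pytest.raises(ValueError, match="not unassigned"):
            grow_module(net, "g00", {"g01", "g02"})

    @given(st.integers(0, 10 ** 6))
    @settings(max_examples=50)
    def test_matches_bfs_oracle(self, seed):
        net = random_net(seed)
        genes = net.gene_ids
        rng = np.random.default_rng(seed + 2)
        unassigned = {g for g in genes if rng.random() < 0.8}
        if not unassigned:
            return
        core = sorted(unassigned)[0]
        got = grow_module(net, core, unassigned)
        idx = {g: i for i, g in enumerate(genes)}
        sel = sorted(idx[g] for g in unassigned)
        sub = net.adjacency[np.ix_(sel, sel)]
        comp = bfs_component(sub, sel.index(idx[core]))
        assert got == {genes[sel[k]] for k in comp}


class TestMarkBorder:
    def test_star_leaves_are_border(self):
        net = net_from_edges(5, [(0, 1), (0, 2), (0, 3), (0, 4)])
        members = set(net.gene_ids)
        assert mark_border(net, members, rho=3) == {"g01", "g02", "g03", "g04"}

    def test_clique_has_no_border(self):
        net = net_from_edges(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])
        assert mark_border(net, set(net.gene_ids), rho=3) == set()

    def test_full_scope_counts_assigned_neighbors(self):
        # g01 has degree 1 among unassigned but 3 in the full graph
        net = net_from_edges(5, [(0, 1), (1, 2), (1, 3), (0, 4)])
        members = {"g00", "g01", "g04"}
        unassigned = members
        assert "g01" in mark_border(net, members, 2, "unassigned", unassigned)
        assert "g01" not in mark_border(net, members, 2, "full")

    @given(st.integers(0, 10 ** 6))
    @settings(max_examples=50)
    def test_matches_brute_force_filter(self, seed):
        net = random_net(seed)
        genes = net.gene_ids
        rng = np.random.default_rng(seed + 3)
        members = {g for g in genes if rng.random() < 0.5}
        got = mark_border(net, members, rho=2, scope="full")
        idx = {g: i for i, g in enumerate(genes)}
        expected = {g for g in members
                    if net.adjacency[idx[g]].sum() < 2}
        assert got == expected


class TestTHDConfig:
    def test_default_schedule(self):
        np.testing.assert_allclose(THDConfig().delta_schedule(),
                                   [0.9, 0.8, 0.7, 0.6, 0.5])

    @pytest.mark.parametrize("kwargs", [
        {"delta_start": 1.2}, {"delta_end": 0.0},
        {"delta_start": 0.5, "delta_end": 0.9},
        {"alpha": 0.0}, {"rho": 0}, {"degree_scope": "sideways"},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            THDConfig(**kwargs)


class TestExtractModules:
    def test_empty_similarity_yields_no_modules(self):
        S = np.zeros((6, 6))
        np.fill_diagonal(S, 1.0)
        modules, unassigned = extract_modules(S)
        assert modules == []
        assert len(unassigned) == 6

    def test_planted_affine_modules_recovered_at_first_delta(self):
        spec = SyntheticSpec(seed=11)
        em, truth = generate_expression(spec)
        S = similarity_matrix(em)
        modules, unassigned = extract_modules(S)
        assert len(modules) == 2
        assert all(m.delta == 0.9 for m in modules)
        extracted = sorted((sorted(m.members) for m in modules), key=len,
                           reverse=True)
        planted = sorted((sorted(v) for v in truth.module_genes.values()),
                         key=len, reverse=True)
        assert extracted == planted

    def test_module_invariants_on_random_inputs(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            n = rng.integers(8, 25)
            S = rng.random((n, n))
            S = (S + S.T) / 2
            np.fill_diagonal(S, 1.0)
            cfg = THDConfig(rho=int(rng.integers(1, 4)))
            modules, unassigned = extract_modules(S, cfg)
            seen = set()
            for m in modules:
                assert m.core_gene in m.members
                assert m.border_genes <= m.members
                assert m.core_gene not in m.border_genes
                assert m.core_degree >= cfg.rho
                assert not (m.members & seen)  # pairwise disjoint
                seen |= m.members
                for g in m.members:
                    if g in m.border_genes:
                        assert m.degrees[g] < cfg.rho
                    elif g != m.core_gene:
                        # non-border members may have any degree >= 1
                        assert m.degrees[g] >= 1
            assert not (seen & unassigned)
            assert seen | unassigned == set(map(str, range(0, 0))) | \
                {f"g{i}" for i in range(n)}

    def test_genes_assigned_high_delta_stay_assigned(self):
        rng = np.random.default_rng(33)
        S = rng.random((20, 20))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 1.0)
        modules, _ = extract_modules(S)
        order = [m.delta for m in modules]
        assert order == sorted(order, reverse=True)


class TestEstimatorAPI:
    def test_fit_predict_labels(self):
        em, truth = generate_expression(SyntheticSpec(seed=2))
        est = ThresholdDecrementExtractor()
        labels = est.fit_predict(em.data)
        assert labels.shape == (em.shape[0],)
        assert planted_recovery_ari(est.gene_ids_, labels, truth) == 1.0
        # planted modules are cliques at sigma=0: none of their members
        # can be border genes
        assert not {g for g in est.border_pool_
                    if truth.module_label[g] >= 0}

    def test_precomputed_similarity(self):
        S = np.array([[1.0, 0.95, 0.2], [0.95, 1.0, 0.2], [0.2, 0.2, 1.0]])
        est = ThresholdDecrementExtractor(measure="precomputed", rho=1)
        labels = est.fit_predict(S)
        assert labels[0] == labels[1] != labels[2]
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            ThresholdDecrementExtractor(measure="precomputed").fit(S * 3)

    def test_sklearn_param_contract(self):
        est = ThresholdDecrementExtractor(rho=2)
        params = est.get_params()
        assert params["rho"] == 2 and params["delta_start"] == 0.9
        cloned = clone(est).set_params(alpha=0.05)
        assert cloned.get_params()["alpha"] == 0.05

    def test_invalid_params_raise_on_fit(self):
        with pytest.raises(ValueError):
            ThresholdDecrementExtractor(rho=0).fit(np.eye(4))
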