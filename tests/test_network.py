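"""Co-presence network construction, module detection and summaries."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from microfunc import (
    build_core_network,
    build_noncore_subnetwork,
    detect_modules,
    largest_module_overlap,
    summarize_network,
)


def _norm_frame(values, samples=None):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=[f"g{i}" for i in range(len(values))], columns=samples)


def _aa_annotation(genes):
    return pd.DataFrame(
        {
            "family": "f",
            "category": "Amino acid synthesis",
            "pathway_group": "AA",
        },
        index=list(genes),
    )


class TestCoreNetwork:
    def test_proportional_profiles_link_anticorrelated_do_not(self):
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        norm = _norm_frame([base, 2 * base, base[::-1]])
        net = build_core_network(norm, norm.index, norm.columns, min_abs_corr=0.8)
        assert net.graph.has_edge("g0", "g1")  # r = +1
        assert not net.graph.has_edge("g0", "g2")  # r = -1, positive-only rule
        assert not net.graph.has_edge("g1", "g2")

    def test_constant_gene_stays_isolated(self):
        norm = _norm_frame([[1, 2, 3], [0.5, 0.5, 0.5]])
        net = build_core_network(norm, norm.index, norm.columns, min_abs_corr=0.5)
        assert net.graph.degree("g1") == 0
        assert "g1" in net.graph  # still a node

    def test_edges_match_bruteforce_pearson_oracle(self):
        rng = np.random.default_rng(8)
        norm = _norm_frame(rng.random((30, 10)))
        threshold = 0.6
        net = build_core_network(norm, norm.index, norm.columns, min_abs_corr=threshold)
        oracle = set()
        for i in range(30):
            for j in range(i + 1, 30):
                r, _ = pearsonr(norm.iloc[i], norm.iloc[j])
                if r >= threshold and r > 0:
                    oracle.add(tuple(sorted((f"g{i}", f"g{j}"))))
        observed = {tuple(sorted(e)) for e in net.graph.edges}
        assert observed == oracle

    def test_raising_threshold_never_adds_edges(self):
        rng = np.random.default_rng(3)
        norm = _norm_frame(rng.random((25, 8)))
        counts = [
            build_core_network(norm, norm.index, norm.columns, min_abs_corr=t).n_edges
            for t in (0.3, 0.5, 0.7, 0.9)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_too_few_samples_rejected(self):
        norm = _norm_frame([[1, 2], [2, 4]])
        with pytest.raises(ValueError, match="3 samples"):
            build_core_network(norm, norm.index, norm.columns)


class TestNoncoreSubnetwork:
    def test_phi_matches_contingency_oracle(self):
        rng = np.random.default_rng(1)
        binary = _norm_frame(rng.integers(0, 2, (20, 12)))
        annotation = _aa_annotation(binary.index)
        threshold = 0.5
        net = build_noncore_subnetwork(
            binary, annotation, "AA", binary.columns, min_abs_corr=threshold
        )
        n = binary.shape[1]
        oracle = set()
        for i in range(20):
            for j in range(i + 1, 20):
                x, y = binary.iloc[i].to_numpy(), binary.iloc[j].to_numpy()
                n11 = int((x * y).sum())
                n10 = int((x * (1 - y)).sum())
                n01 = int(((1 - x) * y).sum())
                n00 = n - n11 - n10 - n01
                denom = (n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
                if denom == 0:
                    continue
                phi = (n11 * n00 - n10 * n01) / np.sqrt(denom)
                if phi >= threshold and phi > 0:
                    oracle.add(tuple(sorted((f"g{i}", f"g{j}"))))
        observed = {tuple(sorted(e)) for e in net.graph.edges}
        assert observed == oracle

    def test_identical_and_complementary_profiles(self):
        prof = [1, 1, 0, 0, 1, 0]
        binary = _norm_frame([prof, prof, [1 - v for v in prof]])
        net = build_noncore_subnetwork(
            binary, _aa_annotation(binary.index), "AA", binary.columns, min_abs_corr=0.8
        )
        assert net.graph.has_edge("g0", "g1")  # phi = +1
        assert not net.graph.has_edge("g0", "g2")  # phi = -1

    def test_all_present_gene_is_isolated(self):
        binary = _norm_frame([[1, 1, 1, 1], [1, 0, 1, 0], [1, 0, 1, 0]])
        net = build_noncore_subnetwork(
            binary, _aa_annotation(binary.index), "AA", binary.columns, min_abs_corr=0.5
        )
        assert net.graph.degree("g0") == 0

    def test_unknown_pathway_group_rejected(self):
        binary = _norm_frame([[1, 0], [0, 1]])
        with pytest.raises(ValueError, match="pathway group"):
            build_noncore_subnetwork(
                binary, _aa_annotation(binary.index), "Sulfur", binary.columns
            )

    def test_pathway_scope_restricts_nodes(self):
        binary = _norm_frame([[1, 0, 1], [0, 1, 1]])
        annotation = _aa_annotation(binary.index)
        annotation.loc["g1", "category"] = "Respiration"
        net = build_noncore_subnetwork(binary, annotation, "AA", binary.columns)
        assert set(net.graph.nodes) == {"g0"}


class TestModules:
    def _net_from_graph(self, G):
        from microfunc.network import CoPresenceNetwork

        return CoPresenceNetwork(G)

    def test_two_disjoint_triangles(self):
        G = nx.Graph()
        for offset in (0, 3):
            nodes = [f"g{offset + i}" for i in range(3)]
            G.add_edges_from(
                [(nodes[0], nodes[1]), (nodes[1], nodes[2]), (nodes[0], nodes[2])],
                score=1.0,
            )
        net = self._net_from_graph(G)
        modules = detect_modules(net)
        assert len(set(modules.values())) == 2
        summary = summarize_network(net)
        assert summary.largest_module_nodes == 3
        assert summary.largest_module_edges == 3

    def test_path_graph_single_module(self):
        G = nx.Graph()
        G.add_edges_from([("a", "b"), ("b", "c")], score=1.0)
        net = self._net_from_graph(G)
        assert len(set(detect_modules(net).values())) == 1

    def test_components_match_dfs_oracle(self):
        rng = np.random.default_rng(17)
        G = nx.Graph()
        nodes = [f"g{i}" for i in range(40)]
        G.add_nodes_from(nodes)
        for i in range(40):
            for j in range(i + 1, 40):
                if rng.random() < 0.05:
                    G.add_edge(nodes[i], nodes[j], score=1.0)
        net = self._net_from_graph(G)
        modules = detect_modules(net)

        # independent iterative depth-first search
        adj = {n: set(G.neighbors(n)) for n in nodes}
        seen, oracle_components = set(), []
        for n in nodes:
            if n in seen or not adj[n]:
                continue
            stack, comp = [n], set()
            while stack:
                v = stack.pop()
                if v in comp:
                    continue
                comp.add(v)
                stack.extend(adj[v] - comp)
            seen |= comp
            oracle_components.append(comp)
        by_module = {}
        for g, m in modules.items():
            by_module.setdefault(m, set()).add(g)
        assert sorted(map(sorted, by_module.values())) == sorted(
            map(sorted, oracle_components)
        )

    def test_module_ids_stable_under_node_relabeling(self):
        rng = np.random.default_rng(2)
        norm = _norm_frame(rng.random((15, 8)))
        net1 = build_core_network(norm, norm.index, norm.columns, min_abs_corr=0.5)
        shuffled = norm.sample(frac=1, random_state=1)
        net2 = build_core_network(shuffled, shuffled.index, shuffled.columns, min_abs_corr=0.5)
        assert detect_modules(net1) == detect_modules(net2)
        s1, s2 = summarize_network(net1), summarize_network(net2)
        assert s1.as_dict() == s2.as_dict()

    def test_greedy_modularity_partitions_connected_nodes(self):
        rng = np.random.default_rng(6)
        norm = _norm_frame(rng.random((20, 8)))
        net = build_core_network(norm, norm.index, norm.columns, min_abs_corr=0.4)
        comp = dict(detect_modules(net, method="components"))
        greedy = detect_modules(net, method="greedy_modularity")
        assert set(greedy) == set(comp)  # same covered nodes
        assert len(set(greedy.values())) >= len(set(comp.values()))

    def test_empty_edge_set_zero_modules(self):
        norm = _norm_frame([[1, 2, 3], [3, 1, 2]])
        net = build_core_network(norm, norm.index, norm.columns, min_abs_corr=0.99)
        summary = summarize_network(net)
        assert summary.n_modules == 0 and summary.n_edges == 0


class TestPlantedStructure:
    @staticmethod
    def _block_binary(rng, n_blocks, block_size, n_noise, n_samples, flip):
        """Binary matrix with correlated gene blocks plus independent noise."""
        rows = []
        for _ in range(n_blocks):
            latent = rng.integers(0, 2, n_samples)
            for _ in range(block_size):
                row = latent.copy()
                flips = rng.random(n_samples) < flip
                row[flips] = 1 - row[flips]
                rows.append(row)
        for _ in range(n_noise):
            rows.append(rng.integers(0, 2, n_samples))
        return np.array(rows)

    def test_block_members_share_a_module_at_zero_noise(self):
        rng = np.random.default_rng(0)
        M = self._block_binary(rng, n_blocks=2, block_size=5, n_noise=10, n_samples=10, flip=0.0)
        binary = _norm_frame(M)
        net = build_noncore_subnetwork(
            binary, _aa_annotation(binary.index), "AA", binary.columns, min_abs_corr=0.9
        )
        modules = detect_modules(net)
        for start in (0, 5):
            block = [f"g{start + i}" for i in range(5)]
            assert len({modules[g] for g in block}) == 1

    def test_divergent_group_has_smaller_largest_module(self):
        # one group carries correlated presence blocks, the other is
        # independent noise; the conserved group's largest module dominates
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            H = self._block_binary(rng, 3, 8, 20, 10, flip=0.05)
            C = rng.integers(0, 2, H.shape)
            binary = _norm_frame(np.hstack([H, C]),
                                 samples=[f"H{j}" for j in range(10)] + [f"C{j}" for j in range(10)])
            annotation = _aa_annotation(binary.index)
            kwargs = dict(min_abs_corr=0.7)
            net_h = build_noncore_subnetwork(
                binary, annotation, "AA", [f"H{j}" for j in range(10)], **kwargs
            )
            net_c = build_noncore_subnetwork(
                binary, annotation, "AA", [f"C{j}" for j in range(10)], **kwargs
            )
            sh, sc = summarize_network(net_h), summarize_network(net_c)
            wins += sh.largest_module_nodes > sc.largest_module_nodes
        assert wins >= 0.9 * n_seeds

    def test_largest_module_overlap_percentage(self):
        prof = np.array([[1, 2, 3, 4]] * 3 + [[4, 3, 2, 1]] * 2, dtype=float)
        norm = _norm_frame(prof + np.random.default_rng(1).normal(0, 1e-3, prof.shape))
        net1 = build_core_network(norm, norm.index, norm.columns, min_abs_corr=0.9)
        net2 = build_core_network(norm, norm.index, norm.columns, min_abs_corr=0.9)
        assert largest_module_overlap(net1, net2) == 100.0
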