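"""Network construction, subnetwork rules, summaries vs brute force, rank tests."""

import itertools
from collections import deque

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import essgenes as eg
from essgenes.classify import Group
from essgenes.io import EdgeList, EdgePair
from tests.conftest import make_gene_table


def edges(*pairs):
    return EdgeList([EdgePair(a, b) for a, b in pairs])


def brute_force_summary(edge_set):
    """Independent recomputation: adjacency dict, BFS components, degree counts."""
    adj: dict[str, set[str]] = {}
    for u, v in edge_set:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    nodes = sorted(adj)
    seen, comps = set(), []
    for start in nodes:
        if start in seen:
            continue
        comp, queue = set(), deque([start])
        while queue:
            x = queue.popleft()
            if x in comp:
                continue
            comp.add(x)
            queue.extend(adj[x] - comp)
        seen |= comp
        comps.append(comp)
    n, e = len(nodes), len(edge_set)
    degrees = {v: len(adj[v]) for v in nodes}
    lcc = sorted(
        comps,
        key=lambda c: (-len(c), -sum(1 for u, v in edge_set if u in c and v in c), min(c)),
    )[0]
    lcc_e = sum(1 for u, v in edge_set if u in lcc and v in lcc)
    return {
        "proteins": n,
        "interactions": e,
        "max_degree": max(degrees.values()),
        "avg_degree": 2 * e / n,
        "components": len(comps),
        "lcc_protein_pct": 100 * len(lcc) / n,
        "lcc_interaction_pct": 100 * lcc_e / e,
        "lcc_avg_degree": 2 * lcc_e / len(lcc),
    }


class TestBuildNetwork:
    def test_self_and_duplicate_pairs_dropped(self):
        g = eg.build_network(edges(("A", "B"), ("B", "A"), ("C", "C")))
        assert set(map(frozenset, g.edges)) == {frozenset({"A", "B"})}
        assert set(g.nodes) == {"A", "B"}

    def test_empty(self):
        g = eg.build_network(EdgeList([]))
        assert g.number_of_nodes() == 0

    def test_twenty_pair_fixture(self):
        pairs = [(f"n{i}", f"n{i + 1}") for i in range(15)]  # 15 distinct edges
        raw = pairs + [pairs[0][::-1], pairs[1], pairs[2]] + [("s1", "s1"), ("s2", "s2")]
        assert len(raw) == 20
        g = eg.build_network(edges(*raw))
        assert g.number_of_edges() == 15


class TestCategorySubnetwork:
    def test_one_or_both_keeps_any_member_edge(self):
        g = eg.build_network(edges(("A", "B"), ("B", "C")))
        sub = eg.category_subnetwork(g, {"A"}, "one_or_both")
        assert set(map(frozenset, sub.edges)) == {frozenset({"A", "B"})}

    def test_both_requires_two_members(self):
        g = eg.build_network(edges(("A", "B"), ("B", "C")))
        assert eg.category_subnetwork(g, {"A"}, "both").number_of_edges() == 0
        both = eg.category_subnetwork(g, {"A", "B"}, "both")
        one = eg.category_subnetwork(g, {"A", "B"}, "one_or_both")
        assert set(map(frozenset, both.edges)) == {frozenset({"A", "B"})}
        assert set(map(frozenset, one.edges)) == {frozenset({"A", "B"}), frozenset({"B", "C"})}

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_both_mode_is_subgraph_of_one_or_both(self, data):
        n = data.draw(st.integers(4, 12))
        pool = [f"v{i}" for i in range(n)]
        pairs = data.draw(
            st.lists(st.tuples(st.sampled_from(pool), st.sampled_from(pool)), max_size=30)
        )
        members = set(data.draw(st.lists(st.sampled_from(pool), max_size=6)))
        g = eg.build_network(edges(*pairs))
        both = eg.category_subnetwork(g, members, "both")
        one = eg.category_subnetwork(g, members, "one_or_both")
        assert set(both.nodes) <= set(one.nodes)
        assert set(map(frozenset, both.edges)) <= set(map(frozenset, one.edges))

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            eg.category_subnetwork(eg.build_network(EdgeList([])), set(), "either")


class TestSummarize:
    def test_triangle(self):
        s = eg.summarize(eg.build_network(edges(("A", "B"), ("B", "C"), ("C", "A"))))
        assert (s.proteins, s.interactions, s.max_degree) == (3, 3, 2)
        assert s.avg_degree == 2.0 and s.components == 1
        assert s.lcc_protein_pct == 100.0 and s.lcc_interaction_pct == 100.0

    def test_path_plus_isolated_pair(self):
        g = eg.build_network(edges(("A", "B"), ("B", "C"), ("C", "D"), ("E", "F")))
        s = eg.summarize(g)
        assert (s.proteins, s.interactions, s.components) == (6, 4, 2)
        assert s.lcc_protein_pct == pytest.approx(400 / 6)
        assert s.lcc_interaction_pct == pytest.approx(75.0)

    def test_empty_network_zero_summary(self):
        s = eg.summarize(eg.build_network(EdgeList([])))
        assert s.proteins == 0 and s.components == 0

    def test_random_networks_match_brute_force(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(2, 60))
            m = int(rng.integers(1, 3 * n))
            pairs = [tuple(rng.choice(n, size=2, replace=False)) for _ in range(m)]
            edge_set = {tuple(sorted((f"v{a}", f"v{b}"))) for a, b in pairs}
            s = eg.summarize(eg.build_network(edges(*edge_set)))
            expected = brute_force_summary(edge_set)
            for field, value in expected.items():
                assert getattr(s, field) == pytest.approx(value), field

    def test_component_sizes_sum_to_protein_count(self):
        import networkx as nx

        g = eg.build_network(edges(("A", "B"), ("C", "D"), ("D", "E"), ("F", "G")))
        sizes = [len(c) for c in nx.connected_components(g)]
        assert sum(sizes) == eg.summarize(g).proteins
        assert eg.summarize(g).lcc_protein_pct == pytest.approx(100 * max(sizes) / sum(sizes))


class TestDegreeSequence:
    def test_path_degrees(self):
        g = eg.build_network(edges(("A", "B"), ("B", "C")))
        assert sorted(eg.degree_sequence(g)) == [1, 1, 2]
        assert eg.degree_sequence(g, restrict_to={"B"}) == [2]

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        pairs = {tuple(sorted(map(int, rng.choice(30, 2, replace=False)))) for _ in range(60)}
        named = [(f"v{a}", f"v{b}") for a, b in pairs]
        g = eg.build_network(edges(*named))
        counts: dict[str, int] = {}
        for a, b in named:
            counts[a] = counts.get(a, 0) + 1
            counts[b] = counts.get(b, 0) + 1
        assert sorted(eg.degree_sequence(g)) == sorted(counts.values())


def wmw_enumeration_p(x, y):
    """Oracle: exact two-sided rank-sum p over all group assignments (integer ranks ×2)."""
    pooled = list(x) + list(y)
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    double_ranks = [0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and pooled[order[j]] == pooled[order[i]]:
            j += 1
        dr = (i + 1) + j  # 2 * midrank
        for k in range(i, j):
            double_ranks[order[k]] = dr
        i = j
    m, n_tot = len(x), len(pooled)
    ew2 = m * (n_tot + 1)  # 2 * E[W]
    obs = abs(sum(double_ranks[:m]) - ew2)
    hits = total = 0
    for idx in itertools.combinations(range(n_tot), m):
        total += 1
        if abs(sum(double_ranks[i] for i in idx) - ew2) >= obs:
            hits += 1
    return hits / total


class TestCompareDegreeDistributions:
    def test_identical_sequences(self):
        wmw, ks = eg.compare_degree_distributions([1, 2, 3, 4], [1, 2, 3, 4])
        assert wmw == 1.0 and ks == 1.0

    def test_separated_samples_exact_enumeration(self):
        wmw, _ = eg.compare_degree_distributions([1, 2, 3], [10, 11, 12])
        assert wmw == pytest.approx(2 / 20)

    @pytest.mark.parametrize(
        "x, y",
        [
            ([1, 2, 3], [2, 3, 4, 5]),
            ([1, 1, 2, 2], [2, 2, 3]),  # heavy ties
            ([5], [1, 2, 3, 4, 5, 6]),
            ([0, 0, 0], [0, 0, 1]),
        ],
    )
    def test_small_samples_match_enumeration_oracle(self, x, y):
        wmw, _ = eg.compare_degree_distributions(x, y)
        assert wmw == pytest.approx(wmw_enumeration_p(x, y), abs=1e-12)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            eg.compare_degree_distributions([], [1])

    def test_null_rejection_rate_calibrated(self):
        """Samples from one distribution: rejection at alpha=0.05 within 0.05±0.02."""
        rng = np.random.default_rng(17)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            x, y = rng.normal(size=15), rng.normal(size=15)
            wmw, _ = eg.compare_degree_distributions(x.tolist(), y.tolist())
            rejections += wmw < 0.05
        assert abs(rejections / n_rep - 0.05) <= 0.02


class TestExportSubnetworks:
    def test_group_rows_in_standard_order(self, twelve_gene_classified, tmp_path):
        g = eg.build_network(edges(("dl0", "dl1"), ("dl1", "dv0"), ("du0", "l0"), ("v0", "x1")))
        df = eg.export_subnetworks(twelve_gene_classified, g, tmp_path)
        assert df["group"].tolist() == ["DL", "DV", "L", "V", "DU"]
        dl = df[df.group == "DL"].iloc[0]
        assert dl.proteins == 3 and dl.interactions == 2
        assert (tmp_path / "DL_edges.tsv").exists()

    def test_empty_group_zero_row(self, twelve_gene_classified):
        g = eg.build_network(edges(("x", "y")))  # no classified members interact
        df = eg.export_subnetworks(twelve_gene_classified, g)
        assert (df[["proteins", "interactions"]].to_numpy() == 0).all()
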