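"""Spearman screen, network construction, topology, modules, Zi-Pi roles."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from streamnet import (
    CountTable,
    EdgeCandidate,
    ModulePartition,
    build_network,
    classify_role,
    detect_modules,
    keystone_summary,
    node_roles,
    select_core_taxa,
    spearman_screen,
    topology_metrics,
    zi_pi,
)
from streamnet.network import degree_powerlaw_exponent, positive_edge_fraction


def table_from_columns(columns: dict) -> CountTable:
    df = pd.DataFrame(columns)
    df.index = [f"s{i}" for i in range(len(df))]
    return CountTable(df)


def brute_spearman(x, y):
    """Independent oracle: explicit mid-ranks, then the Pearson formula."""

    def midranks(v):
        v = list(v)
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    mx = sum(rx) / len(rx)
    my = sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    ) ** 0.5
    return num / den if den > 0 else float("nan")


def all_partitions(nodes):
    """Every set partition of ``nodes`` (Bell-number enumeration)."""
    nodes = list(nodes)
    if not nodes:
        yield []
        return
    first, rest = nodes[0], nodes[1:]
    for partial in all_partitions(rest):
        for i in range(len(partial)):
            yield partial[:i] + [partial[i] | {first}] + partial[i + 1:]
        yield partial + [{first}]


class TestSelectCoreTaxa:
    def test_prevalence_boundary(self):
        cols = {
            "common": [1, 1, 1, 1, 1, 0, 0, 0],  # 5/8
            "rare": [3, 0, 0, 0, 0, 0, 0, 0],  # 1/8
        }
        t = table_from_columns(cols)
        assert select_core_taxa(t, 0.5).taxon_ids == ["common"]
        assert select_core_taxa(t, 0.3).taxon_ids == ["common"]
        assert select_core_taxa(t, 0.125).taxon_ids == ["common", "rare"]

    def test_matches_brute_force(self, small_table):
        out = select_core_taxa(small_table, 0.4)
        expected = [
            t
            for t in small_table.taxon_ids
            if (small_table.data[t] > 0).sum() / small_table.shape[0] >= 0.4
        ]
        assert out.taxon_ids == expected

    def test_empty_stratum_errors(self, small_table):
        with pytest.raises(ValueError, match="no samples"):
            select_core_taxa(small_table, 0.5, [])


class TestSpearmanScreen:
    def test_monotone_pair_retained_positive(self):
        t = table_from_columns({"x": [1, 2, 3, 4, 5], "y": [2, 4, 6, 8, 10]})
        (c,) = spearman_screen(t, 0.7, 0.05)
        assert c.rho == pytest.approx(1.0)
        assert c.sign == "positive"

    def test_antimonotone_pair_retained_negative(self):
        t = table_from_columns({"x": [1, 2, 3, 4, 5], "y": [10, 8, 6, 4, 2]})
        (c,) = spearman_screen(t, 0.7, 0.05)
        assert c.rho == pytest.approx(-1.0)
        assert c.sign == "negative"

    def test_rho_point_six_not_retained(self):
        # rank formula: rho = 1 - 6*8/120 = 0.6 < 0.7
        t = table_from_columns({"x": [1, 2, 3, 4, 5], "y": [3, 1, 2, 5, 4]})
        assert spearman_screen(t, 0.7, 1.0) == []

    def test_matches_brute_force_oracle(self, rng):
        """Screen rho equals explicit mid-rank + Pearson on random tables."""
        for _ in range(10):
            counts = rng.integers(0, 25, size=(9, 6))
            t = CountTable(pd.DataFrame(
                counts, index=[f"s{i}" for i in range(9)],
                columns=[f"t{j}" for j in range(6)]))
            cands = spearman_screen(t, 0.01, 1.0)
            got = {(c.taxon_a, c.taxon_b): c.rho for c in cands}
            for i, j in itertools.combinations(range(6), 2):
                x, y = counts[:, i], counts[:, j]
                if x.var() == 0 or y.var() == 0:
                    continue
                expected = brute_spearman(x, y)
                key = (f"t{i}", f"t{j}")
                if abs(expected) > 0.01:
                    assert got[key] == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_monotone_taxon_transform(self, small_table):
        """Rank property: strictly monotone per-taxon transforms (here
        x -> 3x + 1, an integer-preserving stand-in for log1p) leave every
        retained correlation unchanged."""
        cands = spearman_screen(small_table, 0.2, 1.0)
        t2 = CountTable(small_table.data * 3 + 1)
        cands2 = spearman_screen(t2, 0.2, 1.0)
        assert [(c.taxon_a, c.taxon_b, round(c.rho, 12)) for c in cands] == [
            (c.taxon_a, c.taxon_b, round(c.rho, 12)) for c in cands2
        ]

    def test_constant_taxa_skipped(self):
        t = table_from_columns(
            {"x": [1, 2, 3, 4, 5], "y": [2, 4, 6, 8, 10], "c": [7] * 5}
        )
        cands = spearman_screen(t, 0.5, 0.05)
        taxa = {c.taxon_a for c in cands} | {c.taxon_b for c in cands}
        assert "c" not in taxa and len(cands) == 1

    def test_too_few_samples_errors(self):
        t = table_from_columns({"x": [1, 2, 3], "y": [1, 2, 3]})
        with pytest.raises(ValueError, match="at least 5"):
            spearman_screen(t)

    def test_permutation_p_seeded(self):
        t = table_from_columns(
            {"x": [1, 2, 3, 4, 5, 6, 7], "y": [2, 1, 4, 3, 6, 5, 7]}
        )
        a = spearman_screen(t, 0.5, 0.5, p_method="permutation", seed=1)
        b = spearman_screen(t, 0.5, 0.5, p_method="permutation", seed=1)
        assert [(c.rho, c.p) for c in a] == [(c.rho, c.p) for c in b]


class TestBuildNetworkAndTopology:
    def test_empty_candidates(self):
        net = build_network([])
        rep = topology_metrics(net)
        assert rep.n_nodes == 0 and rep.n_edges == 0
        assert rep.connectance == 0.0

    def test_triangle(self):
        cands = [
            EdgeCandidate("a", "b", 0.9, 1e-5),
            EdgeCandidate("b", "c", 0.8, 1e-5),
            EdgeCandidate("a", "c", -0.85, 1e-5),
        ]
        net = build_network(cands)
        rep = topology_metrics(net)
        assert (rep.n_nodes, rep.n_edges) == (3, 3)
        assert rep.average_degree == pytest.approx(2.0)
        assert rep.connectance == pytest.approx(1.0)
        assert rep.avg_clustering == pytest.approx(1.0)
        assert positive_edge_fraction(net) == pytest.approx(2 / 3)

    def test_path_hand_values(self):
        net = build_network(
            [EdgeCandidate("a", "b", 0.8, 0), EdgeCandidate("b", "c", 0.8, 0)]
        )
        rep = topology_metrics(net)
        assert rep.average_degree == pytest.approx(4 / 3)
        assert rep.connectance == pytest.approx(2 / 3)
        assert rep.avg_clustering == 0.0

    def test_conflicting_duplicate_errors(self):
        cands = [EdgeCandidate("a", "b", 0.8, 0), EdgeCandidate("a", "b", 0.9, 0)]
        with pytest.raises(ValueError, match="conflicting"):
            build_network(cands)

    def test_avg_clustering_matches_brute_force(self, rng):
        """Local clustering = triangles / possible triples, averaged with
        zeros for degree < 2 nodes."""
        for _ in range(10):
            g = nx.gnp_random_graph(10, 0.4, seed=int(rng.integers(2**31)))
            rep = topology_metrics(g)
            total = 0.0
            for v in g.nodes:
                nbrs = list(g.neighbors(v))
                k = len(nbrs)
                if k < 2:
                    continue
                links = sum(
                    1
                    for a, b in itertools.combinations(nbrs, 2)
                    if g.has_edge(a, b)
                )
                total += 2 * links / (k * (k - 1))
            assert rep.avg_clustering == pytest.approx(
                total / g.number_of_nodes(), abs=1e-12
            )


class TestModules:
    def test_two_disjoint_cliques(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        part = detect_modules(g, seed=0)
        assert part.n_modules == 2
        assert part.q == pytest.approx(0.5, abs=1e-12)

    def test_single_clique(self):
        part = detect_modules(nx.complete_graph(5), seed=0)
        assert part.n_modules == 1
        assert part.q == pytest.approx(0.0, abs=1e-12)

    def test_isolated_nodes_own_modules(self):
        g = nx.Graph()
        g.add_nodes_from(["a", "b", "c"])
        part = detect_modules(g, seed=0)
        assert part.n_modules == 3

    def test_matches_exhaustive_enumeration(self, rng):
        """On graphs small enough to enumerate every partition, the seeded
        heuristic attains the true modularity optimum."""

        def modularity_q(g, parts):
            e = g.number_of_edges()
            if e == 0:
                return 0.0
            q = 0.0
            for block in parts:
                sub = g.subgraph(block)
                ls = sub.number_of_edges()
                ds = sum(g.degree(v) for v in block)
                q += ls / e - (ds / (2 * e)) ** 2
            return q

        for k in range(8):
            g = nx.gnp_random_graph(7, 0.45, seed=k)
            best = max(
                modularity_q(g, p) for p in all_partitions(list(g.nodes))
            )
            part = detect_modules(g, seed=100 + k)
            assert part.q >= best - 1e-9

    def test_edge_counts_partition_invariant(self, rng):
        g = nx.gnp_random_graph(12, 0.35, seed=9)
        part = detect_modules(g, seed=2)
        within = sum(
            1 for a, b in g.edges
            if part.membership[a] == part.membership[b]
        )
        between = g.number_of_edges() - within
        assert within + between == g.number_of_edges()
        modules = part.modules()
        per_module = sum(
            g.subgraph(block).number_of_edges() for block in modules.values()
        )
        assert per_module == within


class TestZiPi:
    def test_all_neighbors_same_module_pi_zero(self):
        g = nx.complete_graph(4)
        part = ModulePartition({v: 0 for v in g.nodes}, 0.0)
        df = zi_pi(g, part).set_index("node")
        assert (df.pi == 0.0).all()

    def test_even_split_two_modules(self):
        g = nx.star_graph(4)  # hub 0 with leaves 1-4
        part = ModulePartition({0: 0, 1: 0, 2: 0, 3: 1, 4: 1}, 0.0)
        df = zi_pi(g, part).set_index("node")
        assert df.loc[0, "pi"] == pytest.approx(0.5)  # 1 - 2*(0.5)^2

    def test_three_module_split(self):
        g = nx.star_graph(4)
        part = ModulePartition({0: 0, 1: 0, 2: 0, 3: 1, 4: 2}, 0.0)
        df = zi_pi(g, part).set_index("node")
        assert df.loc[0, "pi"] == pytest.approx(0.625)  # 1 - (4+1+1)/16

    def test_matches_brute_force(self, rng):
        for _ in range(10):
            g = nx.gnp_random_graph(10, 0.4, seed=int(rng.integers(2**31)))
            part = detect_modules(g, seed=int(rng.integers(2**31)))
            df = zi_pi(g, part).set_index("node")
            member = part.membership
            for v in g.nodes:
                mod = member[v]
                same = [u for u in g.nodes if member[u] == mod]
                kis = {
                    u: sum(1 for w in g.neighbors(u) if member[w] == mod)
                    for u in same
                }
                mean = np.mean(list(kis.values()))
                sd = np.sqrt(
                    np.mean([(k - mean) ** 2 for k in kis.values()])
                )
                zi = (kis[v] - mean) / sd if sd > 0 else 0.0
                ki = g.degree(v)
                pi = (
                    1 - sum(
                        (
                            sum(1 for w in g.neighbors(v) if member[w] == m)
                            / ki
                        )
                        ** 2
                        for m in set(member.values())
                    )
                    if ki
                    else 0.0
                )
                assert df.loc[v, "zi"] == pytest.approx(zi, abs=1e-12)
                assert df.loc[v, "pi"] == pytest.approx(pi, abs=1e-12)

    def test_missing_node_errors(self):
        g = nx.path_graph(3)
        with pytest.raises(ValueError, match="missing"):
            zi_pi(g, ModulePartition({0: 0, 1: 0}, 0.0))


class TestRoles:
    @pytest.mark.parametrize(
        "zi,pi,expected",
        [
            (3.0, 0.7, "network hub"),
            (1.0, 0.1, "peripheral"),
            (1.0, 0.7, "connector"),
            (3.0, 0.3, "module hub"),
            (2.5, 0.62, "network hub"),  # boundary assigned upward
            (2.5, 0.3, "module hub"),
            (1.0, 0.62, "connector"),
        ],
    )
    def test_classification(self, zi, pi, expected):
        assert classify_role(zi, pi) == expected

    def test_keystone_counts(self):
        roles = pd.DataFrame(
            {
                "node": list("abcde"),
                "role": [
                    "module hub",
                    "module hub",
                    "connector",
                    "peripheral",
                    "peripheral",
                ],
            }
        )
        summ = keystone_summary(roles)
        total = summ[(summ.label == "TOTAL") & (summ.role == "keystone")]
        assert total["count"].iloc[0] == 3

    def test_all_peripherals_zero_keystones(self):
        roles = pd.DataFrame({"node": ["a", "b"], "role": ["peripheral"] * 2})
        summ = keystone_summary(roles)
        total = summ[(summ.label == "TOTAL") & (summ.role == "keystone")]
        assert total["count"].iloc[0] == 0

    def test_node_roles_pipeline(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        part = detect_modules(g, seed=0)
        df = node_roles(g, part)
        assert set(df.role) == {"peripheral"}  # symmetric cliques: no hubs


class TestDegreePowerlaw:
    def test_descriptive_only(self):
        g = nx.star_graph(5)
        alpha = degree_powerlaw_exponent(g)
        assert alpha > 1
        assert np.isnan(degree_powerlaw_exponent(nx.empty_graph(3)))
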