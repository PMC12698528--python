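"""Spearman co-occurrence networks, topology, modules and Zi–Pi node roles.

The screen retains taxon pairs with |Spearman rho| above a cutoff (default
0.7) and a p-value below a cutoff (default 0.001, two-sided t
approximation). Negative correlations pass the screen too — drought-era
microbiome networks contain negative associations — and the edge keeps its
sign while the topological weight is |rho|.

Node roles follow the classic network-role cartography: within-module
connectivity Zi is the node's within-module degree standardised by its
module's mean and population standard deviation; among-module connectivity
Pi = 1 - sum_t (k_it / k_i)^2 measures how evenly a node's edges spread
over modules. Thresholds Zi = 2.5 and Pi = 0.62 split nodes into
peripherals, connectors, module hubs and network hubs; module hubs,
connectors and network hubs together are the keystone taxa.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .profiles import CountTable

log = logging.getLogger(__name__)

__all__ = [
    "EdgeCandidate",
    "ModulePartition",
    "TopologyReport",
    "select_core_taxa",
    "spearman_screen",
    "build_network",
    "topology_metrics",
    "detect_modules",
    "zi_pi",
    "classify_role",
    "node_roles",
    "keystone_summary",
    "degree_powerlaw_exponent",
    "write_graphml",
    "write_edge_list",
]

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62

KEYSTONE_ROLES = ("module hub", "connector", "network hub")


@dataclass(frozen=True)
class EdgeCandidate:
    """A screened taxon pair with its correlation and p-value."""

    taxon_a: str
    taxon_b: str
    rho: float
    p: float

    @property
    def sign(self) -> str:
        return "positive" if self.rho > 0 else "negative"


@dataclass
class ModulePartition:
    """Node -> module assignment plus the partition's modularity Q."""

    membership: dict
    q: float

    def modules(self) -> dict:
        out: dict = {}
        for node, mod in self.membership.items():
            out.setdefault(mod, set()).add(node)
        return out

    @property
    def n_modules(self) -> int:
        return len(set(self.membership.values()))


@dataclass
class TopologyReport:
    n_nodes: int
    n_edges: int
    connectance: float
    average_degree: float
    avg_clustering: float
    graph_density: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def select_core_taxa(
    table: CountTable,
    prevalence_min: float = 0.3,
    stratum_samples: list[str] | None = None,
) -> CountTable:
    """Keep taxa present (count > 0) in at least ``prevalence_min`` of the
    stratum's samples.

    Mostly-zero taxa produce rank ties that make Spearman estimates
    unstable, so networks are built on this "core" community.
    """
    if not 0 < prevalence_min <= 1:
        raise ValueError("prevalence_min must be in (0, 1]")
    sub = table if stratum_samples is None else table.subset_samples(stratum_samples)
    if sub.shape[0] == 0:
        raise ValueError("stratum contains no samples")
    prevalence = (sub.data > 0).mean(axis=0)
    kept = prevalence.index[prevalence >= prevalence_min]
    return CountTable(sub.data[kept])


def spearman_screen(
    table: CountTable,
    rho_min: float = 0.7,
    alpha: float = 0.001,
    p_method: str = "t_approx",
    seed: int | None = None,
    n_permutations: int = 999,
    signed_only: bool = False,
    bh_correct: bool = False,
) -> list[EdgeCandidate]:
    """All-pairs Spearman screen: retain |rho| > rho_min and p < alpha.

    ``p_method='t_approx'`` uses the two-sided t approximation
    t = rho * sqrt((n-2)/(1-rho^2)) on n-2 degrees of freedom;
    ``'permutation'`` recomputes p for the rho-passing pairs by seeded
    permutation (add-one estimator), which is preferable at small n.
    Constant (zero-variance) taxa are skipped with a log entry. With
    ``signed_only=True`` only positive correlations are screened in; with
    ``bh_correct=True`` the p cutoff is applied after Benjamini–Hochberg
    adjustment across all tested pairs.
    """
    if not 0 < rho_min < 1:
        raise ValueError("rho_min must be in (0, 1)")
    n, n_taxa = table.shape
    if n < 5:
        raise ValueError(f"need at least 5 samples for a rank screen, got {n}")
    if n_taxa < 2:
        return []
    X = table.data.to_numpy(dtype=float)
    variances = X.var(axis=0)
    constant = variances == 0
    if constant.any():
        log.info(
            "spearman_screen skipping %d constant taxa: %s",
            int(constant.sum()),
            [t for t, c in zip(table.taxon_ids, constant) if c][:10],
        )
    keep_idx = np.flatnonzero(~constant)
    if keep_idx.size < 2:
        return []
    ids = [table.taxon_ids[i] for i in keep_idx]
    if len(keep_idx) == 2:  # scipy collapses the 2-column case to a scalar
        r2, p2 = stats.spearmanr(X[:, keep_idx[0]], X[:, keep_idx[1]])
        rho = np.array([[1.0, r2], [r2, 1.0]])
        pval = np.array([[0.0, p2], [p2, 0.0]])
    else:
        res = stats.spearmanr(X[:, keep_idx])
        rho = np.asarray(res.statistic)
        pval = np.asarray(res.pvalue)

    iu, ju = np.triu_indices(len(keep_idx), k=1)
    rhos = rho[iu, ju]
    ps = pval[iu, ju]
    if bh_correct:
        order = np.argsort(ps, kind="stable")
        m = ps.size
        ranked = ps[order] * m / (np.arange(m) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        ps = np.empty_like(ps)
        ps[order] = np.minimum(adj, 1.0)

    strong = rhos > rho_min if signed_only else np.abs(rhos) > rho_min
    candidates: list[EdgeCandidate] = []
    rng = np.random.default_rng(seed)
    ranks = None
    if p_method == "permutation":
        ranks = stats.rankdata(X[:, keep_idx], axis=0)
    elif p_method != "t_approx":
        raise ValueError(f"unknown p_method {p_method!r}")
    for i, j, r, p in zip(iu[strong], ju[strong], rhos[strong], ps[strong]):
        if p_method == "permutation":
            ra = ranks[:, i]
            rb = ranks[:, j]
            obs = abs(r)
            hits = 0
            for _ in range(n_permutations):
                perm = rng.permutation(rb)
                rp = np.corrcoef(ra, perm)[0, 1]
                if abs(rp) >= obs - 1e-12:
                    hits += 1
            p = (hits + 1) / (n_permutations + 1)
        if p < alpha:
            candidates.append(
                EdgeCandidate(ids[i], ids[j], float(r), float(p))
            )
    return candidates


def build_network(candidates: list[EdgeCandidate], name: str = "") -> nx.Graph:
    """Simple undirected graph from screened candidates.

    Nodes are the taxa that appear in at least one retained edge; edge
    attributes are rho, p, sign and weight = |rho|. A duplicate pair with a
    conflicting rho indicates an upstream bug and raises.
    """
    g = nx.Graph(name=name)
    for c in candidates:
        if c.taxon_a == c.taxon_b:
            raise ValueError(f"self-loop candidate for taxon {c.taxon_a!r}")
        if g.has_edge(c.taxon_a, c.taxon_b):
            old = g.edges[c.taxon_a, c.taxon_b]["rho"]
            if old != c.rho:
                raise ValueError(
                    f"conflicting duplicate edge ({c.taxon_a}, {c.taxon_b}): "
                    f"rho {old} vs {c.rho}"
                )
            continue
        g.add_edge(
            c.taxon_a,
            c.taxon_b,
            rho=c.rho,
            p=c.p,
            sign=c.sign,
            weight=abs(c.rho),
        )
    return g


def positive_edge_fraction(net: nx.Graph) -> float:
    """Fraction of edges with a positive correlation sign (NaN if empty)."""
    if net.number_of_edges() == 0:
        return float("nan")
    pos = sum(1 for *_, d in net.edges(data=True) if d.get("sign") == "positive")
    return pos / net.number_of_edges()


def topology_metrics(net: nx.Graph) -> TopologyReport:
    """Node/edge counts, connectance, average degree, average clustering.

    For a simple undirected graph connectance and graph density coincide at
    2E / (N(N-1)); both names are reported. Nodes with degree < 2 contribute
    0 to the average clustering coefficient. An empty network yields zeros.
    """
    n = net.number_of_nodes()
    e = net.number_of_edges()
    if n == 0:
        return TopologyReport(0, 0, 0.0, 0.0, 0.0, 0.0)
    ad = 2 * e / n
    density = 2 * e / (n * (n - 1)) if n > 1 else 0.0
    avgcc = nx.average_clustering(net, count_zeros=True) if n > 0 else 0.0
    return TopologyReport(n, e, density, ad, avgcc, density)


def _iter_set_partitions(items: list):
    """All set partitions (restricted-growth enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partial in _iter_set_partitions(rest):
        for i in range(len(partial)):
            yield partial[:i] + [partial[i] | {first}] + partial[i + 1:]
        yield partial + [{first}]


def detect_modules(
    net: nx.Graph,
    seed: int | None = None,
    n_runs: int = 16,
    weighted: bool = False,
    exact_max_nodes: int = 8,
) -> ModulePartition:
    """Seeded modularity maximisation; exact on tiny graphs.

    Graphs with at most ``exact_max_nodes`` nodes are solved by exhaustive
    partition enumeration (the global modularity optimum); larger graphs use
    Louvain restarts with the best Q kept, which is a heuristic. Modularity
    is Newman–Girvan on edge counts by default (``weighted=True`` switches
    to |rho|-weighted modularity). Isolated nodes each form their own
    module. Module labels are renumbered deterministically (by smallest
    member node) so identical partitions always get identical labels.
    """
    n = net.number_of_nodes()
    if n == 0:
        return ModulePartition({}, 0.0)
    weight = "weight" if weighted else None
    if net.number_of_edges() == 0:
        membership = {node: i for i, node in enumerate(sorted(net.nodes))}
        return ModulePartition(membership, 0.0)
    best_comms = None
    best_q = -np.inf
    if n <= exact_max_nodes:
        for parts in _iter_set_partitions(list(net.nodes)):
            q = nx.community.modularity(net, parts, weight=weight)
            if q > best_q:
                best_q = q
                best_comms = parts
    else:
        rng = np.random.default_rng(seed)
        for _ in range(max(1, n_runs)):
            comms = nx.community.louvain_communities(
                net, weight=weight, seed=int(rng.integers(2**31))
            )
            q = nx.community.modularity(net, comms, weight=weight)
            if q > best_q:
                best_q = q
                best_comms = comms
    assert best_comms is not None
    # deterministic labels: order modules by their smallest node id
    ordered = sorted(best_comms, key=lambda c: min(map(str, c)))
    membership = {node: i for i, comm in enumerate(ordered) for node in comm}
    return ModulePartition(membership, float(best_q))


def zi_pi(net: nx.Graph, partition: ModulePartition) -> pd.DataFrame:
    """Within-module (Zi) and among-module (Pi) connectivity per node.

    Zi standardises the node's within-module degree by the mean and
    population standard deviation over its module's nodes (sd = 0 gives
    Zi = 0). Pi = 1 - sum_t (k_it / k_i)^2; an isolated node has Pi = 0.
    """
    missing = [v for v in net.nodes if v not in partition.membership]
    if missing:
        raise ValueError(f"nodes missing from partition: {sorted(missing)[:10]}")
    member = partition.membership
    within_degree = {
        v: sum(1 for u in net.neighbors(v) if member[u] == member[v])
        for v in net.nodes
    }
    by_module: dict = {}
    for v in net.nodes:
        by_module.setdefault(member[v], []).append(within_degree[v])
    mod_mean = {m: float(np.mean(ks)) for m, ks in by_module.items()}
    mod_sd = {m: float(np.std(ks)) for m, ks in by_module.items()}  # population sd

    rows = []
    for v in sorted(net.nodes, key=str):
        k_total = net.degree(v)
        sd = mod_sd[member[v]]
        zi = (within_degree[v] - mod_mean[member[v]]) / sd if sd > 0 else 0.0
        if k_total == 0:
            pi = 0.0
        else:
            per_module: dict = {}
            for u in net.neighbors(v):
                per_module[member[u]] = per_module.get(member[u], 0) + 1
            pi = 1.0 - sum((k / k_total) ** 2 for k in per_module.values())
        rows.append({"node": v, "module": member[v], "zi": float(zi),
                     "pi": float(pi), "degree": int(k_total)})
    return pd.DataFrame(rows)


def classify_role(zi: float, pi: float) -> str:
    """Role from (Zi, Pi) at thresholds 2.5 / 0.62.

    Boundary equality is assigned upward (to the hub/connector side), so
    (2.5, 0.62) is a network hub.
    """
    high_z = zi >= ZI_THRESHOLD
    high_p = pi >= PI_THRESHOLD
    if high_z and high_p:
        return "network hub"
    if high_z:
        return "module hub"
    if high_p:
        return "connector"
    return "peripheral"


def node_roles(net: nx.Graph, partition: ModulePartition) -> pd.DataFrame:
    """Zi–Pi table with the categorical role column appended."""
    df = zi_pi(net, partition)
    df["role"] = [classify_role(z, p) for z, p in zip(df.zi, df.pi)]
    return df


def keystone_summary(
    roles: pd.DataFrame, taxonomy: dict | None = None
) -> pd.DataFrame:
    """Counts of each role overall and (optionally) per taxonomy label.

    Keystone taxa are module hubs + connectors + network hubs.
    """
    df = roles.copy()
    df["label"] = (
        [taxonomy.get(n, "unassigned") for n in df.node]
        if taxonomy
        else "all"
    )
    counts = (
        df.groupby(["label", "role"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    keystone = (
        df[df.role.isin(KEYSTONE_ROLES)]
        .groupby("label", observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    keystone["role"] = "keystone"
    out = pd.concat([counts, keystone[["label", "role", "count"]]],
                    ignore_index=True)
    total = pd.DataFrame(
        {
            "label": "TOTAL",
            "role": ["keystone"],
            "count": [int(df.role.isin(KEYSTONE_ROLES).sum())],
        }
    )
    return pd.concat([out, total], ignore_index=True)


def degree_powerlaw_exponent(net: nx.Graph) -> float:
    """Descriptive power-law exponent of the degree distribution.

    Continuous maximum-likelihood (Hill) estimator with x_min = 1:
    alpha = 1 + n / sum(log k). Purely descriptive — never used to filter
    edges. NaN when no node has degree >= 1.
    """
    degrees = np.array([d for _, d in net.degree() if d >= 1], dtype=float)
    if degrees.size == 0:
        return float("nan")
    return float(1.0 + degrees.size / np.log(degrees).sum())


def write_graphml(
    net: nx.Graph,
    path: str | Path,
    roles: pd.DataFrame | None = None,
    taxonomy: dict | None = None,
) -> None:
    """GraphML export with module/Zi/Pi/role node attributes when given."""
    g = net.copy()
    if roles is not None:
        meta = roles.set_index("node")
        for v in g.nodes:
            if v in meta.index:
                g.nodes[v]["module"] = int(meta.loc[v, "module"])
                g.nodes[v]["zi"] = float(meta.loc[v, "zi"])
                g.nodes[v]["pi"] = float(meta.loc[v, "pi"])
                if "role" in meta.columns:
                    g.nodes[v]["role"] = str(meta.loc[v, "role"])
    if taxonomy:
        for v in g.nodes:
            g.nodes[v]["taxonomy"] = taxonomy.get(v, "unassigned")
    nx.write_graphml(g, str(path))


def write_edge_list(net: nx.Graph, path: str | Path) -> None:
    """Flat CSV edge list: taxon_a, taxon_b, rho, p, sign."""
    rows = [
        {
            "taxon_a": a,
            "taxon_b": b,
            "rho": d.get("rho"),
            "p": d.get("p"),
            "sign": d.get("sign"),
        }
        for a, b, d in sorted(net.edges(data=True), key=lambda e: (str(e[0]), str(e[1])))
    ]
    pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "rho", "p", "sign"]).to_csv(
        path, index=False
    )
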