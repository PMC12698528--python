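"""Network stability: global efficiency, vulnerability, robustness.

Global efficiency averages inverse shortest-path lengths over ordered node
pairs (disconnected pairs contribute 0). Vulnerability is the worst-case
relative efficiency loss over single-node deletions,

    V = max_i (E_glob - E_glob(G - i)) / E_glob,

where the residual graph is normalised by its own node count. Robustness is
the expected proportion of the original community that remains connected
(degree >= 1) after randomly removing a fixed fraction of the nodes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .network import ModulePartition, TopologyReport, topology_metrics

__all__ = [
    "RobustnessResult",
    "StabilityReport",
    "global_efficiency",
    "vulnerability",
    "robustness",
    "robustness_expectation",
    "stability_report",
    "compare_networks",
]


def global_efficiency(net: nx.Graph, weighted: bool = False) -> float:
    """Average inverse shortest-path length over ordered node pairs.

    Unweighted hop distances by default; ``weighted=True`` uses edge
    lengths 1/|rho| (shorter = stronger association). Graphs with fewer
    than 2 nodes have efficiency 0.
    """
    n = net.number_of_nodes()
    if n < 2:
        return 0.0
    if not weighted:
        return float(nx.global_efficiency(net))
    g = net.copy()
    for a, b, d in g.edges(data=True):
        w = abs(d.get("rho", d.get("weight", 1.0)))
        d["length"] = 1.0 / w if w > 0 else np.inf
    total = 0.0
    for _, dists in nx.all_pairs_dijkstra_path_length(g, weight="length"):
        total += sum(1.0 / v for v in dists.values() if v > 0)
    return total / (n * (n - 1))


def vulnerability(net: nx.Graph, weighted: bool = False) -> tuple[float, dict]:
    """Worst-case relative efficiency drop over single-node deletions.

    Returns (V, per-node contributions). Per-node values can be negative
    when removing a node raises efficiency. Requires E_glob > 0.
    """
    e0 = global_efficiency(net, weighted=weighted)
    if e0 == 0:
        raise ValueError("vulnerability undefined: global efficiency is 0")
    contrib = {}
    for v in net.nodes:
        g = net.copy()
        g.remove_node(v)
        contrib[v] = (e0 - global_efficiency(g, weighted=weighted)) / e0
    return max(contrib.values()), contrib


def edge_vulnerability(net: nx.Graph) -> tuple[float, dict]:
    """Analogue of :func:`vulnerability` over single-edge deletions."""
    e0 = global_efficiency(net)
    if e0 == 0:
        raise ValueError("edge vulnerability undefined: global efficiency is 0")
    contrib = {}
    for a, b in net.edges:
        g = net.copy()
        g.remove_edge(a, b)
        contrib[(a, b)] = (e0 - global_efficiency(g)) / e0
    return max(contrib.values()), contrib


@dataclass
class RobustnessResult:
    mean: float
    sd: float
    values: np.ndarray
    removal_fraction: float
    n_reps: int
    seed: int | None


def _surviving_fraction(net: nx.Graph, removed: set) -> float:
    n = net.number_of_nodes()
    g = net.copy()
    g.remove_nodes_from(removed)
    alive = sum(1 for _, d in g.degree() if d >= 1)
    return alive / n


def robustness(
    net: nx.Graph,
    removal_fraction: float = 0.5,
    n_reps: int = 100,
    seed: int | None = None,
    removal_sets: list[set] | None = None,
) -> RobustnessResult:
    """Proportion of the original taxa still connected after random removal.

    Each repetition removes floor(removal_fraction * N) nodes uniformly at
    random (seeded); a surviving taxon is one with degree >= 1 in the
    residual graph, counted against the ORIGINAL node count. Passing
    ``removal_sets`` bypasses the random draw (deterministic variant for
    testing and enumeration).
    """
    n = net.number_of_nodes()
    if n < 2:
        raise ValueError("robustness needs at least 2 nodes")
    if not 0 < removal_fraction < 1:
        raise ValueError("removal_fraction must be in (0, 1)")
    n_remove = int(np.floor(removal_fraction * n))
    if n - n_remove < 1:
        raise ValueError("removal would leave fewer than 1 node")
    nodes = sorted(net.nodes, key=str)
    if removal_sets is not None:
        if any(len(set(s)) >= n for s in removal_sets):
            raise ValueError("a removal set would leave fewer than 1 node")
        values = np.array(
            [_surviving_fraction(net, set(s)) for s in removal_sets]
        )
    else:
        rng = np.random.default_rng(seed)
        values = np.empty(n_reps)
        for k in range(n_reps):
            removed = rng.choice(len(nodes), size=n_remove, replace=False)
            values[k] = _surviving_fraction(net, {nodes[i] for i in removed})
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return RobustnessResult(
        mean=float(values.mean()),
        sd=sd,
        values=values,
        removal_fraction=removal_fraction,
        n_reps=len(values),
        seed=seed,
    )


def robustness_expectation(net: nx.Graph, removal_fraction: float = 0.5) -> float:
    """Exact expectation of robustness by exhaustive enumeration.

    Enumerates all C(N, n_remove) removal sets; only feasible for small
    networks. Serves as the analytic ground truth that the Monte-Carlo
    estimate converges to.
    """
    n = net.number_of_nodes()
    n_remove = int(np.floor(removal_fraction * n))
    nodes = sorted(net.nodes, key=str)
    vals = [
        _surviving_fraction(net, set(combo))
        for combo in itertools.combinations(nodes, n_remove)
    ]
    return float(np.mean(vals))


@dataclass
class StabilityReport:
    """One network's full stability/complexity profile."""

    name: str
    topology: TopologyReport
    modularity_q: float | None
    global_efficiency: float
    vulnerability: float | None
    robustness_mean: float
    robustness_sd: float
    removal_fraction: float
    n_reps: int
    seed: int | None
    flags: list = field(default_factory=list)

    @property
    def complexity(self) -> float:
        """Headline complexity scalar (average degree by convention here)."""
        return self.topology.average_degree

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "modularity_q": self.modularity_q,
            "global_efficiency": self.global_efficiency,
            "vulnerability": self.vulnerability,
            "robustness_mean": self.robustness_mean,
            "robustness_sd": self.robustness_sd,
            "removal_fraction": self.removal_fraction,
            "n_reps": self.n_reps,
            "seed": self.seed,
            "complexity": self.complexity,
            "flags": list(self.flags),
        }
        d.update(self.topology.to_dict())
        return d


def stability_report(
    net: nx.Graph,
    partition: ModulePartition | None = None,
    removal_fraction: float = 0.5,
    n_reps: int = 100,
    seed: int | None = None,
) -> StabilityReport:
    """Bundle topology, modularity, efficiency, vulnerability, robustness.

    Degenerate networks (empty, or with zero efficiency) produce zeroed
    metrics with explanatory flags instead of raising.
    """
    flags: list[str] = []
    topo = topology_metrics(net)
    e_glob = global_efficiency(net)
    if e_glob > 0 and net.number_of_nodes() >= 3:
        vuln, _ = vulnerability(net)
    else:
        vuln = None
        flags.append("vulnerability undefined (efficiency 0 or N < 3)")
    if net.number_of_nodes() >= 2:
        rob = robustness(net, removal_fraction, n_reps, seed)
        rmean, rsd = rob.mean, rob.sd
    else:
        rmean, rsd = 0.0, 0.0
        flags.append("robustness undefined (N < 2)")
    return StabilityReport(
        name=str(net.name) if net.name else "network",
        topology=topo,
        modularity_q=partition.q if partition is not None else None,
        global_efficiency=e_glob,
        vulnerability=vuln,
        robustness_mean=rmean,
        robustness_sd=rsd,
        removal_fraction=removal_fraction,
        n_reps=n_reps,
        seed=seed,
        flags=flags,
    )


_METRIC_FIELDS = [
    "n_nodes",
    "n_edges",
    "connectance",
    "average_degree",
    "avg_clustering",
    "graph_density",
    "modularity_q",
    "global_efficiency",
    "vulnerability",
    "robustness_mean",
    "complexity",
]


def compare_networks(
    reports: list[StabilityReport],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format metric table plus all pairwise per-metric differences.

    Returns (long, deltas): ``long`` has one row per (network, metric);
    ``deltas`` has value_a - value_b for every ordered report pair.
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to compare")
    rows = []
    for rep in reports:
        d = rep.to_dict()
        for metric in _METRIC_FIELDS:
            rows.append({"network": rep.name, "metric": metric,
                         "value": d.get(metric)})
    long = pd.DataFrame(rows)
    deltas = []
    for a, b in itertools.combinations(reports, 2):
        da, db = a.to_dict(), b.to_dict()
        for metric in _METRIC_FIELDS:
            va, vb = da.get(metric), db.get(metric)
            delta = None if va is None or vb is None else va - vb
            deltas.append(
                {
                    "network_a": a.name,
                    "network_b": b.name,
                    "metric": metric,
                    "delta": delta,
                }
            )
    return long, pd.DataFrame(deltas)
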