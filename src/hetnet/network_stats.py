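"""Whole-network topological parameters for disease subnetworks.

The parameter bundle mirrors the quantities a NetworkAnalyzer-style report
produces for a disease gene subnetwork: node/edge counts, average degree,
isolated-node fraction, degree centralization, mean clustering coefficient,
and the size of the largest connected component.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .graph_io import InteractionNetwork, largest_connected_component

__all__ = [
    "NetworkStats",
    "degree",
    "local_clustering",
    "average_clustering",
    "centralization",
    "summarize",
    "stats_table",
]


@dataclass
class NetworkStats:
    """Topology summary for one network (or its LCC)."""

    name: str
    n_nodes: int
    n_edges: int
    average_degree: float
    n_isolated: int
    pct_isolated: float
    centralization: float
    avg_clustering: float
    lcc_n_nodes: int
    pct_lcc: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def degree(net: InteractionNetwork, node: str) -> int:
    """Number of edges incident to ``node`` (no self-loops exist by invariant)."""
    if node not in net.graph:
        raise KeyError(f"unknown node: {node!r}")
    return int(net.graph.degree(node))


def local_clustering(net: InteractionNetwork, node: str) -> float:
    """Fraction of the node's neighbor pairs that are themselves connected.

    Nodes of degree < 2 have no neighbor pairs; their coefficient is defined
    as 0 and, by default, still contributes to the network mean — the
    convention that keeps a single network-wide coefficient well-defined for
    disease subnetworks dominated by isolated nodes.
    """
    if node not in net.graph:
        raise KeyError(f"unknown node: {node!r}")
    return float(nx.clustering(net.graph, node))


def average_clustering(
    net: InteractionNetwork, include_low_degree: bool = True
) -> float:
    """Unweighted mean of local clustering coefficients over all nodes.

    ``include_low_degree=False`` averages over degree>=2 nodes only, the
    alternative convention some analyzers apply.
    """
    if net.n_nodes == 0:
        raise ValueError("empty network")
    if include_low_degree:
        return float(nx.average_clustering(net.graph, count_zeros=True))
    eligible = [v for v in net.graph if net.graph.degree(v) >= 2]
    if not eligible:
        return 0.0
    return float(nx.average_clustering(net.graph, nodes=eligible, count_zeros=True))


def centralization(net: InteractionNetwork, variant: str = "cytoscape") -> float:
    """Degree centralization: 1 on a star, 0 on any regular graph.

    freeman:    sum_i (d_max - d_i) / ((n-1)(n-2))
    cytoscape:  (n/(n-2)) * (d_max/(n-1) - density), the NetworkAnalyzer
                formula, with density = 2m / (n(n-1)).  Default.
    """
    n = net.n_nodes
    if n < 3:
        raise ValueError("centralization requires at least 3 nodes")
    degrees = [d for _, d in net.graph.degree()]
    d_max = max(degrees)
    if variant == "freeman":
        return float(sum(d_max - d for d in degrees) / ((n - 1) * (n - 2)))
    if variant == "cytoscape":
        density = 2.0 * net.n_edges / (n * (n - 1))
        return float((n / (n - 2)) * (d_max / (n - 1) - density))
    raise ValueError(f"unknown centralization variant: {variant!r}")


def summarize(
    net: InteractionNetwork,
    variant: str = "cytoscape",
    include_low_degree: bool = True,
) -> NetworkStats:
    """Populate the full parameter bundle for one network.

    Isolated nodes are nodes of degree 0 within this network.  For networks
    of fewer than 3 nodes, centralization is reported as 0.0 (the formula is
    undefined there; such inputs are degenerate fixtures, not study data).
    """
    n = net.n_nodes
    if n == 0:
        raise ValueError("empty network")
    degrees = dict(net.graph.degree())
    n_isolated = sum(1 for d in degrees.values() if d == 0)
    lcc_n = largest_connected_component(net).n_nodes
    central = centralization(net, variant=variant) if n >= 3 else 0.0
    return NetworkStats(
        name=net.name,
        n_nodes=n,
        n_edges=net.n_edges,
        average_degree=2.0 * net.n_edges / n,
        n_isolated=n_isolated,
        pct_isolated=100.0 * n_isolated / n,
        centralization=central,
        avg_clustering=average_clustering(net, include_low_degree=include_low_degree),
        lcc_n_nodes=lcc_n,
        pct_lcc=100.0 * lcc_n / n,
    )


def stats_table(stats: list[NetworkStats]) -> str:
    """Render a parameter table as TSV (percentages to 1 decimal place)."""
    header = [
        "network",
        "n_nodes",
        "n_edges",
        "average_degree",
        "isolated_nodes",
        "pct_isolated",
        "centralization",
        "clustering_coefficient",
        "lcc_nodes",
        "pct_lcc",
    ]
    lines = ["\t".join(header)]
    for s in stats:
        lines.append(
            "\t".join(
                [
                    s.name,
                    str(s.n_nodes),
                    str(s.n_edges),
                    f"{s.average_degree:.3f}",
                    str(s.n_isolated),
                    f"{s.pct_isolated:.1f}",
                    f"{s.centralization:.3f}",
                    f"{s.avg_clustering:.3f}",
                    str(s.lcc_n_nodes),
                    f"{s.pct_lcc:.1f}",
                ]
            )
        )
    return "\n".join(lines) + "\n"
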