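"""Dense-module detection (MCODE) with a modularity-based cross-check.

MCODE finds locally dense, connected subgraphs in three stages:

1. *Vertex weighting* — each node's weight is the highest k-core number of
   its closed neighborhood (the node plus its neighbors) multiplied by the
   density of that highest core.
2. *Complex prediction* — seeds are taken in decreasing weight order;
   from a seed, neighbors whose weight exceeds seed_weight * (1 - VWP)
   are included breadth-first.  A node joins at most one complex.
3. *Post-processing* — complexes without a 2-core are discarded; "haircut"
   iteratively strips members with fewer than two intra-complex links
   (equivalently, keeps the complex's 2-core); optional "fluff" adds
   boundary neighbors whose closed-neighborhood density clears a threshold.

A module's score is its density multiplied by its size; downstream analysis
keeps modules with score strictly greater than 3.  Modules are cross-checked
against an independent modularity-maximization partition (Louvain): a module
is validated when at least 80% of its member pairs land in one community.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
from scipy.stats import hypergeom

from .graph_io import InteractionNetwork

__all__ = [
    "Module",
    "VertexWeighting",
    "ModuleValidation",
    "module_from_members",
    "k_core",
    "vertex_weights",
    "find_modules",
    "filter_modules",
    "crosscheck_modules",
    "label_enrichment",
]

DEFAULT_VWP = 0.2
DEFAULT_MIN_SCORE = 3.0


@dataclass(frozen=True)
class Module:
    """A dense connected subgraph found by clustering."""

    members: frozenset[str]
    seed_node: str
    density: float
    score: float
    method: str = "mcode"

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class VertexWeighting:
    """MCODE stage-1 output: per-node weights plus whole-graph core numbers."""

    weights: dict[str, float]
    core_numbers: dict[str, int]


@dataclass
class ModuleValidation:
    """Agreement between one module and an independent community partition."""

    module: Module
    coassignment_fraction: float
    validated: bool


def module_from_members(
    net: InteractionNetwork,
    members,
    seed_node: str | None = None,
    method: str = "given",
) -> Module:
    """Build a Module from an explicit member set (e.g. a planted truth set
    or an externally supplied partition), computing density and score from
    the network.  The induced subgraph must be connected."""
    members = frozenset(members)
    missing = members - set(net.graph.nodes)
    if missing:
        raise KeyError(f"members absent from network: {sorted(missing)[:3]}")
    sub = net.graph.subgraph(members)
    if len(members) > 1 and not nx.is_connected(sub):
        raise ValueError("module members do not induce a connected subgraph")
    density = _density(sub)
    return Module(
        members=members,
        seed_node=seed_node or min(members),
        density=density,
        score=density * len(members),
        method=method,
    )


def k_core(net: InteractionNetwork, k: int) -> InteractionNetwork:
    """Maximal subgraph in which every node has degree >= k (possibly empty)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    core = nx.k_core(net.graph, k=k) if net.n_nodes else nx.Graph()
    return InteractionNetwork(graph=core.copy(), name=f"{net.name}/{k}-core")


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def vertex_weights(net: InteractionNetwork) -> VertexWeighting:
    """Stage-1 weighting: highest-core number x density of that core.

    The closed neighborhood of v (v plus its neighbors) is extracted, its
    highest k-core found, and weight(v) = k_max * density(highest core).
    Nodes whose closed neighborhood has fewer than 2 nodes (isolated nodes)
    weigh 0.
    """
    g = net.graph
    weights: dict[str, float] = {}
    for v in g:
        nbhd = set(g[v]) | {v}
        if len(nbhd) < 2:
            weights[v] = 0.0
            continue
        sub = g.subgraph(nbhd)
        cores = nx.core_number(sub)
        k_max = max(cores.values())
        highest = sub.subgraph([u for u, c in cores.items() if c >= k_max])
        weights[v] = k_max * _density(highest)
    return VertexWeighting(weights=weights, core_numbers=dict(nx.core_number(g)))


def find_modules(
    net: InteractionNetwork,
    vwp: float = DEFAULT_VWP,
    haircut: bool = True,
    fluff: bool = False,
    fluff_threshold: float = 0.2,
) -> list[Module]:
    """MCODE complex prediction with post-processing.

    ``vwp`` (vertex weight percentage) sets the inclusion tolerance: a
    neighbor joins when its weight is strictly greater than
    seed_weight * (1 - vwp).  Defaults (vwp 0.2, haircut on, fluff off)
    are the algorithm's published defaults.  Ties in seed order and
    neighbor iteration are broken by smallest identifier; the returned list
    is sorted by score descending, then smallest seed, so identical inputs
    give identical output on any platform.
    """
    if not 0.0 <= vwp < 1.0:
        raise ValueError("vwp must be in [0, 1)")
    g = net.graph
    vw = vertex_weights(net)
    w = vw.weights
    order = sorted(g.nodes, key=lambda v: (-w[v], v))
    visited: set[str] = set()
    raw: list[tuple[str, set[str]]] = []
    for seed in order:
        if seed in visited:
            continue
        threshold = w[seed] * (1.0 - vwp)
        members = {seed}
        queue = [seed]
        while queue:
            u = queue.pop(0)
            for nb in sorted(g[u]):
                if nb in visited or nb in members:
                    continue
                if w[nb] > threshold:
                    members.add(nb)
                    queue.append(nb)
        visited |= members
        raw.append((seed, members))

    modules: list[Module] = []
    for seed, members in raw:
        sub = g.subgraph(members)
        two_core = nx.k_core(sub, k=2)
        if two_core.number_of_nodes() == 0:
            continue
        final = set(two_core.nodes) if haircut else set(members)
        if fluff:
            extra: set[str] = set()
            for v in sorted(final):
                for nb in sorted(g[v]):
                    if nb in final or nb in extra:
                        continue
                    nbhd = set(g[nb]) | {nb}
                    if _density(g.subgraph(nbhd)) > fluff_threshold:
                        extra.add(nb)
            final |= extra
        sub_final = g.subgraph(final)
        density = _density(sub_final)
        modules.append(
            Module(
                members=frozenset(final),
                seed_node=seed,
                density=density,
                score=density * len(final),
            )
        )
    modules.sort(key=lambda m: (-m.score, m.seed_node))
    return modules


def filter_modules(modules: list[Module], min_score: float = DEFAULT_MIN_SCORE) -> list[Module]:
    """Keep modules whose score is strictly greater than ``min_score``.

    The inequality is strict: a triangle (score exactly 3.0) does not pass
    the default filter.
    """
    return [m for m in modules if m.score > min_score]


def crosscheck_modules(
    net: InteractionNetwork,
    modules: list[Module],
    seed: int = 0,
    threshold: float = 0.8,
) -> list[ModuleValidation]:
    """Validate modules against an independent Louvain community partition.

    For each module, reports the fraction of its member pairs co-assigned to
    a single community; a module is validated when that fraction reaches
    ``threshold`` (default 0.8 — disconnected modules always validate, random
    scatters of size >= 5 essentially never do).  Single-member modules
    validate vacuously.
    """
    communities = nx.community.louvain_communities(net.graph, seed=seed)
    membership: dict[str, int] = {}
    for i, comm in enumerate(communities):
        for v in comm:
            membership[v] = i
    out: list[ModuleValidation] = []
    for module in modules:
        members = sorted(module.members)
        n = len(members)
        n_pairs = n * (n - 1) // 2
        if n_pairs == 0:
            frac = 1.0
        else:
            same = 0
            for i in range(n):
                for j in range(i + 1, n):
                    if membership.get(members[i]) == membership.get(members[j]):
                        same += 1
            frac = same / n_pairs
        out.append(
            ModuleValidation(
                module=module,
                coassignment_fraction=frac,
                validated=frac >= threshold,
            )
        )
    return out


def label_enrichment(
    module: Module,
    disorder_genes,
    universe: int,
    universe_labeled: int,
) -> float:
    """Hypergeometric upper-tail p for a module's disorder-label content.

    Probability of drawing at least the observed number of labeled members
    when |module| nodes are drawn from a universe of ``universe`` nodes of
    which ``universe_labeled`` carry the label.
    """
    m = len(module.members)
    x = len(module.members & frozenset(disorder_genes))
    if m > universe or universe_labeled > universe or universe_labeled < 0:
        raise ValueError("inconsistent universe counts")
    if x == 0:
        return 1.0
    return float(hypergeom.sf(x - 1, universe, universe_labeled, m))
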