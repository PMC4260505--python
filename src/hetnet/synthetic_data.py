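"""Synthetic interactomes with planted disease-gene structure.

Real curated inputs — a consensus protein-interaction network and
manually curated disorder gene lists — are not redistributable, so every
stage of the pipeline is exercised on generated data that reproduces the
structure the analysis assumes: a heavy-tailed-degree background network,
several disorders each contributing a gene set, and elevated edge density
among genes of the same disorder.  The planted truth record makes each
generated study self-checking: the labeled-neighbor statistic is
recomputed from the truth immediately after generation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import networkx as nx
import numpy as np

from .graph_io import InteractionNetwork, LabelSet, write_network, write_gene_sets
from .interconnectivity import labeled_neighbor_proportion

__all__ = [
    "GeneratorConfig",
    "generate_background",
    "plant_disorders",
    "generate_study",
    "plant_cliques",
    "fixture_networks",
    "write_study",
]


@dataclass
class GeneratorConfig:
    """Parameters of the planted-disorder network generator.

    Defaults describe the study conditions every simulation-based check
    uses: a 2000-node scale-free background (preferential attachment, 3
    edges per new node, giving mean degree just under 6 — the sparse,
    hub-dominated regime of curated interactomes), 5 disorders of 12 genes
    each, and intra-disorder edge probability 0.4, the regime in which
    same-disorder genes are strongly but not perfectly interconnected.
    """

    n_nodes: int = 2000
    background_model: str = "scale_free"  # or "erdos_renyi"
    background_param: float = 3.0  # attachment count, or edge probability
    n_disorders: int = 5
    genes_per_disorder: int = 12
    intra_label_edge_prob: float = 0.4
    overlap_genes: int = 0
    seed: int = 0
    avoid_hubs: bool = True  # sample disorder genes below the 90th degree percentile
    hub_percentile: float = 90.0
    edge_removal_fraction: float = 0.0  # mimic interactome incompleteness

    def validate(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be positive")
        if self.background_model not in ("erdos_renyi", "scale_free"):
            raise ValueError(f"unknown background model: {self.background_model!r}")
        if self.background_model == "erdos_renyi" and not 0 <= self.background_param <= 1:
            raise ValueError("erdos_renyi edge probability must be in [0, 1]")
        if self.background_model == "scale_free" and not (
            1 <= int(self.background_param) < self.n_nodes
        ):
            raise ValueError("scale_free attachment count must be in 1..n_nodes-1")
        if not 0 <= self.intra_label_edge_prob <= 1:
            raise ValueError("intra_label_edge_prob must be in [0, 1]")
        if not 0 <= self.edge_removal_fraction <= 1:
            raise ValueError("edge_removal_fraction must be in [0, 1]")
        if self.n_disorders * self.genes_per_disorder + self.overlap_genes > self.n_nodes:
            raise ValueError("disorders need more genes than the network has nodes")


def _node_name(i: int, width: int) -> str:
    return f"g{i:0{width}d}"


def _child_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence(seed).spawn(index + 1)[index].generate_state(1)[0] % (2**31))


def generate_background(config: GeneratorConfig) -> InteractionNetwork:
    """Seeded background network (Erdős–Rényi or preferential attachment)."""
    config.validate()
    bg_seed = _child_seed(config.seed, 0)
    if config.background_model == "erdos_renyi":
        g = nx.gnp_random_graph(config.n_nodes, config.background_param, seed=bg_seed)
    else:
        g = nx.barabasi_albert_graph(
            config.n_nodes, int(config.background_param), seed=bg_seed
        )
    width = len(str(config.n_nodes - 1))
    g = nx.relabel_nodes(g, {i: _node_name(i, width) for i in g.nodes})
    if config.edge_removal_fraction > 0:
        rng = np.random.default_rng(_child_seed(config.seed, 2))
        edges = sorted(tuple(sorted(e)) for e in g.edges)
        n_remove = int(round(config.edge_removal_fraction * len(edges)))
        for idx in rng.choice(len(edges), size=n_remove, replace=False):
            g.remove_edge(*edges[idx])
    return InteractionNetwork(graph=g, name=f"synthetic-{config.background_model}")


def plant_disorders(
    net: InteractionNetwork, config: GeneratorConfig
) -> tuple[InteractionNetwork, LabelSet, dict]:
    """Plant disorder gene sets with elevated within-disorder edge density.

    Disorder gene sets are sampled disjointly (plus ``overlap_genes`` genes
    shared by every disorder), by default from non-hub nodes (degree below
    the configured percentile) so planted signal is not confounded with
    hubness.  Each within-disorder pair then gains an edge independently
    with ``intra_label_edge_prob``, skipping pairs already connected.  The
    returned truth record lists memberships and added edges, and the
    observed labeled-neighbor statistic is recomputed from it as a
    consistency check before returning.
    """
    config.validate()
    rng = np.random.default_rng(_child_seed(config.seed, 1))
    g = net.graph.copy()
    nodes = sorted(g.nodes)
    if config.avoid_hubs:
        degs = np.array([g.degree(v) for v in nodes])
        cutoff = np.percentile(degs, config.hub_percentile)
        eligible = [v for v, d in zip(nodes, degs) if d < cutoff]
    else:
        eligible = list(nodes)
    needed = config.n_disorders * config.genes_per_disorder + config.overlap_genes
    if len(eligible) < needed:
        raise ValueError(
            f"only {len(eligible)} eligible nodes for {needed} disorder genes"
        )
    pool = [eligible[i] for i in rng.permutation(len(eligible))]
    shared = sorted(pool[: config.overlap_genes])
    cursor = config.overlap_genes
    disorders: dict[str, frozenset[str]] = {}
    for d in range(config.n_disorders):
        own = pool[cursor : cursor + config.genes_per_disorder]
        cursor += config.genes_per_disorder
        disorders[f"disorder{d + 1:02d}"] = frozenset(own) | frozenset(shared)

    added: list[tuple[str, str]] = []
    for name in sorted(disorders):
        genes = sorted(disorders[name])
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                u, v = genes[i], genes[j]
                if g.has_edge(u, v):
                    continue
                if rng.random() < config.intra_label_edge_prob:
                    g.add_edge(u, v)
                    added.append((u, v))

    out_net = InteractionNetwork(graph=g, name=f"{net.name}+planted")
    labels = LabelSet(disorders=disorders, class_name="heterogeneity")
    truth = {
        "config": asdict(config),
        "disorders": {k: sorted(v) for k, v in disorders.items()},
        "shared_genes": shared,
        "added_edges": sorted(tuple(sorted(e)) for e in added),
    }
    truth["observed_statistic"] = labeled_neighbor_proportion(out_net, labels.all_genes)
    # consistency: the truth record alone must reproduce the statistic
    flat = set()
    for genes in truth["disorders"].values():
        flat.update(genes)
    check = labeled_neighbor_proportion(out_net, flat)
    assert check == truth["observed_statistic"]
    return out_net, labels, truth


def generate_study(config: GeneratorConfig) -> tuple[InteractionNetwork, LabelSet, dict]:
    """Background plus planted disorders in one call."""
    return plant_disorders(generate_background(config), config)


def plant_cliques(
    n_nodes: int,
    edge_prob: float,
    clique_sizes: list[int],
    seed: int = 0,
) -> tuple[InteractionNetwork, dict[str, frozenset[str]]]:
    """Plant vertex-disjoint, mutually non-adjacent cliques on a sparse
    Erdős–Rényi background.

    The planted structure is a set of fully separated dense modules:
    background edges *between* two different planted sets are removed
    (edges from a clique to the unplanted background remain), because a
    single stray cross-clique edge merges two cliques into one legitimate
    dense neighborhood and the planted truth would no longer be the
    module-level ground truth.  Returns the network and a name ->
    member-set map.
    """
    cfg = GeneratorConfig(
        n_nodes=n_nodes,
        background_model="erdos_renyi",
        background_param=edge_prob,
        n_disorders=1,
        genes_per_disorder=1,
        seed=seed,
    )
    net = generate_background(cfg)
    g = net.graph
    rng = np.random.default_rng(_child_seed(seed, 1))
    nodes = sorted(g.nodes)
    if sum(clique_sizes) > len(nodes):
        raise ValueError("cliques need more nodes than the network has")
    pool = [nodes[i] for i in rng.permutation(len(nodes))]
    cliques: dict[str, frozenset[str]] = {}
    cursor = 0
    for size in clique_sizes:
        members = sorted(pool[cursor : cursor + size])
        cursor += size
        for i in range(size):
            for j in range(i + 1, size):
                g.add_edge(members[i], members[j])
        cliques[f"K{size}_{len(cliques)}"] = frozenset(members)
    planted = set().union(*cliques.values())
    for u, v in list(g.edges):
        if u in planted and v in planted:
            cu = next(c for c in cliques.values() if u in c)
            if v not in cu:
                g.remove_edge(u, v)
    return InteractionNetwork(graph=g, name="planted-cliques"), cliques


def fixture_networks() -> dict[str, tuple[InteractionNetwork, LabelSet | None]]:
    """Small closed-form fixtures with documented exact statistics.

    - ``star5``: 4-leaf star (centralization 1.0 under both variants,
      clustering 0).
    - ``cycle6``: 6-cycle (regular; centralization 0).
    - ``K4_pendant``: K4 {a,b,c,d} plus pendant e-a (2-core = K4).
    - ``path3``: path A-B-C with labels {A, C} (statistic 0.0; exact null
      {0: 1/3, 1: 2/3}).
    - ``K5_K6_bridge``: disjoint K5 and K6 joined by one bridge edge
      (dense modules exactly K5 score 5.0 and K6 score 6.0).
    - ``bbs_like``: four pairwise-connected labeled genes B1,B2,B4,B7 with
      unlabeled X adjacent to B1,B2 and unlabeled Y adjacent to B1 only
      (candidate rule at min_links 2 nominates exactly X).
    """
    out: dict[str, tuple[InteractionNetwork, LabelSet | None]] = {}

    star = nx.star_graph(4)
    star = nx.relabel_nodes(star, {0: "C", 1: "L1", 2: "L2", 3: "L3", 4: "L4"})
    out["star5"] = (InteractionNetwork(graph=star, name="star5"), None)

    cyc = nx.relabel_nodes(nx.cycle_graph(6), {i: f"n{i}" for i in range(6)})
    out["cycle6"] = (InteractionNetwork(graph=cyc, name="cycle6"), None)

    k4p = nx.complete_graph(["a", "b", "c", "d"])
    k4p.add_edge("a", "e")
    out["K4_pendant"] = (InteractionNetwork(graph=k4p, name="K4_pendant"), None)

    p3 = nx.Graph([("A", "B"), ("B", "C")])
    out["path3"] = (
        InteractionNetwork(graph=p3, name="path3"),
        LabelSet(disorders={"toy": frozenset({"A", "C"})}, class_name="toy"),
    )

    k5 = [f"a{i}" for i in range(5)]
    k6 = [f"b{i}" for i in range(6)]
    bridge = nx.compose(nx.complete_graph(k5), nx.complete_graph(k6))
    bridge.add_edge("a0", "b0")
    out["K5_K6_bridge"] = (InteractionNetwork(graph=bridge, name="K5_K6_bridge"), None)

    bbs = nx.complete_graph(["B1", "B2", "B4", "B7"])
    bbs.add_edges_from([("X", "B1"), ("X", "B2"), ("Y", "B1")])
    out["bbs_like"] = (
        InteractionNetwork(graph=bbs, name="bbs_like"),
        LabelSet(
            disorders={"BBS": frozenset({"B1", "B2", "B4", "B7"})},
            class_name="heterogeneity",
        ),
    )
    return out


def write_study(
    net: InteractionNetwork,
    labels: LabelSet,
    truth: dict,
    out_dir,
) -> dict[str, Path]:
    """Write a generated study as edge-list TSV + GMT labels + truth JSON.

    Output is fully sorted, so identical seeds produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "network": out_dir / "network.sif",
        "labels": out_dir / "labels.gmt",
        "truth": out_dir / "truth.json",
    }
    write_network(net, paths["network"], dialect="sif")
    write_gene_sets(labels, paths["labels"])
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
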