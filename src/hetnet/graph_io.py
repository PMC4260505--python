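"""Readers, writers and cleaning for interaction networks and disease gene sets.

Interaction networks are simple undirected graphs over opaque gene/protein
identifier strings: self-loops and duplicate (parallel) edges are removed on
ingestion and a cleaning report records how many were dropped.  Disease gene
sets come in as GMT records (one named disorder per line); identifier
translation (e.g. gene symbol -> UniProt accession) is a plain two-column
table applied locally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "CleaningReport",
    "InteractionNetwork",
    "LabelSet",
    "IdMapping",
    "MappingReport",
    "load_network",
    "write_network",
    "load_gene_sets",
    "write_gene_sets",
    "load_mapping",
    "apply_mapping",
    "largest_connected_component",
    "induce_subnetwork",
]


@dataclass
class CleaningReport:
    """Counts of records dropped while enforcing the simple-graph invariants."""

    self_loops_dropped: int = 0
    duplicate_edges_dropped: int = 0


@dataclass
class InteractionNetwork:
    """A simple undirected interaction network.

    Wraps a :class:`networkx.Graph`; the invariants (no self-loops, no
    parallel edges, every edge endpoint a node) are enforced by the
    constructors in this module.  Identifiers are compared case-sensitively —
    UniProt accessions are case-significant.
    """

    graph: nx.Graph
    name: str = ""
    cleaning: CleaningReport = field(default_factory=CleaningReport)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        """Edge set with each edge canonicalized as a sorted identifier pair."""
        return {tuple(sorted((u, v))) for u, v in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbors(self, node: str) -> set[str]:
        return set(self.graph[node])

    def adjacency(self) -> dict[str, set[str]]:
        """Node -> neighbor-set map (a plain-dict snapshot for tight loops)."""
        return {v: set(self.graph[v]) for v in self.graph}

    def validate(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise ValueError("network contains a self-loop")

    @classmethod
    def from_edges(
        cls,
        edges,
        nodes=(),
        name: str = "",
    ) -> "InteractionNetwork":
        """Build a network from an iterable of (u, v) pairs, cleaning as it goes.

        Self-loops and repeated unordered pairs are dropped and counted.
        ``nodes`` may add isolated nodes beyond the edge endpoints.
        """
        g = nx.Graph()
        report = CleaningReport()
        seen: set[tuple[str, str]] = set()
        for u, v in edges:
            if u == v:
                report.self_loops_dropped += 1
                g.add_node(u)
                continue
            key = (u, v) if u <= v else (v, u)
            if key in seen:
                report.duplicate_edges_dropped += 1
                continue
            seen.add(key)
            g.add_edge(u, v)
        g.add_nodes_from(nodes)
        return cls(graph=g, name=name, cleaning=report)


@dataclass
class LabelSet:
    """Named disorders mapped to gene identifier sets.

    A gene may belong to several disorders (ERCC2, for instance, causes both
    trichothiodystrophy and xeroderma pigmentosum); the flat label set is the
    union over disorders.
    """

    disorders: dict[str, frozenset[str]]
    class_name: str = "disease"

    @property
    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.disorders.values():
            out |= genes
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.disorders)

    def restrict_to(self, universe) -> "LabelSet":
        """Drop genes outside ``universe``; disorders emptied entirely are removed."""
        uni = set(universe)
        kept = {
            name: frozenset(g & uni)
            for name, g in self.disorders.items()
            if g & uni
        }
        return LabelSet(disorders=kept, class_name=self.class_name)

    def without_gene(self, gene: str) -> "LabelSet":
        kept = {
            name: frozenset(g - {gene})
            for name, g in self.disorders.items()
            if g - {gene}
        }
        return LabelSet(disorders=kept, class_name=self.class_name)


@dataclass
class IdMapping:
    """Many-to-one identifier translation (each source has at most one target)."""

    pairs: dict[str, str]
    unmapped: set[str] = field(default_factory=set)

    def translate(self, identifier: str) -> str:
        """Map an identifier, passing it through unchanged when unlisted."""
        return self.pairs.get(identifier, identifier)


@dataclass
class MappingReport:
    """What happened when a mapping was pushed through a network and labels."""

    unmapped_network_ids: set[str] = field(default_factory=set)
    unmapped_label_ids: set[str] = field(default_factory=set)
    labels_not_in_network: set[str] = field(default_factory=set)
    nodes_merged: int = 0
    self_loops_from_merge: int = 0
    label_count_before_merge: int = 0
    label_count_after_merge: int = 0


def load_network(path, dialect: str = "tsv", name: str = "") -> InteractionNetwork:
    """Read an edge list (2-column TSV or SIF) into a cleaned network.

    TSV records are exactly two tab/whitespace-separated identifiers; lines
    starting with ``#`` are comments.  SIF records are
    ``source [interaction-type target ...]`` — the interaction-type column is
    ignored, multi-target lines are expanded, and a bare single identifier is
    an isolated node.  Malformed records raise with their line number.
    """
    path = Path(path)
    if dialect not in ("tsv", "sif"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    edges: list[tuple[str, str]] = []
    isolated: list[str] = []
    n_records = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            n_records += 1
            if dialect == "tsv":
                if len(fields) != 2:
                    raise ValueError(
                        f"{path}:{lineno}: expected 2 columns, got {len(fields)}"
                    )
                edges.append((fields[0], fields[1]))
            else:  # sif
                if len(fields) == 1:
                    isolated.append(fields[0])
                elif len(fields) == 2:
                    raise ValueError(
                        f"{path}:{lineno}: SIF record has an interaction type "
                        "but no target"
                    )
                else:
                    src = fields[0]
                    for target in fields[2:]:
                        edges.append((src, target))
    if n_records == 0:
        raise ValueError(f"{path}: no records found")
    net = InteractionNetwork.from_edges(edges, nodes=isolated, name=name or path.stem)
    logger.info(
        "loaded %s: %d nodes, %d edges (%d self-loops, %d duplicates dropped)",
        path,
        net.n_nodes,
        net.n_edges,
        net.cleaning.self_loops_dropped,
        net.cleaning.duplicate_edges_dropped,
    )
    return net


def write_network(net: InteractionNetwork, path, dialect: str = "sif") -> None:
    """Write a network so it round-trips through :func:`load_network`.

    The SIF dialect (default) preserves isolated nodes as bare-identifier
    lines; the TSV dialect writes edges only and warns when isolated nodes
    would be lost.
    """
    path = Path(path)
    edges = sorted(net.edges)
    isolated = sorted(v for v in net.graph if net.graph.degree(v) == 0)
    with open(path, "w") as fh:
        if dialect == "sif":
            for u, v in edges:
                fh.write(f"{u}\tpp\t{v}\n")
            for v in isolated:
                fh.write(f"{v}\n")
        elif dialect == "tsv":
            if isolated:
                logger.warning(
                    "TSV edge list cannot represent %d isolated nodes", len(isolated)
                )
            for u, v in edges:
                fh.write(f"{u}\t{v}\n")
        else:
            raise ValueError(f"unknown dialect: {dialect!r}")


def load_gene_sets(path, class_name: str = "disease") -> LabelSet:
    """Read GMT records (set name, description, genes...) into a LabelSet.

    Duplicate genes within a record are collapsed; a record listing zero
    genes raises, naming the set.  An empty file yields an empty LabelSet
    (the pipeline treats that as a stats-only run).
    """
    path = Path(path)
    disorders: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3 or not any(f.strip() for f in fields[2:]):
                name = fields[0] if fields else f"line {lineno}"
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no genes")
            name = fields[0]
            genes = frozenset(f.strip() for f in fields[2:] if f.strip())
            disorders[name] = genes
    return LabelSet(disorders=disorders, class_name=class_name)


def write_gene_sets(labels: LabelSet, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(labels.disorders):
            genes = "\t".join(sorted(labels.disorders[name]))
            fh.write(f"{name}\t{labels.class_name}\t{genes}\n")


def load_mapping(path) -> IdMapping:
    """Read a two-column TSV of source -> target identifier pairs.

    Rows with an empty target column mark explicitly-unmapped sources.  A
    source listed twice with conflicting targets raises (the mapping must be
    a function).
    """
    path = Path(path)
    pairs: dict[str, str] = {}
    unmapped: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            src = fields[0].strip()
            tgt = fields[1].strip() if len(fields) > 1 else ""
            if not src:
                raise ValueError(f"{path}:{lineno}: empty source identifier")
            if not tgt:
                unmapped.add(src)
                continue
            if src in pairs and pairs[src] != tgt:
                raise ValueError(
                    f"{path}:{lineno}: conflicting targets for {src!r}"
                )
            pairs[src] = tgt
    return IdMapping(pairs=pairs, unmapped=unmapped)


def apply_mapping(
    net: InteractionNetwork,
    labels: LabelSet,
    mapping: IdMapping,
) -> tuple[InteractionNetwork, LabelSet, MappingReport]:
    """Rewrite network and label identifiers through a many-to-one mapping.

    Nodes merged by the mapping have their edges unioned; self-loops created
    by merging are dropped.  Label genes whose translated identifier is
    absent from the translated network are removed from the label set and
    reported (this is the attrition step: curated symbols that cannot be
    placed on the interactome).  Unlisted identifiers pass through unchanged
    and are reported, not dropped.
    """
    report = MappingReport()
    report.unmapped_network_ids = {
        v for v in net.graph if v not in mapping.pairs
    }
    old_n = net.n_nodes
    edges = (
        (mapping.translate(u), mapping.translate(v)) for u, v in net.graph.edges
    )
    nodes = (mapping.translate(v) for v in net.graph)
    mapped_net = InteractionNetwork.from_edges(edges, nodes=nodes, name=net.name)
    report.nodes_merged = old_n - mapped_net.n_nodes
    report.self_loops_from_merge = mapped_net.cleaning.self_loops_dropped

    report.unmapped_label_ids = {
        g for g in labels.all_genes if g not in mapping.pairs
    }
    translated = {
        name: frozenset(mapping.translate(g) for g in genes)
        for name, genes in labels.disorders.items()
    }
    report.label_count_before_merge = len(labels.all_genes)
    flat = frozenset().union(*translated.values()) if translated else frozenset()
    report.label_count_after_merge = len(flat)
    net_nodes = mapped_net.nodes
    report.labels_not_in_network = set(flat - net_nodes)
    mapped_labels = LabelSet(
        disorders=translated, class_name=labels.class_name
    ).restrict_to(net_nodes)
    if report.labels_not_in_network:
        logger.info(
            "%d label genes could not be placed on the network",
            len(report.labels_not_in_network),
        )
    return mapped_net, mapped_labels, report


def largest_connected_component(net: InteractionNetwork) -> InteractionNetwork:
    """Induced subgraph on the largest component.

    Size ties are broken by the lexicographically smallest member identifier
    so output is deterministic.
    """
    if net.n_nodes == 0:
        raise ValueError("cannot take the LCC of an empty network")
    best = min(
        nx.connected_components(net.graph),
        key=lambda comp: (-len(comp), min(comp)),
    )
    sub = net.graph.subgraph(best).copy()
    return InteractionNetwork(graph=sub, name=f"{net.name}/lcc" if net.name else "lcc")


def induce_subnetwork(net: InteractionNetwork, genes) -> InteractionNetwork:
    """Induced subgraph on ``genes`` ∩ network nodes.

    Members with no within-set interaction partner are kept as degree-0
    (isolated) nodes — in the disease subnetworks these isolated nodes are a
    reported quantity, not noise.
    """
    keep = set(genes) & set(net.graph.nodes)
    sub = nx.Graph()
    sub.add_nodes_from(keep)
    sub.add_edges_from(
        (u, v) for u, v in net.graph.edges if u in keep and v in keep
    )
    return InteractionNetwork(graph=sub, name=f"{net.name}/induced" if net.name else "induced")
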