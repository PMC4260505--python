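"""Labeled-neighbor interconnectivity and its permutation null.

The headline statistic is the proportion of labeled (e.g. locus
heterogeneity) nodes that have at least one labeled interaction partner.
Significance comes from re-assigning the same number of labels to random
node subsets of the network and recomputing the statistic, typically 10,000
times.  On small graphs the null can instead be enumerated exactly over all
C(n, k) label placements, which serves as an independent oracle for the
Monte Carlo machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .graph_io import InteractionNetwork

__all__ = [
    "PermutationResult",
    "labeled_neighbor_proportion",
    "permutation_test",
    "exact_null",
    "exact_p_value",
    "compare_classes",
    "null_histogram",
]


@dataclass
class PermutationResult:
    """Observed statistic, Monte Carlo null sample, and p-value.

    ``p_value`` uses the add-one estimator (r + 1) / (n + 1), where r counts
    null samples >= observed (ties are exceedances, which is conservative);
    it can therefore never be exactly 0.  ``exceedance_fraction`` is the raw
    r / n, so a claim like "below 1/n" can be restated from the same object.
    """

    observed: float
    null_samples: np.ndarray
    n_permutations: int
    p_value: float
    exceedance_fraction: float
    seed: int
    mode: str

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_samples))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_samples, ddof=1)) if self.n_permutations > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "n_permutations": self.n_permutations,
            "p_value": self.p_value,
            "exceedance_fraction": self.exceedance_fraction,
            "seed": self.seed,
            "mode": self.mode,
        }


def _proportion(adjacency: dict[str, set[str]], labeled: set[str]) -> float:
    """Fraction of labeled nodes with >= 1 labeled neighbor."""
    hit = sum(1 for v in labeled if not adjacency[v].isdisjoint(labeled))
    return hit / len(labeled)


def labeled_neighbor_proportion(net: InteractionNetwork, labeled) -> float:
    """Proportion of labeled nodes having at least one labeled neighbor.

    All labeled identifiers must already be present in the network —
    identifier mapping and attrition are handled upstream, so that the
    statistic's denominator is unambiguous.
    """
    labeled = set(labeled)
    if not labeled:
        raise ValueError("labeled set is empty")
    missing = labeled - set(net.graph.nodes)
    if missing:
        raise KeyError(
            f"{len(missing)} labeled identifiers absent from the network "
            f"(e.g. {sorted(missing)[:3]}); apply mapping first"
        )
    return _proportion({v: set(net.graph[v]) for v in labeled}, labeled)


def _degree_strata(net: InteractionNetwork, n_strata: int = 10):
    """Assign every node to a degree-decile stratum.

    Returns (node -> stratum index, stratum index -> node list).  Boundaries
    are degree-distribution quantiles; heavy ties can leave some strata
    empty, which is an error only if labels would need to be drawn from one.
    """
    nodes = sorted(net.graph.nodes)
    degs = np.array([net.graph.degree(v) for v in nodes])
    qs = np.quantile(degs, np.linspace(0, 1, n_strata + 1)[1:-1])
    idx = np.searchsorted(qs, degs, side="left")
    assignment = {v: int(i) for v, i in zip(nodes, idx)}
    strata: dict[int, list[str]] = {i: [] for i in range(n_strata)}
    for v, i in assignment.items():
        strata[i].append(v)
    return assignment, strata


def permutation_test(
    net: InteractionNetwork,
    labeled,
    n_permutations: int = 10_000,
    seed: int = 0,
    mode: str = "uniform",
) -> PermutationResult:
    """Permutation null for the labeled-neighbor proportion.

    Each randomization assigns the label to |labeled| distinct nodes —
    uniformly over all network nodes (``uniform``, default) or within
    degree-decile strata matching the observed labels
    (``degree_stratified``) — and recomputes the statistic.  One root seed
    spawns an independent substream per permutation, so results are
    identical regardless of evaluation order or parallel scheduling.
    """
    if mode not in ("uniform", "degree_stratified"):
        raise ValueError(f"unknown mode: {mode!r}")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    labeled = set(labeled)
    observed = labeled_neighbor_proportion(net, labeled)

    nodes = sorted(net.graph.nodes)
    adjacency = {v: set(net.graph[v]) for v in nodes}
    k = len(labeled)
    node_arr = np.array(nodes, dtype=object)

    if mode == "degree_stratified":
        assignment, strata = _degree_strata(net)
        needed: dict[int, int] = {}
        for v in labeled:
            needed[assignment[v]] = needed.get(assignment[v], 0) + 1
        stratum_arrays = {}
        for i, count in sorted(needed.items()):
            members = strata[i]
            if not members:
                raise ValueError(f"degree stratum {i} is empty")
            stratum_arrays[i] = np.array(sorted(members), dtype=object)

    children = np.random.SeedSequence(seed).spawn(n_permutations)
    null = np.empty(n_permutations)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        if mode == "uniform":
            pick = node_arr[rng.choice(len(node_arr), size=k, replace=False)]
            sample = set(pick.tolist())
        else:
            sample = set()
            for s, count in sorted(needed.items()):
                arr = stratum_arrays[s]
                pick = arr[rng.choice(len(arr), size=count, replace=False)]
                sample.update(pick.tolist())
        null[i] = _proportion(adjacency, sample)

    r = int(np.sum(null >= observed))
    return PermutationResult(
        observed=observed,
        null_samples=null,
        n_permutations=n_permutations,
        p_value=(r + 1) / (n_permutations + 1),
        exceedance_fraction=r / n_permutations,
        seed=seed,
        mode=mode,
    )


def exact_null(net: InteractionNetwork, k: int) -> dict[float, float]:
    """Exact null distribution of the statistic over all C(n, k) placements.

    Brute-force enumeration; refuses to run past 10^6 combinations.  Returns
    a map proportion -> probability mass (masses sum to 1).
    """
    nodes = sorted(net.graph.nodes)
    n = len(nodes)
    if k < 1 or k > n:
        raise ValueError("k must be in 1..n_nodes")
    if math.comb(n, k) > 10**6:
        raise ValueError(f"C({n},{k}) exceeds the 10^6 enumeration bound")
    adjacency = {v: set(net.graph[v]) for v in nodes}
    counts: dict[int, int] = {}
    total = 0
    for combo in combinations(nodes, k):
        labeled = set(combo)
        hit = sum(1 for v in labeled if not adjacency[v].isdisjoint(labeled))
        counts[hit] = counts.get(hit, 0) + 1
        total += 1
    return {hit / k: c / total for hit, c in sorted(counts.items())}


def exact_p_value(net: InteractionNetwork, labeled) -> float:
    """Exact upper-tail probability P(null >= observed) by enumeration."""
    labeled = set(labeled)
    observed = labeled_neighbor_proportion(net, labeled)
    dist = exact_null(net, len(labeled))
    # proportions are exact multiples of 1/k on both sides; tolerance guards
    # against float representation of the same rational
    eps = 1e-12
    return float(sum(p for value, p in dist.items() if value >= observed - eps))


def compare_classes(
    net: InteractionNetwork,
    class_labels: dict[str, set[str]],
    n_permutations: int = 10_000,
    seed: int = 0,
    mode: str = "uniform",
) -> dict[str, PermutationResult]:
    """Run the permutation test for several label classes on one network.

    Classes are processed in sorted name order, each on its own child seed of
    the root seed, so per-class results do not depend on which other classes
    are present.
    """
    for name, genes in class_labels.items():
        if not genes:
            raise ValueError(f"class {name!r} is empty")
    names = sorted(class_labels)
    children = np.random.SeedSequence(seed).spawn(len(names))
    out: dict[str, PermutationResult] = {}
    for name, child in zip(names, children):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        out[name] = permutation_test(
            net,
            class_labels[name],
            n_permutations=n_permutations,
            seed=child_seed,
            mode=mode,
        )
    return out


def null_histogram(result: PermutationResult, n_bins: int = 20) -> str:
    """TSV histogram of the null sample (bin_left, bin_right, count).

    The observed value is appended as a final annotated row, mirroring the
    usual observed-vs-null figure.
    """
    counts, edges = np.histogram(result.null_samples, bins=n_bins, range=(0.0, 1.0))
    lines = ["bin_left\tbin_right\tcount"]
    for left, right, c in zip(edges[:-1], edges[1:], counts):
        lines.append(f"{left:.4f}\t{right:.4f}\t{int(c)}")
    lines.append(f"# observed\t{result.observed:.6f}\t")
    return "\n".join(lines) + "\n"
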