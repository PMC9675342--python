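"""Directed transition networks and modularity-based community detection.

Nodes are play elements; an edge A -> B carries the conditional transition
probability for every transition that passed the significance filter
(observed at least ``min_transition_count`` times, permutation p <= alpha).
Communities are groups of elements with strong within-group transitions —
candidate "games".  Community detection maximizes Newman-Girvan weighted
modularity on the direction-collapsed (weight-summed) graph, exhaustively
for small networks and with a seeded Louvain refinement above that; the
partition counts as structured when modularity exceeds 0.3.
"""

from __future__ import annotations

import itertools
from collections import Counter
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from .io_model import MARKERS, PipelineConfig
from .preprocess import ElementSequence
from .transition_stats import TransitionProbabilities, TransitionTestResult


@dataclass(frozen=True)
class NetworkEdge:
    source: str
    target: str
    weight: float  # transition probability
    count: float
    p_value: float


@dataclass
class TransitionNetwork:
    nodes: tuple[str, ...]
    edges: tuple[NetworkEdge, ...]
    isolates: tuple[str, ...] = ()  # elements with no significant transition

    def to_networkx(self, include_self_loops: bool = True) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            if not include_self_loops and e.source == e.target:
                continue
            g.add_edge(e.source, e.target, weight=e.weight, count=e.count, p_value=e.p_value)
        return g


@dataclass
class CommunityPartition:
    memberships: dict[str, int]
    modularity: float
    acceptable: bool
    method: str = "exhaustive"


def build_network(
    tests: Sequence[TransitionTestResult],
    probs: TransitionProbabilities,
    config: PipelineConfig | None = None,
) -> TransitionNetwork:
    """Assemble the network of significant transitions.

    ``tests`` must already be filtered; this is re-asserted when a config is
    supplied.  Elements with no significant transition are excluded from the
    node set and reported as isolates (the "no significant transitions"
    group).  Self-loops (elements significantly following themselves) are
    kept as edges.
    """
    if config is not None:
        bad = [
            t
            for t in tests
            if t.observed_count < config.min_transition_count or t.p_value > config.alpha
        ]
        if bad:
            raise ValueError(f"{len(bad)} edges fail the significance filter")
    edges = tuple(
        NetworkEdge(
            source=t.antecedent,
            target=t.consequent,
            weight=t.observed_prob,
            count=t.observed_count,
            p_value=t.p_value,
        )
        for t in sorted(tests, key=lambda t: (t.antecedent, t.consequent))
    )
    connected = {e.source for e in edges} | {e.target for e in edges}
    vocab = sorted(
        {a for (a,) in probs.table} | {c for row in probs.table.values() for c in row}
    )
    isolates = tuple(el for el in vocab if el not in connected)
    return TransitionNetwork(
        nodes=tuple(sorted(connected)), edges=edges, isolates=isolates
    )


# ---------------------------------------------------------------------------
# Modularity
# ---------------------------------------------------------------------------


def _symmetric_weights(network: TransitionNetwork) -> tuple[list[str], np.ndarray]:
    """Direction-collapsed weight matrix, self-loops dropped."""
    nodes = list(network.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    W = np.zeros((len(nodes), len(nodes)), dtype=np.float64)
    for e in network.edges:
        if e.source == e.target:
            continue
        i, j = index[e.source], index[e.target]
        W[i, j] += e.weight
        W[j, i] += e.weight
    return nodes, W


def _modularity_matrix(W: np.ndarray) -> tuple[np.ndarray, float]:
    two_m = W.sum()
    if two_m == 0:
        raise ValueError("network has no (non-loop) edge weight")
    k = W.sum(axis=1)
    B = W / two_m - np.outer(k, k) / two_m**2
    return B, two_m


def modularity(network: TransitionNetwork, memberships: dict[str, int]) -> float:
    """Newman-Girvan weighted modularity of a partition.

    Computed on the symmetrized weight matrix with self-loops excluded:
    Q = sum_c [ W_c / W - (S_c / 2W)^2 ] where W_c is within-community
    weight and S_c the community strength sum.
    """
    nodes, W = _symmetric_weights(network)
    unknown = set(memberships) - set(nodes)
    if unknown:
        raise ValueError(f"memberships refer to unknown nodes: {sorted(unknown)}")
    missing = set(nodes) - set(memberships)
    if missing:
        raise ValueError(f"memberships missing nodes: {sorted(missing)}")
    B, _ = _modularity_matrix(W)
    labels = np.asarray([memberships[n] for n in nodes])
    same = labels[:, None] == labels[None, :]
    return float((B * same).sum())


def _partitions(n: int):
    """All set partitions of range(n) as restricted-growth label arrays."""
    labels = np.zeros(n, dtype=np.int64)

    def rec(i: int, maxlab: int):
        if i == n:
            yield labels
            return
        for lab in range(maxlab + 1):
            labels[i] = lab
            yield from rec(i + 1, max(maxlab, lab + 1))

    yield from rec(1, 1)


def exhaustive_max_modularity(
    network: TransitionNetwork,
) -> tuple[dict[str, int], float]:
    """True modularity maximum by enumerating every partition."""
    nodes, W = _symmetric_weights(network)
    B, _ = _modularity_matrix(W)
    n = len(nodes)
    best_q = -np.inf
    best = None
    for labels in _partitions(n):
        same = labels[:, None] == labels[None, :]
        q = float((B * same).sum())
        if q > best_q + 1e-12:
            best_q = q
            best = labels.copy()
    assert best is not None
    memberships = {}
    remap: dict[int, int] = {}
    for node, lab in zip(nodes, best.tolist()):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        memberships[node] = remap[lab]
    return memberships, best_q


def _louvain_max_modularity(
    network: TransitionNetwork, rng: np.random.Generator
) -> tuple[dict[str, int], float]:
    """Seeded Louvain with greedy single-node refinement passes."""
    nodes, W = _symmetric_weights(network)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for i, a in enumerate(nodes):
        for j in range(i + 1, len(nodes)):
            if W[i, j] > 0:
                g.add_edge(a, nodes[j], weight=W[i, j])
    best_q, best = -np.inf, None
    for _ in range(5):
        seed = int(rng.integers(0, 2**31 - 1))
        comms = nx.community.louvain_communities(g, weight="weight", seed=seed)
        labels = {n: ci for ci, c in enumerate(comms) for n in c}
        labels = _refine(nodes, W, labels)
        q = _labels_modularity(nodes, W, labels)
        if q > best_q:
            best_q, best = q, labels
    remap: dict[int, int] = {}
    memberships = {}
    for n in nodes:
        lab = best[n]
        if lab not in remap:
            remap[lab] = len(remap) + 1
        memberships[n] = remap[lab]
    return memberships, best_q


def _labels_modularity(nodes: list[str], W: np.ndarray, labels: dict[str, int]) -> float:
    B, _ = _modularity_matrix(W)
    arr = np.asarray([labels[n] for n in nodes])
    return float((B * (arr[:, None] == arr[None, :])).sum())


def _refine(nodes: list[str], W: np.ndarray, labels: dict[str, int]) -> dict[str, int]:
    """Greedy single-node moves until no move improves modularity."""
    B, _ = _modularity_matrix(W)
    arr = np.asarray([labels[n] for n in nodes])
    improved = True
    while improved:
        improved = False
        for i in range(len(nodes)):
            current = arr[i]
            options = set(arr.tolist()) | {max(arr) + 1}
            gains = {}
            for lab in options:
                if lab == current:
                    continue
                mask_new = arr == lab
                mask_old = arr == current
                gain = 2 * (B[i, mask_new].sum() - B[i, mask_old].sum()) + 2 * B[i, i]
                gains[lab] = gain
            lab, gain = max(gains.items(), key=lambda kv: kv[1])
            if gain > 1e-12:
                arr[i] = lab
                improved = True
    return {n: int(l) for n, l in zip(nodes, arr.tolist())}


def detect_communities(
    network: TransitionNetwork,
    config: PipelineConfig,
    rng: np.random.Generator | None = None,
) -> CommunityPartition:
    """Modularity-maximizing partition of the transition network.

    Exhaustive partition enumeration (the true maximum) up to
    ``exact_community_limit`` nodes; above that, seeded Louvain with greedy
    refinement, labelled as such in the result.
    """
    if not network.nodes:
        raise ValueError("empty network")
    if len(network.nodes) <= config.exact_community_limit:
        memberships, q = exhaustive_max_modularity(network)
        method = "exhaustive"
    else:
        rng = rng or np.random.default_rng(config.rng_seed)
        memberships, q = _louvain_max_modularity(network, rng)
        method = "louvain_refined"
    return CommunityPartition(
        memberships=memberships,
        modularity=q,
        acceptable=q > config.modularity_threshold,
        method=method,
    )


# ---------------------------------------------------------------------------
# Within- vs between-community transitions, partition agreement
# ---------------------------------------------------------------------------


def community_transition_fractions(
    sequences: Iterable[Sequence[ElementSequence]] | Sequence[ElementSequence],
    memberships: dict[str, int],
    n_label_perms: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, float]:
    """Observed vs chance share of transitions that stay within a community.

    Counts adjacent transitions among partitioned elements only.  The chance
    expectation permutes community labels across nodes (community sizes
    preserved) ``n_label_perms`` times and averages the same statistic.
    Returns (observed_within, expected_within, ratio).
    """
    rng = rng or np.random.default_rng()
    items = list(sequences)
    if items and isinstance(items[0], ElementSequence):
        ensemble = [items]  # a single linearization
    else:
        ensemble = [list(lin) for lin in items]
    if not ensemble:
        raise ValueError("no sequences supplied")
    nodes = sorted(memberships)
    index = {n: i for i, n in enumerate(nodes)}
    counts = np.zeros((len(nodes), len(nodes)), dtype=np.float64)
    for lin in ensemble:
        for seq in lin:
            toks = seq.tokens
            for a, b in zip(toks, toks[1:]):
                if a in index and b in index:
                    counts[index[a], index[b]] += 1.0
    counts /= len(ensemble)
    total = counts.sum()
    if total == 0:
        raise ValueError("no transitions among partitioned nodes")
    labels = np.asarray([memberships[n] for n in nodes])
    observed = float(counts[labels[:, None] == labels[None, :]].sum() / total)
    exp = 0.0
    for _ in range(n_label_perms):
        perm = rng.permutation(labels)
        exp += float(counts[perm[:, None] == perm[None, :]].sum() / total)
    expected = exp / n_label_perms
    return observed, expected, observed / expected


def compare_partitions(
    a: dict[str, int], b: dict[str, int]
) -> tuple[float, float, dict[tuple[int, int], int]]:
    """ARI, NMI, and the cross-tabulation over the shared element set."""
    shared = sorted(set(a) & set(b))
    if not shared:
        raise ValueError("partitions share no elements")
    la = [a[e] for e in shared]
    lb = [b[e] for e in shared]
    ari = float(adjusted_rand_score(la, lb))
    nmi = float(normalized_mutual_info_score(la, lb))
    contingency = Counter(zip(la, lb))
    return ari, nmi, dict(contingency)


def write_network(network: TransitionNetwork, graphml_path=None, csv_path=None) -> None:
    """Export the directed network as GraphML and/or an edge-list CSV."""
    import pandas as pd

    if graphml_path is not None:
        nx.write_graphml(network.to_networkx(), graphml_path)
    if csv_path is not None:
        pd.DataFrame(
            [
                (e.source, e.target, e.weight, e.count, e.p_value)
                for e in network.edges
            ],
            columns=["source", "target", "weight", "count", "p_value"],
        ).to_csv(csv_path, index=False, float_format="%.10g")
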