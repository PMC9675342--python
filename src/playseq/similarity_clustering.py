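"""Clustering of play elements by the similarity of their transition profiles.

Each element is represented by its vector of first-order conditional
transition probabilities to every other element; elements used at similar
sequence positions ("synonyms") have similar vectors.  The vectors are
embedded into two dimensions with UMAP, clustered by k-means with the number
of clusters selected by mean silhouette on the embedded Euclidean distances,
and a Ward dendrogram cut at the selected k gives the hierarchical view.
Because the stochastic embedding varies between runs, the whole procedure is
repeated with varying epoch counts and the modal number of clusters across
runs is retained (consensus), together with pairwise co-assignment
frequencies as a stability measure.
"""

from __future__ import annotations

import warnings
from collections import Counter
from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage, to_tree
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .io_model import PipelineConfig
from .transition_stats import TransitionProbabilities


@dataclass
class TransitionProfileMatrix:
    elements: tuple[str, ...]
    rows: np.ndarray  # square; row i = P(next = j | current = i)
    zero_rows: tuple[str, ...] = ()  # never observed as antecedent

    def __post_init__(self) -> None:
        n = len(self.elements)
        assert self.rows.shape == (n, n)


@dataclass
class ClusterSolution:
    memberships: dict[str, int]  # element -> cluster id, 1..k
    k: int
    silhouette: float
    dendrogram: np.ndarray | None = None  # scipy linkage matrix
    run_id: int = -1
    acceptable: bool = False
    epochs: int = 0
    hierarchical_silhouette: float = float("nan")


def transition_profile_matrix(
    probs: TransitionProbabilities, vocabulary: Sequence[str] | None = None
) -> TransitionProfileMatrix:
    """Square matrix of outgoing first-order transition probabilities.

    Elements never observed as antecedents get all-zero rows and are flagged.
    """
    if probs.order != 1:
        raise ValueError("profile matrix requires first-order probabilities")
    if vocabulary is None:
        vocab = sorted(
            {a for (a,) in probs.table} | {c for row in probs.table.values() for c in row}
        )
    else:
        vocab = sorted(vocabulary)
    index = {el: i for i, el in enumerate(vocab)}
    mat = np.zeros((len(vocab), len(vocab)), dtype=np.float64)
    for (ant,), row in probs.table.items():
        for cons, p in row.items():
            mat[index[ant], index[cons]] = p
    zero = tuple(el for el in vocab if mat[index[el]].sum() == 0)
    return TransitionProfileMatrix(elements=tuple(vocab), rows=mat, zero_rows=zero)


def embed_2d(
    matrix: TransitionProfileMatrix,
    epochs: int,
    rng: np.random.Generator,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> dict[str, tuple[float, float]]:
    """2-D UMAP embedding of the transition profile vectors.

    The embedding seed is drawn from ``rng`` so repeated calls differ unless
    the generator state is fixed.  The neighbourhood size shrinks with a
    warning when there are too few elements.
    """
    import umap  # deferred: slow import

    n = len(matrix.elements)
    if n < 4:
        raise ValueError("embedding needs at least 4 elements")
    if n_neighbors >= n:
        warnings.warn(
            f"n_neighbors={n_neighbors} >= {n} elements; reducing", stacklevel=2
        )
        n_neighbors = max(2, n - 1)
    seed = int(rng.integers(0, 2**31 - 1))
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", module="umap")
        warnings.filterwarnings("ignore", module="sklearn")
        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            n_epochs=int(epochs),
            random_state=seed,
            n_jobs=1,
        )
        coords = reducer.fit_transform(matrix.rows)
    return {el: (float(x), float(y)) for el, (x, y) in zip(matrix.elements, coords)}


def _points_array(points: dict[str, tuple[float, float]]) -> tuple[list[str], np.ndarray]:
    elements = sorted(points)
    return elements, np.asarray([points[e] for e in elements], dtype=np.float64)


def optimal_k(
    points: dict[str, tuple[float, float]],
    k_range: Sequence[int] | None = None,
    rng: np.random.Generator | None = None,
    n_init: int = 10,
) -> tuple[int, float, dict[str, int]]:
    """Select k by mean silhouette over k-means solutions on embedded points."""
    elements, X = _points_array(points)
    n = len(elements)
    if k_range is None:
        k_range = range(2, min(20, n - 1) + 1)
    k_range = [k for k in k_range if 2 <= k <= n - 1]
    if not k_range:
        raise ValueError("no feasible k in range")
    if np.allclose(X, X[0]):
        # all points identical: no structure to cluster
        return 1, float("nan"), {e: 1 for e in elements}
    rng = rng or np.random.default_rng()
    best = (-2.0, None, None)
    for k in k_range:
        seed = int(rng.integers(0, 2**31 - 1))
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels = km.fit_predict(X)
        if len(set(labels)) < 2:
            continue
        sil = float(silhouette_score(X, labels))
        if sil > best[0]:
            best = (sil, k, labels)
    sil, k, labels = best
    if k is None:
        raise ValueError("clustering degenerate for every k")
    memberships = _relabel(elements, labels)
    return k, sil, memberships


def _relabel(elements: Sequence[str], labels: np.ndarray) -> dict[str, int]:
    """Contiguous cluster ids 1..k in order of first appearance."""
    remap: dict[int, int] = {}
    out = {}
    for el, lab in zip(elements, labels):
        lab = int(lab)
        if lab not in remap:
            remap[lab] = len(remap) + 1
        out[el] = remap[lab]
    return out


def hierarchical_dendrogram(
    points: dict[str, tuple[float, float]], k: int
) -> ClusterSolution:
    """Ward agglomerative tree on embedded Euclidean distances, cut at k."""
    elements, X = _points_array(points)
    n = len(elements)
    if not 1 <= k <= n:
        raise ValueError("k out of range")
    Z = linkage(X, method="ward")
    labels = cut_tree(Z, n_clusters=k).ravel()
    memberships = _relabel(elements, labels)
    sil = float("nan")
    if 2 <= k <= n - 1 and len(set(labels)) >= 2:
        sil = float(silhouette_score(X, labels))
    return ClusterSolution(
        memberships=memberships, k=k, silhouette=sil, dendrogram=Z
    )


def dendrogram_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Serialize a scipy linkage tree to a Newick string with branch lengths."""
    tree = to_tree(Z)

    def render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0) if parent_height else 0.0
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    left = render(tree.left, tree.dist)
    right = render(tree.right, tree.dist)
    return f"({left},{right});"


def consensus_clusters(
    matrix: TransitionProfileMatrix,
    config: PipelineConfig,
    rng: np.random.Generator,
) -> tuple[ClusterSolution, dict[tuple[str, str], float]]:
    """Repeat embedding + k selection, keep the modal-k run, score stability.

    Runs ``n_embedding_runs`` embeddings with epoch counts drawn uniformly in
    [0.5, 1.5] x ``mean_epochs``.  The most frequent selected k across runs
    defines the consensus; among runs with that k the one with the highest
    silhouette is reported, with its Ward dendrogram cut at k and the
    silhouette of that hierarchical cut alongside.  Stability is the
    fraction of runs in which each element pair co-clustered.
    """
    if config.n_embedding_runs < 2:
        raise ValueError("need at least 2 embedding runs")
    runs: list[ClusterSolution] = []
    points_by_run: list[dict[str, tuple[float, float]]] = []
    for run_id in range(config.n_embedding_runs):
        epochs = int(rng.uniform(0.5, 1.5) * config.mean_epochs)
        points = embed_2d(matrix, epochs, rng)
        k, sil, memberships = optimal_k(points, rng=rng)
        runs.append(
            ClusterSolution(
                memberships=memberships,
                k=k,
                silhouette=sil,
                run_id=run_id,
                epochs=epochs,
            )
        )
        points_by_run.append(points)

    modal_k = Counter(r.k for r in runs).most_common(1)[0][0]
    candidates = [r for r in runs if r.k == modal_k]
    final = max(candidates, key=lambda r: (r.silhouette, -r.run_id))
    dendro = hierarchical_dendrogram(points_by_run[final.run_id], final.k)
    final.dendrogram = dendro.dendrogram
    final.hierarchical_silhouette = dendro.silhouette
    final.acceptable = final.silhouette > config.silhouette_threshold

    elements = matrix.elements
    co = Counter()
    for r in runs:
        for i, a in enumerate(elements):
            for b in elements[i + 1 :]:
                if r.memberships[a] == r.memberships[b]:
                    co[(a, b)] += 1
    stability = {
        pair: co.get(pair, 0) / len(runs)
        for i, a in enumerate(elements)
        for pair in [(a, b) for b in elements[i + 1 :]]
    }
    return final, stability
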