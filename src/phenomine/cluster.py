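"""Hierarchical clustering with bootstrap support, 2-D embedding, export.

Agglomerative average-linkage clustering is run under either the Euclidean
metric or the *uncentered* similarity
``s(x, y) = sum(x_i y_i) / sqrt(sum(x_i^2) sum(y_i^2))`` (cosine-type,
without mean-centering; distance = 1 - s).

Cluster support comes from bootstrap resampling of the feature axis (the
columns: abstracts when clustering terms, features when clustering
conditions). BP for a cluster is the percentage of bootstrap trees that
contain its exact leaf set. The approximately unbiased (AU) value corrects
BP's sample-size bias via multiscale bootstrap: resampling is repeated at a
grid of scale factors r around 1, the per-scale bootstrap probabilities are
fitted on the probit scale with the two-parameter signed-distance model
``z(r) = v * sqrt(r) + c / sqrt(r)`` by weighted least squares, and
``AU = Phi(-(v - c))``. Nodes whose fit is degenerate (bootstrap
probability 0 or 1 at nearly every scale) fall back to BP with a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "SupportedDendrogram",
    "Embedding2D",
    "uncentered_distance",
    "hac",
    "bootstrap_support",
    "cut_clusters",
    "tsne_embed",
    "kmeans_clusters",
    "to_newick",
]

DEFAULT_SCALES = tuple(np.round(np.linspace(0.5, 1.4, 10), 10))


@dataclass
class SupportedDendrogram:
    """A binary merge tree with optional per-internal-node support values.

    ``merges`` is a SciPy linkage matrix over ``leaf_labels``; ``bp`` and
    ``au`` (percent, [0, 100]) are indexed like its rows, root last.
    ``au_fallback[i]`` marks nodes where the multiscale fit was degenerate
    and AU was set to BP.
    """

    merges: np.ndarray
    leaf_labels: list[str]
    metric: str
    bp: np.ndarray | None = None
    au: np.ndarray | None = None
    au_fallback: np.ndarray | None = None

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def node_leaf_sets(self) -> list[frozenset[str]]:
        """Leaf-label set of each internal node, in merge order."""
        n = self.n_leaves
        sets: list[frozenset[str]] = []
        pool: dict[int, frozenset[str]] = {
            i: frozenset([lab]) for i, lab in enumerate(self.leaf_labels)
        }
        for k, (a, b, _, _) in enumerate(self.merges):
            merged = pool[int(a)] | pool[int(b)]
            pool[n + k] = merged
            sets.append(merged)
        return sets


@dataclass
class Embedding2D:
    """2-D embedding coordinates with optional k-means cluster labels."""

    coords: np.ndarray  # (n, 2)
    labels: np.ndarray | None  # in 1..k
    seed: int
    n_iter: int


def uncentered_distance(
    X: np.ndarray, pairwise_complete: bool = False, row_labels: list[str] | None = None
) -> np.ndarray:
    """Condensed distance vector 1 - s(x, y) between the rows of ``X``.

    With ``pairwise_complete`` the similarity of each pair is computed over
    the columns where both rows are non-missing (NaN marks missing), which
    equals the full-data value when nothing is missing. A row with zero
    norm (on the relevant columns) has undefined similarity and is an
    error.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not pairwise_complete:
        norms = np.sqrt((X**2).sum(axis=1))
        bad = np.flatnonzero(norms == 0)
        if bad.size:
            name = row_labels[bad[0]] if row_labels else str(bad[0])
            raise ValueError(f"all-zero row {name!r} has undefined uncentered similarity")
        S = (X @ X.T) / np.outer(norms, norms)
        return 1.0 - squareform(np.clip(S, -1.0, 1.0), checks=False)
    out = np.empty(n * (n - 1) // 2)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            valid = ~(np.isnan(X[i]) | np.isnan(X[j]))
            xi, xj = X[i, valid], X[j, valid]
            denom = np.sqrt((xi**2).sum() * (xj**2).sum())
            if denom == 0:
                name_i = row_labels[i] if row_labels else str(i)
                name_j = row_labels[j] if row_labels else str(j)
                raise ValueError(
                    f"zero-norm overlap between rows {name_i!r} and {name_j!r}"
                )
            out[k] = 1.0 - min(1.0, (xi * xj).sum() / denom)
            k += 1
    return out


def _condensed(X: np.ndarray, metric: str, pairwise_complete: bool = False,
               row_labels: list[str] | None = None) -> np.ndarray:
    if metric == "euclidean":
        return pdist(X, metric="euclidean")
    if metric == "uncentered":
        return uncentered_distance(X, pairwise_complete, row_labels)
    raise ValueError(f"unknown metric {metric!r}")


def hac(
    X: np.ndarray,
    row_labels: list[str],
    metric: str = "euclidean",
    method: str = "average",
    pairwise_complete: bool = False,
) -> SupportedDendrogram:
    """Agglomerative clustering of the rows of ``X`` (no support values)."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("clustering needs at least two rows")
    if X.shape[0] != len(row_labels):
        raise ValueError("row_labels length does not match matrix")
    d = _condensed(X, metric, pairwise_complete, row_labels)
    Z = linkage(d, method=method)
    return SupportedDendrogram(Z, list(row_labels), metric)


def _tree_leaf_sets(Z: np.ndarray, n: int) -> set[frozenset[int]]:
    pool: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    out: set[frozenset[int]] = set()
    for k, (a, b, _, _) in enumerate(Z):
        merged = pool[int(a)] | pool[int(b)]
        pool[n + k] = merged
        out.add(merged)
    return out


def bootstrap_support(
    X: np.ndarray,
    row_labels: list[str],
    metric: str = "euclidean",
    method: str = "average",
    n_boot: int = 100,
    scales: tuple[float, ...] | None = None,
    seed: int = 0,
    compute_au: bool = True,
    pairwise_complete: bool = False,
) -> SupportedDendrogram:
    """Cluster the rows of ``X`` and attach BP (and AU) support values.

    Resampling is over the columns (features), with replacement; at scale
    r each pseudo-dataset has ``round(r * p)`` columns. ``scales`` defaults
    to ten values 0.5 ... 1.4; BP is read off at scale 1. With
    ``compute_au=False`` only the plain bootstrap at scale 1 is run.
    Deterministic for a given seed, independent of column order.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    X = np.asarray(X, dtype=float)
    base = hac(X, row_labels, metric, method, pairwise_complete)
    n, p = X.shape
    base_sets_int = []
    pool: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    for k, (a, b, _, _) in enumerate(base.merges):
        merged = pool[int(a)] | pool[int(b)]
        pool[n + k] = merged
        base_sets_int.append(merged)

    scale_grid = list(scales) if scales is not None else (
        list(DEFAULT_SCALES) if compute_au else [1.0]
    )
    if 1.0 not in scale_grid:
        scale_grid.append(1.0)
    scale_grid = sorted(set(scale_grid))

    counts = np.zeros((len(scale_grid), len(base_sets_int)), dtype=int)
    for si, r in enumerate(scale_grid):
        m = max(2, int(round(r * p)))
        for b in range(n_boot):
            rng = np.random.default_rng([seed, si, b])
            cols = rng.integers(0, p, size=m)
            Xb = X[:, cols]
            try:
                db = _condensed(Xb, metric, pairwise_complete, row_labels)
            except ValueError:
                continue  # degenerate resample (e.g. zero-norm row); skip
            tree_sets = _tree_leaf_sets(linkage(db, method=method), n)
            for ci, cs in enumerate(base_sets_int):
                if cs in tree_sets:
                    counts[si, ci] += 1

    i1 = scale_grid.index(1.0)
    bp = 100.0 * counts[i1] / n_boot
    au = bp.copy()
    fallback = np.ones(len(base_sets_int), dtype=bool)
    if compute_au and len(scale_grid) >= 2:
        r_arr = np.asarray(scale_grid)
        for ci in range(len(base_sets_int)):
            frac = counts[:, ci] / n_boot
            ok = (frac > 0) & (frac < 1)
            if ok.sum() < 2:
                continue
            z = stats.norm.ppf(1.0 - frac[ok])  # signed distance at each scale
            A = np.column_stack([np.sqrt(r_arr[ok]), 1.0 / np.sqrt(r_arr[ok])])
            w = n_boot * stats.norm.pdf(z) ** 2 / (frac[ok] * (1.0 - frac[ok]))
            Aw = A * w[:, None]
            try:
                coef, *_ = np.linalg.lstsq(Aw.T @ A, Aw.T @ z, rcond=None)
            except np.linalg.LinAlgError:
                continue
            v, c = coef
            au[ci] = 100.0 * stats.norm.cdf(-(v - c))
            fallback[ci] = False
    if compute_au and fallback.any():
        warnings.warn(
            f"AU fit degenerate for {int(fallback.sum())} node(s); BP reported instead",
            stacklevel=2,
        )
    base.bp = bp
    base.au = np.clip(au, 0.0, 100.0) if compute_au else None
    base.au_fallback = fallback if compute_au else None
    return base


def cut_clusters(dendrogram: SupportedDendrogram, k: int) -> dict[str, int]:
    """Flat cluster assignment (labels 1..k) by cutting the tree at k groups."""
    assign = fcluster(dendrogram.merges, t=k, criterion="maxclust")
    return dict(zip(dendrogram.leaf_labels, (int(a) for a in assign)))


def tsne_embed(
    X: np.ndarray,
    perplexity: float = 9.0,
    learning_rate: float = 10.0,
    n_iter: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """2-D t-SNE coordinates of the rows of ``X`` (no whitening/spherizing).

    Defaults mirror an interactive embedding setup for small term sets:
    perplexity 9 and learning rate 10. Deterministic for a given seed.
    """
    from sklearn.manifold import TSNE

    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if perplexity >= n:
        raise ValueError(f"perplexity {perplexity} must be below the row count {n}")
    if n < 3 * perplexity:
        warnings.warn(
            f"only {n} rows for perplexity {perplexity}; embedding may be unstable",
            stacklevel=2,
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        learning_rate=learning_rate,
        max_iter=max(250, int(n_iter)),
        init="random",
        random_state=seed,
    )
    return np.asarray(tsne.fit_transform(X))


def kmeans_clusters(
    coords: np.ndarray, k: int = 14, seed: int = 0, n_restarts: int = 10
) -> np.ndarray:
    """Seeded k-means labels (1..k) on embedding coordinates, best of
    ``n_restarts`` initializations by inertia."""
    from sklearn.cluster import KMeans

    coords = np.asarray(coords, dtype=float)
    if k > coords.shape[0]:
        raise ValueError(f"k={k} exceeds the number of points {coords.shape[0]}")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    return km.fit_predict(coords) + 1


def embed_and_cluster(
    X: np.ndarray,
    perplexity: float = 9.0,
    learning_rate: float = 10.0,
    n_iter: int = 1000,
    k: int = 14,
    seed: int = 0,
) -> Embedding2D:
    """t-SNE embedding followed by k-means coloring of the embedded points."""
    coords = tsne_embed(X, perplexity, learning_rate, n_iter, seed)
    labels = kmeans_clusters(coords, k=k, seed=seed)
    return Embedding2D(coords, labels, seed, n_iter)


def _newick_quote(label: str) -> str:
    if any(ch in label for ch in " \t(){}[],;:'\""):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(dendrogram: SupportedDendrogram, support_digits: int = 0) -> str:
    """Serialize the tree as Newick with branch lengths from merge heights.

    Internal nodes carry a label ``au|bp`` (rounded to ``support_digits``)
    when support values are present; parseable by standard Newick readers.
    """
    Z = dendrogram.merges
    n = dendrogram.n_leaves
    heights = {i: 0.0 for i in range(n)}
    for k, (_, _, h, _) in enumerate(Z):
        heights[n + k] = float(h)

    def fmt(x: float) -> str:
        return f"{x:.10g}"

    def support_label(k: int) -> str:
        if dendrogram.bp is None:
            return ""
        bp = round(float(dendrogram.bp[k]), support_digits)
        if dendrogram.au is not None:
            au = round(float(dendrogram.au[k]), support_digits)
            return f"{fmt(au)}|{fmt(bp)}"
        return fmt(bp)

    def render(node: int, parent_height: float) -> str:
        length = fmt(max(0.0, parent_height - heights[node]))
        if node < n:
            return f"{_newick_quote(dendrogram.leaf_labels[node])}:{length}"
        k = node - n
        a, b = int(Z[k, 0]), int(Z[k, 1])
        inner = f"({render(a, heights[node])},{render(b, heights[node])})"
        return f"{inner}{_newick_quote(support_label(k)) if support_label(k) else ''}:{length}"

    root = n + len(Z) - 1
    a, b = int(Z[-1, 0]), int(Z[-1, 1])
    h = heights[root]
    label = support_label(len(Z) - 1)
    return f"({render(a, h)},{render(b, h)}){_newick_quote(label) if label else ''};"
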