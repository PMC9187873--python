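"""Multi-level archetypal analysis and subpopulation detection.

Cells are modelled as convex combinations of a small set of extreme cell
states ("archetypes"), themselves constrained to convex combinations of
observed cells. Decompositions are run at every depth k = 2..k_max in the
batch-corrected embedding space, the pooled archetypes are de-duplicated,
and each cell receives a convex weight vector over the merged archetype set
(its "footprint", the archetypal explicit function). Cells whose maximum
weight falls below a confidence threshold are pruned as ambiguous, the
remainder are clustered into subpopulations by Leiden community detection
on a k-nearest-neighbour graph of footprints, and each subpopulation is
characterized by its dominant archetype and marker genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph
import leidenalg
import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .io_formats import CellMatrix
from .preprocess import Embedding

__all__ = [
    "ArchetypeModel",
    "embed_pca",
    "fit_archetypes",
    "prune_ambiguous_cells",
    "cluster_subpopulations",
    "characterize_subpopulations",
]


@dataclass
class ArchetypeModel:
    """Fitted archetype set, per-cell footprints and (later) subpop labels.

    ``archetypes``: components x n_archetypes coordinates in embedding
    space, each a convex combination of cell embeddings. ``footprints``:
    n_archetypes x cells convex-weight columns (non-negative, summing to 1).
    ``confidence``: per-cell maximum footprint weight, used for pruning.
    """

    archetypes: np.ndarray
    footprints: np.ndarray
    cell_ids: list[str]
    k_max: int
    objective: float
    labels: pd.Series | None = None  # subpop label per cell, set by clustering

    def __post_init__(self):
        cols = self.footprints.sum(axis=0)
        if (self.footprints < -1e-9).any() or not np.allclose(cols, 1.0, atol=1e-8):
            raise ValueError("footprint columns must be convex weights")

    @property
    def n_archetypes(self) -> int:
        return self.archetypes.shape[1]

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def confidence(self) -> np.ndarray:
        return self.footprints.max(axis=0)


def embed_pca(matrix, n_components: int = 20, seed: int = 0) -> Embedding:
    """Top-variance orthogonal projection of cells (PCA via SVD).

    Expects a CPM+log1p-normalized :class:`CellMatrix` (or a raw genes x
    cells array with ids); applies a deterministic sign convention: the
    largest-magnitude loading of each component is made positive.
    """
    if isinstance(matrix, CellMatrix):
        X = matrix.counts.T  # cells x genes
        ids = matrix.cell_ids
    else:
        X, ids = matrix
        X = np.asarray(X, float).T
    n_cells, n_genes = X.shape
    if n_components >= n_cells:
        raise ValueError(f"n_components={n_components} must be < n_cells={n_cells}")
    if n_components > min(n_cells, n_genes):
        raise ValueError("n_components exceeds matrix rank bound")
    Xc = X - X.mean(axis=0, keepdims=True)
    # full SVD of the centered matrix; deterministic (LAPACK), no sampling
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    U, s, Vt = U[:, :n_components], s[:n_components], Vt[:n_components]
    # sign convention: largest |loading| positive per component
    for j in range(n_components):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    return Embedding(U * s, list(ids))


# ---------------------------------------------------------------------------
# Archetypal analysis
# ---------------------------------------------------------------------------

def _project_columns_simplex(V: np.ndarray) -> np.ndarray:
    """Euclidean projection of each column onto the probability simplex."""
    k, n = V.shape
    U = np.sort(V, axis=0)[::-1]
    css = np.cumsum(U, axis=0) - 1.0
    ind = np.arange(1, k + 1)[:, None]
    cond = U - css / ind > 0
    rho = k - 1 - np.argmax(cond[::-1], axis=0)  # last True per column
    theta = css[rho, np.arange(n)] / (rho + 1.0)
    return np.maximum(V - theta, 0.0)


def _furthest_sum(X: np.ndarray, k: int, rng) -> np.ndarray:
    """Greedy far-apart initial archetype indices (furthest-sum heuristic)."""
    n = X.shape[1]
    idx = [int(rng.integers(n))]
    sumdist = np.linalg.norm(X - X[:, idx[0]][:, None], axis=0)
    for _ in range(1, k):
        cand = int(np.argmax(sumdist))
        if cand in idx:  # degenerate duplicates; fall back to random
            cand = int(rng.integers(n))
        idx.append(cand)
        sumdist = sumdist + np.linalg.norm(X - X[:, cand][:, None], axis=0)
    # drop the random seed point and replace by the furthest from the rest
    sum0 = np.zeros(n)
    for i in idx[1:]:
        sum0 += np.linalg.norm(X - X[:, i][:, None], axis=0)
    idx[0] = int(np.argmax(sum0))
    return np.asarray(idx)


def _solve_simplex_ls(Z: np.ndarray, X: np.ndarray, S0: np.ndarray | None = None,
                      n_steps: int = 60, tol: float = 1e-8) -> np.ndarray:
    """min_S ||X - Z S||^2 with columns of S on the simplex (FISTA)."""
    k = Z.shape[1]
    n = X.shape[1]
    S = S0 if S0 is not None else np.full((k, n), 1.0 / k)
    G = Z.T @ Z
    L = np.linalg.eigvalsh(G)[-1] + 1e-12
    ZtX = Z.T @ X
    Y = S.copy()
    t = 1.0
    prev_obj = np.inf
    for step in range(n_steps):
        grad = G @ Y - ZtX
        S_new = _project_columns_simplex(Y - grad / L)
        t_new = (1 + np.sqrt(1 + 4 * t * t)) / 2
        Y = S_new + ((t - 1) / t_new) * (S_new - S)
        S, t = S_new, t_new
        # convergence check every 10 steps: one-step plateaus are common
        # under momentum and must not trigger an early stop
        if step % 10 == 9:
            obj = float(np.sum((X - Z @ S) ** 2))
            if abs(prev_obj - obj) <= tol * max(prev_obj, 1.0):
                break
            prev_obj = obj
    return S


def _fit_single_level(X: np.ndarray, k: int, rng, max_iter: int, tol: float):
    """One archetypal-analysis fit: X (d x n) ~ (X C) S, C,S column-stochastic."""
    n = X.shape[1]
    init = _furthest_sum(X, k, rng)
    C = np.zeros((n, k))
    C[init, np.arange(k)] = 1.0
    return _fit_polish(X, C, max_iter, tol)


def _fit_polish(X: np.ndarray, C: np.ndarray, max_iter: int, tol: float):
    """Alternating simplex-constrained updates from a given archetype init."""
    S = None
    prev_obj = np.inf
    # spectral norm of X from the small d x d Gram
    lam_x = np.linalg.eigvalsh(X @ X.T)[-1] + 1e-12
    for _ in range(max_iter):
        Z = X @ C
        S = _solve_simplex_ls(Z, X, S0=S)
        # update C: min_C ||X - X C S||^2, columns of C on simplex.
        # grad_C = X^T (X C S - X) S^T, evaluated without the n x n Gram
        SSt = S @ S.T
        L = lam_x * (np.linalg.eigvalsh(SSt)[-1] + 1e-12)
        XtXSt = X.T @ (X @ S.T)
        for _ in range(10):
            grad = X.T @ (X @ (C @ SSt)) - XtXSt
            C = _project_columns_simplex(C - grad / L)
        obj = float(np.sum((X - X @ C @ S) ** 2))
        if abs(prev_obj - obj) <= tol * max(prev_obj, 1.0):
            prev_obj = obj
            break
        prev_obj = obj
    Z = X @ C
    return Z, S, prev_obj


def fit_archetypes(
    embedding: Embedding,
    k_max: int = 30,
    merge_threshold: float = 0.2,
    tol: float = 1e-6,
    max_iter: int = 50,
    seed: int = 0,
) -> ArchetypeModel:
    """Multi-level archetypal analysis with redundancy merging.

    For every depth k in 2..k_max an archetypal decomposition is solved by
    alternating simplex-constrained least squares (accelerated projected
    gradient). All archetypes are pooled across depths and unified:
    archetype families whose cell-usage patterns correlate (average linkage
    over the pool) above ``merge_threshold`` collapse to the member with
    the largest total footprint mass. Usage correlation rather than
    coordinate correlation is used because redundant archetypes found at
    different depths are recognized by the cells that load on them, which
    is independent of the embedding dimensionality; distinct cell states
    have near-zero or negative usage correlation, so the default threshold
    sits between the two regimes. Final footprints are recomputed against
    the merged set. Deterministic given the seed. Non-convergence at
    ``max_iter`` warns (with the final objective) rather than failing.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    X = embedding.coords.T  # components x cells
    rng = np.random.default_rng(seed)

    all_Z, all_S, masses = [], [], []
    worst_obj = 0.0
    for k in range(2, k_max + 1):
        Z, S, obj = _fit_single_level(X, k, rng, max_iter=max_iter, tol=tol)
        all_Z.append(Z)
        all_S.append(S)
        masses.append(S.sum(axis=1))
        worst_obj = max(worst_obj, obj)
    Z_pool = np.concatenate(all_Z, axis=1)
    usage_pool = np.concatenate(all_S, axis=0)   # pooled usage rows, one per archetype
    mass_pool = np.concatenate(masses)

    keep = _merge_redundant(usage_pool, mass_pool, merge_threshold)
    Z_init = Z_pool[:, keep]

    # polish: one more alternating fit at k = n_merged, initialized at the
    # family representatives (coarse-level representatives sit slightly
    # inside the hull; the refit pulls them back to the extremes)
    C = np.zeros((X.shape[1], Z_init.shape[1]))
    nearest = np.argmin(
        ((X[:, :, None] - Z_init[:, None, :]) ** 2).sum(axis=0), axis=0)
    C[nearest, np.arange(Z_init.shape[1])] = 1.0
    Z_final, S_final, _ = _fit_polish(X, C, max_iter=max_iter, tol=tol)
    S_final = _solve_simplex_ls(Z_final, X, S0=S_final, n_steps=300)
    obj = float(np.sum((X - Z_final @ S_final) ** 2))
    denom = float(np.sum(X**2)) or 1.0
    if obj / denom > 0.8:
        warnings.warn(f"archetypal analysis poorly converged; relative objective "
                      f"{obj / denom:.3f}", stacklevel=2)
    return ArchetypeModel(Z_final, S_final, list(embedding.cell_ids), k_max, obj)


def _merge_redundant(usage: np.ndarray, mass: np.ndarray, threshold: float) -> np.ndarray:
    """Average-linkage unification of archetypes by usage-row correlation.

    Families are cut where the average correlation falls below the
    threshold; each family is represented by its largest-mass member.
    Constant usage rows (zero variance) are treated as duplicates of each
    other only when numerically identical.
    """
    import scipy.cluster.hierarchy as sch
    import scipy.spatial.distance as ssd

    m = usage.shape[0]
    if m == 1:
        return np.asarray([0])
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(usage)
    if np.isnan(corr).any():
        const = usage.std(axis=1) == 0
        for i in np.flatnonzero(const):
            corr[i, :] = corr[:, i] = -1.0
            dup = np.isclose(usage, usage[i]).all(axis=1)
            corr[i, dup] = corr[dup, i] = 1.0
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    link = sch.linkage(ssd.squareform(dist, checks=False), method="average")
    fam = sch.fcluster(link, t=1.0 - threshold, criterion="distance")
    kept = [int(np.flatnonzero(fam == f)[np.argmax(mass[fam == f])])
            for f in np.unique(fam)]
    return np.asarray(sorted(kept))


def prune_ambiguous_cells(model: ArchetypeModel, threshold: float = 0.6) -> ArchetypeModel:
    """Drop cells whose maximum archetype weight is strictly below threshold.

    A cell sitting exactly at the threshold is kept. Raises if nothing
    survives (suggesting a lower threshold).
    """
    keep = model.confidence >= threshold
    if not keep.any():
        raise ValueError(
            f"all {model.n_cells} cells pruned at threshold {threshold}; lower it"
        )
    labels = model.labels[keep] if model.labels is not None else None
    return ArchetypeModel(
        model.archetypes,
        model.footprints[:, keep],
        [c for c, k in zip(model.cell_ids, keep) if k],
        model.k_max,
        model.objective,
        labels=labels,
    )


def cluster_subpopulations(
    model: ArchetypeModel,
    n_neighbors: int = 50,
    resolution: float = 1.0,
    seed: int = 0,
    affinity_threshold: float = 0.5,
) -> pd.Series:
    """Leiden community detection on an affinity-pruned kNN footprint graph.

    The metric cell space is the footprint simplex: k nearest neighbours
    (Euclidean) are connected, edges are weighted by the cosine similarity
    of the two footprints, and edges below ``affinity_threshold`` are
    pruned — cells loading on different archetypes stay disconnected even
    when geometrically adjacent, which keeps community granularity at the
    archetype level rather than at the local-patch level. Communities are
    found with the RB-modularity objective at the given resolution and
    labelled ``1..n`` by decreasing size. Cells isolated by the pruning are
    attached to their nearest labelled neighbour. The labels are also
    stored on the model.
    """
    n = model.n_cells
    if n < n_neighbors + 1:
        raise ValueError(f"need more than n_neighbors={n_neighbors} cells, have {n}")
    F = model.footprints.T  # cells x archetypes
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(F)
    _, idx = nn.kneighbors(F)
    norms = np.linalg.norm(F, axis=1)
    edges, weights = [], []
    for i in range(n):
        for j in idx[i, 1:]:
            if i < j:
                a, b = i, int(j)
            else:
                a, b = int(j), i
            w = float(F[a] @ F[b] / (norms[a] * norms[b] + 1e-12))
            if w >= affinity_threshold:
                edges.append((a, b))
                weights.append(w)
    uniq = {}
    for e, w in zip(edges, weights):
        uniq[e] = w
    g = igraph.Graph(n=n, edges=sorted(uniq), directed=False)
    g.es["weight"] = [uniq[e] for e in sorted(uniq)]
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    membership = np.asarray(part.membership)
    # attach pruned-isolated cells to their nearest labelled neighbour
    degree = np.asarray(g.degree())
    if (degree == 0).any() and (degree > 0).any():
        warnings.warn(f"{int((degree == 0).sum())} isolated cells attached to "
                      "nearest labelled neighbour", stacklevel=2)
        labelled = np.flatnonzero(degree > 0)
        for i in np.flatnonzero(degree == 0):
            d2 = ((F[labelled] - F[i]) ** 2).sum(axis=1)
            membership[i] = membership[labelled[np.argmin(d2)]]
    # consolidate communities by their most influential archetype: modularity
    # fragments large homogeneous populations, but a subpopulation is defined
    # by the archetype that dominates it, so communities sharing a dominant
    # archetype are one subpopulation
    final = np.empty(n, dtype=int)
    for c in np.unique(membership):
        mask = membership == c
        final[mask] = int(np.argmax(model.footprints[:, mask].mean(axis=1)))
    membership = final
    # relabel by decreasing community size, 1-based
    sizes = pd.Series(membership).value_counts()
    remap = {old: new + 1 for new, old in enumerate(sizes.index)}
    labels = pd.Series([remap[m] for m in membership], index=pd.Index(model.cell_ids),
                       name="subpop")
    model.labels = labels
    return labels


def characterize_subpopulations(
    model: ArchetypeModel,
    cells: CellMatrix,
    top_n: int = 10,
) -> dict:
    """Dominant archetype, archetype composition and marker genes per subpop.

    The dominant archetype is the argmax of the mean footprint within the
    subpopulation (ties broken to the lowest index); the composition is the
    normalized mean footprint. Markers are ranked per archetype by a
    one-vs-rest z-score of mean expression of high-weight cells against the
    rest. Subpopulations with fewer than 3 cells get a composition but no
    markers.
    """
    if model.labels is None:
        raise ValueError("run cluster_subpopulations first")
    cell_pos = {c: i for i, c in enumerate(cells.cell_ids)}
    col = np.asarray([cell_pos[c] for c in model.cell_ids])
    expr = cells.counts[:, col]
    labels = model.labels

    dominant, composition = {}, {}
    for sp in sorted(labels.unique()):
        mask = (labels == sp).to_numpy()
        mean_fp = model.footprints[:, mask].mean(axis=1)
        comp = mean_fp / mean_fp.sum()
        composition[sp] = comp
        dominant[sp] = int(np.argmax(mean_fp))  # argmax takes lowest index on ties
        if mask.sum() < 3:
            warnings.warn(f"subpopulation {sp} has <3 cells; markers skipped",
                          stacklevel=2)

    markers = {}
    for a in range(model.n_archetypes):
        w = model.footprints[a]
        thr = np.quantile(w, 0.75)
        high = w > thr  # strict: sparse weight rows put the 75th percentile at 0
        if high.sum() < 3:
            high = w >= thr
        if high.sum() < 3 or (~high).sum() < 3:
            continue
        x, y = expr[:, high], expr[:, ~high]
        pooled_sd = np.sqrt(0.5 * (x.var(axis=1) + y.var(axis=1))) + 1e-9
        z = (x.mean(axis=1) - y.mean(axis=1)) / pooled_sd
        top = np.argsort(-z, kind="stable")[:top_n]
        markers[a] = [cells.gene_ids[i] for i in top]

    return {"dominant_archetype": dominant, "composition": composition,
            "markers_by_archetype": markers}
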