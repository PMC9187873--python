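"""Quality control, normalization and nuisance-signal removal.

Covers the steps that precede subpopulation learning: mitochondrial /
gene-count cell filtering, counts-per-million normalization, de-logging of
log2-scaled bulk input, cell-cycle phase scoring, and an iterative
soft-clustering batch correction of the PCA embedding in the style of
Harmony (mutual nearest behaviour is contract-level, not a port: batch
mixing improves while subpopulation structure is preserved).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import BulkMatrix, CellMatrix

__all__ = [
    "QcPreset",
    "MCF7_QC",
    "PBMC_QC",
    "Embedding",
    "qc_filter",
    "cpm_normalize",
    "delog",
    "assign_cycle_phase",
    "correct_batches",
]


@dataclass(frozen=True)
class QcPreset:
    """Cell-filtering thresholds; all comparisons are strict as stated."""

    name: str
    mito_max: float
    mito_min: float
    genes_max: int
    genes_min: int

    def __post_init__(self):
        if not (0 <= self.mito_min < self.mito_max <= 1):
            raise ValueError("need 0 <= mito_min < mito_max <= 1")
        if not self.genes_min < self.genes_max:
            raise ValueError("need genes_min < genes_max")


# Cells with >15% or <1% mitochondrial content, or >5,000 / <1,000 expressed
# genes, are discarded for MCF-7; the PBMC bounds are 10%/1% and 3,500/500.
MCF7_QC = QcPreset("mcf7", mito_max=0.15, mito_min=0.01, genes_max=5000, genes_min=1000)
PBMC_QC = QcPreset("pbmc", mito_max=0.10, mito_min=0.01, genes_max=3500, genes_min=500)


def qc_filter(cells: CellMatrix, preset: QcPreset, mito_prefix: str = "MT-",
              drop_mito_genes: bool = False) -> tuple[CellMatrix, dict]:
    """Remove low-quality cells; returns (filtered matrix, removal report).

    A cell is removed when its mitochondrial fraction is strictly above
    ``mito_max`` or strictly below ``mito_min``, or its expressed-gene count
    (genes with count > 0) is strictly above ``genes_max`` or strictly below
    ``genes_min``. With ``drop_mito_genes`` the mitochondrial genes
    themselves are removed after filtering (useful when merging datasets of
    which one lacks them). Idempotent: filtering twice equals once.
    """
    counts = cells.counts
    mito_idx = np.asarray([g.startswith(mito_prefix) for g in cells.gene_ids])
    report = {"n_input": cells.n_cells}
    keep = np.ones(cells.n_cells, dtype=bool)

    if mito_idx.any():
        totals = counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(totals > 0, counts[mito_idx].sum(axis=0) / totals, 0.0)
        high = mito_frac > preset.mito_max
        low = mito_frac < preset.mito_min
        report["removed_mito_high"] = int(high.sum())
        report["removed_mito_low"] = int(low.sum())
        keep &= ~(high | low)
    else:
        warnings.warn(
            f"no genes with prefix {mito_prefix!r}; mitochondrial rules skipped",
            stacklevel=2,
        )
        report["removed_mito_high"] = report["removed_mito_low"] = 0

    n_expressed = (counts > 0).sum(axis=0)
    high_g = n_expressed > preset.genes_max
    low_g = n_expressed < preset.genes_min
    report["removed_genes_high"] = int(high_g.sum())
    report["removed_genes_low"] = int(low_g.sum())
    keep &= ~(high_g | low_g)
    report["n_kept"] = int(keep.sum())

    out = cells.subset_cells(keep)
    if drop_mito_genes and mito_idx.any():
        out = out.subset_genes(~mito_idx)
    return out, report


def cpm_normalize(matrix):
    """Scale every column (cell or sample) to one million total counts.

    Works on :class:`CellMatrix` and :class:`BulkMatrix`; a bulk matrix must
    be on linear scale and comes back flagged ``linear-normalized``.
    Idempotent and invariant to positive per-column scaling.
    """
    if isinstance(matrix, BulkMatrix):
        if matrix.scale == "log2":
            raise ValueError("cannot CPM-normalize a log2-scaled matrix; delog first")
        vals = matrix.values
        sums = vals.sum(axis=0)
        zero = np.flatnonzero(sums == 0)
        if zero.size:
            raise ValueError(f"all-zero columns: {[matrix.sample_ids[i] for i in zero[:5]]}")
        return BulkMatrix(vals * (1e6 / sums), matrix.gene_ids, matrix.sample_ids,
                          scale="linear-normalized")
    vals = matrix.counts
    sums = vals.sum(axis=0)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise ValueError(f"all-zero columns: {[matrix.cell_ids[i] for i in zero[:5]]}")
    return CellMatrix(vals * (1e6 / sums), matrix.gene_ids, matrix.cell_ids,
                      matrix.cell_meta, normalized=True)


def delog(matrix: BulkMatrix, pseudocount: float = 0.0) -> BulkMatrix:
    """Back-transform a log2-scaled bulk matrix to linear space.

    Applies ``2**x - pseudocount`` entrywise; the default pseudocount is 0
    (log2 of positive expression with no documented offset), so ``delog``
    is the exact inverse of ``log2``.
    """
    if matrix.scale != "log2":
        raise ValueError(f"delog expects a log2-scaled matrix, got scale={matrix.scale!r}")
    vals = np.power(2.0, matrix.values) - pseudocount
    return BulkMatrix(vals, matrix.gene_ids, matrix.sample_ids, scale="linear")


def assign_cycle_phase(cells: CellMatrix, s_markers: list[str], g2m_markers: list[str],
                       seed: int = 0, n_background_bins: int = 25) -> pd.Series:
    """Score S and G2M programs per cell and call a phase label.

    Expression is CPM-log1p normalized, each gene standardized across
    cells; a program score is the mean standardized expression of its
    marker set minus the mean of a size-matched random background drawn
    from expression-matched bins. Label is the argmax program if its score
    is positive, else ``"G1"``. Marker genes absent from the matrix are
    dropped with a warning.
    """
    if not s_markers or not g2m_markers:
        raise ValueError("marker lists must be non-empty")
    rng = np.random.default_rng(seed)
    gene_index = {g: i for i, g in enumerate(cells.gene_ids)}

    def resolve(markers, name):
        idx = [gene_index[g] for g in markers if g in gene_index]
        missing = [g for g in markers if g not in gene_index]
        if missing:
            warnings.warn(f"{len(missing)} {name} markers absent from matrix; dropped",
                          stacklevel=3)
        if not idx:
            raise ValueError(f"no {name} marker genes found in matrix")
        return np.asarray(idx)

    s_idx = resolve(s_markers, "S")
    g2m_idx = resolve(g2m_markers, "G2M")

    vals = cells.counts
    sums = vals.sum(axis=0)
    sums[sums == 0] = 1.0
    ln = np.log1p(vals * (1e6 / sums))
    mu = ln.mean(axis=1, keepdims=True)
    sd = ln.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (ln - mu) / sd

    # expression-matched background: bin genes by mean expression
    order = np.argsort(mu.ravel(), kind="stable")
    bin_of = np.empty(cells.n_genes, int)
    bin_of[order] = np.arange(cells.n_genes) * n_background_bins // cells.n_genes
    by_bin = [np.flatnonzero(bin_of == b) for b in range(n_background_bins)]

    def score(idx):
        bg = []
        for g in idx:
            pool = by_bin[bin_of[g]]
            bg.append(pool[rng.integers(len(pool))])
        return z[idx].mean(axis=0) - z[np.asarray(bg)].mean(axis=0)

    s_score = score(s_idx)
    g2m_score = score(g2m_idx)
    best = np.where(s_score >= g2m_score, s_score, g2m_score)
    label = np.where(best <= 0, "G1", np.where(s_score >= g2m_score, "S", "G2M"))
    return pd.Series(label, index=pd.Index(cells.cell_ids), name="phase")


@dataclass
class Embedding:
    """Cells x components coordinates aligned to a cell-id list."""

    coords: np.ndarray
    cell_ids: list[str]

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.isfinite(self.coords).all():
            raise ValueError("embedding contains non-finite entries")
        if self.coords.shape[0] != len(self.cell_ids):
            raise ValueError("embedding rows must match cell ids")

    @property
    def n_components(self) -> int:
        return self.coords.shape[1]


def correct_batches(
    embedding: Embedding,
    batch_labels,
    n_soft_clusters: int = 10,
    max_iter: int = 30,
    theta: float = 2.0,
    seed: int = 0,
    stability_tol: float = 0.003,
) -> Embedding:
    """Iteratively remove per-batch offsets from an embedding.

    Alternates (a) soft k-means assignment with a diversity penalty that
    down-weights clusters already dominated by a cell's batch (penalty
    strength ``theta``; 0 disables it) and (b) removal, per cluster and
    batch, of the soft-weighted batch-specific offset from the cluster
    centroid. Iterates until fewer than ``stability_tol`` of cells change
    their hard cluster assignment, or ``max_iter``. Cell order and ids are
    never altered; single-batch input (or ``max_iter=0``) is returned
    unchanged.
    """
    if n_soft_clusters < 2:
        raise ValueError("n_soft_clusters must be >= 2")
    batch = pd.Categorical(np.asarray(batch_labels))
    if len(batch) != len(embedding.cell_ids):
        raise ValueError("batch labels must match cells")
    n_batches = len(batch.categories)
    if n_batches < 2 or max_iter == 0:
        return Embedding(embedding.coords.copy(), list(embedding.cell_ids))

    Z = embedding.coords.copy()
    n, d = Z.shape
    B = np.zeros((n, n_batches))
    B[np.arange(n), batch.codes] = 1.0
    batch_freq = B.mean(axis=0)  # expected batch proportions

    rng = np.random.default_rng(seed)
    centroids = _kmeanspp(Z, n_soft_clusters, rng)
    sigma = 0.5 * np.median(np.linalg.norm(Z - Z.mean(0), axis=1)) ** 2 + 1e-12
    prev_hard = None

    for _ in range(max_iter):
        # soft assignment with diversity penalty
        d2 = ((Z[:, None, :] - centroids[None, :, :]) ** 2).sum(-1)
        logR = -d2 / sigma
        R = _softmax_rows(logR)
        if theta > 0:
            for _ in range(3):
                O = R.T @ B + 1e-8                      # observed cluster x batch
                E = np.outer(R.sum(0), batch_freq) + 1e-8  # expected under mixing
                pen = theta * (np.log(E) - np.log(O))   # reward under-represented
                R = _softmax_rows(logR + pen[:, batch.codes].T)
        hard = R.argmax(axis=1)

        # per-cluster, per-batch offset removal (soft-weighted)
        correction = np.zeros_like(Z)
        for c in range(n_soft_clusters):
            w = R[:, c]
            tot = w.sum()
            if tot < 1e-8:
                continue
            mu_c = (w[:, None] * Z).sum(0) / tot
            for b in range(n_batches):
                wb = w * B[:, b]
                tb = wb.sum()
                if tb < 1e-8:
                    continue
                mu_cb = (wb[:, None] * Z).sum(0) / tb
                correction += np.outer(w * B[:, b], mu_cb - mu_c)
        Z = Z - correction

        # recenter centroids on corrected data
        centroids = (R.T @ Z) / (R.sum(0)[:, None] + 1e-12)
        if prev_hard is not None and np.mean(hard != prev_hard) < stability_tol:
            break
        prev_hard = hard
    return Embedding(Z, list(embedding.cell_ids))


def _softmax_rows(logits: np.ndarray) -> np.ndarray:
    m = logits.max(axis=1, keepdims=True)
    e = np.exp(logits - m)
    return e / e.sum(axis=1, keepdims=True)


def _kmeanspp(X: np.ndarray, k: int, rng) -> np.ndarray:
    n = X.shape[0]
    centers = [X[rng.integers(n)]]
    for _ in range(1, k):
        d2 = np.min(((X[:, None, :] - np.asarray(centers)[None]) ** 2).sum(-1), axis=1)
        p = d2 / d2.sum() if d2.sum() > 0 else np.full(n, 1 / n)
        centers.append(X[rng.choice(n, p=p)])
    return np.asarray(centers)
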