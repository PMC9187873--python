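"""Signature-matrix construction from labelled single cells.

For each subpopulation, genes differentially expressed against all other
cells are found with a two-sided Wilcoxon rank-sum test (exact enumeration
for tiny groups, normal approximation with tie and continuity correction
otherwise). The union of significant genes, after removal of genes with
mean raw expression below a floor, forms the rows of the signature matrix:
the per-subpopulation mean CPM profile that serves as the regression design
for deconvolution.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .io_formats import CellMatrix

__all__ = ["SignatureMatrix", "wilcoxon_de", "build_signature", "exact_ranksum_p"]

_EXACT_MAX_GROUP = 8  # exhaustive enumeration bound per group


@dataclass
class SignatureMatrix:
    """Selected genes x subpopulations mean-CPM matrix with provenance."""

    values: np.ndarray
    gene_ids: list[str]
    subpop_ids: list[str]
    provenance: dict | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("signature must be non-negative")
        if self.values.shape != (len(self.gene_ids), len(self.subpop_ids)):
            raise ValueError("signature shape does not match id lists")
        if len(self.subpop_ids) < 2:
            raise ValueError("signature needs at least 2 subpopulations")
        if (self.values.sum(axis=1) == 0).any():
            raise ValueError("signature contains an all-zero gene row")

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.values))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.subpop_ids)


def exact_ranksum_p(x, y) -> float:
    """Two-sided exact rank-sum p by exhaustive enumeration (midranks for ties).

    Enumerates every assignment of the pooled values into the two groups
    and doubles the smaller tail probability of the observed rank sum
    (capped at 1). Intended for group sizes <= 8.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)  # midranks
    n_x = len(x)
    w_obs = ranks[:n_x].sum()
    sums = np.asarray([
        ranks[list(comb)].sum()
        for comb in itertools.combinations(range(len(pooled)), n_x)
    ])
    eps = 1e-9
    lo = np.mean(sums <= w_obs + eps)
    hi = np.mean(sums >= w_obs - eps)
    return float(min(1.0, 2.0 * min(lo, hi)))


def wilcoxon_de(cells: CellMatrix, labels, alpha: float = 0.01) -> dict[str, np.ndarray]:
    """One-vs-rest rank-sum DE per subpopulation; returns significant gene sets.

    ``labels`` is a per-cell Series/array of subpopulation ids aligned to
    ``cells.cell_ids`` (a Series is aligned by id). Expression should be
    CPM-normalized. Groups where both sides have <= 8 cells use the exact
    enumeration null; larger groups use the normal approximation with tie
    and continuity corrections. Subpopulations with a single cell are
    excluded with a warning. Returns ``{subpop: array of gene indices with
    p < alpha}``.
    """
    if isinstance(labels, pd.Series):
        labels = labels.reindex(cells.cell_ids)
        if labels.isna().any():
            raise ValueError("labels missing for some cells")
        labels = labels.to_numpy()
    labels = np.asarray(labels)
    if len(labels) != cells.n_cells:
        raise ValueError("labels length must match cell count")
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 subpopulations")

    expr = cells.counts
    out: dict[str, np.ndarray] = {}
    for sp in uniq:
        mask = labels == sp
        n_in, n_out = int(mask.sum()), int((~mask).sum())
        if n_in < 2:
            warnings.warn(f"subpopulation {sp!r} has {n_in} cell(s); excluded from DE",
                          stacklevel=2)
            continue
        x = expr[:, mask]
        y = expr[:, ~mask]
        if max(n_in, n_out) <= _EXACT_MAX_GROUP:
            pvals = np.asarray([exact_ranksum_p(x[g], y[g]) for g in range(cells.n_genes)])
        else:
            res = scipy.stats.mannwhitneyu(
                x, y, axis=1, alternative="two-sided",
                method="asymptotic", use_continuity=True,
            )
            pvals = res.pvalue
        out[sp] = np.flatnonzero(pvals < alpha)
    return out


def build_signature(
    cells_cpm: CellMatrix,
    labels,
    de_gene_sets: dict[str, np.ndarray],
    min_expression: float = 0.5,
    cells_raw: CellMatrix | None = None,
) -> SignatureMatrix:
    """Assemble the signature matrix from DE gene sets.

    Candidate genes are the union of the per-subpopulation significant
    sets; genes whose mean raw count across **all** cells is strictly below
    ``min_expression`` (default 0.5 counts per cell) are removed. Values
    are per-subpopulation mean CPM over that subpopulation's cells. Pass
    ``cells_raw`` when ``cells_cpm`` no longer carries raw counts for the
    expression floor; otherwise the floor is computed on ``cells_cpm``
    rescaled is not attempted and raw counts are required.
    """
    if isinstance(labels, pd.Series):
        labels = labels.reindex(cells_cpm.cell_ids).to_numpy()
    labels = np.asarray(labels)
    if not de_gene_sets:
        raise ValueError("empty DE gene sets")
    candidate = np.unique(np.concatenate([np.asarray(v, int) for v in de_gene_sets.values()
                                          if len(v)])) if any(
        len(v) for v in de_gene_sets.values()) else np.array([], int)

    raw = cells_raw.counts if cells_raw is not None else cells_cpm.counts
    if cells_raw is not None:
        # align by gene id in case QC dropped genes
        pos = {g: i for i, g in enumerate(cells_raw.gene_ids)}
        raw = raw[np.asarray([pos[g] for g in cells_cpm.gene_ids]), :]
    mean_raw = raw.mean(axis=1)
    keep = candidate[mean_raw[candidate] >= min_expression]
    if len(keep) < 2:
        raise ValueError(
            f"only {len(keep)} genes survive the filters; lower alpha or min_expression"
        )

    subpops = sorted(de_gene_sets, key=str)
    cols = []
    n_cells = {}
    for sp in subpops:
        mask = labels == sp
        n_cells[sp] = int(mask.sum())
        cols.append(cells_cpm.counts[np.ix_(keep, np.flatnonzero(mask))].mean(axis=1))
    values = np.stack(cols, axis=1)
    nonzero = values.sum(axis=1) > 0
    values, keep = values[nonzero], keep[nonzero]

    sig = SignatureMatrix(
        values,
        [cells_cpm.gene_ids[i] for i in keep],
        [str(s) for s in subpops],
        provenance={"min_expression": min_expression, "cells_per_subpop": n_cells},
    )
    if sig.condition_number > 1e4:
        warnings.warn(f"signature condition number {sig.condition_number:.3g} > 1e4; "
                      "deconvolution may be unstable", stacklevel=2)
    return sig
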