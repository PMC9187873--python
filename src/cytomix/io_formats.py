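"""Readers, writers and the in-memory containers shared by every stage.

All matrices are stored genes x columns (cells or samples). Joins between
matrices are always by gene identifier, never by row position, and
identifiers are case-sensitive. Bulk matrices carry an explicit scale flag
(``linear`` or ``log2``); downstream stages refuse to operate on the wrong
scale rather than guessing.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from . import __version__

__all__ = [
    "CellMatrix",
    "BulkMatrix",
    "SampleMeta",
    "FormatError",
    "read_sparse_counts",
    "write_sparse_counts",
    "read_gct",
    "write_gct",
    "read_dense_table",
    "write_results",
    "read_results",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def _check_unique(ids, what: str) -> None:
    s = pd.Index(ids)
    if s.has_duplicates:
        dups = s[s.duplicated()].unique().tolist()[:5]
        raise FormatError(f"duplicate {what}: {dups}")


@dataclass
class CellMatrix:
    """Genes x cells count matrix with per-cell metadata.

    ``counts`` holds non-negative values; raw counts unless ``normalized``
    is set. ``cell_meta`` is indexed by cell id and may carry ``batch``,
    ``clone``, ``phase`` and (for synthetic fixtures) ``subpop`` columns.
    """

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    cell_meta: pd.DataFrame = None
    normalized: bool = False

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.cell_ids, "cell ids")
        if (self.counts < 0).any():
            raise FormatError("negative entries in count matrix")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.cell_ids))
        else:
            self.cell_meta = self.cell_meta.reindex(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def subset_cells(self, keep: np.ndarray) -> "CellMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CellMatrix(
            self.counts[:, keep],
            self.gene_ids,
            [self.cell_ids[i] for i in keep],
            self.cell_meta.iloc[keep],
            normalized=self.normalized,
        )

    def subset_genes(self, keep: np.ndarray) -> "CellMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CellMatrix(
            self.counts[keep, :],
            [self.gene_ids[i] for i in keep],
            self.cell_ids,
            self.cell_meta,
            normalized=self.normalized,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class BulkMatrix:
    """Genes x samples expression matrix with an explicit scale flag."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    scale: str = "linear"  # linear | log2 | linear-normalized

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"values shape {self.values.shape} does not match id lists "
                f"({len(self.gene_ids)} x {len(self.sample_ids)})"
            )
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.sample_ids, "sample ids")
        if self.scale not in ("linear", "log2", "linear-normalized"):
            raise FormatError(f"unknown scale flag {self.scale!r}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class SampleMeta:
    """Per-sample screen annotations: perturbagen, dose (uM), time (h), plate.

    ``table`` is indexed by sample id with columns ``perturbagen``,
    ``concentration``, ``time``, ``plate``, ``is_control`` and
    ``replicate_group``. Members of a replicate group share the same
    perturbagen-concentration-time-plate condition; the group forms the
    replicate index set of the susceptibility statistic.
    """

    table: pd.DataFrame

    REQUIRED = ("perturbagen", "concentration", "time", "plate", "is_control")

    def __post_init__(self):
        t = self.table.copy()
        for col in self.REQUIRED:
            if col not in t.columns:
                if col == "is_control":
                    t[col] = False
                else:
                    t[col] = np.nan
        t["is_control"] = t["is_control"].astype(bool)
        if "replicate_group" not in t.columns:
            key = t[["perturbagen", "concentration", "time", "plate"]].astype(str)
            t["replicate_group"] = key.agg("|".join, axis=1)
        noncontrol = t[~t["is_control"]]
        for col in ("perturbagen", "concentration", "time", "plate"):
            if noncontrol[col].isna().any():
                bad = noncontrol.index[noncontrol[col].isna()][:5].tolist()
                raise FormatError(f"non-control samples missing {col!r}: {bad}")
        self.table = t

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def controls(self) -> pd.DataFrame:
        return self.table[self.table["is_control"]]

    def treated(self) -> pd.DataFrame:
        return self.table[~self.table["is_control"]]


# ---------------------------------------------------------------------------
# 10x-style sparse triplets
# ---------------------------------------------------------------------------

def read_sparse_counts(matrix_path, features_path, barcodes_path, meta_path=None) -> CellMatrix:
    """Read a MatrixMarket triplet plus feature/barcode lists (10x layout).

    The optional ``meta_path`` is a TSV keyed by barcode in its first
    column; cells absent from it get empty metadata rows.
    """
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # noqa: BLE001 - normalize to FormatError
        raise FormatError(f"cannot parse MatrixMarket file {matrix_path}: {exc}") from exc
    mat = scipy.sparse.coo_matrix(mat)
    genes = _read_id_list(features_path)
    cells = _read_id_list(barcodes_path)
    if mat.shape != (len(genes), len(cells)):
        raise FormatError(
            f"matrix header declares {mat.shape} but id files give "
            f"{len(genes)} features x {len(cells)} barcodes"
        )
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        meta.index = meta.index.astype(str)
        if meta.index.has_duplicates:
            raise FormatError("duplicate barcodes in metadata file")
    return CellMatrix(mat.toarray(), genes, cells, meta)


def _read_id_list(path) -> list[str]:
    with open(path) as fh:
        # 10x feature files may carry extra tab-separated columns; id is first
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def write_sparse_counts(cells: CellMatrix, matrix_path, features_path, barcodes_path,
                        meta_path=None) -> None:
    scipy.io.mmwrite(str(matrix_path), scipy.sparse.coo_matrix(cells.counts))
    with open(features_path, "w") as fh:
        fh.write("\n".join(cells.gene_ids) + "\n")
    with open(barcodes_path, "w") as fh:
        fh.write("\n".join(cells.cell_ids) + "\n")
    if meta_path is not None:
        cells.cell_meta.to_csv(meta_path, sep="\t", index_label="barcode")


# ---------------------------------------------------------------------------
# GCT 1.3
# ---------------------------------------------------------------------------

# column-annotation names recognized as screen metadata (L1000 conventions)
_GCT_META_ALIASES = {
    "perturbagen": ("pert_id", "pert_iname", "perturbagen"),
    "concentration": ("pert_dose", "dose", "concentration"),
    "time": ("pert_time", "time"),
    "plate": ("det_plate", "plate", "plate_id"),
    "is_control": ("is_control", "control"),
}


def read_gct(path, scale: str = "log2"):
    """Parse a GCT 1.3 text file into a :class:`BulkMatrix`.

    Returns ``(BulkMatrix, SampleMeta | None)``. Column annotations whose
    names match L1000 conventions (``pert_id``, ``pert_dose``, ``pert_time``,
    ``det_plate``) are mapped onto :class:`SampleMeta`. The scale flag
    defaults to ``log2`` because L1000 level-3 matrices ship log2-scaled;
    pass ``scale="linear"`` for plain-space GCTs.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("#1.3"):
        raise FormatError(f"{path}: missing '#1.3' GCT sentinel")
    dims = lines[1].split("\t")
    if len(dims) < 4:
        raise FormatError(f"{path}: GCT dims line needs 4 fields, got {lines[1]!r}")
    n_rows, n_cols, n_rowmeta, n_colmeta = (int(x) for x in dims[:4])
    header = lines[2].split("\t")
    sample_ids = header[1 + n_rowmeta:]
    if len(sample_ids) != n_cols:
        raise FormatError(f"{path}: header declares {len(sample_ids)} samples, dims say {n_cols}")

    col_meta = {}
    for i in range(n_colmeta):
        fields = lines[3 + i].split("\t")
        col_meta[fields[0]] = fields[1 + n_rowmeta:]

    body = lines[3 + n_colmeta:]
    body = [ln for ln in body if ln.strip()]
    if len(body) != n_rows:
        raise FormatError(f"{path}: dims declare {n_rows} data rows, found {len(body)}")
    gene_ids, data = [], []
    for ln in body:
        fields = ln.split("\t")
        gene_ids.append(fields[0])
        try:
            data.append([float(x) for x in fields[1 + n_rowmeta:]])
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric value in data row {fields[0]!r}") from exc
    values = np.asarray(data, dtype=float)
    if values.shape[1] != n_cols:
        raise FormatError(f"{path}: data row width disagrees with dims")
    bulk = BulkMatrix(values, gene_ids, sample_ids, scale=scale)

    meta = None
    if col_meta:
        mapped = {}
        for canonical, aliases in _GCT_META_ALIASES.items():
            for alias in aliases:
                if alias in col_meta:
                    mapped[canonical] = col_meta[alias]
                    break
        if mapped:
            df = pd.DataFrame(mapped, index=pd.Index(sample_ids))
            for col in ("concentration", "time"):
                if col in df:
                    df[col] = pd.to_numeric(df[col], errors="coerce")
            if "is_control" in df:
                df["is_control"] = df["is_control"].astype(str).str.lower().isin(
                    ("1", "true", "yes"))
            meta = SampleMeta(df)
    return bulk, meta


def write_gct(bulk: BulkMatrix, path, meta: SampleMeta | None = None) -> None:
    """Write a GCT 1.3 file; screen metadata becomes column annotations."""
    col_meta = {}
    if meta is not None:
        t = meta.table.reindex(bulk.sample_ids)
        col_meta = {
            "pert_id": t["perturbagen"].fillna("").astype(str).tolist(),
            "pert_dose": t["concentration"].map(
                lambda x: "" if pd.isna(x) else repr(float(x))).tolist(),
            "pert_time": t["time"].map(
                lambda x: "" if pd.isna(x) else repr(float(x))).tolist(),
            "det_plate": t["plate"].fillna("").astype(str).tolist(),
            "is_control": ["1" if v else "0" for v in t["is_control"]],
        }
    with open(path, "w") as fh:
        fh.write("#1.3\n")
        fh.write(f"{bulk.n_genes}\t{bulk.n_samples}\t0\t{len(col_meta)}\n")
        fh.write("id\t" + "\t".join(bulk.sample_ids) + "\n")
        for name, vals in col_meta.items():
            fh.write(name + "\t" + "\t".join(vals) + "\n")
        for g, row in zip(bulk.gene_ids, bulk.values):
            fh.write(g + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Dense tables
# ---------------------------------------------------------------------------

def read_dense_table(path, orientation: str = "genes-in-rows", kind: str = "bulk",
                     scale: str = "linear"):
    """Read a TSV/CSV expression table into genes x columns orientation.

    ``orientation`` declares the on-disk layout; the returned matrix is
    always genes x samples (or genes x cells for ``kind="cells"``).
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    if orientation == "genes-in-columns":
        df = df.T
    elif orientation != "genes-in-rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    if df.index.has_duplicates:
        raise FormatError("duplicated gene ids in table")
    if kind == "cells":
        return CellMatrix(df.to_numpy(float), list(df.index), list(df.columns))
    return BulkMatrix(df.to_numpy(float), list(df.index), list(df.columns), scale=scale)


# ---------------------------------------------------------------------------
# Result tables (TSV with provenance header)
# ---------------------------------------------------------------------------

_RESULT_PRECISION = 12  # decimal digits kept on write; round-trip tolerance


def write_results(obj, path, kind: str, params: dict | None = None) -> None:
    """Write a result object as TSV with a provenance header comment.

    ``kind`` is one of ``composition``, ``susceptibility``, ``cocktail``,
    ``signature``; the corresponding reader is :func:`read_results`.
    Numbers are written with enough digits that read-back reproduces the
    object to ~1e-12.
    """
    frame = _result_frame(obj, kind)
    header = f"# cytomix v{__version__} kind={kind}"
    if params:
        header += " " + " ".join(f"{k}={v}" for k, v in sorted(params.items()))
    buf = io.StringIO()
    frame.to_csv(buf, sep="\t", float_format=f"%.{_RESULT_PRECISION}g")
    with open(path, "w") as fh:
        fh.write(header + "\n")
        fh.write(buf.getvalue())


def _result_frame(obj, kind: str) -> pd.DataFrame:
    if kind == "composition":
        frame = obj.fractions.copy()
        if obj.diagnostics is not None:
            frame = frame.join(obj.diagnostics)
        return frame
    if kind == "susceptibility":
        return obj.to_frame()
    if kind == "cocktail":
        return obj.to_frame()
    if kind == "signature":
        return pd.DataFrame(obj.values, index=obj.gene_ids, columns=obj.subpop_ids)
    if isinstance(obj, pd.DataFrame):
        return obj
    raise ValueError(f"unknown result kind {kind!r}")


def read_results(path, kind: str):
    """Read back a TSV written by :func:`write_results` (as a DataFrame)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return df
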