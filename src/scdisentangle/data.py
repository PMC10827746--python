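"""Dataset container and I/O for multi-batch multi-condition count data.

The central object is :class:`MultiConditionDataset`: a cells x genes raw
count matrix together with a per-cell batch identifier, one categorical
condition label per condition type (e.g. treatment and severity), and an
optional cell-type annotation that is used only by the evaluation code,
never by the model.

Categorical levels (batches, condition labels) are recorded in order of
first appearance and that order is persisted with trained models, so label
references at prediction time are stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


class DatasetError(ValueError):
    """Raised when a dataset violates its structural invariants."""


def _codes(values: pd.Series) -> tuple[np.ndarray, list[str]]:
    """Integer codes with levels in first-appearance order."""
    levels = list(pd.unique(values.astype(str)))
    lookup = {v: i for i, v in enumerate(levels)}
    return np.array([lookup[v] for v in values.astype(str)], dtype=np.int64), levels


@dataclass
class MultiConditionDataset:
    """Raw counts plus batch / condition / (optional) cell-type annotations.

    Parameters
    ----------
    counts
        Non-negative integer matrix, cells x genes.
    gene_ids
        Unique gene identifiers, one per column.
    batches
        Per-cell batch label (any hashable, stored as str).
    conditions
        DataFrame with one column per condition type, one row per cell.
    cell_types
        Optional per-cell annotation, evaluation only.
    """

    counts: np.ndarray
    gene_ids: list[str]
    batches: pd.Series
    conditions: pd.DataFrame
    cell_types: pd.Series | None = None

    batch_codes: np.ndarray = field(init=False)
    batch_levels: list[str] = field(init=False)
    condition_codes: np.ndarray = field(init=False)       # cells x K
    condition_levels: list[list[str]] = field(init=False)  # per type

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise DatasetError(f"counts must be 2-D, got shape {self.counts.shape}")
        n, g = self.counts.shape
        if len(self.gene_ids) != g:
            raise DatasetError(
                f"{len(self.gene_ids)} gene ids but counts have {g} columns"
            )
        if len(set(self.gene_ids)) != g:
            raise DatasetError("gene ids must be unique")
        if np.issubdtype(self.counts.dtype, np.floating):
            if not np.all(np.mod(self.counts, 1) == 0):
                raise DatasetError("counts contain non-integer entries")
            self.counts = self.counts.astype(np.int64)
        if self.counts.min(initial=0) < 0:
            raise DatasetError("counts contain negative entries")
        self.batches = pd.Series(np.asarray(self.batches), name="batch")
        if len(self.batches) != n:
            raise DatasetError(
                f"{len(self.batches)} batch labels for {n} cells"
            )
        if self.batches.isna().any():
            bad = int(np.flatnonzero(self.batches.isna().to_numpy())[0])
            raise DatasetError(f"cell {bad} has no batch label")
        self.conditions = pd.DataFrame(self.conditions).reset_index(drop=True)
        if self.conditions.shape[1] < 1:
            raise DatasetError("at least one condition type is required")
        if len(self.conditions) != n:
            raise DatasetError(
                f"{len(self.conditions)} condition rows for {n} cells"
            )
        for col in self.conditions.columns:
            if self.conditions[col].isna().any():
                bad = int(np.flatnonzero(self.conditions[col].isna().to_numpy())[0])
                raise DatasetError(f"cell {bad} has no label for condition type {col!r}")
        self.batch_codes, self.batch_levels = _codes(self.batches)
        codes, levels = [], []
        for col in self.conditions.columns:
            c, lv = _codes(self.conditions[col])
            codes.append(c)
            levels.append(lv)
        self.condition_codes = np.stack(codes, axis=1)
        self.condition_levels = levels
        if self.cell_types is not None:
            self.cell_types = pd.Series(np.asarray(self.cell_types), name="cell_type")
            if len(self.cell_types) != n:
                raise DatasetError("cell_types length mismatch")

    # -- basic facts ------------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def n_batches(self) -> int:
        return len(self.batch_levels)

    @property
    def condition_types(self) -> list[str]:
        return [str(c) for c in self.conditions.columns]

    @property
    def n_condition_types(self) -> int:
        return self.conditions.shape[1]

    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=1).astype(np.float64)

    def subset(self, mask: np.ndarray) -> "MultiConditionDataset":
        """Row subset preserving the original categorical level order."""
        mask = np.asarray(mask)
        sub = MultiConditionDataset(
            counts=self.counts[mask],
            gene_ids=list(self.gene_ids),
            batches=self.batches.iloc[mask].reset_index(drop=True),
            conditions=self.conditions.iloc[mask].reset_index(drop=True),
            cell_types=None if self.cell_types is None
            else self.cell_types.iloc[mask].reset_index(drop=True),
        )
        # keep parent level order so codes remain comparable across subsets
        sub._relevel(self.batch_levels, self.condition_levels)
        return sub

    def _relevel(self, batch_levels: list[str], condition_levels: list[list[str]]) -> None:
        blookup = {v: i for i, v in enumerate(batch_levels)}
        self.batch_levels = list(batch_levels)
        self.batch_codes = np.array(
            [blookup[str(v)] for v in self.batches], dtype=np.int64
        )
        self.condition_levels = [list(lv) for lv in condition_levels]
        cols = []
        for k, col in enumerate(self.conditions.columns):
            lookup = {v: i for i, v in enumerate(self.condition_levels[k])}
            cols.append(np.array(
                [lookup[str(v)] for v in self.conditions[col]], dtype=np.int64
            ))
        self.condition_codes = np.stack(cols, axis=1)

    def group_keys(self) -> np.ndarray:
        """Per-cell key over (batch, all condition labels) combinations."""
        return np.ascontiguousarray(
            np.column_stack([self.batch_codes, self.condition_codes])
        )


# -- I/O -------------------------------------------------------------------


def _read_counts(count_path, fmt: str):
    if fmt == "csv":
        df = pd.read_csv(count_path, index_col=0)
        return df.to_numpy(), [str(g) for g in df.columns], [str(c) for c in df.index]
    if fmt == "mtx":
        mat = spio.mmread(str(count_path))
        return np.asarray(sparse.csr_matrix(mat).todense()), None, None
    if fmt == "h5":
        import anndata as ad
        adata = ad.read_h5ad(count_path)
        x = adata.X
        if sparse.issparse(x):
            x = np.asarray(x.todense())
        return np.asarray(x), [str(g) for g in adata.var_names], adata
    raise ValueError(f"unknown format {fmt!r}; expected csv, mtx or h5")


def load_dataset(count_path, metadata_path=None, fmt: str = "csv",
                 batch_col: str = "batch",
                 condition_cols: list[str] | None = None,
                 cell_type_col: str | None = "cell_type",
                 gene_path=None) -> MultiConditionDataset:
    """Load counts + per-cell metadata into a validated dataset.

    ``fmt='csv'``: dense matrix with a header row of gene ids and an index
    column of cell ids.  ``fmt='mtx'``: MatrixMarket coordinate file
    (cells x genes) with a required `gene_path` listing gene ids one per
    line.  ``fmt='h5'``: an ``.h5ad`` file; metadata is taken from ``.obs``
    and `metadata_path` may be omitted.
    """
    if fmt == "h5":
        counts, gene_ids, adata = _read_counts(count_path, fmt)
        meta = adata.obs.reset_index(drop=True)
    else:
        counts, gene_ids, _cells = _read_counts(count_path, fmt)
        if fmt == "mtx":
            if gene_path is None:
                raise ValueError("mtx format requires gene_path with gene ids")
            gene_ids = [ln.strip() for ln in open(gene_path) if ln.strip()]
        if metadata_path is None:
            raise ValueError("metadata_path is required for csv/mtx input")
        meta = pd.read_csv(metadata_path, sep=None, engine="python")
    if len(meta) != counts.shape[0]:
        raise DatasetError(
            f"counts have {counts.shape[0]} cells but metadata has {len(meta)} rows"
        )
    if batch_col not in meta.columns:
        raise DatasetError(f"metadata lacks batch column {batch_col!r}")
    if condition_cols is None:
        reserved = {batch_col, cell_type_col}
        condition_cols = [c for c in meta.columns if c not in reserved]
    if not condition_cols:
        raise DatasetError("no condition columns found in metadata")
    ct = None
    if cell_type_col is not None and cell_type_col in meta.columns:
        ct = meta[cell_type_col]
    return MultiConditionDataset(
        counts=counts,
        gene_ids=list(gene_ids),
        batches=meta[batch_col],
        conditions=meta[list(condition_cols)],
        cell_types=ct,
    )


def save_dataset(ds: MultiConditionDataset, out_dir, fmt: str = "csv") -> None:
    """Write counts + metadata in one of the supported formats (round-trip safe)."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = pd.DataFrame({"batch": ds.batches.to_numpy()})
    for col in ds.conditions.columns:
        meta[str(col)] = ds.conditions[col].to_numpy()
    if ds.cell_types is not None:
        meta["cell_type"] = ds.cell_types.to_numpy()
    if fmt == "csv":
        pd.DataFrame(
            ds.counts, columns=ds.gene_ids,
            index=[f"cell{i}" for i in range(ds.n_cells)],
        ).to_csv(out / "counts.csv")
        meta.to_csv(out / "meta.tsv", sep="\t", index=False)
    elif fmt == "mtx":
        spio.mmwrite(str(out / "counts.mtx"), sparse.coo_matrix(ds.counts))
        (out / "genes.tsv").write_text("\n".join(ds.gene_ids) + "\n")
        meta.to_csv(out / "meta.tsv", sep="\t", index=False)
    elif fmt == "h5":
        import anndata as ad
        adata = ad.AnnData(X=ds.counts.astype(np.float64), obs=meta)
        adata.var_names = ds.gene_ids
        adata.write_h5ad(out / "counts.h5ad")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def load_dataset_dir(path, fmt: str = "csv", **kw) -> MultiConditionDataset:
    """Load a directory written by :func:`save_dataset`."""
    from pathlib import Path

    p = Path(path)
    if fmt == "csv":
        return load_dataset(p / "counts.csv", p / "meta.tsv", "csv", **kw)
    if fmt == "mtx":
        return load_dataset(p / "counts.mtx", p / "meta.tsv", "mtx",
                            gene_path=p / "genes.tsv", **kw)
    if fmt == "h5":
        return load_dataset(p / "counts.h5ad", fmt="h5", **kw)
    raise ValueError(f"unknown format {fmt!r}")


# -- operations -------------------------------------------------------------


def filter_genes(ds: MultiConditionDataset, min_cells: int) -> MultiConditionDataset:
    """Keep genes with a nonzero count in at least `min_cells` cells.

    Support is pooled across all batches; gene order is preserved among the
    survivors.  Idempotent for a fixed threshold.
    """
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    support = (ds.counts > 0).sum(axis=0)
    keep = support >= min_cells
    if not keep.any():
        raise DatasetError(
            f"min_cells={min_cells} removes every gene; lower the threshold"
        )
    out = replace(
        ds,
        counts=ds.counts[:, keep],
        gene_ids=[g for g, k in zip(ds.gene_ids, keep) if k],
        batches=ds.batches,
        conditions=ds.conditions,
        cell_types=ds.cell_types,
    )
    out._relevel(ds.batch_levels, ds.condition_levels)
    return out


def make_batch_factors(ds: MultiConditionDataset) -> np.ndarray:
    """Per-cell one-hot batch factor matrix, cells x B.

    Column order follows the recorded batch-level (first appearance) order.
    """
    b = np.zeros((ds.n_cells, ds.n_batches), dtype=np.float64)
    b[np.arange(ds.n_cells), ds.batch_codes] = 1.0
    return b
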