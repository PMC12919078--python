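"""Data model, readers/writers, normalization and pseudobulk aggregation.

The in-memory container is :class:`ExpressionDataset`: a cells x genes
nonnegative-integer count matrix (dense or CSR) with per-cell metadata
(donor, timepoint, perturbation; the reserved label ``"ctrl"`` marks
control cells).  On-disk formats are MatrixMarket + TSV metadata, or a
single HDF5 container (AnnData ``.h5ad``).
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .simdata import CONTROL_LABEL

__all__ = [
    "ExpressionDataset",
    "Configuration",
    "PseudobulkTable",
    "read_dataset",
    "write_dataset",
    "lognormalize",
    "pseudobulk",
]

META_COLUMNS = ("cell_id", "donor", "timepoint", "perturbation")


@dataclass(frozen=True)
class Configuration:
    """A (donor, timepoint, perturbation) triplet - the unit of evaluation."""

    donor: str
    timepoint: str
    perturbation: str

    def __post_init__(self) -> None:
        if self.perturbation == CONTROL_LABEL:
            raise ValueError(
                f"a Configuration's perturbation cannot be {CONTROL_LABEL!r}")

    @property
    def context(self) -> tuple[str, str]:
        return (self.donor, self.timepoint)

    def astuple(self) -> tuple[str, str, str]:
        return (self.donor, self.timepoint, self.perturbation)


class ExpressionDataset:
    """Cells x genes counts plus per-cell metadata.

    Parameters
    ----------
    counts
        Nonnegative integer matrix, dense ndarray or scipy sparse.
    genes
        Unique gene identifiers, length = number of columns.
    obs
        Per-cell metadata with columns cell_id, donor, timepoint,
        perturbation; one row per matrix row.
    on_missing_controls
        "warn" (default) or "raise" when some (donor, timepoint) context
        holding perturbed cells lacks control cells.
    """

    def __init__(self, counts, genes, obs: pd.DataFrame,
                 on_missing_controls: str = "warn") -> None:
        if sp.issparse(counts):
            counts = counts.tocsr()
        else:
            counts = np.asarray(counts)
        genes = np.asarray(genes, dtype=object)
        if counts.shape[1] != genes.size:
            raise ValueError(
                f"counts has {counts.shape[1]} columns but {genes.size} "
                "gene identifiers were given")
        if len(obs) != counts.shape[0]:
            raise ValueError(
                f"metadata has {len(obs)} rows but the count matrix has "
                f"{counts.shape[0]} cells")
        missing = [c for c in META_COLUMNS if c not in obs.columns]
        if missing:
            raise ValueError(f"metadata is missing columns: {missing}")
        if len(set(genes)) != genes.size:
            dupes = pd.Index(genes)[pd.Index(genes).duplicated()].unique()
            raise ValueError(f"duplicate gene identifiers: {list(dupes)[:5]}")
        self.counts = counts
        self.genes = genes
        self.obs = obs.reset_index(drop=True)
        self._group_index: dict | None = None
        self._check_controls(on_missing_controls)

    def _check_controls(self, mode: str) -> None:
        is_ctrl = self.obs["perturbation"] == CONTROL_LABEL
        pert_ctx = set(map(tuple, self.obs.loc[~is_ctrl,
                                               ["donor", "timepoint"]]
                           .drop_duplicates().itertuples(index=False)))
        ctrl_ctx = set(map(tuple, self.obs.loc[is_ctrl,
                                               ["donor", "timepoint"]]
                           .drop_duplicates().itertuples(index=False)))
        orphans = sorted(pert_ctx - ctrl_ctx)
        if orphans:
            msg = (f"contexts with perturbed cells but no controls: "
                   f"{orphans}")
            if mode == "raise":
                raise ValueError(msg)
            warnings.warn(msg)

    # -- basic protocol ---------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def dense_counts(self) -> np.ndarray:
        return self.counts.toarray() if sp.issparse(self.counts) \
            else np.asarray(self.counts)

    def contexts(self) -> list[tuple[str, str]]:
        return sorted(set(map(tuple, self.obs[["donor", "timepoint"]]
                              .drop_duplicates().itertuples(index=False))))

    def configurations(self) -> list[Configuration]:
        sub = self.obs.loc[self.obs["perturbation"] != CONTROL_LABEL,
                           ["donor", "timepoint", "perturbation"]]
        return [Configuration(*t) for t in
                sorted(set(map(tuple, sub.itertuples(index=False))))]

    def group_rows(self, donor: str, timepoint: str,
                   perturbation: str) -> np.ndarray:
        """Row indices of one (donor, timepoint, perturbation) group
        (cached; empty array when the group is absent)."""
        if self._group_index is None:
            self._group_index = self.obs.groupby(
                ["donor", "timepoint", "perturbation"],
                observed=True).indices
        rows = self._group_index.get((donor, timepoint, perturbation))
        return (np.asarray(rows) if rows is not None
                else np.empty(0, dtype=np.intp))

    def mask(self, donor=None, timepoint=None, perturbation=None) -> np.ndarray:
        m = np.ones(self.n_cells, dtype=bool)
        if donor is not None:
            m &= (self.obs["donor"] == donor).to_numpy()
        if timepoint is not None:
            m &= (self.obs["timepoint"] == timepoint).to_numpy()
        if perturbation is not None:
            m &= (self.obs["perturbation"] == perturbation).to_numpy()
        return m

    def equals(self, other: "ExpressionDataset") -> bool:
        if self.counts.shape != other.counts.shape:
            return False
        a, b = self.dense_counts(), other.dense_counts()
        return (np.array_equal(a, b)
                and np.array_equal(self.genes, other.genes)
                and self.obs[list(META_COLUMNS)].equals(
                    other.obs[list(META_COLUMNS)]))


# -- input / output -------------------------------------------------------

def write_dataset(ds: ExpressionDataset, path: str,
                  format: str = "mtx") -> None:
    """Write a dataset to disk.

    ``format="mtx"``: a directory with matrix.mtx (coordinate, cells x
    genes), genes.tsv and cells.tsv.  ``format="h5ad"``: one AnnData HDF5
    container.
    """
    if ds.n_cells == 0:
        raise ValueError("refusing to write an empty dataset (0 cells)")
    if format == "mtx":
        os.makedirs(path, exist_ok=True)
        mat = sp.coo_matrix(ds.counts)
        mmwrite(os.path.join(path, "matrix.mtx"), mat)
        pd.DataFrame({"gene": ds.genes}).to_csv(
            os.path.join(path, "genes.tsv"), sep="\t", index=False)
        ds.obs[list(META_COLUMNS)].to_csv(
            os.path.join(path, "cells.tsv"), sep="\t", index=False)
    elif format == "h5ad":
        import anndata as ad

        obs = ds.obs[list(META_COLUMNS)].copy()
        obs.index = obs["cell_id"].astype(str)
        adata = ad.AnnData(
            X=sp.csr_matrix(ds.counts),
            obs=obs,
            var=pd.DataFrame(index=pd.Index(ds.genes, name="gene")),
        )
        adata.write_h5ad(path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_dataset(path: str, format: str = "mtx") -> ExpressionDataset:
    """Read a dataset written by :func:`write_dataset` (lossless round-trip)."""
    if format == "mtx":
        mat = mmread(os.path.join(path, "matrix.mtx")).tocsr()
        mat.sum_duplicates()
        mat.eliminate_zeros()
        genes = pd.read_csv(os.path.join(path, "genes.tsv"),
                            sep="\t")["gene"].astype(str).to_numpy()
        obs = pd.read_csv(os.path.join(path, "cells.tsv"), sep="\t",
                          dtype=str)
        return ExpressionDataset(counts=mat.astype(np.int32), genes=genes,
                                 obs=obs)
    if format == "h5ad":
        import anndata as ad

        adata = ad.read_h5ad(path)
        obs = adata.obs[list(META_COLUMNS)].astype(str).reset_index(drop=True)
        return ExpressionDataset(counts=adata.X, genes=adata.var_names
                                 .to_numpy(), obs=obs)
    raise ValueError(f"unknown format {format!r}")


# -- normalization --------------------------------------------------------

def lognormalize(ds, scale: float = 1e4, dtype=np.float64):
    """Per-cell normalized log expression.

    ``value(i, g) = log(1 + scale * count(i, g) / total(i))`` with the
    natural log.  Accepts an :class:`ExpressionDataset` or a raw matrix;
    preserves sparsity (zeros map to zeros).  ``dtype`` may be lowered to
    float32 for large matrices.
    """
    counts = ds.counts if isinstance(ds, ExpressionDataset) else ds
    if sp.issparse(counts):
        counts = counts.tocsr()
        totals = np.asarray(counts.sum(axis=1)).ravel()
        _check_totals(totals)
        out = counts.astype(dtype)
        inv = (scale / totals).astype(dtype)
        out = sp.diags(inv) @ out
        out.data = np.log1p(out.data)
        return out.tocsr().astype(dtype)
    counts = np.asarray(counts)
    totals = counts.sum(axis=1, dtype=np.float64)
    _check_totals(totals)
    out = counts.astype(dtype)
    out *= (scale / totals)[:, None].astype(dtype)
    np.log1p(out, out=out)
    return out


def _check_totals(totals: np.ndarray) -> None:
    bad = np.flatnonzero(totals <= 0)
    if bad.size:
        raise ValueError(
            f"cells with zero total counts cannot be normalized: "
            f"indices {bad[:10].tolist()}"
            + (" ..." if bad.size > 10 else ""))


# -- pseudobulk -----------------------------------------------------------

@dataclass
class PseudobulkTable:
    """Mean normalized expression per (donor, timepoint, perturbation) group."""

    groups: pd.DataFrame          # columns donor, timepoint, perturbation
    values: np.ndarray            # (n_groups, G) group means
    n_cells: np.ndarray           # (n_groups,)
    genes: np.ndarray

    def get(self, donor: str, timepoint: str, perturbation: str) -> np.ndarray:
        m = ((self.groups["donor"] == donor)
             & (self.groups["timepoint"] == timepoint)
             & (self.groups["perturbation"] == perturbation))
        idx = np.flatnonzero(m.to_numpy())
        if idx.size == 0:
            raise KeyError((donor, timepoint, perturbation))
        return self.values[idx[0]]


def pseudobulk(norm_matrix, metadata: pd.DataFrame,
               genes=None) -> PseudobulkTable:
    """Arithmetic mean over cells within each (donor, timepoint,
    perturbation) group; control cells group under (d, t, "ctrl")."""
    keys = metadata[["donor", "timepoint", "perturbation"]]
    codes, uniques = pd.factorize(
        pd.MultiIndex.from_frame(keys), sort=True)
    n_groups = len(uniques)
    n_cells = np.bincount(codes, minlength=n_groups)
    if np.any(n_cells == 0):
        raise ValueError("empty pseudobulk group requested")
    indicator = sp.csr_matrix(
        (np.ones(len(codes)), (codes, np.arange(len(codes)))),
        shape=(n_groups, len(codes)))
    sums = indicator @ norm_matrix
    if sp.issparse(sums):
        sums = sums.toarray()
    values = np.asarray(sums) / n_cells[:, None]
    groups = pd.DataFrame(list(uniques),
                          columns=["donor", "timepoint", "perturbation"])
    if genes is None:
        genes = np.arange(norm_matrix.shape[1])
    return PseudobulkTable(groups=groups, values=values,
                           n_cells=n_cells, genes=np.asarray(genes))
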