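"""Per-configuration perturbation effects (pseudobulk delta) and DEG calls.

The perturbation effect for configuration (d, t, p) is the difference
between the mean log-normalized expression of perturbed cells and of the
context's control cells — the pseudobulk delta.  Under randomized
perturbation assignment within a context this contrast identifies the
context-specific causal effect of the perturbation.

DEG calling uses the standard Perturb-seq recipe: a per-gene two-sided
Wilcoxon rank-sum test between perturbed and control cells on normalized
values, Benjamini-Hochberg adjustment across genes, and a minimum absolute
effect filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .dataio import Configuration, ExpressionDataset, lognormalize
from .simdata import CONTROL_LABEL

__all__ = [
    "DeltaVector",
    "DEGSet",
    "estimate_delta",
    "delta_table",
    "call_degs",
    "degs_from_delta",
    "benjamini_hochberg",
]


@dataclass
class DeltaVector:
    """Estimated or predicted pseudobulk effect over genes for one
    configuration, in log-normalized-expression units."""

    config: Configuration
    values: np.ndarray
    genes: np.ndarray
    n_perturbed_cells: int = 0
    n_control_cells: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("delta vector contains non-finite values")


@dataclass
class DEGSet:
    """Differentially expressed genes for one configuration."""

    config: Configuration
    genes: set[str]
    pvalues: np.ndarray
    qvalues: np.ndarray
    effect: np.ndarray       # per-gene delta used for the effect filter
    alpha: float
    min_abs_effect: float

    def to_frame(self, gene_names) -> pd.DataFrame:
        """Per-gene table (gene, p, q, effect, is_deg) for TSV export."""
        gene_names = np.asarray(gene_names)
        return pd.DataFrame({
            "gene": gene_names,
            "p": self.pvalues,
            "q": self.qvalues,
            "effect": self.effect,
            "is_deg": [g in self.genes for g in gene_names],
        })


def _group_rows(ds: ExpressionDataset, config: Configuration,
                cap: int | None = None,
                cap_seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    pert_rows = ds.group_rows(config.donor, config.timepoint,
                              config.perturbation)
    ctrl_rows = ds.group_rows(config.donor, config.timepoint, CONTROL_LABEL)
    if pert_rows.size == 0:
        raise ValueError(f"no cells for configuration {config.astuple()}")
    if ctrl_rows.size == 0:
        raise ValueError(
            f"no control cells in context ({config.donor}, "
            f"{config.timepoint})")
    if cap is not None and pert_rows.size > cap:
        rng = np.random.default_rng(
            cap_seed if cap_seed is not None else 0)
        pert_rows = np.sort(rng.choice(pert_rows, size=cap, replace=False))
    return pert_rows, ctrl_rows


def estimate_delta(ds: ExpressionDataset, config: Configuration,
                   norm=None, scale: float = 1e4,
                   cap: int | None = None,
                   cap_seed: int | None = None) -> DeltaVector:
    """Pseudobulk effect: mean(log-normalized perturbed) - mean(controls).

    ``norm`` may carry a precomputed log-normalized matrix aligned with
    ``ds`` to avoid renormalizing per call; ``cap`` subsamples perturbed
    cells (seeded) to at most that many, used by matched-cell-count splits.
    """
    if norm is None:
        norm = lognormalize(ds, scale=scale)
    pert_rows, ctrl_rows = _group_rows(ds, config, cap, cap_seed)
    mp = _row_mean(norm, pert_rows)
    mc = _row_mean(norm, ctrl_rows)
    return DeltaVector(config=config, values=mp - mc, genes=ds.genes,
                       n_perturbed_cells=pert_rows.size,
                       n_control_cells=ctrl_rows.size)


def _row_mean(mat, rows: np.ndarray) -> np.ndarray:
    sub = mat[rows]
    if sp.issparse(sub):
        return np.asarray(sub.mean(axis=0)).ravel()
    return np.asarray(sub).mean(axis=0)


def delta_table(ds: ExpressionDataset, configs, norm=None,
                scale: float = 1e4, split=None,
                cap_seed: int | None = None) -> pd.DataFrame:
    """Delta vectors for many configurations as a configurations x genes
    DataFrame (MultiIndex rows donor/timepoint/perturbation).

    If ``split`` is given, its per-configuration training-cell caps are
    applied when subsampling perturbed cells.
    """
    if norm is None:
        norm = lognormalize(ds, scale=scale)
    rows, index = [], []
    for cfg in configs:
        cfg = cfg if isinstance(cfg, Configuration) else Configuration(*cfg)
        cap = None
        if split is not None:
            c = split.cap_for(*cfg.astuple())
            cap = None if np.isnan(c) else int(c)
        dv = estimate_delta(ds, cfg, norm=norm, cap=cap, cap_seed=cap_seed)
        rows.append(dv.values)
        index.append(cfg.astuple())
    idx = pd.MultiIndex.from_tuples(index,
                                    names=["donor", "timepoint",
                                           "perturbation"])
    return pd.DataFrame(np.asarray(rows), index=idx, columns=ds.genes)


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    pvalues = np.asarray(pvalues, dtype=float)
    return multipletests(pvalues, method="fdr_bh")[1]


def call_degs(ds: ExpressionDataset, config: Configuration,
              alpha: float = 0.05, min_abs_effect: float = 0.1,
              norm=None, scale: float = 1e4) -> DEGSet:
    """Wilcoxon rank-sum DEG calling for one configuration.

    Per gene: two-sided Mann-Whitney U between perturbed and control
    normalized values (average ranks for ties; exact null for small
    tie-free samples, tie-corrected normal approximation otherwise), BH
    adjustment across genes, then DEG iff adjusted p < alpha and
    |delta| >= min_abs_effect.  Genes constant across both groups get p=1.
    """
    if norm is None:
        norm = lognormalize(ds, scale=scale)
    pert_rows, ctrl_rows = _group_rows(ds, config)
    if pert_rows.size < 3 or ctrl_rows.size < 3:
        raise ValueError(
            f"need >= 3 cells per side for DEG calling; got "
            f"{pert_rows.size} perturbed and {ctrl_rows.size} controls")
    x = _dense_rows(norm, pert_rows)
    y = _dense_rows(norm, ctrl_rows)
    constant = (x.min(axis=0) == x.max(axis=0)) \
        & (y.min(axis=0) == y.max(axis=0)) \
        & (x.min(axis=0) == y.min(axis=0))
    with np.errstate(all="ignore"):
        res = scipy.stats.mannwhitneyu(x, y, axis=0,
                                       alternative="two-sided",
                                       method="auto")
    pvals = np.asarray(res.pvalue, dtype=float)
    pvals[constant] = 1.0
    pvals = np.clip(np.nan_to_num(pvals, nan=1.0), 0.0, 1.0)
    qvals = benjamini_hochberg(pvals)
    delta = x.mean(axis=0) - y.mean(axis=0)
    hits = (qvals < alpha) & (np.abs(delta) >= min_abs_effect)
    return DEGSet(config=config, genes=set(np.asarray(ds.genes)[hits]),
                  pvalues=pvals, qvalues=qvals, effect=delta,
                  alpha=alpha, min_abs_effect=min_abs_effect)


def _dense_rows(mat, rows: np.ndarray) -> np.ndarray:
    sub = mat[rows]
    return sub.toarray() if sp.issparse(sub) else np.asarray(sub)


def degs_from_delta(delta: DeltaVector | np.ndarray, genes=None,
                    threshold: float = 0.5) -> set[str]:
    """DEG set implied by an effect vector alone: {g : |delta_g| >= t}.

    This is the rule applied to *predicted* effect vectors, which carry no
    cell-level replication on which a rank test could run.
    """
    if isinstance(delta, DeltaVector):
        values, genes = delta.values, delta.genes
    else:
        values = np.asarray(delta, dtype=float)
        if genes is None:
            raise ValueError("genes required when delta is a bare array")
    return set(np.asarray(genes)[np.abs(values) >= threshold])
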