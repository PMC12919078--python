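"""Reference predictors of perturbation effects in held-out contexts.

All predictors operate in effect (delta) space: they are fitted on a table
of training-configuration delta vectors and asked for a delta vector in a
test configuration.  Three reference models are provided:

- ``context_mean``: the mean training delta within the queried context,
  ignoring the perturbation — a perturbation-blind negative control that
  mimics the collapsed behavior of models exploiting systematic variation.
- ``perturbation_mean``: the mean of the perturbation's training deltas
  across the contexts where it was observed — the pooled estimator of a
  context-invariant effect.
- ``additive``: per-gene least squares delta(p, c) ~ a_p + b_c with a
  sum-to-zero constraint on the context terms.

External models plug in through the same file contract (a TSV of predicted
deltas per test configuration); nothing here trains on test-configuration
perturbed cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .dataio import Configuration
from .effects import DeltaVector

__all__ = [
    "Predictor",
    "fit_context_mean",
    "fit_perturbation_mean",
    "fit_additive",
    "predict_delta",
    "read_predictions",
    "write_predictions",
]


@dataclass
class Predictor:
    kind: str
    genes: np.ndarray
    params: dict[str, Any] = field(default_factory=dict)
    #: sorted training configurations, recorded for provenance
    train_fingerprint: tuple = ()


def _check_train(train: pd.DataFrame) -> pd.DataFrame:
    if len(train) == 0:
        raise ValueError("empty training delta set")
    if not isinstance(train.index, pd.MultiIndex) \
            or train.index.names != ["donor", "timepoint", "perturbation"]:
        raise ValueError(
            "training deltas must be indexed by donor/timepoint/"
            "perturbation (see effects.delta_table)")
    return train


def _fingerprint(train: pd.DataFrame) -> tuple:
    return tuple(sorted(train.index.tolist()))


def fit_context_mean(train: pd.DataFrame) -> Predictor:
    """Predict, for any configuration, the mean training delta of its
    context (over all perturbations); global mean for unseen contexts."""
    train = _check_train(train)
    by_ctx = train.groupby(level=["donor", "timepoint"]).mean()
    params = {
        "context_means": {ctx: by_ctx.loc[ctx].to_numpy()
                          for ctx in by_ctx.index},
        "global_mean": train.to_numpy().mean(axis=0),
    }
    return Predictor(kind="context_mean", genes=train.columns.to_numpy(),
                     params=params, train_fingerprint=_fingerprint(train))


def fit_perturbation_mean(train: pd.DataFrame,
                          fallback_to_context_mean: bool = False) -> Predictor:
    """Predict the mean of the queried perturbation's training deltas over
    the contexts containing it.  Unseen perturbations raise, unless the
    zero-shot fallback to the context mean is enabled."""
    train = _check_train(train)
    by_pert = train.groupby(level="perturbation").mean()
    params = {
        "pert_means": {p: by_pert.loc[p].to_numpy() for p in by_pert.index},
        "fallback": None,
    }
    if fallback_to_context_mean:
        params["fallback"] = fit_context_mean(train)
    return Predictor(kind="perturbation_mean",
                     genes=train.columns.to_numpy(),
                     params=params, train_fingerprint=_fingerprint(train))


def fit_additive(train: pd.DataFrame) -> Predictor:
    """Per-gene least squares delta(p, c) ~ a_p + b_c.

    The context terms {b_c} are constrained to sum to zero within each
    connected component of the bipartite perturbation-context incidence
    graph; disconnected designs are fitted per component with a warning.
    """
    train = _check_train(train)
    idx = train.index.to_frame(index=False)
    perts = sorted(idx["perturbation"].unique())
    ctxs = sorted(set(map(tuple, idx[["donor", "timepoint"]]
                          .itertuples(index=False))))
    p_of = {p: i for i, p in enumerate(perts)}
    c_of = {c: i for i, c in enumerate(ctxs)}
    nP, nC = len(perts), len(ctxs)

    rows_p = np.array([p_of[r.perturbation] for r in idx.itertuples()])
    rows_c = np.array([c_of[(r.donor, r.timepoint)]
                       for r in idx.itertuples()])

    adj = sp.coo_matrix((np.ones(len(idx)), (rows_p, rows_c)),
                        shape=(nP, nC))
    bip = sp.bmat([[None, adj], [adj.T, None]])
    n_comp, labels = connected_components(bip, directed=False)
    if n_comp > 1:
        warnings.warn(
            f"training design is disconnected ({n_comp} components); "
            "fitting each component separately")
    comp_p, comp_c = labels[:nP], labels[nP:]

    Y = train.to_numpy()
    a = np.zeros((nP, Y.shape[1]))
    b = np.zeros((nC, Y.shape[1]))
    for comp in range(n_comp):
        sel = np.flatnonzero(np.isin(rows_p, np.flatnonzero(comp_p == comp)))
        if sel.size == 0:
            continue
        cp = np.flatnonzero(comp_p == comp)
        cc = np.flatnonzero(comp_c == comp)
        pmap = {g: i for i, g in enumerate(cp)}
        cmap = {g: i for i, g in enumerate(cc)}
        # design: perturbation one-hot plus sum-to-zero coded contexts
        X = np.zeros((sel.size, len(cp) + max(len(cc) - 1, 0)))
        for r, obs in enumerate(sel):
            X[r, pmap[rows_p[obs]]] = 1.0
            j = cmap[rows_c[obs]]
            if len(cc) > 1:
                if j < len(cc) - 1:
                    X[r, len(cp) + j] = 1.0
                else:
                    X[r, len(cp):] = -1.0
        coef, *_ = np.linalg.lstsq(X, Y[sel], rcond=None)
        a[cp] = coef[:len(cp)]
        if len(cc) > 1:
            b_free = coef[len(cp):]
            b[cc[:-1]] = b_free
            b[cc[-1]] = -b_free.sum(axis=0)

    params = {
        "a": {p: a[p_of[p]] for p in perts},
        "b": {c: b[c_of[c]] for c in ctxs},
        "component_of_pert": {p: int(comp_p[p_of[p]]) for p in perts},
        "component_of_ctx": {c: int(comp_c[c_of[c]]) for c in ctxs},
    }
    return Predictor(kind="additive", genes=train.columns.to_numpy(),
                     params=params, train_fingerprint=_fingerprint(train))


def predict_delta(predictor: Predictor, config) -> DeltaVector:
    """Dispatch a single-configuration prediction."""
    cfg = config if isinstance(config, Configuration) else Configuration(*config)
    p = predictor.params
    if predictor.kind == "context_mean":
        vec = p["context_means"].get(cfg.context, p["global_mean"])
    elif predictor.kind == "perturbation_mean":
        if cfg.perturbation in p["pert_means"]:
            vec = p["pert_means"][cfg.perturbation]
        elif p["fallback"] is not None:
            return predict_delta(p["fallback"], cfg)
        else:
            raise ValueError(
                f"perturbation {cfg.perturbation!r} unseen in training and "
                "zero-shot fallback disabled")
    elif predictor.kind == "additive":
        if cfg.perturbation not in p["a"]:
            raise ValueError(
                f"perturbation {cfg.perturbation!r} unseen in training")
        vec = p["a"][cfg.perturbation].copy()
        ctx = cfg.context
        if ctx in p["b"] and (p["component_of_ctx"][ctx]
                              == p["component_of_pert"][cfg.perturbation]):
            vec = vec + p["b"][ctx]
        else:
            warnings.warn(
                f"context {ctx} not connected to perturbation "
                f"{cfg.perturbation!r} in training; using b=0")
    else:
        raise ValueError(f"unknown predictor kind {predictor.kind!r}")
    return DeltaVector(config=cfg, values=np.asarray(vec, dtype=float),
                       genes=predictor.genes)


FITTERS = {
    "context_mean": fit_context_mean,
    "perturbation_mean": fit_perturbation_mean,
    "additive": fit_additive,
}


# -- file contract for external models ------------------------------------

def write_predictions(preds: pd.DataFrame, path: str) -> None:
    """Write a configurations x genes prediction table as TSV."""
    preds.reset_index().to_csv(path, sep="\t", index=False)


def read_predictions(path: str) -> pd.DataFrame:
    """Read a TSV of predicted deltas (donor/timepoint/perturbation columns
    plus one column per gene) into the internal MultiIndex layout."""
    df = pd.read_csv(path, sep="\t",
                     dtype={"donor": str, "timepoint": str,
                            "perturbation": str})
    return df.set_index(["donor", "timepoint", "perturbation"])
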