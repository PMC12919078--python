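"""The per-configuration metric panel and results assembly.

Aggregate metrics compare a predicted effect vector to the measured one:
Pearson correlation, cosine distance, L2 distance, and a rank-based
discrimination score (how well the prediction singles out its own
perturbation among all measured effects in the same context).  Biological
recovery is measured as precision/recall/F1 of the predicted DEG set
against the true one.  ``evaluate_all`` joins the per-configuration
metric records with training-coverage covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .dataio import Configuration, ExpressionDataset, lognormalize
from .effects import DeltaVector, call_degs, degs_from_delta, estimate_delta
from .predict import Predictor, predict_delta
from .split import SplitAssignment, coverage_table

__all__ = [
    "pearson_delta",
    "cosine_distance",
    "l2_distance",
    "discrimination_score",
    "deg_f1",
    "evaluate_all",
]


def _values(v) -> np.ndarray:
    return v.values if isinstance(v, DeltaVector) else np.asarray(v, float)


def pearson_delta(pred, truth) -> float:
    """Sample Pearson correlation across genes; NaN (with a warning) when
    either vector is constant."""
    x, y = _values(pred), _values(truth)
    if x.shape != y.shape:
        raise ValueError("gene sets differ between prediction and truth")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: Pearson correlation undefined")
        return float("nan")
    return float(scipy.stats.pearsonr(x, y).statistic)


def cosine_distance(pred, truth) -> float:
    """1 - cosine similarity, in [0, 2]; NaN (with warning) for zero
    vectors."""
    x, y = _values(pred), _values(truth)
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        warnings.warn("zero vector: cosine distance undefined")
        return float("nan")
    return float(1.0 - float(x @ y) / (nx * ny))


def l2_distance(pred, truth) -> float:
    """Euclidean norm of (pred - truth)."""
    x, y = _values(pred), _values(truth)
    if x.shape != y.shape:
        raise ValueError("gene sets differ between prediction and truth")
    return float(np.linalg.norm(x - y))


def discrimination_score(pred, true_deltas: dict, target) -> float:
    """Normalized retrieval rank of the target perturbation.

    All measured effect vectors in the context (``true_deltas``: mapping
    perturbation -> vector) are sorted by ascending L2 distance to the
    prediction; with the target at (average, for ties) rank r among N,
    the score is ``1 - (r - 1)/(N - 1)``: 1 when the prediction is closest
    to its own perturbation's effect, 0.5 on average for an uninformative
    prediction, 0 when it is farthest.
    """
    if target not in true_deltas:
        raise ValueError(f"target {target!r} not among the measured effects")
    if len(true_deltas) < 2:
        raise ValueError("discrimination needs >= 2 measured perturbations")
    perts = sorted(true_deltas)
    x = _values(pred)
    dists = np.array([np.linalg.norm(x - _values(true_deltas[p]))
                      for p in perts])
    ranks = scipy.stats.rankdata(dists, method="average")
    r = ranks[perts.index(target)]
    n = len(perts)
    return float(1.0 - (r - 1.0) / (n - 1.0))


def deg_f1(pred_set: set, true_set: set) -> tuple[float, float, float]:
    """Precision, recall and F1 of DEG recovery.

    Empty-set conventions: both empty -> all NaN (recorded missing, so
    trivially empty predictions are never rewarded); empty prediction
    against a nonempty truth -> (0, 0, 0).
    """
    pred_set, true_set = set(pred_set), set(true_set)
    if not pred_set and not true_set:
        return (float("nan"),) * 3
    tp = len(pred_set & true_set)
    precision = tp / len(pred_set) if pred_set else 0.0
    recall = tp / len(true_set) if true_set else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return precision, recall, f1


@dataclass
class MetricRecord:
    config: Configuration
    pearson_delta: float
    cosine_distance: float
    l2_distance: float
    discrimination: float
    deg_precision: float
    deg_recall: float
    deg_f1: float
    n_true_degs: int
    n_pred_degs: int


def evaluate_all(predictions, ds: ExpressionDataset, split: SplitAssignment,
                 gt=None, deg_truth: str = "data",
                 tau: float | None = None,
                 pred_deg_threshold: float = 0.5,
                 alpha: float = 0.05, min_abs_effect: float = 0.1,
                 scale: float = 1e4, norm=None) -> pd.DataFrame:
    """Metric panel over every test configuration, joined with coverage.

    Parameters
    ----------
    predictions
        A fitted :class:`~ctxbench.predict.Predictor`, or a
        configurations x genes DataFrame (e.g. from
        :func:`~ctxbench.predict.read_predictions`).
    deg_truth
        "data": true DEGs are called on the held-out cells by the rank-sum
        recipe.  "simulator": true DEGs are thresholded on the simulator's
        latent effects (requires ``gt``; threshold ``tau``, defaulting to
        the value used at simulation time only if given).
    pred_deg_threshold
        |delta| cutoff converting a predicted effect vector into a
        predicted DEG set.

    Truth effect vectors are always data-derived (pseudobulk delta on
    held-out cells).  Missing predictions are reported as all-NaN rows.
    """
    if deg_truth not in ("data", "simulator"):
        raise ValueError("deg_truth must be 'data' or 'simulator'")
    if deg_truth == "simulator":
        if gt is None:
            raise ValueError("simulator DEG truth requires gt")
        if tau is None:
            raise ValueError("simulator DEG truth requires tau")

        def _sim_truth(cfg: Configuration) -> set[str]:
            dvec = gt.delta(cfg.perturbation, cfg.donor, cfg.timepoint)
            return set(gt.genes[np.abs(dvec) >= tau])

    if norm is None:
        norm = lognormalize(ds, scale=scale)
    test_configs = [Configuration(*c) for c in split.test_configs]

    # measured (held-out) effects, grouped by context for discrimination
    truth_by_ctx: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    truth_vec: dict[tuple[str, str, str], DeltaVector] = {}
    for cfg in test_configs:
        dv = estimate_delta(ds, cfg, norm=norm)
        truth_vec[cfg.astuple()] = dv
        truth_by_ctx.setdefault(cfg.context, {})[cfg.perturbation] = dv.values

    def _prediction(cfg: Configuration):
        if isinstance(predictions, Predictor):
            return predict_delta(predictions, cfg)
        key = cfg.astuple()
        if key in predictions.index:
            return DeltaVector(config=cfg,
                               values=predictions.loc[key].to_numpy(),
                               genes=np.asarray(predictions.columns))
        return None

    records = []
    missing = []
    for cfg in test_configs:
        pred = _prediction(cfg)
        truth = truth_vec[cfg.astuple()]
        if pred is None:
            missing.append(cfg.astuple())
            records.append(MetricRecord(cfg, *([float("nan")] * 7), 0, 0))
            continue
        ctx_truths = truth_by_ctx[cfg.context]
        disc = (discrimination_score(pred, ctx_truths, cfg.perturbation)
                if len(ctx_truths) >= 2 else float("nan"))
        if deg_truth == "simulator":
            true_set = _sim_truth(cfg)
        else:
            true_set = call_degs(ds, cfg, alpha=alpha,
                                 min_abs_effect=min_abs_effect,
                                 norm=norm).genes
        pred_set = degs_from_delta(pred, threshold=pred_deg_threshold)
        prec, rec, f1 = deg_f1(pred_set, true_set)
        records.append(MetricRecord(
            cfg,
            pearson_delta=pearson_delta(pred, truth),
            cosine_distance=cosine_distance(pred, truth),
            l2_distance=l2_distance(pred, truth),
            discrimination=disc,
            deg_precision=prec, deg_recall=rec, deg_f1=f1,
            n_true_degs=len(true_set), n_pred_degs=len(pred_set)))
    if missing:
        warnings.warn(f"missing predictions for {len(missing)} test "
                      f"configurations: {missing[:5]}")

    rows = []
    for r in records:
        d = {"donor": r.config.donor, "timepoint": r.config.timepoint,
             "perturbation": r.config.perturbation}
        for f in ("pearson_delta", "cosine_distance", "l2_distance",
                  "discrimination", "deg_precision", "deg_recall",
                  "deg_f1", "n_true_degs", "n_pred_degs"):
            d[f] = getattr(r, f)
        rows.append(d)
    results = pd.DataFrame(rows)
    cov = coverage_table(ds, split)
    results = results.join(cov, on="perturbation")
    return results
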