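"""Coverage analysis: how training-context diversity and training cell
count relate to held-out performance.

Three views over a results table (one row per test configuration, metric
columns joined with ``n_train_contexts`` and ``n_train_cells``):
stratified summaries by context coverage with bootstrap confidence
intervals, metric-versus-covariate Pearson correlations, and a
cell-count-matched two-group rank-sum comparison of high- versus
low-diversity configurations.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "stratify_by_coverage",
    "metric_vs_covariate_correlation",
    "matched_cells_comparison",
    "render_report",
    "MatchedComparison",
]

DEFAULT_METRICS = ("pearson_delta", "cosine_distance", "l2_distance",
                   "discrimination", "deg_precision", "deg_recall",
                   "deg_f1")


def stratify_by_coverage(results: pd.DataFrame, metrics=None,
                         n_boot: int = 1000, seed: int = 0,
                         ci: float = 0.95) -> pd.DataFrame:
    """Per coverage level k: mean, median, n and a nonparametric bootstrap
    CI of the mean for each metric.  Empty strata are omitted."""
    if "n_train_contexts" not in results.columns:
        raise ValueError("results must carry n_train_contexts (join with "
                         "the coverage table first)")
    metrics = list(metrics or [m for m in DEFAULT_METRICS
                               if m in results.columns])
    rng = np.random.default_rng(seed)
    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    rows = []
    for k, grp in results.groupby("n_train_contexts", sort=True):
        for m in metrics:
            vals = grp[m].dropna().to_numpy()
            if vals.size == 0:
                continue
            boots = rng.choice(vals, size=(n_boot, vals.size),
                               replace=True).mean(axis=1)
            rows.append({
                "n_train_contexts": int(k), "metric": m,
                "mean": vals.mean(), "median": float(np.median(vals)),
                "n": int(vals.size),
                "ci_lo": float(np.quantile(boots, lo_q)),
                "ci_hi": float(np.quantile(boots, hi_q)),
            })
    return pd.DataFrame(rows)


def metric_vs_covariate_correlation(results: pd.DataFrame, covariate: str,
                                    metric: str) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between a metric and a
    training-coverage covariate across test configurations."""
    if covariate not in ("n_train_contexts", "n_train_cells"):
        raise ValueError("covariate must be n_train_contexts or "
                         "n_train_cells")
    sub = results[[covariate, metric]].dropna()
    if len(sub) < 3:
        raise ValueError("need >= 3 configurations")
    x = sub[covariate].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"covariate {covariate} is constant")
    r, p = scipy.stats.pearsonr(x, sub[metric].to_numpy(dtype=float))
    return float(r), float(p)


@dataclass
class MatchedComparison:
    """Cell-count-matched high- vs low-diversity comparison for one
    metric."""

    metric: str
    window: tuple[float, float]
    k_star: int
    n_high: int
    n_low: int
    statistic: float            # Mann-Whitney U for the high group
    pvalue: float               # two-sided
    median_high: float
    median_low: float


def matched_cells_comparison(results: pd.DataFrame,
                             window: tuple[float, float] = (700, 1700),
                             k_star: int | None = None,
                             metrics=None) -> list[MatchedComparison]:
    """Two-sided Mann-Whitney U per metric between configurations at the
    top coverage level (k = k*) and below it (k < k*), restricted to
    configurations whose perturbation was trained on a similar total cell
    count (``window`` applied to n_train_cells)."""
    metrics = list(metrics or [m for m in DEFAULT_METRICS
                               if m in results.columns])
    lo, hi = window
    sub = results[(results["n_train_cells"] >= lo)
                  & (results["n_train_cells"] <= hi)]
    if k_star is None:
        k_star = int(sub["n_train_contexts"].max()) if len(sub) else 0
    high = sub[sub["n_train_contexts"] == k_star]
    low = sub[sub["n_train_contexts"] < k_star]
    if len(high) == 0 or len(low) == 0:
        raise ValueError(
            f"empty group in matched comparison: window={window}, "
            f"k*={k_star} gives {len(high)} high / {len(low)} low rows")
    out = []
    for m in metrics:
        x = high[m].dropna().to_numpy()
        y = low[m].dropna().to_numpy()
        if x.size == 0 or y.size == 0:
            continue
        res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                       method="auto")
        out.append(MatchedComparison(
            metric=m, window=(float(lo), float(hi)), k_star=k_star,
            n_high=int(x.size), n_low=int(y.size),
            statistic=float(res.statistic), pvalue=float(res.pvalue),
            median_high=float(np.median(x)), median_low=float(np.median(y))))
    return out


def render_report(results: pd.DataFrame, outdir: str,
                  window: tuple[float, float] = (700, 1700),
                  n_boot: int = 1000, seed: int = 0) -> list[str]:
    """Write TSV summaries and static plots; returns the file manifest."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    os.makedirs(outdir, exist_ok=True)
    written = []

    results.to_csv(os.path.join(outdir, "results.tsv"), sep="\t",
                   index=False)
    written.append("results.tsv")

    strat = stratify_by_coverage(results, n_boot=n_boot, seed=seed)
    strat.to_csv(os.path.join(outdir, "coverage_summary.tsv"), sep="\t",
                 index=False)
    written.append("coverage_summary.tsv")

    corr_rows = []
    for cov in ("n_train_contexts", "n_train_cells"):
        if results[cov].nunique() < 2:
            continue
        for m in [m for m in DEFAULT_METRICS if m in results.columns]:
            try:
                r, p = metric_vs_covariate_correlation(results, cov, m)
            except ValueError:
                continue
            corr_rows.append({"covariate": cov, "metric": m, "r": r, "p": p})
    pd.DataFrame(corr_rows).to_csv(
        os.path.join(outdir, "covariate_correlations.tsv"), sep="\t",
        index=False)
    written.append("covariate_correlations.tsv")

    try:
        matched = matched_cells_comparison(results, window=window)
        pd.DataFrame([m.__dict__ for m in matched]).to_csv(
            os.path.join(outdir, "matched_comparison.tsv"), sep="\t",
            index=False)
        written.append("matched_comparison.tsv")
    except ValueError:
        pass

    for metric in ("deg_f1", "l2_distance"):
        if metric not in results.columns or strat.empty:
            continue
        sub = strat[strat["metric"] == metric]
        if sub.empty:
            continue
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.errorbar(sub["n_train_contexts"].to_numpy(),
                    sub["mean"].to_numpy(),
                    yerr=[(sub["mean"] - sub["ci_lo"]).to_numpy(),
                          (sub["ci_hi"] - sub["mean"]).to_numpy()],
                    fmt="o-", capsize=3)
        ax.set_xlabel("training contexts per perturbation")
        ax.set_ylabel(f"mean {metric}")
        fig.tight_layout()
        name = f"{metric}_vs_coverage.png"
        fig.savefig(os.path.join(outdir, name), dpi=120)
        plt.close(fig)
        written.append(name)

        fig, ax = plt.subplots(figsize=(4, 3))
        ax.scatter(results["n_train_cells"], results[metric], s=8,
                   alpha=0.5)
        ax.set_xlabel("training cells per perturbation")
        ax.set_ylabel(metric)
        fig.tight_layout()
        name = f"{metric}_vs_cells.png"
        fig.savefig(os.path.join(outdir, name), dpi=120)
        plt.close(fig)
        written.append(name)

    return written
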