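"""End-to-end orchestration: simulate -> split -> effects -> predict ->
evaluate -> analyze, with seeded determinism and a reproducibility
manifest.

A single global seed spawns fixed per-stage child seeds, so every stage is
individually reproducible and reruns with the same configuration are
byte-identical.  ``run_coverage_experiment`` is the matched-total-cells
context-diversity experiment: perturbations are allocated across coverage
levels k with a fixed total training cell budget each, the dataset is
simulated with exactly the planned cells, the perturbation-mean predictor
is evaluated on held-out configurations, and results are pooled across
seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import coverage as cov_mod
from .dataio import write_dataset
from .effects import delta_table
from .evaluate import evaluate_all
from .predict import FITTERS
from .simdata import SimConfig, sample_ground_truth, simulate_cells
from .split import CoverageSpec, SplitAssignment, make_split

__all__ = [
    "BenchmarkConfig",
    "run_benchmark",
    "run_coverage_experiment",
    "StageError",
]

log = logging.getLogger("ctxbench")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class BenchmarkConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    dataset_path: str | None = None      # use an existing dataset instead
    dataset_format: str = "mtx"
    split_spec: CoverageSpec = field(default_factory=CoverageSpec)
    predictors: tuple[str, ...] = ("perturbation_mean", "context_mean")
    deg_truth: str = "data"
    tau: float | None = None
    pred_deg_threshold: float = 0.5
    alpha: float = 0.05
    min_abs_effect: float = 0.1
    matched_window: tuple[float, float] = (700, 1700)
    n_boot: int = 1000
    outdir: str = "ctxbench_out"
    seed: int = 0
    write_data: bool = False             # dataset export is opt-in (large)

    @classmethod
    def from_yaml(cls, path: str) -> "BenchmarkConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        spec_raw = raw.pop("split_spec", {})
        if "n_train_contexts" in spec_raw \
                and isinstance(spec_raw["n_train_contexts"], list):
            spec_raw["n_train_contexts"] = [
                tuple(x) for x in spec_raw["n_train_contexts"]]
        spec = CoverageSpec(**spec_raw)
        if "predictors" in raw:
            raw["predictors"] = tuple(raw["predictors"])
        if "matched_window" in raw:
            raw["matched_window"] = tuple(raw["matched_window"])
        return cls(sim=sim, split_spec=spec, **raw)


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    ss = np.random.SeedSequence(int(seed))
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_benchmark(cfg: BenchmarkConfig) -> str:
    """Execute the full pipeline; returns the output directory."""
    os.makedirs(cfg.outdir, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(message)s")
    fh = logging.FileHandler(os.path.join(cfg.outdir, "run.log"))
    log.addHandler(fh)
    seeds = _stage_seeds(cfg.seed)
    manifest: dict = {"seed": cfg.seed, "stage_seeds": seeds, "files": {}}

    try:
        stage = "simulate"
        if cfg.dataset_path is None:
            sim = replace(cfg.sim, seed=seeds[0])
            log.info("simulate: G=%d P=%d grid=%dx%d", sim.n_genes,
                     sim.n_perturbations, sim.n_donors, sim.n_timepoints)
            gt = sample_ground_truth(sim)
            ds = simulate_cells(gt, sim)
            if cfg.write_data:
                write_dataset(ds, os.path.join(cfg.outdir, "dataset"),
                              format="mtx")
        else:
            from .dataio import read_dataset
            gt = None
            ds = read_dataset(cfg.dataset_path, format=cfg.dataset_format)

        stage = "split"
        split = make_split(ds, cfg.split_spec, seed=seeds[1])
        split.to_tsv(os.path.join(cfg.outdir, "split.tsv"))

        stage = "effects"
        from .dataio import lognormalize
        norm = lognormalize(ds, dtype=np.float32)
        train = delta_table(ds, split.train_configs, norm=norm,
                            split=split, cap_seed=seeds[2])
        train.reset_index().to_csv(
            os.path.join(cfg.outdir, "train_deltas.tsv"), sep="\t",
            index=False)

        stage = "predict+evaluate"
        for name in cfg.predictors:
            if name not in FITTERS:
                raise ValueError(f"unknown predictor {name!r}; "
                                 f"choose from {sorted(FITTERS)}")
            predictor = FITTERS[name](train)
            results = evaluate_all(
                predictor, ds, split, gt=gt, deg_truth=cfg.deg_truth,
                tau=cfg.tau, pred_deg_threshold=cfg.pred_deg_threshold,
                alpha=cfg.alpha, min_abs_effect=cfg.min_abs_effect,
                norm=norm)
            out = os.path.join(cfg.outdir, f"results_{name}.tsv")
            results.to_csv(out, sep="\t", index=False)

            stage = "analyze"
            report_dir = os.path.join(cfg.outdir, f"report_{name}")
            cov_mod.render_report(results, report_dir,
                                  window=cfg.matched_window,
                                  n_boot=cfg.n_boot, seed=seeds[3])
            stage = "predict+evaluate"
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise StageError(stage, exc) from exc
    finally:
        log.removeHandler(fh)
        fh.close()

    for root, _dirs, files in os.walk(cfg.outdir):
        for f in sorted(files):
            if f.endswith((".tsv", ".json")) and f != "manifest.json":
                p = os.path.join(root, f)
                manifest["files"][os.path.relpath(p, cfg.outdir)] = _sha256(p)
    with open(os.path.join(cfg.outdir, "manifest.json"), "w") as fh2:
        json.dump(manifest, fh2, indent=1, sort_keys=True)
    return cfg.outdir


# -- the matched-total-cells context-diversity experiment ------------------

def plan_cells(split: SplitAssignment, test_cells: int) -> dict:
    """Per-configuration cell budgets implementing a split's caps: train
    configurations get their cap (matched design), test configurations get
    ``test_cells``, excluded configurations get none."""
    cells: dict[tuple[str, str, str], int] = {}
    for d, t, p, label, cap in split.table.itertuples(index=False):
        if label == "train":
            cells[(d, t, p)] = int(cap) if not np.isnan(cap) else test_cells
        elif label == "test":
            cells[(d, t, p)] = int(test_cells)
    return cells


def run_coverage_experiment(
        ks=(1, 2, 4, 6), perts_per_k: int = 25,
        mechanism_shift: float = 0.6,
        total_train_cells: int = 720, test_cells: int = 100,
        n_test_contexts: int = 1, control_cells: int = 200,
        n_seeds: int = 10, base_seed: int = 0,
        sim_overrides: dict | None = None,
        predictor: str = "perturbation_mean",
        pred_deg_threshold: float | None = None) -> pd.DataFrame:
    """Pooled per-configuration results of the context-diversity experiment.

    Perturbations are allocated evenly across coverage levels ``ks`` with a
    fixed total training cell budget each (split evenly over the k training
    contexts), so coverage varies while the training cell count stays
    matched.  One dataset is simulated per seed containing exactly the
    planned cells; the named predictor is fitted on training deltas and
    evaluated on the held-out configurations against simulator DEG truth.
    Returns the concatenated results tables with a ``seed`` column.
    """
    overrides = dict(sim_overrides or {})
    results = []
    for i in range(n_seeds):
        seed = int(base_seed) + i
        base = SimConfig(mechanism_shift=mechanism_shift,
                         control_cells_per_context=control_cells,
                         seed=seed, **overrides)
        tau = base.deg_truth_threshold
        thr = tau if pred_deg_threshold is None else pred_deg_threshold
        alloc = [(k, perts_per_k) for k in ks]
        if perts_per_k * len(ks) != base.n_perturbations:
            raise ValueError("ks x perts_per_k must cover all perturbations")
        spec = CoverageSpec(n_train_contexts=alloc,
                            n_test_contexts=n_test_contexts,
                            matched_total_cells=total_train_cells)
        split = make_split((base.contexts, base.perturbations), spec,
                           seed=seed + 10_000)
        sim = replace(base, cells_per_config=plan_cells(split, test_cells))
        gt = sample_ground_truth(sim)
        ds = simulate_cells(gt, sim)
        from .dataio import lognormalize
        norm = lognormalize(ds, dtype=np.float32)
        train = delta_table(ds, split.train_configs, norm=norm, split=split)
        fitted = FITTERS[predictor](train)
        res = evaluate_all(fitted, ds, split, gt=gt, deg_truth="simulator",
                           tau=tau, pred_deg_threshold=thr, norm=norm)
        res["seed"] = seed
        results.append(res)
        del ds, norm
    return pd.concat(results, ignore_index=True)
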