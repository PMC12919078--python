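"""Synthetic context-dependent Perturb-seq generator with known ground truth.

Emulates the structure of a large pooled CRISPR screen read out by
single-cell RNA-seq across a donor x activation-timepoint context grid:
sparse gene-level perturbation effects with a shared (transportable)
component and context-specific modulation, control cells in every context,
and negative-binomial counts with per-cell library-size variation.

The central knob is ``mechanism_shift`` (rho): the per-context effect is the
convex mixture ``delta(g,p,c) = (1-rho)*theta(g,p) + rho*theta'(g,p,c)``
where ``theta`` is shared across contexts and ``theta'`` is redrawn per
context on a partially resampled target set.  At rho=0 the perturbation
response mechanism is invariant across contexts; at rho=1 it is fully
context-specific.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "GroundTruth",
    "sample_ground_truth",
    "simulate_cells",
    "true_deg_sets",
]

CONTROL_LABEL = "ctrl"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic screen.

    Defaults mirror a desk-scale version of a genome-scale CD4+ T cell
    knockdown screen: a 4-donor x 3-timepoint context grid, sparse strong
    effects (median |theta| of 1 natural-log unit over 40 target genes),
    and moderately overdispersed counts.
    """

    n_genes: int = 2000
    n_perturbations: int = 100
    n_donors: int = 4
    n_timepoints: int = 3
    #: cells per (donor, timepoint, perturbation) configuration; either a
    #: single integer or a mapping {(donor, timepoint, perturbation): n}.
    #: Configurations absent from the mapping receive zero cells.
    cells_per_config: int | Mapping[tuple[str, str, str], int] = 300
    control_cells_per_context: int = 300
    targets_per_perturbation: int = 40
    #: log-scale parameters of the effect-magnitude distribution
    #: |theta| ~ LogNormal(effect_size_mean, effect_size_sd), random sign.
    effect_size_mean: float = 0.0
    effect_size_sd: float = 0.5
    #: rho in [0, 1]: weight of the context-specific effect component.
    mechanism_shift: float = 0.0
    #: fraction of each perturbation's target set that is resampled
    #: (replaced by other genes) in each context's effect component.
    context_resample_fraction: float = 0.5
    #: sd of additive per-gene donor and timepoint offsets to the baseline
    #: log expression rate.
    baseline_context_sd: float = 0.1
    #: scale nu of the dataset-wide systematic shift added to every
    #: perturbed cell's log rate (0 disables the confound).
    systematic_shift_scale: float = 0.0
    #: negative-binomial dispersion phi (var = mu + mu^2/phi); scalar or a
    #: per-gene array.
    dispersion: float | np.ndarray = 10.0
    library_size_log_mean: float = math.log(8000.0)
    library_size_log_sd: float = 0.35
    #: |delta| threshold defining true differentially expressed genes.
    deg_truth_threshold: float = 0.5
    #: targets (and context replacement genes) are drawn from genes above
    #: this baseline-expression quantile, so planted effects land in the
    #: measurable range; 0 draws from all genes.
    target_min_baseline_quantile: float = 0.5
    #: sd of the heavy-tailed (log-normal) gene-level baseline rates.
    baseline_log_sd: float = 1.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.targets_per_perturbation > self.n_genes:
            raise ValueError(
                f"targets_per_perturbation ({self.targets_per_perturbation}) "
                f"exceeds n_genes ({self.n_genes})"
            )
        if not 0.0 <= self.mechanism_shift <= 1.0:
            raise ValueError("mechanism_shift must lie in [0, 1]")
        if not 0.0 <= self.context_resample_fraction <= 1.0:
            raise ValueError("context_resample_fraction must lie in [0, 1]")
        for name in ("n_genes", "n_perturbations", "n_donors", "n_timepoints",
                     "control_cells_per_context", "targets_per_perturbation"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if isinstance(self.cells_per_config, int) and self.cells_per_config < 1:
            raise ValueError("cells_per_config must be positive")
        phi = np.asarray(self.dispersion, dtype=float)
        if np.any(phi <= 0):
            raise ValueError("dispersion must be strictly positive")
        if self.baseline_context_sd < 0 or self.systematic_shift_scale < 0:
            raise ValueError("scale parameters must be nonnegative")
        if self.deg_truth_threshold < 0:
            raise ValueError("deg_truth_threshold must be nonnegative")

    # -- label helpers ----------------------------------------------------
    @property
    def donors(self) -> list[str]:
        return [f"d{i + 1}" for i in range(self.n_donors)]

    @property
    def timepoints(self) -> list[str]:
        return [f"t{i + 1}" for i in range(self.n_timepoints)]

    @property
    def perturbations(self) -> list[str]:
        width = len(str(self.n_perturbations))
        return [f"p{i + 1:0{width}d}" for i in range(self.n_perturbations)]

    @property
    def genes(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"g{i + 1:0{width}d}" for i in range(self.n_genes)]

    @property
    def contexts(self) -> list[tuple[str, str]]:
        return [(d, t) for d in self.donors for t in self.timepoints]

    def n_cells_for(self, donor: str, timepoint: str, pert: str) -> int:
        if isinstance(self.cells_per_config, int):
            return self.cells_per_config
        return int(self.cells_per_config.get((donor, timepoint, pert), 0))


@dataclass
class GroundTruth:
    """Latent parameters of one simulated screen."""

    genes: np.ndarray                      # (G,) str
    perturbations: np.ndarray              # (P,) str
    contexts: list[tuple[str, str]]        # C pairs (donor, timepoint)
    baseline_log_mean: np.ndarray          # (G, C) lambda(g, c)
    shared_effect: np.ndarray              # (G, P) theta, sparse support
    context_effect: np.ndarray             # (G, P, C) delta
    systematic_shift: np.ndarray           # (G,) s_g
    target_sets: list[np.ndarray]          # per p: gene indices of S_p
    context_target_sets: dict[tuple[str, str, str], np.ndarray] = field(
        default_factory=dict)              # (p, d, t) -> gene indices

    def context_index(self, donor: str, timepoint: str) -> int:
        return self.contexts.index((donor, timepoint))

    def pert_index(self, pert: str) -> int:
        return int(np.flatnonzero(self.perturbations == pert)[0])

    def delta(self, pert: str, donor: str, timepoint: str) -> np.ndarray:
        """True effect vector delta(., p, c) over genes."""
        return self.context_effect[:, self.pert_index(pert),
                                   self.context_index(donor, timepoint)]


def sample_ground_truth(cfg: SimConfig) -> GroundTruth:
    """Draw the latent parameters of a screen; reproducible from cfg.seed."""
    rng = np.random.default_rng([int(cfg.seed), 0])
    G, P = cfg.n_genes, cfg.n_perturbations
    contexts = cfg.contexts
    C = len(contexts)
    rho = cfg.mechanism_shift

    # baseline: lambda(g,c) = lambda_g + a(g,donor) + b(g,timepoint)
    lam_g = rng.normal(0.0, cfg.baseline_log_sd, size=G)
    a = rng.normal(0.0, cfg.baseline_context_sd, size=(G, cfg.n_donors))
    b = rng.normal(0.0, cfg.baseline_context_sd, size=(G, cfg.n_timepoints))
    baseline = np.empty((G, C))
    for ci, (d, t) in enumerate(contexts):
        di, ti = cfg.donors.index(d), cfg.timepoints.index(t)
        baseline[:, ci] = lam_g + a[:, di] + b[:, ti]

    s_g = rng.normal(0.0, 1.0, size=G)

    K = cfg.targets_per_perturbation
    n_resample = int(round(cfg.context_resample_fraction * K))
    theta = np.zeros((G, P))
    delta = np.zeros((G, P, C))
    target_sets: list[np.ndarray] = []
    context_target_sets: dict[tuple[str, str, str], np.ndarray] = {}

    def _signed_magnitudes(n: int) -> np.ndarray:
        mag = rng.lognormal(cfg.effect_size_mean, cfg.effect_size_sd, size=n)
        return rng.choice([-1.0, 1.0], size=n) * mag

    q = cfg.target_min_baseline_quantile
    eligible = np.flatnonzero(lam_g >= np.quantile(lam_g, q)) if q > 0 \
        else np.arange(G)
    if eligible.size < K:
        raise ValueError(
            f"only {eligible.size} genes above the target baseline "
            f"quantile but {K} targets requested")
    for pi, p in enumerate(cfg.perturbations):
        S_p = np.sort(rng.choice(eligible, size=K, replace=False))
        theta[S_p, pi] = _signed_magnitudes(K)
        target_sets.append(S_p)
        non_targets = np.setdiff1d(eligible, S_p, assume_unique=False)
        for ci, (d, t) in enumerate(contexts):
            S_pc = S_p.copy()
            if n_resample > 0:
                drop = rng.choice(K, size=n_resample, replace=False)
                repl = rng.choice(non_targets, size=n_resample, replace=False)
                S_pc[drop] = repl
            theta_prime = np.zeros(G)
            theta_prime[S_pc] = _signed_magnitudes(K)
            delta[:, pi, ci] = (1.0 - rho) * theta[:, pi] + rho * theta_prime
            context_target_sets[(p, d, t)] = np.sort(S_pc)

    return GroundTruth(
        genes=np.asarray(cfg.genes),
        perturbations=np.asarray(cfg.perturbations),
        contexts=contexts,
        baseline_log_mean=baseline,
        shared_effect=theta,
        context_effect=delta,
        systematic_shift=s_g,
        target_sets=target_sets,
        context_target_sets=context_target_sets,
    )


def true_deg_sets(gt: GroundTruth,
                  threshold: float) -> dict[tuple[str, str, str], set[str]]:
    """True DEG sets {g : |delta(g,p,c)| >= threshold} keyed by (p, d, t)."""
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    out: dict[tuple[str, str, str], set[str]] = {}
    for pi, p in enumerate(gt.perturbations):
        for ci, (d, t) in enumerate(gt.contexts):
            hits = np.abs(gt.context_effect[:, pi, ci]) >= threshold
            out[(str(p), d, t)] = set(gt.genes[hits])
    return out


def simulate_cells(gt: GroundTruth, cfg: SimConfig):
    """Draw the observed count matrix and per-cell metadata.

    For every configuration (d, t, p) with a positive cell budget and for
    every context's control group: library sizes are log-normal, relative
    expression is a softmax of the perturbed log rate, and counts are
    negative binomial (gamma-Poisson) with dispersion phi.
    """
    from .dataio import ExpressionDataset  # local import to avoid a cycle

    rng = np.random.default_rng([int(cfg.seed), 1])
    G = cfg.n_genes
    nu = cfg.systematic_shift_scale
    phi = np.asarray(cfg.dispersion, dtype=float)

    plan: list[tuple[int, str, str, str, np.ndarray]] = []  # ci, d, t, label, eta
    for ci, (d, t) in enumerate(gt.contexts):
        base = gt.baseline_log_mean[:, ci]
        plan.append((cfg.control_cells_per_context, d, t, CONTROL_LABEL, base))
        for pi, p in enumerate(gt.perturbations):
            n = cfg.n_cells_for(d, t, str(p))
            if n > 0:
                eta = base + gt.context_effect[:, pi, ci] \
                    + nu * gt.systematic_shift
                plan.append((n, d, t, str(p), eta))

    total_cells = sum(n for n, *_ in plan)
    counts = np.empty((total_cells, G), dtype=np.int32)
    meta_rows: list[tuple[str, str, str, int]] = []
    row = 0
    for n, d, t, label, eta in plan:
        pi_rel = np.exp(eta - eta.max())
        pi_rel /= pi_rel.sum()
        lib = rng.lognormal(cfg.library_size_log_mean,
                            cfg.library_size_log_sd, size=n)
        mu = lib[:, None] * pi_rel[None, :]
        if phi.ndim == 0:
            shape_draws = rng.standard_gamma(float(phi), size=(n, G))
        else:
            shape_draws = rng.standard_gamma(np.broadcast_to(phi, (n, G)))
        counts[row:row + n] = rng.poisson(shape_draws * (mu / phi))
        meta_rows.append((d, t, label, n))
        row += n
    donor = np.repeat([r[0] for r in meta_rows], [r[3] for r in meta_rows])
    timep = np.repeat([r[1] for r in meta_rows], [r[3] for r in meta_rows])
    pert = np.repeat([r[2] for r in meta_rows], [r[3] for r in meta_rows])
    n_cells = counts.shape[0]
    obs = pd.DataFrame({
        "cell_id": [f"cell{i + 1:07d}" for i in range(n_cells)],
        "donor": donor,
        "timepoint": timep,
        "perturbation": pert,
    })
    return ExpressionDataset(counts=counts, genes=gt.genes.copy(), obs=obs)


def null_config(cfg: SimConfig) -> SimConfig:
    """Variant of cfg describing a null screen (useful for calibration)."""
    return replace(cfg, mechanism_shift=0.0)


def zero_effects(gt: GroundTruth) -> GroundTruth:
    """Return a copy of gt with all perturbation effects set to zero.

    Together with ``systematic_shift_scale = 0`` this yields a null screen in
    which perturbed and control cells are exchangeable.
    """
    out = GroundTruth(
        genes=gt.genes.copy(),
        perturbations=gt.perturbations.copy(),
        contexts=list(gt.contexts),
        baseline_log_mean=gt.baseline_log_mean.copy(),
        shared_effect=np.zeros_like(gt.shared_effect),
        context_effect=np.zeros_like(gt.context_effect),
        systematic_shift=gt.systematic_shift.copy(),
        target_sets=[s.copy() for s in gt.target_sets],
        context_target_sets={k: v.copy()
                             for k, v in gt.context_target_sets.items()},
    )
    return out


def export_ground_truth(gt: GroundTruth, cfg: SimConfig, path) -> None:
    """Write nonzero true effects as TSV plus a JSON sidecar of the config."""
    import json
    import os

    os.makedirs(path, exist_ok=True)
    rows = []
    for pi, p in enumerate(gt.perturbations):
        for ci, (d, t) in enumerate(gt.contexts):
            dvec = gt.context_effect[:, pi, ci]
            nz = np.flatnonzero(dvec)
            for gi in nz:
                rows.append((gt.genes[gi], str(p), d, t, dvec[gi]))
    pd.DataFrame(rows, columns=["gene", "perturbation", "donor",
                                "timepoint", "delta"]).to_csv(
        os.path.join(path, "ground_truth_effects.tsv"), sep="\t", index=False)
    cfg_dict = {k: (v if not isinstance(v, np.ndarray) else v.tolist())
                for k, v in cfg.__dict__.items()
                if not isinstance(v, Mapping)}
    cells = cfg.cells_per_config
    if isinstance(cells, Mapping):
        cfg_dict["cells_per_config"] = {
            "|".join(k): int(v) for k, v in cells.items()}
    with open(os.path.join(path, "sim_config.json"), "w") as fh:
        json.dump(cfg_dict, fh, indent=1)
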