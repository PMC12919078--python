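"""Configuration-level train/test splits and training-coverage accounting.

The unit of assignment is the configuration (donor, timepoint,
perturbation).  For each perturbation, k training contexts and a disjoint
set of test contexts are sampled uniformly without replacement from the
donor x timepoint grid; control cells are shared infrastructure and are
never held out.  A matched-total-cells variant fixes the total number of
training cells per perturbation while varying k, enabling controlled
context-diversity versus cell-count comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataio import ExpressionDataset
from .simdata import CONTROL_LABEL

__all__ = [
    "CoverageSpec",
    "SplitAssignment",
    "make_split",
    "coverage_table",
]

TRAIN, TEST, EXCLUDED = "train", "test", "excluded"


@dataclass(frozen=True)
class CoverageSpec:
    """How many training/test contexts each perturbation receives.

    ``n_train_contexts`` is a single integer applied to every perturbation,
    a mapping {perturbation: k}, or a sequence of (k, count) pairs
    allocating `count` perturbations to coverage level k (in the listed
    order over the sorted perturbation labels; a trailing count of -1 means
    "all remaining").
    """

    n_train_contexts: int | Mapping[str, int] | Sequence[tuple[int, int]] = 8
    n_test_contexts: int = 4
    zero_shot: bool = False
    #: if set, cap training cells so each perturbation contributes this
    #: many cells in total, split evenly across its k training contexts.
    matched_total_cells: int | None = None

    def k_for(self, perturbations: Sequence[str]) -> dict[str, int]:
        ks: dict[str, int] = {}
        spec = self.n_train_contexts
        if isinstance(spec, int):
            return {p: spec for p in perturbations}
        if isinstance(spec, Mapping):
            missing = [p for p in perturbations if p not in spec]
            if missing:
                raise ValueError(f"no coverage level for: {missing[:5]}")
            return {p: int(spec[p]) for p in perturbations}
        perts = list(perturbations)
        i = 0
        for k, count in spec:
            n = len(perts) - i if count == -1 else count
            for p in perts[i:i + n]:
                ks[p] = int(k)
            i += n
        if i < len(perts):
            raise ValueError(
                f"coverage allocation covers {i} of {len(perts)} "
                "perturbations")
        return ks


@dataclass
class SplitAssignment:
    """Per-configuration labels plus optional per-configuration cell caps."""

    table: pd.DataFrame  # donor, timepoint, perturbation, label, n_cells_cap
    contexts: list[tuple[str, str]]
    seed: int

    def configs(self, label: str) -> list[tuple[str, str, str]]:
        sub = self.table.loc[self.table["label"] == label,
                             ["donor", "timepoint", "perturbation"]]
        return list(map(tuple, sub.itertuples(index=False)))

    @property
    def train_configs(self) -> list[tuple[str, str, str]]:
        return self.configs(TRAIN)

    @property
    def test_configs(self) -> list[tuple[str, str, str]]:
        return self.configs(TEST)

    def cap_for(self, donor: str, timepoint: str, pert: str) -> float:
        t = self.table
        m = ((t["donor"] == donor) & (t["timepoint"] == timepoint)
             & (t["perturbation"] == pert))
        idx = np.flatnonzero(m.to_numpy())
        return float(t["n_cells_cap"].iloc[idx[0]]) if idx.size else np.nan

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str, seed: int = -1) -> "SplitAssignment":
        table = pd.read_csv(path, sep="\t",
                            dtype={"donor": str, "timepoint": str,
                                   "perturbation": str, "label": str})
        if "n_cells_cap" not in table.columns:
            table["n_cells_cap"] = np.nan
        contexts = sorted(set(map(tuple, table[["donor", "timepoint"]]
                                  .drop_duplicates().itertuples(index=False))))
        return cls(table=table, contexts=contexts, seed=seed)


def _contexts_and_perts(source) -> tuple[list[tuple[str, str]], list[str]]:
    if isinstance(source, ExpressionDataset):
        contexts = source.contexts()
        perts = sorted(set(source.obs["perturbation"]) - {CONTROL_LABEL})
        return contexts, perts
    contexts, perts = source
    return sorted(map(tuple, contexts)), sorted(perts)


def make_split(source, spec: CoverageSpec, seed: int) -> SplitAssignment:
    """Sample a configuration-level split.

    ``source`` is either an :class:`ExpressionDataset` or an explicit
    ``(contexts, perturbations)`` pair (useful for planning a simulation
    before any cells exist).  For each perturbation, k training contexts
    and ``spec.n_test_contexts`` disjoint test contexts are drawn uniformly
    without replacement; all other configurations are labelled excluded.
    """
    contexts, perts = _contexts_and_perts(source)
    n_ctx = len(contexts)
    ks = spec.k_for(perts)
    for p, k in ks.items():
        if k == 0 and not spec.zero_shot:
            raise ValueError(
                f"perturbation {p!r} has 0 training contexts; set "
                "zero_shot=True to allow held-out-perturbation splits")
        if k + spec.n_test_contexts > n_ctx:
            raise ValueError(
                f"infeasible spec for {p!r}: k={k} training plus "
                f"{spec.n_test_contexts} test contexts exceed the "
                f"{n_ctx}-context grid")
        if spec.matched_total_cells is not None and k > 0 \
                and spec.matched_total_cells < k:
            raise ValueError("matched_total_cells smaller than k")

    rng = np.random.default_rng(seed)
    rows = []
    for p in perts:
        k = ks[p]
        order = rng.permutation(n_ctx)
        train_idx = set(order[:k].tolist())
        test_idx = set(order[k:k + spec.n_test_contexts].tolist())
        cap = (np.nan if spec.matched_total_cells is None or k == 0
               else spec.matched_total_cells // k)
        for ci, (d, t) in enumerate(contexts):
            if ci in train_idx:
                rows.append((d, t, p, TRAIN, cap))
            elif ci in test_idx:
                rows.append((d, t, p, TEST, np.nan))
            else:
                rows.append((d, t, p, EXCLUDED, np.nan))
    table = pd.DataFrame(rows, columns=["donor", "timepoint",
                                        "perturbation", "label",
                                        "n_cells_cap"])
    return SplitAssignment(table=table, contexts=contexts, seed=seed)


def coverage_table(ds: ExpressionDataset,
                   split: SplitAssignment) -> pd.DataFrame:
    """Per-perturbation training coverage.

    Returns a DataFrame indexed by perturbation with columns
    ``n_train_contexts`` (distinct training (d, t) contexts) and
    ``n_train_cells`` (total training cells carrying the perturbation,
    after any per-configuration cap).
    """
    obs = ds.obs
    cell_counts = (obs[obs["perturbation"] != CONTROL_LABEL]
                   .groupby(["donor", "timepoint", "perturbation"],
                            observed=True).size())
    perts = sorted(set(split.table["perturbation"]))
    rows = []
    train = split.table[split.table["label"] == TRAIN]
    for p in perts:
        sub = train[train["perturbation"] == p]
        n_ctx = 0
        n_cells = 0
        for d, t, cap in sub[["donor", "timepoint", "n_cells_cap"]]\
                .itertuples(index=False):
            avail = int(cell_counts.get((d, t, p), 0))
            if avail > 0:
                n_ctx += 1
                n_cells += avail if np.isnan(cap) else min(avail, int(cap))
        rows.append((p, n_ctx, n_cells))
    return pd.DataFrame(rows, columns=["perturbation", "n_train_contexts",
                                       "n_train_cells"])\
        .set_index("perturbation")
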