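import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ctxbench import (Configuration, ExpressionDataset, SimConfig,
                      benjamini_hochberg, call_degs, degs_from_delta,
                      delta_table, estimate_delta, lognormalize,
                      sample_ground_truth, simulate_cells, pearson_delta)
from ctxbench.simdata import zero_effects


def bh_bruteforce(p):
    """Literal BH step-up: q_i = min_{j >= i} ( p_(j) * m / j ), capped."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q


def _two_group_dataset(x, y):
    """Datasets whose 'normalized values' are exactly the given matrices
    (identity normalization via equal totals is not needed; tests call the
    rank test on raw constructed counts)."""
    counts = np.vstack([x, y]).astype(np.int32)
    n, m = len(x), len(y)
    obs = pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(n + m)],
        "donor": ["d1"] * (n + m),
        "timepoint": ["t1"] * (n + m),
        "perturbation": ["p1"] * n + ["ctrl"] * m,
    })
    genes = np.array([f"g{j}" for j in range(counts.shape[1])])
    return ExpressionDataset(counts, genes, obs)


class TestEstimateDelta:
    def test_identical_groups_give_zero(self, toy_dataset):
        norm = lognormalize(toy_dataset)
        obs = toy_dataset.obs.copy()
        # relabel the two control cells in d1 as a perturbation: the groups
        # then share values with the original controls only if identical
        # cells; instead duplicate perturbed cells as controls
        counts = np.vstack([toy_dataset.dense_counts()[:2]] * 2)
        obs = pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(4)],
            "donor": ["d1"] * 4, "timepoint": ["t1"] * 4,
            "perturbation": ["pX", "pX", "ctrl", "ctrl"],
        })
        ds = ExpressionDataset(counts, toy_dataset.genes, obs)
        dv = estimate_delta(ds, Configuration("d1", "t1", "pX"))
        np.testing.assert_allclose(dv.values, 0.0, atol=1e-12)

    def test_subtraction_of_group_means(self):
        # normalized means constructed directly: perturbed (2.0, 1.0),
        # control (1.5, 1.0) -> delta (0.5, 0.0)
        norm = np.array([[2.0, 1.0], [1.5, 1.0]])
        counts = np.ones((2, 2), dtype=np.int32)
        obs = pd.DataFrame({"cell_id": ["a", "b"], "donor": ["d1"] * 2,
                            "timepoint": ["t1"] * 2,
                            "perturbation": ["p1", "ctrl"]})
        ds = ExpressionDataset(counts, np.array(["g1", "g2"]), obs)
        dv = estimate_delta(ds, Configuration("d1", "t1", "p1"), norm=norm)
        np.testing.assert_allclose(dv.values, [0.5, 0.0])

    def test_missing_controls_error_names_context(self, toy_dataset):
        obs = toy_dataset.obs.copy()
        obs.loc[5, "perturbation"] = "pB"
        with pytest.warns(UserWarning):
            ds = ExpressionDataset(toy_dataset.dense_counts(),
                                   toy_dataset.genes, obs)
        with pytest.raises(ValueError, match=r"d2.*t1"):
            estimate_delta(ds, Configuration("d2", "t1", "pB"))

    def test_antisymmetry_under_label_swap(self, toy_dataset):
        norm = lognormalize(toy_dataset)
        dv = estimate_delta(toy_dataset, Configuration("d1", "t1", "pA"),
                            norm=norm)
        obs = toy_dataset.obs.copy()
        swap = {"pA": "ctrl", "ctrl": "pA"}
        obs["perturbation"] = obs["perturbation"].map(
            lambda v: swap.get(v, v))
        ds2 = ExpressionDataset(toy_dataset.dense_counts(),
                                toy_dataset.genes, obs)
        dv2 = estimate_delta(ds2, Configuration("d1", "t1", "pA"),
                             norm=norm)
        np.testing.assert_allclose(dv.values, -dv2.values, atol=1e-12)

    def test_recovers_simulated_truth(self):
        # invariant mechanism, 500 cells per side: the pseudobulk contrast
        # tracks the latent effect gene-wise
        cfg = SimConfig(n_perturbations=4, n_donors=1, n_timepoints=1,
                        cells_per_config=500, control_cells_per_context=500,
                        mechanism_shift=0.0, seed=11)
        gt = sample_ground_truth(cfg)
        ds = simulate_cells(gt, cfg)
        norm = lognormalize(ds, dtype=np.float32)
        for c in ds.configurations():
            dv = estimate_delta(ds, c, norm=norm)
            r = pearson_delta(dv.values,
                              gt.delta(c.perturbation, c.donor, c.timepoint))
            assert r > 0.8

    def test_delta_table_respects_caps(self, tiny_screen):
        from ctxbench import CoverageSpec, make_split
        cfg, gt, ds = tiny_screen
        spec = CoverageSpec(n_train_contexts=2, n_test_contexts=1,
                            matched_total_cells=40)
        split = make_split(ds, spec, seed=1)
        norm = lognormalize(ds)
        table = delta_table(ds, split.train_configs[:4], norm=norm,
                            split=split, cap_seed=0)
        assert table.shape == (4, cfg.n_genes)


class TestBenjaminiHochberg:
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0,
                              allow_nan=False, allow_subnormal=False),
                    min_size=1, max_size=20))
    @settings(max_examples=200, deadline=None)
    def test_matches_bruteforce_stepup(self, pvals):
        np.testing.assert_allclose(benjamini_hochberg(pvals),
                                   bh_bruteforce(pvals), rtol=1e-12)

    def test_monotone_in_input_order_statistics(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        q = benjamini_hochberg(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestCallDegs:
    def test_constant_gene_gets_p_one(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 30, size=(30, 4))
        y = rng.integers(0, 30, size=(30, 4))
        x[:, 2] = 5
        y[:, 2] = 5
        x[:, 0] += 1
        y[:, 0] += 1
        ds = _two_group_dataset(x, y)
        # treat the raw values as the normalized matrix so the gene is
        # genuinely constant across every cell
        degs = call_degs(ds, Configuration("d1", "t1", "p1"),
                         norm=np.vstack([x, y]).astype(float))
        assert degs.pvalues[2] == 1.0
        assert "g2" not in degs.genes

    def test_too_few_cells_rejected(self):
        x = np.ones((2, 3), dtype=int)
        y = np.ones((5, 3), dtype=int)
        ds = _two_group_dataset(x, y)
        with pytest.raises(ValueError, match=">= 3 cells"):
            call_degs(ds, Configuration("d1", "t1", "p1"))

    def test_null_calibration(self):
        # no effects: raw p < 0.05 at ~5% of 2000 genes
        cfg = SimConfig(n_genes=2000, n_perturbations=1, n_donors=1,
                        n_timepoints=1, cells_per_config=150,
                        control_cells_per_context=150, seed=7)
        gt = zero_effects(sample_ground_truth(cfg))
        ds = simulate_cells(gt, cfg)
        degs = call_degs(ds, ds.configurations()[0])
        rate = np.mean(degs.pvalues < 0.05)
        se = np.sqrt(0.05 * 0.95 / cfg.n_genes)
        assert abs(rate - 0.05) <= 3 * se

    def test_planted_effect_detected(self):
        # a single 1.0 log-unit effect with 200 cells per side is found
        cfg = SimConfig(n_genes=2000, n_perturbations=1, n_donors=1,
                        n_timepoints=1, cells_per_config=200,
                        control_cells_per_context=200, seed=8)
        gt = zero_effects(sample_ground_truth(cfg))
        gi = 500
        gt.context_effect[gi, 0, 0] = 1.0
        ds = simulate_cells(gt, cfg)
        degs = call_degs(ds, ds.configurations()[0])
        assert gt.genes[gi] in degs.genes

    def test_qvalues_monotone_with_pvalues(self):
        rng = np.random.default_rng(5)
        x = rng.poisson(3.0, size=(40, 50)) + 1
        y = rng.poisson(3.5, size=(40, 50)) + 1
        ds = _two_group_dataset(x, y)
        degs = call_degs(ds, Configuration("d1", "t1", "p1"))
        order = np.argsort(degs.pvalues)
        assert np.all(np.diff(degs.qvalues[order]) >= -1e-12)


class TestDegsFromDelta:
    def test_threshold_rule(self):
        genes = np.array(["a", "b", "c"])
        got = degs_from_delta(np.array([0.6, -0.7, 0.1]), genes=genes,
                              threshold=0.5)
        assert got == {"a", "b"}


class TestConsistency:
    def test_error_shrinks_with_more_cells(self):
        # paired by seed: same latent truth, 100 vs 1000 cells per side
        maes = {}
        for n in (100, 1000):
            cfg = SimConfig(n_perturbations=5, n_donors=1, n_timepoints=1,
                            cells_per_config=n,
                            control_cells_per_context=n,
                            mechanism_shift=0.0, seed=42)
            gt = sample_ground_truth(cfg)
            ds = simulate_cells(gt, cfg)
            norm = lognormalize(ds, dtype=np.float32)
            errs = []
            for c in ds.configurations():
                dv = estimate_delta(ds, c, norm=norm)
                true = gt.delta(c.perturbation, c.donor, c.timepoint)
                tgt = np.abs(true) > 0
                errs.append(np.mean(np.abs(dv.values[tgt] - true[tgt])))
            maes[n] = float(np.mean(errs))
        assert maes[1000] < maes[100]
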