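import numpy as np
import pytest
import scipy.stats

from ctxbench import (SimConfig, sample_ground_truth, simulate_cells,
                      true_deg_sets, lognormalize, call_degs)
from ctxbench.simdata import zero_effects


def _corr_across_contexts(gt):
    """Mean Pearson correlation of per-context effect vectors between the
    first two contexts, over perturbations."""
    rs = []
    for pi in range(len(gt.perturbations)):
        a = gt.context_effect[:, pi, 0]
        b = gt.context_effect[:, pi, 1]
        if np.ptp(a) > 0 and np.ptp(b) > 0:
            rs.append(scipy.stats.pearsonr(a, b).statistic)
    return float(np.mean(rs))


class TestGroundTruth:
    def test_invariant_mechanism_collapses_contexts(self):
        cfg = SimConfig(n_genes=200, n_perturbations=5, n_donors=2,
                        n_timepoints=2, mechanism_shift=0.0, seed=1)
        gt = sample_ground_truth(cfg)
        for ci in range(1, len(gt.contexts)):
            assert np.array_equal(gt.context_effect[:, :, ci],
                                  gt.context_effect[:, :, 0])
        assert np.array_equal(gt.context_effect[:, :, 0], gt.shared_effect)

    def test_full_shift_decorrelates_contexts(self):
        # rho=1, full resampling: effect vectors in two contexts share no
        # construction, so their gene-wise correlation averages ~0
        cfg = SimConfig(n_genes=2000, n_perturbations=100,
                        mechanism_shift=1.0, context_resample_fraction=1.0,
                        seed=2)
        gt = sample_ground_truth(cfg)
        assert abs(_corr_across_contexts(gt)) < 0.1

    def test_seeded_determinism_bitwise(self):
        cfg = SimConfig(n_genes=150, n_perturbations=4, seed=33)
        a, b = sample_ground_truth(cfg), sample_ground_truth(cfg)
        assert np.array_equal(a.context_effect, b.context_effect)
        assert np.array_equal(a.baseline_log_mean, b.baseline_log_mean)
        assert np.array_equal(a.shared_effect, b.shared_effect)
        assert all(np.array_equal(x, y)
                   for x, y in zip(a.target_sets, b.target_sets))

    def test_target_set_size(self):
        cfg = SimConfig(n_genes=200, n_perturbations=6,
                        targets_per_perturbation=15, seed=3)
        gt = sample_ground_truth(cfg)
        for pi in range(6):
            assert np.count_nonzero(gt.shared_effect[:, pi]) == 15

    def test_too_many_targets_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            SimConfig(n_genes=10, targets_per_perturbation=11)

    @pytest.mark.parametrize("bad", [
        dict(mechanism_shift=1.5), dict(mechanism_shift=-0.1),
        dict(context_resample_fraction=2.0), dict(dispersion=0.0),
        dict(n_donors=0), dict(deg_truth_threshold=-1.0),
    ])
    def test_invalid_configuration_rejected(self, bad):
        with pytest.raises(ValueError):
            SimConfig(**bad)

    def test_mechanism_shift_monotone_decorrelation(self):
        # across-context effect correlation is non-increasing in rho
        means = []
        for rho in (0.0, 0.3, 0.6, 1.0):
            vals = [_corr_across_contexts(sample_ground_truth(
                SimConfig(n_genes=500, n_perturbations=40,
                          mechanism_shift=rho, seed=s)))
                for s in range(3)]
            means.append(np.mean(vals))
        assert all(means[i] >= means[i + 1] - 0.02
                   for i in range(len(means) - 1))


class TestTrueDegSets:
    def test_threshold_zero_gives_support(self):
        cfg = SimConfig(n_genes=100, n_perturbations=3, n_donors=1,
                        n_timepoints=2, targets_per_perturbation=10,
                        mechanism_shift=0.5, seed=5)
        gt = sample_ground_truth(cfg)
        # smallest positive |delta| sits above threshold 0 by construction
        sets = true_deg_sets(gt, 0.0)
        for pi, p in enumerate(gt.perturbations):
            for ci, (d, t) in enumerate(gt.contexts):
                support = set(gt.genes[gt.context_effect[:, pi, ci] != 0])
                assert sets[(p, d, t)] >= support

    def test_huge_threshold_gives_empty_sets(self):
        cfg = SimConfig(n_genes=100, n_perturbations=3, n_donors=1,
                        n_timepoints=1, targets_per_perturbation=10, seed=5)
        gt = sample_ground_truth(cfg)
        hi = np.abs(gt.context_effect).max() + 1
        assert all(len(s) == 0 for s in true_deg_sets(gt, hi).values())

    def test_invariant_mechanism_shares_deg_sets(self):
        cfg = SimConfig(n_genes=200, n_perturbations=4, n_donors=2,
                        n_timepoints=2, mechanism_shift=0.0, seed=6)
        gt = sample_ground_truth(cfg)
        sets = true_deg_sets(gt, 0.5)
        for p in gt.perturbations:
            per_ctx = [sets[(p, d, t)] for (d, t) in gt.contexts]
            assert all(s == per_ctx[0] for s in per_ctx)


class TestSimulateCells:
    def test_counts_and_layout(self, tiny_screen):
        cfg, gt, ds = tiny_screen
        counts = ds.dense_counts()
        assert counts.min() >= 0
        assert np.issubdtype(counts.dtype, np.integer)
        sizes = ds.obs.groupby(["donor", "timepoint", "perturbation"],
                               observed=True).size()
        for (d, t) in gt.contexts:
            assert sizes[(d, t, "ctrl")] == cfg.control_cells_per_context
            for p in gt.perturbations:
                assert sizes[(d, t, p)] == cfg.cells_per_config

    def test_per_config_cell_table(self):
        cfg = SimConfig(n_genes=50, n_perturbations=2, n_donors=1,
                        n_timepoints=2, control_cells_per_context=5,
                        targets_per_perturbation=5,
                        cells_per_config={("d1", "t1", "p1"): 7}, seed=9)
        gt = sample_ground_truth(cfg)
        ds = simulate_cells(gt, cfg)
        sizes = ds.obs.groupby(["donor", "timepoint", "perturbation"],
                               observed=True).size()
        assert sizes[("d1", "t1", "p1")] == 7
        assert ("d1", "t1", "p2") not in sizes.index
        assert sizes[("d1", "t2", "ctrl")] == 5

    def test_simulation_deterministic(self, tiny_config):
        gt = sample_ground_truth(tiny_config)
        a = simulate_cells(gt, tiny_config)
        b = simulate_cells(gt, tiny_config)
        assert a.equals(b)

    def test_null_screen_pvalues_uniform(self):
        # zero effects, no systematic shift: perturbed and control cells
        # are exchangeable, so rank-test p-values are ~Uniform(0,1)
        cfg = SimConfig(n_genes=2000, n_perturbations=1, n_donors=1,
                        n_timepoints=1, cells_per_config=150,
                        control_cells_per_context=150, seed=7)
        gt = zero_effects(sample_ground_truth(cfg))
        ds = simulate_cells(gt, cfg)
        degs = call_degs(ds, ds.configurations()[0])
        ks = scipy.stats.kstest(degs.pvalues, "uniform")
        assert ks.pvalue > 0.01

    def test_mean_counts_match_expected_rates(self):
        # law of large numbers: observed gene means approach E[L]*pi(g)
        cfg = SimConfig(n_genes=100, n_perturbations=1, n_donors=1,
                        n_timepoints=1, cells_per_config=10,
                        control_cells_per_context=10_000,
                        targets_per_perturbation=5, seed=13)
        gt = sample_ground_truth(cfg)
        ds = simulate_cells(gt, cfg)
        ctrl = ds.dense_counts()[
            (ds.obs["perturbation"] == "ctrl").to_numpy()]
        eta = gt.baseline_log_mean[:, 0]
        pi_rel = np.exp(eta - eta.max())
        pi_rel /= pi_rel.sum()
        e_lib = np.exp(cfg.library_size_log_mean
                       + cfg.library_size_log_sd ** 2 / 2)
        expected = e_lib * pi_rel
        obs_mean = ctrl.mean(axis=0)
        se = ctrl.std(axis=0, ddof=1) / np.sqrt(ctrl.shape[0])
        frac_within = np.mean(np.abs(obs_mean - expected) <= 3 * se)
        assert frac_within > 0.97


class TestGroundTruthExport:
    def test_tsv_and_json_sidecar(self, tmp_path):
        import json, os
        from ctxbench.simdata import export_ground_truth
        import pandas as pd

        cfg = SimConfig(n_genes=80, n_perturbations=3, n_donors=1,
                        n_timepoints=2, targets_per_perturbation=8,
                        mechanism_shift=0.5, seed=12)
        gt = sample_ground_truth(cfg)
        export_ground_truth(gt, cfg, str(tmp_path))
        tab = pd.read_csv(tmp_path / "ground_truth_effects.tsv", sep="\t")
        assert {"gene", "perturbation", "donor", "timepoint",
                "delta"} <= set(tab.columns)
        # one row per nonzero effect
        assert len(tab) == int((gt.context_effect != 0).sum())
        side = json.load(open(tmp_path / "sim_config.json"))
        assert side["n_genes"] == 80 and side["seed"] == 12
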