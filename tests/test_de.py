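"""NB Wald engine: cell means, dispersions, contrasts, BH."""

import numpy as np
import pytest

import temporade as tp
from temporade.de import bh_adjust, estimate_dispersions, fit_cell_means, wald_contrast
from temporade.design import ContrastSpec

from conftest import random_design


def _one_condition_counts(counts_by_cell, sf=None):
    """Build a tiny CountMatrix + design from {(cond,time): [counts...]} for
    a single gene."""
    samples, cols = [], []
    for (c, t), vals in counts_by_cell.items():
        for r, v in enumerate(vals, 1):
            samples.append(tp.SampleInfo(f"{c}_{t}_r{r}", c, t, r))
            cols.append(v)
    conds = tuple(dict.fromkeys(s.condition for s in samples))
    times = tuple(sorted({s.time for s in samples}))
    design = tp.ExperimentalDesign(tuple(samples), conds, times)
    cm = tp.CountMatrix(["g1"], [s.sample_id for s in samples],
                        np.array([cols]))
    return cm, design


class TestFitCellMeans:
    def test_unit_size_factors_group_mean(self):
        cm, design = _one_condition_counts({("A", "t0"): [4, 6]})
        fit = fit_cell_means(cm, design, np.array([1.0, 1.0]))
        assert fit.mu[0, fit.cell_index[("A", "t0")]] == pytest.approx(5.0)

    def test_size_factor_weighted_mean(self):
        cm, design = _one_condition_counts({("A", "t0"): [4, 12]})
        fit = fit_cell_means(cm, design, np.array([1.0, 2.0]))
        assert fit.mu[0, 0] == pytest.approx(16.0 / 3.0)

    def test_all_zero_gene_flagged(self):
        cm, design = _one_condition_counts({("A", "t0"): [0, 0],
                                            ("A", "t1"): [0, 0]})
        fit = fit_cell_means(cm, design, np.ones(4))
        assert fit.mu[0].max() == 0.0
        assert fit.cell_zero[0].all()


class TestWaldContrast:
    def _fit(self, counts_by_cell, alpha=0.1):
        cm, design = _one_condition_counts(counts_by_cell)
        fit = fit_cell_means(cm, design, np.ones(cm.n_samples))
        return fit, np.full(cm.n_genes, alpha)

    def test_identical_cells_null(self):
        fit, alpha = self._fit({("A", "t0"): [10, 20], ("A", "t1"): [10, 20]})
        c = ContrastSpec("temporal", "A", None, "t1", t0="t0")
        df = wald_contrast(fit, alpha, c)
        assert df["log2_fold_change"][0] == 0.0
        assert df["pvalue"][0] == pytest.approx(1.0)

    def test_fourfold_means_approach_lfc_two(self):
        fit, _ = self._fit({("A", "t0"): [5] * 50, ("A", "t1"): [20] * 50})
        c = ContrastSpec("temporal", "A", None, "t1", t0="t0")
        df = wald_contrast(fit, np.array([1e-8]), c)
        assert df["log2_fold_change"][0] == pytest.approx(2.0)
        assert df["pvalue"][0] < 1e-10

    def test_direction_swap_flips_lfc_keeps_p(self):
        rng = np.random.default_rng(0)
        design = random_design(rng, 2, 2, replicates=3)
        cm = tp.CountMatrix([f"g{i}" for i in range(30)],
                            design.sample_ids,
                            rng.integers(1, 500, size=(30, 12)))
        fit = fit_cell_means(cm, design, np.ones(12))
        alpha = np.full(30, 0.1)
        ab = wald_contrast(fit, alpha, ContrastSpec("condition", "A", "B", "t0"))
        # manual reversed contrast: temporal style with cells swapped
        ba_lfc = []
        ia, ib = fit.cell_index[("A", "t0")], fit.cell_index[("B", "t0")]
        pseudo = 0.5 / np.mean(fit.sf)
        ba_lfc = np.log2(np.maximum(fit.mu[:, ib], pseudo)
                         / np.maximum(fit.mu[:, ia], pseudo))
        assert np.allclose(ab["log2_fold_change"], -ba_lfc, atol=1e-12)
        assert np.allclose(ab["stat"], ab["log2_fold_change"] / ab["lfc_se"],
                           atol=1e-8)

    def test_both_cells_zero_untestable(self):
        fit, alpha = self._fit({("A", "t0"): [0, 0], ("A", "t1"): [0, 0]})
        c = ContrastSpec("temporal", "A", None, "t1", t0="t0")
        df = wald_contrast(fit, alpha, c)
        assert np.isnan(df["pvalue"][0])
        assert np.isnan(df["stat"][0])


class TestDispersions:
    def test_poisson_data_recovers_near_zero(self):
        spec = tp.SimulationSpec(conditions=("A",), times=("t0", "t1"),
                                 replicates=20, n_genes=50, dispersion=0.0,
                                 seed=2)
        cm, design, _ = tp.simulate(spec)
        disp = estimate_dispersions(cm, design, tp.size_factors(cm))
        assert np.median(disp.final) <= 0.01

    def test_nb_dispersion_recovered_within_band(self):
        spec = tp.SimulationSpec(conditions=("A",), times=("t0", "t1"),
                                 replicates=6, n_genes=50, dispersion=0.2,
                                 seed=3)
        cm, design, _ = tp.simulate(spec)
        disp = estimate_dispersions(cm, design, tp.size_factors(cm))
        assert 0.1 <= np.median(disp.final) <= 0.4

    def test_single_gene_uses_constant_trend_with_warning(self):
        cm, design = _one_condition_counts({("A", "t0"): [5, 9, 4],
                                            ("A", "t1"): [30, 22, 41]})
        with pytest.warns(UserWarning, match="trend"):
            disp = estimate_dispersions(cm, design, np.ones(6))
        assert disp.final[0] > 0

    def test_outlier_gene_keeps_genewise_value(self):
        rng = np.random.default_rng(4)
        spec = tp.SimulationSpec(conditions=("A",), times=("t0", "t1"),
                                 replicates=6, n_genes=80, dispersion=0.05,
                                 seed=5)
        cm, design, _ = tp.simulate(spec)
        counts = cm.counts.copy()
        # inflate one gene's within-cell scatter massively
        counts[0, :6] = [1, 1000, 2, 900, 3, 1200]
        cm2 = tp.CountMatrix(cm.gene_ids, cm.sample_ids, counts)
        disp = estimate_dispersions(cm2, design, tp.size_factors(cm2))
        assert disp.outlier[0]
        assert disp.final[0] == pytest.approx(disp.genewise[0])


class TestBHAdjust:
    def test_hand_example(self):
        out = bh_adjust([0.005, 0.01, 0.03, 0.04])
        assert np.allclose(out, [0.02, 0.02, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_equal_stay_equal(self):
        out = bh_adjust([0.2] * 5)
        assert np.allclose(out, 0.2)

    def test_nan_passthrough_excluded_from_m(self):
        out = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        assert np.allclose(out[[0, 2]], bh_adjust([0.01, 0.04]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_brute_force_and_statsmodels(self):
        statsmodels = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(6)
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            ours = bh_adjust(p)
            # brute-force step-up definition
            m = len(p)
            brute = np.empty(m)
            for i in range(m):
                rank_vals = [p[j] * m / (np.sum(p <= p[j])) for j in range(m)]
                brute[i] = min(min(v for j, v in enumerate(rank_vals)
                                   if p[j] >= p[i]), 1.0)
            ref = statsmodels.multipletests(p, method="fdr_bh")[1]
            assert np.allclose(ours, ref, atol=1e-12)
            assert np.allclose(ours, brute, atol=1e-12)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(7)
        p = rng.random(200)
        assert (bh_adjust(p) >= p - 1e-15).all()


class TestRunDE:
    def test_planted_effects_recovered(self):
        rng = np.random.default_rng(8)
        genes = rng.choice(400, 40, replace=False)
        eff = tuple(tp.Effect(int(g), "A", "t1", float(rng.choice([-2.0, 2.0])))
                    for g in genes)
        spec = tp.SimulationSpec(conditions=("A",), times=("t0", "t1"),
                                 replicates=4, n_genes=400, dispersion=0.1,
                                 effects=eff, seed=9)
        cm, design, _ = tp.simulate(spec)
        df = tp.run_de(cm, design).results["A:t1_vs_t0"]
        called = set(df.loc[df["padj"] < 0.05, "gene_id"])
        truth = {f"g{g:04d}" for g in genes}
        sens = len(called & truth) / len(truth)
        fdr = len(called - truth) / max(len(called), 1)
        assert sens >= 0.8
        assert fdr <= 0.1
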