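"""Synthetic worlds: determinism, calibration, bias structure, exports."""

import numpy as np
import pytest
from scipy import stats

from ppisize import (
    AssaySamplingConfig,
    InputError,
    InteractomeSizeModel,
    generate_world,
    recovery_experiment,
    sample_ht_dataset,
    sample_lc_dataset,
)
from ppisize.diagnostics import ist_coverage_curve
from ppisize.io import (
    filter_binary_physical_low_throughput,
    load_biogrid_tab,
    load_edge_list,
    load_study_levels,
)
from ppisize.synthetic import export_biogrid_tab, export_edge_list

SMALL = dict(n_proteins=400, n_true=3000)


class TestGenerateWorld:
    def test_identical_seed_identical_world(self):
        w1 = generate_world(**SMALL, seed=5)
        w2 = generate_world(**SMALL, seed=5)
        assert np.array_equal(w1.pair_i, w2.pair_i)
        assert np.array_equal(w1.pair_j, w2.pair_j)
        assert np.array_equal(w1.papers, w2.papers)
        assert np.array_equal(w1.detectability, w2.detectability)
        assert w1.manifest() == w2.manifest()

    def test_requested_size_and_canonical_pairs(self):
        w = generate_world(**SMALL, seed=1)
        assert w.n_true == 3000
        assert (w.pair_i <= w.pair_j).all()
        assert len(w.true_pairs) == 3000

    def test_infeasible_size_rejected(self):
        with pytest.raises(InputError):
            generate_world(n_proteins=10, n_true=100, seed=0)

    def test_zero_correlation_null(self):
        rhos = []
        for seed in range(8):
            w = generate_world(**SMALL, study_degree_correlation=0.0, seed=seed)
            rhos.append(stats.spearmanr(w.degree(), w.papers).statistic)
        assert abs(np.mean(rhos)) < 0.05

    def test_requested_rank_correlation_realized(self):
        rhos = []
        for seed in range(10):
            w = generate_world(**SMALL, study_degree_correlation=0.6, seed=seed)
            rhos.append(stats.spearmanr(w.degree(), w.papers).statistic)
        assert np.mean(rhos) == pytest.approx(0.6, abs=0.1)


class TestSamplers:
    def test_ht_zero_fdr_is_subset_of_truth(self):
        w = generate_world(**SMALL, seed=2)
        ht = sample_ht_dataset(w, AssaySamplingConfig(expected_size=500, seed=3))
        assert ht.pairs <= w.true_pairs
        assert ht.attrs["true_fdr"] == 0.0

    def test_realized_fdr_near_target(self):
        w = generate_world(n_proteins=800, n_true=10000, seed=4)
        fdrs, sizes = [], []
        for seed in range(15):
            ht = sample_ht_dataset(
                w, AssaySamplingConfig(expected_size=2000, target_fdr=0.25, seed=seed)
            )
            fdrs.append(ht.attrs["true_fdr"])
            sizes.append(len(ht))
        assert np.mean(fdrs) == pytest.approx(0.25, abs=0.02)
        assert np.mean(sizes) == pytest.approx(2000, rel=0.05)

    def test_lc_unbiased_uniform_subset(self):
        w = generate_world(**SMALL, seed=6)
        lc = sample_lc_dataset(w, AssaySamplingConfig(expected_size=800, seed=7))
        assert lc.pairs <= w.true_pairs
        assert lc.attrs["n_fp"] == 0
        # every record has at least one publication with a plausible year
        rec = next(iter(lc))
        assert rec.publications and all(p.year > 1900 for p in rec.publications)

    def test_lc_fp_rate_among_singles(self):
        w = generate_world(n_proteins=800, n_true=10000, seed=8)
        shares = []
        for seed in range(10):
            lc = sample_lc_dataset(
                w,
                AssaySamplingConfig(
                    expected_size=2500, fp_single_rate=0.3, single_paper_prob=0.6, seed=seed
                ),
            )
            singles = [r for r in lc if len(r.publications) == 1]
            fp = sum(1 for r in singles if r.pair not in w.true_pairs)
            shares.append(fp / len(singles))
        assert np.mean(shares) == pytest.approx(0.3, abs=0.03)

    def test_detectability_bias_shows_in_ist_curve(self):
        """Curated coverage rises with IST count when curation favors
        detectable interactions, and stays flat when it does not."""
        w = generate_world(n_proteins=1200, n_true=12000, seed=9)
        ht = sample_ht_dataset(
            w,
            AssaySamplingConfig(
                expected_size=3000, assay_sensitivity_exponent=0.5, seed=10
            ),
            with_ist=True,
        )
        biased = sample_lc_dataset(
            w, AssaySamplingConfig(expected_size=4000, detectability_bias_weight=1.5, seed=11)
        )
        flat = sample_lc_dataset(w, AssaySamplingConfig(expected_size=4000, seed=12))
        curve_b = ist_coverage_curve(ht, biased, min_bin_size=400)
        curve_f = ist_coverage_curve(ht, flat, min_bin_size=400)
        rho_b = stats.spearmanr(
            curve_b["weighted_mean_ist"], curve_b["lc_coverage"]
        ).statistic
        assert rho_b > 0.8
        spread_b = curve_b["lc_coverage"].max() - curve_b["lc_coverage"].min()
        spread_f = curve_f["lc_coverage"].max() - curve_f["lc_coverage"].min()
        assert spread_b > 2 * spread_f

    def test_study_bias_steepens_degree_study_relation(self):
        from ppisize.diagnostics import degree_vs_study_regression
        from ppisize.pairs import InteractionDataset

        w = generate_world(n_proteins=1000, n_true=10000, seed=13)
        levels = w.study_levels()
        truth = InteractionDataset.from_pairs("truth", w.pair_names)
        biased = sample_lc_dataset(
            w, AssaySamplingConfig(expected_size=3000, study_bias_weight=1.0, seed=14)
        )
        slope_truth = degree_vs_study_regression(truth, levels, bin_size=5).slope
        slope_biased = degree_vs_study_regression(biased, levels, bin_size=5).slope
        assert slope_biased > slope_truth


class TestRecoveryExperiment:
    def test_single_replicate_reproducible(self):
        kw = dict(
            world_params=SMALL,
            lc_cfg=AssaySamplingConfig(expected_size=900),
            ht_cfg=AssaySamplingConfig(expected_size=500, target_fdr=0.2),
            n_replicates=1,
            seed=99,
            assumed_fp_rate=0.0,
        )
        r1 = recovery_experiment(**kw)
        r2 = recovery_experiment(**kw)
        assert r1["naive_mean"] == r2["naive_mean"]
        assert r1["ws_mean"] == r2["ws_mean"]

    def test_report_fields_present(self):
        rep = recovery_experiment(
            SMALL,
            AssaySamplingConfig(expected_size=900),
            AssaySamplingConfig(expected_size=500, target_fdr=0.2),
            n_replicates=3,
            seed=1,
            assumed_fp_rate=0.0,
        )
        for key in ("naive_mean", "ws_mean", "naive_ci_coverage", "ws_rmse", "true_n"):
            assert key in rep
        assert len(rep["replicates"]) == 3


class TestExports:
    def test_round_trip_through_real_loaders(self, tmp_path):
        """Exported files feed the same parsers the real data would."""
        w = generate_world(n_proteins=200, n_true=800, seed=20)
        lc = sample_lc_dataset(
            w, AssaySamplingConfig(expected_size=300, single_paper_prob=0.5, seed=21)
        )
        ht = sample_ht_dataset(
            w, AssaySamplingConfig(expected_size=150, target_fdr=0.2, seed=22), with_ist=True
        )
        biogrid = tmp_path / "synth.tab"
        export_biogrid_tab(lc, biogrid)
        raws = load_biogrid_tab(biogrid)
        reloaded = filter_binary_physical_low_throughput(raws)
        assert reloaded.pairs == lc.pairs

        sgd = tmp_path / "levels.tsv"
        w.export_study_levels(sgd)
        levels = load_study_levels(sgd)
        nonzero = [i for i, n in enumerate(w.papers) if n > 0][:20]
        assert all(levels[w.proteins[i]] == w.papers[i] for i in nonzero)

        edges = tmp_path / "ht.tsv"
        export_edge_list(ht, edges, with_ist=True)
        ht2 = load_edge_list(edges, "HT", with_ist=True)
        assert ht2.pairs == ht.pairs

        # the reloaded pieces drive a full model fit end-to-end
        model = InteractomeSizeModel(
            reloaded, {"HT": ht2}, levels,
            reference_dataset="HT", reference_fdr=0.2,
            well_studied_cutoff=w.papers_cutoff_for_quantile(0.8),
        )
        res = model.fit("HT")
        assert res.interactome_size > 0
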