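"""Bias diagnostics: binning, regressions, curves, enrichment, recuration."""

import numpy as np
import pytest
from scipy import stats

from ppisize import EstimationError, InteractionDataset, StudyLevels
from ppisize.diagnostics import (
    bin_by_ist,
    binned_loglog_regression,
    degree_vs_study_regression,
    evidence_code_enrichment,
    ht_coverage_vs_cutoff,
    ist_coverage_curve,
    recuration_ws_proportions,
    well_studied_count_curve,
)
from ppisize.pairs import InteractionRecord


def _ist_records(spec):
    """spec: list of (count, ist) blocks."""
    recs = []
    i = 0
    for count, ist in spec:
        for _ in range(count):
            recs.append(InteractionRecord((f"A{i}", f"B{i}"), ist_count=ist))
            i += 1
    return recs


class TestIstBinning:
    def test_equal_values_never_split(self):
        bins = bin_by_ist(_ist_records([(400, 1)]), min_bin_size=200)
        assert len(bins) == 1 and len(bins[0]) == 400

    def test_two_clean_bins(self):
        bins = bin_by_ist(_ist_records([(250, 1), (250, 2)]), min_bin_size=200)
        assert [len(b) for b in bins] == [250, 250]
        means = [np.mean([r.ist_count for r in b]) for b in bins]
        assert means == [1.0, 2.0]

    def test_trailing_short_bin_merged(self):
        bins = bin_by_ist(_ist_records([(250, 1), (30, 5)]), min_bin_size=200)
        assert [len(b) for b in bins] == [280]

    def test_partition_property(self):
        rng = np.random.default_rng(3)
        recs = _ist_records([(int(rng.integers(20, 120)), ist) for ist in range(1, 12)])
        bins = bin_by_ist(recs, min_bin_size=150)
        flat = [r.pair for b in bins for r in b]
        assert sorted(flat) == sorted(r.pair for r in recs)
        means = [np.mean([r.ist_count for r in b]) for b in bins]
        assert means == sorted(means) and len(set(means)) == len(means)

    def test_small_input_single_bin_with_warning(self):
        with pytest.warns(UserWarning):
            bins = bin_by_ist(_ist_records([(10, 1)]), min_bin_size=200)
        assert len(bins) == 1


class TestIstCoverage:
    def test_full_and_zero_coverage(self):
        recs = _ist_records([(120, 1), (120, 3)])
        screen = InteractionDataset("screen", recs)
        full = InteractionDataset("lc", [InteractionRecord(r.pair) for r in recs])
        curve = ist_coverage_curve(screen, full, min_bin_size=100)
        assert (curve["lc_coverage"] == 1.0).all()
        empty = InteractionDataset("lc2")
        curve0 = ist_coverage_curve(screen, empty, min_bin_size=100)
        assert (curve0["lc_coverage"] == 0.0).all()


class TestDegreeStudyRegression:
    def test_exact_power_law_recovered(self):
        # papers constant within each bin of 5 -> bin means sit exactly on the law
        papers = np.repeat([4, 16, 64, 256, 1024, 4096], 5).astype(float)
        degree = 3.0 * papers**0.5
        for bin_size in (1, 5):
            res = binned_loglog_regression(papers, degree, bin_size=bin_size)
            assert res.slope == pytest.approx(0.5, abs=1e-9)
            assert res.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_null_slope_near_zero(self):
        rng = np.random.default_rng(11)
        slopes = []
        for _ in range(5):
            papers = rng.integers(1, 400, 600).astype(float)
            degree = rng.integers(1, 30, 600).astype(float)  # independent of papers
            slopes.append(binned_loglog_regression(papers, degree, bin_size=5).slope)
        assert abs(np.mean(slopes)) < 0.05

    def test_dataset_wrapper_counts_degree(self):
        # star around H: degree(H) = 4, leaves degree 1
        ds = InteractionDataset.from_pairs("d", [("H", f"L{i}") for i in range(4)])
        levels = StudyLevels({"H": 100, "L0": 2, "L1": 3, "L2": 5, "L3": 8})
        res = degree_vs_study_regression(ds, levels, bin_size=1)
        assert res.slope > 0

    def test_insufficient_bins_rejected(self):
        with pytest.raises(EstimationError):
            binned_loglog_regression(np.array([1.0, 2.0]), np.array([1.0, 2.0]), bin_size=1)


class TestCoverageAndCensusCurves:
    def test_ht_equal_lc_gives_full_coverage(self, micro_lc, micro_levels):
        df = ht_coverage_vs_cutoff(micro_lc, {"self": micro_lc}, [1, 5, 10], micro_levels)
        assert (df["coverage"] == 1.0).all()

    def test_cutoff_below_all_counts_equals_unrestricted_coverage(
        self, micro_lc, micro_ht, micro_levels
    ):
        df = ht_coverage_vs_cutoff(micro_lc, micro_ht, [1], micro_levels)
        ref_cov = df[df["dataset"] == "REF"]["coverage"].iloc[0]
        assert ref_cov == pytest.approx(len(micro_lc.pairs & micro_ht["REF"].pairs) / len(micro_lc))

    def test_census_curve_non_increasing(self, micro_levels):
        df = well_studied_count_curve(micro_levels, range(1, 15))
        counts = df["n_proteins"].to_numpy()
        assert (np.diff(counts) <= 0).all()
        assert df[df["cutoff"] == 1]["n_proteins"].iloc[0] == 7
        assert df[df["cutoff"] == 10]["n_proteins"].iloc[0] == 4


class TestEnrichment:
    def test_identical_datasets_null_result(self, micro_lc):
        df = evidence_code_enrichment(micro_lc, micro_lc, ["two-hybrid"])
        assert df["delta"].iloc[0] == 0.0
        assert df["p_value"].iloc[0] == pytest.approx(1.0)

    def test_matches_textbook_chi_square(self):
        # 30/100 vs 60/100 carrying the code
        lc = InteractionDataset(
            "lc",
            [
                InteractionRecord((f"A{i}", f"B{i}"),
                                  {"fret"} if i < 30 else {"pca"})
                for i in range(100)
            ],
        )
        ws = InteractionDataset(
            "ws",
            [
                InteractionRecord((f"C{i}", f"D{i}"),
                                  {"fret"} if i < 60 else {"pca"})
                for i in range(100)
            ],
        )
        df = evidence_code_enrichment(lc, ws, ["fret"])
        expected = stats.chi2_contingency(
            np.array([[60, 40], [30, 70]]), correction=False
        )[1]
        assert df["p_value"].iloc[0] == pytest.approx(expected, rel=1e-12)
        assert df["delta"].iloc[0] == pytest.approx(0.3)


class TestRecuration:
    def _scores(self):
        import pandas as pd

        rows = (
            [("F1", "X1", 0), ("F2", "X2", 0), ("F3", "X3", 0), ("W1", "X4", 0)]
            + [("T1", "X5", 2), ("T2", "X6", 2), ("T3", "X7", 2),
               ("W1", "X8", 2), ("W2", "X9", 2)]
            + [("U1", "X10", 1)]
        )
        return pd.DataFrame(rows, columns=["protein_a", "protein_b", "score"])

    def test_hand_counted_fractions(self):
        # 4 FPs (1 with a WS endpoint), 5 TPs (2 with a WS endpoint)
        fp, tp = recuration_ws_proportions(self._scores(), {"W1", "W2"})
        assert fp == pytest.approx(0.25)
        assert tp == pytest.approx(0.4)

    def test_no_ws_proteins(self):
        fp, tp = recuration_ws_proportions(self._scores(), set())
        assert (fp, tp) == (0.0, 0.0)

    def test_empty_class_flagged_as_nan(self):
        import pandas as pd

        scores = pd.DataFrame(
            [("A", "B", 2)], columns=["protein_a", "protein_b", "score"]
        )
        with pytest.warns(UserWarning):
            fp, _ = recuration_ws_proportions(scores, {"A"})
        assert np.isnan(fp)
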