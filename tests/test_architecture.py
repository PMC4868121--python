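"""Binning, the bin x motif matrix, trend classes, flank/core contrast."""

import numpy as np
import pytest

from esescan import (
    MotifSet,
    architecture_metrics,
    assign_bins,
    find_hits,
    motif_trend_tests,
)
from esescan.architecture import family_datapoints, motif_bin_matrix
from esescan.nulls import build_control_sets
from esescan.scan import exon_windows
from esescan.seqprep import GeneRecord


class TestAssignBins:
    def test_default_yields_49_bins(self, rng):
        values = np.concatenate([np.zeros(122), rng.uniform(100, 5000, 5845)])
        bins = assign_bins(values)
        assert bins.n_bins == 49
        assert (bins.bin_index[:122] == 0).all()
        occupancy = np.bincount(bins.bin_index, minlength=49)[1:]
        assert occupancy.mean() == pytest.approx(5845 / 48)

    def test_all_zero_single_bin(self):
        with pytest.warns(UserWarning):
            bins = assign_bins(np.zeros(10))
        assert bins.n_bins == 1

    def test_96_positive_values_two_per_bin(self, rng):
        values = rng.permutation(np.arange(1.0, 97.0))
        bins = assign_bins(values, 48)
        occupancy = np.bincount(bins.bin_index, minlength=49)
        assert occupancy[0] == 0
        assert (occupancy[1:] == 2).all()

    def test_boundary_ties_go_low(self):
        values = np.array([0.0, 1.0, 1.0, 2.0, 3.0, 4.0])
        bins = assign_bins(values, 2)
        # both 1.0 points land in the same (lower) positive bin
        assert bins.bin_index[1] == bins.bin_index[2] == 1


class TestArchitectureMetrics:
    def test_values(self):
        g = GeneRecord(
            "g", "t", "ATG" + "GCT" * 332 + "TAA", 5,
            ((0, 200), (200, 400), (400, 600), (600, 800), (800, 1002)),
            (100, 200, 300, 400),
        )
        intron_density, mis, gc4, exon_count = architecture_metrics(g)
        assert intron_density == pytest.approx(4 / 1002)
        assert mis == pytest.approx(250.0)
        assert exon_count == 5

    def test_intronless(self):
        g = GeneRecord("g", "t", "ATG" + "GCT" * 99 + "TAA", 1, ((0, 300),), ())
        intron_density, mis, gc4, _ = architecture_metrics(g)
        assert intron_density == 0 and mis == 0
        assert gc4 == 0.0  # all third positions are T


def _gene(gid, cds, mean_intron=0.0):
    n_intron = 1 if mean_intron > 0 else 0
    return GeneRecord(
        gid, f"T_{gid}", cds, n_intron + 1,
        ((0, len(cds)),) if n_intron == 0 else ((0, len(cds) // 2), (len(cds) // 2, len(cds))),
        (int(mean_intron),) * n_intron,
    )


class TestMotifBinMatrix:
    def test_single_cell_raw_density(self):
        motif = "GAAGAA"
        cds = "ATG" + motif + "T" * 285 + "TAA"  # one hit in 297... pad to 297
        cds = "ATG" + motif + "T" * (300 - 3 - 6 - 3) + "TAA"
        gene = _gene("g", cds)
        dp = family_datapoints([gene], None, MotifSet((motif,), "toy"))
        bins = assign_bins(dp.mean_intron_size.to_numpy(), 2)
        matrix = motif_bin_matrix(dp, bins)
        assert matrix.raw.iloc[0, 0] == pytest.approx(6 / 300)

    def test_absent_motif_with_positive_median_is_minus_one(self, rng):
        # sequence that contains permutations of the motif but not the motif
        motif = "GAACTG"
        controls_hit = "AAGAGA"  # a permutation-control hexamer of GAACTG
        cds = "ATG" + (controls_hit + "TTT") * 33 + "TAA"
        gene = _gene("g", cds)
        dp = family_datapoints([gene], None, MotifSet((motif,), "toy"))
        bins = assign_bins(dp.mean_intron_size.to_numpy(), 2)
        matrix = motif_bin_matrix(dp, bins)
        cell = matrix.normalized.iloc[0, 0]
        if matrix.simulant_medians.iloc[0, 0] > 0:
            assert cell == pytest.approx(-1.0)

    def test_row_sums_match_pooled_density(self, small_cohort, fixture_motifs):
        """Union coverage bounds the per-motif sum from below (overlaps)."""
        genes = small_cohort.genes[:10]
        dp = family_datapoints(genes, None, fixture_motifs)
        from esescan import density

        profiles = [find_hits(g.cds, fixture_motifs, g.gene_id) for g in genes]
        pooled_union = density(profiles, mode="pooled")
        per_motif_sum = dp.counts.to_numpy().sum() / dp.lengths.sum()
        assert per_motif_sum >= pooled_union - 1e-12


class TestMotifTrendTests:
    def _matrix_from_columns(self, columns):
        import pandas as pd

        from esescan.architecture import BinAssignment, MotifBinMatrix

        norm = pd.DataFrame(columns)
        B = len(norm)
        bins = BinAssignment(np.zeros(1, dtype=int), np.empty(0), B)
        return MotifBinMatrix(norm, norm, norm * 0 + 1.0, bins)

    def test_monotone_column_positive(self):
        b = np.arange(12, dtype=float)
        matrix = self._matrix_from_columns({"up": b, "flat": np.ones(12)})
        trends = {t.motif: t for t in motif_trend_tests(matrix)}
        assert trends["up"].statistic == pytest.approx(1.0)
        assert trends["up"].label == "positive"
        assert trends["flat"].label == "nonsignificant"

    def test_constructed_truth_classification(self, rng):
        b = np.arange(20, dtype=float)
        cols = {
            "up1": b + rng.normal(0, 0.5, 20),
            "up2": 2 * b + rng.normal(0, 0.5, 20),
            "down": -b + rng.normal(0, 0.5, 20),
            "flat1": rng.normal(0, 1.0, 20),
            "flat2": rng.normal(0, 1.0, 20),
        }
        trends = {t.motif: t for t in motif_trend_tests(self._matrix_from_columns(cols))}
        assert trends["up1"].label == "positive"
        assert trends["up2"].label == "positive"
        assert trends["down"].label == "negative"
        assert trends["flat1"].label == "nonsignificant"
        assert trends["flat2"].label == "nonsignificant"
        labels = [t.label for t in trends.values()]
        assert len(labels) == 5

    def test_holm_is_applied_across_columns(self):
        """Raw p equal across columns but adjusted p larger with more columns."""
        b = np.arange(8, dtype=float)
        one = motif_trend_tests(self._matrix_from_columns({"a": b}))
        many = motif_trend_tests(
            self._matrix_from_columns({f"m{i}": b + 0.0 for i in range(5)})
        )
        assert many[0].p_adjusted >= one[0].p_adjusted


class TestFlankCoreContrast:
    def _windows(self, rng, n, subset, flank_only):
        out = []
        for _ in range(n):
            seq = list("".join(rng.choice(list("ACGT"), size=213)))
            motif = subset.motifs[int(rng.integers(len(subset)))]
            seq[3:9] = motif  # in the upstream flank
            if not flank_only:
                seq[100:106] = motif
            out.append(exon_windows("".join(seq), 0))
        return out

    def test_flank_planted_subset_has_larger_ratio(self, rng):
        high = MotifSet(("GAAGAC", "ACGATG"), "high")
        low = MotifSet(("TTCAGG", "CATGCA"), "low")
        windows = []
        for _ in range(150):
            seq = list("".join(rng.choice(list("ACGT"), size=213)))
            hm = high.motifs[int(rng.integers(2))]
            lm = low.motifs[int(rng.integers(2))]
            seq[3:9] = hm  # high subset: flank-biased ...
            if rng.random() < 0.25:
                seq[90:96] = hm  # ... with a little core signal
            if rng.random() < 0.5:
                seq[12:18] = lm  # low subset: everywhere
            if rng.random() < 0.5:
                seq[100:106] = lm
            windows.append(exon_windows("".join(seq), 0))
        from esescan import flank_core_contrast

        ctrl_h = build_control_sets(high, 60, np.random.default_rng(1))
        ctrl_l = build_control_sets(low, 60, np.random.default_rng(2))
        res = flank_core_contrast(windows, (high, low), (ctrl_h, ctrl_l))
        assert res.ratios[0] > res.ratios[1]
        assert res.ratio_difference > 0

    def test_identical_subsets_give_zero_difference(self, rng):
        ms = MotifSet(("GAAGAC", "ACGATG"), "s")
        windows = self._windows(rng, 60, ms, flank_only=False)
        from esescan import flank_core_contrast

        ctrl = build_control_sets(ms, 40, np.random.default_rng(3))
        res = flank_core_contrast(windows, (ms, ms), (ctrl, ctrl))
        if not np.isnan(res.ratio_difference):
            assert res.ratio_difference == pytest.approx(0.0, abs=1e-12)
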