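"""Degeneracy annotation, block repair rules, concatenated dS, SNP counts."""

import math

import numpy as np
import pytest

from esescan import CodonAlignment, MotifSet, SnpRecord, annotate_degeneracy
from esescan.genetics import (
    AMINO,
    CODONS,
    CODON_TO_INT,
    DEGENERACY,
    REPAIR_MAP,
    translate,
)
from esescan.nulls import ControlSetCollection, build_control_sets
from esescan.selection import (
    ConcatenatedDsAnalysis,
    concatenated_ds,
    extract_ese_blocks,
    snp_statistics,
)
from esescan.seqprep import GeneRecord


class TestDegeneracy:
    @pytest.mark.parametrize(
        "codon,classes",
        [
            ("ATG", [1, 1, 1]),  # Met: unique codon
            ("GCT", [1, 1, 4]),  # Ala GCN
            ("GAA", [1, 1, 2]),  # Glu GAR
        ],
    )
    def test_reference_codons(self, codon, classes):
        assert list(annotate_degeneracy(codon)) == classes

    def test_degeneracy_consistent_with_translation(self):
        """Class k at a position means exactly k bases preserve the protein."""
        for codon in CODONS:
            ci = CODON_TO_INT[codon]
            for pos in range(3):
                same = sum(
                    AMINO[CODON_TO_INT[codon[:pos] + b + codon[pos + 1 :]]]
                    == AMINO[ci]
                    for b in "ACGT"
                )
                assert DEGENERACY[ci, pos] == same


class TestBlockExtraction:
    def _aln(self, focal, ortho=None):
        return CodonAlignment("g", "o", focal, ortho or focal)

    def test_codon_aligned_mask_needs_no_repair(self):
        aln = self._aln("GAAGCTTGG" * 2)
        mask = np.zeros(18, dtype=bool)
        mask[3:9] = True
        blocks = extract_ese_blocks(aln, mask)
        assert blocks.repaired_positions == []
        f, o = blocks.concatenated()
        assert [CODONS[i] for i in f] == ["GCT", "TGG"]

    def test_leu_twofold_repair(self):
        # mask starts at the 3rd base of TTA (Leu, third position twofold)
        aln = self._aln("TTAGAAGAA")
        mask = np.zeros(9, dtype=bool)
        mask[2:9] = True
        blocks = extract_ese_blocks(aln, mask)
        f, _ = blocks.concatenated()
        assert CODONS[f[0]] == "GAA"
        assert blocks.repaired_positions == [0]

    def test_leu_fourfold_repair(self):
        # mask starts at the 3rd base of CTG (Leu, third position fourfold)
        aln = self._aln("CTGGAAGAA")
        mask = np.zeros(9, dtype=bool)
        mask[2:9] = True
        f, _ = extract_ese_blocks(aln, mask).concatenated()
        assert CODONS[f[0]] == "GCG"

    def test_all_leu_arg_repairs_preserve_third_position_degeneracy(self):
        for codon in ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG",
                      "CGT", "CGC", "CGA", "CGG", "AGA", "AGG"):
            ci = CODON_TO_INT[codon]
            repaired = REPAIR_MAP[ci]
            assert repaired != ci
            assert DEGENERACY[repaired, 2] == DEGENERACY[ci, 2]
            assert repaired % 4 == ci % 4  # third base kept

    def test_incomplete_final_codon_trimmed(self):
        aln = self._aln("GAAGCTTGG")
        mask = np.zeros(9, dtype=bool)
        mask[0:8] = True  # ends mid-codon
        f, _ = extract_ese_blocks(aln, mask).concatenated()
        assert [CODONS[i] for i in f] == ["GAA", "GCT"]

    def test_ortholog_gap_codon_not_rewritten(self):
        aln = CodonAlignment("g", "o", "TTAGAAGAA", "---GAAGAA")
        mask = np.zeros(9, dtype=bool)
        mask[2:9] = True
        blocks = extract_ese_blocks(aln, mask)
        f, o = blocks.concatenated()
        assert CODONS[f[0]] == "GAA" and o[0] == -1

    def test_blocks_translate_without_stops(self, small_cohort):
        codes = small_cohort.config.motifs().codes
        from esescan.scan import KmerIndex

        for aln in small_cohort.ortholog_pairs[:10]:
            mask = KmerIndex(aln.focal_row).coverage_mask(codes)
            blocks = extract_ese_blocks(aln, mask)
            f, _ = blocks.concatenated()
            assert not any(AMINO[c] == "*" for c in f[:-1])


class TestConcatenatedDs:
    def test_identical_rows_give_zero_ds(self, fixture_motifs, rng):
        """With identical rows everywhere, observed dS is 0 and every control
        is tied at 0, so the tie rule drives the one-tailed p to 1."""
        from esescan.synthetic import SyntheticConfig, make_cohort

        cfg = SyntheticConfig(
            n_genes=3, seed=42, ds_background=0.0,
            snp_rate=0, retro_fraction=0, paralog_fraction=0,
        )
        cohort = make_cohort(cfg)
        controls = build_control_sets(fixture_motifs, 50, rng)
        result = concatenated_ds(cohort.ortholog_pairs, fixture_motifs, controls)
        assert result.observed_ds == 0.0
        assert result.test.p == 1.0  # all-tied null

    def test_floor_p_when_only_observed_is_conserved(self, fixture_motifs, rng):
        """Observed dS below every control value reaches the 1/(m+1) floor."""
        from esescan.synthetic import SyntheticConfig, make_cohort

        cfg = SyntheticConfig(
            n_genes=25, seed=43, ese_ds_scaling=0.1,
            snp_rate=0, retro_fraction=0, paralog_fraction=0,
        )
        cohort = make_cohort(cfg)
        controls = build_control_sets(fixture_motifs, 50, rng)
        result = concatenated_ds(cohort.ortholog_pairs, fixture_motifs, controls)
        assert result.test.p == pytest.approx(1 / 51)

    def test_order_invariance_of_counts(self, small_cohort, fixture_motifs):
        a = ConcatenatedDsAnalysis(small_cohort.ortholog_pairs)
        b = ConcatenatedDsAnalysis(small_cohort.ortholog_pairs[::-1])
        codes = fixture_motifs.codes
        assert a.ds_for_codes(codes) == pytest.approx(b.ds_for_codes(codes))


def _plain_gene(gid, cds):
    return GeneRecord(gid, f"T_{gid}", cds, 1, ((0, len(cds)),), ())


class TestSnpStatistics:
    def _setup(self):
        # gene of GCT codons after ATG: every third position fourfold
        cds = "ATG" + "GCTGCAGGT" * 22 + "TAA"
        gene = _plain_gene("g", cds)
        motif = cds[3:9]  # a hexamer present at position 3
        motifs = MotifSet((motif,), "toy")
        return gene, motifs

    def test_counting_definitions(self):
        gene, motifs = self._setup()
        from esescan.scan import find_hits

        profile = find_hits(gene.cds, motifs, "g")
        mask = profile.coverage_mask
        deg4 = annotate_degeneracy(gene.cds) == 4
        n4_in_mask = int((mask & deg4).sum())
        assert n4_in_mask > 0
        pos4 = np.flatnonzero(mask & deg4)
        snps = [
            SnpRecord("g", int(pos4[0]), gene.cds[pos4[0]], "A" if gene.cds[pos4[0]] != "A" else "C", 0.0001, "synonymous"),
            SnpRecord("g", int(pos4[1]), gene.cds[pos4[1]], "A" if gene.cds[pos4[1]] != "A" else "C", 0.01, "synonymous"),
        ]
        controls = ControlSetCollection((motifs,), None)  # self-control
        stats = snp_statistics(
            [gene], snps, motifs, controls, None,
            n_replicates=1, rng=np.random.default_rng(0),
        )
        assert stats.density_4d == pytest.approx(2 / n4_in_mask)
        assert stats.low_maf_fraction == pytest.approx(0.5)

    def test_maf_fraction_example(self):
        gene, motifs = self._setup()
        from esescan.scan import find_hits

        mask = find_hits(gene.cds, motifs, "g").coverage_mask
        pos = np.flatnonzero(mask)[:4]
        mafs = [0.0004, 0.01, 0.2, 0.3]
        snps = [
            SnpRecord("g", int(p), gene.cds[p], "A" if gene.cds[p] != "A" else "C", m, "synonymous")
            for p, m in zip(pos, mafs)
        ]
        controls = ControlSetCollection((motifs,), None)
        stats = snp_statistics(
            [gene], snps, motifs, controls, None,
            n_replicates=1, rng=np.random.default_rng(0),
        )
        assert stats.low_maf_fraction == pytest.approx(0.25)

    def test_no_masked_snps_undefined(self):
        gene, motifs = self._setup()
        controls = ControlSetCollection((motifs,), None)
        stats = snp_statistics(
            [gene], [], motifs, controls, None,
            n_replicates=2, rng=np.random.default_rng(0),
        )
        assert math.isnan(stats.low_maf_fraction)
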