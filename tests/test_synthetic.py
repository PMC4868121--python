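"""Generator contracts: validity, determinism, planted effect recovery."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from esescan import (
    SyntheticConfig,
    derive_retrocopy,
    make_cohort,
    simulate_snps,
    validate_cds,
)
from esescan.genetics import translate
from esescan.scan import KmerIndex, find_hits
from esescan.seqprep import pairwise_codon_rates
from esescan.synthetic import substream


def _quiet(n_genes=20, seed=0, **kw):
    base = dict(snp_rate=0.0, retro_fraction=0.0, paralog_fraction=0.0)
    base.update(kw)
    return SyntheticConfig(n_genes=n_genes, seed=seed, **base)


class TestMakeCohort:
    def test_empty_cohort(self):
        cohort = make_cohort(SyntheticConfig(n_genes=0, seed=1))
        assert cohort.genes == [] and cohort.truth.empty

    def test_all_cds_valid(self, small_cohort):
        for g in small_cohort.genes:
            assert validate_cds(g.cds).passed, g.gene_id

    def test_truth_covers_every_gene(self, small_cohort):
        assert set(small_cohort.truth.index) == {
            g.gene_id for g in small_cohort.genes
        }
        ids = {g.gene_id for g in small_cohort.genes}
        assert {a.focal_id for a in small_cohort.ortholog_pairs} <= ids
        assert {s.gene_id for s in small_cohort.snp_table} <= ids

    def test_determinism_and_seed_sensitivity(self):
        cfg = _quiet(n_genes=6, seed=5)
        a, b = make_cohort(cfg), make_cohort(cfg)
        assert [g.cds for g in a.genes] == [g.cds for g in b.genes]
        assert [x.ortholog_row for x in a.ortholog_pairs] == [
            x.ortholog_row for x in b.ortholog_pairs
        ]
        c = make_cohort(_quiet(n_genes=6, seed=6))
        assert [g.cds for g in a.genes] != [g.cds for g in c.genes]

    def test_gc4_declines_with_exon_number(self):
        cfg = _quiet(n_genes=500, seed=2, planted_nd=0.0)
        cohort = make_cohort(cfg)
        rho, p = spearmanr(
            [g.gc4 for g in cohort.genes], [g.exon_count for g in cohort.genes]
        )
        assert rho < 0 and p < 0.05

    def test_planted_coverage_exceeds_background(self):
        """Planted cohorts carry about planted_nd more motif coverage than
        unplanted cohorts drawn from the same seed."""
        cfg0 = _quiet(n_genes=40, seed=9, planted_nd=0.0)
        cfg1 = _quiet(n_genes=40, seed=9, planted_nd=0.5)
        codes = cfg0.motifs().codes
        def mean_density(cohort):
            return float(
                np.mean(
                    [
                        KmerIndex(g.cds).covered_count(codes) / g.cds_length
                        for g in cohort.genes
                    ]
                )
            )
        d0 = mean_density(make_cohort(cfg0))
        d1 = mean_density(make_cohort(cfg1))
        assert d1 / d0 - 1.0 == pytest.approx(0.5, abs=0.15)

    def test_infeasible_planting_rejected(self):
        cfg = _quiet(n_genes=3, seed=1, planted_nd=60.0,
                     cds_length_law=("constant", 110))
        with pytest.raises(ValueError):
            make_cohort(cfg)

    def test_architecture_invariants(self, small_cohort):
        for g in small_cohort.genes:
            assert g.exon_intervals[0][0] == 0
            assert g.exon_intervals[-1][1] == g.cds_length
            assert len(g.intron_lengths) == g.exon_count - 1
            assert (g.mean_intron_size == 0) == (g.exon_count == 1)


class TestEvolveOrtholog:
    def test_zero_rate_identity(self):
        cfg = _quiet(n_genes=4, seed=3, ds_background=0.0)
        cohort = make_cohort(cfg)
        for aln in cohort.ortholog_pairs:
            assert aln.focal_row == aln.ortholog_row

    def test_translation_invariance(self, small_cohort):
        for aln in small_cohort.ortholog_pairs:
            assert translate(aln.focal_row) == translate(aln.ortholog_row)

    def test_background_rate_recovered(self):
        cfg = _quiet(n_genes=40, seed=4, ese_ds_scaling=1.0, ds_background=0.1)
        cohort = make_cohort(cfg)
        rates = [pairwise_codon_rates(a).ds for a in cohort.ortholog_pairs]
        assert np.mean(rates) == pytest.approx(0.1, abs=0.01)
        assert all(pairwise_codon_rates(a).dn == 0 for a in cohort.ortholog_pairs)

    def test_scaling_recovered_inside_motifs(self):
        """dS inside motif hits / outside recovers ese_ds_scaling = 0.5."""
        from esescan.genetics import (
            IS_STOP,
            SD_TABLE,
            SYN_SITES,
            codons_of,
            encode,
            jukes_cantor,
        )

        cfg = _quiet(
            n_genes=100, seed=7, ese_ds_scaling=0.5,
            cds_length_law=("lognormal_codons", float(np.log(400)), 0.2, 150),
        )
        cohort = make_cohort(cfg)
        codes = cfg.motifs().codes
        acc = {True: [0.0, 0.0], False: [0.0, 0.0]}
        for aln in cohort.ortholog_pairs:
            c1 = codons_of(encode(aln.focal_row))
            c2 = codons_of(encode(aln.ortholog_row))
            mask = KmerIndex(aln.focal_row).coverage_mask(codes)
            third_in = mask[2::3]
            ok = ~IS_STOP[c1]
            for inside in (True, False):
                sel = ok & (third_in == inside)
                acc[inside][0] += (SYN_SITES[c1] + SYN_SITES[c2])[sel].sum() / 2
                acc[inside][1] += SD_TABLE[c1, c2][sel].sum()
        ratio = jukes_cantor(acc[True][1] / acc[True][0]) / jukes_cantor(
            acc[False][1] / acc[False][0]
        )
        assert ratio == pytest.approx(0.5, abs=0.1)


class TestSimulateSnps:
    def test_zero_rate_empty(self, small_cohort):
        cfg = SyntheticConfig(n_genes=1, seed=1, snp_rate=0.0)
        rng = substream(1, "snps")
        assert simulate_snps(small_cohort.genes[0], cfg, rng) == []

    def test_records_are_consistent(self, small_cohort):
        for s in small_cohort.snp_table[:200]:
            gene = small_cohort.gene(s.gene_id)
            assert 0 <= s.cds_pos < gene.cds_length
            assert gene.cds[s.cds_pos] == s.ref
            assert s.alt != s.ref
            assert 0 < s.maf <= 0.5

    def _fractions(self, cfg, seed):
        rng = substream(seed, "snps")
        cohort_rng = substream(seed, "gene")
        cfg2 = SyntheticConfig(
            n_genes=1, seed=seed, planted_nd=cfg.planted_nd,
            rare_excess=cfg.rare_excess, snp_rate=cfg.snp_rate,
            retro_fraction=0.0, paralog_fraction=0.0,
        )
        cohort = make_cohort(cfg2)
        gene = cohort.genes[0]
        snps = simulate_snps(gene, cfg2, rng)
        mask = KmerIndex(gene.cds).coverage_mask(cfg2.motifs().codes)
        inside = [s for s in snps if mask[s.cds_pos]]
        outside = [s for s in snps if not mask[s.cds_pos]]
        thr = cfg2.maf_rare_threshold

        def frac(group):
            return (
                sum(s.maf < thr for s in group) / len(group) if group else np.nan
            )

        return frac(inside), frac(outside)

    def test_rare_excess_null_is_balanced(self):
        cfg = SyntheticConfig(n_genes=1, rare_excess=1.0, snp_rate=0.15)
        ins, outs = [], []
        for seed in range(30):
            i, o = self._fractions(cfg, seed)
            if not np.isnan(i) and not np.isnan(o):
                ins.append(i)
                outs.append(o)
        assert abs(np.mean(ins) - np.mean(outs)) < 0.05

    def test_rare_excess_three_separates(self):
        cfg = SyntheticConfig(n_genes=1, rare_excess=3.0, snp_rate=0.15)
        wins = total = 0
        for seed in range(40):
            i, o = self._fractions(cfg, seed)
            if not np.isnan(i) and not np.isnan(o):
                total += 1
                wins += i > o
        assert total >= 30 and wins / total >= 0.85


class TestDeriveRetrocopy:
    def test_identity_copy(self, small_cohort, rng):
        parent = next(g for g in small_cohort.genes if g.exon_count >= 2)
        retro, interval = derive_retrocopy(parent, rng)
        assert retro.cds == parent.cds
        assert retro.exon_count == 1
        assert interval == (0, parent.cds_length)

    def test_motifs_inherited(self, small_cohort, rng, fixture_motifs):
        parent = next(g for g in small_cohort.genes if g.exon_count >= 2)
        retro, _ = derive_retrocopy(parent, rng)
        assert (
            find_hits(retro.cds, fixture_motifs, "r").covered
            >= find_hits(parent.cds, fixture_motifs, "p").covered
        )

    def test_self_overlap_is_broad_call(self, small_cohort, rng):
        from esescan import broad_retrocopy_calls

        parent = next(g for g in small_cohort.genes if g.exon_count >= 2)
        retro, interval = derive_retrocopy(parent, rng)
        calls = broad_retrocopy_calls(
            {retro.gene_id: ("chrS", *interval)},
            [("chrS", *interval, "anno")],
        )
        assert calls[0].tier == "broad" and calls[0].overlap_fraction == 1.0

    def test_intronless_parent_rejected(self, small_cohort, rng):
        parent = next(g for g in small_cohort.genes if g.exon_count == 1)
        with pytest.raises(ValueError):
            derive_retrocopy(parent, rng)
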