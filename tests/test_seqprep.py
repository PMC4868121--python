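"""CDS validation, NG86 rates, alignment back-threading, family clustering."""

import math

import numpy as np
import pytest

from esescan import (
    CodonAlignment,
    GeneRecord,
    cluster_families,
    pairwise_codon_rates,
    validate_cds,
)
from esescan.seqprep import (
    align_cds_pair,
    family_map,
    ortholog_pair_passes,
    rates_from_codon_arrays,
    similarity_evalue,
)


class TestValidateCds:
    def test_minimal_valid_orf(self):
        assert validate_cds("ATG" + "GCT" * 98 + "TAA").passed

    def test_premature_stop(self):
        seq = "ATG" + "TAA" + "GCT" * 97 + "TAA"
        assert "premature_stop" in validate_cds(seq).reasons

    def test_297nt_too_short(self):
        seq = "ATG" + "GCT" * 97 + "TAA"
        assert len(seq) == 297
        assert validate_cds(seq).reasons == ("too_short",)

    @pytest.mark.parametrize(
        "seq,reason",
        [
            ("ATG" + "GCT" * 98 + "GCA", "no_terminal_stop"),
            ("CTG" + "GCT" * 98 + "TAA", "no_start"),
            ("ATG" + "GCN" * 98 + "TAA", "noncanonical_base"),
            ("ATG" + "GCT" * 98 + "TAAC", "length_not_multiple_of_3"),
        ],
    )
    def test_individual_failures(self, seq, reason):
        assert reason in validate_cds(seq).reasons


class TestPairwiseRates:
    def test_identical_rows_zero(self):
        aln = CodonAlignment("a", "b", "GAAGCT" * 60, "GAAGCT" * 60)
        r = pairwise_codon_rates(aln)
        assert r.ds == 0.0 and r.dn == 0.0
        assert math.isnan(r.ratio)  # undefined but passes ratio filters

    def test_hand_computed_ng86(self):
        # 10 GAA codons, one synonymous GAA->GAG: S=10/3, pS=0.3
        aln = CodonAlignment("a", "b", "GAA" * 10, "GAA" * 9 + "GAG")
        r = pairwise_codon_rates(aln)
        assert r.ds == pytest.approx(-0.75 * math.log(0.6))

    def test_saturation_marked_undefined(self):
        # every codon differs synonymously: pS = 1 >= 0.75
        aln = CodonAlignment("a", "b", "GAA" * 10, "GAG" * 10)
        assert math.isnan(pairwise_codon_rates(aln).ds)

    def test_symmetry(self, rng):
        for _ in range(20):
            c1 = rng.integers(0, 64, size=40)
            c2 = np.where(rng.random(40) < 0.2, rng.integers(0, 64, size=40), c1)
            try:
                a = rates_from_codon_arrays(c1, c2)
                b = rates_from_codon_arrays(c2, c1)
            except ValueError:
                continue
            for u, v in ((a.ds, b.ds), (a.dn, b.dn)):
                assert (math.isnan(u) and math.isnan(v)) or u == pytest.approx(v)

    def test_matches_biopython_ng86(self, rng):
        """Cross-check against Bio.codonalign's independent NG86.

        Restricted to pairs whose differing codons differ at exactly one
        position: site counting and difference counting are then
        convention-free (multi-hit pathway weighting around stop codons is a
        known point of divergence between NG86 implementations).
        """
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from esescan.genetics import SENSE_CODONS, CODONS, IS_STOP
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        def mutate_one_base(codon):
            pos = int(rng.integers(3))
            shift = (16, 4, 1)[pos]
            cur = (codon // shift) % 4
            alt = int(rng.integers(3))
            alt = alt if alt < cur else alt + 1
            return codon + (alt - cur) * shift

        checked = 0
        attempts = 0
        while checked < 100 and attempts < 1000:
            attempts += 1
            c1 = rng.choice(SENSE_CODONS, size=30)
            c2 = c1.copy()
            for i in np.flatnonzero(rng.random(30) < 0.15):
                alt = mutate_one_base(int(c1[i]))
                if not IS_STOP[alt]:
                    c2[i] = alt
            ours = rates_from_codon_arrays(c1, c2)
            if math.isnan(ours.ds) or math.isnan(ours.dn):
                continue
            s1 = "".join(CODONS[i] for i in c1)
            s2 = "".join(CODONS[i] for i in c2)
            dn, ds = cal_dn_ds(CodonSeq(s1), CodonSeq(s2), method="NG86")
            if ds < 0 or dn < 0:  # Biopython's own undefined sentinel
                continue
            assert ours.ds == pytest.approx(ds, abs=1e-3)
            assert ours.dn == pytest.approx(dn, abs=1e-3)
            checked += 1
        assert checked >= 100

    def test_gap_and_stop_columns_excluded(self):
        aln = CodonAlignment("a", "b", "GAA---TAAGCT", "GAAGCTTAAGCT")
        r = pairwise_codon_rates(aln)
        assert r.ds == 0.0 and r.dn == 0.0

    def test_no_countable_columns_errors(self):
        with pytest.raises(ValueError):
            pairwise_codon_rates(CodonAlignment("a", "b", "---", "GAA"))


class TestAlignCdsPair:
    def test_backthreading_is_codon_exact(self):
        f = "ATG" + "GAAGCTTGGCCT" * 3 + "TAA"
        o = "ATG" + "GAAGCTCCT" * 3 + "TAA"  # TGG codon missing
        aln = align_cds_pair("f", f, "o", o)
        assert aln.focal_row.replace("-", "") == f[:-3]
        assert aln.ortholog_row.replace("-", "") == o[:-3]
        assert len(aln.focal_row) % 3 == 0


def _gene(gid, seq, tid=None):
    return GeneRecord(gid, tid or f"T_{gid}", seq, 1, ((0, len(seq)),), ())


class TestClusterFamilies:
    def _related_set(self, rng):
        base = "ATG" + "".join(rng.choice(list("ACGT"), size=600)) + "TAA"
        variant = base[:300] + base[300:]  # identical copy
        other = "ATG" + "".join(rng.choice(list("ACGT"), size=600)) + "TAA"
        return [_gene("A", base), _gene("B", variant), _gene("D", other)]

    def test_components(self, rng):
        genes = self._related_set(rng)
        fams = cluster_families(genes)
        parts = sorted(sorted(f.member_ids) for f in fams)
        assert parts == [["A", "B"], ["D"]]

    def test_transitive_closure_via_precomputed_edges(self):
        genes = [_gene(g, "ATG" + "GCT" * 120 + "TAA") for g in "ABCD"]
        fams = cluster_families(genes, edges=[("A", "B"), ("B", "C")])
        parts = sorted(sorted(f.member_ids) for f in fams)
        assert parts == [["A", "B", "C"], ["D"]]

    def test_no_edges_all_singletons(self):
        genes = [_gene(g, "ATG" + "GCT" * 120 + "TAA") for g in "AB"]
        fams = cluster_families(genes, edges=[])
        assert all(len(f.member_ids) == 1 for f in fams)

    def test_order_invariance(self, rng):
        genes = self._related_set(rng)
        a = cluster_families(genes)
        b = cluster_families(genes[::-1])
        assert sorted(tuple(sorted(f.member_ids)) for f in a) == sorted(
            tuple(sorted(f.member_ids)) for f in b
        )

    def test_representative_longest_then_alphabetical(self):
        g1 = _gene("g1", "ATG" + "GCT" * 99 + "TAA", tid="T2")
        g2 = _gene("g2", "ATG" + "GCT" * 99 + "TAA", tid="T1")
        fams = cluster_families([g1, g2], edges=[("g1", "g2")])
        assert fams[0].representative_id == "g2"  # owner of T1
        g3 = _gene("g3", "ATG" + "GCT" * 150 + "TAA", tid="T9")
        fams = cluster_families([g1, g2, g3], edges=[("g1", "g2"), ("g2", "g3")])
        assert fams[0].representative_id == "g3"  # longest wins over T1

    def test_family_map_covers_all(self, rng):
        genes = self._related_set(rng)
        fams = cluster_families(genes)
        fmap = family_map(fams)
        assert set(fmap) == {"A", "B", "D"}

    def test_unrelated_sequences_not_significant(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=500))
        b = "".join(rng.choice(list("ACGT"), size=500))
        assert similarity_evalue(a, a) < 1e-4
        assert similarity_evalue(a, b) > 1e-4


class TestOrthologFilter:
    def test_modes(self):
        from esescan.seqprep import RatePair

        assert not ortholog_pair_passes(RatePair(0.25, 0.01), "human")
        assert ortholog_pair_passes(RatePair(0.25, 0.01), "mouse")
        assert not ortholog_pair_passes(RatePair(0.1, 0.06), "human")  # ratio 0.6
        assert ortholog_pair_passes(RatePair(0.0, 0.0), "human")  # undefined ratio
        assert not ortholog_pair_passes(RatePair(float("nan"), 0.0), "human")
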