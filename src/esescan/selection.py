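"""Purifying-selection tests inside motif regions.

Motif-hit blocks are cut from codon alignments and repaired to whole codons:
an incomplete final codon is trimmed; an incomplete initial codon is expanded
with 1-2 upstream bases, and if the expanded codon encodes Leu or Arg its
first two bases are rewritten to GA (third position twofold degenerate) or GC
(fourfold), in both rows unless the ortholog codon is a gap. This keeps the
block's original synonymous third position without importing a spurious
synonymous site at the block edge. Blocks are concatenated across genes and a
single NG86 dS computed; the same protocol over dinucleotide-matched control
motif sets yields the null distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from . import genetics
from .motifs import MotifSet
from .nulls import ControlSetCollection
from .scan import KmerIndex
from .seqprep import CodonAlignment, GeneRecord, ParalogFamily
from .stats import EmpiricalTest, empirical_p


# ---------------------------------------------------------------------------
# block extraction
# ---------------------------------------------------------------------------


@dataclass
class CodonBlockAlignment:
    """Codon-complete focal/ortholog block pairs cut from one alignment."""

    gene_id: str
    blocks: list[tuple[np.ndarray, np.ndarray]]
    intervals: list[tuple[int, int]]  # CDS intervals (post-repair) per block
    repaired_positions: list[int]  # CDS positions of rewritten initial codons

    def concatenated(self) -> tuple[np.ndarray, np.ndarray]:
        if not self.blocks:
            return (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
        f = np.concatenate([b[0] for b in self.blocks])
        o = np.concatenate([b[1] for b in self.blocks])
        return f, o


def _mask_runs(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    m = mask.astype(np.int8)
    d = np.diff(m)
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if len(mask) and mask[0]:
        starts = np.concatenate([[0], starts])
    if len(mask) and mask[-1]:
        ends = np.concatenate([ends, [len(mask)]])
    return starts, ends


def _repair_pair(f_codon: int, o_codon: int) -> tuple[int, int, bool]:
    rep = int(genetics.REPAIR_MAP[f_codon])
    if rep == f_codon:
        return f_codon, o_codon, False
    prefix = rep - rep % 4
    o_rep = prefix + o_codon % 4 if o_codon >= 0 else o_codon
    return rep, o_rep, True


def extract_ese_blocks(aln: CodonAlignment, mask: np.ndarray) -> CodonBlockAlignment:
    """Codon-complete blocks for each contiguous masked run of the focal CDS.

    ``mask`` is defined on the focal row's ungapped coordinates (its length
    may not exceed the ungapped focal length).
    """
    focal_cod, ortho_cod = aln.codon_columns()
    # alignment column of each focal codon
    col_of = np.flatnonzero(focal_cod >= 0)
    focal_ungapped = focal_cod[col_of]
    n_cod = len(focal_ungapped)
    if len(mask) > 3 * n_cod:
        raise ValueError("mask longer than ungapped focal sequence")
    starts, ends = _mask_runs(np.asarray(mask, dtype=bool))
    blocks, intervals, repaired = [], [], []
    for s, e in zip(starts, ends):
        s3 = s - s % 3
        e3 = e - e % 3
        if e3 <= s3:
            continue
        cs, ce = s3 // 3, min(e3 // 3, n_cod)
        if ce <= cs:
            continue
        f = focal_ungapped[cs:ce].copy()
        o = ortho_cod[col_of[cs:ce]].copy()
        if s % 3 != 0:
            f0, o0, changed = _repair_pair(int(f[0]), int(o[0]))
            f[0], o[0] = f0, o0
            if changed:
                repaired.append(int(s3))
        blocks.append((f, o))
        intervals.append((int(s3), int(3 * ce)))
    return CodonBlockAlignment(aln.focal_id, blocks, intervals, repaired)


# ---------------------------------------------------------------------------
# concatenated dS over many genes, observed vs control motif sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DsEnrichment:
    observed_ds: float
    null_ds: np.ndarray
    normalized_ds: float  # (observed - null mean) / null mean
    test: EmpiricalTest  # one-tailed for a reduction in dS

    @property
    def reduction(self) -> float:
        """Fractional slowdown relative to the dinucleotide expectation."""
        return -self.normalized_ds


class ConcatenatedDsAnalysis:
    """Precomputed per-gene state for repeated masked-dS evaluations.

    One instance holds, per representative gene, the focal ungapped codon
    array, the ortholog codon per focal codon, and a sorted 6-mer index;
    ``ds_for_codes`` then evaluates the concatenated NG86 dS of the motif-hit
    blocks of an arbitrary motif-code set in vectorized form.
    """

    def __init__(self, alignments: Sequence[CodonAlignment]):
        if not alignments:
            raise ValueError("no alignments")
        self._genes = []
        for aln in alignments:
            focal_cod, ortho_cod = aln.codon_columns()
            col_of = np.flatnonzero(focal_cod >= 0)
            focal_ungapped = focal_cod[col_of]
            ortho_by_focal = ortho_cod[col_of]
            seq_arr = genetics.codon_array_to_bases(
                np.where(focal_ungapped >= 0, focal_ungapped, 0)
            )
            self._genes.append(
                (KmerIndex(seq_arr), focal_ungapped, ortho_by_focal)
            )

    def _counts_for_mask(
        self, mask: np.ndarray, focal: np.ndarray, ortho: np.ndarray
    ) -> tuple[float, float]:
        starts, ends = _mask_runs(mask)
        if len(starts) == 0:
            return 0.0, 0.0
        s3 = starts - starts % 3
        e3 = np.minimum(ends - ends % 3, 3 * len(focal))
        keep = e3 > s3
        s3, e3 = s3[keep], e3[keep]
        incomplete = (starts[keep] % 3) != 0
        cs, ce = s3 // 3, e3 // 3
        lens = ce - cs
        total = int(lens.sum())
        offsets = np.concatenate([[0], np.cumsum(lens)[:-1]])
        idx = np.arange(total) - np.repeat(offsets, lens) + np.repeat(cs, lens)
        f = focal[idx]
        o = ortho[idx]
        first = offsets[incomplete]
        if len(first):
            rep = genetics.REPAIR_MAP[f[first]]
            changed = rep != f[first]
            prefix = rep - rep % 4
            o_first = o[first]
            o_new = np.where(
                changed & (o_first >= 0), prefix + o_first % 4, o_first
            )
            f[first] = rep
            o[first] = o_new
        valid = (o >= 0) & ~genetics.IS_STOP[f] & ~genetics.IS_STOP[np.maximum(o, 0)]
        f, o = f[valid], o[valid]
        if len(f) == 0:
            return 0.0, 0.0
        S = float((genetics.SYN_SITES[f] + genetics.SYN_SITES[o]).sum()) / 2.0
        Sd = float(genetics.SD_TABLE[f, o].sum())
        return S, Sd

    def ds_for_codes(self, codes: np.ndarray) -> float:
        """Concatenated NG86 dS of the motif-hit blocks of one code set."""
        S = Sd = 0.0
        for index, focal, ortho in self._genes:
            mask = index.coverage_mask(codes)
            s, sd = self._counts_for_mask(mask, focal, ortho)
            S += s
            Sd += sd
        if S <= 0:
            raise ValueError("empty concatenation: no motif-hit blocks")
        return genetics.jukes_cantor(Sd / S)


def concatenated_ds(
    alignments: Sequence[CodonAlignment],
    motifs: MotifSet,
    controls: ControlSetCollection,
) -> DsEnrichment:
    """Observed concatenated dS in motif regions against the control null."""
    analysis = ConcatenatedDsAnalysis(alignments)
    observed = analysis.ds_for_codes(motifs.codes)
    null = np.array([analysis.ds_for_codes(c) for c in controls.code_arrays()])
    finite = null[~np.isnan(null)]
    mean = float(finite.mean()) if len(finite) else float("nan")
    nd = (observed - mean) / mean if mean > 0 else float("nan")
    test = empirical_p(observed, finite, "less")
    return DsEnrichment(observed, null, nd, test)


# ---------------------------------------------------------------------------
# SNP statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SnpRecord:
    gene_id: str
    cds_pos: int  # 0-based
    ref: str
    alt: str
    maf: float
    consequence: str  # "synonymous" | "nonsynonymous"

    def __post_init__(self):
        if not 0.0 < self.maf <= 0.5:
            raise ValueError("maf must lie in (0, 0.5]")


@dataclass(frozen=True)
class SnpStatistics:
    """Median-over-replicates SNP statistics in motif regions.

    ``density_4d`` uses synonymous SNPs at fourfold sites inside the mask over
    fourfold sites inside the mask; ``density_4d_all`` counts all SNPs at
    those sites. ``low_maf_fraction`` is the share of masked segregating sites
    below the MAF threshold (all SNPs). Empirical p-values compare against the
    control motif sets (density: one-tailed depletion; rare fraction:
    one-tailed excess); medians are over representative-redraw replicates.
    """

    density_4d: float
    density_4d_all: float
    low_maf_fraction: float
    p_density: float
    p_low_maf: float
    replicate_fractions: tuple[float, ...]
    replicate_densities: tuple[float, ...]


def _per_gene_snp_arrays(
    genes: Sequence[GeneRecord], snps: Iterable[SnpRecord]
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    by_gene: dict[str, list[SnpRecord]] = {g.gene_id: [] for g in genes}
    for s in snps:
        if s.gene_id in by_gene:
            by_gene[s.gene_id].append(s)
    out = {}
    for gid, recs in by_gene.items():
        pos = np.array([r.cds_pos for r in recs], dtype=np.int64)
        maf = np.array([r.maf for r in recs])
        syn = np.array([r.consequence == "synonymous" for r in recs], dtype=bool)
        out[gid] = (pos, maf, syn)
    return out


def snp_statistics(
    genes: Sequence[GeneRecord],
    snps: Iterable[SnpRecord],
    motifs: MotifSet,
    controls: ControlSetCollection,
    families: Sequence[ParalogFamily] | None = None,
    maf_threshold: float = 1.0 / 2000.0,
    n_replicates: int = 10,
    rng: np.random.Generator | None = None,
) -> SnpStatistics:
    """SNP density at fourfold sites and low-MAF fraction in motif regions.

    Each replicate redraws one random member per paralogous family; medians
    of the statistics and of their empirical p-values are reported. Replicates
    with no masked SNPs are undefined-marked and excluded from medians.
    """
    if rng is None:
        rng = np.random.default_rng()
    genes = list(genes)
    snp_arrays = _per_gene_snp_arrays(genes, snps)
    by_id = {g.gene_id: g for g in genes}
    code_sets = [motifs.codes] + controls.code_arrays()
    n_sets = len(code_sets)

    # per gene x code-set summary counts
    per_gene: dict[str, np.ndarray] = {}
    for g in genes:
        index = KmerIndex(g.cds)
        deg = genetics.annotate_degeneracy(g.cds)
        four = deg == 4
        pos, maf, syn = snp_arrays[g.gene_id]
        rare = maf < maf_threshold
        counts = np.zeros((n_sets, 5))
        for k, codes in enumerate(code_sets):
            mask = index.coverage_mask(codes)
            in_mask = mask[pos] if len(pos) else np.zeros(0, dtype=bool)
            counts[k, 0] = np.count_nonzero(mask & four)  # 4-fold sites in mask
            if len(pos):
                at4 = four[pos] & in_mask
                counts[k, 1] = np.count_nonzero(at4 & syn)  # syn SNPs at 4-fold
                counts[k, 2] = np.count_nonzero(at4)  # all SNPs at 4-fold
                counts[k, 3] = np.count_nonzero(in_mask)  # masked SNPs
                counts[k, 4] = np.count_nonzero(in_mask & rare)  # masked rare
        per_gene[g.gene_id] = counts

    if families is None:
        member_lists = [[g.gene_id] for g in genes]
    else:
        member_lists = [sorted(f.member_ids) for f in families]

    rep_fracs, rep_dens, rep_dens_all = [], [], []
    rep_p_frac, rep_p_dens = [], []
    for _ in range(n_replicates):
        chosen = [members[rng.integers(len(members))] for members in member_lists]
        total = sum((per_gene[gid] for gid in chosen if gid in by_id), np.zeros((n_sets, 5)))
        with np.errstate(invalid="ignore", divide="ignore"):
            dens_syn = total[:, 1] / total[:, 0]
            dens_all = total[:, 2] / total[:, 0]
            frac = total[:, 4] / total[:, 3]
        if total[0, 3] > 0:
            rep_fracs.append(float(frac[0]))
            ok = ~np.isnan(frac[1:])
            if ok.any():
                rep_p_frac.append(empirical_p(frac[0], frac[1:][ok], "greater").p)
        if total[0, 0] > 0 and not math.isnan(dens_syn[0]):
            rep_dens.append(float(dens_syn[0]))
            rep_dens_all.append(float(dens_all[0]))
            ok = ~np.isnan(dens_syn[1:])
            if ok.any():
                rep_p_dens.append(empirical_p(dens_syn[0], dens_syn[1:][ok], "less").p)

    def med(values):
        return float(np.median(values)) if values else float("nan")

    return SnpStatistics(
        density_4d=med(rep_dens),
        density_4d_all=med(rep_dens_all),
        low_maf_fraction=med(rep_fracs),
        p_density=med(rep_p_dens),
        p_low_maf=med(rep_p_frac),
        replicate_fractions=tuple(rep_fracs),
        replicate_densities=tuple(rep_dens),
    )
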