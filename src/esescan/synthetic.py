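"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates, at configurable strength: a negative GC4 gradient
with exon number (single-exon genes most GC-rich at fourfold sites),
purine-rich hexamer motifs planted at a controlled fractional excess over
their background occurrence with a positional bias toward exon ends, ortholog
pairs whose synonymous divergence is reduced inside motif hits, SNPs with an
excess of rare alleles inside motif hits, and intronless retrocopies that
inherit their parent's CDS verbatim.

All randomness flows through named substreams of one seed, so stages can be
re-run independently yet reproducibly; an identical seed yields a
byte-identical cohort.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from . import genetics
from .motifs import MOTIF_LENGTH, MotifSet, packaged_fixture_set
from .scan import KmerIndex
from .seqprep import CodonAlignment, GeneRecord
from .selection import SnpRecord

CHROM = "chrS"
_INTERGENIC_GAP = 1000
_MIN_EXON_BP = 48


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible random stream named after a pipeline stage."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    Distribution laws are small tagged tuples:
    ``exon_number_law = ("mixture_poisson", p_intronless, mean_extra_exons)``
    draws 1 with probability ``p_intronless`` and ``2 + Poisson(mean)``
    otherwise; ``cds_length_law = ("lognormal_codons", log_median, sigma,
    min_codons)`` draws a codon count (CDS length is three times that,
    always a multiple of 3 and at least 300 nt).
    """

    n_genes: int = 200
    exon_number_law: tuple = ("mixture_poisson", 0.2, 6.0)
    gc4_slope: float = -0.012  # change in expected GC4 per added exon
    gc4_intercept: float = 0.62
    gc4_noise_sd: float = 0.05
    cds_length_law: tuple = ("lognormal_codons", float(np.log(600.0)), 0.35, 100)
    motif_set: MotifSet | None = None  # None -> packaged synthetic fixture
    planted_nd: float = 0.25  # target fractional excess of motif coverage
    end_bias: float = 2.0  # planting rate in exon-end windows vs cores
    ds_background: float = 0.16  # expected synonymous divergence per site
    ese_ds_scaling: float = 0.8  # dS multiplier inside motif hits
    snp_rate: float = 0.02  # per-site segregation probability
    rare_excess: float = 1.3  # multiplier on rare-allele prob inside motifs
    rare_base_prob: float = 0.28  # background probability a SNP is rare
    maf_rare_threshold: float = 1.0 / 2000.0
    paralog_fraction: float = 0.05  # genes generated as near-copies
    retro_fraction: float = 0.05  # multi-exon genes that spawn a retrocopy
    seed: int = 0

    def __post_init__(self):
        for name in ("snp_rate", "rare_base_prob", "ese_ds_scaling"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.planted_nd < 0:
            raise ValueError("planted_nd must be >= 0")
        if self.ds_background < 0 or self.ds_background >= 0.75:
            raise ValueError("ds_background out of the JC-correctable range")
        if self.end_bias <= 0 or self.rare_excess <= 0:
            raise ValueError("end_bias and rare_excess must be positive")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")

    def motifs(self) -> MotifSet:
        return self.motif_set if self.motif_set is not None else packaged_fixture_set()

    def echo(self) -> str:
        d = asdict(self)
        ms = self.motifs()
        d["motif_set"] = {"name": ms.name, "motifs": list(ms.motifs)}
        return json.dumps(d, indent=1, sort_keys=True)


@dataclass
class SyntheticCohort:
    genes: list[GeneRecord]
    ortholog_pairs: list[CodonAlignment]
    snp_table: list[SnpRecord]
    retro_annotations: list[tuple[str, int, int, str]]  # chrom, start, end, name
    gene_intervals: dict[str, tuple[str, int, int]]  # genomic span per gene
    truth: pd.DataFrame
    config: SyntheticConfig

    def gene(self, gene_id: str) -> GeneRecord:
        return next(g for g in self.genes if g.gene_id == gene_id)

    def alignment(self, gene_id: str) -> CodonAlignment:
        return next(a for a in self.ortholog_pairs if a.focal_id == gene_id)


# ---------------------------------------------------------------------------
# sequence construction
# ---------------------------------------------------------------------------


def _draw_exon_count(law: tuple, rng: np.random.Generator) -> int:
    tag = law[0]
    if tag == "mixture_poisson":
        _, p1, mean = law
        if rng.random() < p1:
            return 1
        return 2 + int(rng.poisson(mean))
    if tag == "constant":
        return int(law[1])
    raise ValueError(f"unknown exon_number_law {tag!r}")


def _draw_n_codons(law: tuple, rng: np.random.Generator) -> int:
    tag = law[0]
    if tag == "lognormal_codons":
        _, mu, sigma, min_codons = law
        n = int(round(np.exp(rng.normal(mu, sigma))))
        return max(int(min_codons), n)
    if tag == "constant":
        return int(law[1])
    raise ValueError(f"unknown cds_length_law {tag!r}")


def _random_cds_codons(
    n_codons: int, target_gc4: float, rng: np.random.Generator
) -> np.ndarray:
    """Codon array (start..stop) with third positions biased toward target GC4."""
    aas = rng.choice(list(genetics.AA_TO_CODONS), size=n_codons - 2)
    codons = np.empty(n_codons, dtype=np.int64)
    codons[0] = genetics.CODON_TO_INT["ATG"]
    codons[-1] = genetics.STOP_CODONS[rng.integers(3)]
    for i, aa in enumerate(aas):
        options = genetics.AA_TO_CODONS[aa]
        third = options % 4
        gc = (third == 1) | (third == 2)
        w = np.where(gc, target_gc4, 1.0 - target_gc4)
        w = w / w.sum()
        codons[i + 1] = rng.choice(options, p=w)
    return codons


def _exon_structure(
    length: int, exon_count: int, rng: np.random.Generator
) -> tuple[tuple[tuple[int, int], ...], tuple[int, ...]]:
    exon_count = min(exon_count, max(1, length // _MIN_EXON_BP))
    if exon_count == 1:
        return ((0, length),), ()
    # internal boundaries with a minimum exon size
    slack = length - exon_count * _MIN_EXON_BP
    cuts = np.sort(rng.integers(0, slack + 1, size=exon_count - 1))
    bounds = [0]
    for i, c in enumerate(cuts):
        bounds.append((i + 1) * _MIN_EXON_BP + int(c))
    bounds.append(length)
    intervals = tuple((bounds[i], bounds[i + 1]) for i in range(exon_count))
    introns = tuple(
        int(np.round(np.exp(rng.normal(np.log(1500.0), 1.0))))
        for _ in range(exon_count - 1)
    )
    return intervals, introns


def _end_window_weight(
    length: int, exon_intervals, end_bias: float
) -> np.ndarray:
    """Per-start planting weight: higher within 69 bp of an exon boundary."""
    w = np.ones(max(0, length - MOTIF_LENGTH + 1))
    if len(w) == 0:
        return w
    pos = np.arange(len(w))
    near = np.zeros(len(w), dtype=bool)
    for (a, b) in exon_intervals:
        near |= (pos >= a) & (pos < a + 69)
        near |= (pos >= b - 69 - MOTIF_LENGTH) & (pos < b)
    w[near] = end_bias
    return w


def _plant_motifs(
    arr: np.ndarray,
    motifs: MotifSet,
    n_plant: int,
    weights: np.ndarray,
    rng: np.random.Generator,
) -> list[int]:
    """Overwrite ``n_plant`` non-overlapping motif instances into a CDS.

    Planting respects ORF validity: the start and stop codons are never
    touched and no in-frame stop codon may result; positions where this is
    impossible are skipped. Returns the planted start offsets.
    """
    L = len(arr)
    protected = np.zeros(L, dtype=bool)
    protected[:3] = True
    protected[-3:] = True
    planted: list[int] = []
    if n_plant == 0:
        return planted
    w = weights.copy()
    w[: 3] = 0
    w[max(0, L - MOTIF_LENGTH - 2) :] = 0
    attempts = 0
    max_attempts = 200 * n_plant + 200
    motif_arrays = [genetics.encode(m) for m in motifs.motifs]
    while len(planted) < n_plant:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {n_plant} motif instances "
                f"(placed {len(planted)}): planted coverage target infeasible"
            )
        total = w.sum()
        if total <= 0:
            raise ValueError("no free positions left for motif planting")
        s = int(rng.choice(len(w), p=w / total))
        if protected[s : s + MOTIF_LENGTH].any():
            w[s] = 0
            continue
        m = motif_arrays[rng.integers(len(motif_arrays))]
        backup = arr[_codon_span(s)].copy()
        arr[s : s + MOTIF_LENGTH] = m
        if _fix_stops(arr, s, protected, rng):
            planted.append(s)
            protected[s : s + MOTIF_LENGTH] = True
            lo = max(0, s - MOTIF_LENGTH + 1)
            w[lo : s + MOTIF_LENGTH] = 0
        else:
            arr[_codon_span(s)] = backup
            w[s] = 0
    return planted


def _codon_span(s: int) -> slice:
    a = (s // 3) * 3
    b = ((s + MOTIF_LENGTH + 2) // 3) * 3
    return slice(a, b)


def _fix_stops(
    arr: np.ndarray, s: int, protected: np.ndarray, rng: np.random.Generator
) -> bool:
    """Repair in-frame stops in codons touched by a planting at ``s``.

    Only unprotected bases may change; returns False if a stop cannot be
    removed (caller rolls the planting back).
    """
    span = _codon_span(s)
    for c0 in range(span.start, span.stop, 3):
        codon = arr[c0 : c0 + 3]
        code = int(codon[0]) * 16 + int(codon[1]) * 4 + int(codon[2])
        if not genetics.IS_STOP[code]:
            continue
        free = [
            p
            for p in range(3)
            if not protected[c0 + p] and not (s <= c0 + p < s + MOTIF_LENGTH)
        ]
        fixed = False
        for p in rng.permutation(free) if free else []:
            for alt in rng.permutation(4):
                if alt == codon[p]:
                    continue
                trial = codon.copy()
                trial[p] = alt
                t_code = int(trial[0]) * 16 + int(trial[1]) * 4 + int(trial[2])
                if not genetics.IS_STOP[t_code]:
                    arr[c0 + p] = alt
                    fixed = True
                    break
            if fixed:
                break
        if not fixed:
            return False
    return True


# ---------------------------------------------------------------------------
# per-stage operations
# ---------------------------------------------------------------------------

# inverse Jukes-Cantor: the per-site substitution probability that makes the
# corrected NG86 estimate recover the configured divergence in expectation
def _p_sub_for_ds(ds: float) -> float:
    return 0.75 * (1.0 - np.exp(-4.0 * ds / 3.0))


def evolve_ortholog(
    gene: GeneRecord, config: SyntheticConfig, rng: np.random.Generator
) -> CodonAlignment:
    """Gap-free codon alignment of a gene against a synonymously mutated copy.

    Each codon position carrying synonymous alternatives substitutes with
    probability ``q * s_p`` (q inverts the JC correction at ds_background,
    s_p is the NG86 fractional synonymous-site weight of the position),
    scaled by ``ese_ds_scaling`` at positions inside motif hits. Only
    synonymous changes are made, so both rows translate identically.
    """
    arr = genetics.encode(gene.cds)
    cods = genetics.codons_of(arr)
    mask = KmerIndex(arr).coverage_mask(config.motifs().codes)
    q = _p_sub_for_ds(config.ds_background)
    out = cods.copy()
    n = len(cods)
    u = rng.random((n, 3))
    for i in range(n):
        c = int(out[i])
        neigh = genetics.SYN_NEIGHBORS[c]
        if not neigh:
            continue
        by_pos: dict[int, list[int]] = {}
        for p, alt in neigh:
            by_pos.setdefault(p, []).append(alt)
        for p, alts in by_pos.items():
            scale = config.ese_ds_scaling if mask[3 * i + p] else 1.0
            prob = q * scale * len(alts) / 3.0
            if u[i, p] < prob:
                c = int(alts[rng.integers(len(alts))])
        out[i] = c
    return CodonAlignment(
        gene.gene_id,
        f"{gene.gene_id}_ortholog",
        gene.cds,
        genetics.decode(genetics.codon_array_to_bases(out)),
    )


def simulate_snps(
    gene: GeneRecord, config: SyntheticConfig, rng: np.random.Generator
) -> list[SnpRecord]:
    """Segregating sites with a configurable excess of rare alleles in motifs.

    Every CDS position segregates with probability ``snp_rate``; the alt
    allele is a uniform different base and the consequence follows from the
    codon change. A variant is rare (MAF below the configured threshold) with
    probability ``rare_base_prob``, multiplied by ``rare_excess`` (capped at
    0.95) inside motif hits.
    """
    if config.snp_rate == 0:
        return []
    arr = genetics.encode(gene.cds)
    cods = genetics.codons_of(arr)
    mask = KmerIndex(arr).coverage_mask(config.motifs().codes)
    thr = config.maf_rare_threshold
    positions = np.flatnonzero(rng.random(len(arr)) < config.snp_rate)
    out = []
    for pos in positions:
        ref = int(arr[pos])
        alt = int(rng.integers(3))
        if alt >= ref:
            alt += 1
        ci = pos // 3
        p = pos % 3
        old = int(cods[ci])
        new = old + (alt - ref) * (16, 4, 1)[p]
        if genetics.IS_STOP[new]:
            continue  # segregating premature stops are not modelled
        consequence = (
            "synonymous" if genetics.AMINO[new] == genetics.AMINO[old] else "nonsynonymous"
        )
        p_rare = config.rare_base_prob * (config.rare_excess if mask[pos] else 1.0)
        p_rare = min(p_rare, 0.95)
        if rng.random() < p_rare:
            maf = rng.uniform(thr / 5.0, thr)
            maf = min(maf, np.nextafter(thr, 0.0))  # strictly below threshold
        else:
            maf = float(np.exp(rng.uniform(np.log(thr), np.log(0.5))))
        out.append(
            SnpRecord(
                gene.gene_id,
                int(pos),
                genetics.BASES[ref],
                genetics.BASES[alt],
                float(maf),
                consequence,
            )
        )
    return out


def derive_retrocopy(
    parent: GeneRecord,
    rng: np.random.Generator,
    n_substitutions: int = 0,
) -> tuple[GeneRecord, tuple[int, int]]:
    """Intronless copy of a multi-exon parent, motifs inherited verbatim.

    Optional substitutions are synonymous only, keeping dN at 0 (below any
    parent-matching bound). Returns the new record and its local genomic
    interval (the caller places it on the synthetic chromosome).
    """
    if parent.exon_count < 2:
        raise ValueError("retrocopies derive from multi-exon parents only")
    arr = genetics.encode(parent.cds)
    if n_substitutions:
        cods = genetics.codons_of(arr)
        candidates = [i for i in range(len(cods)) if genetics.SYN_NEIGHBORS[cods[i]]]
        chosen = rng.choice(
            len(candidates), size=min(n_substitutions, len(candidates)), replace=False
        )
        for idx in np.atleast_1d(chosen):
            i = candidates[int(idx)]
            _, alt = genetics.SYN_NEIGHBORS[cods[i]][
                rng.integers(len(genetics.SYN_NEIGHBORS[cods[i]]))
            ]
            cods[i] = alt
        arr = genetics.codon_array_to_bases(cods)
    cds = genetics.decode(arr)
    gid = f"{parent.gene_id}_retro"
    record = GeneRecord(
        gene_id=gid,
        transcript_id=f"T_{gid}",
        cds=cds,
        exon_count=1,
        exon_intervals=((0, len(cds)),),
        intron_lengths=(),
    )
    return record, (0, len(cds))


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------


def make_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Generate a full cohort: genes, orthologs, SNPs, retrocopies, truth."""
    motifs = config.motifs()
    rng_arch = substream(config.seed, "architecture")
    rng_seq = substream(config.seed, "sequence")
    rng_plant = substream(config.seed, "planting")
    rng_orth = substream(config.seed, "orthologs")
    rng_snp = substream(config.seed, "snps")
    rng_retro = substream(config.seed, "retrocopies")

    genes: list[GeneRecord] = []
    truth_rows = []
    for i in range(config.n_genes):
        gid = f"G{i:05d}"
        if genes and rng_seq.random() < config.paralog_fraction:
            parent = genes[rng_seq.integers(len(genes))]
            record, planted_count = _near_copy(parent, gid, rng_seq)
        else:
            record, planted_count = _fresh_gene(gid, config, motifs, rng_arch, rng_seq, rng_plant)
        genes.append(record)
        truth_rows.append(
            {
                "gene_id": gid,
                "planted_count": planted_count,
                "planted_density": planted_count * MOTIF_LENGTH / record.cds_length,
                "ds_scaling": config.ese_ds_scaling,
                "is_retrocopy": False,
                "parent_id": "",
            }
        )

    # retrocopies from multi-exon parents
    retro_annotations = []
    multi = [g for g in genes if g.exon_count >= 2]
    n_retro = int(round(config.retro_fraction * len(multi)))
    if n_retro:
        chosen = rng_retro.choice(len(multi), size=n_retro, replace=False)
        for idx in np.atleast_1d(chosen):
            parent = multi[int(idx)]
            record, _ = derive_retrocopy(parent, rng_retro)
            genes.append(record)
            truth_rows.append(
                {
                    "gene_id": record.gene_id,
                    "planted_count": 0,
                    "planted_density": float("nan"),
                    "ds_scaling": config.ese_ds_scaling,
                    "is_retrocopy": True,
                    "parent_id": parent.gene_id,
                }
            )

    # genomic layout along one synthetic chromosome
    gene_intervals: dict[str, tuple[str, int, int]] = {}
    cursor = 0
    for g in genes:
        span = g.cds_length + int(sum(g.intron_lengths))
        gene_intervals[g.gene_id] = (CHROM, cursor, cursor + span)
        cursor += span + _INTERGENIC_GAP
    for g in genes:
        if g.gene_id.endswith("_retro"):
            chrom, a, b = gene_intervals[g.gene_id]
            retro_annotations.append((chrom, a, b, f"retro_{g.gene_id}"))

    ortholog_pairs = [evolve_ortholog(g, config, rng_orth) for g in genes]
    snp_table = [s for g in genes for s in simulate_snps(g, config, rng_snp)]

    if truth_rows:
        truth = pd.DataFrame(truth_rows).set_index("gene_id")
    else:
        truth = pd.DataFrame(
            columns=[
                "planted_count", "planted_density", "ds_scaling",
                "is_retrocopy", "parent_id",
            ]
        )
    return SyntheticCohort(
        genes, ortholog_pairs, snp_table, retro_annotations, gene_intervals,
        truth, config,
    )


def _fresh_gene(
    gid: str,
    config: SyntheticConfig,
    motifs: MotifSet,
    rng_arch: np.random.Generator,
    rng_seq: np.random.Generator,
    rng_plant: np.random.Generator,
) -> tuple[GeneRecord, int]:
    exon_count = _draw_exon_count(config.exon_number_law, rng_arch)
    n_codons = _draw_n_codons(config.cds_length_law, rng_arch)
    target_gc4 = float(
        np.clip(
            config.gc4_intercept
            + config.gc4_slope * (exon_count - 1)
            + rng_arch.normal(0.0, config.gc4_noise_sd),
            0.15,
            0.9,
        )
    )
    codons = _random_cds_codons(n_codons, target_gc4, rng_seq)
    arr = genetics.codon_array_to_bases(codons)
    L = len(arr)
    exon_intervals, introns = _exon_structure(L, exon_count, rng_arch)
    exon_count = len(exon_intervals)

    planted_count = 0
    if config.planted_nd > 0:
        cov_bg = KmerIndex(arr).covered_count(motifs.codes)
        extra = config.planted_nd * cov_bg
        if extra > 0.9 * (L - cov_bg):
            raise ValueError(
                f"planted_nd={config.planted_nd} demands more motif coverage "
                f"than the sequence can hold (background {cov_bg}/{L} bases)"
            )
        n_plant = int(rng_plant.poisson(extra / MOTIF_LENGTH))
        if n_plant:
            weights = _end_window_weight(L, exon_intervals, config.end_bias)
            planted = _plant_motifs(arr, motifs, n_plant, weights, rng_plant)
            planted_count = len(planted)

    record = GeneRecord(
        gene_id=gid,
        transcript_id=f"T_{gid}",
        cds=genetics.decode(arr),
        exon_count=exon_count,
        exon_intervals=exon_intervals,
        intron_lengths=introns,
    )
    return record, planted_count


def _near_copy(
    parent: GeneRecord, gid: str, rng: np.random.Generator
) -> tuple[GeneRecord, int]:
    """A paralog: the parent CDS with ~2% synonymous divergence."""
    arr = genetics.encode(parent.cds)
    cods = genetics.codons_of(arr)
    for i in range(len(cods)):
        neigh = genetics.SYN_NEIGHBORS[int(cods[i])]
        if neigh and rng.random() < 0.06:
            _, alt = neigh[rng.integers(len(neigh))]
            cods[i] = alt
    record = GeneRecord(
        gene_id=gid,
        transcript_id=f"T_{gid}",
        cds=genetics.decode(genetics.codon_array_to_bases(cods)),
        exon_count=parent.exon_count,
        exon_intervals=parent.exon_intervals,
        intron_lengths=parent.intron_lengths,
    )
    return record, 0
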