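"""CDS validation, pairwise divergence, and paralogous-family clustering.

Divergence is estimated with an in-repo Nei–Gojobori (1986) counting scheme
plus Jukes–Cantor correction (the reference estimator for users with PAML
installed is codeml with model=0, but nothing here shells out). Sequence
similarity for family clustering uses a shared-12-mer prescreen followed by
local alignment with a Karlin–Altschul-style e-value threshold; families are
the connected components of the resulting similarity graph, found by seeded
expansion (equivalent to connected components and order-invariant).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from . import genetics

MIN_CDS_LEN = 300


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneRecord:
    """A CDS with its gene-architecture metrics.

    ``exon_intervals`` are 0-based half-open intervals on the CDS;
    ``intron_lengths`` has ``exon_count - 1`` entries (empty if intronless).
    """

    gene_id: str
    transcript_id: str
    cds: str
    exon_count: int
    exon_intervals: tuple[tuple[int, int], ...] = ()
    intron_lengths: tuple[int, ...] = ()

    @property
    def cds_length(self) -> int:
        return len(self.cds)

    @property
    def gc4(self) -> float:
        return genetics.gc4_fraction(self.cds)

    @property
    def mean_intron_size(self) -> float:
        if self.exon_count == 1 or not self.intron_lengths:
            return 0.0
        return float(np.mean(self.intron_lengths))

    @property
    def intron_density(self) -> float:
        return (self.exon_count - 1) / self.cds_length


VALIDATION_REASONS = (
    "too_short",
    "noncanonical_base",
    "no_start",
    "no_terminal_stop",
    "premature_stop",
    "length_not_multiple_of_3",
)


@dataclass(frozen=True)
class ValidationVerdict:
    reasons: tuple[str, ...]

    @property
    def passed(self) -> bool:
        return not self.reasons

    def __bool__(self) -> bool:
        return self.passed


def validate_cds(seq: str, min_len: int = MIN_CDS_LEN) -> ValidationVerdict:
    """ORF-integrity verdict: length, alphabet, start, stop, internal stops."""
    if not seq:
        raise ValueError("empty sequence")
    reasons = []
    seq = seq.upper()
    if len(seq) < min_len:
        reasons.append("too_short")
    canonical = set(seq) <= set("ACGT")
    if not canonical:
        reasons.append("noncanonical_base")
    if not seq.startswith(genetics.START_CODON):
        reasons.append("no_start")
    multiple = len(seq) % 3 == 0
    if not multiple:
        reasons.append("length_not_multiple_of_3")
    if multiple and seq[-3:] not in genetics.STOP_STRINGS:
        reasons.append("no_terminal_stop")
    if multiple and canonical:
        cods = genetics.codons_of(genetics.encode(seq))
        if genetics.IS_STOP[cods[:-1]].any():
            reasons.append("premature_stop")
    return ValidationVerdict(tuple(reasons))


@dataclass(frozen=True)
class RatePair:
    """NG86 + Jukes–Cantor divergence estimates for one aligned pair.

    nan marks an undefined value (correction argument out of domain, or a
    dn/ds ratio with ds = 0 — such a pair passes ratio-based filters, since
    its ratio cannot exceed any threshold).
    """

    ds: float
    dn: float

    @property
    def ratio(self) -> float:
        if self.ds == 0 or math.isnan(self.ds) or math.isnan(self.dn):
            return float("nan")
        return self.dn / self.ds


@dataclass(frozen=True)
class CodonAlignment:
    """Gap-aware codon-level pairwise alignment (gaps are ``-`` triplets)."""

    focal_id: str
    ortholog_id: str
    focal_row: str
    ortholog_row: str

    def __post_init__(self):
        if len(self.focal_row) != len(self.ortholog_row):
            raise ValueError("alignment rows differ in length")
        if len(self.focal_row) % 3:
            raise ValueError("alignment length not a multiple of 3")

    def codon_columns(self) -> tuple[np.ndarray, np.ndarray]:
        """Codon indices per column, -1 for columns containing a gap."""
        return (_row_codons(self.focal_row), _row_codons(self.ortholog_row))

    def focal_ungapped(self) -> str:
        return self.focal_row.replace("-", "")


def _row_codons(row: str) -> np.ndarray:
    out = np.empty(len(row) // 3, dtype=np.int64)
    for i in range(0, len(row), 3):
        codon = row[i : i + 3]
        out[i // 3] = genetics.CODON_TO_INT.get(codon, -1) if "-" not in codon else -1
    return out


# ---------------------------------------------------------------------------
# NG86 rates
# ---------------------------------------------------------------------------


def rates_from_codon_arrays(c1: np.ndarray, c2: np.ndarray) -> RatePair:
    """NG86 rates from two equal-length codon-index arrays (-1 = gap).

    Columns with a gap or a stop codon in either row are excluded. Raises if
    no countable columns remain.
    """
    ok = (c1 >= 0) & (c2 >= 0)
    ok &= ~genetics.IS_STOP[np.where(ok, c1, 0)] & ~genetics.IS_STOP[np.where(ok, c2, 0)]
    a, b = c1[ok], c2[ok]
    if len(a) == 0:
        raise ValueError("no countable codon columns")
    S = float((genetics.SYN_SITES[a] + genetics.SYN_SITES[b]).sum()) / 2.0
    total_sites = 3.0 * len(a)
    N = total_sites - S
    Sd = float(genetics.SD_TABLE[a, b].sum())
    Nd = float(genetics.ND_TABLE[a, b].sum())
    ps = Sd / S if S > 0 else float("nan")
    pn = Nd / N if N > 0 else float("nan")
    ds = genetics.jukes_cantor(ps) if not math.isnan(ps) else float("nan")
    dn = genetics.jukes_cantor(pn) if not math.isnan(pn) else float("nan")
    return RatePair(ds, dn)


def pairwise_codon_rates(aln: CodonAlignment) -> RatePair:
    c1, c2 = aln.codon_columns()
    return rates_from_codon_arrays(c1, c2)


# ---------------------------------------------------------------------------
# protein-level alignment of coding sequences
# ---------------------------------------------------------------------------


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "global"
    return aligner


def align_cds_pair(
    focal_id: str, focal_cds: str, ortholog_id: str, ortholog_cds: str
) -> CodonAlignment:
    """Codon alignment of two CDSs via global protein alignment.

    Terminal stop codons are stripped before translation; the protein
    alignment is back-threaded to codons, so gap columns are whole codons.
    """
    f = _strip_stop(focal_cds)
    o = _strip_stop(ortholog_cds)
    pf, po = genetics.translate(f), genetics.translate(o)
    if "*" in pf or "*" in po:
        raise ValueError("internal stop codon; validate sequences first")
    aln = _protein_aligner().align(pf, po)[0]
    rows = str(aln).splitlines()
    # Biopython >=1.80 pairwise alignment: use aligned coordinates directly
    row_f, row_o = _thread_codons(aln, f, o)
    return CodonAlignment(focal_id, ortholog_id, row_f, row_o)


def _strip_stop(cds: str) -> str:
    if len(cds) % 3 == 0 and cds[-3:].upper() in genetics.STOP_STRINGS:
        return cds[:-3]
    return cds


def _thread_codons(aln, f: str, o: str) -> tuple[str, str]:
    out_f, out_o = [], []
    pos_f = pos_o = 0
    a_f, a_o = aln.indices  # per-column protein indices, -1 for gaps
    for col in range(aln.length):
        if a_f[col] >= 0:
            out_f.append(f[3 * a_f[col] : 3 * a_f[col] + 3])
        else:
            out_f.append("---")
        if a_o[col] >= 0:
            out_o.append(o[3 * a_o[col] : 3 * a_o[col] + 3])
        else:
            out_o.append("---")
    return "".join(out_f), "".join(out_o)


# ---------------------------------------------------------------------------
# similarity graph and paralogous families
# ---------------------------------------------------------------------------

# Karlin–Altschul parameters for +1/-2 nucleotide scoring (ungapped estimates)
_KA_LAMBDA = 1.28
_KA_K = 0.46
_SEED_K = 12


def _nucleotide_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -3
    aligner.extend_gap_score = -2
    aligner.mode = "local"
    return aligner


def similarity_evalue(seq1: str, seq2: str) -> float:
    """Karlin–Altschul e-value of the best local alignment of two sequences."""
    score = _nucleotide_aligner().score(seq1, seq2)
    return _KA_K * len(seq1) * len(seq2) * math.exp(-_KA_LAMBDA * score)


def _kmer_set(seq: str, k: int = _SEED_K) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


@dataclass(frozen=True)
class ParalogFamily:
    member_ids: frozenset[str]
    representative_id: str

    def __post_init__(self):
        if self.representative_id not in self.member_ids:
            raise ValueError("representative must be a member")


def similarity_edges(
    genes: Sequence[GeneRecord],
    evalue_threshold: float = 1e-4,
    min_shared_kmers: int = 3,
) -> set[tuple[str, str]]:
    """Undirected significant-similarity edges between genes.

    Pairs sharing fewer than ``min_shared_kmers`` 12-mers are skipped without
    alignment (unrelated sequences essentially never pass this screen).
    """
    kmers = {g.gene_id: _kmer_set(g.cds) for g in genes}
    edges: set[tuple[str, str]] = set()
    for i, g1 in enumerate(genes):
        for g2 in genes[i + 1 :]:
            shared = len(kmers[g1.gene_id] & kmers[g2.gene_id])
            if shared < min_shared_kmers:
                continue
            if similarity_evalue(g1.cds, g2.cds) <= evalue_threshold:
                edges.add((g1.gene_id, g2.gene_id))
    return edges


def cluster_families(
    genes: Sequence[GeneRecord],
    evalue_threshold: float = 1e-4,
    edges: Iterable[tuple[str, str]] | None = None,
) -> list[ParalogFamily]:
    """Partition genes into paralogous families (similarity components).

    Seeded expansion over the similarity graph; equivalent to connected
    components, hence invariant to input order. The representative is the
    longest CDS in the family, ties broken by the lexicographically smallest
    transcript identifier. Precomputed ``edges`` may be supplied.
    """
    if not genes:
        raise ValueError("no genes")
    if edges is None:
        edges = similarity_edges(genes, evalue_threshold)
    by_id = {g.gene_id: g for g in genes}
    adj: dict[str, set[str]] = {g.gene_id: set() for g in genes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    unassigned = set(by_id)
    families = []
    for seed in sorted(by_id):  # deterministic seeding order
        if seed not in unassigned:
            continue
        members = {seed}
        frontier = [seed]
        unassigned.discard(seed)
        while frontier:
            nxt = []
            for node in frontier:
                for nb in adj[node]:
                    if nb in unassigned:
                        unassigned.discard(nb)
                        members.add(nb)
                        nxt.append(nb)
            frontier = nxt
        rep = min(
            members,
            key=lambda gid: (-by_id[gid].cds_length, by_id[gid].transcript_id),
        )
        families.append(ParalogFamily(frozenset(members), rep))
    return families


def family_map(families: Iterable[ParalogFamily]) -> dict[str, str]:
    """gene_id -> family representative id (used as the family label)."""
    out = {}
    for fam in families:
        for gid in fam.member_ids:
            out[gid] = fam.representative_id
    return out


# ---------------------------------------------------------------------------
# ortholog-pair divergence filters
# ---------------------------------------------------------------------------


def ortholog_pair_passes(rates: RatePair, mode: str = "human") -> bool:
    """Divergence filter for focal/ortholog pairs.

    ``human`` drops pairs with ds >= 0.2 or dn/ds >= 0.5; ``mouse`` keeps
    pairs with ds < 0.3 and dn/ds < 0.5. An undefined ratio (ds = 0) passes
    the ratio criterion; an undefined ds fails both modes.
    """
    if math.isnan(rates.ds):
        return False
    ratio_ok = math.isnan(rates.ratio) or rates.ratio < 0.5
    if mode == "human":
        return rates.ds < 0.2 and ratio_ok
    if mode == "mouse":
        return rates.ds < 0.3 and ratio_ok
    raise ValueError(f"unknown mode {mode!r}")
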