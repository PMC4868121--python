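"""Exact hexamer scanning, union-coverage densities, and exon windows.

Scanning is exhaustive exact matching at every offset. Coverage is the union
of all hit intervals: a base overlapped by several hits counts once. The
``KmerIndex`` pre-sorts a sequence's 6-mer codes so that repeated scans with
different motif sets (the null-model hot loop) cost one binary search per
motif instead of one pass per set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import genetics
from .motifs import MOTIF_LENGTH, MotifSet

_POW4 = 4 ** np.arange(MOTIF_LENGTH - 1, -1, -1)


def _rolling_codes(arr: np.ndarray) -> np.ndarray:
    """6-mer code at every offset of an encoded sequence (empty if len < 6)."""
    n = len(arr) - MOTIF_LENGTH + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    a = arr.astype(np.int64)
    for j in range(MOTIF_LENGTH):
        out += a[j : j + n] * _POW4[j]
    return out


class KmerIndex:
    """Sorted 6-mer index of one sequence for fast repeated motif-set scans."""

    def __init__(self, seq: str | np.ndarray):
        arr = genetics.encode(seq) if isinstance(seq, str) else seq
        self.length = len(arr)
        codes = _rolling_codes(arr)
        self._order = np.argsort(codes, kind="stable")
        self._sorted = codes[self._order]

    def starts_of(self, codes: np.ndarray | int) -> np.ndarray:
        """Start offsets (ascending) of hits to any of the given codes."""
        q = np.atleast_1d(np.asarray(codes, dtype=np.int64))
        lo = np.searchsorted(self._sorted, q, side="left")
        hi = np.searchsorted(self._sorted, q, side="right")
        if len(q) == 1:
            starts = self._order[lo[0] : hi[0]]
        else:
            parts = [self._order[l:h] for l, h in zip(lo, hi) if h > l]
            starts = np.concatenate(parts) if parts else np.empty(0, dtype=np.intp)
        starts = np.sort(starts)
        return starts

    def coverage_mask(self, codes: np.ndarray | int) -> np.ndarray:
        """Boolean union-coverage mask over the sequence for a motif-code set."""
        return mask_from_starts(self.starts_of(codes), self.length)

    def covered_count(self, codes: np.ndarray | int) -> int:
        """Number of bases covered by at least one hit (union of intervals)."""
        starts = self.starts_of(codes)
        if len(starts) == 0:
            return 0
        gaps = np.diff(starts)
        return int(MOTIF_LENGTH + np.minimum(gaps, MOTIF_LENGTH).sum())


def mask_from_starts(starts: np.ndarray, length: int) -> np.ndarray:
    delta = np.zeros(length + MOTIF_LENGTH + 1, dtype=np.int32)
    np.add.at(delta, starts, 1)
    np.add.at(delta, starts + MOTIF_LENGTH, -1)
    return np.cumsum(delta)[:length] > 0


@dataclass
class HitProfile:
    """Per-gene scan result: union mask plus per-motif starts and coverage."""

    gene_id: str
    coverage_mask: np.ndarray
    per_motif_counts: dict[str, int]
    hit_starts: dict[str, np.ndarray]

    @property
    def covered(self) -> int:
        return int(np.count_nonzero(self.coverage_mask))

    @property
    def length(self) -> int:
        return len(self.coverage_mask)

    @property
    def density(self) -> float:
        if self.length == 0:
            raise ValueError("zero-length sequence")
        return self.covered / self.length


def find_hits(seq: str, motifs: MotifSet, gene_id: str = "") -> HitProfile:
    """Scan a sequence for every motif; overlapping hit bases count once."""
    index = KmerIndex(seq)
    per_counts: dict[str, int] = {}
    per_starts: dict[str, np.ndarray] = {}
    for m in motifs.motifs:
        starts = index.starts_of(
            np.array([_motif_code(m)], dtype=np.int64)
        )
        per_starts[m] = starts
        if len(starts) == 0:
            per_counts[m] = 0
        else:
            gaps = np.diff(starts)
            per_counts[m] = int(MOTIF_LENGTH + np.minimum(gaps, MOTIF_LENGTH).sum())
    mask = index.coverage_mask(motifs.codes)
    return HitProfile(gene_id, mask, per_counts, per_starts)


def _motif_code(m: str) -> int:
    return int(genetics.encode(m) @ _POW4)


def density(
    profiles: Iterable[HitProfile],
    families: Mapping[str, str] | None = None,
    mode: str = "per_gene",
):
    """Union-coverage density at gene, family-mean, or pooled granularity.

    ``families`` maps gene_id -> family_id (required for ``family_mean``).
    Returns a pandas Series for the first two modes, a float for ``pooled``.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles")
    for p in profiles:
        if p.length == 0:
            raise ValueError(f"zero-length sequence {p.gene_id!r}")
    per_gene = pd.Series(
        {p.gene_id: p.covered / p.length for p in profiles}, dtype=float
    )
    if mode == "per_gene":
        return per_gene
    if mode == "family_mean":
        if families is None:
            raise ValueError("family_mean mode requires a gene->family mapping")
        fam = pd.Series({p.gene_id: families[p.gene_id] for p in profiles})
        return per_gene.groupby(fam).mean()
    if mode == "pooled":
        return float(
            sum(p.covered for p in profiles) / sum(p.length for p in profiles)
        )
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# exon flank/core windows
# ---------------------------------------------------------------------------

WINDOW_BP = 69
#: shortest exon from which three codon-aligned 69-bp windows can be cut
#: after trimming up to two bases at each end: 69*3 + 2*2.
MIN_EXON_BP = 3 * WINDOW_BP + 2 * 2


@dataclass(frozen=True)
class ExonWindows:
    """Three non-overlapping, codon-aligned 69-bp windows of one exon.

    Offsets are 0-based starts of each window within the input exon sequence.
    """

    upstream_flank: str
    core: str
    downstream_flank: str
    upstream_offset: int
    core_offset: int
    downstream_offset: int


def exon_windows(exon_seq: str, frame_offset: int = 0) -> ExonWindows:
    """Cut upstream-flank / core / downstream-flank windows from one exon.

    ``frame_offset`` is the codon phase of the exon's first base (0 means the
    exon starts on a codon boundary). Up to two bases are trimmed at each end
    so that all three windows are codon-aligned. The core sits midway between
    the flanks when the inter-flank codon gap minus 23 codons is even,
    otherwise one codon nearer the 5' end (margins of n and n+3 bases).
    """
    L = len(exon_seq)
    if L < MIN_EXON_BP:
        raise ValueError(f"exon of {L} bp shorter than {MIN_EXON_BP} bp")
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    lead = (3 - frame_offset) % 3
    trail = (L - lead) % 3
    trimmed_len = L - lead - trail
    n_codons = trimmed_len // 3
    flank_codons = WINDOW_BP // 3  # 23
    gap_codons = n_codons - 2 * flank_codons
    spare = gap_codons - flank_codons
    up_margin = spare // 2 if spare % 2 == 0 else (spare - 1) // 2
    up_off = lead
    core_off = lead + (flank_codons + up_margin) * 3
    down_off = lead + (n_codons - flank_codons) * 3
    return ExonWindows(
        upstream_flank=exon_seq[up_off : up_off + WINDOW_BP],
        core=exon_seq[core_off : core_off + WINDOW_BP],
        downstream_flank=exon_seq[down_off : down_off + WINDOW_BP],
        upstream_offset=up_off,
        core_offset=core_off,
        downstream_offset=down_off,
    )


def extract_windows_batch(
    exons: Iterable[tuple[str, str, int]],
    exclude_ids: Iterable[str] = (),
) -> tuple[list[tuple[str, ExonWindows]], list[tuple[str, str]]]:
    """Windows for a batch of (exon_id, sequence, frame_offset) triples.

    Exons shorter than the minimum or in the exclusion list are logged to the
    rejected list rather than raising.
    """
    excluded = set(exclude_ids)
    out: list[tuple[str, ExonWindows]] = []
    rejected: list[tuple[str, str]] = []
    for exon_id, seq, frame in exons:
        if exon_id in excluded:
            rejected.append((exon_id, "excluded"))
            continue
        try:
            out.append((exon_id, exon_windows(seq, frame)))
        except ValueError as e:
            rejected.append((exon_id, str(e)))
    return out, rejected
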