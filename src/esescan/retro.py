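"""Retrocopy identification, parent matching, ancestral junction mapping,
and leave-k-out resampling of their contribution to motif enrichment.

A gene is a *broad* retrocopy call when at least half of its genomic span is
overlapped by annotated retrocopy intervals; the *strict* tier additionally
requires a translatable parent CDS aligning at dN < 0.2 (the lowest-dN
candidate becomes the parent). Strict calls are a subset of broad calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .motifs import MotifSet
from .nulls import ControlSetCollection
from .scan import HitProfile, KmerIndex
from .seqprep import (
    CodonAlignment,
    GeneRecord,
    ParalogFamily,
    align_cds_pair,
    pairwise_codon_rates,
    similarity_edges,
)
from .stats import EmpiricalTest, empirical_p


@dataclass(frozen=True)
class RetrocopyCall:
    gene_id: str
    overlap_fraction: float
    tier: str  # broad | strict | none
    parent_id: str | None = None
    parent_dn: float | None = None


def _union_overlap(
    interval: tuple[int, int], others: Sequence[tuple[int, int]]
) -> int:
    """Overlapped bases of ``interval`` with the union of ``others``."""
    a, b = interval
    clipped = sorted(
        (max(a, s), min(b, e)) for s, e in others if min(b, e) > max(a, s)
    )
    covered = 0
    cur_start = cur_end = None
    for s, e in clipped:
        if cur_end is None or s > cur_end:
            if cur_end is not None:
                covered += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        covered += cur_end - cur_start
    return covered


def broad_retrocopy_calls(
    gene_intervals: Mapping[str, tuple[str, int, int]],
    retro_intervals: Iterable[tuple],
    min_fraction: float = 0.5,
) -> list[RetrocopyCall]:
    """Overlap-based calls: fraction of each gene span covered by retrocopy
    annotations (union over annotations, boundary-inclusive at the cutoff)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in retro_intervals:
        chrom, s, e = iv[0], int(iv[1]), int(iv[2])
        if e <= s:
            raise ValueError(f"malformed interval {iv!r}")
        by_chrom.setdefault(chrom, []).append((s, e))
    out = []
    for gid, (chrom, s, e) in sorted(gene_intervals.items()):
        if e <= s:
            raise ValueError(f"malformed gene interval for {gid!r}")
        covered = _union_overlap((s, e), by_chrom.get(chrom, ()))
        frac = covered / (e - s)
        out.append(
            RetrocopyCall(gid, frac, "broad" if frac >= min_fraction else "none")
        )
    return out


def strict_parent_match(
    retrocopy: GeneRecord,
    candidates: Sequence[GeneRecord],
    max_dn: float = 0.2,
    min_length_ratio: float = 0.5,
) -> RetrocopyCall:
    """Match a broad-call retrocopy to its lowest-dN translatable parent.

    Candidate pairs where the shorter CDS is not over ``min_length_ratio`` of
    the longer are dropped before alignment. The call stays broad when no
    candidate aligns below the dN bound.
    """
    best_id, best_dn = None, math.inf
    for cand in sorted(candidates, key=lambda g: g.gene_id):
        shorter = min(retrocopy.cds_length, cand.cds_length)
        longer = max(retrocopy.cds_length, cand.cds_length)
        if shorter <= min_length_ratio * longer:
            continue
        aln = align_cds_pair(
            retrocopy.gene_id, retrocopy.cds, cand.gene_id, cand.cds
        )
        dn = pairwise_codon_rates(aln).dn
        if not math.isnan(dn) and dn < best_dn:
            best_dn, best_id = dn, cand.gene_id
    if best_id is not None and best_dn < max_dn:
        return RetrocopyCall(retrocopy.gene_id, 1.0, "strict", best_id, best_dn)
    return RetrocopyCall(
        retrocopy.gene_id,
        1.0,
        "broad",
        best_id,
        None if math.isinf(best_dn) else best_dn,
    )


def dedupe_strict_calls(
    calls: Sequence[RetrocopyCall], families: Sequence[ParalogFamily]
) -> list[RetrocopyCall]:
    """Keep the lowest-dN strict call per paralogous family."""
    fam_of = {}
    for f in families:
        for gid in f.member_ids:
            fam_of[gid] = f.representative_id
    best: dict[str, RetrocopyCall] = {}
    for c in calls:
        if c.tier != "strict":
            continue
        key = fam_of.get(c.gene_id, c.gene_id)
        if key not in best or c.parent_dn < best[key].parent_dn:
            best[key] = c
    return sorted(best.values(), key=lambda c: c.gene_id)


# ---------------------------------------------------------------------------
# ancestral exon-exon junctions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class JunctionMap:
    parent_junctions: tuple[int, ...]  # positions on parent CDS
    mapped_junctions: tuple[int, ...]  # pseudo-junctions on retrocopy CDS
    intact_flags: tuple[bool, ...]  # per parent junction


def junction_proximity(
    parent: GeneRecord,
    aln: CodonAlignment,
    hits: HitProfile,
    window: int = 50,
    probe: int = 30,
    min_intact: float = 0.5,
) -> tuple[JunctionMap, float]:
    """Fraction of motif hits starting within ``window`` bp of an ancestral
    exon-exon junction of a retrocopy.

    ``aln`` aligns the retrocopy (focal row) to its parent (ortholog row);
    ``hits`` is the retrocopy's scan profile. A junction whose first
    ``probe`` parent bases align with fewer than ``min_intact`` non-indel
    columns is kept among parent junctions but yields no pseudo-junction.
    """
    retro_row, parent_row = aln.focal_row, aln.ortholog_row
    retro_pos = np.cumsum([c != "-" for c in retro_row]) - 1
    parent_pos = np.cumsum([c != "-" for c in parent_row]) - 1
    col_of_parent = {}
    for col, ch in enumerate(parent_row):
        if ch != "-":
            col_of_parent[int(parent_pos[col])] = col
    junctions = tuple(int(a) for a, _ in parent.exon_intervals[1:])
    mapped, flags = [], []
    for j in junctions:
        cols = [col_of_parent[p] for p in range(j, j + probe) if p in col_of_parent]
        if not cols:
            flags.append(False)
            continue
        intact = sum(1 for c in cols if retro_row[c] != "-") / probe
        if intact < min_intact:
            flags.append(False)
            continue
        flags.append(True)
        first = next((c for c in cols if retro_row[c] != "-"), None)
        if first is not None:
            mapped.append(int(retro_pos[first]))
    jmap = JunctionMap(junctions, tuple(mapped), tuple(flags))
    all_starts = sorted(
        int(s) for starts in hits.hit_starts.values() for s in starts
    )
    if not all_starts or not mapped:
        return jmap, float("nan")
    near = sum(
        1 for s in all_starts if any(abs(s - m) <= window for m in mapped)
    )
    return jmap, near / len(all_starts)


# ---------------------------------------------------------------------------
# leave-k-out resampling
# ---------------------------------------------------------------------------


@dataclass
class LeaveKOutResult:
    full_nd: float
    full_p: float
    removed_nd: float
    removed_p: float
    delta_nd: float  # decrease in ND after the true removal
    delta_p: float  # increase in p after the true removal
    null_delta_nd: np.ndarray
    null_delta_p: np.ndarray
    test_nd: EmpiricalTest
    test_p: EmpiricalTest


class _DensityEvaluator:
    """Median family-level density and ND for arbitrary gene subsets.

    Per-gene covered counts for the real set and every control set are
    computed once; a subset evaluation then only re-derives families
    (components of the induced similarity subgraph) and aggregates.
    """

    def __init__(
        self,
        genes: Sequence[GeneRecord],
        motifs: MotifSet,
        controls: ControlSetCollection,
        edges: Iterable[tuple[str, str]] | None = None,
    ):
        self.genes = list(genes)
        self.ids = [g.gene_id for g in self.genes]
        self.pos = {gid: i for i, gid in enumerate(self.ids)}
        code_sets = [motifs.codes] + controls.code_arrays()
        dens = np.empty((len(self.genes), len(code_sets)))
        for i, g in enumerate(self.genes):
            index = KmerIndex(g.cds)
            dens[i] = [
                index.covered_count(c) / g.cds_length for c in code_sets
            ]
        self.densities = dens
        if edges is None:
            edges = similarity_edges(self.genes)
        self.edges = [(self.pos[a], self.pos[b]) for a, b in edges]

    def _components(self, keep: np.ndarray) -> list[list[int]]:
        parent = np.arange(len(self.genes))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in self.edges:
            if keep[a] and keep[b]:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra
        comps: dict[int, list[int]] = {}
        for i in np.flatnonzero(keep):
            comps.setdefault(find(i), []).append(i)
        return list(comps.values())

    def evaluate(self, keep: np.ndarray) -> tuple[float, float]:
        """(ND, enrichment p) of the kept subset."""
        comps = self._components(keep)
        fam = np.array([self.densities[c].mean(axis=0) for c in comps])
        med = np.median(fam, axis=0)
        observed, null = med[0], med[1:]
        mean = null.mean()
        nd = (observed - mean) / mean if mean > 0 else float("nan")
        p = empirical_p(observed, null, "greater").p
        return nd, p


def leave_k_out(
    genes: Sequence[GeneRecord],
    motifs: MotifSet,
    controls: ControlSetCollection,
    true_removal_ids: Iterable[str],
    k: int | None = None,
    iterations: int = 1000,
    rng: np.random.Generator | None = None,
    edges: Iterable[tuple[str, str]] | None = None,
) -> LeaveKOutResult:
    """Is the enrichment change after removing the retrocopies larger than
    after removing an equally sized random subset?

    At each iteration ``k`` random genes (default: the size of the true
    removal set) are removed, families re-derived, and the decrease in ND and
    increase in empirical p recorded; the true removal's deltas are placed in
    those null distributions (one-tailed).
    """
    if rng is None:
        rng = np.random.default_rng()
    ev = _DensityEvaluator(genes, motifs, controls, edges)
    true_ids = set(true_removal_ids)
    if k is None:
        k = len(true_ids)
    n = len(ev.genes)
    if k >= n:
        raise ValueError("k must be smaller than the number of genes")
    full_keep = np.ones(n, dtype=bool)
    full_nd, full_p = ev.evaluate(full_keep)
    true_keep = np.array([gid not in true_ids for gid in ev.ids])
    removed_nd, removed_p = ev.evaluate(true_keep)
    delta_nd = full_nd - removed_nd
    delta_p = removed_p - full_p
    null_nd = np.empty(iterations)
    null_p = np.empty(iterations)
    for it in range(iterations):
        keep = np.ones(n, dtype=bool)
        keep[rng.choice(n, size=k, replace=False)] = False
        nd_i, p_i = ev.evaluate(keep)
        null_nd[it] = full_nd - nd_i
        null_p[it] = p_i - full_p
    return LeaveKOutResult(
        full_nd,
        full_p,
        removed_nd,
        removed_p,
        delta_nd,
        delta_p,
        null_nd,
        null_p,
        empirical_p(delta_nd, null_nd, "greater"),
        empirical_p(delta_p, null_p, "greater"),
    )
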