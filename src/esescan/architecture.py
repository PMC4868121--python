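"""Gene-architecture analyses: mean-intron-size binning, the per-motif
bin-by-motif density matrix with dinucleotide-permutation controls, trend
classification, and the exon flank/core contrast.

Data points are paralogous families: per-motif overlap counts, CDS lengths
and mean intron sizes are averaged within families before binning.
Intronless data points (mean intron size 0) form bin 0; intron-containing
points are cut at every 1/n-th quantile, ties at a boundary falling into the
lower bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .motifs import MOTIF_LENGTH, MotifSet
from .nulls import ControlSetCollection, permutation_controls
from .scan import ExonWindows, KmerIndex
from .seqprep import GeneRecord, ParalogFamily
from .stats import EmpiricalTest, empirical_p, holm_adjust


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BinAssignment:
    bin_index: np.ndarray  # per data point, 0..B-1
    boundaries: np.ndarray  # quantile cut values for the positive bins
    n_bins: int


def assign_bins(values, n_quantile_bins: int = 48) -> BinAssignment:
    """Bin 0 holds the zeros (intronless points); positives are cut at every
    1/n-th quantile into ``n_quantile_bins`` further bins."""
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValueError("values must be >= 0")
    positive = v > 0
    idx = np.zeros(len(v), dtype=int)
    if not positive.any():
        warnings.warn("no positive values: a single (intronless) bin")
        return BinAssignment(idx, np.empty(0), 1)
    qs = np.arange(1, n_quantile_bins) / n_quantile_bins
    boundaries = np.quantile(v[positive], qs)
    # a value equal to a boundary goes to the lower bin
    idx[positive] = 1 + np.searchsorted(boundaries, v[positive], side="left")
    return BinAssignment(idx, boundaries, n_quantile_bins + 1)


def architecture_metrics(gene: GeneRecord) -> tuple[float, float, float, int]:
    """(intron_density, mean_intron_size, gc4, exon_count) of one gene."""
    return (gene.intron_density, gene.mean_intron_size, gene.gc4, gene.exon_count)


# ---------------------------------------------------------------------------
# family-level data points and the bin x motif matrix
# ---------------------------------------------------------------------------


@dataclass
class FamilyDatapoints:
    """Family-averaged per-motif overlap counts plus covariates."""

    counts: pd.DataFrame  # families x motifs, averaged covered bases
    lengths: pd.Series  # family-averaged CDS length
    mean_intron_size: pd.Series
    motifs: MotifSet


def family_datapoints(
    genes: Sequence[GeneRecord],
    families: Sequence[ParalogFamily] | None,
    motifs: MotifSet,
) -> FamilyDatapoints:
    indexes = {g.gene_id: KmerIndex(g.cds) for g in genes}
    codes = _codes_in_order(motifs)
    per_gene = {
        gid: np.array([_union_covered(ix.starts_of(int(c))) for c in codes])
        for gid, ix in indexes.items()
    }
    if families is None:
        fam_members = {g.gene_id: [g.gene_id] for g in genes}
    else:
        fam_members = {f.representative_id: sorted(f.member_ids) for f in families}
    by_id = {g.gene_id: g for g in genes}
    rows, lengths, mis = {}, {}, {}
    for rep, members in fam_members.items():
        rows[rep] = np.mean([per_gene[m] for m in members], axis=0)
        lengths[rep] = float(np.mean([by_id[m].cds_length for m in members]))
        mis[rep] = float(np.mean([by_id[m].mean_intron_size for m in members]))
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=list(motifs.motifs))
    counts = counts.sort_index()
    dp = FamilyDatapoints(
        counts,
        pd.Series(lengths).sort_index(),
        pd.Series(mis).sort_index(),
        motifs,
    )
    # kept for the permutation-control rescans of motif_bin_matrix
    dp._index_cache = (fam_members, indexes)
    return dp


def _codes_in_order(motifs: MotifSet) -> list[int]:
    from .motifs import hexamer_code

    return [hexamer_code(m) for m in motifs.motifs]


def _union_covered(starts: np.ndarray) -> int:
    if len(starts) == 0:
        return 0
    gaps = np.diff(starts)
    return int(MOTIF_LENGTH + np.minimum(gaps, MOTIF_LENGTH).sum())


@dataclass
class MotifBinMatrix:
    """Bin x motif pooled densities, raw and permutation-normalized.

    ``raw[b, j]`` = family-averaged covered bases of motif j summed over the
    data points of bin b, divided by the summed family-averaged CDS lengths.
    ``normalized`` subtracts and divides by the per-cell median over that
    motif's dinucleotide-permutation controls (nan where the median is 0 or
    the bin is empty).
    """

    raw: pd.DataFrame
    normalized: pd.DataFrame
    simulant_medians: pd.DataFrame
    bins: BinAssignment


def motif_bin_matrix(
    datapoints: FamilyDatapoints,
    bins: BinAssignment,
    exclude_original: bool = False,
) -> MotifBinMatrix:
    """Assemble the bin x motif density matrix with 60-permutation controls."""
    motifs = datapoints.motifs
    idx = bins.bin_index
    B = bins.n_bins
    if len(idx) != len(datapoints.counts):
        raise ValueError("bin assignment does not match the data points")
    lengths = datapoints.lengths.to_numpy()
    bin_len = np.bincount(idx, weights=lengths, minlength=B)
    raw = np.full((B, len(motifs)), np.nan)
    counts = datapoints.counts.to_numpy()
    for b in range(B):
        sel = idx == b
        if sel.any() and bin_len[b] > 0:
            raw[b] = counts[sel].sum(axis=0) / bin_len[b]

    # per-motif permutation controls -> per-cell simulant medians.
    # For the control scans only the per-gene indexes are needed; rebuild the
    # family averaging with the same membership as the real counts.
    med = np.full((B, len(motifs)), np.nan)
    fam_index = datapoints.counts.index
    for j, motif in enumerate(motifs.motifs):
        controls = permutation_controls(motif, exclude_original=exclude_original)
        ctrl_cells = np.full((len(controls), B), np.nan)
        per_fam = _per_family_counts_for_motifs(datapoints, controls)
        for k in range(len(controls)):
            col = per_fam[:, k]
            for b in range(B):
                sel = idx == b
                if sel.any() and bin_len[b] > 0:
                    ctrl_cells[k, b] = col[sel].sum() / bin_len[b]
        med[:, j] = np.median(ctrl_cells, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        normalized = np.where(med > 0, (raw - med) / med, np.nan)
    cols = list(motifs.motifs)
    return MotifBinMatrix(
        pd.DataFrame(raw, columns=cols),
        pd.DataFrame(normalized, columns=cols),
        pd.DataFrame(med, columns=cols),
        bins,
    )


def _per_family_counts_for_motifs(
    datapoints: FamilyDatapoints, motifs: MotifSet
) -> np.ndarray:
    """Family-averaged covered counts for an arbitrary motif list (F x M)."""
    fam_members, indexes = datapoints._index_cache
    codes = _codes_in_order(motifs)
    per_gene = {
        gid: np.array([_union_covered(ix.starts_of(int(c))) for c in codes])
        for gid, ix in indexes.items()
    }
    return np.array(
        [
            np.mean([per_gene[m] for m in fam_members[rep]], axis=0)
            for rep in datapoints.counts.index
        ]
    )


# ---------------------------------------------------------------------------
# trend classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotifTrendClass:
    motif: str
    label: str  # positive | negative | nonsignificant
    statistic: float
    p_raw: float
    p_adjusted: float


def motif_trend_tests(
    matrix: MotifBinMatrix, alpha: float = 0.05
) -> list[MotifTrendClass]:
    """Rank-correlate each normalized column against bin indices 0..B-1,
    Holm-adjust across motifs, and classify by sign and significance."""
    norm = matrix.normalized
    B = len(norm)
    if B < 3:
        raise ValueError("need at least 3 bins")
    bin_idx = np.arange(B, dtype=float)
    stats_, raw_p = [], []
    for motif in norm.columns:
        col = norm[motif].to_numpy()
        ok = ~np.isnan(col)
        if ok.sum() < 3 or np.nanstd(col[ok]) == 0:
            stats_.append(float("nan"))
            raw_p.append(1.0)
            continue
        rho, p = sps.spearmanr(bin_idx[ok], col[ok])
        stats_.append(float(rho))
        raw_p.append(float(p) if not np.isnan(p) else 1.0)
    adjusted = holm_adjust(raw_p)
    out = []
    for motif, s, p, q in zip(norm.columns, stats_, raw_p, adjusted):
        if np.isnan(s) or q >= alpha:
            label = "nonsignificant"
        else:
            label = "positive" if s > 0 else "negative"
        out.append(MotifTrendClass(motif, label, s, p, q))
    return out


# ---------------------------------------------------------------------------
# flank/core contrast
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FlankCoreResult:
    nd_flank: tuple[float, float]  # (high subset, low subset)
    nd_core: tuple[float, float]
    ratios: tuple[float, float]  # flank ND / core ND per subset
    ratio_difference: float
    test: EmpiricalTest | None
    n_usable_controls: int


def _pooled_window_density(windows: Sequence[ExonWindows], codes, which: str) -> float:
    covered = total = 0
    for w in windows:
        seq = getattr(w, which)
        covered += KmerIndex(seq).covered_count(codes)
        total += len(seq)
    if total == 0:
        raise ValueError("no windows")
    return covered / total


def flank_core_contrast(
    windows: Sequence[ExonWindows],
    subsets: tuple[MotifSet, MotifSet],
    controls: tuple[ControlSetCollection, ControlSetCollection],
) -> FlankCoreResult:
    """Positional-bias contrast between two motif subsets.

    For each subset, pooled ND in upstream flanks and in cores is computed
    against that subset's own dinucleotide-matched control sets; the observed
    statistic is the difference of flank/core ND ratios. The null substitutes
    the index-paired control sets for the observed subsets; control
    iterations with a nonpositive core ND are undefined and dropped.
    """
    high, low = subsets
    ctrl_high, ctrl_low = controls
    if ctrl_high.n_sets != ctrl_low.n_sets:
        raise ValueError("control collections must be index-paired")

    def densities(collection_codes):
        return (
            _pooled_window_density(windows, collection_codes, "upstream_flank"),
            _pooled_window_density(windows, collection_codes, "core"),
        )

    obs = [densities(s.codes) for s in (high, low)]
    null_d = [
        [densities(c) for c in coll.code_arrays()] for coll in (ctrl_high, ctrl_low)
    ]
    means = [
        (
            float(np.mean([d[0] for d in nd])),
            float(np.mean([d[1] for d in nd])),
        )
        for nd in null_d
    ]

    def nd(value, mean):
        return (value - mean) / mean if mean > 0 else float("nan")

    nd_flank = tuple(nd(obs[s][0], means[s][0]) for s in range(2))
    nd_core = tuple(nd(obs[s][1], means[s][1]) for s in range(2))
    ratios = tuple(
        nd_flank[s] / nd_core[s] if nd_core[s] and nd_core[s] > 0 else float("nan")
        for s in range(2)
    )
    if any(np.isnan(r) for r in ratios):
        return FlankCoreResult(nd_flank, nd_core, ratios, float("nan"), None, 0)
    observed_diff = ratios[0] - ratios[1]
    null_diffs = []
    for i in range(ctrl_high.n_sets):
        vals = []
        for s in range(2):
            f = nd(null_d[s][i][0], means[s][0])
            c = nd(null_d[s][i][1], means[s][1])
            vals.append(f / c if c > 0 else float("nan"))
        if not any(np.isnan(v) for v in vals):
            null_diffs.append(vals[0] - vals[1])
    test = (
        empirical_p(observed_diff, null_diffs, "greater") if null_diffs else None
    )
    return FlankCoreResult(
        nd_flank, nd_core, ratios, observed_diff, test, len(null_diffs)
    )
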