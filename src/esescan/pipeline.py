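"""End-to-end orchestration of the analysis stages.

``run_pipeline`` executes: data preparation (validation, ortholog-divergence
filtering, family clustering) -> motif scan -> dinucleotide-controlled nulls
-> enrichment per gene group (intronless vs intron-containing) -> selection
tests (concatenated dS, SNP statistics) -> architecture matrix and trend
classes -> retrocopy contrasts; it emits a machine-readable JSON report plus
TSV tables. Identical configuration and seed yield byte-identical reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as eio
from .architecture import (
    assign_bins,
    family_datapoints,
    motif_bin_matrix,
    motif_trend_tests,
)
from .motifs import MotifSet, load_motifs
from .nulls import ControlSetCollection, build_control_sets
from .retro import broad_retrocopy_calls, leave_k_out
from .scan import KmerIndex
from .selection import concatenated_ds, snp_statistics
from .seqprep import (
    GeneRecord,
    ParalogFamily,
    cluster_families,
    ortholog_pair_passes,
    pairwise_codon_rates,
    validate_cds,
)
from .stats import empirical_p, gk_gamma, partial_rank_correlation
from .synthetic import SyntheticConfig, make_cohort, substream


@dataclass
class RunConfig:
    """Pipeline configuration: synthetic mode or explicit input files."""

    synthetic: SyntheticConfig | None = None
    motif_file: str | None = None
    cds_fasta: str | None = None
    architecture_tsv: str | None = None
    ortholog_fasta: str | None = None
    snp_tsv: str | None = None
    retro_bed: str | None = None
    n_control_sets: int = 10000
    n_control_sets_ds: int = 1000
    n_quantile_bins: int = 48
    species_mode: str = "human"  # ortholog divergence filter mode
    include_retrocopies: bool = True
    leave_k_out_iterations: int = 200
    min_exon_class_size: int = 50
    run_architecture_matrix: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.synthetic is None and not (self.cds_fasta and self.motif_file):
            raise ValueError(
                "either a synthetic config or cds_fasta + motif_file inputs "
                "are required"
            )


def group_enrichment(
    genes: Sequence[GeneRecord],
    motifs: MotifSet,
    controls: ControlSetCollection,
    families: Sequence[ParalogFamily] | None = None,
) -> dict:
    """Median family-level density of a gene group against the control null.

    Returns the observed median density, the control mean of medians, ND,
    and one-tailed enrichment/depletion p-values, plus per-data-point ND
    (family-averaged) for downstream correlations.
    """
    if not genes:
        raise ValueError("empty gene group")
    code_sets = [motifs.codes] + controls.code_arrays()
    dens = np.empty((len(genes), len(code_sets)))
    for i, g in enumerate(genes):
        index = KmerIndex(g.cds)
        dens[i] = [index.covered_count(c) / g.cds_length for c in code_sets]
    ids = [g.gene_id for g in genes]
    if families is None:
        fam_rows = [[i] for i in range(len(genes))]
    else:
        pos = {gid: i for i, gid in enumerate(ids)}
        fam_rows = [sorted(pos[m] for m in f.member_ids) for f in families]
    fam = np.array([dens[rows].mean(axis=0) for rows in fam_rows])
    med = np.median(fam, axis=0)
    observed, null = float(med[0]), med[1:]
    mean = float(null.mean())
    nd = (observed - mean) / mean if mean > 0 else float("nan")
    with np.errstate(invalid="ignore", divide="ignore"):
        ctrl_mean_per_point = fam[:, 1:].mean(axis=1)
        point_nd = np.where(
            ctrl_mean_per_point > 0,
            (fam[:, 0] - ctrl_mean_per_point) / ctrl_mean_per_point,
            np.nan,
        )
    return {
        "n_data_points": int(fam.shape[0]),
        "observed_median_density": observed,
        "null_mean_of_medians": mean,
        "nd": float(nd),
        "median_nd_per_point": float(np.nanmedian(point_nd)),
        "p_enrichment": empirical_p(observed, null, "greater").p,
        "p_depletion": empirical_p(observed, null, "less").p,
        "point_nd": point_nd,
        "family_density": fam[:, 0],
    }


def _load_inputs(config: RunConfig):
    if config.synthetic is not None:
        cohort = make_cohort(config.synthetic)
        motifs = config.synthetic.motifs()
        return cohort, motifs
    genes = eio.load_genes(config.cds_fasta, config.architecture_tsv)
    motifs = load_motifs(config.motif_file)
    from .synthetic import SyntheticCohort

    orth = {}
    if config.ortholog_fasta:
        orth = eio.read_fasta(config.ortholog_fasta)
    from .seqprep import align_cds_pair

    pairs = []
    for g in genes:
        key = f"{g.gene_id}_ortholog"
        if key in orth:
            pairs.append(align_cds_pair(g.gene_id, g.cds, key, orth[key]))
    snps = eio.read_snps(config.snp_tsv) if config.snp_tsv else []
    retro = eio.read_bed(config.retro_bed) if config.retro_bed else []
    intervals = {g.gene_id: ("chr0", 0, g.cds_length) for g in genes}
    cohort = SyntheticCohort(
        genes, pairs, snps, retro, intervals, pd.DataFrame(), config.synthetic
    )
    return cohort, motifs


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    report: dict = {"schema_version": 1, "seed": config.seed, "stages": {}}
    cohort, motifs = _load_inputs(config)
    genes = cohort.genes
    if not genes:
        if config.synthetic is not None and config.synthetic.n_genes == 0:
            report["stages"]["prep"] = {"n_input": 0, "n_valid": 0}
            return _finish(report, out_dir)
        raise ValueError("prep stage: empty gene set")

    # --- prep: validation + ortholog filtering + clustering ---------------
    verdicts = {g.gene_id: validate_cds(g.cds) for g in genes}
    valid = [g for g in genes if verdicts[g.gene_id].passed]
    if not valid:
        raise ValueError("prep stage: no gene passed CDS validation")
    aln_of = {a.focal_id: a for a in cohort.ortholog_pairs}
    kept = []
    n_diverged = 0
    for g in valid:
        aln = aln_of.get(g.gene_id)
        if aln is None:
            kept.append(g)
            continue
        if ortholog_pair_passes(pairwise_codon_rates(aln), config.species_mode):
            kept.append(g)
        else:
            n_diverged += 1
    intronless = [g for g in kept if g.exon_count == 1]
    multi = [g for g in kept if g.exon_count > 1]
    groups = {"intronless": intronless, "intron_containing": multi}
    families = {
        name: cluster_families(gs) if gs else []
        for name, gs in groups.items()
    }
    report["stages"]["prep"] = {
        "n_input": len(genes),
        "n_valid": len(valid),
        "n_dropped_diverged": n_diverged,
        "n_intronless": len(intronless),
        "n_intron_containing": len(multi),
        "n_families": {k: len(v) for k, v in families.items()},
    }

    # --- nulls -------------------------------------------------------------
    controls = build_control_sets(
        motifs, config.n_control_sets, substream(config.seed, "controls")
    )
    ds_controls = ControlSetCollection(
        controls.sets[: config.n_control_sets_ds], controls.seed
    )

    # --- enrichment per group ----------------------------------------------
    enrich = {}
    point_tables = {}
    for name, gs in groups.items():
        if not gs:
            continue
        res = group_enrichment(gs, motifs, controls, families[name])
        point_nd = res.pop("point_nd")
        fam_density = res.pop("family_density")
        enrich[name] = res
        reps = [f.representative_id for f in families[name]]
        by_id = {g.gene_id: g for g in gs}
        fam_members = {f.representative_id: sorted(f.member_ids) for f in families[name]}
        point_tables[name] = pd.DataFrame(
            {
                "nd": point_nd,
                "density": fam_density,
                "exon_count": [
                    float(np.mean([by_id[m].exon_count for m in fam_members[r]]))
                    for r in reps
                ],
                "cds_length": [
                    float(np.mean([by_id[m].cds_length for m in fam_members[r]]))
                    for r in reps
                ],
            },
            index=reps,
        )
    report["stages"]["enrichment"] = enrich

    # --- trend statistics: ND vs exon number, controlling CDS length -------
    if point_tables:
        allpoints = pd.concat(point_tables.values())
        allpoints = allpoints.dropna()
        counts = allpoints["exon_count"].round().value_counts()
        small = counts[counts < config.min_exon_class_size].index
        trimmed = allpoints[~allpoints["exon_count"].round().isin(small)]
        trends = {}
        if len(trimmed) >= 4 and trimmed["exon_count"].nunique() > 1:
            g = gk_gamma(
                trimmed["exon_count"].to_numpy(),
                trimmed["density"].to_numpy(),
                n_shuffles=1000,
                rng=substream(config.seed, "gamma"),
            )
            pc = partial_rank_correlation(
                trimmed["nd"].to_numpy(),
                trimmed["exon_count"].to_numpy(),
                trimmed["cds_length"].to_numpy(),
            )
            trends = {
                "gamma_density_exon_number": g.statistic,
                "gamma_p": g.p_raw,
                "partial_spearman_nd_exon_number": pc.statistic,
                "partial_spearman_p": pc.p_raw,
                "n_points": int(len(trimmed)),
            }
        report["stages"]["trends"] = trends

    # --- selection tests ----------------------------------------------------
    selection = {}
    rng_sel = substream(config.seed, "selection")
    for name, gs in groups.items():
        if not gs:
            continue
        reps = []
        for f in families[name]:
            members = sorted(f.member_ids)
            reps.append(members[rng_sel.integers(len(members))])
        alns = [aln_of[r] for r in reps if r in aln_of]
        entry = {}
        if alns:
            ds = concatenated_ds(alns, motifs, ds_controls)
            entry["ds"] = {
                "observed": ds.observed_ds,
                "null_mean": float(np.nanmean(ds.null_ds)),
                "normalized": ds.normalized_ds,
                "reduction_percent": 100.0 * ds.reduction,
                "p_reduction": ds.test.p,
            }
        if cohort.snp_table:
            snp = snp_statistics(
                gs,
                cohort.snp_table,
                motifs,
                ds_controls,
                families[name],
                rng=substream(config.seed, f"snp_{name}"),
            )
            entry["snp"] = {
                "density_4d": snp.density_4d,
                "density_4d_all": snp.density_4d_all,
                "low_maf_fraction": snp.low_maf_fraction,
                "p_density": snp.p_density,
                "p_low_maf": snp.p_low_maf,
            }
        selection[name] = entry
    report["stages"]["selection"] = selection

    # --- broad retrocopy calls (also feed the architecture stage) ----------
    broad_ids: list[str] = []
    if cohort.retro_annotations and intronless:
        retro_intervals = {
            g.gene_id: cohort.gene_intervals[g.gene_id] for g in intronless
        }
        broad_ids = [
            c.gene_id
            for c in broad_retrocopy_calls(retro_intervals, cohort.retro_annotations)
            if c.tier == "broad"
        ]

    # --- architecture -------------------------------------------------------
    architecture = {}
    if config.run_architecture_matrix and kept:
        # broad-call retrocopies are excluded from the matrix unless the run
        # keeps them (a smaller bin count preserves per-bin sample sizes then)
        if config.include_retrocopies or not broad_ids:
            arch_genes = kept
            arch_families = families["intronless"] + families["intron_containing"]
        else:
            arch_genes = [g for g in kept if g.gene_id not in set(broad_ids)]
            arch_families = cluster_families(arch_genes) if arch_genes else []
        dp = family_datapoints(arch_genes, arch_families, motifs)
        bins = assign_bins(dp.mean_intron_size.to_numpy(), config.n_quantile_bins)
        matrix = motif_bin_matrix(dp, bins)
        trends = motif_trend_tests(matrix)
        labels = pd.Series([t.label for t in trends])
        architecture = {
            "n_bins": bins.n_bins,
            "n_positive": int((labels == "positive").sum()),
            "n_negative": int((labels == "negative").sum()),
            "n_nonsignificant": int((labels == "nonsignificant").sum()),
        }
        if out_dir is not None:
            matrix.raw.to_csv(Path(out_dir) / "motif_bin_matrix_raw.tsv", sep="\t")
            matrix.normalized.to_csv(
                Path(out_dir) / "motif_bin_matrix_normalized.tsv", sep="\t"
            )
    report["stages"]["architecture"] = architecture

    # --- retrocopies ---------------------------------------------------------
    retro = {}
    if cohort.retro_annotations and intronless:
        retro["n_broad"] = len(broad_ids)
        if (
            broad_ids
            and len(broad_ids) < len(intronless)
            and config.leave_k_out_iterations > 0
        ):
            lko = leave_k_out(
                intronless,
                motifs,
                ds_controls,
                broad_ids,
                iterations=config.leave_k_out_iterations,
                rng=substream(config.seed, "leave_k_out"),
            )
            retro["leave_k_out"] = {
                "full_nd": lko.full_nd,
                "removed_nd": lko.removed_nd,
                "delta_nd": lko.delta_nd,
                "p_delta_nd": lko.test_nd.p,
                "p_delta_p": lko.test_p.p,
            }
    report["stages"]["retro"] = retro
    return _finish(report, out_dir)


def _finish(report: dict, out_dir) -> dict:
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True, allow_nan=True) + "\n"
        )
    return report
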