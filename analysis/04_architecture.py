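"""Architecture-stratified motif usage.

Bins family data points by mean intron size (intronless genes are bin 0,
intron-containing genes cut at quantiles), builds the bin x motif density
matrix normalized by each motif's 60 dinucleotide-permutation controls,
classifies per-motif trends against bin index (Holm-adjusted Spearman), and
contrasts flank vs core motif density in long exons for the high- and
low-purine motif subsets.
"""

import pandas as pd
from _common import STUDY_CONFIG, STUDY_SEED, results_dir

from esescan import assign_bins, flank_core_contrast, make_cohort, split_motifs
from esescan.architecture import family_datapoints, motif_bin_matrix, motif_trend_tests
from esescan.nulls import build_control_sets
from esescan.scan import extract_windows_batch
from esescan.seqprep import cluster_families
from esescan.synthetic import substream


def main():
    out = results_dir("architecture")
    cohort = make_cohort(STUDY_CONFIG)
    motifs = STUDY_CONFIG.motifs()
    genes = cohort.genes
    families = cluster_families(genes)
    dp = family_datapoints(genes, families, motifs)
    bins = assign_bins(dp.mean_intron_size.to_numpy(), 8)
    matrix = motif_bin_matrix(dp, bins)
    matrix.raw.to_csv(out / "motif_bin_matrix_raw.tsv", sep="\t")
    matrix.normalized.to_csv(out / "motif_bin_matrix_normalized.tsv", sep="\t")
    trends = motif_trend_tests(matrix)
    pd.DataFrame(
        [
            {"motif": t.motif, "label": t.label, "rho": t.statistic,
             "p_raw": t.p_raw, "p_holm": t.p_adjusted}
            for t in trends
        ]
    ).to_csv(out / "motif_trend_classes.tsv", sep="\t", index=False)
    labels = pd.Series([t.label for t in trends]).value_counts()
    print(f"{bins.n_bins} intron-size bins; trend classes: {labels.to_dict()}")

    # flank/core contrast in exons long enough for three 69-bp windows
    exons = []
    for g in genes:
        if g.exon_count < 3:
            continue
        for idx, (a, b) in enumerate(g.exon_intervals[1:-1], start=1):
            exons.append((f"{g.gene_id}_e{idx}", g.cds[a:b], a % 3))
    windows, rejected = extract_windows_batch(exons)
    print(f"exon windows: {len(windows)} usable, {len(rejected)} rejected")
    if len(windows) >= 20:
        high, low = split_motifs(motifs, "purine")
        ctrl_h = build_control_sets(high, 200, substream(STUDY_SEED, "fc_high"))
        ctrl_l = build_control_sets(low, 200, substream(STUDY_SEED, "fc_low"))
        res = flank_core_contrast(
            [w for _, w in windows], (high, low), (ctrl_h, ctrl_l)
        )
        print(
            f"flank/core ND ratio: high-purine {res.ratios[0]:.3f}, "
            f"low-purine {res.ratios[1]:.3f}, difference "
            f"{res.ratio_difference:.3f}"
            + (f" (one-tailed p {res.test.p:.3g})" if res.test else " (undefined)")
        )
        pd.DataFrame(
            {
                "subset": ["high_purine", "low_purine"],
                "nd_flank": list(res.nd_flank),
                "nd_core": list(res.nd_core),
                "ratio": list(res.ratios),
            }
        ).to_csv(out / "flank_core.tsv", sep="\t", index=False)
    print(f"tables in {out}")


if __name__ == "__main__":
    main()
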