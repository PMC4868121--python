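# esescan

Exonic splice enhancers (ESEs) are short exonic motifs — treated here as
literal hexamers — that promote splice-site recognition, classically through
SR-protein binding. Intronless genes are never spliced, so any enrichment of
ESE motifs in their coding sequence, or purifying selection acting on those
motifs, is evidence of splicing-independent function. `esescan` implements
the complete analysis chain for asking that question from coding sequences,
gene architecture, ortholog pairs, SNP tables and retrocopy annotations:

* exact hexamer scanning with union coverage (overlapping hits count once)
  and density at gene, paralogous-family, pooled and exon-window granularity;
* dinucleotide-controlled nulls: random hexamer sets drawn from the real
  motifs' dinucleotide pool, windowed codon shuffling, and the 60
  dinucleotide-permutation controls of each individual motif;
* the statistics layer: normalized density ND = (obs − null mean)/null mean,
  add-one empirical p-values p = (n+1)/(m+1), exact binomial tests,
  Goodman–Kruskal gamma with a shuffle null, partial Spearman correlation,
  Holm adjustment;
* selection tests inside motif regions: codon-repaired block extraction,
  concatenated Nei–Gojobori dS against control motif sets, SNP density at
  fourfold-degenerate sites, and the fraction of low-MAF (< 1/2000) variants;
* architecture stratification: mean-intron-size quantile bins (intronless
  genes form bin 0), the bin × motif ND matrix, Holm-classified per-motif
  trends, and exon flank-versus-core contrasts;
* retrocopy analyses: overlap-based broad calls, strict parent matching at
  dN < 0.2, ancestral exon–exon junction mapping, and leave-k-out resampling
  of the retrocopies' contribution to enrichment.

A first-class synthetic-data generator (`esescan.synthetic`) produces cohorts
with known planted structure — GC4 declining with exon number, motifs planted
at a controlled excess over dinucleotide expectation with an exon-end bias,
orthologs whose synonymous rate is scaled inside motif hits, SNPs with a
rare-allele excess inside motifs, and retrocopies inheriting parent motifs —
so the whole pipeline is testable without external data. A packaged
*synthetic* 84-hexamer fixture set stands in when no real motif file is
supplied.

## Worked example

```python
from esescan import SyntheticConfig, make_cohort, build_control_sets
from esescan import group_enrichment, cluster_families
from esescan.selection import concatenated_ds
from esescan.synthetic import substream

cfg = SyntheticConfig(n_genes=150, seed=20160331)   # defaults: planted_nd=0.25, ese_ds_scaling=0.8
cohort = make_cohort(cfg)
motifs = cfg.motifs()

intronless = [g for g in cohort.genes if g.exon_count == 1]
families = cluster_families(intronless)
controls = build_control_sets(motifs, 1000, substream(cfg.seed, "controls"))

enr = group_enrichment(intronless, motifs, controls, families)
print(enr["observed_median_density"], enr["nd"], enr["p_enrichment"])
# 0.1508...  0.220...  0.000999...
```

The median motif density of intronless genes (0.151) exceeds the mean of the
control-set medians by 22% (ND ≈ +0.22, close to the planted 25% excess), and
no control set reaches it, so the enrichment p-value sits at its floor
1/1001 ≈ 0.001. Running the numbered drivers reproduces the full study on
the same cohort:

```text
$ python analysis/01_simulate_cohort.py
cohort: 156 genes (38 intronless), 156 pass ORF validation
$ python analysis/02_enrichment.py
intronless: median density 0.1508, ND +0.220, enrichment p 0.000999 (35 family data points)
intron_containing: median density 0.1502, ND +0.241, enrichment p 0.000999 (112 family data points)
$ python analysis/03_selection_tests.py
intronless: dS 0.1264 vs expected 0.1498 (15.6% slower, p 0.01397); low-MAF fraction 0.365 (p 0.016)
intron_containing: dS 0.1193 vs expected 0.1512 (21.1% slower, p 0.001996); low-MAF fraction 0.391 (p 0.002)
```

The dS numbers recover the planted 20% synonymous slowdown inside motif
regions (the expected dS is itself slightly depressed because control regions
overlap real motif hits); the elevated low-MAF fractions inside motifs
reflect the planted rare-variant excess. `analysis/04_architecture.py` and
`analysis/05_retrocopies.py` cover the bin × motif matrix with trend classes,
the flank/core contrast, retrocopy calls and the leave-k-out resampling;
tables land under `results/`.

A `esescan` console script exposes the stages (`simulate`, `prep`, `scan`,
`enrich`, `selection`, `architecture`, `retro`, `run-all`) over
FASTA/BED/TSV inputs; see `esescan --help`.

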