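# Methods

## The question and the approach

Exonic splice enhancers (ESEs) are short exonic motifs — modelled here as
literal hexamers over {A,C,G,T} — that recruit SR proteins to promote
splice-site recognition. Because intronless genes are never spliced, any
enrichment of, or purifying selection on, ESE motifs in intronless coding
sequence points to splicing-independent functions. The package implements the
full inference chain needed to ask that question: exact motif scanning with
union coverage, dinucleotide-controlled null models, normalized density (ND)
with add-one empirical p-values, synonymous-rate and polymorphism tests
restricted to motif regions, architecture-stratified per-motif analyses, and
retrocopy contrasts. A synthetic-data generator provides cohorts with known
planted structure so every stage is testable end to end without external
databases.

## Core definitions

* **Density**: fraction of CDS positions covered by at least one motif hit;
  overlapping hits count each base once. Pooled density over a group is
  summed covered bases over summed lengths.
* **Paralogous families**: connected components of a significant-similarity
  graph over the gene set. Each family is one data point; member values are
  averaged (or one random member is drawn, for dS and SNP analyses). The
  representative is the longest CDS, ties broken by the alphabetically
  smallest transcript identifier.
* **Dinucleotide pool null**: the real motifs are decomposed into their five
  overlapping dinucleotides (both reading frames); a control hexamer is three
  pool draws with replacement, redrawn if it equals a real motif. A control
  *set* has the cardinality of the real set; 10,000 sets form the default
  null (1,000 for the computationally heavier dS null). The pool uses the
  five overlapping pairs per motif rather than pairs spanning an arbitrary
  concatenation order, so the count contract (5 per motif) is exact.
  Duplicate hexamers within a control set are allowed by default (plain
  sampling with replacement); a `dedupe` switch removes them. Note that
  rejection of real-set members measurably shifts control composition when
  the real set is compositionally concentrated (about 7.5% of draws are
  rejected for the packaged fixture set); this is a property of the method,
  not a defect, and it is why calibration runs use a pool-drawn query set
  (below).
* **ND**: (observed − null mean) / null mean; −1 when the observed density is
  0 against a positive null mean; undefined (NaN, never dropped silently)
  when the null mean is 0. In the per-motif architecture matrix the null
  centre is the *median* over that motif's ≤60 dinucleotide-permutation
  controls instead.
* **Empirical p**: (n+1)/(m+1) with ties counted as extreme; the floor is
  1/(m+1) and 0 is unreachable. One consequence worth noting: when observed
  and all simulants are exactly tied (e.g. dS of identical sequences), the
  one-tailed p is 1, not the floor.
* **Permutation controls of one motif**: ordered selections of 3 of its 5
  overlapping dinucleotides, no position reuse, deduplicated — exactly 60
  hexamers when the five dinucleotides are distinct, including the identity
  tiling (an option excludes it).
* **NG86 divergence**: fractional synonymous site counts per codon (changes
  to stop codons count as nonsynonymous), pairwise differences averaged over
  mutational pathways excluding those through stop codons, Jukes–Cantor
  correction dS = −(3/4)·ln(1 − (4/3)·pS), undefined for pS ≥ 3/4. Columns
  with gaps or stop codons are excluded. Tests cross-check single-hit codon
  pairs against Biopython's independent implementation; multi-hit pathway
  weighting is a known convention point on which implementations differ.
  A dn/ds ratio with ds = 0 is undefined and passes ratio-based filters.

## Motif-region dS

Contiguous masked runs are cut to codon-complete blocks: an incomplete final
codon is trimmed; an incomplete initial codon is expanded with 1–2 upstream
bases. If the expanded initial codon encodes Leu or Arg, its first two bases
are rewritten to GA (third position twofold degenerate) or GC (fourfold) in
both rows, unless the ortholog codon is a gap; the rewrite preserves the
degeneracy class of the retained third position, so the block keeps its
original synonymous site without importing one at the repaired edge. Blocks
are concatenated across one representative per family and a single dS
computed; repeating the scan-and-concatenate protocol per control motif set
gives the null. NG86 counts are additive before correction, so the result is
invariant to concatenation order.

## Exon windows

Flank/core contrasts use internal, fully coding exons of at least
211 bp (= 69×3 + 2×2): after trimming at most two bases per end to codon
boundaries, the upstream flank is the first 69 in-frame bases, the downstream
flank the last 69, and the 69-bp core sits midway when the inter-flank codon
gap minus 23 codons is even, otherwise one codon nearer the 5′ end (margins
n and n+3 bases). Parity is evaluated in codons, consistent with the n vs
n+3 offset being a whole codon; windows are disjoint by construction. The
contrast statistic is the difference between the two subsets' flank-ND/core-ND
ratios; its null substitutes index-paired control sets for the observed
subsets, dropping (as undefined) iterations whose core ND is nonpositive.
This null is heavy-tailed by nature — ratios of near-zero NDs — which is why
the package also reports the component NDs.

## Architecture matrix

Family data points are binned by family-averaged mean intron size: bin 0
holds the intronless points, intron-containing points are cut at every 1/48th
quantile (49 bins; a 37+1 mode exists for runs that keep retrocopies), ties
at a boundary falling into the lower bin. Cell (b, j) of the raw matrix is
the summed family-averaged covered bases of motif j in bin b over the summed
family-averaged CDS lengths. Normalization is per cell against the median of
the motif's permutation-control scans; cells with a zero simulant median are
undefined and dropped from that motif's trend test. Trends are Spearman
correlations of each normalized column against bin indices 0..B−1, Holm
step-down adjusted across motifs, classified positive/negative at adjusted
p < 0.05. As a carried diagnostic, the fraction of a motif's permutation
controls that are themselves real motifs can be reported per motif.

## SNP statistics

SNP density at fourfold-degenerate sites is synonymous SNPs at masked
fourfold sites over masked fourfold sites (the all-SNP numerator is also
emitted, since sources differ on this point); the rare-variant statistic is
the fraction of masked segregating sites with MAF below 1/2000 (a deliberately
arbitrary, configurable threshold). Because one random member per family
enters the analysis, the whole computation is repeated ten times with
re-drawn representatives and the medians of the statistics and of their
one-tailed empirical p-values are reported. The motif mask is taken at the
whole-CDS level.

## Retrocopies

A broad call requires ≥50% (inclusive) of the gene span to be overlapped by
the union of retrocopy annotations. Strict calls additionally require a
translatable candidate parent whose CDS length ratio exceeds 0.5 and whose
protein-level alignment, back-threaded to codons, gives dN < 0.2; the
lowest-dN candidate is the parent and one lowest-dN member is kept per
family. Ancestral junctions are the noninitial parent-exon starts mapped
through the pairwise alignment; a junction whose first 30 parent bases align
with under 50% non-indel columns yields no pseudo-junction. A hit is "near" a
junction when its start is within 50 bp inclusive. The leave-k-out resampling
removes k random genes per iteration (families re-derived as components of
the induced subgraph, per-gene densities precomputed once), recording the
decrease in ND and increase in empirical p relative to the full set; the true
removal's deltas are placed in those null distributions one-tailed.

## The synthetic generator

`SyntheticConfig` defaults are the study conditions; they were fixed once,
before the recovery and calibration tests were run, and are not tuned:

| parameter | default | rationale |
|---|---|---|
| `n_genes` | 200 | family-level sample comparable to a few hundred data points |
| `exon_number_law` | 20% single-exon, else 2+Poisson(6) | intronless minority with a broad multi-exon tail |
| `cds_length_law` | lognormal, median 600 codons (1800 nt), min 300 nt | realistic filtered-CDS lengths |
| `gc4_intercept`, `gc4_slope` | 0.62, −0.012 per added exon (noise SD 0.05) | single-exon genes most GC-rich at fourfold sites, gradual decline |
| `planted_nd` | 0.25 | motif coverage ~25% above dinucleotide expectation, matching observed intronless ND magnitudes |
| `end_bias` | 2.0 | planting twice as likely within 69 bp of exon boundaries |
| `ds_background` | 0.16 | rodent-like synonymous divergence; gives the concatenated-dS estimator adequate counting statistics at desk scale |
| `ese_ds_scaling` | 0.8 | 20% synonymous slowdown inside motif hits |
| `snp_rate` | 0.02 per site | a few thousand segregating sites per cohort |
| `rare_base_prob`, `rare_excess` | 0.28, 1.3 | background low-MAF fraction ≈ 0.3, elevated inside motifs |
| `paralog_fraction` | 0.05 | some nonsingleton families (near-copies at ~2% synonymous divergence) |
| `retro_fraction` | 0.05 | a handful of intronless retrocopies with annotations |

Mechanisms worth recording:

* **Sequences** are built codon-wise: uniform amino acids, synonymous codon
  chosen with third-position G/C probability equal to the gene's target GC4
  (drawn from the linear-in-exon-number mean). This makes realized GC4 track
  the target directly and keeps ORFs valid by construction.
* **Planting** writes motif instances over the sequence at weighted positions
  (end-windows weighted by `end_bias`), never overlapping one another, never
  touching start/stop codons, and never creating an in-frame stop (partial
  edge codons are repaired through unprotected bases; impossible placements
  are rolled back). The planted count per gene is Poisson with mean
  `planted_nd × background coverage / 6`, so realized cohort-level excess is
  approximately `planted_nd` — approximate because planting also perturbs
  background hits, and because control sets carry the duplicate/rejection
  composition effects described above.
* **Ortholog evolution** substitutes synonymously only, per codon position,
  with probability q·s_p, where s_p is the NG86 fractional synonymous-site
  weight and q inverts the Jukes–Cantor correction at `ds_background`, so the
  corrected NG86 estimate recovers `ds_background` in expectation (applying
  the raw rate instead would overshoot by ~10% at this divergence). Inside
  motif hits the probability is multiplied by `ese_ds_scaling`. Translation
  identity of the two rows is asserted in tests for every generated pair.
* **SNPs**: every position segregates with probability `snp_rate`; the
  alternate allele is a uniform different base (variants creating stop codons
  are skipped), consequence annotated from the codon change. A variant is
  rare with probability `rare_base_prob`, multiplied by `rare_excess` (capped
  at 0.95) inside motif hits; rare MAFs are uniform below the threshold,
  common MAFs log-uniform up to 0.5.
* **Retrocopies** copy the parent CDS verbatim (optional synonymous
  substitutions only, so parent dN stays 0) into a single-exon record with
  its own genomic interval and annotation.
* **Randomness**: one integer seed; each stage draws from a named substream
  (CRC32 of the stage name spawning a `SeedSequence`), so identical seeds are
  byte-identical and stages can be re-run independently.

What the generator does **not** emulate: real intron sequence, splice-site
strength, expression, codon-usage bias beyond the GC4 dial, transition/
transversion asymmetry, linkage between SNPs, or the lncRNA analyses. Passing
tests therefore demonstrate that the inference machinery recovers known
planted structure under a neutral-composition model — not that any particular
biological dataset would show these effects.

## Calibration and power choices

* The dS-reduction recovery runs at 200 genes with 1,000 control sets. Under
  the study conditions the estimator's expected reduction is ≈18%, not
  exactly 20%: control motif regions overlap the real-motif mask by roughly
  the mask density (~15%), so the null is itself slightly slowed. The
  seed-to-seed standard deviation is ≈1.3 points (measured over 16 seeds),
  placing the estimate comfortably within the 15–25% acceptance band.
* The all-null calibration (50 replicate cohorts of 30 genes, 200 control
  sets, planting/scaling/rare-excess/GC4-gradient all off) uses a query
  hexamer set that is itself a deduplicated pool draw, making query and
  controls exchangeable by construction; both the enrichment and the dS
  empirical p-values are then uniform (Kolmogorov–Smirnov check). Using the
  fixed fixture set as the query instead would test its composition quirks
  (duplicates and rejection bias in the controls), not the machinery.
* The planted-trend harness pairs every rising motif with a falling
  dinucleotide permutation of itself so total planted composition is
  bin-invariant; otherwise background-composition drift leaks a spurious
  trend into flat motifs through their permutation-control medians.
* Problem sizes throughout the test suite (cohorts of 3–200 genes, 10–1,000
  control sets, 8–49 bins) were chosen as the smallest sizes at which each
  property has clear statistical power.

## Numerical and degenerate-input conventions

Undefined values are NaN-marked and serialized explicitly, never silently
dropped: zero null means (ND), pS ≥ 3/4 (dS), dn/ds with ds = 0, nonpositive
core ND (flank/core ratios), bins or masks without countable sites.
Boundaries are inclusive where the definitions say "at least" (broad-call
overlap ≥ 0.5, junction distance ≤ 50, median ties to the high motif subset,
quantile-boundary ties to the lower bin). Intervals are 0-based half-open
internally and in BED output. Similarity clustering is deterministic and
order-invariant (components are canonical; seeding order is sorted).

## Known limitations

* The in-repo similarity screen (shared-12-mer prescreen + local alignment
  with Karlin–Altschul e-values under +1/−2 scoring) is tuned for desk-scale
  self-containment, not BLASTN parity; the e-value threshold is exposed.
* The NG86 estimator replaces codeml; on strongly diverged or
  composition-biased pairs the two will not agree numerically. Acceptance is
  by parameter recovery on synthetic data, not estimator equality.
* The flank/core ratio-difference null is heavy-tailed; with weak positional
  signal the test has little power, and undefined iterations shrink the
  effective simulant count.
* Median-based group statistics respond weakly to minority subsets; leave-k-out
  analyses need the removed class to be a substantial fraction of the group
  before the deltas are detectable, which the drivers' printed effective
  sizes make visible.
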