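# Methods

This note documents the models behind `polyhomeo`, the defaults of the
synthetic allopolyploid generator, the numerical choices in each estimator,
and what the test suite does and does not demonstrate about real data.

## The system being modelled

A selfing allotetraploid formed from two diverged parents. The two
subgenomes (TH: 5 chromosomes; AR: 8 chromosomes; ~11.6% diverged) are each
present in two homozygous copies. Analyses compare four population panels:
the natural allopolyploid, the two pure ancestors, and a resynthesized
("synthetic") hybrid. Homeologs are restricted to 1:1 pairs; tandem
duplications, fractionation and many-to-many orthology are out of scope.

## Expression model and normalization

### Cross-mapping

Short reads from one subgenome can align to the homeologous copy. This is
modelled at the **count level**: in a pure-ancestor sample a fraction of
every gene's expected signal is reassigned to the partner's row (defaults
`leak_th = 0.06` into TH rows from an AR-parent sample, `leak_ar = 0.01`
into AR rows from a TH-parent sample, the asymmetry reflecting the higher
polymorphism of the AR parent). Allopolyploid samples express both rows with
no reassignment; within the polyploid, diversity is low enough that reads
map to the correct subgenome. Read-level simulation (FASTQ) is deliberately
not attempted: the observable consequence of cross-mapping is the count
displacement, and that is what the filter and the leak estimator operate on.

The cross-mapping **filter** removes a gene when the wrong species drives
its signal: for a TH-subgenome gene, log2((mean count in thaliana samples +
p) / (mean count in arenosa samples + p)) < 0 with p = 0.5, mirrored for AR
genes. The inequality is strict; ties are kept. The orientation (filtering
*out* genes failing the inequality) is the one consistent with gene counts
decreasing after the step.

### Library sizes

Pure ancestors transcribe one subgenome, the polyploid both, so raw library
sizes are incomparable. The pipeline: counts → TPM (length-normalized,
sums to 1e6 per sample) → TMM factors per subgenome → effective sizes:

- ancestor sample: TPM total over its own subgenome × that subgenome's TMM
  factor (the other subgenome's rows, which carry only cross-mapping noise,
  are excluded);
- allopolyploid sample: mean of the two TMM-scaled subgenome totals.

TMM uses the standard published parameters (30% two-sided trim on M-values,
5% on A-values, inverse-asymptotic-variance weights, factors normalized to
geometric mean 1, reference sample = closest to the mean upper quartile).
The implementation reproduces the reference R implementation (edgeR) to
~1e-6 relative on shared fixtures; one subtlety is that the M-ratio must be
computed as a single log so exact count ties stay tied through the rank
trimming. TMM factors per subgenome are computed across the samples whose
species transcribes that subgenome; other samples keep factor 1 (their
factor is never used).

log2(CPM) = log2((x + prior)/size × 1e6) with prior 1. "Expressed" in the
pair filter means CPM > 1 in an accession (replicate mean); the pair filter
requires the TH member expressed in ≥3 thaliana and ≥3 natural-polyploid
accessions, the AR member in ≥1 arenosa and ≥3 natural-polyploid
accessions, and each member in ≥1 synthetic accession. The panel-to-member
assignment is a design choice: a member can only meaningfully be "expressed"
in panels that carry its subgenome.

### Downstream statistics

All tests run on accession means of log2(CPM) (replicates collapsed first).
Differential expression between species panels is a two-sided Wilcoxon
rank-sum per gene: exact null enumeration when both groups have ≤8
accessions and the data are tie-free, otherwise the normal approximation
with tie and continuity corrections; genes constant across both groups get
p = 1. BH correction is applied across all genes tested; DEG means q <
0.05. PCA is per subgenome on gene-centred (not scaled) values, components
signed so the largest-magnitude loading is positive. DEG clustering uses
hierarchical clustering with 1 − Pearson distance and average linkage, cut
at k = 3 clusters per subgenome (the number of interpretable clusters in
this kind of analysis); labels are canonicalized by each cluster's smallest
gene id so the partition is row-order invariant, and zero-variance genes
(no correlation defined) are assigned to the nearest centroid afterwards.

## Copy number and nucleolar dominance

copies = (mean window depth over the locus / genome-wide mean depth) ×
baseline. The genome-wide normalizer **excludes the locus windows**: the
locus under measurement is typically a collapsed repeat consensus carried
alongside the assembly and must not inflate its own reference level. The
mean is the primary normalizer; the median is reported alongside as a
robustness diagnostic. When comparing two consensus sequences, both are
first truncated to their best mutual alignment span; the coordinate span
and the gapped alignment length can differ (alignment gaps), so both are
reported rather than reconciled.

45S expression calls use log2(CPM) with a strict (>) cut-off of 15 — the
maximum cross-mapping level observed in ancestral controls — giving four
dominance classes (both / th_only / ar_only / neither) that partition a
panel. The flow-cytometry formula 2C = (sample G1 mean / standard G1 mean) ×
standard 2C is implemented verbatim.

## Homeologous-exchange caller

The observational evidence chain (coverage loss + doubled homeologous coverage
+ Hi-C breakpoint contacts + discordant pairs) is formalized as a caller;
all thresholds are engineering choices exposed as configuration:

- depth ratio r = depth / genome median → states: r < 0.25 → 0 copies,
  0.5 ≤ r ≤ 1.5 → 2, r > 1.6 → 4; other ratios are ambiguous and inherit
  the flanking state (longer flank wins, left on ties);
- maximal same-state runs; runs shorter than 5 windows are absorbed into
  the longer flanking run;
- a 0-segment is a candidate HE when its interval, projected through the
  homeolog pairs it contains, overlaps a 4-segment on the other subgenome
  with Jaccard ≥ 0.5 on gene sets (projection is gene-anchored, not
  sequence-based);
- a candidate is called when trans-contact enrichment around the
  breakpoints is ≥ 2 (mean over ±2 bins around each breakpoint pair over
  the chromosome-pair trans mean) or ≥ 3 discordant pairs fall within 2 kb
  of the breakpoints.

The copy baseline is fixed at 2 per subgenome (selfing allotetraploid ⇒
homozygous), so HE states are exactly {0, 2, 4}; heterozygous 1/3 states
are out of scope. Breakpoint resolution is one window. Note the contact
enrichment statistic divides by the *whole* chromosome-pair trans mean; on
a miniature genome the spike itself inflates that background, so simulated
Hi-C should use bins small relative to chromosome length (the test fixtures
use 10 kb bins on 125–400 kb chromosomes; real data at 25 kb resolution has
no such problem).

## TE population dynamics

Raw per-accession insertion calls of the same family within 400 bp are
single-linkage merged (midpoint position), first within accessions, then
across the population — merging is idempotent. Sites are matched across
panels (polyploid vs ancestor, both on the polyploid's coordinates) by
family and position within the same 400 bp, giving sharing classes
shared / unique_polyploid / unique_ancestor. Missing calls ("NA": no
coverage) never enter frequency denominators; sites with >20% missing are
excluded from spectra (an explicit rule of this artifact). Frequencies are
binned at the panel's modal non-missing denominator; the fixed class is
included. For an outcrossing autotetraploid ancestor, four random polyploid
accessions are pooled by union ("4n") before load comparisons.

Family collapse removes a consensus when another is >85% identical over
>85% of its length (longest representative kept per connected component);
ancestry assignment uses the analogous 80%/80% rule against the two
ancestral genomes, with "ambiguous" (both pass) surfaced as its own class
rather than resolved by best hit.

The jump null model is exact arithmetic: E[A→B]/E[B→A] =
(N_A × L_B)/(N_B × L_A); the observed fold and its excess over expectation
are reported, with zero observed counts reported as undefined rather than
dropped.

## Synthetic data generator

The generator is first-class, tested code; its defaults are the study
conditions:

| parameter | default | meaning |
|---|---|---|
| chromosomes | 5 TH + 8 AR | two-subgenome reference |
| divergence | 0.116 | recorded subgenome divergence |
| leak_th / leak_ar | 0.06 / 0.01 | cross-mapping into TH / AR rows |
| expression panels | 15 / 4 / 15 / 2 | thaliana / arenosa / natural / synthetic accessions |
| replicates | 3 | per accession |
| nb_dispersion | 0.05 | NB var = m + 0.05 m² |
| accession_sd | 0.25 | log2 accession effect (biological variation) |
| TE panels | 18 / 9 / 15 | thaliana / arenosa / polyploid accessions |
| founder_k | 4 | founder bottleneck draws |
| shared TE freq | Beta(0.5, 0.5) | ancestral insertion frequencies |
| private TE freq | Beta(0.2, 2) | rare-skewed (purifying selection) |
| depth_mean | 20 | reads per 5 kb window |
| Hi-C | background 5, spike 10 | trans counts; breakpoint multiplier |

Counts are negative-binomial around per-gene lognormal means (log2 mean 6,
sd 1.5); accession effects are shared across replicates so accessions, not
replicates, carry the biological variance that the Wilcoxon tests consume.
Window depth is Poisson(depth_mean × copies/2 × multiplier); rDNA-like
arrays are a per-locus multiplier. Hi-C matrices have distance-decay cis
expectations, uniform trans background, and breakpoint spikes; a
`noise=False` mode returns the expectation matrix for by-construction
checks. All generators are pure functions of (params, seed); each derives
its RNG stream from the global seed at a fixed offset, so adding one output
never perturbs another.

Where the real system's quantities are unknown the choices are explicit
stand-ins, not inferences: the Beta shapes for insertion frequencies, the
founder count of 4 (a severe bottleneck), the NB dispersion and accession
variance. The generator omits — and the passing tests therefore say nothing
about — GC or mappability biases, positionally clustered TEs, linkage,
heterozygosity, partial (mosaic) HEs, and read-level artefacts.

## Calibration and recovery (what the suite verifies)

- Wilcoxon p-values equal brute-force enumeration on small groups;
  hypergeometric/Fisher p-values equal exact integer enumeration for every
  table with N ≤ 25.
- Under the expression null the population mean homeolog logFC is within 3
  SE of 0, and BH at q < 0.05 over 2,000 genes × (15 vs 15) accessions
  yields a false-discovery proportion consistent with the nominal level;
  planted 4-fold effects are recovered with sensitivity ≥ 0.9.
- Planted leak rates (6%/1%) are recovered within 3 SE.
- The copy-number estimator is unbiased within 1% at depth 10 for planted
  arrays of 1–174 copies (500 replicates).
- The HE caller attains recall 1.0 with breakpoint error ≤ 1 window on 50
  planted 20-window events at depth 20, and zero calls on 50 event-free
  simulations.
- Founder resampling (k = 4 vs no-bottleneck control) shifts shared TEs at
  intermediate ancestral frequency toward polyploid fixation (paired
  difference positive at >3 SE over 200 replicates).

Problem sizes (200–2,000 gene pairs, 5 kb windows, 125–400 kb chromosomes)
are chosen so the full suite runs in minutes; all recovery statements above
are at these sizes.

## Known limitations

- The expression filter's panel thresholds and the "expressed" cutoff are
  conventions; the original analysis did not define them precisely.
- HE thresholds (0.25/0.5–1.5/1.6, min-run 5, Jaccard 0.5, contact ≥ 2,
  pairs ≥ 3) are this package's formalization of a qualitative evidence
  chain; they are exposed as configuration, not tuned constants.
- The contact-enrichment background includes the spike bins; see above.
- Interval projection requires at least one contained homeolog pair;
  gene-poor segments are skipped with a warning.
- TE accessions are haploid-like presence profiles (selfing); dosage within
  an accession is out of scope.
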