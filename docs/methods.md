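# Methods

`placentakit` implements the quantitative procedures used to characterise
the evolutionary specialization of an RNA-binding splicing regulator
(MBNL3) in the eutherian placenta, as a reusable, tested pipeline.  Every
stage can be exercised on synthetic data with planted effects, so each
procedure's recovery behaviour is measurable.  This note records the
models and assumptions behind each stage, the defaults and why they were
chosen, and what the synthetic data does and does not emulate.

## 1. RNA-binding preference statistics (`motif_metrics`)

An RNAcompete experiment summarises a protein's in vitro RNA affinity as
a one-sided Z-score per 7-mer; higher Z means stronger preferred binding.
All statistics are computed over the top-`n` 7-mers by Z (default
`n = 100`):

* **Motif contribution.** For a literal motif set M (e.g. {GCUU} or
  {GCAGC}), the fraction of the cumulative top-n Z carried by 7-mers
  containing a motif of M as a substring.  It is a fraction in [0, 1]
  (also reported as a percent), invariant to uniform positive scaling of
  Z, and monotone under motif-set union.
* **GC-following-base partition.** Restricted to top-n 7-mers containing
  exactly one GC dinucleotide with a following base, the Z mass is
  partitioned by that base (GCA/GCC/GCG/GCU) and normalised to sum to 1.
  The single-GC restriction makes the classification unambiguous; a flag
  (`single_gc=False`) switches to crediting every GCx occurrence, and a
  7-mer whose only GC occupies the final two positions has no following
  base and is excluded.
* **GC spacing log-ratio.** log2 of the Z-mass ratio between top-n
  7-mers matching GCxGC and those matching GCxxGC (x = any base).  When
  either class is absent or has non-positive mass the statistic is
  undefined and reported as missing, never as a number.

Numerical choices: ties at the top-n boundary are broken
lexicographically on the k-mer, which makes the boundary deterministic
and input-order independent.  Negative-Z 7-mers are *included* in the
top-n selection (they can only enter when the table has fewer than n
positive entries); a top-n with non-positive total mass makes the
fraction statistics undefined and raises.  Tables are normalised to the
RNA alphabet (T→U) at load, and missing Z values are dropped with a
logged count.

## 2. Competing splice-donor usage (`tss_usage`)

Alternative promoters produce transcripts whose first exon splices from
distinct 5' donors onto one shared reference acceptor; junction-read
counts over those competing donors therefore proxy promoter (TSS) usage.
Donors carry one of four evolutionary classes (ancestral long-isoform,
ancestral with first coding exon skipped, eutherian-specific,
lineage-specific), and usage is the percent of a sample group's junction
reads per class.  Two aggregation modes exist: `pooled` (default) sums
counts across a group's samples before taking percentages, which is
robust when individual samples have low coverage; `mean` averages
per-sample percentages.  They coincide when all samples have equal
totals.  A group with zero total reads yields missing values with a
warning, never a silent zero.

The packaged mouse donor→class map is a synthetic stand-in (its filename
says so): it keeps the published numbering scheme and the one printed
eutherian-specific donor coordinate (chrX:132413583), but the remaining
coordinates are invented placeholders.  Analyses of real data should
supply their own annotation TSV.

## 3. Litter-aware weight statistics (`litter_stats`)

**Exchangeability model.** Between-litter variability in placenta and
embryo weights is large, so the litter is the exchangeable unit: genotype
labels may be permuted only within litters.

**Effective genotype.** Mbnl3 is X-linked and expressed almost
exclusively from the maternal allele in placenta.  Heterozygous females
with a WT maternal allele are therefore effectively WT; with a KO
maternal allele they are effectively KO in placental tissue (and mosaic,
hence excluded, in constitutive analyses).  Males are hemizygous and
follow the maternal allele.  Autosomal heterozygotes (Mbnl2) count as WT.

**Permutation test.** Weights are ranked within each litter (ascending;
ties get mid-ranks, keeping the statistic exchangeable) and the statistic
is the KO rank-sum summed over litters.  Labels are permuted
independently within each litter preserving per-litter genotype counts;
the one-sided p-value counts permutations at least as extreme as the
observed statistic in the user-stated direction (`ko_heavier` or
`ko_lighter` — the direction is always explicit, never inferred).  When
the number of distinct arrangements is ≤ 10^6 (or on request) the exact
permutation distribution is obtained by convolving per-litter rank-sum
distributions (ranks are doubled so mid-ranks stay integral), replacing
sampling entirely.  The default Monte-Carlo p is `count / n_iter` with
1,000 iterations; `smooth=True` switches to `(count+1)/(n_iter+1)` for
conservative hygiene.  Litters containing a single genotype carry no
information and are dropped with a warning.

**Normalization.** Within each litter, weights are divided by the
average of the litter's mean WT and mean KO weight; by construction the
per-litter identity (mean normalized WT + mean normalized KO)/2 = 1
holds exactly.  The per-genotype minimum (default 3, the calorie
restriction cohort rule) is configurable because pooled-litter analyses
do not apply it.

**Rank-sum comparison.** Two-sided Wilcoxon rank-sum; for combined
n ≤ 20 the p-value is computed exactly by enumerating all assignments of
pooled mid-ranks (correct under ties), otherwise the tie-corrected
normal approximation from scipy is used.

## 4. PolyA-site usage (`polya_usage`)

Reverse-primed 3'-end reads start at the transcript cleavage site on the
strand opposite the mRNA, so cleavage sites are the alignments' 5' ends
with the strand inverted.  Sites are called by greedy peak clustering per
chromosome and mRNA strand: repeatedly take the position with maximal
read count, absorb all reads within ±50 nt (the clustering tolerance),
and emit the site at the peak.  Ties break toward the smaller
coordinate; every read is assigned to at most one site, so assignments
partition the reads and called sites are pairwise more than one
tolerance apart.  Greedy max-support clustering was chosen over density
methods because it gives a deterministic peak definition.

**Internal-priming filter.** Oligo-dT can prime on genomic A-tracts,
producing artifact sites.  A site is kept iff a polyA-signal hexamer
(default {AATAAA, ATTAAA}, mRNA sense) occurs 10–40 nt upstream of the
cleavage position, OR the 20 nt downstream are not A-rich (no run of
≥ 6 A and fewer than 12 A total).  These hexamer/window/A-rich defaults
are standard practice and fully configurable; they are this package's
documented choices, not asserted to be identical to any published
pipeline's unstated filter.  Removed sites are logged with the reason.

**Differential usage.** For a per-gene proximal/distal pair, percent
usage is PU = 100·proximal/(proximal+distal).  Per KO-vs-WT comparison,
replicates are summed into a 2×2 (site × condition) table and tested
with Fisher's exact test; Benjamini–Hochberg correction runs across all
pairs within a comparison, and a pair is `enhanced`/`repressed` when the
proximal site's usage moves up/down at FDR < 0.1 (with two sites, the
usage fractions necessarily move in opposite directions).  A zero margin
gets a Haldane (+0.5) continuity correction for the fold-change estimate
and is flagged; the p-value uses the raw table (Fisher handles zeros).
The significance engine is deliberately simple and pluggable —
generalized-linear differential-usage models are out of scope, and
precomputed per-pair results can be supplied through the same interface.

**Representative pair.** One pair per gene is selected among those
significant in the maximal number of comparisons: (i) the largest-|FC|
candidate if its reads are ≥ 15% of the gene's max-read pair; (ii) else
the max-read pair among all pairs; (iii) else the candidate if it
exceeds 30% of max reads; (iv) else the gene is discarded.  As stated,
step (ii) always resolves, making (iii)/(iv) unreachable; the original
rule's ordering is ambiguous, so the fixed interpretation above is
implemented literally, with a flag disabling the step-(ii) fallback so
the remaining paths stay testable.  Every decision is trace-logged.

## 5. Differential splicing filters (`splicing_psi`)

Events carry per-sample PSI (0–100) and an ordinal coverage score
(N < VLOW < LOW < OK < SOK).  The coverage filter keeps events scoring
at least LOW in *every* sample; unknown labels are a hard error.  A
differential call requires |mean ΔPSI| ≥ 15 between conditions AND every
replicate-level difference ≥ 5 in the same direction.  The replicate
rule is ambiguous for a 2-vs-2 design; the default `all_pairs` reading
requires all KO×WT pairwise differences to pass (equivalently
min(KO) − max(WT) ≥ 5), the strictest deterministic interpretation with
no hidden replicate pairing; `by_index` pairing is available and is
provably never stricter.  Developmental events apply the same rule to WT
samples at two stages, and the maturation summary reports median KO
shifts over developmentally up/down events plus the fraction of events
whose KO shift opposes the developmental direction (zero shifts count as
non-opposing).  Calls are invariant to sample order and symmetric under
the PSI → 100−PSI reflection.

ESC-differential reference call sets are produced by external resources
in practice; the maturation interface accepts any externally supplied
call set.

## 6. Expression screen (`expression_screen`)

For each candidate splicing factor, per-tissue-group mean TPMs are
computed first and the enrichment is
log2((target mean + ε) / (mean of other group means + ε)) with
ε = 0.01 TPM guarding zero denominators (the TPM > 10 target-side filter
makes the numerator-side ε immaterial).  Averaging group means rather
than samples keeps unbalanced tissue panels from dominating the
reference.  The TPM > 10 filter applies to the target group *mean*.  The
DE set filters are pure, idempotent set operations: "Mbnl3-specific"
genes are significant (padj < 0.05) in the M3KO and DKO comparisons but
not in M2KO; relaxed candidate sets use raw P < 0.1 and |log2FC| > 0.1
(both strict inequalities) split by fold-change sign.

## 7. Synthetic data (`synthetic_data`)

The generators define the package's reference study conditions; all
randomness flows through a single seeded generator per call, so outputs
are byte-identical under a fixed seed, and every emitted file round-trips
through its consumer's reader.

* **7-mer tables**: all 16,384 RNA 7-mers; Z = planted motif bonuses +
  Gaussian noise (default bonus 5, noise sd 0.5).
* **Junction counts**: multinomial draws of a configurable depth over
  donor classes; the default placenta profile puts ~50% of reads on the
  eutherian-specific class, the regime described for mouse placenta.
* **Litter weights**: 6 litters of 6–10 pups (≥ 3 per genotype at the
  default sizes), placenta baseline 0.10 g (sd 0.012 g between litters),
  residual sd 0.008 g, KO effect +0.012 g (~+12%), all in grams at an
  E18.5-like scale.  Non-positive weights are truncated at 10^-3 g
  rather than redrawn, preserving litter sizes.
* **3'-seq reads**: one synthetic chromosome per gene (coordinates stay
  trivial and the FASTA small); two true polyA sites ≥ 3× the clustering
  tolerance apart, each with an AATAAA planted 25–30 nt upstream and a
  non-A-rich downstream context wide enough to cover jittered peaks; one
  A-tract decoy whose upstream window is scrubbed of signal hexamers.
  Defaults: depth 1,000 per condition over 2 replicates, positional
  jitter sd 5 nt, internal-priming rate 0.2, usage shift 2%→50%
  (Mbd2-like) or as configured.
* **PSI tables**: 2 KO and 2 WT replicates, planted |ΔPSI| = 20 in half
  the events with random sign, measurement noise sd 3 PSI points,
  clipped to [0, 100]; coverage scores drawn from a configurable
  categorical distribution over the ordinal scale.
* **TPM matrices**: lognormal baseline expression, planted target-group
  enrichment of 3 log2 units in 10 of 200 genes, multiplicative
  lognormal noise with CV 0.2.

What the synthetic data does *not* emulate: read sequences and base
qualities, alignment artifacts other than internal priming, transcript
quantification uncertainty, correlated noise between samples, litter-size
covariates, and real genomic sequence composition.  Passing recovery
tests therefore demonstrates the correctness and calibration of the
*procedures* under their stated noise models, not performance on real
sequencing data.

## Problem sizes

The shipped tests and the acceptance script use deliberately compact
problem sizes chosen as the package's own reference conditions: 1,000
random tables (≤ 1,000 rows) for oracle-equivalence checks, 500
simulated cohorts for type-I-error calibration (using the exact
convolution form of the permutation test), depth 1,000 per condition for
3'-seq recovery, and 100-event PSI tables.  All complete in seconds on a
single CPU.

## Known limitations

* The polyA significance engine is a pooled-replicate 2×2 test; it
  ignores replicate-level overdispersion and will be anticonservative on
  real data with biological replicate variability.
* The permutation test conditions on observed per-litter genotype
  counts; it does not model litter size as a covariate and no
  mixed-effects alternative is provided.
* The GC-partition statistic's single-GC restriction discards multi-GC
  7-mers; the any-GC mode double-counts 7-mers containing several GCx
  occurrences.  Both behaviours are intentional and documented.
* The screen's ε pseudocount makes near-zero reference expression yield
  large but finite log2 fold changes; ranking among such genes is
  ε-dependent.
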