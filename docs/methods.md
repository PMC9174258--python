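# Methods

## Statistical model

### Unit of evidence

The unit of evidence is the *mutated sample*, not the mutation. For gene
g and sample s, s contributes 1 to g's incidence if s carries at least one
somatic SNV inside g's interval, regardless of how many. Only single
nucleotide substitutions are analysed; insertions, deletions and
multi-nucleotide variants are counted in a rejection report at parse time
and excluded. Cohort sizes (`n_case`, `n_total`) come from the design
file, not from the mutation file, so samples with zero SNVs in every
tested gene still contribute to the denominators. Strand is carried on
gene records but ignored by all overlap computations except the promoter
anchor (below).

### Per-gene test and permutation calibration

Each gene's 2×2 table (a = mutated case samples, b = unmutated case,
c = mutated control, d = unmutated control) is scored one-sided in the
case-enrichment direction,

    p = P(X ≥ a),  X ~ Hypergeometric(N = a+b+c+d, K = a+c, n = a+b).

Significance is calibrated per gene against the label-permutation null:
hold the gene's total mutated-sample count m = a + c fixed, randomly
reassign case/control labels, recompute the Fisher p. Under that scheme
the mutated-case count is exactly K ~ Hypergeometric(n_total, m, n_case),
so the null is sampled by drawing K directly rather than shuffling label
vectors; the shortcut is an algebraic identity, not an approximation, and
a literal label-shuffle implementation is retained as a slow reference
(`permutation_null_shuffle`) and checked against it atom by atom in the
tests. Permutations are per gene and marginal; a joint shuffle across
genes would additionally preserve cross-gene correlation, which nothing
downstream uses.

Two modes:

* `mc` — Monte-Carlo with `n_perm` draws (default 1,000,000,
  user-settable). The empirical p uses the (1 + #{null p ≤ observed p}) /
  (n_perm + 1) correction so it is never 0. Each gene draws from an RNG
  stream seeded by (master seed, SHA-256 of gene_id), so results are
  independent of gene order and reproducible gene by gene.
* `exact` — closed form: enumerate the reachable K values, weight the
  induced Fisher p atoms by the hypergeometric pmf, and report the exact
  tail probability with no +1 correction. Exact nulls are cached per m
  within a run.

A gene is significant when its empirical permutation p is ≤ alpha
(default 0.01 — the "99 % confidence" threshold, operationalized
one-sided; equivalently the observed p falls at or below the 1 % quantile
of the gene's null, which is reported as `threshold_p`). Because the
exact null is the same hypergeometric distribution that defines the
Fisher p, in exact mode the empirical p coincides with the Fisher p; the
Monte-Carlo mode converges to it. The calibration still matters: the
per-gene threshold quantifies what "extreme" means for each gene's own
discrete null (genes with small m can never reach small p), which is the
property the threshold column exposes. No Bonferroni/FDR correction is
layered on top — the per-gene permutation threshold is deliberately the
only multiple-testing answer, and callers wanting a stricter family-wise
control can lower alpha.

### Ranked sets

Genes are sorted by (Fisher p ascending, gene_id ascending — the
deterministic tie-break). The candidate set is the significant genes
(size k); the 2nd and 3rd sets are the next two blocks of k
non-candidates in sorted order; the last set is the final k
non-candidates. When the significant genes are not an exact prefix of the
sorted list (possible because per-gene thresholds differ), "next after
the candidates" is read as "first k non-candidates in sorted order".
Construction requires at least 4k tested genes.

### Cross-cancer specificity

With per-cancer significance calls (each cancer as case vs the rest
pooled), two count vectors characterize the reference cancer's candidate
set: per other cancer, (1) how many reference candidates are also
significant there, and (2) how many fall in its top-k by Fisher p with k
the reference candidate-set size. The reference against itself returns k
in both.

## Overlap and aggregation

All coordinates are internally 0-based half-open; 1-based inputs (GTF,
mutation and SNP positions) are converted at the parse boundary. A
1-based position P lies in [s, e) iff s ≤ P−1 < e. Chromosome names are
matched as exact strings (no "chr" harmonization). Overlap fractions are
always relative to *gene* length, never to peak length.

* **binary** — ≥ 1 bp intersection with any track interval.
* **counted** — number of GWAS SNP positions inside the gene (after
  pooling catalogs, dedup key (chrom, pos, trait), keep p < 1e−8 strictly)
  or the number of distinct eQTL `variation_id||gene_id` keys whose
  position falls inside.
* **segmented** — per chromatin state, (bp of gene covered by the union
  of that state's ranges) / gene length. For a non-overlapping tiling the
  fractions sum to 1. Computing per state over the union (rather than
  summing ranges) is a choice; it only differs for self-overlapping
  segmentations.
* **scored** — coverage is the union of overlapping peaks over gene
  length (cannot exceed 1); the weighted score is Σ sᵢwᵢ / Σ wᵢ with
  wᵢ the per-peak overlap fraction, so stacked peaks contribute
  independently to the mean. The asymmetry (union for coverage, per-peak
  for weights) is deliberate. A gene with no overlapping peak reports a
  *missing* score, not 0 — 0 is a legal signal value. A `min_score`
  argument filters peaks before aggregation for threshold sweeps.
* **id_aggregated** — for tracks whose ranges carry several (id, score)
  pairs: per id, overlap fractions are *summed* over that id's ranges
  (may exceed 1 for self-overlapping input) and scores are averaged with
  those fractions as weights; the per-id maximum score is retained for
  minimum-signal sweeps.

Interval queries run through an interval-tree index whose results are
asserted equal to a naive all-pairs scan on random instances in the test
suite.

## Enrichment

For a catalog of N genes with A carrying a trait and a set of S genes
with Y carrying it: ratio = (Y/S)/(A/N), expected count S·A/N, and
p = P(X ≥ Y) for X ~ Binomial(S, A/N) — the with-replacement
approximation of sampling S genes, adequate for S ≪ N; an exact
hypergeometric alternative sits behind `model="hypergeom"`. Y = 0 yields
ratio 0 and p 1; A = 0 with Y > 0 is an input error, and A = 0 at a sweep
point is reported as missing rather than 0. Ratios are stored unrounded;
rounding to 2 d.p. is display-only. Sweep traits: "≥ k items" over
counted entries and "≥ 1 peak with signal ≥ t" over scored / id
aggregated entries; both are non-increasing in their threshold.

## Hi-C linkage

Interactions are consumed as fixed-bin fragment pairs with read counts
and background-model p-values (upstream significance calling is out of
scope). Filters: cis only; p < 0.01 strict; reads ≥ 10; fragment
start-to-start distance strictly between 5 kb and 20 Mb (start-to-start
equals midpoint-to-midpoint on same-size bins; the distance definition is
otherwise arbitrary). A gene annotates a fragment when
|gene ∩ fragment| / gene length ≥ 0.10 — the denominator is the gene
because genes here are typically smaller than the 5 kb bins;
it is configurable. Links require a candidate ncRNA on one end and a
coding gene on the other, either by gene body (same 10 % rule) or by
promoter window [TSS−w, TSS+w) with w = 2 kb by default (the window, not
the gene, is the 10 % denominator in that mode); both modes are emitted
and labelled `via_promoter`, since only the gene-overlap rule is
externally fixed and the promoter window is a modelling choice. The TSS
is strand-aware (start for +, end−1 for −; unstranded genes fall back to
start with a warning). Library intersection is exact unordered
fragment-pair equality — no slack window. Support fractions are reported
over both the candidate set and all genes, with the binomial enrichment
model comparing the two.

## Catalog merging

Gene lists are merged in priority order (first catalog wins conflicts).
Two genes from different catalogs are "the same gene" when their names
match case-insensitively (or their ids coincide) OR they lie on the same
chromosome with reciprocal overlap ≥ 0.5 (both |∩|/|g₁| and |∩|/|g₂|; the
threshold is a package choice, exposed as `--reciprocal`). Name matches
that fail the coordinate check (other chromosome, low overlap) still
merge but are flagged in the merge report. Genes are never merged within
one catalog — each input list is taken as internally non-redundant —
which is what makes the merge idempotent (merging a catalog with itself
is the identity) and keeps priority inversion exact.

## Synthetic data

The generator emulates the target study design at desk scale: two 10 Mb
chromosomes; 150 case + 600 control samples (three control cohorts of
200); 205 non-overlapping genes of 1–10 kb; per-(gene, sample) mutation
probability 0.02 at background and 0.5 for the 5 spiked genes in case
samples only; mutated samples receive 1 + Poisson(0.3) SNVs at uniform
positions. Tracks: ~300 scored peaks with a guaranteed high-signal peak
on each spiked gene; a gap-free chromatin-state tiling; a GWAS trait with
≥ 2 genome-wide-significant SNPs planted in each spiked gene plus
background SNPs straddling the 1e−8 threshold; eQTL associations; a
multi-id DNase-style track. Hi-C: 5 kb bins, 4 planted dual-library
ncRNA-promoter contacts passing all filters, plus noise interactions
constructed to fail specific filters. All generation derives from one
seed (byte-identical files per seed), and the planted truth is written as
a machine-readable manifest.

What the generator does **not** emulate: mutational signatures and
trinucleotide context, covariate-dependent background mutation rates
(replication timing, expression), gene-length–rate correlation, sample
hypermutators, overlapping genes, and realistic genome-scale catalog
sizes. Passing tests therefore demonstrate correctness of the counting,
testing, aggregation and linkage machinery under the stated model — not
robustness to the confounders of real tumour cohorts.

## Problem sizes and numerical choices

The shipped study conditions (205 genes, 750 samples) make exact
permutation nulls instantaneous; the exact mode is the pipeline default,
with Monte-Carlo (vectorized hypergeometric draws, per-gene RNG streams)
available for conditions where enumeration is unwanted. The acceptance
script and the test suite run the full pipeline at these sizes; the
deeper property suites use n_perm = 1e5 (Monte-Carlo vs exact, 3σ per
atom) and 1e4 (literal shuffle vs shortcut). Fisher tails are validated
exhaustively against rational-arithmetic enumeration for every table
total ≤ 30, and binomial enrichment tails for every S ≤ 20.

Tie-breaks are everywhere (p, gene_id) lexicographic. Null-distribution
quantiles are inf{v : CDF(v) ≥ q} on the discrete support. Degenerate
inputs: m = 0 genes have a point-mass null at p = 1 and are never
significant; m = n_total gives a point-mass null whose threshold is that
single p; n_perm < 100 warns that quantile estimates are unstable.
Monte-Carlo empirical p is floored at 1/(n_perm+1) by construction.

## Known limitations

* The binomial enrichment model ignores gene length and genomic
  clustering of annotations; no position-matched permutation background
  (GAT/regioneR style) is provided.
* No background-mutation-rate covariates, signature analysis or
  positive-selection models; the test is purely comparative between
  cohorts, so a gene mutable in all cancers is (by design) not a hit.
* Catalog merging is gene-level only; transcript structure is ignored.
* VCF support is a minimal dialect (CHROM POS ID REF ALT + SAMPLE=/CANCER=
  INFO keys), not the full specification; ref alleles are not validated
  against a reference genome; no liftover.
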