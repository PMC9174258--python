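# ncburden

Case-specific somatic mutation burden testing for non-coding genes, with
regulatory-annotation enrichment and Hi-C promoter linkage.

## The problem

Whole-genome sequencing of tumour cohorts yields millions of somatic single
nucleotide variants (SNVs), the great majority in non-coding DNA. A
recurring question is which non-coding genes (lncRNAs, pseudogenes,
antisense transcripts, ...) are mutated in a given cancer type *more often
than in other cancers* — and whether those genes look like regulatory
elements (enhancer marks, accessible chromatin, GWAS risk loci) and contact
the promoters of protein-coding genes in 3D.

`ncburden` implements that analysis for cohorts of the form "one case
cancer type versus all other cancer types pooled":

1. **Incidence.** For each gene interval, count the *distinct* case and
   control samples carrying at least one SNV inside it (a sample counts
   once per gene, however many SNVs it has there).
2. **Per-gene test.** Score the 2×2 table
   (case mutated `a`, case unmutated `b`, control mutated `c`, control
   unmutated `d`) with a one-sided Fisher exact test in the case-enrichment
   direction: `p = P(X ≥ a)` for
   `X ~ Hypergeom(n_total, a+c, a+b)`.
3. **Permutation calibration.** For each gene separately, permute
   case/control labels holding the gene's total mutated-sample count `m`
   fixed, and recompute the Fisher p. A gene is significant when its
   empirical permutation p is ≤ 0.01 (the "99% confidence" threshold).
   Because the label permutation with fixed `m` makes the mutated-case
   count exactly `Hypergeometric(n_total, m, n_case)`, the null can be
   sampled by drawing that count directly — an exact shortcut, with the
   literal label shuffle kept as a test oracle — or enumerated in closed
   form (`mode=exact`). No Bonferroni/FDR layer is applied on top; the
   per-gene permutation threshold *is* the calibration.
4. **Ranked sets.** Genes sorted by Fisher p are split into the
   *candidate* set (significant genes, size k), the next two blocks of k
   (*2nd*, *3rd* sets) and the k genes at the tail (*last* set), for
   contrast in downstream enrichment.
5. **Annotation profiles.** Each gene is profiled against annotation
   tracks under five aggregation rules: binary overlap, item counts (GWAS
   SNPs, eQTL `variation_id||gene_id` keys), per-chromatin-state coverage
   fractions, union coverage with overlap-weighted mean peak scores, and
   per-identifier aggregation for multi-id tracks (DNase cell types, TF
   names).
6. **Enrichment.** For a gene set of size `S` in a catalog of `N` genes,
   of which `A` carry a trait and `Y` in the set carry it, the enrichment
   ratio is `(Y/S)/(A/N)` with upper-tail p from `X ~ Binomial(S, A/N)`.
   Sweeps over minimum item counts ("≥ k GWAS SNPs") and minimum signal
   scores are built in.
7. **Hi-C linkage.** Significance-annotated interaction lists are filtered
   (cis, p < 0.01, reads ≥ 10, 5 kb < distance < 20 Mb), fragment ends are
   annotated with genes at ≥ 10 % gene overlap, candidate ncRNAs are linked
   to coding genes via gene body or promoter window (TSS ± 2 kb), two
   libraries are intersected by exact fragment-pair identity, and the
   fraction of candidates with dual-library support is compared against
   all genes.

A deterministic synthetic-data generator (`ncburden.fixtures`) produces
every input format with planted structure — spiked genes, a planted GWAS
trait, planted dual-library Hi-C links — so the full pipeline is testable
without any downloads.

## Worked example

```bash
ncburden -v simulate --seed 17 --outdir demo/fixtures
ncburden -v run-all --indir demo/fixtures --outdir demo/results
```

The simulated cohort has 150 case and 600 control samples, 205 genes of
which 5 are spiked (case mutation probability 0.5 vs background 0.02), a
GWAS trait planted in the spiked genes, and 4 planted dual-library Hi-C
links. The run prints, among other stage logs:

```
INFO ncburden: significance: 9 of 205 genes significant at alpha=0.01
INFO ncburden: enrichment: candidate gwas(atleast=1.0): Y=5 S=9 A=5 N=205 ratio=22.778
INFO ncburden: hic: 4 common interactions; 4/9 candidates supported (44.4%)
significant genes: 9 / 205
```

Reading: all 5 spiked genes are recovered (plus 4 borderline background
genes at the 1 % threshold over 200 null genes); all 5 genes carrying the
planted GWAS trait fall in the candidate set, a 22.8-fold enrichment over
the genome-wide rate; and the 4 planted ncRNA–promoter contacts survive
filtering, end-annotation and library intersection, supporting 4 of the 9
candidates in both libraries.

`demo/results/` then contains `calls.tsv` (per-gene 2×2 cells, Fisher p,
permutation threshold and empirical p, significance, ranked-set label),
`profiles.tsv`, `enrichment.tsv`, `links.tsv`, `summary.json`, and the
resolved `run_config.yaml`. Rerunning with the same config reproduces the
tables byte for byte.

Every stage is also available separately (`merge-genes`, `mutsig`,
`annotate`, `enrich`, `hic-link`), and everything the CLI does is a thin
wrapper over the library modules.

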