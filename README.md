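# varrank

Variant prioritization for very small targeted-sequencing cohorts (e.g. 12 vs
12 patients), where conventional inferential statistics are off the table.
The pipeline compares two patient groups against a reference population and
works in two branches:

1. **Variant branch** — genotypes are oriented to the population minor
   allele (variants recorded against the major allele are folded: MAF =
   1 − AltAF, genotypes complemented, ref/alt labels swapped; variants with
   no recorded AltAF get the theoretical floor 1/N), monomorphic rows are
   pruned, and per-variant variant-allele frequencies (VAF) of both groups
   plus the population MAF form a three-column contingency table. Factorial
   correspondence analysis (chi-square residual SVD) embeds the variants,
   and hierarchical clustering on the principal coordinates (Ward tree,
   automatic cut, k-means consolidation) yields clusters labelled by
   enrichment direction.
2. **Gene branch** — protein-altering exonic variants are selected, naive
   bootstrap resampling of each patient group fabricates replicate
   experiments, per-gene frequencies (mean VAF or size-normalized sum) feed
   a bootstrap-averaged odds-ratio statistic against the population
   frequency, and a two-class rank-product test with permutation p-values
   and pfp (percentage of false prediction) ranks the genes.

A fully tested synthetic-cohort generator (Hardy–Weinberg genotypes,
odds-ratio enrichment, missing / major-oriented AltAF fractions) makes every
stage reproducible without any external downloads.

## Test

```sh
python -m pytest tests/
```

The suite includes property tests (hypothesis), brute-force oracles for the
correspondence analysis and the rank-product permutation p-values, and an
acceptance module (`tests/test_acceptance.py`). Four acceptance tests
reproduce counts from the original study's supplementary data files; they
skip unless you place `matrix.csv`, `groups.csv`, `annotations.csv` and
`popfreq.csv` under `data/supplementary/`.

## CLI

```sh
varrank simulate  --spec spec.json --out-dir cohort/
varrank adjust    --matrix cohort/matrix.csv --groups cohort/groups.csv \
                  --popfreq cohort/popfreq.csv --out-table table.csv --out-report report.json
varrank fca       --table table.csv --out-coords coords.csv --out-summary ca.json
varrank cluster   --table table.csv --k auto --out-assignments clusters.csv
varrank rankgenes --matrix cohort/matrix.csv --groups cohort/groups.csv \
                  --annotations cohort/annotations.csv --popfreq cohort/popfreq.csv \
                  --filter protein-altering --agg mean --seed 1 --out ranks.csv
varrank full      --matrix ... --groups ... --annotations ... --seed 1 --out-dir out/
```

Notable flags: `--drop-missing-af` drops variants without a recorded AltAF
instead of imputing the 1/N floor; `--agg sum_over_size` normalizes gene
frequencies by captured gene size (needs `--gene-sizes`); `--null-scheme`
selects the rank-product permutation null (`per-class` default — calibrated
for bootstrap pseudo-replicates; `per-experiment` and `per-pairing` mirror
the classical rank-product conventions); `--k 3` forces the cluster count
instead of the automatic relative-loss criterion.

All inputs and outputs are plain delimited text; genotype matrices can also
be read from a multi-sample VCF (`--dialect vcf`).

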