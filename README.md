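# rohpipe

Inbreeding and diversity analysis for sparse, capture-style SNP panels —
built for conservation-genomics settings where a small, possibly isolated
population (island wolves are the motivating case) is genotyped at tens of
thousands of non-coding SNPs with shallow coverage, and the questions are:
*how inbred is each individual, how recently did that inbreeding arise, and
how much diversity and differentiation is left?*

The pipeline works from genotype likelihoods rather than hard genotype
calls, so sites too shallow to pass strict filters still contribute
evidence. Its stages:

- **Runs of homozygosity (ROH)** called by a windowed log-likelihood-ratio
  scan: per SNP, LOD = log₁₀ of P(reads | homozygous-IBD site model) over
  P(reads | Hardy–Weinberg site model at population frequency q).
- **F_ROH** — the fraction of the autosomes in ROH ≥ 1 Mb and ≥ 10 Mb — per
  individual, with population means and 95% nonparametric bootstrap CIs
  (5000 resamples, percentile method).
- **ROH dating**: a tract's genetic length *l* (cM, from a linkage map)
  estimates the generations back to the common ancestor as
  *g* = 100/(2*l*); Mb-in-ROH is profiled over six age bins
  (<10 … >50 generations).
- **Nucleotide diversity** π via site allele-frequency likelihoods → folded
  site-frequency spectrum (EM) → per-site pairwise theta
  E[k(2N−k)]/C(2N,2) → genome-wide average over covered sites.
- **Weir–Cockerham F_ST** (1984 variance components, weighted Σa/Σ(a+b+c))
  between populations.
- **SNP filter ladder** (biallelic, missingness, GQ masking, depth bounds,
  MAF, exact Hardy–Weinberg test) with a per-rule rejection tally, plus
  panel-equalization pruning.
- **Capture design**: greedy tiling of probe targets with spacing and
  exclusion masks, and 3×-mean pilot-coverage pruning.
- **A synthetic-cohort simulator** that plants IBD tracts of known
  coalescent age (exponential genetic length, mean 100/(2g) cM), simulates
  read pileups and genotype likelihoods, and emits VCF + truth BED +
  population tables — so every stage above is testable against exact truth
  with no external data.

See `docs/methods.md` for the models, defaults, and their rationale.

## Worked example

A two-population cohort (6 + 6 individuals, Balding–Nichols divergence
F_div = 0.1, four 20 Mb chromosomes, 50 kb SNP spacing, depth 10) with IBD
tracts planted at ages 5 and 20 generations covering 10% of the genome each:

```yaml
# run.yaml
seed: 77
genome: {n_chrom: 4, chrom_length_bp: 20000000, cm_per_mb: 1.0}
simulate:
  n_individuals: 6
  n_populations: 2
  f_div: 0.1
  depth_mean: 10
  snp_spacing_bp: 50000
  roh_age_spec: [[5, 0.1], [20, 0.1]]
filter: {preset: likelihood}
froh: {n_boot: 300}
```

```bash
rohpipe pipeline run --config run.yaml --out out/
```

The run writes `cohort.vcf`, `truth_roh.bed`, `roh.bed`, `froh.tsv`,
`roh_age_bins.tsv`, `pi.json`, `fst.tsv`, a manifest, and `report.json`,
which for this seed contains:

```
froh pop1:  F_ROH>=1Mb mean 0.251  (95% CI 0.230 - 0.284)
            F_ROH>=10Mb mean 0.045 (95% CI 0.000 - 0.112)
froh pop2:  F_ROH>=1Mb mean 0.276  (95% CI 0.239 - 0.320)
fst:        pop1 vs pop2  0.114
truth_comparison (per individual, called - planted F_ROH>=1Mb):
            pop1_i01 +0.007   pop1_i02 -0.003   pop1_i03 +0.016 ...
```

Reading the numbers: both cohorts were planted with ~20% of the genome in
IBD tracts, of which the tracts ≥ 1 Mb amount to ~0.25 of the genome frame
per individual in this draw; the caller recovers each individual's value to
within ~0.02 (the `truth_comparison` deltas). The F_ST of 0.114 reflects
the Balding–Nichols divergence of 0.1 plus sampling noise at ~1,600 SNPs.
The `pi.json` values divide summed pairwise theta by the *variant* site
count unless `diversity.n_total_sites` supplies the full covered-site
total — pass it to get per-nucleotide diversity rather than per-SNP
heterozygosity.

Every stage is also a standalone command (`rohpipe simulate`, `filter`,
`roh`, `froh`, `rohage`, `pi`, `fst`, `design`, `design-prune`) operating on
files, with stage seeds derived from the global seed so isolated re-runs
reproduce the pipeline exactly.

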