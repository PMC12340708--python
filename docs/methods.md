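# Methods

`rohpipe` re-implements, as a tested and reusable pipeline, a genomic
inbreeding and diversity analysis for sparse capture-style SNP panels on a
canid-like genome: runs of homozygosity (ROH) called from genotype
likelihoods, F_ROH inbreeding coefficients with bootstrap confidence
intervals, coalescent dating of ROH from genetic map length, nucleotide
diversity through a folded site-frequency spectrum, Weir–Cockerham F_ST, the
SNP filtering ladder, and the interval arithmetic of hybridization-capture
target design. Every stage can be exercised end to end against a synthetic
cohort generator that plants identity-by-descent (IBD) tracts of known
coalescent age, so recovery of known truth — not agreement with an external
dataset — is the package's acceptance surface.

## The synthetic cohort generator (`simgenome`)

**Genome frame.** A `GenomeLayout` holds named autosomes (default 38), their
physical lengths, and a linkage map as per-chromosome anchors (bp, cumulative
cM) interpolated piecewise linearly. The same interpolation object converts
genetic to physical length when planting tracts and back again when dating
called segments, so the simulator and the dating stage share one source of
truth for the map.

**Tract model.** Inbreeding is planted tract-by-tract rather than through a
pedigree or coalescent simulation. For an ancestor `g` generations back, a
surviving IBD tract has genetic length drawn Exponential with mean
`100/(2g)` cM; tracts are placed uniformly (chromosome chosen proportional to
physical length) and added until each age class reaches its configured genome
fraction, with overlaps resolved by rejection and truncation at chromosome
ends recorded as the realized (shorter) span. This matches the quantity the
downstream analysis interprets — tract length maps to coalescent age — and
keeps the truth set exact. The cost is realism: no linkage between
individuals, no spatial correlation of tracts, no background relatedness, and
the tract-length law is exactly exponential rather than the mixture a real
pedigree produces.

**Genotypes, reads and likelihoods.** Site positions tile each chromosome
with inter-SNP gaps uniform in [0.5, 1.5] × the mean spacing (default
50 kb) — capture panels tile the genome fairly regularly, unlike shotgun
SNPs. Ancestral allele frequencies are Beta(0.5, 0.5) truncated to
[0.05, 0.95], emulating a post-MAF-filter panel; per-population frequencies
follow the Balding–Nichols model with divergence parameter `F_div`, which
makes the expected Weir–Cockerham F_ST between populations equal `F_div`.
Outside planted tracts genotypes are Hardy–Weinberg draws at the population
frequency; inside a tract the two haplotypes are identical — a single allele
drawn at the population frequency — except for a residual heterozygosity
`h = 0.001` (mutation since the ancestor, or genotyping noise). Read depth
is Poisson (default mean 10, configurable per individual), each read shows
the alternate allele with probability ε (hom-ref), 1/2 (het), or 1 − ε
(hom-alt) with ε = 0.01 — a single biallelic flip probability, not a
per-nucleotide ε/3 model — and genotype likelihoods are binomial, stored
log10-scaled and normalized so the best genotype is 0. Depth 0 yields a flat
triple: the site is missing for that individual but carries exactly zero
evidence downstream, by construction.

What passing tests on these cohorts shows is that the *estimators* recover
the truth their own model class generates at realistic depth, spacing and
error; it does not establish robustness to mapping artifacts, batch effects,
allele-specific capture bias, or reference bias in real data.

## SNP filtering (`variantio`)

The hard-filter ladder mirrors a VCFtools-style command: minimum genotype
quality 20 applied as per-genotype masking first, then per-site drops in a
fixed order — biallelic, missingness (≥ 85% of individuals with data), site
mean depth ≥ 10, site mean depth ≤ 24, minor allele frequency ≥ 0.05,
Hardy–Weinberg exact test p ≥ 0.001 — with each rejected site attributed to
the first rule it fails. Joint filtering (as VCFtools does) and this ordered
ladder keep exactly the same sites; the order only fixes the attribution
tally, which is what makes the tally reproducible. Allele frequencies come
from an EM on genotype likelihoods (`q ← Σ E[g|GL, q]/2N`, tolerance 1e-8)
so low-depth data are handled consistently; the exact HWE test needs integer
counts and therefore uses maximum-likelihood genotype calls under a flat
prior. Individuals with genome-wide mean read depth below 5 are removed
before site filtering.

The pipeline exposes two filter presets. `structure` is the full ladder
above, appropriate for called-genotype analyses (F_ST). `likelihood` keeps
only the structural rules (biallelic, depth cap, individual depth) — the
appropriate panel for the likelihood-based ROH and diversity stages, which
are designed precisely to use sites whose genotypes would not survive hard
filtering.

## ROH calling (`rohcall`)

Per SNP, the evidence for lying in a homozygous-IBD tract is a log10
likelihood ratio between two site models evaluated on the GL triple: outside
an ROH, Hardy–Weinberg proportions at the population allele frequency
(estimated within the focal individual's population, falling back to the
whole cohort below 4 members); inside, homozygous for an allele drawn once
from the population, heterozygous with probability `h = 0.001`. A flat
triple gives LOD 0 exactly, so missing data neither create nor destroy
evidence. Two consequences worth noting: the LOD is invariant to affine
rescaling of the GL triple, and for *heterozygous* data the LOD increases
with `h` while for homozygous data it decreases slightly (the IBD model
concedes probability mass to the het class).

Windows of 25 SNPs slide in steps of 5; windows with summed LOD above 0 are
flagged, overlapping or near-flagged windows (gap ≤ 100 kb) merge, merged
spans are trimmed to their outermost SNPs, split at inter-SNP gaps > 500 kb
(a sparse panel has no information inside a gap), and finally each candidate
has its worst-scoring prefix and suffix peeled off (deepest non-positive
partial sum from each end) subject to retaining at least 25 SNPs. The edge
peel exists because flagged boundary windows overhang homozygous-by-chance
SNPs just outside the true tract; without it, cohort F_ROH is biased upward
by roughly 0.03 at 50 kb spacing, and with it the bias falls to ~0.01 and
the median boundary error to ≲ 1.5 × the SNP spacing. Window size, step,
threshold, gaps and `h` are all configuration; the defaults were validated
against planted-truth cohorts at capture density (sensitivity ≥ 0.9 for
tracts ≥ 1 Mb, ≥ 0.95 for ≥ 10 Mb, false ROH < 2% of outbred genomes at
depth 10, ε = 0.01, 50 kb spacing).

## F_ROH and diagnostics (`inbreed`)

F_ROH is the summed length of segments at or above a threshold (1 Mb and
10 Mb) divided by the physical autosome length of the layout. The
"proportion of the autosomes" denominator is the default; an
assayable-length denominator can be supplied explicitly where capture
coverage is very uneven. Population means carry 95% nonparametric bootstrap
CIs: resample N individual values with replacement 5000 times, take the
0.025/0.975 quantiles of the resampled means, with quantiles by linear
interpolation of order statistics (numpy default; stated because quantile
conventions differ between tools). A diagnostic OLS regression of F_ROH on
individual mean depth (p from the t distribution, n − 2 df) guards against
coverage-driven artifacts; on simulated cohorts with depth varying 6–15×
independently of inbreeding the association is null in ≥ 90% of seeds.

## ROH dating (`rohage`)

A called segment's genetic length `l` (cM) comes from the map interpolation;
the generations to the common ancestor are estimated by inverting the
expected-length relation: `g_hat = 100/(2 l) = 50/l`. Segments are binned
into six classes — <10, 10–20, 20–30, 30–40, 40–50, >50 generations — with
half-open edges `[a, b)` so a boundary estimate falls in the older-labelled
bin and `g_hat = 50` exactly falls in ">50"; `l = 0` (map plateau) is
assigned to ">50" with an infinite flag. Per population the package reports
both the mean over individuals of summed Mb per bin (default; individuals
without segments contribute zeros) and the pooled mean over segments. Bin
sums conserve each individual's total Mb exactly.

A distributional caveat documented here because it is easy to get wrong:
with exponential tract lengths the estimator `g_hat = 50/l` does *not*
concentrate around the true `g` — its density peaks near `g/2` and a mass
`1 − exp(−g/50)` of tracts fall below 1 cM and hence into the oldest bin.
The statement that *is* true, and that the test suite asserts, is the
converse: planting equal numbers of tracts per age class, each bin receives
more tracts from its matching class than from any other. Age is estimated
from called segment spans with no correction for call-boundary shrinkage
(an optional half-spacing pad exists, off by default).

## Diversity and differentiation (`diversity`)

Nucleotide diversity follows the standard genotype-likelihood recipe:
(1) per-site allele-frequency likelihood vectors over alternate-allele count
j ∈ {0..2N} by dynamic programming over individuals with genotype weights
C(2, g); (2) folding to minor-allele counts (k = N class not doubled);
(3) a maximum-likelihood folded SFS by EM across sites from a uniform start
(monotone log-likelihood, asserted every iteration; tolerance 1e-8);
(4) per-site pairwise theta `tP = E[k(2N−k)]/C(2N,2)` under the
SFS-posterior; (5) π = Σ tP divided by the total number of covered sites —
variant plus invariant, supplied explicitly by the caller, because dividing
by variant sites alone answers a different question. On simulated panels
(N = 10, depth 20, 10⁵ sites) the GL-based π is within 5% of the
true-genotype pairwise π.

F_ST is the Weir & Cockerham (1984) variance-component estimator computed
from maximum-likelihood genotype calls at GQ ≥ 20 (matching the
called-genotype path of standard VCF tooling), with the weighted multi-site
form Σa / Σ(a+b+c). Sites where any population lacks calls are skipped and
counted. Under Balding–Nichols divergence `F_div = 0.2` (25 + 25
individuals, 20k SNPs) the estimate lands within ±0.03 of 0.2.

## Capture design (`capdesign`)

Targets of fixed length are tiled greedily left-to-right with an
end-to-start gap ≥ `min_gap` (default 19,700 bp), skipping a merged
exclusion mask of repeat intervals plus exons padded by 100 kb flanks.
Greedy earliest placement is deterministic and maximal for fixed-length
non-overlapping placement; start-to-start spacing can be emulated by
adjusting `min_gap` by the target length. Pilot-coverage pruning removes
targets with mean coverage ≥ 3× the mean over targets with non-zero
coverage; zero-coverage targets reflect sequencing effort, not probe
failure, and are excluded from the mean and never pruned.

## Numerical and design choices

- Seeds are mandatory everywhere; the pipeline derives per-stage seeds from
  the global seed so stages re-run in isolation reproduce the full run.
  Outputs are byte-identical across runs with the same seed.
- GL triples are normalized max = 0 on read and write; PL input converts as
  −PL/10. VCF text output prints GLs at 4 decimals, which bounds round-trip
  error at 1e-4.
- The SAF dynamic programme renormalizes per site each step, so it is safe
  for cohorts far larger than the defaults.
- EM allele frequencies start at 0.5; an all-missing site keeps the
  initialization value and is flagged rather than guessed.
- Sites whose estimated allele frequency is exactly 0 or 1 are uninformative
  for the ROH likelihood ratio and are excluded from the scan with a
  counter, as are chromosomes with fewer SNPs than one window.
- Problem sizes in the acceptance script (10 × 50 Mb genomes, 20 + 6
  individuals, 10⁵-site diversity panels, 500 bootstrap replicates, 100
  regression seeds) were chosen as the smallest cohorts at which the
  sampling error of each recovery metric is well below its tolerance.

## Known limitations

- The tract-based simulator does not model linkage disequilibrium, related
  individuals, or selection; F_ST and SFS behavior under those forces is
  untested.
- The ROH caller is a windowed scan, not an HMM; very short ROH (below ~25
  SNPs, i.e. ~1.25 Mb at 50 kb spacing) are below its design resolution, and
  boundary placement is limited by SNP spacing.
- Dating assumes a constant coalescent age along a tract and an exact
  linkage map; map error propagates directly into `g_hat`.
- π requires the caller to supply the invariant-site total; the package
  cannot infer callable sites from a variant-only VCF.
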