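# Methods

`introscan` analyses genome-wide introgression between a crop and its wild
relative (the implementation speaks of maize and the highland teosinte
*mexicana*, but nothing is maize-specific) from SNP genotypes in sympatric
population pairs plus allopatric reference panels. Because field datasets of
this kind are rarely deposited, the package ships a synthetic-data generator
with exact ancestry ground truth, and every inferential component is validated
against that truth or against independent oracles.

## The synthetic cohort

Two source taxa are simulated under a Balding–Nichols allele-frequency model:
each site draws an ancestral frequency p ~ U(0.05, 0.95) and per-taxon
frequencies from Beta(p(1−F)/F, (1−p)(1−F)/F) with `divergence_scale` F
(default 0.30, giving multilocus F_ST between panels of roughly 0.4 after
founder drift — strong differentiation, as between a crop and a diverged wild
subspecies). Chip ascertainment in the crop is emulated two ways: the maize
frequency is kept off fixation, and the mexicana minor-allele frequency is
multiplied by `ascertainment_bias` (default 0.7), so the receiving taxon is
systematically more polymorphic on the marker set. This bias factor is a free
knob, not an estimate — no quantitative ascertainment model is available for
a discovery panel consisting of one taxon.

Reference panels are **founder mosaics**: 8 founder haplotypes per taxon are
drawn from the taxon frequencies, and each panel haplotype is a Markov mosaic
of founders (switch rate 3/Morgan, per-site mutation 0.003). Real panels
share recent ancestry, which is exactly the property a haplotype-copying
model exploits; sitewise-independent haplotypes would make the copying layer
uninformative within a taxon and inflate the leave-one-out baseline.

Admixed haplotypes follow the standard exponential tract model: a two-state
Markov process along the genetic map with recipient→donor rate T·m and
donor→recipient rate T·(1−m) per Morgan (T = `admixture_time`, default 100
generations; m = `admixture_proportion`, defaults 0.20 for mexicana→maize
and 0.10 for maize→mexicana). Alleles are copied from a random panel
haplotype of the tract's taxon with a 0.002 per-site copy error. Forced
tracts (`shared_tract_spec`) overwrite ancestry inside an interval: each
haplotype becomes donor with probability = the tract's `frequency`,
recipient otherwise, so frequency ≈ 1 plants a shared introgression and
frequency = 0 plants an introgression-resistant locus. The defaults place two
shared mexicana→maize tracts (12 Mb each at frequency 0.95) and one
introgression-free interval per direction on a 2-chromosome, 160 Mb/chromosome
genome at 1 SNP per 80 kb (≈ 2,000 SNPs per chromosome) with a uniform
1 cM/Mb map — a deliberately scaled-down genome that keeps the full pipeline
and its tests fast while preserving the marker density and admixture design
of the study setting. Nine sympatric pairs of 20 individuals each and
24-haplotype reference panels complete the cohort. Missing genotypes are
added to the diploid matrix at rate 0.02 (haplotype outputs stay complete,
standing in for phased data).

What the generator does **not** emulate: demographic history (bottlenecks,
growth), selection during admixture, non-uniform recombination, genotyping
error beyond uniform allele flips, and linkage between populations beyond the
forced tracts (populations are otherwise independent, so "shared because
forced" is distinguishable from "shared by chance"). Passing tests therefore
demonstrate correctness of the machinery and recoverability under a clean
admixture model, not performance on real data with phasing error or complex
demography.

## Local ancestry: haplotype-copying HMM

Each phased query haplotype is modelled as a mosaic of reference haplotypes
from two panels. The hidden state is (ancestry, copied haplotype); per
interval of d Morgans an ancestry-switch event occurs with probability
1 − exp(−T·d) and lands on donor/recipient with the prior weights (m, 1−m),
choosing a uniform haplotype in the destination panel; within an ancestry,
Li–Stephens switching occurs at `panel_switch_rate` (default 10/Morgan);
emission is match/mismatch with `miscopy_rate` (default 0.002, matching the
generator's copy error). Decoding is a scaled forward–backward pass,
vectorised over all haplotypes of a population; posteriors on ≤8-site toys
equal exhaustive path enumeration to 1e-8, and scaling keeps chromosomes of
1e5 sites finite. Admixed individuals are analysed as two phased haplotypes
(the unphased-diploid emission model is not implemented — a documented
limitation; population-level quantities are insensitive to phase at this
marker density).

Per individual, the per-site donor **dosage** is the sum of its two haplotype
posteriors (in [0, 2]); the population track is mean dosage/2. For carrier
calls ("does this individual carry at least one donor chromosome here?") the
package also reports P(≥1 donor chromosome) = p₁ + p₂ − p₁p₂: the expected
dosage of a true heterozygous carrier is exactly 1, so thresholding the
expectation at 1 is a coin flip, while thresholding the carrier probability
at 1/2 is the MAP decision.

**Admixture time** is profiled by summing per-individual log-likelihoods over
a grid (default 1–5000 generations) and taking the argmax, ties toward the
smaller value. At 80 kb marker spacing, tracts much shorter than the spacing
are invisible, so the estimate is biased toward older-looking (smaller T̂ by
roughly a factor 2 at T = 100) — consistently within one grid step of truth
on the default grid, which is what the package promises. Forced ancient
tracts bias any single-T estimate further; time recovery is therefore
evaluated on the stochastic admixture process alone.

**Jackknife reference correction**: each reference individual is removed and
scanned against the remaining panel (recipient) and the other taxon's panel
(donor). The mean donor dosage/2 across jackknifed individuals is the per-site
baseline — near zero for clean panels, elevated inside contaminated tracts —
and is subtracted from population tracks with a floor at zero. Individual
dosages are left untouched; only the population mean is corrected.

## Frequency-based second scan

SNPs are grouped left-to-right into haplotype loci separated by at least
5 kb; a locus's alleles are the haplotype strings observed in the two
reference panels, with +0.5 pseudocount per catalogue allele (an allele
absent from the catalogue receives one extra pseudocount's mass). Each
phased copy is assigned by a two-state HMM over loci: emissions are the
smoothed taxon frequencies; between loci the chain relaxes toward a
stationary prior π with P(i→j) = s·π_j + (1−s)·δ_ij, s = 1 − exp(−2rΔcM),
r = `switch_rate_per_cM` (default 1). With π = (½, ½) this is the symmetric
two-state chain and, as r → ∞, reduces to per-locus naive Bayes. The study
scans pass the direction's admixture proportion as the donor's stationary
weight, playing the role of the linkage model's per-individual ancestry
fractions; with a symmetric prior the donor posterior in truly
non-introgressed regions floors near 0.09 and the 5% resistance rule could
never fire. A sensitivity question remains open: cluster frequencies here are
fixed from the reference panels rather than estimated jointly from all
samples, and the effect of that substitution on region calls is untested.

## Region calling

Introgressed regions are maximal runs of ≥ `min_sites` (default 2)
consecutive markers with population mean donor fraction ≥ 0.5 ("an average
of one donor chromosome per individual"); boundaries sit at inter-marker
midpoints, clamped to chromosome ends, reported 0-based half-open.
Consensus = interval intersection of the two scans' calls. Sharing across
populations is a coverage-depth sweep (default k = 7 of 9). Resistant
regions are markers at ≤ 5% donor fraction in ≥ k populations under **both**
scans, with each supporting population confirmed region-wide (its maximum
over the region stays below threshold). The frequency scan clears the 5%
bound at only ~60% of markers per population in introgression-free
sequence, so resistant calls are specific to depleted loci but fragmentary —
the dual-confirmation rule trades sensitivity for precision.

## Diversity statistics

Observed/expected heterozygosity, %P (strict 0 < p < 1, no MAF floor) and
F_IS = (H_E − H_O)/H_E per population; per-site polymorphism classification
(shared / private / fixed difference / monomorphic, with a separate untyped
class excluded from the partition); Weir–Cockerham F_ST from the 1984
variance components with the ratio-of-sums multilocus convention (per-site
undefined values are NaN, never zero); and per-SNP f3 = (t−s1)(t−s2) with
the genome-wide median, negative medians flagged as admixture-consistent.
The small-sample heterozygosity correction for f3 is available behind a flag
and off by default. All statistics skip missing genotypes site-wise.

## Enrichment tests

Two null schemes, each preserving the structure its test conditions on:
interval-vs-interval tests rotate the called-region set circularly by a
uniform per-chromosome offset (region lengths and spacing preserved
exactly); SNP-set tests resample candidate-sized SNP sets without
replacement. Empirical p-values use (b+1)/(n+1) and are never zero. The
Bayes-factor candidate rule keeps a SNP iff it reaches the 95th percentile
in every replicate run and the 99th percentile of mean Bayes factors,
percentiles by nearest rank. Discreteness caveat: the resampling null is
discrete and the (b+1)/(n+1) estimator is conservative, so the achievable
rejection rate at nominal α sits slightly below α; calibration checks use a
2000-SNP toy whose exact achievable rate at α = 0.05 is 0.044.

## IBS tracts

For every (query, donor) haplotype pair, maximal runs without mismatch that
contain ≥ 5 consecutive exact matches are retained when spanning ≥ 3 cM
(first to last SNP). Missing alleles break seeds but extend runs as
wildcards (both behaviours flag-controlled; the data source is silent on
this point). Near-adjacent runs are not merged. Per-site IBS profiles count
the fraction of pairs covering each site; the differential profile
IBS(donor A) − IBS(donor B) per query group localises which donor a group
resembles, with the fraction of positive sites as the summary. The scan is a
deliberate exhaustive pair loop — at this scale it is fast, and its
simplicity is what makes the brute-force oracle in the tests meaningful.

## Numerical and design choices

- 1-based SNP positions internally (VCF convention), 0-based half-open
  exported intervals (BED convention); conversion only at I/O boundaries.
- Missing dosage is a sentinel (−1), excluded rather than imputed everywhere.
- Forward–backward is scaled (not log-space); per-site normalisation keeps
  likelihood sums exact in the scaling factors.
- Likelihood-grid ties break toward smaller T; flat curves are flagged.
- Degenerate inputs: empty panels, zero-length chromosomes, all-identical
  panels, k > n populations, and empty candidate sets raise explicit errors.
- All randomness flows from one root seed; the pipeline derives named
  substreams per stage, and re-running with the same config and seed gives a
  bit-identical report.

## Known limitations

Unphased real data must be pre-phased upstream; the copying model assumes
the reference panels contain the query's recipient haplotypes (a recipient
panel missing local haplotype classes produces false donor signal no
correction can fully remove); the time-since-admixture estimate is
resolution-limited as described; and the resistance rule's sensitivity is
bounded by the frequency scan's posterior floor. The BAYENV-style MCMC,
phasing, and genotype calling are out of scope — Bayes factors, phased
haplotypes and dosages are consumed as inputs.
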