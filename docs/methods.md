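# Methods

## Problem setting

Imputation services return per-genotype posterior probabilities and a
per-variant quality score; an evaluation against a second genotyping
array asks how often the imputed alleles agree with directly genotyped
ones. `impuconcord` implements the whole measurement chain — array QC,
posterior hard-calling, allele-set concordance, quality summaries — plus
a generative model of an admixed cohort so the chain can be validated
against known ground truth.

## Concordance model

Matching is **variant-level on observed allele sets**, not per-genotype
concordance. For a variant with allele pair (A, B), the observed set over
a column of hard calls is {A, B} if both alleles have nonzero counts among
called genotypes, else the observed singleton. With imputed set Sᵢ and
truth set Sₜ and c(·) the base-complement image:

* COMPLETE if Sᵢ = Sₜ;
* FLIP if c(Sᵢ) = Sₜ — alleles correct, strand swapped;
* HALF if |Sᵢ ∩ Sₜ| = 1 — in direct orientation only, no complement
  retry, because a flip is defined on the full pair;
* NONE otherwise, flagged *ambiguous* iff both sets are palindromic pairs
  ({A,T} or {G,C}), where strand orientation alone could explain the
  disagreement.

Two structural facts about the four-base alphabet are worth recording.
(1) A palindromic pair matched against itself is resolved as COMPLETE; a
flip is unobservable there. (2) For a non-palindromic pair the only
disjoint pair is its complement, so a NONE with two polymorphic sets can
only arise between the two palindromic pairs — every other no-match
involves a monomorphic side. The exhaustive oracle test enumerates all
196 ordered pairs of size-1/2 allele multisets and checks the classifier,
its symmetry, and the ambiguity flag against an independently coded
brute-force implementation.

Flips count as matches: accuracy = 100·(COMPLETE + FLIP)/n over the
classified overlap, error = 100 − accuracy, and adjusted accuracy
additionally counts ambiguous NONEs as correct. Variants uninformative
(all calls missing) on either side are excluded from n and reported
separately, so either convention — exclude or penalise — is recomputable.
Strata: pooled, autosomes, X, and optionally per chromosome. Cross-dataset
variant pairing is by (chrom, pos), never by identifier, since IDs differ
across arrays and panels.

## Hard-calling

An entry is called to argmax(p₀, p₁, p₂) when that maximum is unique and
≥ the threshold (default 0.7); ties and sub-threshold maxima are no-calls,
as are all-zero triples (the Oxford GEN no-data convention). The threshold
comparison is inclusive, matching the behaviour of the standard
`--vcf-min-gp` conversion; ties abstain because no genotype has posterior
dominance. Indels are dropped before calling; after calling, uncalled
variants are pruned under the `all_missing` rule by default (`any_missing`
is available) — with 25–45% of entries below threshold in realistic data,
`any_missing` would discard nearly everything, so it cannot be the
operative convention. `sweep_threshold` tabulates the accuracy-vs-yield
trade-off that motivates 0.7.

A subtlety the test suite deliberately exercises: at high thresholds the
surviving calls of a variant are a thinned sample, so a rare allele can
vanish from the observed set and produce a genuine HALF match on perfectly
clean data. Accuracy equals 100% exactly only at threshold 0, where every
modal genotype is kept.

## Iterative QC

One pass applies, in order: sample missingness (> 0.10), variant
missingness (> 0.02, on the surviving samples), MAF (< 0.05, over called
genotypes), then heterozygosity outliers. All comparisons are strict,
following the "more than"/"below" phrasing of the thresholds. Passes
repeat until one removes nothing; strict shrinkage bounds the iteration
count by samples + variants. The filter order within a pass is fixed for
determinism; because samples are filtered before variants, a cross-step
cascade (e.g. a heterozygosity-outlier sample whose removal tips a
variant over the missingness threshold) is what pushes work into a second
iteration, and the planted-cascade test is built exactly that way.

Heterozygosity is summarised per sample as F = 1 − O(het)/E(het), with
E(het) = Σ 2p(1−p) over the variants called in that sample and p the
cohort B-allele frequency; "excessive heterozygosity" is operationalised
as |F − mean F| > 3 SD, the standard GWAS convention, since no exact rule
is fixed by the thresholds themselves. Sex concordance uses the same F on
X-chromosome variants: F < 0.2 infers female, F > 0.8 male, the band
between abstains, and unknown reported sex is never discordant.
Relatedness filtering is intentionally absent.

## Formats

VCF v4.2 is read through cyvcf2/htslib (FORMAT/GT and GP; per-variant
quality from INFO keys INFO > R2 > DR2, covering the IMPUTE2, Minimac/PBWT
and Beagle conventions with one deterministic rule). Genotype
probabilities are linear-scale, as emitted by the imputation servers, not
phred-scaled. Multiallelic, symbolic-allele and off-target-chromosome
records are skipped with logged counts rather than failing, since the
evaluated panels are biallelic SNPs. Oxford GEN/SAMPLE (5 leading columns
+ 3 probabilities per sample, two SAMPLE header lines) has no parser in
the supporting libraries and is parsed directly. Both readers round GP
values to 6 decimals — the text precision both writers emit — which makes
the GEN rendering and the VCF rendering of the same posteriors
bit-identical in memory and therefore makes the two calling procedures
provably interchangeable (htslib surfaces FORMAT floats as float32; the
rounding removes that representation artifact). Coordinates are 1-based;
X is encoded "X"; B allele = ALT/alleleB.

## Synthetic cohort generator

The generator defines the study conditions for every stochastic test.
Truth genotypes follow Balding–Nichols with Dirichlet admixture:

* ancestral frequency p ~ Uniform(0.05, 0.95) per variant;
* population frequency p_k ~ Beta(p(1−F_ST)/F_ST, (1−p)(1−F_ST)/F_ST),
  K = 5 populations, F_ST = 0.1 each — five-way admixture with moderate
  differentiation;
* admixture q ~ Dirichlet(α), default α = (4.4, 3.0, 1.6, 0.6, 0.4), a
  skewed preset with a dominant first (KhoeSan-like) component;
* genotype ~ Binomial(2, Σ_k q_k p_k).

Default scale is 200 samples × 20 000 variants with 5% of variants on X —
large enough that three-binomial-SE recovery bands are tight (±0.6% on a
10% rate) while the whole suite stays in seconds. Variants get random
allele pairs, palindromic with probability 0.2 (roughly the share of
ambiguous SNPs on dense arrays).

The corruption step assigns each variant a label with probabilities
(1−e−f−m, e, f, m):

* **clean** — posterior mass m* ~ Uniform(0.5, 1.0) on the true genotype,
  remainder split randomly over the other two (the winner is always
  unique since m* > 0.5). The uniform winning mass gives the no-call
  fraction a closed form, (t−lo)/(hi−lo) at threshold t.
* **error** — the allele pair is replaced by the disjoint pair and every
  sample is concentrated on one homozygous genotype of it, so the
  observed set is a disjoint singleton → NONE. The channel is homozygous
  by construction: for a non-palindromic pair the disjoint pair *is* the
  strand complement, so a heterozygous draw would classify as FLIP and
  the channel would not inject what its name promises.
* **flip** — alleles complemented, genotype codes preserved → FLIP.
  Flips drawn on palindromic variants are reassigned to clean (and
  flagged), mirroring the classifier's inability to see them.
* **mono** — every sample concentrated on the homozygous-major genotype
  → observed singleton → HALF against a polymorphic truth (COMPLETE in
  the degenerate case where the truth column is itself monomorphic for
  the major allele; the label table makes this auditable).

Per-variant quality is expit(8·MAF + ε), ε ~ N(0, 0.3), halved on
error/mono variants — qualities rise with MAF and corrupted variants sit
low, reproducing the qualitative quality-vs-MAF and quality-by-class
patterns. All draws flow from the config seed; the corruption stream is
decoupled from the cohort stream so the same truth can be re-corrupted.

What the generator does **not** emulate: linkage disequilibrium (the
evaluated statistics are LD-free, so simulating it adds cost without test
power), chip ascertainment bias, male X hemizygosity (X is diploid for
everyone; sex checks are exercised on constructed fixtures), batch or
cluster-calling artifacts, and the imputation HMM itself. Passing tests
therefore certify the *evaluator* — that it recovers whatever corruption
is present — not the field accuracy of any imputation service.

## Pipeline and reporting

The orchestrated run simulates a cohort, splits it into two partially
overlapping arrays (a sparser imputation-input array and a denser truth
array), QCs the truth array, corrupts the cohort restricted to array-A
samples into pseudo-imputed posteriors, calls, classifies the overlap
minus the pre-imputation shared-variant list, and writes four fixed-schema
TSVs (counts, accuracy, quality-by-class, quality-by-MAF; floats at two
decimals, absent strata as NA) plus a three-section summary file. The
accuracy identities (error = 100 − accuracy, class counts summing to the
overlap) are re-verified at render time. A manifest records the config
hash, seed and a SHA-256 per output; a rerun with the same config and
seed is byte-identical.

## Numerical and degenerate-input choices

* MAF = min(f_B, 1−f_B) over called genotypes only; NaN when nothing is
  called, and such variants propagate as excluded rather than guessed.
* MAF bins are half-open (lo, hi] with the first bin closed at 0; default
  edges 0, .01, .05, .10, .20, .30, .40, .50 (none are canonical; these
  cover the rare-variant end more finely). Both median and mean are
  emitted, since either can be the reported central statistic.
* Quality histogram: half-open bins of width 0.05, score 1.0 in the top
  bin.
* Probability triples must sum to 1 ± 1e-3 (all-zero allowed as no-call);
  per-variant quality must lie in [0, 1] or be NaN.
* Empty strata report n = 0 with NaN/NA statistics instead of raising;
  an all-indel matrix prunes to an empty matrix without error.

## Known limitations

* The heterozygosity and sex-inference statistics are declared
  conventions (3 SD on F; 0.2/0.8 X-F cutoffs), not uniquely determined
  by the thresholds they accompany.
* LD-based strand harmonisation against a reference panel is out of
  scope; the classifier only *labels* flips and ambiguity, it does not
  re-orient.
* Genotype-level (per-sample) concordance, dosage r², and haplotype
  switch error are out of scope by design.
* The generator's independence across variants makes binomial SE the
  exact error model for recovery tests; real data would be
  LD-correlated, widening those bands.
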