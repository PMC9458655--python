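# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `clonalshift`, in the order the pipeline runs them.

## Synthetic cohort model

The generator is the package's ground truth: every calling and testing
stage is validated by recovery against it. A sample consists of two
germline three-SNP *JAK2* haplotypes, an optional somatic V617F mutation,
an optional single 9p mosaic chromosomal alteration (mCA), and a relative
telomere length (rTL).

**Germline.** Each haplotype is the 46/1 risk string GGC with probability
q = 1 − √(1 − c), where c = 0.6861 is the configured carrier frequency
(Hardy–Weinberg), and the major non-risk string TCT otherwise. Restricting
the alphabet to two true strings (plus sequencing-error derivatives) keeps
the phase and QC logic unambiguous while covering every informative
configuration (non-carrier, heterozygous, homozygous carrier).

**Somatic point mutation.** Overall V617F prevalence is 0.6082 with an
odds ratio of 2.69 given carriership; the conditional probabilities
(p₀, p₁) are solved numerically from (c, prevalence, OR). Among
heterozygous carriers the mutation lands on the risk haplotype with
probability 0.80 — chosen because, combined with the frequencies above, it
implies an overall "mutation on a GGC background" fraction of 66.0%,
matching the observed 65.8% in the cohorts this emulates. A small fraction
(0.5%) of mutated samples acquire independent mutations on both
haplotypes. The allelic fraction on the background haplotype is drawn as
0.04 + 0.96·Beta(1.2, 0.75) (mean ≈ 0.63, median ≈ 0.67, a broad
left-skewed distribution consistent with reported AF summaries); the floor
reflects the quantification limit of a targeted assay whose haplotype
table filters at 1% frequency.

**mCA.** Prevalence 0.7331 overall, coupled to mutation status through an
odds ratio of 82.6 (the value implied by the published co-occurrence
table), with state mix (gain 0.20, loss 0.30, CNLOH 0.50) dominated by
CNLOH as observed on 9p. In heterozygous carriers the event retains or
duplicates the risk haplotype with per-state probabilities 23/28, 14/16
and 51/59. Cell fractions: for mutated samples, cf < AF with probability
0.95 (cf uniform below the AF), otherwise cf uniform above it — encoding
"mutation first, expansion second"; for unmutated samples
cf ~ 0.02 + 0.98·Beta(2, 2). One event per sample (multiplicity is a
config extension); events span the V617F position on 9p, occasionally the
whole chromosome.

**Telomere.** rTL = N(1.20, 0.25) + β·cf, floored at 0.05, with
β = −1.17 for events spanning *JAK2* and −0.57 otherwise; the linear link
matches the reported rTL-vs-clonal-fraction association.

**Emission.** Array signal: per-site phased genotypes (A|B coding), BAF
from allele-copy accounting (below) plus N(0, 0.03) noise clipped to
[0, 1], LRR = log₂(total copies / 2) plus N(0, 0.14). Reads: haplotype of
origin drawn with the mCA-shifted share (e.g. (1+f)/2 for CNLOH retaining
that haplotype), the mutant allele appended to its background at the
sample's AF, and per-site miscalls flipping to the specific other tracked
allele at error_rate/3 (a substitution hits a given alternate base about a
third of the time; off-alphabet bases never enter the 4-site table).

**Randomness.** One root seed; cohort-level draws use stream
`[seed, 0]`, sample i uses `[seed, i+1, tag]` with tag 1 for array signal
and 2 for reads. Everything is bitwise reproducible.

**What the generator does not emulate** — and therefore what passing tests
do not establish about real data: population phasing switch errors (phase
is given exactly, so phase-based mCA detection is never degraded),
genotyping error in the gt column, multiple concurrent clones or nested
subclones, recurrent events outside chromosome 9, GC-wave LRR artifacts,
and ancestry structure. The rescue segmentation tier and the QC rules are
exercised structurally but their real-data failure modes (switch-error
masking, sample contamination) are out of scope.

## mCA detection

Two-tier segmentation per chromosome over heterozygous sites:

1. **Phase-oriented tier.** x_i = s_i·(BAF_i − 0.5), where s_i = +1 when
   the B allele is on haplotype 2. Under an event E[x] = ±ΔBAF with the
   sign identifying the retained haplotype; the statistic is unbiased at
   any noise level (the unphased mean |BAF − 0.5| is biased upward at
   small shifts by the folded-normal mean, ~+0.006 at σ = 0.03, which
   would exceed the cell-fraction error budget).
2. **Unphased rescue tier.** y_i = |BAF_i − 0.5| − σ√(2/π), scanned
   one-sided (events can only raise |BAF − 0.5|). Centering at the folded
   mean, not the median, matters: the folded distribution is skewed and a
   median-centered one-sided scan accumulates a √L drift that produces
   spurious calls on long null chromosomes. The tier exists for data whose
   phase carries no information over the event; with exact phase it is
   redundant but harmless (overlapping calls merge, phased tier preferred).

Each tier runs an exhaustive best-segment scan — all contiguous ranges of
≥ min_het (20) sites, score |Σx| / (σ√L), ties broken toward the longer
segment — with recursive splitting of the flanks. On small inputs the
boundaries are therefore exactly the brute-force best changepoint pair,
which the tests assert against an independent double loop. Significance is
a normal test Bonferroni-corrected over the chromosome's candidate
segments at α = 1e−4; this is conservative and holds the per-sample
false-positive rate well under 1% (measured ~0). The noise scale σ is the
median absolute successive difference of x times 1.4826/√2, robust to
level shifts at event boundaries; a floor of 1e−4 keeps noiseless input
well-defined.

**State and cell fraction.** Allele-copy accounting gives the heterozygous
BAF for event fraction f: (1±f)/2 under CNLOH, 1/(2−f) or (1−f)/(2−f)
under loss, (1+f)/(2+f) or 1/(2+f) under gain, and LRR = log₂(total/2).
Inverting the deviation ΔBAF yields the formulas in the README; gain
saturates at ΔBAF = 1/6 (clonal trisomy) and is capped at f = 1 with a
warning beyond. Classification: when ΔBAF ≤ 0.02 only the LRR gates act
(gain > +0.04, loss < −0.10, otherwise undetermined). When ΔBAF is
informative, the state is the one whose predicted LRR at its
ΔBAF-implied f is closest to the observed median LRR. Pure thresholds
cannot work there: a loss at f between 0.11 and 0.27 has true LRR in
(−0.10, −0.04) and would always fall between the gates. The "undetermined"
state is exactly the sub-threshold convention above, since no external
definition exists.

**Region.** Whole-chromosome = covering the chromosome's full
heterozygous-site extent; telomeric = contained within 1 Mb of either
chromosome end (containment, not endpoint proximity — the looser reading
would also label near-whole-arm events telomeric); interstitial otherwise.
Coordinates are 1-based inclusive internally; BED output converts to
0-based half-open.

## Long-read haplotype calling

Reads are tabulated into (3-SNP background, somatic state) haplotypes with
exact counts. The rare-haplotype filter drops rows with frequency strictly
below 1% of the sample's total reads — strictly, so a haplotype at exactly
1.000% survives — and does not renormalize the surviving frequencies
(counts are preserved; the total-read denominator is the documented
convention). QC: fail on total reads < 1000, more than two distinct
backgrounds after filtering, or mutant rows on both backgrounds; the
biallelic case is a flag rather than silent removal because genuinely
independent double mutations exist and deserve a distinct status. The
allelic fraction is mutant reads on the mutation's background divided by
all reads on that background; phase is cis/trans only for samples with one
GGC and one non-GGC background, uninformative otherwise.

Two identifiability limits are inherent and surface in the recovery
suites: (1) homozygous-background samples pool both haplotypes into one
background, so the measured AF is roughly half the per-haplotype value —
the pipeline's clonal-ordering stage therefore uses heterozygous-background
samples only; (2) near-clonal CNLOH (f → 1) pushes the minor background
below the 1% filter, collapsing the sample to one background and losing
phase — the same behaviour the real assay exhibits. AF recovery (95th
percentile error ≤ 0.03) is evaluated at depth 3155, the minimum depth of
the sequencing design this emulates; at depth 1000 the binomial counting
noise alone (SE ≈ 0.022 for a 50% AF on a half-depth background) makes
that bound unreachable for any estimator.

## Interaction statistics

The two-sided binomial doubles the smaller exact tail,
p = min(1, 2·min(P[X≤k], P[X≥k])); at p₀ = 0.5 this is exact, symmetric,
and identical to the minimum-likelihood convention (available via
`method="minlike"`). Allelic-shift counting: gain → risk haplotype
duplicated, loss → retained, CNLOH → duplicated, over informative
heterozygous carriers, against a 50:50 null. The exact test is discrete:
its size at n = 59 is 0.038, so the type-I calibration check runs at
n = 997 where the attainable size is 0.0495. Co-occurrence uses Fisher's
exact test up to 10,000 total counts and chi-square beyond, with
Haldane-corrected odds ratios when a cell is zero and the method recorded.
Clonal ordering is the classical sign test (ties dropped; an even-split
policy is available). Published p-values whose null probabilities are not
recoverable (the overall cis binomials) are not asserted anywhere; the
package computes cis statistics only under its documented
informative-heterozygote p₀ = 0.5 null.

## Telomere genetics

**PRS.** Effect-allele-oriented weighted dosage sum, z-scored across the
cohort (population SD); allele flips are resolved via 2 − dosage when the
counted allele is the other allele, otherwise an error per variant.

**MR estimators** (log-odds outcome scale, exponentiated for reporting):
IVW with first-order weights βX²/σY² and multiplicative random-effects
inflation √(Q/(n−1)) when Cochran's Q exceeds its df (recorded); MR-Egger
as a WLS of βY on βX with intercept after orienting βX ≥ 0, t-based
p-values on n−2 df and residual scale never deflated below 1; simple and
weighted medians as weighted 50th percentiles (equal weights vs βX²/σY²)
with seeded parametric-bootstrap SEs (default 10,000 draws, seed 2021; the
1,000-simulation coverage suites use 400 draws per fit as a problem-size
choice); maximum likelihood under the joint normal model with the true
exposure effects profiled out in closed form, optimized over θ (bounded
Brent, xatol 1e−12), SE from the profile curvature. On homogeneous
instruments ML coincides with IVW to numerical precision, which the suite
asserts at 1e−6.

**Pleiotropy screening.** For each variant, the consensus effect is
re-estimated on the remaining variants and the held-out squared residual,
scaled by σY² + θ²σX², is referred to χ²(1); Benjamini–Hochberg at
FDR 0.2 flags removals, which are reported for audit. The leave-one-out
consensus is the weighted median rather than IVW: with several variants
sharing large pleiotropic effects, an IVW consensus is dragged toward the
outliers and flags the clean variants instead (masking); the median keeps
its breakdown point. This screen is an approximation to dedicated
pleiotropy software and is documented as such.

**Liability conversion.** h²_liab = h²_obs · K²(1−K)² / (z²P(1−P)) with z
the standard normal density at Φ⁻¹(1−K); linear in h²_obs by construction.

**qPCR rTL.** Reaction quantities are interpolated on the standard curve
in log₁₀-quantity space (the curve is log-linear in Cq); T and S are
triplicate means; rTL is a configurable transform of T/S — default `exp`,
recorded in the output, since the exact normalizing exponentiation used in
practice varies between labs. Records whose triplicate quantity CV exceeds
15% are flagged, not dropped. The control CV is 100·sd/mean across runs;
the ICC is the one-way random-effects ICC(1,1) with the unbalanced-design
effective group size, cross-checked against pingouin in the tests. The
generated plates have between-sample log-ratio SD 0.20 and replicate noise
0.03, yielding ICC ≈ 0.98 — the precision regime of a well-run assay.

## Pipeline and problem sizes

`run_pipeline` chains the stages on one synthetic cohort and writes
deterministic outputs: `summary.json` holds no timestamps and uses sorted
keys, so identical config + seed reproduce it byte-for-byte (the manifest
carries the timestamp and file digests instead). Stage failures abort with
a stage-tagged error after removing partial outputs. The cohort "cis"
percentage counts mutated samples whose mutation background is GGC
(homozygous carriers included); the cis binomial uses heterozygous
informative samples only. The reported mCA percentage is the *detected*
fraction, necessarily below the generator's true prevalence because clones
under a few percent cell fraction sit below any caller's floor.

Default problem sizes — demo pipeline 933 samples at 500 array sites,
recovery suites 200 events + 200 nulls at 700 sites, 400 long-read samples,
1,000 MR coverage simulations, 100 pleiotropy-power simulations — were
chosen so the binomial uncertainty of each recovery metric is small
relative to its acceptance margin while a full run stays around a minute on
one CPU.

## Known limitations

* Single event per sample; no nested or competing clones.
* Phase is exact; real population phasing would degrade the phased tier
  and shift weight to the rescue tier.
* The pleiotropy screen is a robust approximation, not a likelihood-based
  pleiotropy model.
* The Egger CI uses t quantiles but the suite's coverage is reported under
  normal-based intervals for all estimators.
* Telomere associations are fit on generator truth cf in the pipeline's
  regression demo; an end-to-end version against *called* cell fractions
  attenuates the slope slightly (calls are unbiased but noisy).
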