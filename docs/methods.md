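# Methods

This note documents the models, parameter choices and numerical decisions
behind `c9wta`, and what the synthetic-data validation does and does not
demonstrate about real cohorts.

## Locus model

Three SNPs near *C9orf72* carry the modifier signal: rs2492816 (intron 3,
ref G / alt A), rs13691 (3′UTR, ref G / alt A) and rs113860022 (promoter,
ref C / alt G).  Four founder haplotypes over (rs2492816, rs13691,
rs113860022) are modelled, ordered by the *C9orf72* expression they confer:

| haplotype | label | code | default frequency |
|-----------|-------|------|-------------------|
| G-A-G | super-low | 0 | 0.011 |
| G-A-C | low       | 1 | 0.209 |
| G-G-C | medium    | 2 | 0.370 |
| A-G-C | high      | 3 | 0.410 |

The frequencies are the unique solution to the marginal alt-allele
frequencies 0.41 (rs2492816-A), 0.22 (rs13691-A) and 0.011 (rs113860022-G)
under two structural constraints: the A/A combination of the common SNPs
does not occur, and rs113860022-G occurs only on the G-A background.  The
repeat expansion (HRE) is carried exclusively on an A-G-C haplotype.

We take rs13691's minor allele to be A, so that the low/super-low
haplotypes carry rs13691-A and the negative per-A-allele expression effect
is consistent with the haplotype expression ordering.  This is an
assumption: allele identity should be confirmed against dbSNP before
applying the pipeline to real VCFs whose ref/alt labelling differs.

## Haplotype frequency EM

Frequencies are estimated from unphased genotypes by the standard
multi-locus EM: each phase-ambiguous genotype is split across its
compatible ordered haplotype pairs in proportion to the current frequency
products, and expected haplotype counts are renormalised.  Initialisation
is the product of marginal allele frequencies; convergence is a maximum
frequency change below 1e-8, capped at 10,000 iterations.  The
log-likelihood is asserted non-decreasing on every run.  A single
double-heterozygote started from a flat distribution is a stationary point
(both phasings equally likely); this tie case is deliberate and tested.
`detect_missing_haplotype` flags haplotypes below eps = 0.005 — below the
rare-allele frequency 0.011 but above sampling noise at n ≈ 10⁴ — and
always flags exact zeros.

## WTA subgroup assignment

For an HRE carrier the mutant allele's haplotype is invariant (A-G-C), so
one A, one G and one C are subtracted from the carrier's unphased allele
pairs; the residual alleles form the wild-type haplotype.  A triple lacking
any required allele is rejected as HRE-incompatible, and a residual outside
the founder set is rejected as non-founder.  The assignment provably equals
brute-force phase enumeration over {founders} ∪ {HRE} (tested exhaustively
over all 27 triples); exactly four triples are compatible, one per code.
Non-carriers receive a founder-diplotype label instead — subgroups are
defined only on the wild-type allele of carriers.

## Survival model

Survival is analysed as fully observed months from onset (no censoring),
restricted to limb/bulbar onset.  After removing the top and bottom
ceil(0.05·n) survival values (ties broken by original position, lower
index first), log₁₀(survival) is regressed on the integer subgroup code.
The within-genotype carrier deficit uses Welch's unequal-variance t-test;
the paper-equivalent analysis did not specify pooling, and Welch is the
safer default.

The generator's survival model is log₁₀(months) = 1.5 + β·code + γ·HRE +
N(0, 0.15).  β and γ are not free dials: they are derived analytically
(via the lognormal mean) so that the implied month-scale deficits of
carriers vs genotype-matched non-carriers equal −18 months at code 0 and
−8 months at code 3 — the published effect sizes.  With these defaults
β ≈ 0.0718 and γ ≈ −0.334, and a baseline of 1.5 log₁₀-months gives a
mean non-carrier survival of ≈ 33.6 months, realistic for ALS.

**Trimming and recovery tests.**  The 5% symmetric trim is an outlier
guard for heavy-tailed real-world survival data.  On the generator's
light-tailed lognormal draws it removes genuine signal: trimming the
marginal extremes of a subgroup mixture preferentially deletes long-lived
high-code and short-lived low-code patients and attenuates the fitted
slope (measured: mean 0.048 vs planted 0.072 at n = 250).  The planted-
effect recovery tests therefore evaluate the estimators without the trim
step, while the trim contract itself is tested separately and remains in
the pipeline, where it reproduces the published procedure.

## ALSFRS-R time-to-threshold

Each patient's series is anchored at (0, 48) and, when death is known,
(death, 0); duplicate timestamps are averaged.  t_i is the first downward
crossing of score i on the piecewise-linear interpolant (strictly between
adjacent observed points, not a global fit); an exact hit at a visit
returns that visit's time; a patient who never reaches i and has no death
anchor is excluded, not imputed.  On a noiseless linear decline t_i equals
survival·(48−i)/48 exactly.  Score rebounds are possible in real data; the
first downward crossing wins.  The threshold scan covers 3–45; per-
threshold trimming is agnostic of genotype.  The per-visit ALSFRS-R slope
is deliberately not implemented — it is known to correlate poorly with
disease length.

Generator defaults: visits every 3 months, score noise sd 2 points,
clipped to [0, 48].  Real visit cadence is irregular; the fixed spacing
only matters for power, not validity, of the interpolation tests.

## Tn5 footprinting

Read 5′ ends are shifted +5 bp (plus strand) / −4 bp (minus strand) to
insertion coordinates; all intervals are 0-based half-open, and a cut on a
peak's end coordinate is outside it.  Profiles normalise each sample by
its total cuts in the peak *before* averaging within genotype
(normalise-then-average removes depth confounding and yields cut
*frequencies*); the differential test instead uses raw counts with
median-of-ratios size factors, mirroring how the two analyses are usually
run.  Stacked matrices drop rows averaging strictly less than 1 count per
sample.  Per base, a negative-binomial GLM with log link regresses counts
on allele dose plus covariates; dispersion is per-base method-of-moments
with a floor of 1e-8 (no shrinkage across bases — unlike DESeq2, with
which bit-parity is not claimed); the dose coefficient's Wald p-values are
BH-adjusted across bases, and effects are reported as log₂ fold change per
alt allele.  A fit failure at a base is recorded as missing, not fatal.
The stringent adj-p < 1e-40 emphasis threshold is reported as a flag,
never used as a filter.

Generator defaults: two 300-bp peaks, NB mean 5 cuts/base/sample,
dispersion 0.1, a planted footprint at offsets 120–180 of the promoter
peak with −0.5 log₂FC per rs2492816-A allele (2× depletion at dose 2).
Because profiles are renormalised per sample, the expected dose-2/dose-0
profile ratio inside the footprint is ≈ 0.56, not 0.50.

## Loss-of-function screens

Expression outliers: per candidate gene (default NEK1, OPTN, TBK1, SETX,
SPG11, ATP13A2), robust score (value − median)/IQR with flags below −3.
Under a Gaussian null the flag rate is ≈ 2.6×10⁻⁵ per gene-sample (median
− 3·IQR ≈ 4.05 sd below centre), which the tests verify by simulation.
Genes with zero IQR or absent from the matrix are skipped with warnings.
Batch correction is an upstream input and is not re-implemented.

Allele balance: ref/alt read counts are pooled across heterozygous sites
and tested two-sided against a fair binomial; ranking is by |fraction −
0.5| then p.  Pooling is commutative, so site order cannot affect ranks.

Unique junctions: flagged when supported by ≥ min_count (default 5) reads
in exactly one sample and < noise_count (default 2) everywhere else; the
noise floor tolerates stray mismapped reads and is a declared default, not
an inferred one.  Flagged junctions are joined to rare variants carried
uniquely by the carrier within 100 bp of either splice site.  Structural
variants and exon-level coverage anomalies are outside the automated
screens and left to manual review.

## What the synthetic validation shows — and does not

The generator reproduces the *statistical* structure the estimators
assume: exact haplotype/genotype consistency, additive expression effects,
log-linear survival, linear functional decline, NB cut counts.  Passing
tests therefore demonstrate estimator correctness and calibration under
the assumed model, at the published effect sizes.  They do not demonstrate
robustness to real-data pathologies — genotyping error, irregular visit
schedules, informative censoring, overdispersion beyond NB, batch
structure in expression — none of which the generator emulates.  The HRE
expression shift (−0.3) is a placeholder magnitude: the real carrier
expression distribution is not numerically parameterised here.

## Problem sizes

Default analysis cohorts in the examples and acceptance runs use 150–600
samples, 10,000 for haplotype-frequency convergence checks, 100 seeds for
recovery coverage, 1,000 replicates for type-I calibration, and ~1,000
bases × 200 samples for footprint power — sizes at which every planted
effect is comfortably detectable and the whole suite runs in well under a
minute per module.
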