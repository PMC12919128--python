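# c9wta

Genetic-modifier analysis of the *C9orf72* wild-type allele (WTA) in ALS,
implemented as a tested Python pipeline.

The *C9orf72* hexanucleotide repeat expansion (HRE) is the most common
genetic cause of ALS, but disease duration among expansion carriers varies
widely.  Part of that variation traces to the *other* — wild-type — copy of
*C9orf72*: common regulatory variants on the WTA set its expression level,
and the residual expression from the WTA modifies how fast carriers
progress.  This package implements that analysis end to end for anyone who
wants to run it on genotype + clinical + functional-genomics cohorts, or to
study its statistical behaviour on simulated data:

1. **Founder-haplotype inference** (`c9wta.haplotypes`) — a two/three-locus
   EM algorithm estimates haplotype frequencies over rs2492816, rs13691 and
   rs113860022 from unphased genotypes.  Population structure at this locus
   is explained by four founder haplotypes with ordered *C9orf72* expression
   (super-low `G-A-G`, low `G-A-C`, medium `G-G-C`, high `A-G-C`); the
   `A/A` combination of the two common SNPs is absent, and the rare
   rs113860022-G allele is nested inside the low haplotype.
2. **WTA subgroup assignment** — the HRE travels exclusively on the
   `A-G-C` background, so subtracting one `A-G-C` haplotype from a
   carrier's unphased triple reveals the wild-type allele.  Carriers are
   coded 0–3 by increasing WTA expression (`GA/AG/GC → 0` … `AA/GG/CC → 3`).
3. **Survival statistics** (`c9wta.progression`) — after removing the top
   and bottom 5% of survival times, ordinary least squares of
   log₁₀(survival months) on the subgroup code tests whether higher WTA
   expression is protective; Welch t-tests quantify the carrier vs
   non-carrier survival deficit within each shared genotype.
4. **ALSFRS-R time-to-threshold** (`c9wta.alsfrs`) — each patient's
   functional-score trajectory is anchored at 48 at onset and 0 at death
   and linearly interpolated; the months to reach a score of 24 (and a
   robustness scan over thresholds 3–45) replace the noisy per-visit slope.
5. **Single-basepair Tn5 footprinting** (`c9wta.footprint`) — ATAC-seq
   read 5′ ends are shifted +5/−4 bp to insertion sites, tabulated per base
   and sample within peaks, and tested base-by-base for an allele-dose
   effect with a negative-binomial regression (median-of-ratios size
   factors, Benjamini–Hochberg adjustment).
6. **Rare loss-of-function screens** (`c9wta.outliers`) — samples >3
   interquartile ranges below a candidate ALS gene's median expression,
   pooled allele-balance imbalance at heterozygous sites, and splice
   junctions unique to a single carrier joined to nearby carrier-unique
   rare variants.

A first-class synthetic cohort generator (`c9wta.synthetic`) emulates the
statistical structure of all of the above — founder haplotypes, co-inherited
HRE, additive expression effects, log-scale survival, linear ALSFRS-R
decline, negative-binomial cut counts with a planted footprint, planted
outliers and junctions — so every estimator can be validated against known
truth.

## Worked example

```bash
c9wta --seed 1 --out-dir cohort simulate --n-cases 300 --n-controls 300
c9wta --seed 1 --out-dir results all cohort
```

On this cohort (seed 1, HRE prevalence 0.3 so subgroup statistics are well
populated) the result tables contain:

```text
haplotype  frequency  missing        # 2-SNP EM frequencies
       GG     0.3458    False        # truth 0.37
       GA     0.1892    False        # truth 0.22
       AG     0.4650    False        # truth 0.41
       AA     0.0000     True        # the missing founder haplotype

         term  estimate_log10_months_per_code     se      p   n
subgroup_code                          0.0701 0.0195 0.0006  70
```

The fitted slope 0.070 log₁₀-months per subgroup code (planted: 0.072)
means each step up in WTA expression multiplies carrier survival by
10^0.070 ≈ 1.18 — the high-expression WTA is protective (p = 6×10⁻⁴).
The within-genotype Welch t-tests, the time-to-24 table (mean 10.8 / 11.5 /
14.0 months for codes 1/2/3), the threshold scan (43/43 thresholds with
p < 0.05), the footprint table (top bases all inside the planted interval
at offsets 120–180 of the promoter peak, log₂FC ≈ −0.5 to −0.6 per allele)
and the outlier calls (both planted outliers flagged near −4 IQR; the
planted carrier-unique junction linked to its rare variant 40 bp inside the
intron) are written alongside.

Every stage is also callable as a library function; see the module
docstrings.

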