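# lipidomix

Statistical tooling for asking how gut microbial colonization reshapes host
lipid metabolism. The package re-implements, as a tested and reusable
library, the computations needed for a multi-omics comparison of germfree
(GF) and specific-pathogen-free (SPF) mice: quantitative lipidomics with a
two-experiment replication filter, mass isotopomer distribution analysis
(MIDA) of ¹³C-acetate tracer data, transcriptome–proteome–phosphoproteome
integration, and a sparse composite fatty-acid classification score. Every
stage can be exercised on synthetic data with known ground truth, so the
whole pipeline is testable without animal data.

## What it computes

**Lipidomics statistics** (`lipidomix.lipid_stats`). Concentration tables
(samples × lipid species, shorthand names like `PC 34:1` or
`PE P-16:0/20:4`) are quotient-normalized per lipid class (the per-sample
dilution factor is the fixed point of the median-quotient update), filtered
by a 50%-per-group detection rule, and tested species-wise with Welch's
unequal-variance *t* on log₂ concentrations plus Benjamini–Hochberg FDR
control. A species is *verified* when it is significant (FDR < 0.05) in two
independent experiments with the same direction of regulation:

```
verified = {s : q₁(s) < 0.05  ∧  q₂(s) < 0.05  ∧  sign Δ₁(s) = sign Δ₂(s) ≠ 0}
```

where Δᵢ is the log₂ fold change (SPF − GF) in experiment *i*. Fisher's
exact test flags group-biased missingness; desaturation (FA 16:1 n-7 /
FA 16:0, an SCD1 proxy) and elongation (FA 20:3 n-6 / FA 18:3 n-6, an
ELOVL5 proxy) indices are computed per sample.

**Isotope mathematics and MIDA** (`lipidomix.isotopes`). Natural-abundance
(NA) isotopologue distributions by per-element convolution; NA
deconvolution via a lower-triangular linear system; species-level M+2
deisotoping for shotgun-lipidomics class scans; and the MIDA estimators for
a polymer of *n* identical subunits (palmitate: *n* = 8 acetyl units). With
EM the excess distribution (labeled − unlabeled control, both
NA-deconvolved), the precursor-pool enrichment and fractional synthesis are

```
r = EM₃ / EM₂,   p = r(k+1) / (n − k + r(k+1))   (k = 2: p = r / (2 + r))
f = EM₂ / B(2; n, p)
```

where B is the binomial pmf. The methyl ester of FA 16:0 is C₁₇H₃₄O₂,
monitored at nominal *m/z* 270.

**Multi-omics integration** (`lipidomix.integration`). Total-intensity
normalization and per-feature minimum imputation for proteome /
phosphoproteome matrices; gene-symbol merge with an interquartile-range
tie-break for duplicate features; directed p-values (−log₁₀ p × effect
sign) and concordance-quadrant partition (Q2 = up in both layers toward
SPF, Q4 = down in both); Pearson/Spearman correlation of product/precursor
ratios with enzyme expression.

**Composite classification score** (`lipidomix.classifier`). L1-penalized
logistic regression of germfree status (y = 0 GF/antibiotic-treated, 1
colonized) on log₂, standardized FA concentrations, with the experiment
batch as a fixed *unpenalized* covariate. The penalty λ is chosen by
leave-one-out cross-validation of the binomial deviance with the
one-standard-error rule. The optimizer (FISTA + active-set Newton) is
written here and agrees with an IRLS oracle at λ = 0 to 1e-6 and with
`glmnet` along the path. The score of a new sample is the predicted
probability of the colonized class, standardized with the *training*
means/SDs.

**Synthetic data** (`lipidomix.synth`) generates all of the above with
known truth: two-cohort lipid tables (6/6 and 12/14 mice), binomial-model
tracer profiles with replicate averaging (3 animals per dose), co-regulated
omics layers with target enzyme–ratio correlations, and classifier cohorts
whose antibiotic groups interpolate between the SPF and GF mean profiles.

## Worked example

```python
import lipidomix as lx

# two GF/SPF cohorts with planted effects on two fatty acids
cfg = lx.LipidSimConfig(effects={"FA 16:1 n-7": 1.2, "FA 22:6 n-3": -0.8}, seed=1)
exp1, exp2 = lx.generate_lipid_experiments(cfg)
a1 = lx.differential_test(lx.quotient_normalize(exp1))
a2 = lx.differential_test(lx.quotient_normalize(exp2))
for v in lx.replication_filter(a1, a2, q=0.05).verified:
    print(v.species.label, round(v.exp1.log2_fc, 2), round(v.exp2.log2_fc, 2))
```

prints exactly the two planted species, with concordant directions:

```
FA 16:1 n-7 1.32 1.12
FA 22:6 n-3 -0.67 -0.77
```

Tracer MIDA on a simulated dose (true p = 0.1, f = 0.3, 2% noise,
3 animals averaged):

```python
(lab, ctl), = lx.generate_isotopologue_series(lx.TracerSimConfig(seed=1))
res = lx.mida_estimate(lab, ctl)
# p_hat=0.0957  f_hat=0.3203
```

The estimated precursor enrichment (9.6%) and fractional synthesis (32%)
recover the simulated truth within the noise of a three-animal group. And
the classification score end to end:

```python
train, test = lx.generate_classifier_cohorts(lx.TrainCohortSpec(), lx.TestCohortSpec(), seed=1)
model = lx.train_classifier(train)          # LOO-CV, one-SE rule
scored = lx.classify_and_score(model, test,
                               truth=test.sample_meta["group"].isin(["SPF", "control"]).astype(int))
print(model.selected_species)
print(scored.group_means.round(3))
```

```
['FA 16:0', 'FA 20:3 n-6', 'FA 20:4 n-6', 'FA 22:6 n-3', 'FA 18:1 n-9', 'FA 18:3 n-3']
GF         0.009
M          0.011
VM         0.025
V          0.437
A          0.565
SPF        0.994
control    0.999
```

The signature contains the four informative species; germfree animals and
the strongly microbiota-depleting treatments (VM, M) score near 0, controls
and SPF animals near 1, and the milder antibiotics sit in between, ordered
by their interpolation weight.

A thin CLI mirrors the library:
`lipidomix simulate|lipids|mida|integrate|classify --help`.

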