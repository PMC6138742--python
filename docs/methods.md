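# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `lipidomix`, and what the synthetic-data generators do
and do not emulate.

## Lipid nomenclature and data model

Species labels follow MS shorthand: class abbreviation + total acyl
carbons : total double bonds (`PC 34:1`), optionally sn-resolved
(`PE P-16:0/20:4`), with `O-`/`P-` marking ether and plasmalogen species
and an `n-x` omega-series suffix on GC-MS fatty-acid names. The parser
accepts a closed set of class abbreviations and rejects unknown prefixes
rather than guessing; the omega suffix is metadata and never enters
carbon/double-bond arithmetic. `PC O` is kept as a class distinct from
`PC`; whether ether species are aggregated into diacyl class totals is
left to callers. Concentration tables store missing values as NaN; all
stored concentrations are validated non-negative.

## Quotient (dilution) normalization

Probabilistic quotient normalization estimates a per-sample dilution
factor as the median, over species, of the ratio to a reference profile
(the species-wise median over samples). A single pass leaves a residual:
after dividing, the median quotient against the recomputed reference is
not exactly 1 (we measured residuals up to ~8% on random 6×10 tables).
We therefore iterate the update to its fixed point (tolerance 1e-12 on
the factors, typically a few dozen iterations), which makes the operation
exactly idempotent and leaves every sample with unit median quotient —
properties the rest of the pipeline relies on. The first iteration is
classical PQN; the cumulative factors are reported. Normalization is per
lipid-class block by default (each class is acquired in its own scan mode
and carries its own effective dilution); a global mode is available.
Missing cells are excluded from all medians and stay missing. The
normalization removes per-sample scale only: rescaling samples changes
the output by at most one common block factor.

## Detection filter and missingness

Species are retained when detected in at least 50% of the samples of
*every* group, boundary inclusive. (The alternative literal reading
"excluded if undetectable in less than 50%" would exclude nearly every
species; the chosen reading is recorded in the output metadata.) A
two-sided Fisher exact test on the 2×2 detected/missing × group table
flags species whose missingness is group-biased, i.e. informative rather
than random; such species deserve presence/absence treatment rather than
a mean comparison.

## Differential testing and replication

Concentrations are log₂-transformed (zeros treated as missing first — a
zero concentration is a detection failure, not a measured value) and
compared with Welch's unequal-variance t-test, two-sided, with
Welch–Satterthwaite degrees of freedom. Degenerate cases: both groups
constant and equal → t = 0, p = 1; constant but unequal → p = 0 with a
flag. BH adjustment is applied across all species of one experiment ×
matrix analysis by default (one FDR threshold per comparison); per-class
families are available since classes are analyzed separately upstream.
The replication filter verifies a species only when it is FDR-significant
in *both* independent experiments with the same nonzero fold-change
direction; this is deliberately conservative — direction consistency at
FDR 0.05 twice — and its output is by construction a subset of each
experiment's significant set. Re-running this rule over the bundled
two-cohort reference panel yields 16 liver and 15 plasma species.

## Isotope mathematics

Isotopologues are indexed by nominal mass shift (M0, M1, …); quadrupole
instruments do not resolve isobaric fine structure, so exact masses are
never needed. The NA distribution of a formula is the convolution, over
elements, of per-atom mass-shift distributions raised to the atom count
(binary-exponentiation convolution). Bundled abundances: ¹³C 0.0107,
²H 0.000115, ¹⁵N 0.00364, ¹⁷O 0.00038, ¹⁸O 0.00205, ³³S/³⁴S/³⁶S
0.0075/0.0425/0.0001; all overridable. The test suite checks the
implementation against an exact rational-arithmetic polynomial-expansion
oracle (sympy) to 1e-9.

NA deconvolution solves the lower-triangular system C·x = measured, where
column j of C is the NA distribution shifted to start at Mj. Negative
components beyond −1e-3 (after unit normalization) raise; smaller ones
are clamped with a diagnostic. The MIDA pipeline instead *keeps* negative
components (`keep_negative=True`): measurement noise produces mean-zero
negatives, and clamping them would bias the excess distribution.

## MIDA

Model: a newly synthesized palmitate draws n = 8 acetyl subunits i.i.d.
from a precursor pool with ¹³C enrichment p, so new molecules carry
Binomial(n, p) labels; the pool is a (1−f)/f mixture of pre-existing and
new molecules. On NA-deconvolved profiles the excess distribution is
EM = f·(B(·; n, p) − δ₀), giving the closed forms

- p from the consecutive-isotopologue excess ratio r = EM₃/EM₂:
  p = r(k+1)/(n−k+r(k+1)), i.e. p = r/(2+r) for the default (3,2) pair
  (a numeric bisection fallback covers general pairs and agrees with the
  closed form to 1e-10);
- f = EM₂ / B(2; n, p), clamped to [0,1] with pre-clamp values retained
  in the diagnostics.

NA correction is applied *before* the excess computation: the binomial
ratio formulas are exact only on deconvolved distributions. Both modes
are exposed for comparison. Noise-free round trips recover (p, f) to
1e-8 across p ∈ {0.02…0.2} × f ∈ {0.05…0.8}. With 2% per-channel
multiplicative noise and three replicate animals per dose (the gavage
group size the generator emulates), the median |f̂ − f| at (p = 0.1,
f = 0.3) is ≈0.017 over 200 simulated experiments. Limitation: the M3
excess scales as p³, so for p ≲ 0.05 it falls below a 2% noise floor and
the estimator degrades sharply — dose series at very low enrichment need
more replicates or a different ratio pair.

## Species-level deisotoping

In precursor/neutral-loss class scans, the M+2 isotopologue of a species
with one more double bond is isobaric with the monoisotopic peak 2 Da up
(same carbon count). Species are sorted by ascending nominal mass and,
iterating upward, each *already corrected* donor intensity times its a2
factor (NA₂/NA₀ of the donor formula) is subtracted from its +2 Da
acceptor; negatives are clamped to zero with a flag. M+1 overlap cannot
collide on even-carbon species grids, so only the a2 cascade is applied.
The correction is the exact inverse of its forward cascade (tested to
1e-10).

## Multi-omics integration

Intensity matrices are normalized so every sample's total equals the mean
of the original totals, missing values are replaced by the per-feature
observed minimum (features never observed are dropped and reported), and
values are log₂-transformed. Per-feature Welch t + BH gives layer-wise
effects. Layers are inner-joined on the case-normalized gene symbol;
duplicate features resolve to the one with the highest interquartile
range on the normalized log₂ matrix. Directed p-values are −log₁₀(p)
signed by the effect; quadrants follow the convention Q2 = concordant up
(toward the colonized group on both axes), Q4 = concordant down, Q1 =
x-down/y-up, Q3 = x-up/y-down, with x = transcriptome by convention.
Genes with a zero effect on either axis are counted separately so
quadrant counts always conserve the merged total. Ratio–expression
correlations (e.g. Scd1 vs the 16:1 n-7/16:0 index) use Pearson by
default with Spearman optional, on samples aligned by id.

## Classification score

The model is logistic regression of colonization status on log₂
FA concentrations with an L1 penalty on the FA coefficients only;
the intercept and the experiment (batch) indicators are never penalized,
so additive batch offsets common to all species cannot contaminate the
sparse signature. Features are standardized (mean 0, SD 1) with
parameters frozen from the training data; coefficients are reported on
both scales. Objective: mean Bernoulli negative log-likelihood +
λ‖β_FA‖₁.

Optimizer: FISTA with adaptive restart identifies the support, then an
active-set Newton method with a backtracking line search solves the
stationarity conditions on the support; KKT violators are admitted with
the sign their gradient demands and coefficients may not cross zero
within a step. The fit is deterministic, matches an unpenalized IRLS
oracle to 1e-6 at λ = 0, and reproduces `glmnet`'s selected support and
coefficients on shared datasets.

λ is selected by leave-one-out CV of the held-out binomial deviance
(probabilities clipped at 1e-10) on a log-spaced grid from λ_max (the
smallest penalty zeroing all FA coefficients, computed from the KKT
conditions at the covariate-only fit) down four decades, 40 points,
warm-started along the path. The one-standard-error rule picks the
largest λ whose mean deviance is within one SE (SD over the n held-out
deviances / √n) of the minimum. Deviance, not misclassification, is the
CV loss — it is smooth under LOO.

Scoring a held-out cohort uses the training standardization and assigns
unseen experiments the reference batch level (coefficient 0). The score
is the predicted probability of the colonized class; a linear (log-odds)
output is available via a flag. For *ranking* treatment groups we use
group means of the log-odds: for strongly germfree-like groups the
probability scale saturates near 0 and group ordering there degenerates
into noise, while the linear predictor remains informative. Sensitivity
(colonized class) and specificity are reported at a 0.5 default threshold
together with the full ROC sweep and trapezoidal AUC; the threshold is a
convention, hence the sweep.

## Synthetic-data generators

All generators are pure functions of (config, seed), bit-identical on
repeated calls, built on `numpy.random.default_rng`.

*Lipid cohorts.* Log-normal concentrations around per-species baselines
(the analysis model log₂-transforms, so log-normal noise is the matched
choice), group effects as log₂ shifts applied with the same sign in two
cohorts of 6/6 and 12/14 animals, missingness injected completely at
random (a group-biased mode exercises the Fisher test). The 30-species
default panel spans the dynamic range of a liver FA/PC panel.

*Classifier cohorts.* Four informative species among 16 decoys. Effects
(log₂, SPF − GF, liver): FA 20:3 n-6 +0.48 and FA 22:6 n-3 −0.40 from
the verified panel; FA 20:4 n-6 −0.35 (verified in plasma only; its
liver effect is set just below the verification bar); FA 16:0 −0.40 (not
in the verified list; a comparable shift toward the germfree
saturated-FA excess). Within-group CV 0.10, back-derived from the
verified panel: fold changes near 0.4 passing FDR < 0.05 at n = 6/6
imply raw t ≈ 5 and a within-group log₂ SD ≈ 0.14. (Reading the printed
p-values as raw instead gives CV ≈ 0.16; that setting contradicts the
reported classification outcome — the four-species signature, clean
GF/SPF separation and stable antibiotic ranking — so the FDR-consistent
reading is used.) Training spans two batches with additive log₂ offsets
common to all species, mirroring what the unpenalized experiment
covariate absorbs. The test cohort reproduces the held-out design: a
small GF (5) / SPF (6) validation experiment plus an antibiotics
experiment (ampicillin 6, vancomycin 6, metronidazole 5, V+M 6, untreated
controls 6), each treated group's mean log₂ profile placed on the convex
interpolation w·GF + (1−w)·SPF. Weight 1 is fully germfree-like; weight
0 is indistinguishable from controls.

*Tracer profiles.* Control = clean NA distribution; labeled = the
binomial mixture convolved with NA, with per-channel multiplicative
log-normal noise drawn independently per replicate animal (3 per dose
group) and averaged. Profiles always renormalize to unit sum.

*Omics layers.* Concordantly up/down-regulated gene fractions shared
across transcript/protein/phosphopeptide layers with per-layer Gaussian
noise on the log₂ scale; named enzyme genes are constructed (by
orthogonalized mixing) to correlate with a simulated substrate ratio at
an exact target ρ, so correlation-recovery tests have a controlled
truth.

What the generators do *not* emulate: inter-species correlation within a
sample (noise is independent per species), instrument drift within a
batch, missingness that depends on abundance, isobaric interferences
beyond the M+2 cascade, and real biological effect-size distributions on
non-planted species. Passing tests therefore demonstrate correctness of
the estimators under the stated models, not robustness to every property
of real data.

## Problem sizes in the test suite

Simulation-backed tests run at the study's own scale (6–40 samples,
20–30 species, 200–1000 genes) with seed-pinned generators; Monte-Carlo
checks use 25–500 replicates depending on the statistic, chosen so the
full suite completes in a few minutes on one CPU.
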