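# Methods

This note documents the models, parameter choices and numerical decisions
behind `mirogtt`, and what the synthetic-data generator does and does not
emulate.

## Glucose-tolerance classification

Classification is a pure function of the OGTT glucose fields, evaluated
with a fixed precedence: CFRD (2-h glucose ≥ 11.1 mmol/l), then IGT
(7.8 ≤ 2-h < 11.1), then INDET (any mid-OGTT value ≥ 11.1 with a normal
2-h), then NGT.  All thresholds are applied exactly as printed in the
clinical definitions; the IGT upper bound "11.0" is implemented as
`< 11.1` so the scale is gap-free.  "Mid-OGTT" means the 10/30/60-min
samples — the only sampled points strictly between baseline and the 2-h
draw; the 180-min value does not trigger INDET (it is not mid-OGTT),
though it participates in the NGT "all values < 11.1" reading.  The
120-min glucose is a required input in its own right: the sampling grid
(−1, 10, 30, 60, 180 min) does not contain it and we do not interpolate.
A missing 2-h value makes the participant unclassifiable — an error, not
a default.

## Plate calibration and QC gates

Calibration subtracts, from every Ct on a plate, that plate's UniSp3 mean
minus the unweighted grand mean of plate means.  UniSp3 plate means
coincide afterwards, making the transform idempotent; a side effect worth
knowing is that shifting one plate moves all calibrated Cts by a common
constant (1/n_plates of the shift), which cancels in every downstream Ct
difference.

Gates run on calibrated Cts (plate offsets cancel within a sample either
way; calibrating first standardises reporting):

* RT inhibition: UniSp6 Ct > 23 fails (strict; Ct = 23.0 passes).
  Undetected UniSp6 fails; a missing UniSp6 record is an error, never a
  silent pass.
* Haemolysis: index = Ct(miR-23a-3p) − Ct(miR-451a); pass iff index < 7
  (strict; 7.0 fails).  miR-451a is erythrocyte-enriched, so haemolysis
  lowers its Ct and inflates the index.
* Extraction consistency: for each of UniSp2/4/5 separately, the Ct range
  across all of a participant's OGTT samples must not exceed 3 cycles
  (range = 3.0 passes).  We read the rule as cross-sample drift per
  spike-in within a participant; a failure excludes the participant
  entirely.

Inclusion requires the baseline sample plus at least two later timepoints
to pass all sample gates.  Undetected reactions are represented as
missing values, never as a sentinel cycle number such as 40.

## Normalization schemes

Two schemes, both against the endogenous serum controls miR-16-5p,
miR-23a-3p and miR-486-5p:

* ΔCt scheme (volcano comparisons): per sample,
  ΔCt = Ct(miRNA) − arithmetic mean of the three control Cts.
  Normalization must be in-sample to yield per-sample values for a t
  test.
* ΔΔCt scheme (across-group analyses): the in-sample step subtracts the
  geometric mean of the three control Cts, computed on the Ct scale
  exactly as the protocol states (even though Cts are already
  logarithmic).  The between-group step subtracts the NGT-baseline
  reference per miRNA.  A geometric mean of the in-sample values
  themselves would be undefined (they can be zero or negative), so the
  reference is the geometric mean of NGT-baseline *expression*
  2^(−ΔCt'), which on the Ct scale is the arithmetic mean of ΔCt'.  This
  choice makes the anchoring exact: the geometric mean of fold over
  NGT-baseline samples is 1 by construction.

Volcano classification uses the equal-variance two-sample t test on the
log (ΔCt) scale — the GeneGlobe-platform default; `equal_var=False` gives
Welch — with fold change as the ratio of group mean relative expression.
The ±1.5-fold cut-off is inclusive (fold = 1.5 with p < 0.05 is
classified, keeping the printed value on the significant side).

The across-group baseline comparison is a one-way ANOVA on fold values
with Tukey HSD (studentized range).  The time course is a linear mixed
model on ΔΔCt — fixed effects group, timepoint and their interaction, a
single random intercept per participant, fitted by REML (no random
slopes: not identifiable with ≤ 5 timepoints and missingness).  Pairwise
group contrasts at each timepoint use Wald z tests with no multiplicity
correction (Fisher's LSD convention).  A variance component estimated on
the boundary (random-intercept variance ~ 0) is accepted as a legitimate
REML solution; optimizer failure across lbfgs/bfgs/powell/cg raises with
diagnostics.  In balanced complete data the fixed effects coincide with
the ordinary two-way ANOVA estimates (tested to 1e-6).

## Count arm: the glucose differential-response statistic

Counts are normalized with median-of-ratios size factors over the miRNAs
with all-positive counts (a documented `pseudo_reference` switch handles
matrices without such a reference, using positive-count geometric means).
The expressed filter retains miRNAs with normalized counts strictly
above 5 in at least half of the samples (fraction inclusive).

The differential-response estimand is the group × timepoint interaction
on the log2 scale.  Rather than a negative-binomial GLM with dispersion
shrinkage, we use a deliberately simple paired statistic: per participant
r_i = log2((n60 + c)/(n0 + c)) with pseudocount c = 0.5 (configurable),
and interaction effect = mean r(group) − mean r(NGT).  Pairing within
participant is the correction for participant-level variability.

With three participants per group the per-miRNA pooled variance has four
degrees of freedom, and a raw Wald z would be t4-distributed under the
null — its maximum over a few hundred miRNAs is typically 6–8, swamping
any realistic signal and invalidating a normal reference.  We therefore
squeeze the pooled variances across miRNAs with the standard
empirical-Bayes scaled-F model (prior scale and degrees of freedom
estimated by moments of log s², digamma/trigamma inversion) before
forming z; the same moderation (per group) applies to the baseline
Welch-style comparison.  This is small-sample variance moderation on the
log-ratio scale, not a reimplementation of NB dispersion shrinkage.
`moderate=False` restores the raw statistics.  p-values are two-sided
normal; BH step-up q-values; volcano classes at |effect| ≥ 1 log2 unit
(2-fold) and q < 0.05.

Zero pooled variance (possible with identical small counts) receives the
prior-dominated moderated value, avoiding infinite z.

Known property: size factors are defined up to scale, so scaling one
sample by λ scales its factor by λ only *relative* to the others; and
results are invariant to per-group library rescaling exactly when the
pseudocount is 0, and to O(pseudocount/count) otherwise.

## Correlations

Spearman rho uses midranks; the p-value is exact for n ≤ 10 (full
enumeration of orderings, two-sided as the share of permutations with
|rho| ≥ |rho_obs|; the distribution is cached per rank multiset, so the
n! enumeration runs once per tie pattern) and the t approximation with
n − 2 df above that.  Small strata motivated the exact branch: with a
six-participant group the t approximation is materially off.  A constant
vector leaves rho undefined (reported as missing, never coerced to 0).
The panel applies no multiplicity correction — it is exploratory, and is
reported per (group, timepoint) stratum with the pair count; strata with
n < 3 are skipped with a note.  By default correlations use the ΔΔCt
fold values; the value column is switchable.

## Target enrichment

Target tables are generic TSV exports (mirna, gene, source); "validated"
status is the union over source databases, since requiring every
database would conflate coverage with evidence.  The common-target set
intersects the targets of *every* queried miRNA with the expressed-gene
universe (a user input — the expression threshold defining "expressed in
islets" is study-specific).  Over-representation is the hypergeometric
upper tail P[X ≥ k] with BH adjustment across pathways.  Nothing is
queried online.

## The synthetic-data generator

The generator emulates the study design the analysis assumes: four
glucose-tolerance groups with the published group sizes (18/6/12/14 for
the qPCR cohort; 3/group for the paired count matrix), five OGTT
timepoints plus the 2-h diagnostic glucose, clinical analytes drawn
within the published per-group baseline ranges (Beta marginals matching
the published means), plate structure with spike-ins, and injected
haemolysis/RT-inhibition artifacts recorded in a truth object.

Key constructions:

* Glucose trajectories are built per group so that the classifier
  reproduces the intended label with certainty (a construction guard
  asserts it), with curve shapes — rise to a 30/60-min peak, partial
  return by 180 min — that look physiological for each category.
* Target Cts are anchored to the sample's realized control Cts and
  expressed as ΔCt offsets minus the injected log2 effects.  With zero
  noise and offsets, control-based normalization inverts the
  construction exactly — parameter recovery becomes a sharp test
  (injected +1 log2 ⇒ mean fold 2.0 to 1e-9).
* Haemolysis is modelled as a miR-451a Ct decrease (erythrocyte miRNA
  release), the direction the index actually responds to; clean samples
  sit at index ≈ 5, flagged samples at ≥ 8.5, so gates are exact under
  zero noise.
* Analyte–miRNA couplings use a Gaussian copula: one latent normal per
  analyte drives both the Beta-mapped analyte value and the coupled
  miRNA's per-participant log2 level.  Latent Pearson 0.8 corresponds to
  Spearman (6/π)·asin(0.4) ≈ 0.79.
* Counts are negative-binomial (Gamma–Poisson) with a per-participant
  lognormal factor shared between the two timepoints — the paired
  structure the response statistic exploits.

Defaults and why: Ct noise 0.25 cycles and plate offsets 0.5 cycles
(typical qPCR replicate spread and batch drift); haemolysis 10 % and RT
inhibition 5 % (visible-artifact rates in serum panels); NB dispersion
0.1 (biological serum miRNA-seq); per-participant spread 0.3 log2 units;
library sizes 0.5–2 million.  The injected effect maps default to the
directions reported for this biology (liver-enriched miR-122-5p and
p53-responsive miR-34a-5p/miR-885-5p elevated at baseline in INDET/CFRD;
a CFRD-specific positive miR-223-3p and negative miR-363-3p glucose
response; miR-122-5p/miR-34a-5p coupled to liver enzymes).  Power and
recovery checks use near-Poisson dispersion (0.01) — the low-dispersion
regime in which a 1.5-log2 interaction is reliably top-ranked at
3 participants per group.

What the generator does **not** emulate: raw reads, UMIs and adapter
chemistry; amplification-efficiency differences between assays (all
assays are treated as perfectly efficient, so Pfaffl-style correction is
out of scope); CFTR genotype or modulator-treatment effects; missing
visits other than QC-driven exclusion; age/sex structure beyond drawing
them.  Passing tests therefore demonstrate the pipeline's correctness
and calibration under the stated noise model, not the biological effect
sizes of any real cohort.

## Problem sizes

The test suite and acceptance checks run at deliberately modest sizes
chosen as the smallest that exercise each property sharply: QC truth
recovery on 400 samples; null calibration over 200 replicates of a
12-participant qPCR comparison and a 6-participant count design
(215 miRNAs); power over 100 seeds; copula recovery over 200 replicates
at n = 50; exhaustive oracles at n ≤ 6 (Spearman, BH) and N ≤ 12
(hypergeometric).

## Known limitations

* The moderated z is approximately, not exactly, normal under the null;
  at 200 tests the residual anti-conservativeness is small (measured
  null q < 0.05 fraction ≈ 0.001–0.01) but nonzero.
* The mixed-model contrasts use Wald z rather than Satterthwaite or
  Kenward–Roger df, and are mildly liberal at small n.
* The exact-permutation Spearman branch at n = 10 enumerates 3.6 M
  orderings on first use per tie pattern; repeated tied patterns beyond
  the cache width re-enumerate.
* Replicate wells are aggregated by mean before gating; no melt-curve or
  efficiency QC is modelled.
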