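# Methods

This note documents the models, defaults and numerical choices behind
`hypomir`, in the spirit of a package vignette: what is simulated, what each
statistical step assumes, and what the passing test suite does and does not
establish about real data.

## Synthetic study design

The generator (`hypomir.simulate`) emulates the three data layers of a
hypoxia-biomarker study.  All expression is generated directly on the log2
scale (the analyses all operate on log2(x+1)-transformed values, so
simulating raw counts would add machinery without exercising any additional
code path); survival times are exponential, the simplest law satisfying the
proportional-hazards assumption that every Cox analysis in the pipeline
makes.  Hypoxia is a binary latent state H (the pipeline dichotomises
everything), with a noisy continuous companion score exposed for
correlation tests.  One seeded generator drives everything; the qPCR,
cohort and trial blocks use separate child streams of the same seed, so the
planted biology (which miRNAs respond to hypoxia) is shared across blocks
while patients are independent draws.

**qPCR block.** 4 cell lines × {21, 0.2, 1}% O₂ × 3 replicates × 384 target
miRNAs + 3 endogenous controls.  Target baseline Ct ~ U(22, 28), controls
U(15, 17), per-line offset N(0, 0.5), per-sample (cell line × condition ×
replicate) global offset N(0, 0.5) — this is what control normalisation
must remove — and measurement noise N(0, 0.25) per well.  30 planted
features have Ct lowered by 1.5 cycles under hypoxia in 2–4 lines each
(every planted feature in ≥ 2 lines, so all are legitimate seed
candidates); 4% of features are "low expression" (baseline U(31, 34)) to
exercise the Ct ≥ 30 exclusion.  With these values the per-comparison
Welch test detects a planted feature with probability ≈ 0.95 (measured; the
shared control noise within a card makes per-seed recall vary a few points
around that), so seed discovery is informative but not saturated.

**Cohort block.** n = 400 patients, P(H = 1) = 0.5.  99 anchor mRNA genes
(+100 background genes) shifted +1 log2 unit under H; of the 30 planted
miRNAs, 7 are shifted +1 (positive arm), 7 are shifted −1 (negative arm),
3 are emitted as ~80% zeros (mirroring seeds excluded for no/low cohort
expression), the rest are cell-line-only inductions with no cohort effect —
exactly the miRNAs the Boruta/Spearman steps must reject.  Expression noise
sd = 1.  Survival: OS and PFS (PFS rate ×1.3), baseline hazard
0.015/month, hazard ratio 2 for H, administrative censoring at 60 months,
dropout 0.005/month (≈ 30% censoring without dropout, ≈ 38% with).

**Trial block.** 95 patients per arm, forced 1:1 to RT vs RT+CON,
P(H = 1) = 0.25 (matching upper-quartile stratification), endpoints OS and
LRFS.  Log-hazard = log h₀ + (log 2)·H + [log 0.45·H + 0·(1−H)]·I(RT+CON):
the treatment benefit exists only in the hypoxic stratum.  Continuous
IHC-like markers (CAIX, GLUT1, HIF1A) are N(5, 1) + 1·H.

Where the study this design emulates reports a quantity (4 lines, 384
features, triplicates, 70:30 split, 5-year censoring, thresholds 0.05/1.0,
log 0.45 treatment effect), the default is that quantity; effect sizes and
noise levels the study does not state (induction shift, expression effect,
hazard scale) were chosen once for realistic-but-not-saturated power and
are listed above.  What the generator does **not** emulate: batch effects,
platform-specific count distributions and normalisation chemistry,
correlated miRNA co-regulation, non-proportional hazards, informative
censoring.  Passing tests therefore demonstrate that the *procedures* are
implemented correctly and are well calibrated under their own assumptions —
not that the signature would validate on any particular real cohort.

## ΔΔCt analysis

ΔCt = Ct(target) − reference of the endogenous controls, per sample.  Two
reference modes exist:

* `geometric` (default): geometric mean of the control Ct values, the
  literal reading of "normalised using the geometric mean of the endogenous
  controls".  A per-sample additive Ct shift then cancels only to first
  order (geomean(c+k) = geomean(c) + k·(1 + O((k/c)²)) for Ct ≈ 16 the
  residual is ~10⁻³ cycles per shifted cycle) — far below the measurement
  noise, but not exact.
* `arithmetic`: arithmetic mean of the control Cts, which equals geometric-
  mean averaging of the linear-scale abundances 2^(−Ct) (the convention of
  reference-gene normalisation on the expression scale) and cancels
  per-sample shifts *exactly*.  The exact shift-invariance test runs in
  this mode; the default stays `geometric` to match the stated wording.

Control subsets are chosen by brute force over all non-empty subsets,
minimising the SD across samples of the per-sample reference value (ties →
larger subset, then lexicographic).  ΔΔCt = mean ΔCt(hypoxia) − mean
ΔCt(normoxia); FC = 2^(−ΔΔCt); p from Welch's unequal-variance t test on
the ΔCt replicates (the quantity actually thresholded), two-sided, with
degenerate-limit conventions p = 1 (both groups constant and equal) and
p = 0 (both constant, unequal).  At n = 3 per group the Welch test is
conservative — its true size is ≈ 0.035 at nominal 0.05 (measured by
simulation) — which the null-calibration test accounts for by using the
binomial band around the nominal rate for a 384-feature card rather than a
pooled multi-card band.  Exclusion rule: a feature is dropped (per cell
line) iff Ct ≥ 30 or undetermined in *all* replicates of both conditions —
the permissive reading; undetermined Ct is NaN throughout, never a numeric
sentinel.  Induced = p < 0.05 and FC > 1.0, both strict, uncorrected.

## Boruta

Implemented from scratch (no reference implementation is available in the
environment), following the published algorithm: per iteration, one
freshly shuffled shadow copy of every surviving feature (padded so at least
five shadows are always present); a 500-tree random forest
(balanced class weights, √p features per split) on [real | shadow]; a *hit*
when a feature's impurity importance exceeds the iteration's maximum shadow
importance; two one-sided Binomial(iterations, ½) tests per undecided
feature, Bonferroni-corrected **over all features that entered the run**,
confirming (significantly more hits) or rejecting (significantly fewer;
the feature and its shadow leave the matrix).  Features undecided at the
iteration cap (default 1000, the published signature's setting) are
tentative, and by default tentative features pass forward to the Spearman
filter (the published signature kept 19 confirmed-or-tentative of 59).

Two details matter and were validated empirically. First, the Bonferroni
correction must stay constant: correcting only over the currently
undecided features loosens the decision boundary exactly when the shadow
bar is weakest (few survivors ⇒ max-of-few-shadows), and in pure-noise
data that combination confirms the most chance-correlated features in
nearly every run.  Second, even with the constant correction, an
all-relevant selector genuinely flags features whose *in-sample* chance
correlation with the labels is large (at n = 200 with 50 features the top
|r| is ≈ 0.17–0.20); such features are "relevant" to the forest on that
dataset, and their confirmation under the global null is a property of the
shadowMax procedure itself, not of this implementation.  The null-
calibration test quantifies this honestly rather than asserting an
unconditional zero false-confirmation rate.

Z-scores (importance standardised by the per-iteration shadow mean/sd) are
computed for the decision plot only; decisions always use raw importances
against shadowMax.

## Scoring and stratification

Unsigned signatures score as the mean log2 expression of members present;
signed signatures as mean(positive) − mean(negative), which is invariant
to per-sample additive shifts and scales linearly under global scaling.
Missing members are dropped with the coverage fraction recorded (the
published analyses scored 13-of-14 and 5-of-6 when a platform lacked a
probe).  The anchor mRNA signature is scored as unsigned mean expression
and dichotomised at the cohort median — the convention of the anchor-
signature literature; the choice is recorded in output metadata.  Quantile
cut-offs use linear interpolation (numpy's default), fixed so thresholds
are reproducible across cohorts; ties at the cut-off are normoxic
(strict >), the conservative direction for hypoxia calling.  A stored
numeric cut-off and re-applying the reference cohort's quantile are both
supported, since published practice varies.

## Train/test split

Stratified by the anchor label.  The total training size is
round-half-up(0.7·n) and is apportioned across strata by largest remainder;
this agrees with rounding each stratum separately whenever the two agree,
and guarantees the canonical 405 → 284/121 split for any label balance
(plain per-stratum rounding gives 283/122 when the strata split 202/203).

## Survival analysis

Cox fits delegate to lifelines (Efron ties); the module's contract is the
reported quantities and their calibration, which the simulation suite
verifies (HR recovery within [1.8, 2.2] at true HR 2, n = 400; 95% CI
coverage 0.92–0.97; interaction type-I error 0.03–0.07).  Conventions:
univariable two-group comparisons report the log-rank (score) p;
multivariable models screen candidates at univariable p < 0.1 and report
Wald p, returning an explicit empty-model marker when nothing passes the
screen; the treatment × hypoxia interaction p is the likelihood-ratio test
of the product term (better behaved than Wald at small within-stratum
event counts), with Wald also reported.  Hypoxia labels always encode
hypoxic = 1, so HRs read hypoxic-vs-normoxic; arm encodes RT+CON = 1, so
HR < 1 means treatment benefit.  Administrative censoring sets
time > horizon to (horizon, censored), strict inequality.  Degenerate
designs (no events, constant terms, empty strata) return flagged fits with
diagnostics instead of numbers.  Mann–Whitney marker tests use exact
enumeration when both groups have ≤ 10 observations and no ties, otherwise
the tie-corrected normal approximation.

## Problem sizes in the test suite

The acceptance-style tests run the study at its native scale (cohort
n = 400, trial n = 2×95 or 2×200, 384-feature cards) and scale replicate
counts to what one CPU handles comfortably: 200 cohort replicates for HR
recovery/coverage, 1000 null trials for interaction type-I error, 100
trials for interaction power, 5 seeds for Boruta/derivation recovery,
20 seeded cards for the qPCR null calibration and 5 seeded runs for the
Boruta null calibration (each run costs ~100 forest fits).  The
acceptance script reports single-seed pipeline quantities plus 40-replicate
HR recovery and 60-replicate power summaries.

## Known limitations

* The Boruta null behaviour discussed above: all-relevant selection
  confirms strong in-sample chance correlations by design.
* The anchor signature is a config input; selecting *which* published
  anchor to use (prognostic screening across candidate signatures) is out
  of scope, as it depends on external cohorts.
* No competing risks, time-varying covariates or PH diagnostics beyond
  convergence flags; no raw-count simulation mode; no NanoString
  normalisation internals (pre-normalised log2 counts are accepted as
  input).
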