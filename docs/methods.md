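# Methods

This note documents the models, procedures and numerical choices behind
`porc`. It is the package's own account of its science; every number quoted
here is computed by the test suite or by `scripts/acceptance.py`.

## Problem setting

After general anaesthesia with a non-depolarising relaxant, a fraction of
awake patients in the post-anaesthesia care unit still has residual
neuromuscular block: a train-of-four ratio (TOFR) below 0.9 by the modern
convention, below 0.7 by the historical one. Calibrated electromyography
(EMG) of the adductor pollicis is the quantitative gold standard but is
rarely available postoperatively. The package implements the derivation and
validation machinery for bedside alternatives: a fixed pathway of muscle
function tests, uncalibrated acceleromyography (AMG), and tactile fading
judged after peripheral nerve stimulation (PNS) — each evaluated against
EMG.

## Cohort simulation (`porc.simulate`)

The raw patient data behind the published study are not public, so all
pipeline stages run on simulated cohorts whose generator encodes the
study's reported structure.

* **Latent TOFR.** Truncated normal on a configurable range, default mean
  0.61, SD 0.31 on [0.0, 1.15] — the published development-cohort summary
  (mean ± SD and observed range) at the time of assessment. A truncated
  normal is the simplest distribution reproducing all three statistics.
* **EMG.** Latent TOFR plus additive Gaussian noise (SD 0.02), clipped at
  0. EMG is the reference channel, so its noise is kept small.
* **AMG.** Latent TOFR times a multiplicative bias (default 1.10) plus
  Gaussian noise (SD 0.05), clipped at 0. AMG is known to overestimate EMG;
  the magnitude is not quantified in the source cohort (its published
  group means differ by only 0.02–0.04), so the bias is an explicit free
  parameter, not a reproduced value. Multiplicative form suits ratio-scale
  data.
* **Test scores.** Each of the eight bedside tests (timed tests 0–5 s,
  graded tests 0–3, diplopia 0–1) follows an ordered-threshold cumulative
  logistic link: a logistic latent variable centred on the patient's TOFR
  is compared with evenly spaced cutpoints (spanning ~0.5 TOFR units)
  around a per-test location. Two parameters per test — location and
  steepness — give a monotone expected score with realistic scatter.
  Default locations (0.30–0.55) encode the muscle-group ordering of
  sensitivity to residual block: facial muscles recover early, lifts and
  swallowing late. `steepness = inf` gives a noiseless step link, used for
  degenerate-case tests.
* **Tactile fading.** Detection probability is piecewise linear: a
  configurable maximum (default 0.9) below TOFR 0.1, ramping to zero at the
  detection limit (default 0.4) and exactly zero above it — encoding the
  established fact that fading is not palpable at TOFR above ~0.4.
* **T1/T0.** First-twitch recovery is generated as
  `clip(0.25 + 0.7·TOFR + N(0, 0.1), 0, 1.2)`, which reproduces the
  reported assessment-time mean (≈0.68 at TOFR 0.61) and SD (≈0.22). It is
  carried in the record but not used by any decision tool.
* **EMG traces.** One reading per 20 s stimulation interval (default 15
  readings ≈ 5 min of assessment). Baseline readings jitter
  multiplicatively within ±5%, which cannot produce a >20% relative drop;
  with per-reading probability `instability_rate` a reading is replaced by
  30–70% of its baseline value (a disconnection/movement artefact). The
  default rate 0.045 makes P(≥2 artefact drops per trace) ≈ 0.13 by the
  binomial closed form, matching the 26/200 instability exclusions of the
  development cohort. `inject_artefacts` places deterministic drops for
  oracle tests.
* **Intraoral surgery.** Bernoulli flag (default rate 9/200 = 0.045);
  flagged patients lack swallow and spatula scores, as those tests cannot
  be performed.

What the generator does **not** emulate: pharmacokinetics of the relaxant
or its reversal, time-course within the assessment (the latent TOFR is a
single value per patient), inter-test correlation beyond the shared latent
TOFR, and examiner-to-examiner variability. Passing tests on these cohorts
therefore demonstrates correctness of the *statistical machinery* under
the stated data-generating assumptions, not clinical performance on real
patients.

## Stability QC (`porc.qc`)

A record is excluded when no trace data exist or when the TOFR dropped by
more than 20% at least twice. "Dropped by more than 20%" is read as a
relative decrease between **consecutive** readings (the pattern electrode
artefacts produce); a drop-from-running-maximum variant is available via
`rule="running_max"` since the source text does not fix the reference
point. The rule is strict (>20%), scale-invariant, and tolerates exactly
one drop. A patient who is both unstable and post-intraoral counts under
instability, keeping the exclusion reasons a partition.

## Tree derivation (`porc.cart`)

Regression CART, written from scratch because the split-and-stop procedure
is the methodological core:

* **Split criterion.** Exhaustive enumeration of every variable and every
  midpoint between adjacent observed score values; the split maximising the
  SSE reduction wins, subject to both children holding ≥ `min_leaf`
  patients. Ties break deterministically by test-battery order, then lower
  threshold.
* **Stopping.** A node splits only if it holds ≥ `min_split` patients
  (default 20) and the winning split's subgroups differ significantly:
  Welch's unequal-variance t-test, Bonferroni-corrected by the number of
  candidate splits examined at that node, at `alpha = 0.05`. Zero-variance
  degenerate groups give p = 1 (equal means) or 0. There is no pruning —
  stopping is by significance and size only, and the original study names
  neither its significance test nor its thresholds, so these defaults are
  documented choices, not a claim to replicate the original software.
* **Numbering.** Depth-first preorder from 1 (left subtree first), the
  numbering used by the published pathway figure (terminals 3, 5, 6, 8,
  10, 11 with node 9 the swallowing split).
* **Determinism.** No randomness anywhere; row order never changes the
  tree. Correctness is checked against a brute-force recursive enumerator
  on ≥100 small instances and by parameter recovery (the root split
  `arm_lift ≥ 5 s` is recovered in ≥95/100 simulated 400-patient step
  cohorts).

Grown trees serialise to the same JSON dialect the classifier consumes;
terminal nodes predict block at a cut-off when their mean TOFR lies below
it.

## The published pathway (`porc.algorithm`)

The shipped `published_tree.json` encodes the six-terminal pathway: arm
lift at 5 s, head lift at 2 s (weak branch) or 5 s (strong branch), then
eye opening at 5 s (weak branch) or swallowing without any hindrance
(strong branch). Only node 11 (arm ≥ 5 s ∧ head ≥ 5 s ∧ swallow = 3)
predicts *no* block, at both cut-offs — consistent with the validation
result that the pathway's specificity is low at 0.9 while its sensitivity
at 0.7 is 100%. The source text fixes the root, the head-lift cuts, node 3
and node 11 exactly; the interior of the weak branch (nodes 4–6) is stated
only as involving eye opening, so its cut (5 s) is an encoding choice. The
spec is data-driven JSON precisely so holders of the original figure can
re-encode it without touching code. Timed comparisons use the ≥ convention
(holding for exactly 5 s passes).

Routing is total and deterministic over the score lattice; a missing score
on a used variable yields an explicit unclassifiable result. `validate_spec`
checks id uniqueness, single-rootedness, absence of shared children and
cycles, routing totality and terminal reachability by exhaustive lattice
enumeration. Under this pointer-tree dialect two leaves cannot claim the
same score vector; the shared-child check covers the malformed-graph case.

## Accuracy statistics (`porc.diagnostics`)

* Positive class = residual block, strict cut (block iff EMG TOFR < ε).
* Clopper–Pearson intervals via beta quantiles, with the conventional
  closures at 0 and n. Verified against the published validation table at
  one-decimal precision (e.g. 0/7 → upper 41.0%; 71/71 → lower 94.9%) and
  against `statsmodels` as an independent oracle.
* ROC by explicit threshold sweep (predictors are TOFR-scale, so low
  values indicate block; `block_low=True` handles the orientation);
  trapezoid AUC equals the tie-corrected Mann–Whitney concordance, checked
  against a brute-force pairwise oracle and `scikit-learn`.
* Paired AUC comparison by the DeLong placement-value covariance test; the
  original study reports p-values without naming its method, so DeLong is
  a documented choice with a paired-bootstrap alternative
  (`compare_auc_bootstrap`). At n = 40 the two agree to within ~0.1 in p;
  they are asymptotically equivalent.
* Correlation: Spearman by default (tool outputs are ordinal), Pearson on
  request.

The original cohort's correlation (r = 0.844/0.873), AUC p-values and
validation-table point estimates are cohort-dependent quantities on
unavailable raw data; the package property-tests their machinery on
synthetic cohorts instead of claiming to reproduce them.

## Overlook risk and sample size (`porc.risk`)

The risk of overlooking a residual block given a passing tool result is

    P(TOFR_EMG < ε | tool passes)
        = p(1 − sens) / (p(1 − sens) + (1 − p)·spec),

i.e. 1 − NPV as a function of prevalence p. Boundary behaviour: sens = 1
gives risk 0 at any prevalence; spec = 0 with sens < 1 gives risk 1 for
any p > 0. The degenerate 0/0 case (the tool never passes anyone) is
defined as 0 with a warning. Confidence envelopes substitute CI endpoints
(lower envelope from both upper endpoints, upper from both lower) —
conservative and assumption-free, since the source figure does not state
its propagation method.

Sample size for estimating a sensitivity s to CI half-width h: the Wald
closed form ⌈z²s(1−s)/h²⌉ gives 35 diseased patients at s = 0.9, h = 0.1;
the exact method (smallest n whose Clopper–Pearson interval at the nearest
integer count has half-width ≤ h, half-width = (upper−lower)/2) gives 42.
The study's printed figure of 36 is reproduced by neither route and its
derivation is unreported; both methods are provided and the discrepancy is
surfaced rather than hidden.

## Pipeline and problem sizes

`run_pipeline` chains simulate → QC → CART → evaluation → risk and writes a
manifest with a configuration hash and per-file SHA-256 checksums; a rerun
with the same seed reproduces every checksum. Default cohort sizes follow
the study design (165/200-patient development-scale cohorts, 100–118 for
validation-style fixtures). Property tests use the sizes stated above
(8 000 patients for monotone-link deciles, 10⁴ for rank-correlation checks,
10⁵ for the risk-vs-simulation check, 100 replicates for recovery rates);
these sizes were chosen as the smallest that make the checks sharp.

Percentage cells render with one decimal, except an exact 100 which
renders bare ("100% [94.9; 100]"), mirroring the published table's
formatting.

## Known limitations

* The interior of the published tree's weak branch is an encoding choice
  (see above); classification of patients who fail the arm lift but pass
  the head lift may differ from the original figure's node 5/6 split.
* The generator's per-test locations/steepnesses are plausibility choices,
  not fitted values; absolute sensitivities/specificities on simulated
  cohorts depend on them and are not estimates of clinical performance.
* The DeLong test is asymptotic; at very small n or AUC near 1 its p-values
  are approximate (use the bootstrap alternative).
* `sample_size_sensitivity(method="exact")` evaluates the interval at the
  nearest integer count to n·s; other conventions (worst case over counts)
  would give larger n.
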