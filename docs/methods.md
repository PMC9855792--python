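# Methods

## Model

The larynx treatment model is a discrete Bayesian network over nine
categorical variables.  Four are observables — the TNM staging triplet
and chemotherapy tolerance, a prerequisite variable — and five are
binary treatment targets (larynx surgery, radiotherapy,
radiochemotherapy, chemotherapy, immunotherapy), each with states
ordered `(false, true)`.  T, N and M are parents of every treatment
node (15 edges); tolerance is a parent of surgery, chemotherapy and
radiochemotherapy (3 edges, 18 in total).  Tolerance feeds exactly
these three because intolerance is a hard contraindication for the two
systemic-chemotherapy modalities, and the surgery anchor probability is
itself conditioned on tolerance; the membership is configurable for
custom models, fixed for the packaged one.

M includes all of MX, M0 and M1.  T0 is retained as a declared state
although the reference cohort never observes it; its empirical prior
mass is therefore zero, and entering `T=T0` as evidence raises an
explicit impossible-evidence error rather than returning NaNs.

### Guideline rules → CPTs

Treatment CPTs are compiled from declarative rules.  A rule names
subsets of T/N/M states (or *any*), a tolerance condition, a treatment,
an indication probability `p_true`, and an integer priority.  Per
parent-state combination the winning rule is the highest-priority
match; among equal priorities the rule listed last wins (a warning is
logged if their probabilities differ); unmatched cells fall back to a
per-treatment default.  `P(false)` is always `1 − p_true`, so compiled
columns are normalized by construction.

The packaged rule set (`data/larynx_nccn_like.yaml`) layers, in
increasing priority: stage groups (early node-negative, early
node-positive, locally advanced) for M0/MX disease; T4b as technically
unresectable; M1 as palliative intent with elevated systemic options;
chemotherapy intolerance suppressing chemotherapy and
radiochemotherapy to 0.02; and the two fixed anchors
(surgery | T2,N2a,M0,tolerant = 0.74; surgery | T2,N2a,M1,tolerant =
0.17).  Only the anchors are published values; everything else is this
package's own documented elicitation in the spirit of consensus
head-and-neck guidelines, intended to be edited.  The packaged build
refuses a rule set in which either anchor is absent or overridden
(`require_anchors=False` disables the check for custom models).
Defaults of 0.5 deliberately encode "uncertain" recommendations for
staging the rules do not cover (TX, T0, TIS, early disease with NX),
so unclear inputs yield non-committal posteriors rather than
confident ones.

Root priors: T uses the published empirical cohort marginal
(counts / 97); N, M and tolerance default to uniform because no
marginals are published, and are configurable.  Priors are irrelevant
to full-evidence inference on the treatment nodes.

### Inference

Posteriors are computed by exact variable elimination over
evidence-reduced CPT factors.  The elimination order is a greedy
min-degree heuristic with declaration-order tie-breaks — a cost choice
only; results are order-independent, which the tests assert directly by
permuting orders.  Correctness is verified against a brute-force
full-joint enumeration oracle (15,360 joint states) to within 1e-9 on
100 seeded random evidence/query pairs.  Zero normalizer raises
`ImpossibleEvidenceError` in both engines.  Distributions are
double-precision; CPT columns must sum to 1 within 1e-9 at load time.

MAP prediction takes the argmax of the posterior, ties resolving to the
first state in declared order.  Since treatment states are declared
`(false, true)`, a 0.5/0.5 tie yields the negative recommendation; for
binary nodes argmax is equivalent to a 0.5 threshold.

## Synthetic cohorts

The generator emulates the reference study's data conditions: 97
collected cases, of which 5 are excluded as inconsistent, leaving 92
analyzed.  Demographics and staging are drawn independently from
categorical marginals — gender 83/97 male, age groups (30, 32, 21, 12,
2)/97 and T stages from the published tables; N
(node-negative-dominant), M (M0 0.85, M1 0.10, MX 0.05) and tolerance
(tolerant 0.85) are this package's clinically plausible defaults, as no
marginals are published.  Because only marginals are published, no T–N
or other inter-variable correlation is emulated; passing tests
therefore demonstrate correctness of the pipeline under
independent-marginal cohorts, not performance on real, correlated
clinical data.

Treatment truth labels come in two modes:

* `sample` (default) — each treatment drawn from its CPT given the
  case's staging: the model's own uncertainty, so even the generating
  model scores only the CPTs' intrinsic accuracy
  (≈ E[max(p, 1−p)] ≈ 0.80 under the default marginals);
* `argmax_noise` — the model's MAP recommendation flipped with
  probability ε, a calibration device giving expected accuracy exactly
  1 − ε (ε is ignored, with a warning, in `sample` mode).

Missingness (default 0) blanks observables after labels are assigned;
inconsistency injection (default 5/97) then corrupts cases either by a
prerequisite violation (chemotherapy recorded despite intolerance) or
by wiping the staging triplet.  The screen excludes records for
(i) invalid state labels, (ii) prerequisite violations,
(iii) completely missing staging — a documented reconstruction, since
the original exclusion criteria are unpublished and only the 97 → 92
count is known.  Summary tables report absolute counts and relative
frequencies rounded to three decimals, by default against the cohort
size, optionally against the pre-exclusion denominator (the published
convention divides by 97).

Demographics pass through I/O untouched; the network has no such nodes.
Case files are plain UTF-8 CSV, header required, empty cell = missing,
one row per case — the layout used by GeNIe-style validation.

## Validation metrics

Per (case, target) the posterior P(true), MAP prediction and recorded
truth form one prediction record; 92 cases × 5 targets = 460 records.
Accuracy is reported per target and pooled (the pooled counts equal the
per-target sums).  F1 is computed per class, each class in turn as
positive; a class with no true and no predicted members has undefined
F1, reported as 0 by convention, and the weighted average uses
true-class frequencies as weights (so an empty class contributes
weight 0).  ROC (trapezoidal AUC) and precision-recall (step-area AP,
no linear interpolation) sweep the distinct posterior values; the
micro-averaged AP pools the score–label pairs of both class
orientations.  Curves for targets or classes with single-class truth
are not given numbers but explicit "undefined"/"omitted" markers, the
same convention under which curves for never-performed therapies are
omitted from reports.  ROC/PR/F1 go through scikit-learn; the tests
verify them against independent Mann–Whitney pair-counting and
confusion-matrix/staircase oracles.

## Parameter learning and cross-validation

For a fixed structure, complete rows are counted exactly and each CPT
column is the Dirichlet posterior mean `(count + a) / (total + a·k)`
with uniform pseudo-count `a` per cell (default 1, the uniform
initialization).  Rows with any missing value are handled by EM from a
uniform start: expected family counts are accumulated per unique
incomplete row by enumerating its completions under current
parameters, until the largest CPT change is below 1e-6 or 200
iterations.  Columns never observed with `a = 0` are reported as
undefined and left uniform.

Recovery error is exposed as two metrics: the raw maximum absolute CPT
error over observed parent combinations, and an observation-count-
weighted mean of per-column errors.  The weighted metric is the one
that behaves like a sample-size diagnostic (0.090 → 0.038 → 0.019 at
n = 500 / 5,000 / 20,000 in the test suite): the raw maximum is pinned
at the level of whichever observed combination got the fewest cases
(rare staging cells receive ~4–9 observations even at n = 20,000, so
their individual binomial error is ~0.1–0.5 regardless of estimator).

K-fold cross-validation (default k = 10) shuffles cases once with the
seed, splits into near-equal folds (remainders on the first folds, no
stratification), fits on k−1 folds and scores the held-out fold with
the full prediction pipeline.  On n = 92 cohorts the trained model
reliably underperforms the expert-elicited one: ~83 training rows
cannot populate hundreds of CPT columns, so most predictions fall back
to the uniform-tie negative recommendation.

## Problem sizes and seeds

All randomness flows from explicit integer seeds
(`numpy.random.default_rng`); identical configuration + seed
reproduces cohorts, folds and reports bit-for-bit.  The test suite
uses: 100 evidence/query pairs for oracle equivalence, n = 100,000 for
marginal calibration (±0.005), n = 2,000 × 5 targets for noise
calibration (3 standard errors around 0.9), n = 20,000 for parameter
recovery, and 10 seeds × (n = 92, 10-fold) for the expert-vs-trained
comparison — sizes chosen so each property is measured well inside its
sampling tolerance.

## Known limitations

* The non-anchor CPT values are reconstructed, not published; absolute
  accuracies on synthetic cohorts characterize the pipeline, not the
  clinical performance of any published model.
* Cohorts have independent marginals; real staging variables are
  correlated, and real tumor-board decisions depend on factors outside
  TNM + tolerance (general condition, patient preference).
* XDSL export is write-only and best-effort; there is no importer.
* No decision/utility nodes, continuous variables, approximate
  inference or structure learning.
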