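# larynxbn

Bayesian-network treatment decision support for laryngeal carcinoma.

Tumor boards choose among a handful of treatment modalities — larynx
surgery, radiotherapy, radiochemotherapy, chemotherapy, immunotherapy —
mainly from the TNM stage of the tumor and a few therapy prerequisites
such as chemotherapy tolerance.  `larynxbn` packages that decision
pathway as a discrete Bayesian network for clinical-informatics
researchers who want a transparent, probabilistic, fully testable
alternative to black-box recommenders, together with the machinery to
validate such a model against recorded tumor-board decisions.

## The model

A Bayesian network is a DAG of categorical variables $X_1,\dots,X_n$
whose joint distribution factorizes by the chain rule

$$P(x_1,\dots,x_n) = \prod_i P(x_i \mid \mathrm{pa}(x_i)),$$

with one conditional probability table (CPT) per variable.  The
packaged larynx model has **nine nodes and eighteen edges**: observables
T (TX, T0, TIS, T1, T1a, T1b, T2, T3, T4a, T4b), N (NX–N3b), M (MX, M0,
M1) and chemotherapy tolerance, and five binary treatment targets.
T, N and M feed every treatment node; tolerance additionally feeds
surgery, chemotherapy and radiochemotherapy.  Treatment CPTs are not
entered cell by cell but **compiled from declarative guideline rules**
(state subsets + indication probability + priority), shipped in
`src/larynxbn/data/larynx_nccn_like.yaml`.  Two cells are fixed
anchors: $P(\text{surgery}=\text{true} \mid$ T2, N2a, M0, tolerant$) =
0.74$ and $P(\text{surgery}=\text{true} \mid$ T2, N2a, M1, tolerant$) =
0.17$; the remaining values are a documented, editable elicitation.

Inference is exact variable elimination, verified against a brute-force
full-joint enumeration oracle (the model's joint space has
$10\cdot8\cdot3\cdot2\cdot2^5 = 15{,}360$ states).  Validation follows
the standard protocol: per case, enter the non-missing observables as
evidence (missing values are marginalized), take the MAP state of each
treatment posterior, and score accuracy, per-class F1, ROC/AUC and
precision-recall/AP against the recorded therapy — plus k-fold
cross-validation of CPTs learned from the data themselves
(Dirichlet-uniform counting, EM for incomplete rows), which quantifies
how much a data-trained model loses to the expert-elicited one on
small cohorts.  Because no patient-level dataset is publicly available,
a cohort generator produces synthetic tumor-board cases matching the
published marginal statistics (83/97 male, 23/97 T4a, …) with
configurable label noise, missingness, and an inconsistency screen
emulating the published 97 → 92 case exclusion.

## Worked example

```bash
$ larynxbn infer --T T2 --N N2a --M M0 --tolerance tolerant
evidence: {'T': 'T2', 'N': 'N2a', 'M': 'M0', 'chemo_tolerance': 'tolerant'}
      larynx_surgery: P(true) = 0.7400
        radiotherapy: P(true) = 0.4500
   radiochemotherapy: P(true) = 0.7000
        chemotherapy: P(true) = 0.3500
       immunotherapy: P(true) = 0.0500
```

The anchor constellation: a T2 N2a M0 patient who tolerates
chemotherapy is recommended surgery with probability 0.74, with
radiochemotherapy the strongest alternative.  An end-to-end synthetic
validation run:

```bash
$ larynxbn simulate --n 97 --seed 42 --out cohort.csv
wrote 97 cases to cohort.csv (seed 42)
$ larynxbn validate --cases cohort.csv --seed 42 --out metrics.json
Accuracy (absolute / relative):
             All nodes  367/460  0.79783
        larynx_surgery  73/92  0.79348
          radiotherapy  67/92  0.72826
     radiochemotherapy  72/92  0.78261
          chemotherapy  71/92  0.77174
         immunotherapy  84/92  0.91304
...
$ larynxbn crossval --cases cohort.csv --k 10 --seed 42
mean CV accuracy 0.7447 vs expert model 0.7978 over 92 cases
```

At this seed the inconsistency screen excludes 5 of 97 simulated cases,
leaving 92 cases × 5 targets = 460 scored decisions.  Treatment labels
were *sampled* from the model's own CPTs, so even the generating model
cannot exceed the CPTs' intrinsic uncertainty (~0.80 here); training
the CPTs from the same 92 cases by 10-fold cross-validation does worse
(0.74) — with ~83 training cases spread over hundreds of CPT columns,
most learned columns stay near their uniform initialization, which is
exactly why the model is elicited from guidelines rather than learned.

The same workflow is available as library calls
(`build_larynx_model`, `posterior`, `generate_cohort`,
`predict_targets`, `kfold_cv`, …), and `model export --format xdsl`
writes a GeNIe-compatible XDSL file.

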