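# Methods

## Problem and data model

The package predicts whether a child/youth mental-health outpatient who has
visited a pediatric emergency department (ED) will revisit it within 30
days.  The unit of analysis is the patient, not the visit: each patient
contributes one labeled instance built from their own visit sequence.

A visit carries five features: age in years at the visit (numeric, 4–18),
CTAS triage level (categorical: 1 resuscitation … 5 non-urgent, 9 unknown;
unknown is a category, not missing data), a disposition code (how the
patient separated from ambulatory care), a most-responsible ICD-10-style
diagnosis code, and one or more service-type codes for the responsible
health professionals.  Dates order the visits; the models see order, not
elapsed time.

## Label construction

For a patient with `n > 1` visits, the final visit is removed from the
input and the label is 1 iff it occurred within `window_days` of visit
`n−1`.  The window is 30 days and **inclusive**: a gap of exactly 30 days
counts as a revisit ("within 30 days" read inclusively; configurable).
Inputs are the visits `1..n−1`, truncated to the most recent `visit_cap`
(default 10) visits.

Single-visit patients are labeled 0 and contribute their one visit as the
input window.  Their input window is observationally indistinguishable
from that of a two-visit patient, which matters for the synthetic
generator (below).  Whether the original study trained on single-visit
patients' inputs or used them only as labels is not determinable from its
description; keeping them trainable is this package's committed reading.

## Feature encoding

Age is z-scored with training-set mean/SD (min-max available by config;
scale falls back to 1 when degenerate).  The four categorical features are
one-hot encoded against vocabularies fitted **on training folds only**,
with indices assigned in sorted order for determinism; the service feature
is multi-hot (a visit can involve several services).  Codes unseen at fit
time encode to an all-zero block rather than erroring, because
cross-validation folds routinely hold out rare codes.  With the reference
vocabulary sizes (6 triage, 20 disposition, 1377 diagnosis, 61 service)
the visit vector has width 1 + 6 + 20 + 1377 + 61 = 1465.

## Patient graphs

Each instance becomes one heterogeneous graph:

* one **visit** node per input visit, chained consecutively
  (visit t — visit t+1), so the graph encodes order only;
* one **service** node per *distinct* service code, linked to every visit
  at which it occurred;
* one **diagnosis** node per distinct diagnosis code, linked to every
  service node that co-occurred with it at some visit.

Design choices where the construction was genuinely open, all recorded as
this package's assumptions: edges are undirected (the motivation for graph
models here is bidirectional relationships); only the three listed edge
types exist (no visit–diagnosis shortcuts); service and diagnosis nodes
are shared across visits within a patient, which is what lets one service
bridge the diagnoses of two visits; self-loops are excluded from the
stored adjacency (the model operator adds self-inclusion itself).  Node
features are type-specific — visit nodes carry [age, triage, disposition],
service/diagnosis nodes their own one-hot — zero-padded to a shared width
with a 3-slot node-type indicator prepended, because a single node-feature
matrix per graph is required.  Whether visit nodes should also carry the
diagnosis one-hot is unknowable from the source description; here the
diagnosis lives only on diagnosis nodes.

## Models

All models are one layer deep so that the comparison isolates
representation rather than capacity, and all are trained on binary
cross-entropy.

* **GNN**: one message-passing layer — degree-normalized neighbor
  averaging with self-inclusion (row-normalized `A+I`; sum aggregation as
  config alternative), affine map, ReLU — then mean-pool readout over all
  nodes (visit-nodes-only readout as alternative), affine map, sigmoid.
  Output is invariant to node relabeling.
* **RNN**: one gated recurrent (GRU-style) layer over the encoded visit
  sequence (plain tanh cell as alternative); final hidden state → affine →
  sigmoid.  Output is order sensitive.
* **Baselines**: logistic regression (L2, scikit-learn), an
  unconstrained-depth decision tree, and gradient boosting (XGBoost
  defaults), all on the visits concatenated into one fixed-width row:
  `visit_cap` slots, right-aligned in temporal order, zero-padded on the
  left so temporal position is comparable across instances.

The neural models are implemented directly on numpy with analytically
derived gradients and Adam; the backward passes are validated against
central finite differences in the test suite.  Reference training
settings: 300 epochs in minibatches of 500.  Hidden width 64 and learning
rate 1e-3 are this package's defaults, chosen on synthetic data and
recorded in config, since the source settings are not stated.  The
classification threshold is fixed at 0.5 (probability exactly at the
threshold is called positive); PPV/NPV share that threshold.

## Evaluation protocol

The revisit class is rare (~17%), so evaluation uses balanced
undersampling: `n_subsets` (5) datasets, each containing every positive
instance plus an equal-count uniform sample of negatives, drawn without
replacement within a subset and independently across subsets (a negative
may recur across subsets).  Each subset is split into `n_folds` (5)
stratified folds (stratification keeps fold label balance; toggleable);
every model is fitted on four folds and scored on the fifth, with all
model kinds sharing identical splits and the feature schema refitted per
training fold.  The 5 × 5 = 25 fold scores are summarized as mean and
sample SD per metric, and models are compared with **paired** two-sided
t-tests on fold-aligned scores (pairing is natural because splits are
shared; zero-variance differences are flagged degenerate instead of
failing).

Metrics per fold: precision (= PPV), recall, F1, accuracy, NPV at the 0.5
threshold, and AUROC by trapezoidal integration of the ROC curve, which
equals the positive–negative concordance probability with ties counted
half (asserted against a brute-force oracle to 1e-9).  Zero-denominator
metrics report 0 with a degeneracy flag.  The reported ROC curve per model
is the vertical average of per-fold curves on a fixed 101-point
false-positive-rate grid.

## Synthetic cohort generator

Because the study data are private, every stage is exercised on synthetic
cohorts that emulate the published summary statistics:

* **visit counts**: discretized normal with SD 5, truncated to ≥ 1.
  Clipping an N(5, 5) at 1 inflates the realized mean to ≈ 5.6, so the
  pre-truncation location is calibrated by bisection on the exact
  discretized expectation; the realized mean then matches the requested
  mean (5) to well within the generator's ±0.3 contract.
* **ages**: N(12.4, 3.9) clipped to [4, 18] at the first visit, advanced
  by elapsed time across visits and capped at 18.
* **categories**: geometric-decay multinomials (decay 0.9) over the code
  vocabularies, mimicking the skewed code frequencies of real EHR data.
  Desk-scale vocabulary defaults are small (30 diagnoses, 15 services, 20
  dispositions); the full reference sizes are reachable by config.
* **prevalence**: the label is drawn from a logistic hazard
  `h = σ(base + beta_seq·x_seq + beta_rel·x_rel)` and the final
  inter-visit gap is then drawn from 1–30 days (revisit) or 31–365 days
  (no revisit) — a deliberately simple two-range construction, not an
  inference about real inter-visit gap distributions.  The intercept
  `base` is calibrated by bisection so the expected prevalence over the
  generated covariates hits the target (0.17 by default).

Planted signal comes in two shapes chosen to separate the model families:
`x_seq` = high acuity (CTAS 1–2) at the last input visit, learnable from
last-visit features alone; `x_rel` = presence of a designated
service–diagnosis co-occurrence pair anywhere in the capped input window —
a within-visit AND of two feature slots that the patient graph represents
explicitly as a service–diagnosis edge, while a linear model on
concatenated rows sees only the two marginals.

**Null integrity.** Single-visit patients are structurally label-0, yet
their one-visit input windows are indistinguishable from those of
two-visit patients.  Left alone this makes input length predictive even
with zero betas.  The generator therefore boosts two-visit patients'
hazard by exactly the factor `1 + n₁/n₂` (single- to two-visit count
ratio) that equalizes the label rate conditional on observable input
length.  With `beta_seq = beta_rel = 0` the cohort is then genuinely null:
no function of the inputs has expected AUROC above 0.5, and the
Bayes-optimal score — the observable posterior `σ(base + β·x)` reported by
`planted_signal_report` — is exactly constant, giving a Bayes AUROC of
exactly 0.5.

What the generator does **not** emulate: real ICD-10 semantics and code
correlations, seasonal/COVID-era visit-pattern shifts, inter-visit gap
distributions, comorbidity structure, or demographics beyond age.  Passing
tests therefore demonstrate that the pipeline's machinery is correct and
that the graph model can exploit relational structure when it exists —
not that any model would achieve the same performance on real EHR data.

## Problem sizes used in the checked experiments

The package's own experiment scale, chosen to make the full protocol
routine on a laptop CPU: cohorts of 2,000 patients with the desk-scale
vocabularies; 30 epochs for the no-signal sanity check (nothing to learn);
the reference 300 epochs for the planted-signal model comparison on a
reduced 2-subset × 3-fold protocol over 5 seeds and for the headline
end-to-end run in `scripts/acceptance.py`.

## Numerical and degenerate-case choices

* Probabilities are clipped to [1e-7, 1 − 1e-7] inside the loss only.
* Same-date visits are kept as distinct visits in input order (dates alone
  order visits; the sort is stable).
* All randomness flows through `numpy.random.default_rng` seeds; per-fit
  seeds are derived deterministically from (subset, fold, model) so every
  report is reproducible from its config, and identical configs produce
  byte-identical metrics CSVs.
* Equal classes degrade undersampling gracefully (each subset equals the
  full data); negatives fewer than positives raise an error, since the
  protocol's direction would be violated.

## Known limitations

* The exact architectures of the original GNN/RNN were published only in
  supplementary material; the operator choices here (GCN-style mean
  aggregation, GRU cell, mean-pool readout) are declared assumptions with
  config alternatives.
* The published headline metrics were computed on private single-site
  data and are not reproducible here; the package reproduces the protocol
  and the *direction* of the model ordering on planted-signal synthetic
  data, not the magnitudes.
* In the source report, precision and PPV columns differ slightly although
  their definitions coincide; this package computes them identically and
  does not reproduce that divergence.
* The Bayes AUROC bound treats the observable posterior as exactly
  `σ(base + β·x)`; for patients whose input window was truncated by the
  visit cap the relational covariate is computed on the capped window, so
  the bound refers to what a capped-window model can achieve.
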