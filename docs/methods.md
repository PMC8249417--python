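# Methods

## Problem setting

Diagnosis-related groups (DRGs) drive prospective hospital payment: every
inpatient stay is assigned one DRG code, and each code carries a relative
weight expressing its expected resource use. Because coding happens after
discharge, DRG-based indicators such as the case mix index (CMI — the mean
relative weight of a patient population) are only available retrospectively.
This package implements and tests an early-prediction pipeline: classify a
stay's DRG from the free-text notes charted around ICU admission, map the
predicted code to its payment weight, and aggregate weights into population
CMI and payment estimates as a function of time since ICU admission (HPA,
hours post-admission; negative values precede ICU entry) and of cohort size.

Two DRG dialects are supported: a flat, MS-style code space, and an
APR-style space where each clinical group splits into four
severity-of-illness tiers, each with its own weight, so a code is
effectively (group, severity).

## The classifier

Text is modelled with a convolutional encoder pooled by per-label attention
(the CAML family of architectures for automatic clinical coding), adapted to
single-label prediction:

- token ids are embedded (`E`, pad row pinned to zero), and a 1-D
  convolution of width `k` (default 5, so attended windows are 5-grams)
  followed by `tanh` produces a feature vector `H_t` per position;
- each DRG code `l` owns an attention vector `u_l`;
  `a_l = softmax(H' u_l)` over positions and `v_l = H a_l` give a
  label-specific document representation;
- per-label scores `s_l = b_l' v_l + c_l` pass through a single softmax and
  training minimises cross-entropy; at inference the argmax code is reported
  together with its catalog weight (ties break to the lowest label index for
  determinism).

Positions holding padding are masked to −∞ before the attention softmax, so
appending padding can never absorb attention mass or change scores; a fully
empty document (legal at early cutoffs) receives zero attention mass and is
scored by the output bias alone — it is still predicted rather than dropped,
because the population analyses evaluate a fixed cohort at every cutoff.
Attention is computed on the post-`tanh` feature map.

A regression variant shares the encoder but uses a single attention vector
and a linear head trained with mean absolute error to predict the payment
weight directly, skipping classification.

The network, gradients and Adam optimiser are implemented in NumPy. The
model is the package's own contribution and small enough that hand-derived
backprop is faster to audit than an external framework dependency; training
is deterministic given the config seed.

Word embeddings are trained from scratch (random initialisation); no
pretrained vectors are used. Defaults: embedding dim 100, 50 filters,
kernel 5, dropout 0.2 on embeddings, Adam at 1e-3, batch 16, and the epoch
snapshot with the best validation accuracy (or MAE) is returned.

## Text processing

Notes with chart time ≤ the cutoff are concatenated in chart-time order
(stable sort, so earlier-cutoff documents are prefixes of later ones).
De-identification placeholders of the form `[** ... **]` are removed, text
is lowercased and split into alphanumeric tokens. The vocabulary maps every
token seen at least 3 times to a dense id; everything else falls to a single
unknown id. Documents are truncated to 2000 tokens (head truncation — the
earliest text is what an early-prediction system actually has; tail
truncation is available behind a flag) and right-padded. By default the
vocabulary is counted over training-fold stays only, to avoid leakage; a
`cohort` scope reproduces counting over the full cohort where that reading
is wanted.

## Cohorts and splits

Eligibility: age strictly over 18 (a flag allows ≥ 18), exactly one ICU
visit, at least one note within 48 HPA, and a DRG present in the catalog.
The label space is the full filtered catalog, not just observed codes. The
hold-out test set takes whole patients, in seeded shuffled order, until it
holds ≥ 10% of stays; fivefold cross-validation partitions the remaining
patients. No patient ever appears on both sides of any split. For
population-level cost estimation the test set is trimmed to one stay per
patient — the earliest admission, ordered by a monotone admission index the
generator carries in the stay id.

## CMI, scenarios, payment

`CMI = mean(weights)`; the absolute CMI error is `|pred − true| / true`.
Two scenario analyses mirror hospital questions:

- **HPA sweep**: re-assemble, re-encode and re-predict the fixed population
  at each cutoff on a −24…48 h grid in 6-h steps (13 points), reporting the
  mean and SD of the error over the five fold models.
- **Cohort-size analysis**: for each size, draw 20 subgroups with
  replacement and predict each with each of the 5 models — 100 subpopulation
  estimates — and report their mean with a percentile-bootstrap 95% CI
  (1000 resamples, seeded). Whether the interval should cover subgroup
  errors or subgroup CMIs is ambiguous in principle, so both are emitted.

Payment is approximated as `base_rate × CMI × n_stays` with a default base
rate of $6000; wage indices, outlier payments and transfer rules are out of
scope. Because the CMI is a mean, individual over- and under-predictions of
weight offset each other: the population error is bounded by the mean
per-stay weight error divided by the true CMI, which is why CMI can be
estimated far more accurately than per-stay DRG accuracy suggests.

## Evaluation

One-vs-rest AUC per code, macro-averaged over codes with at least one
positive and one negative test case (codes without both classes have no
defined AUC and are dropped from the macro mean; their count is reported)
and micro-averaged over the pooled (code, stay) indicator set. F1 is
macro-averaged over the subset's full code list — absent codes contribute
zero, which keeps macro-F1 honest on long-tailed label spaces — and
micro-averaged by pooling TP/FP/FN; for single-label prediction over the
full label space micro-F1 equals accuracy. Reported subsets: all codes, one
per major diagnostic category, the top-30/top-50 codes by test frequency
(boundary ties break by code order), and the smallest frequency-ranked
prefix covering 80% of stays. Metrics from the five fold models are
aggregated as mean and sample SD (ddof 1).

## Synthetic data generator

Real DRG-labelled note corpora are restricted, so the generator produces a
cohort with the structural properties the pipeline depends on, all
deterministic given a seed:

- **Catalog**: configurable number of groups; APR-style catalogs expand each
  group by severity multipliers (0.5, 0.8, 1.1, 1.6 — strictly increasing,
  mean 1). Weights are lognormal draws clipped below at 0.2, calibrated so
  the catalog mean/SD converge to 3.0/2.8, the scale typical of adult ICU
  case mixes (for APR catalogs the base-draw SD is deflated to compensate
  for the multiplier spread). Each code carries two planted signal n-grams
  built from tokens unique to its base group (plus a severity marker token
  for APR codes).
- **Stays**: DRGs follow a Zipf rank-frequency law (exponent 1.2) over the
  catalog; notes are Poisson-placed in 6-h bins over [−24, 48) h with one
  expected note per bin; note length is Poisson around 30 tokens; background
  tokens follow their own Zipf law. Configured fractions of under-18
  patients (5%), multi-ICU-visit stays (10%) and repeat patients (15%)
  exercise the filters and the patient-level splitting; `[** ... **]`
  placeholders are injected at rate 0.3 per note to exercise cleanup.
- **Signal accrual**: each token slot emits one of the stay's signal n-grams
  with probability `slope × (hpa + 24)` (clipped to [0, 1]); the default
  slope 0.002 doubles to 0.004 in the "strong signal" test conditions. The
  linear ramp makes prediction error fall as the cutoff moves from −24 to
  48 h in a controlled way.

What the generator does *not* emulate: real clinical language and its
misspellings, note-category-specific style, structured vitals/labs,
discharge summaries (excluded by design in the study setting), ICD-to-DRG
grouper logic, or fiscal-year weight tables. Passing tests therefore
demonstrate that the pipeline's machinery is correct and that it recovers
planted signal under realistic cohort structure — not that any particular
clinical accuracy would be achieved on real data. Per-note length and
category mix are free parameters, not calibrated claims.

## Problem sizes used in the test and acceptance runs

Chosen as the package's own desk-scale conditions: the parameter-recovery
check trains on a 2000-patient, 10-group cohort (strong slope 0.004,
max_len 400, 10 epochs, 32-dim embeddings, 24 filters); the
seed-averaged HPA-trend check uses ten 250-patient cohorts with a smaller
model; the acceptance script runs an 800-patient, 10-group study with five
fold models (max_len 300, 8 epochs). At these scales the whole suite and
the script each run in well under an hour on one CPU core.

## Known limitations

- The official hyper-parameters of the reference architecture family are
  not reproduced; defaults here are declared package choices.
- CPU-only NumPy training does not scale to thousand-label catalogs at
  MIMIC scale; the design target is correctness and auditability at
  synthetic scale.
- The greedy 10%-of-stays hold-out rule overshoots by at most one patient's
  stays; with heavily repeated patients the test share can exceed 10%
  accordingly.
- Macro-AUC over labels missing a class is undefined; dropping them is a
  choice, and alternative conventions will disagree on sparse subsets.
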