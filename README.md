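# drgcast

Early prediction of diagnosis-related groups (DRGs) and DRG-based hospital
cost from timestamped clinical notes.

Hospitals are paid prospectively: each inpatient stay maps to one DRG code
with a relative weight `w`, and the case mix index of a population,
`CMI = (1/n) Σᵢ wᵢ`, times a base payment rate and the population size,
approximates total reimbursement. DRGs are normally coded after discharge;
`drgcast` implements and stress-tests a pipeline that predicts them while
the patient is still in the ICU, from nothing but routine notes, and tracks
how population CMI and payment estimates sharpen as notes accrue from 24 h
before to 48 h after ICU admission.

The classifier is a convolutional text encoder pooled by **per-label
attention** (the CAML family, adapted to single-label prediction): with
`H = tanh(conv(embed(x)))`, each code `l` attends
`a_l = softmax(Hᵀu_l)`, pools `v_l = H a_l`, and scores
`s_l = β_lᵀv_l + c_l`; a softmax over codes gives the posterior, the argmax
code is looked up in the DRG catalog for its weight, and the attention row
names the 5-gram windows that drove the decision. A regression variant
predicts the weight directly with an MAE objective. The network and its
training loop are implemented in NumPy with hand-derived gradients, so CPU
runs are fast, dependency-light and bit-reproducible under a fixed seed.

Because real DRG-labelled note corpora are access-restricted, the package
ships a synthetic-data module (`drgcast.synthgen`) that generates DRG
catalogs (flat MS-style or group × 4-severity APR-style), Zipf-distributed
code frequencies, lognormal-like weights (mean ≈ 3.0, SD ≈ 2.8), and notes
whose DRG-indicative n-gram density grows linearly with chart time — plus
under-18 patients, multi-ICU-visit stays, repeat patients and
de-identification placeholders to exercise every filter in the pipeline.

## Worked example

```python
import numpy as np
from drgcast.synthgen import GenConfig, make_drg_catalog, simulate_cohort
from drgcast.cohort import build_cohort, split_train_test, make_test_population
from drgcast.textprep import build_vocab, clean_and_tokenize, assemble_document, encode_stay
from drgcast.model import ModelConfig, train
from drgcast.cmi import hpa_sweep, compute_cmi, estimate_payment

cfg = GenConfig(seed=17, n_patients=2000, n_drg_groups=10,
                signal_rate_slope=0.004, note_len_mean=15,
                background_vocab_size=500)
catalog = make_drg_catalog(cfg)
cohort = build_cohort(simulate_cohort(catalog, cfg), catalog)
split = split_train_test(cohort, test_frac=0.10, seed=5)

train_stays = [s for s in cohort.stays if s.patient_id not in split.test_patient_ids]
vocab = build_vocab(clean_and_tokenize(assemble_document(s, 48)) for s in train_stays)
docs = [encode_stay(s, 48, vocab, max_len=400) for s in train_stays]
model = train(docs, [s.drg_code for s in train_stays],
              ModelConfig(seed=5, embed_dim=32, n_filters=24, epochs=10),
              label_space=cohort.label_space, vocab=vocab)

population = make_test_population(cohort, split)   # one stay per test patient
_, sweep = hpa_sweep([model], population, catalog, vocab, max_len=400)
for row in sweep[::4]:
    print(f"HPA {row['cutoff_hpa']:+.0f} h  CMI error {100*row['mean_error']:.2f}%")
```

prints

```
HPA -24 h  CMI error 9.63%
HPA +0 h  CMI error 2.48%
HPA +24 h  CMI error 0.22%
HPA +48 h  CMI error 0.06%
```

i.e. before ICU admission the model misestimates the population's mean
payment weight by ~10%, and two days of notes shrink the error to a fraction
of a percent. On the same run the held-out per-stay DRG accuracy at 48 h is
0.995 — but note the CMI error is far smaller than per-stay mistakes would
suggest, because offsetting over- and under-predictions cancel in the mean.
At a $6000 base rate, `estimate_payment(cmi, n)` turns a CMI into dollars: a
5% CMI error on a 500-stay cohort with true CMI 3.15 is a $472,500 swing in
projected reimbursement.

The full pipeline (simulate → split → 5-fold training → Table-style
evaluation report → CMI scenario analyses) runs as one command:

```bash
drgcast run --config run.yaml --out runs/demo
```

where `run.yaml` holds a global `seed` plus optional `gen:` / `model:`
blocks (see `drgcast.pipeline.RunConfig`); `drgcast simulate` and
`drgcast split` expose the first stages individually.

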