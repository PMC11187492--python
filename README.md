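# ehrseq

Unsupervised patient representations from time-ordered disease-code
sequences, compared head-to-head on 1-year clinical outcome prediction.

A primary-care health record is a time-ordered sequence of coded diagnoses.
For patients with multiple long-term conditions (≥ 2 chronic diseases), that
sequence can be treated like a document — codes as words, visits as
positions — and summarized by an unsupervised embedding that is reusable
across prediction tasks.  `ehrseq` implements the full comparison pipeline:

* **a synthetic cohort simulator** — seeded, longitudinal, multimorbid
  patients with recurrent coded events from a latent-topic Markov process,
  a many-to-one fine-code → disease-category map, sociodemographics with
  explicit missing levels, and nine binary 1-year outcomes (mortality in
  the 60+ stratum, ED attendance, emergency admission, any/new
  hypertension, diabetes and depression) generated from logistic models
  that combine disease co-occurrence, *sequence-order* terms (precedence
  and recency effects) and demographics;
* **sequence construction** — dual vocabularies (disease categories or
  fine codes), date ordering with deterministic tie-breaks, minimum length
  2, truncation to the most recent 128 codes, and the cohort eligibility
  rules (≥ 1 year registration, alive and registered at the index date);
* **representations** — binary disease indicators, frequency counts,
  sociodemographics-only; LDA topic proportions with perplexity-driven
  selection of the topic count (80:20 split, refit on the full corpus);
  doc2vec paragraph vectors (DBOW and DM, negative sampling, selected by an
  identical-sequence similarity criterion); and a configurable BERT-family
  encoder reproducing three published EHR input conventions (`medbert`,
  `behrt`, `ehrbert` — the last adds gender/ethnicity/deprivation/calendar
  year embedding tables), pretrained with masked-language modelling only
  and pooled by averaging the second-to-last layer over code positions.
  The encoder is plain numpy with a hand-derived backward pass; gradients
  are verified against finite differences in the test-suite;
* **a fixed evaluation harness** — stratified 4-fold CV logistic
  regression (L2, C = 1, ≤ 100 iterations) with one-hot covariates, pooled
  out-of-fold ROC-AUC and average precision, and threshold tables
  (sensitivity/specificity/PPV/NPV at 40/70/90% sensitivity).

The package's core experiment plants a pure sequence-order signal in the
admission outcome (symmetric "disease *a* before disease *b*" contrasts and
recency-weighted exposures) and shows that the order-aware transformer
embedding beats binary disease indicators exactly when order effects exist,
with the advantage disappearing when they are zeroed.

## Worked example

```python
import numpy as np
from ehrseq import (SimulationConfig, simulate_cohort, build_sequences,
                    eligible_cohort, binary_indicators, frequency_counts,
                    sociodemographic_features, fit_lda,
                    OUTCOMES, EvalConfig, build_outcome_cohort,
                    run_comparison)

cfg = SimulationConfig(n_patients=5000, rng_seed=7)
cohort = simulate_cohort(cfg)
seqs = build_sequences(cohort.history_events, cohort.code_map,
                       cohort.records, "diseases", cfg.index_date)
keep = eligible_cohort(cohort.records, seqs, cfg.index_date)
seqs = {p: s for p, s in seqs.items() if p in keep}
print(f"{len(seqs)} eligible patients; median sequence length "
      f"{int(np.median([len(s) for s in seqs.values()]))}")

cats = sorted(cohort.code_map["disease"].unique())
reps = {
    "binary": binary_indicators(seqs, cats),
    "counts": frequency_counts(seqs, cats),
    "lda": fit_lda({p: s.tokens for p, s in seqs.items()},
                   10, seed=0).embeddings(),
}
cov = sociodemographic_features(cohort.records, cfg.index_date)
labels = build_outcome_cohort(cohort.records, cohort.followup_events,
                              OUTCOMES["any_hypertension"], cfg.index_date,
                              history_events=cohort.history_events,
                              eligible_ids=keep)
result = run_comparison(reps, cov, {"any_hypertension": labels},
                        EvalConfig(seed=0))
print(result.ranking("any_hypertension")[["representation", "value"]]
      .to_string(index=False))
```

prints

```
4902 eligible patients; median sequence length 14
representation    value
        binary 0.696141
        counts 0.650641
           lda 0.636475
```

i.e. of 5000 simulated patients, 4902 survive the eligibility rules; on the
"any attendance with hypertension" outcome the binary disease indicators
(pooled out-of-fold ROC-AUC 0.696) beat frequency counts (0.651) and a
10-topic LDA representation (0.636) — attendance with a disease is driven
by having the disease, which the indicators encode exactly.  The
order-effect experiment, where the transformer representation wins instead,
is one call:

```python
from ehrseq.experiments import headline_comparison
headline_comparison(seed=0, order_strength=1.5)   # ~40 s on one CPU
# {'auc_ehrbert': 0.662, 'auc_binary': 0.643, 'gap': +0.020, ...}
```

## Command line

Every stage is also a CLI step (`ehrseq --help`): `simulate`,
`build-sequences`, `fit baselines|lda|doc2vec|bert`, `embed`, `evaluate`,
`compare`, `report`.  Each run writes a `manifest.json` with the config
hash, seed and input checksums so deterministic stages reproduce bit for
bit.

```bash
ehrseq simulate --seed 7 --n-patients 20000 --out runs/cohort
ehrseq build-sequences --cohort runs/cohort --vocabulary diseases \
       --out runs/seqs.jsonl
ehrseq fit baselines --sequences runs/seqs.jsonl --cohort runs/cohort \
       --out runs/base
ehrseq compare --embeddings binary=runs/base/binary.csv \
       --embeddings counts=runs/base/counts.csv \
       --covariates runs/base/covariates.csv \
       --cohort runs/cohort --outcomes ed_attendance,emergency_admission \
       --out runs/cmp
```

## Documentation

`docs/methods.md` describes the generating model, every representation, the
harness, the parameter defaults and their rationale, and what the
desk-scale experiments do and do not demonstrate.
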