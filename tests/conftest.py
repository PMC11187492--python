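import numpy as np
import pandas as pd
import pytest

from ehrseq.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 3000-patient cohort shared across read-only tests."""
    return simulate_cohort(SimulationConfig(n_patients=3000, rng_seed=42))


@pytest.fixture(scope="session")
def small_sequences(small_cohort):
    from ehrseq.sequences import build_sequences
    cfg = small_cohort.config
    return build_sequences(small_cohort.history_events, small_cohort.code_map,
                           small_cohort.records, "diseases", cfg.index_date)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def trained_grammar_model():
    """Desk-scale encoder pretrained on the deterministic-grammar corpus
    (token B always directly follows token A)."""
    from ehrseq.experiments import grammar_corpus
    from ehrseq.transformer import TransformerConfig, pretrain_mlm
    seqs = grammar_corpus(n_sequences=2000, seed=0)
    cfg = TransformerConfig.desk("ehrbert", epochs=8, seed=0)
    model, history = pretrain_mlm(seqs, None, cfg)
    return model, history, seqs


def make_records(rows):
    """Build a patient table from (id, birth, reg, dereg, death, ...) dicts."""
    defaults = dict(gender="female", ethnicity="White", imd_decile=5.0,
                    deregistration_date=pd.NaT, death_date=pd.NaT)
    recs = []
    for r in rows:
        d = dict(defaults)
        d.update(r)
        recs.append(d)
    df = pd.DataFrame(recs)
    for c in ["birth_date", "registration_date", "deregistration_date",
              "death_date"]:
        df[c] = pd.to_datetime(df[c])
    return df
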