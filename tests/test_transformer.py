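"""Encoder input composition, masking, pooling and training behaviour."""

import dataclasses

import numpy as np
import pytest

from ehrseq.experiments import grammar_corpus
from ehrseq.sequences import PatientSequence, TokenVocabulary
from ehrseq.transformer import (EHRTransformer, TransformerConfig,
                                build_batch, compose_inputs,
                                extract_embeddings, load_model, mean_pool,
                                pretrain_mlm, save_model, _mask_batch)

RECORD = {"gender": "female", "ethnicity": "Black", "imd_decile": 7.0}


@pytest.fixture(scope="module")
def vocab():
    return TokenVocabulary([f"d{i}" for i in range(8)])


def five_codes_four_visits():
    """Five codes across four visits (the second visit has two codes)."""
    return PatientSequence(
        patient_id="p1", vocabulary_tag="diseases",
        tokens=["d0", "d1", "d2", "d3", "d4"],
        visit_index=[1, 1, 2, 3, 4],
        age_years=[60, 60, 61, 62, 63],
        calendar_year=[2010, 2010, 2011, 2012, 2013])


def test_ehrbert_special_tokens(vocab):
    cfg = TransformerConfig.desk("ehrbert")
    x = compose_inputs(five_codes_four_visits(), RECORD, cfg, vocab)
    ids = list(x["input_ids"])
    assert len(ids) == 7  # [CLS] + 5 codes + [SEP]
    assert ids[0] == vocab.index["[CLS]"]
    assert ids[-1] == vocab.index["[SEP]"]
    assert list(x["visit"]) == [0, 1, 1, 2, 3, 4, 0]
    assert list(x["code_mask"]) == [0, 1, 1, 1, 1, 1, 0]
    assert set(x["gender"]) == {1}  # female broadcast to all positions
    assert set(x["imd"]) == {7}


def test_behrt_separators_between_visits(vocab):
    cfg = TransformerConfig.desk("behrt")
    x = compose_inputs(five_codes_four_visits(), RECORD, cfg, vocab)
    sep = vocab.index["[SEP]"]
    toks = list(x["input_ids"])
    # [CLS] d0 d1 [SEP] d2 [SEP] d3 [SEP] d4 — separators between visits
    assert toks[0] == vocab.index["[CLS]"]
    assert toks.count(sep) == 3
    assert toks[3] == sep and toks[5] == sep and toks[7] == sep
    segs = [s for s, c in zip(x["segment"], x["code_mask"]) if c]
    assert segs == [0, 0, 1, 0, 1]  # alternates per visit


def test_medbert_has_no_special_tokens(vocab):
    cfg = TransformerConfig.desk("medbert")
    x = compose_inputs(five_codes_four_visits(), RECORD, cfg, vocab)
    assert len(x["input_ids"]) == 5
    assert list(x["visit"]) == [1, 1, 2, 3, 4]
    assert all(x["code_mask"] == 1)


def test_compose_is_pure_and_handles_missing_covariates(vocab):
    cfg = TransformerConfig.desk("ehrbert")
    s = five_codes_four_visits()
    a = compose_inputs(s, {}, cfg, vocab)
    b = compose_inputs(s, {}, cfg, vocab)
    for k in a:
        if k != "patient_id":
            assert np.array_equal(a[k], b[k]), k
    assert set(a["gender"]) == {0}  # reserved missing id, not an error
    assert set(a["imd"]) == {0}


def test_sequence_longer_than_max_len_asserts(vocab):
    cfg = TransformerConfig.desk("ehrbert", max_len=4)
    with pytest.raises(ValueError, match="max_len"):
        compose_inputs(five_codes_four_visits(), RECORD, cfg, vocab)


def test_config_validation():
    with pytest.raises(ValueError, match="divisible"):
        TransformerConfig(hidden_size=65, attention_heads=4)
    with pytest.raises(ValueError, match="variant"):
        TransformerConfig(variant="gpt")


@pytest.mark.parametrize("variant,hidden,heads,inter", [
    ("medbert", 192, 6, 64), ("behrt", 288, 12, 512),
    ("ehrbert", 288, 12, 512)])
def test_published_presets(variant, hidden, heads, inter):
    cfg = TransformerConfig.preset(variant)
    assert cfg.hidden_size == hidden
    assert cfg.attention_heads == heads
    assert cfg.intermediate_size == inter
    assert cfg.hidden_layers == 6


def test_preset_embedding_dimensions(vocab):
    """Pooled embeddings have length equal to the preset hidden size."""
    seqs = {"p1": five_codes_four_visits()}
    for variant, dim in [("medbert", 192), ("ehrbert", 288)]:
        model = EHRTransformer(TransformerConfig.preset(variant), vocab)
        emb = extract_embeddings(model, seqs, None)
        assert emb.X.shape == (1, dim)


def test_mean_pool_of_constant_states_returns_constant(rng):
    v = rng.normal(size=8)
    states = np.tile(v, (2, 6, 1))
    code_mask = np.array([[0, 1, 1, 1, 0, 0], [1, 1, 0, 0, 0, 0]])
    pooled = mean_pool(states, code_mask)
    assert np.allclose(pooled, v)


def test_pooling_matches_brute_force_recount(vocab, rng):
    cfg = TransformerConfig.desk("ehrbert", seed=3)
    model = EHRTransformer(cfg, vocab)
    seqs = {}
    for p in range(10):
        L = int(rng.integers(2, 9))
        seqs[f"p{p}"] = PatientSequence(
            f"p{p}", "diseases", [f"d{rng.integers(8)}" for _ in range(L)],
            sorted(rng.integers(1, 4, size=L).tolist()),
            [50] * L, [2010] * L)
    emb = extract_embeddings(model, seqs, None)
    composed = [compose_inputs(s, {}, cfg, vocab) for s in seqs.values()]
    for c in composed:
        batch = build_batch([c])
        states = model.hidden_states(batch)
        second_to_last = states[-2][0]
        manual = np.zeros(cfg.hidden_size)
        count = 0
        for t in range(len(c["input_ids"])):
            if c["code_mask"][t]:
                manual += second_to_last[t]
                count += 1
        manual /= count
        row = emb.align([c["patient_id"]])[0]
        assert np.allclose(row, manual, atol=1e-6)


def test_mask_selection_rate_and_policy(vocab, rng):
    cfg = TransformerConfig.desk("ehrbert")
    seqs = grammar_corpus(n_sequences=400, seed=1)
    gvocab = TokenVocabulary.from_sequences(seqs)
    composed = [compose_inputs(s, {}, cfg, gvocab) for s in seqs.values()]
    batch = build_batch(composed)
    mb, sel, labels = _mask_batch(batch, gvocab, 0.15, rng)
    n_code = batch.code_mask.sum()
    frac = sel.sum() / n_code
    assert abs(frac - 0.15) < 0.01
    # special and padded positions are never selected
    assert not (sel & (batch.code_mask == 0)).any()
    # ~80% of selected positions become [MASK]
    mask_id = gvocab.index["[MASK]"]
    frac_masked = (mb.input_ids[sel] == mask_id).mean()
    assert 0.74 < frac_masked < 0.86
    # labels hold the original tokens
    assert np.array_equal(labels, batch.input_ids[sel])


def test_padding_is_inert(vocab):
    """Padded positions change neither the loss nor other positions'
    hidden states."""
    cfg = TransformerConfig.desk("ehrbert", seed=0)
    model = EHRTransformer(cfg, vocab)
    s = five_codes_four_visits()
    alone = build_batch([compose_inputs(s, RECORD, cfg, vocab)])
    short = PatientSequence("p2", "diseases", ["d0", "d1"], [1, 2],
                            [40, 41], [2009, 2010])
    padded = build_batch([compose_inputs(s, RECORD, cfg, vocab),
                          compose_inputs(short, RECORD, cfg, vocab)])
    h_alone = model.hidden_states(alone)[-1][0]
    h_padded = model.hidden_states(padded)[-1][0]
    assert np.allclose(h_alone, h_padded, atol=1e-10)


def test_zeroed_extra_tables_match_code_position_encoder(vocab):
    """With the sociodemographic/visit/age tables zeroed, the full-input
    variant reduces exactly to a code+position encoder."""
    full_cfg = TransformerConfig.desk("ehrbert", seed=7)
    bare_cfg = dataclasses.replace(full_cfg,
                                   inputs=("code", "absolute_position"))
    full = EHRTransformer(full_cfg, vocab)
    bare = EHRTransformer(bare_cfg, vocab)
    for k, v in full.params.items():
        if k in bare.params:
            bare.params[k] = v.copy()
    for tname in full_cfg.inputs:
        if tname not in ("code", "absolute_position"):
            full.params[f"emb.{tname}"][:] = 0.0
    batch = build_batch([compose_inputs(five_codes_four_visits(), RECORD,
                                        full_cfg, vocab)])
    assert np.allclose(full.hidden_states(batch)[-1],
                       bare.hidden_states(batch)[-1], atol=1e-12)


def test_mlm_loss_decreases(trained_grammar_model):
    _, history, _ = trained_grammar_model
    assert history[-1] < history[0]
    # non-increasing on average: each epoch no worse than the running mean
    diffs = np.diff(history)
    assert np.mean(diffs) < 0


def test_grammar_rule_learned(trained_grammar_model):
    """Token B always follows token A; after pretraining, a masked B is
    recovered from its context with high accuracy."""
    model, _, seqs = trained_grammar_model
    vocab = model.vocab
    cfg = model.config
    composed = [compose_inputs(s, {}, cfg, vocab)
                for s in list(seqs.values())[:400]]
    batch = build_batch(composed)
    b_id, mask_id = vocab.index["B"], vocab.index["[MASK]"]
    to_mask = batch.input_ids == b_id
    masked_ids = batch.input_ids.copy()
    masked_ids[to_mask] = mask_id
    mb = dataclasses.replace(batch, input_ids=masked_ids)
    states = model.hidden_states(mb)
    logits = states[-1] @ model.params["mlm.W"] + model.params["mlm.b"]
    pred = logits.argmax(-1)
    acc = (pred[to_mask] == b_id).mean()
    assert acc > 0.9


def test_pretrain_determinism_and_persistence(tmp_path):
    seqs = grammar_corpus(n_sequences=200, seed=3)
    cfg = TransformerConfig.desk("ehrbert", epochs=2, seed=9, batch_size=32)
    m1, h1 = pretrain_mlm(seqs, None, cfg)
    m2, h2 = pretrain_mlm(seqs, None, cfg)
    assert h1 == h2
    assert all(np.array_equal(m1.params[k], m2.params[k]) for k in m1.params)
    save_model(m1, tmp_path / "ckpt")
    m3 = load_model(tmp_path / "ckpt")
    e1 = extract_embeddings(m1, seqs, None)
    e3 = extract_embeddings(m3, seqs, None)
    assert np.allclose(e1.X, e3.X)


def test_corpus_smaller_than_batch_rejected():
    seqs = grammar_corpus(n_sequences=10, seed=0)
    cfg = TransformerConfig.desk("ehrbert", epochs=1, batch_size=64)
    with pytest.raises(ValueError, match="batch"):
        pretrain_mlm(seqs, None, cfg)
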