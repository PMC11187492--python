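"""BERT-style encoders for coded EHR sequences, in three input variants.

One configurable bidirectional transformer encoder reproduces the three
published input/embedding conventions for EHR code sequences:

* ``medbert`` — code + visit-number (+ absolute position) embeddings, no
  special tokens;
* ``behrt``  — code + visit-number + age + alternating per-visit segment
  embeddings, ``[CLS]`` at the start and ``[SEP]`` between visits;
* ``ehrbert`` — code + visit-number + age + gender + ethnicity + deprivation
  + calendar-year embeddings, ``[CLS]`` at the start and one ``[SEP]`` at the
  end (no per-visit separators, no segment).

The position-wise input embedding is the elementwise sum of the enabled
embedding tables.  Pretraining is masked-language modelling only: 15% of
code positions are selected, of which 80% become ``[MASK]``, 10% a random
code and 10% stay unchanged; cross-entropy is computed on selected positions
only, and special/padded positions are never selected.  Patient embeddings
are the mean of the second-to-last layer's hidden states over code positions
(special tokens and padding excluded).

Everything is plain numpy: forward pass, hand-derived backward pass, and an
Adam optimizer with linear warmup.  The default configuration is desk-scale
(2 layers, hidden 64); the published presets (6 layers, hidden 192/288) are
available through :meth:`TransformerConfig.preset`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

from ehrseq.containers import EmbeddingSet
from ehrseq.sequences import CLS, SEP, MASK, PatientSequence, TokenVocabulary

__all__ = ["TransformerConfig", "EHRTransformer", "ModelInputBatch",
           "compose_inputs", "build_batch", "pretrain_mlm",
           "extract_embeddings", "mean_pool"]

VARIANT_INPUTS = {
    "medbert": ("code", "visit_number", "absolute_position"),
    "behrt": ("code", "visit_number", "age", "segment", "absolute_position"),
    "ehrbert": ("code", "visit_number", "age", "gender", "ethnicity", "imd",
                "calendar_year", "absolute_position"),
}

GENDER_IDS = {"female": 1, "male": 2, "indeterminate": 3}
ETHNICITY_IDS = {"White": 1, "South Asian": 2, "Black": 3, "Other": 4,
                 "Mixed": 5, "missing": 6}
MISSING_ID = 0  # reserved id for absent/missing categorical values


@dataclass
class TransformerConfig:
    """Architecture, input-embedding and training settings.

    ``hidden_size`` must be divisible by ``attention_heads``.  ``inputs``
    defaults to the variant's published convention; ``max_len`` bounds the
    number of *code* tokens per sequence (special tokens come on top).
    """

    variant: str = "ehrbert"
    hidden_layers: int = 2
    attention_heads: int = 4
    hidden_size: int = 64
    intermediate_size: int = 128
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_len: int = 128
    inputs: tuple[str, ...] | None = None
    mask_prob: float = 0.15
    epochs: int = 5
    seed: int = 0
    warmup_frac: float = 0.1
    max_visits: int = 512
    age_max: int = 110
    year_min: int = 1985
    year_max: int = 2015

    def __post_init__(self) -> None:
        if self.variant not in VARIANT_INPUTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.hidden_size % self.attention_heads:
            raise ValueError(
                f"hidden_size {self.hidden_size} is not divisible by "
                f"attention_heads {self.attention_heads}")
        if self.inputs is None:
            self.inputs = VARIANT_INPUTS[self.variant]
        if "code" not in self.inputs:
            raise ValueError("the code embedding cannot be disabled")

    @classmethod
    def preset(cls, variant: str, **overrides) -> "TransformerConfig":
        """Published full-scale presets for the three variants."""
        table = {
            "medbert": dict(hidden_layers=6, attention_heads=6,
                            hidden_size=192, intermediate_size=64,
                            learning_rate=5e-5, batch_size=32),
            "behrt": dict(hidden_layers=6, attention_heads=12,
                          hidden_size=288, intermediate_size=512,
                          learning_rate=3e-5, batch_size=256),
            "ehrbert": dict(hidden_layers=6, attention_heads=12,
                            hidden_size=288, intermediate_size=512,
                            learning_rate=3e-5, batch_size=256),
        }
        if variant not in table:
            raise ValueError(f"unknown variant {variant!r}")
        kw = dict(table[variant])
        kw.update(overrides)
        return cls(variant=variant, **kw)

    @classmethod
    def desk(cls, variant: str, **overrides) -> "TransformerConfig":
        """Small configuration for CPU-scale experiments and tests."""
        kw = dict(hidden_layers=2, attention_heads=4, hidden_size=64,
                  intermediate_size=128, learning_rate=1e-3, batch_size=64)
        kw.update(overrides)
        return cls(variant=variant, **kw)


@dataclass
class ModelInputBatch:
    """Parallel integer tensors for one batch (padded with 0)."""

    input_ids: np.ndarray  # (B, T)
    position: np.ndarray
    visit: np.ndarray
    age: np.ndarray
    year: np.ndarray
    segment: np.ndarray
    gender: np.ndarray  # (B, T), per-sequence value broadcast to positions
    ethnicity: np.ndarray
    imd: np.ndarray
    attention_mask: np.ndarray  # (B, T) 1 = real token
    code_mask: np.ndarray  # (B, T) 1 = code position (not special/pad)
    ids: list[str] = field(default_factory=list)


def compose_inputs(sequence: PatientSequence, record: dict | "pd.Series",
                   config: TransformerConfig,
                   vocabulary: TokenVocabulary) -> dict[str, np.ndarray]:
    """Token ids plus per-position context ids for one patient.

    Pure function of its arguments.  Special-token placement follows the
    variant; special positions carry the reserved id 0 in every auxiliary
    table.  ``record`` supplies gender/ethnicity/IMD; missing values map to
    the reserved missing id, never an error.
    """
    if len(sequence) > config.max_len:
        raise ValueError(
            f"sequence of length {len(sequence)} exceeds max_len "
            f"{config.max_len}; truncate upstream")
    code_ids = vocabulary.encode(sequence.tokens)
    visits = sequence.visit_index
    ages = [min(a, config.age_max) + 1 for a in sequence.age_years]
    span = config.year_max - config.year_min
    years = [min(max(y - config.year_min, 0), span) + 1
             for y in sequence.calendar_year]

    toks, pos_visit, pos_age, pos_year, pos_seg, is_code = [], [], [], [], [], []

    def put(tid: int, v: int, a: int, y: int, s: int, code: bool) -> None:
        toks.append(tid)
        pos_visit.append(v)
        pos_age.append(a)
        pos_year.append(y)
        pos_seg.append(s)
        is_code.append(code)

    cls_id, sep_id = vocabulary.index[CLS], vocabulary.index[SEP]
    if config.variant == "medbert":
        for c, v, a, y in zip(code_ids, visits, ages, years):
            put(c, min(v, config.max_visits), a, y, 0, True)
    elif config.variant == "behrt":
        put(cls_id, 0, 0, 0, 0, False)
        for i, (c, v, a, y) in enumerate(zip(code_ids, visits, ages, years)):
            seg = (v - 1) % 2
            put(c, min(v, config.max_visits), a, y, seg, True)
            nxt = visits[i + 1] if i + 1 < len(visits) else None
            if nxt is not None and nxt != v:
                put(sep_id, 0, 0, 0, seg, False)  # separator between visits
    else:  # ehrbert
        put(cls_id, 0, 0, 0, 0, False)
        for c, v, a, y in zip(code_ids, visits, ages, years):
            put(c, min(v, config.max_visits), a, y, 0, True)
        put(sep_id, 0, 0, 0, 0, False)

    gid = GENDER_IDS.get(record.get("gender"), MISSING_ID)
    eid = ETHNICITY_IDS.get(record.get("ethnicity"), MISSING_ID)
    d = record.get("imd_decile")
    try:
        did = int(d) if d is not None and not np.isnan(float(d)) else MISSING_ID
    except (TypeError, ValueError):
        did = MISSING_ID
    T = len(toks)
    return {
        "input_ids": np.array(toks),
        "position": np.arange(T),
        "visit": np.array(pos_visit),
        "age": np.array(pos_age),
        "year": np.array(pos_year),
        "segment": np.array(pos_seg),
        "gender": np.full(T, gid),
        "ethnicity": np.full(T, eid),
        "imd": np.full(T, did),
        "attention_mask": np.ones(T, dtype=int),
        "code_mask": np.array(is_code, dtype=int),
        "patient_id": sequence.patient_id,
    }


def build_batch(composed: list[dict[str, np.ndarray]]) -> ModelInputBatch:
    """Pad composed inputs to a common length (pad id 0 everywhere)."""
    T = max(len(c["input_ids"]) for c in composed)
    B = len(composed)
    fields = ["input_ids", "position", "visit", "age", "year", "segment",
              "gender", "ethnicity", "imd", "attention_mask", "code_mask"]
    arrs = {f: np.zeros((B, T), dtype=int) for f in fields}
    for i, c in enumerate(composed):
        t = len(c["input_ids"])
        for f in fields:
            arrs[f][i, :t] = c[f]
    return ModelInputBatch(ids=[c["patient_id"] for c in composed], **arrs)


# ---------------------------------------------------------------------------
# numpy encoder internals

_GELU_C = 0.7978845608028654  # sqrt(2/pi)


def _gelu(x):
    """tanh-approximation GELU; returns (value, cached tanh term)."""
    x2 = x * x
    t = np.tanh(_GELU_C * (x + 0.044715 * x2 * x))
    return 0.5 * x * (1.0 + t), t


def _gelu_grad(x, t):
    x2 = x * x
    return 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * _GELU_C * (
        1.0 + 3 * 0.044715 * x2)


def _ln_forward(x, g, b, eps=1e-5):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv
    return g * xhat + b, (xhat, inv)


def _ln_backward(dy, cache, g):
    xhat, inv = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    m1 = dxhat.mean(axis=-1, keepdims=True)
    m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    return dx, dg, db


class EHRTransformer:
    """Trainable encoder + MLM head over a code vocabulary."""

    EMB_TABLES = {
        "code": None,  # sized from vocabulary
        "absolute_position": None,  # sized from max_len
        "visit_number": None,
        "age": None,
        "calendar_year": None,
        "segment": 2,
        "gender": 4,
        "ethnicity": 7,
        "imd": 11,
    }
    _EMB_KEY = {"code": "input_ids", "absolute_position": "position",
                "visit_number": "visit", "age": "age",
                "calendar_year": "year", "segment": "segment",
                "gender": "gender", "ethnicity": "ethnicity", "imd": "imd"}

    def __init__(self, config: TransformerConfig,
                 vocabulary: TokenVocabulary):
        self.config = config
        self.vocab = vocabulary
        H = config.hidden_size
        rng = np.random.default_rng(config.seed)
        self.params: dict[str, np.ndarray] = {}

        def mk(name, shape, scale=0.02):
            self.params[name] = rng.normal(0.0, scale, size=shape)

        sizes = dict(self.EMB_TABLES)
        sizes["code"] = len(vocabulary)
        sizes["absolute_position"] = 2 * config.max_len + 2
        sizes["visit_number"] = config.max_visits + 1
        sizes["age"] = config.age_max + 2
        sizes["calendar_year"] = config.year_max - config.year_min + 2
        for tname in config.inputs:
            mk(f"emb.{tname}", (sizes[tname], H))
        self.params["ln0.g"] = np.ones(H)
        self.params["ln0.b"] = np.zeros(H)
        for l in range(config.hidden_layers):
            for w in ("q", "k", "v", "o"):
                mk(f"l{l}.{w}.W", (H, H))
                self.params[f"l{l}.{w}.b"] = np.zeros(H)
            mk(f"l{l}.f1.W", (H, config.intermediate_size))
            self.params[f"l{l}.f1.b"] = np.zeros(config.intermediate_size)
            mk(f"l{l}.f2.W", (config.intermediate_size, H))
            self.params[f"l{l}.f2.b"] = np.zeros(H)
            for ln in ("ln1", "ln2"):
                self.params[f"l{l}.{ln}.g"] = np.ones(H)
                self.params[f"l{l}.{ln}.b"] = np.zeros(H)
        mk("mlm.W", (H, len(vocabulary)))
        self.params["mlm.b"] = np.zeros(len(vocabulary))

    # -- forward -----------------------------------------------------------

    def _embed(self, batch: ModelInputBatch) -> np.ndarray:
        P = self.params
        x = None
        for tname in self.config.inputs:
            ids = getattr(batch, self._EMB_KEY[tname])
            if tname == "absolute_position":
                ids = batch.position
            v = P[f"emb.{tname}"][ids]
            x = v if x is None else x + v
        return x

    def hidden_states(self, batch: ModelInputBatch,
                      cache: list | None = None) -> list[np.ndarray]:
        """Forward pass; returns ``[h_emb, h_1, ..., h_L]``."""
        cfg, P = self.config, self.params
        nh = cfg.attention_heads
        H = cfg.hidden_size
        dh = H // nh
        mask_bias = (batch.attention_mask[:, None, None, :] - 1.0) * 1e9

        e = self._embed(batch)
        x, ln0c = _ln_forward(e, P["ln0.g"], P["ln0.b"])
        states = [x]
        if cache is not None:
            cache.append(("emb", ln0c))
        B, T, _ = x.shape
        for l in range(cfg.hidden_layers):
            q = x @ P[f"l{l}.q.W"] + P[f"l{l}.q.b"]
            k = x @ P[f"l{l}.k.W"] + P[f"l{l}.k.b"]
            v = x @ P[f"l{l}.v.W"] + P[f"l{l}.v.b"]
            qh = q.reshape(B, T, nh, dh).transpose(0, 2, 1, 3)
            kh = k.reshape(B, T, nh, dh).transpose(0, 2, 1, 3)
            vh = v.reshape(B, T, nh, dh).transpose(0, 2, 1, 3)
            s = qh @ kh.transpose(0, 1, 3, 2) / np.sqrt(dh) + mask_bias
            s -= s.max(axis=-1, keepdims=True)
            a = np.exp(s)
            a /= a.sum(axis=-1, keepdims=True)
            ctx = (a @ vh).transpose(0, 2, 1, 3).reshape(B, T, H)
            attn = ctx @ P[f"l{l}.o.W"] + P[f"l{l}.o.b"]
            x1, ln1c = _ln_forward(x + attn, P[f"l{l}.ln1.g"],
                                   P[f"l{l}.ln1.b"])
            u = x1 @ P[f"l{l}.f1.W"] + P[f"l{l}.f1.b"]
            gu, gt = _gelu(u)
            f = gu @ P[f"l{l}.f2.W"] + P[f"l{l}.f2.b"]
            x2, ln2c = _ln_forward(x1 + f, P[f"l{l}.ln2.g"],
                                   P[f"l{l}.ln2.b"])
            if cache is not None:
                cache.append((x, qh, kh, vh, a, ctx, ln1c, x1, (u, gt), gu,
                              ln2c))
            x = x2
            states.append(x)
        return states

    # -- MLM loss + gradients ---------------------------------------------

    def mlm_step(self, batch: ModelInputBatch, sel: np.ndarray,
                 labels: np.ndarray) -> tuple[float, dict[str, np.ndarray]]:
        """Cross-entropy on selected positions and gradients for all params.

        ``sel`` is a boolean (B, T) mask of positions entering the loss;
        ``labels`` the original token ids at those positions (row-major
        order).
        """
        cfg, P = self.config, self.params
        nh, H = cfg.attention_heads, cfg.hidden_size
        dh = H // nh
        cache: list = []
        states = self.hidden_states(batch, cache)
        x = states[-1]
        B, T, _ = x.shape
        u = x[sel]  # (S, H)
        logits = u @ P["mlm.W"] + P["mlm.b"]
        logits -= logits.max(axis=1, keepdims=True)
        expl = np.exp(logits)
        prob = expl / expl.sum(axis=1, keepdims=True)
        S = len(labels)
        loss = float(-np.log(prob[np.arange(S), labels] + 1e-12).mean())

        grads = {k: np.zeros_like(v) for k, v in P.items()}
        dlogits = prob.copy()
        dlogits[np.arange(S), labels] -= 1.0
        dlogits /= S
        grads["mlm.W"] = u.T @ dlogits
        grads["mlm.b"] = dlogits.sum(axis=0)
        du = dlogits @ P["mlm.W"].T
        dx = np.zeros_like(x)
        dx[sel] = du

        for l in range(cfg.hidden_layers - 1, -1, -1):
            (xin, qh, kh, vh, a, ctx, ln1c, x1, (uff, gt), gu,
             ln2c) = cache[l + 1]
            dy, dg, db = _ln_backward(dx, ln2c, P[f"l{l}.ln2.g"])
            grads[f"l{l}.ln2.g"] += dg
            grads[f"l{l}.ln2.b"] += db
            # dy is gradient wrt (x1 + f)
            df = dy
            grads[f"l{l}.f2.W"] += gu.reshape(-1, gu.shape[-1]).T @ \
                df.reshape(-1, H)
            grads[f"l{l}.f2.b"] += df.sum(axis=(0, 1))
            dgu = df @ P[f"l{l}.f2.W"].T
            duff = dgu * _gelu_grad(uff, gt)
            grads[f"l{l}.f1.W"] += x1.reshape(-1, H).T @ \
                duff.reshape(-1, duff.shape[-1])
            grads[f"l{l}.f1.b"] += duff.sum(axis=(0, 1))
            dx1 = dy + duff @ P[f"l{l}.f1.W"].T
            dz, dg, db = _ln_backward(dx1, ln1c, P[f"l{l}.ln1.g"])
            grads[f"l{l}.ln1.g"] += dg
            grads[f"l{l}.ln1.b"] += db
            # dz is gradient wrt (xin + attn)
            dattn = dz
            grads[f"l{l}.o.W"] += ctx.reshape(-1, H).T @ dattn.reshape(-1, H)
            grads[f"l{l}.o.b"] += dattn.sum(axis=(0, 1))
            dctx = (dattn @ P[f"l{l}.o.W"].T).reshape(B, T, nh, dh) \
                .transpose(0, 2, 1, 3)
            da = dctx @ vh.transpose(0, 1, 3, 2)
            dvh = a.transpose(0, 1, 3, 2) @ dctx
            ds = a * (da - (da * a).sum(axis=-1, keepdims=True))
            ds /= np.sqrt(dh)
            dqh = ds @ kh
            dkh = ds.transpose(0, 1, 3, 2) @ qh
            dq = dqh.transpose(0, 2, 1, 3).reshape(B, T, H)
            dk = dkh.transpose(0, 2, 1, 3).reshape(B, T, H)
            dv = dvh.transpose(0, 2, 1, 3).reshape(B, T, H)
            xin2 = xin.reshape(-1, H)
            for w, dproj in (("q", dq), ("k", dk), ("v", dv)):
                grads[f"l{l}.{w}.W"] += xin2.T @ dproj.reshape(-1, H)
                grads[f"l{l}.{w}.b"] += dproj.sum(axis=(0, 1))
            dx = (dz + dq @ P[f"l{l}.q.W"].T + dk @ P[f"l{l}.k.W"].T
                  + dv @ P[f"l{l}.v.W"].T)

        de, dg, db = _ln_backward(dx, cache[0][1], P["ln0.g"])
        grads["ln0.g"] += dg
        grads["ln0.b"] += db
        for tname in cfg.inputs:
            ids = getattr(batch, self._EMB_KEY[tname])
            np.add.at(grads[f"emb.{tname}"], ids.ravel(),
                      de.reshape(-1, H))
        return loss, grads


def _mask_batch(batch: ModelInputBatch, vocab: TokenVocabulary,
                mask_prob: float, rng: np.random.Generator):
    """BERT masking: select code positions, 80/10/10 replacement."""
    sel = (rng.random(batch.input_ids.shape) < mask_prob) & \
        (batch.code_mask == 1)
    if not sel.any():
        return None
    labels = batch.input_ids[sel]
    masked = batch.input_ids.copy()
    u = rng.random(int(sel.sum()))
    n_codes = len(vocab)
    n_special = len(vocab.tokens) - vocab.n_codes
    repl = np.where(
        u < 0.8, vocab.index[MASK],
        np.where(u < 0.9,
                 rng.integers(n_special, n_codes, size=len(u)),
                 labels))
    masked[sel] = repl
    out = replace(batch, input_ids=masked)
    return out, sel, labels


class _Adam:
    def __init__(self, params, lr, warmup_steps, total_steps):
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0
        self.lr = lr
        self.warmup = max(1, warmup_steps)
        self.total = total_steps

    def step(self, params, grads):
        self.t += 1
        if self.t <= self.warmup:
            lr = self.lr * self.t / self.warmup
        else:
            frac = (self.total - self.t) / max(1, self.total - self.warmup)
            lr = self.lr * max(0.05, frac)
        b1, b2, eps = 0.9, 0.999, 1e-8
        c1 = 1 - b1 ** self.t
        c2 = 1 - b2 ** self.t
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            params[k] -= lr * (self.m[k] / c1) / (
                np.sqrt(self.v[k] / c2) + eps)


def pretrain_mlm(sequences: dict[str, PatientSequence], records,
                 config: TransformerConfig,
                 vocabulary: TokenVocabulary | None = None
                 ) -> tuple[EHRTransformer, list[float]]:
    """Masked-language-model pretraining; returns model and per-epoch loss.

    ``records`` is the patient table (DataFrame indexed or keyed by
    ``patient_id``) supplying sociodemographics for variants that embed
    them.  Deterministic for a given config seed.
    """
    if vocabulary is None:
        vocabulary = TokenVocabulary.from_sequences(sequences)
    model = EHRTransformer(config, vocabulary)
    rec_by_id = _records_by_id(records)
    composed = [compose_inputs(s, rec_by_id.get(pid, {}), config, vocabulary)
                for pid, s in sequences.items()]
    if len(composed) < config.batch_size:
        raise ValueError(
            f"corpus of {len(composed)} sequences is smaller than one batch "
            f"({config.batch_size}); lower batch_size")
    rng = np.random.default_rng(config.seed + 1)
    n = len(composed)
    # length-bucketed batches: sequences sorted by length so each batch pads
    # to its own maximum, not the corpus maximum
    by_len = sorted(range(n), key=lambda i: len(composed[i]["input_ids"]))
    steps_per_epoch = n // config.batch_size
    batches = [by_len[b * config.batch_size:(b + 1) * config.batch_size]
               for b in range(steps_per_epoch)]
    total = max(1, steps_per_epoch * config.epochs)
    opt = _Adam(model.params, config.learning_rate,
                int(config.warmup_frac * total), total)
    history = []
    border = np.arange(len(batches))
    for _ in range(config.epochs):
        rng.shuffle(border)
        losses = []
        for b in border:
            batch = build_batch([composed[i] for i in batches[b]])
            masked = _mask_batch(batch, vocabulary, config.mask_prob, rng)
            if masked is None:
                continue
            mb, sel, labels = masked
            loss, grads = model.mlm_step(mb, sel, labels)
            opt.step(model.params, grads)
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return model, history


def _records_by_id(records) -> dict:
    if records is None:
        return {}
    if hasattr(records, "iterrows"):
        return {str(r["patient_id"]): r for _, r in records.iterrows()}
    return dict(records)


def mean_pool(states: np.ndarray, code_mask: np.ndarray) -> np.ndarray:
    """Mean of per-position hidden states over code positions only."""
    m = code_mask.astype(float)
    denom = np.maximum(m.sum(axis=1, keepdims=True), 1.0)
    return (states * m[:, :, None]).sum(axis=1) / denom


def extract_embeddings(model: EHRTransformer,
                       sequences: dict[str, PatientSequence], records,
                       batch_size: int = 128) -> EmbeddingSet:
    """Pooled patient embeddings: mean of the second-to-last layer's hidden
    states over code positions; one ``hidden_size`` vector per patient."""
    cfg = model.config
    rec_by_id = _records_by_id(records)
    composed = [compose_inputs(s, rec_by_id.get(pid, {}), cfg, model.vocab)
                for pid, s in sequences.items()]
    composed.sort(key=lambda c: len(c["input_ids"]))  # minimal padding
    ids, rows = [], []
    for i in range(0, len(composed), batch_size):
        chunk = composed[i:i + batch_size]
        batch = build_batch(chunk)
        states = model.hidden_states(batch)
        pooled = mean_pool(states[-2], batch.code_mask)
        rows.append(pooled)
        ids.extend(batch.ids)
    return EmbeddingSet(ids=ids, X=np.vstack(rows),
                        method=cfg.variant, vocabulary_tag="")


# ---------------------------------------------------------------------------
# persistence


def save_model(model: EHRTransformer, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "config.json", "w") as f:
        json.dump(asdict(model.config), f, indent=2)
    model.vocab.to_tsv(path / "vocabulary.tsv")
    np.savez(path / "weights.npz", **model.params)


def load_model(path: str | Path) -> EHRTransformer:
    path = Path(path)
    with open(path / "config.json") as f:
        d = json.load(f)
    d["inputs"] = tuple(d["inputs"])
    cfg = TransformerConfig(**d)
    vocab = TokenVocabulary.from_tsv(path / "vocabulary.tsv")
    model = EHRTransformer(cfg, vocab)
    with np.load(path / "weights.npz") as z:
        for k in model.params:
            model.params[k] = z[k]
    return model
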