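"""Seeded synthetic EHR cohort generator.

Emulates the statistical structure that the representation-learning and
evaluation stages assume in real primary-care data: adult patients with at
least two distinct long-term conditions, time-ordered recurrent coded events
generated by a per-patient latent-topic Markov process over visits, a
many-to-one map from fine-grained codes to disease categories,
sociodemographics with explicit missing levels, and binary 1-year outcomes
drawn from a logistic model whose linear predictor combines disease
co-occurrence, sequence-order terms (precedence indicators and
recency-weighted exposures) and sociodemographics.

Every quantity is drawn from a single :class:`numpy.random.Generator`, so a
configuration plus seed fully determines the cohort.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SimulationConfig",
    "OutcomeModel",
    "SimulatedCohort",
    "SimulationError",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
    "headline_config",
    "default_outcomes",
    "outcome_design",
    "ED_CODE",
    "ADMISSION_CODE",
    "ED_CATEGORY",
    "ADMISSION_CATEGORY",
]

#: reserved follow-up-only marker codes (not part of the long-term-condition
#: code map; they never occur in history and never enter sequences)
ED_CODE = "EDVISIT"
ADMISSION_CODE = "EMADM"
ED_CATEGORY = "ed_attendance"
ADMISSION_CATEGORY = "emergency_admission"

GENDER_LEVELS = ("female", "male", "indeterminate")
ETHNICITY_LEVELS = ("White", "South Asian", "Black", "Other", "Mixed", "missing")

DAYS_PER_YEAR = 365.25


class SimulationError(ValueError):
    """Raised when a configuration cannot produce the requested cohort."""


@dataclass
class OutcomeModel:
    """Logistic generating model for one binary 1-year outcome.

    The linear predictor is

    ``eta = b0 + sum_d w_d * present_d + sum_(a,b) v_ab * [first(a) < first(b)]
    + sum_d u_d * recency_d + age_w*(age-50)/10 + female_w*female
    + imd_w*(imd-5.5)/4.5``

    where ``present_d`` is a binary disease-category indicator computed on
    pre-index history, the precedence indicator is 1 only when both diseases
    are present, and ``recency_d`` is ``sum_events 0.5**(days_before_index /
    half_life_days)`` over occurrences of category ``d``.  The intercept
    ``b0`` is calibrated numerically so the mean event probability over the
    outcome's eligible stratum equals ``target_rate``.
    """

    name: str
    target_rate: float
    kind: str = "utilisation"  # {"mortality", "utilisation", "disease"}
    disease: str | None = None  # category token for disease outcomes
    presence_weights: dict[str, float] = field(default_factory=dict)
    order_weights: list[tuple[str, str, float]] = field(default_factory=list)
    recency_weights: dict[str, float] = field(default_factory=dict)
    age_weight: float = 0.0
    female_weight: float = 0.0
    imd_weight: float = 0.0
    #: target rate for incident ("new") diagnoses among patients without the
    #: disease in history; only used when kind == "disease"
    new_target_rate: float | None = None

    def zero_order(self) -> "OutcomeModel":
        out = dataclasses.replace(self, order_weights=[], recency_weights={})
        return out


def _cat(i: int) -> str:
    return f"d{i:03d}"


def default_outcomes(n_categories: int) -> dict[str, OutcomeModel]:
    """The nine default outcome generating models.

    Target event rates follow the observed rates in a national multimorbidity
    cohort: 3.3% 1-year mortality in the 60+ stratum, 19.9% emergency
    department (ED) attendance, 7.3% emergency admission, any-attendance rates
    of 10.5/9.1/3.9% and incident rates of 1.5/0.8/1.1% for hypertension,
    diabetes and depression respectively.  Hypertension, diabetes and
    depression are identified with the three most frequent synthetic
    categories.  Sequence-order effects are attached to the emergency
    admission outcome.
    """
    if n_categories < 10:
        raise SimulationError("need at least 10 disease categories")
    htn, dm, dep = _cat(0), _cat(1), _cat(2)
    pairs = [(_cat(3), _cat(4), 1.2), (_cat(5), _cat(6), 1.2), (_cat(7), _cat(8), 1.2)]
    return {
        "mortality_60plus": OutcomeModel(
            name="mortality_60plus", target_rate=0.033, kind="mortality",
            presence_weights={_cat(4): 0.6, _cat(6): 0.6, _cat(9): 0.8},
            age_weight=0.55, female_weight=-0.15, imd_weight=0.15,
        ),
        "ed_attendance": OutcomeModel(
            name="ed_attendance", target_rate=0.199, kind="utilisation",
            presence_weights={_cat(3): 0.4, _cat(5): 0.4, _cat(9): 0.5},
            age_weight=0.10, imd_weight=0.25,
        ),
        "emergency_admission": OutcomeModel(
            name="emergency_admission", target_rate=0.073, kind="utilisation",
            presence_weights={_cat(3): 0.4, _cat(5): 0.4, _cat(7): 0.4},
            order_weights=pairs,
            recency_weights={_cat(9): 0.4},
            age_weight=0.25, imd_weight=0.15,
        ),
        "any_hypertension": OutcomeModel(
            name="any_hypertension", target_rate=0.105, kind="disease",
            disease=htn, new_target_rate=0.015,
            presence_weights={dm: 0.5, _cat(3): 0.3},
            age_weight=0.35, imd_weight=0.10,
        ),
        "any_diabetes": OutcomeModel(
            name="any_diabetes", target_rate=0.091, kind="disease",
            disease=dm, new_target_rate=0.008,
            presence_weights={htn: 0.5, _cat(4): 0.3},
            age_weight=0.30, imd_weight=0.20,
        ),
        "any_depression": OutcomeModel(
            name="any_depression", target_rate=0.039, kind="disease",
            disease=dep, new_target_rate=0.011,
            presence_weights={_cat(5): 0.4, _cat(8): 0.3},
            age_weight=-0.10, female_weight=0.30, imd_weight=0.25,
        ),
    }


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults are desk-scale: 20 000 patients, 400 fine codes mapped onto 40
    disease categories.  Marginal sociodemographic distributions follow the
    reference cohort (age ~ normal(53.8, 18.2) truncated to [18, 100], 53.1%
    female, ethnicity shares 86.2/5.9/3.5/1.3/1.0/2.0%, near-uniform
    deprivation deciles).
    """

    n_patients: int = 20_000
    index_date: str = "2015-01-01"
    fine_vocab_size: int = 400
    category_vocab_size: int = 40
    n_latent_topics: int = 6
    markov_persistence: float = 0.8
    mean_extra_visits: float = 8.0  # visits per patient = 2 + Poisson(this)
    codes_per_visit_probs: tuple[float, float, float] = (0.7, 0.2, 0.1)
    recurrent_rate: float = 0.35
    recurrent_imd_gradient: float = 0.15  # deprivation gradient in re-coding
    recency_half_life_days: float = 730.0
    history_years: float = 15.0
    followup_days: int = 365
    topic_sharpness: float = 8.0  # Dirichlet concentration for topic-category
    category_zipf: float = 0.8  # popularity decay of category base measure
    patient_topic_alpha: float = 0.4
    # demographics
    age_mean: float = 53.8
    age_sd: float = 18.2
    age_min: float = 18.0
    age_max: float = 100.0
    female_prop: float = 0.531
    indeterminate_prop: float = 1e-5
    ethnicity_props: dict[str, float] = field(default_factory=lambda: {
        "White": 0.862, "South Asian": 0.059, "Black": 0.035,
        "Other": 0.013, "Mixed": 0.010, "missing": 0.020,
    })
    imd_missing_prop: float = 0.001
    frac_recent_registration: float = 0.03
    prior_death_rate: float = 0.004
    dereg_rate: float = 0.049
    mean_followup_disease_events: float = 0.5  # extra codes beyond the first
    outcomes: dict[str, OutcomeModel] | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name, p in [
            ("markov_persistence", self.markov_persistence),
            ("recurrent_rate", self.recurrent_rate),
            ("female_prop", self.female_prop),
            ("dereg_rate", self.dereg_rate),
            ("prior_death_rate", self.prior_death_rate),
        ]:
            if not 0.0 <= p <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1]; got {p}")
        tot = sum(self.ethnicity_props.values())
        if abs(tot - 1.0) > 0.01:
            raise SimulationError("ethnicity_props must sum to 1")
        # published shares are rounded; renormalize exactly
        self.ethnicity_props = {k: v / tot
                                for k, v in self.ethnicity_props.items()}
        if self.fine_vocab_size < self.category_vocab_size:
            raise SimulationError("fine vocabulary must be at least as large "
                                  "as the category vocabulary")
        if self.outcomes is None:
            self.outcomes = default_outcomes(self.category_vocab_size)

    @property
    def index_ts(self) -> pd.Timestamp:
        return pd.Timestamp(self.index_date)

    def zero_order_effects(self) -> "SimulationConfig":
        """Copy of the config with every sequence-order weight set to zero."""
        out = dataclasses.replace(self)
        out.outcomes = {k: m.zero_order() for k, m in self.outcomes.items()}
        return out


def headline_config(order_strength: float = 1.5, n_patients: int = 6000,
                    seed: int = 0) -> SimulationConfig:
    """Compact cohort whose admission outcome is driven by sequence order.

    Used for the head-to-head comparison of order-aware and co-occurrence
    representations: a small vocabulary (120 codes, 12 categories) keeps the
    categories common enough that the precedence pairs are active for a large
    share of patients, and the single evaluated outcome carries the order
    signal.  ``order_strength=0`` gives the matched no-order control.
    """
    # symmetric +/- precedence contrasts: conditional on both diseases being
    # present the term is +w when a came first and -w when b came first, so
    # co-occurrence alone carries no part of the order signal and only an
    # order-aware representation can separate the two directions
    pairs = []
    recency: dict[str, float] = {}
    if order_strength != 0.0:
        for a, b in [(_cat(1), _cat(2)), (_cat(3), _cat(4)),
                     (_cat(0), _cat(5))]:
            pairs.append((a, b, order_strength))
            pairs.append((b, a, -order_strength))
        # timing effects: recent disease activity raises admission risk in a
        # way a presence/absence summary cannot represent
        recency = {_cat(1): 0.6 * order_strength,
                   _cat(4): 0.6 * order_strength}
    outcome = OutcomeModel(
        name="emergency_admission", target_rate=0.20, kind="utilisation",
        presence_weights={_cat(0): 0.4, _cat(2): 0.4, _cat(6): 0.4},
        order_weights=pairs,
        recency_weights=recency,
        age_weight=0.15, imd_weight=0.10,
    )
    return SimulationConfig(
        n_patients=n_patients,
        fine_vocab_size=120,
        category_vocab_size=12,
        n_latent_topics=4,
        mean_extra_visits=9.0,
        category_zipf=0.35,
        outcomes={"emergency_admission": outcome},
        rng_seed=seed,
    )


@dataclass
class SimulatedCohort:
    """Output bundle of :func:`simulate_cohort`."""

    records: pd.DataFrame  # one row per patient
    events: pd.DataFrame  # history + follow-up coded events
    code_map: pd.DataFrame  # medcode -> disease, many-to-one
    outcomes: pd.DataFrame  # patient_id + one {0,1,NaN} column per outcome
    config: SimulationConfig

    @property
    def history_events(self) -> pd.DataFrame:
        return self.events[self.events["event_date"] < self.config.index_ts]

    @property
    def followup_events(self) -> pd.DataFrame:
        return self.events[self.events["event_date"] >= self.config.index_ts]


# --------------------------------------------------------------------------
# generation internals


def _category_base_measure(cfg: SimulationConfig) -> np.ndarray:
    w = (np.arange(1, cfg.category_vocab_size + 1, dtype=float)) ** (-cfg.category_zipf)
    return w / w.sum()


def _draw_demographics(cfg: SimulationConfig, rng: np.random.Generator):
    n = cfg.n_patients
    a, b = ((cfg.age_min - cfg.age_mean) / cfg.age_sd,
            (cfg.age_max - cfg.age_mean) / cfg.age_sd)
    age = stats.truncnorm.rvs(a, b, loc=cfg.age_mean, scale=cfg.age_sd,
                              size=n, random_state=rng)
    p_f, p_i = cfg.female_prop, cfg.indeterminate_prop
    gender = rng.choice(np.array(GENDER_LEVELS),
                        p=[p_f, 1.0 - p_f - p_i, p_i], size=n)
    eth_levels = list(cfg.ethnicity_props)
    ethnicity = rng.choice(np.array(eth_levels),
                           p=list(cfg.ethnicity_props.values()), size=n)
    imd = rng.integers(1, 11, size=n).astype(float)
    imd[rng.random(n) < cfg.imd_missing_prop] = np.nan
    return age, gender, ethnicity, imd


def _expected_truncnorm_moments(cfg: SimulationConfig) -> tuple[float, float]:
    """Theoretical mean/sd of the configured truncated age distribution."""
    a, b = ((cfg.age_min - cfg.age_mean) / cfg.age_sd,
            (cfg.age_max - cfg.age_mean) / cfg.age_sd)
    m, v = stats.truncnorm.stats(a, b, loc=cfg.age_mean, scale=cfg.age_sd,
                                 moments="mv")
    return float(m), float(np.sqrt(v))


def _simulate_history(cfg: SimulationConfig, rng: np.random.Generator,
                      age: np.ndarray, imd: np.ndarray):
    """Per-patient latent-topic Markov event generation.

    Returns flat arrays (patient index, day offset < 0 relative to the index
    date, medcode id) for the pre-index history.
    """
    n = cfg.n_patients
    n_cat, n_code = cfg.category_vocab_size, cfg.fine_vocab_size
    base = _category_base_measure(cfg)

    # many-to-one code map: every category gets at least one code, remaining
    # codes assigned with popularity proportional to the base measure
    code_cat = np.empty(n_code, dtype=int)
    code_cat[:n_cat] = np.arange(n_cat)
    code_cat[n_cat:] = rng.choice(n_cat, size=n_code - n_cat, p=base)

    # per-category code distribution (Dirichlet over the category's codes)
    cat_codes = [np.flatnonzero(code_cat == c) for c in range(n_cat)]
    cat_code_cdf = []
    for codes in cat_codes:
        w = rng.dirichlet(np.full(len(codes), 0.7))
        cat_code_cdf.append(np.cumsum(w))

    # topic-category distributions, concentrated around the base measure
    topic_cat = rng.dirichlet(cfg.topic_sharpness * base * n_cat,
                              size=cfg.n_latent_topics)
    topic_cat_cdf = np.cumsum(topic_cat, axis=1)

    theta = rng.dirichlet(np.full(cfg.n_latent_topics, cfg.patient_topic_alpha),
                          size=n)
    theta_cdf = np.cumsum(theta, axis=1)

    history_days = int(cfg.history_years * DAYS_PER_YEAR)
    n_visits = 2 + rng.poisson(cfg.mean_extra_visits, size=n)

    grad = cfg.recurrent_imd_gradient
    imd_c = np.where(np.isnan(imd), 5.5, imd)
    eff_rec = np.clip(cfg.recurrent_rate * (1 + grad * (imd_c - 5.5) / 4.5),
                      0.0, 0.9)

    pvq = np.cumsum(cfg.codes_per_visit_probs)

    pids, days, codes = [], [], []
    for i in range(n):
        nv = n_visits[i]
        # event window: from max(age-16 years ago, history window) to index
        span = min(history_days, int((age[i] - 16.0) * DAYS_PER_YEAR))
        span = max(span, 365)
        vdays = np.unique(rng.integers(-span, 0, size=nv))
        nv = len(vdays)
        # latent topic chain with persistence
        u = rng.random(nv)
        redraw = u >= cfg.markov_persistence
        redraw[0] = True
        t = 0
        topics = np.empty(nv, dtype=int)
        draws = np.searchsorted(theta_cdf[i], rng.random(nv))
        for v in range(nv):
            if redraw[v]:
                t = draws[v]
            topics[v] = t
        ncodes_v = 1 + np.searchsorted(pvq, rng.random(nv))
        total = int(ncodes_v.sum())
        u_rec = rng.random(total)
        u_cat = rng.random(total)
        u_code = rng.random(total)
        u_pick = rng.random(total)
        my_codes: list[int] = []
        my_days: list[int] = []
        e = 0
        for v in range(nv):
            for _ in range(ncodes_v[v]):
                if my_codes and u_rec[e] < eff_rec[i]:
                    code = my_codes[int(u_pick[e] * len(my_codes))]
                else:
                    c = int(np.searchsorted(topic_cat_cdf[topics[v]], u_cat[e]))
                    code = cat_codes[c][np.searchsorted(cat_code_cdf[c], u_code[e])]
                my_codes.append(int(code))
                my_days.append(int(vdays[v]))
                e += 1
        # guarantee >= 2 distinct disease categories
        cats_present = {code_cat[c] for c in my_codes}
        while len(cats_present) < 2:
            c = int(rng.integers(n_cat))
            if c in cats_present:
                continue
            code = cat_codes[c][np.searchsorted(cat_code_cdf[c], rng.random())]
            my_codes.append(int(code))
            my_days.append(int(rng.integers(-span, 0)))
            cats_present.add(c)
        pids.extend([i] * len(my_codes))
        days.extend(my_days)
        codes.extend(my_codes)

    return (np.array(pids), np.array(days), np.array(codes), code_cat)


def _history_facts(cfg: SimulationConfig, pid: np.ndarray, day: np.ndarray,
                   cat: np.ndarray):
    """Presence, first-occurrence day and recency-weighted exposure matrices."""
    n, n_cat = cfg.n_patients, cfg.category_vocab_size
    presence = np.zeros((n, n_cat), dtype=bool)
    presence[pid, cat] = True
    first_day = np.full((n, n_cat), np.inf)
    np.minimum.at(first_day, (pid, cat), day.astype(float))
    recency = np.zeros((n, n_cat))
    w = 0.5 ** (np.abs(day) / cfg.recency_half_life_days)
    np.add.at(recency, (pid, cat), w)
    return presence, first_day, recency


def _outcome_eta(model: OutcomeModel, cfg: SimulationConfig,
                 presence: np.ndarray, first_day: np.ndarray,
                 recency: np.ndarray, age: np.ndarray, gender: np.ndarray,
                 imd: np.ndarray) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Linear predictor (without intercept), design matrix and column names."""
    cat_idx = {_cat(i): i for i in range(cfg.category_vocab_size)}
    cols, names = [], []
    for d, w in model.presence_weights.items():
        cols.append((presence[:, cat_idx[d]].astype(float), w))
        names.append(f"present:{d}")
    for a, b, w in model.order_weights:
        ia, ib = cat_idx[a], cat_idx[b]
        both = np.isfinite(first_day[:, ia]) & np.isfinite(first_day[:, ib])
        prec = both & (first_day[:, ia] < first_day[:, ib])
        cols.append((prec.astype(float), w))
        names.append(f"precedes:{a}<{b}")
    for d, w in model.recency_weights.items():
        cols.append((recency[:, cat_idx[d]], w))
        names.append(f"recency:{d}")
    cols.append(((age - 50.0) / 10.0, model.age_weight))
    names.append("age_std")
    cols.append(((gender == "female").astype(float), model.female_weight))
    names.append("female")
    imd_c = np.where(np.isnan(imd), 5.5, imd)
    cols.append(((imd_c - 5.5) / 4.5, model.imd_weight))
    names.append("imd_std")
    X = np.column_stack([c for c, _ in cols])
    w = np.array([wt for _, wt in cols])
    return X @ w, X, names


def _calibrate_intercept(eta: np.ndarray, target: float, name: str) -> float:
    if not 0.0 < target < 1.0:
        raise SimulationError(
            f"outcome {name!r}: target rate {target} is not attainable "
            "(must be strictly between 0 and 1)")
    if eta.size == 0:
        raise SimulationError(f"outcome {name!r}: eligible stratum is empty")

    def gap(b: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(eta + b))))) - target

    return float(optimize.brentq(gap, -40.0, 40.0, xtol=1e-10))


def outcome_design(cohort: SimulatedCohort, outcome: str):
    """True generating design matrix for one outcome (for recoverability
    checks): returns ``(patient_ids, X, column_names, true_weights)`` over the
    outcome's eligible stratum, excluding the intercept."""
    cfg = cohort.config
    if outcome in cfg.outcomes:
        model = cfg.outcomes[outcome]
    elif outcome.startswith("new_") and f"any_{outcome[4:]}" in cfg.outcomes:
        # incident outcomes share the any-attendance generating weights,
        # restricted to the non-prevalent stratum via their labels
        model = cfg.outcomes[f"any_{outcome[4:]}"]
    else:
        raise KeyError(f"unknown outcome {outcome!r}")
    hist = cohort.history_events
    cat_tokens = [_cat(i) for i in range(cfg.category_vocab_size)]
    cat_of = {t: i for i, t in enumerate(cat_tokens)}
    pid_of = {p: i for i, p in enumerate(cohort.records["patient_id"])}
    pid = hist["patient_id"].map(pid_of).to_numpy()
    day = (hist["event_date"] - cfg.index_ts).dt.days.to_numpy()
    cat = hist["disease"].map(cat_of).to_numpy()
    presence, first_day, recency = _history_facts(cfg, pid, day, cat)
    rec = cohort.records
    age = ((cfg.index_ts - rec["birth_date"]).dt.days / DAYS_PER_YEAR).to_numpy()
    _, X, names = _outcome_eta(model, cfg, presence, first_day, recency,
                               age, rec["gender"].to_numpy(),
                               rec["imd_decile"].to_numpy(dtype=float))
    labels = cohort.outcomes[outcome].to_numpy(dtype=float)
    keep = ~np.isnan(labels)
    weights = ([w for w in model.presence_weights.values()]
               + [w for _, _, w in model.order_weights]
               + [w for w in model.recency_weights.values()]
               + [model.age_weight, model.female_weight, model.imd_weight])
    ids = rec["patient_id"].to_numpy()[keep]
    return ids, X[keep], names, np.array(weights)


# --------------------------------------------------------------------------
# main entry point


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a full synthetic cohort under ``config``.

    Deterministic given ``config.rng_seed``.  Raises
    :class:`SimulationError` when a configured target event rate cannot be
    met (naming the outcome).
    """
    cfg = config
    rng = np.random.default_rng(cfg.rng_seed)
    n = cfg.n_patients
    index = cfg.index_ts

    age, gender, ethnicity, imd = _draw_demographics(cfg, rng)
    birth = index - pd.to_timedelta(np.round(age * DAYS_PER_YEAR), unit="D")

    # registration: a small fraction registered recently (within 2y of index),
    # the rest uniformly 2-40 years before index, never before birth
    reg_years = rng.uniform(2.0, 40.0, size=n)
    recent = rng.random(n) < cfg.frac_recent_registration
    reg_years[recent] = rng.uniform(0.05, 2.0, size=int(recent.sum()))
    reg_days = np.round(reg_years * DAYS_PER_YEAR)
    registration = index - pd.to_timedelta(reg_days, unit="D")
    registration = pd.Series(np.maximum(registration, birth))

    pid_i, day, code_id, code_cat = _simulate_history(cfg, rng, age, imd)
    cat_id = code_cat[code_id]

    presence, first_day, recency = _history_facts(cfg, pid_i, day, cat_id)

    # ---- outcome generation -------------------------------------------------
    labels: dict[str, np.ndarray] = {}
    age60 = age >= 60.0
    death_in_window = np.zeros(n, dtype=bool)
    outcome_order: list[str] = []

    for name, model in cfg.outcomes.items():
        outcome_order.append(name)
        eta, _, _ = _outcome_eta(model, cfg, presence, first_day, recency,
                                 age, gender, imd)
        if model.kind == "mortality":
            b0 = _calibrate_intercept(eta[age60], model.target_rate, name)
            p = 1.0 / (1.0 + np.exp(-(eta + b0)))
            died = rng.random(n) < p
            death_in_window = died
            lab = np.where(age60, died.astype(float), np.nan)
        elif model.kind == "disease":
            d_idx = int(model.disease[1:])
            prevalent = presence[:, d_idx]
            nonprev = ~prevalent
            if model.new_target_rate is None:
                raise SimulationError(
                    f"outcome {name!r}: disease outcomes need new_target_rate")
            b_new = _calibrate_intercept(eta[nonprev], model.new_target_rate,
                                         name)
            p_new = 1.0 / (1.0 + np.exp(-(eta + b_new)))
            n_prev = int(prevalent.sum())
            if n_prev == 0:
                raise SimulationError(
                    f"outcome {name!r}: no prevalent patients for disease "
                    f"{model.disease}; any-rate target unreachable")
            need_prev = (model.target_rate * n
                         - model.new_target_rate * (n - n_prev)) / n_prev
            if not 0.0 < need_prev < 1.0:
                raise SimulationError(
                    f"outcome {name!r}: any-attendance target "
                    f"{model.target_rate} not attainable given prevalence "
                    f"{n_prev / n:.3f} and incident target "
                    f"{model.new_target_rate}")
            b_prev = _calibrate_intercept(eta[prevalent], need_prev, name)
            p_prev = 1.0 / (1.0 + np.exp(-(eta + b_prev)))
            attend = np.where(prevalent,
                              rng.random(n) < p_prev,
                              rng.random(n) < p_new)
            lab = attend.astype(float)
            labels[name.replace("any_", "new_")] = np.where(
                nonprev, attend.astype(float), np.nan)
        else:
            b0 = _calibrate_intercept(eta, model.target_rate, name)
            p = 1.0 / (1.0 + np.exp(-(eta + b0)))
            lab = (rng.random(n) < p).astype(float)
        labels[name] = lab

    # ---- dates and follow-up events ----------------------------------------
    fu = cfg.followup_days
    prior_death = rng.random(n) < cfg.prior_death_rate
    death_date = pd.Series(pd.NaT, index=range(n), dtype="datetime64[ns]")
    dd = rng.integers(0, fu, size=n)
    death_date[death_in_window] = index + pd.to_timedelta(
        dd[death_in_window], unit="D")
    pre_dd = rng.integers(1, 3 * 365, size=n)
    death_date[prior_death] = index - pd.to_timedelta(pre_dd[prior_death],
                                                      unit="D")
    dereg = (rng.random(n) < cfg.dereg_rate) & ~prior_death
    dereg_date = pd.Series(pd.NaT, index=range(n), dtype="datetime64[ns]")
    rd = rng.integers(0, fu, size=n)
    dereg_date[dereg] = index + pd.to_timedelta(rd[dereg], unit="D")

    # patients dead before index carry no outcome labels
    for name in labels:
        labels[name] = np.where(prior_death, np.nan, labels[name])
    death_in_window = death_in_window & ~prior_death

    pids = np.array([f"p{i:07d}" for i in range(n)])

    fu_pid, fu_day, fu_code, fu_cat = [], [], [], []
    cat_codes = [np.flatnonzero(code_cat == c)
                 for c in range(cfg.category_vocab_size)]
    for name, model in cfg.outcomes.items():
        lab = labels[name]
        pos = np.flatnonzero((lab == 1.0) & ~prior_death)
        if model.kind == "mortality":
            continue  # death is recorded on the patient record
        if model.kind == "utilisation":
            code = ED_CODE if name == "ed_attendance" else ADMISSION_CODE
            catn = (ED_CATEGORY if name == "ed_attendance"
                    else ADMISSION_CATEGORY)
            d = rng.integers(0, fu, size=len(pos))
            fu_pid.extend(pos)
            fu_day.extend(d)
            fu_code.extend([code] * len(pos))
            fu_cat.extend([catn] * len(pos))
        else:
            d_idx = int(model.disease[1:])
            codes = cat_codes[d_idx]
            k = 1 + rng.poisson(cfg.mean_followup_disease_events,
                                size=len(pos))
            for j, i in enumerate(pos):
                d = rng.integers(0, fu, size=k[j])
                c = rng.choice(codes, size=k[j])
                fu_pid.extend([i] * k[j])
                fu_day.extend(d)
                fu_code.extend(f"m{ci:04d}" for ci in c)
                fu_cat.extend([model.disease] * k[j])

    records = pd.DataFrame({
        "patient_id": pids,
        "birth_date": birth,
        "gender": gender,
        "ethnicity": ethnicity,
        "imd_decile": imd,
        "registration_date": registration.to_numpy(),
        "deregistration_date": dereg_date.to_numpy(),
        "death_date": death_date.to_numpy(),
    })

    hist_events = pd.DataFrame({
        "patient_id": pids[pid_i],
        "event_date": index + pd.to_timedelta(day, unit="D"),
        "medcode": [f"m{c:04d}" for c in code_id],
        "disease": [_cat(c) for c in cat_id],
    })
    fu_events = pd.DataFrame({
        "patient_id": pids[np.array(fu_pid, dtype=int)] if fu_pid else
        np.array([], dtype=str),
        "event_date": index + pd.to_timedelta(np.array(fu_day, dtype="int64"),
                                              unit="D"),
        "medcode": fu_code,
        "disease": fu_cat,
    })
    events = pd.concat([hist_events, fu_events], ignore_index=True)
    events = events.sort_values(
        ["patient_id", "event_date", "medcode"]).reset_index(drop=True)

    code_map = pd.DataFrame({
        "medcode": [f"m{c:04d}" for c in range(cfg.fine_vocab_size)],
        "disease": [_cat(c) for c in code_cat],
    })

    out = pd.DataFrame({"patient_id": pids})
    for name in labels:
        out[name] = labels[name]

    return SimulatedCohort(records=records, events=events, code_map=code_map,
                           outcomes=out, config=cfg)


# --------------------------------------------------------------------------
# serialization

_RECORD_DATE_COLS = ["birth_date", "registration_date",
                     "deregistration_date", "death_date"]


def write_cohort(records: pd.DataFrame, events: pd.DataFrame,
                 code_map: pd.DataFrame, path: str | Path,
                 outcomes: pd.DataFrame | None = None) -> None:
    """Write cohort tables as CSV under ``path`` (ISO-8601 dates)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    r = records.copy()
    for c in _RECORD_DATE_COLS:
        r[c] = pd.to_datetime(r[c]).dt.strftime("%Y-%m-%d")
    r.to_csv(path / "patients.csv", index=False)
    e = events.copy()
    e["event_date"] = pd.to_datetime(e["event_date"]).dt.strftime("%Y-%m-%d")
    e.to_csv(path / "events.csv", index=False)
    code_map.to_csv(path / "code_map.csv", index=False)
    if outcomes is not None:
        outcomes.to_csv(path / "outcomes.csv", index=False)


def read_cohort(path: str | Path):
    """Read cohort tables written by :func:`write_cohort`.

    Returns ``(records, events, code_map)`` and validates the schema: date
    ordering invariants per patient, and that every history medcode is in the
    map (follow-up utilisation markers are exempt).
    """
    path = Path(path)
    records = pd.read_csv(path / "patients.csv",
                          parse_dates=_RECORD_DATE_COLS)
    events = pd.read_csv(path / "events.csv", parse_dates=["event_date"])
    if events.empty:
        events = pd.DataFrame(columns=["patient_id", "event_date", "medcode",
                                       "disease"])
    code_map = pd.read_csv(path / "code_map.csv")

    for col in ["patient_id", "birth_date", "registration_date"]:
        if records[col].isna().any():
            raise SimulationError(f"patients.csv: column {col!r} has missing "
                                  "values")
    bad = records["registration_date"] < records["birth_date"]
    if bad.any():
        raise SimulationError(
            "patients.csv: registration_date before birth_date for "
            f"{records.loc[bad, 'patient_id'].iloc[0]!r}")
    known = set(code_map["medcode"]) | {ED_CODE, ADMISSION_CODE}
    unknown = set(events["medcode"]) - known
    if unknown:
        raise SimulationError(
            f"events.csv: medcode {sorted(unknown)[0]!r} is not in the code "
            "map")
    return records, events, code_map
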