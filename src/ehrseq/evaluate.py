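"""Outcome cohorts and the fixed logistic evaluation harness.

Nine 1-year binary outcomes are supported: mortality in the 60+ stratum,
any emergency-department attendance, any emergency admission, any attendance
with hypertension/diabetes/depression, and new (incident) diagnoses of the
same three diseases.  Cohort rules: patients deregistering during follow-up
are removed for every outcome; patients dying during follow-up are removed
for every non-mortality outcome; incident-disease cohorts drop patients with
the disease in history; the mortality cohort is restricted to age >= 60 at
the index date.

Every representation is scored by the same classifier: logistic regression
with L2 penalty (inverse regularization strength ``C = 1``), at most 100
iterations, stratified 4-fold cross-validation.  Embedding features are
standardized on each training fold only; sociodemographic one-hot covariates
are appended unless the harness is run embeddings-only.  Reported metrics
are pooled out-of-fold ROC-AUC and average precision (plus per-fold values),
and sensitivity/specificity/PPV/NPV at requested sensitivity thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from ehrseq.containers import EmbeddingSet
from ehrseq.simulate import ED_CATEGORY, ADMISSION_CATEGORY

__all__ = ["OutcomeSpec", "OUTCOMES", "EvalConfig", "EvalResult",
           "build_outcome_cohort", "evaluate_representation",
           "run_comparison", "threshold_metrics"]


@dataclass(frozen=True)
class OutcomeSpec:
    """Eligibility and labelling rule for one binary 1-year outcome."""

    name: str
    kind: str  # {"mortality", "utilisation", "any_disease", "new_disease"}
    disease: str | None = None  # category token (utilisation: marker name)
    min_age: float | None = None


def outcome_specs(hypertension: str = "d000", diabetes: str = "d001",
                  depression: str = "d002") -> dict[str, OutcomeSpec]:
    """The nine outcome specifications, keyed by name.

    Disease outcomes are parameterized by which category token plays each
    disease (defaults match the simulator's convention).
    """
    specs = [
        OutcomeSpec("mortality_60plus", "mortality", min_age=60.0),
        OutcomeSpec("ed_attendance", "utilisation", ED_CATEGORY),
        OutcomeSpec("emergency_admission", "utilisation", ADMISSION_CATEGORY),
        OutcomeSpec("any_hypertension", "any_disease", hypertension),
        OutcomeSpec("any_diabetes", "any_disease", diabetes),
        OutcomeSpec("any_depression", "any_disease", depression),
        OutcomeSpec("new_hypertension", "new_disease", hypertension),
        OutcomeSpec("new_diabetes", "new_disease", diabetes),
        OutcomeSpec("new_depression", "new_disease", depression),
    ]
    return {s.name: s for s in specs}


OUTCOMES = outcome_specs()


def build_outcome_cohort(records: pd.DataFrame,
                         followup_events: pd.DataFrame,
                         spec: OutcomeSpec,
                         index_date: str | pd.Timestamp,
                         history_events: pd.DataFrame | None = None,
                         followup_days: int = 365,
                         eligible_ids: set[str] | None = None) -> pd.Series:
    """Binary labels for one outcome, indexed by patient_id.

    ``history_events`` is required for incident-disease outcomes (prevalent
    cases must be excluded).  ``eligible_ids`` optionally restricts to a
    pre-computed analysis cohort (e.g. from
    :func:`ehrseq.sequences.eligible_cohort`).
    """
    if isinstance(spec, str):
        try:
            spec = OUTCOMES[spec]
        except KeyError:
            raise KeyError(f"unknown outcome name {spec!r}") from None
    index_date = pd.Timestamp(index_date)
    end = index_date + pd.Timedelta(days=followup_days)
    rec = records.copy()
    rec["patient_id"] = rec["patient_id"].astype(str)
    death = pd.to_datetime(rec["death_date"], errors="coerce")
    dereg = pd.to_datetime(rec["deregistration_date"], errors="coerce")

    keep = np.ones(len(rec), dtype=bool)
    # equal follow-up time: drop within-window deregistrations, all outcomes
    keep &= ~(dereg.notna() & (dereg >= index_date) & (dereg < end))
    keep &= ~(death.notna() & (death < index_date))  # dead before index
    if spec.kind != "mortality":
        keep &= ~(death.notna() & (death >= index_date) & (death < end))
    if spec.min_age is not None:
        age = ((index_date - pd.to_datetime(rec["birth_date"])).dt.days
               / 365.25)
        keep &= age >= spec.min_age

    cohort = rec.loc[keep, "patient_id"]
    if eligible_ids is not None:
        cohort = cohort[cohort.isin(eligible_ids)]

    if spec.kind == "new_disease":
        if history_events is None:
            raise ValueError(
                f"outcome {spec.name!r} needs history_events to exclude "
                "prevalent cases")
        prevalent = set(history_events.loc[
            history_events["disease"] == spec.disease, "patient_id"
        ].astype(str))
        cohort = cohort[~cohort.isin(prevalent)]

    if spec.kind == "mortality":
        d = death[cohort.index]
        labels = (d.notna() & (d >= index_date) & (d < end)).astype(int)
    else:
        fu = followup_events
        dates = pd.to_datetime(fu["event_date"])
        hits = fu.loc[(fu["disease"] == spec.disease)
                      & (dates >= index_date) & (dates < end), "patient_id"]
        pos = set(hits.astype(str))
        labels = cohort.isin(pos).astype(int)
    labels.index = pd.Index(cohort.to_numpy(), name="patient_id")
    labels.name = spec.name
    return labels


@dataclass
class EvalConfig:
    n_folds: int = 4
    C: float = 1.0  # inverse L2 regularization strength
    max_iter: int = 100
    seed: int = 0
    embeddings_only: bool = False  # sensitivity analysis: drop covariates
    sensitivities: tuple[float, ...] = (0.4, 0.7, 0.9)


@dataclass
class EvalResult:
    """Metrics for one outcome x representation pair."""

    outcome: str
    representation: str
    pooled_auc: float
    pooled_aps: float
    fold_auc: list[float]
    fold_aps: list[float]
    threshold_table: pd.DataFrame
    n: int
    n_events: int
    oof_scores: pd.Series = field(repr=False, default=None)

    @property
    def event_rate(self) -> float:
        return self.n_events / self.n

    def summary(self) -> str:
        lines = [
            f"outcome {self.outcome} | representation {self.representation}",
            f"  n = {self.n}, events = {self.n_events} "
            f"({100 * self.event_rate:.1f}%)",
            f"  pooled out-of-fold ROC-AUC = {self.pooled_auc:.3f} "
            f"(folds: {', '.join(f'{a:.3f}' for a in self.fold_auc)})",
            f"  pooled out-of-fold APS     = {self.pooled_aps:.3f} "
            f"(folds: {', '.join(f'{a:.3f}' for a in self.fold_aps)})",
            self.threshold_table.to_string(index=False),
        ]
        return "\n".join(lines)


def threshold_metrics(tp: int, fn: int, fp: int, tn: int) -> dict[str, float]:
    """Sensitivity/specificity/PPV/NPV from a confusion table (percent)."""
    return {
        "sensitivity": 100.0 * tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": 100.0 * tn / (tn + fp) if tn + fp else float("nan"),
        "ppv": 100.0 * tp / (tp + fp) if tp + fp else float("nan"),
        "npv": 100.0 * tn / (tn + fn) if tn + fn else float("nan"),
    }


def _threshold_table(y: np.ndarray, scores: np.ndarray,
                     sensitivities: tuple[float, ...]) -> pd.DataFrame:
    fpr, tpr, thr = roc_curve(y, scores)
    rows = []
    for s in sensitivities:
        i = int(np.searchsorted(tpr, s))  # first threshold reaching sens >= s
        i = min(i, len(thr) - 1)
        t = thr[i]
        pred = scores >= t
        tp = int(((pred == 1) & (y == 1)).sum())
        fp = int(((pred == 1) & (y == 0)).sum())
        fn = int(((pred == 0) & (y == 1)).sum())
        tn = int(((pred == 0) & (y == 0)).sum())
        row = {"target_sensitivity": 100.0 * s}
        row.update(threshold_metrics(tp, fn, fp, tn))
        rows.append(row)
    return pd.DataFrame(rows)


def evaluate_representation(embeddings: EmbeddingSet,
                            covariates: pd.DataFrame | None,
                            labels: pd.Series,
                            config: EvalConfig | None = None,
                            representation: str | None = None) -> EvalResult:
    """Score one representation on one outcome with the fixed classifier.

    Embeddings, covariates and labels are aligned on patient_id; patients
    missing an embedding are dropped from the cohort (they had no valid
    sequence).  Raises when a fold ends up single-class, naming outcome and
    fold.
    """
    config = config or EvalConfig()
    ids = [p for p in labels.index if p in set(embeddings.ids)]
    y = labels.loc[ids].to_numpy(dtype=int)
    X_emb = embeddings.align(ids)
    if config.embeddings_only or covariates is None:
        X_cov = np.zeros((len(ids), 0))
    else:
        X_cov = covariates.loc[ids].to_numpy(dtype=float)
    name = representation or embeddings.method

    if len(np.unique(y)) < 2:
        raise ValueError(
            f"outcome {labels.name!r}: only one class present overall")

    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True,
                          random_state=config.seed)
    oof = np.zeros(len(y))
    fold_auc, fold_aps = [], []
    for fold, (tr, te) in enumerate(skf.split(X_emb, y)):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            raise ValueError(
                f"outcome {labels.name!r}, fold {fold}: single-class fold; "
                "the outcome is too rare for stratified "
                f"{config.n_folds}-fold CV at n={len(y)}")
        scaler = StandardScaler().fit(X_emb[tr])
        Xtr = np.hstack([scaler.transform(X_emb[tr]), X_cov[tr]])
        Xte = np.hstack([scaler.transform(X_emb[te]), X_cov[te]])
        # L2 penalty (sklearn's default) with inverse strength C
        clf = LogisticRegression(C=config.C, max_iter=config.max_iter,
                                 solver="lbfgs")
        clf.fit(Xtr, y[tr])
        p = clf.predict_proba(Xte)[:, 1]
        oof[te] = p
        fold_auc.append(float(roc_auc_score(y[te], p)))
        fold_aps.append(float(average_precision_score(y[te], p)))

    return EvalResult(
        outcome=str(labels.name),
        representation=name,
        pooled_auc=float(roc_auc_score(y, oof)),
        pooled_aps=float(average_precision_score(y, oof)),
        fold_auc=fold_auc,
        fold_aps=fold_aps,
        threshold_table=_threshold_table(y, oof, config.sensitivities),
        n=len(y),
        n_events=int(y.sum()),
        oof_scores=pd.Series(oof, index=pd.Index(ids, name="patient_id")),
    )


@dataclass
class ComparisonResult:
    table: pd.DataFrame  # long format: outcome, representation, metric, ...
    results: dict[tuple[str, str], EvalResult]
    missing: list[tuple[str, str]]

    def ranking(self, outcome: str, metric: str = "pooled_auc"
                ) -> pd.DataFrame:
        t = self.table
        sub = t[(t["outcome"] == outcome) & (t["metric"] == metric)
                & (t["fold"] == "pooled")]
        return sub.sort_values("value", ascending=False).reset_index(drop=True)

    def to_markdown(self) -> str:
        lines = ["# Representation comparison", ""]
        for outcome in self.table["outcome"].unique():
            lines.append(f"## {outcome}")
            r = self.ranking(outcome)[["representation", "value"]]
            a = self.ranking(outcome, "pooled_aps")[["representation",
                                                     "value"]]
            merged = r.merge(a, on="representation",
                             suffixes=("_auc", "_aps"))
            lines.append(merged.round(4).to_markdown(index=False))
            lines.append("")
        if self.missing:
            lines.append("Missing combinations: "
                         + ", ".join(f"{o}/{r}" for o, r in self.missing))
        return "\n".join(lines)


def run_comparison(embeddings: dict[str, EmbeddingSet],
                   covariates: pd.DataFrame | None,
                   cohorts: dict[str, pd.Series],
                   config: EvalConfig | None = None) -> ComparisonResult:
    """Evaluate every representation on every outcome cohort.

    A representation that cannot be evaluated for an outcome (no overlapping
    patients) is recorded as missing rather than failing the run.
    """
    rows, results, missing = [], {}, []
    for outcome, labels in cohorts.items():
        for name, emb in embeddings.items():
            overlap = set(labels.index) & set(emb.ids)
            if not overlap:
                missing.append((outcome, name))
                continue
            res = evaluate_representation(emb, covariates, labels, config,
                                          representation=name)
            results[(outcome, name)] = res
            for metric, pooled, folds in [
                ("pooled_auc", res.pooled_auc, res.fold_auc),
                ("pooled_aps", res.pooled_aps, res.fold_aps),
            ]:
                rows.append({"outcome": outcome, "representation": name,
                             "metric": metric, "fold": "pooled",
                             "value": pooled})
                for f, v in enumerate(folds):
                    rows.append({"outcome": outcome, "representation": name,
                                 "metric": metric, "fold": str(f),
                                 "value": v})
    table = pd.DataFrame(rows)
    return ComparisonResult(table=table, results=results, missing=missing)
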