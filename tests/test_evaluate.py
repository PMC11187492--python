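"""Outcome cohorts and the logistic evaluation harness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ehrseq.containers import EmbeddingSet
from ehrseq.evaluate import (EvalConfig, OUTCOMES, OutcomeSpec,
                             build_outcome_cohort, evaluate_representation,
                             run_comparison, threshold_metrics)
from tests.conftest import make_records

INDEX = pd.Timestamp("2015-01-01")


def followup(rows):
    df = pd.DataFrame(rows, columns=["patient_id", "event_date", "medcode",
                                     "disease"])
    df["event_date"] = pd.to_datetime(df["event_date"])
    return df


def cohort_fixture():
    """Twelve patients: 2 deregister in-window, 1 dies in-window, 3 have
    prevalent hypertension."""
    ok = {"birth_date": "1960-01-01", "registration_date": "2000-01-01"}
    rows = [dict(patient_id=f"p{i:02d}", **ok) for i in range(12)]
    rows[0]["deregistration_date"] = "2015-03-01"
    rows[1]["deregistration_date"] = "2015-11-30"
    rows[2]["death_date"] = "2015-06-15"
    records = make_records(rows)
    history = followup([
        (f"p{i:02d}", "2010-05-01", "m_htn", "hypertension")
        for i in (3, 4, 5)])
    fu = followup([
        ("p06", "2015-02-01", "m_htn", "hypertension"),
        ("p03", "2015-04-01", "m_htn", "hypertension"),
    ])
    return records, history, fu


def test_new_disease_cohort_applies_all_exclusions():
    records, history, fu = cohort_fixture()
    spec = OutcomeSpec("new_hypertension", "new_disease", "hypertension")
    labels = build_outcome_cohort(records, fu, spec, INDEX,
                                  history_events=history)
    # 12 - 2 deregistered - 1 died - 3 prevalent = 6
    assert len(labels) == 6
    assert labels["p06"] == 1  # incident case
    assert labels.drop("p06").sum() == 0


def test_any_disease_retains_prevalent_cases():
    records, history, fu = cohort_fixture()
    spec = OutcomeSpec("any_hypertension", "any_disease", "hypertension")
    labels = build_outcome_cohort(records, fu, spec, INDEX,
                                  history_events=history)
    assert "p03" in labels.index and labels["p03"] == 1
    assert len(labels) == 9  # only dereg/death exclusions apply


def test_mortality_cohort_restricted_to_60_plus():
    rows = [
        {"patient_id": "a59", "birth_date": "1955-06-01",  # 59 at index
         "registration_date": "2000-01-01"},
        {"patient_id": "a60", "birth_date": "1954-12-31",  # just 60
         "registration_date": "2000-01-01", "death_date": "2015-08-01"},
        {"patient_id": "a75", "birth_date": "1939-01-01",
         "registration_date": "2000-01-01"},
    ]
    records = make_records(rows)
    spec = OUTCOMES["mortality_60plus"]
    labels = build_outcome_cohort(records, followup([]), spec, INDEX)
    assert set(labels.index) == {"a60", "a75"}
    assert labels["a60"] == 1 and labels["a75"] == 0


def test_deaths_in_window_kept_for_mortality_dropped_elsewhere():
    records, history, fu = cohort_fixture()
    ed = build_outcome_cohort(records, fu, OUTCOMES["ed_attendance"], INDEX)
    assert "p02" not in ed.index


def test_new_disease_without_history_errors():
    records, _, fu = cohort_fixture()
    spec = OutcomeSpec("new_hypertension", "new_disease", "hypertension")
    with pytest.raises(ValueError, match="history"):
        build_outcome_cohort(records, fu, spec, INDEX)


def test_unknown_outcome_name_errors():
    records, _, fu = cohort_fixture()
    with pytest.raises(KeyError, match="readmission"):
        build_outcome_cohort(records, fu, "readmission", INDEX)


# ---------------------------------------------------------------------------
# classifier harness


def labelled_embedding(rng, n=2000, dim=5, prevalence=0.1,
                       informative=False):
    ids = [f"p{i}" for i in range(n)]
    X = rng.normal(size=(n, dim))
    if informative:
        y = (X[:, 0] > np.quantile(X[:, 0], 1 - prevalence)).astype(int)
    else:
        y = (rng.random(n) < prevalence).astype(int)
    emb = EmbeddingSet(ids=ids, X=X, method="test")
    labels = pd.Series(y, index=pd.Index(ids, name="patient_id"),
                       name="outcome")
    return emb, labels


def test_perfectly_separable_fixture_scores_one(rng):
    emb, labels = labelled_embedding(rng, n=800, informative=True)
    res = evaluate_representation(emb, None, labels, EvalConfig(seed=0))
    assert res.pooled_auc == pytest.approx(1.0, abs=5e-3)
    assert res.pooled_aps == pytest.approx(1.0, abs=5e-2)


def test_uninformative_scores_near_chance(rng):
    emb, labels = labelled_embedding(rng, n=20_000, prevalence=0.1)
    res = evaluate_representation(emb, None, labels, EvalConfig(seed=1))
    assert abs(res.pooled_auc - 0.5) < 0.02
    assert abs(res.pooled_aps - 0.1) < 0.01


def test_constant_score_aps_equals_prevalence_exactly():
    from sklearn.metrics import average_precision_score
    y = np.array([0] * 90 + [1] * 10)
    aps = average_precision_score(y, np.full(100, 0.3))
    assert aps == pytest.approx(0.1, abs=1e-12)


def test_threshold_metrics_on_printed_confusion_table():
    m = threshold_metrics(tp=40, fn=60, fp=129, tn=771)
    assert m["sensitivity"] == pytest.approx(40.0)
    assert m["ppv"] == pytest.approx(23.7, abs=0.05)  # 40/169
    assert m["specificity"] == pytest.approx(100 * 771 / 900, abs=1e-9)
    assert m["npv"] == pytest.approx(100 * 771 / 831, abs=1e-9)


def test_threshold_table_hits_requested_sensitivities(rng):
    emb, labels = labelled_embedding(rng, n=4000, prevalence=0.2,
                                     informative=True)
    res = evaluate_representation(emb, None, labels, EvalConfig(seed=2))
    tab = res.threshold_table
    assert list(tab["target_sensitivity"]) == [40.0, 70.0, 90.0]
    assert (tab["sensitivity"] >= tab["target_sensitivity"] - 1e-9).all()


@settings(max_examples=10, deadline=None)
@given(st.sampled_from(["exp", "logit", "cube", "affine"]))
def test_auc_invariant_under_monotone_transforms(transform):
    from sklearn.metrics import roc_auc_score
    rng = np.random.default_rng(4)
    y = rng.integers(0, 2, size=300)
    s = rng.random(300)
    f = {"exp": np.exp, "logit": lambda x: np.log(x / (1 - x + 1e-9)),
         "cube": lambda x: x ** 3, "affine": lambda x: 5 * x - 2}[transform]
    assert roc_auc_score(y, f(s)) == pytest.approx(roc_auc_score(y, s),
                                                   abs=1e-12)


def test_fold_assignment_deterministic_and_stratified(rng):
    emb, labels = labelled_embedding(rng, n=1000, prevalence=0.1)
    r1 = evaluate_representation(emb, None, labels, EvalConfig(seed=5))
    r2 = evaluate_representation(emb, None, labels, EvalConfig(seed=5))
    assert np.array_equal(r1.oof_scores.to_numpy(),
                          r2.oof_scores.to_numpy())
    # per-fold positives differ by at most 1 under stratification
    from sklearn.model_selection import StratifiedKFold
    y = labels.to_numpy()
    counts = [y[te].sum() for _, te in
              StratifiedKFold(4, shuffle=True,
                              random_state=5).split(emb.X, y)]
    assert max(counts) - min(counts) <= 1


def test_single_class_outcome_raises_with_name(rng):
    emb, labels = labelled_embedding(rng, n=200, prevalence=0.0)
    with pytest.raises(ValueError, match="outcome"):
        evaluate_representation(emb, None, labels, EvalConfig(seed=0))


def test_covariates_are_appended_unless_embeddings_only(rng):
    emb, labels = labelled_embedding(rng, n=5000, prevalence=0.3)
    # covariate equal to the label: with covariates AUC ~ 1
    cov = pd.DataFrame({"leak": labels.to_numpy().astype(float)},
                       index=labels.index)
    with_cov = evaluate_representation(emb, cov, labels, EvalConfig(seed=0))
    without = evaluate_representation(
        emb, cov, labels, EvalConfig(seed=0, embeddings_only=True))
    assert with_cov.pooled_auc > 0.99
    assert abs(without.pooled_auc - 0.5) < 0.05


def test_run_comparison_table_and_ranking(rng):
    emb_good, labels = labelled_embedding(rng, n=1200, prevalence=0.2,
                                          informative=True)
    emb_bad = EmbeddingSet(ids=emb_good.ids,
                           X=rng.normal(size=(1200, 3)), method="noise")
    other = EmbeddingSet(ids=[f"q{i}" for i in range(10)],
                         X=rng.normal(size=(10, 3)), method="disjoint")
    result = run_comparison(
        {"good": emb_good, "noise": emb_bad, "disjoint": other},
        None, {"outcome": labels}, EvalConfig(seed=0))
    ranked = result.ranking("outcome")
    assert list(ranked["representation"])[:1] == ["good"]
    assert ("outcome", "disjoint") not in result.results
    assert ("outcome", "disjoint") in result.missing
    assert {"pooled", "0", "1", "2", "3"} <= set(result.table["fold"])
    assert "## outcome" in result.to_markdown()
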