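"""Non-NLP comparator representations.

Binary disease indicators (1 if a category ever occurs in history), disease
frequency counts (number of occurrences), and a one-hot sociodemographic
covariate block (age band, gender, ethnicity, deprivation decile, with
explicit missing levels).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ehrseq.containers import EmbeddingSet
from ehrseq.sequences import PatientSequence

__all__ = [
    "binary_indicators",
    "frequency_counts",
    "sociodemographic_features",
    "AGE_BANDS",
]

AGE_BANDS = ("18-29", "30-39", "40-49", "50-59", "60-69", "70-79", "80+")
GENDERS = ("female", "male", "indeterminate")
ETHNICITIES = ("White", "South Asian", "Black", "Other", "Mixed", "missing")


def _category_matrix(sequences: dict[str, PatientSequence],
                     categories: list[str], counts: bool) -> EmbeddingSet:
    for s in sequences.values():
        if s.vocabulary_tag != "diseases":
            raise ValueError(
                "binary indicators / frequency counts are defined at the "
                "disease-category level; got a "
                f"{s.vocabulary_tag!r}-vocabulary sequence")
    cat_idx = {c: j for j, c in enumerate(categories)}
    ids = list(sequences)
    X = np.zeros((len(ids), len(categories)))
    for i, pid in enumerate(ids):
        for t in sequences[pid].tokens:
            j = cat_idx.get(t)
            if j is None:
                raise ValueError(f"token {t!r} not in the category list")
            if counts:
                X[i, j] += 1.0
            else:
                X[i, j] = 1.0
    return EmbeddingSet(ids=ids, X=X,
                        method="counts" if counts else "binary",
                        vocabulary_tag="diseases",
                        feature_names=list(categories))


def binary_indicators(sequences: dict[str, PatientSequence],
                      categories: list[str]) -> EmbeddingSet:
    """Per-patient binary presence of each disease category.

    The representation dimension equals ``len(categories)`` regardless of
    which categories actually occur, so cohorts with different disease mixes
    stay comparable.
    """
    return _category_matrix(sequences, categories, counts=False)


def frequency_counts(sequences: dict[str, PatientSequence],
                     categories: list[str]) -> EmbeddingSet:
    """Per-patient occurrence count of each disease category."""
    return _category_matrix(sequences, categories, counts=True)


def age_band(age_years: float) -> str:
    if age_years < 18:
        raise ValueError(f"age {age_years:.1f} is below the adult cohort "
                         "threshold of 18")
    if age_years < 30:
        return "18-29"
    if age_years >= 80:
        return "80+"
    lo = int(age_years // 10) * 10
    return f"{lo}-{lo + 9}"


def sociodemographic_features(records: pd.DataFrame,
                              index_date: str | pd.Timestamp) -> pd.DataFrame:
    """One-hot covariate block per patient at the index date.

    Categorical blocks: age band {18-29, ..., 80+}, gender, ethnicity
    (including an explicit missing level), IMD decile 1..10 plus a missing
    level.  Each block sums to exactly 1 per patient; missingness is encoded,
    never dropped.
    """
    index_date = pd.Timestamp(index_date)
    age = ((index_date - pd.to_datetime(records["birth_date"])).dt.days
           / 365.25).to_numpy()
    if (age < 18).any():
        bad = records.loc[age < 18, "patient_id"].iloc[0]
        raise ValueError(
            f"patient {bad!r} is aged under 18 at the index date; the cohort "
            "is adults only")
    bands = [age_band(a) for a in age]
    out = {}
    for b in AGE_BANDS:
        out[f"age:{b}"] = np.array([x == b for x in bands], dtype=float)
    for g in GENDERS:
        out[f"gender:{g}"] = (records["gender"] == g).to_numpy(dtype=float)
    for e in ETHNICITIES:
        out[f"ethnicity:{e}"] = (records["ethnicity"] == e).to_numpy(dtype=float)
    imd = pd.to_numeric(records["imd_decile"], errors="coerce")
    for d in range(1, 11):
        out[f"imd:{d}"] = (imd == d).to_numpy(dtype=float)
    out["imd:missing"] = imd.isna().to_numpy(dtype=float)
    return pd.DataFrame(out, index=pd.Index(records["patient_id"].astype(str),
                                            name="patient_id"))
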