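"""Tokenized, time-ordered code sequences and cohort eligibility rules.

Dated coded events become one token sequence per patient, in either of two
vocabularies: coarse disease categories or fine-grained codes.  Patients need
at least 2 tokens; sequences longer than ``max_len`` keep the most recent
``max_len`` codes.  Same-date events are ordered by medcode lexicographically
(a deterministic tie-break; recorded here because source data carry no
within-day ordering).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "PatientSequence",
    "TokenVocabulary",
    "SequenceError",
    "build_sequences",
    "eligible_cohort",
    "write_sequences",
    "read_sequences",
]

PAD, UNK, CLS, SEP, MASK = "[PAD]", "[UNK]", "[CLS]", "[SEP]", "[MASK]"
SPECIAL_TOKENS = (PAD, UNK, CLS, SEP, MASK)


class SequenceError(ValueError):
    """Raised on malformed event input (unmapped codes, post-index events)."""


@dataclass
class PatientSequence:
    """One patient's ordered token sequence with per-position context."""

    patient_id: str
    vocabulary_tag: str  # "diseases" | "medcodes"
    tokens: list[str]
    visit_index: list[int]  # 1-based, increments per distinct event date
    age_years: list[int]
    calendar_year: list[int]

    def __post_init__(self) -> None:
        n = len(self.tokens)
        if not (len(self.visit_index) == len(self.age_years)
                == len(self.calendar_year) == n):
            raise SequenceError(
                f"patient {self.patient_id}: parallel arrays differ in length")

    def __len__(self) -> int:
        return len(self.tokens)


class TokenVocabulary:
    """Dense token→index map with reserved special-token slots 0..4."""

    def __init__(self, tokens: list[str]):
        for t in tokens:
            if t in SPECIAL_TOKENS:
                raise SequenceError(f"code token collides with special {t!r}")
        self.tokens: list[str] = list(SPECIAL_TOKENS) + sorted(set(tokens))
        self.index: dict[str, int] = {t: i for i, t in enumerate(self.tokens)}

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def n_codes(self) -> int:
        return len(self.tokens) - len(SPECIAL_TOKENS)

    @classmethod
    def from_sequences(cls, sequences: dict[str, PatientSequence]
                       ) -> "TokenVocabulary":
        toks = sorted({t for s in sequences.values() for t in s.tokens})
        return cls(toks)

    def encode(self, tokens: list[str]) -> list[int]:
        unk = self.index[UNK]
        return [self.index.get(t, unk) for t in tokens]

    def decode(self, ids: list[int]) -> list[str]:
        return [self.tokens[i] for i in ids]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as f:
            for i, t in enumerate(self.tokens):
                f.write(f"{t}\t{i}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TokenVocabulary":
        toks = []
        with open(path) as f:
            for line in f:
                t, i = line.rstrip("\n").split("\t")
                toks.append(t)
        vocab = cls.__new__(cls)
        vocab.tokens = toks
        vocab.index = {t: i for i, t in enumerate(toks)}
        return vocab


def build_sequences(events: pd.DataFrame, code_map: pd.DataFrame,
                    records: pd.DataFrame, vocabulary_tag: str,
                    index_date: str | pd.Timestamp,
                    max_len: int = 128) -> dict[str, PatientSequence]:
    """Turn dated history events into per-patient token sequences.

    Parameters
    ----------
    events
        History event table (``patient_id``, ``event_date``, ``medcode``);
        every event must fall strictly before ``index_date``.
    code_map
        Many-to-one ``medcode -> disease`` map.
    records
        Patient table providing ``birth_date`` for per-token ages.
    vocabulary_tag
        ``"diseases"`` for category tokens, ``"medcodes"`` for raw codes.
    max_len
        Sequences longer than this keep the most recent ``max_len`` tokens.

    Patients with fewer than 2 tokens are excluded.  Ages are integer years at
    the event, clipped to [0, 110]; visit indices are 1-based per distinct
    event date (re-based after truncation so they stay dense).
    """
    if vocabulary_tag not in ("diseases", "medcodes"):
        raise SequenceError(f"unknown vocabulary_tag {vocabulary_tag!r}")
    index_date = pd.Timestamp(index_date)
    if events.empty:
        return {}
    ev = events.copy()
    ev["event_date"] = pd.to_datetime(ev["event_date"])
    late = ev["event_date"] >= index_date
    if late.any():
        pid = ev.loc[late, "patient_id"].iloc[0]
        raise SequenceError(
            f"events on or after the index date ({index_date.date()}) are "
            f"not history; first offender: patient {pid!r}")
    mapping = dict(zip(code_map["medcode"], code_map["disease"]))
    unmapped = set(ev["medcode"]) - set(mapping)
    if unmapped:
        raise SequenceError(
            f"medcode {sorted(unmapped)[0]!r} is absent from the code map")
    ev["disease"] = ev["medcode"].map(mapping)
    ev = ev.sort_values(["patient_id", "event_date", "medcode"],
                        kind="mergesort")
    birth = dict(zip(records["patient_id"], pd.to_datetime(records["birth_date"])))

    token_col = "disease" if vocabulary_tag == "diseases" else "medcode"
    out: dict[str, PatientSequence] = {}
    for pid, g in ev.groupby("patient_id", sort=True):
        if len(g) < 2:
            continue
        g = g.iloc[-max_len:] if len(g) > max_len else g
        dates = g["event_date"]
        visit = dates.ne(dates.shift()).cumsum().to_list()
        if pid not in birth:
            raise SequenceError(f"patient {pid!r} has events but no record")
        b = birth[pid]
        ages = [min(110, max(0, math.floor((d - b).days / 365.25)))
                for d in dates]
        out[str(pid)] = PatientSequence(
            patient_id=str(pid),
            vocabulary_tag=vocabulary_tag,
            tokens=g[token_col].to_list(),
            visit_index=visit,
            age_years=ages,
            calendar_year=[d.year for d in dates],
        )
    return out


def eligible_cohort(records: pd.DataFrame,
                    sequences: dict[str, PatientSequence],
                    index_date: str | pd.Timestamp) -> set[str]:
    """Patients meeting the analysis-cohort entry rules at the index date.

    Keeps patients (i) registered for at least one year before the index
    date, (ii) alive at the index date, (iii) still registered at the index
    date, and (iv) holding a valid disease sequence with at least 2 distinct
    disease categories.  ``sequences`` must be built on the diseases
    vocabulary so distinctness is category-level.
    """
    index_date = pd.Timestamp(index_date)
    for s in sequences.values():
        if s.vocabulary_tag != "diseases":
            raise SequenceError(
                "eligibility needs diseases-vocabulary sequences (the >=2 "
                "distinct long-term conditions rule is category-level)")
        break
    reg = pd.to_datetime(records["registration_date"])
    dereg = pd.to_datetime(records["deregistration_date"], errors="coerce")
    death = pd.to_datetime(records["death_date"], errors="coerce")
    ok = (reg <= index_date - pd.Timedelta(days=365))
    ok &= death.isna() | (death >= index_date)
    ok &= dereg.isna() | (dereg >= index_date)
    candidates = set(records.loc[ok, "patient_id"].astype(str))
    return {pid for pid, s in sequences.items()
            if pid in candidates and len(set(s.tokens)) >= 2}


def write_sequences(sequences: dict[str, PatientSequence],
                    path: str | Path) -> None:
    """Serialize sequences as JSON-lines (one object per patient)."""
    with open(path, "w") as f:
        for s in sequences.values():
            f.write(json.dumps({
                "patient_id": s.patient_id,
                "vocabulary_tag": s.vocabulary_tag,
                "tokens": s.tokens,
                "visit_index": s.visit_index,
                "age_years": s.age_years,
                "calendar_year": s.calendar_year,
            }) + "\n")


def read_sequences(path: str | Path) -> dict[str, PatientSequence]:
    out: dict[str, PatientSequence] = {}
    with open(path) as f:
        for line in f:
            d = json.loads(line)
            out[d["patient_id"]] = PatientSequence(**d)
    return out
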