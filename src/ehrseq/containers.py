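"""Shared containers for patient-level representations."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class EmbeddingSet:
    """A patient-id-indexed dense matrix of fixed-length representations.

    Parameters
    ----------
    ids
        Patient identifiers, one per row of ``X``.
    X
        Array of shape ``(n_patients, dim)``.
    method
        Name of the producing method (e.g. ``"binary"``, ``"lda"``,
        ``"doc2vec-dbow"``, ``"ehrbert"``).
    vocabulary_tag
        Which token vocabulary the representation was built from
        (``"diseases"`` or ``"medcodes"``); ``""`` when not applicable.
    feature_names
        Optional per-column names (used by the count/indicator baselines).
    """

    ids: list[str]
    X: np.ndarray
    method: str = ""
    vocabulary_tag: str = ""
    feature_names: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.ids):
            raise ValueError(
                f"X must be (n_patients, dim); got {self.X.shape} for "
                f"{len(self.ids)} ids"
            )

    @property
    def dim(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = self.feature_names or [f"e{j}" for j in range(self.dim)]
        return pd.DataFrame(self.X, index=pd.Index(self.ids, name="patient_id"),
                            columns=cols)

    def align(self, ids: list[str]) -> np.ndarray:
        """Rows of ``X`` reordered to ``ids``; raises on unknown ids."""
        pos = {p: i for i, p in enumerate(self.ids)}
        try:
            idx = np.array([pos[p] for p in ids])
        except KeyError as e:  # pragma: no cover - message clarity only
            raise KeyError(f"patient id {e.args[0]!r} has no embedding") from None
        return self.X[idx]

    def save(self, path: str | Path) -> None:
        df = self.to_frame()
        df.insert(0, "_method", self.method)
        df.insert(1, "_vocabulary", self.vocabulary_tag)
        df.to_csv(path)

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingSet":
        df = pd.read_csv(path, index_col="patient_id")
        method = str(df.pop("_method").iloc[0]) if "_method" in df else ""
        vocab = df.pop("_vocabulary") if "_vocabulary" in df else None
        vocab_tag = "" if vocab is None or pd.isna(vocab.iloc[0]) else str(vocab.iloc[0])
        return cls(
            ids=[str(i) for i in df.index],
            X=df.to_numpy(dtype=float),
            method=method,
            vocabulary_tag=vocab_tag,
            feature_names=list(df.columns),
        )
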