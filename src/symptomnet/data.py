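"""The subject-by-item score table that the whole pipeline consumes.

Missing entries are stored as NaN; the boolean ``observed`` mask is derived
from the score matrix, so the two can never disagree.  Optional per-subject
covariates (e.g. lesion location) ride along in ``subject_data`` and are
kept row-aligned through filtering and splitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .items import ItemSpec, check_unique_labels, read_item_metadata, write_item_metadata


@dataclass
class SymptomDataset:
    """Subject-by-item score matrix with item metadata.

    Parameters
    ----------
    scores : ndarray, shape (n_subjects, n_items)
        Float matrix; NaN marks a missing entry.
    items : list of ItemSpec
        Column metadata, aligned with ``scores``.
    cohort_id : str
        Cohort/study-site identifier.
    subject_data : DataFrame, optional
        Per-subject covariates (one row per subject).
    """

    scores: np.ndarray
    items: list[ItemSpec]
    cohort_id: str = "cohort"
    subject_data: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise ValueError("scores must be a 2-D matrix")
        self.items = list(self.items)
        if len(self.items) != self.scores.shape[1]:
            raise ValueError(
                f"{len(self.items)} item specs for {self.scores.shape[1]} columns"
            )
        check_unique_labels(self.items)
        if self.subject_data is not None:
            if len(self.subject_data) != self.scores.shape[0]:
                raise ValueError("subject_data must have one row per subject")
            self.subject_data = self.subject_data.reset_index(drop=True)

    # -- basic geometry ------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.scores.shape[0]

    @property
    def n_items(self) -> int:
        return self.scores.shape[1]

    @property
    def labels(self) -> list[str]:
        return [it.label for it in self.items]

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask, True where the score is observed."""
        return ~np.isnan(self.scores)

    @property
    def is_complete(self) -> bool:
        return bool(np.all(self.observed))

    def column(self, label: str) -> np.ndarray:
        return self.scores[:, self.labels.index(label)]

    # -- subsetting ----------------------------------------------------
    def copy(self) -> "SymptomDataset":
        sd = None if self.subject_data is None else self.subject_data.copy()
        return SymptomDataset(self.scores.copy(), list(self.items), self.cohort_id, sd)

    def select_subjects(self, idx: np.ndarray | Sequence[int]) -> "SymptomDataset":
        idx = np.asarray(idx)
        sd = None if self.subject_data is None else self.subject_data.iloc[idx]
        return SymptomDataset(self.scores[idx], list(self.items), self.cohort_id, sd)

    def select_items(self, labels: Sequence[str]) -> "SymptomDataset":
        pos = [self.labels.index(l) for l in labels]
        return SymptomDataset(
            self.scores[:, pos],
            [self.items[p] for p in pos],
            self.cohort_id,
            self.subject_data,
        )

    def drop_items(self, labels: Sequence[str]) -> "SymptomDataset":
        drop = set(labels)
        keep = [l for l in self.labels if l not in drop]
        missing = drop - set(self.labels)
        if missing:
            raise KeyError(f"items not in dataset: {sorted(missing)}")
        return self.select_items(keep)

    # -- I/O -----------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, columns=self.labels)

    def write_csv(
        self, scores_path: str | Path, metadata_path: str | Path | None = None
    ) -> None:
        """Write the score table (empty field = missing) and, optionally,
        the companion item-metadata CSV."""
        self.to_frame().to_csv(scores_path, index=False)
        if metadata_path is not None:
            write_item_metadata(self.items, metadata_path)

    @classmethod
    def read_csv(
        cls,
        scores_path: str | Path,
        metadata_path: str | Path | None = None,
        cohort_id: str | None = None,
    ) -> "SymptomDataset":
        df = pd.read_csv(scores_path)
        if metadata_path is not None:
            items = read_item_metadata(metadata_path)
            meta_labels = [it.label for it in items]
            if meta_labels != list(df.columns):
                # allow metadata supersets; reorder to the score columns
                by_label = {it.label: it for it in items}
                try:
                    items = [by_label[c] for c in df.columns]
                except KeyError as exc:
                    raise ValueError(
                        f"item metadata missing column {exc.args[0]!r}"
                    ) from None
        else:
            items = [ItemSpec(label=c, domain="psychopathology") for c in df.columns]
        if cohort_id is None:
            cohort_id = Path(scores_path).stem
        return cls(df.to_numpy(dtype=float), items, cohort_id)
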