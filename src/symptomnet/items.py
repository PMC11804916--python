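"""Item metadata: labels, clinical domains, polarity, and response types.

Every column of a cohort table is described by an :class:`ItemSpec`.  The
domain vocabulary follows the usual grouping of poststroke complications:
depression, anxiety, apathy and fatigue symptoms, cognitive test scores,
activities-of-daily-living (ADL) items, plus catch-all psychopathology and
pathology/medication categories.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import pandas as pd

DOMAINS = (
    "depression",
    "anxiety",
    "apathy",
    "fatigue",
    "cognition",
    "adl",
    "psychopathology",
    "pathology_medication",
)

POLARITIES = ("higher_is_worse", "higher_is_better")

RESPONSE_TYPES = ("binary", "likert", "continuous")


@dataclass(frozen=True)
class ItemSpec:
    """Description of one scored item (one network node).

    Parameters
    ----------
    label : str
        Unique item name within a cohort (e.g. ``"worry"``).
    domain : str
        Clinical domain, one of :data:`DOMAINS`.
    polarity : str
        ``"higher_is_worse"`` for symptom severity items,
        ``"higher_is_better"`` for cognition/function scores that are
        inverted during preprocessing.
    response_type : str
        ``"binary"``, ``"likert"`` or ``"continuous"``.
    likert_levels : int, optional
        Number of ordered response levels; required for likert items.
    loadings : tuple of float, optional
        Loadings on the latent domain factors used by the synthetic
        generator (one entry per factor); ``None`` for observed data.
    worry : bool
        Flags the worry item used for the worry+/worry- group split.
    """

    label: str
    domain: str
    polarity: str = "higher_is_worse"
    response_type: str = "continuous"
    likert_levels: int | None = None
    loadings: tuple[float, ...] | None = None
    worry: bool = False

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("item label must be a non-empty string")
        if self.domain not in DOMAINS:
            raise ValueError(
                f"unknown domain {self.domain!r}; expected one of {DOMAINS}"
            )
        if self.polarity not in POLARITIES:
            raise ValueError(
                f"unknown polarity {self.polarity!r}; expected one of {POLARITIES}"
            )
        if self.response_type not in RESPONSE_TYPES:
            raise ValueError(
                f"unknown response_type {self.response_type!r}; "
                f"expected one of {RESPONSE_TYPES}"
            )
        if self.response_type == "likert":
            if self.likert_levels is None or self.likert_levels < 2:
                raise ValueError("likert items need likert_levels >= 2")
        if self.loadings is not None:
            object.__setattr__(self, "loadings", tuple(float(x) for x in self.loadings))

    def inverted(self) -> "ItemSpec":
        """Return a copy with polarity set to higher_is_worse."""
        return replace(self, polarity="higher_is_worse")


def check_unique_labels(items: Sequence[ItemSpec]) -> None:
    labels = [it.label for it in items]
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate item labels: {dupes}")


def items_to_frame(items: Sequence[ItemSpec]) -> pd.DataFrame:
    """Tabulate item metadata (label, domain, polarity, response_type,
    likert_levels, worry_flag)."""
    return pd.DataFrame(
        {
            "label": [it.label for it in items],
            "domain": [it.domain for it in items],
            "polarity": [it.polarity for it in items],
            "response_type": [it.response_type for it in items],
            "likert_levels": [it.likert_levels for it in items],
            "worry_flag": [int(it.worry) for it in items],
        }
    )


def write_item_metadata(items: Sequence[ItemSpec], path: str | Path) -> None:
    items_to_frame(items).to_csv(path, index=False)


def read_item_metadata(path: str | Path) -> list[ItemSpec]:
    df = pd.read_csv(path)
    out: list[ItemSpec] = []
    for _, row in df.iterrows():
        levels = row.get("likert_levels")
        levels = None if pd.isna(levels) else int(levels)
        out.append(
            ItemSpec(
                label=str(row["label"]),
                domain=str(row["domain"]),
                polarity=str(row["polarity"]),
                response_type=str(row["response_type"]),
                likert_levels=levels,
                worry=bool(int(row.get("worry_flag", 0))),
            )
        )
    check_unique_labels(out)
    return out
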