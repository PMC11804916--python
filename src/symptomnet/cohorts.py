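"""Published demographic summary of the nine STROKOG study sites.

These are the per-cohort participant counts and mean ages reported for the
consortium's pooled symptom-network sample.  Where a cohort computed its
age summary on a subset (SSS reports age for n = 101 of 117 participants),
``age_n`` records the subset size, and pooled summaries weight by it.
"""

from __future__ import annotations

import pandas as pd

#: study site, participants, mean age (years), SD of age, n used for age
_ROWS = [
    ("Bulgarian PSS", 78, 65.18, 5.73, 78),
    ("CASPER", 230, 67.70, 11.65, 230),
    ("COAST", 270, 59.83, 11.44, 270),
    ("EpiUSA", 416, 71.43, 7.94, 416),
    ("Hallym VCI", 655, 65.14, 12.12, 655),
    ("PROPOLIS", 226, 65.57, 12.57, 226),
    ("SSS", 117, 70.16, 8.58, 101),
    ("STRATEGIC", 52, 69.47, 8.45, 52),
    ("STROKDEM", 141, 63.23, 12.53, 141),
]


def cohort_demographics() -> pd.DataFrame:
    """Per-cohort demographic summary table."""
    return pd.DataFrame(
        _ROWS, columns=["study", "n", "age_mean", "age_sd", "age_n"]
    )


def total_participants() -> int:
    """Pooled sample size: the sum of the nine per-cohort counts."""
    return int(cohort_demographics()["n"].sum())


def pooled_mean_age() -> float:
    """n-weighted average of the per-cohort mean ages.

    Weights are the age-specific sample sizes where a cohort reported its
    age summary on a subset of participants."""
    df = cohort_demographics()
    return float((df["age_mean"] * df["age_n"]).sum() / df["age_n"].sum())
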