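"""Ashcroft-score bookkeeping: validation, severity classes, frequencies.

The Ashcroft scale (as modified by Hübner) grades lung fibrosis severity
visually on integers 0–8 per microscopic field; a sample's final score is
the mean of its field scores.  For distribution analysis the integer field
scores are binned into three severity classes: mild (0–3), moderate (4),
severe (5–8).

Grading itself is a human task — this module only validates, bins and
tabulates scores.  Binning applies to individual integer field scores, not
to the (possibly fractional) per-sample mean; passing a fractional value
is rejected with a message pointing at the distinction.  Group-comparison
statistics (ANOVA, chi-squared, ...) are delegated to standard statistics
libraries and not re-implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AshcroftRecord",
    "classify_ashcroft",
    "frequency_distribution",
    "SEVERITY_CLASSES",
]

SEVERITY_CLASSES = ("mild", "moderate", "severe")


def classify_ashcroft(score: int | float) -> str:
    """Map an integer Ashcroft field score to its severity class.

    0–3 → mild, 4 → moderate, 5–8 → severe.  Non-integers are rejected:
    severity classes apply to individual field scores, not to per-sample
    mean scores (which may be fractional).
    """
    value = float(score)
    if not value.is_integer():
        raise ValueError(
            f"Ashcroft severity classes apply to integer field scores, got "
            f"{score}; per-sample mean scores are reported separately and "
            f"are not binned"
        )
    iv = int(value)
    if not 0 <= iv <= 8:
        raise ValueError(f"Ashcroft score must be in [0, 8], got {score}")
    if iv <= 3:
        return "mild"
    if iv == 4:
        return "moderate"
    return "severe"


@dataclass
class AshcroftRecord:
    """Field scores for one sample; mean_score is derived on construction."""

    sample_id: str
    group: str
    scores: list[int]
    timepoint_day: int | None = None
    mean_score: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.scores:
            raise ValueError(f"sample {self.sample_id}: empty score list")
        for s in self.scores:
            classify_ashcroft(s)  # validates range and integrality
        self.scores = [int(s) for s in self.scores]
        self.mean_score = float(np.mean(self.scores))


def frequency_distribution(records: list[AshcroftRecord]) -> pd.DataFrame:
    """Severity-class counts and percentages per group.

    Counts are over all individual field scores within each group (not over
    per-sample means); percentages sum to 100 per group within rounding.
    Returns a tidy frame with columns (group, severity, count, pct); the
    frame's ``attrs["binning"]`` records the field-level convention.
    """
    if not records:
        raise ValueError("no Ashcroft records provided")
    rows = [
        {"group": r.group, "severity": classify_ashcroft(s)}
        for r in records
        for s in r.scores
    ]
    df = pd.DataFrame(rows)
    counts = (
        df.groupby(["group", "severity"], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=list(SEVERITY_CLASSES), fill_value=0)
    )
    tidy = counts.stack().rename("count").reset_index()
    totals = tidy.groupby("group")["count"].transform("sum")
    tidy["pct"] = 100.0 * tidy["count"] / totals
    tidy["severity"] = pd.Categorical(
        tidy["severity"], categories=list(SEVERITY_CLASSES), ordered=True
    )
    tidy = tidy.sort_values(["group", "severity"]).reset_index(drop=True)
    tidy.attrs["binning"] = "per-field integer scores (not per-sample means)"
    return tidy
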