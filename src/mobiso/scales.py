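"""LSNS-6 and UCLA-3 questionnaire scoring and loneliness-risk labelling.

The Lubben Social Network Scale-6 (LSNS-6) measures social engagement: six
items each scored 0-5, total 0-30, higher = more engaged; a total of 12 or
lower conventionally flags the respondent as at risk of social isolation.
The UCLA 3-Item Loneliness Scale measures perceived loneliness: three items
each scored 1-3, total 3-9, higher = lonelier.

Both totals are binned into three risk labels (0 = low, 1 = medium,
2 = high loneliness risk). The two scales run in opposite directions, so a
*high* Lubben score maps to the *low*-risk label. The three-level cutoffs
are an explicit, validated configuration: the only externally anchored
boundary is the Lubben at-risk threshold of 12, which the defaults place at
the high-risk label's upper edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

LSNS6_MIN, LSNS6_MAX = 0, 30
UCLA3_MIN, UCLA3_MAX = 3, 9
AT_RISK_THRESHOLD = 12  # LSNS-6 total at or below this flags social-isolation risk


@dataclass(frozen=True)
class SurveyResponse:
    """Raw item scores for one respondent: six LSNS-6 items and three UCLA-3 items."""

    lsns6: tuple[int, ...]
    ucla3: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.lsns6) != 6:
            raise ValueError(f"LSNS-6 needs exactly 6 items, got {len(self.lsns6)}")
        if len(self.ucla3) != 3:
            raise ValueError(f"UCLA-3 needs exactly 3 items, got {len(self.ucla3)}")
        for v in self.lsns6:
            if not (0 <= int(v) <= 5) or int(v) != v:
                raise ValueError(f"LSNS-6 item {v!r} outside integer range 0-5")
        for v in self.ucla3:
            if not (1 <= int(v) <= 3) or int(v) != v:
                raise ValueError(f"UCLA-3 item {v!r} outside integer range 1-3")


@dataclass(frozen=True)
class LabelCutoffs:
    """Three-level binning of the two scale totals.

    ``ucla_bins`` and ``lubben_bins`` give the inclusive upper bound of label
    0's and label 1's score band, read in the direction of increasing risk:
    UCLA risk increases with the score, Lubben risk decreases with it.

    Defaults: UCLA 3-4 → 0, 5-6 → 1, 7-9 → 2; Lubben ≥ 18 → 0, 13-17 → 1,
    ≤ 12 → 2 (so the published at-risk boundary is the high-risk boundary).
    """

    ucla_low_max: int = 4      # UCLA total ≤ this → label 0
    ucla_medium_max: int = 6   # UCLA total ≤ this (and > low) → label 1
    lubben_low_min: int = 18   # Lubben total ≥ this → label 0
    lubben_medium_min: int = 13  # Lubben total ≥ this (and < low) → label 1

    def __post_init__(self) -> None:
        if not (UCLA3_MIN <= self.ucla_low_max < self.ucla_medium_max < UCLA3_MAX):
            raise ValueError(
                "UCLA cutoffs must satisfy "
                f"{UCLA3_MIN} <= low_max < medium_max < {UCLA3_MAX}; "
                f"got low_max={self.ucla_low_max}, medium_max={self.ucla_medium_max}"
            )
        if not (LSNS6_MIN < self.lubben_medium_min < self.lubben_low_min <= LSNS6_MAX):
            raise ValueError(
                "Lubben cutoffs must satisfy "
                f"{LSNS6_MIN} < medium_min < low_min <= {LSNS6_MAX}; "
                f"got medium_min={self.lubben_medium_min}, low_min={self.lubben_low_min}"
            )


@dataclass(frozen=True)
class LabelRecord:
    """Per-user scale totals, three-level risk labels and the at-risk flag."""

    user_id: int
    lubben_score: int
    ucla_score: int
    lubben_label: int
    ucla_label: int
    at_risk: bool


def score_lsns6(response: SurveyResponse | Sequence[int]) -> int:
    """Total LSNS-6 score: the sum of the six item scores (0-30)."""
    items = response.lsns6 if isinstance(response, SurveyResponse) else tuple(response)
    if len(items) != 6:
        raise ValueError(f"LSNS-6 needs exactly 6 items, got {len(items)}")
    for v in items:
        if not (0 <= int(v) <= 5) or int(v) != v:
            raise ValueError(f"LSNS-6 item {v!r} outside integer range 0-5")
    return int(sum(items))


def score_ucla3(response: SurveyResponse | Sequence[int]) -> int:
    """Total UCLA-3 score: the sum of the three item scores (3-9, higher = lonelier)."""
    items = response.ucla3 if isinstance(response, SurveyResponse) else tuple(response)
    if len(items) != 3:
        raise ValueError(f"UCLA-3 needs exactly 3 items, got {len(items)}")
    for v in items:
        if not (1 <= int(v) <= 3) or int(v) != v:
            raise ValueError(f"UCLA-3 item {v!r} outside integer range 1-3")
    return int(sum(items))


def is_at_risk(lubben_score: int) -> bool:
    """At-risk flag for social isolation: LSNS-6 total ≤ 12."""
    if not (LSNS6_MIN <= lubben_score <= LSNS6_MAX):
        raise ValueError(f"Lubben score {lubben_score} outside 0-30")
    return lubben_score <= AT_RISK_THRESHOLD


def assign_labels(
    lubben_score: int,
    ucla_score: int,
    user_id: int = 0,
    cutoffs: LabelCutoffs | None = None,
) -> LabelRecord:
    """Map the two scale totals to three-level loneliness-risk labels.

    UCLA risk is monotone increasing in the score; Lubben risk is monotone
    decreasing (high social engagement → low risk). The at-risk flag is set
    from the Lubben ≤ 12 rule regardless of the configured bins.
    """
    cutoffs = cutoffs or LabelCutoffs()
    if not (UCLA3_MIN <= ucla_score <= UCLA3_MAX):
        raise ValueError(f"UCLA score {ucla_score} outside {UCLA3_MIN}-{UCLA3_MAX}")
    if not (LSNS6_MIN <= lubben_score <= LSNS6_MAX):
        raise ValueError(f"Lubben score {lubben_score} outside {LSNS6_MIN}-{LSNS6_MAX}")

    if ucla_score <= cutoffs.ucla_low_max:
        ucla_label = 0
    elif ucla_score <= cutoffs.ucla_medium_max:
        ucla_label = 1
    else:
        ucla_label = 2

    if lubben_score >= cutoffs.lubben_low_min:
        lubben_label = 0
    elif lubben_score >= cutoffs.lubben_medium_min:
        lubben_label = 1
    else:
        lubben_label = 2

    return LabelRecord(
        user_id=user_id,
        lubben_score=int(lubben_score),
        ucla_score=int(ucla_score),
        lubben_label=lubben_label,
        ucla_label=ucla_label,
        at_risk=is_at_risk(lubben_score),
    )


def read_survey_csv(path, cutoffs: LabelCutoffs | None = None) -> pd.DataFrame:
    """Score a survey CSV (user_id, lsns6_1..lsns6_6, ucla3_1..ucla3_3) into a label table."""
    df = pd.read_csv(path)
    lsns_cols = [f"lsns6_{i}" for i in range(1, 7)]
    ucla_cols = [f"ucla3_{i}" for i in range(1, 4)]
    missing = [c for c in ["user_id", *lsns_cols, *ucla_cols] if c not in df.columns]
    if missing:
        raise ValueError(f"survey file missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        resp = SurveyResponse(
            lsns6=tuple(int(row[c]) for c in lsns_cols),
            ucla3=tuple(int(row[c]) for c in ucla_cols),
        )
        rec = assign_labels(
            lubben_score=score_lsns6(resp),
            ucla_score=score_ucla3(resp),
            user_id=int(row["user_id"]),
            cutoffs=cutoffs,
        )
        records.append(rec.__dict__)
    return pd.DataFrame.from_records(records)


def labels_to_frame(records: Sequence[LabelRecord]) -> pd.DataFrame:
    """Stack label records into a DataFrame keyed by user_id."""
    return pd.DataFrame.from_records([r.__dict__ for r in records])
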