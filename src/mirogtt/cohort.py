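"""Participant metadata and OGTT glucose-tolerance classification.

Participants undergo an oral glucose tolerance test with blood sampled at
-1 (baseline), 10, 30, 60 and 180 minutes, plus a separate diagnostic
glucose at 120 minutes (the "2 h" value the clinical categories are defined
on).  Four glucose-tolerance categories are assigned from venous glucose in
mmol/l:

* CFRD   -- cystic fibrosis-related diabetes: 2 h glucose >= 11.1
* IGT    -- impaired glucose tolerance: 7.8 <= 2 h glucose < 11.1
* INDET  -- indeterminate: 2 h glucose < 7.8 but a mid-OGTT value
            (10, 30 or 60 min) >= 11.1
* NGT    -- normal: everything below the thresholds

Evaluation follows exactly this precedence, so every valid input maps to
one and only one label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import pandas as pd

GROUPS = ("NGT", "INDET", "IGT", "CFRD")

#: OGTT sampling grid in minutes; -1 is the pre-load baseline.
OGTT_TIMEPOINTS = (-1, 10, 30, 60, 180)

#: The sampled points strictly between baseline and the 2 h diagnostic draw.
MID_OGTT_TIMEPOINTS = (10, 30, 60)

#: 2 h glucose at or above this -> CFRD; a mid-OGTT value at or above -> INDET.
DIABETES_GLUCOSE_MMOL_L = 11.1

#: 2 h glucose at or above this (but below the diabetic cut) -> IGT.
IGT_GLUCOSE_MMOL_L = 7.8

ANALYTE_NAMES = ("ASAT", "ALAT", "ALP", "GGT", "CRP", "LPK")


class ClassificationError(ValueError):
    """Raised when the glucose inputs do not permit classification."""


def _check_positive(label: str, value: float) -> None:
    if not value > 0:
        raise ClassificationError(f"{label} must be positive, got {value!r}")


def classify_glucose_tolerance(
    glucose_by_timepoint: Mapping[int, float],
    glucose_120: Optional[float],
    *,
    diabetes_threshold: float = DIABETES_GLUCOSE_MMOL_L,
    igt_threshold: float = IGT_GLUCOSE_MMOL_L,
) -> str:
    """Assign the glucose-tolerance category from OGTT glucose values.

    Parameters
    ----------
    glucose_by_timepoint
        Glucose (mmol/l) keyed by sampling timepoint in minutes; keys must
        come from the OGTT grid (-1, 10, 30, 60, 180).  At least one
        mid-OGTT value (10, 30 or 60 min) must be present.
    glucose_120
        The 2 h diagnostic glucose (mmol/l).  Required: the categories are
        defined on it and no interpolation from the grid is attempted.

    Returns
    -------
    str
        One of ``"NGT"``, ``"INDET"``, ``"IGT"``, ``"CFRD"``.
    """
    if glucose_120 is None or pd.isna(glucose_120):
        raise ClassificationError(
            "unclassifiable: the 120-min (2 h) glucose is required"
        )
    _check_positive("glucose_120", glucose_120)
    unknown = set(glucose_by_timepoint) - set(OGTT_TIMEPOINTS)
    if unknown:
        raise ClassificationError(
            f"unknown OGTT timepoints {sorted(unknown)}; "
            f"expected labels from {OGTT_TIMEPOINTS}"
        )
    for tp, value in glucose_by_timepoint.items():
        if value is None or pd.isna(value):
            continue
        _check_positive(f"glucose at {tp} min", value)
    mid = [
        glucose_by_timepoint[tp]
        for tp in MID_OGTT_TIMEPOINTS
        if tp in glucose_by_timepoint
        and glucose_by_timepoint[tp] is not None
        and not pd.isna(glucose_by_timepoint[tp])
    ]
    if not mid:
        raise ClassificationError(
            "at least one mid-OGTT glucose (10, 30 or 60 min) is required"
        )
    if glucose_120 >= diabetes_threshold:
        return "CFRD"
    if glucose_120 >= igt_threshold:
        return "IGT"
    if any(v >= diabetes_threshold for v in mid):
        return "INDET"
    return "NGT"


@dataclass
class ParticipantProfile:
    """One study participant: OGTT series, clinical analytes and group.

    The group label is derived, not free-set: it is recomputed from the
    glucose fields on construction via :func:`classify_glucose_tolerance`.
    """

    participant_id: str
    glucose_by_timepoint: dict[int, float]
    glucose_120: float
    insulin_by_timepoint: Optional[dict[int, float]] = None
    analytes: Optional[dict[str, float]] = None
    sex: Optional[str] = None
    age: Optional[float] = None
    group: str = field(init=False)

    def __post_init__(self) -> None:
        if self.sex is not None and self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        self.group = classify_glucose_tolerance(
            self.glucose_by_timepoint, self.glucose_120
        )


def profiles_from_sample_sheet(
    samples: pd.DataFrame, analytes: Optional[pd.DataFrame] = None
) -> list[ParticipantProfile]:
    """Build participant profiles from a long-format OGTT sample sheet.

    ``samples`` has one row per participant x timepoint with columns
    ``participant_id``, ``timepoint_min``, ``glucose_mmol_l`` and optionally
    ``insulin_pmol_l``; the 120-min diagnostic glucose appears as a row with
    ``timepoint_min == 120``.  ``analytes`` is a wide table keyed by
    ``participant_id`` with any of the analyte columns (ASAT, ALAT, ALP,
    GGT, CRP, LPK) plus optional ``sex`` and ``age``.
    """
    required = {"participant_id", "timepoint_min", "glucose_mmol_l"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    analyte_map: dict[str, dict] = {}
    if analytes is not None:
        analyte_map = analytes.set_index("participant_id").to_dict("index")
    profiles = []
    for pid, grp in samples.groupby("participant_id", sort=True):
        glucose: dict[int, float] = {}
        insulin: dict[int, float] = {}
        g120 = None
        for row in grp.itertuples(index=False):
            tp = int(row.timepoint_min)
            if tp == 120:
                g120 = float(row.glucose_mmol_l)
                continue
            glucose[tp] = float(row.glucose_mmol_l)
            ins = getattr(row, "insulin_pmol_l", None)
            if ins is not None and not pd.isna(ins):
                insulin[tp] = float(ins)
        extra = analyte_map.get(pid, {})
        profile_analytes = {
            k: float(extra[k])
            for k in ANALYTE_NAMES
            if k in extra and not pd.isna(extra[k])
        }
        profiles.append(
            ParticipantProfile(
                participant_id=str(pid),
                glucose_by_timepoint=glucose,
                glucose_120=g120,
                insulin_by_timepoint=insulin or None,
                analytes=profile_analytes or None,
                sex=extra.get("sex") if not pd.isna(extra.get("sex", None)) else None,
                age=float(extra["age"]) if "age" in extra and not pd.isna(extra["age"]) else None,
            )
        )
    return profiles


def profiles_to_frames(
    profiles: list[ParticipantProfile],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Serialize profiles to (sample sheet, analyte table) DataFrames.

    The derived group label is written back onto the analyte table as a
    column.
    """
    sample_rows = []
    analyte_rows = []
    for p in profiles:
        for tp in sorted(p.glucose_by_timepoint):
            sample_rows.append(
                {
                    "participant_id": p.participant_id,
                    "timepoint_min": tp,
                    "glucose_mmol_l": p.glucose_by_timepoint[tp],
                    "insulin_pmol_l": (p.insulin_by_timepoint or {}).get(tp),
                }
            )
        sample_rows.append(
            {
                "participant_id": p.participant_id,
                "timepoint_min": 120,
                "glucose_mmol_l": p.glucose_120,
                "insulin_pmol_l": None,
            }
        )
        row = {"participant_id": p.participant_id, "group": p.group,
               "sex": p.sex, "age": p.age}
        row.update(p.analytes or {})
        analyte_rows.append(row)
    return pd.DataFrame(sample_rows), pd.DataFrame(analyte_rows)


def group_labels(profiles: list[ParticipantProfile]) -> dict[str, str]:
    """Mapping participant_id -> derived glucose-tolerance group."""
    return {p.participant_id: p.group for p in profiles}
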