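"""Interplate calibration and RT-qPCR sample/participant quality control.

Three gates, applied to calibrated Cts:

* RT inhibition: a sample fails when its UniSp6 spike-in Ct exceeds 23
  cycles (or is undetected) — the reverse-transcription/PCR reaction was
  inhibited.
* Haemolysis: the index Ct(miR-23a-3p) - Ct(miR-451a) must stay below 7
  cycles; miR-451a is erythrocyte-enriched, so haemolysis inflates the
  index.
* Extraction consistency: within one participant, the Ct range (max - min)
  of each extraction spike-in (UniSp2, UniSp4, UniSp5) across all OGTT
  samples must not exceed 3 cycles; a larger drift indicates uneven
  extraction and excludes the participant entirely.

A participant is included when the baseline (-1 min) sample and at least
two further timepoints pass all per-sample gates and all three extraction
spike-ins are consistent.

Undetected reactions are represented as missing (NaN) Cts, never as a
sentinel cycle number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
import math
from typing import Optional

import numpy as np
import pandas as pd

CONTROL_ASSAYS = ("miR-16-5p", "miR-23a-3p", "miR-486-5p")
EXTRACTION_SPIKE_INS = ("UniSp2", "UniSp4", "UniSp5")
CALIBRATOR = "UniSp3"
RT_CONTROL = "UniSp6"
HAEMOLYSIS_NUMERATOR = "miR-23a-3p"
HAEMOLYSIS_DENOMINATOR = "miR-451a"

RT_INHIBITION_MAX_CT = 23.0
HAEMOLYSIS_MAX_INDEX = 7.0
EXTRACTION_MAX_RANGE = 3.0

CT_COLUMNS = ("participant_id", "timepoint_min", "plate_id", "assay_id", "ct")


class QcError(ValueError):
    """Raised when a QC computation cannot be evaluated."""


def _require_columns(df: pd.DataFrame) -> None:
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise QcError(f"Ct table missing columns: {sorted(missing)}")


def interplate_calibrate(ct_records: pd.DataFrame) -> pd.DataFrame:
    """Adjust every Ct to the UniSp3 interplate calibrator.

    calibrated ct = raw ct - (plate UniSp3 mean - grand UniSp3 mean), where
    the grand mean is the unweighted mean of the per-plate means.  After
    calibration the UniSp3 plate means coincide, so the transform is
    idempotent; with one plate it is the identity.
    """
    _require_columns(ct_records)
    sp3 = ct_records[ct_records["assay_id"] == CALIBRATOR]
    plates = ct_records["plate_id"].unique()
    missing = set(plates) - set(sp3.dropna(subset=["ct"])["plate_id"].unique())
    if missing:
        raise QcError(
            f"plate(s) missing a UniSp3 calibrator record: {sorted(missing)}"
        )
    plate_means = sp3.groupby("plate_id")["ct"].mean()
    grand = plate_means.mean()
    out = ct_records.copy()
    out["ct"] = out["ct"] - out["plate_id"].map(plate_means - grand)
    return out


def _sample_ct(sample_records: pd.DataFrame, assay: str) -> Optional[float]:
    """The (mean) Ct of one assay in one sample; None if no record exists,
    NaN if present but undetected."""
    sub = sample_records[sample_records["assay_id"] == assay]
    if sub.empty:
        return None
    vals = sub["ct"].astype(float)
    if vals.isna().all():
        return math.nan
    return float(vals.mean())


def rt_inhibition_gate(sample_records: pd.DataFrame,
                       max_ct: float = RT_INHIBITION_MAX_CT) -> bool:
    """Pass iff the sample's UniSp6 Ct is detected and <= ``max_ct``."""
    ct = _sample_ct(sample_records, RT_CONTROL)
    if ct is None:
        raise QcError("sample has no UniSp6 record; RT-inhibition gate "
                      "cannot be evaluated")
    if math.isnan(ct):
        return False
    return not ct > max_ct


def haemolysis_gate(sample_records: pd.DataFrame,
                    max_index: float = HAEMOLYSIS_MAX_INDEX,
                    ) -> tuple[float, bool, Optional[str]]:
    """Haemolysis index and gate outcome for one sample.

    index = Ct(miR-23a-3p) - Ct(miR-451a); pass iff index < ``max_index``
    (strict).  Returns (index, pass, reason); an undetected assay yields
    (nan, False, "haemolysis_unevaluable").
    """
    ct23 = _sample_ct(sample_records, HAEMOLYSIS_NUMERATOR)
    ct451 = _sample_ct(sample_records, HAEMOLYSIS_DENOMINATOR)
    if ct23 is None or ct451 is None:
        raise QcError("sample lacks miR-23a-3p or miR-451a records; "
                      "haemolysis gate cannot be evaluated")
    if math.isnan(ct23) or math.isnan(ct451):
        return math.nan, False, "haemolysis_unevaluable"
    index = ct23 - ct451
    return index, index < max_index, None if index < max_index else "haemolysis"


def extraction_consistency_gate(
    participant_records: pd.DataFrame,
    max_range: float = EXTRACTION_MAX_RANGE,
) -> dict[str, dict]:
    """Per-spike-in Ct-range check across one participant's OGTT samples.

    For each of UniSp2/4/5, fail iff (max Ct - min Ct) across the
    participant's samples exceeds ``max_range`` (strict).
    """
    out = {}
    for spike in EXTRACTION_SPIKE_INS:
        vals = participant_records.loc[
            participant_records["assay_id"] == spike, "ct"
        ].dropna().astype(float)
        if vals.empty:
            raise QcError(f"extraction spike-in {spike} absent from all of "
                          "the participant's samples")
        rng = float(vals.max() - vals.min())
        out[spike] = {"ct_range": rng, "pass": not rng > max_range}
    return out


@dataclass
class QcReport:
    """Gate outcomes per sample and inclusion decisions per participant."""

    samples: pd.DataFrame  # participant_id, timepoint_min, gate results
    participants: dict[str, dict] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)

    def included_participants(self) -> list[str]:
        return sorted(p for p, rec in self.participants.items()
                      if rec["included"])

    def to_json(self, path=None) -> str:
        payload = {
            "thresholds": self.thresholds,
            "samples": self.samples.to_dict(orient="records"),
            "participants": self.participants,
        }
        text = json.dumps(payload, indent=2, sort_keys=True, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def inclusion_rule(sample_gates: pd.DataFrame, extraction_pass: bool,
                   ) -> tuple[bool, list[str]]:
    """Participant inclusion from per-sample gate outcomes.

    Included iff the baseline (-1 min) sample passes all sample gates, at
    least two of the later timepoints pass all sample gates, and the
    extraction-consistency gate passed.  Returns (included, reason codes).
    """
    reasons: list[str] = []
    if not extraction_pass:
        reasons.append("extraction_inconsistent")
    base = sample_gates[sample_gates["timepoint_min"] == -1]
    if base.empty:
        reasons.append("no_baseline")
        return False, reasons
    if not bool(base["sample_pass"].iloc[0]):
        reasons.append("baseline_failed_qc")
    n_later = int(sample_gates.loc[
        sample_gates["timepoint_min"] != -1, "sample_pass"
    ].sum())
    if n_later < 2:
        reasons.append("fewer_than_two_passing_followups")
    return not reasons, reasons


def run_qc(
    ct_records: pd.DataFrame,
    *,
    rt_max_ct: float = RT_INHIBITION_MAX_CT,
    haemolysis_max_index: float = HAEMOLYSIS_MAX_INDEX,
    extraction_max_range: float = EXTRACTION_MAX_RANGE,
    calibrate: bool = True,
) -> QcReport:
    """Calibrate, run every gate, and decide participant inclusion."""
    _require_columns(ct_records)
    dup = ct_records.duplicated(
        subset=["participant_id", "timepoint_min", "plate_id", "assay_id"]
    )
    if dup.any():
        raise QcError(f"{int(dup.sum())} duplicate (participant, timepoint, "
                      "plate, assay) Ct rows")
    cal = interplate_calibrate(ct_records) if calibrate else ct_records

    sample_rows = []
    for (pid, tp), sample in cal.groupby(["participant_id", "timepoint_min"],
                                         sort=True):
        rt_pass = rt_inhibition_gate(sample, rt_max_ct)
        index, haem_pass, haem_reason = haemolysis_gate(
            sample, haemolysis_max_index)
        reasons = []
        if not rt_pass:
            reasons.append("rt_inhibition")
        if not haem_pass:
            reasons.append(haem_reason or "haemolysis")
        sample_rows.append({
            "participant_id": pid, "timepoint_min": tp,
            "rt_inhibition_pass": rt_pass, "haemolysis_pass": haem_pass,
            "haemolysis_index": index,
            "sample_pass": rt_pass and haem_pass,
            "reasons": reasons,
        })
    samples = pd.DataFrame(sample_rows)

    participants: dict[str, dict] = {}
    for pid, part in cal.groupby("participant_id", sort=True):
        spikes = extraction_consistency_gate(part, extraction_max_range)
        extraction_pass = all(v["pass"] for v in spikes.values())
        gates = samples[samples["participant_id"] == pid]
        included, reasons = inclusion_rule(gates, extraction_pass)
        participants[pid] = {
            "extraction": spikes,
            "extraction_pass": extraction_pass,
            "included": included,
            "reasons": reasons,
        }
    return QcReport(
        samples=samples,
        participants=participants,
        thresholds={
            "rt_inhibition_max_ct": rt_max_ct,
            "haemolysis_max_index": haemolysis_max_index,
            "extraction_max_range": extraction_max_range,
        },
    )


def filtered_ct_table(ct_records: pd.DataFrame, report: QcReport,
                      calibrate: bool = True) -> pd.DataFrame:
    """Calibrated Ct rows restricted to included participants' passing samples."""
    cal = interplate_calibrate(ct_records) if calibrate else ct_records
    passing = report.samples[report.samples["sample_pass"]]
    included = set(report.included_participants())
    keys = {(r.participant_id, r.timepoint_min)
            for r in passing.itertuples() if r.participant_id in included}
    mask = [
        (r.participant_id, r.timepoint_min) in keys
        for r in cal.itertuples()
    ]
    return cal[np.array(mask, dtype=bool)].reset_index(drop=True)
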