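"""Synthetic cohort, qPCR-plate and count-matrix generator.

The generator reproduces the statistical structure the analysis stages
assume, so the whole pipeline is testable without patient-level data:

* a cohort with four glucose-tolerance groups whose OGTT glucose
  trajectories are built to classify into the intended group, and clinical
  analytes drawn within the published per-group baseline ranges;
* long-format Ct plates with endogenous serum controls (miR-16-5p,
  miR-23a-3p, miR-486-5p), extraction spike-ins (UniSp2/4/5), the
  interplate calibrator (UniSp3) and the RT/PCR control (UniSp6), with
  per-plate Ct offsets and injected haemolysis / RT-inhibition artifacts;
* a paired negative-binomial miRNA count matrix (baseline and 60 min) with
  group- and timepoint-specific log2 fold effects.

Target Cts are anchored to the sample's realized control Cts (targets are
generated as delta-Ct offsets), so control-based normalization exactly
inverts the construction when noise and plate offsets are zero; this makes
parameter recovery a sharp test.  Haemolysis is modelled as a decrease in
miR-451a Ct (erythrocyte miRNA release), which is what the haemolysis index
Ct(miR-23a-3p) - Ct(miR-451a) responds to.

Everything injected (artifacts, effects, coupling levels) is recorded in
``SyntheticDataset.truth``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mirogtt.cohort import (
    GROUPS,
    OGTT_TIMEPOINTS,
    ParticipantProfile,
    classify_glucose_tolerance,
)

# Per-group baseline clinical characteristics, (mean, low, high), from the
# study cohort the generator emulates.  Units: glucose mmol/l, insulin
# pmol/l, CRP mg/l, LPK 10^6 cells/l, enzymes U/l, age years.
COHORT_BASELINE_RANGES: dict[str, dict[str, tuple[float, float, float]]] = {
    "NGT": {
        "glucose": (5.3, 5.0, 6.8), "insulin": (47.4, 9.9, 119.0),
        "CRP": (2.9, 1.0, 12.0), "LPK": (6.9, 4.3, 10.2),
        "GGT": (21.8, 10.0, 100.0), "ALP": (94.5, 62.0, 157.0),
        "ALAT": (31.8, 14.0, 72.0), "ASAT": (27.7, 17.0, 47.0),
        "age": (27.0, 18.0, 42.0),
    },
    "INDET": {
        "glucose": (5.4, 5.0, 5.8), "insulin": (47.4, 37.2, 72.5),
        "CRP": (2.0, 1.0, 7.0), "LPK": (5.6, 3.9, 7.6),
        "GGT": (97.2, 10.0, 238.0), "ALP": (167.0, 55.0, 336.0),
        "ALAT": (31.5, 15.0, 54.0), "ASAT": (38.2, 16.0, 60.0),
        "age": (25.7, 18.0, 40.0),
    },
    "IGT": {
        "glucose": (5.5, 4.2, 6.8), "insulin": (31.9, 11.4, 62.7),
        "CRP": (3.8, 1.0, 19.0), "LPK": (7.0, 3.7, 10.1),
        "GGT": (37.0, 7.0, 190.0), "ALP": (112.3, 61.0, 335.0),
        "ALAT": (28.5, 12.0, 57.0), "ASAT": (30.9, 19.0, 75.0),
        "age": (38.4, 24.0, 53.0),
    },
    "CFRD": {
        "glucose": (7.7, 4.3, 11.0), "insulin": (37.8, 6.0, 136.0),
        "CRP": (5.4, 1.0, 36.0), "LPK": (7.7, 2.5, 14.9),
        "GGT": (105.7, 9.0, 767.0), "ALP": (161.6, 49.0, 391.0),
        "ALAT": (68.7, 16.0, 278.0), "ASAT": (39.3, 18.0, 118.0),
        "age": (32.1, 21.0, 45.0),
    },
}

#: The endogenous serum controls and their nominal Cts.
CONTROL_BASE_CT = {"miR-16-5p": 21.0, "miR-23a-3p": 24.0, "miR-486-5p": 23.0}

#: Spike-in nominal Cts (extraction: UniSp2/4/5; calibration: UniSp3; RT: UniSp6).
SPIKE_BASE_CT = {
    "UniSp2": 19.0,
    "UniSp4": 24.0,
    "UniSp5": 29.0,
    "UniSp3": 20.0,
    "UniSp6": 20.0,
}

#: Target panel: delta-Ct offset of each miRNA relative to the arithmetic
#: mean of the three control Cts (lower offset = more abundant).
TARGET_BASE_DELTA_CT = {
    "miR-34a-5p": 6.0,
    "miR-122-5p": 2.0,
    "miR-885-5p": 7.0,
    "miR-885-3p": 8.5,
    "miR-363-3p": 5.0,
    "miR-134-5p": 7.5,
    "miR-28-3p": 5.5,
    "miR-127-3p": 6.5,
    "miR-223-3p": 1.0,
    "miR-223-5p": 6.0,
    "miR-224-5p": 7.0,
    "miR-382-5p": 8.0,
    "miR-409-3p": 7.5,
    "miR-432-5p": 8.0,
    "miR-1301-3p": 9.0,
}

# Effects observed in the study this generator emulates: liver-enriched
# miR-122-5p and p53-responsive miR-34a-5p/miR-885-5p elevated at baseline
# in INDET and CFRD; miR-223-3p with a CFRD-specific positive and
# miR-363-3p a negative glucose response.
DEFAULT_BASELINE_LOG2FC = {
    ("miR-122-5p", "INDET"): 1.2,
    ("miR-122-5p", "CFRD"): 1.0,
    ("miR-34a-5p", "INDET"): 1.0,
    ("miR-34a-5p", "CFRD"): 0.8,
    ("miR-885-5p", "INDET"): 1.0,
    ("miR-885-5p", "CFRD"): 0.8,
}

DEFAULT_RESPONSE_LOG2FC = {
    ("miR-223-3p", "CFRD"): 1.5,
    ("miR-134-5p", "CFRD"): 1.2,
    ("miR-363-3p", "CFRD"): -1.0,
}

#: Liver-enzyme coupling of the hepatocyte-derived miRNAs.
DEFAULT_ANALYTE_COUPLING = {
    "miR-122-5p": ("ALAT", 0.6),
    "miR-34a-5p": ("ASAT", 0.5),
}

HAEMOLYSIS_ASSAY = "miR-451a"

#: Nominal haemolysis index Ct(miR-23a-3p) - Ct(miR-451a) for clean serum;
#: well under the gate at 7 cycles.
CLEAN_HAEMOLYSIS_INDEX = 5.0


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the emulated study design."""

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"NGT": 18, "INDET": 6, "IGT": 12, "CFRD": 14}
    )
    timepoints: tuple[int, ...] = OGTT_TIMEPOINTS
    plate_size: int = 15  # samples per 384-well custom panel plate
    plate_offsets_sd: float = 0.5  # cycles
    baseline_log2fc: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_LOG2FC)
    )
    response_log2fc: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_RESPONSE_LOG2FC)
    )
    # optional extra shifts keyed (mirna, group, timepoint); used to inject
    # single-timepoint effects for the time-course analysis
    timepoint_log2fc: dict[tuple[str, str, int], float] = field(default_factory=dict)
    ct_noise_sd: float = 0.25  # cycles
    haemolysis_fraction: float = 0.1
    inhibition_fraction: float = 0.05
    nb_dispersion: float = 0.1
    library_size_range: tuple[float, float] = (5e5, 2e6)
    analyte_coupling: dict[str, tuple[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_ANALYTE_COUPLING)
    )
    coupling_sd_log2: float = 0.5  # per-participant miRNA level spread (log2)
    target_mirnas: tuple[str, ...] = tuple(TARGET_BASE_DELTA_CT)
    n_background_mirnas: int = 200  # extra null miRNAs in the count matrix
    participant_sd_log2: float = 0.3  # paired lognormal factor for counts
    seed: int = 0

    def validate(self) -> None:
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if n < 0:
                raise ValueError("n_per_group entries must be >= 0")
        if all(n == 0 for n in self.n_per_group.values()):
            raise ValueError("empty cohort: every group has n_per_group == 0")
        for name, frac in (
            ("haemolysis_fraction", self.haemolysis_fraction),
            ("inhibition_fraction", self.inhibition_fraction),
        ):
            if not 0 <= frac <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name, sd in (
            ("plate_offsets_sd", self.plate_offsets_sd),
            ("ct_noise_sd", self.ct_noise_sd),
            ("coupling_sd_log2", self.coupling_sd_log2),
            ("participant_sd_log2", self.participant_sd_log2),
        ):
            if sd < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValueError("library_size_range must be positive and ordered")
        for m, (_, rho) in self.analyte_coupling.items():
            if not -1 <= rho <= 1:
                raise ValueError(f"coupling strength for {m} outside [-1, 1]")


@dataclass
class SyntheticDataset:
    """The generated cohort, Ct plates, count matrix and ground truth."""

    participants: list[ParticipantProfile]
    ct_records: pd.DataFrame
    counts: Optional[pd.DataFrame]
    count_meta: Optional[pd.DataFrame]
    truth: dict


def _beta_in_range(rng, mean: float, lo: float, hi: float, n: int,
                   z: Optional[np.ndarray] = None, concentration: float = 4.0):
    """Draw within [lo, hi] with the given mean via a Beta marginal.

    When latent standard normals ``z`` are supplied, the values are the
    monotone Beta-quantile map of Phi(z) — the Gaussian-copula marginal step.
    """
    if hi <= lo:
        return np.full(n, lo)
    mf = min(max((mean - lo) / (hi - lo), 0.05), 0.95)
    a, b = mf * concentration, (1.0 - mf) * concentration
    if z is None:
        u = rng.beta(a, b, size=n)
    else:
        u = stats.beta.ppf(stats.norm.cdf(z), a, b)
    return lo + (hi - lo) * u


def _glucose_trajectory(rng, group: str, baseline: float) -> tuple[dict, float]:
    """OGTT glucose series constructed to classify into ``group``."""
    if group == "NGT":
        peak = min(baseline + rng.uniform(2.5, 4.5), 10.8)
        g120 = rng.uniform(4.8, 7.4)
        g180 = rng.uniform(3.9, 7.0)
    elif group == "INDET":
        peak = rng.uniform(11.2, 14.5)
        g120 = rng.uniform(5.0, 7.4)
        g180 = rng.uniform(3.9, 7.0)
    elif group == "IGT":
        peak = rng.uniform(8.5, 10.9)
        g120 = rng.uniform(7.9, 10.9)
        g180 = rng.uniform(5.0, 9.0)
    elif group == "CFRD":
        peak = rng.uniform(12.0, 17.0)
        g120 = rng.uniform(11.2, 15.5)
        g180 = rng.uniform(7.0, 12.9)
    else:  # pragma: no cover
        raise ValueError(group)
    g10 = baseline + rng.uniform(0.1, 0.25) * (peak - baseline)
    g30 = baseline + rng.uniform(0.8, 1.0) * (peak - baseline)
    traj = {-1: baseline, 10: g10, 30: g30, 60: peak, 180: g180}
    return traj, g120


def simulate_cohort(config: SimulationConfig, rng: Optional[np.random.Generator] = None,
                    ) -> tuple[list[ParticipantProfile], dict]:
    """Generate participant profiles and the latent coupling truth.

    Glucose trajectories are built so that the classifier reproduces the
    intended group for every participant; clinical analytes are drawn
    within the published per-group baseline ranges; analyte-miRNA
    couplings are realized through a Gaussian copula at the configured
    Pearson-latent strength.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    profiles: list[ParticipantProfile] = []
    coupling_levels: dict[str, dict[str, float]] = {}
    for group in GROUPS:
        n = config.n_per_group.get(group, 0)
        ranges = COHORT_BASELINE_RANGES[group]
        for i in range(n):
            pid = f"{group}{i + 1:03d}"
            baseline = float(
                _beta_in_range(rng, *ranges["glucose"], 1)[0]
            )
            glucose, g120 = _glucose_trajectory(rng, group, baseline)
            # latent normals per analyte drive both the analyte value and
            # any coupled miRNA level (Gaussian copula)
            z = {a: rng.standard_normal() for a in
                 ("ASAT", "ALAT", "ALP", "GGT", "CRP", "LPK", "insulin")}
            analytes = {
                a: float(_beta_in_range(rng, *ranges[a], 1,
                                        z=np.array([z[a]]))[0])
                for a in ("ASAT", "ALAT", "ALP", "GGT", "CRP", "LPK")
            }
            ins_base = float(
                _beta_in_range(rng, *ranges["insulin"], 1,
                               z=np.array([z["insulin"]]))[0]
            )
            insulin = {
                tp: round(ins_base * max(0.2, 1.0 + 2.5 * (glucose[tp] - baseline)
                                         / max(baseline, 1.0)), 1)
                for tp in config.timepoints
            }
            levels = {}
            for mirna, (analyte, rho) in config.analyte_coupling.items():
                eps = rng.standard_normal()
                zm = rho * z[analyte] + np.sqrt(max(0.0, 1 - rho**2)) * eps
                levels[pid + "/" + mirna] = float(zm * config.coupling_sd_log2)
            coupling_levels.update(levels)
            profile = ParticipantProfile(
                participant_id=pid,
                glucose_by_timepoint={tp: round(glucose[tp], 1)
                                      for tp in config.timepoints},
                glucose_120=round(g120, 1),
                insulin_by_timepoint=insulin,
                analytes={k: round(v, 1) for k, v in analytes.items()},
                sex="male" if rng.random() < 0.5 else "female",
                age=round(float(_beta_in_range(rng, *ranges["age"], 1)[0]), 1),
            )
            if profile.group != group:  # pragma: no cover - construction guard
                raise AssertionError(
                    f"constructed glucose for {pid} classifies as "
                    f"{profile.group}, wanted {group}"
                )
            profiles.append(profile)
    truth = {"coupling_levels": coupling_levels,
             "analyte_coupling": {m: list(v) for m, v in
                                  config.analyte_coupling.items()}}
    return profiles, truth


def simulate_ct_plates(
    participants: Sequence[ParticipantProfile],
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    coupling_levels: Optional[Mapping[str, float]] = None,
) -> tuple[pd.DataFrame, dict]:
    """Generate the long-format Ct table with plate structure and artifacts.

    Returns the Ct DataFrame (columns participant_id, timepoint_min,
    plate_id, assay_id, ct) and the truth dict with per-plate offsets and
    the injected haemolysed / RT-inhibited sample lists.
    """
    if not participants:
        raise ValueError("participants must be non-empty")
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    coupling_levels = coupling_levels or {}
    group_of = {p.participant_id: p.group for p in participants}

    samples = [(p.participant_id, tp)
               for p in participants for tp in config.timepoints]
    n_plates = int(np.ceil(len(samples) / config.plate_size))
    plate_ids = [f"P{k + 1:02d}" for k in range(n_plates)]
    plate_offsets = {pid: float(rng.normal(0.0, config.plate_offsets_sd))
                     for pid in plate_ids}

    n_samples = len(samples)
    haemolysed = rng.random(n_samples) < config.haemolysis_fraction
    inhibited = rng.random(n_samples) < config.inhibition_fraction

    noise = config.ct_noise_sd
    rows = []
    truth_haem, truth_inhib = [], []
    for idx, (pid, tp) in enumerate(samples):
        plate = plate_ids[idx // config.plate_size]
        off = plate_offsets[plate]
        group = group_of[pid]

        def emit(assay: str, ct: float) -> None:
            rows.append((pid, tp, plate, assay, round(ct, 4)))

        control_ct = {}
        for assay, base in CONTROL_BASE_CT.items():
            control_ct[assay] = base + rng.normal(0.0, noise)
            emit(assay, control_ct[assay] + off)
        anchor = np.mean(list(control_ct.values()))

        for assay, base in SPIKE_BASE_CT.items():
            ct = base + rng.normal(0.0, noise)
            if assay == "UniSp6" and inhibited[idx]:
                ct = 23.0 + 1.0 + rng.uniform(0.0, 3.0)
            emit(assay, ct + off)
        if inhibited[idx]:
            truth_inhib.append((pid, tp))

        # haemolysis index realized on the same (pre-offset) scale as the
        # miR-23a-3p control of this sample; offsets cancel within-sample
        if haemolysed[idx]:
            index = 8.5 + abs(rng.normal(0.0, 1.0))
            truth_haem.append((pid, tp))
        else:
            index = CLEAN_HAEMOLYSIS_INDEX + rng.normal(0.0, noise)
        emit(HAEMOLYSIS_ASSAY, control_ct["miR-23a-3p"] - index + off)

        for mirna in config.target_mirnas:
            base_delta = TARGET_BASE_DELTA_CT.get(mirna, 6.0)
            effect = config.baseline_log2fc.get((mirna, group), 0.0)
            if tp == 60:
                effect += config.response_log2fc.get((mirna, group), 0.0)
            effect += config.timepoint_log2fc.get((mirna, group, tp), 0.0)
            effect += coupling_levels.get(pid + "/" + mirna, 0.0)
            ct = anchor + base_delta - effect + rng.normal(0.0, noise)
            emit(mirna, ct + off)

    df = pd.DataFrame(
        rows, columns=["participant_id", "timepoint_min", "plate_id",
                       "assay_id", "ct"]
    )
    truth = {
        "plate_offsets": plate_offsets,
        "haemolysed_samples": truth_haem,
        "inhibited_samples": truth_inhib,
        "baseline_log2fc": {f"{m}|{g}": v for (m, g), v in
                            config.baseline_log2fc.items()},
        "response_log2fc": {f"{m}|{g}": v for (m, g), v in
                            config.response_log2fc.items()},
    }
    return df, truth


def simulate_counts(
    participants: Sequence[ParticipantProfile],
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Paired negative-binomial count matrix at baseline and 60 min.

    counts_ij ~ NB(mean = library_size_j x base_abundance_i x
    2^(baseline + response effects) x participant factor, dispersion =
    ``nb_dispersion``); the per-participant lognormal factor encodes the
    paired design.  Returns (counts miRNA x sample, sample metadata, truth).
    """
    if not participants:
        raise ValueError("participants must be non-empty")
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    mirnas = list(config.target_mirnas) + [
        f"mir-null-{k + 1:03d}" for k in range(config.n_background_mirnas)
    ]
    n_mir = len(mirnas)
    base_log2 = rng.uniform(3.0, 12.0, size=n_mir)
    timepoints = (-1, 60)

    sample_ids, meta_rows = [], []
    mu_cols = []
    lib_lo, lib_hi = config.library_size_range
    mean_lib = np.sqrt(lib_lo * lib_hi)
    for p in participants:
        part_factor = 2.0 ** rng.normal(0.0, config.participant_sd_log2, size=n_mir)
        for tp in timepoints:
            sid = f"{p.participant_id}_t{tp}"
            lib = rng.uniform(lib_lo, lib_hi)
            effects = np.zeros(n_mir)
            for i, m in enumerate(mirnas):
                e = config.baseline_log2fc.get((m, p.group), 0.0)
                if tp == 60:
                    e += config.response_log2fc.get((m, p.group), 0.0)
                effects[i] = e
            mu = (lib / mean_lib) * 2.0 ** (base_log2 + effects) * part_factor
            mu_cols.append(mu)
            sample_ids.append(sid)
            meta_rows.append({"sample_id": sid,
                              "participant_id": p.participant_id,
                              "timepoint_min": tp, "group": p.group})
    mu_mat = np.column_stack(mu_cols)
    if config.nb_dispersion <= 1e-12:
        counts = rng.poisson(mu_mat)
    else:
        shape = 1.0 / config.nb_dispersion
        lam = rng.gamma(shape, mu_mat * config.nb_dispersion)
        counts = rng.poisson(lam)
    counts_df = pd.DataFrame(counts, index=mirnas, columns=sample_ids)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    truth = {
        "base_log2_abundance": dict(zip(mirnas, base_log2.round(4))),
        "response_log2fc": {f"{m}|{g}": v for (m, g), v in
                            config.response_log2fc.items()},
        "baseline_log2fc": {f"{m}|{g}": v for (m, g), v in
                            config.baseline_log2fc.items()},
    }
    return counts_df, meta, truth


def simulate_dataset(config: Optional[SimulationConfig] = None,
                     n_sequenced_per_group: int = 3) -> SyntheticDataset:
    """Full study emulation: cohort, Ct plates and a paired count matrix.

    The count matrix covers ``n_sequenced_per_group`` participants per group
    (the sequencing sub-study design) at the -1 and 60 min timepoints.
    Deterministic given ``config.seed``.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    participants, truth = simulate_cohort(config, rng)
    ct_records, plate_truth = simulate_ct_plates(
        participants, config, rng, truth["coupling_levels"]
    )
    truth.update(plate_truth)
    by_group: dict[str, list[ParticipantProfile]] = {g: [] for g in GROUPS}
    for p in participants:
        by_group[p.group].append(p)
    sequenced = [p for g in GROUPS
                 for p in by_group[g][:n_sequenced_per_group]]
    counts, meta, count_truth = (None, None, {})
    if sequenced:
        counts, meta, count_truth = simulate_counts(sequenced, config, rng)
    truth["counts"] = count_truth
    return SyntheticDataset(participants=participants, ct_records=ct_records,
                            counts=counts, count_meta=meta, truth=truth)
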