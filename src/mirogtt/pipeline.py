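"""End-to-end orchestration: configuration, validation, staged execution.

``run_pipeline`` chains classification, interplate calibration, sample QC,
both normalization schemes, the per-timepoint volcano comparisons, the
baseline ANOVA and mixed-effects time course, the optional count-matrix
response arm, the analyte correlation panel and (when target/pathway files
are supplied) the over-representation analysis.  Every decision threshold
lives in one ``Thresholds`` namespace, so printed defaults are defaults,
not constants.  All outputs are tidy CSV/JSON plus a manifest with the
configuration hash and seed; a fixed config and seed reproduce the run
byte for byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from mirogtt import cohort, qc, quantify, response, association, enrichment
from mirogtt.simulate import SimulationConfig, simulate_dataset

log = logging.getLogger("mirogtt")


@dataclass
class Thresholds:
    """Every decision threshold of the pipeline, with the study defaults."""

    diabetes_glucose: float = 11.1      # mmol/l, CFRD / INDET trigger
    igt_glucose: float = 7.8            # mmol/l, IGT lower bound
    haemolysis_max_index: float = 7.0   # delta-Ct cycles
    rt_inhibition_max_ct: float = 23.0  # UniSp6 Ct cycles
    extraction_max_range: float = 3.0   # spike-in Ct range, cycles
    volcano_fold: float = 1.5           # qPCR volcano fold cut-off
    response_fold: float = 2.0          # count-arm volcano fold cut-off
    alpha: float = 0.05                 # nominal / FDR significance level
    expressed_min_count: float = 5.0    # normalized counts, strict >
    expressed_min_fraction: float = 0.5
    pseudocount: float = 0.5            # for count log-ratios

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"threshold {f.name} must be positive")


@dataclass
class PipelineConfig:
    """Input/output paths, scheme selections, thresholds and the seed."""

    ct_table: Optional[str] = None
    sample_sheet: Optional[str] = None
    analyte_table: Optional[str] = None
    counts: Optional[str] = None
    count_meta: Optional[str] = None
    targets: Optional[str] = None
    pathways: Optional[str] = None
    universe: Optional[str] = None
    simulate: bool = False
    sim_n_per_group: Optional[dict] = None  # override the cohort size
    equal_variance_t: bool = True
    correlation_value: str = "fold"  # expression scheme fed to correlations
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        thresholds = raw.pop("thresholds", {})
        t_known = {f.name for f in dataclasses.fields(Thresholds)}
        t_unknown = set(thresholds) - t_known
        if t_unknown:
            raise ValueError(f"unknown threshold keys: {sorted(t_unknown)}")
        cfg = cls(**raw, thresholds=Thresholds(**thresholds))
        cfg.thresholds.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def validate_inputs(config: PipelineConfig) -> dict:
    """Schema checks per input file; machine-readable report."""
    report: dict[str, dict] = {}

    def check(name, path, fn):
        if path is None:
            return
        entry: dict = {"path": str(path), "errors": []}
        try:
            fn(entry)
        except FileNotFoundError as exc:
            entry["errors"].append(f"unreadable: {exc}")
        report[name] = entry
        entry["ok"] = not entry["errors"]

    def check_ct(entry):
        df = pd.read_csv(config.ct_table, sep=None, engine="python")
        missing = set(qc.CT_COLUMNS) - set(df.columns)
        if missing:
            entry["errors"].append(f"missing columns: {sorted(missing)}")
            return
        dup = df.duplicated(["participant_id", "timepoint_min", "plate_id",
                             "assay_id"])
        if dup.any():
            entry["errors"].append(
                f"{int(dup.sum())} duplicate (participant, timepoint, "
                "plate, assay) rows")
        bad_ct = df["ct"].dropna() <= 0
        if bad_ct.any():
            entry["errors"].append(f"{int(bad_ct.sum())} non-positive Cts")

    def check_samples(entry):
        df = pd.read_csv(config.sample_sheet, sep=None, engine="python")
        required = {"participant_id", "timepoint_min", "glucose_mmol_l"}
        missing = required - set(df.columns)
        if missing:
            entry["errors"].append(f"missing columns: {sorted(missing)}")
            return
        dup = df.duplicated(["participant_id", "timepoint_min"])
        if dup.any():
            entry["errors"].append(
                f"{int(dup.sum())} duplicate (participant, timepoint) rows")
        bad = df["glucose_mmol_l"].dropna() <= 0
        if bad.any():
            entry["errors"].append(
                f"{int(bad.sum())} non-positive glucose values")

    def check_counts(entry):
        df = pd.read_csv(config.counts, sep="\t", index_col=0)
        if (df.to_numpy() < 0).any():
            entry["errors"].append("negative counts")

    check("ct_table", config.ct_table, check_ct)
    check("sample_sheet", config.sample_sheet, check_samples)
    check("counts", config.counts, check_counts)
    report["ok"] = all(v.get("ok", True) for v in report.values()
                       if isinstance(v, dict))
    return report


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _config_hash(config: PipelineConfig) -> str:
    text = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Execute every applicable stage and write the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    th.validate()
    manifest: dict = {"config_hash": _config_hash(config),
                      "seed": config.seed,
                      "thresholds": dataclasses.asdict(th),
                      "stages": {}}

    def stage(name):
        def deco(fn):
            try:
                out = fn()
            except Exception as exc:
                manifest["stages"][name] = {"status": "failed",
                                            "error": str(exc)}
                (outdir / "manifest.json").write_text(
                    json.dumps(manifest, indent=2, sort_keys=True))
                raise StageError(name, exc) from exc
            manifest["stages"][name] = {"status": "ok", **(out or {})}
            log.info("stage %s: %s", name, manifest["stages"][name])
            return out

        return deco

    # ---- load or simulate -------------------------------------------------
    if config.simulate:
        sim_cfg = (SimulationConfig(seed=config.seed,
                                    n_per_group=dict(config.sim_n_per_group))
                   if config.sim_n_per_group
                   else SimulationConfig(seed=config.seed))
        ds = simulate_dataset(sim_cfg)
        profiles = ds.participants
        ct_df = ds.ct_records
        counts_df, count_meta = ds.counts, ds.count_meta
        sheet, analytes = cohort.profiles_to_frames(profiles)
        sheet.to_csv(outdir / "sample_sheet.csv", index=False)
        analytes.to_csv(outdir / "analytes.csv", index=False)
        ct_df.to_csv(outdir / "ct_table.csv", index=False)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(ds.truth, fh, indent=2, sort_keys=True, default=str)
    else:
        if config.ct_table is None or config.sample_sheet is None:
            raise StageError("load", ValueError(
                "ct_table and sample_sheet are required unless simulate=true"))
        report = validate_inputs(config)
        if not report["ok"]:
            raise StageError("validate", ValueError(json.dumps(report)))
        ct_df = pd.read_csv(config.ct_table, sep=None, engine="python")
        sheet = pd.read_csv(config.sample_sheet, sep=None, engine="python")
        analytes = (pd.read_csv(config.analyte_table, sep=None,
                                engine="python")
                    if config.analyte_table else None)
        profiles = cohort.profiles_from_sample_sheet(sheet, analytes)
        counts_df = count_meta = None
        if config.counts and config.count_meta:
            counts_df = pd.read_csv(config.counts, sep="\t", index_col=0)
            count_meta = pd.read_csv(config.count_meta, sep="\t",
                                     index_col=0)

    groups = cohort.group_labels(profiles)

    @stage("classify")
    def _classify():
        _, analyte_frame = cohort.profiles_to_frames(profiles)
        analyte_frame.to_csv(outdir / "groups.csv", index=False)
        counts = pd.Series(list(groups.values())).value_counts().to_dict()
        return {"participants": len(profiles), "by_group": counts}

    @stage("qc")
    def _qc():
        report = qc.run_qc(
            ct_df,
            rt_max_ct=th.rt_inhibition_max_ct,
            haemolysis_max_index=th.haemolysis_max_index,
            extraction_max_range=th.extraction_max_range,
        )
        report.to_json(outdir / "qc_report.json")
        filtered = qc.filtered_ct_table(ct_df, report)
        filtered.to_csv(outdir / "ct_filtered.csv", index=False)
        n_samples = len(report.samples)
        return {
            "samples_in": n_samples,
            "samples_pass": int(report.samples["sample_pass"].sum()),
            "participants_in": len(report.participants),
            "participants_included": len(report.included_participants()),
        }

    filtered = pd.read_csv(outdir / "ct_filtered.csv")

    @stage("quantify")
    def _quantify():
        expr_dct = quantify.normalize_group_timepoint(filtered, groups)
        expr_ddct = quantify.normalize_ddct(filtered, groups)
        expr_dct.to_csv(outdir / "expression_dct.csv", index=False)
        expr_ddct.to_csv(outdir / "expression_ddct.csv", index=False)
        return {"records_dct": len(expr_dct), "records_ddct": len(expr_ddct)}

    expr_dct = pd.read_csv(outdir / "expression_dct.csv")
    expr_ddct = pd.read_csv(outdir / "expression_ddct.csv")

    @stage("volcano")
    def _volcano():
        frames = []
        for tp in (-1, 30, 60):
            for grp in ("INDET", "IGT", "CFRD"):
                if grp not in groups.values():
                    continue
                frames.append(quantify.volcano_per_timepoint(
                    expr_dct, "NGT", grp, tp,
                    fold_cutoff=th.volcano_fold, alpha=th.alpha,
                    equal_var=config.equal_variance_t))
        vol = pd.concat(frames, ignore_index=True)
        vol.to_csv(outdir / "volcano.csv", index=False)
        n_sig = int((vol["volcano_class"].isin(["up", "down"])).sum())
        return {"comparisons": len(frames), "significant": n_sig}

    @stage("timecourse")
    def _timecourse():
        anova_rows, contrast_frames = [], []
        for mirna in sorted(expr_ddct["mirna"].unique()):
            try:
                res = quantify.baseline_group_anova(expr_ddct, mirna)
            except quantify.DegenerateDataError:
                continue
            anova_rows.append({"mirna": mirna, "f": res["f"], "p": res["p"]})
            try:
                mx = quantify.dynamic_mixed_effects(expr_ddct, mirna)
            except (RuntimeError, quantify.DegenerateDataError) as exc:
                log.warning("time course for %s skipped: %s", mirna, exc)
                continue
            c = mx["contrasts"].copy()
            c.insert(0, "mirna", mirna)
            contrast_frames.append(c)
        pd.DataFrame(anova_rows).to_csv(outdir / "baseline_anova.csv",
                                        index=False)
        if contrast_frames:
            pd.concat(contrast_frames, ignore_index=True).to_csv(
                outdir / "timecourse_contrasts.csv", index=False)
        return {"mirnas": len(anova_rows)}

    if counts_df is not None:
        @stage("response")
        def _response():
            cm = response.CountMatrix(counts_df, count_meta)
            frames = []
            for grp in ("INDET", "IGT", "CFRD"):
                if grp not in set(count_meta["group"]):
                    continue
                frames.append(response.differential_response(
                    cm, grp, pseudocount=th.pseudocount,
                    fold_cutoff=th.response_fold, alpha=th.alpha,
                    min_count=th.expressed_min_count,
                    min_fraction=th.expressed_min_fraction))
            res = pd.concat(frames, ignore_index=True)
            res.to_csv(outdir / "response.csv", index=False)
            base = response.baseline_de(
                cm, "NGT", "CFRD", pseudocount=th.pseudocount,
                min_count=th.expressed_min_count,
                min_fraction=th.expressed_min_fraction)
            base.to_csv(outdir / "baseline_de.csv", index=False)
            return {"tested": len(res),
                    "significant": int((res["q"] < th.alpha).sum())}

    @stage("correlate")
    def _correlate():
        _, analyte_frame = cohort.profiles_to_frames(profiles)
        panel = association.correlate_panel(
            expr_ddct, analyte_frame, value_col=config.correlation_value)
        panel.to_csv(outdir / "correlations.csv", index=False)
        return {"pairs": len(panel)}

    if config.targets and config.pathways and config.universe:
        @stage("enrich")
        def _enrich():
            targets = enrichment.read_targets(config.targets)
            pathways = enrichment.read_gmt(config.pathways)
            universe = [
                line.strip() for line in open(config.universe)
                if line.strip()
            ]
            mirnas = sorted(set(targets["mirna"]))
            common = enrichment.common_targets(targets, mirnas, universe)
            ora = enrichment.hypergeom_ora(common["common"], pathways,
                                           universe)
            ora.to_csv(outdir / "enrichment.csv", index=False)
            with open(outdir / "common_targets.json", "w") as fh:
                json.dump(common, fh, indent=2, sort_keys=True)
            return {"common_targets": len(common["common"]),
                    "pathways": len(ora)}

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    summary_lines = [f"mirogtt run {manifest['config_hash']} seed={config.seed}"]
    for name, info in manifest["stages"].items():
        summary_lines.append(f"  {name}: " + ", ".join(
            f"{k}={v}" for k, v in info.items() if k != "status"))
    (outdir / "summary.txt").write_text("\n".join(summary_lines) + "\n")
    return outdir
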