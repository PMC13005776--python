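"""Normalization schemes, volcano classification and time-course analysis.

Two normalization schemes over the calibrated Ct table, both against the
three endogenous serum controls (miR-16-5p, miR-23a-3p, miR-486-5p):

* ``group_timepoint_mean`` — per sample, delta Ct = Ct(miRNA) - arithmetic
  mean of the three control Cts; feeds the per-timepoint two-group volcano
  comparisons.
* ``geometric_ngt_baseline`` — per sample, the geometric mean of the three
  control Cts (on the Ct scale) is subtracted; then the NGT-baseline
  reference is subtracted, giving delta-delta Ct and fold = 2^(-ddCt).
  The reference is the log2 of the geometric mean of the NGT-baseline
  expression values, i.e. the arithmetic mean of their in-sample
  normalized Cts, so the geometric mean of fold over NGT baseline is 1
  exactly.

Downstream: equal-variance two-sample t volcano with cut-offs at 1.5-fold
and p<0.05; one-way ANOVA with Tukey HSD across the four groups at
baseline; and a random-intercept mixed model over the full time course
with per-timepoint pairwise group contrasts left uncorrected (Fisher's
LSD convention).
"""

from __future__ import annotations

import itertools
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

from mirogtt.qc import CONTROL_ASSAYS

SCHEME_GROUP_TIMEPOINT = "group_timepoint_mean"
SCHEME_DDCT = "geometric_ngt_baseline"


class NormalizationError(ValueError):
    pass


class DegenerateDataError(ValueError):
    pass


def _control_stats(ct_records: pd.DataFrame) -> pd.DataFrame:
    """Per-sample arithmetic and geometric means of the three control Cts.

    Samples missing any control (undetected or absent) are dropped.
    """
    ctrl = ct_records[ct_records["assay_id"].isin(CONTROL_ASSAYS)]
    wide = ctrl.pivot_table(index=["participant_id", "timepoint_min"],
                            columns="assay_id", values="ct", aggfunc="mean")
    complete = wide.dropna()
    if len(complete) < len(wide):
        dropped = wide.index.difference(complete.index)
        warnings.warn(
            f"{len(dropped)} sample(s) dropped: endogenous control "
            f"undetected ({list(dropped[:5])}...)", stacklevel=3,
        )
    out = pd.DataFrame(index=complete.index)
    out["control_mean"] = complete.mean(axis=1)
    out["control_geomean"] = np.exp(np.log(complete).mean(axis=1))
    return out


def _target_table(ct_records: pd.DataFrame,
                  groups: dict[str, str]) -> pd.DataFrame:
    mask = ~ct_records["assay_id"].isin(
        set(CONTROL_ASSAYS) | {"UniSp2", "UniSp3", "UniSp4", "UniSp5",
                               "UniSp6"}
    )
    targets = ct_records[mask].dropna(subset=["ct"]).copy()
    targets["group"] = targets["participant_id"].map(groups)
    if targets["group"].isna().any():
        unknown = targets.loc[targets["group"].isna(),
                              "participant_id"].unique()
        raise NormalizationError(
            f"no group label for participant(s): {list(unknown[:5])}"
        )
    return targets.rename(columns={"assay_id": "mirna"})


def normalize_group_timepoint(ct_records: pd.DataFrame,
                              groups: dict[str, str]) -> pd.DataFrame:
    """Per-sample delta Ct against the arithmetic control mean.

    Returns a tidy frame (participant_id, timepoint_min, group, mirna,
    delta_ct, rel_expr, scheme) with rel_expr = 2^(-delta_ct).
    """
    ctrl = _control_stats(ct_records)
    targets = _target_table(ct_records, groups)
    merged = targets.merge(ctrl, left_on=["participant_id", "timepoint_min"],
                           right_index=True, how="inner")
    merged["delta_ct"] = merged["ct"] - merged["control_mean"]
    merged["rel_expr"] = 2.0 ** (-merged["delta_ct"])
    merged["scheme"] = SCHEME_GROUP_TIMEPOINT
    return merged[["participant_id", "timepoint_min", "group", "mirna",
                   "delta_ct", "rel_expr", "scheme"]].reset_index(drop=True)


def normalize_ddct(ct_records: pd.DataFrame,
                   groups: dict[str, str],
                   reference_group: str = "NGT",
                   reference_timepoint: int = -1) -> pd.DataFrame:
    """Delta-delta Ct against the NGT-baseline reference.

    In-sample step: subtract the geometric mean of the three control Cts
    (computed on the Ct scale).  Between-group step: subtract, per miRNA,
    the reference value over NGT baseline samples — the arithmetic mean of
    their in-sample normalized Cts, equivalently the log2 of the geometric
    mean of their expression.  fold = 2^(-ddct).
    """
    ctrl = _control_stats(ct_records)
    targets = _target_table(ct_records, groups)
    merged = targets.merge(ctrl, left_on=["participant_id", "timepoint_min"],
                           right_index=True, how="inner")
    merged["delta_ct"] = merged["ct"] - merged["control_geomean"]
    ref_mask = (merged["group"] == reference_group) & (
        merged["timepoint_min"] == reference_timepoint)
    if not ref_mask.any():
        raise NormalizationError(
            f"no {reference_group} samples at {reference_timepoint} min "
            "passed QC; the ddCt reference cannot be formed"
        )
    ref = merged[ref_mask].groupby("mirna")["delta_ct"].mean()
    missing_ref = set(merged["mirna"]) - set(ref.index)
    if missing_ref:
        raise NormalizationError(
            f"no {reference_group} baseline measurement for miRNA(s): "
            f"{sorted(missing_ref)[:5]}"
        )
    merged["ddct"] = merged["delta_ct"] - merged["mirna"].map(ref)
    merged["fold"] = 2.0 ** (-merged["ddct"])
    merged["scheme"] = SCHEME_DDCT
    return merged[["participant_id", "timepoint_min", "group", "mirna",
                   "delta_ct", "ddct", "fold", "scheme"]].reset_index(drop=True)


def volcano_per_timepoint(
    expr: pd.DataFrame,
    group_a: str,
    group_b: str,
    timepoint: int,
    *,
    fold_cutoff: float = 1.5,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Two-group differential expression at one timepoint, volcano style.

    Per miRNA: a two-sample Student's t test (equal variances by default)
    on the per-sample delta Ct values; fold change = ratio of group mean
    relative expression (``group_b`` over ``group_a``).  Class ``up`` iff
    fold >= ``fold_cutoff`` and p < ``alpha``; ``down`` iff fold <=
    1/``fold_cutoff`` and p < ``alpha``; otherwise ``ns``.  miRNAs with
    fewer than two samples in either group are skipped with a reason.
    """
    sub = expr[expr["timepoint_min"] == timepoint]
    rows = []
    for mirna, d in sub.groupby("mirna", sort=True):
        a = d.loc[d["group"] == group_a, "delta_ct"].to_numpy(float)
        b = d.loc[d["group"] == group_b, "delta_ct"].to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            rows.append({"mirna": mirna, "comparison":
                         f"{group_b} vs {group_a} @ {timepoint} min",
                         "log2fc": np.nan, "fold": np.nan, "p": np.nan,
                         "volcano_class": "skipped",
                         "reason": "fewer_than_two_samples_in_a_group"})
            continue
        fold = float(np.mean(2.0 ** (-b)) / np.mean(2.0 ** (-a)))
        t, p = stats.ttest_ind(b, a, equal_var=equal_var)
        if fold >= fold_cutoff and p < alpha:
            cls = "up"
        elif fold <= 1.0 / fold_cutoff and p < alpha:
            cls = "down"
        else:
            cls = "ns"
        rows.append({"mirna": mirna,
                     "comparison": f"{group_b} vs {group_a} @ {timepoint} min",
                     "log2fc": float(np.log2(fold)), "fold": fold,
                     "p": float(p), "volcano_class": cls, "reason": ""})
    return pd.DataFrame(rows)


def baseline_group_anova(expr: pd.DataFrame, mirna: str,
                         timepoint: int = -1,
                         value_col: str = "fold") -> dict:
    """One-way ANOVA across groups at baseline with Tukey HSD post hoc.

    Operates on the fold values of the ddCt scheme.  Returns the omnibus p
    and a tidy DataFrame of pairwise Tukey comparisons (studentized-range
    distribution).
    """
    sub = expr[(expr["mirna"] == mirna) &
               (expr["timepoint_min"] == timepoint)]
    samples, names = [], []
    for group, d in sub.groupby("group", sort=True):
        vals = d[value_col].to_numpy(float)
        if len(vals) >= 2:
            samples.append(vals)
            names.append(group)
    if len(samples) < 2:
        raise DegenerateDataError(
            f"need >=2 groups with >=2 samples for {mirna} at "
            f"{timepoint} min"
        )
    if all(np.ptp(s) == 0 for s in samples):
        raise DegenerateDataError(
            "zero within-group variance in every group; ANOVA undefined")
    f_stat, p = stats.f_oneway(*samples)
    tukey = stats.tukey_hsd(*samples)
    pair_rows = []
    for i, j in itertools.combinations(range(len(samples)), 2):
        pair_rows.append({
            "group_a": names[i], "group_b": names[j],
            "mean_diff": float(np.mean(samples[j]) - np.mean(samples[i])),
            "p": float(tukey.pvalue[i, j]),
        })
    return {"mirna": mirna, "f": float(f_stat), "p": float(p),
            "groups": names, "tukey": pd.DataFrame(pair_rows)}


def dynamic_mixed_effects(
    expr: pd.DataFrame,
    mirna: str,
    value_col: str = "ddct",
    reference_group: str = "NGT",
) -> dict:
    """Random-intercept mixed model over the OGTT time course.

    Fits ``value ~ group * timepoint`` with a per-participant random
    intercept by REML, then tests every pairwise group contrast at every
    timepoint with no multiplicity correction (Fisher's LSD convention).
    Missing timepoints are allowed.  Returns the fitted result, the fixed
    effects and a tidy contrast table (timepoint, group_a, group_b,
    estimate, se, z, p).  Non-convergence raises with diagnostics.
    """
    sub = expr[expr["mirna"] == mirna].copy()
    if sub.empty:
        raise DegenerateDataError(f"no records for {mirna}")
    sub["value"] = sub[value_col].astype(float)
    sub["tp"] = sub["timepoint_min"].astype(str)
    groups_present = sorted(sub["group"].unique())
    formula = (
        f"value ~ C(group, Treatment('{reference_group}')) * C(tp)"
        if reference_group in groups_present else "value ~ C(group) * C(tp)"
    )
    model = smf.mixedlm(formula, data=sub, groups=sub["participant_id"])
    fit = None
    errors = []
    # a variance component on the boundary (random intercept ~ 0) is a
    # legitimate REML solution, so only true optimizer failure is fatal
    for method in ("lbfgs", "bfgs", "powell", "cg"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                candidate = model.fit(reml=True, method=method)
            except (np.linalg.LinAlgError, ValueError) as exc:
                errors.append(f"{method}: {exc}")
                continue
        if getattr(candidate, "converged", True):
            fit = candidate
            break
        errors.append(f"{method}: optimizer did not converge")
    if fit is None:
        raise RuntimeError(
            f"mixed model for {mirna} did not converge "
            f"(n={len(sub)}, groups={groups_present}); " + "; ".join(errors)
        )
    design_info = model.data.design_info
    from patsy import build_design_matrices

    k_fe = len(fit.fe_params)
    cov = np.asarray(fit.cov_params())[:k_fe, :k_fe]
    fe = np.asarray(fit.fe_params)
    rows = []
    for tp in sorted(sub["timepoint_min"].unique()):
        for ga, gb in itertools.combinations(groups_present, 2):
            (xa,) = build_design_matrices(
                [design_info], {"group": [ga], "tp": [str(tp)]})
            (xb,) = build_design_matrices(
                [design_info], {"group": [gb], "tp": [str(tp)]})
            L = np.asarray(xb)[0] - np.asarray(xa)[0]
            est = float(L @ fe)
            se = float(np.sqrt(max(L @ cov @ L, 0.0)))
            z = est / se if se > 0 else 0.0
            p = float(2 * stats.norm.sf(abs(z))) if se > 0 else 1.0
            rows.append({"timepoint_min": tp, "group_a": ga, "group_b": gb,
                         "estimate": est, "se": se, "z": z, "p": p})
    return {"mirna": mirna, "result": fit,
            "fixed_effects": fit.fe_params,
            "contrasts": pd.DataFrame(rows)}
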