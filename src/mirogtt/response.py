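"""Count-matrix arm: normalization, expressed filter and response testing.

Counts are normalized by median-of-ratios size factors (the DESeq2
normalization, reimplemented), filtered to expressed miRNAs (more than
five normalized counts in at least half of the samples), then tested:

* ``baseline_de`` — Welch t on log2(normalized + pseudocount) between two
  groups at baseline, BH-adjusted.
* ``differential_response`` — the glucose-response (group x timepoint
  interaction) test.  Per participant, the paired log-ratio
  r_i = log2((n60 + c) / (n0 + c)) on normalized counts summarizes the
  baseline-to-60-min change; the interaction effect is mean r in the test
  group minus mean r in NGT, with a Wald-type z from the pooled two-sample
  standard error and a two-sided normal p.  Pairing within participant is
  the correction for participant-level variability.  This is a deliberate
  simplification of a negative-binomial GLM with dispersion shrinkage:
  same estimand (the group x timepoint interaction on the log scale),
  desk-scale and checkable against exhaustive arithmetic.

With three participants per group the per-miRNA pooled variance has four
degrees of freedom, so a raw Wald z would be t4-distributed under the
null — far too heavy-tailed for a normal reference.  The pooled variances
are therefore squeezed across miRNAs with the standard empirical-Bayes
scaled-F model (prior df and scale estimated by moments of log s^2)
before forming the z, which makes the normal p defensible and stabilises
the ranking; ``moderate=False`` restores the raw per-miRNA SE.

Volcano classes use cut-offs at 2-fold (|effect| >= 1 log2 unit) and BH
FDR < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class CountDataError(ValueError):
    pass


@dataclass
class CountMatrix:
    """miRNA x sample counts plus sample metadata.

    ``counts``: non-negative integer DataFrame, rows miRNAs, columns sample
    ids.  ``meta``: indexed by sample id with columns participant_id,
    timepoint_min (in {-1, 60}) and group.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    size_factors: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.meta.index):
            missing = set(self.counts.columns) ^ set(self.meta.index)
            if missing:
                raise CountDataError(
                    f"counts columns and metadata index disagree: {sorted(missing)[:5]}"
                )
            self.meta = self.meta.loc[self.counts.columns]
        if (self.counts.to_numpy() < 0).any():
            raise CountDataError("counts must be non-negative")

    def normalized(self) -> pd.DataFrame:
        if self.size_factors is None:
            self.size_factors = size_factors_median_of_ratios(self.counts)
        return self.counts / self.size_factors


def size_factors_median_of_ratios(counts: pd.DataFrame,
                                  pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    s_j = median over reference miRNAs of count_ij / geometric-mean_i.  The
    reference set is the miRNAs with all-positive counts; when none exist,
    ``pseudo_reference=True`` computes each miRNA's geometric mean over its
    positive counts only (and takes the median over miRNAs positive in the
    sample), otherwise an error instructs to enable it.
    """
    mat = counts.to_numpy(float)
    all_positive = (mat > 0).all(axis=1)
    if all_positive.any() and not pseudo_reference:
        ref = mat[all_positive]
        geo = np.exp(np.log(ref).mean(axis=1))
        sf = np.median(ref / geo[:, None], axis=0)
    elif pseudo_reference:
        with np.errstate(divide="ignore"):
            logs = np.where(mat > 0, np.log(mat), np.nan)
        geo = np.exp(np.nanmean(logs, axis=1))
        keep = np.isfinite(geo) & (geo > 0)
        if not keep.any():
            raise CountDataError("no miRNA with any positive count")
        ratios = np.where(mat[keep] > 0, mat[keep] / geo[keep, None], np.nan)
        sf = np.nanmedian(ratios, axis=0)
    else:
        raise CountDataError(
            "no miRNA has positive counts in every sample; rerun with "
            "pseudo_reference=True to use positive-count geometric means"
        )
    if not (np.isfinite(sf).all() and (sf > 0).all()):
        raise CountDataError("size factors must be finite and positive")
    return pd.Series(sf, index=counts.columns, name="size_factor")


def filter_expressed(normalized: pd.DataFrame, min_count: float = 5.0,
                     min_fraction: float = 0.5) -> pd.Index:
    """Expressed miRNAs: normalized count strictly above ``min_count`` in at
    least ``min_fraction`` of the samples (fraction inclusive)."""
    frac = (normalized > min_count).mean(axis=1)
    return normalized.index[frac >= min_fraction]


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} min(1, m * p_(j) / j) over the ordered p-values.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _inv_trigamma(y: float) -> float:
    """Solve polygamma(1, x) = y for x > 0 (Newton, as in limma)."""
    from scipy.special import polygamma

    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(polygamma(1, x))
        step = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += step
        if abs(step) < 1e-10 * x:
            break
    return x


def moderate_variances(s2: np.ndarray, df: int) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes squeeze of sample variances toward a common value.

    Models s2_i ~ s0^2 * F(df, d0) and estimates the prior scale s0^2 and
    prior df d0 by moments of log s2 (digamma/trigamma inversion).
    Returns (moderated variances (d0*s0^2 + df*s2)/(d0 + df), d0, s0^2).
    Zero variances (possible with identical small counts) are excluded
    from estimation and receive the prior-dominated value.
    """
    from scipy.special import digamma, polygamma

    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if pos.size < 2:
        # nothing to learn from; fall back to the grand mean
        s0 = float(s2.mean()) if s2.mean() > 0 else 1e-8
        return np.full_like(s2, s0), np.inf, s0
    z = np.log(pos)
    e_constant = float(digamma(df / 2.0) - np.log(df / 2.0))
    var_z = float(z.var(ddof=1)) - float(polygamma(1, df / 2.0))
    if var_z > 0:
        d0 = 2.0 * _inv_trigamma(var_z)
        s0 = float(np.exp(z.mean() - e_constant
                          + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        mod = (d0 * s0 + df * s2) / (d0 + df)
    else:
        # variances more concentrated than chi-square sampling alone:
        # infinite prior df, every variance shrunk to the common value
        d0 = np.inf
        s0 = float(np.exp(z.mean() - e_constant))
        mod = np.full_like(s2, s0)
    return mod, d0, s0


def _paired_log_ratios(cm: CountMatrix, pseudocount: float) -> pd.DataFrame:
    """Per-participant log2((n60+c)/(n0+c)) matrix (miRNA x participant)."""
    norm = cm.normalized()
    meta = cm.meta
    by_tp = {}
    for tp in (-1, 60):
        cols = meta.index[meta["timepoint_min"] == tp]
        sub = norm[cols]
        sub.columns = meta.loc[cols, "participant_id"]
        by_tp[tp] = sub
    base, sixty = by_tp[-1], by_tp[60]
    common = base.columns.intersection(sixty.columns)
    unpaired = set(base.columns) ^ set(sixty.columns)
    if unpaired:
        raise CountDataError(
            f"participants without a complete -1/60 min pair: "
            f"{sorted(unpaired)[:5]}"
        )
    return np.log2((sixty[common] + pseudocount) /
                   (base[common] + pseudocount))


def differential_response(
    cm: CountMatrix,
    group: str,
    reference: str = "NGT",
    *,
    pseudocount: float = 0.5,
    fold_cutoff: float = 2.0,
    alpha: float = 0.05,
    expressed_only: bool = True,
    min_count: float = 5.0,
    min_fraction: float = 0.5,
    moderate: bool = True,
) -> pd.DataFrame:
    """Glucose differential-response (group x timepoint interaction) test.

    Compares the paired baseline-to-60-min log2 change between ``group``
    and ``reference`` per miRNA.  Returns a tidy frame with the per-group
    mean responses, the interaction effect, Wald z, p, BH q and the
    volcano class at ``fold_cutoff`` / q < ``alpha``.  ``moderate``
    squeezes the pooled variances across miRNAs (empirical Bayes) before
    forming the z; see the module docstring.
    """
    if group == reference:
        raise CountDataError("test group must differ from the reference")
    ratios = _paired_log_ratios(cm, pseudocount)
    part_group = cm.meta.drop_duplicates("participant_id").set_index(
        "participant_id")["group"]
    g_cols = [p for p in ratios.columns if part_group[p] == group]
    r_cols = [p for p in ratios.columns if part_group[p] == reference]
    if len(g_cols) < 2 or len(r_cols) < 2:
        raise CountDataError(
            f"need >=2 participants per group; have {len(g_cols)} in "
            f"{group} and {len(r_cols)} in {reference}"
        )
    if expressed_only:
        keep = filter_expressed(cm.normalized(), min_count, min_fraction)
        ratios = ratios.loc[keep]
    rg = ratios[g_cols].to_numpy(float)
    rr = ratios[r_cols].to_numpy(float)
    ng, nr = rg.shape[1], rr.shape[1]
    mg, mr = rg.mean(axis=1), rr.mean(axis=1)
    effect = mg - mr
    vg = rg.var(axis=1, ddof=1)
    vr = rr.var(axis=1, ddof=1)
    pooled = ((ng - 1) * vg + (nr - 1) * vr) / (ng + nr - 2)
    if moderate:
        pooled, _, _ = moderate_variances(pooled, ng + nr - 2)
    se = np.sqrt(pooled * (1.0 / ng + 1.0 / nr))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, effect / se,
                     np.where(effect == 0, 0.0, np.inf * np.sign(effect)))
    p = 2 * stats.norm.sf(np.abs(z))
    q = bh_fdr(p)
    log2_cut = np.log2(fold_cutoff)
    cls = np.where((q < alpha) & (effect >= log2_cut), "up",
                   np.where((q < alpha) & (effect <= -log2_cut), "down", "ns"))
    return pd.DataFrame({
        "mirna": ratios.index,
        "comparison": f"{group} vs {reference} response (-1 -> 60 min)",
        f"response_{group}": mg, f"response_{reference}": mr,
        "interaction_effect": effect, "se": se, "z": z, "p": p, "q": q,
        "volcano_class": cls,
    }).sort_values("p", kind="mergesort").reset_index(drop=True)


def baseline_de(
    cm: CountMatrix,
    group_a: str,
    group_b: str,
    *,
    pseudocount: float = 0.5,
    timepoint: int = -1,
    expressed_only: bool = True,
    min_count: float = 5.0,
    min_fraction: float = 0.5,
    moderate: bool = True,
) -> pd.DataFrame:
    """Baseline differential expression on log2 normalized counts.

    Welch-style unequal-variance comparison of ``group_b`` against
    ``group_a``; positive log2fc means higher in ``group_b``.  With
    ``moderate`` (default) each group's per-miRNA variances are squeezed
    across miRNAs before forming the statistic, for the same small-n
    reason as in :func:`differential_response`, and the p-value is normal;
    ``moderate=False`` gives the plain Welch t.  BH-adjusted q; ranked by
    p.
    """
    norm = cm.normalized()
    if expressed_only:
        norm = norm.loc[filter_expressed(norm, min_count, min_fraction)]
    meta = cm.meta
    cols_a = meta.index[(meta["group"] == group_a) &
                        (meta["timepoint_min"] == timepoint)]
    cols_b = meta.index[(meta["group"] == group_b) &
                        (meta["timepoint_min"] == timepoint)]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise CountDataError("need >=2 baseline samples per group")
    la = np.log2(norm[cols_a].to_numpy(float) + pseudocount)
    lb = np.log2(norm[cols_b].to_numpy(float) + pseudocount)
    na, nb = la.shape[1], lb.shape[1]
    effect = lb.mean(axis=1) - la.mean(axis=1)
    va = la.var(axis=1, ddof=1)
    vb = lb.var(axis=1, ddof=1)
    if moderate:
        va, _, _ = moderate_variances(va, na - 1)
        vb, _, _ = moderate_variances(vb, nb - 1)
        se = np.sqrt(va / na + vb / nb)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, effect / se, 0.0)
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        t, p = stats.ttest_ind(lb, la, axis=1, equal_var=False)
        p = np.where(np.isnan(p), 1.0, p)
    q = bh_fdr(p)
    return pd.DataFrame({
        "mirna": norm.index,
        "comparison": f"{group_b} vs {group_a} @ {timepoint} min",
        "log2fc": effect, "t": t, "p": p, "q": q,
    }).sort_values("p", kind="mergesort").reset_index(drop=True)
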