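"""Spearman correlation of miRNA expression with clinical blood analytes.

Correlations are computed per (group, timepoint) stratum between a miRNA's
relative-expression values and a blood analyte (glucose, insulin, liver
enzymes ASAT/ALAT/ALP/GGT, CRP, leukocyte count).  rho comes from average
(mid-)ranks; the p-value uses the t approximation for n > 10 and an exact
permutation enumeration for n <= 10, where small stratum sizes make the
approximation unreliable.  No multiplicity correction is applied across
the panel — it is exploratory.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations
from math import isnan
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

EXACT_PERMUTATION_MAX_N = 10


@lru_cache(maxsize=64)
def _dot_distribution(rx_key: tuple, ry_key: tuple) -> np.ndarray:
    """All values of dot(rx, permuted ry).

    The distribution depends only on the two rank multisets, so the cache
    collapses every untied call at a given n onto one enumeration.
    """
    rx = np.array(rx_key, dtype=float)
    perms = np.array(list(permutations(ry_key)), dtype=float)
    return perms @ rx


def _exact_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p: share of orderings with |rho| >= |rho_obs|."""
    n = len(rx)
    mx, my = rx.mean(), ry.mean()
    ssx = float(((rx - mx) ** 2).sum())
    ssy = float(((ry - my) ** 2).sum())
    denom = np.sqrt(ssx * ssy)
    dots = _dot_distribution(tuple(sorted(rx)), tuple(sorted(ry)))
    rho_perm = (dots - n * mx * my) / denom
    return float(np.mean(np.abs(rho_perm) >= abs(rho_obs) - 1e-12))


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with small-n exact permutation p.

    Missing pairs are dropped pairwise.  Ties are handled with midranks.
    For n <= 10 the p-value enumerates all n! orderings; above that the
    usual t approximation with n - 2 degrees of freedom is used.  A
    constant input leaves rho undefined: (nan, nan) is returned, never 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >=3 complete pairs, have {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_PERMUTATION_MAX_N:
        p = _exact_p(rx, ry, rho)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return rho, p


def correlate_panel(
    expr: pd.DataFrame,
    analytes: pd.DataFrame,
    mirnas: Optional[Sequence[str]] = None,
    analyte_names: Optional[Sequence[str]] = None,
    value_col: str = "fold",
) -> pd.DataFrame:
    """All requested miRNA x analyte Spearman correlations per stratum.

    ``expr`` is a tidy expression table (participant_id, timepoint_min,
    group, mirna, ``value_col``); ``analytes`` is wide, keyed by
    participant_id.  Strata (group, timepoint) with fewer than three
    complete pairs are skipped and recorded with n and NaN statistics.
    """
    if mirnas is None:
        mirnas = sorted(expr["mirna"].unique())
    if analyte_names is None:
        analyte_names = [c for c in analytes.columns
                         if c not in ("participant_id", "group", "sex", "age")]
    analytes = analytes[["participant_id", *analyte_names]]
    merged = expr.merge(analytes, on="participant_id", how="inner")
    if merged.empty:
        import warnings

        warnings.warn("expression/analyte join produced zero rows",
                      stacklevel=2)
        return pd.DataFrame(columns=["mirna", "analyte", "group",
                                     "timepoint_min", "rho", "p", "n"])
    rows = []
    for (group, tp), stratum in merged.groupby(["group", "timepoint_min"],
                                               sort=True):
        for mirna in mirnas:
            d = stratum[stratum["mirna"] == mirna]
            for analyte in analyte_names:
                pairs = d[[value_col, analyte]].dropna()
                n = len(pairs)
                if n < 3:
                    rows.append({"mirna": mirna, "analyte": analyte,
                                 "group": group, "timepoint_min": tp,
                                 "rho": np.nan, "p": np.nan, "n": n,
                                 "note": "skipped_n_lt_3"})
                    continue
                rho, p = spearman(pairs[value_col], pairs[analyte])
                rows.append({"mirna": mirna, "analyte": analyte,
                             "group": group, "timepoint_min": tp,
                             "rho": rho, "p": p, "n": n, "note": ""})
    return pd.DataFrame(rows)
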