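"""miRNA-target intersection and hypergeometric over-representation.

Experimentally validated miRNA-target tables (e.g. TarBase / miRTarBase
exports, consumed as generic TSV) are combined by union of sources, the
genes targeted by *every* miRNA of interest are intersected with an
expressed-gene universe (e.g. genes expressed in human islets), optionally
flagged against a disease-association list, and tested for pathway
over-representation with the hypergeometric upper tail:

    p = P[X >= k],  X ~ Hypergeometric(N population, K in pathway, n drawn)

followed by Benjamini-Hochberg adjustment across pathways.  All database
access is file-based; nothing is queried online.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from scipy import stats

from mirogtt.response import bh_fdr

TARGET_COLUMNS = ("mirna", "gene", "source")


def read_targets(path) -> pd.DataFrame:
    """Read a miRNA-target TSV (columns mirna, gene, source[, evidence])."""
    df = pd.read_csv(path, sep="\t")
    missing = set(TARGET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"target table missing columns: {sorted(missing)}")
    return df


def read_gmt(path) -> dict[str, set[str]]:
    """Parse a GMT pathway file: name <tab> description <tab> genes..."""
    pathways: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            pathways[parts[0]] = {g.upper() for g in parts[2:] if g}
    return pathways


def _normalize(genes: Iterable[str]) -> set[str]:
    return {str(g).upper() for g in genes}


def common_targets(
    targets: pd.DataFrame,
    mirnas: Sequence[str],
    universe: Iterable[str],
    disease_genes: Optional[Iterable[str]] = None,
) -> dict:
    """Genes targeted by every listed miRNA, within the expressed universe.

    Target support is the union over source databases (validation in any
    one source suffices); duplicate (mirna, gene) rows collapse to one.
    Returns the common set and, when a disease-association list is given,
    the flagged subset.
    """
    if not len(mirnas):
        raise ValueError("mirna list is empty")
    universe = _normalize(universe)
    if not universe:
        raise ValueError("expressed universe is empty")
    per_mirna = {}
    for mirna in mirnas:
        sub = targets[targets["mirna"] == mirna]
        if sub.empty:
            raise ValueError(f"miRNA {mirna!r} absent from all target tables")
        per_mirna[mirna] = _normalize(sub["gene"])
    common = set.intersection(*per_mirna.values()) & universe
    out = {"common": sorted(common),
           "per_mirna_counts": {m: len(g) for m, g in per_mirna.items()}}
    if disease_genes is not None:
        out["disease_associated"] = sorted(common & _normalize(disease_genes))
    return out


def hypergeom_ora(
    query: Iterable[str],
    pathways: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each pathway.

    The query must lie within the universe; each pathway is intersected
    with the universe before testing.  Returns a DataFrame (pathway, k, K,
    n, N, p, q) sorted by p.
    """
    query = _normalize(query)
    universe = _normalize(universe)
    if not query:
        raise ValueError("query gene set is empty")
    outside = query - universe
    if outside:
        raise ValueError(
            f"query genes outside the universe: {sorted(outside)[:5]}")
    N, n = len(universe), len(query)
    rows = []
    for name, genes in pathways.items():
        in_universe = _normalize(genes) & universe
        K = len(in_universe)
        k = len(in_universe & query)
        # upper tail P[X >= k]
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"pathway": name, "k": k, "K": K, "n": n, "N": N,
                     "p": min(p, 1.0)})
    df = pd.DataFrame(rows)
    if not df.empty:
        df["q"] = bh_fdr(df["p"].to_numpy())
        df = df.sort_values(["p", "pathway"],
                            kind="mergesort").reset_index(drop=True)
    return df
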