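"""Gene-set over-representation: fold enrichment with Fisher/EASE p-values.

For a query list of n genes drawn from a universe of N genes, a term with
K members in the universe and a genes in the list has

    fold_enrichment = (a / n) / (K / N)

("actual over expected" overlap) and a one-sided upper-tail hypergeometric
p-value P(X >= a).  The EASE variant (the DAVID tool's "modified Fisher
exact") removes one gene from the overlap before taking the tail,
P(X >= a - 1), which penalizes terms supported by very few genes; for a = 0
both modes give p = 1.  A term is flagged enriched when fold enrichment > 1
and p < .05 (both strict).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .detest import bh_adjust


def _check_bounds(a: int, n: int, K: int, N: int) -> None:
    if min(n, K, N) <= 0:
        raise ValueError("n, K, N must be positive")
    if not (0 <= a <= min(n, K)):
        raise ValueError(f"overlap a={a} outside [0, min(n={n}, K={K})]")
    if K > N or n > N:
        raise ValueError("term and list must fit inside the universe")


def fold_enrichment(a: int, n: int, K: int, N: int) -> float:
    """Observed over expected overlap: (a/n) / (K/N)."""
    _check_bounds(a, n, K, N)
    return (a / n) / (K / N)


def overrep_p(a: int, n: int, K: int, N: int, mode: str = "ease") -> float:
    """Upper-tail hypergeometric p-value; EASE drops one overlap gene.

    fisher: P(X >= a) with X ~ Hypergeom(N, K, n);
    ease:   P(X >= a - 1), and p = 1 when a = 0.
    """
    _check_bounds(a, n, K, N)
    if mode not in ("ease", "fisher"):
        raise ValueError(f"unknown mode {mode!r}")
    eff = a - 1 if mode == "ease" else a
    if eff <= 0:
        return 1.0
    return float(hypergeom.sf(eff - 1, N, K, n))


def enrich(
    gene_list,
    annotation: dict[str, set[str]],
    universe,
    mode: str = "ease",
    alpha: float = 0.05,
    min_count: int = 1,
    term_names: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Over-representation of ``gene_list`` against GMT-style gene sets.

    Term members are intersected with the universe; terms with overlap
    a < 1 are dropped.  Overlaps below ``min_count`` keep their row but
    report p as NaN (mirrors tools that refuse p-values for tiny lists).
    Rows are sorted by p ascending, ties broken by term id; BH adjustment
    is across the reported terms of this one query.
    """
    universe = set(universe)
    gene_list = set(gene_list)
    if not universe:
        raise ValueError("empty universe")
    if not gene_list:
        raise ValueError("empty gene list")
    if not gene_list <= universe:
        missing = sorted(gene_list - universe)[:5]
        raise ValueError(f"gene list not contained in universe (e.g. {missing})")

    N, n = len(universe), len(gene_list)
    rows = []
    for term_id, members in annotation.items():
        in_universe = members & universe
        K = len(in_universe)
        if K == 0:
            continue
        a = len(in_universe & gene_list)
        if a < 1:
            continue
        fe = fold_enrichment(a, n, K, N)
        p = overrep_p(a, n, K, N, mode) if a >= min_count else np.nan
        rows.append((term_id, a, n, K, N, fe, p))

    result = pd.DataFrame(
        rows,
        columns=["term_id", "a", "n", "K", "N", "fold_enrichment", "p"],
    )
    if result.empty:
        result["padj"] = []
        result["enriched"] = []
        result["term_name"] = []
        return result
    defined = result["p"].notna()
    padj = np.full(len(result), np.nan)
    if defined.any():
        padj[defined.to_numpy()] = bh_adjust(result.loc[defined, "p"].to_numpy())
    result["padj"] = padj
    result["enriched"] = (result["fold_enrichment"] > 1) & (result["p"] < alpha)
    result["term_name"] = result["term_id"].map(term_names or {}).fillna("")
    result = result.sort_values(
        ["p", "term_id"], na_position="last", kind="mergesort"
    ).reset_index(drop=True)
    return result
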