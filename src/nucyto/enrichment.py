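"""Over-representation analysis of a gene list against GMT gene sets.

The test is the one-sided upper-tail hypergeometric probability
P(X >= k) for an overlap of k between a query of size n and a set of size K
inside a universe of size N, evaluated by exact summation in log space, with
Benjamini-Hochberg control across sets.
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .io_formats import GeneSetCollection


def _log_comb(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_sf(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), exact log-space summation."""
    if k <= max(0, K + n - N):
        return 1.0
    upper = min(K, n)
    if k > upper:
        return 0.0
    i = np.arange(k, upper + 1)
    log_terms = _log_comb(K, i) + _log_comb(N - K, n - i) - _log_comb(N, n)
    return float(min(np.exp(logsumexp(log_terms)), 1.0))


def ora_test(
    query: Iterable[str], gene_set: Iterable[str], universe: Iterable[str]
) -> float:
    """Upper-tail hypergeometric p-value of the query/gene-set overlap.

    The query and the gene set are restricted to the universe first.  An
    empty query returns p = 1 by convention; an empty universe is an error.
    """
    uni = frozenset(universe)
    if not uni:
        raise ValueError("ora_test: empty universe")
    q = frozenset(query) & uni
    s = frozenset(gene_set) & uni
    if not q:
        return 1.0
    return hypergeom_sf(len(q & s), len(uni), len(s), len(q))


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adjusted[i] = min over j with p_(j) >= p_(i) of p_(j) * m / j, capped at
    1; monotone non-decreasing after sorting by raw p.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m, dtype=float)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    return adjusted


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    top_k: int | None = None,
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Rank every set in the collection by hypergeometric enrichment.

    Returns a table with one row per set (or the ``top_k`` best), columns
    ``set_name, overlap_k, set_size_K, query_size_n, universe_size_N,
    p_value, adjusted_p, enrichment_score``; rank order is increasing p, ties
    broken by larger overlap then name.  BH adjustment spans all sets in the
    collection regardless of ``top_k``.
    """
    uni = frozenset(universe) if universe is not None else collection.universe
    if not uni:
        raise ValueError("enrich: empty universe")
    q = frozenset(query) & uni
    rows = []
    for name, members in collection.sets.items():
        s = members & uni
        k = len(q & s)
        p = 1.0 if not q else hypergeom_sf(k, len(uni), len(s), len(q))
        rows.append((name, k, len(s), len(q), len(uni), p))
    table = pd.DataFrame(
        rows,
        columns=[
            "set_name",
            "overlap_k",
            "set_size_K",
            "query_size_n",
            "universe_size_N",
            "p_value",
        ],
    )
    if len(table):
        table["adjusted_p"] = bh_adjust(table["p_value"].to_numpy())
        table["enrichment_score"] = -np.log10(table["p_value"])
        table["_neg_k"] = -table["overlap_k"]
        table = table.sort_values(
            ["p_value", "_neg_k", "set_name"], kind="mergesort", ignore_index=True
        ).drop(columns="_neg_k")
    else:
        table["adjusted_p"] = []
        table["enrichment_score"] = []
    if top_k is not None:
        table = table.head(top_k).reset_index(drop=True)
    return table
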