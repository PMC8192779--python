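"""Hypergeometric over-representation, BH-FDR, coverage and Sankey tables.

Enrichment of a query gene list against a gene-set collection uses the
upper-tail hypergeometric probability P(X >= k) for an overlap of k between
a query of size n and a set of size K inside a universe of N genes, followed
by Benjamini-Hochberg adjustment across all tested sets (significance at
FDR < 0.05 by default).  Only over-representation is tested.

Coverage answers a different question: for one gene, which fraction of the
sets in a category (e.g. fibrosis-related collections) contain it.  Sankey
links enumerate the (gene, set) membership pairs that back a Sankey diagram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSetCollection, StagenetError


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    Parameters are the overlap ``k``, the set size ``K``, the query size
    ``n`` and the universe size ``N``.
    """
    if not (0 <= k <= min(K, n)) or K > N or n > N or min(k, K, n, N) < 0:
        raise ValueError(f"invalid hypergeometric bounds k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``q_(i) = min_(j >= i) ( p_(j) * m / j )`` over the ascending ordering,
    capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d vector")
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values outside [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


@dataclass(frozen=True)
class CoverageRow:
    gene: str
    n_containing: int
    n_total: int

    @property
    def fraction(self) -> float:
        return self.n_containing / self.n_total


def enrich(
    query: set[str],
    universe: set[str],
    gsc: GeneSetCollection,
    fdr: float = 0.05,
    category: str | None = None,
) -> pd.DataFrame:
    """Hypergeometric enrichment of a query against a collection.

    Set members are intersected with the universe before testing; sets
    empty after intersection are not tested.  Returns one row per tested set
    (set_name, k, K, n, N, p, q, significant) with q the BH adjustment over
    all tested sets.
    """
    query = set(query)
    universe = set(universe)
    if not query:
        raise StagenetError("empty query")
    if not universe:
        raise StagenetError("empty universe")
    if not query <= universe:
        extra = query - universe
        raise StagenetError(
            f"query genes outside the universe: {sorted(extra)[:10]}"
        )
    sets = gsc.by_category(category) if category else list(gsc)
    N, n = len(universe), len(query)
    rows = []
    for s in sets:
        members = s.members & universe
        K = len(members)
        if K == 0:
            continue
        k = len(members & query)
        rows.append(
            {"set_name": s.name, "k": k, "K": K, "n": n, "N": N,
             "p": hypergeom_tail(k, K, n, N)}
        )
    table = pd.DataFrame(rows, columns=["set_name", "k", "K", "n", "N", "p"])
    if len(table):
        table["q"] = bh_adjust(table["p"].to_numpy())
        table["significant"] = table["q"] < fdr
        table = table.sort_values(["p", "set_name"]).reset_index(drop=True)
    else:
        table["q"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
    return table


def coverage(
    gene: str, gsc: GeneSetCollection, category: str = "fibrosis"
) -> CoverageRow:
    """Fraction of category sets that contain the gene."""
    sets = gsc.by_category(category)
    if not sets:
        raise StagenetError(f"no sets in category {category!r}")
    n_containing = sum(1 for s in sets if gene in s.members)
    return CoverageRow(gene=gene, n_containing=n_containing, n_total=len(sets))


def sankey_links(
    genes: set[str], gsc: GeneSetCollection, category: str = "fibrosis"
) -> pd.DataFrame:
    """One (gene, set_name) row per membership pair within the category."""
    rows = [
        {"gene": g, "set_name": s.name}
        for s in gsc.by_category(category)
        for g in sorted(set(genes) & s.members)
    ]
    out = pd.DataFrame(rows, columns=["gene", "set_name"])
    return out.sort_values(["gene", "set_name"]).reset_index(drop=True)
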