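"""Bipartite lncRNA-mRNA co-expression networks and scale-free diagnostics.

An edge joins a lncRNA to an mRNA when their expression across the chosen
sample subset passes a joint Pearson threshold: ``|r| > 0.8`` and two-sided
``p < 0.01``, with p obtained from the t-transform
``t = r * sqrt(n - 2) / sqrt(1 - r^2)`` against the t distribution with
``n - 2`` degrees of freedom.  Three networks are built in practice: a
pathogenic network over all disease samples and two stage-specific
progression networks over early-only and advanced-only samples.

Scale-free behaviour is diagnosed by ordinary least squares of
log10(node count) on log10(degree); the regression's R-squared and F-test
p-value summarise the goodness of fit of the power-law line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import StagenetError

logger = logging.getLogger(__name__)


class ZeroVarianceError(StagenetError):
    pass


@dataclass(frozen=True)
class CorrResult:
    r: float
    p: float
    n: int


@dataclass(frozen=True)
class PowerLawFit:
    slope: float
    intercept: float
    r2: float
    p_fit: float
    n_points: int


def corr_p_from_r(r: float, n: int) -> float:
    """Two-sided Pearson p-value from (r, n) via the t-transform.

    ``|r| = 1`` maps to p = 0.  This is the transform used to check
    published (r, n, p) triples for internal consistency.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if not -1.0 <= r <= 1.0:
        raise ValueError("r outside [-1, 1]")
    if abs(r) == 1.0:
        return 0.0
    t = abs(r) * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(t, n - 2))


def pearson_test(x, y) -> CorrResult:
    """Pearson correlation with a two-sided t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors differ in length")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("zero variance in one of the vectors")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    return CorrResult(r=r, p=corr_p_from_r(r, n), n=n)


@dataclass
class CoexpressionNetwork:
    """Bipartite lncRNA-mRNA network with per-edge correlation statistics.

    ``edges`` has columns ``lnc``, ``mrna``, ``r``, ``p``, ``sign``; nodes
    with no retained edge are excluded.
    """

    edges: pd.DataFrame
    stage_tag: str
    n_samples: int
    r_min: float = 0.8
    alpha: float = 0.01
    nodes: dict[str, str] = field(default_factory=dict)  # gene_id -> role

    def __post_init__(self) -> None:
        if not self.nodes:
            self.nodes = {
                **{g: "lncRNA" for g in self.edges["lnc"]},
                **{g: "mRNA" for g in self.edges["mrna"]},
            }

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_set(self) -> set[tuple[str, str]]:
        return {(a, b) for a, b in zip(self.edges["lnc"], self.edges["mrna"])}

    def degrees(self) -> dict[str, int]:
        deg: dict[str, int] = {}
        for a, b in zip(self.edges["lnc"], self.edges["mrna"]):
            deg[a] = deg.get(a, 0) + 1
            deg[b] = deg.get(b, 0) + 1
        return deg

    def neighbors(self, gene: str) -> set[str]:
        out = set(self.edges.loc[self.edges["lnc"] == gene, "mrna"])
        out |= set(self.edges.loc[self.edges["mrna"] == gene, "lnc"])
        return out

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(stage=self.stage_tag)
        for node, role in self.nodes.items():
            g.add_node(node, role=role, bipartite=0 if role == "lncRNA" else 1)
        for row in self.edges.itertuples():
            g.add_edge(row.lnc, row.mrna, r=row.r, p=row.p, sign=row.sign)
        return g


def build_network(
    em: pd.DataFrame,
    lnc: set[str],
    mrna: set[str],
    samples: list[str],
    r_min: float = 0.8,
    alpha: float = 0.01,
    stage_tag: str = "pathogenic",
) -> CoexpressionNetwork:
    """Test every lncRNA x mRNA pair over a sample subset and keep edges
    with ``|r| > r_min`` and ``p < alpha``.

    Genes constant over the subset are skipped with a warning (their pairs
    are untested).  Pairs within one biotype are never tested: the network
    is bipartite by construction.
    """
    lnc = set(lnc)
    mrna = set(mrna)
    if lnc & mrna:
        raise ValueError("lncRNA and mRNA candidate sets overlap")
    missing = (lnc | mrna) - set(em.index)
    if missing:
        raise StagenetError(f"genes absent from matrix: {sorted(missing)[:10]}")
    if len(samples) < 3:
        raise StagenetError("need at least 3 samples for correlation")

    n = len(samples)
    lnc_ids = sorted(lnc)
    mrna_ids = sorted(mrna)
    rows: list[dict] = []
    if lnc_ids and mrna_ids:
        a = em.loc[lnc_ids, samples].to_numpy(dtype=float)
        b = em.loc[mrna_ids, samples].to_numpy(dtype=float)

        def _standardize(m: np.ndarray, ids: list[str]):
            sd = m.std(axis=1, ddof=0)
            const = sd == 0
            for g in np.asarray(ids)[const]:
                logger.warning("gene %s constant over subset; pairs skipped", g)
            z = np.zeros_like(m)
            ok = ~const
            z[ok] = (m[ok] - m[ok].mean(axis=1, keepdims=True)) / sd[ok, None]
            return z, const

        za, const_a = _standardize(a, lnc_ids)
        zb, const_b = _standardize(b, mrna_ids)
        r = za @ zb.T / n
        np.clip(r, -1.0, 1.0, out=r)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.abs(r) * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
        p = 2.0 * stats.t.sf(t, n - 2)
        p[np.abs(r) == 1.0] = 0.0
        keep = (np.abs(r) > r_min) & (p < alpha)
        keep[const_a, :] = False
        keep[:, const_b] = False
        for i, j in zip(*np.nonzero(keep)):
            rows.append(
                {
                    "lnc": lnc_ids[i],
                    "mrna": mrna_ids[j],
                    "r": float(r[i, j]),
                    "p": float(p[i, j]),
                    "sign": "positive" if r[i, j] > 0 else "negative",
                }
            )
    edges = pd.DataFrame(rows, columns=["lnc", "mrna", "r", "p", "sign"])
    return CoexpressionNetwork(
        edges=edges, stage_tag=stage_tag, n_samples=n, r_min=r_min, alpha=alpha
    )


def degree_distribution(net: CoexpressionNetwork) -> pd.DataFrame:
    """Tabulate node counts per observed degree (both roles pooled)."""
    deg = net.degrees()
    if not deg:
        return pd.DataFrame(columns=["degree", "node_count"])
    counts = pd.Series(list(deg.values())).value_counts().sort_index()
    return pd.DataFrame({"degree": counts.index, "node_count": counts.values})


def fit_power_law(dt: pd.DataFrame, log_binning: bool = False) -> PowerLawFit:
    """OLS fit of log10(node count) on log10(degree).

    ``p_fit`` is the regression F-test p-value (for one predictor it equals
    the two-sided t-test on the slope).  With ``log_binning`` the degrees are
    first pooled into powers-of-two bins and counts averaged per bin width.
    """
    dt = dt[dt["node_count"] >= 1]
    if log_binning and len(dt) >= 2:
        edges_ = 2 ** np.arange(0, np.ceil(np.log2(dt["degree"].max())) + 2)
        idx = np.digitize(dt["degree"], edges_)
        binned = []
        for b in np.unique(idx):
            sel = dt[idx == b]
            width = edges_[b] - edges_[b - 1]
            binned.append(
                {
                    "degree": np.exp(np.mean(np.log(sel["degree"]))),
                    "node_count": sel["node_count"].sum() / width,
                }
            )
        dt = pd.DataFrame(binned)
        dt = dt[dt["node_count"] > 0]
    if len(dt) < 2:
        raise StagenetError("need >=2 distinct degrees for a power-law fit")
    x = np.log10(dt["degree"].to_numpy(dtype=float))
    y = np.log10(dt["node_count"].to_numpy(dtype=float))
    res = stats.linregress(x, y)
    p_fit = float(res.pvalue) if np.isfinite(res.pvalue) else 0.0
    return PowerLawFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p_fit=p_fit,
        n_points=len(dt),
    )


def rank_hubs(net: CoexpressionNetwork, quantile: float = 0.95) -> pd.DataFrame:
    """Rank nodes by degree (descending, ties broken by gene id).

    Nodes whose degree reaches the given degree quantile are flagged hubs.
    """
    deg = net.degrees()
    if not deg:
        return pd.DataFrame(columns=["gene_id", "role", "degree", "is_hub"])
    cutoff = float(np.quantile(list(deg.values()), quantile))
    rows = sorted(deg.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        {
            "gene_id": [g for g, _ in rows],
            "role": [net.nodes[g] for g, _ in rows],
            "degree": [d for _, d in rows],
            "is_hub": [d >= cutoff for _, d in rows],
        }
    )


@dataclass
class StageComparison:
    """Node/edge partition between two networks: common vs specific."""

    common_nodes: set[str]
    a_specific_nodes: set[str]
    b_specific_nodes: set[str]
    common_edges: set[tuple[str, str]]
    a_specific_edges: set[tuple[str, str]]
    b_specific_edges: set[tuple[str, str]]


def compare_networks(
    a: CoexpressionNetwork, b: CoexpressionNetwork
) -> StageComparison:
    """Partition the union of nodes and edges into common / a-only / b-only.

    Edge identity is the unordered endpoint pair; since edges always run
    lncRNA-to-mRNA the (lnc, mrna) tuple already canonicalises it.
    """
    na, nb = set(a.nodes), set(b.nodes)
    ea, eb = a.edge_set(), b.edge_set()
    return StageComparison(
        common_nodes=na & nb,
        a_specific_nodes=na - nb,
        b_specific_nodes=nb - na,
        common_edges=ea & eb,
        a_specific_edges=ea - eb,
        b_specific_edges=eb - ea,
    )
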