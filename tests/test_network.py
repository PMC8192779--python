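import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stagenet.io import StagenetError
from stagenet.network import (
    CoexpressionNetwork,
    ZeroVarianceError,
    build_network,
    compare_networks,
    corr_p_from_r,
    degree_distribution,
    fit_power_law,
    pearson_test,
    rank_hubs,
)


class TestPearson:
    def test_perfect_correlation(self):
        res = pearson_test([1, 2, 3], [1, 2, 3])
        assert res.r == 1 and res.p == 0

    def test_hand_computed_example(self):
        # sum dx*dy = 9, sum dx^2 = sum dy^2 = 10 -> r = 0.9; df = 3
        res = pearson_test([1, 2, 3, 4, 5], [1, 2, 3, 5, 4])
        assert res.r == pytest.approx(0.9, abs=1e-12)
        t = 0.9 * math.sqrt(3) / math.sqrt(1 - 0.81)
        assert res.p == pytest.approx(2 * stats.t.sf(t, 3), rel=1e-12)
        assert res.p == pytest.approx(0.0374, abs=5e-4)

    def test_matches_scipy_pearsonr(self):
        rng = np.random.default_rng(3)
        for n in (4, 7, 15, 30):
            x = rng.normal(size=n)
            y = 0.5 * x + rng.normal(size=n)
            mine = pearson_test(x, y)
            ref = stats.pearsonr(x, y)
            assert mine.r == pytest.approx(ref.statistic, rel=1e-10)
            assert mine.p == pytest.approx(ref.pvalue, rel=1e-8)

    def test_constant_vector_raises(self):
        with pytest.raises(ZeroVarianceError):
            pearson_test([1, 1, 1], [1, 2, 3])

    def test_short_vectors_raise(self):
        with pytest.raises(ValueError):
            pearson_test([1, 2], [1, 2])

    def test_permutation_p_agreement_small_n(self):
        """The t-transform p tracks the exhaustive-permutation p (n=7: all
        5040 permutations): small mean discrepancy, and accept/reject at
        alpha=0.05 agrees away from the discreteness boundary."""
        rng = np.random.default_rng(9)
        diffs = []
        checked = 0
        for _ in range(30):
            x = rng.normal(size=7)
            y = rng.normal(size=7) + rng.uniform(0, 1.2) * x
            res = pearson_test(x, y)
            robs = abs(res.r)
            perm = [
                abs(np.corrcoef(x, np.asarray(p))[0, 1])
                for p in itertools.permutations(y)
            ]
            p_perm = np.mean([v >= robs - 1e-12 for v in perm])
            diffs.append(abs(p_perm - res.p))
            if not 0.02 < res.p < 0.125 and not 0.02 < p_perm < 0.125:
                assert (res.p < 0.05) == (p_perm < 0.05)
                checked += 1
        assert np.mean(diffs) < 0.02
        assert checked >= 15  # the comparison actually exercised cases


class TestPrintedTriples:
    """Published (r, n, p) values must be self-consistent under the
    t-transform, allowing for r being printed with 2 decimals."""

    TRIPLES = [
        (0.85, 8, 6.99e-3),
        (0.89, 8, 3.01e-3),
        (0.87, 8, 4.24e-3),
        (0.85, 9, 3.67e-3),
        (0.81, 9, 8.71e-3),
        (0.95, 8, 2.82e-4),
        (-0.51, 17, 0.036),
        (-0.57, 17, 0.018),
        (-0.75, 17, 4.94e-4),
        (-0.76, 17, 4.41e-4),
        (-0.65, 17, 4.69e-3),
        (-0.64, 17, 6.12e-3),
    ]

    @pytest.mark.parametrize("r,n,p_printed", TRIPLES)
    def test_triple_consistent_within_rounding(self, r, n, p_printed):
        # best agreement over the half-unit rounding band of the printed r
        candidates = [abs(r), abs(r) - 0.005, abs(r) + 0.005]
        rel = min(
            abs(corr_p_from_r(c * np.sign(r), n) - p_printed) / p_printed
            for c in candidates
        )
        assert rel <= 0.15


def _matrix(cols: dict, samples=None):
    samples = samples or [f"s{i}" for i in range(len(next(iter(cols.values()))))]
    return pd.DataFrame(cols, index=samples).T


class TestBuildNetwork:
    def test_exact_edge_retained(self):
        em = _matrix({"lnc1": [1, 2, 3, 4, 5], "m1": [2, 4, 6, 8, 10]})
        net = build_network(em, {"lnc1"}, {"m1"}, list(em.columns))
        assert net.n_edges == 1
        assert net.edges.iloc[0]["sign"] == "positive"
        assert net.edges.iloc[0]["p"] == pytest.approx(0.0, abs=1e-10)

    def test_joint_threshold_rejects_high_r_high_p(self):
        # r = 0.9 but p = 0.0375 >= 0.01 at n = 5: rejected
        em = _matrix({"lnc1": [1, 2, 3, 4, 5], "m2": [1, 2, 3, 5, 4]})
        net = build_network(em, {"lnc1"}, {"m2"}, list(em.columns))
        assert net.n_edges == 0

    def test_bipartite_contract(self, tiny_expression):
        em, samples = tiny_expression
        with pytest.raises(ValueError):
            build_network(em, {"L1", "L2"}, {"L2", "M1"}, samples)
        net = build_network(em, {"L1", "L2"}, {"M1", "M2"}, samples)
        for row in net.edges.itertuples():
            assert row.lnc.startswith("L") and row.mrna.startswith("M")

    def test_constant_gene_skipped_not_fatal(self):
        em = _matrix(
            {"lnc1": [1, 2, 3, 4, 5], "lnc2": [2, 2, 2, 2, 2],
             "m1": [2, 4, 6, 8, 10]}
        )
        net = build_network(em, {"lnc1", "lnc2"}, {"m1"}, list(em.columns))
        assert set(net.edges["lnc"]) == {"lnc1"}

    def test_brute_force_equivalence(self, default_cohort):
        em, st_, ann, _ = default_cohort
        rng = np.random.default_rng(17)
        genes = list(rng.choice(em.index, size=20, replace=False))
        lnc = {g for g in genes if g.startswith("LNC")} or {genes[0]}
        mrna = set(genes) - lnc
        samples = list(em.columns[:9])
        net = build_network(em, lnc, mrna, samples, r_min=0.3, alpha=0.05)
        expected = set()
        for a in lnc:
            for b in mrna:
                r, p = stats.pearsonr(em.loc[a, samples], em.loc[b, samples])
                if abs(r) > 0.3 and p < 0.05:
                    expected.add((a, b))
        assert net.edge_set() == expected

    def test_edge_count_monotone_in_thresholds(self, default_cohort):
        em, st_, ann, truth = default_cohort
        lnc = set(em.index[:30]) & set(truth.index[truth.index.str.startswith("LNC")])
        mrna = set(em.index[-80:])
        samples = list(em.columns)
        counts = [
            build_network(em, lnc, mrna, samples, r_min=r, alpha=a).n_edges
            for r, a in [(0.2, 0.2), (0.4, 0.2), (0.4, 0.05), (0.8, 0.01)]
        ]
        assert counts == sorted(counts, reverse=True)


class TestDegreeAndPowerLaw:
    def _net(self, pairs):
        edges = pd.DataFrame(
            [(a, b, 0.9, 1e-4, "positive") for a, b in pairs],
            columns=["lnc", "mrna", "r", "p", "sign"],
        )
        return CoexpressionNetwork(edges=edges, stage_tag="early", n_samples=8)

    def test_hand_enumerated_distribution(self):
        net = self._net([("L1", "M1"), ("L1", "M2"), ("L2", "M1")])
        dt = degree_distribution(net)
        assert dict(zip(dt["degree"], dt["node_count"])) == {1: 2, 2: 2}

    def test_single_edge(self):
        dt = degree_distribution(self._net([("L1", "M1")]))
        assert dict(zip(dt["degree"], dt["node_count"])) == {1: 2}

    def test_handshake_lemma_random_networks(self, default_cohort):
        em, st_, ann, _ = default_cohort
        lnc = set(em.index[:40]) & set(ann.index[ann["biotype"] == "lncRNA"])
        mrna = set(em.index[60:200])
        net = build_network(em, lnc, mrna, list(em.columns), r_min=0.3, alpha=0.1)
        dt = degree_distribution(net)
        assert (dt["degree"] * dt["node_count"]).sum() == 2 * net.n_edges
        # cross-check degrees through the networkx view
        g = net.to_networkx()
        assert dict(g.degree) == net.degrees()

    def test_exactly_collinear_table(self):
        dt = pd.DataFrame({"degree": [1, 2, 4, 8], "node_count": [8, 4, 2, 1]})
        fit = fit_power_law(dt)
        assert fit.slope == pytest.approx(-1.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_hand_ols_three_points(self):
        dt = pd.DataFrame({"degree": [1, 2, 4], "node_count": [5, 3, 1]})
        fit = fit_power_law(dt)
        assert fit.slope == pytest.approx(-1.161, abs=1e-3)
        assert fit.r2 == pytest.approx(0.957, abs=1e-3)

    def test_sampled_power_law_recovery(self):
        d = np.arange(1, 51)
        w = d**-1.5
        rng = np.random.default_rng(7)
        sample = rng.choice(d, size=500_000, p=w / w.sum())
        vc = pd.Series(sample).value_counts().sort_index()
        fit = fit_power_law(
            pd.DataFrame({"degree": vc.index, "node_count": vc.values})
        )
        assert fit.slope == pytest.approx(-1.5, abs=0.1)
        assert fit.r2 >= 0.99

    def test_single_point_raises(self):
        with pytest.raises(StagenetError):
            fit_power_law(pd.DataFrame({"degree": [3], "node_count": [4]}))


class TestHubsAndComparison:
    def _net(self, pairs, tag="early"):
        edges = pd.DataFrame(
            [(a, b, 0.9, 1e-4, "positive") for a, b in pairs],
            columns=["lnc", "mrna", "r", "p", "sign"],
        )
        return CoexpressionNetwork(edges=edges, stage_tag=tag, n_samples=8)

    def test_ranking_and_tie_break(self):
        net = self._net([("L1", "M1"), ("L1", "M2"), ("L2", "M3"), ("L2", "M4")])
        hubs = rank_hubs(net)
        assert hubs["gene_id"].tolist()[:2] == ["L1", "L2"]  # ties lexicographic

    def test_all_equal_degrees_all_hubs(self):
        net = self._net([("L1", "M1"), ("L2", "M2")])
        hubs = rank_hubs(net, quantile=1.0)
        assert hubs["is_hub"].all()

    def test_compare_partitions(self):
        a = self._net([("L1", "M1"), ("L1", "M2")])
        b = self._net([("L1", "M1"), ("L2", "M3")], tag="advanced")
        comp = compare_networks(a, b)
        assert comp.common_edges == {("L1", "M1")}
        assert comp.a_specific_edges == {("L1", "M2")}
        assert comp.b_specific_edges == {("L2", "M3")}
        union = comp.common_nodes | comp.a_specific_nodes | comp.b_specific_nodes
        assert union == set(a.nodes) | set(b.nodes)

    def test_compare_identical_and_disjoint(self):
        a = self._net([("L1", "M1")])
        assert compare_networks(a, a).a_specific_edges == set()
        b = self._net([("L9", "M9")])
        comp = compare_networks(a, b)
        assert comp.common_nodes == set() and comp.common_edges == set()
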