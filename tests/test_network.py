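import math

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from mediatornet.cohort import SubgroupKey
from mediatornet.network import (CorrelationRecord, MediatorNetwork,
                                 build_edges, connectivity,
                                 correlation_matrix, export_network, hub_set,
                                 records_frame, venn_classify)
from mediatornet.panel import DEFAULT_PANEL

from conftest import make_cohort

MEDS = DEFAULT_PANEL.mediators


def record(a="IL-6", b="CXCL8", r=0.0, p_r=1.0, rho=0.0, p_s=1.0, n=20, ok=True):
    return CorrelationRecord(a, b, r, p_r, rho, p_s, n, ok)


def small_cohort_with_pair(n, x, y, rng):
    data = rng.lognormal(size=(n, 27))
    data[:, 0] = x
    data[:, 1] = y
    return make_cohort({("HC", 1): data})


class TestCorrelationRecords:
    def test_monotone_pair_has_rho_one(self, rng):
        n = 12
        x = np.arange(1.0, n + 1)
        cohort = small_cohort_with_pair(n, x, np.exp(x), rng)
        recs = {frozenset((r.a, r.b)): r
                for r in correlation_matrix(cohort, SubgroupKey("HC", 1))}
        assert recs[frozenset((MEDS[0], MEDS[1]))].rho_spearman == pytest.approx(1.0)

    def test_exact_permutation_p_for_n7_antimonotone(self, rng):
        x = np.arange(1.0, 8.0)
        cohort = small_cohort_with_pair(7, x, x[::-1] + 0.5, rng)
        recs = {frozenset((r.a, r.b)): r
                for r in correlation_matrix(cohort, SubgroupKey("HC", 1))}
        rec = recs[frozenset((MEDS[0], MEDS[1]))]
        assert rec.rho_spearman == pytest.approx(-1.0)
        assert rec.p_spearman == pytest.approx(2 / math.factorial(7))

    def test_all_351_pairs_present(self, rng):
        cohort = make_cohort({("COVID", 2): rng.lognormal(size=(12, 27))})
        recs = correlation_matrix(cohort, SubgroupKey("COVID", 2))
        assert len(recs) == 351
        frame = records_frame(recs)
        assert frame["n"].eq(12).all()

    def test_sample_order_invariance(self, rng):
        data = rng.lognormal(size=(15, 27))
        c1 = make_cohort({("HC", 1): data})
        c2 = make_cohort({("HC", 1): data[::-1]})
        r1 = records_frame(correlation_matrix(c1, SubgroupKey("HC", 1)))
        r2 = records_frame(correlation_matrix(c2, SubgroupKey("HC", 1)))
        assert np.allclose(r1["rho_spearman"], r2["rho_spearman"])
        assert np.allclose(r1["r_pearson"], r2["r_pearson"])

    def test_fast_and_pairwise_paths_agree(self, rng):
        data = rng.lognormal(size=(15, 27))
        c = make_cohort({("HC", 1): data})
        fast = records_frame(correlation_matrix(c, SubgroupKey("HC", 1)))
        # force the pairwise path with a missing value in one analyte
        data_miss = data.copy()
        data_miss[0, 26] = np.nan
        cm = make_cohort({("HC", 1): data_miss})
        slow = records_frame(correlation_matrix(cm, SubgroupKey("HC", 1)))
        both = fast.merge(slow, on=["analyte_a", "analyte_b"],
                          suffixes=("_fast", "_slow"))
        unaffected = both[(both.analyte_a != MEDS[26]) & (both.analyte_b != MEDS[26])]
        assert np.allclose(unaffected["rho_spearman_fast"],
                           unaffected["rho_spearman_slow"])
        assert np.allclose(unaffected["p_spearman_fast"],
                           unaffected["p_spearman_slow"])

    def test_low_n_pairs_flagged_not_called(self, rng):
        data = rng.lognormal(size=(6, 27))
        data[:3, 0] = np.nan  # only 3 complete cases for analyte 0 pairs
        cohort = make_cohort({("HC", 1): data})
        recs = correlation_matrix(cohort, SubgroupKey("HC", 1), min_n=5)
        flagged = [r for r in recs if MEDS[0] in (r.a, r.b)]
        assert all(not r.ok for r in flagged)
        net = build_edges(recs, rule="spearman", r_min=0.0, alpha=1.0)
        assert all(frozenset((r.a, r.b)) not in net.edges for r in flagged)


class TestEdgeRule:
    @pytest.mark.parametrize("rho,p,expected", [
        (0.67, 0.01, True),    # inclusive at the strong threshold
        (-0.70, 0.04, True),   # absolute-value rule
        (0.80, 0.06, False),   # significance gate
        (0.669, 0.01, False),
        (0.67, 0.05, False),   # alpha is strict
    ])
    def test_spearman_rule_boundaries(self, rho, p, expected):
        net = build_edges([record(rho=rho, p_s=p)], rule="spearman")
        assert (net.graph.number_of_edges() == 1) is expected

    def test_rule_combinations(self):
        recs = [record(r=0.9, p_r=0.01, rho=0.1, p_s=0.9)]
        assert build_edges(recs, rule="pearson").graph.number_of_edges() == 1
        assert build_edges(recs, rule="spearman").graph.number_of_edges() == 0
        assert build_edges(recs, rule="either").graph.number_of_edges() == 1
        assert build_edges(recs, rule="both").graph.number_of_edges() == 0

    def test_invalid_rule(self):
        with pytest.raises(ValueError, match="unknown rule"):
            build_edges([record()], rule="spearmen")

    def test_edge_monotonicity_in_threshold_and_alpha(self, rng):
        recs = [record(a=MEDS[i], b=MEDS[j],
                       rho=float(rng.uniform(-1, 1)), p_s=float(rng.uniform()))
                for i in range(10) for j in range(i + 1, 10)]
        base = build_edges(recs, r_min=0.5, alpha=0.1).edges
        assert build_edges(recs, r_min=0.7, alpha=0.1).edges <= base
        assert build_edges(recs, r_min=0.5, alpha=0.01).edges <= base

    def test_bh_adjustment_never_adds_edges(self, rng):
        recs = [record(a=MEDS[i], b=MEDS[j], rho=float(rng.uniform(-1, 1)),
                       p_s=float(rng.uniform(0, 0.2)))
                for i in range(10) for j in range(i + 1, 10)]
        plain = build_edges(recs, r_min=0.0).edges
        adjusted = build_edges(recs, r_min=0.0, adjust="bh").edges
        assert adjusted <= plain


class TestConnectivity:
    def test_empty_network(self):
        net = MediatorNetwork.from_edges([], nodes=MEDS)
        report = connectivity(net)
        assert report.total_connections == 0
        assert all(v == 0 for v in report.by_category.values())

    def test_single_edge_degree_sum(self):
        net = MediatorNetwork.from_edges([("CXCL8", "IL-6")], nodes=MEDS)
        report = connectivity(net)
        assert report.total_connections == 2
        assert report.by_category == {"C": 1, "PROc": 1, "REGc": 0, "GF": 0}

    def test_complete_graph_closed_form(self):
        net = MediatorNetwork.from_edges(
            [(a, b) for i, a in enumerate(MEDS) for b in MEDS[i + 1:]])
        report = connectivity(net)
        assert report.total_connections == 27 * 26
        assert report.by_category == {"C": 7 * 26, "PROc": 7 * 26,
                                      "REGc": 6 * 26, "GF": 7 * 26}

    def test_identity_on_random_graphs(self, rng):
        for _ in range(50):
            g = nx.gnp_random_graph(27, rng.uniform(0.02, 0.5),
                                    seed=int(rng.integers(2**31)))
            g = nx.relabel_nodes(g, dict(enumerate(MEDS)))
            report = connectivity(MediatorNetwork.from_edges(g.edges, nodes=MEDS))
            assert sum(report.by_category.values()) == report.total_connections
            assert report.total_connections == 2 * g.number_of_edges()


class TestHubsAndVenn:
    def test_hub_threshold_inclusive(self):
        edges = [("IL-6", m) for m in MEDS[:5]]  # degree exactly 5
        net = MediatorNetwork.from_edges(edges, nodes=MEDS)
        assert "IL-6" in hub_set(net, k=5)

    def test_degree_four_excluded(self):
        edges = [("IL-6", m) for m in MEDS[:4]]
        net = MediatorNetwork.from_edges(edges, nodes=MEDS)
        assert "IL-6" not in hub_set(net, k=5)

    def test_identical_sets(self):
        hubs = frozenset({"IL-6", "IL-10"})
        res = venn_classify(hubs, hubs, trimester=1)
        assert res.preserved == hubs and not res.lost and not res.acquired

    def test_disjoint_sets(self):
        res = venn_classify({"IL-6"}, {"IL-10"}, trimester=2)
        assert not res.preserved
        assert res.lost == {"IL-6"} and res.acquired == {"IL-10"}

    def test_partition_invariants(self, rng):
        pool = list(MEDS)
        for _ in range(25):
            hc = frozenset(rng.choice(pool, size=rng.integers(0, 15), replace=False))
            cv = frozenset(rng.choice(pool, size=rng.integers(0, 15), replace=False))
            res = venn_classify(hc, cv, trimester=3)
            assert res.preserved | res.lost == hc
            assert res.preserved | res.acquired == cv
            assert not res.preserved & res.lost
            assert not res.preserved & res.acquired

    def test_non_panel_hub_rejected(self):
        with pytest.raises(ValueError, match="not in panel"):
            venn_classify({"IL-33"}, set(), trimester=1)


class TestExport:
    def test_single_edge_sif(self, tmp_path):
        net = MediatorNetwork.from_edges([("CXCL8", "IL-6")])
        path = export_network(net, tmp_path / "n.sif", "sif")
        lines = path.read_text().strip().splitlines()
        assert lines == ["CXCL8\tcorr\tIL-6"]

    def test_graphml_round_trip(self, tmp_path, rng):
        cohort = make_cohort({("HC", 1): rng.lognormal(size=(20, 27))})
        recs = correlation_matrix(cohort, SubgroupKey("HC", 1))
        net = build_edges(recs, r_min=0.2, alpha=0.5, nodes=MEDS)
        path = export_network(net, tmp_path / "n.graphml", "graphml")
        g = nx.read_graphml(path)
        assert {frozenset(e) for e in g.edges} == net.edges
        assert g.nodes["CXCL8"]["display_index"] == 1
        assert g.nodes["CXCL8"]["category"] == "C"

    def test_unknown_format(self, tmp_path):
        with pytest.raises(ValueError, match="unknown format"):
            export_network(MediatorNetwork.from_edges([]), tmp_path / "x", "xml")
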