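import math
from fractions import Fraction

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from clustmmra.network_regulons import (
    MiNetwork,
    apply_dpi,
    build_aracne_network,
    default_bins,
    expressed_genes,
    extract_regulon,
    mi_significance_threshold,
    mutual_information,
    regulon_signature_test,
    target_mi_qc,
)
from clustmmra.subtype_diffexp import CandidateCluster
from clustmmra.target_enrichment import TargetMap
from tests.conftest import make_matrix


class TestMutualInformation:
    def test_constant_vector_gives_zero(self, rng):
        x = np.full(50, 3.0)
        y = rng.normal(size=50)
        assert mutual_information(x, y) == 0.0

    def test_two_by_two_joint_matches_hand_summation(self):
        # 20 samples arranged so the 2x2 equal-frequency joint is
        # (0.4, 0.1; 0.1, 0.4); MI = sum p ln(p / 0.25) over the 4 cells.
        x = np.arange(20, dtype=float)
        y_rank = np.empty(20)
        y_rank[:8] = np.arange(8)        # 8 low-x samples in y's low bin
        y_rank[8:10] = [10, 11]          # 2 low-x samples in y's high bin
        y_rank[10:12] = [8, 9]           # 2 high-x samples in y's low bin
        y_rank[12:] = np.arange(12, 20)  # 8 high-x samples in y's high bin
        got = mutual_information(x, y_rank, bins=2)
        expected = 2 * 0.4 * math.log(0.4 / 0.25) + 2 * 0.1 * math.log(0.1 / 0.25)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_symmetry_exact(self, rng):
        x = rng.normal(size=137)
        y = rng.normal(size=137)
        assert mutual_information(x, y) == mutual_information(y, x)

    def test_invariant_under_strictly_monotone_transforms(self, rng):
        x = rng.normal(size=200)
        y = 0.7 * x + rng.normal(size=200)
        base = mutual_information(x, y)
        assert mutual_information(np.exp(x), y) == base
        assert mutual_information(x, y**3) == base
        # decreasing transforms are exact whenever the equal-frequency bins
        # are all the same size (length divisible by the bin count)
        x6 = rng.normal(size=210)
        y6 = 0.7 * x6 + rng.normal(size=210)
        assert mutual_information(-x6, -y6) == mutual_information(x6, y6)

    def test_nonnegative_on_random_data(self, rng):
        for _ in range(10):
            x, y = rng.normal(size=(2, 60))
            assert mutual_information(x, y) >= 0.0

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError, match="8 samples"):
            mutual_information(np.arange(5.0), np.arange(5.0))

    def test_gaussian_sanity_single_seed(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=5000)
        y = 0.8 * x + 0.6 * rng.normal(size=5000)
        assert mutual_information(x, y) == pytest.approx(0.5108, abs=0.08)

    def test_default_bins_rule(self):
        assert default_bins(20) == 2
        assert default_bins(200) == 6
        assert default_bins(10_000) == 10  # clipped


class TestMiSignificanceThreshold:
    def test_iid_noise_threshold_small_and_nonnegative(self):
        rng = np.random.default_rng(1)
        rows = rng.normal(size=(30, 200))
        thr = mi_significance_threshold(rows, rng=np.random.default_rng(2))
        assert 0.0 <= thr < 0.2

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(1)
        rows = rng.normal(size=(20, 150))
        thr_loose = mi_significance_threshold(
            rows, alpha=0.10, rng=np.random.default_rng(7)
        )
        thr_tight = mi_significance_threshold(
            rows, alpha=0.01, rng=np.random.default_rng(7)
        )
        assert thr_tight >= thr_loose

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(1)
        rows = rng.normal(size=(20, 100))
        a = mi_significance_threshold(rows, rng=np.random.default_rng(3))
        b = mi_significance_threshold(rows, rng=np.random.default_rng(3))
        assert a == b


def _triangle(mi_ab, mi_bc, mi_ac):
    g = nx.Graph()
    g.add_edge("a", "b", mi=mi_ab)
    g.add_edge("b", "c", mi=mi_bc)
    g.add_edge("a", "c", mi=mi_ac)
    return g


class TestDpi:
    def test_weakest_edge_removed_at_zero_tolerance(self):
        g = _triangle(0.8, 0.6, 0.3)
        apply_dpi(g, tolerance=0.0)
        assert not g.has_edge("a", "c")
        assert g.has_edge("a", "b") and g.has_edge("b", "c")

    def test_tolerance_spares_borderline_edge(self):
        g = _triangle(0.8, 0.6, 0.55)
        apply_dpi(g, tolerance=0.15)  # 0.55 >= 0.6 * 0.85 = 0.51
        assert g.has_edge("a", "c")

    def test_removals_follow_the_dpi_rule_never_hitting_a_triangle_maximum(self, rng):
        tol = 0.1
        for _ in range(10):
            g = nx.gnp_random_graph(12, 0.4, seed=int(rng.integers(1e6)))
            for u, v in g.edges:
                g[u][v]["mi"] = float(rng.random())
            before = {tuple(sorted((u, v))): d["mi"] for u, v, d in g.edges(data=True)}
            neighbors = {n: set(g[n]) for n in g}
            apply_dpi(g, tolerance=tol)
            removed = set(before) - {tuple(sorted(e)) for e in g.edges}
            for a, c in removed:
                bounds = [
                    min(before[tuple(sorted((a, b)))], before[tuple(sorted((b, c)))])
                    * (1 - tol)
                    for b in neighbors[a] & neighbors[c]
                ]
                # some triangle justified the removal, and within it the
                # removed edge was strictly below both others -- never the max
                assert any(before[(a, c)] < bound for bound in bounds)

    def test_indirect_edge_pruned_in_chain_simulation(self):
        # miRNA -> g1 -> g2: the transitive miRNA-g2 edge must fall to DPI.
        removed = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            m = rng.normal(size=500)
            g1 = -m + 0.5 * rng.normal(size=500)
            g2 = g1 + 0.5 * rng.normal(size=500)
            mirna = make_matrix(m[None, :], kind="mirna", feature_prefix="mir")
            mrna = make_matrix(np.vstack([g1, g2]), kind="mrna")
            cand = CandidateCluster("c", "TNBC", "down", ["mir0"])
            net = build_aracne_network(
                cand, mirna, mrna, frozenset({"g0", "g1"}),
                mi_threshold=0.05, dpi_tolerance=0.15,
            )
            if not net.graph.has_edge("mir0", "g1") and net.graph.has_edge("mir0", "g0"):
                removed += 1
        assert removed >= 18


class TestBuildNetwork:
    def _dataset(self, rng, n=200, n_genes=30):
        m = rng.normal(size=n)
        genes = rng.normal(size=(n_genes, n))
        genes[0] = -0.9 * m + 0.5 * rng.normal(size=n)  # strong true target
        mirna = make_matrix(m[None, :], kind="mirna", feature_prefix="mir")
        mrna = make_matrix(genes, kind="mrna")
        return mirna, mrna

    def test_edges_shrink_as_threshold_grows(self, rng):
        mirna, mrna = self._dataset(rng)
        cand = CandidateCluster("c", "TNBC", "down", ["mir0"])
        expressed = frozenset(mrna.feature_ids)
        # dpi_tolerance=1 disables pruning so thresholding acts alone
        low = build_aracne_network(cand, mirna, mrna, expressed, 0.01, dpi_tolerance=1.0)
        high = build_aracne_network(cand, mirna, mrna, expressed, 0.10, dpi_tolerance=1.0)
        assert set(high.graph.edges) <= set(low.graph.edges)
        for _, _, d in low.graph.edges(data=True):
            assert d["mi"] >= 0.01

    def test_gene_cap_keeps_top_variance_genes(self, rng):
        mirna, mrna = self._dataset(rng, n_genes=20)
        cand = CandidateCluster("c", "TNBC", "down", ["mir0"])
        net = build_aracne_network(
            cand, mirna, mrna, frozenset(mrna.feature_ids), 0.02, gene_cap=5
        )
        assert net.mirna_gene_mi.shape[1] == 5

    def test_expressed_genes_rule(self):
        values = np.array(
            [[10.0] * 10, [0.0] * 10, [10.0] * 3 + [0.0] * 7]
        )
        m = make_matrix(values)
        assert expressed_genes(m, fraction=0.2) == {"g0", "g2"}
        assert expressed_genes(m, fraction=0.5) == {"g0"}


class TestRegulon:
    def _star_network(self):
        g = nx.Graph()
        g.add_edge("mir", "g1", mi=0.5)
        g.add_edge("mir", "g2", mi=0.4)
        g.add_edge("g2", "g3", mi=0.3)
        mi = pd.DataFrame([[0.5, 0.4, 0.0]], index=["mir"], columns=["g1", "g2", "g3"])
        return MiNetwork(g, ["mir"], 0.1, 0.15, mi)

    def test_radius_one_keeps_direct_partners(self):
        net = self._star_network()
        cand = CandidateCluster("c", "TNBC", "down", ["mir"])
        assert extract_regulon(net, cand, radius=1).genes == {"g1", "g2"}

    def test_radius_two_adds_indirect_gene(self):
        net = self._star_network()
        cand = CandidateCluster("c", "TNBC", "down", ["mir"])
        assert extract_regulon(net, cand, radius=2).genes == {"g1", "g2", "g3"}

    def test_empty_network_gives_empty_regulon(self):
        net = MiNetwork(nx.Graph(), ["mir"], 0.1, 0.15,
                        pd.DataFrame(index=["mir"], columns=[]))
        cand = CandidateCluster("c", "TNBC", "down", ["mir"])
        regulon = extract_regulon(net, cand)
        assert regulon.genes == frozenset()
        tested = regulon_signature_test(regulon, {"g1"}, {"g1", "g2"})
        assert tested.fisher_p == 1.0 and tested.passed is False


class TestRegulonSignatureTest:
    def test_matches_direct_hypergeometric_summation(self):
        universe = frozenset(f"g{i}" for i in range(1000))
        regulon_genes = frozenset(f"g{i}" for i in range(20))
        signature = frozenset(f"g{i}" for i in range(10, 60))  # overlap 10
        from clustmmra.network_regulons import Regulon

        regulon = Regulon("c", "TNBC", regulon_genes, 1)
        tested = regulon_signature_test(regulon, signature, universe)
        tail = sum(
            Fraction(math.comb(50, k) * math.comb(950, 20 - k), math.comb(1000, 20))
            for k in range(10, 21)
        )
        assert tested.fisher_p == pytest.approx(float(tail), rel=1e-10)
        assert tested.passed

    def test_degenerate_everything_equal_gives_p_one(self):
        from clustmmra.network_regulons import Regulon

        universe = frozenset(f"g{i}" for i in range(10))
        regulon = Regulon("c", "TNBC", universe, 1)
        tested = regulon_signature_test(regulon, universe, universe)
        assert tested.fisher_p == pytest.approx(1.0)

    def test_under_enriched_overlap_keeps_large_p(self):
        from clustmmra.network_regulons import Regulon

        universe = frozenset(f"g{i}" for i in range(100))
        regulon = Regulon("c", "TNBC", frozenset(f"g{i}" for i in range(30)), 1)
        signature = frozenset(f"g{i}" for i in range(50, 80))  # overlap 0
        tested = regulon_signature_test(regulon, signature, universe)
        assert tested.fisher_p >= 0.5 and not tested.passed


class TestTargetMiQc:
    def _network_with_mi(self, mi_values, gene_names):
        mi = pd.DataFrame([mi_values], index=["mir"], columns=gene_names)
        return MiNetwork(nx.Graph(), ["mir"], 0.1, 0.15, mi)

    def test_fully_separated_groups_hit_exact_rank_p(self):
        genes = [f"t{i}" for i in range(5)] + [f"n{i}" for i in range(5)]
        net = self._network_with_mi([0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1, 0.05],
                                    genes)
        targets = TargetMap({"mir": frozenset(f"t{i}" for i in range(5))}, 2)
        cand = CandidateCluster("c", "TNBC", "down", ["mir"])
        qc = target_mi_qc(net, targets, cand)
        assert qc.iloc[0]["rank_sum_p"] == pytest.approx(1 / 252, rel=1e-9)

    def test_interleaved_groups_are_null(self):
        genes = [f"x{i}" for i in range(20)]
        mis = [0.1 * (i % 10) for i in range(20)]
        net = self._network_with_mi(mis, genes)
        targets = TargetMap({"mir": frozenset(genes[:10])}, 2)
        cand = CandidateCluster("c", "TNBC", "down", ["mir"])
        p = target_mi_qc(net, targets, cand).iloc[0]["rank_sum_p"]
        assert 0.3 < p < 0.7

    def test_too_few_genes_yields_nan_with_warning(self, caplog):
        import logging

        genes = ["t0", "n0", "n1", "n2", "n3", "n4"]
        net = self._network_with_mi([0.9, 0.1, 0.1, 0.1, 0.1, 0.1], genes)
        targets = TargetMap({"mir": frozenset({"t0"})}, 2)
        cand = CandidateCluster("c", "TNBC", "down", ["mir"])
        with caplog.at_level(logging.WARNING):
            qc = target_mi_qc(net, targets, cand)
        assert np.isnan(qc.iloc[0]["rank_sum_p"])
        assert any("too few" in rec.message for rec in caplog.records)

    def test_planted_mirnas_show_elevated_target_mi(self):
        # synthetic coupling: each miRNA's targets carry higher MI than the
        # non-target background in nearly every replicate
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(300 + seed)
            m = rng.normal(size=200)
            genes = rng.normal(size=(40, 200))
            for i in range(10):  # 10 true targets with coupling
                genes[i] = -0.8 * m + rng.normal(size=200)
            mirna = make_matrix(m[None, :], kind="mirna", feature_prefix="mir")
            mrna = make_matrix(genes, kind="mrna")
            cand = CandidateCluster("c", "TNBC", "down", ["mir0"])
            net = build_aracne_network(
                cand, mirna, mrna, frozenset(mrna.feature_ids), 0.05
            )
            targets = TargetMap({"mir0": frozenset(f"g{i}" for i in range(10))}, 2)
            p = target_mi_qc(net, targets, cand).iloc[0]["rank_sum_p"]
            if p < 0.05:
                hits += 1
        assert hits >= 18
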