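"""Band matching, the Sulston score, net construction, Q-removal, clustering."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from bacmap import simdata as sd
from bacmap.assembly import (
    AssemblyConfig,
    adaptive_cluster,
    build_net,
    contig_stats,
    cutoff_schedule,
    layout_and_check_linearity,
    min_significant_shared,
    remove_q_elements,
    shared_band_count,
    sulston_score,
)
from bacmap.fingerprint_io import filter_bands

from conftest import make_fset, make_profile, true_profile


def max_matching_oracle(xs, ys, tol):
    """Maximum one-to-one matching size via bipartite matching (networkx)."""
    g = nx.Graph()
    a = [("a", i) for i in range(len(xs))]
    g.add_nodes_from(a)
    g.add_nodes_from(("b", j) for j in range(len(ys)))
    for i, x in enumerate(xs):
        for j, y in enumerate(ys):
            if abs(x - y) <= tol:
                g.add_edge(("a", i), ("b", j))
    return len(nx.bipartite.maximum_matching(g, top_nodes=a)) // 2


class TestSharedBandCount:
    def test_identical_profiles(self):
        p = make_profile("a", [60, 75, 75, 200])
        assert shared_band_count(p, p, 1) == 4

    def test_spec_example(self):
        a = make_profile("a", [100, 200, 300])
        b = make_profile("b", [101, 205, 300])
        assert shared_band_count(a, b, 2) == 2

    def test_disjoint(self):
        a = make_profile("a", [100, 200])
        b = make_profile("b", [150, 260])
        assert shared_band_count(a, b, 2) == 0

    @given(
        st.lists(st.integers(50, 80), max_size=12),
        st.lists(st.integers(50, 80), max_size=12),
        st.integers(0, 3),
    )
    @settings(max_examples=200, deadline=None)
    def test_greedy_equals_maximum_matching(self, xs, ys, tol):
        a, b = make_profile("a", xs), make_profile("b", ys)
        assert shared_band_count(a, b, tol) == max_matching_oracle(
            sorted(xs), sorted(ys), tol
        )

    @given(
        st.lists(st.integers(50, 500), max_size=15),
        st.lists(st.integers(50, 500), max_size=15),
    )
    @settings(max_examples=100, deadline=None)
    def test_symmetry(self, xs, ys):
        a, b = make_profile("a", xs), make_profile("b", ys)
        assert shared_band_count(a, b, 2) == shared_band_count(b, a, 2)

    def test_negative_tolerance_rejected(self):
        p = make_profile("a", [100])
        with pytest.raises(ValueError):
            shared_band_count(p, p, -1)


class TestSulstonScore:
    def test_zero_shared_full_mass(self):
        assert sulston_score(5, 10, 0) == 1.0

    def test_zero_tolerance(self):
        assert sulston_score(5, 10, 1, tolerance=0) == 0.0
        assert sulston_score(5, 10, 0, tolerance=0) == 1.0

    def test_derived_value(self):
        # independently verified against the Monte-Carlo band-throwing
        # oracle in the acceptance suite
        assert sulston_score(3, 5, 2, tolerance=2, gellen=100) == pytest.approx(
            0.0897, abs=5e-4
        )

    def test_matches_scipy_binomial_tail(self):
        for n_low, n_high, shared in itertools.product(
            (3, 10, 25), (25, 40), (1, 3, 10)
        ):
            if shared > n_low:
                continue
            x = 1.0 - (1.0 - 2.0 / 451) ** n_high
            expected = sps.binom.sf(shared - 1, n_low, x)
            assert sulston_score(n_low, n_high, shared) == pytest.approx(
                expected, rel=1e-9
            )

    def test_monotone_nonincreasing_in_shared(self):
        scores = [sulston_score(20, 30, s) for s in range(21)]
        assert all(a >= b for a, b in zip(scores, scores[1:]))
        assert all(0.0 <= s <= 1.0 for s in scores)

    def test_shared_beyond_n_low_rejected(self):
        with pytest.raises(ValueError):
            sulston_score(5, 10, 6)
        with pytest.raises(ValueError):
            sulston_score(10, 5, 3)

    def test_min_significant_shared(self):
        m = min_significant_shared(30, 30, 1e-15, 1, 451)
        assert sulston_score(30, 30, m) <= 1e-15
        assert sulston_score(30, 30, m - 1) > 1e-15
        assert min_significant_shared(5, 5, 1e-33, 1, 451) is None


class TestBuildNet:
    def test_identical_clones_linked(self):
        rng = np.random.default_rng(0)
        bands = rng.integers(50, 501, 30)
        fset = make_fset([make_profile("a", bands), make_profile("b", bands)])
        net = build_net(fset, AssemblyConfig())
        assert net.graph.has_edge("a", "b")
        assert net.graph["a"]["b"]["p"] <= 1e-15

    def test_unrelated_clones_unlinked(self):
        rng = np.random.default_rng(1)
        fset = make_fset(
            make_profile(f"c{i}", rng.integers(50, 501, 30)) for i in range(40)
        )
        net = build_net(fset, AssemblyConfig())
        assert net.n_edges == 0

    def test_noise_free_truth_pairs_linked(self, small_arm):
        clones = sd.sample_clone_library(small_arm, 40, purity=1.0, seed=31)
        fset = sd.fingerprint_library(clones, small_arm, sd.NOISE_FREE)
        fset, _ = filter_bands(fset)
        cfg = AssemblyConfig()
        net = build_net(fset, cfg)
        profiles = {p.clone_id: p for p in fset}
        for a, b in itertools.combinations(profiles.values(), 2):
            shared = shared_band_count(a, b, cfg.tolerance)
            n_low, n_high = sorted((a.n_bands, b.n_bands))
            score = sulston_score(n_low, n_high, min(shared, n_low), 1, 451)
            assert net.graph.has_edge(a.clone_id, b.clone_id) == (score <= 1e-15)

    def test_edge_invariants(self, dense_assembly):
        net = dense_assembly["net"]
        nb = nx.get_node_attributes(net.graph, "n_bands")
        for u, v, d in net.graph.edges(data=True):
            assert d["shared"] <= min(nb[u], nb[v])
            assert 0.0 <= d["p"] <= net.cutoff


def _two_region_library(arm, seed=41):
    """Clones tiling two distant regions of the arm."""
    clones = []
    rng = np.random.default_rng(seed)
    for i, s in enumerate(rng.uniform(0, 250, 25)):
        clones.append(sd.TrueClone(f"L{i:02d}", float(s), float(s) + 143))
    for i, s in enumerate(rng.uniform(2500, 2750, 25)):
        clones.append(sd.TrueClone(f"R{i:02d}", float(s), float(s) + 143))
    return clones


def _plant_chimera(arm, fset, name, left, right, insert=143.0):
    """A chimeric profile made of two distant inserts, with close clone
    cover on both pieces so its overlaps are detectable at the net cutoff."""
    chimera = make_profile(
        name,
        true_profile(arm, left, left + insert).bands
        + true_profile(arm, right, right + insert).bands,
    )
    fset.add(chimera)
    for side, anchor in (("l", left), ("r", right)):
        for k, off in enumerate((-6.0, -3.0, 3.0)):
            fset.add(
                true_profile(arm, anchor + off, anchor + off + insert, f"{name}{side}{k}")
            )
    return chimera


class TestRemoveQElements:
    def test_clean_linear_chain_untouched(self, dense_assembly):
        qreport = dense_assembly["qreport"]
        assert qreport.q_clones == []

    def test_planted_chimera_flagged(self):
        arm = sd.simulate_arm(3000, 2.5, seed=40)
        clones = _two_region_library(arm)
        fset = sd.fingerprint_library(clones, arm, sd.NOISE_FREE)
        _plant_chimera(arm, fset, "CHIM", 100.0, 2600.0)
        fset, _ = filter_bands(fset)
        cfg = AssemblyConfig()
        net = build_net(fset, cfg)
        qnet, report = remove_q_elements(net, cfg, fset)
        assert "CHIM" in report.q_clones
        # with the chimera gone the two regions separate
        def side_of(cid):
            return "L" if cid.startswith(("L", "CHIMl")) else "R"

        comps = [c for c in nx.connected_components(qnet.graph) if len(c) > 1]
        assert comps
        for comp in comps:
            assert len({side_of(c) for c in comp}) == 1

    def test_chimera_recall(self):
        arm = sd.simulate_arm(12_000, 2.5, seed=43)
        rng = np.random.default_rng(44)
        clones = [
            sd.TrueClone(f"C{i:03d}", float(s), float(s) + 143)
            for i, s in enumerate(np.sort(rng.uniform(0, 12_000 - 143, 900)))
        ]
        fset = sd.fingerprint_library(clones, arm, sd.NOISE_FREE)
        planted = []
        for k in range(10):
            left = 150.0 + 550 * k  # anchors distinct, sides never shared
            right = left + 6000.0
            prof = _plant_chimera(arm, fset, f"CHIM{k}", left, right)
            planted.append(prof.clone_id)
        fset, _ = filter_bands(fset)
        cfg = AssemblyConfig()
        net = build_net(fset, cfg)
        _, report = remove_q_elements(net, cfg, fset)
        recall = len(set(report.q_clones) & set(planted)) / len(planted)
        assert recall >= 0.9

    def test_q_overlap_removal_preserves_connectivity(self, dense_assembly):
        net, qnet = dense_assembly["net"], dense_assembly["qnet"]
        before = nx.number_connected_components(net.graph)
        after = nx.number_connected_components(
            qnet.graph.subgraph(n for n in net.graph.nodes if n in qnet.graph)
        )
        assert after == before


def _chain_graph(edges, n_bands=30):
    g = nx.Graph()
    for u, v, shared in edges:
        g.add_edge(u, v, shared=shared, p=10.0 ** (-16 - shared))
    for node in g.nodes:
        g.nodes[node]["n_bands"] = n_bands
    return g


class TestLayout:
    def test_chain_order(self):
        g = _chain_graph([("A", "B", 15), ("B", "C", 15)])
        layout = layout_and_check_linearity(g, insert_mean_kb=100)
        assert layout.linear
        assert layout.clones in (["A", "B", "C"], ["C", "B", "A"])

    def test_star_non_linear(self):
        # hub overlapping three mutually non-overlapping clones, none buried
        g = _chain_graph([("H", "A", 12), ("H", "B", 12), ("H", "C", 12)])
        layout = layout_and_check_linearity(g, insert_mean_kb=100)
        assert not layout.linear
        assert layout.branching_clones == ["H"]

    def test_single_clone_layout(self):
        g = nx.Graph()
        g.add_node("A", n_bands=20)
        layout = layout_and_check_linearity(g, insert_mean_kb=143)
        assert layout.linear and layout.length_kb == 143 and layout.depth == 1.0

    def test_noise_free_coordinates_track_truth(self, dense_assembly):
        from scipy.stats import spearmanr

        clones = {c.clone_id: c for c in dense_assembly["clones"]}
        big = max(dense_assembly["assembly"].contigs, key=lambda c: c.n_clones)
        assert big.n_clones >= 40
        coords = [big.coordinates[c] for c in big.clones]
        truth = [clones[c].start_kb for c in big.clones]
        assert abs(spearmanr(coords, truth).statistic) >= 0.99


class TestContigStats:
    def test_single_clone(self):
        g = nx.Graph()
        g.add_node("A", n_bands=20)
        layout = layout_and_check_linearity(g, insert_mean_kb=143)
        length, depth = contig_stats(layout, 143)
        assert (length, depth) == (143, 1.0)

    def test_arithmetic(self):
        from bacmap.assembly import ContigLayout

        layout = ContigLayout(
            "CTG1",
            [f"c{i}" for i in range(10)],
            {f"c{i}": i * (650 - 143) / 9 for i in range(10)},
            650.0,
            2.2,
            True,
        )
        length, depth = contig_stats(layout, 143)
        assert length == pytest.approx(650)
        assert depth == pytest.approx(10 * 143 / 650, rel=1e-6)


class TestAdaptiveCluster:
    def test_schedule_endpoints(self):
        cutoffs = cutoff_schedule(AssemblyConfig())
        assert len(cutoffs) == 7
        assert cutoffs[0] == pytest.approx(1e-15, rel=1e-9)
        assert cutoffs[-1] == pytest.approx(1e-33, rel=1e-9)
        exps = np.log10(cutoffs)
        assert np.allclose(np.diff(exps), -3.0)

    def test_five_clone_component_is_short_contig(self, dense_assembly):
        cfg = dense_assembly["cfg"]
        assembly = dense_assembly["assembly"]
        for contig in assembly.contigs:
            if contig.n_clones == 5:
                assert contig not in assembly.main_contigs
        assert all(c.n_clones >= cfg.min_contig_clones for c in assembly.main_contigs)

    def test_noise_free_partition_matches_truth(self, small_arm, dense_assembly):
        from sklearn.metrics import adjusted_rand_score

        truth = sd.recoverable_partition(dense_assembly["clones"], small_arm)
        part = dense_assembly["assembly"].partition()
        common = sorted(c for c in truth if c in part)
        assert adjusted_rand_score(
            [truth[c] for c in common], [part[c] for c in common]
        ) == pytest.approx(1.0)

    def test_all_contigs_linear(self, dense_assembly):
        assert all(c.linear for c in dense_assembly["assembly"].contigs)

    def test_chimera_excluded_and_contigs_separated(self):
        arm = sd.simulate_arm(3000, 2.5, seed=47)
        clones = _two_region_library(arm, seed=48)
        fset = sd.fingerprint_library(clones, arm, sd.NOISE_FREE)
        _plant_chimera(arm, fset, "CHIM", 100.0, 2600.0)
        fset, _ = filter_bands(fset)
        cfg = AssemblyConfig()
        net = build_net(fset, cfg)
        qnet, report = remove_q_elements(net, cfg, fset)
        assembly = adaptive_cluster(qnet, cfg, fset)
        part = assembly.partition()
        assert "CHIM" not in part
        sides = {
            part[c] for c in part if c.startswith("L")
        }, {part[c] for c in part if c.startswith("R")}
        assert not (sides[0] & sides[1])

    def test_monotone_stringency_never_merges(self, dense_assembly):
        """Tightening the cutoff only refines the clone partition."""
        graph = dense_assembly["qnet"].graph
        for cutoff in (1e-15, 1e-21, 1e-27, 1e-33):
            sub = nx.subgraph_view(
                graph, filter_edge=lambda u, v, c=cutoff: graph[u][v]["p"] <= c
            )
            comps = list(nx.connected_components(sub))
            if cutoff == 1e-15:
                previous = comps
                continue
            for comp in comps:
                assert any(comp <= prev for prev in previous)
            previous = comps
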