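"""Deletion-bin inference, bin sizes, within-bin ordering, supercontigs, AGP."""

import networkx as nx
import pytest

from bacmap.assembly import ContigLayout, OverlapNet
from bacmap.binmap import (
    BinAssignment,
    OrthologRankTable,
    SuperContig,
    assign_contigs_to_bins,
    correct_bin_sizes,
    elongate_supercontigs,
    estimate_bin_sizes,
    infer_bin_from_deletion_lines,
    make_bins,
    order_contigs_within_bins,
    read_agp,
    write_agp,
)


class TestDeletionLineInference:
    def test_absent_in_both_distal(self):
        call = infer_bin_from_deletion_lines({"5DS-5": False, "5DS-2": False})
        assert call.label == "0.78-1.00" and call.consistent

    def test_present_only_in_larger(self):
        call = infer_bin_from_deletion_lines({"5DS-5": False, "5DS-2": True})
        assert call.label == "0.67-0.78" and call.consistent

    def test_present_in_both_proximal_unrefined(self):
        call = infer_bin_from_deletion_lines({"5DS-5": True, "5DS-2": True})
        assert call.consistent
        assert call.label == "0-0.67"  # refined only with genetic evidence

    def test_present_in_both_refined_by_genetic_bin(self):
        call = infer_bin_from_deletion_lines(
            {"5DS-5": True, "5DS-2": True}, genetic_bin="0.63-0.67"
        )
        assert call.label == "0.63-0.67"

    def test_impossible_retention_flagged(self):
        call = infer_bin_from_deletion_lines({"5DS-5": True, "5DS-2": False})
        assert call.label is None and not call.consistent

    def test_three_lines_resolve_all_bins(self):
        lines = {"DL63": 0.63, "DL67": 0.67, "DL78": 0.78}
        call = infer_bin_from_deletion_lines(
            {"DL63": True, "DL67": True, "DL78": True}, lines
        )
        assert call.label == "0-0.63"
        call = infer_bin_from_deletion_lines(
            {"DL63": False, "DL67": True, "DL78": True}, lines
        )
        assert call.label == "0.63-0.67"


class TestContigBinAssignment:
    def test_majority_with_conflict(self):
        out = assign_contigs_to_bins(
            {"m1": ["CTG1"], "m2": ["CTG1"], "m3": ["CTG1"]},
            {"m1": "A", "m2": "A", "m3": "B"},
        )
        (a,) = out
        assert a.bin_label == "A" and a.conflict

    def test_single_marker_no_conflict(self):
        (a,) = assign_contigs_to_bins({"m1": ["CTG1"]}, {"m1": "0-0.63"})
        assert a.bin_label == "0-0.63" and not a.conflict

    def test_conflict_flag_invariant(self):
        with pytest.raises(ValueError):
            BinAssignment("CTG1", "A", [("m1", "A"), ("m2", "B")], conflict=False)

    def test_unbinned_markers_ignored(self):
        out = assign_contigs_to_bins({"m1": ["CTG1"], "m2": ["CTG2"]}, {"m1": "A"})
        assert [a.contig_id for a in out] == ["CTG1"]


class TestBinSizes:
    PAPER = {"0.78-1.00": 26.54, "0.67-0.78": 7.93, "0.63-0.67": 29.71, "0-0.63": 72.92}

    def test_distal_bin_share(self):
        sizes = correct_bin_sizes(self.PAPER, 258.0, total_mapped_mb=138.3)
        assert round(sizes["0.78-1.00"].share_pct, 1) == 19.2
        assert sizes["0.78-1.00"].corrected_mb > 49.0

    def test_narrow_bin_over_55(self):
        sizes = correct_bin_sizes(self.PAPER, 258.0, total_mapped_mb=138.3)
        assert sizes["0.63-0.67"].corrected_mb > 55.0

    def test_mid_bin_share(self):
        sizes = correct_bin_sizes(self.PAPER, 258.0, total_mapped_mb=138.3)
        assert round(sizes["0.67-0.78"].share_pct, 1) == 5.7
        assert sizes["0.67-0.78"].corrected_mb == pytest.approx(14.79, abs=0.05)

    def test_corrected_sizes_sum_to_arm(self):
        sizes = correct_bin_sizes(self.PAPER, 258.0)
        assert sum(s.corrected_mb for s in sizes.values()) == pytest.approx(258.0)
        one = correct_bin_sizes({"A": 31.4}, 200.0)
        assert one["A"].corrected_mb == pytest.approx(200.0)

    def test_zero_mapped_rejected(self):
        with pytest.raises(ValueError):
            correct_bin_sizes({}, 258.0)

    def test_estimate_from_assignments(self):
        assignments = [
            BinAssignment("CTG1", "A", [("m1", "A")]),
            BinAssignment("CTG2", "B", [("m2", "B")]),
        ]
        sizes = estimate_bin_sizes(assignments, {"CTG1": 3000, "CTG2": 1000}, 10_000)
        assert sizes["A"].corrected_mb == pytest.approx(7.5)
        assert sizes["B"].corrected_mb == pytest.approx(2.5)


def _ranked_assignment(cid, bin_label, ranks, offset=0):
    ev = [(f"{cid}m{i}", bin_label) for i in range(len(ranks))]
    return BinAssignment(cid, bin_label, ev), {
        f"{cid}m{i}": r for i, r in enumerate(ranks)
    }


class TestOrdering:
    def test_median_rank_order(self):
        table = OrthologRankTable()
        assignments = []
        for cid, ranks in (("CTGa", [9]), ("CTGb", [2]), ("CTGc", [5])):
            a, marker_ranks = _ranked_assignment(cid, "0-0.63", ranks)
            assignments.append(a)
            for m, r in marker_ranks.items():
                table.add(m, "tauschii", r)
        ordered, _ = order_contigs_within_bins(assignments, table)
        by_index = sorted(
            (a for a in ordered if a.order_index is not None),
            key=lambda a: a.order_index,
        )
        assert [a.contig_id for a in by_index] == ["CTGb", "CTGc", "CTGa"]

    def test_zipper_fallback_interleaves(self):
        table = OrthologRankTable()
        a1, r1 = _ranked_assignment("CTG1", "A", [10])
        a2, r2 = _ranked_assignment("CTG2", "A", [30])
        for m, r in {**r1, **r2}.items():
            table.add(m, "tauschii", r)
            table.add(m, "zipper", r * 2)  # zipper scale is doubled
        a3 = BinAssignment("CTG3", "A", [("zm1", "A")])
        table.add("zm1", "zipper", 40)  # between CTG1 (20) and CTG2 (60)
        ordered, _ = order_contigs_within_bins([a1, a2, a3], table)
        by_index = sorted(ordered, key=lambda a: a.order_index)
        assert [a.contig_id for a in by_index] == ["CTG1", "CTG3", "CTG2"]
        assert a3.rank_source == "zipper"

    def test_contig_without_ranks_unplaced(self):
        a = BinAssignment("CTG1", "A", [("m1", "A")])
        ordered, _ = order_contigs_within_bins([a], OrthologRankTable())
        assert a.order_index is None and a.rank is None

    def test_duplicated_ortholog_reported(self):
        table = OrthologRankTable()
        a1, _ = _ranked_assignment("CTG1", "A", [5])
        a2, _ = _ranked_assignment("CTG2", "B", [5])
        table.add("CTG1m0", "tauschii", 5)
        table.add("CTG2m0", "tauschii", 5)
        _, report = order_contigs_within_bins([a1, a2], table)
        dup = [d for d in report if d.kind == "duplicated_ortholog"]
        assert dup and dup[0].contigs == ("CTG1", "CTG2")

    def test_split_location_flagged(self):
        table = OrthologRankTable()
        ranks = [3, 4, 5, 210, 211]
        a, marker_ranks = _ranked_assignment("CTG134", "A", ranks)
        for m, r in marker_ranks.items():
            table.add(m, "tauschii", r)
        # pad the rank range with other markers so the span threshold is small
        for i in range(300):
            table.add(f"bg{i}", "tauschii", i)
        _, report = order_contigs_within_bins([a], table)
        assert any(
            d.kind == "split_location" and d.contigs == ("CTG134",) for d in report
        )

    def test_rank_table_validation(self):
        table = OrthologRankTable()
        with pytest.raises(ValueError):
            table.add("m", "rice", 1)
        with pytest.raises(ValueError):
            table.add("m", "tauschii", -1)


def _layout(cid, clones, start=0.0, step=50.0):
    coords = {c: start + i * step for i, c in enumerate(clones)}
    return ContigLayout(cid, list(clones), coords, step * len(clones) + 93, 2.0, True)


def _net(edges, nodes, n_bands=40):
    g = nx.Graph()
    for n in nodes:
        g.add_node(n, n_bands=n_bands)
    for u, v, p in edges:
        g.add_edge(u, v, shared=30, p=p)
    return OverlapNet(g, 1e-15)


class TestSupercontigs:
    def test_clone_count_bookkeeping(self):
        sc = SuperContig("SC10", ["CTG143", "CTG120", "CTG82"], [], [251, 61, 136])
        assert sc.total_clones == 448

    def test_end_to_end_pair_merges(self):
        la = _layout("CTG1", ["a1", "a2", "a3"])
        lb = _layout("CTG2", ["b1", "b2", "b3"])
        edges = [
            ("a1", "a2", 1e-40), ("a2", "a3", 1e-40),
            ("b1", "b2", 1e-40), ("b2", "b3", 1e-40),
            ("a3", "b1", 1e-16),  # end-clone overlap at the relaxed cutoff
        ]
        net = _net(edges, ["a1", "a2", "a3", "b1", "b2", "b3"])
        scs, rejected = elongate_supercontigs([la, lb], net, 1e-15)
        assert len(scs) == 1
        assert set(scs[0].members) == {"CTG1", "CTG2"}
        assert scs[0].total_clones == 6
        assert not rejected

    def test_interior_overlap_does_not_merge(self):
        la = _layout("CTG1", ["a1", "a2", "a3", "a4", "a5"])
        lb = _layout("CTG2", ["b1", "b2", "b3", "b4", "b5"])
        chain = [(f"a{i}", f"a{i+1}", 1e-40) for i in range(1, 5)]
        chain += [(f"b{i}", f"b{i+1}", 1e-40) for i in range(1, 5)]
        chain.append(("a3", "b3", 1e-16))  # interior clones only
        net = _net(chain, [f"a{i}" for i in range(1, 6)] + [f"b{i}" for i in range(1, 6)])
        scs, _ = elongate_supercontigs([la, lb], net, 1e-15)
        assert scs == []

    def test_chain_of_three(self):
        las = [_layout(f"CTG{i}", [f"x{i}_{j}" for j in range(3)]) for i in range(3)]
        nodes = [c for l in las for c in l.clones]
        edges = []
        for l in las:
            edges += [(l.clones[0], l.clones[1], 1e-40), (l.clones[1], l.clones[2], 1e-40)]
        edges.append(("x0_2", "x1_0", 1e-17))
        edges.append(("x1_2", "x2_0", 1e-18))
        net = _net(edges, nodes)
        scs, _ = elongate_supercontigs(las, net, 1e-15)
        assert len(scs) == 1
        assert scs[0].members in (["CTG0", "CTG1", "CTG2"], ["CTG2", "CTG1", "CTG0"])
        assert scs[0].total_clones == 9

    def test_membership_is_partition(self):
        las = [_layout(f"CTG{i}", [f"y{i}_{j}" for j in range(3)]) for i in range(4)]
        nodes = [c for l in las for c in l.clones]
        edges = []
        for l in las:
            edges += [(l.clones[0], l.clones[1], 1e-40), (l.clones[1], l.clones[2], 1e-40)]
        edges += [("y0_2", "y1_0", 1e-16), ("y2_2", "y3_0", 1e-16)]
        net = _net(edges, nodes)
        scs, _ = elongate_supercontigs(las, net, 1e-15)
        seen = [m for sc in scs for m in sc.members]
        assert len(seen) == len(set(seen))


class TestAGP:
    def test_roundtrip_preserves_bin_map(self, tmp_path):
        assignments = [
            BinAssignment("CTG2", "0-0.63", [("m1", "0-0.63")], rank=2.0, order_index=0),
            BinAssignment("CTG1", "0-0.63", [("m2", "0-0.63")], rank=5.0, order_index=1),
            BinAssignment("CTG3", "0.78-1.00", [("m3", "0.78-1.00")], order_index=0),
        ]
        lengths = {"CTG1": 1500.0, "CTG2": 900.0, "CTG3": 2000.0}
        path = tmp_path / "map.agp"
        write_agp(assignments, lengths, path)
        back = read_agp(path)
        assert list(back["component_id"]) == ["CTG2", "CTG1", "CTG3"]
        assert list(back["bin"]) == ["0-0.63", "0-0.63", "0.78-1.00"]
        assert list(back["component_length"]) == [900_000, 1_500_000, 2_000_000]

    def test_agp_gaps_between_contigs(self, tmp_path):
        assignments = [
            BinAssignment("CTG1", "A", [("m", "A")], order_index=0),
            BinAssignment("CTG2", "A", [("m2", "A")], order_index=1),
        ]
        path = tmp_path / "map.agp"
        write_agp(assignments, {"CTG1": 100.0, "CTG2": 100.0}, path, gap_size=100)
        lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert len(lines) == 3
        assert lines[1].split("\t")[4] == "U"


def test_make_bins_tile_unit_interval():
    bins = make_bins()
    assert [b.label for b in bins] == ["0-0.63", "0.63-0.67", "0.67-0.78", "0.78-1.00"]
    assert bins[0].lo == 0.0 and bins[-1].hi == 1.0
    assert sum(b.cytogenetic_share for b in bins) == pytest.approx(1.0)
    for b1, b2 in zip(bins, bins[1:]):
        assert b1.hi == b2.lo
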