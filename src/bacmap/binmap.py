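"""Deletion-bin mapping: contig-to-bin allocation, coverage-corrected bin
sizes, ortholog-rank ordering, supercontig elongation, and AGP export."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .assembly import ContigLayout, OverlapNet, layout_and_check_linearity

__all__ = [
    "DeletionBin",
    "BinCall",
    "BinAssignment",
    "OrthologRankTable",
    "SuperContig",
    "make_bins",
    "infer_bin_from_deletion_lines",
    "assign_contigs_to_bins",
    "estimate_bin_sizes",
    "correct_bin_sizes",
    "BinSize",
    "order_contigs_within_bins",
    "elongate_supercontigs",
    "write_agp",
    "read_agp",
]

DEFAULT_DELETION_LINES = {"5DS-5": 0.67, "5DS-2": 0.78}


@dataclass(frozen=True)
class DeletionBin:
    """A cytogenetic deletion bin: an arm-fraction interval [lo, hi)."""

    label: str
    lo: float
    hi: float

    @property
    def cytogenetic_share(self) -> float:
        return self.hi - self.lo


def make_bins(boundaries: Sequence[float] = (0.63, 0.67, 0.78)) -> list[DeletionBin]:
    """Bins tiling [0, 1) from ordered arm-fraction boundaries."""
    edges = [0.0, *boundaries, 1.0]
    if any(b2 <= b1 for b1, b2 in zip(edges, edges[1:])):
        raise ValueError("bin boundaries must be strictly increasing")
    return [
        DeletionBin(f"{lo:g}-{hi:.2f}", lo, hi) for lo, hi in zip(edges[:-1], edges[1:])
    ]


@dataclass(frozen=True)
class BinCall:
    """Outcome of deletion-line bin inference."""

    label: str | None
    consistent: bool
    interval: tuple[float, float] | None = None


def infer_bin_from_deletion_lines(
    present_in: Mapping[str, bool],
    lines: Mapping[str, float] = DEFAULT_DELETION_LINES,
    bins: Sequence[DeletionBin] | None = None,
    genetic_bin: str | None = None,
) -> BinCall:
    """Infer a marker's deletion bin from presence calls on deletion lines.

    A deletion line of fraction length ``f`` retains the proximal ``[0, f)``
    portion of the arm, so presence implies position < f and absence implies
    position >= f.  Impossible retention patterns are flagged inconsistent.
    The proximal interval below the smallest tested fraction is refined into
    sub-bins only when ``genetic_bin`` evidence is supplied.
    """
    if bins is None:
        bins = make_bins()
    upper = 1.0
    lower = 0.0
    for line, present in present_in.items():
        f = lines[line]
        if present:
            upper = min(upper, f)
        else:
            lower = max(lower, f)
    if lower >= upper:
        return BinCall(None, False, None)
    matching = [b for b in bins if b.lo >= lower - 1e-9 and b.hi <= upper + 1e-9]
    if len(matching) == 1:
        return BinCall(matching[0].label, True, (lower, upper))
    if genetic_bin is not None and any(b.label == genetic_bin for b in matching):
        return BinCall(genetic_bin, True, (lower, upper))
    label = f"{lower:g}-{upper:.2f}"
    return BinCall(label, True, (lower, upper))


@dataclass
class BinAssignment:
    """A contig's deletion-bin allocation with its marker evidence."""

    contig_id: str
    bin_label: str | None
    evidence: list[tuple[str, str]] = field(default_factory=list)  # (marker, bin)
    conflict: bool = False
    rank: float | None = None
    rank_source: str | None = None
    order_index: int | None = None

    def __post_init__(self) -> None:
        bins_seen = {b for _, b in self.evidence}
        if self.conflict != (len(bins_seen) >= 2):
            raise ValueError("conflict flag must match multi-bin evidence")


def assign_contigs_to_bins(
    marker_contigs: Mapping[str, Iterable[str]],
    marker_bins: Mapping[str, str],
) -> list[BinAssignment]:
    """Majority vote of marker bins per contig; dissent sets the conflict flag.

    ``marker_contigs`` maps marker id -> contigs it was assigned to;
    ``marker_bins`` maps marker id -> deletion-bin label.
    """
    evidence: dict[str, list[tuple[str, str]]] = {}
    for marker, contigs in marker_contigs.items():
        if marker not in marker_bins:
            continue
        for contig in contigs:
            evidence.setdefault(contig, []).append((marker, marker_bins[marker]))
    out = []
    for contig in sorted(evidence):
        ev = sorted(evidence[contig])
        counts: dict[str, int] = {}
        for _, b in ev:
            counts[b] = counts.get(b, 0) + 1
        best = max(counts.items(), key=lambda kv: (kv[1], kv[0]))[0]
        out.append(
            BinAssignment(
                contig_id=contig,
                bin_label=best,
                evidence=ev,
                conflict=len(counts) >= 2,
            )
        )
    return out


@dataclass(frozen=True)
class BinSize:
    """Coverage-corrected physical size estimate for one bin."""

    label: str
    mapped_mb: float
    corrected_mb: float
    share_pct: float


def correct_bin_sizes(
    mapped_mb: Mapping[str, float],
    arm_length_mb: float,
    total_mapped_mb: float | None = None,
) -> dict[str, BinSize]:
    """Correct per-bin mapped lengths by overall mapped coverage.

    corrected(bin) = mapped(bin) / (total_mapped / arm_length);
    share(bin) = mapped(bin) / total_mapped.  With the default total the
    corrected sizes sum to the arm length exactly.
    """
    if total_mapped_mb is None:
        total_mapped_mb = float(sum(mapped_mb.values()))
    if total_mapped_mb <= 0:
        raise ValueError("total mapped length must be positive")
    coverage = total_mapped_mb / arm_length_mb
    return {
        label: BinSize(
            label=label,
            mapped_mb=mb,
            corrected_mb=mb / coverage,
            share_pct=100.0 * mb / total_mapped_mb,
        )
        for label, mb in mapped_mb.items()
    }


def estimate_bin_sizes(
    assignments: Iterable[BinAssignment],
    contig_lengths_kb: Mapping[str, float],
    arm_length_kb: float,
) -> dict[str, BinSize]:
    """Aggregate mapped contig lengths per bin and apply the coverage correction."""
    mapped: dict[str, float] = {}
    for a in assignments:
        if a.bin_label is None:
            continue
        mapped[a.bin_label] = mapped.get(a.bin_label, 0.0) + contig_lengths_kb.get(
            a.contig_id, 0.0
        ) / 1000.0
    if not mapped:
        raise ValueError("no mapped contigs")
    return correct_bin_sizes(mapped, arm_length_kb / 1000.0)


@dataclass
class OrthologRankTable:
    """Marker -> (reference, rank) for the synteny references."""

    ranks: dict[str, dict[str, int]] = field(default_factory=dict)
    references: tuple[str, ...] = ("tauschii", "zipper")

    def add(self, marker_id: str, reference: str, rank: int) -> None:
        if reference not in self.references:
            raise ValueError(f"unknown reference {reference!r}")
        if rank < 0:
            raise ValueError("ranks must be nonnegative")
        self.ranks.setdefault(marker_id, {})[reference] = int(rank)

    def rank_of(self, marker_id: str, reference: str) -> int | None:
        return self.ranks.get(marker_id, {}).get(reference)

    def markers_with(self, reference: str) -> dict[str, int]:
        return {
            m: refs[reference] for m, refs in self.ranks.items() if reference in refs
        }


@dataclass
class DuplicationEntry:
    kind: str  # "duplicated_ortholog" | "split_location"
    detail: str
    contigs: tuple[str, ...]


def order_contigs_within_bins(
    assignments: list[BinAssignment],
    rank_table: OrthologRankTable,
    span_fraction: float = 0.05,
) -> tuple[list[BinAssignment], list[DuplicationEntry]]:
    """Order contigs inside each bin by median ortholog rank.

    Primary ordering uses the tauschii reference; contigs lacking tauschii
    ranks are slotted in via their median zipper rank, mapped onto the
    tauschii scale by interpolation over contigs carrying both.  Contigs with
    neither stay unplaced.  The duplication report lists orthologs matched by
    non-adjacent contigs and contigs whose ranks split into separated
    clusters (gap > ``span_fraction`` of the reference rank range).
    """
    t_ranks = rank_table.markers_with("tauschii")
    z_ranks = rank_table.markers_with("zipper")

    def contig_ranks(a: BinAssignment, table: Mapping[str, int]) -> list[int]:
        return sorted(table[m] for m, _ in a.evidence if m in table)

    # interpolation anchors between the two rank scales
    anchors_z, anchors_t = [], []
    for a in assignments:
        tr = contig_ranks(a, t_ranks)
        zr = contig_ranks(a, z_ranks)
        if tr and zr:
            anchors_z.append(float(np.median(zr)))
            anchors_t.append(float(np.median(tr)))
    if anchors_z:
        order = np.argsort(anchors_z)
        anchors_z = list(np.asarray(anchors_z)[order])
        anchors_t = list(np.asarray(anchors_t)[order])

    for a in assignments:
        tr = contig_ranks(a, t_ranks)
        zr = contig_ranks(a, z_ranks)
        if tr:
            a.rank = float(np.median(tr))
            a.rank_source = "tauschii"
        elif zr:
            zmed = float(np.median(zr))
            if anchors_z:
                a.rank = float(np.interp(zmed, anchors_z, anchors_t))
            else:
                a.rank = zmed
            a.rank_source = "zipper"
        else:
            a.rank = None
            a.rank_source = None

    by_bin: dict[str, list[BinAssignment]] = {}
    for a in assignments:
        if a.bin_label is not None:
            by_bin.setdefault(a.bin_label, []).append(a)
    for members in by_bin.values():
        ranked = [a for a in members if a.rank is not None]
        ranked.sort(key=lambda a: (a.rank, min_rank_tiebreak(a, t_ranks), a.contig_id))
        for i, a in enumerate(ranked):
            a.order_index = i
    ordered_ids = [
        a.contig_id
        for members in by_bin.values()
        for a in sorted(
            (m for m in members if m.order_index is not None),
            key=lambda m: m.order_index,
        )
    ]

    report: list[DuplicationEntry] = []
    contig_bin = {a.contig_id: a.bin_label for a in assignments}
    # (a) orthologs matched by >= 2 non-adjacent contigs
    for reference, table in (("tauschii", t_ranks), ("zipper", z_ranks)):
        by_ortholog: dict[int, set[str]] = {}
        for a in assignments:
            for m, _ in a.evidence:
                if m in table:
                    by_ortholog.setdefault(table[m], set()).add(a.contig_id)
        for rank, contigs in sorted(by_ortholog.items()):
            if len(contigs) < 2:
                continue
            same_bin = len({contig_bin.get(c) for c in contigs}) == 1
            pos = sorted(
                ordered_ids.index(c) for c in contigs if c in ordered_ids
            )
            adjacent = (
                same_bin
                and len(pos) == len(contigs)
                and all(b - a2 == 1 for a2, b in zip(pos, pos[1:]))
            )
            if not adjacent:
                report.append(
                    DuplicationEntry(
                        "duplicated_ortholog",
                        f"{reference} ortholog rank {rank}",
                        tuple(sorted(contigs)),
                    )
                )
    # (b) contigs whose ranks split into separated clusters
    for reference, table in (("tauschii", t_ranks), ("zipper", z_ranks)):
        if not table:
            continue
        values = list(table.values())
        span = (max(values) - min(values)) * span_fraction
        for a in assignments:
            ranks = contig_ranks(a, table)
            if len(ranks) < 2:
                continue
            gaps = [b - a2 for a2, b in zip(ranks, ranks[1:])]
            if max(gaps) > span > 0:
                report.append(
                    DuplicationEntry(
                        "split_location",
                        f"{reference} ranks {ranks} split by gap > {span:.1f}",
                        (a.contig_id,),
                    )
                )
    return assignments, report


def min_rank_tiebreak(a: BinAssignment, table: Mapping[str, int]) -> float:
    ranks = [table[m] for m, _ in a.evidence if m in table]
    return min(ranks) if ranks else math.inf


@dataclass
class SuperContig:
    """An ordered chain of contigs joined by end-clone overlaps."""

    supercontig_id: str
    members: list[str]
    connecting_pairs: list[tuple[str, str]]
    member_clone_counts: list[int]

    @property
    def total_clones(self) -> int:
        return sum(self.member_clone_counts)


def elongate_supercontigs(
    layouts: Sequence[ContigLayout],
    net: OverlapNet,
    elongation_cutoff: float = 1e-15,
    end_clones: int = 2,
    insert_mean_kb: float = 143.0,
) -> tuple[list[SuperContig], list[tuple[str, str, str]]]:
    """Chain contigs whose end clones overlap at the elongation cutoff.

    Only clones within ``end_clones`` of a contig end may connect; each
    contig end accepts at most one join, and a join is rejected (and logged)
    if the merged overlap subgraph fails the linearity check.
    """
    by_id = {l.contig_id: l for l in layouts}
    ends: dict[str, set[str]] = {
        cid: set(l.clones[:end_clones]) | set(l.clones[-end_clones:])
        for cid, l in by_id.items()
    }
    clone_contig = {
        c: cid for cid, l in by_id.items() for c in l.clones
    }
    graph = net.graph
    candidates = []
    for u, v, d in graph.edges(data=True):
        if d["p"] > elongation_cutoff:
            continue
        cu, cv = clone_contig.get(u), clone_contig.get(v)
        if cu is None or cv is None or cu == cv:
            continue
        if u in ends[cu] and v in ends[cv]:
            candidates.append((d["p"], cu, cv, u, v))
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))

    joins: dict[str, list[tuple[str, tuple[str, str]]]] = {cid: [] for cid in by_id}
    rejected: list[tuple[str, str, str]] = []
    parent = {cid: cid for cid in by_id}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for p, cu, cv, u, v in candidates:
        if find(cu) == find(cv):
            continue
        if len(joins[cu]) >= 2 or len(joins[cv]) >= 2:
            rejected.append((cu, cv, "contig already joined at both ends"))
            continue
        merged_nodes = [
            c
            for cid in by_id
            if find(cid) in (find(cu), find(cv))
            for c in by_id[cid].clones
        ]
        sub = graph.subgraph(merged_nodes).copy()
        sub.remove_edges_from(
            [(a, b) for a, b, d in sub.edges(data=True) if d["p"] > elongation_cutoff]
        )
        if not nx.is_connected(sub):
            rejected.append((cu, cv, "merged subgraph disconnected at cutoff"))
            continue
        merged_layout = layout_and_check_linearity(sub, insert_mean_kb)
        if not merged_layout.linear:
            rejected.append((cu, cv, "merge would create non-linear topology"))
            continue
        joins[cu].append((cv, (u, v)))
        joins[cv].append((cu, (v, u)))
        parent[find(cu)] = find(cv)

    # walk chains
    seen = set()
    supercontigs = []
    counter = 0
    for cid in sorted(by_id):
        if cid in seen or not joins[cid]:
            continue
        root = find(cid)
        members_set = [c for c in by_id if find(c) == root]
        # start from a chain end (degree 1)
        start = next((c for c in members_set if len(joins[c]) == 1), members_set[0])
        chain = [start]
        pairs = []
        seen.add(start)
        cur = start
        while True:
            nxt = None
            for other, pair in joins[cur]:
                if other not in seen:
                    nxt = (other, pair)
                    break
            if nxt is None:
                break
            chain.append(nxt[0])
            pairs.append(nxt[1])
            seen.add(nxt[0])
            cur = nxt[0]
        counter += 1
        supercontigs.append(
            SuperContig(
                supercontig_id=f"SC{counter}",
                members=chain,
                connecting_pairs=pairs,
                member_clone_counts=[by_id[c].n_clones for c in chain],
            )
        )
    return supercontigs, rejected


# ---------------------------------------------------------------------------
# AGP v2.1 export of the ordered bin map


def write_agp(
    assignments: Sequence[BinAssignment],
    contig_lengths_kb: Mapping[str, float],
    path: str | Path,
    object_name: str = "arm_map",
    gap_size: int = 100,
) -> None:
    """Write the ordered map as AGP v2.1 (contigs as W components, bins
    separated by scaffolding gaps of unknown size)."""
    ordered = [a for a in assignments if a.bin_label is not None]
    ordered.sort(
        key=lambda a: (
            a.bin_label,
            a.order_index if a.order_index is not None else math.inf,
            a.contig_id,
        )
    )
    lines = ["##agp-version\t2.1"]
    for label in sorted({a.bin_label for a in ordered}):
        obj = f"{object_name}:{label}"
        members = [a for a in ordered if a.bin_label == label]
        pos = 0
        part = 0
        for i, a in enumerate(members):
            if i > 0:
                part += 1
                lines.append(
                    f"{obj}\t{pos + 1}\t{pos + gap_size}\t{part}\tU\t{gap_size}"
                    f"\tscaffold\tyes\tmap"
                )
                pos += gap_size
            length = max(1, int(round(contig_lengths_kb.get(a.contig_id, 1.0) * 1000)))
            part += 1
            lines.append(
                f"{obj}\t{pos + 1}\t{pos + length}\t{part}\tW\t{a.contig_id}"
                f"\t1\t{length}\t+"
            )
            pos += length
    Path(path).write_text("\n".join(lines) + "\n")


def read_agp(path: str | Path) -> pd.DataFrame:
    """Read back an AGP file into a component table (W rows only)."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        f = line.split("\t")
        if f[4] != "W":
            continue
        rows.append(
            {
                "object": f[0],
                "bin": f[0].split(":", 1)[1] if ":" in f[0] else "",
                "object_beg": int(f[1]),
                "object_end": int(f[2]),
                "component_id": f[5],
                "component_length": int(f[7]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "object",
            "bin",
            "object_beg",
            "object_end",
            "component_id",
            "component_length",
        ],
    )
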