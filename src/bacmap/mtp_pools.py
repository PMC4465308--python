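"""Minimum tiling path selection, reinforcement, and 3D screening pools."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .assembly import ContigLayout, OverlapNet

__all__ = [
    "MTPSelection",
    "PoolDesign",
    "select_mtp",
    "reinforce_mtp",
    "add_q_clones",
    "mtp_bookkeeping",
    "design_3d_pools",
    "clone_spans",
]

MTP_CATEGORIES = ("base", "reinforcement", "q_clone")


def mtp_bookkeeping(counts: Mapping[str, int]) -> int:
    """Total MTP size from per-category clone counts."""
    unknown = set(counts) - set(MTP_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown MTP categories: {sorted(unknown)}")
    return sum(int(counts.get(c, 0)) for c in MTP_CATEGORIES)


@dataclass
class MTPSelection:
    """Per-contig MTP clone lists plus reinforcement and Q-clone additions."""

    base: dict[str, list[str]] = field(default_factory=dict)  # contig -> ordered clones
    reinforcement: dict[str, list[str]] = field(default_factory=dict)
    q_clones: list[str] = field(default_factory=list)
    gap_junctions: list[tuple[str, str, str]] = field(default_factory=list)

    def category_counts(self) -> dict[str, int]:
        return {
            "base": sum(len(v) for v in self.base.values()),
            "reinforcement": sum(len(v) for v in self.reinforcement.values()),
            "q_clone": len(self.q_clones),
        }

    @property
    def total(self) -> int:
        return mtp_bookkeeping(self.category_counts())

    def all_clones(self) -> list[str]:
        out: list[str] = []
        for contig in self.base:
            out.extend(self.base[contig])
            out.extend(self.reinforcement.get(contig, []))
        out.extend(self.q_clones)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for contig, clones in self.base.items():
            rows += [
                {"contig_id": contig, "clone_id": c, "category": "base"} for c in clones
            ]
        for contig, clones in self.reinforcement.items():
            rows += [
                {"contig_id": contig, "clone_id": c, "category": "reinforcement"}
                for c in clones
            ]
        rows += [
            {"contig_id": "", "clone_id": c, "category": "q_clone"} for c in self.q_clones
        ]
        return pd.DataFrame(rows, columns=["contig_id", "clone_id", "category"])


def clone_spans(
    layout: ContigLayout, insert_mean_kb: float = 143.0
) -> dict[str, tuple[float, float]]:
    """Clone spans implied by layout coordinates and a uniform insert size."""
    return {
        c: (coord, coord + insert_mean_kb) for c, coord in layout.coordinates.items()
    }


def select_mtp(
    layout: ContigLayout,
    net: OverlapNet,
    spans: Mapping[str, tuple[float, float]] | None = None,
    insert_mean_kb: float = 143.0,
) -> list[str]:
    """Greedy end-to-end interval cover of a linear laid-out contig.

    Starting from the leftmost clone, repeatedly pick — among clones whose
    span overlaps the current clone and that share a net edge with it — the
    one extending furthest right.  Clones buried inside another clone's span
    are never selected.
    """
    if spans is None:
        spans = clone_spans(layout, insert_mean_kb)
    clones = list(layout.clones)
    if not clones:
        return []
    graph = net.graph
    for c in clones:
        if c not in graph:
            raise ValueError(f"clone {c} missing from the net")
    buried = set()
    for c in clones:
        s, e = spans[c]
        for d in clones:
            if d == c:
                continue
            s2, e2 = spans[d]
            if s2 <= s and e <= e2 and (s2 < s or e < e2):
                buried.add(c)
                break
    eligible = [c for c in clones if c not in buried]
    if not eligible:
        eligible = clones
    right_target = max(spans[c][1] for c in clones)
    current = min(eligible, key=lambda c: (spans[c][0], -spans[c][1], c))
    mtp = [current]
    while spans[current][1] < right_target:
        _, cur_end = spans[current]
        overlapping = [
            c
            for c in eligible
            if c not in mtp and spans[c][0] < cur_end and spans[c][1] > cur_end
        ]
        candidates = [c for c in overlapping if graph.has_edge(current, c)]
        if not candidates:
            # fall back to coordinate overlap: the junction is weak and will
            # be flagged by the reinforcement pass
            candidates = overlapping
        if not candidates:
            # coverage break inside the contig: resume at the next clone
            rest = [c for c in eligible if c not in mtp and spans[c][0] >= cur_end]
            if not rest:
                break
            current = min(rest, key=lambda c: (spans[c][0], -spans[c][1], c))
        else:
            current = max(candidates, key=lambda c: (spans[c][1], c))
        mtp.append(current)
    return mtp


def reinforce_mtp(
    mtp: Sequence[str],
    layout: ContigLayout,
    net: OverlapNet,
    spans: Mapping[str, tuple[float, float]] | None = None,
    insert_mean_kb: float = 143.0,
    reinforce_cutoff: float = 1e-15,
) -> tuple[list[str], list[tuple[str, str]]]:
    """Reinforce weak MTP junctions with one spanning clone each.

    A junction between consecutive MTP clones is weak when its overlap is
    significant only above ``reinforce_cutoff``.  A reinforcement clone must
    span the junction and overlap both flanks more strongly than the weak
    junction itself; junctions with no such clone are flagged as potential
    sequence-level gaps.
    """
    if spans is None:
        spans = clone_spans(layout, insert_mean_kb)
    graph = net.graph
    reinforcements: list[str] = []
    gaps: list[tuple[str, str]] = []
    in_mtp = set(mtp)
    for a, b in zip(mtp[:-1], mtp[1:]):
        p_weak = graph[a][b]["p"] if graph.has_edge(a, b) else 1.0
        if p_weak <= reinforce_cutoff:
            continue
        ja = min(spans[a][1], spans[b][1])
        jb = max(spans[a][0], spans[b][0])
        lo, hi = min(ja, jb), max(ja, jb)  # junction interval (overlap or gap)
        best = None
        for c in layout.clones:
            if c in in_mtp or c in reinforcements:
                continue
            s, e = spans[c]
            if s > lo or e < hi:
                continue
            pa = graph[a][c]["p"] if graph.has_edge(a, c) else 1.0
            pb = graph[b][c]["p"] if graph.has_edge(b, c) else 1.0
            if pa < p_weak and pb < p_weak:
                key = max(pa, pb)
                if best is None or key < best[0]:
                    best = (key, c)
        if best is None:
            gaps.append((a, b))
        else:
            reinforcements.append(best[1])
    return reinforcements, gaps


def add_q_clones(selection: MTPSelection, q_clones: Iterable[str]) -> MTPSelection:
    """Append Q-clones to the MTP, flagged questionable and excluded from
    coverage guarantees."""
    present = set(selection.all_clones())
    for c in q_clones:
        if c not in present:
            selection.q_clones.append(c)
            present.add(c)
    return selection


@dataclass
class PoolDesign:
    """3D pool layout: each clone at one (plate, row, column) address."""

    addresses: dict[str, tuple[int, int, int]]  # clone -> (plate, row, col)
    n_plates: int
    plate_rows: int = 16
    plate_cols: int = 24

    @property
    def n_pools(self) -> int:
        return self.plate_rows + self.plate_cols + self.n_plates

    def pool_ids(self) -> list[str]:
        return (
            [f"R{r:02d}" for r in range(self.plate_rows)]
            + [f"C{c:02d}" for c in range(self.plate_cols)]
            + [f"P{p:02d}" for p in range(self.n_plates)]
        )

    @staticmethod
    def pool_type(pool_id: str) -> str:
        return {"R": "row", "C": "column", "P": "plate"}[pool_id[0]]

    def pools_of(self, clone_id: str) -> tuple[str, str, str]:
        plate, row, col = self.addresses[clone_id]
        return (f"R{row:02d}", f"C{col:02d}", f"P{plate:02d}")

    def members(self, pool_id: str) -> set[str]:
        kind, num = pool_id[0], int(pool_id[1:])
        axis = {"P": 0, "R": 1, "C": 2}[kind]
        return {c for c, addr in self.addresses.items() if addr[axis] == num}

    def clone_at(self, plate: int, row: int, col: int) -> str | None:
        for clone, addr in self.addresses.items():
            if addr == (plate, row, col):
                return clone
        return None

    def address_table(self) -> dict[tuple[int, int, int], str]:
        return {addr: clone for clone, addr in self.addresses.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"clone_id": c, "plate": p, "row": r, "column": col}
            for c, (p, r, col) in self.addresses.items()
        ]
        return pd.DataFrame(rows, columns=["clone_id", "plate", "row", "column"])


def design_3d_pools(
    clones: Sequence[str],
    plate_rows: int = 16,
    plate_cols: int = 24,
    n_plates: int | None = None,
) -> PoolDesign:
    """Fill plates plate-major, row-major, and derive pool membership."""
    per_plate = plate_rows * plate_cols
    if n_plates is None:
        n_plates = max(1, math.ceil(len(clones) / per_plate))
    if len(clones) > n_plates * per_plate:
        raise ValueError(
            f"{len(clones)} clones exceed {n_plates} plates of {per_plate} wells"
        )
    if len(set(clones)) != len(clones):
        raise ValueError("duplicate clone ids in pool design")
    addresses = {}
    for idx, clone in enumerate(clones):
        plate, rem = divmod(idx, per_plate)
        row, col = divmod(rem, plate_cols)
        addresses[clone] = (plate, row, col)
    return PoolDesign(addresses, n_plates, plate_rows, plate_cols)
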