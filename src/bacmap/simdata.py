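"""Synthetic chromosome arms, BAC libraries, noisy fingerprints and markers.

All generators are pure functions of their seed and parameters.  Coordinates
are in kb, half-open intervals ``[start, end)``, with 0 at the centromere;
deletion-bin fractions are measured from the centromere, so the most distal
bin is 0.78-1.00.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .fingerprint_io import BAND_MAX, BAND_MIN, BandProfile, FingerprintSet

DEFAULT_BIN_BOUNDARIES = (0.63, 0.67, 0.78)

MARKER_CLASSES = ("SSR", "EST", "COS", "SNP", "ISBP", "conserved_gene")

__all__ = [
    "ArmModel",
    "TrueClone",
    "NoiseModel",
    "MarkerTruth",
    "simulate_arm",
    "sample_clone_library",
    "fingerprint_clone",
    "fingerprint_library",
    "plant_markers",
    "true_partition",
    "bin_labels",
    "write_clone_table",
    "read_clone_table",
    "write_marker_table",
    "read_marker_table",
]


def bin_labels(boundaries: Sequence[float] = DEFAULT_BIN_BOUNDARIES) -> list[str]:
    """Standard deletion-bin labels for a set of arm-fraction boundaries."""
    edges = [0.0, *boundaries, 1.0]
    return [f"{lo:g}-{hi:.2f}" for lo, hi in zip(edges[:-1], edges[1:])]


@dataclass
class ArmModel:
    """A linear chromosome arm carrying band-generating restriction fragments.

    ``fragment_positions`` are the fragment boundaries (including 0 and the
    arm end), so fragment *i* spans ``[positions[i], positions[i+1])`` and
    carries ``band_values[i]``.
    """

    arm_length_kb: float
    fragment_positions: np.ndarray
    band_values: np.ndarray
    bin_boundaries: tuple[float, ...] = DEFAULT_BIN_BOUNDARIES

    def __post_init__(self) -> None:
        self.fragment_positions = np.asarray(self.fragment_positions, dtype=float)
        self.band_values = np.asarray(self.band_values, dtype=int)
        if self.arm_length_kb <= 0:
            raise ValueError("arm_length_kb must be positive")
        pos = self.fragment_positions
        if np.any(np.diff(pos) <= 0):
            raise ValueError("fragment positions must be strictly increasing")
        if pos[0] < 0 or pos[-1] > self.arm_length_kb:
            raise ValueError("fragment positions must lie within [0, arm_length_kb]")
        if len(self.band_values) != self.n_fragments:
            raise ValueError("need exactly one band value per fragment")
        if np.any((self.band_values < BAND_MIN) | (self.band_values > BAND_MAX)):
            raise ValueError(f"band values must lie in [{BAND_MIN}, {BAND_MAX}]")
        bb = tuple(self.bin_boundaries)
        if any(not 0.0 < b < 1.0 for b in bb) or any(
            b2 <= b1 for b1, b2 in zip(bb, bb[1:])
        ):
            raise ValueError("bin boundaries must be strictly increasing in (0, 1)")

    @property
    def n_fragments(self) -> int:
        return len(self.fragment_positions) - 1

    @property
    def mean_fragment_kb(self) -> float:
        return self.arm_length_kb / self.n_fragments

    @property
    def bin_edges_kb(self) -> np.ndarray:
        return np.array([0.0, *self.bin_boundaries, 1.0]) * self.arm_length_kb

    @property
    def labels(self) -> list[str]:
        return bin_labels(self.bin_boundaries)

    def bin_of_position(self, position_kb: float) -> str:
        """Deletion-bin label containing an arm position."""
        edges = self.bin_edges_kb
        idx = int(np.searchsorted(edges, position_kb, side="right")) - 1
        idx = min(max(idx, 0), len(self.labels) - 1)
        return self.labels[idx]

    def fragments_within(self, start_kb: float, end_kb: float) -> np.ndarray:
        """Indices of fragments fully inside ``[start_kb, end_kb)``."""
        pos = self.fragment_positions
        lo = int(np.searchsorted(pos, start_kb, side="left"))
        hi = int(np.searchsorted(pos, end_kb, side="right")) - 1
        if hi <= lo:
            return np.empty(0, dtype=int)
        return np.arange(lo, hi)


@dataclass(frozen=True)
class TrueClone:
    """A BAC clone with its true arm interval (absent for contaminants)."""

    clone_id: str
    start_kb: float | None
    end_kb: float | None
    is_contaminant: bool = False

    def __post_init__(self) -> None:
        if self.is_contaminant:
            if self.start_kb is not None or self.end_kb is not None:
                raise ValueError("contaminant clones carry no arm interval")
        else:
            if self.start_kb is None or self.end_kb is None:
                raise ValueError("target clones need an arm interval")
            if self.end_kb - self.start_kb <= 0:
                raise ValueError("clone interval must have positive length")

    @property
    def source(self) -> str:
        return "contaminant" if self.is_contaminant else "target"

    @property
    def length_kb(self) -> float:
        if self.is_contaminant:
            return float("nan")
        return self.end_kb - self.start_kb


@dataclass(frozen=True)
class NoiseModel:
    """Band-level noise: missing bands, spurious bands, and size jitter.

    ``size_jitter`` is the maximum absolute band-size error; each retained
    band is shifted by ``±size_jitter`` with probability ``jitter_rate`` per
    direction.  ``decoy_mean_bands`` sets the expected fingerprint size of
    contaminant clones, whose bands come from an independent random pool.
    """

    band_miss_rate: float = 0.05
    spurious_rate: float = 2.0
    size_jitter: int = 1
    jitter_rate: float = 0.1
    decoy_mean_bands: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.band_miss_rate <= 1.0:
            raise ValueError(f"band_miss_rate out of range: {self.band_miss_rate}")
        if not 0.0 <= self.jitter_rate <= 0.5:
            raise ValueError(f"jitter_rate out of range: {self.jitter_rate}")
        if self.spurious_rate < 0 or self.size_jitter < 0:
            raise ValueError("spurious_rate and size_jitter must be >= 0")

    @property
    def noiseless(self) -> bool:
        return self.band_miss_rate == 0 and self.spurious_rate == 0 and (
            self.size_jitter == 0 or self.jitter_rate == 0
        )


NOISE_FREE = NoiseModel(band_miss_rate=0.0, spurious_rate=0.0, size_jitter=0, jitter_rate=0.0)


@dataclass(frozen=True)
class MarkerTruth:
    """A planted marker with its ground-truth attributes."""

    marker_id: str
    marker_class: str
    position_kb: float
    syntenic: bool
    ortholog_rank: int | None = None
    island_id: str | None = None

    def __post_init__(self) -> None:
        if self.marker_class not in MARKER_CLASSES:
            raise ValueError(f"unknown marker class {self.marker_class!r}")
        if self.ortholog_rank is not None and not self.syntenic:
            raise ValueError("ortholog_rank present only for syntenic markers")


def simulate_arm(
    arm_length_kb: float,
    mean_fragment_kb: float,
    seed: int,
    bin_boundaries: Sequence[float] = DEFAULT_BIN_BOUNDARIES,
) -> ArmModel:
    """Draw a chromosome arm with Poisson-process restriction cuts.

    Interior cut positions follow a homogeneous Poisson process with rate
    ``1 / mean_fragment_kb``; band values are uniform integers on
    ``[50, 500]``.
    """
    if arm_length_kb <= 0:
        raise ValueError("arm_length_kb must be positive")
    if mean_fragment_kb <= 0:
        raise ValueError("mean_fragment_kb must be positive")
    rng = np.random.default_rng(seed)
    n_cuts = rng.poisson(arm_length_kb / mean_fragment_kb)
    cuts = np.sort(rng.uniform(0.0, arm_length_kb, size=n_cuts))
    cuts = np.unique(cuts)  # strict monotonicity
    positions = np.concatenate(([0.0], cuts, [arm_length_kb]))
    bands = rng.integers(BAND_MIN, BAND_MAX + 1, size=len(positions) - 1)
    return ArmModel(
        arm_length_kb=float(arm_length_kb),
        fragment_positions=positions,
        band_values=bands,
        bin_boundaries=tuple(bin_boundaries),
    )


def sample_clone_library(
    arm: ArmModel,
    n_clones: int,
    insert_mean_kb: float = 143.0,
    insert_sd_kb: float = 15.0,
    purity: float = 0.88,
    seed: int = 0,
) -> list[TrueClone]:
    """Sample a BAC library with ``ceil((1 - purity) * n_clones)`` contaminants.

    Target clone starts are uniform on the arm; insert lengths are normal,
    truncated below at one mean fragment length.  Clones running off the
    distal end are truncated at the arm end.
    """
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"purity must be in (0, 1]: {purity}")
    if insert_mean_kb <= 0:
        raise ValueError("insert_mean_kb must be positive")
    rng = np.random.default_rng(seed)
    n_contam = math.ceil((1.0 - purity) * n_clones)
    contam_flags = np.zeros(n_clones, dtype=bool)
    if n_contam:
        contam_flags[rng.choice(n_clones, size=n_contam, replace=False)] = True
    width = len(str(max(n_clones, 1)))
    min_len = arm.mean_fragment_kb
    clones: list[TrueClone] = []
    for i in range(n_clones):
        clone_id = f"CL{i + 1:0{width}d}"
        if contam_flags[i]:
            rng.uniform()  # keep stream aligned regardless of flag
            rng.normal()
            clones.append(TrueClone(clone_id, None, None, is_contaminant=True))
            continue
        start = rng.uniform(0.0, arm.arm_length_kb)
        length = max(rng.normal(insert_mean_kb, insert_sd_kb), min_len)
        end = min(start + length, arm.arm_length_kb)
        if end <= start:
            start = max(0.0, end - min_len)
        clones.append(TrueClone(clone_id, float(start), float(end)))
    return clones


def fingerprint_clone(
    clone: TrueClone,
    arm: ArmModel,
    noise: NoiseModel,
    rng: np.random.Generator | None = None,
) -> BandProfile:
    """Fingerprint one clone: bands of fragments fully inside its interval.

    Each true band is dropped with ``band_miss_rate``, jittered within
    ``±size_jitter`` and clamped to [50, 500]; Poisson(``spurious_rate``)
    spurious bands are added.  Contaminants draw their bands from an
    independent uniform decoy pool.
    """
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    if clone.is_contaminant:
        k = rng.poisson(noise.decoy_mean_bands)
        bands = rng.integers(BAND_MIN, BAND_MAX + 1, size=k)
        return BandProfile(clone.clone_id, tuple(int(b) for b in bands))
    idx = arm.fragments_within(clone.start_kb, clone.end_kb)
    bands = arm.band_values[idx].astype(int)
    if noise.band_miss_rate > 0:
        bands = bands[rng.random(len(bands)) >= noise.band_miss_rate]
    if noise.size_jitter > 0 and noise.jitter_rate > 0 and len(bands):
        p = noise.jitter_rate
        shift = rng.choice(
            np.array([-noise.size_jitter, 0, noise.size_jitter]),
            size=len(bands),
            p=[p, 1.0 - 2.0 * p, p],
        )
        bands = np.clip(bands + shift, BAND_MIN, BAND_MAX)
    n_spurious = rng.poisson(noise.spurious_rate) if noise.spurious_rate > 0 else 0
    if n_spurious:
        spurious = rng.integers(BAND_MIN, BAND_MAX + 1, size=n_spurious)
        bands = np.concatenate([bands, spurious])
    return BandProfile(clone.clone_id, tuple(int(b) for b in bands))


def fingerprint_library(
    clones: Iterable[TrueClone],
    arm: ArmModel,
    noise: NoiseModel,
) -> FingerprintSet:
    """Fingerprint a whole library with a single seeded random stream."""
    rng = np.random.default_rng(noise.seed)
    fset = FingerprintSet(provenance=f"simulated seed={noise.seed}")
    for clone in clones:
        fset.add(fingerprint_clone(clone, arm, noise, rng=rng))
    return fset


def plant_markers(
    arm: ArmModel,
    per_bin_density: Mapping[str, float] | Sequence[float],
    island_fraction: float,
    seed: int,
    island_span_kb: float = 100.0,
    island_size_mean: float = 3.0,
    syntenic_fraction: float = 0.6,
    marker_class: str = "conserved_gene",
) -> list[MarkerTruth]:
    """Plant markers bin by bin at the requested genes/Mb densities.

    ``island_fraction`` of each bin's markers are grouped into islands whose
    members lie within ``island_span_kb`` of an island anchor; the rest are
    isolated.  Syntenic markers receive ortholog ranks in positional order.
    """
    labels = arm.labels
    if not isinstance(per_bin_density, Mapping):
        if len(per_bin_density) != len(labels):
            raise ValueError(f"need one density per bin ({len(labels)})")
        per_bin_density = dict(zip(labels, per_bin_density))
    for label, dens in per_bin_density.items():
        if dens < 0:
            raise ValueError(f"negative density for bin {label}: {dens}")
    if not 0.0 <= island_fraction <= 1.0:
        raise ValueError("island_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    edges = arm.bin_edges_kb
    entries: list[tuple[float, bool, str | None]] = []  # (pos, syntenic, island)
    island_counter = 0
    for b, label in enumerate(labels):
        lo, hi = edges[b], edges[b + 1]
        bin_mb = (hi - lo) / 1000.0
        count = int(round(per_bin_density.get(label, 0.0) * bin_mb))
        n_island = int(round(island_fraction * count))
        n_isolated = count - n_island
        placed = 0
        while placed < n_island:
            size = max(2, int(rng.poisson(island_size_mean)))
            size = min(size, n_island - placed)
            if size < 2:  # fold a trailing singleton into the last island
                size = n_island - placed
            island_counter += 1
            island_id = f"ISL{island_counter:04d}"
            anchor = rng.uniform(lo, max(lo, hi - island_span_kb))
            for _ in range(size):
                pos = min(anchor + rng.uniform(0.0, island_span_kb), hi - 1e-9)
                entries.append((pos, bool(rng.random() < syntenic_fraction), island_id))
            placed += size
        for _ in range(n_isolated):
            pos = rng.uniform(lo, hi)
            entries.append((pos, bool(rng.random() < syntenic_fraction), None))
    entries.sort(key=lambda e: e[0])
    markers: list[MarkerTruth] = []
    rank = 0
    width = len(str(max(len(entries), 1)))
    for i, (pos, syntenic, island_id) in enumerate(entries):
        ortholog_rank = None
        if syntenic:
            ortholog_rank = rank
            rank += 1
        markers.append(
            MarkerTruth(
                marker_id=f"MK{i + 1:0{width}d}",
                marker_class=marker_class,
                position_kb=float(pos),
                syntenic=syntenic,
                ortholog_rank=ortholog_rank,
                island_id=island_id,
            )
        )
    return markers


def recoverable_partition(
    clones: Iterable[TrueClone],
    arm: ArmModel,
    cutoff: float = 1e-15,
    tolerance: int = 1,
    gellen: int = 451,
    min_band_count: int = 5,
    retention: float = 1.0,
) -> dict[str, int]:
    """Ground-truth clone partition recoverable from true band content.

    Two clones are linked when their *noise-free* band profiles share enough
    bands to be Sulston-significant at ``cutoff``; the partition is the set
    of connected components.  The computation is an independent route: band
    matching by maximum bipartite matching (networkx) over physically
    overlapping pairs only, and the binomial tail from scipy.  Contaminants
    and clones whose true profiles fall below ``min_band_count`` are
    excluded, mirroring the fingerprint quality filter.

    ``retention`` scales the true shared count before the significance test
    to the expected fraction of band matches surviving a noise model
    (``expected_retention``), giving the partition an ideal assembler could
    recover from fingerprints carrying that noise.
    """
    import networkx as nx
    from scipy import stats as _stats

    targets = []
    for c in clones:
        if c.is_contaminant:
            continue
        idx = arm.fragments_within(c.start_kb, c.end_kb)
        bands = sorted(int(b) for b in arm.band_values[idx])
        if len(bands) < min_band_count:
            continue
        targets.append((c, bands))
    targets.sort(key=lambda t: (t[0].start_kb, t[0].end_kb))

    def match_size(xs: list[int], ys: list[int]) -> int:
        g = nx.Graph()
        a_nodes = [("a", i) for i in range(len(xs))]
        b_nodes = [("b", j) for j in range(len(ys))]
        g.add_nodes_from(a_nodes, bipartite=0)
        g.add_nodes_from(b_nodes, bipartite=1)
        for i, x in enumerate(xs):
            for j, y in enumerate(ys):
                if abs(x - y) <= tolerance:
                    g.add_edge(("a", i), ("b", j))
        matching = nx.bipartite.maximum_matching(g, top_nodes=a_nodes)
        return len(matching) // 2

    def significant(xs: list[int], ys: list[int]) -> bool:
        n_low, n_high = sorted((len(xs), len(ys)))
        if n_low == 0:
            return False
        shared = min(int(round(retention * match_size(xs, ys))), n_low)
        if shared == 0:
            return False
        x = 1.0 - (1.0 - 2.0 * tolerance / gellen) ** n_high
        return bool(_stats.binom.sf(shared - 1, n_low, x) <= cutoff)

    graph = nx.Graph()
    graph.add_nodes_from(c.clone_id for c, _ in targets)
    for i, (ci, bi) in enumerate(targets):
        for j in range(i + 1, len(targets)):
            cj, bj = targets[j]
            if cj.start_kb >= ci.end_kb:
                break
            if significant(bi, bj):
                graph.add_edge(ci.clone_id, cj.clone_id)
    labels: dict[str, int] = {}
    for k, comp in enumerate(nx.connected_components(graph)):
        for cid in comp:
            labels[cid] = k
    return labels


def expected_retention(noise: NoiseModel, tolerance: int = 1) -> float:
    """Expected fraction of true band matches that survive the noise model.

    Both copies of a shared band must escape the miss rate, and their
    independent jitters must not separate them beyond the matching
    tolerance.
    """
    keep = (1.0 - noise.band_miss_rate) ** 2
    if noise.size_jitter > 0 and noise.jitter_rate > 0:
        # jitters differ by 2 * size_jitter with probability 2 * rate^2
        if 2 * noise.size_jitter > tolerance:
            keep *= 1.0 - 2.0 * noise.jitter_rate**2
    return keep


def true_partition(
    clones: Iterable[TrueClone],
    min_overlap_kb: float,
) -> dict[str, int]:
    """Ground-truth clone partition: islands of clones chained by overlaps
    of at least ``min_overlap_kb`` (clones shorter than that connect by
    containment).  Contaminants are excluded.
    """
    targets = sorted(
        (c for c in clones if not c.is_contaminant), key=lambda c: (c.start_kb, c.end_kb)
    )
    labels: dict[str, int] = {}
    group = -1
    reach = -math.inf
    for clone in targets:
        need = min(min_overlap_kb, clone.length_kb)
        if clone.start_kb + need <= reach:
            labels[clone.clone_id] = group
        else:
            group += 1
            labels[clone.clone_id] = group
        reach = max(reach, clone.end_kb)
    return labels


# ---------------------------------------------------------------------------
# truth-table round trips


def write_clone_table(clones: Iterable[TrueClone], path: str | Path) -> None:
    rows = [
        {
            "clone_id": c.clone_id,
            "start_kb": "" if c.start_kb is None else repr(float(c.start_kb)),
            "end_kb": "" if c.end_kb is None else repr(float(c.end_kb)),
            "is_contaminant": int(c.is_contaminant),
        }
        for c in clones
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_clone_table(path: str | Path) -> list[TrueClone]:
    df = pd.read_csv(path, sep="\t", dtype={"clone_id": str}, float_precision="round_trip")
    clones = []
    for row in df.itertuples(index=False):
        contam = bool(row.is_contaminant)
        clones.append(
            TrueClone(
                clone_id=row.clone_id,
                start_kb=None if contam else float(row.start_kb),
                end_kb=None if contam else float(row.end_kb),
                is_contaminant=contam,
            )
        )
    return clones


def write_marker_table(markers: Iterable[MarkerTruth], path: str | Path) -> None:
    rows = [
        {
            "marker_id": m.marker_id,
            "class": m.marker_class,
            "position_kb": repr(float(m.position_kb)),
            "syntenic": int(m.syntenic),
            "ortholog_rank": "" if m.ortholog_rank is None else m.ortholog_rank,
            "island_id": "" if m.island_id is None else m.island_id,
        }
        for m in markers
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_marker_table(path: str | Path) -> list[MarkerTruth]:
    df = pd.read_csv(
        path, sep="\t", dtype={"marker_id": str, "island_id": str},
        float_precision="round_trip",
    )
    markers = []
    for _, row in df.iterrows():
        rank = row["ortholog_rank"]
        rank = None if pd.isna(rank) else int(rank)
        island = row["island_id"]
        island = None if pd.isna(island) else str(island)
        markers.append(
            MarkerTruth(
                marker_id=row["marker_id"],
                marker_class=row["class"],
                position_kb=float(row["position_kb"]),
                syntenic=bool(row["syntenic"]),
                ortholog_rank=rank,
                island_id=island,
            )
        )
    return markers
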