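"""Sulston-score overlap nets and linearity-driven adaptive clustering.

The assembly proceeds in three stages: build an overlap net at a permissive
significance cutoff, strip questionable clones and overlaps, then cluster
adaptively — components that fail the linear-topology check are re-clustered
at increasingly stringent cutoffs, and persistent branching clones are
excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .fingerprint_io import BandProfile, FingerprintSet

__all__ = [
    "AssemblyConfig",
    "OverlapNet",
    "ContigLayout",
    "QReport",
    "Assembly",
    "shared_band_count",
    "sulston_score",
    "min_significant_shared",
    "build_net",
    "remove_q_elements",
    "layout_and_check_linearity",
    "adaptive_cluster",
    "contig_stats",
    "cutoff_schedule",
]


@dataclass(frozen=True)
class AssemblyConfig:
    """Cutoffs and band-matching parameters driving the assembly."""

    net_cutoff: float = 1e-15
    q_clone_cutoff: float = 1e-15
    q_overlap_cutoff: float = 1e-25
    final_cutoff: float = 1e-33
    n_steps: int = 6
    min_contig_clones: int = 6
    tolerance: int = 1
    gellen: int = 451
    insert_mean_kb: float = 143.0

    def __post_init__(self) -> None:
        if self.final_cutoff > self.net_cutoff:
            raise ValueError("final_cutoff must be <= net_cutoff")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.tolerance < 0 or self.gellen <= 0:
            raise ValueError("tolerance >= 0 and gellen > 0 required")


def cutoff_schedule(cfg: AssemblyConfig) -> list[float]:
    """Cutoffs geometric in exponent from net_cutoff to final_cutoff."""
    exponents = np.linspace(
        math.log10(cfg.net_cutoff), math.log10(cfg.final_cutoff), cfg.n_steps + 1
    )
    return [10.0**e for e in exponents]


def shared_band_count(a: BandProfile, b: BandProfile, tolerance: int = 1) -> int:
    """Size of a maximal one-to-one matching of bands within ``tolerance``.

    Greedy two-pointer sweep on the sorted band lists; for points on a line
    this attains the maximum matching.  Symmetric in its arguments.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    xs, ys = a.bands, b.bands
    i = j = shared = 0
    while i < len(xs) and j < len(ys):
        d = xs[i] - ys[j]
        if abs(d) <= tolerance:
            shared += 1
            i += 1
            j += 1
        elif d < 0:
            i += 1
        else:
            j += 1
    return shared


def sulston_score(
    n_low: int, n_high: int, shared: int, tolerance: int = 1, gellen: int = 451
) -> float:
    """Probability of sharing at least ``shared`` bands by chance.

    With ``x = 1 - (1 - 2*tolerance/gellen)**n_high``, returns the upper
    binomial tail ``sum_{j=shared}^{n_low} C(n_low, j) x^j (1-x)^(n_low-j)``,
    evaluated in log space.
    """
    if n_low > n_high:
        raise ValueError("n_low must be <= n_high")
    if not 0 <= shared <= n_low:
        raise ValueError(f"shared must lie in [0, n_low]: {shared}")
    if shared == 0:
        return 1.0
    x = 1.0 - (1.0 - 2.0 * tolerance / gellen) ** n_high
    if x <= 0.0:
        return 0.0
    if x >= 1.0:
        return 1.0
    j = np.arange(shared, n_low + 1)
    log_terms = (
        gammaln(n_low + 1)
        - gammaln(j + 1)
        - gammaln(n_low - j + 1)
        + j * math.log(x)
        + (n_low - j) * math.log1p(-x)
    )
    return float(min(1.0, math.exp(logsumexp(log_terms))))


def min_significant_shared(
    n_low: int, n_high: int, cutoff: float, tolerance: int, gellen: int
) -> int | None:
    """Smallest shared-band count significant at ``cutoff``, or None."""
    lo, hi = 1, n_low
    if sulston_score(n_low, n_high, n_low, tolerance, gellen) > cutoff:
        return None
    while lo < hi:
        mid = (lo + hi) // 2
        if sulston_score(n_low, n_high, mid, tolerance, gellen) <= cutoff:
            hi = mid
        else:
            lo = mid + 1
    return lo


@dataclass
class OverlapNet:
    """Undirected net of significant clone overlaps.

    Edges carry ``shared`` (band count) and ``p`` (Sulston probability);
    nodes carry ``n_bands``.
    """

    graph: nx.Graph
    cutoff: float

    @property
    def n_clones(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def subnet(self, cutoff: float) -> nx.Graph:
        """View of the graph restricted to edges with p <= cutoff."""
        return nx.subgraph_view(
            self.graph, filter_edge=lambda u, v: self.graph[u][v]["p"] <= cutoff
        )

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {"clone_a": u, "clone_b": v, "shared": d["shared"], "p": d["p"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["clone_a", "clone_b", "shared", "p"])

    def copy(self) -> "OverlapNet":
        return OverlapNet(self.graph.copy(), self.cutoff)


def _global_min_shared(max_bands: int, cutoff: float, tolerance: int, gellen: int) -> int:
    """Conservative lower bound on the shared count of any significant pair."""
    for m in range(1, max_bands + 1):
        x = 1.0 - (1.0 - 2.0 * tolerance / gellen) ** m
        if x <= 0:
            continue
        if m * math.log(x) <= math.log(cutoff):
            return m
    return max_bands


def build_net(fset: FingerprintSet, cfg: AssemblyConfig) -> OverlapNet:
    """Build the overlap net: an edge per pair significant at ``net_cutoff``.

    Pairs are pre-screened with a vectorized band-histogram product (an upper
    bound on the one-to-one matching size) before the exact greedy matching
    and Sulston evaluation, so the all-pairs scan stays tractable.
    """
    from .fingerprint_io import BAND_MAX, BAND_MIN

    profiles = list(fset)
    n = len(profiles)
    graph = nx.Graph()
    for p in profiles:
        graph.add_node(p.clone_id, n_bands=p.n_bands)
    if n < 2:
        return OverlapNet(graph, cfg.net_cutoff)
    max_bands = max(p.n_bands for p in profiles)
    min_shared = _global_min_shared(max_bands, cfg.net_cutoff, cfg.tolerance, cfg.gellen)
    tol = cfg.tolerance
    n_values = BAND_MAX - BAND_MIN + 1
    hist = np.zeros((n, n_values), dtype=np.float32)
    for i, p in enumerate(profiles):
        for v in p.bands:
            hist[i, v - BAND_MIN] += 1.0
    # smear one side by the tolerance window: sum_v smear_a(v) * hist_b(v)
    # upper-bounds the matching size
    smear = hist.copy()
    for d in range(1, tol + 1):
        smear[:, d:] += hist[:, :-d]
        smear[:, :-d] += hist[:, d:]
    upper = smear @ hist.T
    cand_i, cand_j = np.nonzero(upper >= min_shared)
    score_cache: dict[tuple[int, int, int], float] = {}
    for i, j in zip(cand_i.tolist(), cand_j.tolist()):
        if j <= i:
            continue
        p, q = profiles[i], profiles[j]
        shared = shared_band_count(p, q, tol)
        if shared < min_shared:
            continue
        n_low, n_high = sorted((p.n_bands, q.n_bands))
        if n_low == 0:
            continue
        shared = min(shared, n_low)
        key = (n_low, n_high, shared)
        score = score_cache.get(key)
        if score is None:
            score = sulston_score(n_low, n_high, shared, tol, cfg.gellen)
            score_cache[key] = score
        if score <= cfg.net_cutoff:
            graph.add_edge(p.clone_id, q.clone_id, shared=shared, p=score)
    return OverlapNet(graph, cfg.net_cutoff)


@dataclass
class QReport:
    """Questionable elements removed from the net."""

    q_clones: list[str] = field(default_factory=list)
    q_overlaps: list[tuple[str, str]] = field(default_factory=list)


def matched_band_indices(
    a: BandProfile, b: BandProfile, tolerance: int = 1
) -> tuple[int, ...]:
    """Indices into ``a.bands`` matched by the greedy one-to-one matching."""
    xs, ys = a.bands, b.bands
    i = j = 0
    out = []
    while i < len(xs) and j < len(ys):
        d = xs[i] - ys[j]
        if abs(d) <= tolerance:
            out.append(i)
            i += 1
            j += 1
        elif d < 0:
            i += 1
        else:
            j += 1
    return tuple(out)


def remove_q_elements(
    net: OverlapNet,
    cfg: AssemblyConfig,
    fset: FingerprintSet | None = None,
    min_branch_side: int = 2,
    max_side_overlap: float = 0.5,
) -> tuple[OverlapNet, QReport]:
    """Remove questionable overlaps and clones from the net.

    A Q-overlap is an edge weaker than ``q_overlap_cutoff`` whose removal is
    supported — a corroborating path of length <= 2 through edges stronger
    than itself keeps its endpoints connected, so the weak direct edge is
    dropped.  A Q-clone bridges otherwise-separate clusters: its
    neighborhood (at ``q_clone_cutoff``) splits into >= 2 connected
    components of ``min_branch_side`` or more clones, and (when fingerprints
    are supplied) the clone's matched bands against the separate sides are
    largely disjoint — the signature of a chimera, as opposed to a genuine
    bridge across a thin spot, whose matches reuse the same bands.
    """
    graph = net.graph.copy()
    report = QReport()

    for u, v, d in list(graph.edges(data=True)):
        if d["p"] <= cfg.q_overlap_cutoff:
            continue
        p_edge = d["p"]
        corroborated = any(
            graph[u][w]["p"] < p_edge and graph[v][w]["p"] < p_edge
            for w in set(graph[u]) & set(graph[v])
        )
        if corroborated:
            report.q_overlaps.append((u, v))

    # Q-clones are detected on the un-pruned net: a chimera's side overlaps
    # are often weak and redundant, exactly what the overlap pruning eats
    qnet = nx.subgraph_view(
        net.graph, filter_edge=lambda u, v: net.graph[u][v]["p"] <= cfg.q_clone_cutoff
    )
    for node in list(graph.nodes):
        nbrs = list(qnet[node]) if node in qnet else []
        if len(nbrs) < 2:
            continue
        comps = [
            sorted(comp) for comp in nx.connected_components(qnet.subgraph(nbrs))
        ]
        big = [c for c in comps if len(c) >= min_branch_side]
        if len(big) < 2:
            continue
        if fset is None or node not in fset:
            report.q_clones.append(node)
            continue
        profile = fset[node]
        side_bands = []
        for comp in big:
            used: set[int] = set()
            for other in comp:
                if other in fset:
                    used.update(
                        matched_band_indices(profile, fset[other], cfg.tolerance)
                    )
            side_bands.append(
                BandProfile(node, tuple(profile.bands[i] for i in sorted(used)))
            )
        chimeric = False
        for i in range(len(side_bands)):
            for j in range(i + 1, len(side_bands)):
                a_, b_ = side_bands[i], side_bands[j]
                denom = min(a_.n_bands, b_.n_bands)
                if denom == 0:
                    continue
                common = shared_band_count(a_, b_, cfg.tolerance)
                if common / denom < max_side_overlap:
                    chimeric = True
        if chimeric:
            report.q_clones.append(node)
    graph.remove_edges_from(report.q_overlaps)
    graph.remove_nodes_from(report.q_clones)
    return OverlapNet(graph, net.cutoff), report


@dataclass
class ContigLayout:
    """An ordered clone layout with coordinates and a linearity verdict."""

    contig_id: str
    clones: list[str]
    coordinates: dict[str, float]
    length_kb: float
    depth: float
    linear: bool
    branching_clones: list[str] = field(default_factory=list)
    cutoff: float = float("nan")

    @property
    def n_clones(self) -> int:
        return len(self.clones)

    @property
    def span(self) -> tuple[float, float]:
        coords = self.coordinates
        return min(coords.values()), max(coords.values())


def _edge_gap(data: dict, na: int, nb: int) -> float:
    """Fractional positional gap implied by an overlap edge."""
    denom = min(na, nb)
    if denom <= 0:
        return 1.0
    return max(0.0, 1.0 - data["shared"] / denom)


def _farthest(graph: nx.Graph, source: str) -> tuple[str, dict[str, float]]:
    nb = nx.get_node_attributes(graph, "n_bands")

    def weight(u, v, d):
        return _edge_gap(d, nb.get(u, 0), nb.get(v, 0)) + 1e-3

    dist = nx.single_source_dijkstra_path_length(graph, source, weight=weight)
    far = max(dist, key=lambda k: (dist[k], k))
    return far, dist


def _find_branching(
    graph: nx.Graph,
    fset: FingerprintSet | None = None,
    tolerance: int = 1,
    buried_fraction: float = 0.7,
) -> list[str]:
    """Branching clones: articulation points where >= 3 chains meet.

    Removing the clone must leave three or more pieces that are not merely
    buried in it — a piece is discounted when every member shares at least
    ``buried_fraction`` of its own bands with the focal clone (a buried or
    near-duplicate clone hanging off a spanning one is a linear feature).
    The buried test consults the fingerprints directly when available, since
    a buried clone's edge to the spanning clone may sit above an edge
    cutoff.  A linear contig tolerates interior cut clones (two sides), but
    never a genuine three-way junction.
    """
    if graph.number_of_nodes() < 4:
        return []
    nb = nx.get_node_attributes(graph, "n_bands")

    def shared_with(node: str, x: str) -> int:
        if graph.has_edge(node, x):
            return graph[node][x]["shared"]
        if fset is not None and node in fset and x in fset:
            return shared_band_count(fset[node], fset[x], tolerance)
        return 0

    branching = []
    for node in nx.articulation_points(graph):
        rest = graph.subgraph(n for n in graph.nodes if n != node)
        pieces = 0
        for comp in nx.connected_components(rest):
            buried = all(
                nb.get(x, 0) > 0
                and shared_with(node, x) >= buried_fraction * nb[x]
                for x in comp
            )
            if not buried:
                pieces += 1
        if pieces >= 3:
            branching.append(node)
    return sorted(branching)


def layout_and_check_linearity(
    component: nx.Graph,
    insert_mean_kb: float = 143.0,
    contig_id: str = "CTG",
    cutoff: float = float("nan"),
    fset: FingerprintSet | None = None,
    tolerance: int = 1,
) -> ContigLayout:
    """Seriate a connected component into a left-to-right clone layout.

    Provisional ends come from a double Dijkstra sweep under gap weights
    (1 - shared/min(n_bands)); clones are ordered by weighted distance from
    one end and each is offset from its best-overlapping predecessor by
    ``insert * (1 - shared/min(n_bands))``.  The component is linear iff no
    clone has three neighbors that are pairwise non-overlapping.
    """
    nodes = sorted(component.nodes)
    if len(nodes) == 1:
        cid = nodes[0]
        return ContigLayout(
            contig_id, [cid], {cid: 0.0}, insert_mean_kb, 1.0, True, [], cutoff
        )
    end_a, _ = _farthest(component, nodes[0])
    end_b, dist = _farthest(component, end_a)
    order = sorted(nodes, key=lambda c: (dist.get(c, math.inf), c))
    nb = nx.get_node_attributes(component, "n_bands")
    coords: dict[str, float] = {order[0]: 0.0}
    for c in order[1:]:
        best = None
        for p in component[c]:
            if p in coords:
                gap = _edge_gap(component[c][p], nb.get(c, 0), nb.get(p, 0))
                pos = coords[p] + insert_mean_kb * gap
                if best is None or pos < best:
                    best = pos
        if best is None:  # ordering outran connectivity; stack after previous
            prev = max(coords.values())
            best = prev + insert_mean_kb
        coords[c] = best
    order = sorted(order, key=lambda c: (coords[c], c))
    branching = _find_branching(component, fset, tolerance)
    left = min(coords.values())
    right = max(coords.values())
    length = right + insert_mean_kb - left
    depth = len(nodes) * insert_mean_kb / length
    return ContigLayout(
        contig_id,
        order,
        coords,
        length,
        depth,
        not branching,
        branching,
        cutoff,
    )


def contig_stats(layout: ContigLayout, insert_mean_kb: float = 143.0) -> tuple[float, float]:
    """(length_kb, depth) of a laid-out contig."""
    left, right = layout.span
    length = right + insert_mean_kb - left
    depth = layout.n_clones * insert_mean_kb / length
    return length, depth


@dataclass
class Assembly:
    """Adaptive-clustering result: laid-out contigs plus excluded clones."""

    contigs: list[ContigLayout]
    excluded_clones: list[str]
    config: AssemblyConfig

    @property
    def main_contigs(self) -> list[ContigLayout]:
        return [c for c in self.contigs if c.n_clones >= self.config.min_contig_clones]

    @property
    def short_contigs(self) -> list[ContigLayout]:
        return [c for c in self.contigs if 1 < c.n_clones < self.config.min_contig_clones]

    @property
    def singletons(self) -> list[ContigLayout]:
        return [c for c in self.contigs if c.n_clones == 1]

    def layout_of(self, clone_id: str) -> ContigLayout | None:
        for c in self.contigs:
            if clone_id in c.coordinates:
                return c
        return None

    def partition(self, include_singletons: bool = True) -> dict[str, str]:
        out = {}
        for c in self.contigs:
            if not include_singletons and c.n_clones == 1:
                continue
            for clone in c.clones:
                out[clone] = c.contig_id
        return out

    def contig_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.contigs:
            for i, clone in enumerate(c.clones):
                rows.append(
                    {
                        "contig_id": c.contig_id,
                        "clone_id": clone,
                        "order_index": i,
                        "coordinate_kb": round(c.coordinates[clone], 3),
                    }
                )
        return pd.DataFrame(
            rows, columns=["contig_id", "clone_id", "order_index", "coordinate_kb"]
        )


def adaptive_cluster(
    net: OverlapNet, cfg: AssemblyConfig, fset: FingerprintSet | None = None
) -> Assembly:
    """Cluster the Q-filtered net into linear contigs.

    Connected components at the current cutoff become candidate contigs;
    non-linear components are re-clustered at the next, more stringent,
    cutoff on a geometric schedule.  Components still non-linear at the
    final cutoff have their branching clones excluded and are re-checked.
    """
    cutoffs = cutoff_schedule(cfg)
    final_layouts: list[ContigLayout] = []
    excluded: list[str] = []

    def components_at(graph: nx.Graph, cutoff: float) -> list[nx.Graph]:
        sub = nx.subgraph_view(
            graph, filter_edge=lambda u, v: graph[u][v]["p"] <= cutoff
        )
        return [graph.subgraph(c).copy() for c in nx.connected_components(sub)]

    def prune(graph: nx.Graph, cutoff: float) -> nx.Graph:
        g = graph.copy()
        g.remove_edges_from(
            [(u, v) for u, v, d in g.edges(data=True) if d["p"] > cutoff]
        )
        return g

    stack: list[tuple[nx.Graph, int]] = [
        (comp, 0) for comp in components_at(net.graph, cutoffs[0])
    ]
    while stack:
        comp, step = stack.pop()
        layout = layout_and_check_linearity(
            prune(comp, cutoffs[step]),
            cfg.insert_mean_kb,
            cutoff=cutoffs[step],
            fset=fset,
            tolerance=cfg.tolerance,
        )
        if layout.linear:
            final_layouts.append(layout)
            continue
        if step < len(cutoffs) - 1:
            for sub in components_at(comp, cutoffs[step + 1]):
                stack.append((sub, step + 1))
            continue
        # final cutoff: exclude the branching clones and re-check
        excluded.extend(layout.branching_clones)
        comp = comp.copy()
        comp.remove_nodes_from(layout.branching_clones)
        for sub in components_at(comp, cutoffs[step]):
            stack.append((sub, step))
    final_layouts.sort(key=lambda c: (-c.n_clones, c.clones[0]))
    width = len(str(max(len(final_layouts), 1)))
    for i, layout in enumerate(final_layouts):
        layout.contig_id = f"CTG{i + 1:0{width}d}"
    return Assembly(final_layouts, excluded, cfg)
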