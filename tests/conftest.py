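"""Shared fixtures: small simulated libraries and synthetic graph builders."""

from __future__ import annotations

import networkx as nx
import pytest

from bacmap import simdata as sd
from bacmap.assembly import (
    AssemblyConfig,
    ContigLayout,
    OverlapNet,
    adaptive_cluster,
    build_net,
    remove_q_elements,
)
from bacmap.fingerprint_io import BandProfile, FingerprintSet, filter_bands


@pytest.fixture(scope="session")
def small_arm() -> sd.ArmModel:
    return sd.simulate_arm(900.0, 2.5, seed=7)


@pytest.fixture(scope="session")
def dense_library(small_arm):
    """60 noise-free clones on a short arm: one dominant contig."""
    clones = sd.sample_clone_library(small_arm, 60, 143, 15, purity=1.0, seed=8)
    fset = sd.fingerprint_library(clones, small_arm, sd.NOISE_FREE)
    fset, _ = filter_bands(fset)
    return clones, fset


@pytest.fixture(scope="session")
def dense_assembly(small_arm, dense_library):
    clones, fset = dense_library
    cfg = AssemblyConfig()
    net = build_net(fset, cfg)
    qnet, qreport = remove_q_elements(net, cfg, fset)
    assembly = adaptive_cluster(qnet, cfg, fset)
    return {
        "clones": clones,
        "fset": fset,
        "cfg": cfg,
        "net": net,
        "qnet": qnet,
        "qreport": qreport,
        "assembly": assembly,
    }


def make_profile(clone_id: str, bands) -> BandProfile:
    return BandProfile(clone_id, tuple(int(b) for b in bands))


def make_fset(profiles) -> FingerprintSet:
    return FingerprintSet.from_profiles(profiles)


def net_from_spans(spans: dict[str, tuple[float, float]], n_bands: int = 30) -> OverlapNet:
    """Overlap net with an edge for every physically overlapping span pair."""
    graph = nx.Graph()
    for cid in spans:
        graph.add_node(cid, n_bands=n_bands)
    ids = list(spans)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            s1, e1 = spans[a]
            s2, e2 = spans[b]
            ov = min(e1, e2) - max(s1, s2)
            if ov > 0:
                span = max(e1, e2) - min(s1, s2)
                shared = max(1, int(round(n_bands * ov / span)))
                graph.add_edge(a, b, shared=shared, p=10.0 ** (-16 - shared))
    return OverlapNet(graph, 1e-15)


def layout_from_spans(spans: dict[str, tuple[float, float]], contig_id="CTG1") -> ContigLayout:
    order = sorted(spans, key=lambda c: spans[c])
    coords = {c: spans[c][0] for c in order}
    left = min(s for s, _ in spans.values())
    right = max(e for _, e in spans.values())
    return ContigLayout(
        contig_id=contig_id,
        clones=order,
        coordinates=coords,
        length_kb=right - left,
        depth=1.0,
        linear=True,
    )


def true_profile(arm: sd.ArmModel, start: float, end: float, clone_id="X") -> BandProfile:
    idx = arm.fragments_within(start, end)
    return BandProfile(clone_id, tuple(int(b) for b in arm.band_values[idx]))
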