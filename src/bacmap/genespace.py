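"""Gene-space statistics: island classification, per-bin gene tables, and
density-gradient correlations."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .assembly import OverlapNet
from .deconvolution import ProbeAssignment

__all__ = [
    "classify_island_genes",
    "bin_density",
    "tabulate_bin_gene_stats",
    "pearson_with_p",
    "correlation_report",
]


def classify_island_genes(
    assignments: Iterable[ProbeAssignment],
    net: OverlapNet | None = None,
    contig_of: Mapping[str, str] | None = None,
) -> tuple[dict[str, str], list[str]]:
    """Label each assigned gene "island" or "isolated".

    Two genes are linked when they share a clone or sit on overlapping
    clones (a net edge); graph components of size >= 2 are islands.
    Unassigned genes are excluded and returned separately.
    """
    graph = nx.Graph()
    clone_genes: dict[str, list[str]] = {}
    excluded: list[str] = []
    gene_clones: dict[str, tuple[str, ...]] = {}
    for a in assignments:
        if a.status != "assigned" or not a.clones:
            excluded.append(a.marker_id)
            continue
        graph.add_node(a.marker_id)
        gene_clones[a.marker_id] = a.clones
        for c in a.clones:
            clone_genes.setdefault(c, []).append(a.marker_id)
    for genes in clone_genes.values():
        for g1, g2 in zip(genes[:-1], genes[1:]):
            graph.add_edge(g1, g2)
    if net is not None:
        overlap = net.graph
        genes = list(gene_clones)
        clone_list = list(clone_genes)
        for i, c1 in enumerate(clone_list):
            if c1 not in overlap:
                continue
            for c2 in overlap[c1]:
                if c2 in clone_genes:
                    for g1 in clone_genes[c1]:
                        for g2 in clone_genes[c2]:
                            if g1 != g2:
                                graph.add_edge(g1, g2)
    labels = {}
    for comp in nx.connected_components(graph):
        kind = "island" if len(comp) >= 2 else "isolated"
        for g in comp:
            labels[g] = kind
    return labels, excluded


def bin_density(count: int, length_mb: float, decimals: int = 2) -> float:
    """Genes per Mb, rounded for presentation."""
    if length_mb <= 0:
        raise ValueError("bin length must be positive for a density")
    return round(count / length_mb, decimals)


def tabulate_bin_gene_stats(
    island_labels: Mapping[str, str],
    gene_bins: Mapping[str, str],
    syntenic: Mapping[str, bool],
    bin_lengths_mb: Mapping[str, float],
) -> pd.DataFrame:
    """Per-bin gene counts and densities, split by synteny and island status.

    Row identities (syntenic + non-syntenic = total; islands + isolated =
    total) hold by construction; densities are count / cumulative mapped Mb,
    rounded to 2 decimals, with raw values in ``*_density_raw`` columns.
    """
    rows = []
    for label in bin_lengths_mb:
        genes = [g for g, b in gene_bins.items() if b == label and g in island_labels]
        n_total = len(genes)
        n_syn = sum(1 for g in genes if syntenic.get(g, False))
        n_island = sum(1 for g in genes if island_labels[g] == "island")
        length = bin_lengths_mb[label]
        row = {
            "bin": label,
            "syntenic": n_syn,
            "non_syntenic": n_total - n_syn,
            "total": n_total,
            "in_islands": n_island,
            "isolated": n_total - n_island,
            "cumulative_length_mb": length,
        }
        if length > 0:
            for col in ("syntenic", "non_syntenic", "total", "in_islands", "isolated"):
                row[f"{col}_density_raw"] = row[col] / length
                row[f"{col}_density"] = round(row[col] / length, 2)
        else:
            row["flag"] = "zero_length_bin"
        rows.append(row)
    return pd.DataFrame(rows)


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r with the two-sided t-distribution p-value.

    ``t = r * sqrt((n - 2) / (1 - r**2))`` on ``n - 2`` degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance input")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.sum(xc * yc) / math.sqrt(np.sum(xc**2) * np.sum(yc**2)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return r, float(p)


@dataclass(frozen=True)
class CorrelationResult:
    pair: str
    r: float
    p: float


def correlation_report(table: pd.DataFrame, use_raw: bool = False) -> pd.DataFrame:
    """Density-gradient correlations of each gene category against the total.

    ``use_raw`` switches from the rounded presentation densities to full
    precision (both conventions are reported because the choice changes the
    third decimal of r).
    """
    suffix = "_density_raw" if use_raw else "_density"
    total = table[f"total{suffix}"].to_numpy()
    rows = []
    for cat in ("syntenic", "non_syntenic", "in_islands", "isolated"):
        r, p = pearson_with_p(table[f"{cat}{suffix}"].to_numpy(), total)
        rows.append({"pair": f"{cat}_vs_total", "r": r, "p": p})
    return pd.DataFrame(rows, columns=["pair", "r", "p"])
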