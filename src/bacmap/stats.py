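"""Map-level summary statistics (N50/L50, coverage, marker density)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["MapStats", "compute_map_stats", "n50_l50"]


def n50_l50(lengths_kb: Sequence[float]) -> tuple[float, int]:
    """N50 and L50 of a contig length list.

    N50 is the length at which the descending cumulative sum first reaches
    half the total; L50 is the number of contigs needed to do so.
    """
    if not len(lengths_kb):
        raise ValueError("need at least one contig")
    desc = np.sort(np.asarray(lengths_kb, dtype=float))[::-1]
    half = desc.sum() / 2.0
    cum = np.cumsum(desc)
    idx = int(np.searchsorted(cum, half))
    return float(desc[idx]), idx + 1


@dataclass(frozen=True)
class MapStats:
    """Headline physical-map statistics."""

    n_contigs: int
    n_main_contigs: int
    total_length_kb: float
    n50_kb: float
    l50: int
    average_contig_kb: float
    longest_contig_kb: float
    n_contigs_over_1mb: int
    arm_coverage_pct: float
    marker_density_per_mb: float | None = None
    anchored_fraction_pct: float | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("n_contigs", self.n_contigs),
            ("n_main_contigs", self.n_main_contigs),
            ("total_length_kb", round(self.total_length_kb)),
            ("n50_kb", round(self.n50_kb)),
            ("l50", self.l50),
            ("average_contig_kb", round(self.average_contig_kb)),
            ("longest_contig_kb", round(self.longest_contig_kb)),
            ("n_contigs_over_1mb", self.n_contigs_over_1mb),
            ("arm_coverage_pct", round(self.arm_coverage_pct, 1)),
        ]
        if self.marker_density_per_mb is not None:
            rows.append(("marker_density_per_mb", round(self.marker_density_per_mb, 1)))
        if self.anchored_fraction_pct is not None:
            rows.append(("anchored_fraction_pct", round(self.anchored_fraction_pct, 1)))
        return pd.DataFrame(rows, columns=["statistic", "value"])


def compute_map_stats(
    contig_lengths_kb: Sequence[float],
    arm_length_kb: float,
    n_markers: int | None = None,
    anchored_lengths_kb: Sequence[float] | None = None,
    min_main_clones_lengths: Sequence[float] | None = None,
) -> MapStats:
    """Summarize a contig length list against the arm length.

    ``min_main_clones_lengths`` optionally gives the length subset of main
    (> 5 clone) contigs for the main-contig count.
    """
    lengths = np.asarray(contig_lengths_kb, dtype=float)
    if lengths.size == 0:
        raise ValueError("need at least one contig")
    if arm_length_kb <= 0:
        raise ValueError("arm length must be positive")
    total = float(lengths.sum())
    n50, l50 = n50_l50(lengths)
    marker_density = None
    if n_markers is not None:
        marker_density = n_markers / (total / 1000.0)
    anchored_pct = None
    if anchored_lengths_kb is not None:
        anchored_pct = 100.0 * float(np.sum(anchored_lengths_kb)) / total
    n_main = (
        len(min_main_clones_lengths)
        if min_main_clones_lengths is not None
        else int(lengths.size)
    )
    return MapStats(
        n_contigs=int(lengths.size),
        n_main_contigs=n_main,
        total_length_kb=total,
        n50_kb=n50,
        l50=l50,
        average_contig_kb=total / lengths.size,
        longest_contig_kb=float(lengths.max()),
        n_contigs_over_1mb=int(np.sum(lengths > 1000.0)),
        arm_coverage_pct=100.0 * total / arm_length_kb,
        marker_density_per_mb=marker_density,
        anchored_fraction_pct=anchored_pct,
    )
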