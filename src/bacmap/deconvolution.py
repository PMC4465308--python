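"""Simulated PCR / microarray screening of 3D pools and signal deconvolution.

Pool intensities are scored per pool type with a robust z statistic (the "C
value" threshold) gated by a replicate t-test; positive pools are intersected
into candidate well addresses and resolved against the contig map.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mtp_pools import PoolDesign
from .simdata import MarkerTruth, TrueClone

__all__ = [
    "ScreenResult",
    "SignalModel",
    "DeconvolutionConfig",
    "ProbeAssignment",
    "TierCalls",
    "carriers_of",
    "simulate_pcr_screen",
    "deconvolve_pcr",
    "simulate_array",
    "score_pools",
    "deconvolve_array",
    "assignment_frame",
]

TIERS = ("high", "medium", "low")
POOL_TYPES = ("row", "column", "plate")


@dataclass
class ScreenResult:
    """Per-pool screening signal for one marker.

    PCR screens carry a binary call per pool; array screens carry one
    log-intensity per replicate per pool (dye-swap design, >= 2 replicates).
    """

    marker_id: str
    method: str  # "pcr" | "array"
    calls: dict[str, bool] = field(default_factory=dict)
    intensities: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in ("pcr", "array"):
            raise ValueError(f"unknown screening method {self.method!r}")
        if self.method == "array":
            for pool, reps in self.intensities.items():
                if len(np.atleast_1d(reps)) < 2:
                    raise ValueError(f"pool {pool}: array screens need >= 2 replicates")


@dataclass(frozen=True)
class SignalModel:
    """Array signal generator: log-intensity = baseline + shift·carrier + noise."""

    baseline: float = 10.0
    shift: float = 2.0
    noise_sd: float = 0.25
    replicates: int = 2

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("dye-swap design requires >= 2 replicates")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


DEFAULT_C_VALUES = {
    "high": {"column": 2.8, "plate": 1.6, "row": 2.6},
    "medium": {"column": 2.6, "plate": 1.6, "row": 2.4},
    "low": {"column": 2.4, "plate": 1.4, "row": 2.2},
}


@dataclass
class DeconvolutionConfig:
    """C-value thresholds per tier and pool type, plus the t-test alpha."""

    c_values: dict[str, dict[str, float]] = field(
        default_factory=lambda: {t: dict(v) for t, v in DEFAULT_C_VALUES.items()}
    )
    alpha: float = 0.01
    overlap_consistency: bool = True

    def __post_init__(self) -> None:
        for pool_type in POOL_TYPES:
            hi = self.c_values["high"][pool_type]
            med = self.c_values["medium"][pool_type]
            lo = self.c_values["low"][pool_type]
            if not hi >= med >= lo:
                raise ValueError(
                    f"C values must nest high >= medium >= low for {pool_type}"
                )
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class ProbeAssignment:
    """Deconvolved marker-to-clone call with a confidence tier."""

    marker_id: str
    clones: tuple[str, ...]
    contigs: tuple[str, ...]
    tier: str | None
    method: str
    status: str  # assigned | ambiguous | discarded | unassigned
    reason: str = ""

    def __post_init__(self) -> None:
        if self.status == "assigned" and not self.clones:
            raise ValueError("assigned probes need >= 1 clone")
        if self.status == "discarded" and not self.reason:
            raise ValueError("discarded probes need a recorded reason")


def carriers_of(
    marker: MarkerTruth,
    clones: Iterable[TrueClone],
    restrict_to: Iterable[str] | None = None,
) -> set[str]:
    """Clones whose true span contains the marker position."""
    keep = set(restrict_to) if restrict_to is not None else None
    out = set()
    for c in clones:
        if c.is_contaminant:
            continue
        if keep is not None and c.clone_id not in keep:
            continue
        if c.start_kb <= marker.position_kb < c.end_kb:
            out.add(c.clone_id)
    return out


def simulate_pcr_screen(
    marker: MarkerTruth,
    pools: PoolDesign,
    carriers: set[str],
    fp_rate: float = 0.0,
    fn_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> ScreenResult:
    """Binary pool calls: carrier pools positive (flipped at ``fn_rate``),
    others positive at ``fp_rate``."""
    if rng is None:
        rng = np.random.default_rng(seed)
    carrier_pools = set()
    for c in carriers:
        if c in pools.addresses:
            carrier_pools.update(pools.pools_of(c))
    calls = {}
    for pool in pools.pool_ids():
        if pool in carrier_pools:
            calls[pool] = bool(rng.random() >= fn_rate)
        else:
            calls[pool] = bool(rng.random() < fp_rate)
    return ScreenResult(marker.marker_id, "pcr", calls=calls)


def _candidate_clones(
    positive: Mapping[str, Sequence[str]], pools: PoolDesign
) -> list[str]:
    """Occupied wells at the Cartesian product of positive row/column/plate pools."""
    table = pools.address_table()
    out = []
    for r, c, p in itertools.product(
        positive["row"], positive["column"], positive["plate"]
    ):
        clone = table.get((int(p[1:]), int(r[1:]), int(c[1:])))
        if clone is not None:
            out.append(clone)
    return sorted(set(out))


def _positive_by_type(calls: Mapping[str, bool]) -> dict[str, list[str]]:
    pos = {"row": [], "column": [], "plate": []}
    for pool, call in calls.items():
        if call:
            pos[PoolDesign.pool_type(pool)].append(pool)
    return pos


def _resolve(
    candidates: list[str],
    contig_of: Mapping[str, str],
    marker_id: str,
    method: str,
    tier: str | None,
) -> ProbeAssignment:
    """Overlap-consistency rule shared by PCR and array deconvolution."""
    if not candidates:
        return ProbeAssignment(marker_id, (), (), None, method, "unassigned")
    if len(candidates) == 1:
        clone = candidates[0]
        contig = contig_of.get(clone)
        return ProbeAssignment(
            marker_id,
            (clone,),
            (contig,) if contig else (),
            tier,
            method,
            "assigned",
        )
    placed = [c for c in candidates if c in contig_of]
    groups: dict[str, list[str]] = {}
    for c in placed:
        groups.setdefault(contig_of[c], []).append(c)
    if placed and len(groups) == 1:
        contig = next(iter(groups))
        return ProbeAssignment(
            marker_id, tuple(placed), (contig,), tier, method, "assigned"
        )
    # multiple map locations: candidates on overlapping clones of one contig
    # are retained; lone strays elsewhere are explained away by the pool
    # intersection and dropped
    multi = {cid: cs for cid, cs in groups.items() if len(cs) >= 2}
    if len(multi) == 1:
        contig, cs = next(iter(multi.items()))
        return ProbeAssignment(
            marker_id, tuple(sorted(cs)), (contig,), tier, method, "assigned"
        )
    if groups:
        return ProbeAssignment(
            marker_id,
            tuple(candidates),
            tuple(sorted(groups)),
            None,
            method,
            "ambiguous",
            reason="candidates span non-overlapping map locations",
        )
    return ProbeAssignment(
        marker_id,
        tuple(candidates),
        (),
        None,
        method,
        "ambiguous",
        reason="multiple unplaced candidates",
    )


def deconvolve_pcr(
    result: ScreenResult,
    pools: PoolDesign,
    contig_of: Mapping[str, str],
) -> ProbeAssignment:
    """Intersect positive pools into addresses and resolve candidates."""
    positive = _positive_by_type(result.calls)
    candidates = _candidate_clones(positive, pools)
    return _resolve(candidates, contig_of, result.marker_id, "pcr", "high")


def simulate_array(
    markers: Sequence[MarkerTruth],
    pools: PoolDesign,
    carriers_map: Mapping[str, set[str]],
    signal_model: SignalModel = SignalModel(),
    seed: int = 0,
) -> dict[str, ScreenResult]:
    """Replicate log-intensities per pool; deterministic under ``seed``."""
    rng = np.random.default_rng(seed)
    results = {}
    for marker in markers:
        carrier_pools = set()
        for c in carriers_map.get(marker.marker_id, ()):  # noqa: B905
            if c in pools.addresses:
                carrier_pools.update(pools.pools_of(c))
        intensities = {}
        for pool in pools.pool_ids():
            mu = signal_model.baseline + (
                signal_model.shift if pool in carrier_pools else 0.0
            )
            intensities[pool] = mu + rng.normal(
                0.0, signal_model.noise_sd, size=signal_model.replicates
            )
        results[marker.marker_id] = ScreenResult(
            marker.marker_id, "array", intensities=intensities
        )
    return results


@dataclass
class TierCalls:
    """Per-tier positive pool calls for one marker."""

    marker_id: str
    positives: dict[str, set[str]]  # tier -> pool ids
    z_scores: dict[str, float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def nested(self) -> bool:
        return self.positives["high"] <= self.positives["medium"] <= self.positives["low"]


def score_pools(
    result: ScreenResult,
    pools: PoolDesign,
    cfg: DeconvolutionConfig,
) -> TierCalls:
    """Robust z (vs the pool-type median/MAD) gated by a replicate t-test.

    The t-test compares a pool's replicates against the replicates of all
    other pools of the same type (two-sample, pooled variance); with only
    two dye-swap replicates a one-sample test has a single degree of freedom
    and no power at alpha = 0.01, so the cross-pool comparison carries the
    replicate information instead.  Zero MAD falls back to the standard
    deviation; zero-variance replicates skip the t-test and are flagged.
    """
    positives: dict[str, set[str]] = {t: set() for t in TIERS}
    z_scores: dict[str, float] = {}
    flags: list[str] = []
    by_type: dict[str, list[str]] = {"row": [], "column": [], "plate": []}
    for pool in result.intensities:
        by_type[PoolDesign.pool_type(pool)].append(pool)
    all_pools = [p for members in by_type.values() for p in members]
    for pool_type, members in by_type.items():
        if not members:
            continue
        if len(members) == 1:
            # a single pool of a type (e.g. one plate) carries no signal
            # contrast; it is trivially positive at every tier
            pool = members[0]
            z_scores[pool] = float("inf")
            flags.append(f"{pool}:single_pool_type")
            for tier in TIERS:
                positives[tier].add(pool)
            continue
        # fewer than 4 pools of a type cannot estimate their own background;
        # normalize against all pools instead
        reference = members if len(members) >= 4 else all_pools
        ref_means = np.array([np.mean(result.intensities[p]) for p in reference])
        med = float(np.median(ref_means))
        mad = float(stats.median_abs_deviation(ref_means, scale="normal"))
        if mad == 0.0:
            mad = float(np.std(ref_means))
        for pool in members:
            reps = np.asarray(result.intensities[pool], dtype=float)
            if mad == 0.0:
                z = 0.0
            else:
                z = (float(np.mean(reps)) - med) / mad
            z_scores[pool] = z
            others = np.concatenate(
                [result.intensities[p] for p in reference if p != pool]
            )
            if np.var(reps) == 0.0 or np.var(others) == 0.0:
                flags.append(f"{pool}:degenerate_replicates")
                t_ok = True  # call by z only
            else:
                _, pval = stats.ttest_ind(reps, others, equal_var=True)
                t_ok = bool(pval < cfg.alpha)
            for tier in TIERS:
                if z >= cfg.c_values[tier][pool_type] and t_ok:
                    positives[tier].add(pool)
    return TierCalls(result.marker_id, positives, z_scores, flags)


def deconvolve_array(
    calls: TierCalls,
    pools: PoolDesign,
    contig_of: Mapping[str, str],
    cfg: DeconvolutionConfig,
) -> ProbeAssignment:
    """Resolve tiered pool calls; tier = highest tier with a consistent call.

    Probes whose candidates span non-overlapping map locations at every tier
    are discarded as ambiguous.
    """
    saw_candidates = False
    saw_conflict = False
    for tier in TIERS:
        pos = {"row": [], "column": [], "plate": []}
        for pool in calls.positives[tier]:
            pos[PoolDesign.pool_type(pool)].append(pool)
        candidates = _candidate_clones(pos, pools)
        if not candidates:
            continue
        saw_candidates = True
        assignment = _resolve(candidates, contig_of, calls.marker_id, "array", tier)
        if assignment.status == "assigned":
            return assignment
        if assignment.status == "ambiguous":
            saw_conflict = True
    if saw_conflict:
        return ProbeAssignment(
            calls.marker_id,
            (),
            (),
            None,
            "array",
            "discarded",
            reason="ambiguous at all tiers: candidates on non-overlapping locations",
        )
    status = "ambiguous" if saw_candidates else "unassigned"
    return ProbeAssignment(calls.marker_id, (), (), None, "array", status,
                           reason="unresolved candidates" if saw_candidates else "")


def assignment_frame(assignments: Iterable[ProbeAssignment]) -> pd.DataFrame:
    rows = []
    for a in assignments:
        rows.append(
            {
                "marker_id": a.marker_id,
                "clones": ",".join(a.clones),
                "contigs": ",".join(a.contigs),
                "tier": a.tier or "",
                "method": a.method,
                "status": a.status,
                "reason": a.reason,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["marker_id", "clones", "contigs", "tier", "method", "status", "reason"],
    )
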