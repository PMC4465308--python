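"""End-to-end pipeline driver: simulate -> fingerprint -> filter -> assemble
-> mtp -> pools -> screen -> deconvolve -> binmap -> genespace -> stats.

Every stage writes its outputs as TSV under the artifact directory and logs
its parameters and seed; stages reload intermediate files when re-run in a
fresh process, so the pipeline is restartable from any point.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import binmap as bm
from . import deconvolution as dc
from . import genespace as gs
from . import mtp_pools as mp
from . import simdata as sd
from .assembly import (
    Assembly,
    ContigLayout,
    OverlapNet,
    adaptive_cluster,
    build_net,
    remove_q_elements,
)
from .config import PipelineConfig
from .fingerprint_io import FingerprintSet, filter_bands, read_band_file, write_band_file
from .stats import compute_map_stats

logger = logging.getLogger("bacmap")

STAGES = (
    "simulate",
    "filter",
    "assemble",
    "mtp",
    "pools",
    "deconvolve",
    "binmap",
    "genespace",
    "stats",
)

__all__ = ["run_pipeline", "STAGES", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# per-stage state loading (restartability)


def _load_clones(outdir: Path) -> list[sd.TrueClone]:
    return sd.read_clone_table(outdir / "clones.tsv")


def _load_markers(outdir: Path) -> list[sd.MarkerTruth]:
    return sd.read_marker_table(outdir / "markers.tsv")


def _load_filtered(outdir: Path) -> FingerprintSet:
    return read_band_file(outdir / "bands.filtered.bands")


def _load_net(outdir: Path, cfg: PipelineConfig) -> OverlapNet:
    fset = _load_filtered(outdir)
    graph = nx.Graph()
    for p in fset:
        graph.add_node(p.clone_id, n_bands=p.n_bands)
    edges = pd.read_csv(outdir / "net_edges.tsv", sep="\t")
    for row in edges.itertuples(index=False):
        graph.add_edge(row.clone_a, row.clone_b, shared=int(row.shared), p=float(row.p))
    return OverlapNet(graph, cfg.assembly.net_cutoff)


def _load_assembly(outdir: Path, cfg: PipelineConfig) -> Assembly:
    table = pd.read_csv(outdir / "contigs.tsv", sep="\t")
    meta = pd.read_csv(outdir / "contigs_meta.tsv", sep="\t")
    layouts = []
    meta_by_id = {r.contig_id: r for r in meta.itertuples(index=False)}
    for contig_id, grp in table.groupby("contig_id", sort=False):
        grp = grp.sort_values("order_index")
        clones = list(grp["clone_id"])
        coords = dict(zip(grp["clone_id"], grp["coordinate_kb"]))
        m = meta_by_id[contig_id]
        layouts.append(
            ContigLayout(
                contig_id=contig_id,
                clones=clones,
                coordinates=coords,
                length_kb=float(m.length_kb),
                depth=float(m.depth),
                linear=bool(m.linear),
                branching_clones=[],
            )
        )
    layouts.sort(key=lambda l: (-l.n_clones, l.clones[0]))
    excluded: list[str] = []
    excl_path = outdir / "excluded_clones.tsv"
    if excl_path.exists():
        df = pd.read_csv(excl_path, sep="\t")
        excluded = list(df["clone_id"].astype(str))
    return Assembly(layouts, excluded, cfg.assembly)


def _load_mtp(outdir: Path) -> mp.MTPSelection:
    df = pd.read_csv(outdir / "mtp.tsv", sep="\t", keep_default_na=False)
    sel = mp.MTPSelection()
    for row in df.itertuples(index=False):
        if row.category == "base":
            sel.base.setdefault(row.contig_id, []).append(row.clone_id)
        elif row.category == "reinforcement":
            sel.reinforcement.setdefault(row.contig_id, []).append(row.clone_id)
        else:
            sel.q_clones.append(row.clone_id)
    return sel


def _load_assignments(outdir: Path) -> list[dc.ProbeAssignment]:
    df = pd.read_csv(outdir / "assignments.tsv", sep="\t", keep_default_na=False)
    return [
        dc.ProbeAssignment(
            r.marker_id,
            tuple(str(r.clones).split(",")) if r.clones else (),
            tuple(str(r.contigs).split(",")) if r.contigs else (),
            r.tier or None,
            r.method,
            r.status,
            r.reason,
        )
        for r in df.itertuples(index=False)
    ]


def _load_binmap(outdir: Path) -> list[bm.BinAssignment]:
    df = pd.read_csv(outdir / "binmap.tsv", sep="\t", keep_default_na=False)
    out = []
    for r in df.itertuples(index=False):
        evidence = [
            tuple(item.rsplit(":", 1)) for item in str(r.evidence).split(";") if item
        ]
        out.append(
            bm.BinAssignment(
                contig_id=r.contig_id,
                bin_label=r.bin or None,
                evidence=[(m, b) for m, b in evidence],
                conflict=bool(r.conflict),
                rank=float(r.rank) if r.rank != "" else None,
                order_index=int(r.order_index) if r.order_index != "" else None,
            )
        )
    return out


def _load_pools(outdir: Path) -> mp.PoolDesign:
    df = pd.read_csv(outdir / "pools.tsv", sep="\t")
    addresses = {
        r.clone_id: (int(r.plate), int(r.row), int(r.column))
        for r in df.itertuples(index=False)
    }
    n_plates = int(df["plate"].max()) + 1 if len(df) else 1
    return mp.PoolDesign(addresses, n_plates)


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> dict:
    sim = cfg.sim
    arm = sd.simulate_arm(
        sim.arm_length_kb, sim.mean_fragment_kb, cfg.seed, sim.bin_boundaries
    )
    clones = sd.sample_clone_library(
        arm, sim.n_clones, sim.insert_mean_kb, sim.insert_sd_kb, sim.purity, cfg.seed + 1
    )
    noise = sd.NoiseModel(
        band_miss_rate=sim.noise.band_miss_rate,
        spurious_rate=sim.noise.spurious_rate,
        size_jitter=sim.noise.size_jitter,
        jitter_rate=sim.noise.jitter_rate,
        decoy_mean_bands=sim.insert_mean_kb / sim.mean_fragment_kb,
        seed=cfg.seed + 2,
    )
    fset = sd.fingerprint_library(clones, arm, noise)
    markers = sd.plant_markers(
        arm,
        dict(zip(arm.labels, sim.marker_density_per_mb)),
        sim.island_fraction,
        cfg.seed + 3,
        island_span_kb=sim.island_span_kb,
        syntenic_fraction=sim.syntenic_fraction,
    )
    sd.write_clone_table(clones, outdir / "clones.tsv")
    sd.write_marker_table(markers, outdir / "markers.tsv")
    write_band_file(fset, outdir / "bands.bands")
    logger.info(
        "simulate: seed=%d arm=%.0fkb clones=%d markers=%d",
        cfg.seed, sim.arm_length_kb, len(clones), len(markers),
    )
    return {"arm": arm, "clones": clones, "markers": markers, "fset": fset}


def stage_filter(cfg: PipelineConfig, outdir: Path, ctx: dict) -> dict:
    fset = ctx.get("fset") or read_band_file(outdir / "bands.bands")
    filtered, report = filter_bands(fset, min_band_count=cfg.min_band_count)
    write_band_file(filtered, outdir / "bands.filtered.bands")
    report.write_tsv(outdir / "filter_report.tsv")
    logger.info(
        "filter: retained=%d dropped=%d (%.1f%%)",
        report.retained, report.dropped, 100 * report.retained_fraction,
    )
    return {"filtered": filtered}


def stage_assemble(cfg: PipelineConfig, outdir: Path, ctx: dict) -> dict:
    fset = ctx.get("filtered") or _load_filtered(outdir)
    net = build_net(fset, cfg.assembly)
    qnet, qreport = remove_q_elements(net, cfg.assembly, fset)
    assembly = adaptive_cluster(qnet, cfg.assembly, fset)
    _tsv(net.edge_frame(), outdir / "net_edges.tsv")
    _tsv(assembly.contig_frame(), outdir / "contigs.tsv")
    meta = pd.DataFrame(
        [
            {
                "contig_id": l.contig_id,
                "n_clones": l.n_clones,
                "length_kb": round(l.length_kb, 3),
                "depth": round(l.depth, 3),
                "linear": l.linear,
            }
            for l in assembly.contigs
        ]
    )
    _tsv(meta, outdir / "contigs_meta.tsv")
    _tsv(
        pd.DataFrame({"clone_id": assembly.excluded_clones + qreport.q_clones,
                      "reason": ["branching"] * len(assembly.excluded_clones)
                      + ["q_clone"] * len(qreport.q_clones)}),
        outdir / "excluded_clones.tsv",
    )
    logger.info(
        "assemble: edges=%d q_clones=%d q_overlaps=%d contigs=%d (main %d)",
        net.n_edges, len(qreport.q_clones), len(qreport.q_overlaps),
        len(assembly.contigs), len(assembly.main_contigs),
    )
    return {"net": net, "assembly": assembly, "q_clones": qreport.q_clones}


def stage_mtp(cfg: PipelineConfig, outdir: Path, ctx: dict) -> dict:
    assembly = ctx.get("assembly") or _load_assembly(outdir, cfg)
    net = ctx.get("net") or _load_net(outdir, cfg)
    insert = cfg.assembly.insert_mean_kb
    selection = mp.MTPSelection()
    for layout in assembly.main_contigs + assembly.short_contigs:
        spans = mp.clone_spans(layout, insert)
        base = mp.select_mtp(layout, net, spans, insert)
        selection.base[layout.contig_id] = base
        reinforcement, gaps = mp.reinforce_mtp(
            base, layout, net, spans, insert, cfg.assembly.net_cutoff
        )
        if reinforcement:
            selection.reinforcement[layout.contig_id] = reinforcement
        for a, b in gaps:
            selection.gap_junctions.append((layout.contig_id, a, b))
    mp.add_q_clones(selection, ctx.get("q_clones", []))
    _tsv(selection.to_frame(), outdir / "mtp.tsv")
    counts = selection.category_counts()
    logger.info("mtp: base=%d reinforcement=%d q_clones=%d total=%d",
                counts["base"], counts["reinforcement"], counts["q_clone"],
                selection.total)
    return {"mtp": selection}


def stage_pools(cfg: PipelineConfig, outdir: Path, ctx: dict) -> dict:
    selection = ctx.get("mtp") or _load_mtp(outdir)
    pools = mp.design_3d_pools(selection.all_clones())
    _tsv(pools.to_frame(), outdir / "pools.tsv")
    logger.info("pools: clones=%d plates=%d pools=%d",
                len(pools.addresses), pools.n_plates, pools.n_pools)
    return {"pools": pools}


def stage_deconvolve(cfg: PipelineConfig, outdir: Path, ctx: dict) -> dict:
    pools = ctx.get("pools") or _load_pools(outdir)
    assembly = ctx.get("assembly") or _load_assembly(outdir, cfg)
    clones = ctx.get("clones") or _load_clones(outdir)
    markers = ctx.get("markers") or _load_markers(outdir)
    contig_of = {
        clone: layout.contig_id
        for layout in assembly.contigs
        if layout.n_clones > 1
        for clone in layout.clones
    }
    carriers_map = {
        m.marker_id: dc.carriers_of(m, clones, restrict_to=pools.addresses)
        for m in markers
    }
    results = dc.simulate_array(
        markers, pools, carriers_map, cfg.screen.signal, cfg.seed + 4
    )
    assignments = []
    for m in markers:
        calls = dc.score_pools(results[m.marker_id], pools, cfg.deconvolution)
        assignments.append(dc.deconvolve_array(calls, pools, contig_of, cfg.deconvolution))
    # PCR confirmation screen on a marker subset
    rng = np.random.default_rng(cfg.seed + 5)
    pcr_assignments = []
    for m in markers[: cfg.screen.n_pcr_markers]:
        res = dc.simulate_pcr_screen(
            m, pools, carriers_map[m.marker_id],
            cfg.screen.pcr_fp_rate, cfg.screen.pcr_fn_rate, rng,
        )
        pcr_assignments.append(dc.deconvolve_pcr(res, pools, contig_of))
    _tsv(dc.assignment_frame(assignments), outdir / "assignments.tsv")
    _tsv(dc.assignment_frame(pcr_assignments), outdir / "assignments_pcr.tsv")
    n_ok = sum(a.status == "assigned" for a in assignments)
    logger.info("deconvolve: markers=%d assigned=%d discarded=%d",
                len(assignments), n_ok,
                sum(a.status == "discarded" for a in assignments))
    return {"assignments": assignments, "pcr_assignments": pcr_assignments,
            "contig_of": contig_of, "carriers_map": carriers_map}


def _marker_bins(cfg: PipelineConfig, markers: list[sd.MarkerTruth]) -> dict[str, str]:
    """Deletion-line screening of markers: presence on a line of fraction f
    iff the marker lies in the retained [0, f) portion."""
    lines = {f"DL{b:.2f}": b for b in cfg.sim.bin_boundaries}
    bins = bm.make_bins(cfg.sim.bin_boundaries)
    out = {}
    for m in markers:
        frac = m.position_kb / cfg.sim.arm_length_kb
        presence = {line: frac < f for line, f in lines.items()}
        call = bm.infer_bin_from_deletion_lines(presence, lines, bins)
        if call.label is not None:
            out[m.marker_id] = call.label
    return out


def stage_binmap(cfg: PipelineConfig, outdir: Path, ctx: dict) -> dict:
    assembly = ctx.get("assembly") or _load_assembly(outdir, cfg)
    net = ctx.get("net") or _load_net(outdir, cfg)
    markers = ctx.get("markers") or _load_markers(outdir)
    assignments = ctx.get("assignments")
    if assignments is None:
        assignments = _load_assignments(outdir)
    marker_bins = _marker_bins(cfg, markers)
    marker_contigs = {
        a.marker_id: list(a.contigs) for a in assignments if a.status == "assigned"
    }
    bin_assignments = bm.assign_contigs_to_bins(marker_contigs, marker_bins)
    lengths = {l.contig_id: l.length_kb for l in assembly.contigs}
    bin_sizes = bm.estimate_bin_sizes(bin_assignments, lengths, cfg.sim.arm_length_kb)
    ranks = bm.OrthologRankTable()
    for m in markers:
        if m.ortholog_rank is not None:
            ranks.add(m.marker_id, "tauschii", m.ortholog_rank)
            ranks.add(m.marker_id, "zipper", m.ortholog_rank)
    bin_assignments, duplications = bm.order_contigs_within_bins(bin_assignments, ranks)
    supercontigs, rejected = bm.elongate_supercontigs(
        assembly.main_contigs + assembly.short_contigs, net,
        cfg.assembly.net_cutoff, insert_mean_kb=cfg.assembly.insert_mean_kb,
    )
    _tsv(
        pd.DataFrame(
            [
                {
                    "contig_id": a.contig_id,
                    "bin": a.bin_label,
                    "rank": "" if a.rank is None else a.rank,
                    "order_index": "" if a.order_index is None else a.order_index,
                    "conflict": a.conflict,
                    "evidence": ";".join(f"{m}:{b}" for m, b in a.evidence),
                }
                for a in bin_assignments
            ]
        ),
        outdir / "binmap.tsv",
    )
    _tsv(
        pd.DataFrame(
            [
                {
                    "bin": s.label,
                    "mapped_mb": round(s.mapped_mb, 3),
                    "corrected_mb": round(s.corrected_mb, 3),
                    "share_pct": round(s.share_pct, 1),
                }
                for s in bin_sizes.values()
            ]
        ),
        outdir / "bin_sizes.tsv",
    )
    _tsv(
        pd.DataFrame(
            [
                {
                    "supercontig_id": s.supercontig_id,
                    "members": ",".join(s.members),
                    "member_clones": ",".join(map(str, s.member_clone_counts)),
                    "total_clones": s.total_clones,
                }
                for s in supercontigs
            ]
        ),
        outdir / "supercontigs.tsv",
    )
    _tsv(
        pd.DataFrame(
            [
                {"kind": d.kind, "detail": d.detail, "contigs": ",".join(d.contigs)}
                for d in duplications
            ]
        ),
        outdir / "duplications.tsv",
    )
    bm.write_agp(bin_assignments, lengths, outdir / "map.agp")
    logger.info("binmap: binned=%d supercontigs=%d duplication_flags=%d",
                len(bin_assignments), len(supercontigs), len(duplications))
    return {
        "bin_assignments": bin_assignments,
        "bin_sizes": bin_sizes,
        "supercontigs": supercontigs,
        "marker_bins": marker_bins,
        "assignments": assignments,
    }


def stage_genespace(cfg: PipelineConfig, outdir: Path, ctx: dict) -> dict:
    assembly = ctx.get("assembly") or _load_assembly(outdir, cfg)
    net = ctx.get("net") or _load_net(outdir, cfg)
    markers = ctx.get("markers") or _load_markers(outdir)
    assignments = ctx.get("assignments") or _load_assignments(outdir)
    bin_assignments = ctx.get("bin_assignments") or _load_binmap(outdir)
    contig_bin = {a.contig_id: a.bin_label for a in bin_assignments}
    labels, excluded = gs.classify_island_genes(assignments, net)
    gene_bins = {}
    for a in assignments:
        if a.status == "assigned" and a.contigs:
            b = contig_bin.get(a.contigs[0])
            if b is not None:
                gene_bins[a.marker_id] = b
    syntenic = {m.marker_id: m.syntenic for m in markers}
    lengths = {l.contig_id: l.length_kb for l in assembly.contigs}
    bin_lengths = {}
    for a in bin_assignments:
        if a.bin_label:
            bin_lengths[a.bin_label] = (
                bin_lengths.get(a.bin_label, 0.0) + lengths.get(a.contig_id, 0.0) / 1000.0
            )
    table = gs.tabulate_bin_gene_stats(labels, gene_bins, syntenic, bin_lengths)
    _tsv(table, outdir / "genespace.tsv")
    if len(table) >= 3:
        corr = pd.concat(
            [
                gs.correlation_report(table).assign(precision="rounded"),
                gs.correlation_report(table, use_raw=True).assign(precision="raw"),
            ]
        )
        _tsv(corr, outdir / "correlations.tsv")
    logger.info("genespace: genes=%d islands=%d",
                len(labels), sum(1 for v in labels.values() if v == "island"))
    return {"genespace": table, "island_labels": labels}


def stage_stats(cfg: PipelineConfig, outdir: Path, ctx: dict) -> dict:
    assembly = ctx.get("assembly") or _load_assembly(outdir, cfg)
    assignments = ctx.get("assignments")
    if assignments is None:
        path = outdir / "assignments.tsv"
        assignments = _load_assignments(outdir) if path.exists() else []
    layouts = assembly.main_contigs + assembly.short_contigs
    lengths = [l.length_kb for l in layouts]
    anchored_contigs = {
        c for a in assignments if a.status == "assigned" for c in a.contigs
    }
    anchored = [l.length_kb for l in layouts if l.contig_id in anchored_contigs]
    n_assigned = sum(1 for a in assignments if a.status == "assigned")
    stats = compute_map_stats(
        lengths,
        cfg.sim.arm_length_kb,
        n_markers=n_assigned or None,
        anchored_lengths_kb=anchored if anchored else None,
        min_main_clones_lengths=[l.length_kb for l in assembly.main_contigs],
    )
    _tsv(stats.to_frame(), outdir / "stats.tsv")
    logger.info("stats: contigs=%d N50=%.0fkb L50=%d coverage=%.1f%%",
                stats.n_contigs, stats.n50_kb, stats.l50, stats.arm_coverage_pct)
    return {"stats": stats}


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "filter": stage_filter,
    "assemble": stage_assemble,
    "mtp": stage_mtp,
    "pools": stage_pools,
    "deconvolve": stage_deconvolve,
    "binmap": stage_binmap,
    "genespace": stage_genespace,
    "stats": stage_stats,
}


def run_pipeline(
    cfg: PipelineConfig,
    outdir: str | Path,
    stages: tuple[str, ...] = STAGES,
) -> dict:
    """Run the requested pipeline stages in order, writing artifacts to
    ``outdir``; any stage failure aborts with the stage name and cause."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    logger.info("pipeline start: seed=%d stages=%s", cfg.seed, ",".join(stages))
    ctx: dict = {}
    try:
        for stage in STAGES:
            if stage not in stages:
                continue
            func = _STAGE_FUNCS[stage]
            try:
                if stage == "simulate":
                    ctx.update(func(cfg, outdir))
                else:
                    ctx.update(func(cfg, outdir, ctx))
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise PipelineError(stage, exc) from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
    return ctx
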