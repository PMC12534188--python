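"""End-to-end orchestration: simulate -> resi -> stats -> report.

Each stage reads/writes plain-text files in a working directory, draws its
randomness from a seed derived from ``(config.seed, stage)`` so stages can
be rerun independently yet reproducibly, and is recorded in a run manifest
(resolved config, per-stage seeds, output digests, timings).

In the stats stage, DBSCAN is run once on the full merged table and the
per-area statistics are restricted to each picked square afterwards, so
that neighbourhood information at square boundaries is not lost (the picks
are interior to the FOV); the CSR references are simulated toroidally on
the square, which is likewise edge-free.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import resi_core, spatial_stats, synthetic_data
from .io_formats import (
    DataError,
    PipelineConfig,
    ValidationError,
    config_to_dict,
    get_logger,
    load_config,
    read_localizations,
    save_config,
    write_localizations,
)

__all__ = ["RunManifest", "run_pipeline", "make_report", "STAGES"]

STAGES = ("simulate", "resi", "stats", "report")
_STAGE_INDEX = {name: i for i, name in enumerate(STAGES)}

__version__ = "0.1.0"


@dataclass
class RunManifest:
    config: dict
    stage_seeds: dict[str, int]
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    timings: dict[str, float] = field(default_factory=dict)
    version: str = __version__

    def save(self, path: Path) -> None:
        with open(path, "w") as f:
            json.dump(dataclasses.asdict(self), f, indent=2, sort_keys=True)


def _stage_seed(seed: int, stage: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(seed), _STAGE_INDEX[stage]])


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise DataError(f"stage '{stage}' requires missing input file: {path}")
    return path


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def _stage_simulate(cfg: PipelineConfig, workdir: Path) -> list[Path]:
    ss = _stage_seed(cfg.seed, "simulate")
    scene_seed, loc_seed = ss.spawn(2)
    area = (cfg.fov_width, cfg.fov_height)
    sim = cfg.simulate
    if sim.mode == "csr":
        scene = synthetic_data.generate_csr_scene(sim.density, area, cfg.n_channels, scene_seed)
    else:
        spec = synthetic_data.SceneSpec(
            mode="glycan",
            area=area,
            protein_density=sim.protein_density,
            glycans_per_protein=sim.glycans_per_protein,
            protein_jitter=sim.protein_jitter,
        )
        scene = synthetic_data.generate_glycan_scene(spec, scene_seed, cfg.n_channels)
    tables = synthetic_data.simulate_localizations(
        scene, sim.kinetics, sim.noise, loc_seed,
        n_frames=cfg.n_frames, n_channels=cfg.n_channels, area=area,
    )
    outputs = []
    scene_path = workdir / "ground_truth.csv"
    scene.to_csv(scene_path, index=False)
    outputs.append(scene_path)
    for ch, t in tables.items():
        t = t.copy()
        t["channel"] = ch
        p = workdir / f"locs_channel_{ch}.csv"
        write_localizations(t, p, dialect=sim.dialect if sim.dialect == "csv" else "csv")
        outputs.append(p)
    cfg_path = workdir / "config_resolved.yaml"
    save_config(cfg, cfg_path)
    outputs.append(cfg_path)
    return outputs


def _stage_resi(cfg: PipelineConfig, workdir: Path) -> list[Path]:
    log = get_logger("resi")
    tables = {}
    for ch in range(cfg.n_channels):
        p = _require(workdir / f"locs_channel_{ch}.csv", "resi")
        tables[ch] = read_localizations(p, dialect="csv")
    qc = {}
    per_channel = {}
    for ch, t in tables.items():
        clusters = resi_core.cluster_channel(t, cfg.clustering)
        n_raw = len(clusters)
        kept = resi_core.filter_time_traces(clusters, cfg.trace_filter, cfg.n_frames)
        per_channel[ch] = resi_core.compute_centers(kept)
        ks = np.array([c.K for c in kept], dtype=float)
        qc[f"channel_{ch}"] = {
            "n_localizations": int(len(t)),
            "clusters_found": n_raw,
            "removed_by_trace_filter": n_raw - len(kept),
            "clusters_retained": len(kept),
            "locs_per_cluster_mean": float(ks.mean()) if ks.size else 0.0,
            "locs_per_cluster_std": float(ks.std(ddof=1)) if ks.size > 1 else 0.0,
        }
        log.info("channel %d: %d clusters retained of %d", ch, len(kept), n_raw)
    # synthetic acquisitions are generated drift-free and pre-aligned, so the
    # channel shifts are identically zero; alignment from fiducials is
    # available through resi_core.align_channels for real acquisitions.
    shifts = resi_core.ChannelShifts(
        shifts={ch: (0.0, 0.0) for ch in tables}, reference_channel=0
    )
    merged = resi_core.merge_channels(per_channel, shifts)
    resi_path = workdir / "resi.csv"
    merged[list(resi_core.RESI_COLUMNS)].to_csv(resi_path, index=False)
    qc_path = workdir / "qc.json"
    with open(qc_path, "w") as f:
        json.dump(qc, f, indent=2, sort_keys=True)
    return [resi_path, qc_path]


def compute_stats(
    table: pd.DataFrame,
    cfg: PipelineConfig,
    seed: np.random.SeedSequence | int | None = None,
):
    """Area-based clusterization and NND analysis of a merged site table.

    Returns ``(picks, area_stats, refs, delta, test, nnd_by_area)``; used by
    the stats stage and directly by end-to-end tests.
    """
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    pick_seed, csr_seed = ss.spawn(2)
    fov = (cfg.fov_width, cfg.fov_height)
    picks = spatial_stats.pick_areas(
        table, cfg.areas.n_areas, cfg.areas.area_side, fov,
        density_band=cfg.areas.density_band, seed=pick_seed,
    )
    # one global DBSCAN pass, then restrict to areas
    labels = spatial_stats.dbscan_cluster(table, cfg.dbscan)
    sizes = np.bincount(labels[labels >= 0]) if (labels >= 0).any() else np.empty(0, dtype=int)
    clustered_flag = np.zeros(len(table), dtype=bool)
    if sizes.size:
        clustered_flag[labels >= 0] = sizes[labels[labels >= 0]] >= 2

    area_nm2 = cfg.areas.area_side**2
    csr_children = csr_seed.spawn(len(picks))
    area_stats, refs, nnd_by_area = [], [], []
    full_nnd = spatial_stats.knn_distances(table, k_max=cfg.nnd.k_max, mode="plain",
                                           bin_width=cfg.nnd.bin_width)
    for i, pick in enumerate(picks):
        idx = pick.indices
        cropped = spatial_stats.cluster_size_stats(labels[idx], area_nm2)
        cropped.f_clustered = float(clustered_flag[idx].mean()) if idx.size else 0.0
        area_stats.append(cropped)
        refs.append(
            spatial_stats.simulate_csr_reference(
                max(int(idx.size), 2), (pick.side, pick.side), cfg.dbscan,
                k_max=cfg.nnd.k_max, n_reps=cfg.csr.n_reps, seed=csr_children[i],
                toroidal=cfg.csr.toroidal,
            )
        )
        nnd_by_area.append(full_nnd.distances[idx])
    delta = spatial_stats.delta_clustered(area_stats, refs)
    test = spatial_stats.compare_conditions(delta)
    return picks, area_stats, refs, delta, test, nnd_by_area


def _stage_stats(cfg: PipelineConfig, workdir: Path) -> list[Path]:
    resi_path = _require(workdir / "resi.csv", "stats")
    table = pd.read_csv(resi_path)
    if len(table) == 0:
        raise DataError(f"{resi_path} holds no records")
    ss = _stage_seed(cfg.seed, "stats")
    picks, area_stats, refs, delta, test, nnd_by_area = compute_stats(table, cfg, ss)

    outputs = []
    # cluster sizes, data vs pooled CSR
    rows = []
    for cs in area_stats:
        for size, count in cs.size_hist.items():
            rows.append(("data", size, count))
    pooled_csr: dict[int, float] = {}
    for ref in refs:
        for h in ref.size_hists:
            for size, count in h.items():
                pooled_csr[size] = pooled_csr.get(size, 0.0) + count / ref.n_reps
    for size, count in sorted(pooled_csr.items()):
        rows.append(("csr", size, count))
    sizes_df = pd.DataFrame(rows, columns=["condition", "size", "count"])
    sizes_df = sizes_df.groupby(["condition", "size"], as_index=False)["count"].sum()
    p = workdir / "cluster_sizes.csv"
    sizes_df.to_csv(p, index=False)
    outputs.append(p)

    delta_df = pd.DataFrame(
        {
            "area_id": np.arange(len(area_stats)),
            "f_data": [cs.f_clustered for cs in area_stats],
            "f_csr_mean": [r.f_mean for r in refs],
            "density_per_um2": [cs.density for cs in area_stats],
        }
    )
    delta_df["delta"] = (delta_df["f_data"] - delta_df["f_csr_mean"]) / delta_df["f_csr_mean"]
    p = workdir / "delta_clustered.csv"
    delta_df.to_csv(p, index=False)
    outputs.append(p)

    for k in range(1, cfg.nnd.k_max + 1):
        rows = []
        for area_id, d in enumerate(nnd_by_area):
            rows.append(pd.DataFrame({"area_id": area_id, "distance_nm": d[:, k - 1]}))
        p = workdir / f"nnd_k{k}.csv"
        pd.concat(rows, ignore_index=True).to_csv(p, index=False)
        outputs.append(p)

    mean_density = float(np.mean([cs.density for cs in area_stats]))
    tests = {
        "delta_clustered": {
            "mean": delta.mean,
            "sem": delta.sem,
            "n_areas": delta.n_areas,
            "statistic": test.statistic,
            "p_value": test.p_value,
            "sidedness": test.sidedness,
            "dof": test.dof,
        },
        "mean_density_per_um2": mean_density,
        "csr_nnd_mean_k1_nm": spatial_stats.nnd_mean_csr(mean_density, 1),
        "seed": cfg.seed,
    }
    p = workdir / "tests.json"
    with open(p, "w") as f:
        json.dump(tests, f, indent=2, sort_keys=True)
    outputs.append(p)
    cfg_path = workdir / "config_resolved.yaml"
    save_config(cfg, cfg_path)
    outputs.append(cfg_path)
    return outputs


def make_report(stats_dir: str | Path, out_path: str | Path | None = None) -> Path:
    """Summarize a stats directory into one human-readable report file."""
    stats_dir = Path(stats_dir)
    tests_path = _require(stats_dir / "tests.json", "report")
    delta_path = _require(stats_dir / "delta_clustered.csv", "report")
    with open(tests_path) as f:
        tests = json.load(f)
    delta_df = pd.read_csv(delta_path)
    lines = []
    lines.append("RESI spatial-statistics report")
    lines.append("=" * 34)
    lines.append(f"areas analysed:      {tests['delta_clustered']['n_areas']}")
    lines.append(f"mean density:        {tests['mean_density_per_um2']:.1f} sites/um^2")
    lines.append(f"CSR mean 1st NND:    {tests['csr_nnd_mean_k1_nm']:.2f} nm")
    dc = tests["delta_clustered"]
    lines.append(
        f"Delta clustered:     {dc['mean']:+.4f} +- {dc['sem']:.4f} (s.e.m., n={dc['n_areas']})"
    )
    signif = "significant (p < 0.05)" if dc["p_value"] < 0.05 else "NS (p > 0.05)"
    lines.append(
        f"one-sided t vs 0:    t={dc['statistic']:.3f}, dof={dc['dof']:.0f}, "
        f"p={dc['p_value']:.3g} -> {signif}"
    )
    lines.append("")
    lines.append("per-area clustered fractions (data vs CSR mean):")
    lines.append(delta_df.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    for k in range(1, 5):
        p = stats_dir / f"nnd_k{k}.csv"
        if p.exists():
            d = pd.read_csv(p)["distance_nm"]
            lines.append("")
            lines.append(
                f"NND k={k}: n={len(d)}, mean={d.mean():.2f} nm, "
                f"median={d.median():.2f} nm, p5={d.quantile(0.05):.2f}, "
                f"p95={d.quantile(0.95):.2f}"
            )
    out_path = Path(out_path) if out_path else stats_dir / "report.txt"
    out_path.write_text("\n".join(lines) + "\n")
    return out_path


# --------------------------------------------------------------------------
# driver
# --------------------------------------------------------------------------

def run_pipeline(
    config: str | Path | PipelineConfig,
    workdir: str | Path,
    stages: tuple[str, ...] | list[str] = STAGES,
) -> RunManifest:
    """Execute the requested stages in order and write a run manifest."""
    cfg = config if isinstance(config, PipelineConfig) else load_config(config)
    cfg.validate()
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    for s in stages:
        if s not in STAGES:
            raise ValidationError(f"unknown stage {s!r}; expected subset of {STAGES}")
    stages = tuple(sorted(stages, key=_STAGE_INDEX.get))
    log = get_logger("pipeline")
    manifest = RunManifest(
        config=config_to_dict(cfg),
        stage_seeds={
            s: int(_stage_seed(cfg.seed, s).generate_state(1)[0]) for s in stages
        },
    )
    runners = {
        "simulate": _stage_simulate,
        "resi": _stage_resi,
        "stats": _stage_stats,
        "report": lambda c, w: [make_report(w)],
    }
    for s in stages:
        t0 = time.perf_counter()
        log.info("stage %s starting", s)
        outputs = runners[s](cfg, workdir)
        manifest.timings[s] = time.perf_counter() - t0
        for p in outputs:
            manifest.outputs[str(p.relative_to(workdir))] = _digest(p)
        log.info("stage %s done in %.1f s", s, manifest.timings[s])
    manifest.save(workdir / "manifest.json")
    return manifest
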