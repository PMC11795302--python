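"""Simulate -> measure -> pca -> report pipeline with a reproducible layout.

One :class:`RunConfig` drives the whole study. The output directory is
deterministic for a given config and base seed:

    out/
      trajectories/<resolution>_v<velocity>_r<replicate>.csv (+ sidecars)
      metrics.csv
      shape_space.json
      pc_scores.csv
      latent_walk_pc1.csv, latent_walk_pc2.csv
      report.md (+ report_*.png panels)
      manifest.json       (config, seeds, content hashes, stage timings)

Stages that already produced their outputs are skipped on rerun, so a
partially completed run resumes where it stopped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .analysis import (DESK_VELOCITIES, PAPER_VELOCITIES, comparison_statistics,
                       make_seed, simulate_one)
from .geometry import generate_parametric_shape
from .metrics import measure_trajectory
from .shapespace import ShapeSpacePCA, collect_shape_samples

log = logging.getLogger("actinshape")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``preset="desk"`` is the default problem size (100 nm filament, the two
    fastest velocities, 5 replicates); ``preset="paper"`` selects the
    full-scale study (500 nm, velocities 4.7/15/47/150 um/s, 5 replicates),
    which takes hours at monomer resolution.
    """

    resolutions: tuple = ("monomer", "fiber")
    velocities: tuple = DESK_VELOCITIES
    replicates: int = 5
    filament_length: float = 100.0        # nm
    compression_fraction: float = 0.7
    seed: int = 0
    output_dir: str = "actinshape_run"
    preset: str | None = None
    n_frames_out: int = 50

    def __post_init__(self) -> None:
        if self.preset == "desk":
            self.velocities = DESK_VELOCITIES
            self.filament_length = 100.0
            self.replicates = 5
        elif self.preset == "paper":
            self.velocities = PAPER_VELOCITIES
            self.filament_length = 500.0
            self.replicates = 5
        elif self.preset is not None:
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(v <= 0 for v in self.velocities):
            raise ValueError("velocities must be > 0")
        bad = set(self.resolutions) - {"monomer", "fiber"}
        if bad:
            raise ValueError(f"unknown resolutions {sorted(bad)}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def trajectory_filename(resolution: str, velocity: float, replicate: int
                        ) -> str:
    return f"{resolution}_v{velocity:g}_r{replicate}.csv"


def run_pipeline(config: RunConfig, verbose: bool = False) -> Path:
    """Execute all stages; returns the output directory.

    Completed stages (existing outputs) are skipped, so interrupted runs
    resume. The manifest records the config, derived per-run seeds, content
    hashes of every product and per-stage wall time.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if verbose:
        logging.basicConfig(
            level=logging.INFO,
            format="%(asctime)s %(name)s %(levelname)s %(message)s")
    manifest: dict = {"config": config.to_dict(), "stages": {}, "seeds": {},
                      "hashes": {}}
    timings = {}

    # -- stage 1: simulate ------------------------------------------------
    t0 = time.time()
    traj_dir = out / "trajectories"
    traj_dir.mkdir(exist_ok=True)
    trajectories = []
    for ires, resolution in enumerate(config.resolutions):
        for iv, v in enumerate(config.velocities):
            for rep in range(config.replicates):
                fname = traj_dir / trajectory_filename(resolution, v, rep)
                seed = make_seed(config.seed, ires, iv, rep)
                manifest["seeds"][fname.name] = seed
                if fname.exists() and tio.sidecar_path(fname).exists():
                    log.info("simulate: reuse %s", fname.name)
                    trajectories.append(tio.read_trajectory(fname))
                    continue
                log.info("simulate: %s v=%g rep=%d seed=%d",
                         resolution, v, rep, seed)
                traj = simulate_one(
                    resolution, v, config.filament_length, seed,
                    replicate=rep,
                    compression_fraction=config.compression_fraction,
                    n_frames_out=config.n_frames_out)
                tio.write_trajectory(traj, fname)
                trajectories.append(traj)
    timings["simulate"] = time.time() - t0

    # -- stage 2: measure + align ----------------------------------------
    t0 = time.time()
    samples, metrics = collect_shape_samples(trajectories)
    tio.metrics_to_csv(metrics, out / "metrics.csv")
    timings["measure"] = time.time() - t0
    log.info("measure: %d frames", len(metrics))

    # -- stage 3: shape space --------------------------------------------
    t0 = time.time()
    space = ShapeSpacePCA(samples, metrics, n_components=6).fit()
    (out / "shape_space.json").write_text(json.dumps({
        "n_points": space.n_points,
        "mean_shape": space.mean_shape.tolist(),
        "components": space.components.tolist(),
        "explained_variance": space.explained_variance.tolist(),
        "explained_variance_ratio": space.explained_variance_ratio.tolist(),
    }, indent=1))
    scores = space.project()
    scores.to_csv(out / "pc_scores.csv", index=False)
    for k in (0, 1):
        rows = []
        for frame in space.latent_walk(k):
            s = frame.metadata["score"]
            for i, p in enumerate(frame.points):
                rows.append((s, i, p[0], p[1], p[2]))
        pd.DataFrame(rows, columns=["score", "point_index",
                                    "x_nm", "y_nm", "z_nm"]).to_csv(
            out / f"latent_walk_pc{k + 1}.csv", index=False)
    timings["pca"] = time.time() - t0
    log.info("pca: %s", np.array2string(space.explained_variance_ratio,
                                        precision=3))

    # -- stage 4: report --------------------------------------------------
    t0 = time.time()
    stats = comparison_statistics(metrics, space)
    _write_report(out, config, metrics, space, stats)
    timings["report"] = time.time() - t0

    manifest["stages"] = {k: round(v, 3) for k, v in timings.items()}
    manifest["stats"] = _jsonable_stats(stats)
    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json" and \
                f.suffix in (".csv", ".json", ".md"):
            manifest["hashes"][str(f.relative_to(out))] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return out


def _jsonable_stats(stats: dict) -> dict:
    out = {}
    for k, v in stats.items():
        if isinstance(v, (list, tuple)):
            out[k] = [float(x) for x in v]
        elif isinstance(v, (bool, np.bool_)):
            out[k] = bool(v)
        elif isinstance(v, (int, float, np.floating, np.integer)):
            out[k] = float(v)
        else:
            out[k] = v
    return out


def _write_report(out: Path, config: RunConfig, metrics: pd.DataFrame,
                  space, stats: dict) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"monomer": "tab:red", "fiber": "tab:blue"}

    # metric-vs-normalized-time panels
    panels = ["compression_ratio", "peak_asymmetry", "non_coplanarity",
              "supertwist_angle"]
    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharex=True)
    for ax, col in zip(axes.ravel(), panels):
        for (res, v, rep), grp in metrics.groupby(
                ["resolution", "velocity_um_s", "replicate"]):
            ax.plot(grp["normalized_time"], grp[col], lw=0.8,
                    color=colors[res], alpha=0.5)
        ax.set_title(col.replace("_", " "))
        ax.set_xlabel("normalized compression time")
    fig.tight_layout()
    fig.savefig(out / "report_metrics.png", dpi=110)
    plt.close(fig)

    # PC trajectories
    scores = space.project()
    fig, ax = plt.subplots(figsize=(6, 5))
    for (res, v, rep), grp in scores.groupby(
            ["source", "velocity_um_s", "replicate"]):
        ax.plot(grp["PC1"], grp["PC2"], lw=0.8, color=colors[res], alpha=0.5)
        ax.scatter(grp["PC1"].iloc[[0]], grp["PC2"].iloc[[0]], marker="D",
                   s=12, color=colors[res])
        ax.scatter(grp["PC1"].iloc[[-1]], grp["PC2"].iloc[[-1]], marker="o",
                   s=12, color=colors[res])
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    fig.tight_layout()
    fig.savefig(out / "report_pc_space.png", dpi=110)
    plt.close(fig)

    # latent walks (yz projections along each PC)
    fig, axes = plt.subplots(2, 5, figsize=(12, 5))
    for k in (0, 1):
        for j, frame in enumerate(space.latent_walk(k)):
            ax = axes[k, j]
            ax.plot(frame.points[:, 1], frame.points[:, 2], lw=1.5)
            ax.set_title(f"PC{k + 1} s={frame.metadata['score']:.0f}",
                         fontsize=8)
            ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(out / "report_latent_walks.png", dpi=110)
    plt.close(fig)

    lines = [
        "# Filament compression comparison report",
        "",
        f"- resolutions: {', '.join(config.resolutions)}",
        f"- velocities (um/s): {', '.join(str(v) for v in config.velocities)}",
        f"- replicates: {config.replicates}, filament {config.filament_length} nm, "
        f"compressed to {config.compression_fraction:.0%} of initial end-to-end",
        f"- base seed: {config.seed}",
        "",
        "## Headline statistics",
        "",
        "```",
        json.dumps(_jsonable_stats(stats), indent=1, sort_keys=True),
        "```",
        "",
        "## Panels",
        "",
        "![metrics](report_metrics.png)",
        "",
        "![PC space](report_pc_space.png)",
        "",
        "![latent walks](report_latent_walks.png)",
        "",
        "## Explained variance",
        "",
        "| PC | ratio |", "|----|-------|",
    ]
    for k, r in enumerate(space.explained_variance_ratio):
        lines.append(f"| PC{k + 1} | {r:.4f} |")
    (out / "report.md").write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def generate_fixtures(out_dir: str | Path) -> list[Path]:
    """Write the parametric shapes with ground-truth metric metadata.

    Produces a straight rod, a symmetric planar arc, and a right/left
    helical-coil pair whose supertwist metadata have equal magnitude and
    opposite sign. Each fixture is a single-frame trajectory CSV whose
    sidecar carries the analytic ground truth.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    shapes = {
        "straight": generate_parametric_shape("straight", length_nm=500.0,
                                              n_points=50),
        "planar_arc": generate_parametric_shape("planar_arc",
                                                end_to_end_nm=350.0,
                                                height_nm=80.0, n_points=50),
        "coil_right": generate_parametric_shape("helical_coil",
                                                length_nm=350.0,
                                                coil_radius_nm=40.0,
                                                winding_deg=60.0,
                                                n_points=50),
        "coil_left": generate_parametric_shape("helical_coil",
                                               length_nm=350.0,
                                               coil_radius_nm=40.0,
                                               winding_deg=-60.0,
                                               n_points=50),
    }
    written = []
    from .dynamics import Trajectory
    for name, frame in shapes.items():
        traj = Trajectory(frames=[frame], times=np.array([0.0]),
                          protocol=None, resolution_label="external",
                          metadata={"fixture": name,
                                    "ground_truth": {
                                        k: v for k, v in frame.metadata.items()
                                        if isinstance(v, (int, float, str))
                                        or v is None}})
        written.append(tio.write_trajectory(traj, out / f"{name}.csv"))
    return written
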