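"""Per-animal outputs: trajectory CSVs, event CSVs, plots, and a run summary.

For each ROI of an analysis run this writes the tidy per-frame kinematics
table, the bout/bend event table, and a trajectory plot, plus one
machine-readable JSON summary (config echo, seed, software version, config
hash) so every output is regenerable from (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import __version__
from .kinematics import KinematicConfig, TrajectorySeries, events_table, trajectory_table
from .roi import RoiGrid

__all__ = ["AnalysisRun", "export_outputs"]


@dataclass
class AnalysisRun:
    """One completed tracking/analysis run over a movie."""

    trajectories: list[TrajectorySeries]
    kin_cfg: KinematicConfig = field(default_factory=KinematicConfig)
    roi_grid: RoiGrid | None = None
    movie_ref: str = ""
    model_ref: str = ""
    seed: int | None = None
    config: dict = field(default_factory=dict)
    log: list[str] = field(default_factory=list)


def _config_hash(config: dict) -> str:
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _plot_trajectory(traj: TrajectorySeries, cfg: KinematicConfig, path: Path) -> None:
    pos = traj.keypoints[:, cfg.reference_keypoint, :]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(pos[:, 0], pos[:, 1], lw=0.8, color="tab:blue")
    ax.scatter([pos[0, 0]], [pos[0, 1]], s=12, color="tab:green", label="start", zorder=3)
    ax.scatter([pos[-1, 0]], [pos[-1, 1]], s=12, color="tab:red", label="end", zorder=3)
    ax.invert_yaxis()  # image coordinates: y down
    ax.set_aspect("equal")
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def export_outputs(run: AnalysisRun, outdir) -> Path:
    """Write all per-animal CSVs, plots, and the run summary under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, traj in enumerate(run.trajectories):
        tag = f"roi{i:03d}"
        trajectory_table(traj, run.kin_cfg).to_csv(
            outdir / f"{tag}_trajectory.csv", index=False, float_format="%.17g"
        )
        events_table(traj, run.kin_cfg).to_csv(
            outdir / f"{tag}_events.csv", index=False, float_format="%.17g"
        )
        _plot_trajectory(traj, run.kin_cfg, outdir / f"{tag}_trajectory.png")
    summary = {
        "software": f"finpose {__version__}",
        "movie": run.movie_ref,
        "model": run.model_ref,
        "seed": run.seed,
        "n_rois": len(run.trajectories),
        "kinematics": dataclasses.asdict(run.kin_cfg),
        "config": run.config,
        "config_hash": _config_hash(
            {"kinematics": dataclasses.asdict(run.kin_cfg), **run.config}
        ),
        "log": run.log,
    }
    (outdir / "run_summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return outdir
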