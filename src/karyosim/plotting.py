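"""Best-effort renderings of the three diagnostic diagram styles.

* ``broom`` — per-replicate traces of one quantity with a median overlay;
* ``marble`` — stacked per-step genotype composition percentages, coloured by
  the genotype RGB key, with detection/relapse markers;
* ``ratio`` — median apoptosis/division gene-ratio with a dispersion band.

Plotting is a convenience layer over the exported data series, not part of
the quantitative surface.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .dynamics import Trajectory
from .exceptions import DomainError
from .experiments import CohortSummary, ratio_series
from .karyotype import GenotypeState, rgb_color

__all__ = ["broom_plot", "marble_plot", "ratio_plot", "render_plots"]


def broom_plot(
    trajectories: Sequence[Trajectory],
    column: str = "population",
    path: Optional[Union[str, Path]] = None,
):
    """Overlay one per-step quantity across replicates with the median in black."""
    if not trajectories:
        raise DomainError("broom_plot needs at least one trajectory")
    fig, ax = plt.subplots(figsize=(7, 4))
    series = []
    for traj in trajectories:
        df = traj.to_frame()
        ax.plot(df["step"], df[column], lw=0.7, alpha=0.6)
        series.append(df.set_index("step")[column])
    joint = np.full((len(series), max(len(s) for s in series)), np.nan)
    for i, s in enumerate(series):
        joint[i, : len(s)] = s.to_numpy()
    # median drawn only while every replicate is still running
    full = ~np.isnan(joint).any(axis=0)
    med = np.nanmedian(joint, axis=0)
    ax.plot(np.arange(joint.shape[1])[full], med[full], color="black", lw=2)
    ax.set_xlabel("time step")
    ax.set_ylabel(column.replace("_", " "))
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def marble_plot(
    trajectory: Trajectory, path: Optional[Union[str, Path]] = None
):
    """Stacked genotype-composition percentages, coloured by the RGB key."""
    comps = [r.composition for r in trajectory.records]
    if any(c is None for c in comps):
        raise DomainError("marble_plot needs a trajectory recorded with composition")
    genotypes: set[GenotypeState] = set()
    for c in comps:
        genotypes.update(c)
    order = sorted(genotypes)
    max_state = GenotypeState(
        max(g.n_div for g in order), max(g.n_apop for g in order),
        max(g.n_seg for g in order),
    )
    steps = [r.step for r in trajectory.records]
    shares = np.zeros((len(order), len(steps)))
    for j, c in enumerate(comps):
        total = sum(c.values())
        if total == 0:
            continue
        for i, g in enumerate(order):
            shares[i, j] = 100.0 * c.get(g, 0) / total
    colors = [rgb_color(g, max_state) for g in order]
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.stackplot(steps, shares, colors=colors, lw=0)
    for marker, style in (
        (trajectory.detection_step, "-"),
        (trajectory.relapse_step, "--"),
    ):
        if marker is not None:
            ax.axvline(marker, color="black", ls=style, lw=1.5)
    ax.set_xlabel("time step")
    ax.set_ylabel("genotype share (%)")
    ax.set_ylim(0, 100)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def ratio_plot(
    cohort: CohortSummary, path: Optional[Union[str, Path]] = None
):
    """Median post-intervention apoptosis/division ratio with variance band."""
    if cohort.trajectories is None:
        raise DomainError("ratio_plot needs a cohort run with keep_trajectories")
    rows = []
    for traj in cohort.trajectories:
        if traj.intervention_step is not None:
            rows.append(ratio_series(traj))
    if not rows:
        raise DomainError("no treated replicates to plot")
    mat = np.vstack(rows)
    med = np.nanmedian(mat, axis=0)
    var = np.nanvar(mat, axis=0)
    x = np.arange(mat.shape[1])
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(x, med, color="black", lw=2)
    ax.fill_between(x, med - var, med + var, alpha=0.3)
    ax.set_xlabel("steps since intervention")
    ax.set_ylabel("apoptosis / division gene ratio")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def render_plots(
    source: Union[Trajectory, CohortSummary],
    out_dir: Union[str, Path],
    styles: Sequence[str] = ("broom", "marble", "ratio"),
) -> list[Path]:
    """Render whichever requested styles the source supports; return the files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if isinstance(source, Trajectory):
        if "broom" in styles:
            p = out / "broom.png"
            broom_plot([source], path=p)
            written.append(p)
        if "marble" in styles and source.records[0].composition is not None:
            p = out / "marble.png"
            marble_plot(source, path=p)
            written.append(p)
    else:
        if "broom" in styles and source.trajectories:
            p = out / "broom.png"
            broom_plot(source.trajectories, path=p)
            written.append(p)
        if "ratio" in styles and source.trajectories:
            try:
                p = out / "ratio.png"
                ratio_plot(source, path=p)
                written.append(p)
            except DomainError:
                pass
    return written
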