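"""Replicate cohorts, diversity and gene-ratio summaries, and the cohort t-test.

A cohort is ``n_replicates`` independently seeded runs of one configuration
(replicate ``i`` uses ``base_seed + i``).  Per replicate it records the
therapy outcome (residual cells, relapse time) and the slope of the
apoptosis/division mean-gene-count ratio over the 25 steps following the
intervention — the ratio falls as tumour suppressors are lost and oncogenes
gained, so a steeper negative slope marks faster malignant progression.
Two cohorts are compared with the classical unpaired, equal-variance,
two-tailed t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .dynamics import SimulationConfig, Trajectory, run_simulation
from .exceptions import DomainError
from .karyotype import GenotypeState
from .therapy import TherapyOutcome, therapy_outcome

__all__ = [
    "CohortSpec",
    "CohortSummary",
    "genotype_diversity",
    "shannon_diversity",
    "ratio_series",
    "ratio_slope",
    "unpaired_ttest",
    "run_cohort",
    "compare_cohorts",
]

RATIO_WINDOW = 25


def genotype_diversity(composition: Mapping[GenotypeState, int]) -> int:
    """Number of distinct genotype states present (richness)."""
    return sum(1 for count in composition.values() if count > 0)


def shannon_diversity(composition: Mapping[GenotypeState, int]) -> float:
    """Shannon entropy (nats) of the genotype composition, for robustness."""
    counts = np.array([c for c in composition.values() if c > 0], dtype=float)
    if counts.size == 0:
        return 0.0
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def ratio_series(trajectory: Trajectory, window: int = RATIO_WINDOW) -> np.ndarray:
    """Apoptosis/division mean-gene-count ratio over the post-intervention window.

    Index 0 is the intervention step itself.  Steps where the mean division
    count is zero, or beyond the end of the run, yield NaN.
    """
    if trajectory.intervention_step is None:
        raise DomainError("ratio_series requires a treated trajectory")
    start = trajectory.intervention_step
    out = np.full(window, np.nan)
    for k in range(window):
        idx = start + k
        if idx >= len(trajectory.records):
            break
        rec = trajectory.records[idx]  # records[i] is step i (step 0 baseline)
        if rec.mean_div > 0:
            out[k] = rec.mean_apop / rec.mean_div
    return out


def ratio_slope(series: Sequence[float], window: int = RATIO_WINDOW) -> float:
    """Ordinary least-squares slope of the ratio against the step index.

    Only the first ``window`` points are used; NaN points (undefined ratio or
    a run that ended inside the window) are dropped.  At least two defined
    points are required.
    """
    y = np.asarray(series, dtype=float)[:window]
    x = np.arange(y.size, dtype=float)
    ok = np.isfinite(y)
    if ok.sum() < 2:
        raise DomainError("ratio_slope needs at least two defined points")
    slope = np.polyfit(x[ok], y[ok], 1)[0]
    return float(slope)


def unpaired_ttest(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float]:
    """Classical unpaired two-sample t-test: equal variance, two-tailed.

    Returns ``(t, p)`` with ``n_a + n_b - 2`` degrees of freedom, computed
    from the pooled-variance closed form.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise DomainError("each sample needs at least two observations")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    if pooled <= 0:
        raise DomainError("degenerate (zero) pooled variance")
    t = (a.mean() - b.mean()) / math.sqrt(pooled * (1.0 / na + 1.0 / nb))
    p = 2.0 * float(scipy.stats.t.sf(abs(t), na + nb - 2))
    return float(t), p


@dataclass(frozen=True)
class CohortSpec:
    """A batch of replicates of one configuration, seeded ``base_seed + i``."""

    base_config: SimulationConfig
    n_replicates: int = 100
    keep_trajectories: bool = False

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise DomainError("n_replicates must be >= 1")

    def replicate_seed(self, i: int) -> int:
        return self.base_config.seed + i


@dataclass
class CohortSummary:
    """Per-replicate outcomes plus the derived cohort statistics."""

    spec: CohortSpec
    outcomes: list[TherapyOutcome]
    slopes: list[Optional[float]]
    terminations: list[str]
    seeds: list[int]
    trajectories: Optional[list[Trajectory]] = None
    chemo_kill_fractions: list[Optional[float]] = field(default_factory=list)
    end_steps: list[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (o, s, term, seed) in enumerate(
            zip(self.outcomes, self.slopes, self.terminations, self.seeds)
        ):
            rows.append(
                {
                    "replicate": i,
                    "seed": seed,
                    "scenario": o.scenario,
                    "detection_step": o.detection_step,
                    "cells_at_detection": o.cells_at_detection,
                    "cells_post_intervention": o.cells_post_intervention,
                    "relapse_step": o.relapse_step,
                    "relapse_time": o.relapse_time,
                    "censored": o.censored,
                    "ratio_slope": s,
                    "chemo_kill_fraction": (
                        self.chemo_kill_fractions[i]
                        if i < len(self.chemo_kill_fractions)
                        else None
                    ),
                    "termination": term,
                }
            )
        return pd.DataFrame(rows)

    # -- scalar statistics ---------------------------------------------------

    def relapse_times(self, include_censored: bool = False) -> np.ndarray:
        """Observed relapse times; censored replicates are dropped unless
        ``include_censored``, in which case they contribute their (lower
        bound) time to run end."""
        out = []
        for i, o in enumerate(self.outcomes):
            if o.relapse_time is not None:
                out.append(float(o.relapse_time))
            elif include_censored and o.detection_step is not None and i < len(self.end_steps):
                # lower bound: steps observed between intervention and run end
                intervention = o.detection_step + 1
                out.append(float(max(0, self.end_steps[i] - intervention)))
        return np.asarray(out, dtype=float)

    def residual_cells(self) -> np.ndarray:
        vals = [
            o.cells_post_intervention
            for o in self.outcomes
            if o.cells_post_intervention is not None
        ]
        return np.asarray(vals, dtype=float)

    def slope_values(self) -> np.ndarray:
        return np.asarray([s for s in self.slopes if s is not None], dtype=float)

    def kill_fraction_values(self) -> np.ndarray:
        return np.asarray(
            [k for k in self.chemo_kill_fractions if k is not None], dtype=float
        )

    def stats(self) -> dict:
        """Cohort means and sample (n-1) standard deviations."""
        def _ms(x: np.ndarray) -> dict:
            if x.size == 0:
                return {"n": 0, "mean": None, "std": None}
            return {
                "n": int(x.size),
                "mean": float(x.mean()),
                "std": float(x.std(ddof=1)) if x.size > 1 else 0.0,
            }

        return {
            "n_replicates": self.spec.n_replicates,
            "relapse_time": _ms(self.relapse_times()),
            "residual_cells": _ms(self.residual_cells()),
            "ratio_slope": _ms(self.slope_values()),
            "chemo_kill_fraction": _ms(self.kill_fraction_values()),
            "n_censored": int(sum(1 for o in self.outcomes if o.censored)),
            "n_detected": int(
                sum(1 for o in self.outcomes if o.detection_step is not None)
            ),
            "terminations": {
                t: self.terminations.count(t) for t in set(self.terminations)
            },
        }


def _chemo_kill_fraction(traj: Trajectory) -> Optional[float]:
    """Mean over active chemo steps of kills / step-start population."""
    if not traj.chemo_steps:
        return None
    fractions = []
    for step in traj.chemo_steps:
        if step >= len(traj.records):
            break
        start_pop = traj.records[step - 1].population
        if start_pop > 0:
            fractions.append(traj.records[step].chemo_kills / start_pop)
    if not fractions:
        return None
    return float(np.mean(fractions))


def run_cohort(spec: CohortSpec) -> CohortSummary:
    """Run every replicate and collect outcomes, slopes and kill fractions.

    Deterministic given the base seed: replicate ``i`` always runs with seed
    ``base_seed + i`` on an otherwise identical configuration.
    """
    outcomes: list[TherapyOutcome] = []
    slopes: list[Optional[float]] = []
    kills: list[Optional[float]] = []
    terms: list[str] = []
    seeds: list[int] = []
    ends: list[int] = []
    trajs: Optional[list[Trajectory]] = [] if spec.keep_trajectories else None
    for i in range(spec.n_replicates):
        seed = spec.replicate_seed(i)
        traj = run_simulation(spec.base_config.with_seed(seed))
        outcomes.append(therapy_outcome(traj))
        if traj.intervention_step is not None:
            try:
                slopes.append(ratio_slope(ratio_series(traj)))
            except DomainError:
                slopes.append(None)
        else:
            slopes.append(None)
        kills.append(_chemo_kill_fraction(traj))
        terms.append(traj.termination_reason)
        seeds.append(seed)
        ends.append(traj.records[-1].step)
        if trajs is not None:
            trajs.append(traj)
    return CohortSummary(
        spec=spec,
        outcomes=outcomes,
        slopes=slopes,
        terminations=terms,
        seeds=seeds,
        trajectories=trajs,
        chemo_kill_fractions=kills,
        end_steps=ends,
    )


def compare_cohorts(a: CohortSummary, b: CohortSummary) -> dict:
    """Unpaired t-tests on relapse times and ratio slopes between two cohorts."""
    out: dict = {"a": a.stats(), "b": b.stats()}
    ra, rb = a.relapse_times(), b.relapse_times()
    if ra.size >= 2 and rb.size >= 2:
        t, p = unpaired_ttest(ra, rb)
        out["relapse_time_ttest"] = {"t": t, "p": p}
    sa, sb = a.slope_values(), b.slope_values()
    if sa.size >= 2 and sb.size >= 2:
        t, p = unpaired_ttest(sa, sb)
        out["ratio_slope_ttest"] = {"t": t, "p": p}
    return out
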