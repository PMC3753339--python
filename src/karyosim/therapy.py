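"""Tumour detection, the three intervention scenarios and relapse bookkeeping.

A tumour is "detected" the first time the end-of-step population reaches the
detection threshold (1000 cells by default); the planned intervention then
executes at the start of the following step, at most once per run:

* **surgery** keeps the first 100 listed cells, deletes the next contiguous
  900, and keeps any overshoot tail (list segments are lineage-correlated, so
  this mimics excising the tumour bulk);
* **chemotherapy** kills every cell that attempts division during the nine
  consecutive steps after detection (an anti-mitotic abstraction);
* **combination** is surgery followed immediately by the nine chemotherapy
  rounds.

Relapse is the population re-reaching the detection threshold, timed from the
intervention step (for the combination, the surgery step).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .dynamics import Tissue, Trajectory
from .exceptions import ConfigurationError, DomainError

__all__ = [
    "SCENARIOS",
    "TherapyPlan",
    "TherapyOutcome",
    "detect_tumour",
    "apply_surgery",
    "chemo_window",
    "relapse_time",
    "therapy_outcome",
]

SCENARIOS = ("none", "surgery", "chemotherapy", "combination")


@dataclass(frozen=True)
class TherapyPlan:
    """What to do once the tumour is detected."""

    scenario: str = "none"
    detection_threshold: int = 1000
    surgery_removal: int = 900
    surgery_keep_head: int = 100
    chemo_rounds: int = 9

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ConfigurationError(
                f"unknown therapy scenario {self.scenario!r}; "
                f"expected one of {SCENARIOS}"
            )
        if min(self.detection_threshold, self.surgery_removal,
               self.surgery_keep_head, self.chemo_rounds) < 0:
            raise ConfigurationError("therapy plan fields must be non-negative")
        if self.surgery_keep_head + self.surgery_removal != self.detection_threshold:
            raise ConfigurationError(
                "surgery_keep_head + surgery_removal must equal the "
                f"detection threshold; got {self.surgery_keep_head} + "
                f"{self.surgery_removal} != {self.detection_threshold}"
            )


@dataclass(frozen=True)
class TherapyOutcome:
    """Per-replicate therapy summary extracted from a trajectory."""

    scenario: str
    detection_step: Optional[int]
    cells_at_detection: Optional[int]
    cells_post_intervention: Optional[int]
    relapse_step: Optional[int]
    relapse_time: Optional[int]
    censored: bool


def detect_tumour(population: int, plan: TherapyPlan, already_treated: bool) -> bool:
    """True when the population first reaches the detection threshold.

    Detection (and hence intervention) fires at most once per run.
    """
    return (not already_treated) and population >= plan.detection_threshold


def apply_surgery(tissue: Tissue, plan: TherapyPlan) -> Tissue:
    """Excise the tumour bulk from the cell list in a single time step.

    The first ``surgery_keep_head`` cells survive, the next contiguous
    ``surgery_removal`` cells are deleted, and any cells beyond that window
    (detection overshoot) survive as well, order preserved.
    """
    needed = plan.surgery_keep_head + plan.surgery_removal
    if tissue.population < needed:
        raise DomainError(
            f"surgery needs at least {needed} cells, tissue has {tissue.population}"
        )
    keep = list(range(plan.surgery_keep_head)) + list(
        range(needed, tissue.population)
    )
    return Tissue(
        tissue.distribution,
        tissue.counts[keep],
        tissue.capacity,
        tissue.ids[keep],
        tissue.parents[keep],
        tissue.next_id,
    )


def chemo_window(detection_step: int, plan: TherapyPlan) -> range:
    """The steps during which chemotherapy is active.

    Exactly ``chemo_rounds`` consecutive steps beginning the step after
    detection: detection at step ``t`` gives the window ``t+1 .. t+rounds``.
    """
    return range(detection_step + 1, detection_step + 1 + plan.chemo_rounds)


def relapse_time(trajectory: Trajectory, plan: Optional[TherapyPlan] = None) -> Optional[int]:
    """Steps from the intervention until the population re-reaches detection size.

    Returns ``None`` when the run ended before relapse (censored).  Calling
    this on an untreated trajectory is a domain error.
    """
    if trajectory.intervention_step is None:
        raise DomainError("relapse_time is undefined for an untreated trajectory")
    if trajectory.relapse_step is None:
        return None
    return trajectory.relapse_step - trajectory.intervention_step


def therapy_outcome(trajectory: Trajectory) -> TherapyOutcome:
    """Summarise a treated (or untreated) trajectory into one outcome row."""
    plan = trajectory.config.therapy
    scenario = plan.scenario if plan is not None else "none"
    if trajectory.intervention_step is None:
        return TherapyOutcome(scenario, trajectory.detection_step,
                              trajectory.cells_at_detection, None, None, None,
                              censored=True)
    rt = relapse_time(trajectory)
    return TherapyOutcome(
        scenario=scenario,
        detection_step=trajectory.detection_step,
        cells_at_detection=trajectory.cells_at_detection,
        cells_post_intervention=trajectory.cells_post_intervention,
        relapse_step=trajectory.relapse_step,
        relapse_time=rt,
        censored=rt is None,
    )
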