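"""The stochastic engine: per-cell probability rules and synchronous updates.

Each time step freezes the population count, then visits every cell in list
order and applies three conditional Bernoulli draws:

1. *death* — only while the tissue is over its homeostatic capacity, with
   probability increasing in the cell's apoptosis-gene dose;
2. *division* — a surviving cell divides with probability increasing in its
   division-gene dose (during an active chemotherapy step a would-be divider
   is killed instead of dividing);
3. *mis-segregation* — a dividing cell mis-segregates one chromosome with
   probability decreasing in its segregation-gene dose.

Daughters are inserted adjacent to the mother's list position and are not
re-examined until the next step.  The tissue is stored column-wise as numpy
arrays (one row of chromosome copy counts per cell, in list order) so a step
is a handful of vectorised operations; the object layer (:class:`Cell`,
:meth:`Tissue.cells`) is a view over those arrays.

Random draws per step occur in a fixed, documented order — death uniforms,
division uniforms, mis-segregation uniforms (each one per cell), then one
chromosome choice and one placement coin per mis-segregating cell — so a run
is bit-reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DomainError
from .karyotype import (
    GeneDistribution,
    Genome,
    GenotypeState,
    make_initial_genome,
)

__all__ = [
    "RateParams",
    "Cell",
    "Tissue",
    "SimulationConfig",
    "StepRecord",
    "Trajectory",
    "apoptosis_probability",
    "division_probability",
    "missegregation_probability",
    "step_tissue",
    "run_simulation",
]

_DOSE_RESPONSES = ("linear", "exponential")
_SAMPLINGS = ("copy", "type")


@dataclass(frozen=True)
class RateParams:
    """Per-gene-copy rate parameters of the three probability rules.

    ``alpha`` scales crowding-gated death per apoptosis-gene copy, ``delta``
    scales division per division-gene copy, and ``mu`` is the mis-segregation
    rate of a diploid (two segregation-gene) cell.  ``dose_response`` selects
    the functional form family (``"linear"`` is the default; ``"exponential"``
    uses saturating ``1 - exp(-rate * n)`` doses for death and division).
    ``crowding_division_scale`` optionally multiplies the division probability
    while the tissue is over capacity (1.0 = crowding acts through death only).
    """

    alpha: float = 0.045
    delta: float = 0.045
    mu: float = 0.02
    dose_response: str = "linear"
    missegregation_sampling: str = "copy"
    crowding_division_scale: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha", "delta", "mu"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.dose_response not in _DOSE_RESPONSES:
            raise ConfigurationError(
                f"unknown dose_response {self.dose_response!r}; "
                f"expected one of {_DOSE_RESPONSES}"
            )
        if self.missegregation_sampling not in _SAMPLINGS:
            raise ConfigurationError(
                f"unknown missegregation_sampling "
                f"{self.missegregation_sampling!r}; expected one of {_SAMPLINGS}"
            )
        if not 0.0 <= self.crowding_division_scale <= 1.0:
            raise ConfigurationError("crowding_division_scale must lie in [0, 1]")


# -- probability rules -------------------------------------------------------

def _death_dose(n_apop: np.ndarray, params: RateParams) -> np.ndarray:
    if params.dose_response == "exponential":
        return 1.0 - np.exp(-params.alpha * n_apop)
    return np.clip(params.alpha * n_apop, 0.0, 1.0)


def _division_dose(n_div: np.ndarray, params: RateParams) -> np.ndarray:
    if params.dose_response == "exponential":
        return 1.0 - np.exp(-params.delta * n_div)
    return np.clip(params.delta * n_div, 0.0, 1.0)


def _missegregation_dose(n_seg: np.ndarray, params: RateParams) -> np.ndarray:
    n = np.asarray(n_seg, dtype=float)
    with np.errstate(divide="ignore"):
        p = np.where(n > 0, 2.0 * params.mu / np.maximum(n, 1e-300), 1.0)
    return np.clip(p, 0.0, 1.0)


def apoptosis_probability(
    state: GenotypeState, population: int, params: RateParams, capacity: int
) -> float:
    """Per-step death probability: zero at or below capacity, then dose in n_apop.

    Crowding is a strict gate — death is only possible while the frozen
    population count exceeds the homeostatic capacity.
    """
    if population < 0:
        raise DomainError("population must be non-negative")
    if population <= capacity:
        return 0.0
    return float(_death_dose(np.asarray(state.n_apop), params))


def division_probability(state: GenotypeState, params: RateParams) -> float:
    """Per-step division probability: dose in the division-gene count.

    Under the default linear form the dose is ``min(1, delta * n_div)``, so a
    cell with six division genes divides three times as often as the diploid.
    """
    return float(_division_dose(np.asarray(state.n_div), params))


def missegregation_probability(state: GenotypeState, params: RateParams) -> float:
    """Probability a division mis-segregates: decreasing in the segregation dose.

    Calibrated so the diploid (n_seg = 2) rate equals ``mu``; a cell that has
    lost every segregation gene mis-segregates at every division.
    """
    return float(_missegregation_dose(np.asarray(state.n_seg), params))


# -- tissue ------------------------------------------------------------------

@dataclass(frozen=True)
class Cell:
    """Object view of one agent: genome, cached genotype state and lineage ids."""

    id: int
    parent_id: int
    genome: Genome

    @property
    def state(self) -> GenotypeState:
        return self.genome.state()


class Tissue:
    """An ordered population of cells (the linked list) with a fixed capacity.

    List order is meaningful: daughters are adjacent to their mother, so
    contiguous segments are lineage-correlated — which is what makes surgical
    removal of a contiguous segment biologically sensible.
    """

    def __init__(
        self,
        distribution: GeneDistribution,
        counts: np.ndarray,
        capacity: int,
        ids: Optional[np.ndarray] = None,
        parents: Optional[np.ndarray] = None,
        next_id: Optional[int] = None,
    ) -> None:
        counts = np.asarray(counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[1] != distribution.n_types:
            raise ConfigurationError(
                f"counts must be (n_cells, {distribution.n_types}), "
                f"got {counts.shape}"
            )
        self.distribution = distribution
        self.counts = counts
        self.capacity = int(capacity)
        n = counts.shape[0]
        self.ids = np.arange(n, dtype=np.int64) if ids is None else np.asarray(ids, dtype=np.int64)
        self.parents = (
            np.full(n, -1, dtype=np.int64) if parents is None else np.asarray(parents, dtype=np.int64)
        )
        self.next_id = int(n if next_id is None else next_id)

    @classmethod
    def initial(
        cls, distribution: GeneDistribution, n_cells: int, capacity: int
    ) -> "Tissue":
        """A founding population of identical diploid cells."""
        diploid = make_initial_genome(distribution)
        counts = np.tile(np.asarray(diploid.copy_counts, dtype=np.int64), (n_cells, 1))
        return cls(distribution, counts, capacity)

    @property
    def population(self) -> int:
        return self.counts.shape[0]

    def __len__(self) -> int:
        return self.population

    def states(self) -> np.ndarray:
        """(n_cells, 3) genotype states in list order."""
        return self.counts @ self.distribution.content_matrix

    def mean_state(self) -> tuple[float, float, float]:
        if self.population == 0:
            return (0.0, 0.0, 0.0)
        m = self.states().mean(axis=0)
        return (float(m[0]), float(m[1]), float(m[2]))

    def composition(self) -> dict[GenotypeState, int]:
        """Counts of cells per distinct genotype state."""
        if self.population == 0:
            return {}
        uniq, cnt = np.unique(self.states(), axis=0, return_counts=True)
        return {
            GenotypeState(int(r[0]), int(r[1]), int(r[2])): int(c)
            for r, c in zip(uniq, cnt)
        }

    def cells(self) -> Iterator[Cell]:
        for i in range(self.population):
            yield Cell(
                id=int(self.ids[i]),
                parent_id=int(self.parents[i]),
                genome=Genome(self.distribution, tuple(int(c) for c in self.counts[i])),
            )

    def __getitem__(self, i: int) -> Cell:
        return Cell(
            id=int(self.ids[i]),
            parent_id=int(self.parents[i]),
            genome=Genome(self.distribution, tuple(int(c) for c in self.counts[i])),
        )


# -- records -----------------------------------------------------------------

@dataclass(frozen=True)
class StepRecord:
    """End-of-step snapshot plus the event tallies that produced it."""

    step: int
    population: int
    mean_div: float
    mean_apop: float
    mean_seg: float
    deaths: int
    divisions: int
    missegregations: int
    chemo_kills: int
    n_genotypes: int
    composition: Optional[dict[GenotypeState, int]] = None


@dataclass
class Trajectory:
    """One full run: the per-step records and its event markers."""

    config: "SimulationConfig"
    records: list[StepRecord] = field(default_factory=list)
    detection_step: Optional[int] = None
    intervention_step: Optional[int] = None
    chemo_steps: tuple[int, ...] = ()
    relapse_step: Optional[int] = None
    termination_reason: str = "max_steps"
    cells_at_detection: Optional[int] = None
    cells_post_surgery: Optional[int] = None
    cells_post_chemo: Optional[int] = None
    final_tissue: Optional[Tissue] = None

    @property
    def cells_post_intervention(self) -> Optional[int]:
        """Population right after the full intervention.

        Post-removal count for surgery alone; end of the last chemotherapy
        step for chemotherapy and for the combination.
        """
        if self.cells_post_chemo is not None:
            return self.cells_post_chemo
        return self.cells_post_surgery

    def to_frame(self) -> pd.DataFrame:
        """Wide per-step table (one row per step, composition excluded)."""
        return pd.DataFrame(
            {
                "step": [r.step for r in self.records],
                "population": [r.population for r in self.records],
                "mean_div": [r.mean_div for r in self.records],
                "mean_apop": [r.mean_apop for r in self.records],
                "mean_seg": [r.mean_seg for r in self.records],
                "deaths": [r.deaths for r in self.records],
                "divisions": [r.divisions for r in self.records],
                "missegregations": [r.missegregations for r in self.records],
                "chemo_kills": [r.chemo_kills for r in self.records],
                "n_genotypes": [r.n_genotypes for r in self.records],
            }
        )

    def composition_frame(self) -> pd.DataFrame:
        """Long per-step genotype composition (requires record_composition)."""
        rows = []
        for r in self.records:
            if r.composition is None:
                continue
            for state, count in sorted(r.composition.items()):
                rows.append(
                    (r.step, state.n_div, state.n_apop, state.n_seg, count)
                )
        return pd.DataFrame(
            rows, columns=["step", "n_div", "n_apop", "n_seg", "count"]
        )


# -- configuration -----------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Everything one run needs; defaults are the reference experiment.

    A run starts from ``initial_population`` diploid cells, homeostatic
    ``capacity`` 200, and ends on reaching ``max_population`` (7000) cells,
    ``max_steps`` (300) steps, or extinction.  ``detection_threshold`` (1000)
    is the tumour-detection size used by the therapy plan, if any.
    """

    distribution: GeneDistribution
    rates: RateParams = RateParams()
    initial_population: int = 100
    capacity: int = 200
    detection_threshold: int = 1000
    max_population: int = 7000
    max_steps: int = 300
    therapy: Optional["TherapyPlan"] = None  # noqa: F821 - therapy module
    seed: int = 0
    record_composition: bool = True
    keep_final_tissue: bool = False

    def __post_init__(self) -> None:
        if not (
            0
            < self.initial_population
            <= self.capacity
            < self.detection_threshold
            <= self.max_population
        ):
            raise ConfigurationError(
                "require 0 < initial_population <= capacity < "
                f"detection_threshold <= max_population; got "
                f"{self.initial_population}, {self.capacity}, "
                f"{self.detection_threshold}, {self.max_population}"
            )
        if self.max_steps <= 0:
            raise ConfigurationError("max_steps must be positive")
        if self.therapy is not None:
            if self.therapy.detection_threshold != self.detection_threshold:
                raise ConfigurationError(
                    "therapy plan and simulation disagree on the detection threshold"
                )

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


# -- the synchronous update --------------------------------------------------

def step_tissue(
    tissue: Tissue,
    params: RateParams,
    chemo_active: bool = False,
    rng: Optional[np.random.Generator] = None,
    step: int = 0,
    record_composition: bool = False,
) -> tuple[Tissue, StepRecord]:
    """Apply one synchronous update and return the new tissue and its record.

    The population count is frozen at step start; every cell is judged against
    that count in list order.  A dying cell leaves the list; a dividing cell
    is replaced in place by its two daughters (mis-segregated or faithful);
    during chemotherapy a would-be divider is killed instead.  A daughter left
    with zero chromosomes of every type is nonviable and is dropped at birth.
    """
    if rng is None:
        rng = np.random.default_rng()
    dist = tissue.distribution
    counts = tissue.counts
    n = counts.shape[0]
    if n == 0:
        rec = StepRecord(step, 0, 0.0, 0.0, 0.0, 0, 0, 0, 0, 0,
                         {} if record_composition else None)
        return tissue, rec

    m = dist.content_matrix
    states = counts @ m
    if n > tissue.capacity:
        p_death = _death_dose(states[:, 1], params)
    else:
        p_death = np.zeros(n)
    p_div = _division_dose(states[:, 0], params)
    if n > tissue.capacity and params.crowding_division_scale != 1.0:
        p_div = p_div * params.crowding_division_scale
    p_mis = _missegregation_dose(states[:, 2], params)

    dies = rng.random(n) < p_death
    attempts = (~dies) & (rng.random(n) < p_div)
    if chemo_active:
        chemo_killed = attempts
        divides = np.zeros(n, dtype=bool)
    else:
        chemo_killed = np.zeros(n, dtype=bool)
        divides = attempts
    mis = divides & (rng.random(n) < p_mis)

    reps = np.ones(n, dtype=np.intp)
    reps[dies | chemo_killed] = 0
    reps[divides] = 2
    starts = np.cumsum(reps) - reps  # output row of each cell's first copy

    new_counts = np.repeat(counts, reps, axis=0)
    new_ids = np.repeat(tissue.ids, reps)
    new_parents = np.repeat(tissue.parents, reps)

    next_id = tissue.next_id
    div_idx = np.flatnonzero(divides)
    if div_idx.size:
        d1 = starts[div_idx]
        d2 = d1 + 1
        kd = div_idx.size
        fresh = np.arange(next_id, next_id + 2 * kd, dtype=np.int64)
        next_id += 2 * kd
        new_ids[d1] = fresh[:kd]
        new_ids[d2] = fresh[kd:]
        new_parents[d1] = tissue.ids[div_idx]
        new_parents[d2] = tissue.ids[div_idx]

    mis_idx = np.flatnonzero(mis)
    n_missegregations = int(mis_idx.size)
    drop_rows: np.ndarray = np.empty(0, dtype=np.intp)
    if mis_idx.size:
        cmat = counts[mis_idx]
        if params.missegregation_sampling == "copy":
            tot = cmat.sum(axis=1)
            r = rng.random(mis_idx.size) * tot
            chosen = (r[:, None] >= np.cumsum(cmat, axis=1)).sum(axis=1)
        else:
            present = cmat > 0
            n_present = present.sum(axis=1)
            r = np.floor(rng.random(mis_idx.size) * n_present)
            chosen = (r[:, None] >= np.cumsum(present, axis=1)).sum(axis=1)
        first_gains = rng.random(mis_idx.size) < 0.5
        m1 = starts[mis_idx]
        m2 = m1 + 1
        gain_pos = np.where(first_gains, m1, m2)
        lose_pos = np.where(first_gains, m2, m1)
        new_counts[gain_pos, chosen] += 1
        new_counts[lose_pos, chosen] -= 1
        nonviable = new_counts[lose_pos].sum(axis=1) == 0
        drop_rows = lose_pos[nonviable]

    if drop_rows.size:
        keep = np.ones(new_counts.shape[0], dtype=bool)
        keep[drop_rows] = False
        new_counts = new_counts[keep]
        new_ids = new_ids[keep]
        new_parents = new_parents[keep]

    new_tissue = Tissue(
        dist, new_counts, tissue.capacity, new_ids, new_parents, next_id
    )
    pop = new_counts.shape[0]
    if pop:
        new_states = new_counts @ m
        means = new_states.mean(axis=0)
        n_genotypes = int(np.unique(new_counts, axis=0).shape[0])
    else:
        means = np.zeros(3)
        n_genotypes = 0
    rec = StepRecord(
        step=step,
        population=pop,
        mean_div=float(means[0]),
        mean_apop=float(means[1]),
        mean_seg=float(means[2]),
        deaths=int(dies.sum()),
        divisions=int(divides.sum()),
        missegregations=n_missegregations,
        chemo_kills=int(chemo_killed.sum()),
        n_genotypes=n_genotypes,
        composition=new_tissue.composition() if record_composition else None,
    )
    return new_tissue, rec


# -- whole-run driver --------------------------------------------------------

def _baseline_record(tissue: Tissue, record_composition: bool) -> StepRecord:
    mean = tissue.mean_state()
    return StepRecord(
        step=0,
        population=tissue.population,
        mean_div=mean[0],
        mean_apop=mean[1],
        mean_seg=mean[2],
        deaths=0,
        divisions=0,
        missegregations=0,
        chemo_kills=0,
        n_genotypes=int(np.unique(tissue.counts, axis=0).shape[0]),
        composition=tissue.composition() if record_composition else None,
    )


def run_simulation(config: SimulationConfig) -> Trajectory:
    """Run one seeded replicate to termination.

    Therapy orchestration: the population is examined at the end of each step;
    once it first reaches the detection threshold the planned intervention
    executes at the start of the next step (surgery removes its segment there;
    chemotherapy is active for the plan's number of consecutive steps starting
    at that step).  Relapse is the first end-of-step population at or above
    the detection threshold from the intervention step onward.
    """
    from .therapy import apply_surgery, detect_tumour  # cycle-free at runtime

    rng = np.random.default_rng(config.seed)
    tissue = Tissue.initial(
        config.distribution, config.initial_population, config.capacity
    )
    traj = Trajectory(config=config)
    traj.records.append(_baseline_record(tissue, config.record_composition))

    plan = config.therapy
    pending = False
    chemo_first: Optional[int] = None
    chemo_last: Optional[int] = None
    reason = "max_steps"

    for step in range(1, config.max_steps + 1):
        if pending:
            traj.intervention_step = step
            if plan.scenario in ("surgery", "combination"):
                tissue = apply_surgery(tissue, plan)
                traj.cells_post_surgery = tissue.population
            if plan.scenario in ("chemotherapy", "combination"):
                chemo_first = step
                chemo_last = step + plan.chemo_rounds - 1
                traj.chemo_steps = tuple(range(chemo_first, chemo_last + 1))
            pending = False
        chemo_active = chemo_first is not None and chemo_first <= step <= chemo_last
        tissue, rec = step_tissue(
            tissue,
            config.rates,
            chemo_active=chemo_active,
            rng=rng,
            step=step,
            record_composition=config.record_composition,
        )
        traj.records.append(rec)
        pop = rec.population
        if chemo_last is not None and step == chemo_last:
            traj.cells_post_chemo = pop
        if (
            plan is not None
            and plan.scenario != "none"
            and detect_tumour(pop, plan, already_treated=traj.detection_step is not None)
        ):
            traj.detection_step = step
            traj.cells_at_detection = pop
            pending = True
        if (
            traj.intervention_step is not None
            and traj.relapse_step is None
            and pop >= config.detection_threshold
        ):
            traj.relapse_step = step
        if pop == 0:
            reason = "extinction"
            break
        if pop >= config.max_population:
            reason = "max_population"
            break
    else:
        reason = "max_steps"

    traj.termination_reason = reason
    if config.keep_final_tissue:
        traj.final_tissue = tissue
    return traj
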