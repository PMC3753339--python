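# Methods

## Model overview and assumptions

karyosim models a homeostatic tissue as an ordered list of cell agents and
asks how whole-chromosome mis-segregation reshapes it into a tumour.  The
deliberate simplifications are:

- **One gene class per behaviour, dose-proportional action.**  Cell death,
  division and segregation fidelity are each governed by a single abstract
  gene class, and the per-step probability of each behaviour depends only on
  the cell's total copy number of that class.  Sub-chromosomal mutation
  (substitutions, indels, translocations) is excluded: the only mutational
  event is the gain/loss of one whole chromosome at division.
- **Linkage as the experimental variable.**  Chromosome types carry fixed
  gene bundles, and the chromosome types of a layout partition the three
  classes (each class sits on exactly one type).  Under layout A every
  reachable genotype has n_div = n_apop, under B n_div = n_seg, under C
  n_apop = n_seg — these invariants are property-tested.
- **No explicit space.**  The list order is the only spatial structure:
  daughters are inserted adjacent to the mother, so contiguous segments are
  lineage-correlated.  This is what gives surgical removal of a contiguous
  segment (and the retained "field" of related pre-malignant cells) its
  meaning.
- **Synchronous conditional updates.**  The population count N is frozen at
  step start.  Per cell, in list order: death is drawn first (only when N
  exceeds the capacity K), division only for survivors, mis-segregation only
  for dividers.  A cell that dies in a step never divides in it; daughters
  are not re-examined until the next step.

## Probability rules and parameters

| parameter | meaning | default | units |
| --- | --- | --- | --- |
| α (`alpha`) | death rate per apoptosis-gene copy | 0.045 | probability/step/copy |
| δ (`delta`) | division rate per division-gene copy | 0.045 | probability/step/copy |
| μ (`mu`) | mis-segregation rate of a diploid cell | 0.02 | probability/division |
| K (`capacity`) | homeostatic tissue size | 200 | cells |
| `initial_population` | founding diploid cells | 100 | cells |
| `detection_threshold` | tumour detection size | 1000 | cells |
| `max_population` / `max_steps` | termination | 7000 / 300 | cells / steps |

Default dose-response forms ("linear"):

- P_death = min(1, α·n_apop), and 0 whenever N ≤ K (strict gate: crowding
  acts through death only; division is never hard-blocked, though
  `crowding_division_scale` can attenuate it for sensitivity analyses);
- P_div = min(1, δ·n_div) — linear, so six division genes give exactly a
  3-fold proliferation increase over the diploid;
- P_mis = min(1, 2μ/n_seg), with P_mis = 1 at n_seg = 0 — calibrated so the
  diploid rate equals μ, monotone decreasing in the segregation dose, and
  producing runaway instability after total loss of segregation genes (the
  (n,0,0) cascades seen under layout C).

These forms are declared modelling assumptions, not measured facts; an
"exponential" family (1 − exp(−rate·n) doses) is available through
`RateParams.dose_response` for robustness checks.  With α = δ the diploid
tissue is self-balancing: above capacity the expected per-step growth factor
is (1−0.09)(1+0.09) ≈ 0.992, below capacity 1.09, so the population
oscillates near K (property-tested band: 160–260 cells for ≥95% of
post-burn-in steps without mis-segregation).

Mis-segregation picks its chromosome uniformly over physical *copies* by
default, so an amplified chromosome is proportionally more exposed;
uniform-over-*types* sampling is available via
`RateParams.missegregation_sampling`.  Which daughter gains the extra copy
is a fair coin and affects only list placement.  A daughter left with zero
chromosomes of every type is nonviable and is dropped at birth; partial
nullisomy (e.g. (3,0,0)) is viable, and no upper copy bound is imposed.

## Therapy semantics

Detection is evaluated on the recorded end-of-step population; the first
time it reaches the detection threshold, the intervention executes at the
start of the next step, at most once per run.  Surgery keeps the first 100
listed cells, deletes the next contiguous 900 and retains any overshoot
tail, so the residual equals 100 plus the detection overshoot.  Chemotherapy
is active for exactly nine consecutive steps beginning the step after
detection; during an active step every cell that attempts division (decided
by its normal division probability) is killed before producing daughters, so
the population cannot grow.  The combination is surgery followed by the nine
chemotherapy rounds.

The relapse clock starts at the intervention step (for the combination, the
surgery step, which is also the first chemotherapy step), and relapse is the
first end-of-step population at or above the detection threshold.  Runs that
end before relapse are censored; cohort relapse means are reported
complete-case, with a censored-floor variant (censored replicates contribute
their observed steps to run end) exported alongside.

## Cohorts and statistics

A cohort runs `n_replicates` seeded simulations (replicate i uses
base_seed + i; all draws in a replicate come from one `numpy` PCG64 stream
in a fixed order: death, division, mis-segregation uniforms, then chromosome
choices and placement coins).  Genotypic diversity is reported as richness
(count of distinct genotype states), with Shannon entropy exported for
robustness.  The apoptosis/division gene-ratio series uses the per-step
population means of the two gene counts over the 25 steps from the
intervention (index 0 = intervention step); its slope is an OLS fit,
dropping steps where the mean division count is zero or the run has ended
(at least two points required).  Cohorts are compared with the classical
unpaired, equal-variance, two-tailed t-test (pooled-variance closed form;
n_a+n_b−2 degrees of freedom).  Reported standard deviations are sample
(n−1) deviations.

## Numerical and design notes

- The engine stores the tissue column-wise (one int64 row of chromosome
  copy counts per cell, in list order); a step is a handful of vectorised
  operations, so a full 300-step run with thousands of cells takes
  milliseconds and a 100-replicate, six-arm experiment grid runs in about a
  minute on one CPU.
- Degenerate inputs: an empty tissue yields an extinction record; a zero
  maximum in the RGB normalisation maps that channel to 0; surgery on fewer
  than 1000 cells and relapse queries on untreated runs are domain errors.
- Detection at end-of-step with intervention the following step means the
  post-surgery residual inherits the detection overshoot (the population's
  last pre-intervention growth step); with tumour growth of several percent
  per step near detection this overshoot averages a few tens of cells.
- Ties/ordering: daughters occupy the mother's position and the slot after
  it; survivor order is never permuted by death, chemotherapy or surgery.

## What the generator does and does not emulate

All inputs are generated by the simulator itself under the reference
conditions above; there is no external data.  Passing cohorts therefore show
that the implementation reproduces the *model's* behaviour — homeostasis
under balanced linkage, linkage-dependent breakout, worse prognosis with
higher chromosomal instability, complementary action of surgery and
anti-mitotic chemotherapy — not that real tumours behave this way.  Real
cancers have polygenic regulation, spatial constraints, sequence-level
mutation and pharmacokinetics, all outside this model's scope.

## Known limitations

- The dose-response forms are assumptions; cohort-level quantities that are
  sensitive to the evolved division-gene load (e.g. the per-step
  chemotherapy kill fraction) depend on them directly.
- Synchronous end-of-step detection quantises intervention timing to whole
  steps, inflating the post-surgery residual by the detection overshoot.
- Censored relapse times receive no survival-analysis treatment beyond
  flagging and the censored-floor mean.
- Plotting reproduces the diagram *content* (trajectory overlays, stacked
  genotype shares, ratio bands), not any particular visual styling.
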