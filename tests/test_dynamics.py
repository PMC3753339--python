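"""Probability rules and the synchronous update engine."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from karyosim import (
    ConfigurationError,
    GeneDistribution,
    GenotypeState,
    RateParams,
    SimulationConfig,
    Tissue,
    apoptosis_probability,
    division_probability,
    missegregation_probability,
    run_simulation,
    step_tissue,
)


class TestProbabilityRules:
    def test_death_requires_crowding_and_scales_with_gene_dose(self, default_rates):
        s = GenotypeState(2, 2, 2)
        assert apoptosis_probability(s, 201, default_rates, 200) == pytest.approx(0.09)
        assert apoptosis_probability(s, 200, default_rates, 200) == 0.0
        assert apoptosis_probability(GenotypeState(2, 0, 2), 5000, default_rates, 200) == 0.0

    def test_division_scales_linearly_with_gene_dose(self, default_rates):
        assert division_probability(GenotypeState(2, 2, 2), default_rates) == pytest.approx(0.09)
        assert division_probability(GenotypeState(0, 2, 2), default_rates) == 0.0
        ratio = division_probability(
            GenotypeState(6, 0, 0), default_rates
        ) / division_probability(GenotypeState(2, 2, 2), default_rates)
        assert ratio == pytest.approx(3.0)

    def test_missegregation_diploid_rate_is_mu_and_total_loss_is_certain(self, default_rates):
        assert missegregation_probability(GenotypeState(2, 2, 2), default_rates) == pytest.approx(0.02)
        assert missegregation_probability(GenotypeState(2, 2, 4), default_rates) == pytest.approx(0.01)
        assert missegregation_probability(GenotypeState(2, 2, 0), default_rates) == 1.0

    @settings(max_examples=200, deadline=None)
    @given(
        n=st.integers(0, 50),
        pop=st.integers(0, 10_000),
        alpha=st.floats(0.0, 1.0),
        form=st.sampled_from(["linear", "exponential"]),
    )
    def test_probabilities_stay_in_unit_interval(self, n, pop, alpha, form):
        params = RateParams(alpha=alpha, delta=alpha, mu=alpha, dose_response=form)
        state = GenotypeState(n, n, n)
        for p in (
            apoptosis_probability(state, pop, params, 200),
            division_probability(state, params),
            missegregation_probability(state, params),
        ):
            assert 0.0 <= p <= 1.0

    @pytest.mark.parametrize("form", ["linear", "exponential"])
    def test_monotonicities(self, form):
        params = RateParams(dose_response=form)
        death = [apoptosis_probability(GenotypeState(2, n, 2), 300, params, 200) for n in range(30)]
        div = [division_probability(GenotypeState(n, 2, 2), params) for n in range(30)]
        mis = [missegregation_probability(GenotypeState(2, 2, n), params) for n in range(30)]
        assert all(a <= b for a, b in zip(death, death[1:]))
        assert all(a <= b for a, b in zip(div, div[1:]))
        assert all(a >= b for a, b in zip(mis, mis[1:]))

    def test_invalid_rate_params_rejected(self):
        with pytest.raises(ConfigurationError):
            RateParams(alpha=1.5)
        with pytest.raises(ConfigurationError):
            RateParams(dose_response="cubic")


def _unlinked_tissue(states, capacity=10_000):
    dist = GeneDistribution.from_name("unlinked")
    return Tissue(dist, np.array(states, dtype=np.int64), capacity)


class TestStepTissue:
    def test_daughters_replace_the_mother_adjacent_in_list_order(self, rng):
        # only the middle cell carries division genes, and divides surely
        tissue = _unlinked_tissue([[0, 2, 2], [2, 2, 2], [0, 2, 2]])
        params = RateParams(alpha=0.0, delta=0.5, mu=0.0)
        new, rec = step_tissue(tissue, params, rng=rng)
        assert rec.divisions == 1 and rec.deaths == 0
        assert new.population == 4
        np.testing.assert_array_equal(
            new.counts, [[0, 2, 2], [2, 2, 2], [2, 2, 2], [0, 2, 2]]
        )
        # flanking cells keep their ids; daughters are fresh with the mother as parent
        assert new.ids[0] == tissue.ids[0] and new.ids[3] == tissue.ids[2]
        assert set(new.parents[1:3]) == {tissue.ids[1]}
        assert len(set(new.ids)) == 4

    def test_fidelity_without_missegregation(self, rng):
        tissue = _unlinked_tissue([[2, 2, 2]] * 50)
        params = RateParams(mu=0.0)
        for _ in range(20):
            tissue, rec = step_tissue(tissue, params, rng=rng)
            assert rec.missegregations == 0
            assert np.all(tissue.counts == 2)

    def test_expected_division_count_below_capacity(self, rng):
        """E[divisions] = n * delta * n_div for a homogeneous diploid tissue."""
        params = RateParams(mu=0.0)
        divisions = []
        tissue = _unlinked_tissue([[2, 2, 2]] * 100, capacity=10_000)
        for _ in range(2000):
            _, rec = step_tissue(tissue, params, rng=rng)
            divisions.append(rec.divisions)
        mean = np.mean(divisions)
        se = np.std(divisions) / np.sqrt(len(divisions))
        assert abs(mean - 9.0) < 3 * se + 1e-9

    def test_growth_law_below_capacity(self, rng):
        """E[N_next] = N * (1 + P_div) for a homogeneous genotype."""
        params = RateParams(mu=0.0)
        pops = []
        tissue = _unlinked_tissue([[2, 2, 2]] * 200, capacity=10_000)
        for _ in range(1500):
            new, _ = step_tissue(tissue, params, rng=rng)
            pops.append(new.population)
        mean = np.mean(pops)
        se = np.std(pops) / np.sqrt(len(pops))
        assert abs(mean - 200 * 1.09) < 3 * se + 1e-9

    def test_chemo_step_kills_attempting_dividers_and_never_grows(self, rng):
        tissue = _unlinked_tissue([[2, 2, 2]] * 500, capacity=100)
        params = RateParams()
        new, rec = step_tissue(tissue, params, chemo_active=True, rng=rng)
        assert rec.divisions == 0
        assert rec.chemo_kills > 0
        assert new.population == 500 - rec.deaths - rec.chemo_kills
        assert new.population <= 500

    def test_nonviable_all_zero_daughter_is_dropped_at_birth(self, rng):
        # one cell holding a single chromosome with every gene on it: a
        # mis-segregation must leave one daughter empty, which is discarded
        dist = GeneDistribution.custom([(1, 1, 1)])
        tissue = Tissue(dist, np.array([[1]] * 200, dtype=np.int64), 10_000)
        params = RateParams(alpha=0.0, delta=1.0, mu=0.5)
        new, rec = step_tissue(tissue, params, rng=rng)
        assert rec.divisions == 200
        assert rec.missegregations > 0
        # every mis-segregation leaves exactly one viable (2-copy) daughter
        assert new.population == 2 * 200 - rec.missegregations
        assert np.all(new.counts.sum(axis=1) > 0)

    def test_step_record_composition_sums_to_population(self, rng):
        tissue = _unlinked_tissue([[2, 2, 2]] * 100, capacity=50)
        params = RateParams(mu=0.3)
        new, rec = step_tissue(tissue, params, rng=rng, record_composition=True)
        assert sum(rec.composition.values()) == rec.population == new.population

    def test_empty_tissue_yields_extinction_record(self, rng):
        tissue = _unlinked_tissue(np.empty((0, 3), dtype=np.int64))
        _, rec = step_tissue(tissue, RateParams(), rng=rng)
        assert rec.population == 0


class TestExhaustiveOneStepOracle:
    """Enumerate every branch of a 1-cell step and chi-square the frequencies.

    For a single distribution-A diploid cell over capacity, the step outcome
    tree is death / survive-without-division / faithful division /
    mis-segregation of either chromosome type with either daughter order.
    """

    def test_branch_frequencies_match_exact_probabilities(self):
        params = RateParams(alpha=0.3, delta=0.4, mu=0.5)
        dist = GeneDistribution.from_name("A")
        p_death, p_div, p_mis = 0.6, 0.8, 0.5
        expected = {
            "dead": p_death,
            "nodiv": (1 - p_death) * (1 - p_div),
            "faithful": (1 - p_death) * p_div * (1 - p_mis),
        }
        for branch in ("t1_gain_first", "t1_lose_first", "t2_gain_first", "t2_lose_first"):
            expected[branch] = (1 - p_death) * p_div * p_mis * 0.5 * 0.5
        assert sum(expected.values()) == pytest.approx(1.0)

        rng = np.random.default_rng(777)
        counts = dict.fromkeys(expected, 0)
        n_trials = 100_000
        base = Tissue(dist, np.array([[2, 2]], dtype=np.int64), capacity=0)
        for _ in range(n_trials):
            new, _ = step_tissue(base, params, rng=rng)
            if new.population == 0:
                counts["dead"] += 1
            elif new.population == 1:
                counts["nodiv"] += 1
            else:
                a, b = new.counts
                if np.array_equal(a, b):
                    counts["faithful"] += 1
                elif a[0] != b[0]:
                    counts["t1_gain_first" if a[0] == 3 else "t1_lose_first"] += 1
                else:
                    counts["t2_gain_first" if a[1] == 3 else "t2_lose_first"] += 1

        keys = sorted(expected)
        obs = np.array([counts[k] for k in keys], dtype=float)
        exp = np.array([expected[k] * n_trials for k in keys])
        stat, p = scipy.stats.chisquare(obs, exp)
        assert p > 0.01


class TestRunSimulation:
    def test_seeded_determinism(self):
        cfg = SimulationConfig(
            distribution=GeneDistribution.from_name("B"),
            max_steps=80,
            seed=42,
            record_composition=True,
        )
        a = run_simulation(cfg)
        b = run_simulation(cfg)
        assert a.to_frame().equals(b.to_frame())
        assert a.termination_reason == b.termination_reason
        assert [r.composition for r in a.records] == [r.composition for r in b.records]

    def test_invalid_config_rejected_before_stepping(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(
                distribution=GeneDistribution.from_name("A"),
                initial_population=500,
                capacity=200,
            )
        with pytest.raises(ConfigurationError):
            SimulationConfig(
                distribution=GeneDistribution.from_name("A"), max_steps=0
            )

    def test_homeostatic_run_reaches_max_steps_near_capacity(self):
        cfg = SimulationConfig(
            distribution=GeneDistribution.from_name("A"),
            rates=RateParams(mu=0.0),
            max_steps=150,
            seed=7,
            record_composition=False,
        )
        traj = run_simulation(cfg)
        assert traj.termination_reason == "max_steps"
        final = traj.records[-1].population
        assert 140 <= final <= 280

    def test_records_are_contiguous_and_start_at_baseline(self):
        cfg = SimulationConfig(
            distribution=GeneDistribution.from_name("A"),
            max_steps=30,
            seed=3,
            record_composition=False,
        )
        traj = run_simulation(cfg)
        assert [r.step for r in traj.records] == list(range(len(traj.records)))
        assert traj.records[0].population == 100
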