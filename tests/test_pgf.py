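import numpy as np
import pytest

import sanctuary as sc
from sanctuary.exceptions import ConfigurationError, NullConditioningError

from conftest import random_small_model


def homogeneous_model(b, d, u=0.0, v=0.0):
    return sc.minimal_model(b, d, b, d, b, d, b, d, u=u, v=v)


def test_all_ones_point_is_stationary():
    model = sc.slow_sanctuary_model()
    traj = sc.solve_pgf(model, np.ones(4), np.linspace(0, 80, 9))
    np.testing.assert_allclose(traj.values, 1.0, atol=1e-12)


def test_birth_death_extinction_matches_closed_form():
    """With u = v = 0 each lineage is a linear birth-death process whose
    extinction CDF d(e^{rt}-1)/(b e^{rt}-d) is known in closed form."""
    b, d = 0.5, 0.4
    model = homogeneous_model(b, d)
    x = np.array([0.0, 1.0, 1.0, 1.0])
    ts = np.linspace(0, 100, 201)
    traj = sc.solve_pgf(model, x, ts)
    r = b - d
    exact = d * (np.exp(r * ts) - 1) / (b * np.exp(r * ts) - d)
    np.testing.assert_allclose(traj.values[0], exact, atol=1e-6)
    assert sc.limiting_pgf(model, x)[0] == pytest.approx(d / b, abs=1e-10)


def test_trajectories_stay_in_unit_cube():
    rng = np.random.default_rng(7)
    for _ in range(6):
        model = random_small_model(rng)
        x = rng.uniform(0, 1, model.n_classes)
        traj = sc.solve_pgf(model, x, np.linspace(0, 60, 13))
        assert np.all(traj.values >= -1e-12)
        assert np.all(traj.values <= 1 + 1e-12)


def test_eval_point_modulus_checked():
    model = sc.slow_sanctuary_model()
    with pytest.raises(ConfigurationError):
        sc.solve_pgf(model, np.array([1.5, 1, 1, 1]), [0, 1])


def test_limit_at_zeros_equals_masked_limit_when_mutation_feeds_resistance(
    slow_sanctuary_model,
):
    """Surviving lineages almost surely generate resistance when u > 0, so the
    all-zeros and resistant-masked limits coincide."""
    lim_zero = sc.limiting_pgf(slow_sanctuary_model, np.zeros(4))
    lim_mask = sc.limiting_pgf(slow_sanctuary_model, np.array([1.0, 1.0, 0.0, 0.0]))
    np.testing.assert_allclose(lim_zero, lim_mask, atol=1e-8)


class TestEscapeProbability:
    def test_no_mutation_means_no_escape(self, resistance_mask):
        model = homogeneous_model(0.5, 0.4, u=0.0, v=1e-3)
        census = sc.PopulationCensus.single_cell(model, (0, 0))
        assert sc.escape_probability(model, census, resistance_mask) == pytest.approx(0.0, abs=1e-12)

    def test_census_composition_is_multiplicative(self, slow_sanctuary_model, resistance_mask):
        """Independence of lineages: escape(A u B) = 1-(1-pA)(1-pB)."""
        m = slow_sanctuary_model
        cA = sc.PopulationCensus.from_dict(m, {(0, 0): 3})
        cB = sc.PopulationCensus.from_dict(m, {(0, 1): 5})
        cAB = sc.PopulationCensus.from_dict(m, {(0, 0): 3, (0, 1): 5})
        pA = sc.escape_probability(m, cA, resistance_mask)
        pB = sc.escape_probability(m, cB, resistance_mask)
        pAB = sc.escape_probability(m, cAB, resistance_mask)
        assert pAB == pytest.approx(1 - (1 - pA) * (1 - pB), rel=1e-9)

    def test_huge_census_stays_in_unit_interval(self, resistance_mask):
        model, census = sc.build_two_lesion(sc.TwoLesionScenario(delta_d=100.0, v=1e-4))
        assert census.total == pytest.approx(1e8 + 1e3)
        p = sc.escape_probability(model, census, resistance_mask)
        assert 0.99 < p <= 1.0

    def test_empty_census_rejected(self, slow_sanctuary_model, resistance_mask):
        with pytest.raises(ConfigurationError):
            sc.escape_probability(
                slow_sanctuary_model,
                sc.PopulationCensus(np.zeros(4)),
                resistance_mask,
            )


class TestRelapse:
    def test_ps_starts_at_one_and_decays(self, slow_sanctuary_model, resistance_mask):
        census = sc.PopulationCensus.single_cell(slow_sanctuary_model, (0, 0))
        curve = sc.relapse_curve(
            slow_sanctuary_model, census, resistance_mask, np.linspace(0, 400, 81)
        )
        assert curve.ps[0] == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(curve.ps) <= 1e-9)
        assert curve.ps[-1] < 0.1

    def test_null_conditioning_is_an_error_not_nan(self, resistance_mask):
        model = homogeneous_model(0.5, 0.4, u=0.0, v=1e-3)
        census = sc.PopulationCensus.single_cell(model, (0, 0))
        with pytest.raises(NullConditioningError):
            sc.relapse_curve(model, census, resistance_mask, np.linspace(0, 10, 5))
        with pytest.raises(NullConditioningError):
            sc.mean_time_to_resistance(model, census, resistance_mask)

    def test_mean_time_decreases_with_mutation_supply(self, resistance_mask):
        def t_mean(u):
            model = sc.minimal_model(
                0.5, 0.4, 0.39, 0.4, 0.48, 0.4, 0.45, 0.4, u=u, v=1e-3
            )
            census = sc.PopulationCensus.single_cell(model, (0, 0))
            return sc.mean_time_to_resistance(model, census, resistance_mask)

        assert t_mean(0.1) < t_mean(1e-4)

    def test_mean_time_decreases_with_census_size(self, resistance_mask):
        model = sc.minimal_model(0.5, 0.4, 0.39, 0.4, 0.48, 0.4, 0.45, 0.4, u=1e-4, v=1e-3)
        t1 = sc.mean_time_to_resistance(
            model, sc.PopulationCensus.from_dict(model, {(0, 0): 1}), resistance_mask
        )
        t2 = sc.mean_time_to_resistance(
            model, sc.PopulationCensus.from_dict(model, {(0, 0): 2}), resistance_mask
        )
        assert t2 < t1

    def test_sanctuary_start_breeds_resistance_sooner(self, slow_sanctuary_model, resistance_mask):
        """A lineage starting in the sanctuary reaches resistance faster than
        one starting in the drug compartment; both starting classes are
        supported."""
        m = slow_sanctuary_model
        t_sanct = sc.mean_time_to_resistance(
            m, sc.PopulationCensus.single_cell(m, (0, 0)), resistance_mask
        )
        t_drug = sc.mean_time_to_resistance(
            m, sc.PopulationCensus.single_cell(m, (0, 1)), resistance_mask
        )
        assert t_sanct < t_drug

    def test_mean_time_stable_under_quadrature_refinement(self, resistance_mask):
        model = sc.minimal_model(0.5, 0.4, 0.39, 0.4, 0.48, 0.4, 0.45, 0.4, u=1e-4, v=1e-3)
        census = sc.PopulationCensus.single_cell(model, (0, 0))
        t_a = sc.mean_time_to_resistance(model, census, resistance_mask, n_quad=2049)
        t_b = sc.mean_time_to_resistance(model, census, resistance_mask, n_quad=8193)
        assert t_a == pytest.approx(t_b, rel=1e-4)


def test_mask_selection_and_compartment_restriction(slow_sanctuary_model):
    m = slow_sanctuary_model
    full = sc.ResistantMask(genotype_min=1)
    np.testing.assert_array_equal(full.class_indices(m), [2, 3])
    np.testing.assert_array_equal(full.eval_point(m), [1, 1, 0, 0])
    only1 = sc.ResistantMask(genotype_min=1, compartments=frozenset({1}))
    np.testing.assert_array_equal(only1.class_indices(m), [3])
    with pytest.raises(ConfigurationError):
        sc.ResistantMask(genotype_min=5).class_indices(m)
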