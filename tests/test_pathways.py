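import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import sanctuary as sc
from sanctuary.exceptions import ConfigurationError, NullConditioningError
from sanctuary.pathways import DESTINATION_MASK, _pathway_mean_time


class TestDominancePredicates:
    def test_threshold_arithmetic(self):
        assert not sc.pathway_dominance_simplified(0.04, 0.038)
        assert sc.pathway_dominance_simplified(0.04, 0.039)
        # threshold itself: s/(1+s) = 0.0384615...
        assert sc.pathway_dominance_simplified(0.04, 0.04 / 1.04 + 1e-9)
        assert not sc.pathway_dominance_simplified(0.04, 0.04 / 1.04 - 1e-9)

    def test_neutral_resistance_always_dominated_by_mutation_first(self):
        assert sc.pathway_dominance_simplified(0.0, 1e-6)
        land = sc.PathwayLandscape.equal_death(b00=0.5, d=0.4, s=0.0, delta=0.1, b11=0.45)
        assert sc.pathway_dominance_general(land)

    def test_general_inequality_on_reference_landscape(self, reference_landscape):
        # s = 0.04, delta = 0.22 >> s/(1+s)
        assert sc.pathway_dominance_general(reference_landscape)

    @given(s=st.floats(0.001, 0.35), delta=st.floats(0.001, 0.9))
    def test_general_reduces_to_simplified_under_equal_death(self, s, delta):
        land = sc.PathwayLandscape.equal_death(b00=0.5, d=0.3, s=s, delta=delta, b11=0.45)
        assert sc.pathway_dominance_general(land) == sc.pathway_dominance_simplified(s, delta)

    def test_invalid_domain_reported(self):
        # delta <= 0: sensitive cells grow as fast as the origin under drug
        land = sc.PathwayLandscape.equal_death(b00=0.5, d=0.3, s=0.05, delta=0.0, b11=0.45)
        with pytest.raises(ConfigurationError):
            sc.pathway_dominance_general(land)


class TestPathwayChains:
    def test_chain_structure(self, reference_landscape):
        mm = sc.build_pathway(reference_landscape, sc.MUTATION_MIGRATION, u=1e-4, v=1e-3)
        assert mm.mut_prob[0] == 1e-4 and mm.mut_target[0] == 1
        assert list(mm.mig_indices) == [2]  # only resistant sanctuary migrates
        migmut = sc.build_pathway(reference_landscape, sc.MIGRATION_MUTATION, u=1e-4, v=1e-3)
        assert migmut.mut_prob[1] == 1e-4 and migmut.mut_target[1] == 2
        assert list(migmut.mig_indices) == [1]  # only the origin migrates

    def test_blocked_chains_have_no_escape(self, reference_landscape):
        census_cls = (0, 0)
        for which, u, v in [
            (sc.MIGRATION_MUTATION, 1e-4, 0.0),  # no migration: chain broken
            (sc.MUTATION_MIGRATION, 0.0, 1e-3),  # no mutation: chain broken
        ]:
            model = sc.build_pathway(reference_landscape, which, u=u, v=v)
            census = sc.PopulationCensus.single_cell(model, census_cls)
            p = sc.escape_probability(model, census, DESTINATION_MASK)
            assert p == pytest.approx(0.0, abs=1e-12)
            with pytest.raises(NullConditioningError):
                sc.mean_time_to_resistance(model, census, DESTINATION_MASK)

    def test_subcritical_sanctuary_rejected(self):
        bad = sc.PathwayLandscape(
            b00=0.3, d00=0.4, b10=0.2, d10=0.4, b01=0.39, d01=0.4, b11=0.45, d11=0.4
        )
        with pytest.raises(ConfigurationError):
            sc.build_pathway(bad, sc.MUTATION_MIGRATION, 1e-4, 1e-3)


class TestPathwayTimes:
    def test_mutation_migration_faster_on_reference_landscape(self, reference_landscape):
        # delta = 0.22 well above s/(1+s) = 0.0385
        t_mm, t_migmut = sc.compare_pathway_times(reference_landscape, u=1e-4, v=1e-3)
        assert t_mm < t_migmut

    def test_ordering_reverses_below_threshold(self):
        land = sc.PathwayLandscape.equal_death(b00=0.5, d=0.4, s=0.04, delta=0.01, b11=0.45)
        t_mm, t_migmut = sc.compare_pathway_times(land, u=1e-4, v=1e-4)
        assert t_migmut < t_mm

    def test_numeric_ordering_agrees_with_low_rate_prediction(self):
        """At low u, v the sign of the time difference matches the analytic
        dominance condition on a seeded landscape sample."""
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 8:
            s = rng.uniform(0.01, 0.3)
            delta = rng.uniform(0.01, 0.5)
            if abs(delta - s / (1 + s)) < 0.02:
                continue  # skip near-threshold landscapes where times nearly tie
            land = sc.PathwayLandscape.equal_death(b00=0.5, d=0.35, s=s, delta=delta, b11=0.45)
            t_mm, t_migmut = sc.compare_pathway_times(land, u=1e-4, v=1e-4)
            assert (t_mm < t_migmut) == sc.pathway_dominance_general(land), (s, delta)
            checked += 1

    def test_sanctuary_slowdown_delays_both_pathways_equally(self, reference_landscape):
        """Scaling sanctuary rates by phi < 1 prolongs both pathway times
        without changing their order."""
        t_mm_1, t_migmut_1 = sc.compare_pathway_times(reference_landscape, u=1e-4, v=1e-3)
        slow = reference_landscape.scaled_sanctuary(0.5)
        t_mm_p, t_migmut_p = sc.compare_pathway_times(slow, u=1e-4, v=1e-3)
        assert t_mm_p > t_mm_1 and t_migmut_p > t_migmut_1
        assert (t_mm_p < t_migmut_p) == (t_mm_1 < t_migmut_1)

    def test_delta_independence_of_mutation_migration_chain(self):
        """The mutation-migration chain never visits the sensitive-under-drug
        class, so its time does not depend on delta."""
        t_a = _pathway_mean_time(
            sc.PathwayLandscape.equal_death(0.5, 0.4, 0.04, 0.05, 0.45),
            sc.MUTATION_MIGRATION, 1e-4, 1e-4,
        )
        t_b = _pathway_mean_time(
            sc.PathwayLandscape.equal_death(0.5, 0.4, 0.04, 0.3, 0.45),
            sc.MUTATION_MIGRATION, 1e-4, 1e-4,
        )
        assert t_a == pytest.approx(t_b, rel=1e-9)


def test_landscape_derived_quantities(reference_landscape):
    assert reference_landscape.s == pytest.approx(0.04)
    assert reference_landscape.delta == pytest.approx(0.22)
    with pytest.raises(ConfigurationError):
        reference_landscape.scaled_sanctuary(1.5)
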