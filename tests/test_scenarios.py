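import numpy as np
import pytest

import sanctuary as sc
from sanctuary.exceptions import ConfigurationError
from sanctuary.scenarios import ring_concentrations


class TestTwoLesion:
    @pytest.mark.parametrize(
        "delta_d, expected",
        [(0.0, (50.0, 50.0)), (50.0, (25.0, 75.0)), (100.0, (0.0, 100.0))],
    )
    def test_concentration_parameterisation(self, delta_d, expected):
        model, _ = sc.build_two_lesion(sc.TwoLesionScenario(delta_d=delta_d))
        rates = sc.build_rate_table(
            [
                sc.CompartmentSpec(0.05, 0.04, expected[0]),
                sc.CompartmentSpec(0.5, 0.4, expected[1]),
            ],
            2,
            sc.DrugResponseParams(50, 2, 5, 0.01),
        )
        np.testing.assert_allclose(model.birth, rates.birth.ravel())

    def test_out_of_range_delta_rejected(self):
        with pytest.raises(ConfigurationError):
            sc.build_two_lesion(sc.TwoLesionScenario(delta_d=120.0))

    def test_census_is_all_sensitive(self):
        model, census = sc.build_two_lesion(sc.TwoLesionScenario())
        np.testing.assert_array_equal(census.counts, [1e3, 1e8, 0, 0])

    def test_lesion_origin_ordering_depends_on_sizes(self):
        """Lineages from the big lesion 1 reach resistance sooner; shrink
        lesion 1 far enough and the order reverses."""
        mask = sc.ResistantMask(genotype_min=1)

        def per_lesion_times(n1):
            model, census = sc.build_two_lesion(
                sc.TwoLesionScenario(delta_d=100.0, v=1e-4, n1=n1)
            )
            t = []
            for j in (0, 1):
                t.append(
                    sc.mean_time_to_resistance(
                        model, census.restricted_to_compartment(model, j), mask
                    )
                )
            return t

        t0_big, t1_big = per_lesion_times(1e8)
        assert t1_big < t0_big
        t0_small, t1_small = per_lesion_times(1e2)
        assert t1_small > t0_small


class TestOnion:
    def test_population_conservation_and_monotone_profile(self):
        model, census = sc.build_onion(sc.OnionScenario(n_cells=1e11))
        assert census.total == 1e11
        M = 30
        b_sens = model.birth[:M]
        assert np.all(np.diff(b_sens) != 0)
        # drug-free rates and drug both decay with shell index: growth of the
        # sensitive class is shaped by both, death strictly decreases
        assert np.all(np.diff(model.death[:M]) < 0)

    def test_uniform_density_limit_weights_are_shell_volumes(self):
        scenario = sc.OnionScenario(tau_c=1e9, m_shells=5, n_cells=1e6)
        _, census = sc.build_onion(scenario)
        pops = census.counts[:5]
        edges = np.linspace(0, scenario.radius, 6)
        vol = np.diff(edges**3)
        np.testing.assert_allclose(pops / pops.sum(), vol / vol.sum(), atol=2e-6)

    def test_cylindrical_weighting_differs(self):
        sph = sc.build_onion(sc.OnionScenario(m_shells=6, n_cells=1e6))[1]
        cyl = sc.build_onion(
            sc.OnionScenario(m_shells=6, n_cells=1e6, weighting="cylindrical")
        )[1]
        assert not np.allclose(sph.counts, cyl.counts)

    def test_penetration_extremes_decide_treatment_outcome(self):
        """Perfect penetration eradicates the tumor; strong heterogeneity
        (short drug decay length) guarantees escape."""
        mask = sc.ResistantMask(genotype_min=2)
        good = sc.build_onion(sc.OnionScenario(tau_d=100.0))
        assert sc.escape_probability(*good, mask) < 0.01
        poor = sc.build_onion(sc.OnionScenario(tau_d=0.25))
        assert sc.escape_probability(*poor, mask) > 0.99


class TestRing:
    def test_sigma_zero_is_homogeneous(self):
        conc = ring_concentrations(sc.RingScenario(sigma=0.0))
        np.testing.assert_allclose(conc, 50.0)

    def test_profile_mean_and_std(self):
        scenario = sc.RingScenario(sigma=24.7)
        conc = ring_concentrations(scenario)
        assert conc.mean() == pytest.approx(50.0)
        assert conc.std() == pytest.approx(24.7, abs=1e-6)
        center = scenario.m_compartments // 2
        assert conc.argmax() == center
        assert np.all(conc >= 0)

    def test_unreachable_sigma_rejected(self):
        with pytest.raises(ConfigurationError):
            ring_concentrations(sc.RingScenario(sigma=500.0))

    def test_ring_equals_global_at_two_compartments(self):
        a, _ = sc.build_ring(sc.RingScenario(m_compartments=2, topology="ring", sigma=10.0))
        b, _ = sc.build_ring(sc.RingScenario(m_compartments=2, topology="global", sigma=10.0))
        np.testing.assert_allclose(a.birth, b.birth)
        np.testing.assert_array_equal(a.mig_indices, b.mig_indices)
        np.testing.assert_allclose(a.mig_rates, b.mig_rates)

    def test_default_census_starts_in_strongest_sanctuary(self):
        model, census = sc.build_ring(sc.RingScenario())
        conc = ring_concentrations(sc.RingScenario())
        assert census.counts[model.class_index((0, int(np.argmin(conc))))] == 1
        assert census.total == 1


class TestRegimeShift:
    def test_required_mutations_steps_up_with_concentration(self):
        """With a modest per-mutation IC50 gain, higher concentrations demand
        more mutations for a supercritical genotype, and the conditional
        time to sufficient resistance jumps up across the step."""
        params = sc.DrugResponseParams(ic50=50, m=2, rho=3.5, s=0.01)
        # critical D where genotype 1 turns subcritical: b1(D) = alpha
        d_crit = 3.5 * 50 * np.sqrt(0.495 / 0.4 - 1)
        assert sc.required_mutations(d_crit - 5, 0.5, 0.4, params) == 1
        assert sc.required_mutations(d_crit + 5, 0.5, 0.4, params) == 2

        def time_at(delta_d):
            scen = sc.TwoLesionScenario(
                delta_d=delta_d, v=1e-4, n_genotypes=3, drug_response=params
            )
            model, census = sc.build_two_lesion(scen)
            d1 = scen.d_mean + delta_d / 2
            n_req = sc.required_mutations(d1, scen.beta1, scen.alpha1, params)
            return sc.mean_time_to_resistance(
                model, census, sc.ResistantMask(genotype_min=n_req)
            )

        # d_crit = 85.3 -> the step sits between delta_d = 66 and 75
        assert time_at(75.0) > time_at(66.0)


def test_sweep_single_point_equals_direct_call():
    base = sc.TwoLesionScenario(delta_d=80.0, v=1e-3)
    table = sc.sweep("escape", base, "delta_d", [80.0])
    model, census = sc.build_two_lesion(base)
    direct = sc.escape_probability(model, census, sc.ResistantMask(genotype_min=1))
    assert len(table) == 1
    assert table.loc[0, "escape"] == pytest.approx(direct, rel=1e-12)


def test_sweep_rejects_empty_grid_and_unknown_quantity():
    base = sc.TwoLesionScenario()
    with pytest.raises(ConfigurationError):
        sc.sweep("escape", base, "delta_d", [])
    with pytest.raises(ConfigurationError):
        sc.sweep("median", base, "delta_d", [1.0])
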