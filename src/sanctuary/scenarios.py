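"""Builders for the canonical experiments of the framework.

Four scenario families:

* ``minimal_model`` — the bare two-genotype, two-compartment process with
  explicitly given rates (no Hill landscape), used for the spatio-temporal
  count-distribution studies.
* ``TwoLesionScenario`` — two metastatic lesions of different sizes and
  drug penetration, parameterised by the mean concentration and the
  concentration difference Delta D at fixed mean.
* ``RingScenario`` — M compartments on a ring (local migration) or fully
  connected (global migration) with a Normal-shaped drug-concentration
  profile peaking in the central compartment.
* ``OnionScenario`` — a solid tumor discretised into M concentric shells
  around a central blood vessel, with exponentially decaying proliferation,
  cell density and drug concentration.

Each builder returns a ``(BranchingModel, PopulationCensus)`` pair ready for
the PGF engine, and ``sweep`` tabulates escape probabilities or conditional
mean relapse times over a parameter grid.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import gammainc

from .exceptions import ConfigurationError
from .fitness import CompartmentSpec, DrugResponseParams, RateTable, build_rate_table, hill_birth_rate
from .model import BranchingModel, MigrationSpec, MutationSpec, build_model
from .pgf import (
    PopulationCensus,
    ResistantMask,
    escape_probability,
    mean_time_to_resistance,
)

__all__ = [
    "minimal_model",
    "slow_sanctuary_model",
    "TwoLesionScenario",
    "build_two_lesion",
    "OnionScenario",
    "build_onion",
    "RingScenario",
    "build_ring",
    "required_mutations",
    "sweep",
]


# --------------------------------------------------------------------------
# minimal two-type, two-compartment model with explicit rates


def minimal_model(
    b00, d00, b01, d01, b10, d10, b11, d11, u, v
) -> BranchingModel:
    """Two genotypes x two compartments with explicitly given rates.

    Rate b_ij belongs to genotype i in compartment j; migration is pairwise
    at rate v each way and a dividing sensitive cell mutates with
    probability u.
    """
    rates = RateTable(
        birth=np.array([[b00, b01], [b10, b11]]),
        death=np.array([[d00, d01], [d10, d11]]),
    )
    return build_model(rates, MutationSpec(u), MigrationSpec(v, "pairwise"))


def slow_sanctuary_model() -> BranchingModel:
    """The slow-sanctuary parameter set used for the count-distribution study.

    Sensitive cells are near-critical in the drug compartment and slowly
    supercritical in the sanctuary; resistant cells grow fast under drug.
    """
    return minimal_model(
        b00=0.1, d00=0.05, b01=0.38, d01=0.4,
        b10=0.099, d10=0.05, b11=0.5, d11=0.4,
        u=1e-4, v=1e-2,
    )


# --------------------------------------------------------------------------
# two-lesion metastasis treatment


@dataclass(frozen=True)
class TwoLesionScenario:
    """Two metastatic lesions under a shared drug budget.

    Lesion 0 is small and slow-growing with poor drug penetration; lesion 1
    is large and fast-growing.  Concentrations are parameterised by the
    fixed mean ``d_mean`` and the difference ``delta_d`` = D1 - D0, so the
    total administered drug stays constant while its spatial heterogeneity
    varies.  Defaults are the reference in-silico patient: N0 = 1e3,
    N1 = 1e8, (beta0, alpha0) = (0.05, 0.04), (beta1, alpha1) = (0.5, 0.4),
    IC50 = 50, m = 2, rho = 5, s = 0.01, u = 1e-9.
    """

    delta_d: float = 100.0
    v: float = 1e-4
    n0: float = 1e3
    n1: float = 1e8
    beta0: float = 0.05
    alpha0: float = 0.04
    beta1: float = 0.5
    alpha1: float = 0.4
    d_mean: float = 50.0
    drug_response: DrugResponseParams = field(
        default_factory=lambda: DrugResponseParams(ic50=50.0, m=2.0, rho=5.0, s=0.01)
    )
    u: float = 1e-9
    n_genotypes: int = 2


def build_two_lesion(scenario: TwoLesionScenario) -> tuple[BranchingModel, PopulationCensus]:
    """Model and all-sensitive census for a two-lesion treatment."""
    sc = scenario
    if not 0 <= sc.delta_d <= 2 * sc.d_mean:
        raise ConfigurationError(
            f"delta_d must lie in [0, {2 * sc.d_mean}] to keep both "
            f"concentrations non-negative, got {sc.delta_d}"
        )
    d0 = sc.d_mean - sc.delta_d / 2
    d1 = sc.d_mean + sc.delta_d / 2
    compartments = [
        CompartmentSpec(beta=sc.beta0, alpha=sc.alpha0, drug=d0),
        CompartmentSpec(beta=sc.beta1, alpha=sc.alpha1, drug=d1),
    ]
    rates = build_rate_table(compartments, sc.n_genotypes, sc.drug_response)
    model = build_model(rates, MutationSpec(sc.u), MigrationSpec(sc.v, "pairwise"))
    census = PopulationCensus.from_dict(model, {(0, 0): sc.n0, (0, 1): sc.n1})
    return model, census


def required_mutations(
    drug: float, beta: float, alpha: float, params: DrugResponseParams, n_max: int = 16
) -> int:
    """Smallest number of mutations whose genotype is supercritical at ``drug``."""
    comp = CompartmentSpec(beta=beta, alpha=alpha, drug=drug)
    for i in range(n_max):
        if hill_birth_rate(i, comp, params) > alpha:
            return i
    raise ConfigurationError(
        f"no genotype with up to {n_max} mutations is supercritical at D={drug}"
    )


# --------------------------------------------------------------------------
# onion solid tumor


@dataclass(frozen=True)
class OnionScenario:
    """Solid tumor as concentric shells around a central blood vessel.

    Proliferation and turnover decay as exp(-x / tau_g) with distance x from
    the vessel, cell density as exp(-x / tau_c) and the drug concentration
    as exp(-x / tau_d) from its maximum d0 at the vessel; 1/tau_d measures
    the spatial drug heterogeneity.  The default tumor holds N = 1e11 cells
    in a radius of 2.3 cm, divided into M = 30 shells of equal width, and
    needs n = 3 genotypes (two point mutations) for full resistance at the
    center.  ``weighting`` selects the Jacobian of the shell-population
    integral: "spherical" (x^2, default) or "cylindrical" (x).
    """

    tau_d: float = 0.5
    n_cells: float = 1e11
    m_shells: int = 30
    n_genotypes: int = 3
    radius: float = 2.3
    tau_g: float = 1.0
    tau_c: float = 1.0
    d0: float = 500.0
    b0: float = 0.5
    death0: float = 0.4
    drug_response: DrugResponseParams = field(
        default_factory=lambda: DrugResponseParams(ic50=50.0, m=2.0, rho=5.0, s=0.01)
    )
    u: float = 1e-9
    v: float = 2e-4
    weighting: str = "spherical"
    edge_mode: str = "half"


def _shell_weights(scenario: OnionScenario) -> np.ndarray:
    """Unnormalised shell populations: integral of x^p exp(-x/tau_c) per shell."""
    sc = scenario
    edges = np.linspace(0.0, sc.radius, sc.m_shells + 1)
    if sc.weighting == "spherical":
        p = 3  # integrand x^2 -> regularised incomplete gamma of order 3
    elif sc.weighting == "cylindrical":
        p = 2
    else:
        raise ConfigurationError(f"unknown weighting {sc.weighting!r}")
    cdf = gammainc(p, edges / sc.tau_c)
    return np.diff(cdf)


def _largest_remainder_round(weights: np.ndarray, total: float) -> np.ndarray:
    """Integer populations summing exactly to ``total``."""
    target = weights / weights.sum() * total
    floors = np.floor(target)
    deficit = int(round(total - floors.sum()))
    order = np.argsort(target - floors)[::-1]
    out = floors.copy()
    out[order[:deficit]] += 1
    return out


def build_onion(scenario: OnionScenario) -> tuple[BranchingModel, PopulationCensus]:
    """Line-local shell model with exponentially decaying rates and drug."""
    sc = scenario
    if sc.m_shells < 2 or sc.n_genotypes < 2:
        raise ConfigurationError("the onion model needs at least 2 shells and 2 genotypes")
    mid = (np.arange(sc.m_shells) + 0.5) * sc.radius / sc.m_shells
    decay = np.exp(-mid / sc.tau_g)
    drug = sc.d0 * np.exp(-mid / sc.tau_d)
    compartments = [
        CompartmentSpec(beta=sc.b0 * g, alpha=sc.death0 * g, drug=D)
        for g, D in zip(decay, drug)
    ]
    rates = build_rate_table(compartments, sc.n_genotypes, sc.drug_response)
    model = build_model(
        rates, MutationSpec(sc.u), MigrationSpec(sc.v, "line", edge_mode=sc.edge_mode)
    )
    pops = _largest_remainder_round(_shell_weights(sc), sc.n_cells)
    if np.any(pops < 0):
        raise ConfigurationError("negative shell population after rounding")
    census = PopulationCensus.from_dict(
        model, {(0, j): pops[j] for j in range(sc.m_shells)}
    )
    return model, census


# --------------------------------------------------------------------------
# ring / fully-connected multi-compartment model


@dataclass(frozen=True)
class RingScenario:
    """M compartments with a Normal-shaped concentration profile.

    The concentration over compartments follows a Gaussian bump centred on
    the middle compartment (ring distance), rescaled to the fixed mean
    ``d_mean``; the spatial width of the bump is solved so that the standard
    deviation of the per-compartment concentrations equals ``sigma``
    (sigma = 0 gives a homogeneous profile).  Defaults follow the reference
    multi-genotype experiment: M = 20, n = 5, IC50 = 100, m = 2, rho = 1.1,
    mean concentration 50, s = 0.01, b0 = 0.2, d0 = 0.1, u = 1e-4.
    """

    sigma: float = 24.7
    v: float = 0.01
    topology: str = "ring"
    m_compartments: int = 20
    n_genotypes: int = 5
    d_mean: float = 50.0
    b0: float = 0.2
    death0: float = 0.1
    drug_response: DrugResponseParams = field(
        default_factory=lambda: DrugResponseParams(ic50=100.0, m=2.0, rho=1.1, s=0.01)
    )
    u: float = 1e-4


def ring_concentrations(scenario: RingScenario) -> np.ndarray:
    """Per-compartment concentrations: Gaussian bump, mean d_mean, std sigma."""
    sc = scenario
    M = sc.m_compartments
    if sc.sigma < 0:
        raise ConfigurationError(f"sigma must be >= 0, got {sc.sigma}")
    if sc.sigma == 0:
        return np.full(M, float(sc.d_mean))
    center = M // 2
    dist = np.abs(np.arange(M) - center)
    if sc.topology in ("ring", "global"):
        dist = np.minimum(dist, M - dist)

    def profile(width):
        z = np.exp(-(dist**2) / (2 * width**2))
        return sc.d_mean * M * z / z.sum()

    sigma_max = sc.d_mean * np.sqrt(M - 1)
    if sc.sigma >= sigma_max:
        raise ConfigurationError(
            f"sigma {sc.sigma} is not reachable: a point mass at the central "
            f"compartment caps the std at {sigma_max:.3g}"
        )
    width = brentq(lambda w: profile(w).std() - sc.sigma, 1e-3, 1e3)
    return np.clip(profile(width), 0.0, None)


def build_ring(
    scenario: RingScenario, start_compartment: int | None = None
) -> tuple[BranchingModel, PopulationCensus]:
    """Ring or fully-connected model; census is one sensitive cell.

    ``start_compartment`` defaults to the lowest-concentration compartment
    (the strongest sanctuary).
    """
    sc = scenario
    conc = ring_concentrations(sc)
    compartments = [
        CompartmentSpec(beta=sc.b0, alpha=sc.death0, drug=D) for D in conc
    ]
    rates = build_rate_table(compartments, sc.n_genotypes, sc.drug_response)
    model = build_model(rates, MutationSpec(sc.u), MigrationSpec(sc.v, sc.topology))
    if start_compartment is None:
        start_compartment = int(np.argmin(conc))
    census = PopulationCensus.single_cell(model, (0, start_compartment))
    return model, census


# --------------------------------------------------------------------------
# parameter sweeps


_BUILDERS = {
    TwoLesionScenario: build_two_lesion,
    OnionScenario: build_onion,
    RingScenario: build_ring,
}


def sweep(
    quantity: str,
    base_scenario,
    param: str,
    values,
    mask: ResistantMask | None = None,
) -> pd.DataFrame:
    """Tabulate ``escape`` or ``mean_time`` over a grid of one scenario field.

    Deterministic given the scenario; returns one row per grid point with
    columns ``[param, quantity]``.
    """
    if quantity not in ("escape", "mean_time"):
        raise ConfigurationError(f"unknown quantity {quantity!r}")
    values = list(values)
    if not values:
        raise ConfigurationError("sweep grid must be non-empty")
    builder = _BUILDERS.get(type(base_scenario))
    if builder is None:
        raise ConfigurationError(
            f"no builder registered for scenario type {type(base_scenario).__name__}"
        )
    if mask is None:
        mask = ResistantMask(genotype_min=base_scenario.n_genotypes - 1)
    rows = []
    for val in values:
        model, census = builder(dataclasses.replace(base_scenario, **{param: val}))
        if quantity == "escape":
            out = escape_probability(model, census, mask)
        else:
            out = mean_time_to_resistance(model, census, mask)
        rows.append({param: val, quantity: out})
    return pd.DataFrame(rows)
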