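"""Competing routes to resistance in a two-compartment drug landscape.

With a drug sanctuary (compartment 0) seeding a high-drug compartment 1,
resistance in the drug compartment can arise through two chains:

* migration-mutation: a sensitive cell migrates into the drug compartment
  and mutates in situ;
* mutation-migration: a sensitive cell mutates in the sanctuary and its
  resistant offspring migrate into the drug compartment.

Each chain is realised as its own three-class branching process with
strictly one-directional transitions (origin -> intermediate ->
destination), because in the full bidirectional model the two routes mix by
construction.  In the limit of low mutation and migration rates the
mutation-migration route is the faster one exactly when

    b00 / [(b00 - d00) - (b10 - d10)]  >  b01 / [(b00 - d00) - (b01 - d01)],

which under the equal-death parameterisation b10 = (1-s) b00,
b01 = (1-delta) b00 collapses to the threshold condition delta > s/(1+s):
the drug's growth inhibition of sensitive cells only needs to exceed
(slightly less than) the fitness cost of resistance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import ConfigurationError
from .model import BranchingModel
from .pgf import (
    PopulationCensus,
    ResistantMask,
    mean_time_to_resistance,
)

__all__ = [
    "PathwayLandscape",
    "MIGRATION_MUTATION",
    "MUTATION_MIGRATION",
    "build_pathway",
    "pathway_dominance_general",
    "pathway_dominance_simplified",
    "compare_pathway_times",
    "crossing_delta",
    "DESTINATION_MASK",
]

MIGRATION_MUTATION = "migration_mutation"
MUTATION_MIGRATION = "mutation_migration"

#: The destination class (resistant in the drug compartment) is always the
#: third class of a pathway chain.
DESTINATION_MASK = ResistantMask(extra_classes=frozenset({2}))


@dataclass(frozen=True)
class PathwayLandscape:
    """Birth/death rates of the four (genotype, compartment) combinations.

    Indices read (genotype, compartment): b10 is the resistant type in the
    sanctuary.  ``validate`` enforces the canonical rugged pattern
    (supercritical sanctuary, sensitive cells subcritical under drug); the
    sanctuary conditions are required for pathway analysis, the
    drug-compartment pattern only under ``strict=True`` since threshold
    scans deliberately cross it.
    """

    b00: float
    d00: float
    b10: float
    d10: float
    b01: float
    d01: float
    b11: float
    d11: float

    @property
    def s(self) -> float:
        """Fitness cost of resistance in the sanctuary, 1 - b10/b00."""
        return 1.0 - self.b10 / self.b00

    @property
    def delta(self) -> float:
        """Drug efficacy of growth inhibition of sensitive cells, 1 - b01/b00."""
        return 1.0 - self.b01 / self.b00

    def validate(self, strict: bool = False) -> None:
        if not (self.b00 > self.d00 and self.b10 > self.d10):
            raise ConfigurationError(
                "sanctuary classes must be supercritical (b00 > d00 and b10 > d10)"
            )
        if strict:
            if not self.b01 < self.d01:
                raise ConfigurationError("sensitive cells must be subcritical under drug (b01 < d01)")
            if not (self.b11 > self.d11 and self.b11 > self.b01):
                raise ConfigurationError("resistant cells must be supercritical under drug")

    def scaled_sanctuary(self, phi: float) -> "PathwayLandscape":
        """Rescale all sanctuary rates by ``phi`` in (0, 1].

        Models sanctuaries whose microenvironment slows proliferation and
        turnover relative to the drug compartment.
        """
        if not 0 < phi <= 1:
            raise ConfigurationError(f"phi must be in (0, 1], got {phi}")
        return replace(
            self, b00=self.b00 * phi, d00=self.d00 * phi,
            b10=self.b10 * phi, d10=self.d10 * phi,
        )

    @classmethod
    def equal_death(
        cls, b00: float, d: float, s: float, delta: float, b11: float
    ) -> "PathwayLandscape":
        """Equal-death parameterisation: b10 = (1-s) b00, b01 = (1-delta) b00."""
        return cls(
            b00=b00, d00=d, b10=(1 - s) * b00, d10=d,
            b01=(1 - delta) * b00, d01=d, b11=b11, d11=d,
        )


def build_pathway(
    landscape: PathwayLandscape, which: str, u: float, v: float
) -> BranchingModel:
    """Three-class chain model for one pathway.

    Class order: 0 = origin (sensitive in sanctuary), 1 = intermediate,
    2 = destination (resistant in drug compartment).  The only inter-class
    flows are the chain transitions; the result plugs into the PGF engine
    unchanged, with ``DESTINATION_MASK`` as the resistance mask and a single
    origin cell as the census.
    """
    landscape.validate(strict=False)
    if not 0 <= u <= 1:
        raise ConfigurationError(f"mutation probability u must be in [0, 1], got {u}")
    if v < 0:
        raise ConfigurationError(f"migration rate v must be >= 0, got {v}")
    L = landscape
    if which == MIGRATION_MUTATION:
        # sensitive sanctuary -(v)-> sensitive in drug -(b01*u)-> resistant in drug
        birth = [L.b00, L.b01, L.b11]
        death = [L.d00, L.d01, L.d11]
        mut_prob = [0.0, u, 0.0]
        mut_target = [-1, 2, -1]
        edges = [[(1, v)], [], []]
    elif which == MUTATION_MIGRATION:
        # sensitive sanctuary -(b00*u)-> resistant sanctuary -(v)-> resistant in drug
        birth = [L.b00, L.b10, L.b11]
        death = [L.d00, L.d10, L.d11]
        mut_prob = [u, 0.0, 0.0]
        mut_target = [1, -1, -1]
        edges = [[], [(2, v)], []]
    else:
        raise ConfigurationError(
            f"unknown pathway {which!r}; expected "
            f"{MIGRATION_MUTATION!r} or {MUTATION_MIGRATION!r}"
        )
    return BranchingModel(
        np.array(birth), np.array(death), np.array(mut_prob),
        np.array(mut_target, dtype=np.int64), edges,
    )


def pathway_dominance_general(landscape: PathwayLandscape) -> bool:
    """Low-rate prediction: is the mutation-migration pathway the faster one?

    Evaluates the general inequality on the raw rates.  Both denominators
    must be positive (the intermediate class must grow strictly slower than
    the origin), otherwise the condition's validity domain is left.
    """
    L = landscape
    L.validate(strict=False)
    den_mm = (L.b00 - L.d00) - (L.b10 - L.d10)
    den_migmut = (L.b00 - L.d00) - (L.b01 - L.d01)
    if den_migmut <= 0:
        raise ConfigurationError(
            "dominance condition undefined: the sensitive class under drug "
            "grows at least as fast as the origin (non-positive denominator)"
        )
    if den_mm <= 0:
        # Neutral or advantageous resistance in the sanctuary: the
        # mutation-migration route wins for any positive drug effect.
        return True
    return L.b00 / den_mm > L.b01 / den_migmut


def pathway_dominance_simplified(s: float, delta: float) -> bool:
    """Threshold form of the dominance condition: delta > s/(1+s).

    Valid under the equal-death parameterisation; agrees exactly with
    the general inequality there.
    """
    if not s < 1:
        raise ConfigurationError(f"cost s must be < 1, got {s}")
    if not 0 <= delta < 1:
        raise ConfigurationError(f"delta must be in [0, 1), got {delta}")
    return delta > s / (1 + s)


def _pathway_mean_time(landscape, which, u, v, **kwargs) -> float:
    model = build_pathway(landscape, which, u, v)
    census = PopulationCensus.single_cell(model, (0, 0))
    return mean_time_to_resistance(model, census, DESTINATION_MASK, **kwargs)


def compare_pathway_times(
    landscape: PathwayLandscape, u: float, v: float, **kwargs
) -> tuple[float, float]:
    """Conditional mean times to destination-class presence for both chains.

    Returns (T_mutation_migration, T_migration_mutation) in days, starting
    from one sensitive cell in the sanctuary.
    """
    if u <= 0 or v <= 0:
        raise ConfigurationError("both chains need u > 0 and v > 0 to be viable")
    t_mm = _pathway_mean_time(landscape, MUTATION_MIGRATION, u, v, **kwargs)
    t_migmut = _pathway_mean_time(landscape, MIGRATION_MUTATION, u, v, **kwargs)
    return t_mm, t_migmut


def crossing_delta(
    s: float = 0.04,
    u: float = 1e-4,
    v: float = 1e-4,
    b00: float = 0.5,
    d: float = 0.4,
    b11: float = 0.45,
    lo: float = 0.005,
    hi: float = 0.12,
    xtol: float = 1e-4,
) -> float:
    """Numerically locate the delta at which the two pathway times cross.

    Bisection on delta -> T_migration_mutation(delta) - T_mutation_migration;
    the mutation-migration time does not depend on delta and is computed
    once.  Defaults reproduce the equal-death landscape used for the
    threshold analysis.  The low-rate theory puts the crossing at s/(1+s).
    """

    def landscape(delta):
        return PathwayLandscape.equal_death(b00=b00, d=d, s=s, delta=delta, b11=b11)

    t_mm = _pathway_mean_time(landscape(lo), MUTATION_MIGRATION, u, v)

    def f(delta):
        return _pathway_mean_time(landscape(delta), MIGRATION_MUTATION, u, v) - t_mm

    f_lo, f_hi = f(lo), f(hi)
    if f_lo * f_hi > 0:
        raise ConfigurationError(
            f"no crossing bracketed in [{lo}, {hi}]: f({lo})={f_lo:.3g}, "
            f"f({hi})={f_hi:.3g}"
        )
    while hi - lo > xtol:
        mid = 0.5 * (lo + hi)
        if f_lo * f(mid) <= 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
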