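"""Hill-function fitness landscape for genotypes under compartment-specific drug levels.

A cell's division rate depends on its genotype (number of acquired
resistance point mutations) and on the drug concentration of the
compartment it sits in.  The dose response is a Hill curve whose midpoint
(IC50) is multiplied by a factor ``rho`` per mutation, while each mutation
also carries a multiplicative fitness cost ``s`` in the absence of drug:

    b_ij = beta_j * (1 - i*s) / (1 + (D_j / (rho**i * IC50))**m)

Death rates are unaffected by the drug (cytostatic, not cytotoxic, drug
action) and are shared by all genotypes within a compartment.  All rates
are per cell per day.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InvalidGenotypeError

__all__ = [
    "DrugResponseParams",
    "CompartmentSpec",
    "RateTable",
    "hill_birth_rate",
    "build_rate_table",
]


@dataclass(frozen=True)
class DrugResponseParams:
    """Parameters of the Hill dose-response and of the mutation fitness effects.

    Parameters
    ----------
    ic50 : float
        Drug concentration halving the division rate of the sensitive
        genotype (arbitrary concentration units, > 0).
    m : float
        Hill steepness exponent (dimensionless, > 0).
    rho : float
        Fold increase in IC50 per resistance mutation (>= 1).
    s : float
        Fitness cost per mutation in the absence of drug.  ``s <= 0``
        models neutral or advantageous resistance; ``s`` must stay below 1
        so that birth rates of genotypes in use remain positive.
    """

    ic50: float
    m: float
    rho: float
    s: float

    def __post_init__(self):
        if not self.ic50 > 0:
            raise ConfigurationError(f"ic50 must be positive, got {self.ic50}")
        if not self.m > 0:
            raise ConfigurationError(f"Hill exponent m must be positive, got {self.m}")
        if not self.rho >= 1:
            raise ConfigurationError(f"rho must be >= 1, got {self.rho}")
        if not self.s < 1:
            raise ConfigurationError(f"cost s must be < 1, got {self.s}")


@dataclass(frozen=True)
class CompartmentSpec:
    """Drug-free rates and drug concentration of one spatial compartment.

    ``beta`` is the division rate and ``alpha`` the death rate of a
    sensitive cell in the absence of drug; ``drug`` is the local drug
    concentration.  Rates are per cell per day.
    """

    beta: float
    alpha: float
    drug: float = 0.0

    def __post_init__(self):
        if not self.beta > 0:
            raise ConfigurationError(f"beta must be positive, got {self.beta}")
        if self.alpha < 0:
            raise ConfigurationError(f"alpha must be >= 0, got {self.alpha}")
        if self.drug < 0:
            raise ConfigurationError(f"drug concentration must be >= 0, got {self.drug}")


@dataclass(frozen=True)
class RateTable:
    """Birth and death rates indexed by genotype (row) and compartment (column)."""

    birth: np.ndarray
    death: np.ndarray
    compartments: tuple[CompartmentSpec, ...] = field(default=(), compare=False)

    def __post_init__(self):
        birth = np.asarray(self.birth, dtype=float)
        death = np.asarray(self.death, dtype=float)
        if birth.ndim != 2 or birth.shape != death.shape:
            raise ConfigurationError(
                f"birth and death must be matching 2-d arrays, got shapes "
                f"{birth.shape} and {death.shape}"
            )
        if np.any(birth < 0) or np.any(death < 0):
            raise ConfigurationError("rates must be non-negative")
        object.__setattr__(self, "birth", birth)
        object.__setattr__(self, "death", death)

    @property
    def growth(self) -> np.ndarray:
        """Net growth rates r_ij = b_ij - d_ij."""
        return self.birth - self.death

    @property
    def n_genotypes(self) -> int:
        return self.birth.shape[0]

    @property
    def n_compartments(self) -> int:
        return self.birth.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns genotype, compartment, birth, death, growth."""
        n, M = self.birth.shape
        geno, comp = np.meshgrid(np.arange(n), np.arange(M), indexing="ij")
        return pd.DataFrame(
            {
                "genotype": geno.ravel(),
                "compartment": comp.ravel(),
                "birth": self.birth.ravel(),
                "death": self.death.ravel(),
                "growth": self.growth.ravel(),
            }
        )


def hill_birth_rate(
    genotype: int, comp: CompartmentSpec, params: DrugResponseParams
) -> float:
    """Division rate of a cell with ``genotype`` mutations in compartment ``comp``.

    Each mutation multiplies the effective IC50 by ``rho`` and the drug-free
    rate by ``(1 - s)`` per step (costs combine linearly as ``1 - i*s``).

    Raises
    ------
    InvalidGenotypeError
        If the cumulative cost ``genotype * s`` reaches 1, which would make
        the birth rate non-positive.  Rejecting (rather than clamping)
        surfaces misconfigured genotype counts early.
    """
    if genotype < 0:
        raise InvalidGenotypeError(f"genotype must be >= 0, got {genotype}")
    cost_factor = 1.0 - genotype * params.s
    if cost_factor <= 0:
        raise InvalidGenotypeError(
            f"genotype {genotype} with cost s={params.s} has non-positive "
            f"drug-free birth rate (1 - i*s = {cost_factor})"
        )
    ic50_eff = params.rho**genotype * params.ic50
    hill = 1.0 + (comp.drug / ic50_eff) ** params.m if comp.drug > 0 else 1.0
    return comp.beta * cost_factor / hill


def build_rate_table(
    compartments: list[CompartmentSpec],
    n_genotypes: int,
    params: DrugResponseParams,
) -> RateTable:
    """Tabulate b_ij and d_ij for all genotypes and compartments.

    Death rows are identical across genotypes within a compartment
    (drug-independent death).
    """
    if n_genotypes < 1:
        raise ConfigurationError(f"n_genotypes must be >= 1, got {n_genotypes}")
    compartments = tuple(compartments)
    if not compartments:
        raise ConfigurationError("at least one compartment is required")
    M = len(compartments)
    birth = np.empty((n_genotypes, M))
    death = np.empty((n_genotypes, M))
    for i in range(n_genotypes):
        for j, comp in enumerate(compartments):
            try:
                b = hill_birth_rate(i, comp, params)
            except InvalidGenotypeError as exc:
                raise ConfigurationError(
                    f"birth rate non-positive for genotype {i}, compartment {j}: {exc}"
                ) from exc
            birth[i, j] = b
            death[i, j] = comp.alpha
    return RateTable(birth=birth, death=death, compartments=compartments)
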