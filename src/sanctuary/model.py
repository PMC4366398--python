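"""Continuous-time multi-type branching process over genotypes and compartments.

Each cell type ("class") is a (genotype, compartment) pair.  A cell of
class (i, j) divides at rate b_ij; upon division one daughter mutates to
genotype i+1 with probability u (never for the top genotype).  It dies at
rate d_ij and migrates to neighbouring compartments according to the
migration topology, keeping its genotype.  The probability generating
function F_ij(X; t) of the lineage started by one (i, j) cell obeys the
backward Kolmogorov system

    dF_ij/dt = d_ij + b_ij (1-u) F_ij^2 + b_ij u F_ij F_(i+1)j
               + sum_k v_(j->k) F_ik - (d_ij + b_ij + v_j) F_ij

with F_ij(X; 0) = x_ij.  Classes are flattened genotype-major:
flat index k = i * M + j, so the minimal model (n = 2, M = 2) orders its
dummy variables (x00, x01, x10, x11).

The in-memory representation is deliberately more general than the
genotype-grid construction: per-class birth/death rates, an arbitrary
single-target mutation map, and an arbitrary sparse migration graph.
Constrained pathway chains reuse the same machinery unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .exceptions import ConfigurationError
from .fitness import RateTable

__all__ = [
    "CellClass",
    "MutationSpec",
    "MigrationSpec",
    "BranchingModel",
    "build_model",
    "pgf_rhs",
]


class CellClass(NamedTuple):
    """One type of the branching process: a (genotype, compartment) pair."""

    genotype: int
    compartment: int


@dataclass(frozen=True)
class MutationSpec:
    """Probability u that one daughter mutates (genotype +1) at a division."""

    u: float

    def __post_init__(self):
        if not 0 <= self.u <= 1:
            raise ConfigurationError(f"mutation probability u must be in [0, 1], got {self.u}")


#: Supported migration topologies.
#:
#: ``pairwise``  two compartments exchanging cells at rate v each way.
#: ``ring``      compartments on a ring; rate v/2 to each nearest neighbour.
#: ``global``    fully connected; rate v/(M-1) to every other compartment.
#: ``line``      compartments on a line (radial shells); interior compartments
#:               send v/2 to each neighbour.  Edge behaviour is set by
#:               ``edge_mode``: "half" (default) keeps the per-neighbour rate
#:               v/2 so edge outflow is v/2; "full" sends rate v to the single
#:               neighbour.
TOPOLOGIES = ("pairwise", "ring", "global", "line", "none")


@dataclass(frozen=True)
class MigrationSpec:
    rate: float
    topology: str = "pairwise"
    edge_mode: str = "half"

    def __post_init__(self):
        if self.rate < 0:
            raise ConfigurationError(f"migration rate must be >= 0, got {self.rate}")
        if self.topology not in TOPOLOGIES:
            raise ConfigurationError(
                f"unknown topology {self.topology!r}; expected one of {TOPOLOGIES}"
            )
        if self.edge_mode not in ("half", "full"):
            raise ConfigurationError(f"edge_mode must be 'half' or 'full', got {self.edge_mode!r}")

    def edges(self, M: int) -> list[list[tuple[int, float]]]:
        """Per-compartment list of (target compartment, rate) pairs."""
        v = self.rate
        if self.topology == "none":
            if v > 0:
                raise ConfigurationError("topology 'none' requires migration rate 0")
            return [[] for _ in range(M)]
        if self.topology == "pairwise":
            if M != 2:
                raise ConfigurationError(f"pairwise topology requires M=2, got M={M}")
            return [[(1, v)], [(0, v)]]
        if M < 2:
            raise ConfigurationError(
                f"topology {self.topology!r} requires at least 2 compartments, got M={M}"
            )
        out: list[list[tuple[int, float]]] = []
        if self.topology == "ring":
            for j in range(M):
                left, right = (j - 1) % M, (j + 1) % M
                if left == right:  # M == 2: both neighbours coincide
                    out.append([(left, v)])
                else:
                    out.append([(left, v / 2), (right, v / 2)])
        elif self.topology == "global":
            each = v / (M - 1)
            for j in range(M):
                out.append([(k, each) for k in range(M) if k != j])
        else:  # line
            for j in range(M):
                nbrs = [k for k in (j - 1, j + 1) if 0 <= k < M]
                if len(nbrs) == 2:
                    out.append([(k, v / 2) for k in nbrs])
                else:
                    edge_rate = v / 2 if self.edge_mode == "half" else v
                    out.append([(nbrs[0], edge_rate)])
        return out


class BranchingModel:
    """Complete rate specification of the multi-type branching process.

    Stores flat per-class arrays: ``birth``, ``death``, ``mut_prob`` and
    ``mut_target`` (flat index of the mutant daughter class, -1 if the class
    cannot mutate), plus a sparse migration graph in CSR layout
    (``mig_indptr``, ``mig_indices``, ``mig_rates``).
    """

    def __init__(
        self,
        birth: np.ndarray,
        death: np.ndarray,
        mut_prob: np.ndarray,
        mut_target: np.ndarray,
        migration_edges: Sequence[Sequence[tuple[int, float]]],
        n_genotypes: int | None = None,
        n_compartments: int | None = None,
        labels: Sequence[CellClass] | None = None,
    ):
        self.birth = np.asarray(birth, dtype=float)
        self.death = np.asarray(death, dtype=float)
        self.mut_prob = np.asarray(mut_prob, dtype=float)
        self.mut_target = np.asarray(mut_target, dtype=np.int64)
        K = self.birth.size
        for name, arr in (("death", self.death), ("mut_prob", self.mut_prob),
                          ("mut_target", self.mut_target)):
            if arr.shape != (K,):
                raise ConfigurationError(f"{name} must have shape ({K},), got {arr.shape}")
        if np.any(self.birth < 0) or np.any(self.death < 0):
            raise ConfigurationError("birth and death rates must be non-negative")
        if np.any((self.mut_prob < 0) | (self.mut_prob > 1)):
            raise ConfigurationError("mutation probabilities must be in [0, 1]")
        bad = (self.mut_prob > 0) & ((self.mut_target < 0) | (self.mut_target >= K))
        if np.any(bad):
            raise ConfigurationError(
                f"classes {np.flatnonzero(bad).tolist()} mutate but lack a valid target"
            )

        indptr = [0]
        indices: list[int] = []
        rates: list[float] = []
        for k, targets in enumerate(migration_edges):
            for tgt, r in targets:
                if not 0 <= tgt < K:
                    raise ConfigurationError(f"migration target {tgt} of class {k} out of range")
                if r < 0:
                    raise ConfigurationError(f"negative migration rate on class {k}")
                indices.append(tgt)
                rates.append(r)
            indptr.append(len(indices))
        if len(migration_edges) != K:
            raise ConfigurationError("migration_edges must have one entry per class")
        self.mig_indptr = np.asarray(indptr, dtype=np.int64)
        self.mig_indices = np.asarray(indices, dtype=np.int64)
        self.mig_rates = np.asarray(rates, dtype=float)

        self.n_genotypes = n_genotypes
        self.n_compartments = n_compartments
        if labels is None and n_genotypes is not None and n_compartments is not None:
            labels = [
                CellClass(i, j) for i in range(n_genotypes) for j in range(n_compartments)
            ]
        self.labels = tuple(labels) if labels is not None else tuple(
            CellClass(0, k) for k in range(K)
        )
        if len(self.labels) != K:
            raise ConfigurationError("labels must have one entry per class")

        # derived, fixed arrays used by the ODE right-hand sides
        self.vout = np.zeros(K)
        for k in range(K):
            self.vout[k] = self.mig_rates[self.mig_indptr[k]: self.mig_indptr[k + 1]].sum()
        self._mut_safe = np.where(self.mut_target >= 0, self.mut_target, 0)
        self._mut_mask = (self.mut_prob > 0).astype(float)
        mig = np.zeros((K, K))
        for k in range(K):
            sl = slice(self.mig_indptr[k], self.mig_indptr[k + 1])
            np.add.at(mig[k], self.mig_indices[sl], self.mig_rates[sl])
        self._mig_matrix = mig
        # linear part of the survival-form ODE (see pgf module)
        A = mig.copy()
        A[np.diag_indices(K)] += self.birth * (1 - self.mut_prob) - self.death - self.vout
        rows = np.flatnonzero(self.mut_prob > 0)
        np.add.at(A, (rows, self.mut_target[rows]), self.birth[rows] * self.mut_prob[rows])
        self._survival_linear = A

    @property
    def n_classes(self) -> int:
        return self.birth.size

    def class_index(self, cc: CellClass | tuple[int, int]) -> int:
        """Flat index of a (genotype, compartment) pair (genotype-major)."""
        cc = CellClass(*cc)
        if self.n_genotypes is not None and self.n_compartments is not None:
            if not (0 <= cc.genotype < self.n_genotypes):
                raise ConfigurationError(f"genotype {cc.genotype} out of range")
            if not (0 <= cc.compartment < self.n_compartments):
                raise ConfigurationError(f"compartment {cc.compartment} out of range")
            return cc.genotype * self.n_compartments + cc.compartment
        try:
            return self.labels.index(cc)
        except ValueError:
            raise ConfigurationError(f"unknown class {cc}") from None

    def total_event_rate(self) -> np.ndarray:
        """Per-class total outflow rate b + d + v (per cell per day)."""
        return self.birth + self.death + self.vout

    def summary(self) -> str:
        """Human-readable dump of all per-class rates for provenance logs."""
        lines = [f"BranchingModel with {self.n_classes} classes"]
        for k, lab in enumerate(self.labels):
            sl = slice(self.mig_indptr[k], self.mig_indptr[k + 1])
            mig = ", ".join(
                f"->{t}@{r:g}" for t, r in zip(self.mig_indices[sl], self.mig_rates[sl])
            )
            lines.append(
                f"  [{k}] {tuple(lab)}: b={self.birth[k]:.6g} d={self.death[k]:.6g} "
                f"u={self.mut_prob[k]:g} mut->{self.mut_target[k]} mig[{mig}]"
            )
        return "\n".join(lines)


def build_model(
    rates: RateTable, mutation: MutationSpec, migration: MigrationSpec
) -> BranchingModel:
    """Assemble the canonical genotype-ladder model from a rate table.

    Mutation is strictly stepwise (genotype i -> i+1, same compartment) and
    the top genotype produces no further mutants.  Migration moves a cell to
    a neighbouring compartment at the topology's per-target rates, keeping
    its genotype.
    """
    n, M = rates.n_genotypes, rates.n_compartments
    comp_edges = migration.edges(M)
    K = n * M
    birth = rates.birth.ravel()
    death = rates.death.ravel()
    mut_prob = np.zeros(K)
    mut_target = np.full(K, -1, dtype=np.int64)
    edges: list[list[tuple[int, float]]] = []
    for i in range(n):
        for j in range(M):
            k = i * M + j
            if i < n - 1:
                mut_prob[k] = mutation.u
                mut_target[k] = k + M
            edges.append([(i * M + tgt, r) for tgt, r in comp_edges[j]])
    return BranchingModel(
        birth, death, mut_prob, mut_target, edges,
        n_genotypes=n, n_compartments=M,
    )


def pgf_rhs(model: BranchingModel, F: np.ndarray) -> np.ndarray:
    """Time derivative of the backward PGF system at the point F.

    Accepts a vector of shape (K,) or a batch (K, B).  F identically one is
    a fixed point (normalisation), and at F = 0 the derivative equals the
    death-rate vector.
    """
    F = np.asarray(F)
    if F.shape[0] != model.n_classes:
        raise ConfigurationError(
            f"F must have {model.n_classes} entries per column, got shape {F.shape}"
        )
    b, d, u = model.birth, model.death, model.mut_prob
    if F.ndim == 2:
        b, d, u = b[:, None], d[:, None], u[:, None]
        vout = model.vout[:, None]
        mask = model._mut_mask[:, None]
    else:
        vout = model.vout
        mask = model._mut_mask
    Fmut = F[model._mut_safe] * mask
    mig = model._mig_matrix @ F
    return (
        d
        + b * (1 - u) * F**2
        + b * u * F * Fmut
        + mig
        - (d + b + vout) * F
    )
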