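"""Joint resistant-cell-count distributions by PGF inversion on the unit torus.

The probability p_mn(t) that a lineage holds exactly m cells of one target
class and n of another is a double Cauchy contour integral of the PGF,
approximated by the trapezoid rule on an N x N grid of torus points

    p_mn(t) ~= (1/N^2) sum_{k1,k2} F(..., e^{i 2 pi k1 / N}, e^{i 2 pi k2 / N}; t)
                         e^{-i 2 pi m k1 / N} e^{-i 2 pi n k2 / N},

i.e. a two-dimensional discrete Fourier transform of the PGF evaluated with
the two target dummy variables on the unit circle and all other coordinates
clamped at 1.  The N^2 evaluations share one batched integration of the
backward ODEs (only the initial conditions differ).  Aliasing folds the
probability of counts >= N onto the grid, so N must comfortably exceed the
largest count of interest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .exceptions import ConfigurationError, ConvergenceError
from .model import BranchingModel, CellClass
from .pgf import _survival_rhs_batched

__all__ = [
    "InversionConfig",
    "JointCountDistribution",
    "joint_resistant_distribution",
    "marginal_count_distribution",
    "conditional_on_presence",
]


@dataclass(frozen=True)
class InversionConfig:
    """Settings for the torus inversion.

    ``grid_size`` is the number of torus nodes per dimension; ``max_count``
    the largest count kept in the reported matrix.  The grid must be much
    finer than the counts of interest to control aliasing (at least 2x).
    ``target_classes`` are the two (genotype, compartment) coordinates kept
    as free dummy variables; None selects the resistant classes of a
    two-compartment, two-genotype model (sanctuary first).
    """

    grid_size: int = 128
    max_count: int = 20
    target_classes: tuple | None = None
    rtol: float = 1e-10
    atol: float = 1e-12

    def __post_init__(self):
        if self.grid_size < 2 * (self.max_count + 1):
            raise ConfigurationError(
                f"grid_size {self.grid_size} must be at least twice max_count+1 "
                f"({self.max_count + 1}) to control aliasing"
            )

    def resolve_targets(self, model: BranchingModel) -> tuple[int, int]:
        if self.target_classes is not None:
            a, b = self.target_classes
            return model.class_index(a), model.class_index(b)
        if model.n_genotypes != 2 or model.n_compartments != 2:
            raise ConfigurationError(
                "target_classes must be given explicitly for models other "
                "than the two-genotype, two-compartment minimal model"
            )
        return model.class_index(CellClass(1, 0)), model.class_index(CellClass(1, 1))


@dataclass(frozen=True)
class JointCountDistribution:
    """p_mn(t) over counts of the two target classes (rows: first target)."""

    probs: np.ndarray
    time: float
    mass_on_grid: float
    max_imag: float
    target_classes: tuple

    def marginal(self, axis: int) -> np.ndarray:
        return self.probs.sum(axis=1 - axis)

    def mean_counts(self) -> tuple[float, float]:
        m = np.arange(self.probs.shape[0])
        n = np.arange(self.probs.shape[1])
        return float(m @ self.probs.sum(axis=1)), float(self.probs.sum(axis=0) @ n)


def _torus_pgf_grid(
    model: BranchingModel,
    start_class: int,
    t: float,
    targets: tuple[int, int],
    N: int,
    rtol: float,
    atol: float,
) -> np.ndarray:
    """F_start on the N x N torus grid (all other coordinates at 1)."""
    K = model.n_classes
    theta = 2.0 * np.pi * np.arange(N) / N
    circle = np.exp(1j * theta)
    g0 = np.zeros((K, N, N), dtype=np.complex128)
    ta, tb = targets
    g0[ta] = (1.0 - circle)[:, None]
    g0[tb] = (1.0 - circle)[None, :]
    if ta == tb:
        raise ConfigurationError("the two target classes must differ")
    if t == 0:
        F0 = 1.0 - g0[start_class]
        return F0
    rhs = _survival_rhs_batched(model, N * N)
    sol = solve_ivp(
        rhs,
        (0.0, t),
        g0.reshape(K, N * N).ravel().view(np.float64),
        method="DOP853",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise ConvergenceError(f"torus PGF integration failed: {sol.message}")
    G = sol.y[:, -1].copy().view(np.complex128).reshape(K, N, N)
    return 1.0 - G[start_class]


def joint_resistant_distribution(
    model: BranchingModel,
    start_class: CellClass | tuple | int,
    t: float,
    config: InversionConfig = InversionConfig(),
) -> JointCountDistribution:
    """Joint distribution of the two target-class counts at time ``t``.

    The lineage starts from a single cell of ``start_class``.  Negative and
    imaginary numerical noise is checked against tolerances *before* being
    clipped, so clipping cannot mask an integrator failure.
    """
    if t < 0:
        raise ConfigurationError("t must be >= 0")
    start = start_class if isinstance(start_class, (int, np.integer)) \
        else model.class_index(start_class)
    targets = config.resolve_targets(model)
    N = config.grid_size
    F = _torus_pgf_grid(model, start, t, targets, N, config.rtol, config.atol)
    P = np.fft.fft2(F) / N**2
    max_imag = float(np.abs(P.imag).max())
    if max_imag > 1e-8:
        raise ConvergenceError(
            f"imaginary residue {max_imag:.2e} of the inverse transform exceeds "
            "1e-8; tighten the integrator tolerances"
        )
    Pr = P.real
    mass = float(Pr.sum())
    neg = float(-min(Pr.min(), 0.0))
    if neg > 1e-8:
        raise ConvergenceError(
            f"negative probability {-neg:.2e} beyond numerical noise; "
            "tighten the integrator tolerances"
        )
    if mass < 1 - 1e-6:
        warnings.warn(
            f"probability mass on the inversion grid is {mass:.8f}; "
            f"an estimated {1 - mass:.2e} spills beyond counts of {N - 1} "
            "(aliasing) — increase grid_size",
            stacklevel=2,
        )
    Pr = np.clip(Pr, 0.0, None)
    k = config.max_count + 1
    return JointCountDistribution(
        probs=Pr[:k, :k].copy(),
        time=t,
        mass_on_grid=mass,
        max_imag=max_imag,
        target_classes=targets,
    )


def marginal_count_distribution(
    model: BranchingModel,
    start_class: CellClass | tuple | int,
    t: float,
    target_class: CellClass | tuple | int,
    grid_size: int = 128,
    max_count: int = 20,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> np.ndarray:
    """One-dimensional count distribution of a single target class."""
    start = start_class if isinstance(start_class, (int, np.integer)) \
        else model.class_index(start_class)
    tgt = target_class if isinstance(target_class, (int, np.integer)) \
        else model.class_index(target_class)
    K, N = model.n_classes, grid_size
    circle = np.exp(2j * np.pi * np.arange(N) / N)
    g0 = np.zeros((K, N), dtype=np.complex128)
    g0[tgt] = 1.0 - circle
    if t == 0:
        F = 1.0 - g0[start]
    else:
        rhs = _survival_rhs_batched(model, N)
        sol = solve_ivp(
            rhs, (0.0, t), g0.ravel().view(np.float64),
            method="DOP853", rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise ConvergenceError(f"torus PGF integration failed: {sol.message}")
        F = 1.0 - sol.y[:, -1].copy().view(np.complex128).reshape(K, N)[start]
    p = (np.fft.fft(F) / N).real
    return np.clip(p[: max_count + 1], 0.0, None)


def conditional_on_presence(dist: JointCountDistribution, axis: int) -> JointCountDistribution:
    """Renormalise on {count > 0 along ``axis``} (0: first target, 1: second)."""
    if axis not in (0, 1):
        raise ConfigurationError("axis must be 0 or 1")
    probs = dist.probs.copy()
    if axis == 0:
        probs[0, :] = 0.0
    else:
        probs[:, 0] = 0.0
    mass = probs.sum()
    if mass <= 0:
        raise ConfigurationError(
            "conditioning event {count > 0} has zero probability mass"
        )
    return JointCountDistribution(
        probs=probs / mass,
        time=dist.time,
        mass_on_grid=float(mass),
        max_imag=dist.max_imag,
        target_classes=dist.target_classes,
    )
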