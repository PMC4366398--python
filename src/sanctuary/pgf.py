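"""Backward-ODE engine: escape probabilities and conditional relapse kinetics.

Everything downstream of the branching model reduces to evaluating the
probability generating function F(X; t) of single-cell lineages at chosen
dummy-variable points X, then composing over an initial census N_ij by
lineage independence:  P(no resistant cells at t) = prod_ij F_ij(X*; t)^N_ij
with X* the resistant mask point (resistant coordinates 0, others 1).

Numerically the system is integrated in *survival form* G = 1 - F:

    dG_ij/dt = (b(1-u) - d - v) G_ij + b u G_(i+1)j
               + sum_k v_(j->k) G_ik - b(1-u) G_ij^2 - b u G_ij G_(i+1)j

which is algebraically identical to the F-form but keeps G = 0 an exact
fixed point, so probabilities within 1e-9 of one survive the cancellation
in log1p/expm1-composed census products (initial cell counts up to 1e11
with per-cell escape probabilities of order u ~ 1e-9 are routine).

The t -> infinity limit of the backward flow is obtained by integrating
until the RHS norm is below tolerance and then Newton-polishing the
algebraic fixed-point system; starting the flow at the evaluation point
itself selects the relevant (minimal) fixed point in [0, 1]^K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .exceptions import ConfigurationError, ConvergenceError, NullConditioningError
from .model import BranchingModel, CellClass

__all__ = [
    "PopulationCensus",
    "ResistantMask",
    "PGFTrajectory",
    "RelapseCurve",
    "solve_pgf",
    "limiting_pgf",
    "escape_probability",
    "relapse_curve",
    "mean_time_to_resistance",
]

#: Default integrator tolerances.  Conditional relapse probabilities involve
#: differences of order u*v, so the relative tolerance is deliberately tight.
RTOL = 1e-10
ATOL = 1e-14


# --------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class PopulationCensus:
    """Initial cell counts per class, as a flat array aligned with the model."""

    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 1 or np.any(counts < 0):
            raise ConfigurationError("census must be a flat vector of non-negative counts")
        object.__setattr__(self, "counts", counts)

    @classmethod
    def from_dict(cls, model: BranchingModel, counts: dict) -> "PopulationCensus":
        """Build from a {(genotype, compartment): count} mapping."""
        flat = np.zeros(model.n_classes)
        for cc, n in counts.items():
            flat[model.class_index(cc)] += n
        return cls(flat)

    @classmethod
    def single_cell(cls, model: BranchingModel, cc: CellClass | tuple) -> "PopulationCensus":
        return cls.from_dict(model, {tuple(cc): 1})

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def restricted_to_compartment(self, model: BranchingModel, j: int) -> "PopulationCensus":
        """Sub-census of the lineages that start in compartment ``j``."""
        flat = np.where(
            np.array([lab.compartment == j for lab in model.labels]), self.counts, 0.0
        )
        return PopulationCensus(flat)


@dataclass(frozen=True)
class ResistantMask:
    """Which classes count as "resistance present".

    Default: genotype >= ``genotype_min`` in any compartment; optionally
    restricted to a set of compartments.  ``extra_classes`` admits masks that
    are not genotype thresholds (e.g. the destination class of a pathway
    chain).
    """

    genotype_min: int | None = None
    compartments: frozenset[int] | None = None
    extra_classes: frozenset[int] = frozenset()

    def class_indices(self, model: BranchingModel) -> np.ndarray:
        idx = set(self.extra_classes)
        if self.genotype_min is not None:
            for k, lab in enumerate(model.labels):
                if lab.genotype >= self.genotype_min and (
                    self.compartments is None or lab.compartment in self.compartments
                ):
                    idx.add(k)
        if not idx:
            raise ConfigurationError("resistant mask selects no classes")
        return np.array(sorted(idx), dtype=np.int64)

    def eval_point(self, model: BranchingModel) -> np.ndarray:
        """Dummy-variable point: 0 at resistant classes, 1 elsewhere."""
        x = np.ones(model.n_classes)
        x[self.class_indices(model)] = 0.0
        return x


@dataclass(frozen=True)
class PGFTrajectory:
    """F(X; t) on a time grid; values has shape (n_classes, n_times)."""

    times: np.ndarray
    values: np.ndarray
    eval_point: np.ndarray


@dataclass(frozen=True)
class RelapseCurve:
    """Conditional no-resistance probability p_s(t) and its mean integral."""

    times: np.ndarray
    ps: np.ndarray
    ps_infinity: float = 0.0
    mean_time: float = field(default=np.nan)
    escape_probability: float = field(default=np.nan)


# --------------------------------------------------------------------------
# survival-form right-hand side


def _survival_rhs_factory(model: BranchingModel):
    A = model._survival_linear
    bq = model.birth * (1 - model.mut_prob)
    bu = model.birth * model.mut_prob
    mt, mask = model._mut_safe, model._mut_mask

    def rhs(t, g):
        gm = g[mt] * mask
        return A @ g - bq * g * g - bu * g * gm

    def jac(t, g):
        J = A.copy()
        gm = g[mt] * mask
        J[np.diag_indices_from(J)] -= 2 * bq * g + bu * gm
        rows = np.flatnonzero(mask)
        np.add.at(J, (rows, mt[rows]), -bu[rows] * g[rows])
        return J

    return rhs, jac


def _survival_rhs_batched(model: BranchingModel, n_batch: int):
    """Complex, batched RHS over flattened real state (for torus inversion)."""
    A = model._survival_linear
    bq = (model.birth * (1 - model.mut_prob))[:, None]
    bu = (model.birth * model.mut_prob)[:, None]
    mt, mask = model._mut_safe, model._mut_mask[:, None]
    K = model.n_classes

    def rhs(t, y):
        g = y.view(np.complex128).reshape(K, n_batch)
        gm = g[mt] * mask
        dg = A @ g - bq * g * g - bu * g * gm
        return dg.ravel().view(np.float64)

    return rhs


def _integrate_survival(model, g0, t_grid, rtol=RTOL, atol=ATOL, dense=False):
    rhs, jac = _survival_rhs_factory(model)
    t_grid = np.asarray(t_grid, dtype=float)
    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        np.asarray(g0, dtype=float),
        method="LSODA",
        jac=jac,
        t_eval=None if dense else t_grid,
        dense_output=dense,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise ConvergenceError(
            f"PGF integration failed near t={sol.t[-1]:.6g}: {sol.message}",
            last_iterate=sol.y[:, -1],
        )
    return sol


# --------------------------------------------------------------------------
# public operations


def solve_pgf(
    model: BranchingModel,
    eval_point: np.ndarray,
    t_grid: np.ndarray,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> PGFTrajectory:
    """Integrate the backward PGF system from F(X; 0) = X on ``t_grid``.

    ``eval_point`` may be real in [0, 1]^K or complex with modulus <= 1 (the
    torus points used by the count-distribution inversion).  F(1; t) = 1 is
    preserved exactly, and real trajectories stay in [0, 1]^K.
    """
    x = np.asarray(eval_point)
    if x.shape != (model.n_classes,):
        raise ConfigurationError(
            f"eval_point must have shape ({model.n_classes},), got {x.shape}"
        )
    if np.any(np.abs(x) > 1 + 1e-12):
        raise ConfigurationError("eval_point entries must have modulus <= 1")
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
    if t_grid[0] != 0:
        t_grid = np.concatenate([[0.0], t_grid])
    g0 = 1.0 - x
    if t_grid[-1] == 0.0:
        return PGFTrajectory(times=t_grid, values=x[:, None], eval_point=x)
    if np.iscomplexobj(g0):
        rhs = _survival_rhs_batched(model, 1)
        sol = solve_ivp(
            rhs, (0.0, t_grid[-1]), g0[:, None].ravel().view(np.float64),
            method="DOP853", t_eval=t_grid, rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise ConvergenceError(f"PGF integration failed: {sol.message}")
        G = sol.y.T.copy().view(np.complex128).T.reshape(model.n_classes, -1)
    else:
        sol = _integrate_survival(model, g0, t_grid, rtol=rtol, atol=atol)
        G = np.clip(sol.y, 0.0, 1.0)
    return PGFTrajectory(times=t_grid, values=1.0 - G, eval_point=x)


def _limiting_survival(
    model: BranchingModel,
    g0: np.ndarray,
    rhs_tol: float = 1e-12,
    t_max: float = 1e8,
) -> np.ndarray:
    """Stable limit of the backward flow started at g0 (survival form)."""
    rhs, jac = _survival_rhs_factory(model)
    g = np.asarray(g0, dtype=float).copy()
    T = 50.0
    while True:
        if np.max(np.abs(rhs(0.0, g))) < rhs_tol:
            break
        sol = _integrate_survival(model, g, [0.0, T])
        g = np.clip(sol.y[:, -1], 0.0, 1.0)
        T *= 2
        if T > t_max:
            raise ConvergenceError(
                "backward flow did not settle within the configured horizon",
                last_iterate=g,
            )
    # Newton polish of the algebraic fixed point; keep the integrated value
    # if the root-finder wanders off to a different fixed point.
    res = root(lambda x: rhs(0.0, x), g, jac=lambda x: jac(0.0, x), method="hybr", tol=1e-14)
    if res.success and np.max(np.abs(res.x - g)) < 1e-6:
        g = res.x
    return np.clip(g, 0.0, 1.0)


def limiting_pgf(model: BranchingModel, eval_point: np.ndarray) -> np.ndarray:
    """Per-class limits F(X; infinity) of the backward flow started at X."""
    x = np.asarray(eval_point, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ConfigurationError("limiting_pgf requires a real eval_point in [0, 1]^K")
    return 1.0 - _limiting_survival(model, 1.0 - x)


def _log_no_resistance(counts: np.ndarray, g: np.ndarray) -> float | np.ndarray:
    """log prod (1 - g_k)^{N_k}, safely for counts up to ~1e11.

    Returns -inf when a populated class has g = 1 exactly.
    """
    active = counts > 0
    with np.errstate(divide="ignore"):
        logs = np.log1p(-g[..., active])
    return logs @ counts[active]


def escape_probability(
    model: BranchingModel,
    census: PopulationCensus,
    mask: ResistantMask,
) -> float:
    """Probability that resistance ever establishes, composed over the census.

    1 - prod_ij F_ij(X*; infinity)^{N_ij}, evaluated in the log domain.
    """
    if census.total < 1:
        raise ConfigurationError("census must contain at least one cell")
    ginf = _limiting_survival(model, 1.0 - mask.eval_point(model))
    return float(-np.expm1(_log_no_resistance(census.counts, ginf)))


def relapse_curve(
    model: BranchingModel,
    census: PopulationCensus,
    mask: ResistantMask,
    t_grid: np.ndarray,
) -> RelapseCurve:
    """Conditional no-resistance probability p_s(t) on an explicit time grid.

        p_s(t) = [P(t) - P(inf)] / [1 - P(inf)],
        P(t) = prod F_ij(X*; t)^{N_ij},

    i.e. the probability that no resistant cell is present at time t,
    conditional on eventual resistance.  Raises NullConditioningError when
    the conditioning event has (numerically) zero probability.
    """
    if census.total < 1:
        raise ConfigurationError("census must contain at least one cell")
    g0 = 1.0 - mask.eval_point(model)
    ginf = _limiting_survival(model, g0)
    L_inf = _log_no_resistance(census.counts, ginf)
    denom = -np.expm1(L_inf)  # escape probability
    if denom < 1e-12:
        raise NullConditioningError(
            f"eventual-resistance probability is {denom:.3e}; "
            "the conditional relapse curve is undefined"
        )
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
    if t_grid[0] != 0:
        t_grid = np.concatenate([[0.0], t_grid])
    sol = _integrate_survival(model, g0, t_grid)
    G = np.clip(sol.y, 0.0, 1.0)
    L_t = np.array([_log_no_resistance(census.counts, G[:, i]) for i in range(G.shape[1])])
    ps = _conditional_ps(L_t, L_inf, denom)
    return RelapseCurve(
        times=t_grid,
        ps=ps,
        ps_infinity=float(np.exp(L_inf)),
        escape_probability=float(denom),
    )


def _conditional_ps(L_t: np.ndarray, L_inf: float, denom: float) -> np.ndarray:
    """(exp(L_t) - exp(L_inf)) / denom without cancellation at either end."""
    if np.isinf(L_inf) or np.exp(L_inf) < 0.25:
        ps = (np.exp(L_t) - np.exp(L_inf)) / denom
    else:
        ps = np.exp(L_inf) * np.expm1(np.maximum(L_t - L_inf, 0.0)) / denom
    return np.clip(ps, 0.0, 1.0)


def mean_time_to_resistance(
    model: BranchingModel,
    census: PopulationCensus,
    mask: ResistantMask,
    ps_tail: float = 1e-4,
    t_start: float = 100.0,
    t_max: float = 2e6,
    n_quad: int = 4097,
) -> float:
    """Conditional mean time to resistance, the time integral of p_s.

    The horizon is doubled until p_s drops below ``ps_tail``; the integral is
    a trapezoid rule on ``n_quad`` points plus an analytic exponential-tail
    correction fitted to the final decade of decay (truncating at a finite
    horizon alone would bias the mean low).
    """
    if census.total < 1:
        raise ConfigurationError("census must contain at least one cell")
    g0 = 1.0 - mask.eval_point(model)
    ginf = _limiting_survival(model, g0)
    L_inf = _log_no_resistance(census.counts, ginf)
    denom = -np.expm1(L_inf)
    if denom < 1e-12:
        raise NullConditioningError(
            f"eventual-resistance probability is {denom:.3e}; "
            "the conditional mean time is undefined"
        )
    T = t_start
    while True:
        sol = _integrate_survival(model, g0, [0.0, T], dense=True)
        t_q = np.linspace(0.0, T, n_quad)
        G = np.clip(sol.sol(t_q), 0.0, 1.0)
        L_t = _log_no_resistance(census.counts, G.T)
        ps = _conditional_ps(np.asarray(L_t), L_inf, denom)
        if ps[-1] < ps_tail:
            break
        T *= 2
        if T > t_max:
            raise ConvergenceError(
                f"p_s(t) has not decayed below {ps_tail} by t={t_max:g} days; "
                "the resistant classes may be misconfigured (subcritical)",
                last_iterate=ps[-1],
            )
    integral = float(np.trapezoid(ps, t_q))
    # exponential-tail correction from the last decade of decay
    tail = 0.0
    sel = (ps <= 10 * ps[-1]) & (ps > 0)
    if ps[-1] > 0 and sel.sum() >= 3:
        slope = np.polyfit(t_q[sel], np.log(ps[sel]), 1)[0]
        if slope < 0:
            tail = float(ps[-1] / -slope)
    return integral + tail
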