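"""Exact stochastic simulation of the branching process (the oracle).

Direct Gillespie SSA over the same per-class event list the PGF engine
integrates: exponential waiting times at the total rate, events chosen
proportionally to their rates.  Tau-leaping is deliberately not offered —
the whole point of this module is exactness, so PGF-derived probabilities
and times can be validated against replicate ensembles.  Large-population
regimes are the PGF engine's job; a population cap (with an explicit
truncation flag) guards against unbounded supercritical growth.

Per-replicate seeds are derived from the ensemble seed through numpy's
SeedSequence spawning, so ensembles are reproducible and replicates
independent regardless of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .exceptions import ConfigurationError
from .model import BranchingModel
from .pgf import PopulationCensus, ResistantMask

__all__ = ["SimSummary", "simulate", "replicate_ensemble"]


@dataclass(frozen=True)
class SimSummary:
    """Aggregated ensemble record.

    ``checkpoint_counts`` has shape (n_reps, n_checkpoints, n_classes) and
    holds the per-class cell counts at each checkpoint time.
    ``first_resistance`` is the first time a masked class became occupied
    (inf if never, within the horizon).  ``truncated`` flags replicates that
    hit the population cap (their later checkpoints repeat the state at
    truncation).
    """

    checkpoint_times: np.ndarray
    checkpoint_counts: np.ndarray
    first_resistance: np.ndarray
    final_counts: np.ndarray
    truncated: np.ndarray
    mask_indices: np.ndarray

    @property
    def n_reps(self) -> int:
        return self.checkpoint_counts.shape[0]

    def resistance_present(self, checkpoint: int) -> np.ndarray:
        """Boolean per replicate: any masked-class cell at the checkpoint."""
        return self.checkpoint_counts[:, checkpoint, :][:, self.mask_indices].sum(axis=1) > 0

    def no_resistance_fraction(self, checkpoint: int) -> float:
        """Empirical P(no resistant cells present at the checkpoint time)."""
        return float(1.0 - self.resistance_present(checkpoint).mean())

    def survival_fraction(self, checkpoint: int) -> float:
        """Fraction of replicates with any cell alive at the checkpoint."""
        return float((self.checkpoint_counts[:, checkpoint, :].sum(axis=1) > 0).mean())

    def joint_histogram(
        self, checkpoint: int, class_a: int, class_b: int, max_count: int
    ) -> np.ndarray:
        """Empirical joint distribution of two class counts, clipped at max_count."""
        ca = np.minimum(self.checkpoint_counts[:, checkpoint, class_a], max_count)
        cb = np.minimum(self.checkpoint_counts[:, checkpoint, class_b], max_count)
        hist = np.zeros((max_count + 1, max_count + 1))
        np.add.at(hist, (ca, cb), 1.0)
        return hist / self.n_reps

    def standard_error(self, fraction: float) -> float:
        """Binomial Monte-Carlo standard error of an empirical fraction."""
        return float(np.sqrt(max(fraction * (1 - fraction), 1e-12) / self.n_reps))


@njit(cache=True)
def _ssa_one(
    counts0, birth, death, mut_prob, mut_target,
    mig_indptr, mig_indices, mig_rates, vout,
    horizon, checkpoints, mask, cap, seed,
):
    np.random.seed(seed)
    K = counts0.size
    counts = counts0.copy()
    rate_per = birth + death + vout
    n_ck = checkpoints.size
    ck_counts = np.zeros((n_ck, K), dtype=np.int64)
    ick = 0
    t = 0.0
    truncated = False
    total_cells = 0
    res_cells = 0
    for k in range(K):
        total_cells += counts[k]
        if mask[k]:
            res_cells += counts[k]
    first_res = np.inf if res_cells == 0 else 0.0

    while True:
        total_rate = 0.0
        for k in range(K):
            total_rate += counts[k] * rate_per[k]
        if total_rate <= 0.0 or truncated:
            t_next = horizon
        else:
            t_next = t + np.random.exponential(1.0 / total_rate)
        while ick < n_ck and checkpoints[ick] <= t_next:
            ck_counts[ick] = counts
            ick += 1
        if t_next >= horizon:
            break
        t = t_next

        # pick the class
        r = np.random.random() * total_rate
        acc = 0.0
        k = K - 1
        for kk in range(K):
            acc += counts[kk] * rate_per[kk]
            if r < acc:
                k = kk
                break
        # pick the event within the class
        r2 = np.random.random() * rate_per[k]
        if r2 < birth[k]:
            if mut_prob[k] > 0.0 and np.random.random() < mut_prob[k]:
                tgt = mut_target[k]
                counts[tgt] += 1
                if mask[tgt]:
                    res_cells += 1
                    if first_res == np.inf:
                        first_res = t
            else:
                counts[k] += 1
                if mask[k]:
                    res_cells += 1
                    if first_res == np.inf:
                        first_res = t
            total_cells += 1
        elif r2 < birth[k] + death[k]:
            counts[k] -= 1
            total_cells -= 1
            if mask[k]:
                res_cells -= 1
        elif mig_indptr[k + 1] == mig_indptr[k]:
            # float roundoff landed past b + d for a class without migration
            counts[k] -= 1
            total_cells -= 1
            if mask[k]:
                res_cells -= 1
        else:
            r3 = r2 - birth[k] - death[k]
            acc3 = 0.0
            tgt = mig_indices[mig_indptr[k + 1] - 1]
            for e in range(mig_indptr[k], mig_indptr[k + 1]):
                acc3 += mig_rates[e]
                if r3 < acc3:
                    tgt = mig_indices[e]
                    break
            counts[k] -= 1
            counts[tgt] += 1
            if mask[tgt] and not mask[k]:
                res_cells += 1
                if first_res == np.inf:
                    first_res = t
            elif mask[k] and not mask[tgt]:
                res_cells -= 1
        if total_cells > cap:
            truncated = True
    return ck_counts, first_res, counts, truncated


@njit(cache=True)
def _ssa_ensemble(
    counts0, birth, death, mut_prob, mut_target,
    mig_indptr, mig_indices, mig_rates, vout,
    horizon, checkpoints, mask, cap, seeds,
):
    n_reps = seeds.size
    K = counts0.size
    n_ck = checkpoints.size
    all_ck = np.zeros((n_reps, n_ck, K), dtype=np.int64)
    first_res = np.empty(n_reps)
    finals = np.zeros((n_reps, K), dtype=np.int64)
    trunc = np.zeros(n_reps, dtype=np.bool_)
    for r in range(n_reps):
        ck, fr, fin, tr = _ssa_one(
            counts0, birth, death, mut_prob, mut_target,
            mig_indptr, mig_indices, mig_rates, vout,
            horizon, checkpoints, mask, cap, seeds[r],
        )
        all_ck[r] = ck
        first_res[r] = fr
        finals[r] = fin
        trunc[r] = tr
    return all_ck, first_res, finals, trunc


def _prepare(model: BranchingModel, census: PopulationCensus, mask: ResistantMask):
    counts0 = np.asarray(np.round(census.counts), dtype=np.int64)
    if not np.allclose(counts0, census.counts):
        raise ConfigurationError("simulation requires an integer census")
    mask_idx = mask.class_indices(model)
    mask_arr = np.zeros(model.n_classes, dtype=np.bool_)
    mask_arr[mask_idx] = True
    return counts0, mask_idx, mask_arr


def simulate(
    model: BranchingModel,
    census: PopulationCensus,
    horizon: float,
    seed: int,
    checkpoints=None,
    mask: ResistantMask | None = None,
    cap: int = 10**6,
) -> SimSummary:
    """One exact SSA replicate (an ensemble of size 1)."""
    return replicate_ensemble(
        model, census, horizon, n_reps=1, seed=seed,
        checkpoints=checkpoints, mask=mask, cap=cap,
    )


def replicate_ensemble(
    model: BranchingModel,
    census: PopulationCensus,
    horizon: float,
    n_reps: int,
    seed: int,
    checkpoints=None,
    mask: ResistantMask | None = None,
    cap: int = 10**6,
) -> SimSummary:
    """Ensemble of exact SSA replicates with spawned per-replicate seeds."""
    if horizon <= 0:
        raise ConfigurationError("horizon must be positive")
    if n_reps < 1:
        raise ConfigurationError("n_reps must be >= 1")
    if mask is None:
        if model.n_genotypes is None:
            raise ConfigurationError("a resistant mask is required for this model")
        mask = ResistantMask(genotype_min=model.n_genotypes - 1)
    if checkpoints is None:
        checkpoints = [horizon]
    checkpoints = np.sort(np.asarray(checkpoints, dtype=float))
    if checkpoints[-1] > horizon:
        raise ConfigurationError("checkpoints must not exceed the horizon")
    counts0, mask_idx, mask_arr = _prepare(model, census, mask)
    seeds = np.random.SeedSequence(seed).generate_state(n_reps).astype(np.int64)
    ck, first_res, finals, trunc = _ssa_ensemble(
        counts0, model.birth, model.death, model.mut_prob, model.mut_target,
        model.mig_indptr, model.mig_indices, model.mig_rates, model.vout,
        float(horizon), checkpoints, mask_arr, cap, seeds,
    )
    return SimSummary(
        checkpoint_times=checkpoints,
        checkpoint_counts=ck,
        first_resistance=first_res,
        final_counts=finals,
        truncated=trunc,
        mask_indices=mask_idx,
    )
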