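"""Stochastic simulation of multi-arm multi-stage trials with early stopping.

Replicated trials are simulated on the Gaussian score scale that the
design machinery assumes: each group's cumulative standardized score is a
Brownian-motion path in the information (sample size) scale, treatment
arms carry drift ``sqrt(2) * Phi^{-1}(nu_k)`` per unit information, and
the pairwise statistic of arm ``k`` at stage ``j`` is
``Z_kj = (U_kj - U_0j) / sqrt(2)``.

Stopping semantics
------------------
* An arm whose statistic falls at or below the futility bound is dropped
  and stops accruing; the rest of the trial continues.
* Any arm crossing the efficacy bound stops the *entire* trial at that
  interim (simultaneous stopping); every arm that crosses at that same
  interim is flagged rejected.
* The trial also ends when all arms have been dropped, or after stage J.

Sample accounting: each treatment group contributes its cumulative
allocation up to its own stop stage; the control group accrues until the
whole trial stops.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .design import BoundarySet, DesignSpec

__all__ = [
    "AllocationMatrix",
    "TrialOutcome",
    "ScenarioResult",
    "build_allocation",
    "simulate_trial",
    "apply_stopping_rules",
    "operating_characteristics",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AllocationMatrix:
    """Cumulative per-group, per-stage sample sizes.

    ``entries[j, g]`` is the number of observations accrued by group ``g``
    through stage ``j`` (column 0 is the shared control).  Under equal
    allocation row ``j`` equals ``(j+1)/J`` times the final row.
    """

    entries: np.ndarray
    total_n: int

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=np.int64)
        if entries.ndim != 2:
            raise ValueError("entries must be a J x (K+1) matrix")
        if np.any(entries[0] < 1) or np.any(np.diff(entries, axis=0) <= 0):
            raise ValueError("cumulative allocations must be positive and strictly increasing")
        entries.setflags(write=False)
        object.__setattr__(self, "entries", entries)
        object.__setattr__(self, "total_n", int(entries[-1].sum()))

    @property
    def stages(self) -> int:
        return self.entries.shape[0]

    @property
    def n_groups(self) -> int:
        return self.entries.shape[1]

    @property
    def stage_totals(self) -> np.ndarray:
        """Grand total accrued through each stage if nothing stops early."""
        return self.entries.sum(axis=1)

    def increments(self) -> np.ndarray:
        """Per-stage (non-cumulative) group sizes, same shape as ``entries``."""
        return np.diff(self.entries, axis=0, prepend=0)


@dataclass(frozen=True)
class TrialOutcome:
    """Result of a single simulated trial."""

    stop_stage_by_arm: tuple[int, ...]
    rejected_by_arm: tuple[bool, ...]
    trial_stop_stage: int
    sample_used: int


@dataclass(frozen=True)
class ScenarioResult:
    """Operating characteristics of one (design, hypothesis-configuration) pair."""

    scenario: str
    ess_mean: float
    ess_min: int
    ess_max: int
    ess_std: float
    power_estimate: float
    any_rejection_rate: float
    mean_stages: float
    n_reps: int
    seed: int

    def __post_init__(self) -> None:
        if not self.ess_min <= self.ess_mean <= self.ess_max:
            raise ValueError("expected sample size must lie between min and max")
        if not 0.0 <= self.power_estimate <= 1.0:
            raise ValueError("power_estimate must be a probability")


def build_allocation(total_n: int, K: int, J: int) -> AllocationMatrix:
    """Equal-split cumulative allocation of ``total_n`` over ``K+1`` groups and ``J`` stages.

    If ``total_n`` is not divisible into ``J * (K+1)`` equal cells the cell
    size is rounded down and the remainder is logged (those units are
    simply not allocated).
    """
    if total_n < 1 or K < 1 or J < 1:
        raise ValueError("total_n, K and J must be positive")
    cells = J * (K + 1)
    cell = total_n // cells
    if cell < 1:
        raise ValueError(f"total_n={total_n} is too small for {cells} allocation cells")
    remainder = total_n - cell * cells
    if remainder:
        logger.info(
            "build_allocation: total_n=%d not divisible by %d cells; "
            "using cell size %d and dropping remainder %d",
            total_n, cells, cell, remainder,
        )
    entries = np.outer(np.arange(1, J + 1), np.full(K + 1, cell, dtype=np.int64))
    return AllocationMatrix(entries=entries, total_n=int(entries[-1].sum()))


# ---------------------------------------------------------------------------
# statistic generation and stopping rules
# ---------------------------------------------------------------------------


def _simulate_z_gaussian(
    alloc: AllocationMatrix, nu_vector: np.ndarray, rng: np.random.Generator, n_reps: int
) -> np.ndarray:
    """Pairwise statistics Z with shape (n_reps, K, J) under the Gaussian model."""
    n = alloc.entries.T.astype(float)  # (K+1, J) cumulative
    m = alloc.increments().T.astype(float)
    K = n.shape[0] - 1
    theta = np.sqrt(2.0) * stats.norm.ppf(nu_vector)  # standardized effect per arm
    incr = rng.standard_normal((n_reps, K + 1, n.shape[1])) * np.sqrt(m)
    incr[:, 1:, :] += theta[:, None] * m[1:]
    cum = np.cumsum(incr, axis=2) / np.sqrt(n)
    return (cum[:, 1:, :] - cum[:, :1, :]) / np.sqrt(2.0)


def apply_stopping_rules(
    z: np.ndarray, bounds: BoundarySet, alloc: AllocationMatrix
) -> dict[str, np.ndarray]:
    """Apply futility/efficacy stopping to a batch of statistic paths.

    Parameters
    ----------
    z : ndarray, shape (n_reps, K, J)
        Pairwise test statistics for every replicate, arm and stage
        (values at stages after a stop are ignored).

    Returns
    -------
    dict with per-replicate arrays: ``arm_stop_stage`` (1-based, shape
    ``(n_reps, K)``), ``rejected`` (bool, same shape), ``trial_stop_stage``
    (1-based, shape ``(n_reps,)``) and ``sample_used``.
    """
    n_reps, K, J = z.shape
    if bounds.stages != J or alloc.stages != J or alloc.n_groups != K + 1:
        raise ValueError("statistics, bounds and allocation disagree on dimensions")
    upper = bounds.upper_array()
    lower = bounds.lower_array()

    active = np.ones((n_reps, K), dtype=bool)
    arm_stop = np.full((n_reps, K), J, dtype=np.int64)
    rejected = np.zeros((n_reps, K), dtype=bool)
    trial_stop = np.full(n_reps, J, dtype=np.int64)
    trial_over = np.zeros(n_reps, dtype=bool)

    for j in range(J):
        live = ~trial_over
        zj = z[:, :, j]
        efficacy = active & (zj >= upper[j]) & live[:, None]
        futility = active & (zj <= lower[j]) & ~efficacy & live[:, None]

        rejected |= efficacy
        arm_stop[futility] = j + 1
        active &= ~futility

        stop_now = efficacy.any(axis=1)
        arm_stop[stop_now[:, None] & active] = j + 1
        active[stop_now] = False
        all_dropped = live & ~stop_now & ~active.any(axis=1)
        ended = stop_now | all_dropped
        trial_stop[ended & live] = j + 1
        trial_over |= ended

    entries = alloc.entries
    sample_used = entries[trial_stop - 1, 0].copy()
    for k in range(K):
        sample_used += entries[arm_stop[:, k] - 1, k + 1]
    return {
        "arm_stop_stage": arm_stop,
        "rejected": rejected,
        "trial_stop_stage": trial_stop,
        "sample_used": sample_used,
    }


def simulate_trial(
    bounds: BoundarySet,
    alloc: AllocationMatrix,
    nu_vector,
    rng: np.random.Generator,
) -> TrialOutcome:
    """Simulate a single trial replicate from the Gaussian score model."""
    nu = _check_nu(nu_vector, alloc)
    z = _simulate_z_gaussian(alloc, nu, rng, 1)
    out = apply_stopping_rules(z, bounds, alloc)
    return TrialOutcome(
        stop_stage_by_arm=tuple(int(s) for s in out["arm_stop_stage"][0]),
        rejected_by_arm=tuple(bool(r) for r in out["rejected"][0]),
        trial_stop_stage=int(out["trial_stop_stage"][0]),
        sample_used=int(out["sample_used"][0]),
    )


def _check_nu(nu_vector, alloc: AllocationMatrix) -> np.ndarray:
    nu = np.asarray(nu_vector, dtype=float)
    if nu.shape != (alloc.n_groups - 1,):
        raise ValueError(f"nu_vector must have K={alloc.n_groups - 1} entries")
    if np.any(nu <= 0.0) or np.any(nu >= 1.0):
        raise ValueError("nu_vector entries must lie strictly inside (0, 1)")
    return nu


def summarize_outcomes(
    out: dict[str, np.ndarray],
    designated_arm: int,
    scenario: str,
    n_reps: int,
    seed: int,
) -> ScenarioResult:
    """Aggregate a batch of stopped trials into a :class:`ScenarioResult`."""
    sample = out["sample_used"]
    return ScenarioResult(
        scenario=scenario,
        ess_mean=float(sample.mean()),
        ess_min=int(sample.min()),
        ess_max=int(sample.max()),
        ess_std=float(sample.std(ddof=1)) if sample.size > 1 else 0.0,
        power_estimate=float(out["rejected"][:, designated_arm].mean()),
        any_rejection_rate=float(out["rejected"].any(axis=1).mean()),
        mean_stages=float(out["trial_stop_stage"].mean()),
        n_reps=n_reps,
        seed=seed,
    )


def operating_characteristics(
    spec: DesignSpec,
    bounds: BoundarySet,
    alloc: AllocationMatrix,
    nu_vector,
    n_reps: int,
    seed,
    scenario: str = "",
) -> ScenarioResult:
    """Operating characteristics over ``n_reps`` replicated trials.

    ``power_estimate`` is the fraction of replicates in which the
    designated effective arm (the arm with the largest ``nu``) is
    rejected; ``any_rejection_rate`` is the familywise rejection fraction,
    which estimates the FWER when all ``nu`` equal 0.5.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be positive")
    nu = _check_nu(nu_vector, alloc)
    if alloc.n_groups != spec.K + 1:
        raise ValueError("allocation and spec disagree on the number of groups")
    seed_int = seed if isinstance(seed, (int, np.integer)) else 0
    rng = np.random.default_rng(seed)
    z = _simulate_z_gaussian(alloc, nu, rng, n_reps)
    out = apply_stopping_rules(z, bounds, alloc)
    designated = int(np.argmax(nu))
    return summarize_outcomes(out, designated, scenario, n_reps, int(seed_int))
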