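"""Raw Bernoulli outcome streams and stagewise test statistics.

The design and simulation machinery works on the asymptotic Gaussian
score scale.  This module generates the data the study actually assumes
-- independent, identically distributed Bernoulli outcomes per group --
and builds the stagewise standardized difference-of-proportions
statistics from them, so the Gaussian approximation can be validated
against the stated data-generating process.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .design import BoundarySet, DesignSpec
from .engine import AllocationMatrix, ScenarioResult, apply_stopping_rules, summarize_outcomes

__all__ = [
    "OutcomeStream",
    "generate_outcomes",
    "stagewise_statistics",
    "bernoulli_operating_characteristics",
    "write_outcome_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OutcomeStream:
    """Per-group binary outcome sequences for one trial.

    ``outcomes[g]`` holds the full planned accrual of group ``g`` (control
    first); stagewise prefixes are defined by an allocation matrix.
    """

    outcomes: tuple[np.ndarray, ...]
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.outcomes) != len(self.probs):
            raise ValueError("one probability per group is required")
        for arr in self.outcomes:
            if arr.ndim != 1 or not np.isin(arr, (0, 1)).all():
                raise ValueError("outcomes must be one-dimensional 0/1 sequences")

    @property
    def n_groups(self) -> int:
        return len(self.outcomes)


def generate_outcomes(
    p_vector, alloc: AllocationMatrix, rng: np.random.Generator
) -> OutcomeStream:
    """Independent Bernoulli draws per group, lengths set by the final allocation row.

    ``p_vector`` holds the success probability of each of the ``K+1``
    groups, control first.  Degenerate probabilities (0 or 1) are
    rejected: the pooled-variance statistic is undefined without outcome
    variability.
    """
    p = np.asarray(p_vector, dtype=float)
    if p.ndim != 1 or p.size != alloc.n_groups:
        raise ValueError(f"p_vector must have one entry per group ({alloc.n_groups})")
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("success probabilities must lie strictly inside (0, 1)")
    lengths = alloc.entries[-1]
    streams = tuple(
        (rng.random(int(n)) < pi).astype(np.int8) for n, pi in zip(lengths, p)
    )
    return OutcomeStream(outcomes=streams, probs=tuple(float(x) for x in p))


def stagewise_statistics(stream: OutcomeStream, alloc: AllocationMatrix) -> np.ndarray:
    """K x J matrix of standardized cumulative difference-of-proportions statistics.

    For arm ``k`` at stage ``j`` the statistic is the score-test form

    ``Z = (phat_k - phat_0) / sqrt(pbar (1 - pbar) (1/n_k + 1/n_0))``

    with ``pbar`` the success proportion pooled over the two groups
    (the null-variance estimate).  If the pooled variance is zero the two
    proportions are necessarily equal and the statistic is set to 0 by
    convention; the degenerate case is logged when group counts differ.
    """
    if stream.n_groups != alloc.n_groups:
        raise ValueError("stream and allocation disagree on the number of groups")
    for g, arr in enumerate(stream.outcomes):
        if arr.size < alloc.entries[-1, g]:
            raise ValueError(f"group {g} stream is shorter than its planned allocation")
    J, n_groups = alloc.entries.shape
    K = n_groups - 1
    z = np.zeros((K, J))
    for j in range(J):
        n0 = int(alloc.entries[j, 0])
        x0 = int(stream.outcomes[0][:n0].sum())
        for k in range(K):
            nk = int(alloc.entries[j, k + 1])
            xk = int(stream.outcomes[k + 1][:nk].sum())
            pooled = (x0 + xk) / (n0 + nk)
            var = pooled * (1.0 - pooled) * (1.0 / n0 + 1.0 / nk)
            if var == 0.0:
                if n0 != nk:
                    logger.debug(
                        "degenerate pooled variance at arm %d stage %d with unequal "
                        "counts (%d vs %d); statistic set to 0", k, j + 1, nk, n0,
                    )
                z[k, j] = 0.0
            else:
                z[k, j] = (xk / nk - x0 / n0) / np.sqrt(var)
    return z


def _simulate_z_bernoulli(
    alloc: AllocationMatrix, p_vector: np.ndarray, rng: np.random.Generator, n_reps: int
) -> np.ndarray:
    """Batch of stagewise statistics from binomial stage increments, shape (R, K, J).

    Only per-stage success counts matter for the statistics, so the
    streams are summarised by binomial draws per (replicate, group, stage).
    """
    m = alloc.increments().T  # (K+1, J)
    n = alloc.entries.T.astype(float)
    counts = rng.binomial(m[None, :, :], p_vector[None, :, None], size=(n_reps,) + m.shape)
    cum = np.cumsum(counts, axis=2)
    n0 = n[0]
    nk = n[1:]
    x0 = cum[:, :1, :]
    xk = cum[:, 1:, :]
    pooled = (x0 + xk) / (n0 + nk)
    var = pooled * (1.0 - pooled) * (1.0 / n0 + 1.0 / nk)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (xk / nk - x0 / n0) / np.sqrt(var)
    return np.where(var == 0.0, 0.0, z)


def bernoulli_operating_characteristics(
    spec: DesignSpec,
    bounds: BoundarySet,
    alloc: AllocationMatrix,
    p_vector,
    n_reps: int,
    seed,
    scenario: str = "",
) -> ScenarioResult:
    """Operating characteristics with statistics built from raw Bernoulli outcomes.

    The stopping rules and sample accounting are identical to the Gaussian
    engine; only the statistic-generation step differs.  ``p_vector``
    holds the ``K+1`` group success probabilities, control first.
    """
    p = np.asarray(p_vector, dtype=float)
    if p.shape != (spec.K + 1,):
        raise ValueError(f"p_vector must have K+1={spec.K + 1} entries")
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("success probabilities must lie strictly inside (0, 1)")
    seed_int = seed if isinstance(seed, (int, np.integer)) else 0
    rng = np.random.default_rng(seed)
    z = _simulate_z_bernoulli(alloc, p, rng, n_reps)
    out = apply_stopping_rules(z, bounds, alloc)
    designated = int(np.argmax(p[1:]))
    return summarize_outcomes(out, designated, scenario, n_reps, int(seed_int))


def write_outcome_table(stream: OutcomeStream, path) -> None:
    """Dump a per-observation outcome table (group, index, outcome) to CSV."""
    import pandas as pd

    frames = [
        pd.DataFrame(
            {"group": g, "observation": np.arange(1, arr.size + 1), "outcome": arr}
        )
        for g, arr in enumerate(stream.outcomes)
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
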