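"""Orchestration of the full simulation study.

Four experiments are reproduced as a pipeline over a scenario grid of
baseline success probabilities and interesting effect sizes:

1. required-sample-size comparison between the single-stage multi-arm
   RCT and the multi-stage MAMS design (with expected sample sizes under
   the global null and the least favorable configuration);
2. power curves for both designs over a fixed grid of total sample sizes;
3. sensitivity of sample size and power to misestimating the effect size
   at the design phase;
4. a per-unit cost comparison in the style of a campaign budget table.

Every function is deterministic given its seed: per-cell random streams
are spawned from one base ``SeedSequence`` so cells are independent and
the whole study is reproducible from the configuration alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import (
    BinaryEndpointModel,
    DesignSpec,
    required_sample_size,
)
from .engine import build_allocation, operating_characteristics

__all__ = [
    "StudyGrid",
    "MisestimationConfig",
    "CostModel",
    "run_scenario_grid",
    "run_power_curves",
    "run_misestimation",
    "cost_report",
    "run_cost_scenarios",
]

logger = logging.getLogger(__name__)

#: Scenario grid used throughout the study.
DEFAULT_P0 = (0.10, 0.30, 0.50, 0.70)
DEFAULT_DELTA = (0.02, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.40)
DEFAULT_N_GRID = (150, 300, 600, 900, 1200, 1800, 2400, 3000)


@dataclass(frozen=True)
class StudyGrid:
    """Scenario grid and replication settings for the study pipeline."""

    p0_values: tuple[float, ...] = DEFAULT_P0
    delta_values: tuple[float, ...] = DEFAULT_DELTA
    n_grid: tuple[int, ...] = DEFAULT_N_GRID
    n_reps: int = 10_000
    seed: int = 12_345

    def feasible_cells(self) -> list[tuple[float, float]]:
        """All (p0, delta) cells with delta < 1 - p0; infeasible cells are logged."""
        cells = []
        for p0 in self.p0_values:
            for delta in self.delta_values:
                if delta >= 1.0 - p0 - 1e-9:
                    logger.info(
                        "skipping infeasible cell p0=%.2f delta=%.2f "
                        "(delta must be less than 1 - p0)", p0, delta,
                    )
                    continue
                cells.append((p0, delta))
        return cells


@dataclass(frozen=True)
class MisestimationConfig:
    """True effect, scenario baseline, and the grid of assumption errors.

    The design is sized for the assumed effect ``delta + eps`` but the
    trial runs under the true ``delta``; every ``eps`` on the grid must
    leave the assumed effect feasible.
    """

    p0: float = 0.30
    delta: float = 0.20
    epsilons: tuple[float, ...] = tuple(np.round(np.arange(-0.10, 0.1001, 0.01), 2))

    def __post_init__(self) -> None:
        for eps in self.epsilons:
            assumed = self.delta + eps
            if assumed <= 1e-9 or assumed >= 1.0 - self.p0 - 1e-9:
                raise ValueError(
                    f"assumed effect delta+eps={assumed:.3g} out of (0, 1-p0) "
                    f"for eps={eps:.3g}"
                )


@dataclass(frozen=True)
class CostModel:
    """Per-unit and per-stage costs, in currency units."""

    unit_cost: float = 1000.0
    per_stage_cost: float = 0.0

    def __post_init__(self) -> None:
        if self.unit_cost < 0.0 or self.per_stage_cost < 0.0:
            raise ValueError("costs must be nonnegative")

    def trial_cost(self, sample_size: float, stages_executed: float) -> float:
        return sample_size * self.unit_cost + stages_executed * self.per_stage_cost


def _resolve_specs(
    spec_mams: DesignSpec | None, spec_rct: DesignSpec | None
) -> tuple[DesignSpec, DesignSpec]:
    """Fill in missing design specs; the RCT spec mirrors the MAMS one at J=1."""
    if spec_mams is None:
        spec_mams = DesignSpec()
    if spec_rct is None:
        spec_rct = DesignSpec(
            K=spec_mams.K, J=1, alpha=spec_mams.alpha,
            power_target=spec_mams.power_target,
            quadrature_points=spec_mams.quadrature_points,
        )
    return spec_mams, spec_rct


def _lfc_nu(model: BinaryEndpointModel, K: int) -> list[float]:
    """Effect vector under the least favorable configuration: one effective arm."""
    return [model.nu] + [0.5] * (K - 1)


def run_scenario_grid(
    grid: StudyGrid,
    spec_mams: DesignSpec | None = None,
    spec_rct: DesignSpec | None = None,
) -> pd.DataFrame:
    """Required sizes, expected sample sizes and MAMS/RCT ratios per scenario.

    One row per feasible (p0, delta) cell with the RCT and MAMS planned
    totals, simulated MAMS expected sample size under the global null and
    the least favorable configuration, the replicate min/max, and the
    ratio columns used throughout the study.
    """
    spec_mams, spec_rct = _resolve_specs(spec_mams, spec_rct)
    seeds = np.random.SeedSequence(grid.seed).spawn(2 * len(grid.feasible_cells()))
    rows = []
    for i, (p0, delta) in enumerate(grid.feasible_cells()):
        model = BinaryEndpointModel(p0, delta)
        rct = required_sample_size(spec_rct, model)
        mams = required_sample_size(spec_mams, model)
        alloc = build_allocation(mams.total, spec_mams.K, spec_mams.J)
        null = operating_characteristics(
            spec_mams, mams.bounds, alloc, [0.5] * spec_mams.K,
            grid.n_reps, seeds[2 * i], scenario=f"p0={p0},delta={delta},null",
        )
        lfc = operating_characteristics(
            spec_mams, mams.bounds, alloc, _lfc_nu(model, spec_mams.K),
            grid.n_reps, seeds[2 * i + 1], scenario=f"p0={p0},delta={delta},lfc",
        )
        observed_min = min(null.ess_min, lfc.ess_min)
        observed_max = max(null.ess_max, lfc.ess_max)
        rows.append({
            "p0": p0,
            "delta": delta,
            "rct_total": rct.total,
            "mams_total": mams.total,
            "mams_stage1_total": mams.stage1_total,
            "ratio_required": mams.total / rct.total,
            "ess_null_mean": null.ess_mean,
            "ess_lfc_mean": lfc.ess_mean,
            "ess_min": observed_min,
            "ess_max": observed_max,
            "ratio_null": null.ess_mean / rct.total,
            "ratio_lfc": lfc.ess_mean / rct.total,
            "ratio_best": observed_min / rct.total,
            "ratio_worst": observed_max / rct.total,
            "power_lfc": lfc.power_estimate,
            "fwer_null": null.any_rejection_rate,
            "n_reps": grid.n_reps,
        })
    return pd.DataFrame(rows)


def run_power_curves(
    grid: StudyGrid,
    spec_mams: DesignSpec | None = None,
    spec_rct: DesignSpec | None = None,
) -> pd.DataFrame:
    """Power under the LFC for both designs over the fixed total-sample-size grid.

    Boundaries are held at the designs' critical constants (they do not
    depend on the sample size); only the allocation matrices change with
    ``n``, split equally over groups (and stages, cumulatively, for MAMS).
    """
    spec_mams, spec_rct = _resolve_specs(spec_mams, spec_rct)
    from .design import find_critical_constant, obf_boundaries

    bounds = {
        "MAMS": obf_boundaries(spec_mams.J, find_critical_constant(spec_mams),
                               spec_mams.lower_fixed_value),
        "RCT": obf_boundaries(spec_rct.J, find_critical_constant(spec_rct),
                              spec_rct.lower_fixed_value),
    }
    specs = {"MAMS": spec_mams, "RCT": spec_rct}
    cells = grid.feasible_cells()
    seeds = np.random.SeedSequence((grid.seed, 2)).spawn(2 * len(cells) * len(grid.n_grid))
    rows = []
    i = 0
    for p0, delta in cells:
        model = BinaryEndpointModel(p0, delta)
        for n in grid.n_grid:
            for design in ("RCT", "MAMS"):
                spec = specs[design]
                alloc = build_allocation(n, spec.K, spec.J)
                res = operating_characteristics(
                    spec, bounds[design], alloc, _lfc_nu(model, spec.K),
                    grid.n_reps, seeds[i],
                    scenario=f"p0={p0},delta={delta},n={n},{design}",
                )
                i += 1
                rows.append({
                    "design": design, "p0": p0, "delta": delta, "n": n,
                    "power": res.power_estimate, "n_reps": grid.n_reps,
                })
    return pd.DataFrame(rows)


def run_misestimation(
    config: MisestimationConfig,
    n_reps: int = 10_000,
    seed: int = 12_345,
    spec_mams: DesignSpec | None = None,
    spec_rct: DesignSpec | None = None,
) -> pd.DataFrame:
    """Impact of sizing the design for an assumed effect while the true effect differs.

    For each assumption error ``eps`` the designs are sized for
    ``delta + eps`` and simulated under the true ``delta`` (least
    favorable configuration).  Deltas relative to the ``eps = 0`` row are
    reported for required totals, MAMS expected sample size and power.
    """
    spec_mams, spec_rct = _resolve_specs(spec_mams, spec_rct)
    true_model = BinaryEndpointModel(config.p0, config.delta)
    nu = _lfc_nu(true_model, spec_mams.K)
    seeds = np.random.SeedSequence((seed, 4)).spawn(2 * len(config.epsilons))
    rows = []
    for i, eps in enumerate(config.epsilons):
        assumed = BinaryEndpointModel(config.p0, config.delta + eps)
        rct = required_sample_size(spec_rct, assumed)
        mams = required_sample_size(spec_mams, assumed)
        alloc_m = build_allocation(mams.total, spec_mams.K, spec_mams.J)
        alloc_r = build_allocation(rct.total, spec_rct.K, spec_rct.J)
        sim_m = operating_characteristics(
            spec_mams, mams.bounds, alloc_m, nu, n_reps, seeds[2 * i],
            scenario=f"mis,eps={eps},MAMS",
        )
        sim_r = operating_characteristics(
            spec_rct, rct.bounds, alloc_r, nu, n_reps, seeds[2 * i + 1],
            scenario=f"mis,eps={eps},RCT",
        )
        rows.append({
            "eps": float(eps),
            "assumed_delta": float(config.delta + eps),
            "rct_required": rct.total,
            "mams_required": mams.total,
            "mams_ess_lfc": sim_m.ess_mean,
            "rct_power": sim_r.power_estimate,
            "mams_power": sim_m.power_estimate,
        })
    table = pd.DataFrame(rows)
    base = table.loc[np.isclose(table["eps"], 0.0)]
    if base.empty:
        raise ValueError("the epsilon grid must contain 0 to serve as the baseline")
    base = base.iloc[0]
    table["d_rct_required"] = table["rct_required"] - base["rct_required"]
    table["d_mams_required"] = table["mams_required"] - base["mams_required"]
    table["d_mams_ess"] = table["mams_ess_lfc"] - base["mams_ess_lfc"]
    table["d_rct_power"] = table["rct_power"] - base["rct_power"]
    table["d_mams_power"] = table["mams_power"] - base["mams_power"]
    return table


def cost_report(results: pd.DataFrame, model: CostModel) -> pd.DataFrame:
    """Cost comparison table from per-scenario sample-size summaries.

    ``results`` needs one row per scenario with columns ``p0``, ``delta``,
    ``rct_total``, ``mams_worst``, ``mams_lfc_ess``, ``mams_best`` and
    (if a per-stage cost is used) ``mams_lfc_stages``.  The output has one
    row per (scenario, case) with RCT cost, MAMS expected cost and the
    absolute/percent expected savings of MAMS over RCT.
    """
    required = {"p0", "delta", "rct_total", "mams_worst", "mams_lfc_ess", "mams_best"}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"results table is missing columns: {sorted(missing)}")
    rows = []
    for _, rec in results.iterrows():
        rct_cost = model.trial_cost(rec["rct_total"], 1)
        stages_lfc = rec.get("mams_lfc_stages", np.nan)
        j_max = rec.get("mams_stages", 3)
        for case, sample, stages in (
            ("Worst", rec["mams_worst"], j_max),
            ("LFC", rec["mams_lfc_ess"], stages_lfc if np.isfinite(stages_lfc) else j_max),
            ("Best", rec["mams_best"], 1),
        ):
            mams_cost = model.trial_cost(sample, stages)
            savings = rct_cost - mams_cost
            rows.append({
                "p0": rec["p0"],
                "delta": rec["delta"],
                "case": case,
                "rct_sample": rec["rct_total"],
                "rct_cost": rct_cost,
                "mams_sample": sample,
                "mams_cost": mams_cost,
                "savings": savings,
                "savings_pct": 100.0 * savings / rct_cost if rct_cost > 0 else 0.0,
            })
    return pd.DataFrame(rows)


def run_cost_scenarios(
    scenarios=((0.3, 0.3), (0.3, 0.1)),
    model: CostModel = CostModel(),
    n_reps: int = 10_000,
    seed: int = 12_345,
    spec_mams: DesignSpec | None = None,
    spec_rct: DesignSpec | None = None,
) -> pd.DataFrame:
    """Size, simulate and cost out a set of scenarios (the budget-table pipeline)."""
    spec_mams, spec_rct = _resolve_specs(spec_mams, spec_rct)
    seeds = np.random.SeedSequence((seed, 8)).spawn(len(scenarios))
    rows = []
    for i, (p0, delta) in enumerate(scenarios):
        m = BinaryEndpointModel(p0, delta)
        rct = required_sample_size(spec_rct, m)
        mams = required_sample_size(spec_mams, m)
        alloc = build_allocation(mams.total, spec_mams.K, spec_mams.J)
        lfc = operating_characteristics(
            spec_mams, mams.bounds, alloc, _lfc_nu(m, spec_mams.K),
            n_reps, seeds[i], scenario=f"cost,p0={p0},delta={delta}",
        )
        rows.append({
            "p0": p0,
            "delta": delta,
            "rct_total": rct.total,
            "mams_worst": mams.total,
            "mams_lfc_ess": lfc.ess_mean,
            "mams_best": mams.stage1_total,
            "mams_lfc_stages": lfc.mean_stages,
            "mams_stages": spec_mams.J,
        })
    return cost_report(pd.DataFrame(rows), model)
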