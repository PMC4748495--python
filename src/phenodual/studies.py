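"""Monte-Carlo calibration and power studies of the dual-analysis pipeline.

These are replicate-level experiments on the synthetic cohort generator:
type-I error of the genotype test under the null scenario, outcome-row
recovery rates under the confounded and direct-effect scenarios, the power
gain from weight adjustment, calibration of the weight-retention gate, and
weight-slope recovery.  They are used both by the test suite and by
``scripts/acceptance.py``; every study takes an explicit seed and derives
per-replicate seeds by counter, so results are reproducible.
"""

from __future__ import annotations

from dataclasses import replace as _dc_replace

import numpy as np

from .datamodel import RunConfig
from .dual import OutcomeRow, Row4Scenario, run_dual
from .lmm import fit_model, genotype_significant, optimize_weight
from .simulate import SimulationConfig, scenario_preset, simulate_dataset

__all__ = [
    "replicate_seeds",
    "null_type1_error",
    "outcome_row_rates",
    "power_curve",
    "weight_gate_retention",
    "gamma_recovery",
]


def replicate_seeds(base_seed: int, n: int) -> np.ndarray:
    """n independent 31-bit seeds derived from base_seed by counter."""
    return np.random.SeedSequence(base_seed).generate_state(n) % (2**31)


def null_type1_error(
    n_reps: int = 500, base_seed: int = 0, config: RunConfig | None = None
) -> dict[str, float]:
    """Rejection rate of the genotype test under the null scenario for both
    pipelines, at the configured alpha."""
    config = config or RunConfig()
    seeds = replicate_seeds(base_seed, n_reps)
    rej_a1 = rej_a2 = 0
    for s in seeds:
        ds = simulate_dataset(scenario_preset("null", seed=int(s)))
        a1 = fit_model(ds, include_weight=False, include_batch=config.include_batch,
                       alpha_interaction=config.alpha_interaction)
        a2 = fit_model(ds, include_weight=True, include_batch=config.include_batch,
                       alpha_interaction=config.alpha_interaction)
        rej_a1 += genotype_significant(a1, config.alpha_genotype)
        rej_a2 += genotype_significant(a2, config.alpha_genotype)
    return {"a1": rej_a1 / n_reps, "a2": rej_a2 / n_reps, "n_reps": n_reps}


def outcome_row_rates(
    preset: str, n_reps: int = 200, base_seed: int = 0,
    config: RunConfig | None = None,
) -> dict[str, float]:
    """Outcome-row frequencies (and the row-4 weight-differs rate) for a
    scenario preset."""
    config = config or RunConfig()
    seeds = replicate_seeds(base_seed, n_reps)
    counts = {row: 0 for row in OutcomeRow}
    weight_differs = 0
    for s in seeds:
        ds = simulate_dataset(scenario_preset(preset, seed=int(s)))
        res = run_dual(ds, config)
        counts[res.outcome.row] += 1
        if (res.outcome.row is OutcomeRow.ROW4_ABSOLUTE_AND_RELATIVE
                and res.outcome.row4_scenario is Row4Scenario.WEIGHT_DIFFERS):
            weight_differs += 1
    out = {row.value: c / n_reps for row, c in counts.items()}
    out["row4_weight_differs"] = weight_differs / n_reps
    out["n_reps"] = n_reps
    return out


def power_curve(
    direct_effects: list[float], n_reps: int = 500, base_seed: int = 0,
    config: RunConfig | None = None,
) -> list[dict[str, float]]:
    """Paired power of A1 vs A2 over a grid of direct genotype effects, in
    the sensitivity scenario (no weight phenotype, steep trait-weight slope).

    The same simulated datasets feed both pipelines at each grid point, so
    the comparison is paired replicate by replicate.
    """
    config = config or RunConfig()
    base = scenario_preset("sensitivity")
    out = []
    for k, beta_g in enumerate(direct_effects):
        seeds = replicate_seeds(base_seed + 7919 * k, n_reps)
        pow_a1 = pow_a2 = 0
        for s in seeds:
            cfg = base.model_copy(
                update={"trait_direct_genotype_effect": beta_g, "seed": int(s)}
            )
            ds = simulate_dataset(cfg)
            a1 = fit_model(ds, include_weight=False,
                           include_batch=config.include_batch,
                           alpha_interaction=config.alpha_interaction)
            a2 = fit_model(ds, include_weight=True,
                           include_batch=config.include_batch,
                           alpha_interaction=config.alpha_interaction)
            pow_a1 += genotype_significant(a1, config.alpha_genotype)
            pow_a2 += genotype_significant(a2, config.alpha_genotype)
        out.append({
            "direct_effect": beta_g,
            "power_a1": pow_a1 / n_reps,
            "power_a2": pow_a2 / n_reps,
            "n_reps": n_reps,
        })
    return out


def weight_gate_retention(
    weight_slope: float, n_reps: int = 500, base_seed: int = 0,
    config: RunConfig | None = None,
) -> float:
    """Fraction of null-scenario replicates (at the given trait-weight slope)
    where the optimized pipeline retains body weight."""
    config = config or RunConfig()
    base = scenario_preset("null").model_copy(update={"weight_slope": weight_slope})
    seeds = replicate_seeds(base_seed, n_reps)
    kept = 0
    for s in seeds:
        ds = simulate_dataset(base.model_copy(update={"seed": int(s)}))
        kept += optimize_weight(ds, config).weight_in_final_model
    return kept / n_reps


def gamma_recovery(
    n_reps: int = 300, base_seed: int = 0, n_per_cell: int = 100,
    config: RunConfig | None = None,
) -> float:
    """Fraction of replicates where the fitted weight slope lies within 3
    standard errors of the generating slope (cohort of 4 x n_per_cell)."""
    config = config or RunConfig()
    gen = SimulationConfig(
        n_control_f=n_per_cell, n_control_m=n_per_cell,
        n_knockout_f=n_per_cell, n_knockout_m=n_per_cell,
    )
    seeds = replicate_seeds(base_seed, n_reps)
    covered = 0
    for s in seeds:
        ds = simulate_dataset(gen.model_copy(update={"seed": int(s)}))
        fit = fit_model(ds, include_weight=True,
                        include_batch=config.include_batch,
                        alpha_interaction=config.alpha_interaction)
        est = fit.weight_estimate
        covered += abs(est.estimate - gen.weight_slope) <= 3.0 * est.std_error
    return covered / n_reps
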