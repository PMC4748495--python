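"""Shared fixtures: hand-built fits/results and small dataset factories."""

from __future__ import annotations

import numpy as np
import pytest

from phenodual.datamodel import (
    Genotype,
    PhenotypeDataset,
    PhenotypeRecord,
    RunConfig,
    Sex,
    VariableOntologyMap,
)
from phenodual.dual import DualAnalysisResult, OutcomeClass, OutcomeRow, Row4Scenario
from phenodual.lmm import FixedEffectEstimate, ModelFitResult, Pipeline


@pytest.fixture(scope="session")
def lean_mass_map() -> VariableOntologyMap:
    return VariableOntologyMap(
        variable_id="lean_mass",
        abnormal_term="MP:0003959",
        increased_term="MP:0003960",
        decreased_term="MP:0003961",
        entity_label="lean body mass",
    )


def make_fit(
    pipeline: Pipeline = Pipeline.A1,
    pooled: tuple[float, float, float] | None = (1.0, 0.5, 0.01),
    female: tuple[float, float, float] | None = None,
    male: tuple[float, float, float] | None = None,
    genotype_test_p: float | None = None,
    log_likelihood: float = -100.0,
    weight: bool = False,
) -> ModelFitResult:
    """Hand-built ModelFitResult; per-sex estimates imply dimorphism."""
    dimorphic = female is not None and male is not None
    mk = lambda t: FixedEffectEstimate(*t) if t is not None else None
    if genotype_test_p is None:
        ps = [t[2] for t in (pooled, female, male) if t is not None]
        genotype_test_p = min(ps)
    return ModelFitResult(
        pipeline=pipeline,
        sexual_dimorphism=dimorphic,
        genotype_test_p=genotype_test_p,
        genotype_test_df=2,
        log_likelihood=log_likelihood,
        n_by_cell={("control", "female"): 200, ("control", "male"): 200,
                   ("knockout", "female"): 7, ("knockout", "male"): 7},
        genotype_overall=None if dimorphic else mk(pooled),
        genotype_female=mk(female),
        genotype_male=mk(male),
        weight_in_final_model=weight,
        weight_p_value=0.01 if weight else None,
    )


def make_result(
    row: OutcomeRow,
    a1_est: float = -2.0,
    a2_est: float = -1.5,
    scenario: Row4Scenario | None = None,
    dimorphic_a1: bool = False,
    variable_id: str = "lean_mass",
) -> DualAnalysisResult:
    """Hand-built classified result with internally consistent significance."""
    sig = lambda s: 0.001 if s else 0.5
    a1_sig = row in (OutcomeRow.ROW1_CONFOUNDED, OutcomeRow.ROW4_ABSOLUTE_AND_RELATIVE)
    a2_sig = row in (OutcomeRow.ROW3_RELATIVE_ONLY, OutcomeRow.ROW4_ABSOLUTE_AND_RELATIVE)
    if dimorphic_a1:
        a1 = make_fit(Pipeline.A1, pooled=None,
                      female=(a1_est, 0.4, sig(a1_sig)),
                      male=(a1_est / 2, 0.4, 0.5),
                      genotype_test_p=sig(a1_sig))
    else:
        a1 = make_fit(Pipeline.A1, pooled=(a1_est, 0.4, sig(a1_sig)),
                      genotype_test_p=sig(a1_sig))
    a2 = make_fit(Pipeline.A2, pooled=(a2_est, 0.4, sig(a2_sig)),
                  genotype_test_p=sig(a2_sig), weight=True)
    if row is OutcomeRow.ROW4_ABSOLUTE_AND_RELATIVE and scenario is None:
        scenario = Row4Scenario.WEIGHT_DIFFERS
    weight_fit = (FixedEffectEstimate(-3.0, 0.7, 0.001)
                  if row is OutcomeRow.ROW4_ABSOLUTE_AND_RELATIVE else None)
    return DualAnalysisResult(
        dataset_id=f"ds_{variable_id}",
        variable_id=variable_id,
        a1=a1, a2=a2,
        outcome=OutcomeClass(row=row, row4_scenario=scenario),
        weight_fit=weight_fit,
        config=RunConfig(),
    )


def tiny_dataset(
    n_control: int = 8, n_knockout: int = 8, seed: int = 0,
    sexes: tuple[Sex, ...] = (Sex.FEMALE, Sex.MALE),
    with_batch: bool = False, variable_id: str = "lean_mass",
) -> PhenotypeDataset:
    """Small random dataset (no genotype effect) for structural tests."""
    rng = np.random.default_rng(seed)
    records = []
    i = 0
    for geno, n in ((Genotype.CONTROL, n_control), (Genotype.KNOCKOUT, n_knockout)):
        for k in range(n):
            sex = sexes[k % len(sexes)]
            w = float(rng.normal(25 + 5 * (sex is Sex.MALE), 2.5))
            records.append(PhenotypeRecord(
                specimen_id=f"m{i:03d}", genotype=geno, sex=sex,
                trait_value=float(rng.normal(20, 2)), variable_id=variable_id,
                body_weight=abs(w) + 0.1,
                batch_id=f"B{i % 3}" if with_batch else None,
            ))
            i += 1
    return PhenotypeDataset(variable_id=variable_id, records=records)
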