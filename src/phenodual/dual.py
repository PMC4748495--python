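"""Dual analysis: run each dataset without (A1) and with (A2) body weight as
a covariate and classify the outcome pair.

The four joint outcomes:

====  ===  ===  =============================================================
row   A1   A2   interpretation
====  ===  ===  =============================================================
1     +    -    absolute change only — confounded by body weight
2     -    -    no abnormality
3     -    +    relative change only — weight adjustment increased sensitivity
4     +    +    absolute and relative change; two sub-scenarios depending on
                whether the knockouts' body weight itself differs
====  ===  ===  =============================================================

The row-4 sub-scenario is resolved by fitting body weight itself as the
response; because that test can miss a real weight phenotype at small cohort
sizes, the sub-scenario is always reported together with its p-value, never
as a hard fact.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .datamodel import PhenotypeDataset, RunConfig
from .lmm import (
    FixedEffectEstimate,
    ModelFitResult,
    Pipeline,
    fit_model,
    fit_weight_model,
    genotype_significant,
)

__all__ = [
    "OutcomeRow",
    "Row4Scenario",
    "OutcomeClass",
    "DualAnalysisResult",
    "classify",
    "run_dual",
    "resolve_row4",
]


class OutcomeRow(str, enum.Enum):
    ROW1_CONFOUNDED = "ROW1_confounded"
    ROW2_NO_ABNORMALITY = "ROW2_no_abnormality"
    ROW3_RELATIVE_ONLY = "ROW3_relative_only"
    ROW4_ABSOLUTE_AND_RELATIVE = "ROW4_absolute_and_relative"


class Row4Scenario(str, enum.Enum):
    WEIGHT_DIFFERS = "weight_differs"
    WEIGHT_SAME = "weight_same"


@dataclass(frozen=True)
class OutcomeClass:
    """Outcome row, plus the row-4 sub-scenario once resolved.

    ``row4_scenario`` is only meaningful (and only allowed) for row 4; it is
    ``None`` on a freshly classified row-4 outcome until :func:`resolve_row4`
    fills it in, and completed :class:`DualAnalysisResult` objects always
    carry it resolved.
    """

    row: OutcomeRow
    row4_scenario: Row4Scenario | None = None

    def __post_init__(self) -> None:
        if (self.row4_scenario is not None
                and self.row is not OutcomeRow.ROW4_ABSOLUTE_AND_RELATIVE):
            raise ValueError("row4_scenario is only defined for row 4")


@dataclass
class DualAnalysisResult:
    """The (A1, A2) fit pair for one dataset plus its outcome classification."""

    dataset_id: str
    variable_id: str
    a1: ModelFitResult
    a2: ModelFitResult | None
    outcome: OutcomeClass | None
    weight_fit: FixedEffectEstimate | None = None
    complete: bool = True
    config: RunConfig | None = None

    def __post_init__(self) -> None:
        if self.a1.pipeline is not Pipeline.A1:
            raise ValueError("a1 must come from pipeline A1")
        if self.a2 is not None and self.a2.pipeline is not Pipeline.A2:
            raise ValueError("a2 must come from pipeline A2")
        if self.complete and (self.a2 is None or self.outcome is None):
            raise ValueError("complete results require an A2 fit and an outcome")
        if (self.complete
                and self.outcome.row is OutcomeRow.ROW4_ABSOLUTE_AND_RELATIVE
                and self.outcome.row4_scenario is None):
            raise ValueError("complete row-4 results must carry a resolved sub-scenario")


_CLASSIFY = {
    (True, False): OutcomeRow.ROW1_CONFOUNDED,
    (False, False): OutcomeRow.ROW2_NO_ABNORMALITY,
    (False, True): OutcomeRow.ROW3_RELATIVE_ONLY,
    (True, True): OutcomeRow.ROW4_ABSOLUTE_AND_RELATIVE,
}


def classify(a1_significant: bool, a2_significant: bool) -> OutcomeClass:
    """Map the (A1, A2) significance pair to its outcome row.

    Total and mutually exclusive on the four boolean pairs; row 4 is returned
    without a sub-scenario (use :func:`resolve_row4` to fill it in).
    """
    return OutcomeClass(row=_CLASSIFY[(bool(a1_significant), bool(a2_significant))])


def resolve_row4(
    dataset: PhenotypeDataset, config: RunConfig
) -> tuple[Row4Scenario, FixedEffectEstimate]:
    """Split row 4 by whether the knockouts' body weight itself differs.

    Fits weight ~ genotype + sex with the batch random intercept and calls
    ``weight_differs`` iff the genotype effect on weight is significant at
    ``alpha_genotype``.  The genotype estimate (grams) is returned so the
    call is always accompanied by its evidence.
    """
    est = fit_weight_model(dataset, include_batch=config.include_batch)
    scenario = (Row4Scenario.WEIGHT_DIFFERS
                if est.p_value < config.alpha_genotype
                else Row4Scenario.WEIGHT_SAME)
    return scenario, est


def run_dual(dataset: PhenotypeDataset, config: RunConfig | None = None) -> DualAnalysisResult:
    """Run one dataset through both pipelines and classify the outcome.

    A2 records lacking a body weight are dropped from the A2 fit (with a
    logged count); if no record carries a weight, A2 is skipped and the
    result is flagged incomplete with an undefined outcome.
    """
    config = config or RunConfig()
    a1 = fit_model(
        dataset, include_weight=False, include_batch=config.include_batch,
        alpha_interaction=config.alpha_interaction, pipeline=Pipeline.A1,
    )
    n_weights = len(dataset) - dataset.n_missing_weight
    if n_weights == 0:
        return DualAnalysisResult(
            dataset_id=dataset.dataset_id, variable_id=dataset.variable_id,
            a1=a1, a2=None, outcome=None, complete=False, config=config,
        )
    a2 = fit_model(
        dataset, include_weight=True, include_batch=config.include_batch,
        alpha_interaction=config.alpha_interaction, pipeline=Pipeline.A2,
    )
    a1_sig = genotype_significant(a1, config.alpha_genotype)
    a2_sig = genotype_significant(a2, config.alpha_genotype)
    row = classify(a1_sig, a2_sig).row
    weight_fit: FixedEffectEstimate | None = None
    if row is OutcomeRow.ROW4_ABSOLUTE_AND_RELATIVE:
        scenario, weight_fit = resolve_row4(dataset, config)
        outcome = OutcomeClass(row=row, row4_scenario=scenario)
    else:
        outcome = OutcomeClass(row=row)
    return DualAnalysisResult(
        dataset_id=dataset.dataset_id, variable_id=dataset.variable_id,
        a1=a1, a2=a2, outcome=outcome, weight_fit=weight_fit, config=config,
    )
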