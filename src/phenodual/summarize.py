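"""Battery-level aggregation: annotation overlap between pipelines and the
weight-inclusion distribution, plus JSON run reports.

The overlap summary mirrors a three-compartment Venn reading: datasets
significant only without weight adjustment (confounded, row 1), only with it
(sensitivity gain, row 3), and in both pipelines (row 4).  Percentages follow
asymmetric denominators — overlap and confounded shares are relative to the
unadjusted pipeline's total, the sensitivity-gain share relative to the
adjusted pipeline's total — and the raw counts are always carried so any
other convention can be recomputed.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

from .datamodel import PhenotypeDataset, RunConfig
from .dual import DualAnalysisResult, OutcomeRow
from .lmm import optimize_weight

logger = logging.getLogger(__name__)

__all__ = [
    "BatterySummary",
    "WeightInclusionSummary",
    "venn_summary",
    "weight_inclusion_distribution",
    "run_report",
]


@dataclass
class BatterySummary:
    """Counts and percentages of the A1/A2 outcome overlap across datasets."""

    n_datasets: int
    n_a1_only: int          # row 1: significant only without weight
    n_a2_only: int          # row 3: significant only with weight
    n_both: int             # row 4
    n_neither: int          # row 2
    pct_a1_overlap: float | None   # share of A1-significant also in A2
    pct_a1_only: float | None      # share of A1-significant lost in A2
    pct_a2_only: float | None      # share of A2-significant exclusive to A2
    weight_retained_fraction: float | None = None
    per_variable: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_datasets": self.n_datasets,
            "n_a1_only": self.n_a1_only,
            "n_a2_only": self.n_a2_only,
            "n_both": self.n_both,
            "n_neither": self.n_neither,
            "pct_a1_overlap": self.pct_a1_overlap,
            "pct_a1_only": self.pct_a1_only,
            "pct_a2_only": self.pct_a2_only,
            "weight_retained_fraction": self.weight_retained_fraction,
            "per_variable": self.per_variable,
        }


_ROW_KEY = {
    OutcomeRow.ROW1_CONFOUNDED: "a1_only",
    OutcomeRow.ROW2_NO_ABNORMALITY: "neither",
    OutcomeRow.ROW3_RELATIVE_ONLY: "a2_only",
    OutcomeRow.ROW4_ABSOLUTE_AND_RELATIVE: "both",
}


def venn_summary(
    results: list[DualAnalysisResult],
    weight_retained_fraction: float | None = None,
) -> BatterySummary:
    """Aggregate classified results into the overlap summary.

    Every complete result lands in exactly one compartment.  Percentages are
    ``None`` (not 0) when their denominator is empty.
    """
    counts = {"a1_only": 0, "a2_only": 0, "both": 0, "neither": 0}
    per_var: dict[str, dict[str, int]] = defaultdict(
        lambda: {"a1_only": 0, "a2_only": 0, "both": 0, "neither": 0}
    )
    for r in results:
        if not r.complete:
            raise ValueError(f"result {r.dataset_id!r} is incomplete")
        key = _ROW_KEY[r.outcome.row]
        counts[key] += 1
        per_var[r.variable_id][key] += 1

    a1_total = counts["a1_only"] + counts["both"]
    a2_total = counts["a2_only"] + counts["both"]
    pct = lambda num, den: (100.0 * num / den) if den else None
    return BatterySummary(
        n_datasets=len(results),
        n_a1_only=counts["a1_only"],
        n_a2_only=counts["a2_only"],
        n_both=counts["both"],
        n_neither=counts["neither"],
        pct_a1_overlap=pct(counts["both"], a1_total),
        pct_a1_only=pct(counts["a1_only"], a1_total),
        pct_a2_only=pct(counts["a2_only"], a2_total),
        weight_retained_fraction=weight_retained_fraction,
        per_variable={k: dict(v) for k, v in sorted(per_var.items())},
    )


@dataclass
class WeightInclusionSummary:
    """Fraction of datasets whose optimized model retained body weight."""

    overall_fraction: float | None
    per_variable: dict[str, float]
    n_datasets: int
    n_failures: int = 0


def weight_inclusion_distribution(
    datasets: list[PhenotypeDataset], config: RunConfig | None = None
) -> WeightInclusionSummary:
    """Run the weight-retention gate over a battery of datasets.

    Fit errors are collected (counted as failures), not fatal.
    """
    config = config or RunConfig()
    retained: dict[str, list[bool]] = defaultdict(list)
    n_fail = 0
    for ds in datasets:
        try:
            fit = optimize_weight(ds, config)
        except Exception as exc:
            n_fail += 1
            logger.warning("weight gate failed for %s: %s", ds.dataset_id, exc)
            continue
        retained[ds.variable_id].append(fit.weight_in_final_model)
    flat = [v for vs in retained.values() for v in vs]
    return WeightInclusionSummary(
        overall_fraction=(sum(flat) / len(flat)) if flat else None,
        per_variable={
            k: sum(v) / len(v) for k, v in sorted(retained.items())
        },
        n_datasets=len(datasets),
        n_failures=n_fail,
    )


def _outcome_record(r: DualAnalysisResult) -> dict:
    return {
        "dataset_id": r.dataset_id,
        "variable_id": r.variable_id,
        "outcome_row": r.outcome.row.value if r.outcome else None,
        "row4_scenario": (r.outcome.row4_scenario.value
                          if r.outcome and r.outcome.row4_scenario else None),
        "a1_genotype_p": r.a1.genotype_test_p,
        "a2_genotype_p": r.a2.genotype_test_p if r.a2 else None,
        "a1_dimorphic": r.a1.sexual_dimorphism,
        "a2_dimorphic": r.a2.sexual_dimorphism if r.a2 else None,
        "weight_genotype_p": (r.weight_fit.p_value
                              if r.weight_fit is not None else None),
        "complete": r.complete,
    }


def run_report(
    summary: BatterySummary,
    path: str | Path,
    config: RunConfig | None = None,
    results: list[DualAnalysisResult] | None = None,
) -> None:
    """Write a deterministic JSON run report (config echo, per-dataset
    outcomes, summary)."""
    payload = {
        "config": config.model_dump() if config is not None else None,
        "summary": summary.to_dict(),
        "datasets": ([_outcome_record(r) for r in results]
                     if results is not None else []),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
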