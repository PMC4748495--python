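"""Core domain types and delimited-text I/O.

The record grain is one mouse x one measured variable: a control-vs-knockout
comparison for a single variable of a single knockout line is held in a
:class:`PhenotypeDataset`, the unit every downstream analysis consumes.
Ontology bookkeeping (each variable's abnormal/increased/decreased term
triple) lives in :class:`VariableOntologyMap`, and run-wide statistical
settings in :class:`RunConfig`.

Input datasets are comma-delimited with a header; a column mapping lets
arbitrary source headers be used.  Annotations are written as TSV with a
stable column and row order so that outputs are byte-reproducible and
round-trip through :func:`read_annotations`.
"""

from __future__ import annotations

import enum
import json
import logging
import math
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .errors import DataValidationError, ParseError, SchemaError, VariableMapError

logger = logging.getLogger(__name__)

__all__ = [
    "Genotype",
    "Sex",
    "PhenotypeRecord",
    "PhenotypeDataset",
    "VariableOntologyMap",
    "RunConfig",
    "Annotation",
    "AnnotationKind",
    "Direction",
    "SexQualifier",
    "read_dataset",
    "read_variable_map",
    "write_annotations",
    "read_annotations",
    "DEFAULT_COLUMNS",
]


class Genotype(str, enum.Enum):
    CONTROL = "control"
    KNOCKOUT = "knockout"


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"


class AnnotationKind(str, enum.Enum):
    ABSOLUTE = "absolute"
    RELATIVE = "relative"


class Direction(str, enum.Enum):
    INCREASED = "increased"
    DECREASED = "decreased"
    ABNORMAL = "abnormal"


class SexQualifier(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"
    BOTH = "both"


@dataclass(frozen=True)
class PhenotypeRecord:
    """One mouse's measurement of one variable.

    ``body_weight`` is in grams and may be missing (``None``); missing weights
    are kept in the dataset and flagged, never silently dropped.
    """

    specimen_id: str
    genotype: Genotype
    sex: Sex
    trait_value: float
    variable_id: str
    body_weight: float | None = None
    batch_id: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "genotype", Genotype(self.genotype))
        object.__setattr__(self, "sex", Sex(self.sex))
        if self.body_weight is not None:
            if not math.isfinite(self.body_weight) or self.body_weight <= 0:
                raise DataValidationError(
                    f"body_weight must be a positive number of grams, got "
                    f"{self.body_weight!r} for specimen {self.specimen_id!r}"
                )
        if not math.isfinite(self.trait_value):
            raise DataValidationError(
                f"trait_value must be finite, got {self.trait_value!r} "
                f"for specimen {self.specimen_id!r}"
            )


@dataclass
class PhenotypeDataset:
    """All records for one variable of one knockout line vs its control pool."""

    variable_id: str
    records: list[PhenotypeRecord]
    units: str = ""
    dataset_id: str | None = None

    def __post_init__(self) -> None:
        if self.dataset_id is None:
            self.dataset_id = self.variable_id
        self.validate()

    def validate(self) -> None:
        if not self.records:
            raise DataValidationError("dataset has no records")
        bad = {r.variable_id for r in self.records} - {self.variable_id}
        if bad:
            raise DataValidationError(
                f"records carry variable_id {sorted(bad)} but dataset is "
                f"{self.variable_id!r}"
            )
        counts = Counter(r.genotype for r in self.records)
        if counts[Genotype.CONTROL] == 0:
            raise DataValidationError("dataset contains no control records")
        if counts[Genotype.KNOCKOUT] == 0:
            raise DataValidationError("dataset contains no knockout records")

    def __len__(self) -> int:
        return len(self.records)

    def counts_by_cell(self) -> dict[tuple[str, str], int]:
        """Record counts per (genotype, sex) cell."""
        c: Counter = Counter((r.genotype.value, r.sex.value) for r in self.records)
        return dict(c)

    @property
    def n_missing_weight(self) -> int:
        return sum(1 for r in self.records if r.body_weight is None)

    @property
    def sexes(self) -> set[Sex]:
        return {r.sex for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        """Analysis view: one row per record, enum values as strings."""
        return pd.DataFrame(
            {
                "specimen_id": [r.specimen_id for r in self.records],
                "genotype": [r.genotype.value for r in self.records],
                "sex": [r.sex.value for r in self.records],
                "body_weight": [r.body_weight for r in self.records],
                "trait_value": [r.trait_value for r in self.records],
                "batch_id": [r.batch_id for r in self.records],
            }
        )

    def drop_missing_weight(self) -> "PhenotypeDataset":
        """Copy without records lacking a body weight (for weight-adjusted fits)."""
        kept = [r for r in self.records if r.body_weight is not None]
        n_dropped = len(self.records) - len(kept)
        if n_dropped:
            logger.info(
                "dataset %s: dropped %d record(s) with missing body weight",
                self.dataset_id, n_dropped,
            )
        return replace(self, records=kept)


@dataclass(frozen=True)
class VariableOntologyMap:
    """Directional ontology term triple plus the trait entity for one variable.

    Term ids are opaque CURIE strings; no ontology-release validation is done.
    """

    variable_id: str
    abnormal_term: str
    increased_term: str
    decreased_term: str
    entity_label: str
    entity_term: str | None = None

    def __post_init__(self) -> None:
        terms = [self.abnormal_term, self.increased_term, self.decreased_term]
        if any(not t for t in terms):
            raise VariableMapError(
                f"variable {self.variable_id!r}: all three directional term ids "
                f"(abnormal/increased/decreased) are required"
            )
        if len(set(terms)) != 3:
            raise VariableMapError(
                f"variable {self.variable_id!r}: directional term ids must be "
                f"distinct, got {terms}"
            )

    def term_for(self, direction: Direction) -> str:
        return {
            Direction.ABNORMAL: self.abnormal_term,
            Direction.INCREASED: self.increased_term,
            Direction.DECREASED: self.decreased_term,
        }[Direction(direction)]


class RunConfig(BaseModel):
    """Statistical settings for a dual-analysis run.

    alpha_genotype : significance threshold for the genotype test in either
        pipeline (strict ``p < alpha``).
    alpha_interaction : threshold for the genotype-by-sex interaction screen
        that triggers per-sex estimate reporting (sexual dimorphism).
    alpha_weight : threshold of the weight-retention gate used by the
        optimized pipeline (weight kept only if it significantly explains
        variation).
    force_weight_in_a2 : pipeline A2 always includes body weight as a
        covariate; the gate applies only to the separate optimized pipeline.
    """

    alpha_genotype: float = Field(default=0.05, gt=0.0, lt=1.0)
    alpha_interaction: float = Field(default=0.05, gt=0.0, lt=1.0)
    alpha_weight: float = Field(default=0.05, gt=0.0, lt=1.0)
    force_weight_in_a2: bool = True
    include_batch: bool = True
    random_seed: int = Field(default=0, ge=0)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2) + "\n")


# Logical column names expected after applying a column map.
DEFAULT_COLUMNS: dict[str, str] = {
    "specimen_id": "specimen_id",
    "genotype": "genotype",
    "sex": "sex",
    "batch": "batch",
    "body_weight": "body_weight",
    "trait_value": "trait_value",
    "variable_id": "variable_id",
}

_REQUIRED = ("specimen_id", "genotype", "sex", "body_weight", "trait_value")


def read_dataset(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    variable_id: str | None = None,
    units: str = "",
) -> PhenotypeDataset:
    """Read a comma-delimited per-specimen table into a :class:`PhenotypeDataset`.

    Parameters
    ----------
    path
        CSV file with a header row.
    column_map
        Mapping of logical column names (keys of :data:`DEFAULT_COLUMNS`) to
        the file's actual headers; unmapped names default to themselves.
    variable_id
        Override for files without a ``variable_id`` column.

    Row order is preserved; missing body weights are kept and flagged.
    """
    path = Path(path)
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [cols[k] for k in _REQUIRED if cols[k] not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s): {', '.join(missing)}"
        )

    has_var_col = cols["variable_id"] in df.columns
    if not has_var_col and variable_id is None:
        raise SchemaError(
            f"{path.name}: missing column {cols['variable_id']!r} and no "
            f"variable_id override given"
        )
    has_batch = cols["batch"] in df.columns

    allowed_geno = {g.value for g in Genotype}
    allowed_sex = {s.value for s in Sex}
    records: list[PhenotypeRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = dict(zip(df.columns, row))
        geno = row[cols["genotype"]].strip().lower()
        if geno not in allowed_geno:
            raise DataValidationError(
                f"{path.name} row {i}: genotype {geno!r} not allowed; "
                f"allowed labels: {sorted(allowed_geno)}"
            )
        sex = row[cols["sex"]].strip().lower()
        if sex not in allowed_sex:
            raise DataValidationError(
                f"{path.name} row {i}: sex {sex!r} not allowed; "
                f"allowed labels: {sorted(allowed_sex)}"
            )
        raw_trait = row[cols["trait_value"]].strip()
        try:
            trait = float(raw_trait)
        except ValueError:
            raise ParseError(
                f"{path.name} row {i}: non-numeric trait value {raw_trait!r}"
            ) from None
        raw_w = row[cols["body_weight"]].strip()
        if raw_w in ("", "NA", "nan", "NaN"):
            weight: float | None = None
        else:
            try:
                weight = float(raw_w)
            except ValueError:
                raise ParseError(
                    f"{path.name} row {i}: non-numeric body weight {raw_w!r}"
                ) from None
        var = row[cols["variable_id"]].strip() if has_var_col else variable_id
        batch = row[cols["batch"]].strip() if has_batch else ""
        records.append(
            PhenotypeRecord(
                specimen_id=row[cols["specimen_id"]].strip(),
                genotype=Genotype(geno),
                sex=Sex(sex),
                trait_value=trait,
                variable_id=var,
                body_weight=weight,
                batch_id=batch or None,
            )
        )
    if variable_id is None:
        var_ids = {r.variable_id for r in records}
        if len(var_ids) != 1:
            raise DataValidationError(
                f"{path.name}: expected a single variable_id, found {sorted(var_ids)}"
            )
        variable_id = records[0].variable_id
    ds = PhenotypeDataset(
        variable_id=variable_id, records=records, units=units, dataset_id=path.stem
    )
    if ds.n_missing_weight:
        logger.warning(
            "%s: %d record(s) have missing body weight; they are kept but will "
            "be dropped from weight-adjusted fits", path.name, ds.n_missing_weight
        )
    return ds


_VARMAP_REQUIRED = ("variable_id", "abnormal_term", "increased_term",
                    "decreased_term", "entity_label")


def read_variable_map(path: str | Path) -> dict[str, VariableOntologyMap]:
    """Read the variable -> ontology term-triple table (CSV, one row per variable)."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.empty and len(df.columns) <= 1:
        logger.warning("%s: empty variable map", path.name)
        return {}
    missing = [c for c in _VARMAP_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s): {', '.join(missing)}"
        )
    out: dict[str, VariableOntologyMap] = {}
    for _, row in df.iterrows():
        vid = row["variable_id"].strip()
        if vid in out:
            raise VariableMapError(f"{path.name}: duplicate variable_id {vid!r}")
        out[vid] = VariableOntologyMap(
            variable_id=vid,
            abnormal_term=row["abnormal_term"].strip(),
            increased_term=row["increased_term"].strip(),
            decreased_term=row["decreased_term"].strip(),
            entity_label=row["entity_label"].strip(),
            entity_term=(row.get("entity_term", "") or "").strip() or None,
        )
    if not out:
        logger.warning("%s: empty variable map", path.name)
    return out


@dataclass(frozen=True)
class Annotation:
    """One disseminated phenotype call.

    ``kind`` distinguishes an absolute change (detected without weight
    adjustment) from a relative change (detected after adjusting for body
    weight); relative annotations always name their confounder.  The
    ``evidence`` map carries the pipeline, estimate, standard error and
    p-value backing the call.
    """

    dataset_id: str
    variable_id: str
    kind: AnnotationKind
    term_id: str
    direction: Direction
    sex_qualifier: SexQualifier
    confounder: str | None = None
    free_text_tag: str | None = None
    qualifier_term: str | None = None
    evidence: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", AnnotationKind(self.kind))
        object.__setattr__(self, "direction", Direction(self.direction))
        object.__setattr__(self, "sex_qualifier", SexQualifier(self.sex_qualifier))
        if self.kind is AnnotationKind.RELATIVE and not self.confounder:
            raise DataValidationError(
                "relative annotations must name their confounder"
            )
        est = self.evidence.get("estimate")
        if est is not None and est != 0:
            expected = Direction.INCREASED if est > 0 else Direction.DECREASED
            if self.direction is not Direction.ABNORMAL and self.direction != expected:
                raise DataValidationError(
                    f"direction {self.direction.value} inconsistent with "
                    f"estimate sign ({est})"
                )


_ANN_COLS = [
    "dataset_id", "variable_id", "kind", "term_id", "direction",
    "sex_qualifier", "confounder", "free_text_tag", "qualifier_term",
    "pipeline", "estimate", "std_error", "p_value",
]


def _fmt(x: object) -> str:
    if x is None:
        return ""
    if isinstance(x, float):
        return repr(x)
    return str(x)


def write_annotations(annotations: Iterable[Annotation], path: str | Path) -> None:
    """Write annotations as TSV, sorted by (variable_id, sex, kind).

    The ordering and float formatting are deterministic, so identical inputs
    produce byte-identical files and :func:`read_annotations` inverts this.
    """
    rows = sorted(
        annotations,
        key=lambda a: (a.variable_id, a.sex_qualifier.value, a.kind.value,
                       a.dataset_id, a.term_id),
    )
    lines = ["\t".join(_ANN_COLS)]
    for a in rows:
        ev = a.evidence
        lines.append("\t".join([
            a.dataset_id, a.variable_id, a.kind.value, a.term_id,
            a.direction.value, a.sex_qualifier.value,
            _fmt(a.confounder), _fmt(a.free_text_tag), _fmt(a.qualifier_term),
            _fmt(ev.get("pipeline")),
            _fmt(ev.get("estimate")), _fmt(ev.get("std_error")),
            _fmt(ev.get("p_value")),
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_annotations(path: str | Path) -> list[Annotation]:
    """Inverse of :func:`write_annotations`."""
    text = Path(path).read_text().splitlines()
    if not text:
        raise SchemaError(f"{path}: empty annotation file")
    header = text[0].split("\t")
    if header != _ANN_COLS:
        raise SchemaError(f"{path}: unexpected annotation header {header}")
    out: list[Annotation] = []
    for line in text[1:]:
        f = dict(zip(_ANN_COLS, line.split("\t")))
        evidence: dict[str, object] = {}
        if f["pipeline"]:
            evidence["pipeline"] = f["pipeline"]
        for k in ("estimate", "std_error", "p_value"):
            if f[k]:
                evidence[k] = float(f[k])
        out.append(Annotation(
            dataset_id=f["dataset_id"],
            variable_id=f["variable_id"],
            kind=AnnotationKind(f["kind"]),
            term_id=f["term_id"],
            direction=Direction(f["direction"]),
            sex_qualifier=SexQualifier(f["sex_qualifier"]),
            confounder=f["confounder"] or None,
            free_text_tag=f["free_text_tag"] or None,
            qualifier_term=f["qualifier_term"] or None,
            evidence=evidence,
        ))
    return out
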