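"""Dissemination of classified dual-analysis results.

An abnormal call can be disseminated four ways, and one
:class:`~phenodual.datamodel.Annotation` record carries all of them so
downstream consumers can pick their representation:

* a pre-composed directional ontology term (the variable's
  abnormal/increased/decreased triple from the variable map);
* a free-text tag on the annotation noting the confounder handling
  (MGI-curation style);
* a standardised qualifier term replacing the free text;
* for relative (weight-adjusted) calls, a post-composed entity-quality
  statement — entity 1: the trait, quality: "relative to", entity 2: body
  weight, qualifier: increased/decreased/abnormal — and an RDF triple
  ``<directional term, relative_to, body_weight>``.

Absolute calls that were explained away by body weight (outcome row 1) are
retained but tagged as confounded rather than suppressed.
"""

from __future__ import annotations

from dataclasses import dataclass

from rdflib import Graph, Literal, Namespace, URIRef
from rdflib.namespace import RDF

from .datamodel import (
    Annotation,
    AnnotationKind,
    Direction,
    SexQualifier,
    VariableOntologyMap,
)
from .dual import DualAnalysisResult, OutcomeRow
from .errors import PrefixError, VariableMapError
from .lmm import FixedEffectEstimate, ModelFitResult

__all__ = [
    "BODY_WEIGHT_LABEL",
    "DEFAULT_NAMESPACES",
    "DEFAULT_QUALIFIER_TERM",
    "PostComposedAnnotation",
    "RdfTriple",
    "direction_from_estimate",
    "make_annotations",
    "post_compose",
    "to_rdf",
    "serialize_turtle",
    "serialize_ntriples",
    "parse_rdf",
]

BODY_WEIGHT_LABEL = "body weight"

# Project-minted CURIE for the "relative to body weight" qualifier: the
# controlled replacement for the free-text tag.  No public ontology mints
# relative-phenotype qualifiers, so these live in a configurable project
# namespace.
DEFAULT_QUALIFIER_TERM = "PHREL:0000001"

DEFAULT_NAMESPACES: dict[str, str] = {
    "MP": "http://purl.obolibrary.org/obo/MP_",
    "PATO": "http://purl.obolibrary.org/obo/PATO_",
    "UBERON": "http://purl.obolibrary.org/obo/UBERON_",
    "PHREL": "http://example.org/phenorel/",
}


@dataclass(frozen=True)
class PostComposedAnnotation:
    """Entity-quality statement for a relative phenotype change."""

    entity1_label: str
    quality: str
    entity2_label: str
    qualifier: Direction
    entity1_term: str | None = None
    entity2_term: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "qualifier", Direction(self.qualifier))
        if not (self.entity1_label and self.quality and self.entity2_label):
            raise ValueError("all EQ statement slots must be populated")

    def to_dict(self) -> dict[str, str]:
        return {
            "entity1": self.entity1_label,
            "quality": self.quality,
            "entity2": self.entity2_label,
            "qualifier": self.qualifier.value,
        }


@dataclass(frozen=True)
class RdfTriple:
    subject: str
    predicate: str
    object: str

    def __post_init__(self) -> None:
        if not (self.subject and self.predicate and self.object):
            raise ValueError("all three triple components must be non-empty")


def direction_from_estimate(estimate: float) -> Direction:
    """Sign rule: positive -> increased, negative -> decreased, zero -> abnormal."""
    if estimate > 0:
        return Direction.INCREASED
    if estimate < 0:
        return Direction.DECREASED
    return Direction.ABNORMAL


def _evidence(fit: ModelFitResult, est: FixedEffectEstimate) -> dict[str, object]:
    return {
        "pipeline": fit.pipeline.value,
        "estimate": est.estimate,
        "std_error": est.std_error,
        "p_value": est.p_value,
    }


def _estimates_for(fit: ModelFitResult, alpha: float) -> list[tuple[SexQualifier, FixedEffectEstimate]]:
    """The (sex qualifier, estimate) contexts an annotation is issued for.

    Non-dimorphic fits yield a single pooled context.  Dimorphic fits yield
    one context per individually significant sex; if the dataset-level call
    came from the omnibus test with neither sex individually significant, the
    smaller-p sex is used with qualifier 'both'.
    """
    if not fit.sexual_dimorphism:
        return [(SexQualifier.BOTH, fit.genotype_overall)]
    out = []
    if fit.genotype_female.p_value < alpha:
        out.append((SexQualifier.FEMALE, fit.genotype_female))
    if fit.genotype_male.p_value < alpha:
        out.append((SexQualifier.MALE, fit.genotype_male))
    if not out:
        best = min((fit.genotype_female, fit.genotype_male), key=lambda e: e.p_value)
        out.append((SexQualifier.BOTH, best))
    return out


def _annotate_fit(
    result: DualAnalysisResult,
    fit: ModelFitResult,
    varmap: VariableOntologyMap,
    kind: AnnotationKind,
    free_text_tag: str | None,
    qualifier_term: str | None,
    alpha: float,
) -> list[Annotation]:
    anns = []
    for sexq, est in _estimates_for(fit, alpha):
        direction = direction_from_estimate(est.estimate)
        anns.append(Annotation(
            dataset_id=result.dataset_id,
            variable_id=varmap.variable_id,
            kind=kind,
            term_id=varmap.term_for(direction),
            direction=direction,
            sex_qualifier=sexq,
            confounder=BODY_WEIGHT_LABEL if kind is AnnotationKind.RELATIVE else None,
            free_text_tag=free_text_tag,
            qualifier_term=qualifier_term,
            evidence=_evidence(fit, est),
        ))
    return anns


def make_annotations(
    result: DualAnalysisResult,
    varmap: VariableOntologyMap,
    qualifier_term: str = DEFAULT_QUALIFIER_TERM,
) -> list[Annotation]:
    """Annotations implied by a classified dual-analysis result.

    Row 1 yields absolute annotation(s) tagged as confounded by body weight;
    row 2 none; row 3 relative annotation(s); row 4 both an absolute and a
    relative annotation per significant sex context.
    """
    if not result.complete:
        raise ValueError(f"result {result.dataset_id!r} is incomplete")
    if varmap.variable_id != result.variable_id:
        raise VariableMapError(
            f"variable map is for {varmap.variable_id!r} but the result is "
            f"for {result.variable_id!r}"
        )
    alpha = result.config.alpha_genotype if result.config is not None else 0.05
    row = result.outcome.row
    relative_tag = "after adjusting for body weight"
    if row is OutcomeRow.ROW2_NO_ABNORMALITY:
        return []
    if row is OutcomeRow.ROW1_CONFOUNDED:
        return _annotate_fit(
            result, result.a1, varmap, AnnotationKind.ABSOLUTE,
            "confounded by body weight: not significant after adjustment",
            None, alpha,
        )
    if row is OutcomeRow.ROW3_RELATIVE_ONLY:
        return _annotate_fit(
            result, result.a2, varmap, AnnotationKind.RELATIVE,
            relative_tag, qualifier_term, alpha,
        )
    # row 4: one absolute + one relative per sex context
    scenario = result.outcome.row4_scenario
    wp = result.weight_fit.p_value if result.weight_fit is not None else None
    phrase = ("body weight differs" if scenario is not None
              and scenario.value == "weight_differs" else "body weight same")
    abs_tag = phrase + (f" (weight-model p={wp:.3g})" if wp is not None else "")
    return (
        _annotate_fit(result, result.a1, varmap, AnnotationKind.ABSOLUTE,
                      abs_tag, None, alpha)
        + _annotate_fit(result, result.a2, varmap, AnnotationKind.RELATIVE,
                        relative_tag, qualifier_term, alpha)
    )


def post_compose(
    annotation: Annotation, varmap: VariableOntologyMap
) -> PostComposedAnnotation:
    """Entity-quality view of a relative annotation.

    Only relative (weight-adjusted) changes are post-composed here; absolute
    changes keep their pre-composed term.
    """
    if annotation.kind is not AnnotationKind.RELATIVE:
        raise ValueError("post-composition is defined for relative annotations only")
    return PostComposedAnnotation(
        entity1_label=varmap.entity_label,
        quality="relative to",
        entity2_label=BODY_WEIGHT_LABEL,
        qualifier=annotation.direction,
        entity1_term=varmap.entity_term,
    )


def _expand(curie_or_iri: str, namespaces: dict[str, str]) -> URIRef:
    if curie_or_iri.startswith(("http://", "https://")):
        return URIRef(curie_or_iri)
    prefix, _, local = curie_or_iri.partition(":")
    if not local or prefix not in namespaces:
        raise PrefixError(
            f"cannot resolve prefix of {curie_or_iri!r}; known prefixes: "
            f"{sorted(namespaces)}"
        )
    return URIRef(namespaces[prefix] + local)


def to_rdf(
    annotations: list[Annotation],
    namespaces: dict[str, str] | None = None,
    oban: bool = False,
) -> Graph:
    """RDF graph of the relative annotations.

    Each relative annotation yields the core triple
    ``<directional term, phrel:relative_to, phrel:body_weight>``.  With
    ``oban=True`` a lightweight OBAN-style association node per annotation is
    added (linking subject, predicate, object plus the sex context), which
    keeps annotations distinct even when they share a term.
    """
    ns = dict(DEFAULT_NAMESPACES)
    if namespaces:
        ns.update(namespaces)
    phrel = Namespace(ns["PHREL"])
    g = Graph()
    for prefix, iri in sorted(ns.items()):
        g.bind(prefix.lower(), Namespace(iri))
    relative_to = phrel["relative_to"]
    body_weight = phrel["body_weight"]
    for a in annotations:
        if a.kind is not AnnotationKind.RELATIVE:
            continue
        subject = _expand(a.term_id, ns)
        g.add((subject, relative_to, body_weight))
        if oban:
            node = phrel[
                f"association/{a.dataset_id}-{a.term_id.replace(':', '_')}-"
                f"{a.sex_qualifier.value}"
            ]
            g.add((node, RDF.type, phrel["association"]))
            g.add((node, phrel["association_has_subject"], subject))
            g.add((node, phrel["association_has_predicate"], relative_to))
            g.add((node, phrel["association_has_object"], body_weight))
            g.add((node, phrel["sex_qualifier"], Literal(a.sex_qualifier.value)))
    return g


def serialize_turtle(graph: Graph) -> str:
    return graph.serialize(format="turtle")


def serialize_ntriples(graph: Graph) -> str:
    """Deterministic N-Triples: one sorted line per triple."""
    lines = sorted(
        f"{s.n3()} {p.n3()} {o.n3()} ." for s, p, o in graph
    )
    return "\n".join(lines) + ("\n" if lines else "")


def parse_rdf(text: str, fmt: str = "turtle") -> Graph:
    g = Graph()
    g.parse(data=text, format=fmt)
    return g
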