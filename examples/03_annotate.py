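"""From a classified result to dissemination: directional ontology terms with
tags, an entity-quality statement, and RDF triples for the relative call."""

from phenodual import (
    RunConfig,
    VariableOntologyMap,
    make_annotations,
    post_compose,
    run_dual,
    scenario_preset,
    serialize_ntriples,
    simulate_dataset,
    to_rdf,
)

varmap = VariableOntologyMap(
    variable_id="lean_mass",
    abnormal_term="MP:0003959",    # abnormal lean body mass
    increased_term="MP:0003960",   # increased lean body mass
    decreased_term="MP:0003961",   # decreased lean body mass
    entity_label="lean body mass",
)

ds = simulate_dataset(scenario_preset("direct_plus_weight", seed=7))
res = run_dual(ds, RunConfig())
anns = make_annotations(res, varmap)

print(f"outcome {res.outcome.row.value}: {len(anns)} annotation(s)")
for a in anns:
    print(f"  [{a.kind.value:8s}] {a.term_id} ({a.direction.value}, "
          f"sex={a.sex_qualifier.value}) tag={a.free_text_tag!r}")

relative = [a for a in anns if a.kind.value == "relative"][0]
print("\nentity-quality statement for the relative call:")
for slot, value in post_compose(relative, varmap).to_dict().items():
    print(f"  {slot:9s}: {value}")

print("\nRDF (N-Triples, association-scoped):")
print(serialize_ntriples(to_rdf(anns, oban=True)))
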