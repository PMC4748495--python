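"""Simulate a synthetic control-knockout cohort with a weight-mediated effect.

The "confounded" preset gives the knockouts a -3.5 g body-weight phenotype
and no direct trait effect: the lean-mass deficit you see below is entirely
carried by the weight difference (slope 0.6 g lean mass per g body weight,
so the expected trait shift is 0.6 * -3.5 = -2.1).
"""

from phenodual import scenario_preset, simulate_dataset

cfg = scenario_preset("confounded", seed=42)
ds = simulate_dataset(cfg)
df = ds.to_frame()

print(f"dataset: {ds.variable_id} ({ds.units}), {len(ds)} mice")
for (geno, sex), n in sorted(ds.counts_by_cell().items()):
    cell = df[(df.genotype == geno) & (df.sex == sex)]
    print(f"  {geno:9s} {sex:6s} n={n:3d}  "
          f"weight {cell.body_weight.mean():5.1f} g  "
          f"trait {cell.trait_value.mean():5.1f}")

ko = df[df.genotype == "knockout"].trait_value.mean()
wt = df[df.genotype == "control"].trait_value.mean()
print(f"\nraw knockout - control trait difference: {ko - wt:+.2f} "
      f"(expected about -2.1, all of it via body weight)")
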