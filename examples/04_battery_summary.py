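"""Battery-level views: the A1/A2 overlap summary and the weight-retention
gate across a small mixed battery of simulated datasets."""

from phenodual import (
    RunConfig,
    run_dual,
    simulate_battery,
    venn_summary,
    weight_inclusion_distribution,
)

battery = simulate_battery(
    {"null": 10, "confounded": 5, "direct_plus_weight": 5}, base_seed=99
)
results = [run_dual(ds, RunConfig()) for ds, _ in battery]
s = venn_summary(results)

print(f"{s.n_datasets} datasets: {s.n_a1_only} A1-only (confounded), "
      f"{s.n_a2_only} A2-only (sensitivity gain), {s.n_both} both, "
      f"{s.n_neither} neither")
if s.pct_a1_overlap is not None:
    print(f"share of unadjusted-pipeline calls that survive weight "
          f"adjustment: {s.pct_a1_overlap:.0f}%")
    print(f"share lost as weight-confounded:                        "
          f"{s.pct_a1_only:.0f}%")

gate = weight_inclusion_distribution([ds for ds, _ in battery], RunConfig())
print(f"\nweight retained by the optimized model in "
      f"{100 * gate.overall_fraction:.0f}% of datasets "
      f"(trait-weight slope is nonzero in every scenario here)")
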