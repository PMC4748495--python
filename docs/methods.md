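# Methods

## Scope and intent

`phenodual` implements a dual-analysis procedure for genotype–phenotype
association when body weight may confound the trait of interest, together
with the annotation machinery needed to disseminate both absolute and
relative (weight-adjusted) phenotype calls.  It operates on one
control-vs-knockout dataset per variable, mirroring high-throughput mouse
phenotyping designs: a large shared wildtype pool and a small knockout
cohort, both sexes, batch structure.  It does not attempt causal or
mediation-proportion inference — with observational body weight one cannot
decide whether the genotype lowers lean mass because it lowers weight or
vice versa — and it does not model non-Gaussian or time-course traits.

## Statistical model

Both pipelines fit a linear mixed model to the trait:

    trait ~ genotype + sex + genotype:sex (+ body_weight) + (1 | batch)

* **A1** omits `body_weight`; its genotype coefficient estimates the
  *absolute* change `β_g + γ·δ_g` (direct effect plus the weight-mediated
  contribution).
* **A2** forces `body_weight` in; its genotype coefficient estimates the
  *relative* change `β_g`, the effect beyond what the weight difference
  predicts.  Records without a body weight are dropped from A2 only (with a
  logged count); a dataset with no weights at all yields an incomplete
  result with an undefined outcome rather than a silent A1-only call.

Estimation is REML (`statsmodels.MixedLM`, L-BFGS with a fallback to the
default optimizer) when at least two non-singleton batches exist, otherwise
OLS.  Batches with one animal each make the random intercept
non-identifiable against the residual, so it is dropped with a warning.
Fixed-effect p-values are Wald tests with a normal reference — a deliberate
simplification over small-sample (Kenward–Roger/Satterthwaite) corrections;
with control pools of hundreds of mice the residual degrees of freedom make
the difference negligible.  Residual variance is homoscedastic across
genotypes.

### Sexual dimorphism

The `genotype:sex` interaction is screened at `alpha_interaction` (default
0.05).  When it is significant the fit is flagged dimorphic and per-sex
genotype estimates are reported as linear contrasts of the interaction
model (female: `β_g`; male: `β_g + β_g:sex`), preserving the shared
variance estimate rather than splitting the data.  Single-sex datasets are
fitted without sex terms, with a warning.

### The genotype test used for classification

The dataset-level significance call is a 2-df omnibus Wald chi-square test
of all genotype terms (main effect + interaction) from the interaction
model, computed unconditionally.  Design rationale: any rule of the form
"pretest the interaction, then test per-sex effects" inherits selection
bias from the pretest — in simulation at the default cohort geometry the
"either sex significant, no correction" rule rejects a true null ~8% of
the time at nominal 5%, Bonferroni ~7%, and a post-pretest joint LRT ~7.4%,
because conditioning on a significant interaction enriches for large
per-sex statistics.  The unconditional omnibus test has exactly nominal
size (measured 5.1% over 6000 null replicates) and still detects
single-sex and opposite-sign effects.  The any-sex rule remains available
(`genotype_significant(..., rule="any_sex")`) and is what decides which
sexes receive their own annotation; its anticonservatism is documented here
so users re-deriving dataset calls from per-sex p-values know what they are
getting.

### Nested-model machinery

A likelihood-ratio utility (`lrt`) is provided for nested ML fits
(`fit_model(..., method="ml")`); REML log-likelihoods are never compared
across fixed-effect structures.  The interaction screen and the
weight-retention gate use Wald tests from the (RE)ML fit itself — the same
asymptotics as the LRT, one fit fewer per dataset, and no selection coupling
between tests.

### Weight-retention gate (optimized pipeline)

Separately from A2's forced inclusion, an *optimized* pipeline starts from
the model including weight and keeps it only if its Wald p-value is below
`alpha_weight` (default 0.05).  Across a battery this yields the
weight-inclusion distribution (overall and per variable).  Under a zero
trait–weight slope the gate retains weight at the nominal rate (measured
4.6–5.0% across 500-replicate runs); at the default slope of 0.6 g/g it
retains essentially always.

## Outcome classification

`classify` maps the (A1, A2) significance pair to the four-row outcome
table (confounded / no abnormality / relative-only / both); it is total and
mutually exclusive on the four boolean pairs.  For row 4 the sub-scenario is
resolved by fitting body weight itself as the response
(`weight ~ genotype + sex + (1|batch)`): `weight_differs` iff the genotype
effect on weight is significant at `alpha_genotype`.  Because a real weight
phenotype can be missed at 7+7 knockouts, the sub-scenario is always
reported together with the weight-model estimate and p-value, never as a
bare fact.  Significance thresholds are configuration, not constants;
defaults are 0.05 with strict inequality.

## Synthetic cohorts

The generator draws weight first, then the trait:

    weight = μ_w + a·male + δ_g·knockout + N(0, σ_w²)
    trait  = β₀ + β_s·male + β_g·knockout + γ·weight + u_batch + N(0, σ_e²)

It deliberately mirrors the analysis model (linear-Gaussian, additive),
which makes parameter recovery well-posed: the A2 genotype coefficient has
`β_g` as its estimand by construction.  Batches are assigned round-robin;
datasets are bit-reproducible given config + seed.  The generator encodes
genotype → weight → trait only, never reverse causation; that is a modelling
choice the package documents rather than a claim about biology.

Defaults (chosen once as a realistic high-throughput geometry): 200
controls and 7 knockouts per sex, 10 batches; female weight 25 g, males
+5 g, σ_w = 2.5 g; trait intercept 5, sex effect +2, slope γ = 0.6 trait
units/g, σ_b = 0.5, σ_e = 1.0.  No genotype×sex interaction is generated by
default (dimorphism handling is exercised in tests by construction).

Scenario presets, with effect sizes fixed by closed-form power sizing
before any experiment was run:

| preset | δ_g (g) | β_g | γ | targets |
|---|---|---|---|---|
| `null` | 0 | 0 | 0.6 | row 2; type-I calibration |
| `confounded` | −3.5 | 0 | 0.6 | row 1 (A1 power ≈ 0.95, A2 estimand 0) |
| `direct_plus_weight` | −3.5 | −1.5 | 0.6 | row 4, weight differs |
| `sensitivity` | 0 | −0.8 | 1.2 | row 3; A2 power ≫ A1 |

What the simulator does **not** emulate: non-Gaussian traits, heterogeneous
variance between genotypes, missing-data mechanisms, litter effects,
genotype×sex interactions in truth, or the empirical correlation structure
of real phenotyping screens.  Passing tests therefore demonstrate that the
procedure behaves as designed under its own assumptions — calibration,
power ordering, scenario recovery — not that real screens would reproduce
any particular published percentage.

## Monte-Carlo studies and problem sizes

The acceptance studies (shared between `tests/test_acceptance.py`, at
pre-registered seeds, and `scripts/acceptance.py`, seeded by the caller)
use: 500 replicates for type-I and gate calibration (99% binomial envelope
of 0.05 at n=500 is [0.027, 0.078]); 200 replicates for scenario-recovery
rates; 500 paired replicates per point on a 3-point effect grid for the
power comparison; 300 replicates at 100 mice per cell for slope-recovery
coverage (±3 SE); 50 small datasets for the OLS normal-equations oracle
(agreement to 1e−8); a 100-dataset mixed battery for the overlap summary.
These sizes keep a full run at a few minutes on one CPU while leaving the
binomial noise well inside the asserted margins.  One caveat: in the
confounded scenario the both-pipelines rate has true value
(A1 power)×α ≈ 4.7%, so any threshold at 5% sits near the sampling
distribution's centre; the suite pins it with a fixed seed and this note
records that the quantity is boundary-close by construction.

## Annotation and dissemination choices

All dissemination representations coexist on one annotation record (tag,
qualifier term, EQ view, RDF view) so downstream consumers can choose.
Row-1 absolute annotations are retained but tagged as confounded rather
than suppressed.  Direction (increased/decreased) follows the sign of the
evidence estimate, with exact zero falling back to the abnormal term.
Dimorphic fits yield one annotation per individually significant sex; if
the omnibus call fired with neither sex individually significant, a single
annotation with qualifier `both` carries the smaller-p sex's estimate.
Post-composition (entity / "relative to" / body weight / qualifier) is
defined for relative annotations only; absolute changes keep their
pre-composed term.  The `relative_to` predicate, `body_weight` resource and
the `PHREL:0000001` qualifier term are minted in a configurable project
namespace — no public ontology provides them.  RDF output deduplicates the
core triple across sexes by design; OBAN-style association nodes
(`oban=True`) preserve annotation-level distinctions.  N-Triples output is
line-sorted, and annotation TSVs are sorted by (variable, sex, kind), so
all artifacts are byte-deterministic.

## Known limitations

* The model-selection sequence (interaction screen, then report) is one
  reasonable reconstruction of high-throughput practice, not a clone of any
  production pipeline; published battery-level percentages from real
  screens are not reproducible from synthetic data and are not targeted.
* Wald/normal inference ignores small-sample corrections; with fewer than
  ~30 residual degrees of freedom p-values will be optimistic.
* The weight-model sub-classification of row 4 has low sensitivity at
  typical knockout cohort sizes; treat `weight_same` as "no detectable
  weight difference".
* Term identifiers are opaque strings; nothing validates them against an
  ontology release.
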