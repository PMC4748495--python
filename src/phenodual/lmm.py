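"""Linear (mixed) model engine for genotype-phenotype association.

Model: ``trait ~ genotype + sex + genotype:sex (+ body_weight)`` with a
random batch intercept when batch structure is present.  Fitting is REML
(statsmodels ``MixedLM``) when a random effect is included, otherwise
ordinary least squares; fixed-effect p-values are Wald tests with a normal
reference.

Two genotype significance notions are exposed:

* the **omnibus genotype test** — a Wald chi-square test of all genotype
  terms (main effect, plus the sex interaction when both sexes are present)
  from the interaction model.  It is computed unconditionally, so no
  pretest selection touches it and its null rejection rate is the nominal
  alpha.  Dataset-level calls in the dual-analysis pipeline use this test.
* the **any-sex rule** — when sexual dimorphism is detected (interaction
  p < alpha_interaction), the dataset is called significant if either sex's
  genotype estimate is (no multiplicity correction); otherwise the pooled
  estimate decides.  This mirrors per-sex reporting practice but is
  anticonservative because of the dimorphism pretest; it is available via
  ``genotype_significant(..., rule="any_sex")`` and governs per-sex
  annotation granularity, not dataset-level classification.

Sexual dimorphism triggers per-sex genotype estimates obtained by linear
contrasts of the interaction model (female: beta_g; male: beta_g +
beta_g:sex), preserving the shared variance estimate rather than splitting
the data.
"""

from __future__ import annotations

import enum
import logging
import warnings as _warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datamodel import Genotype, PhenotypeDataset, RunConfig, Sex
from .errors import FitError, RankDeficiencyError

logger = logging.getLogger(__name__)

__all__ = [
    "Pipeline",
    "FixedEffectEstimate",
    "ModelFitResult",
    "fit_model",
    "fit_weight_model",
    "lrt",
    "optimize_weight",
    "genotype_significant",
]


class Pipeline(str, enum.Enum):
    A1 = "A1"            # no weight covariate
    A2 = "A2"            # weight forced in
    OPTIMIZED = "optimized"  # weight kept only if it passes the retention gate


@dataclass(frozen=True)
class FixedEffectEstimate:
    """Point estimate, standard error and p-value for one fixed effect."""

    estimate: float
    std_error: float
    p_value: float
    test: str = "wald"

    def __post_init__(self) -> None:
        if self.std_error < 0:
            raise ValueError("std_error must be non-negative")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


@dataclass
class ModelFitResult:
    """Fitted model output for one pipeline on one dataset."""

    pipeline: Pipeline
    sexual_dimorphism: bool
    genotype_test_p: float
    genotype_test_df: int
    log_likelihood: float
    n_by_cell: dict[tuple[str, str], int]
    genotype_overall: FixedEffectEstimate | None = None
    genotype_female: FixedEffectEstimate | None = None
    genotype_male: FixedEffectEstimate | None = None
    weight_in_final_model: bool = False
    weight_p_value: float | None = None
    weight_estimate: FixedEffectEstimate | None = None
    interaction_p: float | None = None
    variance_components: dict[str, float] = field(default_factory=dict)
    method: str = "reml"
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pipeline = Pipeline(self.pipeline)
        if self.sexual_dimorphism:
            if self.genotype_female is None or self.genotype_male is None:
                raise ValueError(
                    "dimorphic fits must carry both per-sex genotype estimates"
                )
        elif self.genotype_overall is None:
            raise ValueError("non-dimorphic fits must carry a pooled estimate")
        if self.pipeline is Pipeline.A1 and self.weight_in_final_model:
            raise ValueError("pipeline A1 never includes weight")


class _FitCore(NamedTuple):
    params: pd.Series
    cov: np.ndarray          # fixed-effect covariance
    llf: float
    variance_components: dict[str, float]
    mixed: bool


def _wald_p(estimate: float, se: float) -> float:
    if se == 0.0:
        return 0.0 if estimate != 0.0 else 1.0
    return float(2.0 * stats.norm.sf(abs(estimate / se)))


def _wald_chi2(b: np.ndarray, C: np.ndarray) -> tuple[float, float]:
    stat = float(b @ np.linalg.pinv(C) @ b)
    return stat, float(stats.chi2.sf(stat, df=len(b)))


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank == arr.shape[1]:
        return
    # identify the first non-intercept column lying in the span of the others
    for j, name in enumerate(X.columns):
        if name == "const":
            continue
        others = np.delete(arr, j, axis=1)
        if np.linalg.matrix_rank(others) == rank:
            raise RankDeficiencyError(
                f"design matrix is rank deficient; collinear column: {name}"
            )
    raise RankDeficiencyError("design matrix is rank deficient")


def _fit_linear(
    y: pd.Series, X: pd.DataFrame, groups: pd.Series | None, method: str
) -> _FitCore:
    """Fit y ~ X, optionally with a random intercept per group."""
    if groups is None:
        res = sm.OLS(np.asarray(y, dtype=float), X.astype(float)).fit()
        resid = res.resid
        dof = max(len(y) - X.shape[1], 1)
        sigma2 = float(resid @ resid) / dof
        return _FitCore(
            params=res.params,
            cov=np.asarray(res.cov_params()),
            llf=float(res.llf),
            variance_components={"residual": sigma2},
            mixed=False,
        )
    model = sm.MixedLM(np.asarray(y, dtype=float), X.astype(float),
                       groups=np.asarray(groups))
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=(method == "reml"), method="lbfgs")
            if not np.all(np.isfinite(res.fe_params)):
                raise FitError("non-finite fixed effects")
        except Exception:
            try:
                res = model.fit(reml=(method == "reml"))
            except Exception as exc:  # pragma: no cover - pathological inputs
                raise FitError(f"mixed-model fit failed: {exc}") from exc
    k = X.shape[1]
    cov = np.asarray(res.cov_params())[:k, :k]
    return _FitCore(
        params=pd.Series(np.asarray(res.fe_params), index=X.columns),
        cov=cov,
        llf=float(res.llf),
        variance_components={
            "batch": float(res.cov_re.iloc[0, 0]),
            "residual": float(res.scale),
        },
        mixed=True,
    )


def _prepare(
    dataset: PhenotypeDataset, include_weight: bool, include_batch: bool,
    warnings_out: list[str],
) -> tuple[pd.DataFrame, pd.Series | None]:
    ds = dataset
    if include_weight and ds.n_missing_weight:
        ds = ds.drop_missing_weight()
        warnings_out.append(
            f"dropped {dataset.n_missing_weight} record(s) with missing body "
            f"weight for the weight-adjusted fit"
        )
    df = ds.to_frame()
    if include_weight:
        for geno in (Genotype.CONTROL.value, Genotype.KNOCKOUT.value):
            if not (df.genotype == geno).any():
                raise FitError(
                    f"no {geno} records with body weight; cannot fit the "
                    f"weight-adjusted model"
                )
    n_ko = int((df.genotype == Genotype.KNOCKOUT.value).sum())
    if n_ko < 4:
        warnings_out.append(f"only {n_ko} knockout animals: low power")
        logger.warning("dataset %s: only %d knockout animals", ds.dataset_id, n_ko)

    groups: pd.Series | None = None
    if include_batch:
        batches = df.batch_id.dropna()
        if len(batches) < len(df):
            warnings_out.append("records without batch id: random intercept dropped")
        elif batches.nunique() < 2:
            warnings_out.append("fewer than 2 batches: random intercept dropped")
        elif batches.value_counts().max() == 1:
            warnings_out.append(
                "one animal per batch: random intercept non-identifiable, dropped"
            )
        else:
            groups = df.batch_id
    return df, groups


def fit_model(
    dataset: PhenotypeDataset,
    include_weight: bool,
    include_batch: bool = True,
    *,
    alpha_interaction: float = 0.05,
    pipeline: Pipeline | None = None,
    method: str = "reml",
) -> ModelFitResult:
    """Fit the genotype-phenotype model for one dataset.

    The genotype:sex interaction is screened at ``alpha_interaction``; if
    significant the fit is flagged sexually dimorphic and per-sex genotype
    estimates are reported, otherwise the interaction is dropped and a pooled
    genotype estimate reported.  The omnibus genotype test (all genotype
    terms jointly) is computed from the interaction model regardless of the
    screen, so it is free of pretest selection.

    ``method`` may be ``"reml"`` (default) or ``"ml"``; maximum likelihood is
    needed when log-likelihoods feed nested-model comparisons via :func:`lrt`.
    """
    if pipeline is None:
        pipeline = Pipeline.A2 if include_weight else Pipeline.A1
    warns: list[str] = []
    df, groups = _prepare(dataset, include_weight, include_batch, warns)

    two_sexes = df.sex.nunique() == 2
    if not two_sexes:
        warns.append("single-sex dataset: sex terms omitted")
        logger.warning("dataset %s: single sex, fitting without sex terms",
                       dataset.dataset_id)

    g = (df.genotype == Genotype.KNOCKOUT.value).astype(float)
    X = pd.DataFrame({"const": np.ones(len(df))})
    X["genotype"] = g
    if two_sexes:
        s = (df.sex == Sex.MALE.value).astype(float)
        X["sex"] = s
        X["genotype:sex"] = g * s
    if include_weight:
        X["body_weight"] = df.body_weight.astype(float)
    _check_rank(X)

    y = df.trait_value
    full = _fit_linear(y, X, groups, method)

    geno_terms = ["genotype", "genotype:sex"] if two_sexes else ["genotype"]
    idx = [X.columns.get_loc(t) for t in geno_terms]
    b = full.params.iloc[idx].to_numpy()
    C = full.cov[np.ix_(idx, idx)]
    _, omnibus_p = _wald_chi2(b, C)

    interaction_p: float | None = None
    dimorphic = False
    if two_sexes:
        j = X.columns.get_loc("genotype:sex")
        interaction_p = _wald_p(full.params.iloc[j], float(np.sqrt(full.cov[j, j])))
        dimorphic = interaction_p < alpha_interaction

    genotype_overall = genotype_female = genotype_male = None
    if dimorphic:
        final = full
        final_X = X
        jg = X.columns.get_loc("genotype")
        jgs = X.columns.get_loc("genotype:sex")
        est_f = float(full.params.iloc[jg])
        se_f = float(np.sqrt(full.cov[jg, jg]))
        est_m = float(full.params.iloc[jg] + full.params.iloc[jgs])
        se_m = float(np.sqrt(full.cov[jg, jg] + full.cov[jgs, jgs]
                             + 2.0 * full.cov[jg, jgs]))
        genotype_female = FixedEffectEstimate(est_f, se_f, _wald_p(est_f, se_f))
        genotype_male = FixedEffectEstimate(est_m, se_m, _wald_p(est_m, se_m))
    else:
        if two_sexes:
            final_X = X.drop(columns="genotype:sex")
            final = _fit_linear(y, final_X, groups, method)
        else:
            final_X = X
            final = full
        jg = final_X.columns.get_loc("genotype")
        est = float(final.params.iloc[jg])
        se = float(np.sqrt(final.cov[jg, jg]))
        genotype_overall = FixedEffectEstimate(est, se, _wald_p(est, se))

    weight_p = None
    weight_est = None
    if include_weight:
        jw = final_X.columns.get_loc("body_weight")
        w_est = float(final.params.iloc[jw])
        w_se = float(np.sqrt(final.cov[jw, jw]))
        weight_p = _wald_p(w_est, w_se)
        weight_est = FixedEffectEstimate(w_est, w_se, weight_p)

    n_by_cell = dict(
        pd.Series(1, index=pd.MultiIndex.from_arrays([df.genotype, df.sex]))
        .groupby(level=[0, 1]).sum()
    )
    return ModelFitResult(
        pipeline=pipeline,
        sexual_dimorphism=dimorphic,
        genotype_test_p=omnibus_p,
        genotype_test_df=len(idx),
        log_likelihood=final.llf,
        n_by_cell={(str(a), str(b_)): int(v) for (a, b_), v in n_by_cell.items()},
        genotype_overall=genotype_overall,
        genotype_female=genotype_female,
        genotype_male=genotype_male,
        weight_in_final_model=include_weight,
        weight_p_value=weight_p,
        weight_estimate=weight_est,
        interaction_p=interaction_p,
        variance_components=final.variance_components,
        method=("mixedlm-" + method) if final.mixed else "ols",
        warnings=warns,
    )


def fit_weight_model(
    dataset: PhenotypeDataset, include_batch: bool = True
) -> FixedEffectEstimate:
    """Fit body weight itself as the response: weight ~ genotype + sex.

    Returns the genotype effect on body weight (grams), used to resolve
    which both-pipelines-significant scenario a dataset falls in.
    """
    warns: list[str] = []
    ds = dataset.drop_missing_weight() if dataset.n_missing_weight else dataset
    if not ds.records:
        raise FitError("no records with body weight")
    df, groups = _prepare(ds, False, include_batch, warns)
    w = df.body_weight.astype(float)
    if float(w.var(ddof=0)) == 0.0:
        raise RankDeficiencyError(
            "body weight is constant across all animals; the weight model "
            "is degenerate (collinear column: body_weight)"
        )
    X = pd.DataFrame({"const": np.ones(len(df))})
    X["genotype"] = (df.genotype == Genotype.KNOCKOUT.value).astype(float)
    if df.sex.nunique() == 2:
        X["sex"] = (df.sex == Sex.MALE.value).astype(float)
    _check_rank(X)
    core = _fit_linear(w, X, groups, "reml")
    jg = X.columns.get_loc("genotype")
    est = float(core.params.iloc[jg])
    se = float(np.sqrt(core.cov[jg, jg]))
    return FixedEffectEstimate(est, se, _wald_p(est, se))


def lrt(full: ModelFitResult, reduced: ModelFitResult, df_diff: int) -> float:
    """Likelihood-ratio p-value for nested ML fits on identical records.

    Both fits must be maximum-likelihood (``method="ml"``); REML
    log-likelihoods are not comparable across fixed-effect structures.
    """
    if df_diff < 1:
        raise ValueError("df_diff must be a positive integer")
    ll_full, ll_red = full.log_likelihood, reduced.log_likelihood
    if ll_full < ll_red - 1e-6:
        raise FitError(
            f"full-model log-likelihood ({ll_full:.6f}) below reduced "
            f"({ll_red:.6f}): fitting failure"
        )
    dev = max(2.0 * (ll_full - ll_red), 0.0)
    return float(np.clip(stats.chi2.sf(dev, df=df_diff), 0.0, 1.0))


def optimize_weight(dataset: PhenotypeDataset, config: RunConfig) -> ModelFitResult:
    """Weight-retention gate: start from the model including weight, keep it
    only if it significantly explains variation (p < alpha_weight)."""
    with_w = fit_model(
        dataset, include_weight=True, include_batch=config.include_batch,
        alpha_interaction=config.alpha_interaction, pipeline=Pipeline.OPTIMIZED,
    )
    p_w = with_w.weight_p_value
    if p_w is not None and p_w < config.alpha_weight:
        return with_w
    without = fit_model(
        dataset, include_weight=False, include_batch=config.include_batch,
        alpha_interaction=config.alpha_interaction, pipeline=Pipeline.OPTIMIZED,
    )
    return replace(without, weight_in_final_model=False, weight_p_value=p_w)


def genotype_significant(
    fit: ModelFitResult, alpha: float, rule: str = "omnibus"
) -> bool:
    """Is the genotype effect significant at ``alpha`` (strict inequality)?

    ``rule="omnibus"`` (default) uses the selection-free joint Wald test of
    all genotype terms; ``rule="any_sex"`` uses the per-sex Wald p-values
    when the fit is dimorphic (significant if either sex is) and the pooled
    p-value otherwise.
    """
    if rule == "omnibus":
        return fit.genotype_test_p < alpha
    if rule == "any_sex":
        if fit.sexual_dimorphism:
            return min(fit.genotype_female.p_value, fit.genotype_male.p_value) < alpha
        return fit.genotype_overall.p_value < alpha
    raise ValueError(f"unknown rule {rule!r}; use 'omnibus' or 'any_sex'")
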