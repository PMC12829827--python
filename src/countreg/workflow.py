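"""End-to-end model comparison: full fits, selection, reduced fits, LRT.

The procedure mirrors how overdispersed monthly case counts are analyzed in
practice:

1. (if patient-level input) encode, clean and aggregate to a monthly design;
2. test the response for overdispersion;
3. fit all requested full models and tabulate metrics and coefficients;
4. keep the variables significant (Wald p < alpha) in *every* full model;
5. refit each family on that reduced set;
6. run the likelihood-ratio test of reduced vs full within one family
   (by default the family with the best full-model AIC) — cross-family
   comparison stays with AIC/BIC since only same-family pairs are nested.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from countreg.distributions import FAMILIES
from countreg.evaluate import (
    DispersionTestResult,
    LRTResult,
    MetricSet,
    cv10,
    fit_metrics,
    information_criteria,
    lrt,
    overdispersion_test,
)
from countreg.glm import CountGLM, _split_design
from countreg.preprocess import aggregate_monthly, clean_patients, encode_covariates

__all__ = ["WorkflowConfig", "ComparisonReport", "significant_in_all", "run_workflow"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WorkflowConfig:
    """Knobs of the comparison pipeline.

    alpha is the per-coefficient significance level of the intersection
    step; ``lrt_family`` picks the family for the nested full-vs-reduced
    test (None: best full-model AIC among converged fits).  ``window`` is
    only needed for patient-level input.
    """

    families: tuple[str, ...] = FAMILIES
    alpha: float = 0.05
    lrt_family: Optional[str] = None
    seed: int = 0
    window: Optional[tuple[str, str]] = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        unknown = set(self.families) - set(FAMILIES)
        if unknown:
            raise ValueError(f"unknown families: {sorted(unknown)}")


@dataclass
class ComparisonReport:
    """Everything the pipeline produced, serializable byte-identically."""

    config: WorkflowConfig
    dispersion: DispersionTestResult
    full_metrics: dict[str, MetricSet]
    reduced_metrics: dict[str, MetricSet]
    coef_tables: dict[str, pd.DataFrame]
    selected_variables: list[str]
    lrt: Optional[LRTResult]
    lrt_family_used: Optional[str]
    degraded: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "config": {
                "families": list(self.config.families),
                "alpha": self.config.alpha,
                "lrt_family": self.config.lrt_family,
                "seed": self.config.seed,
                "window": list(self.config.window) if self.config.window else None,
            },
            "dispersion_test": self.dispersion.as_dict(),
            "full_models": {k: v.as_dict() for k, v in self.full_metrics.items()},
            "reduced_models": {k: v.as_dict() for k, v in self.reduced_metrics.items()},
            "selected_variables": list(self.selected_variables),
            "lrt": None if self.lrt is None else self.lrt.as_dict(),
            "lrt_family": self.lrt_family_used,
            "degraded_families": list(self.degraded),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def metrics_frame(self) -> pd.DataFrame:
        """One row per fitted model, columns in comparison-table order."""
        rows = []
        for label, metrics in list(self.full_metrics.items()) + [
            (f"reduced_{k}", v) for k, v in self.reduced_metrics.items()
        ]:
            rows.append({"model": label, **metrics.as_dict()})
        return pd.DataFrame(rows)


def significant_in_all(
    tables: dict[str, pd.DataFrame], alpha: float = 0.05
) -> list[str]:
    """Variables with Wald p < alpha in every model's coefficient table.

    The intercept is excluded and the input variable order is preserved.
    All tables must cover the same variable set.
    """
    if not tables:
        raise ValueError("no coefficient tables given")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    its = iter(tables.items())
    first_name, first = next(its)
    order = [v for v in first["variable"] if v != "const"]
    ref = set(order)
    pvals = {first_name: first.set_index("variable")["p_value"]}
    for name, tab in its:
        got = set(tab["variable"]) - {"const"}
        if got != ref:
            raise ValueError(
                f"coefficient table {name!r} covers different variables than "
                f"{first_name!r}: {sorted(ref ^ got)}"
            )
        pvals[name] = tab.set_index("variable")["p_value"]
    return [v for v in order if all(p[v] < alpha for p in pvals.values())]


def _fit_family(family: str, design: pd.DataFrame) -> CountGLM:
    from countreg.glm import fit as fit_one

    return fit_one(family, design)


def _metrics_for(model: CountGLM, design: pd.DataFrame, seed: int) -> MetricSet:
    _, y = _split_design(design)
    r2, rmse, mae = fit_metrics(y, model.fitted_means_)
    aic, bic = information_criteria(model.loglik_, model.k_params_, model.n_obs_)
    score = cv10(model._spec_cache.family, design, seed=seed)
    return MetricSet(r2=r2, rmse=rmse, mae=mae, aic=aic, bic=bic, cv10=score)


def run_workflow(data: pd.DataFrame, config: WorkflowConfig = WorkflowConfig()) -> ComparisonReport:
    """Run the full comparison pipeline on monthly or patient-level data.

    Patient-level input (recognized by a ``diagnosis_date`` column) is
    encoded, cleaned and aggregated first; monthly input must carry a ``y``
    column.  Non-converged fits are marked degraded: they stay in the
    report but are excluded from best-AIC selection.  The returned report
    is byte-identical for identical (data, config) — all randomness (CV
    folds) derives from ``config.seed``.
    """
    if "diagnosis_date" in data.columns:
        if config.window is None:
            raise ValueError("patient-level input requires config.window")
        design = aggregate_monthly(
            encode_covariates(clean_patients(data, config.window)), config.window
        )
    else:
        design = data

    dispersion = overdispersion_test(design)
    logger.info("overdispersion: DI=%.3f z=%.3f p=%.4g",
                dispersion.di, dispersion.z, dispersion.p)

    full_fits: dict[str, CountGLM] = {}
    full_metrics: dict[str, MetricSet] = {}
    coef_tables: dict[str, pd.DataFrame] = {}
    degraded: list[str] = []
    for fam in config.families:
        model = _fit_family(fam, design)
        full_fits[fam] = model
        coef_tables[fam] = model.coef_table()
        full_metrics[fam] = _metrics_for(model, design, config.seed)
        if not model.converged_:
            degraded.append(fam)
            logger.warning("full %s fit did not converge; marked degraded", fam)
        logger.info("full %s: loglik=%.2f aic=%.2f", fam, model.loglik_,
                    full_metrics[fam].aic)

    selected = significant_in_all(coef_tables, config.alpha)
    logger.info("selected variables: %s", selected)

    reduced_fits: dict[str, CountGLM] = {}
    reduced_metrics: dict[str, MetricSet] = {}
    if selected:
        keep = [c for c in design.columns if c in ("month", "y")] + selected
        reduced_design = design.loc[:, keep]
        for fam in config.families:
            model = _fit_family(fam, reduced_design)
            reduced_fits[fam] = model
            reduced_metrics[fam] = _metrics_for(model, reduced_design, config.seed)
            if not model.converged_ and fam not in degraded:
                degraded.append(fam)
    else:
        logger.warning("no variable significant in every model; skipping reduced fits")

    lrt_result = None
    lrt_family_used = None
    if reduced_fits:
        if config.lrt_family is not None:
            lrt_family_used = config.lrt_family
        else:
            candidates = [f for f in config.families if f not in degraded]
            if candidates:
                lrt_family_used = min(candidates, key=lambda f: full_metrics[f].aic)
        if lrt_family_used is not None:
            full_m = full_fits[lrt_family_used]
            red_m = reduced_fits[lrt_family_used]
            lrt_result = lrt(
                full_m.loglik_, full_m.k_params_, red_m.loglik_, red_m.k_params_
            )
            logger.info("LRT (%s): stat=%.3f df=%d p=%.4g", lrt_family_used,
                        lrt_result.stat, lrt_result.df, lrt_result.p)

    return ComparisonReport(
        config=config,
        dispersion=dispersion,
        full_metrics=full_metrics,
        reduced_metrics=reduced_metrics,
        coef_tables=coef_tables,
        selected_variables=selected,
        lrt=lrt_result,
        lrt_family_used=lrt_family_used,
        degraded=degraded,
    )
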