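"""Stepwise covariate selection on the clearance model.

Forward inclusion at the 5% level and backward elimination at the 1% level,
judged by the drop in objective function value (delta OFV) against the
chi-square critical value with degrees of freedom equal to the number of
parameters the covariate adds (3.84 for 1 df, 5.99 for 2 df at 5%; 6.63 and
9.21 at 1%). A separate clinical-significance screen flags retained
covariates whose maximal fractional effect on clearance over the observed
covariate range falls below 20%.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.base import BaseEstimator

from .data import Dataset
from .estimation import (ALL_CANDIDATES, FitResult, ModelSpec, _CAT_FIELDS,
                         _Engine, as_dataset, covariate_df, fit)

log = logging.getLogger(__name__)

DEFAULT_FORWARD_ALPHA = 0.05
DEFAULT_BACKWARD_ALPHA = 0.01
DEFAULT_CLINICAL_THRESHOLD = 0.20


@dataclass
class SelectionStep:
    covariate: str
    df: int
    delta_ofv: float
    p_value: float
    iiv_explained_pct: float
    decision: str  # added | removed | rejected | retained


@dataclass
class SelectionTrace:
    """Ordered audit trail of the stepwise procedure."""

    steps: list[SelectionStep] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"step": i + 1, "covariate": s.covariate, "df": s.df,
             "delta_ofv": s.delta_ofv, "p_value": s.p_value,
             "iiv_explained_pct": s.iiv_explained_pct, "decision": s.decision}
            for i, s in enumerate(self.steps)])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def chi2_threshold(alpha: float, df: int) -> float:
    """Critical delta OFV: the (1-alpha) quantile of chi-square(df)."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if df < 1 or int(df) != df:
        raise ValueError(f"df must be a positive integer, got {df}")
    return float(chi2.ppf(1.0 - alpha, df))


def delta_ofv_p_value(delta: float, df: int) -> float:
    """Chi-square tail probability of an observed delta OFV."""
    return float(chi2.sf(max(delta, 0.0), df))


def variance_explained(omega2_base: float, omega2_final: float) -> float:
    """Percent of between-subject variance explained by covariates:
    100*(omega2_base - omega2_final)/omega2_base. Negative values (variance
    rose) are returned with a warning."""
    if omega2_base <= 0:
        raise ValueError("omega2_base must be positive")
    out = 100.0 * (omega2_base - omega2_final) / omega2_base
    if out < 0:
        warnings.warn("final omega2 exceeds base omega2; variance rose",
                      stacklevel=2)
    return out


def _should_remove(increase: float, threshold: float) -> bool:
    """Backward rule: retain only if the removal delta OFV strictly exceeds
    the critical value; at the boundary the covariate is removed."""
    return increase <= threshold


def _warm_values(result: FitResult, ds: Dataset, spec: ModelSpec) -> dict:
    engine = _Engine(ds, spec)
    x = engine.x_from_params(result.fe, result.re)
    return dict(zip(engine.names, x.tolist()))


def forward_select(ds: Dataset, base: ModelSpec, candidates=None,
                   alpha: float = DEFAULT_FORWARD_ALPHA,
                   fit_kwargs: dict | None = None
                   ) -> tuple[ModelSpec, SelectionTrace, FitResult]:
    """Forward inclusion: repeatedly add the candidate with the largest
    significant delta OFV (ties broken by larger delta then lexicographic
    name) until none qualifies."""
    candidates = list(ALL_CANDIDATES if candidates is None else candidates)
    candidates = [c for c in candidates if c not in base.covariates]
    fkw = {"compute_rse": False, **(fit_kwargs or {})}
    current_spec = base
    current_fit = fit(ds, current_spec, **fkw)
    omega2_base = current_fit.re.omega2
    trace = SelectionTrace()
    remaining = sorted(candidates)
    while remaining:
        evaluated = []
        warm = _warm_values(current_fit, ds, current_spec)
        for cov in remaining:
            cand_spec = current_spec.with_covariate(cov)
            df_ = covariate_df(ds, cov)
            if df_ == 0:
                log.warning("candidate %s is constant in this dataset; skipped", cov)
                continue
            try:
                cand_fit = fit(ds, cand_spec, warm_start=warm, **fkw)
            except Exception as exc:  # a failed candidate never aborts selection
                log.warning("candidate %s failed to fit (%s); skipped", cov, exc)
                continue
            delta = current_fit.ofv - cand_fit.ofv
            evaluated.append((cov, df_, delta, cand_spec, cand_fit))
        qualifying = [e for e in evaluated
                      if e[2] > chi2_threshold(alpha, e[1])]
        if not qualifying:
            for cov, df_, delta, _spec, _fit in sorted(evaluated):
                trace.steps.append(SelectionStep(
                    covariate=cov, df=df_, delta_ofv=delta,
                    p_value=delta_ofv_p_value(delta, df_),
                    iiv_explained_pct=0.0, decision="rejected"))
            break
        cov, df_, delta, best_spec, best_fit = min(
            qualifying, key=lambda e: (-e[2], e[0]))
        trace.steps.append(SelectionStep(
            covariate=cov, df=df_, delta_ofv=delta,
            p_value=delta_ofv_p_value(delta, df_),
            iiv_explained_pct=100.0 * (current_fit.re.omega2 - best_fit.re.omega2)
            / omega2_base,
            decision="added"))
        current_spec, current_fit = best_spec, best_fit
        remaining.remove(cov)
    return current_spec, trace, current_fit


def backward_eliminate(ds: Dataset, full: ModelSpec,
                       alpha: float = DEFAULT_BACKWARD_ALPHA,
                       removable=None, fit_kwargs: dict | None = None
                       ) -> tuple[ModelSpec, SelectionTrace, FitResult]:
    """Backward elimination: repeatedly remove the covariate whose removal
    costs the least delta OFV while that cost does not exceed the 1%
    critical value; stops when every remaining covariate is significant."""
    fkw = {"compute_rse": False, **(fit_kwargs or {})}
    current_spec = full
    current_fit = fit(ds, current_spec, **fkw)
    omega2_ref = current_fit.re.omega2
    trace = SelectionTrace()
    while True:
        testable = sorted(removable if removable is not None
                          else current_spec.covariates)
        testable = [c for c in testable if c in current_spec.covariates]
        if not testable:
            break
        evaluated = []
        warm = _warm_values(current_fit, ds, current_spec)
        for cov in testable:
            red_spec = current_spec.without_covariate(cov)
            df_ = covariate_df(ds, cov)
            try:
                red_fit = fit(ds, red_spec, warm_start=warm, **fkw)
            except Exception as exc:
                log.warning("removal of %s failed to fit (%s); skipped", cov, exc)
                continue
            increase = red_fit.ofv - current_fit.ofv
            evaluated.append((cov, df_, increase, red_spec, red_fit))
        if not evaluated:
            break
        # candidate whose removal hurts least, normalised by its critical value
        cov, df_, increase, red_spec, red_fit = min(
            evaluated, key=lambda e: (e[2] - chi2_threshold(alpha, e[1]), e[0]))
        if _should_remove(increase, chi2_threshold(alpha, df_)):
            trace.steps.append(SelectionStep(
                covariate=cov, df=df_, delta_ofv=increase,
                p_value=delta_ofv_p_value(increase, df_),
                iiv_explained_pct=100.0 * (red_fit.re.omega2 - current_fit.re.omega2)
                / omega2_ref,
                decision="removed"))
            current_spec, current_fit = red_spec, red_fit
        else:
            for cov, df_, increase, _s, _f in sorted(evaluated):
                trace.steps.append(SelectionStep(
                    covariate=cov, df=df_, delta_ofv=increase,
                    p_value=delta_ofv_p_value(increase, df_),
                    iiv_explained_pct=0.0, decision="retained"))
            break
    return current_spec, trace, current_fit


def clinical_significance_filter(fit_result: FitResult, ds: Dataset,
                                 threshold: float = DEFAULT_CLINICAL_THRESHOLD
                                 ) -> list[str]:
    """Flag retained covariates whose maximal fractional effect on CL across
    the observed covariate range is below ``threshold`` (default 20%)."""
    subs = list(ds.subjects.values())
    fe = fit_result.fe
    flagged = []
    for cov in fit_result.spec.covariates:
        if cov == "cyp2b6_18":
            observed = {s.g_cyp2b6_18 for s in subs}
            ref = fe.cl_18["TT"]
            eff = max((abs(fe.cl_18[l] / ref - 1.0) for l in observed if l != "TT"),
                      default=0.0)
        elif cov == "cyp2b6_6":
            observed = {s.g_cyp2b6_6 for s in subs}
            eff = max((abs(fe.frac_6.get(l, 0.0)) for l in observed), default=0.0)
        elif cov == "sex":
            eff = abs(fe.frac_female)
        elif cov == "weight":
            w = np.array([s.weight for s in subs])
            eff = max(abs(fe.frac_wt * (w.max() - fe.wt_center)),
                      abs(fe.frac_wt * (w.min() - fe.wt_center)))
        elif cov == "age":
            a = np.array([s.age for s in subs])
            eff = max(abs(fe.frac_age * (a.max() - fe.age_center)),
                      abs(fe.frac_age * (a.min() - fe.age_center)))
        else:
            fld, _ref = _CAT_FIELDS[cov]
            observed = {getattr(s, fld) for s in subs}
            table = fe.frac_other.get(cov, {})
            eff = max((abs(table.get(l, 0.0)) for l in observed), default=0.0)
        if eff < threshold:
            flagged.append(cov)
    return flagged


class StepwiseCovariateSelector(BaseEstimator):
    """Forward-then-backward stepwise covariate selection as an estimator.

    After ``fit``, ``selected_covariates_`` holds the retained covariate
    names, ``trace_`` the combined :class:`SelectionTrace`, ``result_`` the
    final :class:`~efavpk.estimation.FitResult` and
    ``clinically_insignificant_`` any retained covariate whose effect is
    below the clinical threshold.
    """

    def __init__(self, candidates=ALL_CANDIDATES, base_covariates=(),
                 forward_alpha=DEFAULT_FORWARD_ALPHA,
                 backward_alpha=DEFAULT_BACKWARD_ALPHA,
                 clinical_threshold=DEFAULT_CLINICAL_THRESHOLD,
                 drop_clinically_insignificant=False,
                 v=150.0, ka=0.18, wt_center=None, age_center=None,
                 tol=1e-8, max_iter=500, random_state=0):
        self.candidates = candidates
        self.base_covariates = base_covariates
        self.forward_alpha = forward_alpha
        self.backward_alpha = backward_alpha
        self.clinical_threshold = clinical_threshold
        self.drop_clinically_insignificant = drop_clinically_insignificant
        self.v = v
        self.ka = ka
        self.wt_center = wt_center
        self.age_center = age_center
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        ds = as_dataset(X, y)
        base = ModelSpec(covariates=tuple(self.base_covariates), v=self.v,
                         ka=self.ka, wt_center=self.wt_center,
                         age_center=self.age_center)
        fkw = {"tol": self.tol, "max_iter": self.max_iter,
               "random_state": self.random_state}
        fwd_spec, fwd_trace, _fwd_fit = forward_select(
            ds, base, candidates=self.candidates, alpha=self.forward_alpha,
            fit_kwargs=fkw)
        added = tuple(c for c in fwd_spec.covariates
                      if c not in base.covariates)
        bwd_spec, bwd_trace, final_fit = backward_eliminate(
            ds, fwd_spec, alpha=self.backward_alpha, removable=added,
            fit_kwargs=fkw)
        self.forward_trace_ = fwd_trace
        self.backward_trace_ = bwd_trace
        self.trace_ = SelectionTrace(steps=fwd_trace.steps + bwd_trace.steps)
        self.selected_covariates_ = tuple(bwd_spec.covariates)
        self.spec_ = bwd_spec
        self.result_ = final_fit
        self.clinically_insignificant_ = clinical_significance_filter(
            final_fit, ds, threshold=self.clinical_threshold)
        if self.drop_clinically_insignificant and self.clinically_insignificant_:
            for cov in self.clinically_insignificant_:
                if cov not in base.covariates:
                    bwd_spec = bwd_spec.without_covariate(cov)
            final_fit = fit(ds, bwd_spec, **fkw, compute_rse=False)
            self.selected_covariates_ = tuple(bwd_spec.covariates)
            self.spec_ = bwd_spec
            self.result_ = final_fit
        return self


__all__ = [
    "SelectionStep", "SelectionTrace", "StepwiseCovariateSelector",
    "forward_select", "backward_eliminate", "clinical_significance_filter",
    "variance_explained", "chi2_threshold", "delta_ofv_p_value",
]
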