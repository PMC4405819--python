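"""Nonlinear mixed-effects estimation for the efavirenz clearance model.

The marginal likelihood of each subject's concentrations is approximated by
a Laplace-type first-order conditional (FOCE) method with interaction: the
scalar random effect eta (log-normal deviation of CL) is profiled to its
conditional mode, and the proportional residual variance is evaluated at the
conditional (individual) prediction, not the population one.

Per subject i with observations y_j at times t_j,

    g_i(eta) = sum_j [ (y_j - f_j(eta))^2 / (sigma^2 f_j(eta)^2)
                       + log(sigma^2 f_j(eta)^2) ] + eta^2 / omega^2

and the objective function value is

    OFV = sum_i [ g_i(eta_hat_i) + log(omega^2) + log g_i''(eta_hat_i) ],

an approximation of -2 log marginal likelihood with additive constants
(n log 2pi and a log 2 per subject) dropped consistently, so that only
differences between nested models (delta OFV) are interpreted -- the usual
reporting convention of mixed-effects PK software.

Because V/F and ka are fixed, the inner problem is one-dimensional and is
solved for all subjects simultaneously by a damped, bound-safeguarded Newton
iteration on eta in [-8, 8]; the outer problem (fixed effects and variance
components) is solved by L-BFGS-B with numerical gradients on a transformed
scale (logs for positive parameters, log(1+theta) for fractional effects).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from sklearn.base import BaseEstimator

from .data import (CNS_LEVELS, GENOTYPE_LEVELS, REGIMEN_LEVELS, SEX_LEVELS,
                   Dataset, Observation, Subject, ValidationError,
                   dataset_from_frame)
from .pk import (DEFAULT_KA, DEFAULT_V, FixedEffects, RandomEffects,
                 conc_ss_arrays, individual_cl)

_BIG = 1e12
_ETA_BOUND = 8.0
_FD_H = 1e-4          # step for eta derivatives of g
_GRAD_EPS = 1e-6      # outer numerical-gradient step (transformed scale)

#: Candidate covariates of the clearance model, in canonical order.
ALL_CANDIDATES = ("cyp2b6_18", "cyp2b6_6", "weight", "sex", "age",
                  "cyp2a6_9", "cyp2a6_17", "abcb1", "regimen_group",
                  "cns_status")

# categorical covariate -> (Subject field, reference level)
_CAT_FIELDS = {
    "cyp2b6_6": ("g_cyp2b6_6", "GT"),
    "sex": ("sex", "male"),
    "cyp2a6_9": ("g_cyp2a6_9", "GG"),
    "cyp2a6_17": ("g_cyp2a6_17", "GG"),
    "abcb1": ("g_abcb1_1236", "CC"),
    "regimen_group": ("regimen_group", "ART_only"),
    "cns_status": ("cns_status", "no"),
}
_CAT_LEVEL_ORDER = {
    "cyp2b6_6": GENOTYPE_LEVELS["g_cyp2b6_6"],
    "sex": SEX_LEVELS,
    "cyp2a6_9": GENOTYPE_LEVELS["g_cyp2a6_9"],
    "cyp2a6_17": GENOTYPE_LEVELS["g_cyp2a6_17"],
    "abcb1": GENOTYPE_LEVELS["g_abcb1_1236"],
    "regimen_group": REGIMEN_LEVELS,
    "cns_status": CNS_LEVELS,
}
_CONT_FIELDS = ("weight", "age")


@dataclass
class ModelSpec:
    """Which covariates enter the clearance model, plus structural constants.

    ``wt_center``/``age_center`` default to the dataset median when None.
    ``prop_err_is_variance`` records whether the proportional-error
    parameter is reported on the variance (default) or SD scale.
    """

    covariates: tuple = ("cyp2b6_18", "cyp2b6_6", "weight", "sex")
    v: float = DEFAULT_V
    ka: float = DEFAULT_KA
    wt_center: float | None = None
    age_center: float | None = None
    prop_err_is_variance: bool = True
    weight_model: str = "linear"  # "linear" (reference) or "allometric"

    def __post_init__(self):
        if not (self.v > 0 and self.ka > 0):
            raise ValueError("v and ka must be positive")
        if self.weight_model not in ("linear", "allometric"):
            raise ValueError("weight_model must be 'linear' or 'allometric'")
        unknown = [c for c in self.covariates if c not in ALL_CANDIDATES]
        if unknown:
            raise ValueError(f"unknown covariates: {unknown}")
        self.covariates = tuple(self.covariates)

    def with_covariate(self, cov: str) -> "ModelSpec":
        if cov in self.covariates:
            return self
        order = [c for c in ALL_CANDIDATES if c in self.covariates + (cov,)]
        return replace(self, covariates=tuple(order))

    def without_covariate(self, cov: str) -> "ModelSpec":
        return replace(self, covariates=tuple(c for c in self.covariates if c != cov))


@dataclass
class FitResult:
    """Converged (or flagged) estimates from one FOCE-I fit."""

    fe: FixedEffects
    re: RandomEffects
    ofv: float
    rse: dict
    ebes: dict
    converged: bool
    n_iter: int
    estimates: dict
    spec: ModelSpec
    hessian_pd: bool | None = None
    eta_curvatures: dict = field(default_factory=dict)


class EstimationError(RuntimeError):
    pass


def covariate_df(ds: Dataset, cov: str) -> int:
    """Number of free parameters a covariate adds to the clearance model:
    one per *observed* non-reference level for categorical covariates, one
    for continuous ones."""
    subs = list(ds.subjects.values())
    if cov == "cyp2b6_18":
        return max(len({s.g_cyp2b6_18 for s in subs}) - 1, 0)
    if cov in _CAT_FIELDS:
        fld, ref = _CAT_FIELDS[cov]
        return len({getattr(s, fld) for s in subs} - {ref})
    if cov in _CONT_FIELDS:
        return 1
    raise ValueError(f"unknown covariate {cov!r}")


class _Engine:
    """Flattened arrays + parameter layout for one dataset/model pair."""

    def __init__(self, ds: Dataset, spec: ModelSpec):
        ds.require_observations()
        self.spec = spec
        self.v, self.ka = spec.v, spec.ka
        subs = list(ds.subjects.values())
        self.subject_ids = [s.id for s in subs]
        n = len(subs)
        self.n_subj = n
        pos = {s.id: i for i, s in enumerate(subs)}
        self.subj_idx = np.array([pos[o.subject_id] for o in ds.observations])
        self.t = np.array([o.time_after_dose for o in ds.observations])
        self.y = np.array([o.conc for o in ds.observations])
        self.dose = np.array([subs[i].dose for i in self.subj_idx])
        self.tau = np.array([subs[i].tau for i in self.subj_idx])
        if np.any(self.t > self.tau):
            raise ValidationError("observation time exceeds dosing interval")
        weight = np.array([s.weight for s in subs])
        age = np.array([s.age for s in subs])
        self.wt_center = (spec.wt_center if spec.wt_center is not None
                          else float(np.median(weight)))
        self.age_center = (spec.age_center if spec.age_center is not None
                           else float(np.median(age)))

        names: list[str] = []
        covs = spec.covariates
        self.has18 = "cyp2b6_18" in covs
        lvl18 = [s.g_cyp2b6_18 for s in subs]
        if self.has18:
            observed = set(lvl18)
            self.base_levels = [l for l in GENOTYPE_LEVELS["g_cyp2b6_18"]
                                if l in observed]
            base_param = {l: i for i, l in enumerate(self.base_levels)}
            names += [f"lnCL_{l}" for l in self.base_levels]
            self.base_idx = np.array([base_param[g] for g in lvl18])
        else:
            self.base_levels = []
            names.append("lnCL")
            self.base_idx = np.zeros(n, dtype=int)
        # categorical fractional effects: (cov, levels, param index per subject,
        # -1 meaning reference/no effect)
        self.cat_terms: list[tuple[str, list, np.ndarray]] = []
        for cov in covs:
            if cov not in _CAT_FIELDS:
                continue
            fld, ref = _CAT_FIELDS[cov]
            vals = [getattr(s, fld) for s in subs]
            observed = set(vals)
            lvls = [l for l in _CAT_LEVEL_ORDER[cov] if l in observed and l != ref]
            if not lvls:
                continue
            pidx = {l: len(names) + i for i, l in enumerate(lvls)}
            names += [f"u_{cov}_{l}" for l in lvls]
            self.cat_terms.append(
                (cov, lvls, np.array([pidx.get(v_, -1) for v_ in vals])))
        # continuous effects: (cov, kind, param index, transformed values);
        # kind "linear" -> multiplier 1 + theta*x, "power" -> exp(theta*x)
        self.cont_terms: list[tuple[str, str, int, np.ndarray]] = []
        for cov in covs:
            if cov not in _CONT_FIELDS:
                continue
            if cov == "weight" and spec.weight_model == "allometric":
                self.cont_terms.append(
                    ("weight", "power", len(names), np.log(weight / self.wt_center)))
            else:
                x = weight if cov == "weight" else age
                c = self.wt_center if cov == "weight" else self.age_center
                self.cont_terms.append((cov, "linear", len(names), x - c))
            names.append(f"th_{cov}")
        self.i_omega = len(names)
        names.append("ln_omega2")
        self.i_sigma = len(names)
        names.append("ln_sigma2")
        self.names = names
        self.n_params = len(names)
        self._eta_warm = np.zeros(n)

    # -- parameter mapping ------------------------------------------------

    def cl_pop(self, x: np.ndarray):
        """Per-subject typical clearance; (cl, penalty) with penalty > 0 when
        a continuous multiplier had to be clipped away from zero."""
        cl = np.exp(x[self.base_idx])
        for _cov, _lvls, idx in self.cat_terms:
            u = np.where(idx >= 0, x[np.maximum(idx, 0)], 0.0)
            cl = cl * np.exp(u)
        penalty = 0.0
        for _cov, kind, p, xc in self.cont_terms:
            if kind == "power":
                cl = cl * np.exp(x[p] * xc)
                continue
            m = 1.0 + x[p] * xc
            viol = np.minimum(m - 1e-3, 0.0)
            if np.any(viol < 0):
                penalty += 1e7 * float(np.sum(viol ** 2))
                m = np.maximum(m, 1e-3)
            cl = cl * m
        return cl, penalty

    def bounds(self):
        bnd = []
        for name in self.names:
            if name.startswith("lnCL"):
                bnd.append((math.log(1e-3), math.log(1e3)))
            elif name.startswith("u_"):
                bnd.append((math.log(0.02), math.log(50.0)))
            elif name == "th_weight" and self.spec.weight_model == "allometric":
                bnd.append((-1.0, 3.0))
            elif name.startswith("th_"):
                bnd.append((-0.5, 0.5))
            else:  # ln_omega2 / ln_sigma2
                bnd.append((-12.0, 5.0))
        return bnd

    def default_x0(self) -> np.ndarray:
        x0 = np.zeros(self.n_params)
        base_per_obs = self.base_idx[self.subj_idx]
        n_bases = len(self.base_levels) if self.has18 else 1
        for b in range(n_bases):
            mask = base_per_obs == b
            med = float(np.median(self.y[mask])) if mask.any() else 1.0
            med = max(med, 1e-3)
            cl0 = float(np.median(self.dose[mask] / self.tau[mask])) / med \
                if mask.any() else 5.0
            x0[b] = math.log(min(max(cl0, 0.05), 200.0))
        x0[self.i_omega] = math.log(0.3)
        x0[self.i_sigma] = math.log(0.1)
        return x0

    def x_from_params(self, fe: FixedEffects, re: RandomEffects) -> np.ndarray:
        if re.omega2 <= 0 or re.sigma2_prop <= 0:
            raise ValueError("omega2 and sigma2 must be positive to evaluate FOCE-I")
        x = np.zeros(self.n_params)
        if self.has18:
            for i, lvl in enumerate(self.base_levels):
                x[i] = math.log(fe.cl_18[lvl])
        else:
            x[0] = math.log(fe.cl_18["TT"])
        k = 0
        for cov, lvls, _idx in self.cat_terms:
            for lvl in lvls:
                if cov == "cyp2b6_6":
                    frac = fe.frac_6.get(lvl, 0.0)
                elif cov == "sex":
                    frac = fe.frac_female
                else:
                    frac = fe.frac_other.get(cov, {}).get(lvl, 0.0)
                pos = self.names.index(f"u_{cov}_{lvl}")
                x[pos] = math.log1p(frac)
            k += len(lvls)
        for cov, kind, p, _xc in self.cont_terms:
            if kind == "power":
                x[p] = fe.wt_allometric_exp if fe.wt_allometric_exp is not None else 0.0
            else:
                x[p] = fe.frac_wt if cov == "weight" else fe.frac_age
        x[self.i_omega] = math.log(re.omega2)
        x[self.i_sigma] = math.log(re.sigma2_prop)
        return x

    def x_from_names(self, values: dict) -> np.ndarray:
        """Warm start: map a {parameter name: value} dict onto this layout;
        names absent from the dict keep the default initial value."""
        x = self.default_x0()
        for i, name in enumerate(self.names):
            if name in values:
                x[i] = values[name]
        return x

    def fixed_effects(self, x: np.ndarray) -> FixedEffects:
        if self.has18:
            vals = {lvl: float(np.exp(x[i])) for i, lvl in enumerate(self.base_levels)}
            fallback = vals[self.base_levels[0]]
            cl_18 = {lvl: vals.get(lvl, fallback)
                     for lvl in GENOTYPE_LEVELS["g_cyp2b6_18"]}
        else:
            cl = float(np.exp(x[0]))
            cl_18 = {lvl: cl for lvl in GENOTYPE_LEVELS["g_cyp2b6_18"]}
        frac_6 = {lvl: 0.0 for lvl in GENOTYPE_LEVELS["g_cyp2b6_6"]}
        frac_female = 0.0
        frac_other: dict = {}
        for cov, lvls, _idx in self.cat_terms:
            for lvl in lvls:
                val = float(np.expm1(x[self.names.index(f"u_{cov}_{lvl}")]))
                if cov == "cyp2b6_6":
                    frac_6[lvl] = val
                elif cov == "sex":
                    frac_female = val
                else:
                    frac_other.setdefault(cov, {})[lvl] = val
        frac_wt = frac_age = 0.0
        wt_exp = None
        for cov, kind, p, _xc in self.cont_terms:
            if kind == "power":
                wt_exp = float(x[p])
            elif cov == "weight":
                frac_wt = float(x[p])
            else:
                frac_age = float(x[p])
        return FixedEffects(cl_18=cl_18, frac_6=frac_6, frac_female=frac_female,
                            frac_wt=frac_wt, wt_center=self.wt_center,
                            frac_age=frac_age, age_center=self.age_center,
                            frac_other=frac_other, wt_allometric_exp=wt_exp)

    def natural_params(self, x: np.ndarray) -> dict:
        out = {}
        for i, name in enumerate(self.names):
            if name.startswith("lnCL_"):
                out["CL_" + name[5:]] = float(np.exp(x[i]))
            elif name == "lnCL":
                out["CL"] = float(np.exp(x[i]))
            elif name.startswith("u_"):
                out["FRAC_" + name[2:]] = float(np.expm1(x[i]))
            elif name == "th_weight":
                key = ("WT_ALLOMETRIC_EXP" if self.spec.weight_model == "allometric"
                       else "FRAC_WT_PER_KG")
                out[key] = float(x[i])
            elif name == "th_age":
                out["FRAC_AGE_PER_YR"] = float(x[i])
            elif name == "ln_omega2":
                out["OMEGA2"] = float(np.exp(x[i]))
            elif name == "ln_sigma2":
                out["SIGMA2"] = float(np.exp(x[i]))
        return out

    def x_from_natural(self, z: np.ndarray) -> np.ndarray:
        x = np.empty(self.n_params)
        for i, name in enumerate(self.names):
            if name.startswith("lnCL") or name.startswith("ln_"):
                x[i] = math.log(z[i])
            elif name.startswith("u_"):
                x[i] = math.log1p(z[i])
            else:
                x[i] = z[i]
        return x

    def natural_vector(self, x: np.ndarray) -> np.ndarray:
        z = np.empty(self.n_params)
        for i, name in enumerate(self.names):
            if name.startswith("lnCL") or name.startswith("ln_"):
                z[i] = math.exp(x[i])
            elif name.startswith("u_"):
                z[i] = math.expm1(x[i])
            else:
                z[i] = x[i]
        return z

    # -- likelihood -------------------------------------------------------

    def _subject_g(self, eta: np.ndarray, cl: np.ndarray, sigma2: float,
                   omega2: float) -> np.ndarray:
        cl_obs = cl[self.subj_idx] * np.exp(eta[self.subj_idx])
        f = conc_ss_arrays(self.t, self.dose, self.tau, cl_obs, self.v, self.ka)
        var = sigma2 * f * f
        terms = (self.y - f) ** 2 / var + np.log(var)
        return np.bincount(self.subj_idx, weights=terms,
                           minlength=self.n_subj) + eta * eta / omega2

    def solve_inner(self, cl, sigma2, omega2, eta0=None, max_iter=40,
                    gtol=1e-7):
        """Conditional modes for all subjects at once (damped Newton)."""
        eta = (self._eta_warm if eta0 is None else eta0).copy()
        np.clip(eta, -_ETA_BOUND, _ETA_BOUND, out=eta)
        h = _FD_H

        def G(e):
            return self._subject_g(e, cl, sigma2, omega2)

        g0 = G(eta)
        for _ in range(max_iter):
            gp_ = G(eta + h)
            gm_ = G(eta - h)
            grad = (gp_ - gm_) / (2 * h)
            curv = (gp_ - 2 * g0 + gm_) / (h * h)
            active = np.abs(grad) > gtol * (1.0 + np.abs(g0))
            if not active.any():
                break
            step = -grad / np.maximum(curv, 1e-6)
            np.clip(step, -2.0, 2.0, out=step)
            step[~active] = 0.0
            new = np.clip(eta + step, -_ETA_BOUND, _ETA_BOUND)
            g1 = G(new)
            for _damp in range(12):
                worse = active & (g1 > g0 + 1e-12)
                if not worse.any():
                    break
                step[worse] *= 0.5
                new = np.clip(eta + step, -_ETA_BOUND, _ETA_BOUND)
                g1 = G(new)
            improved = g1 <= g0
            moved = float(np.max(np.abs(np.where(improved, new, eta) - eta)))
            eta = np.where(improved, new, eta)
            g0 = np.where(improved, g1, g0)
            if moved < 1e-10:  # finite-difference noise floor reached
                break
        gp_ = G(eta + h)
        gm_ = G(eta - h)
        curv = np.maximum((gp_ - 2 * g0 + gm_) / (h * h), 1e-10)
        self._eta_warm = eta
        return eta, g0, curv

    def ofv_components(self, x: np.ndarray):
        cl, penalty = self.cl_pop(x)
        if not np.all(np.isfinite(cl)):
            return None
        omega2 = math.exp(x[self.i_omega])
        sigma2 = math.exp(x[self.i_sigma])
        eta, g, curv = self.solve_inner(cl, sigma2, omega2)
        ofv = float(np.sum(g) + self.n_subj * math.log(omega2)
                    + np.sum(np.log(curv))) + penalty
        return ofv, eta, g, curv, cl, omega2, sigma2

    def ofv(self, x: np.ndarray) -> float:
        comp = self.ofv_components(np.asarray(x, dtype=float))
        if comp is None or not math.isfinite(comp[0]):
            return _BIG
        return comp[0]


# -- public operations ----------------------------------------------------

def ebe(subject: Subject, observations: list[Observation], fe: FixedEffects,
        re: RandomEffects, v: float = DEFAULT_V, ka: float = DEFAULT_KA
        ) -> tuple[float, float]:
    """Empirical-Bayes estimate (conditional mode) of a subject's eta, and
    the curvature d^2 g / d eta^2 at the mode.

    Requires omega2 > 0 and at least one observation.
    """
    if re.omega2 <= 0:
        raise ValueError("omega2 must be positive (infinite-shrinkage limit is eta=0)")
    if not observations:
        raise ValueError(f"subject {subject.id}: no observations")
    cl = individual_cl(subject, fe)
    t = np.array([o.time_after_dose for o in observations])
    y = np.array([o.conc for o in observations])
    s2 = re.sigma2_prop

    def g(e: float) -> float:
        f = conc_ss_arrays(t, subject.dose, subject.tau, cl * math.exp(e), v, ka)
        var = s2 * f * f
        return float(np.sum((y - f) ** 2 / var + np.log(var)) + e * e / re.omega2)

    res = minimize_scalar(g, bounds=(-_ETA_BOUND, _ETA_BOUND), method="bounded",
                          options={"xatol": 1e-10})
    if not res.success:
        raise EstimationError(f"inner optimisation failed for subject {subject.id}")
    e_hat = float(res.x)
    h = _FD_H
    curv = (g(e_hat + h) - 2 * g(e_hat) + g(e_hat - h)) / (h * h)
    if curv <= 0:
        raise EstimationError(
            f"non-positive curvature at conditional mode for subject {subject.id}")
    return e_hat, float(curv)


def ofv_focei(ds: Dataset, spec: ModelSpec, fe: FixedEffects,
              re: RandomEffects) -> float:
    """FOCE-I objective function value at the given parameters."""
    spec = replace(spec,
                   wt_center=spec.wt_center if spec.wt_center is not None else fe.wt_center,
                   age_center=spec.age_center if spec.age_center is not None else fe.age_center)
    engine = _Engine(ds, spec)
    val = engine.ofv(engine.x_from_params(fe, re))
    if val >= _BIG:
        raise EstimationError("non-finite prediction or invalid parameters")
    return val


def evaluate(ds: Dataset, spec: ModelSpec, fe: FixedEffects,
             re: RandomEffects, compute_rse: bool = False) -> FitResult:
    """Build a :class:`FitResult` (OFV, EBEs, curvatures) at fixed
    parameters, without any optimisation."""
    spec = replace(spec,
                   wt_center=spec.wt_center if spec.wt_center is not None else fe.wt_center,
                   age_center=spec.age_center if spec.age_center is not None else fe.age_center)
    engine = _Engine(ds, spec)
    x = engine.x_from_params(fe, re)
    comp = engine.ofv_components(x)
    if comp is None or not math.isfinite(comp[0]):
        raise EstimationError("objective not evaluable at the given parameters")
    ofv, eta, _g, curv, _cl, omega2, sigma2 = comp
    rse_map, hessian_pd = ({}, None)
    if compute_rse:
        rse_map, hessian_pd = _rse_at(engine, x)
    return FitResult(
        fe=engine.fixed_effects(x), re=RandomEffects(omega2, sigma2),
        ofv=float(ofv), rse=rse_map,
        ebes=dict(zip(engine.subject_ids, eta.tolist())),
        converged=True, n_iter=0, estimates=engine.natural_params(x),
        spec=spec, hessian_pd=hessian_pd,
        eta_curvatures=dict(zip(engine.subject_ids, curv.tolist())))


def fit(ds: Dataset, spec: ModelSpec | None = None,
        init: tuple[FixedEffects, RandomEffects] | None = None,
        warm_start: dict | None = None, compute_rse: bool = True,
        tol: float = 1e-8, max_iter: int = 500, n_restarts: int = 3,
        random_state: int = 0) -> FitResult:
    """Maximum-likelihood FOCE-I fit of the clearance model.

    ``init`` optionally provides starting fixed/random effects; otherwise a
    crude moment-based start is used. ``warm_start`` maps parameter names to
    transformed-scale starting values (used by stepwise selection). Seeded
    random restarts are attempted when the optimizer reports failure;
    non-convergence is flagged, never silently returned as success.
    """
    spec = spec or ModelSpec()
    engine = _Engine(ds, spec)
    if init is not None:
        x0 = engine.x_from_params(*init)
    elif warm_start is not None:
        x0 = engine.x_from_names(warm_start)
    else:
        x0 = engine.default_x0()
    bounds = engine.bounds()
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    x0 = np.clip(x0, lo, hi)
    f0 = engine.ofv(x0)
    rng = np.random.default_rng(random_state)

    best = None
    n_iter = 0
    converged = False
    start = x0
    for attempt in range(n_restarts + 1):
        res = minimize(engine.ofv, start, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": max_iter, "ftol": tol,
                                "eps": _GRAD_EPS, "maxcor": 20})
        n_iter += int(res.nit)
        if best is None or res.fun < best.fun:
            best = res
        if res.success and math.isfinite(res.fun) and res.fun < _BIG:
            converged = True
            break
        start = np.clip(x0 + rng.normal(0.0, 0.3, size=x0.size), lo, hi)
    x_hat = np.asarray(best.x)
    ofv_hat = float(best.fun)
    if ofv_hat > f0:  # never return something worse than the start
        x_hat, ofv_hat, converged = x0, f0, False
    comp = _Engine(ds, spec).ofv_components(x_hat)  # fresh warm start: deterministic
    if comp is None:
        raise EstimationError("objective not evaluable at the optimum")
    _ofv, eta, _g, curv, _cl, omega2, sigma2 = comp
    fe_hat = engine.fixed_effects(x_hat)
    re_hat = RandomEffects(omega2=omega2, sigma2_prop=sigma2)
    rse_map: dict = {}
    hessian_pd = None
    if compute_rse:
        rse_map, hessian_pd = _rse_at(engine, x_hat)
    return FitResult(
        fe=fe_hat, re=re_hat, ofv=float(_ofv),
        rse=rse_map, ebes=dict(zip(engine.subject_ids, eta.tolist())),
        converged=bool(converged), n_iter=n_iter,
        estimates=engine.natural_params(x_hat), spec=spec,
        hessian_pd=hessian_pd,
        eta_curvatures=dict(zip(engine.subject_ids, curv.tolist())))


def _rse_at(engine: _Engine, x_hat: np.ndarray, rel_step: float = 1e-3):
    """RSE% from the inverse numerical Hessian of OFV/2 on the natural scale.

    A non-positive-definite or singular Hessian is reported via the flag and
    NaN entries, never masked.
    """
    z0 = engine.natural_vector(x_hat)
    names = list(engine.natural_params(x_hat).keys())
    p = len(z0)

    def f(z):
        try:
            return engine.ofv(engine.x_from_natural(z)) / 2.0
        except ValueError:
            return _BIG

    h = rel_step * np.maximum(np.abs(z0), 1e-2)
    H = np.empty((p, p))
    f0 = f(z0)
    for i in range(p):
        zi = z0.copy(); zi[i] += h[i]
        zm = z0.copy(); zm[i] -= h[i]
        H[i, i] = (f(zi) - 2 * f0 + f(zm)) / (h[i] ** 2)
    for i in range(p):
        for j in range(i + 1, p):
            zpp = z0.copy(); zpp[[i, j]] += [h[i], h[j]]
            zpm = z0.copy(); zpm[i] += h[i]; zpm[j] -= h[j]
            zmp = z0.copy(); zmp[i] -= h[i]; zmp[j] += h[j]
            zmm = z0.copy(); zmm[[i, j]] -= [h[i], h[j]]
            H[i, j] = H[j, i] = (f(zpp) - f(zpm) - f(zmp) + f(zmm)) / (4 * h[i] * h[j])
    rse = {name: float("nan") for name in names}
    try:
        np.linalg.cholesky(H)
        pd_ok = True
    except np.linalg.LinAlgError:
        pd_ok = False
    try:
        cov = np.linalg.inv(H)
        diag = np.diag(cov)
        for k, name in enumerate(names):
            if diag[k] > 0 and abs(z0[k]) > 0:
                rse[name] = float(100.0 * math.sqrt(diag[k]) / abs(z0[k]))
    except np.linalg.LinAlgError:
        pd_ok = False
    return rse, pd_ok


def rse(fit_result: FitResult, ds: Dataset, spec: ModelSpec | None = None) -> dict:
    """Recompute relative standard errors (%) for a converged fit."""
    if not fit_result.converged:
        raise EstimationError("RSE requires a converged fit")
    spec = spec or fit_result.spec
    engine = _Engine(ds, spec)
    x_hat = engine.x_from_params(fit_result.fe, fit_result.re)
    out, _pd = _rse_at(engine, x_hat)
    return out


def write_fit_report(fit_result: FitResult, path) -> None:
    """Plain-text fit report: parameter, estimate, RSE%, fixed flag."""
    lines = [f"{'parameter':<22}{'estimate':>12}  {'RSE%':>8}  fixed",
             "-" * 52]
    for name, est in fit_result.estimates.items():
        r = fit_result.rse.get(name, float("nan"))
        rs = f"{r:8.1f}" if math.isfinite(r) else "      NA"
        lines.append(f"{name:<22}{est:12.4g}  {rs}  no")
    lines.append(f"{'V':<22}{fit_result.spec.v:12.4g}  {'':>8}  yes")
    lines.append(f"{'KA':<22}{fit_result.spec.ka:12.4g}  {'':>8}  yes")
    lines.append(f"IIV %CV = {100*math.sqrt(fit_result.re.omega2):.1f}")
    lines.append(f"OFV = {fit_result.ofv:.4f}")
    lines.append(f"converged = {fit_result.converged}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def as_dataset(X, y=None, dialect=None) -> Dataset:
    """Coerce estimator input (Dataset, or rectangular DataFrame with an
    optional separate concentration vector y) into a Dataset."""
    if isinstance(X, Dataset):
        return X
    if isinstance(X, pd.DataFrame):
        df = X.copy()
        if y is not None:
            df["DV"] = np.asarray(y, dtype=float)
        elif "DV" not in df.columns:
            df["DV"] = 0.0
        return dataset_from_frame(df, dialect=dialect)
    raise TypeError("X must be a Dataset or a pandas DataFrame")


class FoceNlme(BaseEstimator):
    """Scikit-learn style FOCE-I mixed-effects estimator.

    ``fit(X, y)`` accepts a :class:`~efavpk.data.Dataset` (y ignored) or a
    NONMEM-style DataFrame with concentrations either in a DV column or
    passed as ``y``. Fitted attributes: ``fixed_effects_``,
    ``random_effects_``, ``ofv_``, ``ebes_``, ``rse_``, ``converged_``,
    ``n_iter_`` and the full ``result_``.
    """

    def __init__(self, covariates=("cyp2b6_18", "cyp2b6_6", "weight", "sex"),
                 v=DEFAULT_V, ka=DEFAULT_KA, wt_center=None, age_center=None,
                 compute_rse=True, tol=1e-8, max_iter=500, n_restarts=3,
                 random_state=0):
        self.covariates = covariates
        self.v = v
        self.ka = ka
        self.wt_center = wt_center
        self.age_center = age_center
        self.compute_rse = compute_rse
        self.tol = tol
        self.max_iter = max_iter
        self.n_restarts = n_restarts
        self.random_state = random_state

    def _spec(self) -> ModelSpec:
        return ModelSpec(covariates=tuple(self.covariates), v=self.v, ka=self.ka,
                         wt_center=self.wt_center, age_center=self.age_center)

    def fit(self, X, y=None):
        ds = as_dataset(X, y)
        result = fit(ds, self._spec(), compute_rse=self.compute_rse,
                     tol=self.tol, max_iter=self.max_iter,
                     n_restarts=self.n_restarts, random_state=self.random_state)
        self.result_ = result
        self.fixed_effects_ = result.fe
        self.random_effects_ = result.re
        self.ofv_ = result.ofv
        self.ebes_ = result.ebes
        self.rse_ = result.rse
        self.converged_ = result.converged
        self.n_iter_ = result.n_iter
        return self

    def predict(self, X, individual=False):
        """Predicted concentration per observation row; population (eta=0)
        by default, or at the subject's EBE with ``individual=True``."""
        from .pk import predict as _predict
        if not hasattr(self, "result_"):
            raise EstimationError("estimator is not fitted")
        ds = as_dataset(X)
        out = np.empty(ds.n_observations)
        for k, obs in enumerate(ds.observations):
            s = ds.subjects[obs.subject_id]
            eta = self.ebes_.get(obs.subject_id, 0.0) if individual else 0.0
            out[k] = _predict(s, obs.time_after_dose, self.fixed_effects_,
                              eta, v=self.v, ka=self.ka)
        return out


__all__ = [
    "ModelSpec", "FitResult", "FoceNlme", "EstimationError",
    "ebe", "ofv_focei", "fit", "evaluate", "rse", "covariate_df",
    "write_fit_report", "as_dataset", "ALL_CANDIDATES",
]
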