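"""One-compartment oral steady-state concentration model and the
multiplicative covariate model for efavirenz apparent clearance.

Structural model: first-order absorption, first-order elimination, repeated
oral dosing every ``tau`` hours at steady state,

    C(t) = D*ka / (V*(ka-ke)) * [ exp(-ke*t)/(1-exp(-ke*tau))
                                  - exp(-ka*t)/(1-exp(-ka*tau)) ],

with elimination rate ke = CL/V. Only CL/F is subject-specific; V/F and ka
are fixed population constants. When ka approaches ke (flip-flop kinetics)
the analytic limit

    C(t) = D*k/V * exp(-k*t) * [t*(1-E) + tau*E] / (1-E)^2,   E = exp(-k*tau)

is used for numerical stability.

Covariate model: clearance for subject i is the genotype-specific base
multiplied by fractional effects,

    CL_i = CL18[g18] * (1 + f6[g6]) * (1 + f_female*I(female))
           * (1 + f_wt*(WT - WT_center)) * ...,

i.e. each covariate scales a typical value multiplicatively; continuous
covariates are centred. Between-subject variability enters log-normally as
CL_i * exp(eta), eta ~ N(0, omega^2).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data import GENOTYPE_LEVELS, Subject

DEFAULT_V = 150.0   # apparent volume V/F, litres (fixed)
DEFAULT_KA = 0.18   # absorption rate constant, 1/h (fixed)

# Relative width of the ka ~= ke band in which the limit branch is used.
_FLIPFLOP_RTOL = 1e-7


@dataclass
class StructuralParams:
    """Structural constants for one subject: CL/F (L/h), V/F (L), ka (1/h)."""

    cl: float
    v: float = DEFAULT_V
    ka: float = DEFAULT_KA

    def __post_init__(self):
        if not (self.cl > 0 and self.v > 0 and self.ka > 0):
            raise ValueError("cl, v and ka must all be positive")


@dataclass
class FixedEffects:
    """Population fixed effects of the clearance covariate model.

    ``cl_18`` maps the CYP2B6*18 genotype to the base clearance (L/h);
    fractional effects are dimensionless multipliers-minus-one. ``frac_wt``
    is per kg of body weight, centred at ``wt_center``. Covariates outside
    the final model (age, CYP2A6, ABCB1, regimen, CNS status) live in
    ``frac_other`` keyed by covariate name then level.
    """

    cl_18: dict
    frac_6: dict
    frac_female: float = 0.0
    frac_wt: float = 0.0
    wt_center: float = 58.0
    frac_age: float = 0.0
    age_center: float = 38.0
    frac_other: dict = field(default_factory=dict)
    #: when set, weight scales CL as (WT/wt_center)**exp instead of linearly
    wt_allometric_exp: float | None = None


@dataclass
class RandomEffects:
    """Variance components: omega2 for log-normal IIV on CL, sigma2_prop for
    the proportional residual. Reported IIV %CV is 100*sqrt(omega2)."""

    omega2: float
    sigma2_prop: float

    def __post_init__(self):
        if self.omega2 < 0 or self.sigma2_prop < 0:
            raise ValueError("variance components must be non-negative")


def conc_ss_arrays(t, dose, tau, cl, v=DEFAULT_V, ka=DEFAULT_KA):
    """Vectorised steady-state concentration; no domain checks.

    All arguments broadcast; returns ug/ml when dose is mg, v in L.
    """
    t = np.asarray(t, dtype=float)
    cl = np.asarray(cl, dtype=float)
    ke = cl / v
    near = np.abs(ka - ke) <= _FLIPFLOP_RTOL * np.maximum(ka, ke)
    ke_safe = np.where(near, ka * 2.0, ke)  # keep denominator well away from 0
    e_ke = np.exp(-ke_safe * t) / (1.0 - np.exp(-ke_safe * tau))
    e_ka = np.exp(-ka * t) / (1.0 - np.exp(-ka * tau))
    std = dose * ka / (v * (ka - ke_safe)) * (e_ke - e_ka)
    if np.any(near):
        k = (ka + ke) / 2.0
        E = np.exp(-k * tau)
        lim = dose * k / v * np.exp(-k * t) * (t * (1.0 - E) + tau * E) / (1.0 - E) ** 2
        return np.where(near, lim, std)
    return std


def conc_ss(t: float, dose: float, tau: float, p: StructuralParams) -> float:
    """Steady-state plasma concentration (ug/ml) at time ``t`` hours after
    the most recent dose of ``dose`` mg given every ``tau`` hours.

    Raises ValueError unless 0 < t <= tau and dose > 0.
    """
    if not 0 < t <= tau:
        raise ValueError(f"t must lie in (0, tau]; got t={t}, tau={tau}")
    if not dose > 0:
        raise ValueError("dose must be positive")
    return float(conc_ss_arrays(t, dose, tau, p.cl, p.v, p.ka))


def _genotype_frac(fe: FixedEffects, covariate: str, level: str) -> float:
    table = fe.frac_other.get(covariate, {})
    return float(table.get(level, 0.0))


def individual_cl(s: Subject, fe: FixedEffects) -> float:
    """Typical (eta = 0) clearance for a subject under the covariate model.

    Raises ValueError if the covariate combination drives CL non-positive.
    """
    if s.g_cyp2b6_18 not in fe.cl_18:
        raise ValueError(f"no base clearance for CYP2B6*18 level {s.g_cyp2b6_18!r}")
    cl = fe.cl_18[s.g_cyp2b6_18]
    cl *= 1.0 + fe.frac_6.get(s.g_cyp2b6_6, 0.0)
    cl *= 1.0 + fe.frac_female * (1.0 if s.sex == "female" else 0.0)
    if fe.wt_allometric_exp is not None:
        cl *= (s.weight / fe.wt_center) ** fe.wt_allometric_exp
    else:
        cl *= 1.0 + fe.frac_wt * (s.weight - fe.wt_center)
    cl *= 1.0 + fe.frac_age * (s.age - fe.age_center)
    cl *= 1.0 + _genotype_frac(fe, "cyp2a6_9", s.g_cyp2a6_9)
    cl *= 1.0 + _genotype_frac(fe, "cyp2a6_17", s.g_cyp2a6_17)
    cl *= 1.0 + _genotype_frac(fe, "abcb1", s.g_abcb1_1236)
    cl *= 1.0 + _genotype_frac(fe, "regimen_group", s.regimen_group)
    cl *= 1.0 + _genotype_frac(fe, "cns_status", s.cns_status)
    if not cl > 0:
        raise ValueError(
            f"subject {s.id}: covariate model yields non-positive clearance {cl}")
    return float(cl)


def predict(s: Subject, obs_time: float, fe: FixedEffects, eta: float = 0.0,
            v: float = DEFAULT_V, ka: float = DEFAULT_KA) -> float:
    """Predicted concentration for a subject at ``obs_time`` hours post dose,
    with individual deviation ``eta`` applied as CL_i = CL * exp(eta)."""
    cl = individual_cl(s, fe) * math.exp(eta)
    return conc_ss(obs_time, s.dose, s.tau, StructuralParams(cl=cl, v=v, ka=ka))


__all__ = [
    "StructuralParams", "FixedEffects", "RandomEffects",
    "conc_ss", "conc_ss_arrays", "individual_cl", "predict",
    "DEFAULT_V", "DEFAULT_KA",
]
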