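"""Independent numerical oracles used by the test suite.

Each oracle computes a quantity the package also computes, but by a route
the implementation does not share: repeated-dose ODE integration instead of
the closed-form superposition solution, adaptive Gauss-Hermite quadrature
instead of the Laplace/FOCE approximation, dense grid search instead of the
Newton inner solver, and a direct large-sample resimulation of the window
proportions.
"""
from __future__ import annotations

import math

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp
from scipy.stats import truncnorm


def ode_conc_ss(t: float, dose: float, tau: float, cl: float, v: float,
                ka: float) -> float:
    """Steady-state concentration by integrating the one-compartment ODE
    (gut + central) over enough repeated doses that the accumulation error
    is far below 1e-6 relative."""
    ke = cl / v
    n_doses = max(20, math.ceil(18.0 / (ke * tau)))

    def rhs(_t, y):
        a, c = y
        return [-ka * a, ka * a / v - ke * c]

    state = np.array([0.0, 0.0])
    for _ in range(n_doses - 1):
        sol = solve_ivp(rhs, (0.0, tau), state + [dose, 0.0],
                        rtol=1e-11, atol=1e-13, method="LSODA")
        state = sol.y[:, -1]
    sol = solve_ivp(rhs, (0.0, tau), state + [dose, 0.0],
                    rtol=1e-11, atol=1e-13, method="LSODA", dense_output=True)
    return float(sol.sol(t)[1])


def aghq_neg2ll(subjects, fe, re, v=150.0, ka=0.18, n_nodes=64) -> float:
    """-2 log marginal likelihood by adaptive Gauss-Hermite quadrature.

    ``subjects`` is an iterable of (Subject, [Observation, ...]) pairs. The
    quadrature is centred and scaled at the mode of each subject's joint
    log-density (found by bounded scalar minimisation, independent of the
    package's Newton solver). Includes all additive constants.
    """
    from efavpk.pk import conc_ss_arrays, individual_cl

    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    total = 0.0
    for subject, observations in subjects:
        cl = individual_cl(subject, fe)
        t = np.array([o.time_after_dose for o in observations])
        y = np.array([o.conc for o in observations])

        def log_joint(eta):
            f = conc_ss_arrays(t, subject.dose, subject.tau,
                               cl * np.exp(eta), v, ka)
            var = re.sigma2_prop * f * f
            ll = -0.5 * np.sum((y - f) ** 2 / var + np.log(2 * np.pi * var))
            ll += -0.5 * (eta * eta / re.omega2
                          + math.log(2 * np.pi * re.omega2))
            return ll

        res = minimize_scalar(lambda e: -log_joint(e), bounds=(-10, 10),
                              method="bounded", options={"xatol": 1e-10})
        mode = float(res.x)
        h = 1e-4
        curv = -(log_joint(mode + h) - 2 * log_joint(mode)
                 + log_joint(mode - h)) / (h * h)
        scale = 1.0 / math.sqrt(max(curv, 1e-12))
        etas = mode + math.sqrt(2.0) * scale * nodes
        logs = np.array([log_joint(e) for e in etas])
        log_integral = logsumexp(np.log(weights) + nodes ** 2 + logs) \
            + math.log(math.sqrt(2.0) * scale)
        total += -2.0 * log_integral
    return total


def foce_constants(subjects) -> float:
    """Additive constants the package's OFV drops, for comparison with the
    full -2 log likelihood: n_i*log(2*pi) - log(2) per subject."""
    return sum(len(obs) * math.log(2 * math.pi) - math.log(2.0)
               for _s, obs in subjects)


def grid_ebe(subject, observations, fe, re, v=150.0, ka=0.18,
             lo=-5.0, hi=5.0, step=1e-4) -> float:
    """Conditional mode of eta by dense grid search."""
    from efavpk.pk import conc_ss_arrays, individual_cl

    cl = individual_cl(subject, fe)
    etas = np.arange(lo, hi + step, step)
    t = np.array([o.time_after_dose for o in observations])
    y = np.array([o.conc for o in observations])
    g = np.zeros_like(etas)
    for j in range(len(t)):
        f = conc_ss_arrays(t[j], subject.dose, subject.tau,
                           cl * np.exp(etas), v, ka)
        var = re.sigma2_prop * f * f
        g += (y[j] - f) ** 2 / var + np.log(var)
    g += etas ** 2 / re.omega2
    return float(etas[np.argmin(g)])


def dlogc_deta(t, dose, tau, cl, v, ka) -> float:
    """Analytic sensitivity d log C / d eta at eta = 0 for the steady-state
    one-compartment model, via d ke/d eta = ke."""
    ke = cl / v
    E = math.exp(-ke * tau)
    u = math.exp(-ke * t) / (1 - E)
    w = math.exp(-ka * t) / (1 - math.exp(-ka * tau))
    du = math.exp(-ke * t) * (-t * (1 - E) - tau * E) / (1 - E) ** 2
    dlog_dke = 1.0 / (ka - ke) + du / (u - w)
    return ke * dlog_dke


def window_proportions_oracle(stratum, dose, fe, re, cfg, n=1_000_000,
                              seed=12345):
    """Straight-line reimplementation of the stratified window simulation:
    truncated-normal weight, log-normal eta, uniform sampling time,
    resampled proportional error, then binning against 1 and 4 ug/ml."""
    from efavpk.data import Subject
    from efavpk.pk import conc_ss_arrays, individual_cl

    rng = np.random.default_rng(seed)
    if stratum.sex == "female":
        mu, sd = cfg.weight_mean_female, cfg.weight_sd_female
    else:
        mu, sd = cfg.weight_mean_male, cfg.weight_sd_male
    lo, hi = cfg.weight_bounds
    if stratum.weight_class == "<58":
        hi = min(hi, 58.0)
    else:
        lo = max(lo, 58.0)
    a, b = (lo - mu) / sd, (hi - mu) / sd
    weight = truncnorm.rvs(a, b, loc=mu, scale=sd, size=n, random_state=rng)
    eta = rng.normal(0, math.sqrt(re.omega2), size=n)
    t = rng.uniform(*cfg.sampling_window, size=n)
    eps = rng.normal(0, math.sqrt(re.sigma2_prop), size=n)
    bad = 1 + eps <= 0
    while bad.any():
        eps[bad] = rng.normal(0, math.sqrt(re.sigma2_prop), size=int(bad.sum()))
        bad = 1 + eps <= 0
    cl = np.array([individual_cl(
        Subject(id=f"o{k}", sex=stratum.sex, weight=float(weight[k]),
                g_cyp2b6_6=stratum.g_cyp2b6_6,
                g_cyp2b6_18=stratum.g_cyp2b6_18), fe)
        for k in range(n)]) * np.exp(eta)
    c = conc_ss_arrays(t, dose, cfg.tau, cl) * (1 + eps)
    return (float(np.mean(c < 1.0)), float(np.mean((c >= 1.0) & (c <= 4.0))),
            float(np.mean(c > 4.0)))
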