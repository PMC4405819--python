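"""Synthetic cohort and observation generator.

Emulates the statistical structure the analysis assumes: an adult HIV/TB
cohort on 600 mg daily efavirenz, sampled once 12-15 h post dose at steady
state. Default demographics and genotype frequencies reproduce the
reference cohort (n=185; 60 males / 125 females; sex-specific weight
means/SDs; empirical genotype counts per locus). Genotypes are drawn
independently across loci (no haplotype structure), weights from
sex-specific truncated normals, and concentrations from the one-compartment
model with log-normal between-subject variability on CL and proportional
residual error; negative residual draws are resampled so concentrations
stay above the lower limit of quantitation.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import truncnorm

from .data import Dataset, Observation, Subject
from .pk import FixedEffects, RandomEffects, conc_ss_arrays, individual_cl

#: Empirical genotype proportions of the reference cohort, per locus.
DEFAULT_GENOTYPE_FREQS = {
    "g_cyp2b6_6": {"GG": 57 / 180, "GT": 84 / 180, "TT": 39 / 180},
    "g_cyp2b6_18": {"TT": 132 / 185, "TC": 47 / 185, "CC": 6 / 185},
    "g_cyp2a6_9": {"GG": 110 / 134, "GT": 0.0, "TT": 24 / 134},
    "g_cyp2a6_17": {"GG": 120 / 136, "GA": 15 / 136, "AA": 1 / 136},
    "g_abcb1_1236": {"CC": 115 / 137, "CT": 16 / 137, "TT": 6 / 137},
}


@dataclass
class CohortConfig:
    """Study-design and demographic configuration for the generator.

    Defaults are the reference cohort conditions: n=185 with 125/185
    female, male weight 61.52 (10.06) kg, female 57.92 (11.29) kg truncated
    to [35, 120] kg, 600 mg q24h, one sample per subject drawn uniformly
    12-15 h post dose. ``sample_times`` (hours) overrides the random window
    with fixed times, e.g. (2, 13.5, 24) for the replicate-recovery design.
    """

    n_subjects: int = 185
    sex_fraction_female: float = 125 / 185
    weight_mean_male: float = 61.517
    weight_sd_male: float = 10.058
    weight_mean_female: float = 57.92
    weight_sd_female: float = 11.291
    weight_bounds: tuple = (35.0, 120.0)
    age_mean_male: float = 40.167
    age_sd_male: float = 9.141
    age_mean_female: float = 38.336
    age_sd_female: float = 8.065
    age_bounds: tuple = (18.0, 75.0)
    genotype_freqs: dict = field(default_factory=lambda: {
        locus: dict(freqs) for locus, freqs in DEFAULT_GENOTYPE_FREQS.items()})
    regimen_fraction_tb: float = 90 / 185
    cns_fraction_yes: float = 79 / 185
    dose: float = 600.0
    tau: float = 24.0
    sampling_window: tuple = (12.0, 15.0)
    n_samples_per_subject: int = 1
    sample_times: tuple | None = None
    lloq: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.sex_fraction_female <= 1:
            raise ValueError("sex_fraction_female must lie in [0, 1]")
        t_lo, t_hi = self.sampling_window
        if not 0 < t_lo < t_hi <= self.tau:
            raise ValueError("sampling window must satisfy 0 < t_lo < t_hi <= tau")
        for locus, freqs in self.genotype_freqs.items():
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9 or min(freqs.values()) < 0:
                raise ValueError(
                    f"genotype frequencies for {locus} must be non-negative and sum to 1")


def hwe_genotype_freqs(allele_freq_minor: float) -> tuple[float, float, float]:
    """Hardy-Weinberg genotype frequencies ((1-p)^2, 2p(1-p), p^2) for a
    minor-allele frequency p."""
    p = allele_freq_minor
    if not 0 <= p <= 1:
        raise ValueError(f"allele frequency must lie in [0, 1], got {p}")
    return ((1 - p) ** 2, 2 * p * (1 - p), p * p)


def _trunc_ppf(u, mean, sd, lo, hi):
    if sd <= 0:
        return np.full_like(np.asarray(u, dtype=float), mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def generate_cohort(cfg: CohortConfig, seed: int | None = None) -> Dataset:
    """Draw a cohort of subjects (no observations); deterministic given seed."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    subjects: dict[str, Subject] = {}
    for i in range(cfg.n_subjects):
        female = rng.random() < cfg.sex_fraction_female
        if female:
            w_mu, w_sd = cfg.weight_mean_female, cfg.weight_sd_female
            a_mu, a_sd = cfg.age_mean_female, cfg.age_sd_female
        else:
            w_mu, w_sd = cfg.weight_mean_male, cfg.weight_sd_male
            a_mu, a_sd = cfg.age_mean_male, cfg.age_sd_male
        weight = float(_trunc_ppf(rng.random(), w_mu, w_sd, *cfg.weight_bounds))
        age = float(_trunc_ppf(rng.random(), a_mu, a_sd, *cfg.age_bounds))
        genos = {}
        for locus, freqs in cfg.genotype_freqs.items():
            levels = list(freqs)
            probs = np.array([freqs[l] for l in levels])
            genos[locus] = str(rng.choice(levels, p=probs / probs.sum()))
        subjects[f"S{i + 1:04d}"] = Subject(
            id=f"S{i + 1:04d}",
            sex="female" if female else "male",
            weight=weight, age=age,
            regimen_group="ART_plus_TB" if rng.random() < cfg.regimen_fraction_tb
            else "ART_only",
            cns_status="yes" if rng.random() < cfg.cns_fraction_yes else "no",
            dose=cfg.dose, tau=cfg.tau,
            **genos)
    return Dataset(subjects=subjects, observations=[])


def simulate_observations(cohort: Dataset, fe: FixedEffects, re: RandomEffects,
                          cfg: CohortConfig, seed: int | None = None) -> Dataset:
    """Simulate concentrations for every subject of ``cohort``.

    Per subject: eta ~ N(0, omega2); per sample: time from ``sample_times``
    or Uniform over the sampling window, y = f * (1 + eps) with
    eps ~ N(0, sigma2); draws with y <= lloq are resampled (not truncated),
    which leaves the mean unbiased at sigma2 = 0.12 for any practical lloq.
    Deterministic given seed.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    omega = float(np.sqrt(re.omega2))
    sigma = float(np.sqrt(re.sigma2_prop))
    observations = []
    for s in cohort.subjects.values():
        eta = rng.normal(0.0, omega) if omega > 0 else 0.0
        cl_i = individual_cl(s, fe) * float(np.exp(eta))
        if cfg.sample_times is not None:
            times = np.asarray(cfg.sample_times, dtype=float)
        else:
            t_lo, t_hi = cfg.sampling_window
            times = rng.uniform(t_lo, t_hi, size=cfg.n_samples_per_subject)
        f = conc_ss_arrays(times, s.dose, s.tau, cl_i)
        for t_j, f_j in zip(times, f):
            for _ in range(1000):
                eps = rng.normal(0.0, sigma) if sigma > 0 else 0.0
                y = f_j * (1.0 + eps)
                if y > cfg.lloq:
                    break
            else:
                raise RuntimeError("could not draw a concentration above the LLOQ")
            observations.append(Observation(
                subject_id=s.id, time_after_dose=float(t_j), conc=float(y)))
    return cohort.with_observations(observations)


def simulate_cohort(cfg: CohortConfig, fe: FixedEffects, re: RandomEffects,
                    seed: int | None = None) -> Dataset:
    """Cohort plus observations in one call, from a single seed."""
    if isinstance(seed, np.random.SeedSequence):
        root = seed
    else:
        root = np.random.SeedSequence(cfg.seed if seed is None else seed)
    s_cohort, s_obs = root.spawn(2)
    ds = generate_cohort(cfg, seed=s_cohort)
    return simulate_observations(ds, fe, re, cfg, seed=s_obs)


def recovery_config(n_subjects: int = 200) -> CohortConfig:
    """Replicate-recovery design: 3 fixed samples per subject at 2, 13.5 and
    24 h, which (unlike the single-sample study design) separately
    identifies omega2 and sigma2."""
    return CohortConfig(n_subjects=n_subjects, sample_times=(2.0, 13.5, 24.0),
                        n_samples_per_subject=3)


__all__ = [
    "CohortConfig", "DEFAULT_GENOTYPE_FREQS",
    "generate_cohort", "hwe_genotype_freqs", "simulate_observations",
    "simulate_cohort", "recovery_config",
]
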