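import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from efavpk.cohort import CohortConfig, recovery_config, simulate_cohort
from efavpk.data import Dataset, Observation, Subject
from efavpk.params import reference_fixed_effects, reference_random_effects
from efavpk.pk import RandomEffects


@pytest.fixture(scope="session")
def ref_fe():
    return reference_fixed_effects()


@pytest.fixture(scope="session")
def ref_re():
    return reference_random_effects()


@pytest.fixture
def make_subject():
    """Subject factory with reference-covariate defaults (CYP2B6*18 TT,
    *6 GT, male, 58 kg, 600 mg q24h)."""

    def _make(**kwargs):
        defaults = dict(id="S1", sex="male", weight=58.0, g_cyp2b6_18="TT",
                        g_cyp2b6_6="GT", dose=600.0, tau=24.0)
        defaults.update(kwargs)
        return Subject(**defaults)

    return _make


@pytest.fixture
def toy_dataset(make_subject):
    """Two subjects, one observation each."""
    s1 = make_subject(id="A")
    s2 = make_subject(id="B", sex="female", weight=52.0, g_cyp2b6_6="TT")
    obs = [Observation(subject_id="A", time_after_dose=13.5, conc=2.0),
           Observation(subject_id="B", time_after_dose=12.5, conc=6.5)]
    return Dataset(subjects={"A": s1, "B": s2}, observations=obs)


@pytest.fixture(scope="session")
def recovery_cohort(ref_fe, ref_re):
    """One simulated recovery-design cohort (n=120, 3 samples/subject),
    shared across estimation tests."""
    cfg = recovery_config(n_subjects=120)
    return simulate_cohort(cfg, ref_fe, ref_re, seed=2024)


@pytest.fixture(scope="session")
def study_cohort(ref_fe, ref_re):
    """One simulated study-design cohort (n=185, single 12-15 h sample)."""
    cfg = CohortConfig(n_subjects=185)
    return simulate_cohort(cfg, ref_fe, ref_re, seed=77)


@pytest.fixture
def tight_re():
    """Small variance components for near-deterministic toy fits."""
    return RandomEffects(omega2=0.04, sigma2_prop=0.01)
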