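"""Reference parameter set and flat key-value (de)serialisation.

The reference estimates are the final population model for 600 mg daily
efavirenz in an adult African HIV/TB cohort (n=185): base CL/F stratified on
CYP2B6*18 (7.01 / 2.26 / 0.539 L/h for TT / TC / CC), CYP2B6*6 effects
(+93.1% for GG, -63.4% for TT, GT reference), +22.2% for female sex,
+2.11%/kg body weight centred at 58 kg, V/F 150 L and ka 0.18 1/h fixed,
log-normal IIV on CL with omega^2 = 0.494 (70.3 %CV) and proportional
residual variance sigma^2 = 0.12. They are the package default for
simulation and the generating truth for the recovery experiments.
"""
from __future__ import annotations

from .pk import DEFAULT_KA, DEFAULT_V, FixedEffects, RandomEffects

_KEYS = ("CL18_TT", "CL18_TC", "CL18_CC", "FRAC6_GG", "FRAC6_TT",
         "FRAC_FEMALE", "FRAC_WT_PER_KG", "WT_CENTER", "V", "KA",
         "OMEGA2", "SIGMA2")


def reference_fixed_effects() -> FixedEffects:
    """Final-model fixed effects (see module docstring)."""
    return FixedEffects(
        cl_18={"TT": 7.01, "TC": 2.26, "CC": 0.539},
        frac_6={"GG": 0.931, "GT": 0.0, "TT": -0.634},
        frac_female=0.222,
        frac_wt=0.0211,
        wt_center=58.0,
    )


def reference_random_effects() -> RandomEffects:
    """Final-model variance components (see module docstring)."""
    return RandomEffects(omega2=0.494, sigma2_prop=0.12)


def save_params(fe: FixedEffects, re: RandomEffects, path,
                v: float = DEFAULT_V, ka: float = DEFAULT_KA) -> None:
    """Write a parameter set as a flat ``KEY = value`` file."""
    values = {
        "CL18_TT": fe.cl_18["TT"], "CL18_TC": fe.cl_18["TC"],
        "CL18_CC": fe.cl_18["CC"],
        "FRAC6_GG": fe.frac_6.get("GG", 0.0), "FRAC6_TT": fe.frac_6.get("TT", 0.0),
        "FRAC_FEMALE": fe.frac_female, "FRAC_WT_PER_KG": fe.frac_wt,
        "WT_CENTER": fe.wt_center, "V": v, "KA": ka,
        "OMEGA2": re.omega2, "SIGMA2": re.sigma2_prop,
    }
    with open(path, "w") as fh:
        for key in _KEYS:
            fh.write(f"{key} = {values[key]!r}\n")


def load_params(path) -> tuple[FixedEffects, RandomEffects, float, float]:
    """Read a flat parameter file; returns (fixed, random, v, ka)."""
    values = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            values[key.strip()] = float(val)
    missing = [k for k in _KEYS if k not in values]
    if missing:
        raise ValueError(f"parameter file {path}: missing keys {missing}")
    fe = FixedEffects(
        cl_18={"TT": values["CL18_TT"], "TC": values["CL18_TC"],
               "CC": values["CL18_CC"]},
        frac_6={"GG": values["FRAC6_GG"], "GT": 0.0, "TT": values["FRAC6_TT"]},
        frac_female=values["FRAC_FEMALE"],
        frac_wt=values["FRAC_WT_PER_KG"],
        wt_center=values["WT_CENTER"],
    )
    re = RandomEffects(omega2=values["OMEGA2"], sigma2_prop=values["SIGMA2"])
    return fe, re, values["V"], values["KA"]


__all__ = ["reference_fixed_effects", "reference_random_effects",
           "save_params", "load_params"]
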