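"""Dataset model and NONMEM-style rectangular CSV I/O.

One row per observation; subject-level covariates are repeated on every row
of that subject. Concentrations are stored and modelled in ug/ml throughout;
no unit conversion is performed by the reader. TIME is time after the most
recent dose at steady state, not time since first dose.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import pandas as pd

log = logging.getLogger(__name__)

SEX_LEVELS = ("male", "female")
REGIMEN_LEVELS = ("ART_only", "ART_plus_TB")
CNS_LEVELS = ("yes", "no")

#: Allowed genotype strings per locus (field name -> levels, reference first
#: where the covariate model uses one).
GENOTYPE_LEVELS = {
    "g_cyp2b6_6": ("GG", "GT", "TT"),
    "g_cyp2b6_18": ("TT", "TC", "CC"),
    "g_cyp2a6_9": ("GG", "GT", "TT"),
    "g_cyp2a6_17": ("GG", "GA", "AA"),
    "g_abcb1_1236": ("CC", "CT", "TT"),
}

#: Default NONMEM-like column dialect (internal field -> CSV column).
DEFAULT_DIALECT = {
    "id": "ID",
    "occasion": "OCC",
    "time": "TIME",
    "dv": "DV",
    "dose": "DOSE",
    "tau": "TAU",
    "weight": "WT",
    "sex": "SEX",
    "age": "AGE",
    "g_cyp2b6_6": "CYP2B6_6",
    "g_cyp2b6_18": "CYP2B6_18",
    "g_cyp2a6_9": "CYP2A6_9",
    "g_cyp2a6_17": "CYP2A6_17",
    "g_abcb1_1236": "ABCB1",
    "regimen_group": "GRP",
    "cns_status": "CNS",
}

# Columns that must be present in any input file (mapped through the dialect).
REQUIRED_FIELDS = (
    "id", "time", "dv", "dose", "weight", "sex",
    "g_cyp2b6_6", "g_cyp2b6_18",
)

# Sex is encoded 0=male, 1=female on disk; kept as strings in memory.
_SEX_CODE = {"male": 0, "female": 1}
_SEX_DECODE = {0: "male", 1: "female", "0": "male", "1": "female",
               "male": "male", "female": "female"}


class DatasetFormatError(ValueError):
    """Input file does not conform to the expected rectangular dialect."""


class ValidationError(ValueError):
    """A record violates a domain invariant (range or enumeration)."""


@dataclass
class Subject:
    """A study participant: covariates plus regimen.

    Weight in kg, age in years, dose in mg/day, tau (dosing interval) in
    hours. Genotypes are kept as strings to avoid silent coding errors.
    """

    id: str
    sex: str
    weight: float
    age: float = 38.0
    g_cyp2b6_6: str = "GT"
    g_cyp2b6_18: str = "TT"
    g_cyp2a6_9: str = "GG"
    g_cyp2a6_17: str = "GG"
    g_abcb1_1236: str = "CC"
    regimen_group: str = "ART_only"
    cns_status: str = "no"
    dose: float = 600.0
    tau: float = 24.0

    def __post_init__(self):
        if self.sex not in SEX_LEVELS:
            raise ValidationError(f"subject {self.id}: sex {self.sex!r} not in {SEX_LEVELS}")
        if not (math.isfinite(self.weight) and self.weight > 0):
            raise ValidationError(f"subject {self.id}: weight must be finite and positive")
        if not self.dose > 0:
            raise ValidationError(f"subject {self.id}: dose must be positive")
        if not self.tau > 0:
            raise ValidationError(f"subject {self.id}: tau must be positive")
        for fname, levels in GENOTYPE_LEVELS.items():
            val = getattr(self, fname)
            if val not in levels:
                raise ValidationError(
                    f"subject {self.id}: {fname} value {val!r} not in {levels}")
        if self.regimen_group not in REGIMEN_LEVELS:
            raise ValidationError(
                f"subject {self.id}: regimen_group {self.regimen_group!r} not in {REGIMEN_LEVELS}")
        if self.cns_status not in CNS_LEVELS:
            raise ValidationError(
                f"subject {self.id}: cns_status {self.cns_status!r} not in {CNS_LEVELS}")


@dataclass
class Observation:
    """A single plasma concentration sample.

    time_after_dose in hours within (0, tau]; conc in ug/ml, non-negative.
    """

    subject_id: str
    time_after_dose: float
    conc: float
    occasion: int = 1

    def __post_init__(self):
        if not self.time_after_dose > 0:
            raise ValidationError(
                f"observation for {self.subject_id}: time_after_dose must be > 0")
        if self.conc < 0:
            raise ValidationError(
                f"observation for {self.subject_id}: conc must be non-negative")
        if self.occasion < 1:
            raise ValidationError(
                f"observation for {self.subject_id}: occasion must be >= 1")


@dataclass
class Dataset:
    """Subjects plus their observations.

    ``subjects`` preserves insertion order; every observation must reference
    an existing subject. A dataset with no observations (a bare cohort) is
    permitted in memory, but cannot be written or fitted.
    """

    subjects: dict[str, Subject] = field(default_factory=dict)
    observations: list[Observation] = field(default_factory=list)

    def __post_init__(self):
        for obs in self.observations:
            if obs.subject_id not in self.subjects:
                raise ValidationError(
                    f"observation references unknown subject {obs.subject_id!r}")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_observations(self) -> int:
        return len(self.observations)

    def require_observations(self):
        """Raise unless every subject has at least one observation."""
        if not self.observations:
            raise ValidationError("dataset has no observations")
        with_obs = {o.subject_id for o in self.observations}
        missing = [s for s in self.subjects if s not in with_obs]
        if missing:
            raise ValidationError(
                f"{len(missing)} subject(s) without observations, e.g. {missing[0]!r}")

    def with_observations(self, observations: list[Observation]) -> "Dataset":
        return Dataset(subjects=dict(self.subjects), observations=list(observations))

    def to_frame(self, dialect: dict | None = None) -> pd.DataFrame:
        """Flatten to one row per observation using the column dialect."""
        d = dict(DEFAULT_DIALECT)
        if dialect:
            d.update(dialect)
        rows = []
        for obs in self.observations:
            s = self.subjects[obs.subject_id]
            rows.append({
                d["id"]: s.id,
                d["occasion"]: obs.occasion,
                d["time"]: obs.time_after_dose,
                d["dv"]: obs.conc,
                d["dose"]: s.dose,
                d["tau"]: s.tau,
                d["weight"]: s.weight,
                d["sex"]: _SEX_CODE[s.sex],
                d["age"]: s.age,
                d["g_cyp2b6_6"]: s.g_cyp2b6_6,
                d["g_cyp2b6_18"]: s.g_cyp2b6_18,
                d["g_cyp2a6_9"]: s.g_cyp2a6_9,
                d["g_cyp2a6_17"]: s.g_cyp2a6_17,
                d["g_abcb1_1236"]: s.g_abcb1_1236,
                d["regimen_group"]: s.regimen_group,
                d["cns_status"]: s.cns_status,
            })
        return pd.DataFrame(rows)

    def __eq__(self, other):
        if not isinstance(other, Dataset):
            return NotImplemented
        if list(self.subjects) != list(other.subjects):
            return False
        for sid in self.subjects:
            a, b = self.subjects[sid], other.subjects[sid]
            if a != b:
                return False
        if len(self.observations) != len(other.observations):
            return False
        for oa, ob in zip(self.observations, other.observations):
            if oa != ob:
                return False
        return True


def dataset_from_frame(df: pd.DataFrame, dialect: dict | None = None,
                       source: str = "<frame>") -> Dataset:
    """Build a validated Dataset from a rectangular one-row-per-observation frame."""
    d = dict(DEFAULT_DIALECT)
    if dialect:
        d.update(dialect)
    for fname in REQUIRED_FIELDS:
        if d[fname] not in df.columns:
            raise DatasetFormatError(
                f"{source}: required column {d[fname]!r} (field {fname!r}) missing")
    genotype_fields = [f for f in GENOTYPE_LEVELS if d[f] in df.columns]
    subjects: dict[str, Subject] = {}
    observations: list[Observation] = []
    n_dropped = 0
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        rec = dict(zip(df.columns, row))
        dv = rec.get(d["dv"])
        if dv is None or (isinstance(dv, float) and math.isnan(dv)) or dv == ".":
            n_dropped += 1
            log.warning("%s row %d: missing DV, row dropped", source, row_no)
            continue
        sid = str(rec[d["id"]])
        try:
            sex_raw = rec[d["sex"]]
            sex = _SEX_DECODE.get(sex_raw, _SEX_DECODE.get(str(int(sex_raw))
                                  if isinstance(sex_raw, float) else str(sex_raw)))
            if sex is None:
                raise ValidationError(f"unrecognised sex code {sex_raw!r}")
            kwargs = dict(
                id=sid,
                sex=sex,
                weight=float(rec[d["weight"]]),
                dose=float(rec[d["dose"]]),
            )
            if d["age"] in df.columns:
                kwargs["age"] = float(rec[d["age"]])
            if d["tau"] in df.columns:
                kwargs["tau"] = float(rec[d["tau"]])
            for f in genotype_fields:
                kwargs[f] = str(rec[d[f]])
            if d["regimen_group"] in df.columns:
                kwargs["regimen_group"] = str(rec[d["regimen_group"]])
            if d["cns_status"] in df.columns:
                kwargs["cns_status"] = str(rec[d["cns_status"]])
            subj = Subject(**kwargs)
        except ValidationError as exc:
            raise ValidationError(f"{source} row {row_no}: {exc}") from None
        if sid in subjects:
            if subjects[sid] != subj:
                raise ValidationError(
                    f"{source} row {row_no}: subject {sid!r} has inconsistent covariates")
        else:
            subjects[sid] = subj
        occ = int(rec[d["occasion"]]) if d["occasion"] in df.columns else 1
        try:
            observations.append(Observation(
                subject_id=sid,
                time_after_dose=float(rec[d["time"]]),
                conc=float(dv),
                occasion=occ,
            ))
        except ValidationError as exc:
            raise ValidationError(f"{source} row {row_no}: {exc}") from None
    if n_dropped:
        log.info("%s: dropped %d row(s) with missing DV", source, n_dropped)
    return Dataset(subjects=subjects, observations=observations)


def read_dataset(path, dialect=None) -> Dataset:
    """Read a NONMEM-style CSV into a validated :class:`Dataset`.

    ``dialect`` overrides entries of :data:`DEFAULT_DIALECT` (internal field
    name -> column name); it may be a mapping or the path of a YAML file
    holding one. Rows with missing DV are dropped with a logged reason.
    Raises :class:`DatasetFormatError` for missing required columns and
    :class:`ValidationError` (with the row number) for enum or range
    violations.
    """
    if dialect is not None and not isinstance(dialect, dict):
        import yaml
        with open(dialect) as fh:
            dialect = yaml.safe_load(fh) or {}
    df = pd.read_csv(path, float_precision="round_trip")
    return dataset_from_frame(df, dialect=dialect, source=str(path))


def write_dataset(ds: Dataset, path, dialect: dict | None = None) -> None:
    """Write a Dataset as CSV, re-readable by :func:`read_dataset`.

    The written file has one header row plus one row per observation.
    Raises :class:`ValidationError` if the dataset has no observations.
    """
    ds.require_observations()
    df = ds.to_frame(dialect=dialect)
    # shortest round-trip repr keeps the write/read cycle exact
    for col in df.columns:
        if df[col].dtype.kind == "f":
            df[col] = df[col].map(lambda v: repr(float(v)))
    df.to_csv(path, index=False)


__all__ = [
    "Subject", "Observation", "Dataset",
    "read_dataset", "write_dataset", "dataset_from_frame",
    "DatasetFormatError", "ValidationError",
    "DEFAULT_DIALECT", "GENOTYPE_LEVELS", "SEX_LEVELS",
    "REGIMEN_LEVELS", "CNS_LEVELS",
]
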