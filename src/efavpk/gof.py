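"""Goodness-of-fit data products for a converged mixed-effects fit.

One record per observation: population prediction PRED (eta = 0),
individual prediction IPRED (at the subject's empirical-Bayes eta) and the
individually weighted residual IWRES = (y - IPRED) / (sigma * IPRED),
which under the proportional error model with interaction should have mean
about 0 and SD about 1 when the model is well specified.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import Dataset
from .estimation import EstimationError, FitResult
from .pk import predict


@dataclass
class GofRecord:
    subject_id: str
    time_after_dose: float
    observed: float
    pred: float
    ipred: float
    iwres: float


def gof_table(ds: Dataset, fit_result: FitResult) -> list[GofRecord]:
    """Per-observation goodness-of-fit records; requires EBEs for every
    subject with observations."""
    sigma = float(np.sqrt(fit_result.re.sigma2_prop))
    records = []
    for obs in ds.observations:
        if obs.subject_id not in fit_result.ebes:
            raise EstimationError(f"no EBE for subject {obs.subject_id!r}")
        s = ds.subjects[obs.subject_id]
        eta = fit_result.ebes[obs.subject_id]
        pred = predict(s, obs.time_after_dose, fit_result.fe, 0.0,
                       v=fit_result.spec.v, ka=fit_result.spec.ka)
        ipred = predict(s, obs.time_after_dose, fit_result.fe, eta,
                        v=fit_result.spec.v, ka=fit_result.spec.ka)
        iwres = (obs.conc - ipred) / (sigma * ipred) if sigma > 0 else float("nan")
        records.append(GofRecord(
            subject_id=obs.subject_id, time_after_dose=obs.time_after_dose,
            observed=obs.conc, pred=pred, ipred=ipred, iwres=iwres))
    return records


def gof_frame(ds: Dataset, fit_result: FitResult) -> pd.DataFrame:
    recs = gof_table(ds, fit_result)
    return pd.DataFrame([
        {"ID": r.subject_id, "TIME": r.time_after_dose, "DV": r.observed,
         "PRED": r.pred, "IPRED": r.ipred, "IWRES": r.iwres}
        for r in recs])


def ebe_frame(ds: Dataset, fit_result: FitResult) -> pd.DataFrame:
    """Per-observation EBE export (ID, ETA, IPRED)."""
    recs = gof_table(ds, fit_result)
    return pd.DataFrame([
        {"ID": r.subject_id, "ETA": fit_result.ebes[r.subject_id],
         "IPRED": r.ipred}
        for r in recs])


__all__ = ["GofRecord", "gof_table", "gof_frame", "ebe_frame"]
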