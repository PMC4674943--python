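"""Deregression of EBVs into GWAS-ready pseudo-phenotypes.

EBVs are shrunken, family-contaminated predictors: using them directly as
GWAS responses double-counts parent information and under-represents
high-information animals.  Deregression removes the parent average (PA) and
the shrinkage, leaving a pseudo-record that reflects the animal's own and
progeny information only, plus a reliability and a heterogeneous-variance
weight for the association model.

The information partition works on a two-effect system (PA, individual)
with relationship matrix [[1/2, 1/2], [1/2, 1]] sigma_a2 and unknown
per-effect information contents z_PA, z_i (in lambda = (1-h2)/h2 units).
Writing alpha = 1/(0.5 - r2_PA), the prediction-error equations invert in
closed form:

    v   = lambda * (alpha + sqrt(alpha * (alpha + 16 (1 - r2_i)))) /
          (2 alpha (1 - r2_i))
    z_i  = v - 2 lambda,      z_PA = alpha v (1 - r2_i) - 4 lambda

The right-hand side of the individual's equation is recovered from the
solved system, y*_i = -2 lambda PA + (z_i + 2 lambda) EBV_i, and the
deregressed proof is dEBV_i = y*_i / z_i with reliability
r2_d = z_i / (z_i + lambda).  Animals whose own+progeny information content
z_i is non-positive carry no information beyond their parents and are
dropped.  Weights follow w = (1 - h2) / ((c + (1 - r2_d)/r2_d) h2), where c
is the fraction of genetic variance not captured by the markers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from vargwas.errors import ConfigurationError, DomainError, ValidationError

log = logging.getLogger(__name__)


def reliability(s, f, sigma_a2):
    """Reliability of an EBV from its standard error,

        r2 = 1 - s^2 / ((1 + f) sigma_a2),

    clamped to [0, 1].  ``s`` is the prediction-error SE, ``f`` the
    inbreeding coefficient and ``sigma_a2`` the additive genetic variance.
    """
    if sigma_a2 <= 0:
        raise DomainError("sigma_a2 must be positive")
    s = np.asarray(s, float)
    f = np.asarray(f, float)
    r2 = 1.0 - s**2 / ((1.0 + f) * sigma_a2)
    return np.clip(r2, 0.0, 1.0)


@dataclass
class DeregressionReport:
    n_input: int
    n_dropped_no_information: int
    n_output: int
    c: float
    h2: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rule": ["input animals", "dropped: no own/progeny information", "output animals"],
                "count": [self.n_input, self.n_dropped_no_information, self.n_output],
            }
        )


def _solve_information(r2_pa, r2_i, lam):
    """Closed-form information contents (z_pa, z_i) from the two
    prediction-error-variance equations of the (PA, individual) system."""
    r2_pa = np.minimum(r2_pa, 0.4999)
    r2_i = np.minimum(r2_i, 0.9999)
    alpha = 1.0 / (0.5 - r2_pa)
    one_m = 1.0 - r2_i
    v = lam * (alpha + np.sqrt(alpha * (alpha + 16.0 * one_m))) / (2.0 * alpha * one_m)
    z_i = v - 2.0 * lam
    z_pa = alpha * v * one_m - 4.0 * lam
    return z_pa, z_i


def deregress(
    records: pd.DataFrame,
    sigma_a2: float,
    h2: float,
    c: float = 0.5,
) -> tuple[pd.DataFrame, DeregressionReport]:
    """Deregress EBVs, removing parent-average information.

    Parameters
    ----------
    records : DataFrame with columns ``animal, ebv, r2, sire, dam`` (``sire``
        / ``dam`` as ids or ``0``/NaN for unknown; unknown parents contribute
        the base-population mean 0 with reliability 0).  ``r2`` is the EBV
        reliability, e.g. from :func:`reliability`.
    sigma_a2 : additive genetic variance of the trait (used for reporting).
    h2 : heritability of the trait the EBVs refer to (sets lambda).
    c : fraction of genetic variance not explained by markers, in [0, 1).

    Returns a DataFrame ``animal, debv, reliability, weight`` (animals with
    no own/progeny information removed) and a :class:`DeregressionReport`.
    """
    if sigma_a2 is None or sigma_a2 <= 0:
        raise ConfigurationError("sigma_a2 must be supplied and positive")
    if not 0 < h2 < 1:
        raise ConfigurationError("h2 must lie in (0, 1)")
    if not 0 <= c < 1:
        raise ConfigurationError("c must lie in [0, 1)")
    for col in ("animal", "ebv", "r2"):
        if col not in records.columns:
            raise ValidationError(f"deregression input missing column {col!r}")
    rec = records.copy()
    rec["animal"] = rec["animal"].astype(str)
    if rec["animal"].duplicated().any():
        raise ValidationError("duplicate animals in deregression input")
    if not np.all(np.isfinite(rec["ebv"].to_numpy(float))):
        raise ValidationError("non-finite EBVs in deregression input")
    lam = (1.0 - h2) / h2

    by_animal = rec.set_index("animal")
    ebv_map = by_animal["ebv"].to_dict()
    r2_map = by_animal["r2"].to_dict()

    def parent(pid):
        if pid is None or (isinstance(pid, float) and np.isnan(pid)) or str(pid) in ("0", "", "nan"):
            return 0.0, 0.0
        pid = str(pid)
        return ebv_map.get(pid, 0.0), r2_map.get(pid, 0.0)

    sires = rec["sire"] if "sire" in rec else pd.Series([None] * len(rec))
    dams = rec["dam"] if "dam" in rec else pd.Series([None] * len(rec))
    pa = np.empty(len(rec))
    r2_pa = np.empty(len(rec))
    for k, (s, d) in enumerate(zip(sires, dams)):
        es, rs = parent(s)
        ed, rd = parent(d)
        pa[k] = 0.5 * (es + ed)
        r2_pa[k] = 0.25 * (rs + rd)

    ebv = rec["ebv"].to_numpy(float)
    r2_i = rec["r2"].to_numpy(float)
    z_pa, z_i = _solve_information(r2_pa, r2_i, lam)

    keep = z_i > 1e-9
    dropped = int((~keep).sum())
    if dropped:
        log.info("deregression dropped %d animal(s) without own/progeny information", dropped)

    ystar = -2.0 * lam * pa + (z_i + 2.0 * lam) * ebv
    with np.errstate(divide="ignore", invalid="ignore"):
        debv = ystar / z_i
        r2_d = z_i / (z_i + lam)
        weight = (1.0 - h2) / ((c + (1.0 - r2_d) / r2_d) * h2)

    out = pd.DataFrame(
        {
            "animal": rec["animal"].to_numpy(),
            "debv": debv,
            "reliability": r2_d,
            "weight": weight,
        }
    ).loc[keep].reset_index(drop=True)
    report = DeregressionReport(
        n_input=len(rec), n_dropped_no_information=dropped, n_output=len(out), c=c, h2=h2
    )
    return out, report


def filter_reliability(records: pd.DataFrame, threshold: float = 0.05) -> pd.DataFrame:
    """Keep deregressed records with reliability >= threshold (inclusive)."""
    if "reliability" not in records.columns:
        raise ValidationError("records lack a 'reliability' column")
    return records.loc[records["reliability"] >= threshold].reset_index(drop=True)


def own_information_component(debv: np.ndarray, r2_d: np.ndarray, h2: float) -> np.ndarray:
    """Re-regress deregressed proofs: shrink dEBV by its reliability to get
    back the parent-average-free EBV component, y*_i / (z_i + lambda)."""
    return np.asarray(debv) * np.asarray(r2_d)
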