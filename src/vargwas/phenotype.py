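"""Editing rules for repeated litter records and per-sow summaries.

Litter-size counts (TNB, total number born) are edited before any analysis:
records with fewer than 4 piglets are dropped, counts of 27 or more are
capped at 27, and parities of 10 or higher are pooled into a single class.
For the conventional sow-level bivariate analysis each sow with at least
three (edited) litters is summarized by her mean TNB and the natural log of
the unbiased sample variance of her TNB.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from vargwas.errors import ValidationError

log = logging.getLogger(__name__)

MIN_TNB = 4
MAX_TNB = 27
MAX_PARITY_CLASS = 10

REQUIRED_COLUMNS = ("sow", "parity", "fys", "tnb")


@dataclass
class EditReport:
    """Counts of records hit by each editing rule."""

    n_input: int
    dropped_small: int
    capped_large: int
    parity_pooled: int
    n_output: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rule": [
                    "input records",
                    f"dropped: TNB < {MIN_TNB}",
                    f"capped at {MAX_TNB}",
                    f"parity pooled into class {MAX_PARITY_CLASS}",
                    "output records",
                ],
                "count": [self.n_input, self.dropped_small, self.capped_large, self.parity_pooled, self.n_output],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _check_columns(records: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValidationError(f"litter records missing columns {missing}")


def edit_records(records: pd.DataFrame) -> tuple[pd.DataFrame, EditReport]:
    """Apply the editing rules to a table of litter records.

    Parameters
    ----------
    records : DataFrame with columns ``sow, parity, fys, tnb``.

    Returns the edited table (copy) and an :class:`EditReport`. Negative TNB
    or parity < 1 raise :class:`ValidationError`.
    """
    _check_columns(records)
    rec = records.copy()
    rec["tnb"] = pd.to_numeric(rec["tnb"])
    rec["parity"] = pd.to_numeric(rec["parity"])
    if (rec["tnb"] < 0).any():
        raise ValidationError("negative TNB encountered")
    if (rec["parity"] < 1).any():
        raise ValidationError("parity below 1 encountered")

    small = rec["tnb"] < MIN_TNB
    rec = rec.loc[~small].copy()
    large = rec["tnb"] > MAX_TNB
    rec.loc[large, "tnb"] = MAX_TNB
    pooled = rec["parity"] > MAX_PARITY_CLASS
    rec.loc[pooled, "parity"] = MAX_PARITY_CLASS
    rec["parity"] = rec["parity"].astype(int)

    report = EditReport(
        n_input=len(records),
        dropped_small=int(small.sum()),
        capped_large=int(large.sum()),
        parity_pooled=int(pooled.sum()),
        n_output=len(rec),
    )
    return rec.reset_index(drop=True), report


def summarize_sows(records: pd.DataFrame, min_parities: int = 3) -> pd.DataFrame:
    """Per-sow mean TNB and log sample variance for the bivariate analysis.

    Only sows with ``min_parities`` or more litters are summarized; sows whose
    litters are all identical (sample variance exactly zero, log undefined)
    are excluded with a warning.  The farm-year-season class carried along is
    the sow's most frequent one.

    Returns a DataFrame ``sow, n_litters, mean_tnb, log_var_tnb, fys``.
    """
    _check_columns(records)
    g = records.groupby("sow", sort=True)
    out = g.agg(
        n_litters=("tnb", "size"),
        mean_tnb=("tnb", "mean"),
        var_tnb=("tnb", lambda x: x.var(ddof=1)),
        fys=("fys", lambda x: x.mode().iloc[0]),
    ).reset_index()
    out = out.loc[out["n_litters"] >= min_parities].copy()
    zero = out["var_tnb"] <= 0
    if zero.any():
        log.warning("excluding %d sow(s) with zero TNB variance (log undefined)", int(zero.sum()))
        out = out.loc[~zero].copy()
    out["log_var_tnb"] = np.log(out["var_tnb"])
    return out[["sow", "n_litters", "mean_tnb", "log_var_tnb", "fys"]].reset_index(drop=True)
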