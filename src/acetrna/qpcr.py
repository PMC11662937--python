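"""Relative transcript quantification by the comparative Ct method.

Steady-state suppressor-tRNA expression is proxied by a co-transcribed
self-cleaving ribozyme tag (the tRNA transcript tabulator) quantified by
RT-qPCR against a reference gene (TBP).  Quantities are relative:

    dCt  = mean(target Ct) - mean(reference Ct)           per sample
    ddCt = dCt_sample - dCt_calibrator
    RQ   = 2 ** -ddCt                (calibrator RQ = 1 by construction)

Amplification efficiency is fixed at 2 per cycle; triplicate Ct values are
averaged, with an optional maximum-spread filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

CT_RANGE = (0.0, 45.0)


@dataclass
class QPCRRecord:
    """Triplicate target and reference Ct values for one sample."""

    sample_id: str
    target_ct: list[float]
    reference_ct: list[float]
    is_calibrator: bool = False

    def __post_init__(self) -> None:
        for name, values in (("target", self.target_ct),
                             ("reference", self.reference_ct)):
            arr = np.asarray(values, dtype=float)
            if arr.size < 2:
                raise InputError(
                    f"{self.sample_id}: need >= 2 {name} Ct replicates")
            if np.any((arr <= CT_RANGE[0]) | (arr >= CT_RANGE[1])):
                raise InputError(
                    f"{self.sample_id}: {name} Ct outside {CT_RANGE}")


def filter_ct_spread(values: list[float], max_spread: float) -> list[float]:
    """Drop the farthest-from-median Ct values until the spread fits.

    Keeps at least two values; an optional QC step, off by default.
    """
    vals = sorted(float(v) for v in values)
    while len(vals) > 2 and (vals[-1] - vals[0]) > max_spread:
        med = np.median(vals)
        drop = max(vals, key=lambda v: abs(v - med))
        vals.remove(drop)
    return vals


def relative_quantity(records: list[QPCRRecord],
                      max_spread: float | None = None) -> pd.DataFrame:
    """Per-sample RQ = 2^-ddCt relative to the single calibrator sample."""
    calibrators = [r for r in records if r.is_calibrator]
    if len(calibrators) != 1:
        raise InputError(
            f"exactly one calibrator required, found {len(calibrators)}")

    def delta_ct(rec: QPCRRecord) -> float:
        target = rec.target_ct
        ref = rec.reference_ct
        if max_spread is not None:
            target = filter_ct_spread(target, max_spread)
            ref = filter_ct_spread(ref, max_spread)
        return float(np.mean(target)) - float(np.mean(ref))

    base = delta_ct(calibrators[0])
    rows = []
    for rec in records:
        dct = delta_ct(rec)
        ddct = dct - base
        rows.append({"sample_id": rec.sample_id, "delta_ct": dct,
                     "delta_delta_ct": ddct, "rq": 2.0 ** -ddct,
                     "is_calibrator": rec.is_calibrator})
    return pd.DataFrame(rows)


def records_from_frame(df: pd.DataFrame, calibrator: str,
                       target_name: str = "TTT",
                       reference_name: str = "TBP") -> list[QPCRRecord]:
    """Build records from a long-format Ct table.

    Expected columns: ``sample_id``, ``target`` (assay name), ``ct``.  The
    ``target`` column distinguishes the tabulator assay from the reference
    assay; ``calibrator`` names the calibrator sample.
    """
    needed = {"sample_id", "target", "ct"}
    if not needed <= set(df.columns):
        raise InputError(f"Ct table needs columns {sorted(needed)}")
    records = []
    for sample_id, grp in df.groupby("sample_id", sort=False):
        records.append(QPCRRecord(
            sample_id=str(sample_id),
            target_ct=grp.loc[grp["target"] == target_name, "ct"].tolist(),
            reference_ct=grp.loc[grp["target"] == reference_name, "ct"].tolist(),
            is_calibrator=(str(sample_id) == calibrator)))
    return records
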