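"""Scoring of dual-luciferase suppression screens.

The screen couples a PTC-interrupted NanoLuc reporter (signal restored only
when the suppressor tRNA reads through the stop codon) with a constitutive
firefly luciferase for transfection normalization.  The activity statistic
is the normalized suppression ratio

    ratio = (Nluc/Fluc | +tRNA) / (Nluc/Fluc | no tRNA),

so a well without suppression scores 1 regardless of transfection
efficiency: any per-well multiplicative factor hits both channels and
cancels.  The no-tRNA denominator is aggregated per plate as the geometric
mean of the control wells' Nluc/Fluc (ratios are multiplicative), and
member-level summaries (mean, SEM, n) are taken over replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import gmean

from .errors import InputError

logger = logging.getLogger(__name__)

#: member_id value marking a no-tRNA control well.
NO_TRNA = "no_tRNA"

PLATE_COLUMNS = ["plate_id", "well", "member_id", "nluc", "fluc",
                 "cell_line", "replicate"]


@dataclass
class PlateMeasurement:
    """One well of a dual-luciferase plate read."""

    plate_id: str
    well: str
    member_id: str
    nluc: float
    fluc: float
    cell_line: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        for channel, value in (("nluc", self.nluc), ("fluc", self.fluc)):
            if not np.isfinite(value) or value <= 0:
                raise InputError(
                    f"{self.plate_id}/{self.well}: {channel} must be finite "
                    f"and > 0, got {value!r}")


@dataclass
class SuppressionResult:
    """Replicate-level ratios and their summary for one library member."""

    member_id: str
    ratios: list[float]
    mean: float
    sem: float
    n: int
    fold_vs_reference: float | None = None
    low_n: bool = False


def read_plate_csv(path: str | Path) -> pd.DataFrame:
    """Load a plate CSV and validate the well-level invariants."""
    df = pd.read_csv(path, dtype={"plate_id": str, "well": str,
                                  "member_id": str, "cell_line": str})
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"plate CSV missing columns: {sorted(missing)}")
    return validate_plate_frame(df)


def validate_plate_frame(df: pd.DataFrame) -> pd.DataFrame:
    bad = df[~np.isfinite(df["nluc"]) | ~np.isfinite(df["fluc"])
             | (df["nluc"] <= 0) | (df["fluc"] <= 0)]
    if len(bad):
        raise InputError(
            f"nonpositive or non-finite luminescence in wells "
            f"{bad[['plate_id', 'well']].values.tolist()[:5]}")
    dup = df.duplicated(subset=["plate_id", "well"])
    if dup.any():
        raise InputError("duplicate (plate_id, well) rows in plate data")
    return df


def suppression_ratio(nluc_plus, fluc_plus, nluc_minus, fluc_minus):
    """Normalized suppression ratio for one (+tRNA, no-tRNA) well pair.

    Accepts scalars or arrays; every input must be > 0.
    """
    arrays = [np.asarray(x, dtype=float)
              for x in (nluc_plus, fluc_plus, nluc_minus, fluc_minus)]
    for arr in arrays:
        if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
            raise InputError("all luminescence values must be finite and > 0")
    np_, fp, nm, fm = arrays
    out = (np_ / fp) / (nm / fm)
    return float(out) if out.ndim == 0 else out


def per_well_ratios(df: pd.DataFrame, control_id: str = NO_TRNA,
                    control_policy: str = "per_plate") -> pd.DataFrame:
    """Attach a ``ratio`` column: each well's Nluc/Fluc over its control.

    ``control_policy`` is ``"per_plate"`` (each plate normalized by the
    geometric mean of its own control wells; plates lacking a control are
    dropped with an error log) or ``"per_experiment"`` (one pooled control
    geometric mean across all plates).
    """
    df = validate_plate_frame(df.copy())
    df["nf"] = df["nluc"] / df["fluc"]
    is_control = df["member_id"] == control_id
    if control_policy == "per_experiment":
        if not is_control.any():
            raise InputError("no control wells in the experiment")
        denom = gmean(df.loc[is_control, "nf"])
        df["ratio"] = df["nf"] / denom
        return df.drop(columns=["nf"])
    if control_policy != "per_plate":
        raise InputError(f"unknown control_policy {control_policy!r}")
    out = []
    for plate_id, plate in df.groupby("plate_id", sort=False):
        controls = plate.loc[plate["member_id"] == control_id, "nf"]
        if controls.empty:
            logger.error("plate %s has no %s control; dropped", plate_id,
                         control_id)
            continue
        plate = plate.copy()
        plate["ratio"] = plate["nf"] / gmean(controls)
        out.append(plate)
    if not out:
        raise InputError("no plate contained a control well")
    return pd.concat(out, ignore_index=True).drop(columns=["nf"])


def summarize_library(measurements: pd.DataFrame, control_id: str = NO_TRNA,
                      control_policy: str = "per_plate",
                      ) -> list[SuppressionResult]:
    """Per-member replicate summaries of the normalized suppression ratio.

    Each replicate's ratio uses its own plate's control (under the default
    policy).  SEM uses the sample standard deviation (n-1 denominator);
    members observed in fewer than two replicates are flagged ``low_n``.
    """
    ratios = per_well_ratios(measurements, control_id=control_id,
                             control_policy=control_policy)
    results: list[SuppressionResult] = []
    for member_id, grp in ratios.groupby("member_id", sort=False):
        values = grp["ratio"].to_numpy(dtype=float)
        n = len(values)
        mean = float(values.mean())
        sem = float(values.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        results.append(SuppressionResult(
            member_id=str(member_id), ratios=values.tolist(), mean=mean,
            sem=sem, n=n, low_n=n < 2,
        ))
    return results


def reference_normalize(results: list[SuppressionResult],
                        reference_id: str) -> list[SuppressionResult]:
    """Express each member's mean as a fold over a reference member."""
    ref = next((r for r in results if r.member_id == reference_id), None)
    if ref is None:
        raise InputError(f"reference member {reference_id!r} not in results")
    for r in results:
        r.fold_vs_reference = r.mean / ref.mean
    return results


def heatmap_matrix(results: list[SuppressionResult], n_cols: int,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Row-major fill of fold-vs-reference values into an n_cols-wide matrix.

    The column layout carries no meaning; it only reproduces the compact
    heat-map presentation.  Padding cells are NaN (values) / None (ids).
    Returns ``(values, member_ids)`` of identical shape.
    """
    if n_cols < 1:
        raise InputError("n_cols must be >= 1")
    n = len(results)
    n_rows = max(1, -(-n // n_cols))
    values = np.full((n_rows, n_cols), np.nan)
    ids = np.full((n_rows, n_cols), None, dtype=object)
    for k, r in enumerate(results):
        i, j = divmod(k, n_cols)
        values[i, j] = (r.fold_vs_reference if r.fold_vs_reference is not None
                        else r.mean)
        ids[i, j] = r.member_id
    return values, ids


def results_frame(results: list[SuppressionResult]) -> pd.DataFrame:
    """Flatten results to a DataFrame for TSV export."""
    return pd.DataFrame([
        {"member_id": r.member_id, "mean": r.mean, "sem": r.sem, "n": r.n,
         "fold_vs_reference": r.fold_vs_reference, "low_n": r.low_n}
        for r in results
    ])
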