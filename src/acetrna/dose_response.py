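"""DNA dose dependence of nonsense suppression: Sup_max and DD_50.

Delivered suppressor-tRNA DNA saturates: the normalized suppression ratio
rises from its no-tRNA baseline of 1 toward a maximum.  We model this as a
rectangular hyperbola with the baseline pinned at 1,

    S(D) = 1 + (Sup_max - 1) * D / (DD_50 + D),

where Sup_max is the maximal suppression ratio and DD_50 the DNA amount
(ng/ul) giving the half-maximal response above baseline: S(DD_50) =
(1 + Sup_max) / 2.  An optional free Hill exponent is available for
sensitivity analysis.  Dose-sparing between two cassettes compares the DNA
needed to reach the same suppression level by analytic inversion of the
model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import FitError, InputError


def model_S(D, sup_max: float, dd50: float, hill: float = 1.0):
    """Saturating suppression ratio at DNA dose ``D`` (scalar or array)."""
    D = np.asarray(D, dtype=float)
    Dh = np.power(D, hill)
    out = 1.0 + (sup_max - 1.0) * Dh / (np.power(dd50, hill) + Dh)
    return float(out) if out.ndim == 0 else out


@dataclass
class DoseResponseDataset:
    """Doses (ng/ul), observed ratios, and replicate labels."""

    doses: np.ndarray
    ratios: np.ndarray
    replicates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.doses.shape != self.ratios.shape:
            raise InputError("doses and ratios differ in shape")
        if np.any(self.doses < 0):
            raise InputError("doses must be >= 0")
        if np.any(self.ratios <= 0):
            raise InputError("ratios must be > 0")
        if len(np.unique(self.doses)) < 3:
            raise InputError("need >= 3 distinct doses to fit")
        if self.replicates is not None:
            self.replicates = np.asarray(self.replicates)
            if self.replicates.shape != self.doses.shape:
                raise InputError("replicates shape mismatch")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DoseResponseDataset":
        return cls(doses=df["dose_ng_ul"].to_numpy(),
                   ratios=df["ratio"].to_numpy(),
                   replicates=df["replicate"].to_numpy()
                   if "replicate" in df else None)


@dataclass
class DoseResponseFit:
    """Least-squares estimates with optional bootstrap percentile CIs."""

    sup_max: float
    dd50: float
    rss: float
    n: int
    hill: float = 1.0
    ci_sup_max: tuple[float, float] | None = None
    ci_dd50: tuple[float, float] | None = None
    unidentifiable: bool = False
    label: str = ""

    def predict(self, D):
        return model_S(D, self.sup_max, self.dd50, self.hill)


_FLAT_TOL = 1e-9


def _lsq(doses: np.ndarray, ratios: np.ndarray,
         free_exponent: bool) -> tuple[float, float, float]:
    smax0 = float(ratios.max())
    half = (1.0 + smax0) / 2.0
    dd50_0 = float(doses[np.argmin(np.abs(ratios - half))])
    if dd50_0 <= 0:
        positive = doses[doses > 0]
        dd50_0 = float(positive.min()) if positive.size else 1.0
    try:
        if free_exponent:
            popt, _ = curve_fit(
                model_S, doses, ratios, p0=[max(smax0, 1.0 + 1e-6), dd50_0, 1.0],
                bounds=([1.0, 1e-12, 0.1], [np.inf, np.inf, 10.0]),
                maxfev=20000)
            return float(popt[0]), float(popt[1]), float(popt[2])
        popt, _ = curve_fit(
            lambda D, s, d: model_S(D, s, d), doses, ratios,
            p0=[max(smax0, 1.0 + 1e-6), dd50_0],
            bounds=([1.0, 1e-12], [np.inf, np.inf]), maxfev=20000)
        return float(popt[0]), float(popt[1]), 1.0
    except RuntimeError as exc:  # pragma: no cover - scipy non-convergence
        raise FitError(f"dose-response fit did not converge: {exc}") from exc


def fit(dataset: DoseResponseDataset, bootstrap: int = 0,
        seed: int | None = None, free_exponent: bool = False,
        label: str = "") -> DoseResponseFit:
    """Unweighted least-squares fit of (Sup_max, DD_50) on the ratio scale.

    Initialisation: Sup_max at the maximum observed ratio, DD_50 at the dose
    whose mean ratio is nearest half-maximal.  Flat data (all ratios equal)
    yield Sup_max at that level with DD_50 flagged unidentifiable.  With
    ``bootstrap`` > 0, replicates (or rows, when no replicate labels exist)
    are resampled with replacement under a seeded generator and percentile
    CIs attached.
    """
    doses, ratios = dataset.doses, dataset.ratios
    if float(np.ptp(ratios)) < _FLAT_TOL:
        return DoseResponseFit(
            sup_max=float(ratios.mean()), dd50=float("nan"),
            rss=float(np.sum((ratios - ratios.mean()) ** 2)), n=len(ratios),
            unidentifiable=True, label=label)
    sup_max, dd50, hill = _lsq(doses, ratios, free_exponent)
    resid = ratios - model_S(doses, sup_max, dd50, hill)
    result = DoseResponseFit(sup_max=sup_max, dd50=dd50,
                             rss=float(np.sum(resid ** 2)), n=len(ratios),
                             hill=hill, label=label)
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        if dataset.replicates is not None:
            groups = pd.unique(dataset.replicates)
            members = {g: np.flatnonzero(dataset.replicates == g)
                       for g in groups}
        boot_s, boot_d = [], []
        for _ in range(bootstrap):
            if dataset.replicates is not None:
                chosen = rng.choice(groups, size=len(groups), replace=True)
                idx = np.concatenate([members[g] for g in chosen])
            else:
                idx = rng.integers(0, len(ratios), size=len(ratios))
            d, r = doses[idx], ratios[idx]
            if len(np.unique(d)) < 3 or float(np.ptp(r)) < _FLAT_TOL:
                continue
            try:
                s_b, d_b, _ = _lsq(d, r, free_exponent)
            except FitError:
                continue
            boot_s.append(s_b)
            boot_d.append(d_b)
        if boot_s:
            result.ci_sup_max = tuple(np.percentile(boot_s, [2.5, 97.5]))
            result.ci_dd50 = tuple(np.percentile(boot_d, [2.5, 97.5]))
    return result


def invert_dose(fit_result: DoseResponseFit, level: float) -> float:
    """DNA dose at which the fitted curve reaches ``level`` (analytic)."""
    if fit_result.unidentifiable:
        raise InputError(f"fit {fit_result.label or '(unnamed)'} is "
                         "unidentifiable; cannot invert")
    if not 1.0 < level < fit_result.sup_max:
        raise InputError(
            f"level {level} unreachable by fit "
            f"{fit_result.label or '(unnamed)'} (1 < level < "
            f"{fit_result.sup_max:g} required)")
    core = (level - 1.0) / (fit_result.sup_max - level)
    return fit_result.dd50 * core ** (1.0 / fit_result.hill)


def dose_sparing(fit_a: DoseResponseFit, fit_b: DoseResponseFit,
                 level: float) -> float:
    """Fold less DNA needed by cassette A than B to reach ``level``.

    Returns D_b(level) / D_a(level); > 1 means A is dose-sparing relative
    to B.  ``level`` must be reachable by both fits (checked in input
    order, so the error names the first offending fit).
    """
    d_a = invert_dose(fit_a, level)
    d_b = invert_dose(fit_b, level)
    return d_b / d_a
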