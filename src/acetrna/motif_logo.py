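"""Activity-weighted position frequency and significance logos.

Screen activity is converted to sequence abundance: a member with a
normalized suppression ratio of 100 contributes as if 100 identical copies
of its sequence were present (so a weighted computation over members is
identical to an unweighted computation over the count-expanded sequence
set).  From the weighted set we build

* a frequency matrix (L x 4, rows sum to 1), and
* a significance matrix: per position and base, an exact two-sided binomial
  test of the weighted base count against a background frequency, reported
  as sign(observed - expected) * -log10(P), capped at 300.

High/low consensus sequences take the per-position argmax/argmin of either
matrix, ties broken alphabetically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binomtest

from .errors import InputError
from .screen_analysis import SuppressionResult

ALPHABET = "ACGT"
SIG_CAP = 300.0


@dataclass
class WeightedSequenceSet:
    """Equal-length sequences with nonnegative integer copy counts."""

    sequences: list[str]
    counts: list[int]

    def __post_init__(self) -> None:
        if len(self.sequences) != len(self.counts):
            raise InputError("sequences and counts differ in length")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise InputError(f"sequences have mixed lengths: {sorted(lengths)}")
        if any(c < 0 for c in self.counts):
            raise InputError("counts must be nonnegative")

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def total_weight(self) -> int:
        return int(sum(self.counts))

    def expand(self) -> list[str]:
        """The count-expanded (unweighted) sequence list."""
        out: list[str] = []
        for seq, c in zip(self.sequences, self.counts):
            out.extend([seq] * c)
        return out


@dataclass
class PositionLogo:
    """Frequency and signed -log10(P) significance matrices (L x 4)."""

    freq: np.ndarray
    sig: np.ndarray
    background: np.ndarray
    alphabet: str = ALPHABET


def weight_to_counts(results: list[SuppressionResult],
                     sequences: dict[str, str]) -> WeightedSequenceSet:
    """Convert member activities to integer copy counts.

    The count is the mean suppression ratio rounded to the nearest integer
    (banker's rounding, as in Python's ``round``), floored at 0.  Members
    rounding to 0 are retained with count 0; they simply contribute no
    weight.
    """
    seqs: list[str] = []
    counts: list[int] = []
    for r in results:
        if r.member_id not in sequences:
            raise InputError(f"no sequence for member {r.member_id!r}")
        seqs.append(sequences[r.member_id].upper())
        counts.append(max(0, round(r.mean)))
    return WeightedSequenceSet(sequences=seqs, counts=counts)


def _base_counts(ws: WeightedSequenceSet) -> np.ndarray:
    """Weighted base counts per position: L x 4 integer matrix."""
    counts = np.zeros((ws.length, len(ALPHABET)), dtype=np.int64)
    index = {b: k for k, b in enumerate(ALPHABET)}
    for seq, c in zip(ws.sequences, ws.counts):
        if c == 0:
            continue
        for p, base in enumerate(seq):
            try:
                counts[p, index[base]] += c
            except KeyError:
                raise InputError(f"non-ACGT base {base!r} in sequence")
    return counts


def position_frequency(ws: WeightedSequenceSet) -> np.ndarray:
    """Weighted per-position base frequency matrix (rows sum to 1)."""
    total = ws.total_weight
    if total < 1:
        raise InputError("total weight must be >= 1")
    return _base_counts(ws) / total


def pooled_background(ws: WeightedSequenceSet) -> np.ndarray:
    """Per-base frequency pooled over all positions of the weighted set."""
    counts = _base_counts(ws).sum(axis=0)
    return counts / counts.sum()


def resolve_background(ws: WeightedSequenceSet, background) -> np.ndarray:
    """Resolve ``"pooled"`` / ``"uniform"`` / explicit 4-vector backgrounds."""
    if isinstance(background, str):
        if background == "pooled":
            return pooled_background(ws)
        if background == "uniform":
            return np.full(4, 0.25)
        raise InputError(f"unknown background {background!r}")
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or np.any(bg <= 0):
        raise InputError("background must be 4 strictly positive frequencies")
    return bg / bg.sum()


def position_significance(ws: WeightedSequenceSet,
                          background="pooled") -> np.ndarray:
    """Signed -log10(P) of an exact two-sided binomial test per (position, base).

    k is the weighted count of the base at the position, n the total weight,
    p0 the background frequency; the two-sided P sums the probabilities of
    all outcomes no more likely than the observed one.  The sign is positive
    for enrichment (k/n > p0) and negative for depletion; a base exactly at
    background scores 0.  Values are capped at +/-300.
    """
    bg = resolve_background(ws, background)
    counts = _base_counts(ws)
    n = ws.total_weight
    if n < 1:
        raise InputError("total weight must be >= 1")
    sig = np.zeros_like(counts, dtype=float)
    for p in range(counts.shape[0]):
        for b in range(4):
            k = int(counts[p, b])
            p0 = float(bg[b])
            if k == n * p0:
                continue
            pval = binomtest(k, n, p0, alternative="two-sided").pvalue
            mag = min(-np.log10(max(pval, 10.0 ** -SIG_CAP)), SIG_CAP)
            sig[p, b] = np.sign(k / n - p0) * mag
    return sig


def build_logo(ws: WeightedSequenceSet, background="pooled") -> PositionLogo:
    bg = resolve_background(ws, background)
    return PositionLogo(freq=position_frequency(ws),
                        sig=position_significance(ws, bg),
                        background=bg)


def consensus(logo: PositionLogo, mode: str = "high",
              basis: str = "frequency") -> str:
    """Per-position argmax ("high") or argmin ("low") consensus sequence.

    ``basis`` selects the frequency or the significance ("probability")
    matrix.  Ties break alphabetically (A < C < G < T).
    """
    if basis in ("frequency", "freq"):
        matrix = logo.freq
    elif basis in ("probability", "significance", "sig"):
        matrix = logo.sig
    else:
        raise InputError(f"unknown basis {basis!r}")
    if mode == "high":
        picks = np.argmax(matrix, axis=1)
    elif mode == "low":
        picks = np.argmin(matrix, axis=1)
    else:
        raise InputError(f"unknown mode {mode!r}")
    return "".join(logo.alphabet[k] for k in picks)


def logo_frame(matrix: np.ndarray) -> "np.ndarray":
    """Wrap an L x 4 matrix as a DataFrame with ACGT columns for TSV export."""
    import pandas as pd

    return pd.DataFrame(matrix, columns=list(ALPHABET))


def plot_logo(logo: PositionLogo, basis: str = "frequency", ax=None):
    """Simple stacked-letter rendering of a logo matrix (requires matplotlib)."""
    import matplotlib.pyplot as plt

    matrix = logo.freq if basis in ("frequency", "freq") else np.abs(logo.sig)
    if ax is None:
        _, ax = plt.subplots(figsize=(max(4, matrix.shape[0] * 0.3), 2.5))
    colors = {"A": "tab:green", "C": "tab:blue", "G": "tab:orange",
              "T": "tab:red"}
    for p in range(matrix.shape[0]):
        bottom = 0.0
        order = np.argsort(matrix[p])
        for b in order:
            h = matrix[p, b]
            if h <= 0:
                continue
            base = logo.alphabet[b]
            ax.text(p + 0.5, bottom + h / 2, base, ha="center", va="center",
                    fontsize=8 + 10 * h / max(matrix.max(), 1e-12),
                    color=colors[base])
            bottom += h
    ax.set_xlim(0, matrix.shape[0])
    ax.set_ylim(0, matrix.max() * 1.05)
    ax.set_xlabel("position")
    ax.set_ylabel(basis)
    return ax
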