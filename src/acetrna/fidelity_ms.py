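"""Translational-fidelity quantification from targeted proteomics.

To ask which amino acid a suppressor tRNA actually installs at a stop
codon, the reporter protein is purified, trypsin-digested, and the peptide
spanning the suppressed site is quantified for each of the 20 possible
residues.  This module provides

* an in-silico tryptic digest (cleave C-terminal to K/R, not before P, up
  to a configurable number of missed cleavages),
* construction of the 20-member variant inclusion list (one minimal
  missed-cleavage peptide per amino-acid substitution at the site, with
  monoisotopic masses and 2+..5+ m/z, carbamidomethyl-C fixed and Met
  oxidation as a variable modification), and
* ionization-weighted percent incorporation: per-residue abundances are
  reweighted by factors derived from an equimolar control mix (so the
  control itself becomes uniform) and normalized to 100%.

Upstream database search, FDR control and feature detection are assumed
done; the inputs here are their per-residue abundance tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyteomics import mass as pt_mass

from .errors import InputError

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PROTON = 1.00727646688
CARBAMIDOMETHYL = 57.02146
MET_OXIDATION = 15.99491
CHARGES = (2, 3, 4, 5)


def peptide_mono_mass(sequence: str, carbamidomethyl_c: bool = True,
                      n_oxidations: int = 0) -> float:
    """Monoisotopic neutral mass of a peptide, with fixed/variable mods."""
    m = pt_mass.fast_mass(sequence)
    if carbamidomethyl_c:
        m += CARBAMIDOMETHYL * sequence.count("C")
    return m + MET_OXIDATION * n_oxidations


def mz_map(mono_mass: float, charges=CHARGES) -> dict[int, float]:
    return {z: (mono_mass + z * PROTON) / z for z in charges}


@dataclass
class DigestPeptide:
    """A tryptic fragment with its origin and missed-cleavage count."""

    sequence: str
    start: int  # 0-based position in the protein
    missed_cleavages: int

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)


@dataclass
class PeptideRecord:
    """An inclusion-list entry for one amino-acid variant at the site."""

    sequence: str
    variant_aa: str
    missed_cleavages: int
    mono_mass: float
    mz: dict[int, float]
    start: int = 0
    #: m/z maps for each count of oxidized methionines (1..#Met).
    mz_oxidized: dict[int, dict[int, float]] = field(default_factory=dict)


def _validate_protein(protein: str) -> str:
    protein = protein.upper().rstrip("*")
    bad = set(protein) - set(AMINO_ACIDS)
    if bad:
        raise InputError(f"invalid residue(s) {sorted(bad)} in protein")
    return protein


def cleavage_sites(protein: str) -> list[int]:
    """Positions after which trypsin cleaves: K/R not followed by P."""
    return [i + 1 for i in range(len(protein) - 1)
            if protein[i] in "KR" and protein[i + 1] != "P"]


def tryptic_digest(protein: str, max_missed: int = 2) -> list[DigestPeptide]:
    """All tryptic peptides of ``protein`` with 0..max_missed missed cleavages.

    Ordered by start position, then missed-cleavage count.
    """
    protein = _validate_protein(protein)
    if not protein:
        raise InputError("empty protein")
    bounds = [0] + cleavage_sites(protein) + [len(protein)]
    peptides: list[DigestPeptide] = []
    for a in range(len(bounds) - 1):
        for missed in range(max_missed + 1):
            b = a + 1 + missed
            if b >= len(bounds):
                break
            peptides.append(DigestPeptide(
                sequence=protein[bounds[a]:bounds[b]],
                start=bounds[a], missed_cleavages=missed))
    return peptides


def variant_inclusion_list(protein: str, site: int,
                           max_missed: int = 2,
                           carbamidomethyl_c: bool = True,
                           met_oxidation: bool = True,
                           ) -> list[PeptideRecord]:
    """The 20 theoretical variant tryptic peptides spanning ``site``.

    ``site`` is 1-based.  For each amino-acid substitution, the spanning
    peptide with the fewest missed cleavages (shortest on ties) represents
    the variant.  A K/R substitution creates a new cleavage site at the
    variant position itself; the representative peptide is required to
    extend past it (treating that cleavage as missed), so K/R variants use
    >= 1 missed cleavage rather than a fragment truncated at the variant
    residue.  When the protein has no cleavage site at all the whole
    protein is used, with a warning.
    """
    protein = _validate_protein(protein)
    if not 1 <= site <= len(protein):
        raise InputError(f"site {site} outside protein of length {len(protein)}")
    records: list[PeptideRecord] = []
    for aa in AMINO_ACIDS:
        variant = protein[:site - 1] + aa + protein[site:]
        # a cleavage created by the substitution itself must be read through
        new_cut = (aa in "KR" and site < len(variant)
                   and variant[site] != "P")
        spanning = [p for p in tryptic_digest(variant, max_missed=max_missed)
                    if p.start < site <= p.end
                    and (not new_cut or p.end > site)]
        if not spanning:
            logger.warning("no tryptic peptide spans site %d for variant %s; "
                           "using the whole protein", site, aa)
            chosen = DigestPeptide(sequence=variant, start=0,
                                   missed_cleavages=0)
        else:
            chosen = min(spanning,
                         key=lambda p: (p.missed_cleavages, len(p.sequence),
                                        p.start))
        mono = peptide_mono_mass(chosen.sequence,
                                 carbamidomethyl_c=carbamidomethyl_c)
        record = PeptideRecord(
            sequence=chosen.sequence, variant_aa=aa,
            missed_cleavages=chosen.missed_cleavages, mono_mass=mono,
            mz=mz_map(mono), start=chosen.start)
        if met_oxidation:
            for n_ox in range(1, chosen.sequence.count("M") + 1):
                record.mz_oxidized[n_ox] = mz_map(mono + MET_OXIDATION * n_ox)
        records.append(record)
    assert len(records) == len(AMINO_ACIDS)
    if len({r.sequence for r in records}) != len(records):
        raise InputError("variant peptides are not distinct; check the site")
    return records


def inclusion_list_frame(records: list[PeptideRecord]) -> pd.DataFrame:
    """Flatten an inclusion list to one row per (peptide, charge, n_ox)."""
    rows = []
    for r in records:
        for n_ox, mzs in [(0, r.mz)] + sorted(r.mz_oxidized.items()):
            for z, mz in sorted(mzs.items()):
                rows.append({"variant_aa": r.variant_aa, "sequence": r.sequence,
                             "missed_cleavages": r.missed_cleavages,
                             "n_oxidation": n_ox, "z": z, "mz": mz})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ionization weighting and percent incorporation


def _as_series(abundances) -> pd.Series:
    if isinstance(abundances, pd.Series):
        s = abundances.astype(float)
    elif isinstance(abundances, dict):
        s = pd.Series(abundances, dtype=float)
    else:
        raise InputError("abundances must be a dict or Series keyed by residue")
    s.index = [str(k).upper() for k in s.index]
    return s


def ionization_weights(control) -> pd.Series:
    """Per-residue weights from an equimolar control mix.

    weight_aa = mean(control) / control_aa, so reweighting the control
    itself gives a uniform profile.  Residues with zero or missing control
    abundance are excluded with a warning.
    """
    control = _as_series(control)
    bad = control.index[(control <= 0) | control.isna()]
    if len(bad):
        logger.warning("excluding residues with nonpositive control "
                       "abundance: %s", list(bad))
        control = control.drop(bad)
    if control.empty:
        raise InputError("no usable control abundances")
    return control.mean() / control


def percent_incorporation(sample, weights) -> pd.DataFrame:
    """Ionization-corrected percent incorporation per residue.

    percent_aa = 100 * sample_aa * weight_aa / sum(sample * weight), over
    the residues present in both tables.  Percentages sum to 100.
    """
    sample = _as_series(sample)
    weights = _as_series(weights)
    if np.any(sample < 0):
        raise InputError("sample abundances must be >= 0")
    shared = sample.index.intersection(weights.index)
    dropped = sample.index.difference(weights.index)
    if len(dropped):
        logger.warning("sample residues without ionization weights dropped: %s",
                       list(dropped))
    sample = sample.loc[shared]
    weighted = sample * weights.loc[shared]
    total = weighted.sum()
    if total <= 0:
        raise InputError("all sample abundances are zero")
    return pd.DataFrame({
        "raw_abundance": sample,
        "ionization_weight": weights.loc[shared],
        "weighted_abundance": weighted,
        "percent": 100.0 * weighted / total,
    })
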