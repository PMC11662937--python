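"""Small DNA-string helpers shared across modules.

Everything here operates on plain uppercase DNA strings (alphabet ACGT) in
the coding-strand 5'→3' orientation unless stated otherwise.
"""

from __future__ import annotations

import re

from Bio.Seq import Seq

DNA_ALPHABET = frozenset("ACGT")

#: Watson-Crick pairs in DNA sense.
WC_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})

#: G.U wobble written in DNA sense (G.T). Tolerated in tRNA stems.
WOBBLE_PAIRS = frozenset({("G", "T"), ("T", "G")})


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (preserves case via Biopython)."""
    return str(Seq(seq).reverse_complement())


def validate_dna(seq: str, *, what: str = "sequence") -> str:
    """Return ``seq`` uppercased; raise ``ValueError`` on a non-ACGT residue."""
    up = seq.upper()
    bad = set(up) - DNA_ALPHABET
    if bad:
        raise ValueError(f"{what} contains non-ACGT characters: {sorted(bad)}")
    return up


def is_complementary(a: str, b: str, *, allow_wobble: bool = False) -> bool:
    pair = (a.upper(), b.upper())
    return pair in WC_PAIRS or (allow_wobble and pair in WOBBLE_PAIRS)


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def homopolymer_runs(seq: str, base: str, min_len: int) -> list[tuple[int, int]]:
    """Maximal runs of ``base`` of length >= ``min_len`` as (start, length)."""
    return [
        (m.start(), m.end() - m.start())
        for m in re.finditer(f"{base}{{{min_len},}}", seq)
    ]


def max_homopolymer(seq: str) -> int:
    """Length of the longest single-base run in ``seq``."""
    best = 0
    for base in "ACGT":
        for m in re.finditer(f"{base}+", seq):
            best = max(best, m.end() - m.start())
    return best
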