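"""Combinatorial design of suppressor-tRNA expression cassette libraries.

An expression cassette is a 5' upstream control element (UCE), the tRNA body,
and a 3' trailer carrying the RNA polymerase III poly-T terminator.  The
library classes implemented here mirror the screening workflow for such
cassettes:

* ``uce5`` / ``trailer35`` — every unique flank of a given length extracted
  from annotated tRNA genes, strand-aware, exact-duplicate collapsed;
* ``trailer4`` / ``ac_loop`` — saturation mutagenesis of a small set of
  positions (all 4^k combinations);
* ``sticky_stem`` — every combination of original versus C–G/G–C pair at
  stem positions that are non-conserved across a family of functional
  isoacceptors (2^k members);
* ``tstem`` — substitution of the outer T-stem pairs with a table of variant
  pair sets spanning a range of elongation-factor binding strengths.

Each member records its edits relative to the parent so that the parent plus
edits reconstructs the member exactly.  Golden-Gate duplex oligos with 4-nt
overhangs are generated for cloning, and cassettes are scanned for premature
internal poly-T terminators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import pandas as pd

from .errors import DesignError, InputError
from .sequence import homopolymer_runs, is_complementary, revcomp, validate_dna
from .trna_model import Cloverleaf, TRNAGeneRecord

logger = logging.getLogger(__name__)

STOP_CODONS = ("TGA", "TAG", "TAA")


@dataclass
class ExpressionCassette:
    """5' UCE + tRNA body + 3' trailer, in coding-strand orientation."""

    uce5: str
    body: str
    trailer3: str
    label: str = ""

    def __post_init__(self) -> None:
        self.uce5 = validate_dna(self.uce5, what="uce5")
        self.body = validate_dna(self.body, what="body")
        self.trailer3 = validate_dna(self.trailer3, what="trailer3")

    @property
    def full_sequence(self) -> str:
        return self.uce5 + self.body + self.trailer3


@dataclass
class LibraryMember:
    """One designed sequence, with provenance back to its parent.

    ``edits`` is a list of ``(position, from_base, to_base)`` on the member's
    own coordinate system; applying them to the parent sequence reproduces
    ``sequence`` exactly.
    """

    member_id: str
    sequence: str
    edits: list[tuple[int, str, str]]
    library_class: str
    label: str = ""
    cassette: ExpressionCassette | None = None


def apply_edits(parent: str, edits: list[tuple[int, str, str]]) -> str:
    """Apply (position, from, to) edits to ``parent``; verify the from-base."""
    seq = list(parent)
    for pos, old, new in edits:
        if seq[pos] != old:
            raise DesignError(
                f"edit at {pos} expects {old!r} but parent has {seq[pos]!r}"
            )
        seq[pos] = new
    return "".join(seq)


def _diff_edits(parent: str, child: str) -> list[tuple[int, str, str]]:
    return [(k, a, b) for k, (a, b) in enumerate(zip(parent, child)) if a != b]


# ---------------------------------------------------------------------------
# anticodon editing


def edit_anticodon(cl: Cloverleaf, body: str, stop_codon: str) -> str:
    """Replace the anticodon so the tRNA reads ``stop_codon``.

    The stop codon is given in the DNA sense of the mRNA coding strand; the
    new anticodon is its reverse complement (TGA→TCA, TAG→CTA, TAA→TTA).
    All other positions are untouched; the edit is idempotent.
    """
    stop_codon = stop_codon.upper()
    if stop_codon not in STOP_CODONS:
        raise InputError(f"{stop_codon!r} is not a stop codon (TGA/TAG/TAA)")
    new_ac = revcomp(stop_codon)
    seq = list(body)
    for k, base in zip(cl.anticodon, new_ac):
        seq[k] = base
    return "".join(seq)


# ---------------------------------------------------------------------------
# flank extraction


@dataclass(frozen=True)
class Flank:
    """A unique flank sequence with the locus of its first occurrence."""

    sequence: str
    gene_id: str
    chrom: str
    start: int  # genomic, 0-based half-open window [start, end)
    end: int
    strand: str
    side: int  # 5 or 3, in the tRNA's transcriptional sense


def extract_flanks(genes: list[TRNAGeneRecord], genome, side: int,
                   length: int) -> list[Flank]:
    """Unique 5' or 3' flanks of the given length, in transcriptional sense.

    For a minus-strand gene the 5' flank is the genomic window downstream of
    the gene, reverse-complemented.  Flanks running off a chromosome end are
    skipped with a logged warning.  Exact duplicates collapse to their first
    occurrence; output order is input order of first occurrence.
    """
    if side not in (5, 3):
        raise InputError("side must be 5 or 3")
    if length < 1:
        raise InputError("length must be >= 1")
    from pyfaidx import Fasta

    if isinstance(genome, (str, Path)):
        genome = Fasta(str(genome), as_raw=True, sequence_always_upper=True)

    flanks: list[Flank] = []
    seen: dict[str, str] = {}
    skipped = 0
    for rec in genes:
        upstream = (side == 5) == (rec.strand == "+")
        if upstream:
            start, end = rec.start - length, rec.start
        else:
            start, end = rec.end, rec.end + length
        chrom_len = len(genome[rec.chrom])
        if start < 0 or end > chrom_len:
            logger.warning("skipping %s: %d' flank [%d, %d) outside %s",
                           rec.gene_id, side, start, end, rec.chrom)
            skipped += 1
            continue
        seq = str(genome[rec.chrom][start:end])
        if rec.strand == "-":
            seq = revcomp(seq)
        if seq in seen:
            continue
        seen[seq] = rec.gene_id
        flanks.append(Flank(sequence=seq, gene_id=rec.gene_id, chrom=rec.chrom,
                            start=start, end=end, strand=rec.strand, side=side))
    if skipped:
        logger.warning("extract_flanks: skipped %d gene(s) at chromosome edges",
                       skipped)
    return flanks


def default_synthesis_filter(seq: str, *, max_homopolymer_len: int = 15,
                             gc_range: tuple[float, float] = (0.20, 0.80),
                             ) -> bool:
    """Default predicate for synthetic accessibility of long elements.

    Rejects sequences with a homopolymer run longer than 15 nt or GC content
    outside 20–80% — a generic stand-in for vendor synthesis constraints on
    long (e.g. 850-bp) UCE fragments.
    """
    from .sequence import gc_fraction, max_homopolymer

    if max_homopolymer(seq) > max_homopolymer_len:
        return False
    lo, hi = gc_range
    return lo <= gc_fraction(seq) <= hi


# ---------------------------------------------------------------------------
# saturation libraries


def enumerate_saturation(template: str, positions: list[int],
                         alphabet: str = "ACGT",
                         library_class: str = "saturation",
                         ) -> list[LibraryMember]:
    """All |alphabet|^k substitutions of ``positions`` in ``template``.

    Members are ordered lexicographically by the substituted k-mer; the
    member identical to the template is labeled ``"original"``.
    """
    template = validate_dna(template, what="template")
    if len(set(positions)) != len(positions):
        raise InputError("duplicate positions in saturation set")
    for p in positions:
        if not 0 <= p < len(template):
            raise InputError(f"position {p} outside template of length "
                             f"{len(template)}")
    members: list[LibraryMember] = []
    original_kmer = "".join(template[p] for p in positions)
    for combo in product(sorted(alphabet), repeat=len(positions)):
        kmer = "".join(combo)
        edits = [(p, template[p], b) for p, b in zip(positions, combo)
                 if template[p] != b]
        members.append(LibraryMember(
            member_id=f"{library_class}_{kmer}" if kmer else f"{library_class}_original",
            sequence=apply_edits(template, edits),
            edits=edits,
            library_class=library_class,
            label="original" if kmer == original_kmer else "",
        ))
    return members


# ---------------------------------------------------------------------------
# sticky-stem library


@dataclass(frozen=True)
class StickyStemSite:
    """A stem pair position eligible for C–G/G–C stabilisation."""

    stem: str
    pair_index: int  # index within the stem, outermost first
    positions: tuple[int, int]  # (i, j) into the target body
    original_pair: tuple[str, str]
    library_pair: tuple[str, str]
    source_member: int  # index into the family list that supplied the pair


def find_sticky_stem_sites(target_body: str, target_cl: Cloverleaf,
                           family: list[tuple[str, Cloverleaf]],
                           ) -> list[StickyStemSite]:
    """Stem positions where the family licenses a C–G or G–C substitution.

    A site qualifies when the pair is not identical across target and family
    and at least one family member carries C–G or G–C there (ties broken by
    family input order), and that pair differs from the target's own pair.
    Family members must share the target's stem geometry.
    """
    sites: list[StickyStemSite] = []
    for stem_name, target_pairs in target_cl.stems.items():
        for fam_body, fam_cl in family:
            if len(fam_cl.stems[stem_name]) != len(target_pairs):
                raise InputError(
                    f"family member {stem_name}-stem length differs from "
                    "target; bodies must be structurally aligned"
                )
        for k, (i, j) in enumerate(target_pairs):
            target_pair = (target_body[i], target_body[j])
            observed = {target_pair}
            library_pair = None
            source = -1
            for m, (fam_body, fam_cl) in enumerate(family):
                fi, fj = fam_cl.stems[stem_name][k]
                pair = (fam_body[fi], fam_body[fj])
                observed.add(pair)
                if library_pair is None and pair in {("C", "G"), ("G", "C")} \
                        and pair != target_pair:
                    library_pair = pair
                    source = m
            if len(observed) > 1 and library_pair is not None:
                sites.append(StickyStemSite(
                    stem=stem_name, pair_index=k, positions=(i, j),
                    original_pair=target_pair, library_pair=library_pair,
                    source_member=source,
                ))
    return sites


def design_sticky_stem_library(target_body: str, target_cl: Cloverleaf,
                               family: list[tuple[str, Cloverleaf]],
                               ) -> tuple[list[StickyStemSite], list[LibraryMember]]:
    """All 2^k combinations of original versus stabilised pair per site.

    Member ids encode the site bitmask (bit set = library pair applied, site
    order as returned by :func:`find_sticky_stem_sites`).  With no
    qualifying sites the library is just the original, with a warning.
    """
    sites = find_sticky_stem_sites(target_body, target_cl, family)
    if not sites:
        logger.warning("sticky-stem design found no qualifying sites; "
                       "library contains only the original sequence")
    members: list[LibraryMember] = []
    k = len(sites)
    for mask in range(2 ** k):
        edits: list[tuple[int, str, str]] = []
        for bit, site in enumerate(sites):
            if mask >> bit & 1:
                (i, j) = site.positions
                (oi, oj) = site.original_pair
                (li, lj) = site.library_pair
                if oi != li:
                    edits.append((i, oi, li))
                if oj != lj:
                    edits.append((j, oj, lj))
        edits.sort()
        members.append(LibraryMember(
            member_id=f"ss_{mask:0{max(k, 1)}b}",
            sequence=apply_edits(target_body, edits),
            edits=edits,
            library_class="sticky_stem",
            label="original" if mask == 0 else "",
        ))
    return sites, members


# ---------------------------------------------------------------------------
# t-stem library


@dataclass(frozen=True)
class TStemVariant:
    """Nucleotides for the outer T-stem pairs, keyed by Sprinzl pair number.

    ``pairs`` maps 49/50/51 (optionally 52/53) to a (5'-base, 3'-base)
    tuple; pair 49 is the outermost (49–65), 50 the next (50–64), etc.
    """

    name: str
    pairs: dict[int, tuple[str, str]]


def load_tstem_variants(path: str | Path) -> list[TStemVariant]:
    """Read a variant table (TSV: name, pair49, pair50, pair51[, pair52, pair53]).

    Pair cells are written like ``C-G`` (5' base, dash, 3' base).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    variants: list[TStemVariant] = []
    for row in df.itertuples(index=False):
        pairs: dict[int, tuple[str, str]] = {}
        for sprinzl in (49, 50, 51, 52, 53):
            col = f"pair{sprinzl}"
            if hasattr(row, col) and isinstance(getattr(row, col), str):
                five, three = getattr(row, col).strip().upper().split("-")
                pairs[sprinzl] = (five, three)
        variants.append(TStemVariant(name=str(row.name), pairs=pairs))
    return variants


def design_tstem_library(body: str, cl: Cloverleaf,
                         variants: list[TStemVariant],
                         allow_wobble: bool = True) -> list[LibraryMember]:
    """One member per T-stem variant, substituting both strands of each pair."""
    if len(cl.t_stem) < 3:
        raise InputError("T stem has fewer than 3 pairs")
    members: list[LibraryMember] = []
    for var in variants:
        edits: list[tuple[int, str, str]] = []
        for sprinzl, (five, three) in sorted(var.pairs.items()):
            offset = sprinzl - 49
            if offset >= len(cl.t_stem):
                raise InputError(
                    f"variant {var.name}: pair {sprinzl} beyond the T stem")
            if not is_complementary(five, three, allow_wobble=allow_wobble):
                raise InputError(
                    f"variant {var.name}: pair {sprinzl} ({five}-{three}) is "
                    "not complementary")
            if (five, three) not in {("A", "T"), ("T", "A"), ("C", "G"),
                                     ("G", "C")}:
                logger.info("variant %s: wobble pair %s-%s at %d",
                            var.name, five, three, sprinzl)
            i, j = cl.t_stem[offset]
            if body[i] != five:
                edits.append((i, body[i], five))
            if body[j] != three:
                edits.append((j, body[j], three))
        edits.sort()
        members.append(LibraryMember(
            member_id=var.name,
            sequence=apply_edits(body, edits),
            edits=edits,
            library_class="tstem",
            label="original" if not edits else "",
        ))
    return members


# ---------------------------------------------------------------------------
# Golden-Gate oligos


@dataclass(frozen=True)
class GoldenGateOligos:
    """A duplex oligo pair leaving 4-nt 5' overhangs for directional cloning."""

    top: str
    bottom: str
    oh5: str
    oh3: str


def make_golden_gate_oligos(insert: str, oh5: str, oh3: str) -> GoldenGateOligos:
    """Duplex oligos for ``insert`` with 5' overhangs ``oh5`` and ``oh3``.

    The annealed duplex presents ``oh5`` as a single-stranded 5' overhang on
    the top strand and ``revcomp(oh3)`` on the bottom strand, so ligation
    into a vector cut to expose the complementary ends reconstructs
    ``oh5 + insert + oh3``.  Identical or palindromic overhang pairs would
    ligate in either orientation and are rejected.
    """
    insert = validate_dna(insert, what="insert")
    oh5 = validate_dna(oh5, what="oh5")
    oh3 = validate_dna(oh3, what="oh3")
    if len(oh5) != 4 or len(oh3) != 4:
        raise InputError("overhangs must be exactly 4 nt")
    if oh5 == oh3 or oh5 == revcomp(oh3):
        raise DesignError(
            f"overhangs {oh5}/{oh3} are not orientation-unique; "
            "ligation would be ambiguous")
    top = oh5 + insert
    bottom = revcomp(insert + oh3)
    return GoldenGateOligos(top=top, bottom=bottom, oh5=oh5, oh3=oh3)


def simulate_assembly(oligos: GoldenGateOligos) -> str:
    """Simulate anneal + ligate of the duplex into a matching vector.

    Verifies that the double-stranded core of the duplex is complementary
    and returns the reconstructed top-strand sequence ``oh5+insert+oh3``.
    """
    insert = oligos.top[len(oligos.oh5):]
    core_bottom = oligos.bottom[len(oligos.oh3):]
    if core_bottom != revcomp(insert):
        raise DesignError("duplex strands do not anneal: core mismatch")
    bottom_overhang = oligos.bottom[:len(oligos.oh3)]
    if bottom_overhang != revcomp(oligos.oh3):
        raise DesignError("bottom-strand overhang does not match oh3")
    return oligos.oh5 + insert + oligos.oh3


# ---------------------------------------------------------------------------
# terminator safety


@dataclass(frozen=True)
class TerminatorWarning:
    """A premature poly-T run upstream of the designated terminator."""

    position: int  # start index within the full cassette sequence
    run_length: int


def check_internal_terminator(cassette: ExpressionCassette,
                              min_run: int = 4) -> list[TerminatorWarning]:
    """Report poly-T runs that would terminate Pol III before the trailer.

    Vertebrate RNA polymerase III terminates at four or more consecutive
    thymidines on the coding strand.  The first >=4-T run inside the 3'
    trailer is the designated terminator; its absence is a hard design
    error.  Every maximal >=4-T run starting 5' of the designated
    terminator is returned as a warning.
    """
    trailer_runs = homopolymer_runs(cassette.trailer3, "T", min_run)
    if not trailer_runs:
        raise DesignError(
            f"trailer3 {cassette.trailer3!r} lacks a >={min_run}-T Pol III "
            "terminator")
    trailer_offset = len(cassette.uce5) + len(cassette.body)
    terminator_start = trailer_offset + trailer_runs[0][0]
    warnings_out = [
        TerminatorWarning(position=start, run_length=length)
        for start, length in homopolymer_runs(cassette.full_sequence, "T",
                                              min_run)
        if start < terminator_start
    ]
    return warnings_out


# ---------------------------------------------------------------------------
# manifest output


def library_manifest(members: list[LibraryMember]) -> pd.DataFrame:
    """Tabulate a library as a manifest DataFrame (one row per member)."""
    rows = []
    for m in members:
        rows.append({
            "member_id": m.member_id,
            "library_class": m.library_class,
            "label": m.label,
            "sequence": m.sequence,
            "edits": ";".join(f"{p}{a}>{b}" for p, a, b in m.edits),
        })
    return pd.DataFrame(rows)


def write_member_fasta(members: list[LibraryMember], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(m.sequence), id=m.member_id, description="")
               for m in members]
    seqio_write(records, str(path), "fasta")
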