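"""tRNA gene records and the cloverleaf secondary-structure model.

A tRNA gene is represented by its genomic context (BED6 coordinates on a
genome FASTA) together with the transcribed body sequence and a dot-bracket
secondary structure.  :func:`build_cloverleaf` converts the dot-bracket into
an explicit cloverleaf: the four helices (acceptor, D, anticodon, T stems) in
5'→3' order, the loops between them, the anticodon triplet and the
anticodon-loop flanking positions (Sprinzl 32/33/37/38), and the outer three
T-stem pairs (Sprinzl 49–65, 50–64, 51–63) that the elongation-factor
interaction libraries mutate.

All indices are 0-based into ``body_seq``; Sprinzl numbers are labels
derived from helix order, not from alignment to a reference tRNA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from pyfaidx import Fasta

from .errors import InputError, StructureError
from .sequence import is_complementary, revcomp, validate_dna

logger = logging.getLogger(__name__)

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


@dataclass
class TRNAGeneRecord:
    """A tRNA gene: genomic locus plus transcribed body sequence.

    ``body_seq`` is always given in the transcriptional sense (coding
    strand, 5'→3' of the tRNA); minus-strand genes are reverse-complemented
    at parse time.  Coordinates are BED-style 0-based half-open.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    body_seq: str
    structure: str = ""
    isotype: str = ""
    anticodon_dna: str = ""

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise InputError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.end - self.start != len(self.body_seq):
            raise InputError(
                f"{self.gene_id}: genomic span {self.end - self.start} != "
                f"body length {len(self.body_seq)}"
            )
        self.body_seq = validate_dna(self.body_seq, what=f"{self.gene_id} body_seq")
        if self.structure and len(self.structure) != len(self.body_seq):
            raise InputError(
                f"{self.gene_id}: structure length {len(self.structure)} != "
                f"body length {len(self.body_seq)}"
            )


@dataclass
class Cloverleaf:
    """Explicit cloverleaf decomposition of a tRNA body.

    Stems are lists of paired index tuples ``(i, j)`` with ``i < j``,
    outermost pair first.  Loops are lists of unpaired indices.  ``tail``
    holds any 3' positions outside the acceptor stem (discriminator base and,
    for mature-form inputs, the NCCA end).  ``linkers`` holds the remaining
    unpaired single-stranded connectors (Sprinzl 8/9 region, position 26).
    """

    acceptor_stem: list[tuple[int, int]]
    d_stem: list[tuple[int, int]]
    ac_stem: list[tuple[int, int]]
    t_stem: list[tuple[int, int]]
    d_loop: list[int]
    ac_loop: list[int]
    variable_loop: list[int]
    t_loop: list[int]
    anticodon: list[int]
    ac_loop_flank: list[int]
    tstem_pairs_49_51: list[tuple[int, int]]
    tail: list[int] = field(default_factory=list)
    linkers: list[int] = field(default_factory=list)
    wobble_pairs: list[tuple[int, int]] = field(default_factory=list)
    mismatch_pairs: list[tuple[int, int]] = field(default_factory=list)

    @property
    def stems(self) -> dict[str, list[tuple[int, int]]]:
        return {
            "acceptor": self.acceptor_stem,
            "d": self.d_stem,
            "ac": self.ac_stem,
            "t": self.t_stem,
        }

    def all_pairs(self) -> list[tuple[int, int]]:
        return self.acceptor_stem + self.d_stem + self.ac_stem + self.t_stem

    def covered_indices(self) -> set[int]:
        idx: set[int] = set()
        for i, j in self.all_pairs():
            idx.update((i, j))
        for rng in (self.d_loop, self.ac_loop, self.variable_loop, self.t_loop,
                    self.tail, self.linkers):
            idx.update(rng)
        return idx


def match_brackets(structure: str) -> list[tuple[int, int]]:
    """Stack-based bracket matcher; pairs sorted by opening index.

    Raises :class:`StructureError` on unbalanced brackets or characters
    outside ``(.)``.
    """
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for idx, ch in enumerate(structure):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {idx}")
            pairs.append((stack.pop(), idx))
        elif ch != ".":
            raise StructureError(f"invalid character {ch!r} at position {idx}")
    if stack:
        raise StructureError(f"unbalanced '(' at position {stack[-1]}")
    return sorted(pairs)


def _helices(pairs: list[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    """Group sorted pairs into maximal stacked runs (i+1, j-1 continuation)."""
    helices: list[list[tuple[int, int]]] = []
    for pair in pairs:
        if helices:
            li, lj = helices[-1][-1]
            if pair == (li + 1, lj - 1):
                helices[-1].append(pair)
                continue
        helices.append([pair])
    return helices


def build_cloverleaf(rec: TRNAGeneRecord | None = None, *,
                     body: str | None = None,
                     structure: str | None = None) -> Cloverleaf:
    """Decompose a dot-bracket tRNA structure into a :class:`Cloverleaf`.

    Accepts either a :class:`TRNAGeneRecord` (using its ``body_seq`` and
    ``structure``) or explicit ``body``/``structure`` keywords.  The
    structure must contain exactly four helices in cloverleaf order with the
    acceptor helix enclosing the other three, and a 7-nt anticodon loop.
    Deterministic and idempotent: the result depends only on the inputs.
    """
    if rec is not None:
        body = rec.body_seq
        structure = rec.structure
    if body is None or structure is None:
        raise InputError("build_cloverleaf needs a record or body+structure")
    if len(body) != len(structure):
        raise StructureError("body and structure lengths differ")

    pairs = match_brackets(structure)
    helices = _helices(pairs)
    if len(helices) != 4:
        raise StructureError(
            f"expected 4 helices (acceptor, D, anticodon, T), found {len(helices)}"
        )
    acc, d, ac, t = helices
    inner_i, inner_j = acc[-1]
    for helix in (d, ac, t):
        for i, j in helix:
            if not (inner_i < i and j < inner_j):
                raise StructureError(
                    "acceptor helix does not enclose the inner helices; "
                    "not a cloverleaf"
                )

    def hairpin_loop(helix: list[tuple[int, int]]) -> list[int]:
        i, j = helix[-1]
        return list(range(i + 1, j))

    d_loop = hairpin_loop(d)
    ac_loop = hairpin_loop(ac)
    t_loop = hairpin_loop(t)
    if len(ac_loop) != 7:
        raise StructureError(
            f"anticodon loop must have exactly 7 positions, found {len(ac_loop)}"
        )
    for name, loop in (("D", d_loop), ("anticodon", ac_loop), ("T", t_loop)):
        if any(structure[k] != "." for k in loop):
            raise StructureError(f"{name}-loop region contains paired positions")

    variable_loop = list(range(ac[0][1] + 1, t[0][0]))
    linkers = list(range(acc[-1][0] + 1, d[0][0])) + \
        list(range(d[0][1] + 1, ac[0][0])) + \
        list(range(t[0][1] + 1, acc[-1][1]))
    tail = list(range(acc[0][1] + 1, len(body)))
    leader = list(range(0, acc[0][0]))
    if leader:
        # 5' positions before the acceptor stem are not part of a tRNA gene
        # body; treat as a structure problem rather than silently absorbing.
        raise StructureError("unpaired positions precede the acceptor stem")

    anticodon = ac_loop[2:5]
    ac_loop_flank = [ac_loop[0], ac_loop[1], ac_loop[5], ac_loop[6]]
    tstem_pairs = t[:3]

    wobble: list[tuple[int, int]] = []
    mismatch: list[tuple[int, int]] = []
    for i, j in pairs:
        if is_complementary(body[i], body[j]):
            continue
        if is_complementary(body[i], body[j], allow_wobble=True):
            wobble.append((i, j))
        else:
            mismatch.append((i, j))
    if wobble:
        logger.info("wobble (G.T) pairs in stems at %s", wobble)
    if mismatch:
        logger.warning("non-complementary stem pairs at %s", mismatch)

    return Cloverleaf(
        acceptor_stem=acc, d_stem=d, ac_stem=ac, t_stem=t,
        d_loop=d_loop, ac_loop=ac_loop, variable_loop=variable_loop,
        t_loop=t_loop, anticodon=anticodon, ac_loop_flank=ac_loop_flank,
        tstem_pairs_49_51=tstem_pairs, tail=tail, linkers=linkers,
        wobble_pairs=wobble, mismatch_pairs=mismatch,
    )


def read_structures_table(path: str | Path) -> dict[str, str]:
    """Read a TSV of (gene_id, dot-bracket) into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["gene_id", "structure"], dtype=str)
    return dict(zip(df["gene_id"], df["structure"]))


def _infer_identity(name: str) -> tuple[str, str]:
    """Pull isotype and anticodon out of a GtRNAdb-style gene name.

    Names look like ``tRNA-Arg-TCT-3-1`` (optionally with an ``→UCA`` edit
    suffix on the anticodon field).  Returns ("", "") when the name does not
    follow the convention.
    """
    parts = name.split("-")
    if len(parts) >= 3 and parts[0].lower() == "trna":
        isotype = parts[1]
        anticodon = parts[2].split("→")[0].split(">")[0].upper()
        if len(anticodon) == 3 and set(anticodon) <= set("ACGT"):
            return isotype, anticodon
    return "", ""


def parse_trna_genes(bed: str | Path, genome: str | Path,
                     structures: str | Path | dict[str, str] | None = None,
                     ) -> list[TRNAGeneRecord]:
    """Load tRNA gene records from a BED6 file and a genome FASTA.

    ``body_seq`` is the genomic substring, reverse-complemented for minus
    strand genes.  Input order is preserved; duplicate gene names are
    rejected.  ``structures`` may be a TSV path or a mapping gene_id →
    dot-bracket; genes without an entry get an empty structure.
    """
    fasta = Fasta(str(genome), as_raw=True, sequence_always_upper=True)
    bed_df = pd.read_csv(
        bed, sep="\t", header=None, comment="#",
        names=BED6_COLUMNS, dtype={"chrom": str, "name": str, "strand": str},
    )
    if isinstance(structures, (str, Path)):
        structures = read_structures_table(structures)
    structures = structures or {}

    records: list[TRNAGeneRecord] = []
    seen: set[str] = set()
    for row in bed_df.itertuples(index=False):
        if row.name in seen:
            raise InputError(f"duplicate gene_id {row.name!r} in BED input")
        seen.add(row.name)
        if row.chrom not in fasta:
            raise InputError(f"{row.name}: chromosome {row.chrom!r} missing "
                             "from genome FASTA")
        chrom_len = len(fasta[row.chrom])
        start, end = int(row.start), int(row.end)
        if not (0 <= start < end <= chrom_len):
            raise InputError(
                f"{row.name}: interval [{start}, {end}) out of range for "
                f"{row.chrom} (length {chrom_len})"
            )
        seq = str(fasta[row.chrom][start:end])
        if row.strand == "-":
            seq = revcomp(seq)
        structure = structures.get(row.name, "")
        isotype, anticodon = _infer_identity(row.name)
        rec = TRNAGeneRecord(
            gene_id=row.name, chrom=row.chrom, start=start, end=end,
            strand=str(row.strand), body_seq=seq, structure=structure,
            isotype=isotype, anticodon_dna=anticodon,
        )
        if not anticodon and structure:
            cl = build_cloverleaf(rec)
            rec.anticodon_dna = "".join(seq[k] for k in cl.anticodon)
        records.append(rec)
    return records
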