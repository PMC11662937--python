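"""Cassette library design: saturation, sticky-stem, t-stem, oligos."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acetrna import library_design as ld
from acetrna import synthetic_data as sd
from acetrna.errors import DesignError, InputError
from acetrna.sequence import revcomp
from acetrna.trna_model import build_cloverleaf

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


@pytest.fixture()
def arg_trna():
    body, structure = sd.make_canonical_trna(np.random.default_rng(3),
                                             anticodon="TCT")
    return body, build_cloverleaf(body=body, structure=structure)


class TestEditAnticodon:
    @pytest.mark.parametrize("stop,expected", [
        ("TGA", "TCA"), ("TAG", "CTA"), ("TAA", "TTA"),
    ])
    def test_stop_to_anticodon(self, arg_trna, stop, expected):
        body, cl = arg_trna
        edited = ld.edit_anticodon(cl, body, stop)
        assert "".join(edited[i] for i in cl.anticodon) == expected
        # everything else untouched
        untouched = [k for k in range(len(body)) if k not in cl.anticodon]
        assert all(edited[k] == body[k] for k in untouched)

    def test_idempotent(self, arg_trna):
        body, cl = arg_trna
        once = ld.edit_anticodon(cl, body, "TGA")
        assert ld.edit_anticodon(cl, once, "TGA") == once

    def test_non_stop_rejected(self, arg_trna):
        body, cl = arg_trna
        with pytest.raises(InputError):
            ld.edit_anticodon(cl, body, "TGG")


class TestExtractFlanks:
    def test_duplicates_collapse(self, sim_gene_records, sim_genome_files,
                                 sim_cfg):
        paths, genome = sim_genome_files
        flanks = ld.extract_flanks(sim_gene_records, str(paths["fasta"]), 5,
                                   sim_cfg.uce5_length)
        assert len(flanks) == genome.truth["expected_unique_flank5"]
        assert len({f.sequence for f in flanks}) == len(flanks)

    def test_provenance_is_first_occurrence(self, sim_gene_records,
                                            sim_genome_files, sim_cfg):
        paths, genome = sim_genome_files
        flanks = ld.extract_flanks(sim_gene_records, str(paths["fasta"]), 5,
                                   sim_cfg.uce5_length)
        # the planted duplicate flank is attributed to the first gene
        assert flanks[0].gene_id == sim_gene_records[0].gene_id

    def test_flanks_match_truth_and_locus(self, sim_gene_records,
                                          sim_genome_files, sim_cfg):
        paths, genome = sim_genome_files
        for side, length, key in [(5, sim_cfg.uce5_length, "flank5"),
                                  (3, sim_cfg.trailer_length, "flank3")]:
            flanks = ld.extract_flanks(sim_gene_records, str(paths["fasta"]),
                                       side, length)
            by_gene = {g["gene_id"]: g for g in genome.truth["genes"]}
            for f in flanks:
                assert f.sequence == by_gene[f.gene_id][key]
                window = genome.chromosomes[f.chrom][f.start:f.end]
                expected = window if f.strand == "+" else revcomp(window)
                assert f.sequence == expected

    def test_minus_strand_convention(self, tmp_path):
        from conftest import write_fasta
        from acetrna.trna_model import TRNAGeneRecord

        chrom = "A" * 10 + "CGTACGTACG" + "TTTTGGGCCC"
        fasta = write_fasta(tmp_path / "g.fa", {"chr1": chrom})
        rec = TRNAGeneRecord(gene_id="g", chrom="chr1", start=10, end=20,
                             strand="-", body_seq=revcomp(chrom[10:20]))
        (flank,) = ld.extract_flanks([rec], str(fasta), 5, 6)
        assert flank.sequence == revcomp(chrom[20:26])

    def test_edge_genes_skipped(self, tmp_path):
        from conftest import write_fasta
        from acetrna.trna_model import TRNAGeneRecord

        fasta = write_fasta(tmp_path / "g.fa", {"chr1": "ACGTACGTAC"})
        rec = TRNAGeneRecord(gene_id="g", chrom="chr1", start=2, end=6,
                             strand="+", body_seq="GTAC")
        assert ld.extract_flanks([rec], str(fasta), 5, 5) == []


class TestEnumerateSaturation:
    @pytest.mark.parametrize("k,expected", [(0, 1), (1, 4), (2, 16), (4, 256)])
    def test_size_is_4_to_k(self, k, expected):
        template = "ACGTACGTAC"
        members = ld.enumerate_saturation(template, list(range(k)))
        assert len(members) == expected

    def test_matches_brute_force_nested_loops(self):
        template = "AATTCC"
        positions = [1, 4]
        members = ld.enumerate_saturation(template, positions)
        expected = []
        for a in "ACGT":
            for b in "ACGT":
                s = list(template)
                s[1], s[4] = a, b
                expected.append("".join(s))
        assert [m.sequence for m in members] == expected

    def test_original_labeled(self):
        members = ld.enumerate_saturation("ACGT", [0, 1])
        originals = [m for m in members if m.label == "original"]
        assert len(originals) == 1
        assert originals[0].sequence == "ACGT"

    def test_duplicate_positions_rejected(self):
        with pytest.raises(InputError):
            ld.enumerate_saturation("ACGT", [1, 1])

    def test_members_reconstruct_from_edits(self):
        template = "ACGTACGT"
        for m in ld.enumerate_saturation(template, [0, 3, 7]):
            assert ld.apply_edits(template, m.edits) == m.sequence


class TestStickyStem:
    def make_family(self, arg_trna, site_specs):
        """Family copies of the target with C-G/G-C planted at given pairs."""
        body, cl = arg_trna
        stems = cl.stems
        family = []
        for spec in site_specs:
            fam = list(body)
            for (stem, k, pair) in spec:
                i, j = stems[stem][k]
                fam[i], fam[j] = pair
            family.append(("".join(fam), cl))
        return family

    def test_hand_constructed_sites(self, arg_trna):
        body, cl = arg_trna
        # ensure the chosen target pairs are A-T so C-G qualifies
        tweaked = list(body)
        for stem, k in [("acceptor", 1), ("d", 0), ("t", 2)]:
            i, j = cl.stems[stem][k]
            tweaked[i], tweaked[j] = "A", "T"
        body = "".join(tweaked)
        family = self.make_family((body, cl), [
            [("acceptor", 1, ("C", "G"))],
            [("d", 0, ("G", "C"))],
            [("t", 2, ("C", "G"))],
        ])
        sites, members = ld.design_sticky_stem_library(body, cl, family)
        assert {(s.stem, s.pair_index) for s in sites} == {
            ("acceptor", 1), ("d", 0), ("t", 2)}
        assert len(members) == 8
        for mask, m in enumerate(members):
            expected_positions = set()
            for bit, site in enumerate(sites):
                if mask >> bit & 1:
                    expected_positions.update(site.positions)
            assert {p for p, _, _ in m.edits} == expected_positions
            assert ld.apply_edits(body, m.edits) == m.sequence

    def test_identical_family_gives_single_member(self, arg_trna):
        body, cl = arg_trna
        sites, members = ld.design_sticky_stem_library(
            body, cl, [(body, cl), (body, cl)])
        assert sites == []
        assert len(members) == 1
        assert members[0].label == "original"

    def test_tie_breaks_by_family_order(self, arg_trna):
        body, cl = arg_trna
        i, j = cl.stems["acceptor"][0]
        tweaked = list(body)
        tweaked[i], tweaked[j] = "A", "T"
        body = "".join(tweaked)
        family = self.make_family((body, cl), [
            [("acceptor", 0, ("G", "C"))],
            [("acceptor", 0, ("C", "G"))],
        ])
        sites, _ = ld.design_sticky_stem_library(body, cl, family)
        site = next(s for s in sites if (s.stem, s.pair_index) == ("acceptor", 0))
        assert site.library_pair == ("G", "C")
        assert site.source_member == 0


class TestTStemLibrary:
    def test_variant_substitutes_both_strands(self, arg_trna):
        body, cl = arg_trna
        # make the parent differ from TS-9 at all three outer pairs
        tweaked = list(body)
        for (i, j) in cl.tstem_pairs_49_51:
            tweaked[i], tweaked[j] = "A", "T"
        body = "".join(tweaked)
        ts9 = ld.TStemVariant(name="TS-9", pairs={
            49: ("C", "G"), 50: ("C", "G"), 51: ("G", "C")})
        (member,) = ld.design_tstem_library(body, cl, [ts9])
        diff = [k for k, (a, b) in enumerate(zip(body, member.sequence))
                if a != b]
        assert len(diff) == 6
        assert set(diff) == {k for pair in cl.tstem_pairs_49_51 for k in pair}

    def test_variant_equal_to_parent_is_original(self, arg_trna):
        body, cl = arg_trna
        pairs = {49 + k: (body[i], body[j])
                 for k, (i, j) in enumerate(cl.tstem_pairs_49_51)}
        (member,) = ld.design_tstem_library(
            body, cl, [ld.TStemVariant(name="parent", pairs=pairs)])
        assert member.sequence == body
        assert member.label == "original"

    def test_28_variants_in_28_members_out(self, arg_trna):
        body, cl = arg_trna
        wc = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
        variants = []
        combos = list(product(range(4), repeat=3))[:28]
        for n, (a, b, c) in enumerate(combos):
            variants.append(ld.TStemVariant(
                name=f"TS-{n + 1}",
                pairs={49: wc[a], 50: wc[b], 51: wc[c]}))
        members = ld.design_tstem_library(body, cl, variants)
        assert len(members) == 28
        assert [m.member_id for m in members] == [v.name for v in variants]

    def test_non_complementary_pair_rejected(self, arg_trna):
        body, cl = arg_trna
        bad = ld.TStemVariant(name="bad", pairs={49: ("A", "G")})
        with pytest.raises(InputError, match="not complementary"):
            ld.design_tstem_library(body, cl, [bad])


class TestGoldenGate:
    def test_construction_round_trip(self):
        oligos = ld.make_golden_gate_oligos("ACGT", "AATT", "GGCC")
        assert ld.simulate_assembly(oligos) == "AATTACGTGGCC"

    def test_ambiguous_overhangs_rejected(self):
        with pytest.raises(DesignError):
            ld.make_golden_gate_oligos("ACGT", "AATT", "AATT")
        with pytest.raises(DesignError):
            # palindrome-related: oh5 equals revcomp(oh3)
            ld.make_golden_gate_oligos("ACGT", "GATC", "GATC")

    @settings(max_examples=100, derandomize=True)
    @given(insert=st.text(alphabet="ACGT", min_size=10, max_size=60))
    def test_assembly_round_trip_property(self, insert):
        oh5, oh3 = "CACC", "TGGA"
        oligos = ld.make_golden_gate_oligos(insert, oh5, oh3)
        assert ld.simulate_assembly(oligos) == oh5 + insert + oh3


class TestTerminatorCheck:
    def test_internal_poly_t_warned(self):
        cassette = ld.ExpressionCassette(uce5="ACGT", body="GGTTTTGG",
                                         trailer3="GACCTTTTTTT")
        warnings = ld.check_internal_terminator(cassette)
        assert len(warnings) == 1
        assert warnings[0].position == 6
        assert warnings[0].run_length == 4

    def test_clean_cassette_passes(self):
        cassette = ld.ExpressionCassette(uce5="ACGTACGT", body="GGCCGGCC",
                                         trailer3="GACCTTTTTTT")
        warnings = ld.check_internal_terminator(cassette)
        assert warnings == []

    def test_terminator_located_by_scan(self):
        trailer = "GACCTTTTTTT"
        cassette = ld.ExpressionCassette(uce5="AC", body="GGCC",
                                         trailer3=trailer)
        # oracle: first index of 'TTTT' within the trailer
        expected = trailer.index("TTTT")
        from acetrna.sequence import homopolymer_runs
        runs = homopolymer_runs(trailer, "T", 4)
        assert runs[0][0] == expected
        assert ld.check_internal_terminator(cassette) == []

    def test_missing_terminator_is_hard_error(self):
        cassette = ld.ExpressionCassette(uce5="AC", body="GG",
                                         trailer3="GACCTTTA")
        with pytest.raises(DesignError, match="terminator"):
            ld.check_internal_terminator(cassette)


@settings(max_examples=50, derandomize=True)
@given(template=st.text(alphabet="ACGT", min_size=6, max_size=30),
       data=st.data())
def test_library_members_reconstruct_from_edits(template, data):
    """Parent + recorded edits reproduces every member (fuzzed)."""
    k = data.draw(st.integers(min_value=0, max_value=3))
    positions = data.draw(st.lists(
        st.integers(min_value=0, max_value=len(template) - 1),
        min_size=k, max_size=k, unique=True))
    members = ld.enumerate_saturation(template, positions)
    assert len(members) == 4 ** k
    for m in members:
        assert ld.apply_edits(template, m.edits) == m.sequence
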