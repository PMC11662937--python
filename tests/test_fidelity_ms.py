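"""In-silico tryptic digestion and ionization-weighted incorporation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acetrna import fidelity_ms as fm
from acetrna import synthetic_data as sd
from acetrna.errors import InputError

protein_strategy = st.text(alphabet=fm.AMINO_ACIDS, min_size=5, max_size=50)

#: independent monoisotopic residue masses (Da), frozen from standard tables
RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
WATER = 18.010565


def digest_oracle(protein, max_missed):
    """Brute-force digest: every substring with valid tryptic boundaries."""
    sites = set(fm.cleavage_sites(protein))
    bounds = {0, len(protein)} | sites
    out = set()
    for a in range(len(protein)):
        for b in range(a + 1, len(protein) + 1):
            if a not in bounds or b not in bounds:
                continue
            internal = [s for s in sites if a < s < b]
            if len(internal) <= max_missed:
                out.add((protein[a:b], a, len(internal)))
    return out


class TestTrypticDigest:
    def test_hand_case(self):
        peptides = fm.tryptic_digest("MKAGRSTP", max_missed=0)
        assert [p.sequence for p in peptides] == ["MK", "AGR", "STP"]

    def test_kp_suppression(self):
        peptides = fm.tryptic_digest("AKPR", max_missed=0)
        assert [p.sequence for p in peptides] == ["AKPR"]

    def test_missed_cleavage_enumeration(self):
        peptides = fm.tryptic_digest("AKCKDK", max_missed=2)
        got = {(p.sequence, p.start, p.missed_cleavages) for p in peptides}
        assert got == digest_oracle("AKCKDK", 2)

    def test_deterministic_order(self):
        peptides = fm.tryptic_digest("AKCKDKE", max_missed=2)
        keys = [(p.start, p.missed_cleavages) for p in peptides]
        assert keys == sorted(keys)

    @settings(max_examples=60, derandomize=True)
    @given(protein=protein_strategy,
           max_missed=st.integers(min_value=0, max_value=2))
    def test_matches_brute_force_oracle(self, protein, max_missed):
        got = {(p.sequence, p.start, p.missed_cleavages)
               for p in fm.tryptic_digest(protein, max_missed=max_missed)}
        assert got == digest_oracle(protein, max_missed)

    def test_invalid_residue_rejected(self):
        with pytest.raises(InputError):
            fm.tryptic_digest("ACGU1")


class TestInclusionList:
    fixture_protein = ("MSKGEELFTGVVPILVELDGDVNGHKFSVRGEGEGDATNGKLTLKFIC"
                       "TTGKLPVPWPTLVTTLSYGVQCFAR")

    def test_twenty_distinct_peptides(self):
        records = fm.variant_inclusion_list(self.fixture_protein, 30)
        assert len(records) == 20
        assert len({r.sequence for r in records}) == 20

    def test_kr_variants_need_missed_cleavage(self):
        records = {r.variant_aa: r
                   for r in fm.variant_inclusion_list(self.fixture_protein, 35)}
        for aa in "KR":
            assert records[aa].missed_cleavages >= 1
        # a non-K/R substitution in the same context digests cleanly
        assert records["A"].missed_cleavages == 0

    def test_every_peptide_spans_the_site(self):
        site = 30
        for r in fm.variant_inclusion_list(self.fixture_protein, site):
            assert r.start < site <= r.start + len(r.sequence)
            assert r.sequence[site - 1 - r.start] == r.variant_aa

    def test_masses_match_residue_table(self):
        """Monoisotopic masses agree with an independent residue-mass sum."""
        for r in fm.variant_inclusion_list(self.fixture_protein, 30):
            expected = (sum(RESIDUE_MASS[a] for a in r.sequence) + WATER
                        + 57.02146 * r.sequence.count("C"))
            assert r.mono_mass == pytest.approx(expected, abs=1e-4)
            for z, mz in r.mz.items():
                assert mz == pytest.approx(
                    (expected + z * fm.PROTON) / z, abs=1e-4)

    def test_oxidation_expands_mz(self):
        records = {r.variant_aa: r
                   for r in fm.variant_inclusion_list(self.fixture_protein, 30)}
        met = records["M"]
        assert 1 in met.mz_oxidized
        assert met.mz_oxidized[1][2] == pytest.approx(
            met.mz[2] + fm.MET_OXIDATION / 2, abs=1e-6)

    def test_site_out_of_range_rejected(self):
        with pytest.raises(InputError):
            fm.variant_inclusion_list("ACDK", 9)


class TestIonizationWeighting:
    def test_uniform_control_gives_unit_weights(self):
        weights = fm.ionization_weights({"A": 5.0, "R": 5.0, "G": 5.0})
        assert np.allclose(weights, 1.0)

    def test_reweighted_control_is_uniform(self):
        control = {"A": 2.0, "R": 1.0}
        weights = fm.ionization_weights(control)
        assert weights["A"] == pytest.approx(0.75)
        assert weights["R"] == pytest.approx(1.5)
        reweighted = pd.Series(control) * weights
        assert reweighted.nunique() == 1

    def test_recovers_reciprocal_factors_up_to_scale(self):
        control, _, truth = sd.sim_ms(sd.SimConfig(seed=8, ms_cv=0.0))
        weights = fm.ionization_weights(control)
        factors = pd.Series(truth["ionization_factors"])
        product = (weights * factors).loc[weights.index]
        assert product.std() / product.mean() < 1e-9

    def test_zero_control_excluded(self):
        weights = fm.ionization_weights({"A": 1.0, "R": 0.0})
        assert "R" not in weights.index


class TestPercentIncorporation:
    def test_single_residue_is_100(self):
        table = fm.percent_incorporation({"R": 3.0}, {"R": 1.0})
        assert table.loc["R", "percent"] == pytest.approx(100.0)

    def test_uniform_weights_equal_plain_normalization(self):
        sample = {"A": 1.0, "R": 3.0}
        table = fm.percent_incorporation(sample, {"A": 1.0, "R": 1.0})
        assert table.loc["R", "percent"] == pytest.approx(75.0)

    def test_percentages_sum_to_100(self):
        control, sample, _ = sd.sim_ms(sd.SimConfig(seed=9))
        table = fm.percent_incorporation(sample,
                                         fm.ionization_weights(control))
        assert table["percent"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_high_fidelity_truth_recovered(self):
        cfg = sd.SimConfig(seed=10, cognate_fraction=0.999, ms_cv=0.0)
        control, sample, truth = sd.sim_ms(cfg)
        table = fm.percent_incorporation(sample,
                                         fm.ionization_weights(control))
        assert table.loc[truth["cognate_aa"], "percent"] == pytest.approx(
            99.9, abs=1e-9)

    def test_invariant_to_ionization_rescaling(self):
        """Scaling one residue's true ionization efficiency changes nothing."""
        cfg = sd.SimConfig(seed=12, ms_cv=0.0)
        control, sample, truth = sd.sim_ms(cfg)
        base = fm.percent_incorporation(sample,
                                        fm.ionization_weights(control))
        for c in (0.1, 7.0):
            control2, sample2 = control.copy(), sample.copy()
            control2["W"] *= c
            sample2["W"] *= c
            table = fm.percent_incorporation(
                sample2, fm.ionization_weights(control2))
            pd.testing.assert_series_equal(table["percent"], base["percent"],
                                           rtol=1e-9)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(InputError):
            fm.percent_incorporation({"A": 0.0}, {"A": 1.0})
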