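"""Digestion, mass and motif machinery against independent oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hylquant.peptide_core import (
    MONOISOTOPIC_RESIDUE_MASS,
    OXYGEN_MONO,
    Modification,
    MotifMatrix,
    PeptideSpecies,
    ProteinChain,
    digest,
    fragment_ions,
    motif_matrix,
    peptide_mass,
    ppm_delta,
    read_fasta_chains,
    scan_motifs,
)

chains_st = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=50)


def brute_force_digest(sequence: str, max_mc: int):
    """Enumerate cleavage sites by the K/R-not-before-P rule, then emit all
    contiguous joins of up to max_mc+1 consecutive base peptides."""
    cuts = [i + 1 for i in range(len(sequence) - 1)
            if sequence[i] in "KR" and sequence[i + 1] != "P"]
    bounds = [0] + cuts + [len(sequence)]
    base = [sequence[a:b] for a, b in zip(bounds, bounds[1:])]
    out = set()
    for k in range(max_mc + 1):
        for i in range(len(base) - k):
            out.add(("".join(base[i : i + k + 1]), k))
    return out


class TestDigest:
    def test_hotspot_example(self):
        chain = ProteinChain("t", "LTVLSSASTKGPSVFPLAPSSK")
        peps = digest(chain, max_missed_cleavages=1)
        by_mc = {}
        for p in peps:
            by_mc.setdefault(p.missed_cleavages, set()).add(p.sequence)
        assert by_mc[0] == {"LTVLSSASTK", "GPSVFPLAPSSK"}
        assert by_mc[1] == {"LTVLSSASTKGPSVFPLAPSSK"}

    @pytest.mark.parametrize(
        "sequence,max_mc,expected",
        [
            ("AAA", 1, {("AAA", 0)}),
            ("AKPGR", 0, {("AKPGR", 0)}),  # K before P is not cleaved
            ("AKGR", 0, {("AK", 0), ("GR", 0)}),
        ],
    )
    def test_small_cases(self, sequence, max_mc, expected):
        peps = digest(ProteinChain("t", sequence), max_mc)
        assert {(p.sequence, p.missed_cleavages) for p in peps} == expected

    @given(chains_st, st.integers(min_value=0, max_value=2))
    def test_equals_brute_force_enumeration(self, sequence, max_mc):
        peps = digest(ProteinChain("t", sequence), max_mc)
        got = {(p.sequence, p.missed_cleavages) for p in peps}
        # positions disambiguate duplicates; compare the multiset of spans
        assert got == brute_force_digest(sequence, max_mc)
        assert all(p.missed_cleavages <= max_mc for p in peps)

    @given(chains_st)
    def test_zero_mc_peptides_reconstruct_chain(self, sequence):
        peps = [p for p in digest(ProteinChain("t", sequence), 0)]
        peps.sort(key=lambda p: p.start)
        assert "".join(p.sequence for p in peps) == sequence

    def test_agrees_with_pyteomics_cleave(self):
        parser = pytest.importorskip("pyteomics.parser")
        for seq in ["LTVLSSASTKGPSVFPLAPSSK", "AKPGRKKMNRPSTW", "DSTYSLSSTLTLSK"]:
            ours = {p.sequence for p in digest(ProteinChain("t", seq), 1)}
            ref = parser.cleave(seq, parser.expasy_rules["trypsin"],
                                missed_cleavages=1)
            assert ours == set(ref)

    def test_modified_k_spanning_species_emitted_even_at_zero_mc(self):
        chain = ProteinChain("t", "LTVLSSASTKGPSVFPLAPSSK")
        mod = Modification(site=10)
        peps = digest(chain, max_missed_cleavages=0, mods=[mod])
        long = [p for p in peps if p.sequence == "LTVLSSASTKGPSVFPLAPSSK"]
        assert len(long) == 1
        assert long[0].missed_cleavages == 1  # counting stays sequence-based
        assert mod in long[0].mods

    def test_mod_attached_to_all_spanning_species(self):
        chain = ProteinChain("t", "AAKGGKTT")
        mod = Modification(site=3)
        peps = digest(chain, 1, mods=[mod])
        for p in peps:
            assert (mod in p.mods) == (p.start <= 3 <= p.end)

    def test_x_is_not_a_cleavage_site_but_digestible(self):
        peps = digest(ProteinChain("t", "AXKXR"), 0)
        assert {p.sequence for p in peps} == {"AXK", "XR"}

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            ProteinChain("t", "")


class TestMasses:
    def test_hydroxylysine_residue_mass(self):
        assert round(MONOISOTOPIC_RESIDUE_MASS["K"] + OXYGEN_MONO, 4) == 144.0899

    @pytest.mark.parametrize(
        "seq,expected,dp",
        [("K", 146.10553, 5), ("LTVLSSASTK", 1005.5706, 4)],
    )
    def test_known_peptide_masses(self, seq, expected, dp):
        assert round(peptide_mass(seq), dp) == expected

    def test_against_pyteomics_oracle(self):
        mass = pytest.importorskip("pyteomics.mass")
        for seq in ["LTVLSSASTK", "GPSVFPLAPSSK", "ACDEFGHIKLMNPQRSTVWY"]:
            assert peptide_mass(seq) == pytest.approx(
                mass.calculate_mass(sequence=seq), abs=1e-3
            )

    def test_mod_shifts_mass_by_exact_delta(self):
        mod = Modification(site=10)
        assert peptide_mass("LTVLSSASTK", [mod]) - peptide_mass(
            "LTVLSSASTK"
        ) == pytest.approx(mod.delta_mass, abs=1e-9)

    def test_x_rejected(self):
        with pytest.raises(ValueError):
            peptide_mass("AXK")


class TestFragments:
    def test_y1_of_hotspot_peptide(self):
        pep = PeptideSpecies("LTVLSSASTK", 1, 10, 0)
        y = fragment_ions(pep, "y")
        assert round(y[0].mz, 4) == 147.1128

    def test_y1_shift_under_modification(self):
        pep = PeptideSpecies("LTVLSSASTK", 1, 10, 0)
        mod = PeptideSpecies("LTVLSSASTK", 1, 10, 0,
                             frozenset({Modification(site=10)}))
        shift = fragment_ions(mod, "y")[0].mz - fragment_ions(pep, "y")[0].mz
        assert round(shift, 3) == 15.995
        assert fragment_ions(mod, "y")[0].carries_mod

    def test_y13_minus_y12_is_hydroxylysine_residue(self):
        pep = PeptideSpecies(
            "LTVLSSASTKGPSVFPLAPSSK", 1, 22, 1,
            frozenset({Modification(site=10)}),
        )
        y = fragment_ions(pep, "y")
        assert round(y[12].mz - y[11].mz, 4) == 144.0899

    @given(chains_st.filter(lambda s: len(s) >= 2))
    def test_y_series_telescopes_by_residue_masses(self, seq):
        pep = PeptideSpecies(seq, 1, len(seq), 0)
        y = fragment_ions(pep, "y")
        for n in range(1, len(y)):
            residue = seq[len(seq) - 1 - n]
            assert y[n].mz - y[n - 1].mz == pytest.approx(
                MONOISOTOPIC_RESIDUE_MASS[residue], abs=1e-6
            )

    def test_invalid_series_rejected(self):
        with pytest.raises(ValueError):
            fragment_ions(PeptideSpecies("AK", 1, 2, 0), "c")


class TestPpm:
    @pytest.mark.parametrize(
        "obs,theo,expected",
        [(100.0001, 100.0, 1.0), (100.0, 100.0, 0.0)],
    )
    def test_definition(self, obs, theo, expected):
        assert ppm_delta(obs, theo) == pytest.approx(expected, abs=1e-9)

    def test_residue_difference_deviation(self):
        assert round(ppm_delta(144.08910, 144.08990), 2) == -5.55

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            ppm_delta(100.0, 0.0)


class TestMotifs:
    def test_consensus_hit_in_hotspot_context(self, hotspot_chain):
        hits = scan_motifs(hotspot_chain, ("XKG",))
        assert any(h.position == 350 and h.pattern == "XKG" for h in hits)

    def test_kk_has_no_match(self):
        assert scan_motifs(ProteinChain("t", "KK"), ("XKG", "XKA", "XKS")) == []

    def test_exhaustive_scan(self):
        hits = scan_motifs(ProteinChain("t", "AKGAKAAKS"), ("XKG", "XKA", "XKS"))
        assert [(h.position, h.pattern) for h in hits] == [
            (2, "XKG"), (5, "XKA"), (8, "XKS"),
        ]

    def test_x_at_plus_one_never_matches(self):
        assert scan_motifs(ProteinChain("t", "AKXG"), ("XKG",)) == []

    def test_matrix_counts(self):
        chains = {
            "a": ProteinChain("a", "AAKGA"),
            "b": ProteinChain("b", "TTKGT"),
            "c": ProteinChain("c", "SSKAS"),
        }
        m = motif_matrix([("a", 3), ("b", 3), ("c", 3)], chains)
        assert m.probs[1]["G"] == pytest.approx(2 / 3)
        assert m.probs[1]["A"] == pytest.approx(1 / 3)
        assert m.n_sites == 3

    def test_single_site_probabilities_are_one(self):
        chains = {"a": ProteinChain("a", "AAKGA")}
        m = motif_matrix([("a", 3)], chains)
        for d, dist in m.probs.items():
            assert sum(dist.values()) == pytest.approx(1.0)
            assert all(p == 1.0 for p in dist.values())

    def test_rows_sum_to_one_with_truncated_windows(self):
        chains = {"a": ProteinChain("a", "KG")}  # no -2, -1, +2 flanks
        m = motif_matrix([("a", 1)], chains)
        assert set(m.probs) == {0, 1}
        for dist in m.probs.values():
            assert sum(dist.values()) == pytest.approx(1.0, abs=1e-9)

    def test_converges_to_generating_distribution(self, rng):
        truth = {"G": 0.6, "A": 0.25, "S": 0.15}
        residues = rng.choice(list(truth), size=100, p=list(truth.values()))
        chains = {
            f"c{i}": ProteinChain(f"c{i}", f"TTK{r}T")
            for i, r in enumerate(residues)
        }
        m = motif_matrix([(f"c{i}", 3) for i in range(100)], chains)
        for r, p in truth.items():
            assert abs(m.probs[1].get(r, 0.0) - p) <= 0.05

    def test_empty_site_list_rejected(self):
        with pytest.raises(ValueError):
            motif_matrix([], {})


def test_fasta_roundtrip_with_offset(tmp_path):
    path = tmp_path / "chains.fasta"
    path.write_text(">HC-K offset=326 knob heavy chain\nDSTYSLSSTLTLSKLTVLSSASTK\n")
    chains = read_fasta_chains(path)
    assert chains["HC-K"].numbering_offset == 326
    assert chains["HC-K"].reported_position(24) == 350
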