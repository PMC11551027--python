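"""Pooled-area relative quantification: exactness, invariances, reporting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hylquant.quant import (
    EvidenceRecord,
    evidence_from_frame,
    evidence_to_frame,
    locus_report,
    miscleavage_enrichment,
    quantify_locus,
    reduction,
)
from hylquant.simulate import EvidenceSimConfig, gen_evidence

from conftest import evidence_for_locus, locus_from_areas

fractions = st.floats(min_value=0.01, max_value=0.99)


class TestQuantifyLocus:
    def test_direct_substitution(self):
        ev = evidence_for_locus(k0=600, k1=50, kox0=30, kox1=70)
        lq = quantify_locus(ev, "HC-K", 350)
        assert lq.frac_modified == pytest.approx(100 / 750)
        assert lq.frac_modified_cleaved == pytest.approx(0.04)
        assert lq.frac_modified_miscleaved == pytest.approx(70 / 750)

    def test_species_fractions_sum_to_total(self):
        ev = evidence_for_locus(k0=600, k1=50, kox0=30, kox1=70)
        lq = quantify_locus(ev, "HC-K", 350)
        assert lq.frac_modified_cleaved + lq.frac_modified_miscleaved == (
            pytest.approx(lq.frac_modified, abs=1e-12)
        )

    def test_no_modified_signal_gives_zero(self):
        ev = evidence_for_locus(k0=600, k1=50, kox0=0, kox1=0)
        assert quantify_locus(ev, "HC-K", 350).frac_modified == 0.0

    def test_zero_total_area_undefined(self):
        with pytest.raises(ValueError, match="zero total area"):
            quantify_locus([], "HC-K", 350)

    @given(fractions, fractions, fractions)
    def test_exact_on_noiseless_generator(self, f, p_mc, p_block):
        records, _ = gen_evidence(
            EvidenceSimConfig(site_fractions={350: f}, p_mc=p_mc,
                              p_block=p_block, sigma=0.0)
        )
        lq = quantify_locus(records, "HC-K", 350)
        assert lq.frac_modified == pytest.approx(f, abs=1e-12)

    @given(st.floats(min_value=1e-6, max_value=1e6))
    def test_invariant_to_global_area_rescaling(self, scale):
        base = evidence_for_locus(k0=600, k1=50, kox0=30, kox1=70)
        scaled = [
            EvidenceRecord(
                chain_id=r.chain_id, sequence=r.sequence, start=r.start,
                end=r.end, missed_cleavages=r.missed_cleavages,
                modified=r.modified, mod_site=r.mod_site, area=r.area * scale,
            )
            for r in base
        ]
        a = quantify_locus(base, "HC-K", 350).frac_modified
        b = quantify_locus(scaled, "HC-K", 350).frac_modified
        assert b == pytest.approx(a, rel=1e-12)

    def test_median_estimate_under_lognormal_noise(self):
        f_true = 0.123
        estimates = [
            quantify_locus(
                gen_evidence(
                    EvidenceSimConfig(site_fractions={350: f_true},
                                      sigma=0.3, seed=s)
                )[0],
                "HC-K", 350,
            ).frac_modified
            for s in range(500)
        ]
        assert abs(np.median(estimates) - f_true) < 0.01

    def test_other_site_modification_excluded_from_pools(self):
        ev = evidence_for_locus(k0=100, k1=0, kox0=25, kox1=0)
        # a peptide covering K350 but with the oxidation localized elsewhere
        ev.append(EvidenceRecord(
            chain_id="HC-K", sequence="LTVLSSASTKGPSVFPLAPSSK",
            start=341, end=362, missed_cleavages=1, modified=True,
            mod_site=345, area=1e9,
        ))
        assert quantify_locus(ev, "HC-K", 350).frac_modified == pytest.approx(0.2)

    def test_mc_folding_default_and_strict(self):
        ev = evidence_for_locus(k0=100, k1=0, kox0=0, kox1=0)
        ev.append(EvidenceRecord(
            chain_id="HC-K", sequence="DSTYSLSSTLTLSKLTVLSSASTKGPSVFPLAPSSK",
            start=327, end=362, missed_cleavages=2, modified=True,
            mod_site=350, area=100,
        ))
        assert quantify_locus(ev, "HC-K", 350).frac_modified == pytest.approx(0.5)
        assert quantify_locus(ev, "HC-K", 350,
                              strict_mc=True).frac_modified == 0.0


class TestReduction:
    def test_wildtype_vs_ko_example(self):
        wt = locus_from_areas(k0=80, k1=7.7, kox0=4.9, kox1=7.4)
        ko = locus_from_areas(k0=90, k1=9.1, kox0=0.2, kox1=0.7)
        r = reduction(wt, ko)
        assert r.reduction_pct_rounded == 93

    def test_equal_fractions_give_zero(self):
        wt = locus_from_areas(90, 0, 10, 0)
        ko = locus_from_areas(90, 0, 10, 0)
        assert reduction(wt, ko).reduction_pct == pytest.approx(0.0)

    def test_increase_gives_negative_reduction(self):
        wt = locus_from_areas(90, 0, 10, 0)  # 10%
        ko = locus_from_areas(85, 0, 15, 0)  # 15%
        assert reduction(wt, ko).reduction_pct == pytest.approx(-50.0)

    def test_zero_wildtype_undefined(self):
        wt = locus_from_areas(100, 0, 0, 0)
        ko = locus_from_areas(100, 0, 0, 0)
        with pytest.raises(ValueError, match="undefined"):
            reduction(wt, ko)

    def test_mismatched_loci_rejected(self):
        wt = locus_from_areas(90, 0, 10, 0, site=350)
        ko = locus_from_areas(90, 0, 10, 0, site=125)
        with pytest.raises(ValueError):
            reduction(wt, ko)


class TestEnrichment:
    def test_direct_arithmetic(self):
        ev = evidence_for_locus(k0=600, k1=50, kox0=30, kox1=70)
        f1, f0 = miscleavage_enrichment(ev, "HC-K", 350)
        assert f1 == pytest.approx(70 / 120, abs=5e-4)  # 0.583 at 3 sf
        assert f0 == pytest.approx(30 / 630, abs=5e-5)  # 0.0476 at 3 sf

    def test_missing_species_reported_as_none(self):
        ev = evidence_for_locus(k0=600, k1=0, kox0=30, kox1=0)
        f1, f0 = miscleavage_enrichment(ev, "HC-K", 350)
        assert f1 is None and f0 is not None

    def test_blocking_generator_enriches_miscleaved_species(self):
        records, _ = gen_evidence(
            EvidenceSimConfig(site_fractions={350: 0.1}, p_mc=0.05,
                              p_block=0.6, sigma=0.0)
        )
        f1, f0 = miscleavage_enrichment(records, "HC-K", 350)
        assert f1 > f0


class TestLocusReport:
    def test_species_rows_and_sum(self):
        ev = evidence_for_locus(k0=80, k1=7.7, kox0=4.9, kox1=7.4)
        report = locus_report(ev)
        block = report[report.site == 350]
        vals = dict(zip(block.cleaved, block.pct))
        assert vals == {"s": "4.9", "l": "7.4", "sum": "12.3"}

    def test_unmodified_only_locus_excluded(self):
        ev = evidence_for_locus(k0=100, k1=10, kox0=0, kox1=0)
        assert locus_report(ev).empty

    def test_floor_convention(self):
        ev = evidence_for_locus(k0=99.95, k1=0, kox0=0.05, kox1=0)
        report = locus_report(ev)
        assert report.loc[report.cleaved == "sum", "pct"].iloc[0] == "<0.1"

    def test_three_locus_sums_match_generator_truth(self):
        from hylquant.peptide_core import ProteinChain

        # loci separated by arginine-terminated peptides so no miscleaved
        # species of one locus covers a neighbouring modifiable lysine
        chain = ProteinChain("c", "AAKGAARTTKGAARSSKGAAR")
        truth = {3: 0.05, 10: 0.12, 17: 0.3}
        records, _ = gen_evidence(
            EvidenceSimConfig(chain=chain, site_fractions=truth, sigma=0.0)
        )
        report = locus_report(records)
        sums = report[report.cleaved == "sum"].set_index("site")["value"]
        for site, f in truth.items():
            assert sums[site] == pytest.approx(100 * f, abs=1e-9)


def test_evidence_frame_roundtrip():
    ev = evidence_for_locus(k0=600, k1=50, kox0=30, kox1=70)
    back = evidence_from_frame(evidence_to_frame(ev).replace({"": None}))
    assert back == ev
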