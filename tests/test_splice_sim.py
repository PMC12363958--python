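import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import retsdesign as rd
from conftest import lcs_oracle
from retsdesign.errors import ConsistencyError


class TestSimulateHybridization:
    def test_competent_on_own_target(self, design, target):
        report = rd.simulate_hybridization(design, target)
        assert report.competent
        assert report.guide1_sites and report.guide2_sites
        # the binding sites recover the designed window geometry
        window = design.guides.window
        assert window.start in report.guide1_sites
        assert window.start + design.guides.guide_length + 5 in report.guide2_sites

    def test_incompetent_on_unrelated_transcript(self, design):
        unrelated = rd.random_transcript(600, seed=777, label="unrelated")
        report = rd.simulate_hybridization(design, unrelated)
        assert not report.competent
        assert report.first_failure() == "guide1_match"

    @pytest.mark.parametrize("which", ["sub_window_1", "sub_window_2"])
    def test_single_base_guide_mismatch_breaks_competence(self, design, target, which):
        window = design.guides.window
        seq = list(str(target))
        offset = window.start if which == "sub_window_1" else window.start + 35
        seq[offset + 10] = "A" if seq[offset + 10] != "A" else "C"
        mutated = rd.NucleotideSequence("".join(seq), label="SUC1_mut")
        report = rd.simulate_hybridization(design, mutated)
        assert not report.competent

    def test_spacer_mutations_do_not_break_competence(self, design, target):
        # paralog-like transcript differing only inside the 5-nt spacer still
        # scaffolds the complex: specificity is the screen's job, not the
        # simulator's
        window = design.guides.window
        seq = list(str(target))
        spacer_start = window.start + design.guides.guide_length
        for i in range(5):
            seq[spacer_start + i] = "A" if seq[spacer_start + i] != "A" else "C"
        paralog = rd.NucleotideSequence("".join(seq), label="paralog")
        assert rd.simulate_hybridization(design, paralog).competent


class TestSimulateSplice:
    def test_product_equals_cargo_message(self, design, target, cargo):
        report = rd.simulate_hybridization(design, target)
        outcome = rd.simulate_splice(design, report)
        assert outcome.spliced
        assert outcome.product == cargo.message
        # ATG restored across the start-codon junction
        assert outcome.product[len(cargo.utr5) : len(cargo.utr5) + 3] == "ATG"

    def test_internal_site_product(self, cargo, target, scaffold):
        sites = rd.enumerate_splice_sites(cargo, "internal")
        site = rd.select_internal_site(sites, cargo)
        window = rd.enumerate_windows(target, 20)[33]
        design = rd.assemble(scaffold, cargo, site, rd.make_guide_pair(window))
        report = rd.simulate_hybridization(design, target)
        outcome = rd.simulate_splice(design, report)
        assert outcome.product == cargo.message

    def test_refusal_names_first_failed_condition(self, design):
        unrelated = rd.random_transcript(400, seed=55, label="x")
        report = rd.simulate_hybridization(design, unrelated)
        outcome = rd.simulate_splice(design, report)
        assert not outcome.spliced
        assert outcome.product is None
        assert "guide1_match" in outcome.refusal

    def test_mismatched_report_rejected(self, design, cargo, start_site, target):
        other_window = rd.enumerate_windows(target, 20)[0]
        other = rd.design_from_components(
            rd.random_orf(50, seed=5, label="venus"),
            rd.enumerate_splice_sites(rd.random_orf(50, seed=5, label="venus"), "start_codon")[0],
            other_window,
        )
        report = rd.simulate_hybridization(other, target)
        with pytest.raises(ConsistencyError):
            rd.simulate_splice(design, report)


class TestVerifyOrf:
    def test_correct_product_passes(self, design, target, cargo):
        report = rd.simulate_hybridization(design, target)
        product = rd.simulate_splice(design, report).product
        assert rd.verify_orf(product, cargo).passed

    def test_junction_deletion_located(self, design, cargo):
        junction = design.site.junction
        broken = cargo.message[: junction - 1] + cargo.message[junction:]
        check = rd.verify_orf(broken, cargo)
        assert not check.passed
        assert check.divergence == junction - 1

    def test_premature_stop_diagnosed(self, cargo):
        # swap an early CDS codon for TAA: frame intact, stop introduced
        utr = len(cargo.utr5)
        broken = cargo.message[: utr + 9] + "TAA" + cargo.message[utr + 12 :]
        check = rd.verify_orf(broken, cargo)
        assert not check.passed
        assert "stop" in check.diagnostics


class TestDuplexProfile:
    def test_long_guides_flagged_short_not(self, cargo, start_site):
        target = rd.random_transcript(600, seed=200, label="SUC1")
        for guide_length, flagged in ((200, True), (30, False)):
            window = rd.enumerate_windows(target, guide_length)[7]
            design = rd.design_from_components(cargo, start_site, window)
            records = rd.duplex_profile(design, [target])
            assert any(r.flagged for r in records) is flagged
            longest = max(r.longest_duplex for r in records)
            assert longest >= guide_length

    def test_empty_transcriptome(self, design):
        assert rd.duplex_profile(design, []) == []

    @given(
        st.text(alphabet="ACGT", min_size=1, max_size=40),
        st.text(alphabet="ACGT", min_size=1, max_size=40),
    )
    @settings(max_examples=150)
    def test_lcs_matches_quadratic_oracle(self, a, b):
        assert rd.longest_common_substring_length(a, b) == lcs_oracle(a, b)

    def test_duplex_profile_matches_alignment_scan(self, design, target):
        rc1 = rd.reverse_complement(design.fragment_1.sequence)
        records = rd.duplex_profile(design, [target])
        frag1 = next(r for r in records if r.fragment == "fragment_1")
        assert frag1.longest_duplex == lcs_oracle(rc1, str(target))
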