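import pytest

import retsdesign as rd
from conftest import offtarget_scan_oracle
from retsdesign.errors import NoWindowError, ParameterError


class TestEnumerateWindows:
    @pytest.mark.parametrize(
        "target_length,guide_length,expected",
        [
            (65, 30, 1),  # 65 = 2*30 + 5
            (100, 20, 56),  # 100 - 45 + 1
            (45, 20, 1),
        ],
    )
    def test_window_counts(self, target_length, guide_length, expected):
        target = rd.random_transcript(target_length, seed=1, label="t")
        assert len(rd.enumerate_windows(target, guide_length)) == expected

    def test_target_too_short(self):
        target = rd.random_transcript(64, seed=1, label="t")
        with pytest.raises(NoWindowError):
            rd.enumerate_windows(target, 30)

    @pytest.mark.parametrize("guide_length", [20, 25, 30, 50, 200])
    def test_footprint_arithmetic(self, guide_length):
        target = rd.random_transcript(2 * guide_length + 25, seed=2, label="t")
        for window in rd.enumerate_windows(target, guide_length):
            assert window.end - window.start == 2 * guide_length + 5
            assert window.footprint == str(target)[window.start : window.end]
            assert len(window.spacer) == 5

    def test_invalid_guide_length(self, target):
        with pytest.raises(ParameterError):
            rd.enumerate_windows(target, 0)


class TestGuidePair:
    def test_homopolymer_complement(self):
        window = rd.TargetWindow(
            transcript_id="t",
            start=0,
            end=15,
            sub_window_1="AAAAA",
            spacer="CCCCC",
            sub_window_2="GGGGG",
        )
        pair = rd.make_guide_pair(window)
        assert pair.guide_1 == "TTTTT"
        assert pair.guide_2 == "CCCCC"

    def test_guides_invert_to_sub_windows(self, target):
        for window in rd.enumerate_windows(target, 25)[::100]:
            pair = rd.make_guide_pair(window)
            assert rd.reverse_complement(pair.guide_1) == window.sub_window_1
            assert rd.reverse_complement(pair.guide_2) == window.sub_window_2
            assert len(pair.guide_1) == len(pair.guide_2) == 25

    def test_end_to_end_with_simulator(self, cargo, start_site, target):
        window = rd.enumerate_windows(target, 30)[42]
        design = rd.design_from_components(cargo, start_site, window)
        report = rd.simulate_hybridization(design, target)
        assert report.competent


class TestRnaiSafetyCheck:
    @pytest.mark.parametrize(
        "guide_length,passed",
        [(20, True), (25, True), (30, True), (36, True), (37, False), (200, False)],
    )
    def test_boundary_exclusive_at_37(self, guide_length, passed):
        target = rd.random_transcript(2 * guide_length + 5, seed=3, label="t")
        pair = rd.make_guide_pair(rd.enumerate_windows(target, guide_length)[0])
        check = rd.rnai_safety_check(pair)
        assert check.passed is passed
        assert check.duplex_length_1 == check.duplex_length_2 == guide_length

    def test_monotone_in_guide_length(self):
        outcomes = []
        for guide_length in range(10, 60):
            target = rd.random_transcript(2 * guide_length + 5, seed=4, label="t")
            pair = rd.make_guide_pair(rd.enumerate_windows(target, guide_length)[0])
            outcomes.append(rd.rnai_safety_check(pair).passed)
        # once failing, never passes again at longer lengths
        assert outcomes == sorted(outcomes, reverse=True)


class TestOfftargetScreen:
    @pytest.fixture
    def transcriptome(self):
        return rd.make_transcriptome(rd.FixtureSpec(seed=7))

    def test_planted_paralog_detected(self, transcriptome):
        # the paralog diverges from the target's first 400 nt at 25%
        window = rd.enumerate_windows(transcriptome.target, 30)[100]
        hits = rd.offtarget_screen(window, list(transcriptome))
        oracle = offtarget_scan_oracle(window, list(transcriptome), 0.75)
        assert {h.transcript_id for h in hits} <= {"target_paralog"}
        assert len(hits) > 0 or not oracle

    def test_no_hits_on_pure_decoys(self):
        transcriptome = rd.make_transcriptome(
            rd.FixtureSpec(seed=9, paralog_identity=None)
        )
        window = rd.enumerate_windows(transcriptome.target, 30)[10]
        assert rd.offtarget_screen(window, list(transcriptome)) == []

    def test_self_transcript_excluded(self, transcriptome):
        window = rd.enumerate_windows(transcriptome.target, 30)[0]
        hits = rd.offtarget_screen(window, [transcriptome.target])
        assert hits == []

    def test_threshold_validation(self, transcriptome):
        window = rd.enumerate_windows(transcriptome.target, 30)[0]
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ParameterError):
                rd.offtarget_screen(window, list(transcriptome), identity_threshold=bad)

    @pytest.mark.parametrize("start", [0, 150, 320])
    def test_equals_exhaustive_scan_oracle(self, transcriptome, start):
        window = rd.enumerate_windows(transcriptome.target, 30)[start]
        hits = rd.offtarget_screen(window, list(transcriptome))
        got = {(h.transcript_id, h.start, h.end, h.which_segment) for h in hits}
        expected = offtarget_scan_oracle(window, list(transcriptome), 0.75)
        assert got == expected

    def test_deterministic_ordering(self, transcriptome):
        window = rd.enumerate_windows(transcriptome.target, 30)[100]
        hits = rd.offtarget_screen(window, list(transcriptome))
        keys = [(h.transcript_id, h.start, h.which_segment) for h in hits]
        assert keys == sorted(keys)


class TestRankWindows:
    def test_clean_window_outranks_paralogous_one(self):
        transcriptome = rd.make_transcriptome(
            rd.FixtureSpec(seed=21, paralog_region=(0, 400))
        )
        target = transcriptome.target
        windows = rd.enumerate_windows(target, 30)
        # one window inside the paralog-shadowed region, one far outside it
        inside, outside = windows[100], windows[700]
        ranking = rd.rank_windows([inside, outside], list(transcriptome))
        assert ranking.diagnostic is None
        ranked_starts = [r.window.start for r in ranking.windows]
        # the shadowed window is either filtered out or ranked below the clean one
        assert ranked_starts[0] == outside.start or inside.start not in ranked_starts

    def test_tie_break_smaller_start_first(self):
        target = rd.random_transcript(200, seed=22, label="t")
        windows = rd.enumerate_windows(target, 30)
        duplicated = rd.TargetWindow(
            transcript_id="t",
            start=windows[5].start,
            end=windows[5].end,
            sub_window_1=windows[5].sub_window_1,
            spacer=windows[5].spacer,
            sub_window_2=windows[5].sub_window_2,
        )
        ranking = rd.rank_windows([windows[5], duplicated], [])
        assert [r.window.start for r in ranking.windows] == [5, 5]

    def test_all_windows_hit_gives_diagnostic(self):
        target = rd.random_transcript(100, seed=23, label="t")
        clone = rd.NucleotideSequence(str(target), label="identical_twin")
        windows = rd.enumerate_windows(target, 30)[:3]
        ranking = rd.rank_windows(windows, [clone])
        assert ranking.windows == []
        assert ranking.diagnostic is not None
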