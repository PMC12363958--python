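import pytest
from hypothesis import settings

import retsdesign as rd

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture
def scaffold():
    return rd.default_scaffold()


@pytest.fixture
def cargo():
    """An omega-led mScarlet-like toy cargo (80 codons)."""
    return rd.random_orf(80, seed=101, label="mScarlet")


@pytest.fixture
def target():
    """A SUC1-like toy target transcript."""
    return rd.random_transcript(600, seed=102, label="SUC1")


@pytest.fixture
def start_site(cargo):
    return rd.enumerate_splice_sites(cargo, rd.SpliceMode.START_CODON)[0]


@pytest.fixture
def design(cargo, start_site, target):
    window = rd.enumerate_windows(target, 30)[100]
    return rd.design_from_components(cargo, start_site, window)


# ---------------------------------------------------------------------------
# Brute-force oracles (kept deliberately naive and independent of the
# implementations they check)
# ---------------------------------------------------------------------------

_WC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def pair_igs_oracle(igsbs: str) -> str:
    """Pair each IGSBS base antiparallel Watson-Crick, then put G opposite
    the terminal splice-site T."""
    paired = [_WC[b] for b in reversed(igsbs)]
    paired[0] = "G"
    return "".join(paired)


def offtarget_scan_oracle(window, transcriptome, threshold):
    """Exhaustive window-by-window ungapped identity scan.

    Slides the full footprint over every transcript (excluding the window's
    own) and reports every (transcript, start, end, segment) whose identity
    meets the threshold, for the same three segments the screen scores.
    """
    footprint = window.footprint
    span = len(footprint)
    g = window.guide_length
    segments = [
        ("sub_window_1", 0, g),
        ("sub_window_2", g + 5, g),
        ("full_footprint", 0, span),
    ]
    hits = set()
    for transcript in transcriptome:
        if transcript.label == window.transcript_id:
            continue
        seq = str(transcript)
        for d in range(len(seq) - span + 1):
            region = seq[d : d + span]
            for name, off, length in segments:
                matches = sum(
                    x == y
                    for x, y in zip(footprint[off : off + length], region[off : off + length])
                )
                if matches / length >= threshold:
                    hits.add((transcript.label, d + off, d + off + length, name))
    return hits


@pytest.fixture
def offtarget_oracle():
    return offtarget_scan_oracle


def lcs_oracle(a: str, b: str) -> int:
    """Quadratic longest-common-substring scan."""
    best = 0
    for i in range(len(a)):
        for j in range(len(b)):
            k = 0
            while i + k < len(a) and j + k < len(b) and a[i + k] == b[j + k]:
                k += 1
            best = max(best, k)
    return best
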