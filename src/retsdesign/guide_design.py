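"""Target-window enumeration, guide-arm construction and safety screening.

Each design binds its target mRNA through two antisense guide arms whose
binding sites sit side by side on the target, separated by exactly 5 target
bases; across that spacer the two 6-nt helper-stem strands pair with each
other and hold the assembled complex together.  A window of the target
therefore spans ``2 * guide_length + 5`` nt.

Two liabilities are screened:

* **RNAi** — a guide annealed to its target forms a perfect RNA duplex of
  ``guide_length`` bp.  Duplexes of 37 bp or more are efficient DICER
  substrates, so guides are kept below that bound (``rnai_safety_check``).
* **Off-target cross-reactivity** — paralogous transcripts with roughly 75%
  identity to the targeted region can still scaffold the ribozyme, so
  candidate windows are screened against a reference transcriptome for
  near-identical loci (``offtarget_screen``) and ranked to prefer unique,
  well-balanced windows (``rank_windows``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .core import NucleotideSequence, reverse_complement
from .errors import NoWindowError, ParameterError

SPACER_LENGTH = 5
#: RNA duplexes at or above this length are efficient DICER substrates.
MAX_DUPLEX_EXCLUSIVE = 37
DEFAULT_GUIDE_LENGTH = 30
DEFAULT_IDENTITY_THRESHOLD = 0.75
DEFAULT_SEED_LENGTH = 12


@dataclass(frozen=True)
class TargetWindow:
    """A guide footprint on the target: two sub-windows flanking a 5-nt spacer."""

    transcript_id: str
    start: int
    end: int
    sub_window_1: str
    spacer: str
    sub_window_2: str

    def __post_init__(self) -> None:
        if len(self.spacer) != SPACER_LENGTH:
            raise ParameterError(f"spacer must be {SPACER_LENGTH} nt")
        if len(self.sub_window_1) != len(self.sub_window_2):
            raise ParameterError("sub-windows must have equal length")
        if self.end - self.start != len(self.footprint):
            raise ParameterError("window coordinates do not match its sequence span")

    @property
    def guide_length(self) -> int:
        return len(self.sub_window_1)

    @property
    def footprint(self) -> str:
        """The contiguous target sequence covered by the window."""
        return self.sub_window_1 + self.spacer + self.sub_window_2

    @property
    def span(self) -> int:
        return 2 * self.guide_length + SPACER_LENGTH


@dataclass(frozen=True)
class GuidePair:
    """The two antisense guide arms for one target window.

    ``guide_1`` (3' end of fragment 1) is the reverse complement of the
    5'-proximal sub-window; ``guide_2`` (5' end of fragment 2) is the
    reverse complement of the 3'-proximal one.  This orientation juxtaposes
    the two helper stems over the 5-nt spacer when both guides anneal.
    """

    guide_1: str
    guide_2: str
    window: TargetWindow

    @property
    def guide_length(self) -> int:
        return len(self.guide_1)


@dataclass(frozen=True)
class OffTargetHit:
    """A transcriptome locus nearly identical to (part of) a guide footprint."""

    transcript_id: str
    start: int
    end: int
    percent_identity: float
    which_segment: str  # sub_window_1 | sub_window_2 | full_footprint


def enumerate_windows(
    target: NucleotideSequence, guide_length: int = DEFAULT_GUIDE_LENGTH
) -> list[TargetWindow]:
    """All sliding guide footprints (span ``2*guide_length + 5``) at step 1."""
    if guide_length < 1:
        raise ParameterError("guide_length must be >= 1")
    seq = str(target)
    span = 2 * guide_length + SPACER_LENGTH
    if len(seq) < span:
        raise NoWindowError(
            f"target {target.label or '<unnamed>'} is {len(seq)} nt; a "
            f"{guide_length}-nt guide pair needs at least {span} nt"
        )
    windows = []
    for start in range(len(seq) - span + 1):
        w1 = seq[start : start + guide_length]
        spacer = seq[start + guide_length : start + guide_length + SPACER_LENGTH]
        w2 = seq[start + guide_length + SPACER_LENGTH : start + span]
        windows.append(
            TargetWindow(
                transcript_id=target.label,
                start=start,
                end=start + span,
                sub_window_1=w1,
                spacer=spacer,
                sub_window_2=w2,
            )
        )
    return windows


def make_guide_pair(window: TargetWindow) -> GuidePair:
    """Guide arms as exact antiparallel complements of their sub-windows."""
    return GuidePair(
        guide_1=reverse_complement(window.sub_window_1),
        guide_2=reverse_complement(window.sub_window_2),
        window=window,
    )


@dataclass(frozen=True)
class RnaiCheck:
    passed: bool
    duplex_length_1: int
    duplex_length_2: int
    max_duplex_exclusive: int


def rnai_safety_check(
    pair: GuidePair, max_duplex_exclusive: int = MAX_DUPLEX_EXCLUSIVE
) -> RnaiCheck:
    """DICER duplex-length rule: fail iff either guide's perfect duplex is >= 37 bp.

    Each guide forms a contiguous perfect duplex of its full length with its
    sub-window, so the check reduces to comparing guide lengths against the
    exclusive threshold.
    """
    d1, d2 = len(pair.guide_1), len(pair.guide_2)
    return RnaiCheck(
        passed=d1 < max_duplex_exclusive and d2 < max_duplex_exclusive,
        duplex_length_1=d1,
        duplex_length_2=d2,
        max_duplex_exclusive=max_duplex_exclusive,
    )


# ---------------------------------------------------------------------------
# Off-target screening
# ---------------------------------------------------------------------------


def _segment_table(window: TargetWindow) -> list[tuple[str, int, int]]:
    """(name, offset, length) of the scored segments within the footprint."""
    g = window.guide_length
    return [
        ("sub_window_1", 0, g),
        ("sub_window_2", g + SPACER_LENGTH, g),
        ("full_footprint", 0, window.span),
    ]


def _identity(a: str, b: str) -> float:
    return sum(x == y for x, y in zip(a, b)) / len(a)


def _guaranteed_seed_length(
    window: TargetWindow, identity_threshold: float, seed_length: int
) -> int:
    """Longest seed that cannot miss any segment at >= the identity threshold.

    A segment of length L matching at >= t has at most ``floor((1-t)*L)``
    mismatches, which by pigeonhole leave an exact run of at least
    ``floor(L / (mismatches + 1))``.  Capping the configured seed at the
    minimum such run over all scored segments makes the seeded search
    provably as sensitive as an exhaustive scan.
    """
    guaranteed = seed_length
    for _, _, length in _segment_table(window):
        max_mm = math.floor((1.0 - identity_threshold) * length)
        guaranteed = min(guaranteed, length // (max_mm + 1))
    return max(1, guaranteed)


def offtarget_screen(
    window: TargetWindow,
    transcriptome: list[NucleotideSequence],
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    seed_length: int = DEFAULT_SEED_LENGTH,
) -> list[OffTargetHit]:
    """Ungapped seed-and-extend search for near-identical transcriptome loci.

    Exact k-mer matches between the footprint and a transcript anchor a
    diagonal; the full footprint is then aligned ungapped on that diagonal
    and each scored segment (either sub-window and the full footprint) is
    reported as a hit when its identity meets the threshold.  The seed is
    internally shortened when needed so no qualifying locus can be missed
    (see ``_guaranteed_seed_length``).  The window's own transcript is
    excluded by id.  Output is sorted by (transcript id, start, segment).
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ParameterError("identity_threshold must be in (0, 1]")
    if seed_length < 1:
        raise ParameterError("seed_length must be >= 1")
    footprint = window.footprint
    span = len(footprint)
    k = _guaranteed_seed_length(window, identity_threshold, seed_length)
    segments = _segment_table(window)

    hits: list[OffTargetHit] = []
    for transcript in transcriptome:
        if transcript.label == window.transcript_id:
            continue
        seq = str(transcript)
        if len(seq) < span:
            continue
        index: dict[str, list[int]] = {}
        for pos in range(len(seq) - k + 1):
            index.setdefault(seq[pos : pos + k], []).append(pos)
        diagonals = set()
        for q in range(span - k + 1):
            for pos in index.get(footprint[q : q + k], ()):
                d = pos - q
                if 0 <= d <= len(seq) - span:
                    diagonals.add(d)
        for d in sorted(diagonals):
            region = seq[d : d + span]
            for name, off, length in segments:
                ident = _identity(footprint[off : off + length], region[off : off + length])
                if ident >= identity_threshold:
                    hits.append(
                        OffTargetHit(
                            transcript_id=transcript.label,
                            start=d + off,
                            end=d + off + length,
                            percent_identity=round(100.0 * ident, 3),
                            which_segment=name,
                        )
                    )
    hits.sort(key=lambda h: (h.transcript_id, h.start, h.which_segment))
    return hits


@dataclass(frozen=True)
class ScoringConfig:
    """Knobs for window ranking."""

    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD
    near_margin: float = 0.15  # count "near misses" within this band below threshold
    gc_optimum: float = 0.5
    seed_length: int = DEFAULT_SEED_LENGTH


@dataclass(frozen=True)
class RankedWindow:
    window: TargetWindow
    near_threshold_hits: int
    gc_fraction: float


@dataclass
class WindowRanking:
    """Ordered clean candidates plus a diagnostic when none survive."""

    windows: list[RankedWindow] = field(default_factory=list)
    diagnostic: str | None = None


def rank_windows(
    windows: list[TargetWindow],
    transcriptome: list[NucleotideSequence],
    config: ScoringConfig = ScoringConfig(),
) -> WindowRanking:
    """Filter out windows with off-target hits, then rank the survivors.

    Survivors are ordered by (fewest near-threshold similarities, GC fraction
    closest to the configured optimum, smallest start coordinate) — a fully
    deterministic ordering.  An empty surviving set is reported through the
    ``diagnostic`` field rather than raised.
    """
    near_floor = max(1e-9, config.identity_threshold - config.near_margin)
    survivors: list[RankedWindow] = []
    for window in windows:
        near = offtarget_screen(
            window,
            transcriptome,
            identity_threshold=near_floor,
            seed_length=config.seed_length,
        )
        if any(h.percent_identity >= 100.0 * config.identity_threshold for h in near):
            continue
        gc = (
            sum(1 for b in window.footprint if b in "GC") / len(window.footprint)
        )
        survivors.append(
            RankedWindow(window=window, near_threshold_hits=len(near), gc_fraction=gc)
        )
    survivors.sort(
        key=lambda r: (
            r.near_threshold_hits,
            abs(r.gc_fraction - config.gc_optimum),
            r.window.start,
        )
    )
    if not survivors:
        return WindowRanking(
            windows=[],
            diagnostic=(
                f"all {len(windows)} candidate windows have off-target hits at "
                f"identity >= {config.identity_threshold:.2f}; consider a longer "
                "target, a different region, or a higher threshold"
            ),
        )
    return WindowRanking(windows=survivors)


def screen_table(window: TargetWindow, hits: list[OffTargetHit]) -> pd.DataFrame:
    """Tabulate screen hits (coordinates 1-based inclusive for reports)."""
    return pd.DataFrame(
        {
            "query_transcript": [window.transcript_id] * len(hits),
            "query_start": [window.start + 1] * len(hits),
            "query_end": [window.end] * len(hits),
            "hit_transcript": [h.transcript_id for h in hits],
            "hit_start": [h.start + 1 for h in hits],
            "hit_end": [h.end for h in hits],
            "percent_identity": [h.percent_identity for h in hits],
            "segment": [h.which_segment for h in hits],
        }
    )
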