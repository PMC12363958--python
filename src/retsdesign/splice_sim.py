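"""In-silico verification of target-templated assembly and trans-splicing.

The simulator is a strict correctness oracle, not a biophysical model: guide
binding is exact antiparallel matching, complex competence is the
conjunction of the five structural conditions (both guides bound, 5-nt
spacer, paired helper stems, IGS·IGSBS pairing with its single wobble), and
a competent complex splices to exactly ``upstream exon + downstream exon``.
Partial-match tolerance — the cross-reactivity that makes paralogs a risk —
is deliberately the off-target screen's job.

``duplex_profile`` covers the RNAi angle: the longest contiguous perfect
duplex each fragment can form with each transcript, flagged at the 37-bp
DICER bound.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import NucleotideSequence, reverse_complement
from .errors import ConsistencyError
from .guide_design import MAX_DUPLEX_EXCLUSIVE, SPACER_LENGTH
from .splice_sites import pairing_pattern

from .assembly import RETSDesign


@dataclass(frozen=True)
class HybridizationReport:
    """Structural checklist for one design against one candidate target."""

    design_label: str
    target_id: str
    guide1_match: bool
    guide1_sites: tuple[int, ...]  # all start coordinates on the target
    guide2_match: bool
    guide2_sites: tuple[int, ...]
    spacer_ok: bool
    helper_stem_paired: bool
    igs_igsbs_paired: bool

    @property
    def competent(self) -> bool:
        return (
            self.guide1_match
            and self.guide2_match
            and self.spacer_ok
            and self.helper_stem_paired
            and self.igs_igsbs_paired
        )

    def first_failure(self) -> str | None:
        for name in (
            "guide1_match",
            "guide2_match",
            "spacer_ok",
            "helper_stem_paired",
            "igs_igsbs_paired",
        ):
            if not getattr(self, name):
                return name
        return None


def _find_all(haystack: str, needle: str) -> tuple[int, ...]:
    sites = []
    start = 0
    while True:
        idx = haystack.find(needle, start)
        if idx == -1:
            return tuple(sites)
        sites.append(idx)
        start = idx + 1


def simulate_hybridization(
    design: RETSDesign, target: NucleotideSequence
) -> HybridizationReport:
    """Check whether the target can scaffold the two fragments into a
    splice-competent complex.

    Guide binding sites are the exact antiparallel matches (occurrences of
    each guide's reverse complement on the target, all listed in coordinate
    order); ``spacer_ok`` requires some pair of sites separated by exactly 5
    target bases.  Absence of matches is a normal ``competent=False``
    outcome, never an error.
    """
    seq = str(target)
    bind1 = reverse_complement(design.guides.guide_1)
    bind2 = reverse_complement(design.guides.guide_2)
    sites1 = _find_all(seq, bind1)
    sites2 = _find_all(seq, bind2)
    glen = design.guides.guide_length
    spacer_ok = any(
        p2 - (p1 + glen) == SPACER_LENGTH for p1 in sites1 for p2 in sites2
    )
    pattern = pairing_pattern(design.site.igs, design.site.igsbs)
    igs_ok = (
        pattern.count("WC") == 5
        and pattern.count("wobble") == 1
        and pattern[0] == "wobble"
    )
    return HybridizationReport(
        design_label=design.notation_label,
        target_id=target.label,
        guide1_match=bool(sites1),
        guide1_sites=sites1,
        guide2_match=bool(sites2),
        guide2_sites=sites2,
        spacer_ok=spacer_ok,
        helper_stem_paired=(
            design.scaffold.helper_stem_b
            == reverse_complement(design.scaffold.helper_stem_a)
        ),
        igs_igsbs_paired=igs_ok,
    )


@dataclass(frozen=True)
class SpliceOutcome:
    spliced: bool
    product: str | None
    refusal: str | None


def simulate_splice(design: RETSDesign, report: HybridizationReport) -> SpliceOutcome:
    """Splice the scaffolded complex, or refuse with the first failed condition.

    The product of a competent complex is the ligation of the two exons —
    the ribozyme halves, helper stems and guides are excised — which by
    construction equals the cargo's ``utr5 + cds``.
    """
    if report.design_label != design.notation_label:
        raise ConsistencyError(
            f"report is for {report.design_label!r}, not {design.notation_label!r}"
        )
    if not report.competent:
        return SpliceOutcome(
            spliced=False,
            product=None,
            refusal=f"complex not splice-competent: {report.first_failure()} failed",
        )
    return SpliceOutcome(
        spliced=True,
        product=design.upstream_exon + design.downstream_exon,
        refusal=None,
    )


@dataclass(frozen=True)
class OrfCheck:
    passed: bool
    diagnostics: str
    divergence: int | None = None


def verify_orf(spliced: str, cargo) -> OrfCheck:
    """Check that a spliced product carries the cargo CDS intact and in frame.

    Passes iff the product equals ``utr5`` followed by the unmodified CDS at
    the annotated start.  On failure the diagnostics name the first
    divergence position (or a premature stop codon within the recovered
    frame, which is the usual symptom of a junction shifted off-frame).
    """
    expected = cargo.message
    if spliced == expected:
        return OrfCheck(passed=True, diagnostics="cargo CDS intact and in frame")
    n = min(len(spliced), len(expected))
    divergence = next(
        (i for i in range(n) if spliced[i] != expected[i]), n
    )
    cds_region = spliced[len(cargo.utr5) :]
    for idx in range(0, max(0, len(cds_region) - 2), 3):
        codon = cds_region[idx : idx + 3]
        if codon in ("TAA", "TAG", "TGA") and idx < len(cargo.cds) - 3:
            return OrfCheck(
                passed=False,
                diagnostics=(
                    f"sequence diverges at position {divergence}; premature stop "
                    f"codon {codon} at CDS codon {idx // 3}"
                ),
                divergence=divergence,
            )
    return OrfCheck(
        passed=False,
        diagnostics=f"sequence diverges from 5'UTR+CDS at position {divergence}",
        divergence=divergence,
    )


# ---------------------------------------------------------------------------
# Duplex profiling (RNAi liability)
# ---------------------------------------------------------------------------


def longest_common_substring_length(a: str, b: str) -> int:
    """Length of the longest exact substring shared by ``a`` and ``b``.

    Binary search on the run length with rolling k-mer sets: O((n+m) log n)
    and comfortably fast at transcriptome-fixture scale.
    """
    if not a or not b:
        return 0
    lo, hi = 0, min(len(a), len(b))
    while lo < hi:
        k = (lo + hi + 1) // 2
        kmers = {a[i : i + k] for i in range(len(a) - k + 1)}
        if any(b[i : i + k] in kmers for i in range(len(b) - k + 1)):
            lo = k
        else:
            hi = k - 1
    return lo


@dataclass(frozen=True)
class DuplexRecord:
    fragment: str  # fragment_1 | fragment_2
    transcript_id: str
    longest_duplex: int
    flagged: bool


def duplex_profile(
    design: RETSDesign,
    transcriptome: list[NucleotideSequence],
    flag_at: int = MAX_DUPLEX_EXCLUSIVE,
) -> list[DuplexRecord]:
    """Longest perfect antiparallel duplex of each fragment with each transcript.

    A run of contiguous complementarity between a fragment and a transcript
    is an exact substring match between the fragment's reverse complement
    and the transcript; runs of 37 bp or more are flagged as DICER
    substrates.  An empty transcriptome yields an empty profile.
    """
    records = []
    for frag_name, frag in (
        ("fragment_1", design.fragment_1),
        ("fragment_2", design.fragment_2),
    ):
        rc = reverse_complement(frag.sequence)
        for transcript in transcriptome:
            run = longest_common_substring_length(rc, str(transcript))
            records.append(
                DuplexRecord(
                    fragment=frag_name,
                    transcript_id=transcript.label,
                    longest_duplex=run,
                    flagged=run >= flag_at,
                )
            )
    return records


def hybridization_table(report: HybridizationReport) -> pd.DataFrame:
    """One-row tabular rendering of a hybridization report."""
    return pd.DataFrame(
        [
            {
                "design": report.design_label,
                "target": report.target_id,
                "guide1_match": report.guide1_match,
                "guide1_sites": ",".join(map(str, report.guide1_sites)),
                "guide2_match": report.guide2_match,
                "guide2_sites": ",".join(map(str, report.guide2_sites)),
                "spacer_ok": report.spacer_ok,
                "helper_stem_paired": report.helper_stem_paired,
                "igs_igsbs_paired": report.igs_igsbs_paired,
                "competent": report.competent,
            }
        ]
    )
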