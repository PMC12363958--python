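"""Sequence primitives and the split-ribozyme scaffold data model.

The toolkit designs trans-splicing constructs around a split group I intron
ribozyme (the 419-nt *Tetrahymena thermophila* rRNA intron, TtRz).  The
ribozyme is split inside its first helix (the P1 loop) into a 9-nt upstream
half and an 11-nt downstream half; the downstream fragment additionally
carries the 6-nt internal guide sequence (IGS) and the remaining 387-nt
catalytic core.  Together with the 6 exon-derived bases of the IGS binding
site (IGSBS) this accounts for the full 419-nt ribozyme unit:

    6 (IGSBS) + 9 (P1 up) + 11 (P1 down) + 6 (IGS) + 387 (core) = 419

All sequences are held internally in the DNA alphabet (T, uppercase);
RNA (U) is a presentation option at output time.  Coordinates are 0-based,
half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml
from Bio.Seq import Seq

from .errors import AlphabetError, CargoError, ScaffoldDefinitionError

DNA_ALPHABET = frozenset("ACGT")

#: Watson-Crick complement table (DNA alphabet).
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

IGS_LENGTH = 6
IGSBS_LENGTH = 6
P1_UPSTREAM_LENGTH = 9
P1_DOWNSTREAM_LENGTH = 11
CORE_LENGTH = 387
HELPER_STEM_LENGTH = 6
RIBOZYME_UNIT_LENGTH = 419  # IGSBS + P1 halves + IGS + core

#: First helper-stem strand, appended between the upstream P1 half and guide 1.
HELPER_STEM_A = "GGATCA"
#: Second helper-stem strand (reverse complement of the first), placed between
#: guide 2 and the downstream P1 half.
HELPER_STEM_B = "TGATCC"


def _check_alphabet(residues: str, what: str = "sequence") -> str:
    if not residues:
        raise AlphabetError(f"empty {what}: sequences must contain at least one base")
    bad = set(residues) - DNA_ALPHABET
    if bad:
        raise AlphabetError(
            f"{what} contains characters outside {{A,C,G,T}}: {sorted(bad)!r} "
            "(lowercase and degenerate IUPAC codes are rejected at ingest)"
        )
    return residues


@dataclass(frozen=True)
class NucleotideSequence:
    """An immutable, validated DNA sequence with an optional label.

    Residues are strictly uppercase ``{A,C,G,T}``; anything else (including
    degenerate IUPAC codes) is rejected at construction.  Use :meth:`as_rna`
    for U-notation display.
    """

    residues: str
    label: str = ""

    def __post_init__(self) -> None:
        _check_alphabet(self.residues, self.label or "sequence")

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues

    def __getitem__(self, index) -> str:
        return self.residues[index]

    def as_rna(self) -> str:
        """Render in RNA notation (T -> U)."""
        return self.residues.replace("T", "U")

    def reverse_complement(self, label: str | None = None) -> "NucleotideSequence":
        return NucleotideSequence(
            reverse_complement(self.residues),
            label if label is not None else self.label,
        )

    def gc_fraction(self) -> float:
        gc = sum(1 for b in self.residues if b in "GC")
        return gc / len(self.residues)


def reverse_complement(seq: str | NucleotideSequence) -> str:
    """Antiparallel Watson-Crick complement (an involution).

    Accepts a raw string or a :class:`NucleotideSequence`; always returns a
    plain string so it composes freely in the assembly arithmetic.
    """
    residues = str(seq)
    _check_alphabet(residues)
    return str(Seq(residues).reverse_complement())


def complement_base(base: str) -> str:
    try:
        return COMPLEMENT[base]
    except KeyError:
        raise AlphabetError(f"not a DNA base: {base!r}") from None


# ---------------------------------------------------------------------------
# Ribozyme scaffold
# ---------------------------------------------------------------------------

# Synthetic stand-in scaffold segments.  The construct grammar depends only on
# the segment lengths and the helper-stem/IGS pairing rules, so the packaged
# default uses fixed synthetic sequences of the correct lengths (generated once
# from a seeded RNG and frozen here).  For bench work, supply the real TtRz
# segments through a scaffold config file (see ``load_scaffold``).
_SYNTHETIC_P1_UPSTREAM = "TAGGAGTCG"
_SYNTHETIC_P1_DOWNSTREAM = "CTGTCCTCACT"
_SYNTHETIC_CORE = (
    "TCTTTAGTTGTAGCTTACTTGATATAACGAGGTACCTCTGGGACAACTAGGTTGATATTA"
    "TTATATGGATGATGAAAATGTAAATCCAGAACCGGATGAAGAAGGCAAACTGTGGCGGAC"
    "ATTGTGCAATGTTATAGGCTAGACTCTATTTAGATGTGAATTTAGTAGTACCAAAGCCCC"
    "CGGTTGTCATGGCTAAAGAGTCATACGGGATGGCCATCTTAACTGTAGAAACGCAGCGAA"
    "GTCTAGTATCTCTATCCGGTGCTCTTTGGTTGGAAGCAGCAAGCGCACATGGTTAAGGAT"
    "CAAGCGACGCGGAATGCCGTAACCAACAGCGGTGTGCGTACTGATCGGGGACTCCTTTCC"
    "GAAGGTAGTACAATCTCTGGTATTCCT"
)

#: Synthetic stand-in for the 68-nt tobacco mosaic virus omega translational
#: enhancer.  Only the leader's final four bases (TTAC, RNA: UUAC) are
#: functionally constrained — they complete the IGSBS when the cargo is split
#: at its start codon — so the stand-in preserves that terminus and the length.
DEFAULT_OMEGA_LEADER = (
    "ATTACCCTCAGGACCCCCGAAACTCCGGGTAAGCAATTACCCCCAATTCCCCAGGATCCCGCCCTTAC"
)


@dataclass(frozen=True)
class RibozymeScaffold:
    """The invariant split-TtRz part set with segment-length bookkeeping.

    ``p1_upstream`` (9 nt) ends fragment 1's ribozyme-side region;
    ``p1_downstream`` (11 nt), the IGS slot (6 nt, derived per splice site)
    and ``core`` (387 nt) form fragment 2's ribozyme body.  The helper stems
    are the complementary 6-nt pair that brackets the guide arms and pairs
    across the 5-nt target spacer.
    """

    p1_upstream: str = _SYNTHETIC_P1_UPSTREAM
    p1_downstream: str = _SYNTHETIC_P1_DOWNSTREAM
    core: str = _SYNTHETIC_CORE
    helper_stem_a: str = HELPER_STEM_A
    helper_stem_b: str = HELPER_STEM_B
    igs_length: int = IGS_LENGTH
    igsbs_length: int = IGSBS_LENGTH

    def __post_init__(self) -> None:
        validate_scaffold(self)


def validate_scaffold(scaffold: RibozymeScaffold) -> dict[str, int]:
    """Check every scaffold segment and return the length-accounting report.

    Returns per-segment lengths ``{igsbs, p1_up, p1_down, igs, core}`` plus
    their ``total`` (419) and the length of fragment 1's fixed ribozyme-side
    region ``upstream_fixed`` (IGSBS + P1 upstream = 15, the split point).
    Raises :class:`ScaffoldDefinitionError` on any mismatch.
    """
    checks = [
        ("p1_upstream", scaffold.p1_upstream, P1_UPSTREAM_LENGTH),
        ("p1_downstream", scaffold.p1_downstream, P1_DOWNSTREAM_LENGTH),
        ("core", scaffold.core, CORE_LENGTH),
        ("helper_stem_a", scaffold.helper_stem_a, HELPER_STEM_LENGTH),
        ("helper_stem_b", scaffold.helper_stem_b, HELPER_STEM_LENGTH),
    ]
    for name, seq, expected in checks:
        _check_alphabet(seq, name)
        if len(seq) != expected:
            raise ScaffoldDefinitionError(
                f"{name} must be {expected} nt, got {len(seq)}"
            )
    if scaffold.igs_length != IGS_LENGTH or scaffold.igsbs_length != IGSBS_LENGTH:
        raise ScaffoldDefinitionError(
            "igs_length and igsbs_length are fixed at 6 by the IGS/IGSBS pairing rule"
        )
    if scaffold.helper_stem_b != reverse_complement(scaffold.helper_stem_a):
        raise ScaffoldDefinitionError(
            "helper_stem_b must be the reverse complement of helper_stem_a "
            f"({scaffold.helper_stem_a!r} vs {scaffold.helper_stem_b!r})"
        )
    report = {
        "igsbs": scaffold.igsbs_length,
        "p1_up": len(scaffold.p1_upstream),
        "p1_down": len(scaffold.p1_downstream),
        "igs": scaffold.igs_length,
        "core": len(scaffold.core),
    }
    report["total"] = sum(report.values())
    report["upstream_fixed"] = report["igsbs"] + report["p1_up"]
    if report["total"] != RIBOZYME_UNIT_LENGTH:
        raise ScaffoldDefinitionError(
            f"ribozyme unit must total {RIBOZYME_UNIT_LENGTH} nt, got {report['total']}"
        )
    return report


def default_scaffold() -> RibozymeScaffold:
    """The packaged synthetic-segment scaffold (correct lengths, fixed bytes)."""
    return RibozymeScaffold()


_SCAFFOLD_KEYS = ("p1_upstream", "p1_downstream", "core", "helper_stem_a", "helper_stem_b")


def load_scaffold(path) -> RibozymeScaffold:
    """Load a scaffold definition from a YAML key-value file.

    Expected keys: ``p1_upstream``, ``p1_downstream``, ``core``,
    ``helper_stem_a``, ``helper_stem_b`` (stems optional; default to the
    GGATCA/TGATCC pair).  Sequences may be given in RNA notation.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ScaffoldDefinitionError(f"scaffold config {path} is not a key-value mapping")
    kwargs = {}
    for key in _SCAFFOLD_KEYS:
        if key in raw:
            kwargs[key] = str(raw[key]).strip().upper().replace("U", "T")
    return RibozymeScaffold(**kwargs)


def save_scaffold(scaffold: RibozymeScaffold, path) -> None:
    """Write a scaffold definition as a YAML key-value file."""
    with open(path, "w") as fh:
        yaml.safe_dump(
            {key: getattr(scaffold, key) for key in _SCAFFOLD_KEYS},
            fh,
            sort_keys=False,
        )


# ---------------------------------------------------------------------------
# Cargo ORF
# ---------------------------------------------------------------------------

_STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class CargoORF:
    """The cargo open reading frame, optionally led by a 5'UTR.

    The CDS must start with ATG, end with a stop codon and contain no
    internal stop.  With ``omega`` mode (the default leader) the UTR ends in
    TTAC so that, when the cargo is split at the U of the start codon, the
    leader's final four bases complete the 6-nt IGSBS (TTAC + AT).
    """

    cds: str
    utr5: str = field(default=DEFAULT_OMEGA_LEADER)
    label: str = "cargo"

    def __post_init__(self) -> None:
        _check_alphabet(self.cds, f"{self.label} CDS")
        if self.utr5:
            _check_alphabet(self.utr5, f"{self.label} 5'UTR")
        if not self.cds.startswith("ATG"):
            raise CargoError(f"{self.label}: CDS must begin with ATG")
        if len(self.cds) % 3 != 0:
            raise CargoError(
                f"{self.label}: CDS length {len(self.cds)} is not a multiple of 3"
            )
        codons = [self.cds[i : i + 3] for i in range(0, len(self.cds), 3)]
        if codons[-1] not in _STOP_CODONS:
            raise CargoError(f"{self.label}: CDS must end with a stop codon")
        internal = [i for i, c in enumerate(codons[:-1]) if c in _STOP_CODONS]
        if internal:
            raise CargoError(
                f"{self.label}: premature stop codon at codon index {internal[0]}"
            )

    @property
    def message(self) -> str:
        """The full pre-split message: 5'UTR + CDS."""
        return self.utr5 + self.cds

    def __len__(self) -> int:
        return len(self.message)

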