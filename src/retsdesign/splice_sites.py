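"""Splice-junction enumeration and IGS/IGSBS derivation.

A trans-splice junction sits at the end of the upstream exon, whose final
base must be U (T in the DNA alphabet) — this is the base the ribozyme's
internal guide sequence (IGS) recognises through a G·U wobble pair.  The
last 6 bases of the upstream exon form the IGS binding site (IGSBS); the
IGS is its antiparallel complement with a G (not A) opposite the splice-site
U, giving 5 Watson-Crick pairs plus exactly one wobble.

Two splicing modes are supported:

* ``start_codon`` — the cargo is split inside its AUG, after the U, so the
  5'UTR must supply the first four IGSBS bases (the omega leader ends in
  UUAC precisely for this);
* ``internal`` — any codon position whose preceding base is U, as in
  splitting mScarlet at "UU/U of F66" or GAIrht at "CU/C of L56".
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd
from Bio.Seq import Seq

from .core import (
    IGSBS_LENGTH,
    CargoORF,
    complement_base,
    reverse_complement,
)
from .errors import InsufficientContextError, InvalidSpliceSiteError


class SpliceMode(str, Enum):
    START_CODON = "start_codon"
    INTERNAL = "internal"


@dataclass(frozen=True)
class SpliceSite:
    """A junction in the cargo message with its derived IGSBS and IGS.

    ``junction`` is a 0-based, half-open offset into ``utr5 + cds`` marking
    the end of the upstream exon; the base at ``junction - 1`` is the
    splice-site T.
    """

    junction: int
    mode: SpliceMode
    igsbs: str
    igs: str
    codon_context: str = ""

    def __post_init__(self) -> None:
        if len(self.igsbs) != IGSBS_LENGTH or len(self.igs) != IGSBS_LENGTH:
            raise InvalidSpliceSiteError("IGSBS and IGS must both be 6 nt")
        if self.igsbs[-1] != "T":
            raise InvalidSpliceSiteError(
                "the final IGSBS base must be the splice-site T (U)"
            )


def derive_igsbs(cargo: CargoORF, junction: int) -> str:
    """The 6 bases of ``utr5 + cds`` ending at ``junction`` (the IGSBS).

    Raises if fewer than 6 bases lie upstream, or if the base at the
    junction is not the required splice-site T.
    """
    message = cargo.message
    if junction < IGSBS_LENGTH:
        raise InsufficientContextError(
            f"junction {junction} has fewer than {IGSBS_LENGTH} upstream bases; "
            "no IGSBS can be formed"
        )
    if junction > len(message):
        raise InsufficientContextError(
            f"junction {junction} beyond end of cargo message ({len(message)} nt)"
        )
    igsbs = message[junction - IGSBS_LENGTH : junction]
    if igsbs[-1] != "T":
        raise InvalidSpliceSiteError(
            f"base before junction {junction} is {igsbs[-1]!r}; the upstream exon "
            "must end in T (the splice-site U)"
        )
    return igsbs


def derive_igs(igsbs: str) -> str:
    """The internal guide sequence for an IGSBS.

    Antiparallel complement of the IGSBS with the base opposite the
    splice-site T replaced by G, creating the single G·U wobble that the
    ribozyme requires at the splice junction.  For the canonical omega +
    start-codon site: TTACAT -> GTGTAA (RNA: UUACAU -> GUGUAA).
    """
    if len(igsbs) != IGSBS_LENGTH:
        raise InvalidSpliceSiteError(f"IGSBS must be {IGSBS_LENGTH} nt, got {len(igsbs)}")
    if igsbs[-1] != "T":
        raise InvalidSpliceSiteError(
            f"IGSBS must end in the splice-site T, got {igsbs[-1]!r}"
        )
    # igs[i] pairs with igsbs[5 - i]; position 0 faces the splice-site T.
    igs = reverse_complement(igsbs)
    return "G" + igs[1:]


def pairing_pattern(igs: str, igsbs: str) -> list[str]:
    """Classify each antiparallel IGS·IGSBS pair as 'WC', 'wobble' or 'mismatch'.

    Position ``i`` of the IGS faces position ``5 - i`` of the IGSBS; a wobble
    is a G on the IGS strand opposite a T on the IGSBS strand.
    """
    if len(igs) != len(igsbs):
        raise InvalidSpliceSiteError("IGS and IGSBS lengths differ")
    pattern = []
    for i, a in enumerate(igs):
        b = igsbs[len(igsbs) - 1 - i]
        if complement_base(a) == b:
            pattern.append("WC")
        elif a == "G" and b == "T":
            pattern.append("wobble")
        else:
            pattern.append("mismatch")
    return pattern


def _codon_context(cargo: CargoORF, junction: int) -> str:
    """Annotate where in the reading frame a junction falls, e.g. "TT/T of F66".

    ``F66`` names the amino acid and 1-based codon index of the codon being
    split; a junction on a codon boundary is annotated against the codon it
    terminates (phase 3, e.g. "TTT/ of F66").
    """
    cds_off = junction - len(cargo.utr5)
    if cds_off <= 0:
        return "5'UTR"
    codon_idx = (cds_off - 1) // 3  # codon containing the splice-site T
    phase = cds_off - codon_idx * 3  # 1, 2 or 3 bases before the cut
    codon = cargo.cds[codon_idx * 3 : codon_idx * 3 + 3]
    aa = str(Seq(codon).translate())
    return f"{codon[:phase]}/{codon[phase:]} of {aa}{codon_idx + 1}"


def enumerate_splice_sites(
    cargo: CargoORF, mode: SpliceMode | str = SpliceMode.START_CODON
) -> list[SpliceSite]:
    """Enumerate valid splice junctions in the cargo, sorted by position.

    ``start_codon`` mode returns the single junction immediately after the T
    of the ATG (requires >= 4 nt of 5'UTR to complete the IGSBS).
    ``internal`` mode returns every junction inside the CDS whose upstream
    final base is T and which has 6 nt of upstream context, each annotated
    with its codon context.
    """
    mode = SpliceMode(mode)
    message = cargo.message
    if mode is SpliceMode.START_CODON:
        if len(cargo.utr5) < IGSBS_LENGTH - 2:
            raise InsufficientContextError(
                "start-codon splicing needs a 5'UTR of at least 4 nt to complete "
                f"the IGSBS; got {len(cargo.utr5)} nt"
            )
        junction = len(cargo.utr5) + 2  # after the T of ATG
        igsbs = derive_igsbs(cargo, junction)
        return [
            SpliceSite(
                junction=junction,
                mode=mode,
                igsbs=igsbs,
                igs=derive_igs(igsbs),
                codon_context=_codon_context(cargo, junction),
            )
        ]

    sites = []
    for junction in range(len(cargo.utr5) + 1, len(message) + 1):
        if message[junction - 1] != "T" or junction < IGSBS_LENGTH:
            continue
        igsbs = derive_igsbs(cargo, junction)
        sites.append(
            SpliceSite(
                junction=junction,
                mode=mode,
                igsbs=igsbs,
                igs=derive_igs(igsbs),
                codon_context=_codon_context(cargo, junction),
            )
        )
    return sites


def select_internal_site(sites: list[SpliceSite], cargo: CargoORF) -> SpliceSite:
    """Pick one internal site: closest to the CDS midpoint, then smallest offset.

    Mirrors the practice of moving the split to the middle of the gene when a
    single internal junction is wanted.
    """
    if not sites:
        raise InvalidSpliceSiteError("no candidate splice sites to select from")
    midpoint = len(cargo.utr5) + len(cargo.cds) / 2
    return min(sites, key=lambda s: (abs(s.junction - midpoint), s.junction))


def splice_site_table(sites: list[SpliceSite]) -> pd.DataFrame:
    """Tabulate sites for reporting (junction reported 1-based inclusive)."""
    return pd.DataFrame(
        {
            "junction": [s.junction for s in sites],  # 1-based inclusive end == offset
            "mode": [s.mode.value for s in sites],
            "igsbs": [s.igsbs for s in sites],
            "igs": [s.igs for s in sites],
            "codon_context": [s.codon_context for s in sites],
        }
    )
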