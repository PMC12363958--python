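"""Deterministic synthetic-sequence generator for targets, cargos and
transcriptomes.

Everything here is reproducible bit-for-bit from an integer seed, so the
whole toolkit can be exercised — including the off-target scenario of a
paralog at ~75% identity over a 400-nt targeted region, which emulates how
closely related transcript-family members can cross-react — without any
downloaded data.  Divergence is substitution-only, matching the ungapped
model of the off-target screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import CargoORF, DEFAULT_OMEGA_LEADER, NucleotideSequence
from .errors import ParameterError

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}


def random_transcript(
    length: int, gc_fraction: float = 0.5, seed: int = 0, label: str = "transcript"
) -> NucleotideSequence:
    """I.i.d. random transcript with P(G)+P(C) = ``gc_fraction``."""
    if length < 1:
        raise ParameterError("length must be >= 1")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ParameterError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array(
        [
            (1 - gc_fraction) / 2,  # A
            gc_fraction / 2,  # C
            gc_fraction / 2,  # G
            (1 - gc_fraction) / 2,  # T
        ]
    )
    residues = "".join(rng.choice(_BASES, size=length, p=p))
    return NucleotideSequence(residues, label=label)


def plant_paralog(
    template: NucleotideSequence,
    identity: float,
    seed: int = 0,
    label: str | None = None,
) -> NucleotideSequence:
    """Derive a paralog by substituting exactly ``round((1-identity)*L)`` bases.

    Positions are drawn uniformly without replacement and each substituted
    base differs from the template base, so the realized identity equals the
    request up to rounding.
    """
    if not 0.0 < identity <= 1.0:
        raise ParameterError("identity must be in (0, 1]")
    rng = np.random.default_rng(seed)
    residues = list(str(template))
    n_sub = round((1.0 - identity) * len(residues))
    positions = rng.choice(len(residues), size=n_sub, replace=False)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != residues[pos]]
        residues[pos] = alternatives[rng.integers(len(alternatives))]
    return NucleotideSequence(
        "".join(residues), label=label or f"{template.label}_paralog"
    )


def random_orf(
    n_codons: int, seed: int = 0, label: str = "cargo", utr5: str = DEFAULT_OMEGA_LEADER
) -> CargoORF:
    """Random cargo ORF: ATG + ``n_codons - 2`` sense codons + TAA.

    Internal stop codons are excluded by resampling, keeping the ORF valid
    for splice-site enumeration and splice verification.
    """
    if n_codons < 2:
        raise ParameterError("an ORF needs at least a start and a stop codon")
    rng = np.random.default_rng(seed)
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        codon = "".join(rng.choice(_BASES, size=3))
        if codon not in _STOPS:
            codons.append(codon)
    codons.append("TAA")
    return CargoORF(cds="".join(codons), utr5=utr5, label=label)


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic screening transcriptome (bit-reproducible)."""

    seed: int
    target_length: int = 1200
    decoy_length: int = 1000
    gc_fraction: float = 0.5
    paralog_identity: float | None = 0.75
    paralog_region: tuple[int, int] | None = (0, 400)
    n_decoys: int = 10
    target_id: str = "target"


@dataclass
class Transcriptome:
    """A synthetic transcriptome plus a manifest of what was planted where."""

    sequences: list[NucleotideSequence]
    manifest: dict = field(default_factory=dict)

    @property
    def target(self) -> NucleotideSequence:
        return self.sequences[0]

    def __iter__(self):
        return iter(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)


def make_transcriptome(spec: FixtureSpec) -> Transcriptome:
    """Target + optional planted paralog + decoys, with deterministic ids.

    The paralog diverges from the target only inside ``paralog_region`` (the
    rest of the paralog is independent random sequence), emulating a family
    member sharing ~75% identity across the targeted region.
    """
    target = random_transcript(
        spec.target_length, spec.gc_fraction, seed=spec.seed, label=spec.target_id
    )
    sequences = [target]
    manifest: dict = {
        "seed": spec.seed,
        "target_id": spec.target_id,
        "target_length": spec.target_length,
        "planted_paralog": None,
        "decoys": [],
    }
    if spec.paralog_identity is not None:
        start, end = spec.paralog_region or (0, spec.target_length)
        region = NucleotideSequence(str(target)[start:end], label="region")
        diverged = plant_paralog(
            region, spec.paralog_identity, seed=spec.seed + 1
        )
        flank = random_transcript(
            max(1, spec.decoy_length - len(diverged)),
            spec.gc_fraction,
            seed=spec.seed + 2,
            label="flank",
        )
        paralog_id = f"{spec.target_id}_paralog"
        sequences.append(
            NucleotideSequence(str(diverged) + str(flank), label=paralog_id)
        )
        manifest["planted_paralog"] = {
            "id": paralog_id,
            "identity": spec.paralog_identity,
            "template_region": [start, end],
            "substitutions": round((1.0 - spec.paralog_identity) * (end - start)),
        }
    for i in range(spec.n_decoys):
        decoy_id = f"decoy_{i + 1:02d}"
        sequences.append(
            random_transcript(
                spec.decoy_length,
                spec.gc_fraction,
                seed=spec.seed + 10 + i,
                label=decoy_id,
            )
        )
        manifest["decoys"].append(decoy_id)
    return Transcriptome(sequences=sequences, manifest=manifest)
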