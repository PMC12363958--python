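"""FASTA ingest/emit for validated nucleotide sequences (Biopython-backed)."""

from __future__ import annotations

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import NucleotideSequence


def read_fasta(path) -> list[NucleotideSequence]:
    """Read a (multi-)FASTA into validated sequences.

    Sequences are uppercased and RNA notation (U) is normalised to DNA (T);
    any other non-ACGT character fails validation at ingest.
    """
    sequences = []
    for record in SeqIO.parse(str(path), "fasta"):
        residues = str(record.seq).upper().replace("U", "T")
        sequences.append(NucleotideSequence(residues, label=record.id))
    return sequences


def write_fasta(sequences: list[NucleotideSequence], path, rna: bool = False) -> None:
    """Write sequences as FASTA; ``rna=True`` renders in U notation."""
    records = [
        SeqRecord(
            Seq(seq.as_rna() if rna else seq.residues),
            id=seq.label or f"seq_{i + 1}",
            description="",
        )
        for i, seq in enumerate(sequences)
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
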