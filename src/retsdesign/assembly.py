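"""Assembly of the two RETS fragment transcripts with feature bookkeeping.

Fragment 1 (5'->3'):  upstream exon (5'UTR + CDS up to the junction, whose
final 6 bases are the IGSBS ending in the splice-site T) + 9-nt upstream P1
half + helper stem A (GGATCA) + guide 1.

Fragment 2 (5'->3'):  guide 2 + helper stem B (TGATCC) + 11-nt downstream P1
half + 6-nt IGS + 387-nt core + downstream exon (rest of the CDS).

The two exons concatenate back to exactly ``utr5 + cds``; everything between
them is excised by the ribozyme on trans-splicing.  Designs are named with
the ``Target:RETS:Cargo`` notation.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .core import (
    CargoORF,
    RibozymeScaffold,
    default_scaffold,
)
from .errors import ConsistencyError, ParameterError, RETSDesignError
from .guide_design import GuidePair, TargetWindow
from .splice_sites import SpliceMode, SpliceSite, derive_igs, derive_igsbs


@dataclass(frozen=True)
class Segment:
    """One annotated fragment segment (0-based, half-open, sense strand)."""

    name: str
    start: int
    end: int


@dataclass(frozen=True)
class AnnotatedFragment:
    sequence: str
    segments: tuple[Segment, ...]

    def segment(self, name: str) -> Segment:
        for seg in self.segments:
            if seg.name == name:
                return seg
        raise KeyError(name)

    def extract(self, name: str) -> str:
        seg = self.segment(name)
        return self.sequence[seg.start : seg.end]


@dataclass(frozen=True)
class RETSDesign:
    """A complete design: scaffold + splice site + guide pair + fragments."""

    scaffold: RibozymeScaffold
    cargo: CargoORF
    site: SpliceSite
    guides: GuidePair
    target_id: str
    fragment_1: AnnotatedFragment
    fragment_2: AnnotatedFragment

    @property
    def notation_label(self) -> str:
        return f"{self.target_id}:RETS:{self.cargo.label}"

    @property
    def upstream_exon(self) -> str:
        return self.fragment_1.sequence[: self.site.junction]

    @property
    def downstream_exon(self) -> str:
        return self.fragment_2.extract("exon_downstream")


def assemble(
    scaffold: RibozymeScaffold,
    cargo: CargoORF,
    site: SpliceSite,
    guides: GuidePair,
    target_id: str | None = None,
) -> RETSDesign:
    """Assemble and annotate both fragment transcripts.

    Re-derives the IGSBS/IGS from the cargo at the site's junction and
    requires them to match the site (guarding against a site built from a
    different cargo), and requires the guides' window to come from the
    declared target.  Output is deterministic byte-for-byte.
    """
    try:
        igsbs = derive_igsbs(cargo, site.junction)
    except RETSDesignError as exc:
        raise ConsistencyError(
            f"splice site at junction {site.junction} is not derivable from "
            f"cargo {cargo.label!r}: {exc}"
        ) from exc
    if igsbs != site.igsbs or derive_igs(igsbs) != site.igs:
        raise ConsistencyError(
            f"splice site at junction {site.junction} is not re-derivable from "
            f"cargo {cargo.label!r}: IGSBS {site.igsbs} vs {igsbs}"
        )
    if target_id is None:
        target_id = guides.window.transcript_id
    elif guides.window.transcript_id != target_id:
        raise ConsistencyError(
            f"guides were designed against {guides.window.transcript_id!r}, "
            f"not declared target {target_id!r}"
        )

    message = cargo.message
    upstream_exon = message[: site.junction]
    downstream_exon = message[site.junction :]

    # --- fragment 1 ---
    parts1 = [
        ("exon_upstream", upstream_exon),
        ("p1_upstream", scaffold.p1_upstream),
        ("helper_stem_a", scaffold.helper_stem_a),
        ("guide_1", guides.guide_1),
    ]
    fragment_1 = _annotate(parts1, extra=_exon_subfeatures(cargo, site, upstream=True))

    # --- fragment 2 ---
    parts2 = [
        ("guide_2", guides.guide_2),
        ("helper_stem_b", scaffold.helper_stem_b),
        ("p1_downstream", scaffold.p1_downstream),
        ("igs", site.igs),
        ("core", scaffold.core),
        ("exon_downstream", downstream_exon),
    ]
    fragment_2 = _annotate(parts2)

    return RETSDesign(
        scaffold=scaffold,
        cargo=cargo,
        site=site,
        guides=guides,
        target_id=target_id,
        fragment_1=fragment_1,
        fragment_2=fragment_2,
    )


def _annotate(
    parts: list[tuple[str, str]], extra: list[Segment] | None = None
) -> AnnotatedFragment:
    segments = []
    cursor = 0
    for name, seq in parts:
        segments.append(Segment(name, cursor, cursor + len(seq)))
        cursor += len(seq)
    if extra:
        segments.extend(extra)
    return AnnotatedFragment(
        sequence="".join(seq for _, seq in parts), segments=tuple(segments)
    )


def _exon_subfeatures(
    cargo: CargoORF, site: SpliceSite, upstream: bool
) -> list[Segment]:
    """Sub-annotations inside fragment 1's upstream exon (UTR, IGSBS)."""
    segs = []
    if cargo.utr5:
        name = "omega_leader" if cargo.utr5.endswith("TTAC") else "utr5"
        segs.append(Segment(name, 0, len(cargo.utr5)))
    segs.append(Segment("igsbs", site.junction - 6, site.junction))
    return segs


def design_from_components(
    cargo: CargoORF,
    site: SpliceSite,
    window: TargetWindow,
    scaffold: RibozymeScaffold | None = None,
) -> RETSDesign:
    """Convenience: window -> guide pair -> assembled design."""
    from .guide_design import make_guide_pair

    return assemble(
        scaffold or default_scaffold(),
        cargo,
        site,
        make_guide_pair(window),
    )


# ---------------------------------------------------------------------------
# Emission: FASTA / GenBank / manifest
# ---------------------------------------------------------------------------


def _safe_name(label: str) -> str:
    return re.sub(r"[^A-Za-z0-9_.-]", "_", label)


def _records(design: RETSDesign, with_features: bool) -> list[SeqRecord]:
    records = []
    for frag_name, frag in (
        ("fragment1", design.fragment_1),
        ("fragment2", design.fragment_2),
    ):
        rec_id = f"{design.notation_label}_{frag_name}"
        record = SeqRecord(
            Seq(frag.sequence),
            id=rec_id,
            name=_safe_name(rec_id)[:16],
            description=f"RETS {frag_name} of {design.notation_label}",
        )
        record.annotations["molecule_type"] = "DNA"
        if with_features:
            for seg in frag.segments:
                record.features.append(
                    SeqFeature(
                        FeatureLocation(seg.start, seg.end, strand=1),
                        type="misc_feature",
                        qualifiers={"label": [seg.name]},
                    )
                )
        records.append(record)
    return records


def emit_constructs(design: RETSDesign, path, format: str = "fasta") -> list[SeqRecord]:
    """Write both fragments to ``path`` as FASTA or feature-annotated GenBank.

    GenBank features carry one ``misc_feature`` per defined segment (IGSBS,
    P1 halves, helper stems, guides, IGS, core, exons, leader); coordinates
    follow the 1-based inclusive GenBank convention on output while the
    in-memory model stays 0-based half-open.
    """
    format = format.lower()
    if format not in ("fasta", "genbank"):
        raise ParameterError(f"unknown output format {format!r}; use fasta or genbank")
    records = _records(design, with_features=(format == "genbank"))
    with open(path, "w") as fh:
        SeqIO.write(records, fh, format)
    return records


def design_manifest(design: RETSDesign) -> dict:
    """A machine-readable key-value capture of every segment and parameter."""
    return {
        "notation_label": design.notation_label,
        "target_id": design.target_id,
        "cargo": {
            "label": design.cargo.label,
            "utr5": design.cargo.utr5,
            "cds": design.cargo.cds,
        },
        "splice_site": {
            "junction": design.site.junction,
            "mode": design.site.mode.value,
            "igsbs": design.site.igsbs,
            "igs": design.site.igs,
            "codon_context": design.site.codon_context,
        },
        "guides": {
            "guide_1": design.guides.guide_1,
            "guide_2": design.guides.guide_2,
            "guide_length": design.guides.guide_length,
            "window": {
                "transcript_id": design.guides.window.transcript_id,
                "start": design.guides.window.start,
                "end": design.guides.window.end,
                "sub_window_1": design.guides.window.sub_window_1,
                "spacer": design.guides.window.spacer,
                "sub_window_2": design.guides.window.sub_window_2,
            },
        },
        "scaffold": {
            "p1_upstream": design.scaffold.p1_upstream,
            "p1_downstream": design.scaffold.p1_downstream,
            "core": design.scaffold.core,
            "helper_stem_a": design.scaffold.helper_stem_a,
            "helper_stem_b": design.scaffold.helper_stem_b,
        },
        "fragments": {
            "fragment_1": {
                "sequence": design.fragment_1.sequence,
                "segments": [
                    {"name": s.name, "start": s.start, "end": s.end}
                    for s in design.fragment_1.segments
                ],
            },
            "fragment_2": {
                "sequence": design.fragment_2.sequence,
                "segments": [
                    {"name": s.name, "start": s.start, "end": s.end}
                    for s in design.fragment_2.segments
                ],
            },
        },
        "cassette_placeholders": {
            "fragment_1_promoter": "pUBQ1",
            "fragment_2_promoter": "p35s",
            "terminator": "tHSP",
            "normalization": "Venus (pUBQ1/tHSP)",
        },
    }


def write_manifest(design: RETSDesign, path) -> None:
    with open(path, "w") as fh:
        json.dump(design_manifest(design), fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_manifest(path) -> RETSDesign:
    """Rebuild a design from its manifest, re-running assembly validation."""
    with open(path) as fh:
        data = json.load(fh)
    cargo = CargoORF(
        cds=data["cargo"]["cds"],
        utr5=data["cargo"]["utr5"],
        label=data["cargo"]["label"],
    )
    site = SpliceSite(
        junction=data["splice_site"]["junction"],
        mode=SpliceMode(data["splice_site"]["mode"]),
        igsbs=data["splice_site"]["igsbs"],
        igs=data["splice_site"]["igs"],
        codon_context=data["splice_site"]["codon_context"],
    )
    wdata = data["guides"]["window"]
    window = TargetWindow(
        transcript_id=wdata["transcript_id"],
        start=wdata["start"],
        end=wdata["end"],
        sub_window_1=wdata["sub_window_1"],
        spacer=wdata["spacer"],
        sub_window_2=wdata["sub_window_2"],
    )
    scaffold = RibozymeScaffold(**data["scaffold"])
    guides = GuidePair(
        guide_1=data["guides"]["guide_1"],
        guide_2=data["guides"]["guide_2"],
        window=window,
    )
    design = assemble(scaffold, cargo, site, guides, target_id=data["target_id"])
    for key, frag in (
        ("fragment_1", design.fragment_1),
        ("fragment_2", design.fragment_2),
    ):
        if frag.sequence != data["fragments"][key]["sequence"]:
            raise ConsistencyError(
                f"manifest {key} sequence does not match reassembly from its "
                "own components; the manifest was edited inconsistently"
            )
    return design
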