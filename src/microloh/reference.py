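"""Hybrid mapping reference: genome contig + inserted cassette as its own contig.

The reference used for zygosity calling keeps the wild-type exon in the
genome contig and adds only the integrated part of the targeting cassette
as a separate template, so wild-type-allele fragments map contiguously on
the genome while knock-in-allele fragments over the replaced exon map to
the cassette contig. A coordinate map relates knock-in-haplotype positions
to (contig, position) pairs in the hybrid reference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import Interval
from .locus import LocusModel

GENOME = "genome"
CASSETTE = "cassette_nongenomic"


@dataclass
class ReferenceSet:
    """Named contigs plus named analysis regions (0-based half-open)."""

    contigs: dict[str, str]
    regions: dict[str, Interval] = field(default_factory=dict)

    def validate(self) -> None:
        for name, iv in self.regions.items():
            if iv.contig not in self.contigs:
                raise ValueError(f"region {name!r} on unknown contig {iv.contig!r}")
            if iv.end > len(self.contigs[iv.contig]):
                raise ValueError(f"region {name!r} exceeds contig bounds")

    def region(self, name: str) -> Interval:
        try:
            return self.regions[name]
        except KeyError:
            raise KeyError(
                f"unknown region {name!r}; known: {sorted(self.regions)}"
            ) from None


def region_lookup(ref: ReferenceSet, name: str) -> Interval:
    return ref.region(name)


@dataclass
class CoordinateMap:
    """Junctions on the genome contig and the ki-haplotype <-> hybrid mapping."""

    junction_left: int  # genome position of the exon replacement start
    junction_right: int  # genome position just past the replaced exon
    inserted_len: int
    exon_len: int

    def ki_to_hybrid(self, pos: int) -> tuple[str, int]:
        """Map a knock-in-haplotype coordinate to (contig, position)."""
        if pos < 0:
            raise ValueError("negative coordinate")
        if pos < self.junction_left:
            return (GENOME, pos)
        if pos < self.junction_left + self.inserted_len:
            return (CASSETTE, pos - self.junction_left)
        return (GENOME, pos - self.inserted_len + self.exon_len)

    def hybrid_to_ki(self, contig: str, pos: int) -> int | None:
        """Inverse mapping; None for genome positions inside the replaced exon."""
        if contig == CASSETTE:
            if not (0 <= pos < self.inserted_len):
                raise ValueError("cassette position out of bounds")
            return self.junction_left + pos
        if contig == GENOME:
            if pos < self.junction_left:
                return pos
            if pos < self.junction_right:
                return None  # wt exon: absent from the ki haplotype
            return pos - self.exon_len + self.inserted_len
        raise ValueError(f"unknown contig {contig!r}")

    def to_json(self) -> str:
        return json.dumps(
            {
                "junction_left": self.junction_left,
                "junction_right": self.junction_right,
                "inserted_len": self.inserted_len,
                "exon_len": self.exon_len,
            },
            indent=2,
        )


def build_hybrid_reference(model: LocusModel) -> tuple[ReferenceSet, CoordinateMap]:
    """Genome contig as-is + inserted cassette segment contig + named regions."""
    model.validate()
    inserted = model.cassette_inserted_seq
    regions = {
        "exon2": model.exon2,
        "exon2_head": model.exon2_head,
        "insertion_window": model.analysis_window,
        "flank_left": model.flank_left,
        "flank_right": model.flank_right,
        "cassette_inserted": Interval(CASSETTE, 0, len(inserted)),
    }
    ref = ReferenceSet(contigs={GENOME: model.genome, CASSETTE: inserted}, regions=regions)
    ref.validate()
    cmap = CoordinateMap(
        junction_left=model.exon2.start,
        junction_right=model.exon2.end,
        inserted_len=len(inserted),
        exon_len=len(model.exon2),
    )
    return ref, cmap


def write_fasta(ref: ReferenceSet, path) -> None:
    """60-column-wrapped FASTA, one record per contig."""
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in ref.contigs.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path) -> ReferenceSet:
    """Read contigs (upper-cased); regions are not stored in FASTA."""
    contigs = {}
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            contigs[rec.id] = str(rec.seq).upper()
    return ReferenceSet(contigs=contigs)


def write_regions_bed(ref: ReferenceSet, path) -> None:
    """Regions as BED (0-based half-open), name in column 4."""
    with open(path, "w") as fh:
        for name, iv in sorted(ref.regions.items()):
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{name}\n")


def read_regions_bed(path) -> dict[str, Interval]:
    regions = {}
    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            if not raw.strip():
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: expected 4 BED columns")
            regions[parts[3]] = Interval(parts[0], int(parts[1]), int(parts[2]))
    return regions
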