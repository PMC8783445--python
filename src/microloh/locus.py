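"""Toy diploid knock-in locus.

Models a fractalkine-receptor-like locus in which the protein-coding exon
("exon2") of one or both alleles is replaced by a CreERT2-EYFP reporter
cassette. The wild-type haplotype is the genome contig as-is; the knock-in
haplotype carries the inserted part of the cassette in place of exon2.

Synthetic primer binding sites with the layout of a three-primer genotyping
assay (common forward upstream of the exon, a wild-type reverse inside the
exon, a mutant reverse inside the cassette, and a long-range reverse
downstream of the exon) are planted so the in-silico PCR module can
reproduce the band logic on the toy locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from ._util import Interval, random_dna, revcomp


class Genotype(str, Enum):
    """Knock-in zygosity: wt allele count 2/1/0, cassette count 0/1/2."""

    WT_WT = "WT_WT"
    KI_WT = "KI_WT"
    KI_KI = "KI_KI"

    @property
    def n_wt(self) -> int:
        return {"WT_WT": 2, "KI_WT": 1, "KI_KI": 0}[self.value]

    @property
    def n_ki(self) -> int:
        return 2 - self.n_wt


#: printed three-primer genotyping set for the CreERT2-EYFP knock-in
#: (common forward + allele-specific reverses + long-range target)
KNOCKIN_PRIMERS = {
    "common": "AAGACTCACGTGGACCTGCT",
    "wt_reverse": "AGGATGTTGACTTCCGAGTTG",
    "mutant_reverse": "CGGTTATTCAACTTGCACCA",
    "long_target": "TGTCCGTATAGGTTGGGAAA",
}

EXON2_HEAD_LEN = 290


@dataclass
class LocusModel:
    """Toy locus: genome contig, replaced exon, cassette and named regions.

    All intervals are 0-based half-open. ``cassette_inserted`` marks the part
    of the cassette sequence that is integrated into the genome (the analog
    of the vector's genomic-insert coordinates); the remainder stands in for
    plasmid backbone and never appears in any haplotype.
    """

    genome: str
    cassette_seq: str
    exon2: Interval
    cassette_inserted: Interval
    flank_left: Interval
    flank_right: Interval
    analysis_window: Interval
    primers: dict = field(default_factory=lambda: dict(KNOCKIN_PRIMERS))
    seed: int | None = None

    @property
    def exon2_head(self) -> Interval:
        """First 290 bases of the replaced exon (coverage read-out region)."""
        return Interval("genome", self.exon2.start, self.exon2.start + EXON2_HEAD_LEN)

    @property
    def cassette_inserted_seq(self) -> str:
        return self.cassette_seq[self.cassette_inserted.start : self.cassette_inserted.end]

    def haplotype(self, allele: str) -> str:
        """Sequence of one allele: 'wt' or 'ki'."""
        if allele == "wt":
            return self.genome
        if allele == "ki":
            return (
                self.genome[: self.exon2.start]
                + self.cassette_inserted_seq
                + self.genome[self.exon2.end :]
            )
        raise ValueError(f"unknown allele {allele!r}")

    def haplotypes(self, genotype: Genotype) -> list[str]:
        """The two haplotype sequences implied by a genotype."""
        return ["wt"] * genotype.n_wt + ["ki"] * genotype.n_ki

    def validate(self) -> None:
        if len(self.exon2) < EXON2_HEAD_LEN:
            raise ValueError(f"exon2 must be >= {EXON2_HEAD_LEN} bp")
        if not (0 <= self.exon2.start < self.exon2.end <= len(self.genome)):
            raise ValueError("exon2 outside genome contig")
        if not (
            self.analysis_window.start <= self.exon2.start
            and self.exon2.end <= self.analysis_window.end
        ):
            raise ValueError("exon2 must lie inside the analysis window")
        for fl in (self.flank_left, self.flank_right):
            if fl.overlaps(Interval("genome", self.exon2.start, self.exon2.end)):
                raise ValueError("flank overlaps exon2")
        if not (
            0 <= self.cassette_inserted.start
            < self.cassette_inserted.end
            <= len(self.cassette_seq)
        ):
            raise ValueError("cassette_inserted outside cassette sequence")


def make_locus_model(
    genome_len: int = 50_000,
    exon2_len: int = 1_500,
    cassette_len: int = 6_000,
    inserted_span: tuple[int, int] = (1_000, 6_000),
    seed: int = 0,
) -> LocusModel:
    """Build a deterministic toy locus.

    Defaults: 50 kb genome contig, 1.5 kb replaced exon centred in a
    40 kb analysis window, 6 kb cassette of which 5 kb is integrated.
    Primer sites are planted as exact 20-21-mers: the common forward
    200 bp upstream of the exon, the wild-type reverse 100 bp into the
    exon, the mutant reverse 150 bp into the inserted cassette segment
    and the long-range reverse 180 bp downstream of the exon.
    """
    if genome_len < 20_000 or genome_len > 200_000:
        raise ValueError("genome_len must be in [20000, 200000]")
    if exon2_len < EXON2_HEAD_LEN:
        raise ValueError(f"exon2_len must be >= {EXON2_HEAD_LEN}")
    if not (4_000 <= cassette_len <= 6_000):
        raise ValueError("cassette_len must be in [4000, 6000]")
    ins_lo, ins_hi = inserted_span
    if not (0 <= ins_lo < ins_hi <= cassette_len):
        raise ValueError("inserted_span outside cassette")

    rng = np.random.default_rng(seed)
    genome = list(random_dna(genome_len, rng))
    cassette = list(random_dna(cassette_len, rng))

    e_start = genome_len // 2 - exon2_len // 2
    exon2 = Interval("genome", e_start, e_start + exon2_len)

    def plant(target: list, pos: int, seq: str) -> None:
        target[pos : pos + len(seq)] = list(seq)

    p = KNOCKIN_PRIMERS
    plant(genome, exon2.start - 200, p["common"])
    plant(genome, exon2.start + 100, revcomp(p["wt_reverse"]))
    plant(genome, exon2.end + 180, revcomp(p["long_target"]))
    plant(cassette, ins_lo + 150, revcomp(p["mutant_reverse"]))

    # flanks sit >= 1 kb clear of the junctions so fragment pairs straddling
    # a junction on the knock-in haplotype cannot bias flank coverage
    win_half = min(20_000, e_start - 2_000, genome_len - exon2.end - 2_000)
    model = LocusModel(
        genome="".join(genome),
        cassette_seq="".join(cassette),
        exon2=exon2,
        cassette_inserted=Interval("cassette", ins_lo, ins_hi),
        flank_left=Interval("genome", exon2.start - 6_000, exon2.start - 1_000),
        flank_right=Interval("genome", exon2.end + 1_000, exon2.end + 6_000),
        analysis_window=Interval("genome", exon2.start - win_half, exon2.end + win_half),
        seed=seed,
    )
    model.validate()
    return model
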