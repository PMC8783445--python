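"""In-silico PCR: primer-site search, amplicon prediction and band logic.

Reproduces three-primer knock-in genotyping on the toy locus: a common
forward primer upstream of the replaced exon pairs with either a wild-type
reverse (inside the exon; product only from the wild-type allele) or a
mutant reverse (inside the cassette; product only from the knock-in allele),
plus a long-range reverse downstream of the exon that spans the whole
replaced region on both alleles with allele-distinct product sizes.
Product length is outer edge to outer edge (both primers included), as gel
sizes are read.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._util import revcomp
from .locus import Genotype, LocusModel

PRIMER_ROLES = ("common", "wt_reverse", "mutant_reverse", "long_target")


@dataclass(frozen=True)
class Primer:
    name: str
    sequence: str  # 5'->3'
    role: str = "common"

    def __post_init__(self):
        if not self.sequence or set(self.sequence.upper()) - set("ACGT"):
            raise ValueError(f"primer {self.name!r}: sequence must be non-empty ACGT")


@dataclass(frozen=True)
class AmpliconPrediction:
    forward: str
    reverse: str
    template: str
    start: int  # 0-based, 5' end of the forward site
    length: int

    @property
    def present(self) -> bool:
        return self.length > 0


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def find_primer_sites(
    template: str, primer: Primer, max_mismatch: int = 0
) -> list[tuple[int, str]]:
    """All (position, strand) binding sites; substitutions only, no indels.

    Plus-strand sites are matches of the primer itself; minus-strand sites
    are matches of its reverse complement on the plus strand (position of
    the site's leftmost template base in both cases).
    """
    template = template.upper()
    hits = []
    for strand, probe in (("+", primer.sequence.upper()), ("-", revcomp(primer.sequence.upper()))):
        L = len(probe)
        for i in range(len(template) - L + 1):
            if max_mismatch == 0:
                if template[i : i + L] == probe:
                    hits.append((i, strand))
            elif _mismatches(template[i : i + L], probe) <= max_mismatch:
                hits.append((i, strand))
    return sorted(hits)


def predict_amplicons(
    template: str,
    forward: Primer,
    reverse: Primer,
    max_len: int = 10_000,
    max_mismatch: int = 0,
    template_name: str = "template",
) -> list[AmpliconPrediction]:
    """Products for every forward plus-strand site with a downstream
    minus-strand reverse site within ``max_len`` (outer edge to outer edge)."""
    fwd_sites = [p for p, s in find_primer_sites(template, forward, max_mismatch) if s == "+"]
    rev_sites = [p for p, s in find_primer_sites(template, reverse, max_mismatch) if s == "-"]
    out = []
    rev_len = len(reverse.sequence)
    for f in fwd_sites:
        for r in rev_sites:
            if r >= f:
                length = r + rev_len - f
                if 0 < length <= max_len:
                    out.append(
                        AmpliconPrediction(
                            forward=forward.name,
                            reverse=reverse.name,
                            template=template_name,
                            start=f,
                            length=length,
                        )
                    )
    return out


@dataclass
class BandPattern:
    """Gel read-out: presence of the allele bands plus long-product sizes."""

    wt_band: bool
    mutant_band: bool
    long_sizes: tuple[int, ...]  # distinct long-range product sizes seen

    def as_dict(self) -> dict:
        return {
            "wt_band": self.wt_band,
            "mutant_band": self.mutant_band,
            "long_sizes": list(self.long_sizes),
        }


def genotype_from_bands(
    model: LocusModel, genotype: Genotype, primers: dict | None = None, max_len: int = 10_000
) -> BandPattern:
    """Deterministic band pattern for a genotype on the toy locus.

    A band is present iff any haplotype of the genotype yields the product.
    On one haplotype the wild-type and mutant bands are mutually exclusive
    because the cassette replaces the exon carrying the wild-type reverse
    site.
    """
    seqs = primers or model.primers
    p = {role: Primer(role, seqs[role], role) for role in PRIMER_ROLES}
    wt = mutant = False
    long_sizes: set[int] = set()
    for allele in set(model.haplotypes(genotype)):
        template = model.haplotype(allele)
        if predict_amplicons(template, p["common"], p["wt_reverse"], max_len):
            wt = True
        if predict_amplicons(template, p["common"], p["mutant_reverse"], max_len):
            mutant = True
        for amp in predict_amplicons(template, p["common"], p["long_target"], max_len):
            long_sizes.add(amp.length)
    return BandPattern(wt_band=wt, mutant_band=mutant, long_sizes=tuple(sorted(long_sizes)))
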