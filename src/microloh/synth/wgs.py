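"""Paired-end whole-genome read simulation from the toy diploid locus.

Fragments are drawn uniformly from the two haplotypes implied by the
genotype (50:50 in expectation for heterozygotes), with truncated-normal
fragment lengths, fixed-length FR-oriented mates, per-base substitution
errors and optional exact duplicate re-emission. Defaults echo a short-read
library: 350 +/- 50 bp fragments, 75 bp reads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .._util import revcomp
from ..locus import Genotype, LocusModel

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ReadPair:
    """One sequenced fragment: FR mates plus simulation ground truth."""

    template_id: str
    read1: str
    read2: str
    haplotype: str  # 'wt' or 'ki' (truth)
    frag_start: int  # truth, haplotype coordinates
    frag_end: int
    is_duplicate_emission: bool = False


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    # fixed random-stream consumption per read (two draws per base), so a
    # common seed yields common fragments across genotypes (paired designs)
    if error_rate <= 0:
        return seq
    hits = rng.random(len(seq)) < error_rate
    shifts = 1 + (rng.random(len(seq)) * 3).astype(int)
    if not hits.any():
        return seq
    arr = np.array(list(seq))
    subs = _BASES[(np.searchsorted(_BASES, arr[hits]) + shifts[hits]) % 4]
    arr[hits] = subs
    return "".join(arr)


def simulate_wgs_readpairs(
    model: LocusModel,
    genotype: Genotype,
    n_fragments: int,
    fragment_mean: float = 350.0,
    fragment_sd: float = 50.0,
    read_len: int = 75,
    error_rate: float = 1e-3,
    dup_rate: float = 0.0,
    seed: int = 0,
) -> list[ReadPair]:
    """Simulate read pairs; duplicates are exact re-emissions of chosen fragments."""
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    if read_len >= fragment_mean:
        raise ValueError("read_len must be smaller than fragment_mean")
    rng = np.random.default_rng(seed)
    haps = model.haplotypes(genotype)
    hap_seqs = {a: model.haplotype(a) for a in set(haps)}
    for a, s in hap_seqs.items():
        if len(s) <= read_len:
            raise ValueError(f"haplotype {a!r} shorter than a read")

    # float-based draws keep the random stream aligned across genotypes for
    # a common seed: fragments landing on the shared (wt) allele slot are
    # then identical between samples, enabling paired simulation designs
    which = (rng.random(n_fragments) >= 0.5).astype(int)  # uniform over alleles
    lengths = rng.normal(fragment_mean, fragment_sd, size=n_fragments)
    lengths = np.clip(lengths, read_len + 1, None).astype(int)
    start_u = rng.random(n_fragments)

    pairs: list[ReadPair] = []
    for i in range(n_fragments):
        allele = haps[which[i]]
        hap = hap_seqs[allele]
        flen = min(int(lengths[i]), len(hap) - 1)
        start = int(start_u[i] * (len(hap) - flen + 1))
        end = start + flen
        r1 = _mutate(hap[start : start + read_len], error_rate, rng)
        r2 = _mutate(revcomp(hap[end - read_len : end]), error_rate, rng)
        pairs.append(ReadPair(f"frag{i:07d}", r1, r2, allele, start, end))

    if dup_rate > 0:
        n_dups = rng.binomial(n_fragments, dup_rate)
        for j, k in enumerate(rng.integers(0, n_fragments, size=n_dups)):
            src = pairs[int(k)]
            pairs.append(
                ReadPair(
                    f"dup{j:07d}",
                    src.read1,
                    src.read2,
                    src.haplotype,
                    src.frag_start,
                    src.frag_end,
                    is_duplicate_emission=True,
                )
            )
    return pairs


def write_fastq_pair(pairs: list[ReadPair], path_r1, path_r2, qual_char: str = "I") -> None:
    """Write mates to two FASTQ files with a constant quality string."""
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.template_id}/1\n{p.read1}\n+\n{qual_char * len(p.read1)}\n")
            f2.write(f"@{p.template_id}/2\n{p.read2}\n+\n{qual_char * len(p.read2)}\n")


def read_fastq_pair(path_r1, path_r2) -> list[ReadPair]:
    """Read mate FASTQs back into ReadPair records (truth fields unset)."""
    def _read(path):
        out = []
        with open(path) as fh:
            lines = [ln.rstrip("\n") for ln in fh]
        for i in range(0, len(lines) - 3, 4):
            name = lines[i].lstrip("@").rsplit("/", 1)[0]
            out.append((name, lines[i + 1]))
        return out

    r1s, r2s = _read(path_r1), _read(path_r2)
    if len(r1s) != len(r2s):
        raise ValueError("mate files differ in read count")
    return [
        ReadPair(n1, s1, s2, haplotype="?", frag_start=-1, frag_end=-1)
        for (n1, s1), (_, s2) in zip(r1s, r2s)
    ]
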