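"""Shared small helpers: intervals, seeds, sequence ops."""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC ACGTN)."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def substage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage sub-seed below 2**31.

    crc32 of the stage name mixed with the global seed, so re-running a
    single stage reproduces its slice of a full run.
    """
    return (zlib.crc32(stage.encode()) ^ (int(global_seed) * 2654435761)) % (2**31)


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval on a named contig."""

    contig: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start <= self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )
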