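"""Read-pair mapping against the hybrid reference and the retention filters.

The aligner is deliberately simple, matched to toy-locus scale: exact-seed
lookup (three seed offsets per read, both strands) followed by ungapped
mismatch counting over the full read window. A unique best placement gets
MAPQ 60; two or more equally good placements get MAPQ 0; reads with no
placement under the mismatch ceiling stay unmapped. Pairs are proper when
both mates map to one contig in FR orientation within 10x the expected
fragment length.

Retention mirrors the conventional WGS clean-up: optical/PCR duplicates are
flagged on the fragment key (contig, outer span, orientation) keeping the
highest base-quality record, then pairs with MAPQ < 20 are removed.
Duplicate marking never removes records; filtering never flags them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._util import revcomp
from .reference import ReferenceSet

DEFAULT_SEED_LEN = 20
MAX_MISMATCH_FRAC = 0.10

# SAM flag bits
_PAIRED, _PROPER, _UNMAP, _MUNMAP = 0x1, 0x2, 0x4, 0x8
_REVERSE, _MREVERSE, _READ1, _READ2, _DUP = 0x10, 0x20, 0x40, 0x80, 0x400


@dataclass(frozen=True)
class MateAlignment:
    contig: str | None
    pos: int  # 0-based leftmost, -1 if unmapped
    strand: str  # '+', '-' or '*'
    n_mismatch: int
    seq: str

    @property
    def mapped(self) -> bool:
        return self.contig is not None

    @property
    def end(self) -> int:
        return self.pos + len(self.seq)


@dataclass(frozen=True)
class AlignmentRecord:
    """One template (read pair): per-mate placements plus pair-level fields."""

    template_id: str
    mate1: MateAlignment
    mate2: MateAlignment
    mapq: int
    proper: bool
    duplicate: bool = False
    base_quality_sum: int = 0

    @property
    def contig(self) -> str | None:
        return self.mate1.contig if self.proper else None

    @property
    def fragment_start(self) -> int:
        return min(self.mate1.pos, self.mate2.pos)

    @property
    def fragment_end(self) -> int:
        return max(self.mate1.end, self.mate2.end)

    @property
    def orientation(self) -> str:
        return self.mate1.strand + self.mate2.strand


@dataclass
class AlignmentSet:
    records: list[AlignmentRecord]
    reference_name: str = "hybrid"
    contig_lengths: dict[str, int] = field(default_factory=dict)
    provenance: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)


class ReferenceIndex:
    """Exact k-mer index over all contigs (forward strand)."""

    def __init__(self, ref: ReferenceSet, k: int = DEFAULT_SEED_LEN):
        if not ref.contigs:
            raise ValueError("empty reference")
        self.k = k
        self.arrays = {
            name: np.frombuffer(seq.encode(), dtype=np.uint8)
            for name, seq in ref.contigs.items()
        }
        self.index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in ref.contigs.items():
            for i in range(len(seq) - k + 1):
                self.index.setdefault(seq[i : i + k], []).append((name, i))

    def align_read(self, seq: str, max_mismatch: int | None = None):
        """Best ungapped placement -> (MateAlignment, mapq)."""
        L = len(seq)
        if max_mismatch is None:
            max_mismatch = int(L * MAX_MISMATCH_FRAC)
        k = self.k
        offsets = sorted({0, max(0, (L - k) // 2), max(0, L - k)})
        candidates: set[tuple[str, int, str]] = set()
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            arr = np.frombuffer(s.encode(), dtype=np.uint8)
            for off in offsets:
                for contig, hit in self.index.get(s[off : off + k], ()):
                    start = hit - off
                    if 0 <= start and start + L <= self.arrays[contig].size:
                        candidates.add((contig, start, strand))
            # keep the encoded array for mismatch counting
            if strand == "+":
                fwd_arr = arr
            else:
                rev_arr = arr

        best: list[tuple[str, int, str]] = []
        best_mm = max_mismatch + 1
        for contig, start, strand in candidates:
            window = self.arrays[contig][start : start + L]
            q = fwd_arr if strand == "+" else rev_arr
            mm = int((window != q).sum())
            if mm < best_mm:
                best_mm, best = mm, [(contig, start, strand)]
            elif mm == best_mm:
                best.append((contig, start, strand))
        if not best:
            return MateAlignment(None, -1, "*", 0, seq), 0
        contig, start, strand = min(best)
        mapq = 60 if len(best) == 1 else 0
        return MateAlignment(contig, start, strand, best_mm, seq), mapq


def map_readpairs(
    pairs,
    ref: ReferenceSet,
    k: int = DEFAULT_SEED_LEN,
    fragment_mean: float = 350.0,
    base_quality: int = 40,
) -> AlignmentSet:
    """Map simulated read pairs; see module docstring for the placement rules."""
    if not pairs:
        raise ValueError("no reads to map")
    index = ReferenceIndex(ref, k=k)
    max_tlen = 10.0 * fragment_mean
    records = []
    for rp in pairs:
        a1, q1 = index.align_read(rp.read1)
        a2, q2 = index.align_read(rp.read2)
        mapq = min(q1, q2) if (a1.mapped and a2.mapped) else 0
        proper = bool(
            a1.mapped
            and a2.mapped
            and a1.contig == a2.contig
            and {a1.strand, a2.strand} == {"+", "-"}
            and _fr_oriented(a1, a2)
            and max(a1.end, a2.end) - min(a1.pos, a2.pos) <= max_tlen
        )
        records.append(
            AlignmentRecord(
                template_id=rp.template_id,
                mate1=a1,
                mate2=a2,
                mapq=mapq,
                proper=proper,
                base_quality_sum=base_quality * (len(rp.read1) + len(rp.read2)),
            )
        )
    return AlignmentSet(
        records=records,
        contig_lengths={n: a.size for n, a in index.arrays.items()},
        provenance=[f"mapped {len(records)} pairs, seed k={k}"],
    )


def _fr_oriented(a1: MateAlignment, a2: MateAlignment) -> bool:
    fwd, rev = (a1, a2) if a1.strand == "+" else (a2, a1)
    return fwd.pos <= rev.pos


def mark_duplicates(aset: AlignmentSet) -> AlignmentSet:
    """Flag duplicate proper pairs; keep the highest base-quality record.

    Duplicate key: (contig, fragment_start, fragment_end, orientation).
    Ties break to the lexicographically smallest template_id. Idempotent;
    never removes records.
    """
    groups: dict[tuple, list[AlignmentRecord]] = {}
    for rec in aset.records:
        if rec.proper:
            key = (rec.contig, rec.fragment_start, rec.fragment_end, rec.orientation)
            groups.setdefault(key, []).append(rec)
    keep_ids = set()
    for recs in groups.values():
        keeper = min(recs, key=lambda r: (-r.base_quality_sum, r.template_id))
        keep_ids.add(keeper.template_id)
    out = [
        replace(rec, duplicate=(rec.proper and rec.template_id not in keep_ids))
        for rec in aset.records
    ]
    n_flagged = sum(r.duplicate for r in out)
    return AlignmentSet(
        records=out,
        reference_name=aset.reference_name,
        contig_lengths=aset.contig_lengths,
        provenance=aset.provenance + [f"mark_duplicates flagged {n_flagged}"],
    )


def filter_alignments(
    aset: AlignmentSet,
    mapq_min: int = 20,
    drop_duplicates: bool = True,
    require_proper: bool = True,
) -> AlignmentSet:
    """Retain pairs passing dedup, MAPQ and (by default) the proper-pair rule.

    Order: duplicates first, then MAPQ, matching the provenance log. With
    ``require_proper=False`` cross-contig (junction-informative) pairs whose
    mates both map are retained as well.
    """
    removed = {"duplicate": 0, "mapq": 0, "not_proper": 0}
    kept = []
    for rec in aset.records:
        if drop_duplicates and rec.duplicate:
            removed["duplicate"] += 1
        elif rec.mapq < mapq_min:
            removed["mapq"] += 1
        elif not rec.proper and (require_proper or not (rec.mate1.mapped and rec.mate2.mapped)):
            removed["not_proper"] += 1
        else:
            kept.append(rec)
    log = aset.provenance + [
        "filter order: dedup -> MAPQ",
        f"removed duplicate={removed['duplicate']} mapq<{mapq_min}={removed['mapq']} "
        f"not_proper={removed['not_proper']}; kept {len(kept)} of {len(aset.records)}",
    ]
    return AlignmentSet(
        records=kept,
        reference_name=aset.reference_name,
        contig_lengths=aset.contig_lengths,
        provenance=log,
    )


# ---------------------------------------------------------------- SAM I/O


def write_sam(aset: AlignmentSet, path) -> None:
    """Valid minimal SAM: @SQ per contig, two lines per template, 1-based POS."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for name, length in aset.contig_lengths.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for rec in aset.records:
            for mate, other, first in ((rec.mate1, rec.mate2, True), (rec.mate2, rec.mate1, False)):
                flag = _PAIRED | (_READ1 if first else _READ2)
                if rec.proper:
                    flag |= _PROPER
                if not mate.mapped:
                    flag |= _UNMAP
                if not other.mapped:
                    flag |= _MUNMAP
                if mate.strand == "-":
                    flag |= _REVERSE
                if other.strand == "-":
                    flag |= _MREVERSE
                if rec.duplicate:
                    flag |= _DUP
                rname = mate.contig or "*"
                pos = mate.pos + 1 if mate.mapped else 0
                cigar = f"{len(mate.seq)}M" if mate.mapped else "*"
                rnext = (
                    "="
                    if (other.mapped and other.contig == mate.contig)
                    else (other.contig or "*")
                )
                pnext = other.pos + 1 if other.mapped else 0
                tlen = 0
                if rec.proper:
                    span = rec.fragment_end - rec.fragment_start
                    tlen = span if mate.strand == "+" else -span
                fh.write(
                    f"{rec.template_id}\t{flag}\t{rname}\t{pos}\t{rec.mapq}\t{cigar}"
                    f"\t{rnext}\t{pnext}\t{tlen}\t{mate.seq}\t*\tBQ:i:{rec.base_quality_sum}\n"
                )


def read_sam(path) -> AlignmentSet:
    """Parse SAM back into an AlignmentSet (POS converted to 0-based)."""
    contig_lengths: dict[str, int] = {}
    mates: dict[str, dict] = {}
    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("@"):
                if line.startswith("@SQ"):
                    fields = dict(f.split(":", 1) for f in line.split("\t")[1:])
                    contig_lengths[fields["SN"]] = int(fields["LN"])
                continue
            parts = line.split("\t")
            if len(parts) < 11:
                raise ValueError(f"{path}:{ln}: truncated SAM record")
            if not contig_lengths:
                raise ValueError(f"{path}:{ln}: alignment before any @SQ header line")
            qname, flag, rname, pos = parts[0], int(parts[1]), parts[2], int(parts[3])
            mapq, seq = int(parts[4]), parts[9]
            if rname != "*" and pos - 1 + len(seq) > contig_lengths.get(rname, 0):
                raise ValueError(f"{path}:{ln}: coordinate overflow on {rname}")
            bq = 0
            for tag in parts[11:]:
                if tag.startswith("BQ:i:"):
                    bq = int(tag[5:])
            mate = MateAlignment(
                contig=None if (flag & _UNMAP or rname == "*") else rname,
                pos=pos - 1 if not (flag & _UNMAP) else -1,
                strand="*" if flag & _UNMAP else ("-" if flag & _REVERSE else "+"),
                n_mismatch=0,
                seq=seq,
            )
            slot = mates.setdefault(
                qname, {"mapq": mapq, "proper": bool(flag & _PROPER),
                        "dup": bool(flag & _DUP), "bq": bq}
            )
            slot["m1" if flag & _READ1 else "m2"] = mate
    records = []
    for qname, slot in mates.items():
        if "m1" not in slot or "m2" not in slot:
            raise ValueError(f"template {qname!r} missing a mate")
        records.append(
            AlignmentRecord(
                template_id=qname,
                mate1=slot["m1"],
                mate2=slot["m2"],
                mapq=slot["mapq"],
                proper=slot["proper"],
                duplicate=slot["dup"],
                base_quality_sum=slot["bq"],
            )
        )
    records.sort(key=lambda r: r.template_id)
    return AlignmentSet(records=records, contig_lengths=contig_lengths)
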