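"""Physical-coverage tracks and knock-in zygosity / LOH calling.

Physical coverage counts, per base, the number of retained fragments whose
outer paired-end span contains that base (fragment-span coverage, not
read-base coverage). Allele dosage at the replaced exon is read out as a
coverage ratio against flanking single-copy-per-allele regions:

    wt_dosage = 2 * cov(exon) / cov(flank)
    ki_dosage = 2 * cov(cassette) / cov(flank)

so the expected (wt, ki) dosage is (2,0), (1,1), (0,2) for wild-type,
heterozygous and homozygous knock-in samples. Junction evidence (fragments
contiguously spanning an insertion junction on the genome vs pairs split
between genomic flank and cassette contig) and the exon/cassette fragment
counts are folded into a Poisson likelihood whose per-copy rate is anchored
on the flanks; the call is the maximum-likelihood genotype with a
log-likelihood-ratio confidence against the runner-up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import Interval
from .align import AlignmentSet
from .locus import Genotype
from .reference import CASSETTE, GENOME, CoordinateMap


@dataclass
class PhysicalCoverageTrack:
    contig: str
    counts: np.ndarray  # per-base fragment-span counts
    n_fragments: int  # retained fragments in the whole set (normalization)

    @property
    def per_million(self) -> float:
        return self.n_fragments / 1e6


def physical_coverage(aset: AlignmentSet, contig: str) -> PhysicalCoverageTrack:
    """Difference-array accumulation of proper-pair outer spans on one contig."""
    if contig not in aset.contig_lengths:
        raise KeyError(f"unknown contig {contig!r}")
    n = aset.contig_lengths[contig]
    diff = np.zeros(n + 1, dtype=np.int64)
    for rec in aset.records:
        if rec.proper and rec.contig == contig:
            diff[rec.fragment_start] += 1
            diff[min(rec.fragment_end, n)] -= 1
    return PhysicalCoverageTrack(
        contig=contig,
        counts=np.cumsum(diff[:-1]),
        n_fragments=sum(1 for r in aset.records if r.proper),
    )


def region_mean_coverage(
    track: PhysicalCoverageTrack, region: Interval, normalize: bool = True
) -> float:
    """Mean C(b) over the region, per million retained fragments if normalize."""
    if region.contig != track.contig:
        raise ValueError(f"region on {region.contig!r}, track on {track.contig!r}")
    if len(region) == 0:
        raise ValueError("zero-length region")
    if region.end > track.counts.size:
        raise ValueError("region outside contig")
    mean = float(track.counts[region.start : region.end].mean())
    if normalize:
        if track.n_fragments == 0:
            return 0.0
        mean /= track.per_million
    return mean


def write_bedgraph(track: PhysicalCoverageTrack, path) -> None:
    """Run-length-compressed bedGraph of the coverage track."""
    c = track.counts
    edges = np.flatnonzero(np.diff(c)) + 1
    starts = np.concatenate([[0], edges])
    ends = np.concatenate([edges, [c.size]])
    with open(path, "w") as fh:
        for s, e in zip(starts, ends):
            fh.write(f"{track.contig}\t{s}\t{e}\t{int(c[s])}\n")


@dataclass
class DosageEstimate:
    cov_exon2: float
    cov_cassette: float
    cov_flank: float

    @property
    def wt_dosage(self) -> float:
        return 2.0 * self.cov_exon2 / self.cov_flank

    @property
    def ki_dosage(self) -> float:
        return 2.0 * self.cov_cassette / self.cov_flank


def estimate_dosage(
    cov_exon2: float, cov_cassette: float, cov_flank: float
) -> DosageEstimate:
    if cov_flank <= 0:
        raise ValueError("insufficient data: flank coverage must be positive")
    if min(cov_exon2, cov_cassette) < 0:
        raise ValueError("coverages must be non-negative")
    return DosageEstimate(cov_exon2, cov_cassette, cov_flank)


@dataclass
class JunctionEvidence:
    n_wt_spanning: int  # fragments strictly containing a junction on the genome
    n_ki_supporting: int  # pairs split genome-flank / cassette contig


def count_junction_pairs(aset: AlignmentSet, cmap: CoordinateMap) -> JunctionEvidence:
    """Count wt-spanning and ki-supporting fragments around the insertion site.

    Spanning requires strict containment of the junction point (>= 1 bp on
    each side of the outer fragment span). Ki support requires one mate on
    the genome contig and the other on the cassette contig, both mapped.
    """
    n_span = 0
    n_split = 0
    for rec in aset.records:
        if rec.proper and rec.contig == GENOME:
            for j in (cmap.junction_left, cmap.junction_right):
                if rec.fragment_start < j < rec.fragment_end:
                    n_span += 1
                    break
        elif rec.mate1.mapped and rec.mate2.mapped and not rec.proper:
            contigs = {rec.mate1.contig, rec.mate2.contig}
            if contigs == {GENOME, CASSETTE}:
                n_split += 1
    return JunctionEvidence(n_wt_spanning=n_span, n_ki_supporting=n_split)


_EXPECTED_COPIES = {
    Genotype.WT_WT: (2, 0),
    Genotype.KI_WT: (1, 1),
    Genotype.KI_KI: (0, 2),
}


@dataclass
class GenotypeCall:
    genotype: Genotype | None
    log_likelihoods: dict
    llr: float  # best minus runner-up; >= 0
    dosage: DosageEstimate | None
    junctions: JunctionEvidence | None


def _poisson_loglik(obs: float, lam: float, floor: float = 0.05) -> float:
    lam = max(lam, floor)  # floor absorbs mismapping noise at zero copies
    from scipy.special import gammaln

    return float(obs * np.log(lam) - lam - gammaln(obs + 1.0))


def call_genotype(
    dosage: DosageEstimate,
    junctions: JunctionEvidence | None = None,
    depth_scale: float = 1.0,
) -> GenotypeCall:
    """Maximum-Poisson-likelihood genotype from dosage (+ junction) evidence.

    Coverage values act as Poisson pseudo-counts after scaling by
    ``depth_scale`` (use raw, unnormalized mean coverages and leave the
    scale at 1 for fragment-depth-sized counts). The per-copy rate is
    cov_flank / 2. Junction counts, when given, enter as independent
    Poisson terms with the same per-copy rate.
    """
    if dosage.cov_flank <= 0:
        return GenotypeCall(None, {}, 0.0, dosage, junctions)
    per_copy = depth_scale * dosage.cov_flank / 2.0
    obs_exon = depth_scale * dosage.cov_exon2
    obs_cas = depth_scale * dosage.cov_cassette

    logl = {}
    for gt, (c_wt, c_ki) in _EXPECTED_COPIES.items():
        ll = _poisson_loglik(obs_exon, c_wt * per_copy)
        ll += _poisson_loglik(obs_cas, c_ki * per_copy)
        if junctions is not None:
            ll += _poisson_loglik(junctions.n_wt_spanning, c_wt * per_copy)
            ll += _poisson_loglik(junctions.n_ki_supporting, c_ki * per_copy)
        logl[gt] = ll
    ranked = sorted(logl, key=logl.get, reverse=True)
    llr = logl[ranked[0]] - logl[ranked[1]]
    return GenotypeCall(
        genotype=ranked[0],
        log_likelihoods={g.value: v for g, v in logl.items()},
        llr=llr,
        dosage=dosage,
        junctions=junctions,
    )


def dosage_from_alignments(aset: AlignmentSet, regions: dict) -> DosageEstimate:
    """Convenience: unnormalized mean coverages over the named analysis regions."""
    genome_track = physical_coverage(aset, GENOME)
    cassette_track = physical_coverage(aset, CASSETTE)
    cov_exon = region_mean_coverage(genome_track, regions["exon2_head"], normalize=False)
    cov_cas = region_mean_coverage(cassette_track, regions["cassette_inserted"], normalize=False)
    cov_flank = 0.5 * (
        region_mean_coverage(genome_track, regions["flank_left"], normalize=False)
        + region_mean_coverage(genome_track, regions["flank_right"], normalize=False)
    )
    return estimate_dosage(cov_exon, cov_cas, cov_flank)
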