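"""Transcript-evidence filtering of RNA-seq reads against a 5' UTR region.

Tests whether a read set contains evidence for an alternatively spliced
transcript placing an AUG start codon upstream of (and in frame with) the
tandem near-cognate site.  Reads sharing at least one exact k-mer with the
UTR region are retained (k = 20 by default), deduplicated exactly, and then
filtered with the published pattern ``ATG(.)*AGGATT``: an ATG anywhere 5'
of an occurrence of the anchor within the read.  A stricter frame-aware
mode additionally requires the ATG-to-anchor spacing to be a multiple of 3.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .sequence_io import SequenceRecord, reverse_complement

__all__ = [
    "EvidenceSummary",
    "match_reads_by_kmer",
    "unique_reads",
    "find_upstream_atg_reads",
    "summarize_evidence",
]


@dataclass(frozen=True)
class EvidenceSummary:
    """Counts from the match -> dedup -> pattern filter chain.

    Invariant: n_with_upstream_atg_pattern <= n_unique <= n_matching_region
    <= n_reads_in, and pattern_frame_aware_count <= n_with_upstream_atg_pattern.
    """

    n_reads_in: int
    n_matching_region: int
    n_unique: int
    n_with_upstream_atg_pattern: int
    pattern_frame_aware_count: int

    def __post_init__(self) -> None:
        chain = (
            self.pattern_frame_aware_count <= self.n_with_upstream_atg_pattern
            <= self.n_unique <= self.n_matching_region <= self.n_reads_in
        )
        if not chain:
            raise ValueError("filter-chain counts are not monotone")


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def match_reads_by_kmer(
    reads: list[SequenceRecord],
    region: str,
    k: int = 20,
    include_reverse_complement: bool = False,
) -> list[SequenceRecord]:
    """Retain reads sharing >= 1 exact k-mer with ``region``.

    Forward orientation by default; ``include_reverse_complement`` also
    accepts reads whose reverse complement shares a k-mer.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(region) < k:
        raise ValueError(f"region ({len(region)} nt) shorter than k={k}")
    region_kmers = _kmers(region, k)
    out = []
    for read in reads:
        hit = not region_kmers.isdisjoint(_kmers(read.seq, k))
        if not hit and include_reverse_complement:
            hit = not region_kmers.isdisjoint(_kmers(reverse_complement(read.seq), k))
        if hit:
            out.append(read)
    return out


def unique_reads(reads: list[SequenceRecord]) -> list[SequenceRecord]:
    """Exact-sequence deduplication; first occurrence kept, order preserved."""
    seen: set[str] = set()
    out = []
    for read in reads:
        if read.seq not in seen:
            seen.add(read.seq)
            out.append(read)
    return out


def find_upstream_atg_reads(
    reads: list[SequenceRecord],
    anchor: str = "AGGATT",
    frame_aware: bool = False,
    include_reverse_complement: bool = False,
) -> list[SequenceRecord]:
    """Reads with an ATG 5' of an occurrence of ``anchor`` within the read.

    Default mode is the literal published pattern (unconstrained spacing);
    ``frame_aware`` additionally requires (anchor_start - atg_start) % 3 == 0.
    """
    if len(anchor) != 6:
        raise ValueError("anchor must be a 6-mer (two codons)")
    out = []
    for read in reads:
        seqs = [read.seq]
        if include_reverse_complement:
            seqs.append(reverse_complement(read.seq))
        if any(_has_upstream_atg(s, anchor, frame_aware) for s in seqs):
            out.append(read)
    return out


def _has_upstream_atg(seq: str, anchor: str, frame_aware: bool) -> bool:
    if not frame_aware:
        return re.search("ATG(.)*" + anchor, seq) is not None
    atg_starts = [m.start() for m in re.finditer("(?=ATG)", seq)]
    anchor_starts = [m.start() for m in re.finditer("(?=" + re.escape(anchor) + ")", seq)]
    return any(
        a < b and (b - a) % 3 == 0 for a in atg_starts for b in anchor_starts
    )


def summarize_evidence(
    reads: list[SequenceRecord],
    region: str,
    anchor: str = "AGGATT",
    k: int = 20,
    include_reverse_complement: bool = False,
) -> EvidenceSummary:
    """Run the match -> dedup -> pattern chain and tabulate counts."""
    matching = match_reads_by_kmer(
        reads, region, k=k, include_reverse_complement=include_reverse_complement
    )
    deduped = unique_reads(matching)
    pattern_hits = find_upstream_atg_reads(
        deduped, anchor=anchor, frame_aware=False,
        include_reverse_complement=include_reverse_complement,
    )
    frame_hits = find_upstream_atg_reads(
        pattern_hits, anchor=anchor, frame_aware=True,
        include_reverse_complement=include_reverse_complement,
    )
    return EvidenceSummary(
        n_reads_in=len(reads),
        n_matching_region=len(matching),
        n_unique=len(deduped),
        n_with_upstream_atg_pattern=len(pattern_hits),
        pattern_frame_aware_count=len(frame_hits),
    )
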