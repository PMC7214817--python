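"""Frame-aware PTS2 motif scanning in upstream sequences.

A type 2 peroxisomal targeting signal (PTS2) is an N-terminal nonapeptide
matching the consensus (R/K)-(L/V/I)-x5-(H/Q)-(L/A), recognized by the
import receptor Pex7.  Here the motif is searched not in an annotated
protein but in the translation of a gene's 5' UTR *in the CDS reading
frame*: a match that lies upstream of the annotated start codon, with no
in-frame AUG above it, is a "cryptic" signal — it can only be expressed by
non-canonical initiation at an upstream near-cognate codon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .sequence_io import GeneLocus, translate_codons, upstream_index

__all__ = [
    "Pts2Pattern",
    "MotifHit",
    "CrypticAssessment",
    "match_pts2",
    "scan_upstream_inframe",
    "assess_cryptic",
    "select_primary_hit",
    "hits_to_rows",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class Pts2Pattern:
    """The PTS2 consensus as four anchored residue classes plus a spacer.

    Defaults encode (R/K)-(L/V/I)-xxxxx-(H/Q)-(L/A); ``spacer_len=1``
    reproduces the compact expression ``[RK][LVI].[HQ][LA]``.  Spacer
    positions accept any standard amino acid; ``'*'`` (stop) and ``'X'``
    (from N-containing codons) fail every position.
    """

    class1: frozenset = frozenset("RK")
    class2: frozenset = frozenset("LVI")
    spacer_len: int = 5
    class3: frozenset = frozenset("HQ")
    class4: frozenset = frozenset("LA")

    def __post_init__(self) -> None:
        if self.spacer_len < 0:
            raise ValueError("spacer_len must be >= 0")
        for name in ("class1", "class2", "class3", "class4"):
            cls = getattr(self, name)
            object.__setattr__(self, name, frozenset(cls))
            if not getattr(self, name):
                raise ValueError(f"{name} must be non-empty")

    @property
    def motif_length(self) -> int:
        return 4 + self.spacer_len

    def window_matches(self, window: str) -> bool:
        if len(window) != self.motif_length:
            return False
        if window[0] not in self.class1 or window[1] not in self.class2:
            return False
        spacer = window[2 : 2 + self.spacer_len]
        if any(aa not in _STANDARD_AA for aa in spacer):
            return False
        return window[-2] in self.class3 and window[-1] in self.class4


@dataclass(frozen=True)
class MotifHit:
    """A PTS2 consensus match in the CDS reading frame of the upstream sequence.

    ``aa_start`` is the 1-based residue index within the translated upstream
    frame; ``nt_start``/``nt_end`` are upstream coordinates of the first and
    last nucleotide of the encoding region (``nt_start % 3 == 0``).
    """

    gene_id: str
    peptide: str
    aa_start: int
    nt_start: int
    nt_end: int


@dataclass(frozen=True)
class CrypticAssessment:
    """Whether a motif hit is cryptic: expressible only by non-AUG initiation.

    ``is_cryptic`` is true iff no in-frame ATG lies upstream of the hit.
    In-frame stops between the hit and the CDS are reported (they disqualify
    initiation candidates, not the motif itself).
    """

    hit: MotifHit
    upstream_inframe_atg_positions: tuple
    inframe_stop_positions_between_hit_and_cds: tuple

    @property
    def is_cryptic(self) -> bool:
        return not self.upstream_inframe_atg_positions


def match_pts2(peptide: str, pattern: Pts2Pattern | None = None) -> list[int]:
    """All (possibly overlapping) 1-based positions where the consensus matches."""
    pattern = pattern or Pts2Pattern()
    m = pattern.motif_length
    return [
        i + 1
        for i in range(len(peptide) - m + 1)
        if pattern.window_matches(peptide[i : i + m])
    ]


def inframe_start(locus: GeneLocus) -> int:
    """5'-most in-frame upstream coordinate: start of the maximal in-frame suffix."""
    return -3 * (locus.utr_len // 3)


def translate_upstream_frame(locus: GeneLocus) -> str:
    """Translation of the maximal in-frame suffix of the upstream sequence."""
    start = inframe_start(locus)
    if start == 0:
        return ""
    return translate_codons(locus.upstream_seq[upstream_index(locus, start) :])


def scan_upstream_inframe(
    locus: GeneLocus, pattern: Pts2Pattern | None = None
) -> list[MotifHit]:
    """Scan the in-frame translation of the upstream sequence for PTS2 matches.

    Hits may span in-frame stop codons; crypticity and reachability are
    assessed separately by :func:`assess_cryptic`.
    """
    pattern = pattern or Pts2Pattern()
    if locus.utr_len < 3 * pattern.motif_length:
        warnings.warn(
            f"{locus.gene_id}: upstream sequence ({locus.utr_len} nt) shorter than "
            f"the {pattern.motif_length}-residue motif"
        )
        return []
    frame_start = inframe_start(locus)
    peptide = translate_upstream_frame(locus)
    hits = []
    for aa_pos in match_pts2(peptide, pattern):
        nt_start = frame_start + 3 * (aa_pos - 1)
        nt_end = nt_start + 3 * pattern.motif_length - 1
        hits.append(
            MotifHit(
                gene_id=locus.gene_id,
                peptide=peptide[aa_pos - 1 : aa_pos - 1 + pattern.motif_length],
                aa_start=aa_pos,
                nt_start=nt_start,
                nt_end=nt_end,
            )
        )
    return hits


def assess_cryptic(locus: GeneLocus, hit: MotifHit) -> CrypticAssessment:
    """List upstream in-frame ATGs and in-frame stops between hit and CDS."""
    frame_start = inframe_start(locus)
    atgs = [
        p
        for p in range(frame_start, hit.nt_start, 3)
        if locus.upstream_codon(p) == "ATG"
    ]
    stops = [
        p
        for p in range(hit.nt_start + 3, 0, 3)
        if locus.upstream_codon(p) in STOP_CODONS
    ]
    return CrypticAssessment(
        hit=hit,
        upstream_inframe_atg_positions=tuple(atgs),
        inframe_stop_positions_between_hit_and_cds=tuple(stops),
    )


def select_primary_hit(
    locus: GeneLocus, hits: list[MotifHit]
) -> tuple[MotifHit, CrypticAssessment] | None:
    """Pick the 3'-most cryptic hit (closest to the CDS); None if no cryptic hit."""
    for hit in sorted(hits, key=lambda h: h.nt_start, reverse=True):
        assessment = assess_cryptic(locus, hit)
        if assessment.is_cryptic:
            return hit, assessment
    return None


def hits_to_rows(locus: GeneLocus, hits: list[MotifHit]) -> list[dict]:
    """Stable TSV-ready rows: one per hit with its crypticity assessment."""
    rows = []
    for hit in hits:
        a = assess_cryptic(locus, hit)
        rows.append(
            {
                "gene_id": hit.gene_id,
                "nt_start": hit.nt_start,
                "nt_end": hit.nt_end,
                "peptide": hit.peptide,
                "is_cryptic": a.is_cryptic,
                "upstream_atg_count": len(a.upstream_inframe_atg_positions),
                "stop_count": len(a.inframe_stop_positions_between_hit_and_cds),
            }
        )
    return rows
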