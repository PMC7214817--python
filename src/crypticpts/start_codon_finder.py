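"""Near-cognate start-codon enumeration and N-terminal extension prediction.

Non-AUG translation initiation typically occurs at near-cognate start
codons: the nine codons that differ from AUG by a single base.  For a
cryptic PTS2, an in-frame near-cognate codon 5' of the motif can initiate
an N-terminally extended isoform that carries the targeting signal.  Two
consecutive in-frame near-cognates form a tandem pair (the validated
pgd1-type site is the pair AGG AUU at -63..-58).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .pts_scanner import MotifHit, Pts2Pattern, STOP_CODONS, inframe_start
from .sequence_io import GeneLocus, translate_codons, upstream_index

__all__ = [
    "InitiationCandidate",
    "near_cognate_codons",
    "find_initiation_candidates",
    "find_tandem_pairs",
    "predict_extension",
    "substitute_codons",
    "rank_candidates",
    "candidates_to_rows",
]


def near_cognate_codons() -> frozenset:
    """The 9 codons at Hamming distance 1 from ATG (ATG itself excluded)."""
    out = set()
    for i, base in enumerate("ATG"):
        for alt in "ACGT":
            if alt != base:
                out.add("ATG"[:i] + alt + "ATG"[i + 1 :])
    return frozenset(out)


NEAR_COGNATE = near_cognate_codons()


@dataclass(frozen=True)
class InitiationCandidate:
    """An in-frame (near-cognate or ATG) codon upstream of a cryptic PTS2.

    ``extension_len`` counts codons between the candidate and the annotated
    start (``-nt_start/3``); ``extension_peptide`` is the predicted
    N-terminal extension, and ``pts2_residue_span`` the 1-based residue
    interval the motif occupies within it.  ``blocked_by_stop`` marks
    candidates separated from the CDS by an in-frame stop.
    """

    gene_id: str
    codon: str
    nt_start: int
    is_near_cognate: bool
    blocked_by_stop: bool
    tandem_with: int | None = None
    extension_len: int | None = None
    extension_peptide: str | None = None
    pts2_residue_span: tuple[int, int] | None = None


def _blocked_by_stop(locus: GeneLocus, p: int) -> bool:
    return any(
        locus.upstream_codon(q) in STOP_CODONS for q in range(p + 3, 0, 3)
    )


def find_initiation_candidates(
    locus: GeneLocus, hit: MotifHit, include_atg: bool = True
) -> list[InitiationCandidate]:
    """Classify every in-frame position from the motif start 5'-ward.

    Returns only near-cognate (and, by default, canonical ATG) codons,
    sorted 5'->3'.  Candidates strictly 3' of the motif start are excluded:
    initiation there would truncate the signal out of the isoform.
    """
    frame_start = inframe_start(locus)
    candidates = []
    for p in range(frame_start, hit.nt_start + 1, 3):
        codon = locus.upstream_codon(p)
        near = codon in NEAR_COGNATE
        if not near and not (include_atg and codon == "ATG"):
            continue
        candidates.append(
            InitiationCandidate(
                gene_id=locus.gene_id,
                codon=codon,
                nt_start=p,
                is_near_cognate=near,
                blocked_by_stop=_blocked_by_stop(locus, p),
            )
        )
    # annotate tandem adjacency among near-cognate candidates
    near_positions = {c.nt_start for c in candidates if c.is_near_cognate}
    annotated = []
    for c in candidates:
        partner = None
        if c.is_near_cognate:
            if c.nt_start + 3 in near_positions:
                partner = c.nt_start + 3
            elif c.nt_start - 3 in near_positions:
                partner = c.nt_start - 3
        annotated.append(replace(c, tandem_with=partner))
    return annotated


def find_tandem_pairs(
    candidates: list[InitiationCandidate],
) -> list[tuple[InitiationCandidate, InitiationCandidate]]:
    """All pairs (c1, c2) of near-cognate candidates with c2 immediately 3' of c1."""
    by_pos = {c.nt_start: c for c in candidates if c.is_near_cognate}
    return [
        (c, by_pos[c.nt_start + 3])
        for c in sorted(by_pos.values(), key=lambda c: c.nt_start)
        if c.nt_start + 3 in by_pos
    ]


def predict_extension(
    locus: GeneLocus,
    candidate: InitiationCandidate,
    hit: MotifHit,
    literal_initiator: bool = False,
) -> InitiationCandidate:
    """Complete a candidate with its predicted N-terminal extension.

    The first residue is reported as 'M' (initiator-tRNA convention)
    regardless of codon unless ``literal_initiator`` is set.  Refuses
    candidates separated from the CDS by an in-frame stop.
    """
    if candidate.blocked_by_stop:
        raise ValueError(
            f"{candidate.gene_id}: candidate at {candidate.nt_start} is separated "
            "from the CDS by an in-frame stop codon; no extended isoform is possible"
        )
    p = candidate.nt_start
    ext_nt = locus.upstream_seq[upstream_index(locus, p) :]
    peptide = translate_codons(ext_nt)
    if not literal_initiator:
        peptide = "M" + peptide[1:]
    ext_len = -p // 3
    motif_first = (hit.nt_start - p) // 3 + 1
    motif_last = motif_first + len(hit.peptide) - 1
    return replace(
        candidate,
        extension_len=ext_len,
        extension_peptide=peptide,
        pts2_residue_span=(motif_first, motif_last),
    )


def substitute_codons(
    locus: GeneLocus, edits: list[tuple[int, str]]
) -> GeneLocus:
    """Return a new locus with upstream codons replaced (in-silico mutagenesis).

    Each edit is (in-frame upstream position, replacement 3-mer); mirrors
    reporter-construct mutagenesis such as AGG ATT -> GCA GCA (knockout) or
    -> ATG ATG (canonical-start knock-in).
    """
    seq = list(locus.upstream_seq)
    occupied: set[int] = set()
    for p, codon in edits:
        if p % 3 != 0:
            raise ValueError(f"edit position {p} is not in frame")
        if len(codon) != 3 or set(codon) - set("ACGTN"):
            raise ValueError(f"replacement {codon!r} is not a nucleotide 3-mer")
        i = upstream_index(locus, p)
        span = {i, i + 1, i + 2}
        if span & occupied:
            raise ValueError(f"edit at {p} overlaps a previous edit")
        occupied |= span
        seq[i : i + 3] = codon
    return GeneLocus(
        gene_id=locus.gene_id, upstream_seq="".join(seq), cds_seq=locus.cds_seq
    )


def rank_candidates(
    candidates: list[InitiationCandidate],
) -> list[InitiationCandidate]:
    """Tandem-pair members first, then 3'-most first; deterministic."""
    return sorted(
        candidates,
        key=lambda c: (c.tandem_with is None, -c.nt_start),
    )


def candidates_to_rows(candidates: list[InitiationCandidate]) -> list[dict]:
    rows = []
    for c in candidates:
        rows.append(
            {
                "gene_id": c.gene_id,
                "nt_start": c.nt_start,
                "codon": c.codon,
                "near_cognate": c.is_near_cognate,
                "tandem_with": c.tandem_with if c.tandem_with is not None else "",
                "blocked_by_stop": c.blocked_by_stop,
                "extension_len": c.extension_len if c.extension_len is not None else "",
                "pts2_span": (
                    f"{c.pts2_residue_span[0]}-{c.pts2_residue_span[1]}"
                    if c.pts2_residue_span
                    else ""
                ),
                "extension_peptide": c.extension_peptide or "",
            }
        )
    return rows
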