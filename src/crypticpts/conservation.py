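"""Ortholog conservation profiling of upstream sequences.

Ortholog 5' UTRs are stacked right-anchored on the annotated start codon
(position -1 column-aligned), per-position identity is computed as the
modal-base fraction, and maximal high-identity windows are extracted.  A
pairwise global aligner (Needleman-Wunsch, linear gap penalty) is provided
for divergent families but is not the default stacking method, since UTR
3' ends are fixed by the annotation anchor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pts_scanner import Pts2Pattern, scan_upstream_inframe, select_primary_hit
from .sequence_io import GeneLocus, SequenceRecord

__all__ = [
    "ConservationProfile",
    "ConservedWindow",
    "MISSING",
    "needleman_wunsch",
    "stack_right_anchored",
    "conservation_profile",
    "find_conserved_windows",
    "motif_conservation",
]

MISSING = "-"  # 5' padding symbol for short sequences; never counted


@dataclass(frozen=True)
class ConservationProfile:
    """Per-position identity across right-anchored ortholog upstream sequences.

    ``positions`` are upstream coordinates -L..-1; ``identity`` is the
    modal-symbol fraction among non-missing symbols (NaN where coverage < 2).
    """

    positions: np.ndarray
    identity: np.ndarray
    coverage: np.ndarray
    n_seqs: int


@dataclass(frozen=True)
class ConservedWindow:
    """A maximal run of consecutive positions at or above an identity threshold."""

    start: int  # upstream coordinate of the 5' boundary
    end: int  # upstream coordinate of the 3' boundary
    mean_identity: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("window start must be <= end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def needleman_wunsch(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> tuple[str, str, float]:
    """Optimal global alignment with linear gap penalty.

    Deterministic traceback with tie order diagonal > up (gap in ``b``) >
    left (gap in ``a``).  Returns (aligned_a, aligned_b, score).
    """
    if match <= 0 or mismatch > 0 or gap > 0:
        raise ValueError("require match > 0, mismatch <= 0, gap <= 0")
    n, m = len(a), len(b)
    score = np.empty((n + 1, m + 1))
    score[0, :] = gap * np.arange(m + 1)
    score[:, 0] = gap * np.arange(n + 1)
    sub = np.where(
        np.frombuffer(a.encode(), dtype=np.uint8)[:, None]
        == np.frombuffer(b.encode(), dtype=np.uint8)[None, :],
        match,
        mismatch,
    )
    for i in range(1, n + 1):
        diag = score[i - 1, :-1] + sub[i - 1]
        up = score[i - 1, 1:] + gap
        row = score[i]
        prev = row[0]
        for j in range(1, m + 1):
            prev = max(diag[j - 1], up[j - 1], prev + gap)
            row[j] = prev
    # traceback
    out_a, out_b = [], []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and np.isclose(
            score[i, j], score[i - 1, j - 1] + sub[i - 1, j - 1]
        ):
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and np.isclose(score[i, j], score[i - 1, j] + gap):
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), float(score[n, m])


def stack_right_anchored(utrs: list[SequenceRecord]) -> np.ndarray:
    """Right-justify upstream sequences into a character matrix.

    The 3' end of every sequence (position -1) is column-aligned; shorter
    sequences are padded 5' with :data:`MISSING`.  No gaps are introduced.
    """
    if not utrs:
        raise ValueError("no sequences to stack")
    width = max(len(r.seq) for r in utrs)
    rows = [MISSING * (width - len(r.seq)) + r.seq for r in utrs]
    return np.array([list(r) for r in rows], dtype="<U1")


def conservation_profile(matrix: np.ndarray) -> ConservationProfile:
    """Modal-symbol identity per column; padding symbols excluded entirely."""
    n_seqs, width = matrix.shape
    if n_seqs < 2:
        raise ValueError("need at least 2 sequences")
    identity = np.full(width, np.nan)
    coverage = np.zeros(width, dtype=int)
    for j in range(width):
        col = matrix[:, j]
        col = col[col != MISSING]
        coverage[j] = col.size
        if col.size >= 2:
            _, counts = np.unique(col, return_counts=True)
            identity[j] = counts.max() / col.size
    positions = np.arange(-width, 0)
    return ConservationProfile(
        positions=positions, identity=identity, coverage=coverage, n_seqs=n_seqs
    )


def find_conserved_windows(
    profile: ConservationProfile,
    min_identity: float = 0.8,
    min_len: int = 6,
) -> list[ConservedWindow]:
    """Maximal runs of positions with identity >= ``min_identity``, length >= ``min_len``."""
    if not (0 < min_identity <= 1):
        raise ValueError("min_identity must be in (0, 1]")
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    ok = np.nan_to_num(profile.identity, nan=-1.0) >= min_identity
    windows = []
    i = 0
    while i < ok.size:
        if ok[i]:
            j = i
            while j + 1 < ok.size and ok[j + 1]:
                j += 1
            if j - i + 1 >= min_len:
                windows.append(
                    ConservedWindow(
                        start=int(profile.positions[i]),
                        end=int(profile.positions[j]),
                        mean_identity=float(np.mean(profile.identity[i : j + 1])),
                    )
                )
            i = j + 1
        else:
            i += 1
    return windows


def motif_conservation(
    ortholog_loci: list[GeneLocus], pattern: Pts2Pattern | None = None
) -> tuple[list[dict], float]:
    """Per-ortholog cryptic-motif table and the fraction of loci conserving one.

    A locus "conserves" the signal when it has at least one cryptic in-frame
    PTS2 (consensus-matching, no upstream in-frame ATG).  The peptide itself
    may vary between orthologs as long as it fits the consensus.
    """
    if not ortholog_loci:
        raise ValueError("need at least one locus")
    pattern = pattern or Pts2Pattern()
    rows = []
    n_conserved = 0
    for locus in ortholog_loci:
        hits = scan_upstream_inframe(locus, pattern)
        primary = select_primary_hit(locus, hits)
        conserved = primary is not None
        n_conserved += conserved
        rows.append(
            {
                "gene_id": locus.gene_id,
                "has_cryptic_pts2": conserved,
                "peptide": primary[0].peptide if conserved else "",
                "nt_start": primary[0].nt_start if conserved else "",
            }
        )
    return rows, n_conserved / len(ortholog_loci)
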