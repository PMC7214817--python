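"""Sequence/annotation I/O and the start-codon-anchored coordinate system.

Every analysis in this package is phrased in *upstream coordinates*:
position ``-k`` denotes the k-th nucleotide 5' of the A of a gene's
annotated ATG start codon (the ATG itself starts at 0).  A codon starting
at upstream position ``p`` lies in the CDS reading frame iff ``p % 3 == 0``.
This makes the printed coordinates of the pgd1-type locus arithmetically
consistent: a 27-nt motif-encoding region occupying -39..-13 and a 6-nt
tandem start-codon pair occupying -63..-58 both start at in-frame positions.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "SequenceRecord",
    "GeneLocus",
    "FastaFormatError",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "extract_locus",
    "upstream_index",
    "translate_codons",
]

_VALID_NT = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# standard genetic code (NCBI table 1); stops rendered as '*'
_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    _CODON_TO_AA[_stop] = "*"


class FastaFormatError(ValueError):
    """Raised when a FASTA file violates the expected syntax or alphabet."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence on the sense strand.

    The alphabet is restricted to uppercase A, C, G, T, N.
    """

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - _VALID_NT
        if bad:
            raise ValueError(
                f"record {self.id!r}: illegal characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GeneLocus:
    """A gene's upstream (5' UTR-containing) sequence plus its CDS.

    ``upstream_seq`` runs 5'->3' and ends immediately before the first base
    of the annotated start codon; ``cds_seq`` begins with that codon.  Both
    are sense-strand (minus-strand genes already reverse-complemented).
    """

    gene_id: str
    upstream_seq: str
    cds_seq: str

    def __post_init__(self) -> None:
        if len(self.cds_seq) < 3:
            raise ValueError(f"{self.gene_id}: CDS shorter than one codon")
        for name, s in (("upstream_seq", self.upstream_seq), ("cds_seq", self.cds_seq)):
            bad = set(s) - _VALID_NT
            if bad:
                raise ValueError(f"{self.gene_id}: illegal characters in {name}: {sorted(bad)!r}")

    @property
    def utr_len(self) -> int:
        return len(self.upstream_seq)

    def upstream_codon(self, p: int) -> str:
        """The 3-mer starting at in-frame upstream position ``p``."""
        i = upstream_index(self, p)
        if i + 3 > self.utr_len:
            raise IndexError(f"codon at {p} extends past the start codon")
        return self.upstream_seq[i : i + 3]


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased; line wrapping is irrelevant.  Malformed
    headers or illegal sequence characters raise :class:`FastaFormatError`
    naming the offending line.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    # validate line-by-line so errors can name the line, then parse via SeqIO
    with open(path) as fh:
        lineno = 0
        saw_header = False
        for line in fh:
            lineno += 1
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if len(line) == 1:
                    raise FastaFormatError(f"{path}:{lineno}: empty FASTA header")
                saw_header = True
            else:
                if not saw_header:
                    raise FastaFormatError(
                        f"{path}:{lineno}: sequence data before first header"
                    )
                bad = set(line.upper()) - _VALID_NT
                if bad:
                    raise FastaFormatError(
                        f"{path}:{lineno}: illegal sequence characters {sorted(bad)!r}"
                    )
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaFormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id) :].strip() if rec.description else ""
        records.append(SequenceRecord(id=rec.id, seq=str(rec.seq).upper(), description=desc))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, wrap: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``wrap`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), wrap):
                fh.write(rec.seq[i : i + wrap] + "\n")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def upstream_index(locus: GeneLocus, p: int) -> int:
    """Map upstream coordinate ``p`` (in [-utr_len, -1]) to a 0-based index.

    ``upstream_index(p) == utr_len + p``; a codon at ``p`` occupies indices
    ``utr_len+p .. utr_len+p+2`` and is in the CDS reading frame iff
    ``p % 3 == 0``.
    """
    if not (-locus.utr_len <= p <= -1):
        raise IndexError(
            f"upstream position {p} outside [-{locus.utr_len}, -1] for {locus.gene_id}"
        )
    return locus.utr_len + p


def translate_codons(nt: str) -> str:
    """Translate a codon-aligned nucleotide string with the standard code.

    Stop codons are rendered as ``'*'`` and never truncate; codons
    containing N translate to ``'X'``.  Length must be divisible by 3.
    """
    if len(nt) % 3:
        raise ValueError(f"length {len(nt)} not divisible by 3")
    out = []
    for i in range(0, len(nt), 3):
        codon = nt[i : i + 3]
        out.append("X" if "N" in codon else _CODON_TO_AA[codon])
    return "".join(out)


def _cds_features(db, gene_id: str):
    """All CDS features under a gene (direct or via mRNA children)."""
    feats = list(db.children(gene_id, featuretype="CDS"))
    if not feats:
        try:
            feat = db[gene_id]
        except Exception:
            return []
        if feat.featuretype == "CDS":
            feats = [feat]
    return feats


def extract_locus(
    genome: Sequence[SequenceRecord],
    annotation,
    gene_id: str,
    upstream_len: int = 300,
) -> GeneLocus:
    """Build a :class:`GeneLocus` from a genome and a gffutils database.

    ``annotation`` is a :mod:`gffutils` ``FeatureDB`` (or a path to a GFF3
    file, in which case an in-memory database is built).  The CDS start
    defines the anchor; ``upstream_seq`` is the ``upstream_len`` nt
    immediately 5' of it on the sense strand, reverse-complemented for
    minus-strand genes and truncated with a warning when the contig is
    shorter.  Only gene/mRNA/CDS/five_prime_UTR features are consulted.
    """
    import gffutils

    if isinstance(annotation, (str, Path)):
        annotation = gffutils.create_db(
            str(annotation), ":memory:", merge_strategy="create_unique", keep_order=True
        )
    contigs = {r.id: r.seq for r in genome}
    feats = _cds_features(annotation, gene_id)
    if not feats:
        raise KeyError(f"gene {gene_id!r} has no CDS in the annotation")
    strand = feats[0].strand
    contig_id = feats[0].seqid
    if contig_id not in contigs:
        raise KeyError(f"contig {contig_id!r} not in genome FASTA")
    contig = contigs[contig_id]
    # GFF3: 1-based closed intervals
    if strand == "-":
        cds_parts = sorted(feats, key=lambda f: f.start, reverse=True)
        cds_seq = "".join(
            reverse_complement(contig[f.start - 1 : f.end]) for f in cds_parts
        )
        anchor_end = cds_parts[0].end  # genomic coord of the CDS start base
        up_start = anchor_end  # 0-based slice start == anchor_end (1-based)+0
        up_stop = min(anchor_end + upstream_len, len(contig))
        upstream = reverse_complement(contig[up_start:up_stop])
    else:
        cds_parts = sorted(feats, key=lambda f: f.start)
        cds_seq = "".join(contig[f.start - 1 : f.end] for f in cds_parts)
        anchor_start = cds_parts[0].start  # 1-based
        up_start = max(anchor_start - 1 - upstream_len, 0)
        upstream = contig[up_start : anchor_start - 1]
    if len(upstream) < upstream_len:
        warnings.warn(
            f"{gene_id}: contig shorter than requested; upstream truncated to "
            f"{len(upstream)} nt"
        )
    if not cds_seq.upper().startswith("ATG"):
        warnings.warn(f"{gene_id}: CDS does not start with ATG")
    # cross-check annotated five_prime_UTR features if present
    utr_feats = list(annotation.children(gene_id, featuretype="five_prime_UTR"))
    if utr_feats:
        if strand == "-":
            ok = all(f.start > anchor_end for f in utr_feats)
        else:
            ok = all(f.end < anchor_start for f in utr_feats)
        if not ok:
            warnings.warn(f"{gene_id}: five_prime_UTR features overlap the CDS anchor")
    return GeneLocus(gene_id=gene_id, upstream_seq=upstream.upper(), cds_seq=cds_seq.upper())
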