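"""Synthetic inputs with recorded ground truth for every pipeline stage.

The default configuration transcribes the geometry of the pgd1-type locus:
a 300-nt 5' UTR whose CDS reading frame encodes the PTS2 nonapeptide
RISSLAAQL at -39..-13, a tandem near-cognate start-codon pair AGG ATT at
-63..-58, no in-frame ATG upstream of the motif, and no in-frame stop
between the tandem pair and the annotated start.  Ortholog families,
RNA-seq-like read sets, densitometry tables, and focus-count tables are
generated around the same locus, each with a manifest of planted truth so
tests can recompute every expected output without rerunning generation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable

from .pts_scanner import STOP_CODONS, Pts2Pattern, inframe_start, scan_upstream_inframe, select_primary_hit
from .sequence_io import GeneLocus, SequenceRecord, translate_codons, write_fasta
from .start_codon_finder import NEAR_COGNATE

__all__ = [
    "SimConfig",
    "GroundTruth",
    "GenerationError",
    "generate_locus",
    "generate_gene_set",
    "generate_ortholog_family",
    "generate_reads",
    "generate_densitometry",
    "generate_foci",
    "write_locus_genome",
    "write_simulation",
]

_MAX_ATTEMPTS = 10_000

# amino acid -> synonymous codons, standard table
_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in CodonTable.unambiguous_dna_by_id[1].forward_table.items():
    _AA_TO_CODONS.setdefault(_aa, []).append(_codon)
for _aa in _AA_TO_CODONS:
    _AA_TO_CODONS[_aa].sort()


class GenerationError(RuntimeError):
    """Raised when rejection sampling cannot satisfy the planted constraints."""


@dataclass
class SimConfig:
    """All knobs of the synthetic-data generators, with pgd1-type defaults."""

    seed: int = 0
    # locus geometry
    utr_len: int = 300
    pts2_offset: int = -39
    pts2_peptide: str = "RISSLAAQL"
    candidate_positions: tuple = ((-63, "AGG"), (-60, "ATT"))
    cryptic: bool = True
    atg_position: int = -72  # planted in-frame ATG when cryptic=False
    gc_content: float = 0.5
    cds_len: int = 240
    # ortholog families
    n_orthologs: int = 8
    sub_rate_background: float = 0.3
    sub_rate_conserved: float = 0.02
    conserved_windows: tuple = ((-68, -53),)
    # read sets
    n_reads: int = 2000
    read_len: int = 75
    error_rate: float = 0.0
    contaminant_fraction: float = 0.0
    contaminant_atg_position: int = -75
    # densitometry
    true_rate_percent: float = 2.0
    noise_cv: float = 0.1
    n_lanes: int = 6
    # foci
    n_foci: int = 200
    true_coloc_fraction: float = 0.7

    def __post_init__(self) -> None:
        for name in (
            "gc_content",
            "sub_rate_background",
            "sub_rate_conserved",
            "error_rate",
            "contaminant_fraction",
            "noise_cv",
            "true_coloc_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.pts2_offset % 3:
            raise ValueError("pts2_offset must be in frame (multiple of 3)")
        for p, codon in self.candidate_positions:
            if p % 3:
                raise ValueError(f"candidate position {p} not in frame")
            if p >= self.pts2_offset:
                raise ValueError(f"candidate position {p} not 5' of the motif")
            if len(codon) != 3:
                raise ValueError(f"candidate codon {codon!r} is not a 3-mer")


@dataclass
class GroundTruth:
    """Manifest of everything a generator planted, for recovery oracles."""

    kind: str
    data: dict

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"kind": self.kind, "data": self.data}, fh, indent=1, default=str)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(kind=obj["kind"], data=obj["data"])


def _rng_named(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng([seed, tag])


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=probs))


def _reverse_translate(peptide: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_AA_TO_CODONS[aa]) for aa in peptide)


def generate_locus(
    config: SimConfig, gene_id: str = "synth_pgd1"
) -> tuple[GeneLocus, GroundTruth]:
    """Random background with the configured motif and start codons planted.

    The PTS2 peptide is reverse-translated with uniform synonymous codon
    choice; when ``cryptic`` the background is rejection-resampled until no
    in-frame ATG lies upstream of the motif and no in-frame stop lies
    between the 5'-most candidate codon and the annotated start.  Two
    transcript-evidence constraints are enforced as well, emulating a locus
    whose read set genuinely carries no spliced-in upstream start codon:
    the candidate anchor 6-mer occurs exactly once in the transcript
    (upstream + first 200 nt of CDS), and no ATG trigram (in any frame)
    lies within ``read_len`` of the anchor on its 5' side, so only planted
    contaminant reads can ever match the upstream-ATG pattern filter.
    """
    rng = _rng_named(config.seed, 1)
    L = config.utr_len
    motif_nt_len = 3 * len(config.pts2_peptide)
    if -config.pts2_offset < motif_nt_len:
        raise ValueError("motif does not fit between pts2_offset and the start codon")
    if L < -min([config.pts2_offset] + [p for p, _ in config.candidate_positions]):
        raise ValueError("utr_len too short for the planted features")
    frame_start = -3 * (L // 3)
    for _ in range(_MAX_ATTEMPTS):
        seq = list(_random_bases(rng, L, config.gc_content))

        def plant(p: int, nt: str) -> None:
            i = L + p
            seq[i : i + len(nt)] = nt

        pts2_codons = _reverse_translate(config.pts2_peptide, rng)
        plant(config.pts2_offset, pts2_codons)
        for p, codon in config.candidate_positions:
            plant(p, codon)
        if not config.cryptic:
            plant(config.atg_position, "ATG")
        s = "".join(seq)

        def codon_at(p: int) -> str:
            return s[L + p : L + p + 3]

        cds = "ATG" + _random_bases(rng, config.cds_len - 3, config.gc_content)
        if config.cryptic:
            if any(
                codon_at(p) == "ATG"
                for p in range(frame_start, config.pts2_offset, 3)
            ):
                continue
            five_prime_most = min(p for p, _ in config.candidate_positions)
            if any(
                codon_at(p) in STOP_CODONS
                for p in range(five_prime_most + 3, 0, 3)
            ):
                continue
            # transcript-evidence cleanliness (see docstring)
            anchor_i = L + five_prime_most
            anchor6 = s[anchor_i : anchor_i + 6]
            transcript = s + cds[:200]
            if transcript.count(anchor6) != 1:
                continue
            lo = max(anchor_i - (config.read_len - 6), 0)
            if "ATG" in s[lo:anchor_i]:  # trigram start <= anchor_i - 3
                continue
        # the planted motif must be the unique consensus match in frame
        probe = GeneLocus(gene_id="probe", upstream_seq=s, cds_seq=cds)
        pattern = Pts2Pattern(spacer_len=len(config.pts2_peptide) - 4)
        if [h.nt_start for h in scan_upstream_inframe(probe, pattern)] != [
            config.pts2_offset
        ]:
            continue
        break
    else:
        raise GenerationError(
            "could not satisfy crypticity constraints after "
            f"{_MAX_ATTEMPTS} attempts; consider different gc_content or geometry"
        )
    locus = GeneLocus(gene_id=gene_id, upstream_seq=s, cds_seq=cds)
    truth = GroundTruth(
        kind="locus",
        data={
            "gene_id": gene_id,
            "seed": config.seed,
            "utr_len": L,
            "pts2_offset": config.pts2_offset,
            "pts2_peptide": config.pts2_peptide,
            "pts2_codons": pts2_codons,
            "candidate_positions": [list(c) for c in config.candidate_positions],
            "cryptic": config.cryptic,
            "atg_position": None if config.cryptic else config.atg_position,
            "upstream_seq": s,
            "cds_seq": cds,
        },
    )
    return locus, truth


def generate_gene_set(
    config: SimConfig, n_genes: int, n_planted: int
) -> tuple[list[GeneLocus], GroundTruth]:
    """A mixed gene set: ``n_planted`` pgd1-type loci among plain backgrounds.

    Unplanted loci are rejection-resampled until they contain no cryptic
    consensus match at all, so planted-recovery tests have exact truth.
    """
    if n_planted > n_genes:
        raise ValueError("n_planted exceeds n_genes")
    loci: list[GeneLocus] = []
    planted_ids = []
    pattern = Pts2Pattern()
    for g in range(n_genes):
        sub = dataclasses.replace(config, seed=config.seed * 100_003 + g + 1)
        gene_id = f"synth_g{g:03d}"
        if g < n_planted:
            locus, _ = generate_locus(sub, gene_id=gene_id)
            planted_ids.append(gene_id)
        else:
            rng = _rng_named(sub.seed, 2)
            for _ in range(_MAX_ATTEMPTS):
                up = _random_bases(rng, config.utr_len, config.gc_content)
                cds = "ATG" + _random_bases(rng, config.cds_len - 3, config.gc_content)
                locus = GeneLocus(gene_id=gene_id, upstream_seq=up, cds_seq=cds)
                hits = scan_upstream_inframe(locus, pattern)
                if select_primary_hit(locus, hits) is None:
                    break
            else:  # pragma: no cover - astronomically unlikely
                raise GenerationError("could not draw a motif-free background")
        loci.append(locus)
    truth = GroundTruth(
        kind="gene_set",
        data={
            "n_genes": n_genes,
            "planted_gene_ids": planted_ids,
            "pts2_offset": config.pts2_offset,
            "candidate_positions": [list(c) for c in config.candidate_positions],
        },
    )
    return loci, truth


def _window_rate(p: int, config: SimConfig) -> float:
    for lo, hi in config.conserved_windows:
        if lo <= p <= hi:
            return config.sub_rate_conserved
    return config.sub_rate_background


def _mutate_upstream(
    base: GeneLocus, config: SimConfig, rng: np.random.Generator
) -> tuple[str, list[int]]:
    """One ortholog's upstream sequence: per-position substitution with repair.

    Repair reverts codons that would (a) break the PTS2 consensus, (b)
    introduce a new in-frame ATG upstream of the motif, or (c) introduce an
    in-frame stop between the 5'-most candidate codon and the start codon —
    the generator emulates orthologs in which the *mechanism* (cryptic
    motif + reachable upstream initiation) is conserved even where
    individual bases are not.
    """
    L = base.utr_len
    seq = list(base.upstream_seq)
    alphabet = "ACGT"
    for i in range(L):
        p = i - L
        rate = _window_rate(p, config)
        if rng.random() < rate:
            cur = seq[i]
            choices = [b for b in alphabet if b != cur]
            seq[i] = choices[rng.integers(len(choices))]
    # repair pass over in-frame codons
    frame_start = inframe_start(base)
    motif_end = config.pts2_offset + 3 * len(config.pts2_peptide)
    pattern = Pts2Pattern(spacer_len=len(config.pts2_peptide) - 4)
    classes = [pattern.class1, pattern.class2] + [None] * pattern.spacer_len + [
        pattern.class3,
        pattern.class4,
    ]
    five_prime_most = min(p for p, _ in config.candidate_positions)
    for p in range(frame_start, 0, 3):
        i = L + p
        codon = "".join(seq[i : i + 3])
        revert = False
        if config.pts2_offset <= p < motif_end:
            res_idx = (p - config.pts2_offset) // 3
            aa = translate_codons(codon)
            cls = classes[res_idx]
            if cls is None:
                revert = aa in ("*", "X")
            else:
                revert = aa not in cls
        elif p < config.pts2_offset and codon == "ATG":
            revert = True
        elif five_prime_most < p < 0 and codon in STOP_CODONS:
            revert = True
        if revert:
            seq[i : i + 3] = base.upstream_seq[i : i + 3]
    mutated = "".join(seq)
    sub_positions = [
        i - L for i in range(L) if mutated[i] != base.upstream_seq[i]
    ]
    return mutated, sub_positions


def generate_ortholog_family(
    base: GeneLocus, config: SimConfig
) -> tuple[list[GeneLocus], GroundTruth]:
    """Indel-free ortholog upstream sequences mutated at window-specific rates."""
    rng = _rng_named(config.seed, 3)
    orthologs = []
    per_ortholog = []
    for k in range(config.n_orthologs):
        mutated, subs = _mutate_upstream(base, config, rng)
        gene_id = f"{base.gene_id}_orth{k:02d}"
        orthologs.append(
            GeneLocus(gene_id=gene_id, upstream_seq=mutated, cds_seq=base.cds_seq)
        )
        per_ortholog.append({"gene_id": gene_id, "substituted_positions": subs})
    truth = GroundTruth(
        kind="ortholog_family",
        data={
            "base_gene_id": base.gene_id,
            "n_orthologs": config.n_orthologs,
            "conserved_windows": [list(w) for w in config.conserved_windows],
            "sub_rate_background": config.sub_rate_background,
            "sub_rate_conserved": config.sub_rate_conserved,
            "orthologs": per_ortholog,
        },
    )
    return orthologs, truth


def generate_reads(
    locus: GeneLocus, config: SimConfig
) -> tuple[list[SequenceRecord], GroundTruth]:
    """Uniformly sampled reads from the transcript, plus optional contaminants.

    The transcript is the upstream sequence followed by the first 200 nt of
    the CDS.  A ``contaminant_fraction`` of reads is drawn instead from a
    variant transcript carrying an in-frame ATG planted 5' of the tandem
    anchor — emulating an alternatively spliced message that would license
    canonical initiation upstream of the motif.
    """
    rng = _rng_named(config.seed, 4)
    transcript = locus.upstream_seq + locus.cds_seq[:200]
    if config.read_len > len(transcript):
        raise ValueError("read_len exceeds transcript length")
    L = locus.utr_len
    variant = list(transcript)
    atg_i = L + config.contaminant_atg_position
    variant[atg_i : atg_i + 3] = "ATG"
    variant = "".join(variant)
    anchor_p = min(p for p, _ in config.candidate_positions)
    anchor_end_i = L + anchor_p + 6  # one past the 6-mer anchor
    reads, provenance = [], []
    n_starts = len(transcript) - config.read_len + 1
    for r in range(config.n_reads):
        contaminant = bool(rng.random() < config.contaminant_fraction)
        source = variant if contaminant else transcript
        start = int(rng.integers(n_starts))
        seq = list(source[start : start + config.read_len])
        errors = []
        if config.error_rate > 0:
            for i in range(len(seq)):
                if rng.random() < config.error_rate:
                    choices = [b for b in "ACGT" if b != seq[i]]
                    seq[i] = choices[rng.integers(3)]
                    errors.append(i)
        read_id = f"read{r:05d}"
        reads.append(SequenceRecord(id=read_id, seq="".join(seq)))
        provenance.append(
            {
                "id": read_id,
                "contaminant": contaminant,
                "start": start,
                "errors": errors,
                "covers_both": bool(
                    contaminant
                    and start <= atg_i
                    and start + config.read_len >= anchor_end_i
                ),
            }
        )
    truth = GroundTruth(
        kind="reads",
        data={
            "gene_id": locus.gene_id,
            "n_reads": config.n_reads,
            "read_len": config.read_len,
            "error_rate": config.error_rate,
            "contaminant_fraction": config.contaminant_fraction,
            "contaminant_atg_position": config.contaminant_atg_position,
            "anchor_position": anchor_p,
            "transcript": transcript,
            "variant_transcript": variant,
            "reads": provenance,
        },
    )
    return reads, truth


_WT_EXPRESSION = 100.0  # arbitrary units; only ratios are meaningful
_LOADING_CONSTANT = 50.0
_LOADING_SPREAD_CV = 0.2


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=size)


def generate_densitometry(config: SimConfig):
    """Dual-construct densitometry with multiplicative lognormal noise.

    Per lane: latent expression = construct mean (WT 100 units, M1A
    ``true_rate_percent``) x mean-one lognormal noise (cv ``noise_cv``) x a
    lane loading factor; the loading control is the same factor times a
    constant times its own noise.  With ``noise_cv`` 0 the estimator
    recovers ``true_rate_percent`` exactly.
    """
    import pandas as pd

    rng = _rng_named(config.seed, 5)
    rows = []
    latent = {}
    for construct, mean in (("WT", _WT_EXPRESSION), ("M1A", config.true_rate_percent)):
        n = config.n_lanes
        loading_factors = _lognormal_noise(rng, _LOADING_SPREAD_CV, n)
        expr_noise = _lognormal_noise(rng, config.noise_cv, n)
        load_noise = _lognormal_noise(rng, config.noise_cv, n)
        for k in range(n):
            lane_id = f"{construct}_{k + 1}"
            gfp = mean * expr_noise[k] * loading_factors[k]
            loading = loading_factors[k] * _LOADING_CONSTANT * load_noise[k]
            rows.append(
                {
                    "lane_id": lane_id,
                    "construct": construct,
                    "gfp_intensity": gfp,
                    "loading_intensity": loading,
                }
            )
            latent[lane_id] = {
                "loading_factor": float(loading_factors[k]),
                "expression_noise": float(expr_noise[k]),
                "loading_noise": float(load_noise[k]),
            }
    table = pd.DataFrame(rows)
    truth = GroundTruth(
        kind="densitometry",
        data={
            "true_rate_percent": config.true_rate_percent,
            "noise_cv": config.noise_cv,
            "n_lanes": config.n_lanes,
            "wt_expression": _WT_EXPRESSION,
            "lanes": latent,
        },
    )
    return table, truth


def generate_foci(config: SimConfig):
    """Marker-positive foci, each reporter-positive with the true fraction."""
    import pandas as pd

    if config.n_foci < 1:
        raise ValueError("n_foci must be >= 1")
    rng = _rng_named(config.seed, 6)
    signal = rng.random(config.n_foci) < config.true_coloc_fraction
    table = pd.DataFrame(
        {
            "focus_id": [f"focus{k:04d}" for k in range(config.n_foci)],
            "marker_positive": True,
            "signal_positive": signal,
        }
    )
    truth = GroundTruth(
        kind="foci",
        data={
            "true_coloc_fraction": config.true_coloc_fraction,
            "n_foci": config.n_foci,
            "n_signal_positive": int(signal.sum()),
        },
    )
    return table, truth


def write_locus_genome(
    loci: list[GeneLocus],
    fasta_path: str | Path,
    gff_path: str | Path,
    flank: int = 50,
    minus_strand: bool = False,
) -> None:
    """Embed loci in synthetic contigs and write genome FASTA + GFF3.

    One contig per locus: flank + upstream + CDS + flank, with gene/mRNA/CDS
    features (1-based closed coordinates).  ``minus_strand`` writes the
    reverse-complemented contig with minus-strand features, for strand tests.
    """
    from .sequence_io import reverse_complement

    records = []
    lines = ["##gff-version 3"]
    for locus in loci:
        contig_id = f"contig_{locus.gene_id}"
        body = "T" * flank + locus.upstream_seq + locus.cds_seq + "A" * flank
        cds_start = flank + locus.utr_len + 1  # 1-based
        cds_end = cds_start + len(locus.cds_seq) - 1
        if minus_strand:
            body_out = reverse_complement(body)
            n = len(body)
            cds_start_m = n - cds_end + 1
            cds_end_m = n - cds_start + 1
            cds_start, cds_end, strand = cds_start_m, cds_end_m, "-"
        else:
            body_out, strand = body, "+"
        records.append(SequenceRecord(id=contig_id, seq=body_out))
        gid = locus.gene_id
        lines.append(
            f"{contig_id}\tcrypticpts\tgene\t1\t{len(body)}\t.\t{strand}\t.\tID={gid}"
        )
        lines.append(
            f"{contig_id}\tcrypticpts\tmRNA\t1\t{len(body)}\t.\t{strand}\t.\t"
            f"ID={gid}.t1;Parent={gid}"
        )
        lines.append(
            f"{contig_id}\tcrypticpts\tCDS\t{cds_start}\t{cds_end}\t.\t{strand}\t0\t"
            f"ID={gid}.cds;Parent={gid}.t1"
        )
    write_fasta(records, fasta_path)
    with open(gff_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_simulation(config: SimConfig, outdir: str | Path) -> dict:
    """Generate and write a complete synthetic input bundle; returns file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    locus, locus_truth = generate_locus(config)
    orthologs, orth_truth = generate_ortholog_family(locus, config)
    reads, reads_truth = generate_reads(locus, config)
    dens, dens_truth = generate_densitometry(config)
    foci, foci_truth = generate_foci(config)

    paths = {
        "genome": outdir / "genome.fasta",
        "gff": outdir / "annotation.gff3",
        "orthologs": outdir / "ortholog_upstreams.fasta",
        "reads": outdir / "reads.fasta",
        "densitometry": outdir / "densitometry.tsv",
        "foci": outdir / "foci.tsv",
        "truth": outdir / "ground_truth.json",
    }
    write_locus_genome([locus], paths["genome"], paths["gff"])
    write_fasta(
        [SequenceRecord(id=o.gene_id, seq=o.upstream_seq) for o in orthologs],
        paths["orthologs"],
    )
    write_fasta(reads, paths["reads"])
    dens.to_csv(paths["densitometry"], sep="\t", index=False)
    foci.to_csv(paths["foci"], sep="\t", index=False)
    manifest = {
        "locus": locus_truth.data,
        "orthologs": orth_truth.data,
        "reads": {k: v for k, v in reads_truth.data.items() if k != "reads"},
        "densitometry": dens_truth.data,
        "foci": foci_truth.data,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(manifest, fh, indent=1)
    return {k: str(v) for k, v in paths.items()}
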