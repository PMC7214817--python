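"""Orchestration of the analysis stages into a single reproducible report."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .conservation import (
    conservation_profile,
    find_conserved_windows,
    motif_conservation,
    stack_right_anchored,
)
from .pts_scanner import (
    Pts2Pattern,
    assess_cryptic,
    hits_to_rows,
    scan_upstream_inframe,
    select_primary_hit,
)
from .quantification import (
    colocalization_fraction,
    boxplot_stats,
    estimate_initiation_rate,
)
from .read_evidence import summarize_evidence
from .sequence_io import GeneLocus, SequenceRecord, extract_locus
from .start_codon_finder import (
    candidates_to_rows,
    find_initiation_candidates,
    find_tandem_pairs,
    predict_extension,
    rank_candidates,
)
from .synthetic_data import (
    SimConfig,
    generate_densitometry,
    generate_foci,
    generate_locus,
    generate_ortholog_family,
    generate_reads,
)

__all__ = ["AnalysisReport", "scan_locus", "run_scan", "run_full_analysis", "render_report"]

log = logging.getLogger("crypticpts")


@dataclass
class AnalysisReport:
    """Structured result bundle; serializes deterministically to JSON."""

    genes: dict = field(default_factory=dict)
    conservation: dict | None = None
    read_evidence: dict | None = None
    quantification: dict | None = None
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "genes": self.genes,
            "conservation": self.conservation,
            "read_evidence": self.read_evidence,
            "quantification": self.quantification,
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()


def scan_locus(locus: GeneLocus, pattern: Pts2Pattern | None = None) -> dict | None:
    """Full detection chain for one locus; None when no cryptic motif is found."""
    pattern = pattern or Pts2Pattern()
    hits = scan_upstream_inframe(locus, pattern)
    primary = select_primary_hit(locus, hits)
    if primary is None:
        return None
    hit, assessment = primary
    candidates = rank_candidates(find_initiation_candidates(locus, hit))
    completed = [
        predict_extension(locus, c, hit) if not c.blocked_by_stop else c
        for c in candidates
    ]
    pairs = find_tandem_pairs(candidates)
    return {
        "hits": hits_to_rows(locus, hits),
        "primary_hit": {
            "nt_start": hit.nt_start,
            "nt_end": hit.nt_end,
            "peptide": hit.peptide,
            "is_cryptic": assessment.is_cryptic,
            "upstream_inframe_atg_positions": list(
                assessment.upstream_inframe_atg_positions
            ),
            "inframe_stop_positions": list(
                assessment.inframe_stop_positions_between_hit_and_cds
            ),
        },
        "candidates": candidates_to_rows(completed),
        "tandem_pairs": [
            {"five_prime": a.nt_start, "three_prime": b.nt_start, "codons": a.codon + " " + b.codon}
            for a, b in pairs
        ],
    }


def run_scan(
    genome: list[SequenceRecord],
    annotation,
    gene_ids: list[str] | None = None,
    pattern: Pts2Pattern | None = None,
    upstream_len: int = 300,
    verbose: bool = False,
) -> AnalysisReport:
    """Extract -> scan -> assess -> candidates for each gene in the annotation."""
    import gffutils

    if isinstance(annotation, (str, Path)):
        annotation = gffutils.create_db(
            str(annotation), ":memory:", merge_strategy="create_unique", keep_order=True
        )
    if gene_ids is None:
        gene_ids = [f.id for f in annotation.features_of_type("gene")]
    contig_ids = {r.id for r in genome}
    missing = [
        g
        for g in gene_ids
        if next(annotation.children(g, featuretype="CDS"), None) is not None
        and next(annotation.children(g, featuretype="CDS")).seqid not in contig_ids
    ]
    if missing:
        raise ValueError(f"annotation/genome mismatch for genes: {missing}")
    report = AnalysisReport()
    for gene_id in gene_ids:
        log.info("scanning %s", gene_id)
        locus = extract_locus(genome, annotation, gene_id, upstream_len=upstream_len)
        section = scan_locus(locus, pattern)
        if section is not None:
            report.genes[gene_id] = section
        elif verbose:
            report.genes[gene_id] = {"hits": [], "primary_hit": None}
    report.provenance = {"n_genes_scanned": len(gene_ids), "version": __version__}
    return report


def run_full_analysis(config: dict) -> AnalysisReport:
    """Run the configured stages on an all-synthetic bundle.

    ``config`` keys: ``seed`` (required), ``synthetic`` (SimConfig field
    overrides), ``stages`` (subset of scan/conservation/read_evidence/
    quantification; default all), ``params`` (min_identity, min_len, k,
    frame_aware).
    """
    if "seed" not in config:
        raise ValueError("config must declare a seed (no silent clock seeding)")
    sim = SimConfig(seed=int(config["seed"]), **config.get("synthetic", {}))
    stages = config.get(
        "stages", ["scan", "conservation", "read_evidence", "quantification"]
    )
    params = config.get("params", {})
    report = AnalysisReport()

    locus, _ = generate_locus(sim)
    if "scan" in stages:
        log.info("stage: scan")
        section = scan_locus(locus)
        if section is not None:
            report.genes[locus.gene_id] = section
    if "conservation" in stages:
        log.info("stage: conservation")
        orthologs, _ = generate_ortholog_family(locus, sim)
        matrix = stack_right_anchored(
            [SequenceRecord(id=o.gene_id, seq=o.upstream_seq) for o in orthologs]
        )
        profile = conservation_profile(matrix)
        windows = find_conserved_windows(
            profile,
            min_identity=params.get("min_identity", 0.8),
            min_len=params.get("min_len", 6),
        )
        _, conserved_fraction = motif_conservation(orthologs)
        report.conservation = {
            "n_orthologs": len(orthologs),
            "windows": [
                {"start": w.start, "end": w.end, "mean_identity": round(w.mean_identity, 4)}
                for w in windows
            ],
            "motif_conserved_fraction": conserved_fraction,
        }
    if "read_evidence" in stages:
        log.info("stage: read_evidence")
        reads, _ = generate_reads(locus, sim)
        summary = summarize_evidence(
            reads,
            locus.upstream_seq[-300:],
            k=params.get("k", 20),
        )
        report.read_evidence = summary.__dict__.copy()
    if "quantification" in stages:
        log.info("stage: quantification")
        dens, _ = generate_densitometry(sim)
        est = estimate_initiation_rate(dens)
        foci, _ = generate_foci(sim)
        coloc = colocalization_fraction(foci)
        report.quantification = {
            "initiation_rate_percent": est.rate_percent,
            "initiation_rate_dispersion": est.dispersion,
            "per_replicate_rates": list(est.per_replicate_rates),
            "boxplot": boxplot_stats(est.per_replicate_rates),
            "colocalization_fraction": coloc.fraction,
            "n_marker_positive": coloc.n_marker_positive,
            "n_double_positive": coloc.n_double_positive,
        }
    report.provenance = {
        "seed": sim.seed,
        "stages": list(stages),
        "version": __version__,
        "config_digest": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
    }
    return report


def render_report(report: AnalysisReport) -> str:
    """Plain-text summary; numbers are taken from the report, never recomputed."""
    lines = ["# crypticpts analysis report", ""]
    if not report.genes:
        lines.append("No cryptic motifs found.")
    for gene_id, sec in report.genes.items():
        primary = sec.get("primary_hit")
        if not primary:
            lines.append(f"## {gene_id}: no cryptic motif")
            continue
        lines.append(f"## {gene_id}")
        lines.append(
            f"- cryptic PTS2 {primary['peptide']} encoded at "
            f"{primary['nt_start']}..{primary['nt_end']}"
        )
        lines.append(
            f"- upstream in-frame ATGs: {len(primary['upstream_inframe_atg_positions'])}"
        )
        for pair in sec.get("tandem_pairs", []):
            lines.append(
                f"- tandem near-cognate pair {pair['codons']} at "
                f"{pair['five_prime']}..{pair['three_prime'] + 2}"
            )
        for c in sec.get("candidates", []):
            if c["blocked_by_stop"]:
                lines.append(
                    f"- candidate {c['codon']} at {c['nt_start']} "
                    "(blocked by an in-frame stop)"
                )
            else:
                lines.append(
                    f"- candidate {c['codon']} at {c['nt_start']} "
                    f"(extension {c['extension_len']} aa, motif residues {c['pts2_span']})"
                )
    if report.conservation is not None:
        lines.append("")
        lines.append("## Conservation")
        lines.append(
            f"- motif conserved in fraction {report.conservation['motif_conserved_fraction']:.2f} "
            f"of {report.conservation['n_orthologs']} orthologs"
        )
        for w in report.conservation["windows"]:
            lines.append(
                f"- conserved window {w['start']}..{w['end']} "
                f"(mean identity {w['mean_identity']:.3f})"
            )
    if report.read_evidence is not None:
        lines.append("")
        lines.append("## Read evidence")
        for k, v in report.read_evidence.items():
            lines.append(f"- {k}: {v}")
    if report.quantification is not None:
        q = report.quantification
        b = q["boxplot"]
        lines.append("")
        lines.append("## Quantification")
        lines.append(f"- non-canonical initiation rate: {q['initiation_rate_percent']:.2f}%")
        lines.append(
            "- box plot (center line, median; box limits, first and third "
            f"quartiles; whiskers, 1.5x IQR): median {b['median']:.2f}, "
            f"Q1 {b['q1']:.2f}, Q3 {b['q3']:.2f}, whiskers "
            f"[{b['whisker_low']:.2f}, {b['whisker_high']:.2f}]"
        )
        lines.append(
            f"- co-localization: {q['n_double_positive']}/{q['n_marker_positive']} "
            f"marker-positive foci with reporter signal "
            f"({q['colocalization_fraction']:.2f})"
        )
    return "\n".join(lines) + "\n"
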