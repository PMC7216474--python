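"""End-to-end orchestration: validate -> collapse -> classify -> events ->
compare -> summarize, with a deterministic JSON run manifest.

Stage order follows the hybrid workflow: chain validation against
short-read junctions precedes collapse, which precedes classification
(``collapse_before_validation`` flips the first two stages for sensitivity
analysis). All stages are deterministic; randomness lives only in
:mod:`sjkit.simulate`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from . import __version__
from .classify import build_reference_index, classify_all, summarize_categories
from .collapse import CollapseConfig, collapse_isoforms
from .events import EventCatalog, build_catalog, compare_conditions
from .formats import (
    read_genome_fasta,
    read_gtf,
    read_isoform_alignments,
    read_star_sj,
    write_bed12,
)
from .junctions import ValidationConfig, filter_isoforms
from .orf_expr import (
    deg_filter,
    expression_records,
    find_longest_orf,
    length_summaries,
    read_deg_table,
    read_expression_table,
    support_flags,
    transcript_sequence,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@dataclass(frozen=True)
class RunConfig:
    genome: str
    annotation: str
    isoforms_a: str
    isoforms_b: str
    sj_a: str
    sj_b: str
    expression: Optional[str] = None
    deg: Optional[str] = None
    label_a: str = "untreated"
    label_b: str = "treated"
    isoform_format: str = "BED12"
    min_unique: int = 1
    keep_mono_exon: bool = True
    merge_5prime_truncated: bool = False
    mono_exon_tol: int = 50
    tpm_threshold: float = 1.0
    dominance_threshold: float = 0.5
    lfc: float = 1.0
    alpha: float = 0.05
    min_aa: int = 100
    collapse_before_validation: bool = False
    outdir: str = "sjkit_out"
    log_level: str = "INFO"


#: config fields echoed into the manifest (outdir/log_level do not affect
#: results and are excluded so identical inputs give identical manifests)
_ECHO_EXCLUDE = {"outdir", "log_level"}


def _write_validation_report(report, path: str) -> None:
    rows = [
        {
            "isoform_id": o.isoform_id,
            "status": o.status,
            "n_missing": len(o.missing_junctions),
            "min_support": "" if o.min_support_observed is None else o.min_support_observed,
            "missing_junctions": ";".join(
                f"{j.start}-{j.end}" for j in o.missing_junctions
            ),
        }
        for o in report
    ]
    pd.DataFrame(
        rows,
        columns=["isoform_id", "status", "n_missing", "min_support", "missing_junctions"],
    ).to_csv(path, sep="\t", index=False)


def _write_clusters(clusters, path: str) -> None:
    rows = [
        {
            "representative": c.representative.transcript_id,
            "n_members": len(c.members),
            "members": ",".join(c.members),
        }
        for c in clusters
    ]
    pd.DataFrame(
        rows, columns=["representative", "n_members", "members"]
    ).to_csv(path, sep="\t", index=False)


def _write_calls(calls, path: str) -> None:
    rows = [
        {
            "isoform_id": c.isoform_id,
            "category": c.category,
            "associated_genes": ",".join(c.associated_genes),
            "matched_reference": c.matched_reference_transcript or "",
        }
        for c in calls
    ]
    pd.DataFrame(
        rows, columns=["isoform_id", "category", "associated_genes", "matched_reference"]
    ).to_csv(path, sep="\t", index=False)


def write_events_tsv(catalog: EventCatalog, path: str) -> None:
    rows = [
        {
            "gene_id": e.gene_id,
            "event_type": e.event_type,
            "chrom": e.chrom,
            "strand": e.strand,
            "coordinates": ",".join(map(str, e.coordinates)),
            "inclusion_isoforms": ",".join(e.inclusion_isoforms),
            "exclusion_isoforms": ",".join(e.exclusion_isoforms),
        }
        for e in catalog.events
    ]
    pd.DataFrame(
        rows,
        columns=[
            "gene_id", "event_type", "chrom", "strand",
            "coordinates", "inclusion_isoforms", "exclusion_isoforms",
        ],
    ).to_csv(path, sep="\t", index=False)


def _condition_stage(
    label: str,
    isoforms_path: str,
    sj_path: str,
    cfg: RunConfig,
    ref_index,
    genome,
    outdir: str,
) -> Tuple[Dict, EventCatalog, List, List[int], List[int]]:
    """Run validate -> collapse -> classify -> events for one condition."""
    try:
        isoforms = read_isoform_alignments(isoforms_path, cfg.isoform_format)
        sj_table = read_star_sj(sj_path)
    except Exception as exc:
        raise PipelineError(f"stage=read condition={label}: {exc}") from exc

    vconf = ValidationConfig(cfg.min_unique, cfg.keep_mono_exon)
    cconf = CollapseConfig(cfg.merge_5prime_truncated)
    try:
        if cfg.collapse_before_validation:
            clusters0 = collapse_isoforms(isoforms, cconf)
            reps0 = [c.representative for c in clusters0]
            retained, report = filter_isoforms(reps0, sj_table, vconf)
            clusters = collapse_isoforms(retained, cconf)
        else:
            retained, report = filter_isoforms(isoforms, sj_table, vconf)
            clusters = collapse_isoforms(retained, cconf)
    except Exception as exc:
        raise PipelineError(f"stage=validate/collapse condition={label}: {exc}") from exc

    reps = [c.representative for c in clusters]
    try:
        calls = classify_all(reps, ref_index, cfg.mono_exon_tol)
    except Exception as exc:
        raise PipelineError(f"stage=classify condition={label}: {exc}") from exc
    categories = summarize_categories(calls)
    try:
        catalog = build_catalog(reps, label=label)
    except Exception as exc:
        raise PipelineError(f"stage=events condition={label}: {exc}") from exc

    tx_lengths = [t.length for t in reps]
    orf_aa: Dict[str, int] = {}
    cds_lengths: List[int] = []
    cds_starts: List[int] = []
    cds_ends: List[int] = []
    for t in reps:
        call = find_longest_orf(transcript_sequence(t, genome), t.transcript_id)
        if call is not None:
            orf_aa[t.transcript_id] = call.aa_length
            cds_lengths.append(call.cds_end_tx - call.cds_start_tx)
            cds_starts.append(call.cds_start_tx)
            cds_ends.append(call.cds_end_tx)

    write_bed12(retained, os.path.join(outdir, f"{label}.retained.bed"))
    _write_validation_report(report, os.path.join(outdir, f"{label}.validation.tsv"))
    _write_clusters(clusters, os.path.join(outdir, f"{label}.clusters.tsv"))
    _write_calls(calls, os.path.join(outdir, f"{label}.classification.tsv"))
    write_events_tsv(catalog, os.path.join(outdir, f"{label}.events.tsv"))

    statuses = [o.status for o in report]
    counts = {
        "n_input": len(isoforms),
        "n_retained": len(retained),
        "n_valid": statuses.count("valid"),
        "n_invalid": statuses.count("invalid"),
        "n_mono_exon": statuses.count("mono_exon"),
        "n_clusters": len(clusters),
        "categories": dict(categories),
        "n_novel": sum(
            1 for c in calls if c.category not in ("FSM", "ISM")
        ),
        "event_counts": dict(catalog.counts),
        "n_events": len(catalog),
        "n_orf_called": len(orf_aa),
        "n_orf_over_min": sum(1 for aa in orf_aa.values() if aa > cfg.min_aa),
    }
    return counts, catalog, calls, tx_lengths, cds_lengths


def run_pipeline(config: RunConfig) -> Dict:
    """Run the full two-condition workflow; returns the manifest dict.

    The manifest (also written to ``<outdir>/manifest.json``) records all
    stage counts and echoes the analysis-relevant configuration;
    re-running on identical inputs reproduces it byte for byte.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    os.makedirs(config.outdir, exist_ok=True)

    try:
        genome = read_genome_fasta(config.genome)
        annotation = read_gtf(config.annotation)
    except Exception as exc:
        raise PipelineError(f"stage=read-reference: {exc}") from exc
    ref_index = build_reference_index(annotation)

    per_cond: Dict[str, Dict] = {}
    catalogs: Dict[str, EventCatalog] = {}
    calls_by_cond: Dict[str, List] = {}
    lengths: Dict[str, List[int]] = {}
    cds_lengths: Dict[str, List[int]] = {}
    for label, iso_path, sj_path in (
        (config.label_a, config.isoforms_a, config.sj_a),
        (config.label_b, config.isoforms_b, config.sj_b),
    ):
        counts, catalog, calls, tx_len, cds_len = _condition_stage(
            label, iso_path, sj_path, config, ref_index, genome, config.outdir
        )
        per_cond[label] = counts
        catalogs[label] = catalog
        calls_by_cond[label] = calls
        lengths[label] = tx_len
        cds_lengths[label] = cds_len

    deg_genes: set = set()
    if config.deg:
        deg_genes = deg_filter(read_deg_table(config.deg), config.lfc, config.alpha)
    comparison = compare_conditions(
        catalogs[config.label_a], catalogs[config.label_b], deg_genes
    )
    write_events_tsv(
        EventCatalog(comparison.events_only_in_b, "only_in_b"),
        os.path.join(config.outdir, "events_only_in_b.tsv"),
    )

    manifest: Dict = {
        "tool": "sjkit",
        "version": __version__,
        "config": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if k not in _ECHO_EXCLUDE
        },
        "conditions": per_cond,
        "comparison": {
            "n_events_only_in_b": len(comparison.events_only_in_b),
            "n_asg_b": len(comparison.asg_b),
            "n_asg_b_deg": len(comparison.asg_b_deg),
            "n_asg_b_non_deg": len(comparison.asg_b_non_deg),
            "n_deg_genes": len(deg_genes),
            "asg_b": sorted(comparison.asg_b),
        },
    }

    # length distributions between conditions
    if all(lengths[l] for l in lengths):
        summary, pvals = length_summaries(lengths)
        manifest["transcript_lengths"] = {
            "medians": {l: float(summary.loc[l, "median"]) for l in lengths},
            "mwu_p": float(pvals.loc[config.label_a, config.label_b]),
        }
    if all(cds_lengths[l] for l in cds_lengths):
        summary, pvals = length_summaries(cds_lengths)
        manifest["cds_lengths"] = {
            "medians": {l: float(summary.loc[l, "median"]) for l in cds_lengths},
            "mwu_p": float(pvals.loc[config.label_a, config.label_b]),
        }

    # expression support for novel isoforms
    if config.expression:
        expr = read_expression_table(config.expression)
        for label in (config.label_a, config.label_b):
            col = f"tpm_{label}"
            if col not in expr.columns:
                continue
            novel_ids = {
                c.isoform_id
                for c in calls_by_cond[label]
                if c.category not in ("FSM", "ISM")
            }
            records = expression_records(expr, col)
            flags = support_flags(
                records, config.tpm_threshold, config.dominance_threshold
            )
            novel = flags[flags["isoform_id"].isin(novel_ids)]
            per_cond[label]["novel_supported_fraction"] = (
                float(novel["supported"].mean()) if len(novel) else None
            )
            per_cond[label]["n_dominant"] = int(flags["dominant"].sum())

    text = json.dumps(manifest, sort_keys=True, indent=2)
    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        fh.write(text + "\n")
    return manifest
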