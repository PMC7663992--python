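"""End-to-end orchestration: parse -> filter -> architect -> classify ->
motifs/logo -> expression -> select -> report, with a run manifest.

Each stage failure aborts with a stage-named error; outputs are
deterministic given inputs + config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .annotation_io import (
    PipelineConfig,
    filter_annotations,
    load_taxonomy_map,
    parse_blast_annotations,
    parse_domain_hits,
    parse_tm_regions,
    read_fasta,
)
from .architecture import build_architectures, summarize_architectures, write_summary
from .expression_de import (
    CountMatrix,
    comparisons_from_conditions,
    filter_low_counts,
    full_l2fc_table,
    log2_fold_change,
    normalize,
    read_design,
    report_candidates,
    select_candidates,
)
from .receptor_classifier import classify_all, write_assignments
from .tsp1_motifs import (
    build_logo_matrix,
    extract_tsp1_segments,
    reports_to_frame,
    scan_motifs,
)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class PipelineInputs:
    fasta: Path
    domtbl: Path
    tmhmm: Path
    blast: Path | None = None
    taxmap: Path | None = None
    counts: Path | None = None
    design: Path | None = None
    design_kind: str = "fed_vs_starvation"


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(
    inputs: PipelineInputs,
    config: PipelineConfig | None = None,
    out_dir: str | Path = "kleptorecept_out",
) -> dict[str, Any]:
    """Run every stage on the given inputs; write report surfaces + manifest.

    Returns a dict with the in-memory results and the manifest.
    """
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "tool": f"kleptorecept {__version__}",
        "config": asdict(config),
        "inputs": {},
        "counts": {},
    }

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(name, str(exc)) from exc

    for label in ("fasta", "domtbl", "tmhmm", "blast", "taxmap", "counts", "design"):
        p = getattr(inputs, label)
        if p is not None:
            if not Path(p).exists():
                raise StageError("parse", f"missing input {label}: {p}")
            manifest["inputs"][label] = {"path": str(p), "sha256_16": _digest(Path(p))}

    proteins = _stage("parse", read_fasta, inputs.fasta)
    hits = _stage("parse", parse_domain_hits, inputs.domtbl)
    tms = _stage("parse", parse_tm_regions, inputs.tmhmm)
    manifest["counts"]["proteins_read"] = len(proteins)
    manifest["counts"]["domain_hits_read"] = len(hits)
    manifest["counts"]["tm_regions_read"] = len(tms)

    annotations: dict[str, str] = {}
    if inputs.blast is not None:
        if inputs.taxmap is None:
            raise StageError("filter", "BLAST table supplied without a taxonomy map")
        taxmap = _stage("filter", load_taxonomy_map, inputs.taxmap)
        ann_records = _stage("filter", parse_blast_annotations, inputs.blast, taxmap)
        kept = _stage("filter", filter_annotations, ann_records, config)
        annotations = {r.protein_id: r.description for r in kept}
        manifest["counts"]["annotations_read"] = len(ann_records)
        manifest["counts"]["annotations_kept"] = len(kept)

    archs = _stage("architect", build_architectures, proteins, hits, tms, config)
    manifest["counts"]["architectures_built"] = len(archs)
    manifest["counts"]["proteins_length_filtered"] = len(proteins) - len(archs)
    summary = summarize_architectures(archs)
    write_summary(summary, out / "architecture_summary.tsv")

    assignments, category_table = _stage("classify", classify_all, archs)
    write_assignments(assignments, out / "assignments.tsv")
    manifest["counts"]["classified_per_category"] = {
        row["category"]: int(row["n"]) for _, row in category_table.iterrows()
    }

    proteins_by_id = {p.id: p for p in proteins}
    reports = []
    segments = []
    for arch in archs:
        segs = _stage("motifs", extract_tsp1_segments, arch, proteins_by_id[arch.protein_id])
        for i, seg in enumerate(segs):
            reports.append(scan_motifs(seg, protein_id=arch.protein_id, segment_index=i))
            segments.append(seg)
    if reports:
        reports_to_frame(reports).to_csv(out / "tsp1_motifs.tsv", sep="\t", index=False)
    manifest["counts"]["tsp1_segments"] = len(segments)
    logo = None
    lengths = {len(s) for s in segments}
    if segments and len(lengths) == 1:
        # profile-free columnization: only valid when all segments share length
        logo = _stage("motifs", build_logo_matrix, segments, config.logo_pseudocount)
        logo.to_tsv(out / "tsp1_logo_matrix.tsv")

    candidate_table = None
    l2fc_tables: dict[str, pd.Series] = {}
    selected: list[str] = []
    if inputs.counts is not None:
        if inputs.design is None:
            raise StageError("expression", "count matrix supplied without a design file")
        matrix = _stage("expression", CountMatrix.from_tsv, inputs.counts)
        conditions = _stage("expression", read_design, inputs.design)
        filtered = _stage("expression", filter_low_counts, matrix, config)
        manifest["counts"]["genes_read"] = len(matrix.gene_ids)
        manifest["counts"]["genes_after_low_count_filter"] = len(filtered.gene_ids)
        normalized = _stage("expression", normalize, filtered)
        comparisons = _stage(
            "expression", comparisons_from_conditions, conditions, inputs.design_kind
        )
        for comp in comparisons:
            l2fc_tables[comp.name] = _stage(
                "expression", log2_fold_change, normalized, comp, config.prior_count
            )
        selected = _stage(
            "select", select_candidates, l2fc_tables, inputs.design_kind, config
        )
        manifest["counts"]["candidates_selected"] = len(selected)
        assign_by_gene = {a.protein_id: a for a in assignments}
        candidate_table = _stage(
            "report", report_candidates, selected, assign_by_gene, annotations, l2fc_tables
        )
        candidate_table.to_csv(out / "candidates.tsv", sep="\t", index=False)
        full_l2fc_table(l2fc_tables).to_csv(out / "l2fc_full.tsv", sep="\t", index_label="gene_id")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "architectures": archs,
        "architecture_summary": summary,
        "assignments": assignments,
        "category_table": category_table,
        "motif_reports": reports,
        "logo_matrix": logo,
        "l2fc_tables": l2fc_tables,
        "selected": selected,
        "candidate_table": candidate_table,
        "manifest": manifest,
    }
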