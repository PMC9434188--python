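"""End-to-end drivers composing the analysis steps deterministically.

These functions are what the numbered analysis scripts, the CLI and the
acceptance checks call.  All inputs are canonicalized (sorted gene and
sample order) on entry and all outputs are written in sorted order, so a
run is a pure function of the data and parameters: repeated invocations
and permuted input orderings produce byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .candidate_selector import (
    CandidateRecord,
    finalize_candidates,
    functional_category_filter,
    tf_route,
)
from .comparative_filter import (
    ParentComparison,
    fold_change_filter,
    partition_counts,
    sort_parent_ratio,
)
from .coexpression import correlation_network, neighborhood
from .deg_integration import (
    ConservedSet,
    call_degs,
    conserved_overlap,
    conserved_with_external,
)
from .eqtl_mapper import (
    EQTLClassification,
    classify_panel,
    summarize_classifications,
)
from .panel_io import (
    CoexpressionEdge,
    ExpressionMatrix,
    GeneModel,
    ILSegment,
    write_edge_list,
    write_json_summary,
)
from .synthetic_panel import (
    CORE_PATTERN,
    PanelConfig,
    generate_il_design,
    generate_panel_expression,
    generate_stage_matrix,
    generate_transgenic_experiment,
    transgenic_contrasts,
)


@dataclass
class PanelAnalysis:
    comparisons: list[ParentComparison]
    lyco_pass: set[str]
    penn_pass: set[str]
    classifications: dict[str, EQTLClassification]
    eqtl_route: list[CandidateRecord]
    tf_route: list[CandidateRecord]
    candidates: list[CandidateRecord]
    edges: list[CoexpressionEdge]
    summary: dict


def _write_comparisons(comparisons, lyco_pass, penn_pass, path) -> None:
    rows = [
        (c.gene_id, c.expr_lyc, c.expr_penn, c.ratio_lyc_over_penn,
         c.assigned_set, c.gene_id in lyco_pass, c.gene_id in penn_pass)
        for c in comparisons
    ]
    pd.DataFrame(
        rows,
        columns=["gene_id", "expr_lyc", "expr_penn", "ratio_lyc_over_penn",
                 "assigned_set", "passes_lyco_fc", "passes_penn_fc"],
    ).to_csv(path, sep="\t", index=False, float_format="%.9g")


def _write_classifications(classifications, path) -> None:
    rows = [
        (g, cls.specificity, cls.regulatory_class,
         ";".join(sorted(cls.located_ils)),
         ";".join(sorted(c.il_id for c in cls.calls)))
        for g, cls in sorted(classifications.items())
    ]
    pd.DataFrame(
        rows, columns=["gene_id", "specificity", "regulatory_class",
                       "located_ils", "called_ils"],
    ).to_csv(path, sep="\t", index=False)


def _write_candidates(records, path) -> None:
    rows = [
        (r.gene_id, r.route, r.rank, r.functional_category, r.is_tf,
         "" if r.br_induction_ratio is None else "%.9g" % r.br_induction_ratio,
         "" if r.tissue_specificity_score is None else "%.9g" % r.tissue_specificity_score,
         "" if r.lyc_penn_ratio is None else "%.9g" % r.lyc_penn_ratio,
         r.selected)
        for r in records
    ]
    pd.DataFrame(
        rows, columns=["gene_id", "route", "rank", "functional_category",
                       "is_tf", "br_induction_ratio", "tau", "lyc_penn_ratio",
                       "selected"],
    ).to_csv(path, sep="\t", index=False)


def analyze_panel(
    matrix: ExpressionMatrix,
    stage_matrix: ExpressionMatrix,
    annotation: Mapping[str, GeneModel],
    design: Sequence[ILSegment],
    network_genes: Sequence[str] | None = None,
    min_fc: float = 5.0,
    z_min: float = 2.5,
    min_abs_log2: float = 1.0,
    tau_min: float = 0.5,
    ratio_min: float = 5.0,
    top_k_tf: int = 20,
    r_min: float = 0.6,
    alpha: float = 0.05,
    out_dir: Path | str | None = None,
) -> PanelAnalysis:
    """Run the complete candidate-gene screen on one panel dataset.

    Steps: parent-ratio sorting and FC filter; per-gene eQTL
    classification; eQTL-route category filter on specific genes passing
    the FC filter; TF-route ranking; final narrowing on tissue
    specificity and parent ratio; co-expression network over
    ``network_genes`` (default: the TF genes) in the stage matrix.
    """
    matrix = matrix.canonicalized()
    stage_matrix = stage_matrix.canonicalized()
    design = sorted(design, key=lambda s: (s.chromosome, s.start, s.end, s.il_id))

    lyc = matrix.samples_where(genotype="M82")
    penn = matrix.samples_where(genotype="Penn")
    comparisons = sort_parent_ratio(matrix, lyc, penn)
    lyco_pass = fold_change_filter(comparisons, "Lyco", min_fc)
    penn_pass = fold_change_filter(comparisons, "Penn", min_fc)

    classifications = classify_panel(
        matrix, annotation, design, parent_samples=lyc,
        z_min=z_min, min_abs_log2=min_abs_log2,
    )
    specific_pass = {
        g for g, cls in classifications.items()
        if cls.specificity == "specific" and g in (lyco_pass | penn_pass)
    }
    eqtl_records = functional_category_filter(
        specific_pass, annotation, comparisons=comparisons
    )
    tf_records = tf_route(
        comparisons, classifications, annotation, stage_matrix,
        min_fc=min_fc, top_k=top_k_tf,
    )
    candidates = finalize_candidates(
        eqtl_records, tf_records, stage_matrix,
        tau_min=tau_min, ratio_min=ratio_min,
    )

    if network_genes is None:
        network_genes = sorted(
            g for g, gm in annotation.items()
            if gm.is_tf and g in set(stage_matrix.gene_ids)
        )
    edges = correlation_network(
        stage_matrix, list(network_genes), r_min=r_min, alpha=alpha
    )

    summary = {
        "partition": partition_counts(comparisons),
        "fc_filter": {"lyco": len(lyco_pass), "penn": len(penn_pass)},
        "eqtl": summarize_classifications(classifications),
        "candidates": {
            "eqtl_route": len(eqtl_records),
            "tf_route": len(tf_records),
            "selected": sum(1 for r in candidates if r.selected),
        },
        "network": {"genes": len(network_genes), "edges": len(edges)},
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        _write_comparisons(comparisons, lyco_pass, penn_pass,
                           out_dir / "parent_comparisons.tsv")
        _write_classifications(classifications, out_dir / "eqtl_classes.tsv")
        _write_candidates(candidates, out_dir / "candidates.tsv")
        write_edge_list(edges, out_dir / "network_edges.tsv", format="tsv")
        write_edge_list(edges, out_dir / "network_edges.sif", format="sif")
        write_json_summary(summary, out_dir / "summary.json")

    return PanelAnalysis(
        comparisons=comparisons,
        lyco_pass=lyco_pass,
        penn_pass=penn_pass,
        classifications=classifications,
        eqtl_route=eqtl_records,
        tf_route=tf_records,
        candidates=candidates,
        edges=edges,
        summary=summary,
    )


def simulate_and_analyze(
    cfg: PanelConfig, out_dir: Path | str | None = None, **params
) -> tuple[PanelAnalysis, "PanelTruthBundle"]:
    """Generate a synthetic panel and run the full screen on it."""
    design = generate_il_design(cfg)
    matrix, truth = generate_panel_expression(cfg, design)
    stage_matrix, ripening = generate_stage_matrix(cfg, truth)
    analysis = analyze_panel(
        matrix, stage_matrix, truth.annotation, design,
        out_dir=out_dir, **params,
    )
    return analysis, PanelTruthBundle(matrix, stage_matrix, truth, ripening, design)


@dataclass
class PanelTruthBundle:
    matrix: ExpressionMatrix
    stage_matrix: ExpressionMatrix
    truth: object
    ripening_tfs: set[str]
    design: list[ILSegment]


def analyze_transgenics(
    matrix: ExpressionMatrix,
    external_sets: Mapping[str, Mapping[str, str]] | None = None,
    min_abs_log2fc: float = 1.0,
    max_fdr: float = 0.05,
    out_dir: Path | str | None = None,
) -> tuple[ConservedSet, ConservedSet | None]:
    """DEG calling on the OE/RNAi/WT series and the conserved overlaps.

    Sign pattern: up in OE at MG, down in RNAi at Br and at Pink; the
    optional external mutant sets must be sign-concordant with the RNAi
    direction.  Returns (internal conserved set, external-merged set).
    """
    matrix = matrix.canonicalized()
    contrasts = transgenic_contrasts(matrix)
    deg_sets = [
        (name, call_degs(matrix, contrast, min_abs_log2fc, max_fdr))
        for name, contrast in sorted(contrasts.items())
    ]
    pattern = {
        name: ("up" if sign > 0 else "down")
        for name, (_g, _s, sign) in CORE_PATTERN.items()
    }
    conserved = conserved_overlap(deg_sets, pattern)
    merged = None
    if external_sets is not None:
        merged = conserved_with_external(conserved, external_sets)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        payload = {
            "sign_pattern": conserved.sign_pattern,
            "members": sorted(conserved.members),
            "venn_counts": conserved.venn_counts,
            "input_sizes": conserved.input_sizes,
        }
        if merged is not None:
            payload["with_external"] = {
                "members": sorted(merged.members),
                "venn_counts": merged.venn_counts,
            }
        write_json_summary(payload, out_dir / "conserved_degs.json")
    return conserved, merged
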