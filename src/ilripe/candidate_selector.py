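"""Candidate prioritization: eQTL-route category filter, TF-route
ranking, and the final ripening-specificity narrowing.

Two routes feed the final list.  The eQTL route keeps specific-eQTL
genes annotated as transcription regulators, oxidases or cytochrome
P450s.  The TF route keeps transcription factors more than ``min_fc``
fold higher in the cultivated parent that also carry an eQTL call, ranks
them by the Breaker+10 / Breaker induction ratio and keeps the top k.
The merged list is then narrowed by tissue specificity (tau) and the
parent-expression ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .comparative_filter import ParentComparison
from .eqtl_mapper import EQTLClassification
from .panel_io import ConfigError, ExpressionMatrix, GeneModel, logger

DEFAULT_CATEGORIES = frozenset(
    {"transcription_regulator", "oxidase", "cytochrome_P450"}
)
DEFAULT_TAU_MIN = 0.5
DEFAULT_PSEUDOCOUNT = 1.0


@dataclass
class CandidateRecord:
    gene_id: str
    route: str                      # "eqtl" | "tf"
    functional_category: str = "other"
    is_tf: bool = False
    br_induction_ratio: float | None = None
    tissue_specificity_score: float | None = None
    lyc_penn_ratio: float | None = None
    rank: int = 0
    selected: bool = False
    filters_passed: dict = field(default_factory=dict)  # audit trail


def tissue_specificity_tau(stage_means: Sequence[float]) -> float:
    """The tau index over per-stage mean expression.

    tau = sum(1 - x_i / x_max) / (n - 1): 0 for uniform expression, 1
    when a gene is expressed in exactly one stage.  All-zero profiles
    return 0 (no specificity evidence).
    """
    x = np.asarray(stage_means, dtype=float)
    if x.size < 2:
        return 0.0
    xmax = x.max()
    if xmax <= 0:
        return 0.0
    return float(np.sum(1.0 - x / xmax) / (x.size - 1))


def _stage_mean_table(matrix: ExpressionMatrix) -> "dict[str, np.ndarray]":
    """Per-stage mean expression vectors keyed by stage label."""
    out = {}
    for stage in dict.fromkeys(matrix.sample_meta["stage"]):
        samples = matrix.samples_where(stage=str(stage))
        out[str(stage)] = matrix.values[samples].to_numpy().mean(axis=1)
    return out


def stage_profile(
    matrix: ExpressionMatrix, gene_id: str
) -> dict[str, float]:
    row = matrix.values.loc[gene_id]
    meta = matrix.sample_meta
    return {
        str(stage): float(row[matrix.samples_where(stage=str(stage))].mean())
        for stage in dict.fromkeys(meta["stage"])
    }


def br_induction_ratio(
    matrix: ExpressionMatrix,
    gene_id: str,
    br_stage: str = "Br",
    br10_stage: str = "Br+10",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """Pseudocounted ratio of mean expression at Breaker+10 over Breaker."""
    br_samples = matrix.samples_where(stage=br_stage)
    br10_samples = matrix.samples_where(stage=br10_stage)
    if not br_samples or not br10_samples:
        raise ConfigError(
            f"stage matrix lacks {br_stage!r} or {br10_stage!r} samples"
        )
    row = matrix.values.loc[gene_id]
    return float(
        (row[br10_samples].mean() + pseudocount)
        / (row[br_samples].mean() + pseudocount)
    )


def functional_category_filter(
    specific_genes: Iterable[str],
    annotation: Mapping[str, GeneModel],
    categories: frozenset[str] | set[str] = DEFAULT_CATEGORIES,
    comparisons: Sequence[ParentComparison] | None = None,
) -> list[CandidateRecord]:
    """eQTL-route candidates: specific-eQTL genes in the kept categories.

    Unannotated genes are excluded with a warning.  ``comparisons``
    (optional) fills the parent-ratio field used by the final narrowing.
    Records are ranked in gene-id order (the route itself imposes no
    scoring).
    """
    if not categories:
        raise ConfigError("categories must be nonempty")
    ratio_of = (
        {c.gene_id: c.ratio_lyc_over_penn for c in comparisons}
        if comparisons is not None else {}
    )
    records = []
    for gene_id in sorted(specific_genes):
        gene = annotation.get(gene_id)
        if gene is None:
            logger.warning("gene %s has no annotation; excluded", gene_id)
            continue
        if gene.functional_category not in categories:
            continue
        records.append(
            CandidateRecord(
                gene_id=gene_id,
                route="eqtl",
                functional_category=gene.functional_category,
                is_tf=gene.is_tf,
                lyc_penn_ratio=ratio_of.get(gene_id),
                filters_passed={"specific_eqtl": True, "category": True},
            )
        )
    for rank, rec in enumerate(records, start=1):
        rec.rank = rank
    return records


def tf_route(
    comparisons: Sequence[ParentComparison],
    classifications: Mapping[str, EQTLClassification] | Sequence[EQTLClassification],
    annotation: Mapping[str, GeneModel],
    stage_matrix: ExpressionMatrix,
    min_fc: float = 5.0,
    top_k: int = 20,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[CandidateRecord]:
    """TF-route candidates ranked by ripening induction.

    Pipeline: TFs with parent ratio strictly above ``min_fc`` -> those
    with at least one eQTL call -> descending Breaker+10/Breaker ratio
    (ties by gene id) -> top ``top_k``.
    """
    if not isinstance(classifications, Mapping):
        classifications = {c.gene_id: c for c in classifications}
    records = []
    for comp in comparisons:
        gene = annotation.get(comp.gene_id)
        if gene is None or not gene.is_tf:
            continue
        if comp.ratio_lyc_over_penn <= min_fc:
            continue
        cls = classifications.get(comp.gene_id)
        if cls is None or not cls.calls:
            continue
        ratio = br_induction_ratio(
            stage_matrix, comp.gene_id, pseudocount=pseudocount
        )
        records.append(
            CandidateRecord(
                gene_id=comp.gene_id,
                route="tf",
                functional_category=gene.functional_category,
                is_tf=True,
                br_induction_ratio=ratio,
                lyc_penn_ratio=comp.ratio_lyc_over_penn,
                filters_passed={
                    "is_tf": True, "parent_fc": True, "has_eqtl": True,
                },
            )
        )
    records.sort(key=lambda r: (-r.br_induction_ratio, r.gene_id))
    records = records[: max(0, top_k)]
    for rank, rec in enumerate(records, start=1):
        rec.rank = rank
    return records


def finalize_candidates(
    eqtl_route: Sequence[CandidateRecord],
    tf_route_records: Sequence[CandidateRecord],
    stage_matrix: ExpressionMatrix,
    tau_min: float = DEFAULT_TAU_MIN,
    ratio_min: float = 5.0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[CandidateRecord]:
    """Merge both routes and keep ripening-specific, parent-skewed genes.

    Duplicates keep the eQTL-route record.  Tissue specificity (tau over
    stage means) and the Breaker induction ratio are computed from the
    stage matrix where missing; survivors require tau >= tau_min and
    parent ratio >= ratio_min and are flagged ``selected``.  Output order
    is deterministic: (route, rank), eqtl route first.
    """
    merged: dict[str, CandidateRecord] = {}
    for rec in list(eqtl_route) + list(tf_route_records):
        if rec.gene_id not in merged or (
            merged[rec.gene_id].route == "tf" and rec.route == "eqtl"
        ):
            merged[rec.gene_id] = rec

    stage_means = _stage_mean_table(stage_matrix)
    gene_index = {g: i for i, g in enumerate(stage_matrix.gene_ids)}
    out = []
    for rec in merged.values():
        rec = replace(rec, filters_passed=dict(rec.filters_passed))
        gi = gene_index.get(rec.gene_id)
        if gi is not None:
            profile = [stage_means[s][gi] for s in stage_means]
            rec.tissue_specificity_score = tissue_specificity_tau(profile)
            if rec.br_induction_ratio is None:
                rec.br_induction_ratio = br_induction_ratio(
                    stage_matrix, rec.gene_id, pseudocount=pseudocount
                )
        elif rec.tissue_specificity_score is None:
            rec.tissue_specificity_score = 0.0
        tau_ok = rec.tissue_specificity_score >= tau_min
        ratio_ok = (
            rec.lyc_penn_ratio is not None and rec.lyc_penn_ratio >= ratio_min
        )
        rec.filters_passed["tissue_specificity"] = tau_ok
        rec.filters_passed["parent_ratio_final"] = ratio_ok
        rec.selected = tau_ok and ratio_ok
        out.append(rec)
    out.sort(key=lambda r: (0 if r.route == "eqtl" else 1, r.rank, r.gene_id))
    return out


def selected_candidates(records: Iterable[CandidateRecord]) -> list[CandidateRecord]:
    return [r for r in records if r.selected]
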