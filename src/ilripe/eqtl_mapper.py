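"""Per-IL eQTL detection, specificity and cis/trans classification.

An introgression-line panel turns eQTL mapping into outlier detection:
for each gene, the expression of the line carrying the causal donor
segment stands apart from the other ~75 lines.  Detection therefore uses
a robust z score of each IL's log2 group mean against the median/MAD of
all IL means (consistency constant 1.4826), combined with an absolute
log2 ratio floor against the recurrent parent.  A call is *specific*
when it is confined to the IL(s) whose introgression contains the gene's
locus, and *cis* when every called IL contains the locus; calls entirely
outside the located ILs are *trans*, a mixture is *mixed*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .panel_io import ExpressionMatrix, GeneModel, ILSegment, logger

MAD_CONSISTENCY = 1.4826
DEFAULT_Z_MIN = 2.5
DEFAULT_MIN_ABS_LOG2 = 1.0
DEFAULT_PSEUDOCOUNT = 1.0


@dataclass(frozen=True)
class EQTLCall:
    gene_id: str
    il_id: str
    log2_ratio_vs_parent: float
    z_score: float

    @property
    def direction(self) -> str:
        return "increased" if self.log2_ratio_vs_parent > 0 else "decreased"


@dataclass
class EQTLClassification:
    gene_id: str
    calls: list[EQTLCall]
    located_ils: set[str]
    specificity: str = "none"       # specific | nonspecific | none
    regulatory_class: str = "not_applicable"  # cis | trans | mixed | not_applicable


def locate_gene_ils(gene: GeneModel, design: Sequence[ILSegment]) -> set[str]:
    """ILs whose introgression contains the gene's start coordinate.

    Point containment on the half-open interval; with nested sub-lines a
    gene can be located in several ILs at once.  Genes outside every
    introgression (impossible under a full-coverage design) yield an
    empty set with a warning.
    """
    hits = {
        seg.il_id
        for seg in design
        if seg.contains(gene.chromosome, gene.start)
    }
    if not hits:
        logger.warning(
            "gene %s at %s:%d lies outside every introgression",
            gene.gene_id, gene.chromosome, gene.start,
        )
    return hits


def detect_eqtls(
    matrix: ExpressionMatrix,
    gene_id: str,
    parent_samples: Sequence[str],
    il_sample_groups: Mapping[str, Sequence[str]],
    z_min: float = DEFAULT_Z_MIN,
    min_abs_log2: float = DEFAULT_MIN_ABS_LOG2,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[EQTLCall]:
    """Call ILs where a gene's expression departs sharply from the panel.

    Replicates are collapsed to per-IL arithmetic means, log2-transformed
    with a pseudocount; IL *i* is called iff |z_i| >= z_min and
    |log2(IL_i / parent)| >= min_abs_log2 with z_i a median/MAD robust z
    over all IL log2 means.  A zero MAD (e.g. noise-free panels) drops
    the z criterion with a warning and calls on the ratio floor alone.
    """
    row = matrix.values.loc[gene_id]
    il_ids = list(il_sample_groups)
    x = np.array(
        [np.log2(row[list(il_sample_groups[i])].mean() + pseudocount)
         for i in il_ids]
    )
    parent = np.log2(row[list(parent_samples)].mean() + pseudocount)
    return _calls_from_log2_means(
        gene_id, il_ids, x, parent, z_min, min_abs_log2
    )


def _calls_from_log2_means(
    gene_id: str,
    il_ids: Sequence[str],
    x: np.ndarray,
    parent: float,
    z_min: float,
    min_abs_log2: float,
) -> list[EQTLCall]:
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    ratio = x - parent
    if mad == 0.0:
        logger.warning(
            "gene %s: zero MAD across ILs; calling on the log2-ratio "
            "criterion alone", gene_id,
        )
        with np.errstate(invalid="ignore"):
            z = np.where(x == med, 0.0, np.inf * np.sign(x - med))
        called = np.abs(ratio) >= min_abs_log2
    else:
        z = (x - med) / (MAD_CONSISTENCY * mad)
        called = (np.abs(z) >= z_min) & (np.abs(ratio) >= min_abs_log2)
    return [
        EQTLCall(gene_id, il_ids[i], float(ratio[i]), float(z[i]))
        for i in np.nonzero(called)[0]
    ]


def classify_specificity(
    calls: Iterable[EQTLCall],
    located: set[str],
    max_extra_ils: int = 0,
) -> str:
    """specific / nonspecific / none per the located-IL confinement rule.

    Specific: a nonempty call set touching at least one located IL and
    straying into at most ``max_extra_ils`` other lines (0 by default:
    the strict reading of an effect confined to "its located IL"; nested
    sub-lines both calling still count as specific since both are
    located).
    """
    called = {c.il_id for c in calls}
    if not called:
        return "none"
    if called & located and len(called - located) <= max_extra_ils:
        return "specific"
    return "nonspecific"


def classify_cis_trans(classification: EQTLClassification) -> str:
    """cis / trans / mixed from IL interval geometry.

    cis: every called IL contains the gene's locus; trans: none does;
    mixed: some do.  No calls => not_applicable.
    """
    called = {c.il_id for c in classification.calls}
    if not called:
        return "not_applicable"
    inside = called & classification.located_ils
    if inside == called:
        return "cis"
    if not inside:
        return "trans"
    return "mixed"


def classify_gene(
    matrix: ExpressionMatrix,
    gene: GeneModel,
    design: Sequence[ILSegment],
    parent_samples: Sequence[str],
    il_sample_groups: Mapping[str, Sequence[str]],
    z_min: float = DEFAULT_Z_MIN,
    min_abs_log2: float = DEFAULT_MIN_ABS_LOG2,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    max_extra_ils: int = 0,
) -> EQTLClassification:
    calls = detect_eqtls(
        matrix, gene.gene_id, parent_samples, il_sample_groups,
        z_min=z_min, min_abs_log2=min_abs_log2, pseudocount=pseudocount,
    )
    located = locate_gene_ils(gene, design)
    cls = EQTLClassification(gene.gene_id, calls, located)
    cls.specificity = classify_specificity(calls, located, max_extra_ils)
    cls.regulatory_class = classify_cis_trans(cls)
    return cls


def il_sample_groups_from_meta(
    matrix: ExpressionMatrix, parent_genotypes: Sequence[str] = ("M82", "Penn")
) -> dict[str, list[str]]:
    """Group samples by genotype, excluding the parents: il_id -> samples."""
    groups: dict[str, list[str]] = {}
    for sample, genotype in matrix.sample_meta["genotype"].items():
        if genotype in parent_genotypes:
            continue
        groups.setdefault(str(genotype), []).append(str(sample))
    return groups


def classify_panel(
    matrix: ExpressionMatrix,
    annotation: Mapping[str, GeneModel],
    design: Sequence[ILSegment],
    parent_samples: Sequence[str],
    il_sample_groups: Mapping[str, Sequence[str]] | None = None,
    genes: Sequence[str] | None = None,
    z_min: float = DEFAULT_Z_MIN,
    min_abs_log2: float = DEFAULT_MIN_ABS_LOG2,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    max_extra_ils: int = 0,
) -> dict[str, EQTLClassification]:
    """Vectorized whole-panel classification (the per-gene rule, batched).

    Requires a panel of at least 8 ILs: the median/MAD statistic is
    meaningless without breadth across lines.
    """
    if il_sample_groups is None:
        il_sample_groups = il_sample_groups_from_meta(matrix)
    il_ids = list(il_sample_groups)
    if len(il_ids) < 8:
        raise ValueError(
            f"panel has {len(il_ids)} ILs; robust detection needs >= 8"
        )
    if genes is None:
        genes = [g for g in matrix.gene_ids if g in annotation]

    values = matrix.values
    col_idx = {s: i for i, s in enumerate(values.columns)}
    arr = values.to_numpy()
    row_idx = {g: i for i, g in enumerate(values.index)}
    rows = np.array([row_idx[g] for g in genes])

    def group_log2_mean(samples: Sequence[str]) -> np.ndarray:
        cols = [col_idx[s] for s in samples]
        return np.log2(arr[np.ix_(rows, cols)].mean(axis=1) + pseudocount)

    x = np.column_stack([group_log2_mean(il_sample_groups[i]) for i in il_ids])
    parent = group_log2_mean(parent_samples)

    med = np.median(x, axis=1, keepdims=True)
    mad = np.median(np.abs(x - med), axis=1, keepdims=True)
    ratio = x - parent[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (x - med) / (MAD_CONSISTENCY * mad)
    zero_mad = mad[:, 0] == 0.0
    if zero_mad.any():
        logger.warning(
            "%d genes have zero MAD across ILs; ratio-only calls",
            int(zero_mad.sum()),
        )
    called = (np.abs(z) >= z_min) & (np.abs(ratio) >= min_abs_log2)
    called[zero_mad] = np.abs(ratio[zero_mad]) >= min_abs_log2
    with np.errstate(invalid="ignore"):
        z = np.where(
            np.isfinite(z), z,
            np.where(x == med, 0.0, np.inf * np.sign(x - med)),
        )

    located_all = {
        g: {seg.il_id for seg in design
            if seg.contains(annotation[g].chromosome, annotation[g].start)}
        for g in genes
    }
    out: dict[str, EQTLClassification] = {}
    for gi, g in enumerate(genes):
        calls = [
            EQTLCall(g, il_ids[j], float(ratio[gi, j]), float(z[gi, j]))
            for j in np.nonzero(called[gi])[0]
        ]
        cls = EQTLClassification(g, calls, located_all[g])
        cls.specificity = classify_specificity(calls, cls.located_ils, max_extra_ils)
        cls.regulatory_class = classify_cis_trans(cls)
        out[g] = cls
    return out


def summarize_classifications(
    classifications: Mapping[str, EQTLClassification]
) -> dict:
    """JSON-ready counts per specificity and regulatory class."""
    spec = {"specific": 0, "nonspecific": 0, "none": 0}
    reg = {"cis": 0, "trans": 0, "mixed": 0, "not_applicable": 0}
    for cls in classifications.values():
        spec[cls.specificity] += 1
        reg[cls.regulatory_class] += 1
    return {
        "n_genes": len(classifications),
        "specificity": spec,
        "regulatory_class": reg,
    }
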