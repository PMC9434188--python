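"""Readers, writers and the shared data model for the IL-panel pipeline.

All genomic coordinates are 0-based, half-open (BED convention).  Sources
using 1-based inclusive coordinates must subtract 1 from starts before
import.  Strand is ignored throughout: no step of the analysis uses it.

Numeric serialization policy: expression values are written with 9
significant digits; correlation coefficients with 12.  Round-trip tests
compare at those precisions.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger("ilripe")

FUNCTIONAL_CATEGORIES = (
    "transcription_regulator",
    "oxidase",
    "cytochrome_P450",
    "other",
)

_EXPR_FLOAT_FMT = "%.9g"
_R_FLOAT_FMT = "%.12g"


class PanelError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(PanelError):
    """Malformed on-disk input (names the offending record)."""


class ValidationError(PanelError):
    """Structurally valid input violating a data-model invariant."""


class ConfigError(PanelError):
    """Invalid configuration or parameter combination."""


def configure_logging(level: int = logging.INFO) -> None:
    """Attach a stderr handler to the package logger (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(levelname)s %(name)s: %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(level)


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance table with per-sample metadata.

    ``values`` is a genes-by-samples DataFrame of nonnegative, finite
    abundances (unit-agnostic: FPKM, RPKM or array intensity — each matrix
    is treated as internally comparable only).  ``sample_meta`` is indexed
    by sample id with columns ``genotype``, ``stage`` and ``replicate``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id: {dup!r}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        numeric = v.to_numpy()
        if numeric.size:
            import numpy as np

            finite = np.isfinite(numeric)
            if not finite.all():
                i, j = [int(x[0]) for x in (~finite).nonzero()]
                raise ValidationError(
                    f"non-finite value for gene {v.index[i]!r} "
                    f"sample {v.columns[j]!r}"
                )
            if (numeric < 0).any():
                i, j = [int(x[0]) for x in (numeric < 0).nonzero()]
                raise ValidationError(
                    f"negative value for gene {v.index[i]!r} "
                    f"sample {v.columns[j]!r}"
                )
        missing = [s for s in v.columns if s not in self.sample_meta.index]
        if missing:
            raise FormatError(f"sample {missing[0]!r} has no metadata record")
        for col in ("genotype", "stage", "replicate"):
            if col not in self.sample_meta.columns:
                raise FormatError(f"sample metadata lacks column {col!r}")
        # align metadata to column order; extra meta rows are dropped
        self.sample_meta = self.sample_meta.loc[list(v.columns)]

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.columns]

    def samples_where(
        self, genotype: str | None = None, stage: str | None = None
    ) -> list[str]:
        """Sample ids matching the given genotype and/or stage label."""
        meta = self.sample_meta
        mask = pd.Series(True, index=meta.index)
        if genotype is not None:
            mask &= meta["genotype"] == genotype
        if stage is not None:
            mask &= meta["stage"] == stage
        return [str(s) for s in meta.index[mask]]

    def canonicalized(self) -> "ExpressionMatrix":
        """Copy with genes and samples in sorted order.

        Running an analysis on the canonical form makes every floating-
        point reduction independent of the on-disk row/column ordering,
        so pipeline outputs are byte-identical across input permutations.
        """
        genes = sorted(self.gene_ids)
        samples = sorted(self.sample_ids)
        return ExpressionMatrix(
            self.values.loc[genes, samples], self.sample_meta.loc[samples]
        )

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise ValidationError(f"unknown gene id: {missing[0]!r}")
        return ExpressionMatrix(
            self.values.loc[list(gene_ids)], self.sample_meta.copy()
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene locus with the annotation fields the filters consume."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    functional_category: str = "other"
    is_tf: bool = False
    tf_family: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"gene {self.gene_id!r}: invalid interval "
                f"[{self.start}, {self.end})"
            )
        if self.functional_category not in FUNCTIONAL_CATEGORIES:
            raise ValidationError(
                f"gene {self.gene_id!r}: unknown category "
                f"{self.functional_category!r}"
            )


@dataclass(frozen=True)
class ILSegment:
    """One introgressed interval of an introgression line (IL).

    A line may own several rows (multi-interval introgressions), and
    panels routinely contain nested sub-lines (e.g. IL4-1-1 inside IL4-1).
    """

    il_id: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"segment {self.il_id!r}: invalid interval "
                f"[{self.start}, {self.end})"
            )

    def contains(self, chromosome: str, position: int) -> bool:
        return (
            chromosome == self.chromosome
            and self.start <= position < self.end
        )


@dataclass(frozen=True)
class Contrast:
    """A named two-group comparison over samples of one matrix."""

    name: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    stage: str = ""

    def __post_init__(self) -> None:
        if not self.group_a or not self.group_b:
            raise ConfigError(f"contrast {self.name!r}: empty sample group")
        if set(self.group_a) & set(self.group_b):
            raise ConfigError(
                f"contrast {self.name!r}: groups are not disjoint"
            )

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        known = set(matrix.sample_ids)
        for s in (*self.group_a, *self.group_b):
            if s not in known:
                raise ConfigError(
                    f"contrast {self.name!r}: unknown sample {s!r}"
                )


@dataclass(frozen=True)
class CoexpressionEdge:
    """An undirected thresholded co-expression edge (gene_a < gene_b)."""

    gene_a: str
    gene_b: str
    r: float
    p_value: float

    def __post_init__(self) -> None:
        if self.gene_a >= self.gene_b:
            raise ValidationError(
                f"edge ({self.gene_a!r}, {self.gene_b!r}): gene_a must sort "
                "before gene_b and self-edges are forbidden"
            )
        if abs(self.r) > 1 + 1e-12:
            raise ValidationError(f"|r| > 1 for edge {self.gene_a}-{self.gene_b}")

    @property
    def sign(self) -> str:
        return "positive" if self.r >= 0 else "negative"


# ---------------------------------------------------------------------------
# Expression matrix TSV + metadata sidecar
# ---------------------------------------------------------------------------


def read_expression_matrix(path, meta_path) -> ExpressionMatrix:
    """Read a genes-x-samples TSV plus its sample-metadata sidecar.

    The matrix TSV has a header row of sample ids and gene ids in the first
    column.  The metadata TSV is keyed by ``sample_id`` with columns
    ``genotype``, ``stage``, ``replicate``.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    if values.index.has_duplicates:
        dup = values.index[values.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    return ExpressionMatrix(values.astype(float), meta)


def write_expression_matrix(matrix: ExpressionMatrix, path, meta_path) -> None:
    matrix.values.to_csv(
        path, sep="\t", float_format=_EXPR_FLOAT_FMT, index_label="gene_id"
    )
    matrix.sample_meta.to_csv(meta_path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# IL design (BED 4-column) and gene annotation TSV
# ---------------------------------------------------------------------------


def read_il_segments(path, chromosomes: Iterable[str] | None = None) -> list[ILSegment]:
    """Read a BED-4 IL design (chrom, start, end, il_id; 0-based half-open).

    If ``chromosomes`` is given, rows on undeclared chromosomes are
    rejected.  Multiple rows per il_id are allowed.
    """
    known = set(chromosomes) if chromosomes is not None else None
    segments: list[ILSegment] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            chrom, start_s, end_s, il_id = parts[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinate"
                ) from exc
            if start >= end:
                raise ValidationError(
                    f"{path}:{lineno}: segment {il_id!r} has start >= end"
                )
            if known is not None and chrom not in known:
                raise ValidationError(
                    f"{path}:{lineno}: unknown chromosome {chrom!r}"
                )
            segments.append(ILSegment(il_id, chrom, start, end))
    return segments


def write_il_segments(segments: Iterable[ILSegment], path) -> None:
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(f"{seg.chromosome}\t{seg.start}\t{seg.end}\t{seg.il_id}\n")


_ANNOT_COLUMNS = ("gene_id", "chromosome", "start", "end",
                  "functional_category", "is_tf", "tf_family")


def read_annotation(path) -> dict[str, GeneModel]:
    """Read the gene annotation TSV into an ordered gene_id -> GeneModel map."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chromosome": str})
    for col in _ANNOT_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: annotation lacks column {col!r}")
    genes: dict[str, GeneModel] = {}
    for row in df.itertuples(index=False):
        if row.gene_id in genes:
            raise FormatError(f"{path}: duplicate gene id {row.gene_id!r}")
        tf_family = None if pd.isna(row.tf_family) else str(row.tf_family)
        genes[row.gene_id] = GeneModel(
            gene_id=str(row.gene_id),
            chromosome=str(row.chromosome),
            start=int(row.start),
            end=int(row.end),
            functional_category=str(row.functional_category),
            is_tf=bool(row.is_tf),
            tf_family=tf_family,
        )
    return genes


def write_annotation(genes: Mapping[str, GeneModel] | Iterable[GeneModel], path) -> None:
    if isinstance(genes, Mapping):
        genes = genes.values()
    rows = [
        (g.gene_id, g.chromosome, g.start, g.end, g.functional_category,
         g.is_tf, g.tf_family if g.tf_family is not None else "")
        for g in genes
    ]
    pd.DataFrame(rows, columns=_ANNOT_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Edge lists (SIF / TSV) and JSON summaries
# ---------------------------------------------------------------------------


def _sorted_edges(edges: Iterable[CoexpressionEdge]) -> list[CoexpressionEdge]:
    return sorted(edges, key=lambda e: (e.gene_a, e.gene_b))


def write_edge_list(edges: Iterable[CoexpressionEdge], path, format: str = "tsv") -> None:
    """Write edges in deterministic (gene_a, gene_b) lexicographic order.

    ``sif`` emits Cytoscape-loadable ``geneA <sign> geneB`` lines; ``tsv``
    keeps r (12 significant digits) and the P value.
    """
    ordered = _sorted_edges(edges)
    with open(path, "w") as fh:
        if format == "sif":
            for e in ordered:
                fh.write(f"{e.gene_a} {e.sign} {e.gene_b}\n")
        elif format == "tsv":
            fh.write("gene_a\tgene_b\tr\tp_value\tsign\n")
            for e in ordered:
                fh.write(
                    f"{e.gene_a}\t{e.gene_b}\t{_R_FLOAT_FMT % e.r}\t"
                    f"{_R_FLOAT_FMT % e.p_value}\t{e.sign}\n"
                )
        else:
            raise ConfigError(f"unknown edge-list format {format!r}")


def read_edge_list(path) -> list[CoexpressionEdge]:
    """Read back a TSV edge list written by :func:`write_edge_list`."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    return [
        CoexpressionEdge(row.gene_a, row.gene_b, float(row.r), float(row.p_value))
        for row in df.itertuples(index=False)
    ]


def write_json_summary(summary: Mapping, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Structured config (YAML/JSON)
# ---------------------------------------------------------------------------


def load_config(path) -> dict:
    """Load a YAML (or JSON, a YAML subset) config file into a dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: top-level config must be a mapping")
    return cfg


def contrasts_from_config(cfg: Mapping, matrix: ExpressionMatrix) -> dict[str, Contrast]:
    """Build validated Contrast objects from a ``contrasts:`` config block.

    Each entry maps a contrast name to ``{group_a: [...], group_b: [...],
    stage: ...}`` sample-id lists.
    """
    out: dict[str, Contrast] = {}
    for name, spec in cfg.get("contrasts", {}).items():
        contrast = Contrast(
            name=str(name),
            group_a=tuple(spec["group_a"]),
            group_b=tuple(spec["group_b"]),
            stage=str(spec.get("stage", "")),
        )
        contrast.validate_against(matrix)
        out[str(name)] = contrast
    return out
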