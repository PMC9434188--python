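"""Parent-expression sorting (Lyco/Penn sets) and the fold-change filter.

Genes are sorted by the ratio of mean expression in the cultivated parent
(M82, *S. lycopersicum*) to the wild donor parent (*S. pennellii*): genes
with ratio > 1 form the Lyco set, ratio < 1 the Penn set, exact ties a
third explicit class.  A pseudocount stabilizes the ratio where the donor
expression is near zero (e.g. an abundance of 31 against 0.17).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .panel_io import ConfigError, ExpressionMatrix

DEFAULT_PSEUDOCOUNT = 1.0


@dataclass(frozen=True)
class ParentComparison:
    gene_id: str
    expr_lyc: float
    expr_penn: float
    ratio_lyc_over_penn: float
    assigned_set: str  # "Lyco" | "Penn" | "tie"


def _group_means(
    matrix: ExpressionMatrix, samples: Sequence[str], geometric: bool
) -> np.ndarray:
    sub = matrix.values[list(samples)].to_numpy()
    if geometric:
        return np.expm1(np.mean(np.log1p(sub), axis=1))
    return sub.mean(axis=1)


def sort_parent_ratio(
    matrix: ExpressionMatrix,
    lyc_samples: Sequence[str],
    penn_samples: Sequence[str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    geometric: bool = False,
) -> list[ParentComparison]:
    """One pseudocounted parent-ratio record per gene, descending ratio.

    ratio = (mean_lyc + pseudocount) / (mean_penn + pseudocount); ties in
    the ordering are broken by gene id.  ``geometric=True`` switches the
    replicate average from arithmetic to geometric (log1p space).
    """
    if not lyc_samples or not penn_samples:
        raise ConfigError("both parent sample sets must be nonempty")
    if pseudocount <= 0:
        raise ConfigError("pseudocount must be > 0")
    mean_lyc = _group_means(matrix, lyc_samples, geometric)
    mean_penn = _group_means(matrix, penn_samples, geometric)
    ratio = (mean_lyc + pseudocount) / (mean_penn + pseudocount)
    records = []
    for g, ml, mp, r in zip(matrix.gene_ids, mean_lyc, mean_penn, ratio):
        if r > 1:
            assigned = "Lyco"
        elif r < 1:
            assigned = "Penn"
        else:
            assigned = "tie"
        records.append(
            ParentComparison(g, float(ml), float(mp), float(r), assigned)
        )
    records.sort(key=lambda rec: (-rec.ratio_lyc_over_penn, rec.gene_id))
    return records


def fold_change_filter(
    comparisons: Iterable[ParentComparison],
    direction: str,
    min_fc: float = 5.0,
) -> set[str]:
    """Genes at least ``min_fc``-fold higher in the chosen parent.

    ``direction="Lyco"`` thresholds the ratio itself, ``"Penn"`` its
    inverse; the boundary is inclusive (ratio exactly min_fc is kept).
    """
    if min_fc < 1:
        raise ConfigError("min_fc must be >= 1")
    if direction not in ("Lyco", "Penn"):
        raise ConfigError(f"direction must be 'Lyco' or 'Penn', got {direction!r}")
    out = set()
    for rec in comparisons:
        fc = rec.ratio_lyc_over_penn if direction == "Lyco" else 1.0 / rec.ratio_lyc_over_penn
        if fc >= min_fc:
            out.add(rec.gene_id)
    return out


def partition_counts(comparisons: Iterable[ParentComparison]) -> dict[str, int]:
    """Sizes of the Lyco / Penn / tie classes (all three reported)."""
    counts = {"Lyco": 0, "Penn": 0, "tie": 0}
    for rec in comparisons:
        counts[rec.assigned_set] += 1
    return counts
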