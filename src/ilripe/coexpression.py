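"""Thresholded co-expression network over a target gene list.

Pairwise Pearson (optionally Spearman) correlation of log2(x+1)
expression across tissues/stages, with the two-sided P value from the
exact t transform t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of
freedom.  An edge is kept iff |r| > r_min and P < alpha — raw P by
default, matching the common |r| > 0.6, P < 0.05 practice for curated
target lists; Benjamini–Hochberg is available behind a flag.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .panel_io import (
    ConfigError,
    CoexpressionEdge,
    ExpressionMatrix,
    logger,
)

DEFAULT_R_MIN = 0.6
DEFAULT_ALPHA = 0.05
_MIN_P = 5e-324  # smallest subnormal double: P at the |r| = 1 singularity


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided P for a correlation of r over n samples (t transform)."""
    if n < 3:
        raise ConfigError("correlation P undefined below 3 samples")
    if abs(r) >= 1.0:
        return _MIN_P
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def correlation_network(
    matrix: ExpressionMatrix,
    genes: Sequence[str],
    r_min: float = DEFAULT_R_MIN,
    alpha: float = DEFAULT_ALPHA,
    method: str = "pearson",
    log_transform: bool = True,
    bh_correct: bool = False,
) -> list[CoexpressionEdge]:
    """All retained edges among ``genes``, in (gene_a, gene_b) order.

    Zero-variance genes cannot carry a correlation; their pairs are
    skipped with a warning.  ``bh_correct=True`` applies BH across all
    tested pairs before the alpha threshold (off by default).
    """
    if method not in ("pearson", "spearman"):
        raise ConfigError(f"unknown correlation method {method!r}")
    sub = matrix.subset_genes(genes)
    n = len(sub.sample_ids)
    if n < 3:
        raise ConfigError("correlation network needs >= 3 samples")
    data = sub.values.to_numpy(dtype=float)
    if log_transform:
        data = np.log2(data + 1.0)
    if method == "spearman":
        data = stats.rankdata(data, axis=1)

    sd = data.std(axis=1)
    keep = sd > 0
    dropped = [g for g, k in zip(genes, keep) if not k]
    if dropped:
        logger.warning(
            "%d zero-variance genes skipped in correlation network (e.g. %s)",
            len(dropped), dropped[0],
        )
    kept_genes = [g for g, k in zip(genes, keep) if k]
    data = data[keep]
    if len(kept_genes) < 2:
        return []

    corr = np.corrcoef(data)
    corr = np.clip(corr, -1.0, 1.0)

    iu, ju = np.triu_indices(len(kept_genes), k=1)
    r_flat = corr[iu, ju]
    p_flat = np.array([correlation_pvalue(float(r), n) for r in r_flat])
    sig = p_flat
    if bh_correct:
        sig = multipletests(p_flat, method="fdr_bh")[1]
    mask = (np.abs(r_flat) > r_min) & (sig < alpha)

    edges = []
    for i, j, r, p in zip(iu[mask], ju[mask], r_flat[mask], p_flat[mask]):
        a, b = kept_genes[int(i)], kept_genes[int(j)]
        if a > b:
            a, b = b, a
        edges.append(CoexpressionEdge(a, b, float(r), float(p)))
    edges.sort(key=lambda e: (e.gene_a, e.gene_b))
    return edges


def neighborhood(
    edges: Iterable[CoexpressionEdge], focal: str
) -> tuple[list[CoexpressionEdge], int]:
    """Edges incident to the focal gene and its distinct partner count."""
    incident = [e for e in edges if focal in (e.gene_a, e.gene_b)]
    partners = {
        e.gene_b if e.gene_a == focal else e.gene_a for e in incident
    }
    incident.sort(key=lambda e: (e.gene_a, e.gene_b))
    return incident, len(partners)
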