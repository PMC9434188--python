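"""DEG calling, direction-aware conserved overlaps, and 2^-ddCt.

DEGs are called per contrast with the dual threshold |log2FC| >= 1 and
Benjamini–Hochberg FDR < 0.05.  The test statistic is Welch's t on
log2(x+1) replicate values — a transparent default for abundance
matrices; a fold-change-only mode exists for n=2 designs whose variance
estimates are uninformative.  Conserved sets intersect per-contrast
direction calls under a required sign pattern and extend to external
sign-annotated mutant DEG lists under a concordance rule.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .panel_io import ConfigError, Contrast, ExpressionMatrix, logger

DEFAULT_MIN_ABS_LOG2FC = 1.0
DEFAULT_MAX_FDR = 0.05
DEFAULT_PSEUDOCOUNT = 1.0


@dataclass(frozen=True)
class DEGRecord:
    gene_id: str
    contrast: str
    log2_fc: float
    p_value: float
    fdr: float
    direction: str  # "up" | "down" | "ns"


@dataclass
class ConservedSet:
    sign_pattern: dict[str, str]
    members: set[str]
    input_sizes: dict[str, int]
    venn_counts: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class DdctMeasurement:
    """Ct quadruple for Livak relative quantification."""

    ct_target_sample: float
    ct_reference_sample: float
    ct_target_calibrator: float
    ct_reference_calibrator: float

    @property
    def ddct(self) -> float:
        return (self.ct_target_sample - self.ct_reference_sample) - (
            self.ct_target_calibrator - self.ct_reference_calibrator
        )

    @property
    def relative_expression(self) -> float:
        return float(2.0 ** (-self.ddct))


def _welch_p(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Welch t P values with a degenerate-variance convention.

    Zero pooled variance: P = 0 when the means differ, 1 when equal
    (the noiseless planted-fixture limit, shared with the test oracle).
    """
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    se2 = va / na + vb / nb
    p = np.empty(len(ma))
    degenerate = se2 == 0
    p[degenerate] = np.where(ma[degenerate] == mb[degenerate], 1.0, 0.0)
    ok = ~degenerate
    if ok.any():
        t = (ma[ok] - mb[ok]) / np.sqrt(se2[ok])
        df = se2[ok] ** 2 / (
            (va[ok] / na) ** 2 / (na - 1) + (vb[ok] / nb) ** 2 / (nb - 1)
        )
        p[ok] = 2.0 * stats.t.sf(np.abs(t), df=df)
    return p


def call_degs(
    matrix: ExpressionMatrix,
    contrast: Contrast,
    min_abs_log2fc: float = DEFAULT_MIN_ABS_LOG2FC,
    max_fdr: float = DEFAULT_MAX_FDR,
    test: str = "welch",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[DEGRecord]:
    """Per-gene DEG records for one contrast (group_a over group_b).

    log2FC is computed on pseudocounted group means of the raw
    abundances; the Welch test runs on log2(x+1) replicate values and is
    BH-adjusted across all genes in the contrast.  ``test="fold_change"``
    skips testing (P and FDR are NaN) and calls on the FC floor alone —
    required for single-replicate groups.
    """
    contrast.validate_against(matrix)
    a = matrix.values[list(contrast.group_a)].to_numpy(dtype=float)
    b = matrix.values[list(contrast.group_b)].to_numpy(dtype=float)
    log2_fc = np.log2(
        (a.mean(axis=1) + pseudocount) / (b.mean(axis=1) + pseudocount)
    )

    if test == "welch":
        if a.shape[1] < 2 or b.shape[1] < 2:
            raise ConfigError(
                f"contrast {contrast.name!r}: Welch's t needs >= 2 replicates "
                "per group; use test='fold_change' for single-replicate designs"
            )
        p = _welch_p(np.log2(a + 1.0), np.log2(b + 1.0))
        fdr = multipletests(p, method="fdr_bh")[1]
    elif test == "fold_change":
        p = np.full(len(log2_fc), np.nan)
        fdr = np.full(len(log2_fc), np.nan)
    else:
        raise ConfigError(f"unknown test {test!r}")

    records = []
    for g, fc, pv, q in zip(matrix.gene_ids, log2_fc, p, fdr):
        significant = (q < max_fdr) if not math.isnan(q) else True
        if fc >= min_abs_log2fc and significant:
            direction = "up"
        elif fc <= -min_abs_log2fc and significant:
            direction = "down"
        else:
            direction = "ns"
        records.append(
            DEGRecord(g, contrast.name, float(fc), float(pv), float(q), direction)
        )
    return records


def direction_sets(records: Iterable[DEGRecord]) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {"up": set(), "down": set()}
    for rec in records:
        if rec.direction in out:
            out[rec.direction].add(rec.gene_id)
    return out


def _venn_counts(named_sets: Mapping[str, set[str]]) -> dict[str, int]:
    """Exclusive region counts for every nonempty combination of sets."""
    names = list(named_sets)
    universe = set().union(*named_sets.values()) if named_sets else set()
    counts: dict[str, int] = {}
    for k in range(1, len(names) + 1):
        for combo in itertools.combinations(names, k):
            inside = set(universe)
            for name in combo:
                inside &= named_sets[name]
            for name in names:
                if name not in combo:
                    inside -= named_sets[name]
            counts["&".join(combo)] = len(inside)
    return counts


def conserved_overlap(
    deg_sets: Sequence[tuple[str, Sequence[DEGRecord]]],
    sign_pattern: Mapping[str, str],
) -> ConservedSet:
    """Genes meeting the required direction in every patterned contrast.

    Also reports all exclusive Venn region counts over the per-contrast
    direction-matching sets (they partition the union).
    """
    available = {name for name, _records in deg_sets}
    for name in sign_pattern:
        if name not in available:
            raise ConfigError(f"sign pattern references unknown contrast {name!r}")
    matching: dict[str, set[str]] = {}
    sizes: dict[str, int] = {}
    for name, records in deg_sets:
        if name not in sign_pattern:
            continue
        want = sign_pattern[name]
        if want not in ("up", "down"):
            raise ConfigError(f"invalid required direction {want!r}")
        matching[name] = {r.gene_id for r in records if r.direction == want}
        sizes[name] = len(matching[name])
    members = (
        set.intersection(*matching.values()) if matching else set()
    )
    return ConservedSet(
        sign_pattern=dict(sign_pattern),
        members=members,
        input_sizes=sizes,
        venn_counts=_venn_counts(matching),
    )


def conserved_with_external(
    internal: ConservedSet,
    external_sets: Mapping[str, Mapping[str, str] | set[str]],
    concordant_with: str | None = None,
) -> ConservedSet:
    """Intersect a conserved set with external sign-annotated DEG lists.

    Sign concordance: each external gene's sign must equal the direction
    the internal pattern requires in the ``concordant_with`` contrast
    (default: the first knockdown-like contrast, i.e. a name containing
    "RNAi", else the first contrast of the pattern) — loss-of-function
    mutants are expected to move with the knockdown.  Unsigned external
    sets (plain gene-id sets) are accepted with sign checks disabled and
    a warning.
    """
    if concordant_with is None:
        rnai = [n for n in internal.sign_pattern if "RNAi" in n]
        concordant_with = rnai[0] if rnai else next(iter(internal.sign_pattern))
    if concordant_with not in internal.sign_pattern:
        raise ConfigError(
            f"concordant_with contrast {concordant_with!r} not in the pattern"
        )
    required = internal.sign_pattern[concordant_with]

    members = set(internal.members)
    sizes = dict(internal.input_sizes)
    pattern = dict(internal.sign_pattern)
    named: dict[str, set[str]] = {"internal": set(internal.members)}
    for name in sorted(external_sets):
        ext = external_sets[name]
        if isinstance(ext, Mapping):
            keep = {g for g, sign in ext.items() if sign == required}
            pattern[name] = required
        else:
            logger.warning(
                "external set %s is unsigned; sign checks disabled", name
            )
            keep = set(ext)
            pattern[name] = "any"
        sizes[name] = len(ext)
        named[name] = keep
        members &= keep
    return ConservedSet(
        sign_pattern=pattern,
        members=members,
        input_sizes=sizes,
        venn_counts=_venn_counts(named),
    )


def read_signed_gene_list(path) -> dict[str, str]:
    """Read a two-column TSV (gene_id, up/down) external DEG list."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#") or line.lower().startswith("gene_id"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or parts[1] not in ("up", "down"):
                raise ConfigError(f"{path}:{lineno}: expected 'gene<TAB>up|down'")
            out[parts[0]] = parts[1]
    return out


def ddct(measurements: Iterable[DdctMeasurement]) -> list[float]:
    """2^-ddCt relative expression per measurement (Livak method)."""
    out = []
    for m in measurements:
        for name in ("ct_target_sample", "ct_reference_sample",
                     "ct_target_calibrator", "ct_reference_calibrator"):
            if not math.isfinite(getattr(m, name)):
                raise ConfigError(f"non-finite Ct value in field {name}")
        out.append(m.relative_expression)
    return out
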