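"""Seeded generators for IL-panel and transgenic expression datasets.

The generators emulate the statistical structure an introgression-line
(IL) eQTL screen assumes: a panel of ~76 lines whose donor segments tile
the genome with adjacent overlaps and occasional nested sub-lines,
genotype-switched cis-eQTL expression (a gene inside an introgression
takes the donor parental mean), sparse trans effects (a donor-allele
regulator shifting a distant target), multiplicative log-normal noise,
ripening-stage induction for a subset of TF genes, and
overexpression/RNAi/mutant differential-expression structure.

Expression is log-normal: log2 abundance ~ Normal(mean, noise_sd_log2).
The pipeline consumes abundance ratios, not read counts, so a count
model (negative binomial) would add nothing the downstream statistics
can see.

Reproducibility contract: a single ``numpy.random.default_rng(seed)``
stream is threaded through each generator, and the draw order is fixed
and documented in the function bodies.  Same seed + config => byte
identical outputs, including in the zero-noise limit (the noise draw is
always made, with sd possibly 0, so the stream position is invariant).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel_io import (
    ConfigError,
    Contrast,
    ExpressionMatrix,
    GeneModel,
    ILSegment,
)

STAGES = ("Leaf", "Root", "Flower", "MG", "Br", "Br+10")
RIPENING_STAGES = ("Br", "Br+10")

TF_FAMILIES = ("MADS", "AP2/ERF", "WRKY", "bHLH", "NAC", "WD40")


@dataclass(frozen=True)
class PanelConfig:
    """Parameters of the synthetic IL panel.

    Defaults encode the emulated study conditions: 12 chromosomes, 76
    overlapping ILs with nested sub-lines, 5,000 genes, 150 cis-eQTLs of
    |log2 effect| 2, 30 trans pairs, log2 noise sd 0.4 and 3 replicates
    per sample group.
    """

    n_chromosomes: int = 12
    chromosome_length: int = 50_000_000
    n_ils: int = 76
    n_genes: int = 5_000
    n_cis_eqtl: int = 150
    n_trans_pairs: int = 30
    cis_effect_log2: float = 2.0        # minimum |log2| donor/recurrent shift
    cis_effect_log2_max: float = 4.0    # magnitudes drawn U(min, max)
    trans_effect_log2: float = 1.5
    noise_sd_log2: float = 0.4
    n_replicates: int = 3
    fraction_tf: float = 0.08
    nested_fraction: float = 0.15
    penn_dropout_prob: float = 0.02
    dropout_log2: float = -2.5          # "negligibly expressed" donor allele
    expr_log2_range: tuple[float, float] = (0.0, 10.0)
    cis_expr_min_log2: float = 3.0      # planted cis genes must be expressed
    ripening_induction_log2: float = 3.0
    fraction_ripening_tf: float = 0.3
    planted_effect_log2: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        counts = dict(
            n_chromosomes=self.n_chromosomes,
            chromosome_length=self.chromosome_length,
            n_ils=self.n_ils,
            n_genes=self.n_genes,
            n_cis_eqtl=self.n_cis_eqtl,
            n_trans_pairs=self.n_trans_pairs,
            n_replicates=self.n_replicates,
        )
        for name, value in counts.items():
            if value < 0:
                raise ConfigError(f"{name} must be >= 0, got {value}")
        for name in ("fraction_tf", "nested_fraction", "penn_dropout_prob",
                     "fraction_ripening_tf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.noise_sd_log2 < 0:
            raise ConfigError("noise_sd_log2 must be >= 0")
        if self.cis_effect_log2_max < self.cis_effect_log2:
            raise ConfigError("cis_effect_log2_max must be >= cis_effect_log2")
        if self.n_ils and self.n_ils < self.n_chromosomes:
            raise ConfigError(
                "n_ils must be >= n_chromosomes to tile every chromosome"
            )
        if self.n_cis_eqtl > self.n_genes:
            raise ConfigError("n_cis_eqtl exceeds n_genes")
        if self.n_trans_pairs > self.n_cis_eqtl:
            raise ConfigError(
                "n_trans_pairs exceeds n_cis_eqtl (regulators are cis genes)"
            )


@dataclass
class PanelTruth:
    """Planted ground truth of a generated panel."""

    annotation: dict[str, GeneModel]
    design: list[ILSegment]
    cis_genes: set[str]
    dropout_genes: set[str]
    cis_sign: dict[str, int]
    trans_map: dict[str, set[str]]
    trans_sign: dict[tuple[str, str], int]
    m82_log2: dict[str, float]
    penn_log2: dict[str, float]
    located_ils: dict[str, set[str]]

    @property
    def trans_targets(self) -> set[str]:
        out: set[str] = set()
        for targets in self.trans_map.values():
            out |= targets
        return out

    def to_json_dict(self) -> dict:
        return {
            "cis_genes": sorted(self.cis_genes),
            "dropout_genes": sorted(self.dropout_genes),
            "cis_sign": {g: self.cis_sign[g] for g in sorted(self.cis_sign)},
            "trans_map": {r: sorted(t) for r, t in sorted(self.trans_map.items())},
            "located_ils": {g: sorted(v) for g, v in sorted(self.located_ils.items())},
            "m82_log2": {g: self.m82_log2[g] for g in sorted(self.m82_log2)},
            "penn_log2": {g: self.penn_log2[g] for g in sorted(self.penn_log2)},
        }


@dataclass
class TransgenicTruth:
    """Planted DEG truth for the transgenic (WT/OE/RNAi) experiment.

    ``core_up_oe`` genes are up in OE at MG and down in RNAi at Br and
    Pink (and down in the mutant label sets); ``core_down_oe`` is the
    mirror.  ``extras`` are genotype-private DEGs per contrast.
    """

    core_up_oe: set[str]
    core_down_oe: set[str]
    extras: dict[str, set[str]]
    rin: dict[str, str]
    nor: dict[str, str]


def _chromosome_names(n: int) -> list[str]:
    return [f"ch{i:02d}" for i in range(1, n + 1)]


# ---------------------------------------------------------------------------
# IL design
# ---------------------------------------------------------------------------


def generate_il_design(cfg: PanelConfig) -> list[ILSegment]:
    """Tile every chromosome with overlapping IL segments plus nested sub-ILs.

    Main segments partition each chromosome into equal spans extended by a
    10% overlap on interior boundaries, so the per-chromosome union is
    exactly [0, chromosome_length).  A ``nested_fraction`` share of the
    lines are sub-segments strictly contained in a randomly chosen main
    segment (named ``<parent>-1``, ``-2``...), emulating IL4-1 / IL4-1-1.

    Draw order: one uniform pair per nested segment (parent choice is by
    round-robin over a seeded permutation of main segments).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    chroms = _chromosome_names(cfg.n_chromosomes)
    L = cfg.chromosome_length

    n_nested = int(round(cfg.nested_fraction * cfg.n_ils))
    n_main = cfg.n_ils - n_nested
    if n_main < cfg.n_chromosomes:
        raise ConfigError(
            f"infeasible tiling: {n_main} main segments cannot cover "
            f"{cfg.n_chromosomes} chromosomes"
        )

    base, extra = divmod(n_main, cfg.n_chromosomes)
    segments: list[ILSegment] = []
    mains: list[ILSegment] = []
    for ci, chrom in enumerate(chroms):
        k = base + (1 if ci < extra else 0)
        span = L // k
        d = max(1, span // 10)
        for i in range(k):
            start = 0 if i == 0 else i * span - d
            end = L if i == k - 1 else (i + 1) * span + d
            seg = ILSegment(f"IL{ci + 1}-{i + 1}", chrom, start, end)
            segments.append(seg)
            mains.append(seg)

    # nested sub-ILs strictly inside seeded-permuted parents
    parent_order = rng.permutation(len(mains))
    child_counts: dict[str, int] = {}
    for j in range(n_nested):
        parent = mains[int(parent_order[j % len(mains)])]
        u1, u2 = rng.uniform(size=2)
        span = parent.end - parent.start
        # keep >= 1 bp clear of both parent ends: strict containment
        start = parent.start + 1 + int(u1 * (span - 3) * 0.5)
        end = start + 1 + int(u2 * (parent.end - 1 - start - 1))
        end = min(end, parent.end - 1)
        child_counts[parent.il_id] = child_counts.get(parent.il_id, 0) + 1
        child_id = f"{parent.il_id}-{child_counts[parent.il_id]}"
        segments.append(ILSegment(child_id, parent.chromosome, start, end))
    return segments


def locate_genes(
    genes: Mapping[str, GeneModel] | Sequence[GeneModel],
    design: Sequence[ILSegment],
) -> dict[str, set[str]]:
    """Map each gene to the ILs whose intervals contain its start position."""
    if isinstance(genes, Mapping):
        genes = list(genes.values())
    by_chrom: dict[str, list[ILSegment]] = {}
    for seg in design:
        by_chrom.setdefault(seg.chromosome, []).append(seg)
    located: dict[str, set[str]] = {}
    for g in genes:
        hits = {
            seg.il_id
            for seg in by_chrom.get(g.chromosome, ())
            if seg.start <= g.start < seg.end
        }
        located[g.gene_id] = hits
    return located


# ---------------------------------------------------------------------------
# Panel expression
# ---------------------------------------------------------------------------


def _draw_annotation(cfg: PanelConfig, rng: np.random.Generator) -> dict[str, GeneModel]:
    """Draw gene loci and annotations (draws 1-5 of the panel stream)."""
    chroms = _chromosome_names(cfg.n_chromosomes)
    chrom_idx = rng.integers(0, cfg.n_chromosomes, cfg.n_genes)        # draw 1
    pos = rng.integers(0, cfg.chromosome_length - 2_000, cfg.n_genes)  # draw 2
    is_tf = rng.random(cfg.n_genes) < cfg.fraction_tf                  # draw 3
    cat_draw = rng.random(cfg.n_genes)                                 # draw 4
    fam_idx = rng.integers(0, len(TF_FAMILIES), cfg.n_genes)           # draw 5

    order = np.lexsort((pos, chrom_idx))
    genes: dict[str, GeneModel] = {}
    per_chrom_rank: dict[int, int] = {}
    for j in order:
        c = int(chrom_idx[j])
        rank = per_chrom_rank.get(c, 0) + 1
        per_chrom_rank[c] = rank
        gene_id = f"Solyc{c + 1:02d}g{rank * 10:06d}"
        if is_tf[j]:
            category = "transcription_regulator"
            family = TF_FAMILIES[int(fam_idx[j])]
        else:
            family = None
            if cat_draw[j] < 0.05:
                category = "oxidase"
            elif cat_draw[j] < 0.10:
                category = "cytochrome_P450"
            else:
                category = "other"
        genes[gene_id] = GeneModel(
            gene_id=gene_id,
            chromosome=chroms[c],
            start=int(pos[j]),
            end=int(pos[j]) + 2_000,
            functional_category=category,
            is_tf=bool(is_tf[j]),
            tf_family=family,
        )
    return genes


def generate_panel_expression(
    cfg: PanelConfig, design: Sequence[ILSegment]
) -> tuple[ExpressionMatrix, PanelTruth]:
    """Generate the ripe-fruit IL-panel expression matrix with planted truth.

    Sample groups: M82 and Penn parents plus one group per IL, each with
    ``n_replicates`` replicates.  Per gene and IL the log2 mean is the
    donor (Penn) parental mean if the gene is a planted cis gene located
    inside that IL's introgression, else the M82 mean, plus the planted
    trans effect for targets whose regulator resides in the introgression.

    Trans targets are drawn outside every IL containing their regulator,
    so a trans effect can never masquerade as a cis signal by chance
    collocation — the confounded geometry the screen cannot distinguish
    is excluded by design.

    Draw order: annotation draws 1-5, M82 means (6), cis gene choice,
    signs and effect magnitudes (7-9; magnitudes uniform on
    [cis_effect_log2, cis_effect_log2_max]), dropout mask (10), trans
    regulators/targets/signs (11+, target redraws consume further
    uniforms), then one Normal noise block.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes = _draw_annotation(cfg, rng)
    gene_ids = list(genes)
    n = len(gene_ids)
    lo, hi = cfg.expr_log2_range

    m82 = rng.uniform(lo, hi, n)                                       # draw 6
    # cis effects are planted on expressed genes only: an eQTL on a
    # transcript below the pseudocount scale is undetectable by any
    # ratio-based screen, so it would not model a discoverable signal
    eligible = np.nonzero(m82 >= cfg.cis_expr_min_log2)[0]
    if len(eligible) < cfg.n_cis_eqtl:
        raise ConfigError(
            f"only {len(eligible)} genes exceed cis_expr_min_log2; "
            f"cannot plant {cfg.n_cis_eqtl} cis eQTLs"
        )
    cis_idx = rng.choice(eligible, size=cfg.n_cis_eqtl, replace=False)  # draw 7
    cis_signs = rng.choice([-1, 1], size=cfg.n_cis_eqtl)               # draw 8
    cis_mags = rng.uniform(cfg.cis_effect_log2, cfg.cis_effect_log2_max,
                           cfg.n_cis_eqtl)                             # draw 9
    dropout = rng.random(n) < cfg.penn_dropout_prob                    # draw 10

    penn = m82.copy()
    cis_set = {gene_ids[int(i)] for i in cis_idx}
    cis_sign = {}
    for i, s, mag in zip(cis_idx, cis_signs, cis_mags):
        penn[int(i)] = m82[int(i)] + int(s) * float(mag)
        cis_sign[gene_ids[int(i)]] = int(s)
    # donor-dropout genes: near-silent donor allele.  Genetically these
    # are cis differences too, so the ILs carrying their locus switch to
    # the (near-zero) donor mean just like planted cis genes.
    dropout_set = set()
    for i in np.nonzero(dropout)[0]:
        if gene_ids[int(i)] not in cis_set:
            dropout_set.add(gene_ids[int(i)])
            penn[int(i)] = cfg.dropout_log2

    located = locate_genes(genes, design)

    # trans pairs: regulators among cis genes, targets outside the
    # regulator's ILs and outside the cis set
    reg_pool = sorted(cis_set)
    reg_idx = rng.choice(len(reg_pool), size=cfg.n_trans_pairs, replace=False)  # draw 10
    trans_map: dict[str, set[str]] = {}
    trans_sign: dict[tuple[str, str], int] = {}
    taken: set[str] = set()
    for ri in reg_idx:
        reg = reg_pool[int(ri)]
        reg_ils = located[reg]
        target = None
        while target is None:
            cand = gene_ids[int(rng.integers(0, n))]                   # draws 11+
            if cand in cis_set or cand in dropout_set or cand in taken or cand == reg:
                continue
            if located[cand] & reg_ils:
                continue
            target = cand
        taken.add(target)
        sign = int(rng.choice([-1, 1]))
        trans_map.setdefault(reg, set()).add(target)
        trans_sign[(reg, target)] = sign

    # sample layout: M82, Penn, then ILs in design order (first interval
    # order, one group per distinct il_id)
    il_order: list[str] = []
    seen = set()
    for seg in design:
        if seg.il_id not in seen:
            seen.add(seg.il_id)
            il_order.append(seg.il_id)
    groups = ["M82", "Penn"] + il_order

    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    means = np.empty((n, len(groups)))
    means[:, 0] = m82
    means[:, 1] = penn
    for gi, il in enumerate(il_order, start=2):
        col = m82.copy()
        for g in cis_set | dropout_set:
            if il in located[g]:
                col[gene_pos[g]] = penn[gene_pos[g]]
        for reg, targets in trans_map.items():
            if il in located[reg]:
                for t in targets:
                    col[gene_pos[t]] += trans_sign[(reg, t)] * cfg.trans_effect_log2
        means[:, gi] = col

    reps = max(1, cfg.n_replicates)
    full_means = np.repeat(means, reps, axis=1)
    noise = rng.normal(0.0, 1.0, full_means.shape)        # final noise block
    log2_values = full_means + cfg.noise_sd_log2 * noise
    values = np.power(2.0, log2_values)

    sample_ids = [f"{g}_r{r + 1}" for g in groups for r in range(reps)]
    meta = pd.DataFrame(
        {
            "genotype": [g for g in groups for _ in range(reps)],
            "stage": "ripe",
            "replicate": [r + 1 for _ in groups for r in range(reps)],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                     columns=sample_ids),
        meta,
    )
    truth = PanelTruth(
        annotation=genes,
        design=list(design),
        cis_genes=cis_set,
        dropout_genes=dropout_set,
        cis_sign=cis_sign,
        trans_map=trans_map,
        trans_sign=trans_sign,
        m82_log2={g: float(m82[gene_pos[g]]) for g in gene_ids},
        penn_log2={g: float(penn[gene_pos[g]]) for g in gene_ids},
        located_ils=located,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Stage/tissue profiles (for the TF route and tissue specificity)
# ---------------------------------------------------------------------------


def generate_stage_matrix(
    cfg: PanelConfig, truth: PanelTruth
) -> tuple[ExpressionMatrix, set[str]]:
    """Expression of the M82 background across tissues and ripening stages.

    A seeded subset (``fraction_ripening_tf``) of TF genes is planted as
    ripening-induced: strongly expressed only from breaker onward with a
    further ``ripening_induction_log2`` induction at Br+10 over Br — the
    pattern the TF route ranks on.  All other genes are stage-uniform.

    Returns the matrix and the planted ripening gene set.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    gene_ids = list(truth.annotation)
    tf_ids = [g for g in gene_ids if truth.annotation[g].is_tf]
    pick = rng.random(len(tf_ids)) < cfg.fraction_ripening_tf
    ripening = {g for g, p in zip(tf_ids, pick) if p}

    base = np.array([truth.m82_log2[g] for g in gene_ids])
    n = len(gene_ids)
    means = np.tile(base[:, None], (1, len(STAGES)))
    for gi, g in enumerate(gene_ids):
        if g in ripening:
            for si, stage in enumerate(STAGES):
                if stage == "Br+10":
                    means[gi, si] = base[gi] + cfg.ripening_induction_log2
                elif stage == "Br":
                    means[gi, si] = base[gi]
                else:
                    means[gi, si] = base[gi] - 2.0 * cfg.ripening_induction_log2

    reps = max(1, cfg.n_replicates)
    full = np.repeat(means, reps, axis=1)
    noise = rng.normal(0.0, 1.0, full.shape)
    values = np.power(2.0, full + cfg.noise_sd_log2 * noise)
    sample_ids = [f"M82_{s}_r{r + 1}" for s in STAGES for r in range(reps)]
    meta = pd.DataFrame(
        {
            "genotype": "M82",
            "stage": [s for s in STAGES for _ in range(reps)],
            "replicate": [r + 1 for _ in STAGES for r in range(reps)],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                     columns=sample_ids),
        meta,
    )
    return matrix, ripening


# ---------------------------------------------------------------------------
# Transgenic (WT / OE / RNAi) experiment
# ---------------------------------------------------------------------------

TRANSGENIC_STAGES = ("MG", "Br", "Pink")
TRANSGENIC_GENOTYPES = ("WT", "OE", "RNAi")

#: contrast name -> (genotype, stage, planted sign for the core_up_oe genes)
CORE_PATTERN = {
    "OE_MG": ("OE", "MG", +1),
    "RNAi_Br": ("RNAi", "Br", -1),
    "RNAi_Pink": ("RNAi", "Pink", -1),
}


def generate_transgenic_experiment(
    cfg: PanelConfig,
    conserved_core_size: int,
    per_genotype_extra: int,
) -> tuple[ExpressionMatrix, TransgenicTruth]:
    """Generate the OE/RNAi/WT stage series plus mutant DEG label sets.

    Plants a conserved core of ``conserved_core_size`` genes up in OE at
    MG, down in RNAi at Br and Pink and down in the rin/nor label sets,
    plus a mirrored core with all signs flipped, plus
    ``per_genotype_extra`` private DEGs per contrast and per mutant set.
    Effect size is ``planted_effect_log2`` in log2 units.

    Draw order: baseline means (1), gene-role permutation (2), extra
    signs (3), mutant extra signs (4), noise block (5).
    """
    cfg.validate()
    n_contrasts = len(CORE_PATTERN)
    need = 2 * conserved_core_size + per_genotype_extra * (n_contrasts + 2)
    if need > cfg.n_genes:
        raise ConfigError(
            f"core/extra assignment needs {need} genes but n_genes={cfg.n_genes}"
        )
    rng = np.random.default_rng(cfg.seed + 2)
    gene_ids = [f"Solyc00g{(i + 1) * 10:06d}" for i in range(cfg.n_genes)]
    lo, hi = cfg.expr_log2_range
    base = rng.uniform(max(lo, 2.0), hi, cfg.n_genes)                  # draw 1
    perm = rng.permutation(cfg.n_genes)                                # draw 2

    cursor = 0

    def take(k: int) -> list[int]:
        nonlocal cursor
        out = [int(i) for i in perm[cursor:cursor + k]]
        cursor += k
        return out

    core_up_idx = take(conserved_core_size)
    core_down_idx = take(conserved_core_size)
    extras_idx = {name: take(per_genotype_extra) for name in CORE_PATTERN}
    rin_extra_idx = take(per_genotype_extra)
    nor_extra_idx = take(per_genotype_extra)

    extra_signs = {
        name: rng.choice([-1, 1], size=per_genotype_extra)             # draw 3
        for name in CORE_PATTERN
    }
    mut_signs = {
        "rin": rng.choice([-1, 1], size=per_genotype_extra),           # draw 4
        "nor": rng.choice([-1, 1], size=per_genotype_extra),
    }

    groups = [(g, s) for g in TRANSGENIC_GENOTYPES for s in TRANSGENIC_STAGES]
    col_of = {gs: i for i, gs in enumerate(groups)}
    means = np.tile(base[:, None], (1, len(groups)))
    e = cfg.planted_effect_log2
    for name, (genotype, stage, sign) in CORE_PATTERN.items():
        col = col_of[(genotype, stage)]
        for i in core_up_idx:
            means[i, col] = base[i] + sign * e
        for i in core_down_idx:
            means[i, col] = base[i] - sign * e
        for i, s in zip(extras_idx[name], extra_signs[name]):
            means[i, col] = base[i] + int(s) * e

    reps = max(1, cfg.n_replicates)
    full = np.repeat(means, reps, axis=1)
    noise = rng.normal(0.0, 1.0, full.shape)                           # draw 5
    values = np.power(2.0, full + cfg.noise_sd_log2 * noise)

    sample_ids = [
        f"{g}_{s}_r{r + 1}" for (g, s) in groups for r in range(reps)
    ]
    meta = pd.DataFrame(
        {
            "genotype": [g for (g, _s) in groups for _ in range(reps)],
            "stage": [s for (_g, s) in groups for _ in range(reps)],
            "replicate": [r + 1 for _ in groups for r in range(reps)],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                     columns=sample_ids),
        meta,
    )

    core_up = {gene_ids[i] for i in core_up_idx}
    core_down = {gene_ids[i] for i in core_down_idx}
    # mutant label sets: loss-of-function mutants behave like the RNAi
    # knockdown, so core_up_oe genes are "down" there and the mirror "up"
    rin = {gene_ids[i]: "down" for i in core_up_idx}
    rin.update({gene_ids[i]: "up" for i in core_down_idx})
    nor = dict(rin)
    rin.update(
        {gene_ids[i]: ("up" if int(s) > 0 else "down")
         for i, s in zip(rin_extra_idx, mut_signs["rin"])}
    )
    nor.update(
        {gene_ids[i]: ("up" if int(s) > 0 else "down")
         for i, s in zip(nor_extra_idx, mut_signs["nor"])}
    )
    truth = TransgenicTruth(
        core_up_oe=core_up,
        core_down_oe=core_down,
        extras={name: {gene_ids[i] for i in idx}
                for name, idx in extras_idx.items()},
        rin=rin,
        nor=nor,
    )
    return matrix, truth


def transgenic_contrasts(matrix: ExpressionMatrix) -> dict[str, Contrast]:
    """The three planted transgenic-vs-WT contrasts of the experiment."""
    out = {}
    for name, (genotype, stage, _sign) in CORE_PATTERN.items():
        out[name] = Contrast(
            name=name,
            group_a=tuple(matrix.samples_where(genotype=genotype, stage=stage)),
            group_b=tuple(matrix.samples_where(genotype="WT", stage=stage)),
            stage=stage,
        )
    return out
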