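#!/usr/bin/env python
"""Generate the synthetic study datasets.

Emulates the study design: two parents (cultivated M82 background and
the wild donor), a 76-line introgression panel tiling 12 chromosomes
with nested sub-lines, 5,000 genes with 150 planted cis-eQTLs and 30
trans pairs, a tissue/stage expression matrix with ripening-induced TF
genes, and an OE/RNAi/WT transgenic series with a planted conserved DEG
core.  Full matrices go to scratch/data (large); compact design and
truth summaries go to results/.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]

from ilripe import PanelConfig
from ilripe.panel_io import (
    write_annotation,
    write_expression_matrix,
    write_il_segments,
    write_json_summary,
)
from ilripe.synthetic_panel import (
    generate_il_design,
    generate_panel_expression,
    generate_stage_matrix,
    generate_transgenic_experiment,
)

SEED = 1


def main() -> None:
    data_dir = ROOT / "scratch" / "data"
    results = ROOT / "results"
    data_dir.mkdir(parents=True, exist_ok=True)
    results.mkdir(exist_ok=True)

    cfg = PanelConfig(seed=SEED)
    design = generate_il_design(cfg)
    matrix, truth = generate_panel_expression(cfg, design)
    stage_matrix, ripening = generate_stage_matrix(cfg, truth)
    tg_cfg = PanelConfig(n_genes=1000, seed=SEED, noise_sd_log2=0.2,
                         n_replicates=6)
    tg_matrix, tg_truth = generate_transgenic_experiment(tg_cfg, 40, 20)

    write_il_segments(design, data_dir / "il_design.bed")
    write_annotation(truth.annotation, data_dir / "annotation.tsv")
    write_expression_matrix(matrix, data_dir / "panel_expression.tsv",
                            data_dir / "panel_samples.tsv")
    write_expression_matrix(stage_matrix, data_dir / "stage_expression.tsv",
                            data_dir / "stage_samples.tsv")
    write_expression_matrix(tg_matrix, data_dir / "transgenic_expression.tsv",
                            data_dir / "transgenic_samples.tsv")
    payload = truth.to_json_dict()
    payload["ripening_tfs"] = sorted(ripening)
    write_json_summary(payload, data_dir / "panel_truth.json")
    write_json_summary(
        {
            "core_up_oe": sorted(tg_truth.core_up_oe),
            "core_down_oe": sorted(tg_truth.core_down_oe),
            "rin": tg_truth.rin,
            "nor": tg_truth.nor,
        },
        data_dir / "transgenic_truth.json",
    )

    nested = sum(
        1 for a in design
        for b in design
        if a is not b and a.chromosome == b.chromosome
        and b.start <= a.start and a.end <= b.end
        and (a.start, a.end) != (b.start, b.end)
    )
    summary = {
        "seed": SEED,
        "panel": {
            "n_ils": len({s.il_id for s in design}),
            "n_segments": len(design),
            "n_nested_segments": nested,
            "n_genes": cfg.n_genes,
            "n_cis_eqtl": len(truth.cis_genes),
            "n_trans_pairs": sum(len(t) for t in truth.trans_map.values()),
            "noise_sd_log2": cfg.noise_sd_log2,
            "n_samples": len(matrix.sample_ids),
        },
        "stage_matrix": {
            "n_ripening_tfs": len(ripening),
            "n_samples": len(stage_matrix.sample_ids),
        },
        "transgenic": {
            "conserved_core_size": len(tg_truth.core_up_oe),
            "n_samples": len(tg_matrix.sample_ids),
            "n_replicates": tg_cfg.n_replicates,
        },
    }
    write_json_summary(summary, results / "01_simulation_design.json")
    print(f"Simulated {len({s.il_id for s in design})} ILs "
          f"({nested} nested sub-lines), {cfg.n_genes} genes, "
          f"{len(truth.cis_genes)} cis eQTLs, "
          f"{sum(len(t) for t in truth.trans_map.values())} trans pairs.")
    print(f"Data under {data_dir}, design summary in results/01_simulation_design.json")


if __name__ == "__main__":
    main()
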