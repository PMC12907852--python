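"""Tumor-progression statistics on a 10-mouse cohort with a known effect.

One sgRNA carries a x5 multiplicative size effect.  Statistics (tumor
number, LN mean, heavy-tail burden) are normalized to the inert sgRNAs
within each mouse and averaged; the LN-mean ratio gets a two-stage
bootstrap CI and p-value, and tumor number gets Fisher's exact test.
"""

import pandas as pd

import tubaquant as tq
from tubaquant.stats import StatsConfig

pool = tq.build_pool_design(8, 2, seed=1)
sg_effect = pool.entries[0].sgRNA_name
config = tq.SimConfig(
    seed=5, tumors_per_sgRNA_rate=100, tail_fraction=0.0,
    effect_multipliers={sg_effect: 5.0},
)

smap = {e.sgID: (e.sgRNA_name, e.target_gene) for e in pool.entries}
rows = []
for i in range(10):
    for t in tq.sample_tumors(config, pool, f"mouse{i:02d}"):
        name, gene = smap[t.sgID]
        rows.append({"mouse_id": t.mouse_id, "sgRNA_name": name,
                     "target_gene": gene, "cells": float(t.true_cells)})
tumor_table = pd.DataFrame(rows)

stats_cfg = StatsConfig(bootstrap_iterations=2000, rng_seed=5)
summary = tq.genotype_statistics(tumor_table, pool, stats_cfg, level="sgRNA")
ln = summary[summary["statistic"] == "ln_mean"].set_index("group")
row = ln.loc[sg_effect]
print(f"{sg_effect}: relative LN mean {row['relative']:.2f} "
      f"(95% CI {row['ci_low']:.2f}-{row['ci_high']:.2f}, p = {row['p_value']:.2g})")
neutral = ln.drop(index=sg_effect)
print(f"other sgRNAs: relative LN mean {neutral['relative'].min():.2f}"
      f"-{neutral['relative'].max():.2f} (all ~1)")

inert = tumor_table[tumor_table["sgRNA_name"].isin(pool.inert_names())]["cells"]
sg = tumor_table[tumor_table["sgRNA_name"] == sg_effect]["cells"]
spectrum = tq.qq_spectrum(sg, inert, grid=[50, 90, 99])
print("Q-Q ratio at 50/90/99th percentile:",
      " ".join(f"{r:.2f}" for r in spectrum["ratio"]))
# The relative LN mean recovers the injected x5 effect and the Q-Q
# spectrum is flat near 5 — a pure location shift on the log scale.
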