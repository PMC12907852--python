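"""Simulate a barcoded amplicon sequencing sample with known ground truth.

Builds a 20-vector lentiviral pool (8 genes x 2 sgRNAs + 2 inerts +
positive/negative controls), draws one mouse's tumors from the
log-normal-body / Pareto-tail size model, and writes paired FASTQ with
realistic recurrent read errors plus the six benchmark spike-ins.
"""

import tempfile
from pathlib import Path

import tubaquant as tq

out = Path(tempfile.mkdtemp(prefix="tubaquant_sim_"))
pool = tq.build_pool_design(n_genes=8, sgRNAs_per_gene=2, seed=1)
config = tq.SimConfig(seed=1, tumors_per_sgRNA_rate=50)
tumors = tq.sample_tumors(config, pool, "mouse01")

truth = tq.simulate_sample(
    tumors,
    tq.default_spikeins(),
    tq.ConstructTemplate(),
    tq.ErrorModel.flat(per_base_substitution=1e-3, ins_rate=3e-5, del_rate=3e-5),
    reads_per_cell=0.1,
    seed=1,
    r1_path=out / "mouse01_R1.fastq",
    r2_path=out / "mouse01_R2.fastq",
)

print(f"pool: {len(pool)} vectors; inerts: {pool.inert_names()}")
print(f"tumors drawn: {len(tumors)}")
print(f"cells, median / max: {truth['true_cells'].median():.0f} / {truth['true_cells'].max()}")
print(f"read pairs written: {truth['reads'].sum()} -> {out}")
# Each truth row ties one (sgID, barcode) clone to its cell number and its
# emitted read count; the FASTQ files are what the pipeline consumes.
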