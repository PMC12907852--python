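"""End-to-end driver: extract -> denoise -> quantify -> stats.

Every read pair entering the pipeline ends up in exactly one terminal
category (tumor call, spike-in, or filtered-with-reason), and every filter
count is logged and written to the QC JSON.  A single global seed fans out
to per-stage, per-sample RNGs: simulation streams derive from
(seed, crc32(mouse_id), stream), and the statistics stage reuses the
global seed as its bootstrap seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .errors import estimate_error_model, filter_spurious, estimate_collision_rate, assess_gc_bias
from .extract import dereplicate, extract_read_pairs, filter_pileups
from .pool import PoolDesign
from .quantify import apply_min_cell_cutoff, spikein_normalize
from .sim import ConstructTemplate, ErrorModel, SimConfig, SpikeInSet, sample_tumors, simulate_sample
from .stats import genotype_statistics

logger = logging.getLogger(__name__)


def simulate_cohort(
    pool: PoolDesign,
    spikeins: SpikeInSet,
    template: ConstructTemplate,
    error_model: ErrorModel,
    config: SimConfig,
    out_dir: str | Path,
) -> dict:
    """Generate a full synthetic cohort on disk.

    Writes per-mouse paired FASTQ, the pooled truth table, the pool design
    and spike-in manifest TSVs, and a sample sheet.  Returns the paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    truths = []
    for i in range(config.n_mice):
        mouse = f"M{i + 1:02d}"
        tumors = sample_tumors(config, pool, mouse)
        r1 = out / f"{mouse}_R1.fastq"
        r2 = out / f"{mouse}_R2.fastq"
        truth = simulate_sample(
            tumors, spikeins, template, error_model, config.reads_per_cell,
            config.seed, r1, r2, mouse_id=mouse,
        )
        truths.append(truth)
        rows.append(
            {"sample_id": mouse, "mouse_id": mouse, "cohort": "synthetic",
             "fastq_r1": str(r1), "fastq_r2": str(r2)}
        )
    sheet = tio.SampleSheet(pd.DataFrame(rows))
    paths = {
        "sample_sheet": str(sheet.write(out / "sample_sheet.tsv")),
        "truth": str(tio.write_tsv(pd.concat(truths, ignore_index=True), out / "truth.tsv")),
        "pool": str(tio.write_pool_design(pool, out / "pool_design.tsv")),
        "spikeins": str(tio.write_spikein_manifest(spikeins, out / "spikein_manifest.tsv")),
    }
    return paths


def _truth_report(calls: pd.DataFrame, truth: pd.DataFrame, min_cells: float) -> dict:
    """Sensitivity / false-pileup / size-error comparison against a truth table."""
    truth = truth[~truth["is_spikein"].astype(bool)].copy()
    truth["key"] = truth["mouse_id"] + ":" + truth["sgID"] + truth["barcode"]
    calls = calls.copy()
    calls["key"] = calls["mouse_id"] + ":" + calls["barcode"]
    merged = truth.merge(calls[["key", "cells"]], on="key", how="left")
    big = merged[merged["true_cells"] >= 4 * min_cells]
    detected = big["cells"].notna()
    rel_err = (big.loc[detected, "cells"] - big.loc[detected, "true_cells"]).abs() / big.loc[
        detected, "true_cells"
    ]
    false_calls = calls[~calls["key"].isin(set(truth["key"]))]
    return {
        "n_true_tumors": int(len(truth)),
        "n_true_above_4x_cutoff": int(len(big)),
        "sensitivity_above_4x_cutoff": float(detected.mean()) if len(big) else float("nan"),
        "n_false_pileups": int(len(false_calls)),
        "size_error_median": float(rel_err.median()) if len(rel_err) else float("nan"),
        "size_error_q90": float(rel_err.quantile(0.9)) if len(rel_err) else float("nan"),
    }


def run_pipeline(
    sample_sheet: tio.SampleSheet,
    pool: PoolDesign,
    spikeins: SpikeInSet,
    config: tio.PipelineConfig,
    out_dir: str | Path,
    template: ConstructTemplate | None = None,
    truth: pd.DataFrame | None = None,
) -> dict:
    """Run the full quantification pipeline and write all artifacts.

    Returns a bundle with the tumor-call table, per-level statistics,
    QC counters, diagnostics, and output paths.  Any stage's hard failure
    raises with the stage and sample named.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    template = template or ConstructTemplate()
    reference = template.reference()
    qc: dict = {"samples": {}}
    log_lines: list[str] = []
    all_kept = []
    for row in sample_sheet.rows.itertuples():
        try:
            pairs = tio.read_fastq_pairs(row.fastq_r1, row.fastq_r2)
            extracted, drops = extract_read_pairs(pairs, reference, config.scoring)
            pileups = dereplicate(extracted, row.mouse_id)
            kept, removed = filter_pileups(pileups, config.scoring)
        except Exception as e:
            raise RuntimeError(f"stage extract failed for sample {row.sample_id}: {e}") from e
        reasons = Counter(r for _, r in removed)
        n_pairs = len(extracted) + sum(drops.values())
        sample_qc = {
            "read_pairs": n_pairs,
            "extracted": len(extracted),
            "dropped": dict(sorted(drops.items())),
            "pileups": len(pileups),
            "pileups_removed": dict(sorted(reasons.items())),
            "pileup_reads_removed": int(sum(p.reads for p, _ in removed)),
        }
        qc["samples"][row.sample_id] = sample_qc
        log_lines.append(f"extract sample={row.sample_id} {json.dumps(sample_qc, sort_keys=True)}")
        all_kept.extend(kept)
    model = estimate_error_model(all_kept, config.error_filter)
    kept, removed_assessments = filter_spurious(all_kept, model, config.error_filter)
    qc["denoise"] = {
        "pileups_in": len(all_kept),
        "pileups_removed": len(removed_assessments),
        "reads_removed": int(sum(a.pileup.reads for a in removed_assessments)),
    }
    log_lines.append(f"denoise {json.dumps(qc['denoise'], sort_keys=True)}")
    collision = estimate_collision_rate(kept)
    gc_bias = assess_gc_bias(kept)

    calls = []
    by_mouse: dict[str, list] = {}
    for p in kept:
        by_mouse.setdefault(p.mouse_id, []).append(p)
    for mouse in sorted(by_mouse):
        try:
            mouse_calls, readout, unrecognized = spikein_normalize(
                by_mouse[mouse], spikeins, config.quant, pool
            )
            mouse_calls, n_cut = apply_min_cell_cutoff(mouse_calls, config.quant)
        except Exception as e:
            raise RuntimeError(f"stage quantify failed for sample {mouse}: {e}") from e
        calls.extend(mouse_calls)
        mouse_qc = {
            "spikein_reads": dict(sorted(readout.reads_by_label.items())),
            "spikein_median": readout.normalizer_median,
            "unrecognized_sgid_pileups": len(unrecognized),
            "below_min_cells": n_cut,
            "tumor_calls": len(mouse_calls),
        }
        qc["samples"].setdefault(mouse, {}).update(mouse_qc)
        log_lines.append(f"quantify sample={mouse} {json.dumps(mouse_qc, sort_keys=True)}")
    calls_frame = tio.calls_to_frame(calls)

    stats_cfg = dataclasses.replace(config.stats, rng_seed=config.seed)
    try:
        stats_sgrna = genotype_statistics(calls_frame, pool, stats_cfg, level="sgRNA")
        stats_gene = genotype_statistics(calls_frame, pool, stats_cfg, level="gene")
    except Exception as e:
        raise RuntimeError(f"stage stats failed: {e}") from e

    bundle = {
        "error_model": model,
        "tumor_calls": calls_frame,
        "stats_sgrna": stats_sgrna,
        "stats_gene": stats_gene,
        "qc": qc,
        "collision": collision,
        "gc_bias": gc_bias,
    }
    if truth is not None:
        bundle["truth_report"] = _truth_report(calls_frame, truth, config.quant.min_cells)
        qc["truth_report"] = bundle["truth_report"]

    paths = {
        "pileups": tio.write_tsv(tio.pileups_to_frame(kept), out / "pileups.tsv"),
        "tumor_calls": tio.write_tsv(calls_frame, out / "tumor_calls.tsv"),
        "stats_sgrna": tio.write_tsv(stats_sgrna, out / "stats_sgrna.tsv"),
        "stats_gene": tio.write_tsv(stats_gene, out / "stats_gene.tsv"),
    }
    if collision.estimable:
        paths["collision"] = tio.write_tsv(collision.per_sgid, out / "collision.tsv")
    (out / "error_model.json").write_text(model.to_json())
    (out / "qc.json").write_text(json.dumps(qc, indent=2, sort_keys=True, default=float))
    (out / "gc_bias.json").write_text(
        json.dumps(dataclasses.asdict(gc_bias), indent=2, sort_keys=True, default=float)
    )
    (out / "pipeline.log").write_text("\n".join(log_lines) + "\n")
    bundle["paths"] = {k: str(v) for k, v in paths.items()}
    return bundle
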