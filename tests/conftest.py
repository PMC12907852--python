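import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

import tubaquant as tq


@pytest.fixture(scope="session")
def pool():
    return tq.build_pool_design(8, 2, seed=1)


@pytest.fixture(scope="session")
def template():
    return tq.ConstructTemplate()


@pytest.fixture(scope="session")
def spikeins():
    return tq.default_spikeins()


@pytest.fixture(scope="session")
def reference(template):
    return template.reference()


def tumors_to_frame(tumors, pool):
    """Ground-truth tumors as a tumor table (mouse_id, sgRNA_name, cells)."""
    smap = {e.sgID: (e.sgRNA_name, e.target_gene) for e in pool.entries}
    rows = [
        {
            "mouse_id": t.mouse_id,
            "sgRNA_name": smap[t.sgID][0],
            "target_gene": smap[t.sgID][1],
            "cells": float(t.true_cells),
        }
        for t in tumors
    ]
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def cohort_frame(pool):
    """10 synthetic mice with a x5 size effect on one sgRNA (ground truth only)."""
    sg = pool.entries[0].sgRNA_name
    # a pure log-normal location shift: the x5 effect acts on every tumor,
    # with no Pareto tail (the recovery target is the LN-mean ratio)
    cfg = tq.SimConfig(
        seed=3, tumors_per_sgRNA_rate=100, tail_fraction=0.0, effect_multipliers={sg: 5.0}
    )
    frames = []
    for i in range(10):
        frames.append(tumors_to_frame(tq.sample_tumors(cfg, pool, f"M{i:02d}"), pool))
    return sg, pd.concat(frames, ignore_index=True)
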