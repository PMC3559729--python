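"""Shared fixtures: small in-memory datasets and one full demo run.

The demo discovery/replication run is expensive enough (~10 s) to share at
session scope; individual tests read different aspects of the same run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import cnvassoc as ca
from cnvassoc import synthetic_data as sd
from cnvassoc.pipeline import RunConfig, run_discovery, run_replication


@pytest.fixture
def small_map() -> ca.MarkerMap:
    """Two chromosomes, 100 probes each, 10 kb spacing, GC = 0.5."""
    rows = []
    for chrom in ("chr1", "chr2"):
        for i in range(100):
            rows.append((f"{chrom}_p{i:03d}", chrom, (i + 1) * 10_000, 0.5))
    return ca.MarkerMap(
        pd.DataFrame(rows, columns=["probe_id", "chrom", "pos", "gc"]))


def make_samples(n_cases: int, n_controls: int) -> list[ca.SampleRecord]:
    out = []
    for i in range(n_cases):
        out.append(ca.SampleRecord(f"case{i:04d}", "case", 0.995, 0.15,
                                   0.01, 0, (0.0, 0.0, 0.0)))
    for i in range(n_controls):
        out.append(ca.SampleRecord(f"ctrl{i:04d}", "control", 0.995, 0.15,
                                   0.01, 0, (0.0, 0.0, 0.0)))
    return out


@pytest.fixture
def small_samples() -> list[ca.SampleRecord]:
    return make_samples(20, 20)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """Full discovery + replication pipeline on the packaged demo."""
    root = tmp_path_factory.mktemp("demo")
    cfg = sd.demo_discovery_config(42)
    mm, samples, calls = sd.simulate_dataset(cfg)
    paths = sd.write_dataset(
        mm, samples, calls, root / "discovery",
        exclusion_track=sd.demo_exclusion_track(cfg),
        gene_track=sd.demo_gene_track(cfg))
    rcfg = sd.demo_replication_config(43)
    rmm, rsamples, rcalls = sd.simulate_dataset(rcfg)
    rpaths = sd.write_dataset(rmm, rsamples, rcalls, root / "replication")
    run_cfg = RunConfig(
        marker_map=paths["marker_map"],
        sample_sheet=paths["sample_sheet"],
        calls=paths["calls"],
        exclusion_track=paths["exclusion_track"],
        gene_track=paths["gene_track"],
        replication_sample_sheet=rpaths["sample_sheet"],
        replication_calls=rpaths["calls"],
        out_dir=str(root / "results"),
        seed=42)
    cnvrs, disc_log = run_discovery(run_cfg)
    cnvrs, rep_log = run_replication(run_cfg, cnvrs)
    return {
        "config": run_cfg,
        "sim_config": cfg,
        "cnvrs": cnvrs,
        "discovery_log": disc_log,
        "replication_log": rep_log,
        "root": root,
    }
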