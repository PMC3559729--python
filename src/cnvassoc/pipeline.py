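"""End-to-end orchestration: discovery scan, filters, replication.

``run_discovery`` executes sample QC -> per-probe carrier counting ->
Fisher scan -> CNVR segmentation -> false-positive screens -> multiple
testing bar, and writes the association table plus a machine-readable run
log with stage-by-stage counts.  ``run_replication`` evaluates every
discovery CNVR in an independent cohort pair: carrier status over the
discovery span (any overlap), a logistic association corrected with the
first three principal components, a hard same-direction gate, and
Fisher's-method combination of the discovery and replication p-values.

Everything is deterministic given the configuration; the seed is recorded
in the run log.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import cnvr_filters, sample_qc
from .cnvr_filters import FilterParams
from .cnvr_segmentation import (Cnvr, SegmentationParams,
                                attach_contributing_samples, collapse_cnvrs,
                                effective_test_count, testable_regions)
from .exceptions import ConfigError, DegenerateInputError
from .io_formats import (read_cnv_calls, read_interval_track,
                         read_marker_map, read_sample_sheet,
                         write_association_table, write_sample_sheet)
from .annotation_enrichment import annotate_genes
from .probe_association import (count_carriers, per_probe_association,
                                write_probe_stats)
from .replication_stats import (bonferroni_bar, fisher_combine,
                                genomic_inflation, logistic_cnv_association)
from .sample_qc import QcThresholds, apply_sample_qc, flag_duplicates

_P_FLOOR = 1e-300     # guard for Fisher's method (log of 0 undefined)


@dataclass
class RunConfig:
    marker_map: str
    sample_sheet: str
    calls: str
    out_dir: str
    seed: int = 0
    duplicate_pairs: str | None = None
    exclusion_track: str | None = None
    gene_track: str | None = None
    replication_sample_sheet: str | None = None
    replication_calls: str | None = None
    alpha_multiple: float = 0.05
    qc: QcThresholds = field(default_factory=QcThresholds)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    filters: FilterParams = field(default_factory=FilterParams)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        for key, klass in (("qc", QcThresholds),
                           ("segmentation", SegmentationParams),
                           ("filters", FilterParams)):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = klass(**kwargs[key])
        try:
            config = cls(**kwargs)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc
        config.validate_paths()
        return config

    def validate_paths(self) -> None:
        for name in ("marker_map", "sample_sheet", "calls",
                     "duplicate_pairs", "exclusion_track", "gene_track",
                     "replication_sample_sheet", "replication_calls"):
            p = getattr(self, name)
            if p is not None and not Path(p).is_file():
                raise ConfigError(f"input {name} does not exist: {p}")


def _read_duplicate_pairs(path) -> list[tuple[str, str, float]]:
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, b, ident = line.split("\t")
            pairs.append((a, b, float(ident)))
    return pairs


def _write_log(log: dict, out_dir: Path, stem: str) -> None:
    with open(out_dir / f"{stem}.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out_dir / f"{stem}.txt", "w") as fh:
        for key in sorted(log):
            fh.write(f"{key}\t{log[key]}\n")


# ---------------------------------------------------------------------------
# discovery
# ---------------------------------------------------------------------------

def run_discovery(config: RunConfig,
                  verbose: bool = False) -> tuple[list[Cnvr], dict]:
    """Run the discovery stage; writes ``discovery_table.tsv``,
    ``qc_samples.tsv``, ``probe_stats.tsv`` and ``discovery_log.{json,txt}``
    under ``config.out_dir``.  Returns (cnvrs, log)."""
    config.validate_paths()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": config.seed, "stage": "discovery"}

    marker_map = read_marker_map(config.marker_map)
    samples = read_sample_sheet(config.sample_sheet)
    calls = read_cnv_calls(config.calls, marker_map)
    log["n_probes"] = marker_map.n_probes
    log["n_samples_total"] = len(samples)
    log["n_calls_total"] = len(calls)

    if config.duplicate_pairs:
        pairs = _read_duplicate_pairs(config.duplicate_pairs)
        samples = flag_duplicates(samples, pairs, threshold=0.99)
    samples = apply_sample_qc(samples, calls, config.qc)
    qc = sample_qc.qc_summary(samples)
    log["qc_included"] = qc["included"]
    log["qc_excluded_by_reason"] = qc["excluded_by_reason"]
    write_sample_sheet(samples, out_dir / "qc_samples.tsv")

    counts = count_carriers(calls, marker_map, samples)
    stats = per_probe_association(counts)
    write_probe_stats(stats, out_dir / "probe_stats.tsv")
    seg = config.segmentation
    for typ in ("del", "dup"):
        mask = (stats["type"] == typ) & (stats["p"] < seg.alpha_probe)
        log[f"n_significant_probes_{typ}"] = int(mask.sum())

    cnvrs = collapse_cnvrs(stats, seg)
    attach_contributing_samples(cnvrs, calls, samples)
    log["n_cnvrs_del"] = sum(1 for c in cnvrs if c.type == "del")
    log["n_cnvrs_dup"] = sum(1 for c in cnvrs if c.type == "dup")

    exclusion = (read_interval_track(config.exclusion_track,
                                     "exclusion_region")
                 if config.exclusion_track else None)
    cnvr_filters.apply_all_filters(
        cnvrs, calls, stats, marker_map, samples, config.filters,
        exclusion_track=exclusion, alpha_probe=seg.alpha_probe,
        min_case_carriers=seg.min_case_carriers)
    log["n_cnvrs_flagged"] = sum(1 for c in cnvrs if c.filter_flags)
    log["n_cnvrs_unflagged"] = sum(1 for c in cnvrs if not c.filter_flags)

    if config.gene_track:
        genes = read_interval_track(config.gene_track, "gene_model")
        for c in cnvrs:
            annotate_genes(c, genes)

    # multiple-testing burden: regions of probes harbouring >= the carrier
    # floor in cases, not just the significant chains
    testable = testable_regions(counts, seg)
    log["n_testable_regions_del"] = len(testable["del"])
    log["n_testable_regions_dup"] = len(testable["dup"])
    n_tests = effective_test_count(testable["del"], testable["dup"])
    log["effective_test_count"] = n_tests
    if n_tests >= 1:
        bar = bonferroni_bar(n_tests, config.alpha_multiple)
        log["bonferroni_bar"] = bar
        log["n_cnvrs_passing_bar"] = sum(
            1 for c in cnvrs if c.p_discovery < bar)
        log["n_unflagged_cnvrs_passing_bar"] = sum(
            1 for c in cnvrs if not c.filter_flags and c.p_discovery < bar)

    write_association_table(cnvrs, out_dir / "discovery_table.tsv")
    _write_log(log, out_dir, "discovery_log")
    if verbose:
        for c in cnvrs:
            print(f"{c.region}\t{c.type}\t{c.direction}\t"
                  f"{c.case_carriers}/{c.control_carriers}\t"
                  f"p={c.p_discovery:.3g}\t"
                  f"flags={','.join(sorted(c.filter_flags)) or '-'}")
    return cnvrs, log


# ---------------------------------------------------------------------------
# replication
# ---------------------------------------------------------------------------

def replication_carrier_status(cnvr: Cnvr, calls, samples
                               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Carrier indicator at the discovery span (any-overlap semantics),
    cohort labels and PC matrix over the included replication samples."""
    included = [s for s in samples if s.included]
    carrier_ids = {
        c.sample_id for c in calls
        if c.cnv_type == cnvr.type and c.chrom == cnvr.chrom
        and c.start_pos <= cnvr.end_pos and c.end_pos >= cnvr.start_pos}
    carrier = np.array([1 if s.sample_id in carrier_ids else 0
                        for s in included])
    label = np.array([1 if s.cohort == "case" else 0 for s in included])
    pcs = np.array([s.pcs[:3] for s in included], dtype=float)
    return carrier, label, pcs


def run_replication(config: RunConfig,
                    cnvrs: list[Cnvr]) -> tuple[list[Cnvr], dict]:
    """Replicate discovery CNVRs in the independent cohorts; writes
    ``combined_table.tsv`` and ``replication_log.{json,txt}``."""
    if not (config.replication_sample_sheet and config.replication_calls):
        raise ConfigError("replication inputs missing from configuration")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": config.seed, "stage": "replication"}

    marker_map = read_marker_map(config.marker_map)
    samples = read_sample_sheet(config.replication_sample_sheet)
    if any(len(s.pcs) < 3 for s in samples):
        raise ConfigError(
            "replication sample sheet must provide >= 3 PC columns")
    calls = read_cnv_calls(config.replication_calls, marker_map)
    samples = apply_sample_qc(samples, calls, config.qc)
    log["replication_included"] = sum(s.included for s in samples)

    alpha = config.segmentation.alpha_probe
    p_values = []
    n_replicated = 0
    for cnvr in cnvrs:
        carrier, label, pcs = replication_carrier_status(cnvr, calls, samples)
        n_case = int(label.sum())
        n_ctrl = int(len(label) - n_case)
        a = int(carrier[label == 1].sum())
        b = int(carrier[label == 0].sum())
        if a * n_ctrl > b * n_case:
            rep_direction = "case_enriched"
        elif a * n_ctrl < b * n_case:
            rep_direction = "control_enriched"
        else:
            rep_direction = "neither"
        same_direction = rep_direction == cnvr.direction
        try:
            result = logistic_cnv_association(carrier, label, pcs)
            cnvr.p_replication = result.p_wald
            p_values.append(result.p_wald)
        except DegenerateInputError:
            cnvr.p_replication = None
        cnvr.replicated = bool(
            same_direction and cnvr.p_replication is not None
            and cnvr.p_replication < alpha)
        if same_direction and cnvr.p_replication is not None:
            combined = fisher_combine([max(cnvr.p_discovery, _P_FLOOR),
                                       max(cnvr.p_replication, _P_FLOOR)])
            cnvr.p_combined = combined.p_combined
        else:
            cnvr.p_combined = None
        n_replicated += bool(cnvr.replicated)

    log["n_loci_tested"] = len(cnvrs)
    log["n_replicated_same_direction"] = n_replicated
    if p_values:
        log["genomic_inflation_lambda"] = genomic_inflation(
            [min(max(p, 1e-12), 1.0) for p in p_values])
    write_association_table(cnvrs, out_dir / "combined_table.tsv")
    _write_log(log, out_dir, "replication_log")
    return cnvrs, log
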