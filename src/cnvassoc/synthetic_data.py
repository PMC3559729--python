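"""Synthetic case/control CNV datasets with known ground truth.

Every downstream stage is testable without any external download: the
generator emulates the structure of a two-cohort SNP-array CNV study —
rare recurrent CNVRs with fixed case/control carrier counts, common-CNV
regions with variable boundary truncation (the substrate of "peninsula"
artefacts), samples with aberrant QC metrics, uniformly scattered
background calls, and smoothly varying probe GC content with a
configurable fraction of extreme-GC probes.

Ground-truth guarantees, by construction:

* each planted CNVR yields exactly the configured number of case and
  control carriers, every carrier's call covering the full planted span
  (plus independent uniform jitter at each end), and no other simulated
  call overlaps a planted span — so per-probe counting at interior probes
  recovers the planted counts exactly;
* exactly ``n_noisy_samples`` samples fail the per-sample QC thresholds
  (LRR SD above 0.30 and recorded CNV call count above 100);
* planted peninsula constructs place a common CNV (similar carrier
  frequency in both cohorts) whose case calls extend variably into one
  flank, producing a significant edge subregion whose contributing calls
  all run back into the non-significant core;
* bias-sample constructs plant one shared carrier into several small
  CNVRs so that removing it breaks their significance.

Distributional choices (uniform jitter, Gaussian PCs, Poisson background)
are stand-ins for mechanisms the underlying array studies do not publish;
all are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .io_formats import (CnvCall, Interval, IntervalTrack, MarkerMap,
                         SampleRecord, write_cnv_calls, write_interval_track,
                         write_marker_map, write_sample_sheet)

_DEL_STATE = 1
_DUP_STATE = 3
_BG_MIN_PROBES, _BG_MAX_PROBES = 3, 25     # background call span range


@dataclass
class PlantedCnvr:
    """A rare recurrent CNVR with exact carrier counts.

    ``probe_span`` is a chromosome-local (start, end) probe index pair,
    inclusive, at least 3 probes wide (matching the minimum-probe rule of
    HMM-based CNV callers).  ``shared_case_carriers`` case carriers are
    drawn from a common pool shared across planted regions — the handle
    used to build sample-bias confounders.
    """

    chrom: str
    probe_span: tuple[int, int]
    type: str                       # "del" | "dup"
    case_carrier_count: int
    control_carrier_count: int
    shared_case_carriers: int = 0

    def __post_init__(self):
        if self.probe_span[1] - self.probe_span[0] + 1 < 3:
            raise ConfigError(
                f"planted CNVR on {self.chrom}: span must be >= 3 probes")
        if self.type not in ("del", "dup"):
            raise ConfigError(f"planted CNVR type {self.type!r}")
        if self.shared_case_carriers > self.case_carrier_count:
            raise ConfigError("shared_case_carriers exceeds carrier count")


@dataclass
class PlantedPeninsula:
    """A common CNV whose case calls over-extend into one flank."""

    chrom: str
    core_span: tuple[int, int]      # probe indices, inclusive
    type: str
    case_carrier_count: int
    control_carrier_count: int
    min_extension_probes: int = 5
    max_extension_probes: int = 25


@dataclass
class SimulationConfig:
    n_cases: int = 7313
    n_controls: int = 2701
    n_probes_per_chrom: int = 1500
    chrom_count: int = 4
    probe_spacing_bp: int = 10_000
    planted_cnvrs: list[PlantedCnvr] = field(default_factory=list)
    planted_peninsulas: list[PlantedPeninsula] = field(default_factory=list)
    n_common_cnv_regions: int = 0
    common_cnv_frequency: float = 0.01
    common_cnv_span_probes: int = 30
    common_jitter_probes: int = 15
    boundary_jitter_probes: int = 0
    n_noisy_samples: int = 0
    background_call_rate_per_sample: float = 0.0
    gc_extreme_fraction: float = 0.02
    structured: bool = False        # shift control PCs (stratified variant)
    pc_shift: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_cases", "n_controls", "n_probes_per_chrom",
                     "chrom_count", "n_common_cnv_regions",
                     "boundary_jitter_probes", "n_noisy_samples"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if self.background_call_rate_per_sample < 0:
            raise ConfigError("background call rate must be nonnegative")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _chrom_names(n: int) -> list[str]:
    return [f"chr{i + 1}" for i in range(n)]


def _smooth_gc(rng: np.random.Generator, n: int) -> np.ndarray:
    """Smooth genome-like GC track around 0.45, clipped to [0.30, 0.70]."""
    noise = rng.normal(0.0, 1.0, n + 40)
    kernel = np.exp(-0.5 * (np.arange(-20, 21) / 8.0) ** 2)
    kernel /= kernel.sum()
    smooth = np.convolve(noise, kernel, mode="valid")[:n]
    return np.clip(0.45 + 0.08 * smooth / smooth.std(), 0.30, 0.70)


class _ReservedSpans:
    """Chromosome-local probe-index spans no other call may touch."""

    def __init__(self):
        self.spans: dict[str, list[tuple[int, int]]] = {}

    def add(self, chrom: str, start: int, end: int) -> None:
        self.spans.setdefault(chrom, []).append((start, end))

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return any(s <= end and e >= start
                   for s, e in self.spans.get(chrom, ()))


def _make_call(marker_map: MarkerMap, sample_id: str, chrom: str,
               i0: int, i1: int, typ: str) -> CnvCall:
    """Build a call covering chromosome-local probe indices [i0, i1]."""
    pos = marker_map.positions(chrom)
    i0 = max(0, i0)
    i1 = min(len(pos) - 1, i1)
    return CnvCall(sample_id, chrom, int(pos[i0]), int(pos[i1]),
                   _DEL_STATE if typ == "del" else _DUP_STATE, i1 - i0 + 1)


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig
                     ) -> tuple[MarkerMap, list[SampleRecord], list[CnvCall]]:
    """Generate a complete discovery dataset.

    Deterministic given ``config.seed``.  Returns the marker map, the
    sample sheet (QC metrics, 3 Gaussian PCs) and the call list.
    """
    rng = np.random.default_rng(config.seed)
    chroms = _chrom_names(config.chrom_count)
    npc = config.n_probes_per_chrom

    reserved = _ReservedSpans()
    for pl in config.planted_cnvrs:
        _check_span(config, pl.chrom, pl.probe_span)
        if reserved.overlaps(pl.chrom, *pl.probe_span):
            raise ConfigError(f"planted spans overlap on {pl.chrom}")
        reserved.add(pl.chrom, *pl.probe_span)
    for pen in config.planted_peninsulas:
        flank_end = pen.core_span[1] + pen.max_extension_probes
        _check_span(config, pen.chrom, (pen.core_span[0], flank_end))
        if reserved.overlaps(pen.chrom, pen.core_span[0], flank_end):
            raise ConfigError(f"peninsula span overlaps on {pen.chrom}")
        reserved.add(pen.chrom, pen.core_span[0], flank_end)

    # ---- marker map -------------------------------------------------------
    rows = []
    for chrom in chroms:
        gc = _smooth_gc(rng, npc)
        pos = (np.arange(npc) + 1) * config.probe_spacing_bp
        for i in range(npc):
            rows.append((f"{chrom}_p{i:05d}", chrom, int(pos[i]), gc[i]))
    map_df = pd.DataFrame(rows, columns=["probe_id", "chrom", "pos", "gc"])
    marker_map = MarkerMap(map_df)

    # common-CNV regions: placed away from planted spans, then reserved
    common_spans: list[tuple[str, int, int, str]] = []
    for k in range(config.n_common_cnv_regions):
        for _ in range(200):
            chrom = chroms[int(rng.integers(len(chroms)))]
            margin = config.common_jitter_probes + 1
            start = int(rng.integers(margin, npc - config.common_cnv_span_probes
                                     - margin))
            end = start + config.common_cnv_span_probes - 1
            if not reserved.overlaps(chrom, start - margin, end + margin):
                reserved.add(chrom, start - margin, end + margin)
                common_spans.append(
                    (chrom, start, end, "del" if k % 2 == 0 else "dup"))
                break
        else:
            raise ConfigError("could not place a common-CNV region")

    # extreme-GC blocks, avoiding reserved spans
    n_extreme = int(config.gc_extreme_fraction * config.chrom_count * npc)
    block = 25
    placed = 0
    gc_col = marker_map.df["gc"].to_numpy().copy()
    tries = 0
    while placed < n_extreme and tries < 2000:
        tries += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, npc - block))
        if reserved.overlaps(chrom, start, start + block - 1):
            continue
        reserved.add(chrom, start, start + block - 1)
        off = marker_map.chrom_offset(chrom)
        level = (rng.uniform(0.78, 0.90) if rng.random() < 0.5
                 else rng.uniform(0.10, 0.22))
        gc_col[off + start: off + start + block] = level
        placed += block
    marker_map.df["gc"] = gc_col

    # ---- samples ----------------------------------------------------------
    case_ids = [f"case{i:05d}" for i in range(config.n_cases)]
    ctrl_ids = [f"ctrl{i:05d}" for i in range(config.n_controls)]
    n_total = config.n_cases + config.n_controls
    if config.n_noisy_samples > n_total:
        raise ConfigError("more noisy samples than samples")
    n_noisy_cases = round(config.n_noisy_samples
                          * config.n_cases / max(n_total, 1))
    noisy = set(case_ids[len(case_ids) - n_noisy_cases:]) \
        | set(ctrl_ids[len(ctrl_ids) - (config.n_noisy_samples
                                        - n_noisy_cases):])
    clean_cases = [s for s in case_ids if s not in noisy]
    clean_ctrls = [s for s in ctrl_ids if s not in noisy]

    calls: list[CnvCall] = []

    # ---- planted CNVRs ----------------------------------------------------
    shared_pool_size = max((p.shared_case_carriers
                            for p in config.planted_cnvrs), default=0)
    case_ptr, ctrl_ptr = shared_pool_size, 0
    for pl in config.planted_cnvrs:
        n_own = pl.case_carrier_count - pl.shared_case_carriers
        if case_ptr + n_own > len(clean_cases):
            raise ConfigError(
                f"planted CNVR on {pl.chrom}: case carrier count exceeds "
                "available clean case samples")
        if ctrl_ptr + pl.control_carrier_count > len(clean_ctrls):
            raise ConfigError(
                f"planted CNVR on {pl.chrom}: control carrier count exceeds "
                "available clean control samples")
        carriers = (clean_cases[:pl.shared_case_carriers]
                    + clean_cases[case_ptr:case_ptr + n_own])
        case_ptr += n_own
        ctrl_carriers = clean_ctrls[ctrl_ptr:ctrl_ptr
                                    + pl.control_carrier_count]
        ctrl_ptr += pl.control_carrier_count
        s, e = pl.probe_span
        for sid in carriers + ctrl_carriers:
            jl = int(rng.integers(0, config.boundary_jitter_probes + 1))
            jr = int(rng.integers(0, config.boundary_jitter_probes + 1))
            calls.append(_make_call(marker_map, sid, pl.chrom,
                                    s - jl, e + jr, pl.type))

    # ---- peninsula constructs ---------------------------------------------
    for pen in config.planted_peninsulas:
        if (pen.case_carrier_count > len(clean_cases)
                or pen.control_carrier_count > len(clean_ctrls)):
            raise ConfigError("peninsula carrier count exceeds cohort size")
        cases = rng.choice(clean_cases, pen.case_carrier_count, replace=False)
        ctrls = rng.choice(clean_ctrls, pen.control_carrier_count,
                           replace=False)
        s, e = pen.core_span
        for sid in cases:
            ext = int(rng.integers(pen.min_extension_probes,
                                   pen.max_extension_probes + 1))
            calls.append(_make_call(marker_map, str(sid), pen.chrom,
                                    s, e + ext, pen.type))
        for sid in ctrls:     # controls truncate at the core boundary
            calls.append(_make_call(marker_map, str(sid), pen.chrom,
                                    s, e, pen.type))

    # ---- common-CNV regions (symmetric truncation jitter) -----------------
    for chrom, s, e, typ in common_spans:
        k_case = round(config.common_cnv_frequency * len(clean_cases))
        k_ctrl = round(config.common_cnv_frequency * len(clean_ctrls))
        for sid in rng.choice(clean_cases, k_case, replace=False):
            jl = int(rng.integers(0, config.common_jitter_probes + 1))
            jr = int(rng.integers(0, config.common_jitter_probes + 1))
            calls.append(_make_call(marker_map, str(sid), chrom,
                                    s + jl, e - jr if e - jr > s + jl
                                    else s + jl + 2, typ))
        for sid in rng.choice(clean_ctrls, k_ctrl, replace=False):
            jl = int(rng.integers(0, config.common_jitter_probes + 1))
            jr = int(rng.integers(0, config.common_jitter_probes + 1))
            calls.append(_make_call(marker_map, str(sid), chrom,
                                    s + jl, e - jr if e - jr > s + jl
                                    else s + jl + 2, typ))

    # ---- background calls (uniform, off the reserved spans) ---------------
    all_ids = case_ids + ctrl_ids
    if config.background_call_rate_per_sample > 0:
        n_bg = rng.poisson(config.background_call_rate_per_sample,
                           len(all_ids))
        for sid, k in zip(all_ids, n_bg):
            for _ in range(int(k)):
                for _attempt in range(100):
                    chrom = chroms[int(rng.integers(len(chroms)))]
                    length = int(rng.integers(_BG_MIN_PROBES,
                                              _BG_MAX_PROBES + 1))
                    start = int(rng.integers(0, npc - length))
                    if not reserved.overlaps(chrom, start,
                                             start + length - 1):
                        break
                else:
                    continue
                typ = "del" if rng.random() < 0.5 else "dup"
                calls.append(_make_call(marker_map, sid, chrom, start,
                                        start + length - 1, typ))

    # ---- sample sheet ------------------------------------------------------
    counts: dict[str, int] = {}
    for c in calls:
        counts[c.sample_id] = counts.get(c.sample_id, 0) + 1
    samples: list[SampleRecord] = []
    for sid in all_ids:
        cohort = "case" if sid.startswith("case") else "control"
        pcs = rng.normal(0.0, 1.0, 3)
        if config.structured and cohort == "control":
            pcs[0] += config.pc_shift
        if sid in noisy:
            lrr_sd = float(rng.uniform(0.32, 0.55))
            cnv_count = int(rng.integers(110, 260))
        else:
            lrr_sd = float(rng.uniform(0.08, 0.25))
            cnv_count = counts.get(sid, 0)
        samples.append(SampleRecord(
            sample_id=sid, cohort=cohort,
            call_rate=float(rng.uniform(0.985, 0.999)),
            lrr_sd=lrr_sd,
            gcwf=float(np.clip(rng.normal(0.0, 0.012), -0.045, 0.045)),
            cnv_count=cnv_count,
            pcs=tuple(pcs)))
    return marker_map, samples, calls


def _check_span(config: SimulationConfig, chrom: str,
                span: tuple[int, int]) -> None:
    if chrom not in _chrom_names(config.chrom_count):
        raise ConfigError(f"planted chromosome {chrom!r} not in map")
    s, e = span
    if s < 0 or e >= config.n_probes_per_chrom or s > e:
        raise ConfigError(f"planted span {span} outside the simulated map")


# ---------------------------------------------------------------------------
# null and structured variants
# ---------------------------------------------------------------------------

def simulate_null_dataset(n_cases: int, n_controls: int, n_probes: int,
                          per_probe_carrier_rate: float = 0.002,
                          seed: int = 0
                          ) -> tuple[MarkerMap, list[SampleRecord],
                                     list[CnvCall]]:
    """Label-independent null dataset for type-I-error studies.

    Calls (spans of 3-25 probes) are placed uniformly and assigned to
    samples irrespective of cohort, calibrated so the expected per-probe
    carrier fraction equals ``per_probe_carrier_rate``; PCs are drawn from
    one shared distribution for both cohorts.  The default rate reflects
    the rare-CNV frequency regime (about 0.2% carriers at a locus).
    """
    if not (0.0 <= per_probe_carrier_rate < 1.0):
        raise ConfigError("per_probe_carrier_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    spacing = 10_000
    map_df = pd.DataFrame({
        "probe_id": [f"chr1_p{i:05d}" for i in range(n_probes)],
        "chrom": "chr1",
        "pos": (np.arange(n_probes) + 1) * spacing,
        "gc": _smooth_gc(rng, n_probes),
    })
    marker_map = MarkerMap(map_df)
    n_total = n_cases + n_controls
    ids = ([f"case{i:05d}" for i in range(n_cases)]
           + [f"ctrl{i:05d}" for i in range(n_controls)])
    mean_len = (_BG_MIN_PROBES + _BG_MAX_PROBES) / 2.0
    n_calls = int(round(n_total * n_probes * per_probe_carrier_rate
                        / mean_len))
    calls = []
    for _ in range(n_calls):
        sid = ids[int(rng.integers(n_total))]
        length = int(rng.integers(_BG_MIN_PROBES, _BG_MAX_PROBES + 1))
        start = int(rng.integers(0, max(n_probes - length, 1)))
        typ = "del" if rng.random() < 0.5 else "dup"
        calls.append(_make_call(marker_map, sid, "chr1", start,
                                start + length - 1, typ))
    counts: dict[str, int] = {}
    for c in calls:
        counts[c.sample_id] = counts.get(c.sample_id, 0) + 1
    samples = [SampleRecord(
        sample_id=sid,
        cohort="case" if sid.startswith("case") else "control",
        call_rate=float(rng.uniform(0.985, 0.999)),
        lrr_sd=float(rng.uniform(0.08, 0.25)),
        gcwf=float(np.clip(rng.normal(0.0, 0.012), -0.045, 0.045)),
        cnv_count=counts.get(sid, 0),
        pcs=tuple(rng.normal(0.0, 1.0, 3)))
        for sid in ids]
    return marker_map, samples, calls


@dataclass
class StructuredDataset:
    """Stratified dataset: carrier probability tied to PC1, cohorts with
    shifted PC1 distributions — the classic confounding geometry."""
    marker_map: MarkerMap
    samples: list[SampleRecord]
    calls: list[CnvCall]
    regions: list[tuple[str, int, int]]   # (chrom, start_pos, end_pos)

    def carrier_matrix(self) -> np.ndarray:
        """(n_samples, n_regions) 0/1 matrix from the call list."""
        idx = {s.sample_id: i for i, s in enumerate(self.samples)}
        starts = np.array([s for _, s, _ in self.regions])
        ends = np.array([e for _, _, e in self.regions])
        mat = np.zeros((len(self.samples), len(self.regions)), dtype=int)
        for call in self.calls:
            # regions are disjoint and sorted; find those the call overlaps
            j0 = int(np.searchsorted(ends, call.start_pos, side="left"))
            j1 = int(np.searchsorted(starts, call.end_pos, side="right"))
            if j1 > j0:
                mat[idx[call.sample_id], j0:j1] = 1
        return mat


def simulate_structured_dataset(n_cases: int = 400, n_controls: int = 400,
                                n_regions: int = 1500,
                                probes_per_region: int = 2,
                                base_rate: float = 0.08,
                                pc_shift: float = 1.0,
                                pc_effect: float = 0.8,
                                seed: int = 0) -> StructuredDataset:
    """Stratification that inflates naive association but is absorbed by
    PC covariates: carrier probability at every region follows
    ``logit p = logit(base_rate) + pc_effect * PC1`` while control PC1 is
    shifted by ``pc_shift``."""
    rng = np.random.default_rng(seed)
    n_total = n_cases + n_controls
    pc1 = np.concatenate([rng.normal(0.0, 1.0, n_cases),
                          rng.normal(pc_shift, 1.0, n_controls)])
    pc23 = rng.normal(0.0, 1.0, (n_total, 2))
    gap = 2
    stride = probes_per_region + gap
    n_probes = n_regions * stride
    spacing = 10_000
    map_df = pd.DataFrame({
        "probe_id": [f"chr1_p{i:06d}" for i in range(n_probes)],
        "chrom": "chr1",
        "pos": (np.arange(n_probes) + 1) * spacing,
        "gc": 0.45,
    })
    marker_map = MarkerMap(map_df)
    ids = ([f"case{i:05d}" for i in range(n_cases)]
           + [f"ctrl{i:05d}" for i in range(n_controls)])
    intercept = np.log(base_rate / (1.0 - base_rate))
    prob = 1.0 / (1.0 + np.exp(-(intercept + pc_effect * pc1)))
    pos = marker_map.positions("chr1")
    regions = []
    calls = []
    for j in range(n_regions):
        i0 = j * stride
        i1 = i0 + probes_per_region - 1
        regions.append(("chr1", int(pos[i0]), int(pos[i1])))
        carriers = np.flatnonzero(rng.random(n_total) < prob)
        for i in carriers:
            calls.append(_make_call(marker_map, ids[i], "chr1", i0, i1,
                                    "del"))
    samples = [SampleRecord(
        sample_id=ids[i],
        cohort="case" if i < n_cases else "control",
        call_rate=0.995, lrr_sd=0.15, gcwf=0.0, cnv_count=0,
        pcs=(float(pc1[i]), float(pc23[i, 0]), float(pc23[i, 1])))
        for i in range(n_total)]
    return StructuredDataset(marker_map, samples, calls, regions)


# ---------------------------------------------------------------------------
# packaged demo configurations
# ---------------------------------------------------------------------------

def demo_discovery_config(seed: int = 42) -> SimulationConfig:
    """The packaged discovery demo: cohort sizes 7313/2701, three clean
    rare CNVRs at carrier counts typical of a genome-wide lifespan-style
    scan, one peninsula confounder, five sample-bias loci sharing one
    carrier, three common-CNV regions and 20 noisy samples."""
    clean = [
        PlantedCnvr("chr1", (300, 311), "del", 26, 0),
        PlantedCnvr("chr2", (400, 423), "dup", 87, 4),
        PlantedCnvr("chr3", (500, 514), "del", 42, 0),
    ]
    # five loci share one carrier; removing it leaves (10, 0), p = 0.066
    bias = [
        PlantedCnvr("chr1", (700, 709), "del", 11, 0, shared_case_carriers=1),
        PlantedCnvr("chr1", (900, 909), "del", 11, 0, shared_case_carriers=1),
        PlantedCnvr("chr2", (700, 709), "del", 11, 0, shared_case_carriers=1),
        PlantedCnvr("chr2", (900, 909), "del", 11, 0, shared_case_carriers=1),
        PlantedCnvr("chr3", (700, 709), "del", 11, 0, shared_case_carriers=1),
    ]
    peninsula = [PlantedPeninsula("chr4", (600, 639), "del", 73, 27)]
    return SimulationConfig(
        n_cases=7313, n_controls=2701,
        n_probes_per_chrom=1500, chrom_count=4,
        planted_cnvrs=clean + bias,
        planted_peninsulas=peninsula,
        n_common_cnv_regions=3,
        boundary_jitter_probes=2,
        n_noisy_samples=20,
        background_call_rate_per_sample=0.05,
        seed=seed)


#: spans of the clean planted loci in :func:`demo_discovery_config`
DEMO_CLEAN_SPANS = [("chr1", (300, 311), "del", 26, 0),
                    ("chr2", (400, 423), "dup", 87, 4),
                    ("chr3", (500, 514), "del", 42, 0)]
DEMO_BIAS_SPANS = [("chr1", (700, 709)), ("chr1", (900, 909)),
                   ("chr2", (700, 709)), ("chr2", (900, 909)),
                   ("chr3", (700, 709))]
DEMO_PENINSULA_CORE = ("chr4", (600, 639))


def demo_replication_config(seed: int = 43) -> SimulationConfig:
    """Replication-stage demo: independent cohorts (2079 cases, 4692
    controls) carrying two of the three discovery loci."""
    planted = [
        PlantedCnvr("chr1", (300, 311), "del", 8, 3),
        PlantedCnvr("chr2", (400, 423), "dup", 30, 24),
        # the chr3 locus is deliberately absent: discovery-only signal
    ]
    return SimulationConfig(
        n_cases=2079, n_controls=4692,
        n_probes_per_chrom=1500, chrom_count=4,
        planted_cnvrs=planted,
        boundary_jitter_probes=2,
        n_noisy_samples=0,
        background_call_rate_per_sample=0.05,
        seed=seed)


def demo_exclusion_track(config: SimulationConfig) -> IntervalTrack:
    """Telomere/centromere stand-in: the outer 30 and middle 20 probes of
    each simulated chromosome."""
    spacing = config.probe_spacing_bp
    npc = config.n_probes_per_chrom
    intervals = []
    for chrom in _chrom_names(config.chrom_count):
        intervals.append(Interval(chrom, 1, 30 * spacing, "telomere_p"))
        mid = npc // 2
        intervals.append(Interval(chrom, (mid - 10) * spacing + 1,
                                  (mid + 10) * spacing, "centromere"))
        intervals.append(Interval(chrom, (npc - 30) * spacing + 1,
                                  (npc + 1) * spacing, "telomere_q"))
    return IntervalTrack(intervals, "exclusion_region")


def demo_gene_track(config: SimulationConfig, seed: int = 7) -> IntervalTrack:
    """Gene models tiling the simulated map (spans include introns)."""
    rng = np.random.default_rng(seed)
    spacing = config.probe_spacing_bp
    intervals = []
    g = 0
    for chrom in _chrom_names(config.chrom_count):
        i = 5
        while i < config.n_probes_per_chrom - 30:
            length = int(rng.integers(3, 20))
            intervals.append(Interval(
                chrom, i * spacing + 1, (i + length) * spacing,
                f"GENE{g:04d}"))
            g += 1
            i += length + int(rng.integers(2, 25))
    return IntervalTrack(intervals, "gene_model")


def write_dataset(marker_map: MarkerMap, samples, calls, out_dir,
                  exclusion_track: IntervalTrack | None = None,
                  gene_track: IntervalTrack | None = None) -> dict[str, str]:
    """Write a simulated dataset in the formats the pipeline reads.

    Returns a dict of logical name -> written path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "marker_map": str(out / "marker_map.tsv"),
        "sample_sheet": str(out / "samples.tsv"),
        "calls": str(out / "calls.rawcnv"),
    }
    write_marker_map(marker_map, paths["marker_map"])
    write_sample_sheet(samples, paths["sample_sheet"])
    write_cnv_calls(calls, paths["calls"])
    if exclusion_track is not None:
        paths["exclusion_track"] = str(out / "exclusion.bed")
        write_interval_track(exclusion_track, paths["exclusion_track"])
    if gene_track is not None:
        paths["gene_track"] = str(out / "genes.bed")
        write_interval_track(gene_track, paths["gene_track"])
    return paths
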