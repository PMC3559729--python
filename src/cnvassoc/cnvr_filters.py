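"""Post-association false-positive screens for CNVRs.

Array-based CNV association has characteristic failure modes that survive
per-sample QC: signals on telomere/centromere-proximal cytobands, edge
artefacts of common CNV regions ("peninsulas"), hybridisation bias at
extreme GC content, sparse probe coverage, and a handful of samples with
atypical intensity waves contributing to many regions at once.  Each
screen here adds a flag to the CNVR's ``filter_flags`` set — regions are
annotated, never silently removed, so the audit trail survives.

A *peninsula* is a significant subregion at the variably truncated edge of
a common CNV: the contributing calls also extend into a flanking stretch
of probes that is itself not significant.  The screen flags a CNVR when at
least ``peninsula_fraction`` of its contributing calls extend at least
``peninsula_extension_probes`` probes beyond a CNVR boundary into
non-significant flanking probes.

All numeric thresholds are explicit, configurable operationalisations of
qualitative criteria; defaults are documented in ``FilterParams``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cnvr_segmentation import Cnvr
from .exceptions import ValidationError
from .io_formats import CnvCall, IntervalTrack, MarkerMap, SampleRecord
from .probe_association import fisher_exact_two_sided

FLAG_TELOMERE_CENTROMERE = "telomere_centromere"
FLAG_PENINSULA = "peninsula"
FLAG_GC_EXTREME = "gc_extreme"
FLAG_GC_UNKNOWN = "gc_unknown"
FLAG_LOW_COVERAGE = "low_coverage"
FLAG_SAMPLE_BIAS = "sample_bias"


@dataclass
class FilterParams:
    gc_low: float = 0.25                  # mean-GC lower bound
    gc_high: float = 0.75                 # mean-GC upper bound
    min_probe_density: float = 1.0        # probes per 100 kb
    peninsula_extension_probes: int = 5   # flank probes defining "extends"
    peninsula_fraction: float = 0.5       # fraction of calls extending
    max_cnvrs_per_sample: int = 3         # bias-sample membership threshold

    def __post_init__(self):
        if not (0.0 < self.gc_low < self.gc_high < 1.0):
            raise ValidationError("need 0 < gc_low < gc_high < 1")
        if not (0.0 < self.peninsula_fraction <= 1.0):
            raise ValidationError("peninsula_fraction must be in (0, 1]")


def flag_positional_exclusions(cnvr: Cnvr,
                               exclusion_track: IntervalTrack) -> set[str]:
    """Flag overlap (>= 1 bp) with any telomere/centromere exclusion
    interval.  Mutates and returns the CNVR's flag set."""
    if exclusion_track.overlapping(cnvr.chrom, cnvr.start_pos, cnvr.end_pos):
        cnvr.filter_flags.add(FLAG_TELOMERE_CENTROMERE)
    return cnvr.filter_flags


def flag_peninsula(cnvr: Cnvr, calls: Sequence[CnvCall],
                   probe_stats: pd.DataFrame, marker_map: MarkerMap,
                   params: FilterParams,
                   alpha_probe: float = 0.05) -> set[str]:
    """Flag CNVRs whose contributing calls extend into non-significant
    flanking probes (common-CNV boundary-truncation artefact)."""
    stats_t = probe_stats.loc[
        (probe_stats["type"] == cnvr.type)
        & (probe_stats["chrom"] == cnvr.chrom)]
    pos = stats_t["pos"].to_numpy()
    nonsig = (stats_t["p"].to_numpy() >= alpha_probe)

    contributing = [
        c for c in calls
        if c.sample_id in cnvr.contributing_samples
        and c.cnv_type == cnvr.type and c.chrom == cnvr.chrom
        and c.start_pos <= cnvr.end_pos and c.end_pos >= cnvr.start_pos]
    if not contributing:
        return cnvr.filter_flags

    n_extending = 0
    for call in contributing:
        extends = False
        # left flank: covered probes strictly before the CNVR start
        left = nonsig[(pos >= call.start_pos) & (pos < cnvr.start_pos)]
        if left.sum() >= params.peninsula_extension_probes:
            extends = True
        right = nonsig[(pos > cnvr.end_pos) & (pos <= call.end_pos)]
        if right.sum() >= params.peninsula_extension_probes:
            extends = True
        n_extending += extends
    if n_extending / len(contributing) >= params.peninsula_fraction:
        cnvr.filter_flags.add(FLAG_PENINSULA)
    return cnvr.filter_flags


def flag_gc_and_coverage(cnvr: Cnvr, marker_map: MarkerMap,
                         params: FilterParams) -> set[str]:
    """Flag extreme mean GC content and poor probe coverage over the span."""
    i0, i1 = marker_map.probe_range(cnvr.chrom, cnvr.start_pos, cnvr.end_pos)
    gc = marker_map.df["gc"].to_numpy()[i0:i1]
    n_probes = i1 - i0
    if n_probes == 0 or np.isnan(gc).all():
        cnvr.filter_flags.add(FLAG_GC_UNKNOWN)
    else:
        mean_gc = float(np.nanmean(gc))
        if mean_gc < params.gc_low or mean_gc > params.gc_high:
            cnvr.filter_flags.add(FLAG_GC_EXTREME)
    span_100kb = (cnvr.end_pos - cnvr.start_pos + 1) / 1e5
    if span_100kb > 0 and n_probes / span_100kb < params.min_probe_density:
        cnvr.filter_flags.add(FLAG_LOW_COVERAGE)
    return cnvr.filter_flags


def flag_sample_bias(cnvrs: Sequence[Cnvr], samples: Sequence[SampleRecord],
                     params: FilterParams, alpha_probe: float = 0.05,
                     min_case_carriers: int = 3) -> list[set[str]]:
    """Flag CNVRs whose signal depends on over-contributing samples.

    A bias sample appears in more than ``max_cnvrs_per_sample`` distinct
    CNVRs.  Each CNVR is flagged iff removing its bias samples drops the
    enriched-cohort carrier count below ``min_case_carriers`` or pushes the
    recomputed Fisher p above ``alpha_probe`` (cohort denominators are kept:
    bias samples are discounted as carriers, not excluded from the study).
    """
    cohort = {s.sample_id: s.cohort for s in samples}
    n1 = sum(1 for s in samples if s.included and s.cohort == "case")
    n2 = sum(1 for s in samples if s.included and s.cohort == "control")
    membership: dict[str, int] = {}
    for cnvr in cnvrs:
        for sid in cnvr.contributing_samples:
            membership[sid] = membership.get(sid, 0) + 1
    bias = {sid for sid, k in membership.items()
            if k > params.max_cnvrs_per_sample}
    for cnvr in cnvrs:
        dropped = cnvr.contributing_samples & bias
        if not dropped:
            continue
        kept = cnvr.contributing_samples - bias
        a = sum(1 for sid in kept if cohort.get(sid) == "case")
        b = len(kept) - a
        enriched = a if cnvr.direction == "case_enriched" else b
        if (enriched < min_case_carriers
                or fisher_exact_two_sided(a, b, n1, n2) > alpha_probe):
            cnvr.filter_flags.add(FLAG_SAMPLE_BIAS)
    return [c.filter_flags for c in cnvrs]


def apply_all_filters(cnvrs: Sequence[Cnvr], calls: Sequence[CnvCall],
                      probe_stats: pd.DataFrame, marker_map: MarkerMap,
                      samples: Sequence[SampleRecord], params: FilterParams,
                      exclusion_track: IntervalTrack | None = None,
                      alpha_probe: float = 0.05,
                      min_case_carriers: int = 3) -> list[Cnvr]:
    """Run every screen over a CNVR list (idempotent; flags only added)."""
    for cnvr in cnvrs:
        if exclusion_track is not None:
            flag_positional_exclusions(cnvr, exclusion_track)
        flag_peninsula(cnvr, calls, probe_stats, marker_map, params,
                       alpha_probe)
        flag_gc_and_coverage(cnvr, marker_map, params)
    flag_sample_bias(cnvrs, samples, params, alpha_probe, min_case_carriers)
    return list(cnvrs)
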