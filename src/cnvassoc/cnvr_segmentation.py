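"""Collapse per-probe statistics into CNVRs and count effective tests.

Consecutive nominally significant probes of one CNV type and one
enrichment direction are chained while neighbouring significant probes lie
within ``max_gap_bp`` of each other (1 Mb by default); each chain becomes
one copy-number-variation region (CNVR) reported at its p-value local
minimum.  Chains whose peak carrier count in the enriched cohort falls
below ``min_case_carriers`` are dropped — a rare-variant inclusion rule
analogous to a minor-allele-frequency floor in SNP association.

The multiple-testing burden is not the number of significant chains (that
would be anti-conservative): ``testable_regions`` collapses all probes
harbouring at least ``min_case_carriers`` case carriers into regions with
the same gap rule, and ``effective_test_count`` counts distinct regions
with deletion/duplication overlaps merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io_formats import CnvCall, MarkerMap, SampleRecord
from .probe_association import CNV_TYPES


@dataclass
class SegmentationParams:
    alpha_probe: float = 0.05        # per-probe nominal significance
    max_gap_bp: int = 1_000_000      # chain break distance between sig probes
    min_case_carriers: int = 3       # peak carrier floor, enriched cohort

    def __post_init__(self):
        if not (0.0 < self.alpha_probe < 1.0):
            raise ValidationError("alpha_probe must be in (0, 1)")
        if self.max_gap_bp <= 0:
            raise ValidationError("max_gap_bp must be positive")


@dataclass
class Cnvr:
    """A collapsed associated region.

    ``p_discovery`` is the minimum per-probe p inside the span; carrier
    counts are taken at ``best_probe`` (ties broken to the leftmost probe).
    ``filter_flags`` is an audit trail — flagged regions are reported, not
    deleted.
    """

    chrom: str
    start_pos: int
    end_pos: int
    type: str                        # "del" | "dup"
    direction: str                   # "case_enriched" | "control_enriched"
    best_probe: str
    p_discovery: float
    case_carriers: int
    control_carriers: int
    best_pos: int = 0
    contributing_samples: frozenset = frozenset()
    filter_flags: set = field(default_factory=set)
    genes: list = field(default_factory=list)
    p_replication: float | None = None
    p_combined: float | None = None
    replicated: bool | None = None

    @property
    def region(self) -> str:
        return f"{self.chrom}:{self.start_pos}-{self.end_pos}"

    @property
    def enriched_carriers(self) -> int:
        return (self.case_carriers if self.direction == "case_enriched"
                else self.control_carriers)


@dataclass(frozen=True)
class Region:
    """A bare genomic span (used for the test-count collapse)."""
    chrom: str
    start_pos: int
    end_pos: int


def _check_sorted(stats: pd.DataFrame) -> None:
    for (typ, chrom), grp in stats.groupby(["type", "chrom"], sort=False):
        pos = grp["pos"].to_numpy()
        if len(pos) > 1 and not (np.diff(pos) > 0).all():
            raise ValidationError(
                f"probe stats not sorted by position on {chrom} ({typ})")


def _chain_indices(pos: np.ndarray, max_gap_bp: int) -> list[np.ndarray]:
    """Split sorted positions into runs with consecutive gaps <= max_gap_bp."""
    if len(pos) == 0:
        return []
    breaks = np.flatnonzero(np.diff(pos) > max_gap_bp)
    return np.split(np.arange(len(pos)), breaks + 1)


def collapse_cnvrs(stats: pd.DataFrame,
                   params: SegmentationParams) -> list[Cnvr]:
    """Chain significant probes into CNVRs.

    ``stats`` is the long-format frame from
    :func:`~cnvassoc.probe_association.per_probe_association`, sorted by
    position within each (type, chromosome).  Deletions and duplications
    are segmented independently, as are the two enrichment directions;
    chains never cross chromosome boundaries.
    """
    _check_sorted(stats)
    cnvrs: list[Cnvr] = []
    for typ in CNV_TYPES:
        for direction, cohort in (("case_enriched", "case"),
                                  ("control_enriched", "control")):
            mask = ((stats["type"] == typ)
                    & (stats["p"] < params.alpha_probe)
                    & (stats["enriched_in"] == cohort))
            sig = stats.loc[mask]
            for chrom, grp in sig.groupby("chrom", sort=False):
                pos = grp["pos"].to_numpy()
                p = grp["p"].to_numpy()
                a = grp["case_carriers"].to_numpy()
                b = grp["control_carriers"].to_numpy()
                ids = grp["probe_id"].to_numpy()
                for run in _chain_indices(pos, params.max_gap_bp):
                    best = run[int(np.argmin(p[run]))]  # argmin -> leftmost
                    enriched = a[best] if cohort == "case" else b[best]
                    if enriched < params.min_case_carriers:
                        continue
                    cnvrs.append(Cnvr(
                        chrom=chrom,
                        start_pos=int(pos[run[0]]),
                        end_pos=int(pos[run[-1]]),
                        type=typ,
                        direction=direction,
                        best_probe=str(ids[best]),
                        best_pos=int(pos[best]),
                        p_discovery=float(p[best]),
                        case_carriers=int(a[best]),
                        control_carriers=int(b[best]),
                    ))
    return cnvrs


def attach_contributing_samples(cnvrs: Sequence[Cnvr],
                                calls: Sequence[CnvCall],
                                samples: Sequence[SampleRecord]) -> None:
    """Record, on each CNVR, the included samples carrying its type at the
    best probe (both cohorts).  Mutates the CNVRs in place."""
    included = {s.sample_id for s in samples if s.included}
    by_type_chrom: dict[tuple[str, str], list[CnvCall]] = {}
    for c in calls:
        if c.sample_id in included:
            by_type_chrom.setdefault((c.cnv_type, c.chrom), []).append(c)
    for cnvr in cnvrs:
        pool = by_type_chrom.get((cnvr.type, cnvr.chrom), [])
        carriers = {c.sample_id for c in pool
                    if c.start_pos <= cnvr.best_pos <= c.end_pos}
        cnvr.contributing_samples = frozenset(carriers)


def testable_regions(counts: pd.DataFrame,
                     params: SegmentationParams) -> dict[str, list[Region]]:
    """Collapse probes with >= ``min_case_carriers`` case carriers into
    regions per type — the denominator of the multiple-testing bar."""
    out: dict[str, list[Region]] = {}
    for typ in CNV_TYPES:
        regions = []
        mask = counts[f"{typ}_case"].to_numpy() >= params.min_case_carriers
        sub = counts.loc[mask]
        for chrom, grp in sub.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            for run in _chain_indices(pos, params.max_gap_bp):
                regions.append(Region(chrom, int(pos[run[0]]),
                                      int(pos[run[-1]])))
        out[typ] = regions
    return out


def effective_test_count(cnvrs_del: Iterable, cnvrs_dup: Iterable) -> int:
    """Number of distinct regions across both types.

    Same-type regions are disjoint by construction; a deletion and a
    duplication region that overlap are counted once (connected overlapping
    spans collapse to a single test).
    """
    spans = [(r.chrom, r.start_pos, r.end_pos)
             for r in list(cnvrs_del) + list(cnvrs_dup)]
    if not spans:
        return 0
    spans.sort()
    count = 0
    cur_chrom, cur_end = None, -1
    for chrom, start, end in spans:
        if chrom != cur_chrom or start > cur_end:
            count += 1
            cur_chrom, cur_end = chrom, end
        else:
            cur_end = max(cur_end, end)
    return count
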