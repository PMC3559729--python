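"""Per-sample quality control ahead of association.

Samples enter the scan only if their array data are clean: genotyping call
rate above 98%, Log R Ratio standard deviation below 0.30 (intensity
noise), |GC wave factor| below 0.05 (hybridisation waviness), and fewer
than 100 CNV calls (an excess indicates poor DNA quality).  All
comparisons are strict, so boundary values fail.  Duplicated individuals
(e.g. monozygotic twins) keep exactly one representative, and ancestry
outliers are removed by an iterative PC-centroid rule: samples farther
than ``pca_sd_limit`` standard deviations from the included-set centroid
on either of the first two principal components are excluded, with the
centroid recomputed once after the first pass.

Every exclusion records the *first* failing reason, checked in the order
call_rate, lrr_sd, gcwf, cnv_count, duplicate, pca_outlier.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .exceptions import ValidationError
from .io_formats import CnvCall, SampleRecord


@dataclass
class QcThresholds:
    min_call_rate: float = 0.98
    max_lrr_sd: float = 0.30
    max_abs_gcwf: float = 0.05
    max_cnv_count: int = 100
    pca_sd_limit: float = 6.0

    def __post_init__(self):
        for name in ("min_call_rate", "max_lrr_sd", "max_abs_gcwf",
                     "max_cnv_count", "pca_sd_limit"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


def flag_duplicates(samples: Sequence[SampleRecord],
                    pairwise_identity: Sequence[tuple[str, str, float]],
                    threshold: float) -> list[SampleRecord]:
    """Keep one sample per duplicate cluster.

    Pairs with identity above ``threshold`` are joined into connected
    components; the lexicographically smallest sample id in each component
    is retained and the rest are excluded with reason ``"duplicate"``.
    """
    ids = {s.sample_id for s in samples}
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent.get(x, x) != x:
            parent[x] = parent.get(parent[x], parent[x])
            x = parent[x]
        return x

    for id_a, id_b, ident in pairwise_identity:
        if not (0.0 <= ident <= 1.0):
            raise ValidationError(
                f"identity {ident} for pair ({id_a}, {id_b}) outside [0, 1]")
        for x in (id_a, id_b):
            if x not in ids:
                raise ValidationError(f"unknown sample id {x!r} in pair list")
        if ident > threshold:
            ra, rb = find(id_a), find(id_b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

    clusters: dict[str, list[str]] = {}
    for sid in {x for pair in pairwise_identity for x in pair[:2]}:
        clusters.setdefault(find(sid), []).append(sid)
    excluded = set()
    for root, members in clusters.items():
        keep = min(members)
        excluded.update(m for m in members if m != keep)

    out = []
    for s in samples:
        if s.sample_id in excluded:
            out.append(replace(s, included=False,
                               exclusion_reason="duplicate"))
        else:
            out.append(replace(s))
    return out


def apply_sample_qc(samples: Sequence[SampleRecord],
                    calls: Sequence[CnvCall],
                    thresholds: QcThresholds | None = None
                    ) -> list[SampleRecord]:
    """Set inclusion flags on a copy of the sample list.

    ``cnv_count`` is taken from the record when present, otherwise derived
    by counting the sample's calls.  Samples already excluded as
    duplicates (by :func:`flag_duplicates`) stay excluded.
    """
    thresholds = thresholds or QcThresholds()
    call_counts: dict[str, int] = {}
    for c in calls:
        call_counts[c.sample_id] = call_counts.get(c.sample_id, 0) + 1

    out: list[SampleRecord] = []
    for s in samples:
        for name in ("call_rate", "lrr_sd", "gcwf"):
            v = getattr(s, name)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                raise ValidationError(
                    f"sample {s.sample_id}: missing QC metric {name!r}")
        cnv_count = s.cnv_count
        if cnv_count is None:
            cnv_count = call_counts.get(s.sample_id, 0)
        reason = ""
        if not (s.call_rate > thresholds.min_call_rate):
            reason = "call_rate"
        elif not (s.lrr_sd < thresholds.max_lrr_sd):
            reason = "lrr_sd"
        elif not (abs(s.gcwf) < thresholds.max_abs_gcwf):
            reason = "gcwf"
        elif not (cnv_count < thresholds.max_cnv_count):
            reason = "cnv_count"
        elif not s.included and s.exclusion_reason == "duplicate":
            reason = "duplicate"
        out.append(replace(s, cnv_count=cnv_count,
                           included=(reason == ""),
                           exclusion_reason=reason))

    _apply_pca_rule(out, thresholds)
    return out


def _apply_pca_rule(samples: list[SampleRecord],
                    thresholds: QcThresholds) -> None:
    """Two-round centroid-distance exclusion on PC1/PC2 (in place)."""
    with_pcs = [s for s in samples if s.included and len(s.pcs) >= 2]
    if len(with_pcs) < 3:
        return
    current = with_pcs
    for _ in range(2):
        pcs = np.array([s.pcs[:2] for s in current])
        mean = pcs.mean(axis=0)
        sd = pcs.std(axis=0, ddof=1)
        sd[sd == 0] = np.inf
        keep = (np.abs(pcs - mean) <= thresholds.pca_sd_limit * sd).all(axis=1)
        current = [s for s, k in zip(current, keep) if k]
    kept_ids = {s.sample_id for s in current}
    for i, s in enumerate(samples):
        if s.included and len(s.pcs) >= 2 and s.sample_id not in kept_ids:
            samples[i] = replace(s, included=False,
                                 exclusion_reason="pca_outlier")


def qc_summary(samples: Sequence[SampleRecord]) -> dict:
    """Counts of included samples and of exclusions per reason."""
    summary: dict[str, int] = {"total": len(samples),
                               "included": sum(s.included for s in samples)}
    reasons: dict[str, int] = {}
    for s in samples:
        if not s.included:
            reasons[s.exclusion_reason] = reasons.get(s.exclusion_reason, 0) + 1
    summary["excluded_by_reason"] = reasons
    return summary
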