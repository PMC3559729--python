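"""Per-probe carrier counting and two-sided Fisher exact tests.

The genome scan that drives CNVR discovery reduces, at each array probe, to
a 2x2 table: deletion (or duplication) carriers versus non-carriers in
cases and controls.  A sample is a carrier at a probe if it has at least
one call of that type whose span covers the probe's position; overlapping
calls from the same sample count once.  Cohort denominators are the full
post-QC cohort sizes at every probe (no per-probe missingness model).

``fisher_exact_two_sided`` implements the minimum-likelihood two-sided
convention: the p-value sums the hypergeometric probabilities of all tables
with the same margins whose probability is at most that of the observed
table (within a relative tolerance of 1e-7 on the comparison).  This is the
convention used by R's ``fisher.test`` and ``scipy.stats.fisher_exact``;
it is re-implemented here on a cached log-factorial table because the scan
and the simulation studies need millions of evaluations.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io_formats import CnvCall, MarkerMap, SampleRecord

CNV_TYPES = ("del", "dup")

#: relative slack on the "probability <= observed" comparison, guarding the
#: tie case against floating-point noise in the log-space pmf
_REL_TOL = 1e-7

_LOG_FACT = np.log(np.arange(1, 2, dtype=float)).cumsum()  # placeholder


def _log_fact(n: int) -> np.ndarray:
    """Cumulative log-factorial table 0..n (grown on demand, cached)."""
    global _LOG_FACT
    if n >= len(_LOG_FACT):
        m = max(n + 1, 2 * len(_LOG_FACT), 1024)
        _LOG_FACT = np.concatenate(
            [[0.0], np.cumsum(np.log(np.arange(1, m, dtype=float)))])
    return _LOG_FACT


@lru_cache(maxsize=1 << 18)
def fisher_exact_two_sided(a: int, b: int, n1: int, n2: int) -> float:
    """Two-sided Fisher exact p for carriers a/n1 (cases) vs b/n2 (controls).

    Symmetric under swapping the cohorts, i.e.
    ``fisher_exact_two_sided(a, b, n1, n2) ==
    fisher_exact_two_sided(b, a, n2, n1)``.
    """
    if min(a, b, n1, n2) < 0 or a > n1 or b > n2:
        raise ValidationError(
            f"invalid 2x2 table: a={a}, b={b}, n1={n1}, n2={n2}")
    k = a + b
    n = n1 + n2
    lo = max(0, k - n2)
    hi = min(k, n1)
    if lo == hi:
        return 1.0
    lf = _log_fact(n)
    support = np.arange(lo, hi + 1)
    # log P(X = x) for hypergeometric with margins (n1, n2 | k)
    logp = (lf[n1] - lf[support] - lf[n1 - support]
            + lf[n2] - lf[k - support] - lf[n2 - k + support])
    logp -= lf[n] - lf[k] - lf[n - k]
    pmf = np.exp(logp)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + _REL_TOL)].sum())
    return min(1.0, p)


# ---------------------------------------------------------------------------
# carrier counting
# ---------------------------------------------------------------------------

def count_carriers(calls: Sequence[CnvCall], marker_map: MarkerMap,
                   samples: Sequence[SampleRecord]) -> pd.DataFrame:
    """Per-probe deletion/duplication carrier counts by cohort.

    Only calls from QC-included samples contribute; calls from excluded
    samples are dropped, and a call naming a sample absent from the sheet
    is an error.  Returns a DataFrame aligned with the marker map, columns
    ``probe_id  chrom  pos  del_case  del_control  dup_case  dup_control``,
    with the post-QC cohort sizes in ``df.attrs["n_cases"]`` /
    ``df.attrs["n_controls"]``.
    """
    known = {s.sample_id: s for s in samples}
    cohort_code = {}          # sample_id -> 0 (case) / 1 (control)
    for s in samples:
        if s.included:
            cohort_code[s.sample_id] = 0 if s.cohort == "case" else 1

    # collect probe-index intervals per (sample, type)
    per_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for call in calls:
        if call.sample_id not in known:
            raise ValidationError(
                f"call names unknown sample {call.sample_id!r}")
        if call.sample_id not in cohort_code:
            continue  # excluded by QC
        if not marker_map.has_chrom(call.chrom):
            raise ValidationError(
                f"call on chromosome {call.chrom!r} absent from marker map")
        i0, i1 = marker_map.probe_range(call.chrom, call.start_pos,
                                        call.end_pos)
        if i1 <= i0:
            continue  # covers no probe
        per_key.setdefault((call.sample_id, call.cnv_type), []).append(
            (i0, i1 - 1))

    n = marker_map.n_probes
    diff = np.zeros((2, 2, n + 1), dtype=np.int64)  # [type][cohort]
    type_code = {"del": 0, "dup": 1}
    for (sid, typ), ivals in per_key.items():
        ivals.sort()
        # merge overlapping probe-index intervals so the sample counts once
        merged = []
        cs, ce = ivals[0]
        for s0, e0 in ivals[1:]:
            if s0 <= ce:
                ce = max(ce, e0)
            else:
                merged.append((cs, ce))
                cs, ce = s0, e0
        merged.append((cs, ce))
        t, c = type_code[typ], cohort_code[sid]
        for s0, e0 in merged:
            diff[t, c, s0] += 1
            diff[t, c, e0 + 1] -= 1

    counts = diff[:, :, :-1].cumsum(axis=2)
    out = pd.DataFrame({
        "probe_id": marker_map.df["probe_id"].to_numpy(),
        "chrom": marker_map.df["chrom"].to_numpy(),
        "pos": marker_map.df["pos"].to_numpy(),
        "del_case": counts[0, 0],
        "del_control": counts[0, 1],
        "dup_case": counts[1, 0],
        "dup_control": counts[1, 1],
    })
    out.attrs["n_cases"] = sum(1 for v in cohort_code.values() if v == 0)
    out.attrs["n_controls"] = sum(1 for v in cohort_code.values() if v == 1)
    return out


def per_probe_association(counts: pd.DataFrame) -> pd.DataFrame:
    """Fisher-test every probe for both CNV types.

    Input is the frame from :func:`count_carriers`.  Output is long-format,
    one row per probe per type, sorted by (type, map order), with columns
    ``probe_id chrom pos type case_carriers control_carriers n_cases
    n_controls p enriched_in``.  Probes with no carriers in either cohort
    get p = 1 and ``enriched_in = "neither"``; otherwise ``enriched_in`` is
    the cohort with the higher carrier frequency ("neither" on exact ties).
    """
    n1 = int(counts.attrs["n_cases"])
    n2 = int(counts.attrs["n_controls"])
    frames = []
    for typ in CNV_TYPES:
        a = counts[f"{typ}_case"].to_numpy()
        b = counts[f"{typ}_control"].to_numpy()
        pairs, inverse = np.unique(
            np.stack([a, b], axis=1), axis=0, return_inverse=True)
        p_unique = np.array([
            fisher_exact_two_sided(int(pa), int(pb), n1, n2)
            for pa, pb in pairs])
        p = p_unique[inverse]
        freq_diff = a * n2 - b * n1
        enriched = np.where(freq_diff > 0, "case",
                            np.where(freq_diff < 0, "control", "neither"))
        frames.append(pd.DataFrame({
            "probe_id": counts["probe_id"],
            "chrom": counts["chrom"],
            "pos": counts["pos"],
            "type": typ,
            "case_carriers": a,
            "control_carriers": b,
            "n_cases": n1,
            "n_controls": n2,
            "p": p,
            "enriched_in": enriched,
        }))
    out = pd.concat(frames, ignore_index=True)
    out.attrs["n_cases"] = n1
    out.attrs["n_controls"] = n2
    return out


def write_probe_stats(stats: pd.DataFrame, path) -> None:
    """Dump per-probe statistics (for Manhattan-style plotting)."""
    stats.to_csv(path, sep="\t", index=False,
                 columns=["probe_id", "chrom", "pos", "type",
                          "case_carriers", "control_carriers", "p",
                          "enriched_in"])
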