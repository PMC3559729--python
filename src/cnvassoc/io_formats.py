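"""Readers, writers and core record types for every external file format.

The pipeline exchanges five text formats:

* CNV call lists in the PennCNV ``rawcnv`` dialect (one call per line),
* a tab-separated marker map (``probe_id  chrom  pos  gc``),
* a tab-separated sample sheet with QC metrics and PC coordinates,
* BED 3+ interval tracks (exclusion regions, gene models),
* the tab-separated association results table.

Internal coordinates are 1-based inclusive throughout (the PennCNV
convention, since call files are the primary input); BED input/output
converts at the boundary.  Floats are serialised with :func:`repr` so every
write/read round trip is lossless and byte-reproducible.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .exceptions import ParseError, ValidationError

DELETION_STATES = frozenset({0, 1})
DUPLICATION_STATES = frozenset({3, 4})

#: copy number -> PennCNV HMM state label used when writing call lines
_CN_TO_HMM_STATE = {0: 1, 1: 2, 3: 5, 4: 6}


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CnvCall:
    """One sample's deletion or duplication call.

    ``copy_state`` is the integer copy number: 0/1 are deletions, 3/4
    duplications; the diploid state 2 is never a call.  ``start_pos`` and
    ``end_pos`` are 1-based inclusive base-pair positions.
    """

    sample_id: str
    chrom: str
    start_pos: int
    end_pos: int
    copy_state: int
    n_probes: int

    def __post_init__(self):
        if self.start_pos > self.end_pos:
            raise ValidationError(
                f"call {self.sample_id} {self.chrom}:{self.start_pos}-"
                f"{self.end_pos}: start > end")
        if self.copy_state not in DELETION_STATES | DUPLICATION_STATES:
            raise ValidationError(
                f"call {self.sample_id}: copy state {self.copy_state} is not "
                "a CNV state (expected 0, 1, 3 or 4)")
        if self.n_probes < 1:
            raise ValidationError(f"call {self.sample_id}: n_probes < 1")

    @property
    def cnv_type(self) -> str:
        """``"del"`` or ``"dup"``."""
        return "del" if self.copy_state in DELETION_STATES else "dup"


@dataclass
class SampleRecord:
    """Per-sample cohort label, QC metrics and PC coordinates."""

    sample_id: str
    cohort: str                      # "case" or "control"
    call_rate: float
    lrr_sd: float
    gcwf: float
    cnv_count: int | None = None
    pcs: tuple[float, ...] = ()
    included: bool = True
    exclusion_reason: str = ""

    def __post_init__(self):
        if self.cohort not in ("case", "control"):
            raise ValidationError(
                f"sample {self.sample_id}: cohort must be 'case' or "
                f"'control', got {self.cohort!r}")
        if not (0.0 <= self.call_rate <= 1.0):
            raise ValidationError(
                f"sample {self.sample_id}: call_rate outside [0, 1]")
        if not self.included and not self.exclusion_reason:
            raise ValidationError(
                f"sample {self.sample_id}: excluded without a reason")


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int     # 1-based inclusive
    end: int       # 1-based inclusive
    name: str = ""


@dataclass
class IntervalTrack:
    """A sorted list of named intervals with overlap queries.

    ``role`` records what the track carries ("exclusion_region" or
    "gene_model").  Intervals are kept exactly as supplied (overlaps are
    preserved, no merging) and sorted by (chrom, start).
    """

    intervals: list[Interval]
    role: str
    _trees: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.intervals = sorted(
            self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        self._trees = {}

    def _tree(self, chrom: str) -> IntervalTree:
        if chrom not in self._trees:
            tree = IntervalTree()
            for iv in self.intervals:
                if iv.chrom == chrom:
                    # intervaltree is half-open
                    tree.addi(iv.start, iv.end + 1, iv)
            self._trees[chrom] = tree
        return self._trees[chrom]

    def overlapping(self, chrom: str, start: int, end: int) -> list[Interval]:
        """All intervals overlapping [start, end] by >= 1 bp, genomic order."""
        hits = [h.data for h in self._tree(chrom).overlap(start, end + 1)]
        return sorted(hits, key=lambda iv: (iv.start, iv.end))

    def __len__(self) -> int:
        return len(self.intervals)


class MarkerMap:
    """The ordered probe coordinate system shared by every statistic.

    Wraps a DataFrame with columns ``probe_id``, ``chrom``, ``pos`` and
    ``gc`` (GC fraction in [0, 1], NaN when unknown).  Chromosome order is
    the order of first appearance in the input; positions must be strictly
    increasing within each chromosome and probe ids unique.
    """

    def __init__(self, df: pd.DataFrame):
        required = ["probe_id", "chrom", "pos"]
        for col in required:
            if col not in df.columns:
                raise ValidationError(f"marker map missing column {col!r}")
        df = df.reset_index(drop=True).copy()
        if "gc" not in df.columns:
            df["gc"] = np.nan
        df["pos"] = df["pos"].astype(np.int64)
        if df["probe_id"].duplicated().any():
            dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise ValidationError(f"duplicate probe id {dup!r} in marker map")
        self.df = df
        self._offsets: dict[str, tuple[int, np.ndarray]] = {}
        offset = 0
        seen: set[str] = set()
        for chrom, grp in df.groupby("chrom", sort=False):
            if not grp.index.equals(pd.RangeIndex(offset, offset + len(grp))):
                raise ValidationError(
                    f"marker map rows for {chrom} are not contiguous")
            pos = grp["pos"].to_numpy()
            if len(pos) > 1 and not (np.diff(pos) > 0).all():
                raise ValidationError(
                    f"positions not strictly increasing on {chrom}")
            if chrom in seen:
                raise ValidationError(f"chromosome {chrom} appears twice")
            seen.add(chrom)
            self._offsets[chrom] = (offset, pos)
            offset += len(grp)

    # -- basic accessors ----------------------------------------------------

    @property
    def n_probes(self) -> int:
        return len(self.df)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._offsets)

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self._offsets

    def positions(self, chrom: str) -> np.ndarray:
        return self._offsets[chrom][1]

    def chrom_offset(self, chrom: str) -> int:
        return self._offsets[chrom][0]

    def probe_range(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        """Global row range [i0, i1) of probes with start <= pos <= end."""
        if chrom not in self._offsets:
            raise ValidationError(f"chromosome {chrom!r} absent from marker map")
        offset, pos = self._offsets[chrom]
        i0 = int(np.searchsorted(pos, start, side="left"))
        i1 = int(np.searchsorted(pos, end, side="right"))
        return offset + i0, offset + i1

    def n_probes_in(self, chrom: str, start: int, end: int) -> int:
        i0, i1 = self.probe_range(chrom, start, end)
        return i1 - i0


# ---------------------------------------------------------------------------
# float serialisation helpers
# ---------------------------------------------------------------------------

def _fmt_float(x: float | None) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    return repr(float(x))


def _parse_float(s: str) -> float | None:
    return None if s == "NA" else float(s)


# ---------------------------------------------------------------------------
# CNV call lists (PennCNV rawcnv dialect)
# ---------------------------------------------------------------------------

_REGION_RE = re.compile(r"^(?P<chrom>[^:\s]+):(?P<start>\d+)-(?P<end>\d+)$")


def read_cnv_calls(path, marker_map: MarkerMap | None = None) -> list[CnvCall]:
    """Parse a PennCNV-style call list.

    Each non-empty line must look like::

        chr1:6240656-6289806 numsnp=12 length=49,151 state2,cn=1 SAMPLE ...

    Trailing tokens (startsnp=..., endsnp=...) are ignored.  Lines with
    ``cn=2`` are rejected (the diploid state is not a CNV).  When a marker
    map is supplied, the chromosome must exist in it and ``numsnp`` must
    equal the number of map probes inside the span.
    """
    calls: list[CnvCall] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            tokens = line.split()
            if len(tokens) < 5:
                raise ParseError(
                    f"{path}:{lineno}: expected >= 5 fields, got {len(tokens)}")
            m = _REGION_RE.match(tokens[0])
            if m is None:
                raise ParseError(
                    f"{path}:{lineno}: malformed region {tokens[0]!r}")
            if not tokens[1].startswith("numsnp="):
                raise ParseError(f"{path}:{lineno}: missing numsnp field")
            if not tokens[2].startswith("length="):
                raise ParseError(f"{path}:{lineno}: missing length field")
            sm = re.match(r"^state\d+,cn=(\d+)$", tokens[3])
            if sm is None:
                raise ParseError(
                    f"{path}:{lineno}: malformed state field {tokens[3]!r}")
            cn = int(sm.group(1))
            if cn == 2:
                raise ParseError(
                    f"{path}:{lineno}: cn=2 is the diploid state, not a CNV")
            if cn not in (0, 1, 3, 4):
                raise ParseError(f"{path}:{lineno}: unsupported cn={cn}")
            chrom = m.group("chrom")
            start, end = int(m.group("start")), int(m.group("end"))
            n_probes = int(tokens[1].split("=", 1)[1])
            if marker_map is not None:
                if not marker_map.has_chrom(chrom):
                    raise ValidationError(
                        f"{path}:{lineno}: chromosome {chrom!r} absent from "
                        "marker map")
                expected = marker_map.n_probes_in(chrom, start, end)
                if expected != n_probes:
                    raise ValidationError(
                        f"{path}:{lineno}: numsnp={n_probes} but the marker "
                        f"map has {expected} probes in {chrom}:{start}-{end}")
            try:
                call = CnvCall(tokens[4], chrom, start, end, cn, n_probes)
            except ValidationError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            calls.append(call)
    return calls


def write_cnv_calls(calls: Iterable[CnvCall], path) -> None:
    with open(path, "w") as fh:
        for c in calls:
            length = c.end_pos - c.start_pos + 1
            fh.write(
                f"{c.chrom}:{c.start_pos}-{c.end_pos} numsnp={c.n_probes} "
                f"length={length:,} state{_CN_TO_HMM_STATE[c.copy_state]},"
                f"cn={c.copy_state} {c.sample_id}\n")


# ---------------------------------------------------------------------------
# marker map
# ---------------------------------------------------------------------------

def read_marker_map(path) -> MarkerMap:
    """Read a tab-separated ``probe_id  chrom  pos  gc`` file (gc may be NA)."""
    df = pd.read_csv(
        path, sep="\t", dtype={"probe_id": str, "chrom": str},
        na_values=["NA"], keep_default_na=False,
        float_precision="round_trip")
    return MarkerMap(df)


def write_marker_map(marker_map: MarkerMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("probe_id\tchrom\tpos\tgc\n")
        for row in marker_map.df.itertuples(index=False):
            gc = "NA" if pd.isna(row.gc) else repr(float(row.gc))
            fh.write(f"{row.probe_id}\t{row.chrom}\t{row.pos}\t{gc}\n")


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

def read_sample_sheet(path) -> list[SampleRecord]:
    """Read the tab-separated sample sheet.

    Fixed columns ``sample_id cohort call_rate lrr_sd gcwf cnv_count``
    followed by any number of ``pc1, pc2, ...`` columns and optional
    ``included``/``exclusion_reason`` columns.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str},
                     na_values=["NA"], keep_default_na=False,
                     float_precision="round_trip")
    pc_cols = sorted(
        (c for c in df.columns if re.fullmatch(r"pc\d+", c)),
        key=lambda c: int(c[2:]))
    samples = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        cnv_count = d.get("cnv_count")
        samples.append(SampleRecord(
            sample_id=d["sample_id"],
            cohort=d["cohort"],
            call_rate=float(d["call_rate"]),
            lrr_sd=float(d["lrr_sd"]),
            gcwf=float(d["gcwf"]),
            cnv_count=None if pd.isna(cnv_count) else int(cnv_count),
            pcs=tuple(float(d[c]) for c in pc_cols),
            included=bool(d.get("included", True))
            if str(d.get("included", "True")) not in ("False", "false")
            else False,
            exclusion_reason=str(d.get("exclusion_reason", "") or ""),
        ))
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sample ids in sample sheet")
    return samples


def write_sample_sheet(samples: Sequence[SampleRecord], path) -> None:
    n_pcs = max((len(s.pcs) for s in samples), default=0)
    pc_cols = [f"pc{i + 1}" for i in range(n_pcs)]
    with open(path, "w") as fh:
        fh.write("sample_id\tcohort\tcall_rate\tlrr_sd\tgcwf\tcnv_count\t"
                 + "\t".join(pc_cols)
                 + "\tincluded\texclusion_reason\n")
        for s in samples:
            pcs = list(s.pcs) + [float("nan")] * (n_pcs - len(s.pcs))
            fh.write("\t".join([
                s.sample_id, s.cohort, repr(float(s.call_rate)),
                repr(float(s.lrr_sd)), repr(float(s.gcwf)),
                "NA" if s.cnv_count is None else str(s.cnv_count),
                *(repr(float(p)) for p in pcs),
                "True" if s.included else "False",
                s.exclusion_reason or "",
            ]) + "\n")


# ---------------------------------------------------------------------------
# interval tracks (BED)
# ---------------------------------------------------------------------------

def read_interval_track(path, role: str) -> IntervalTrack:
    """Read a BED 3+ file into the package's 1-based inclusive convention.

    BED uses 0-based half-open coordinates, so a line ``chr1 0 100`` becomes
    the inclusive interval chr1:1-100.  Overlapping intervals are preserved.
    """
    intervals = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            tokens = line.split()
            if len(tokens) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom, start, end = tokens[0], int(tokens[1]), int(tokens[2])
            if start >= end:
                raise ValidationError(
                    f"{path}:{lineno}: empty or inverted interval "
                    f"{chrom}:{start}-{end}")
            name = tokens[3] if len(tokens) > 3 else ""
            intervals.append(Interval(chrom, start + 1, end, name))
    return IntervalTrack(intervals, role)


def write_interval_track(track: IntervalTrack, path) -> None:
    """Write back to BED (inverse of :func:`read_interval_track`)."""
    with open(path, "w") as fh:
        for iv in track.intervals:
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{iv.name}\n")


# ---------------------------------------------------------------------------
# association results table
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = [
    "region", "type", "direction", "best_probe", "case_carriers",
    "control_carriers", "p_discovery", "p_replication", "p_combined",
    "replicated", "filter_flags", "genes",
]


def write_association_table(cnvrs: Sequence, path) -> None:
    """Write CNVR results as a tab-separated table.

    Empty flag/gene sets are written as ``.``; missing replication columns
    as ``NA``.  Paired with :func:`read_association_table` the round trip is
    the identity on every serialised field.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(_TABLE_COLUMNS) + "\n")
        for c in cnvrs:
            replicated = ("NA" if c.replicated is None
                          else ("true" if c.replicated else "false"))
            fh.write("\t".join([
                f"{c.chrom}:{c.start_pos}-{c.end_pos}",
                c.type,
                c.direction,
                c.best_probe,
                str(c.case_carriers),
                str(c.control_carriers),
                _fmt_float(c.p_discovery),
                _fmt_float(c.p_replication),
                _fmt_float(c.p_combined),
                replicated,
                ",".join(sorted(c.filter_flags)) or ".",
                ",".join(c.genes) or ".",
            ]) + "\n")


def read_association_table(path) -> list:
    """Read a table written by :func:`write_association_table`.

    Contributing-sample sets are not serialised, so round-tripped records
    carry empty ``contributing_samples``.
    """
    from .cnvr_segmentation import Cnvr  # local import avoids a cycle

    cnvrs = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header != _TABLE_COLUMNS:
            raise ParseError(f"{path}: unexpected header {header}")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            tok = line.split("\t")
            if len(tok) != len(_TABLE_COLUMNS):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(_TABLE_COLUMNS)} columns")
            m = _REGION_RE.match(tok[0])
            if m is None:
                raise ParseError(f"{path}:{lineno}: malformed region {tok[0]!r}")
            cnvrs.append(Cnvr(
                chrom=m.group("chrom"),
                start_pos=int(m.group("start")),
                end_pos=int(m.group("end")),
                type=tok[1],
                direction=tok[2],
                best_probe=tok[3],
                p_discovery=float(tok[6]),
                case_carriers=int(tok[4]),
                control_carriers=int(tok[5]),
                p_replication=_parse_float(tok[7]),
                p_combined=_parse_float(tok[8]),
                replicated=None if tok[9] == "NA" else tok[9] == "true",
                filter_flags=set() if tok[10] == "." else set(tok[10].split(",")),
                genes=[] if tok[11] == "." else tok[11].split(","),
            ))
    return cnvrs
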