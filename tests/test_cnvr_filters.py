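"""False-positive screens: positional, peninsula, GC/coverage, sample bias."""

import copy

import numpy as np
import pandas as pd
import pytest

import cnvassoc as ca
from cnvassoc.cnvr_filters import (FLAG_GC_EXTREME, FLAG_LOW_COVERAGE,
                                   FLAG_PENINSULA, FLAG_SAMPLE_BIAS,
                                   FLAG_TELOMERE_CENTROMERE, FilterParams,
                                   flag_gc_and_coverage, flag_peninsula,
                                   flag_positional_exclusions,
                                   flag_sample_bias)
from cnvassoc.cnvr_segmentation import Cnvr
from cnvassoc.io_formats import Interval, IntervalTrack
from cnvassoc.probe_association import count_carriers, per_probe_association
from tests.conftest import make_samples

PARAMS = FilterParams()


def cnvr(start, end, chrom="chr1", typ="del", a=5, b=0, samples=frozenset(),
         best=None):
    return Cnvr(chrom=chrom, start_pos=start, end_pos=end, type=typ,
                direction="case_enriched", best_probe="p", best_pos=best
                or start, p_discovery=0.01, case_carriers=a,
                control_carriers=b, contributing_samples=samples)


class TestPositional:
    TRACK = IntervalTrack([Interval("chr1", 1000, 2000, "cen")],
                          "exclusion_region")

    def test_inside_flagged(self):
        assert FLAG_TELOMERE_CENTROMERE in flag_positional_exclusions(
            cnvr(1500, 1600), self.TRACK)

    def test_one_bp_outside_not_flagged(self):
        assert not flag_positional_exclusions(cnvr(2001, 2500), self.TRACK)
        assert FLAG_TELOMERE_CENTROMERE in flag_positional_exclusions(
            cnvr(2000, 2500), self.TRACK)

    def test_empty_track_flags_nothing(self):
        empty = IntervalTrack([], "exclusion_region")
        assert not flag_positional_exclusions(cnvr(1500, 1600), empty)


class TestGcCoverage:
    def test_high_gc_flagged(self, small_map):
        small_map.df.loc[:30, "gc"] = 0.8
        flags = flag_gc_and_coverage(cnvr(10_000, 100_000), small_map,
                                     PARAMS)
        assert FLAG_GC_EXTREME in flags

    def test_sparse_probes_flagged(self):
        df = pd.DataFrame({"probe_id": ["a", "b"], "chrom": "chr1",
                           "pos": [1, 500_000], "gc": 0.5})
        mm = ca.MarkerMap(df)
        flags = flag_gc_and_coverage(cnvr(1, 500_000), mm, PARAMS)
        assert FLAG_LOW_COVERAGE in flags        # 0.4 probes / 100 kb

    def test_normal_region_clean(self, small_map):
        assert not flag_gc_and_coverage(cnvr(10_000, 100_000), small_map,
                                        PARAMS)


def build_peninsula_fixture(small_map, extension_probes):
    """Common CNV on probes 20-59 of chr1 (equal carriers both cohorts);
    case calls extend `extension_probes` past the core into the flank,
    making flank probes 60.. case-only."""
    samples = make_samples(40, 40)
    calls = []
    for i in range(10):        # 10 case + 10 control common carriers
        calls.append(ca.CnvCall(f"case{i:04d}", "chr1", 21 * 10_000,
                                (60 + extension_probes) * 10_000, 1,
                                40 + extension_probes))
        calls.append(ca.CnvCall(f"ctrl{i:04d}", "chr1", 21 * 10_000,
                                60 * 10_000, 1, 40))
    counts = count_carriers(calls, small_map, samples)
    stats = per_probe_association(counts)
    cnvrs = ca.collapse_cnvrs(stats, ca.SegmentationParams())
    ca.attach_contributing_samples(cnvrs, calls, samples)
    return cnvrs, calls, stats, samples


class TestPeninsula:
    def test_common_cnv_edge_artifact_flagged(self, small_map):
        cnvrs, calls, stats, _ = build_peninsula_fixture(small_map, 8)
        (c,) = cnvrs
        # the significant subregion is the case-only flank
        assert c.start_pos == 61 * 10_000
        flags = flag_peninsula(c, calls, stats, small_map, PARAMS)
        assert FLAG_PENINSULA in flags

    def test_clean_planted_region_not_flagged(self, small_map):
        """Carriers covering exactly the significant span do not extend."""
        samples = make_samples(40, 40)
        calls = [ca.CnvCall(f"case{i:04d}", "chr1", 210_000, 400_000, 1, 20)
                 for i in range(8)]
        counts = count_carriers(calls, small_map, samples)
        stats = per_probe_association(counts)
        cnvrs = ca.collapse_cnvrs(stats, ca.SegmentationParams())
        ca.attach_contributing_samples(cnvrs, calls, samples)
        (c,) = cnvrs
        assert not flag_peninsula(c, calls, stats, small_map, PARAMS)

    def test_fraction_boundary_inclusive(self, small_map):
        """Exactly half the contributing calls extending still flags
        (>= comparison on the fraction)."""
        samples = make_samples(40, 40)
        calls = []
        for i in range(4):     # 4 extending far into a null flank
            calls.append(ca.CnvCall(f"case{i:04d}", "chr1", 210_000,
                                    500_000, 1, 30))
        for i in range(4, 8):  # 4 confined to the significant span
            calls.append(ca.CnvCall(f"case{i:04d}", "chr1", 210_000,
                                    300_000, 1, 10))
        counts = count_carriers(calls, small_map, samples)
        stats = per_probe_association(counts)
        c = cnvr(210_000, 300_000, a=8,
                 samples=frozenset(f"case{i:04d}" for i in range(8)))
        flags = flag_peninsula(c, calls, stats, small_map, PARAMS)
        assert FLAG_PENINSULA in flags


class TestSampleBias:
    def _samples(self):
        return make_samples(500, 500)

    def test_shared_sample_collapses_small_loci(self):
        """One sample in 10 three-carrier loci: removing it leaves 2 < 3
        carriers, so all 10 are flagged."""
        samples = self._samples()
        cnvrs = []
        for k in range(10):
            ids = frozenset({"case0000", f"case{2*k+1:04d}",
                             f"case{2*k+2:04d}"})
            cnvrs.append(cnvr(k * 100_000 + 1, k * 100_000 + 50_000,
                              a=3, samples=ids))
        flag_sample_bias(cnvrs, samples, PARAMS)
        assert all(FLAG_SAMPLE_BIAS in c.filter_flags for c in cnvrs)

    def test_disjoint_carrier_sets_clean(self):
        samples = self._samples()
        cnvrs = [cnvr(k * 100_000 + 1, k * 100_000 + 50_000, a=3,
                      samples=frozenset(f"case{3*k+j:04d}"
                                        for j in range(3)))
                 for k in range(10)]
        flag_sample_bias(cnvrs, samples, PARAMS)
        assert all(not c.filter_flags for c in cnvrs)

    def test_strong_locus_survives_bias_sample(self):
        """A locus with 30 other carriers keeps its signal after the bias
        sample is discounted."""
        samples = self._samples()
        cnvrs = [cnvr(k * 100_000 + 1, k * 100_000 + 50_000, a=3,
                      samples=frozenset({"case0000", f"case{2*k+1:04d}",
                                         f"case{2*k+2:04d}"}))
                 for k in range(10)]
        strong = cnvr(5_000_000, 5_100_000, a=31,
                      samples=frozenset({"case0000"}
                                        | {f"case{100+j:04d}"
                                           for j in range(30)}))
        cnvrs.append(strong)
        flag_sample_bias(cnvrs, samples, PARAMS)
        assert FLAG_SAMPLE_BIAS not in strong.filter_flags
        assert all(FLAG_SAMPLE_BIAS in c.filter_flags for c in cnvrs[:-1])


def test_filters_idempotent_and_non_destructive(small_map):
    cnvrs, calls, stats, samples = build_peninsula_fixture(small_map, 8)
    track = IntervalTrack([Interval("chr1", 1, 50_000, "tel")],
                          "exclusion_region")
    before = [(c.case_carriers, c.control_carriers, c.p_discovery)
              for c in cnvrs]
    ca.apply_all_filters(cnvrs, calls, stats, small_map, samples, PARAMS,
                         exclusion_track=track)
    once = [copy.deepcopy(c.filter_flags) for c in cnvrs]
    ca.apply_all_filters(cnvrs, calls, stats, small_map, samples, PARAMS,
                         exclusion_track=track)
    assert [c.filter_flags for c in cnvrs] == once
    after = [(c.case_carriers, c.control_carriers, c.p_discovery)
             for c in cnvrs]
    assert before == after
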