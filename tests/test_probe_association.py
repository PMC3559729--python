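"""Carrier counting and the two-sided Fisher exact test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact as scipy_fisher

import cnvassoc as ca
from cnvassoc.probe_association import (count_carriers,
                                        fisher_exact_two_sided,
                                        per_probe_association)

N1, N2 = 7313, 2701   # discovery cohort sizes the printed tables use


class TestFisherExact:
    @pytest.mark.parametrize("a,b,expected", [
        (87, 4, 3.33e-8),
        (42, 0, 3.89e-6),
        (60, 1, 1.37e-7),
        (26, 0, 5.0e-4),
        (19, 1, 2.29e-2),
        (14, 0, 1.6e-2),
        (11, 0, 4.3e-2),
        (1, 7, 6.3e-4),
    ])
    def test_rare_cnvr_tables_reproduce_to_2_sig_figs(self, a, b, expected):
        p = fisher_exact_two_sided(a, b, N1, N2)
        assert p == pytest.approx(expected, rel=0.05)

    def test_empty_table_is_certain(self):
        assert fisher_exact_two_sided(0, 0, 100, 50) == 1.0

    def test_negative_or_inconsistent_counts_rejected(self):
        with pytest.raises(ca.ValidationError):
            fisher_exact_two_sided(-1, 0, 10, 10)
        with pytest.raises(ca.ValidationError):
            fisher_exact_two_sided(11, 0, 10, 10)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(1, 60), st.integers(1, 60),
           st.data())
    def test_symmetric_under_cohort_swap(self, n1, n2, data):
        a = data.draw(st.integers(0, n1))
        b = data.draw(st.integers(0, n2))
        assert fisher_exact_two_sided(a, b, n1, n2) == pytest.approx(
            fisher_exact_two_sided(b, a, n2, n1), rel=1e-12)

    def test_decreasing_in_case_only_carriers_at_stride_two(self):
        """More case-only carriers give stronger evidence.  The
        minimum-likelihood two-sided p is not monotone step by step (the
        opposite tail's inclusion set changes discretely), but it is
        strictly decreasing at stride 2 and across the board."""
        ps = [fisher_exact_two_sided(a, 0, N1, N2) for a in range(1, 40)]
        assert all(x > y for x, y in zip(ps, ps[2:]))
        assert ps[-1] < 1e-4 < ps[0]

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.integers(1, 200), st.integers(1, 200), st.data())
    def test_agrees_with_scipy_convention(self, n1, n2, data):
        """Independent cross-check against scipy's implementation of the
        same minimum-likelihood two-sided convention."""
        a = data.draw(st.integers(0, n1))
        b = data.draw(st.integers(0, n2))
        ours = fisher_exact_two_sided(a, b, n1, n2)
        ref = scipy_fisher([[a, n1 - a], [b, n2 - b]])[1]
        assert ours == pytest.approx(ref, rel=1e-9, abs=1e-14)


class TestCountCarriers:
    def test_single_call_marks_covered_probes(self, small_map,
                                              small_samples):
        # probes 10..20 on chr1 sit at 110000..210000
        calls = [ca.CnvCall("case0000", "chr1", 110_000, 210_000, 1, 11)]
        counts = count_carriers(calls, small_map, small_samples)
        assert counts["del_case"].sum() == 11
        assert (counts["del_case"].to_numpy()[10:21] == 1).all()
        assert counts["dup_case"].sum() == 0
        assert counts["del_control"].sum() == 0

    def test_overlapping_same_sample_calls_deduplicated(self, small_map,
                                                        small_samples):
        calls = [ca.CnvCall("case0000", "chr1", 110_000, 210_000, 1, 11),
                 ca.CnvCall("case0000", "chr1", 150_000, 300_000, 0, 16)]
        counts = count_carriers(calls, small_map, small_samples)
        assert counts["del_case"].max() == 1

    def test_excluded_sample_calls_dropped(self, small_map, small_samples):
        small_samples[0].included = False
        small_samples[0].exclusion_reason = "lrr_sd"
        calls = [ca.CnvCall("case0000", "chr1", 110_000, 210_000, 1, 11)]
        counts = count_carriers(calls, small_map, small_samples)
        assert counts["del_case"].sum() == 0
        assert counts.attrs["n_cases"] == 19

    def test_unknown_sample_rejected(self, small_map, small_samples):
        calls = [ca.CnvCall("ghost", "chr1", 110_000, 210_000, 1, 11)]
        with pytest.raises(ca.ValidationError, match="ghost"):
            count_carriers(calls, small_map, small_samples)

    def test_matches_brute_force_overlap_scan(self, small_map):
        """Oracle: per-probe, per-sample any-overlap scan on a random
        call set."""
        rng = np.random.default_rng(11)
        samples = []
        for i in range(30):
            cohort = "case" if i < 15 else "control"
            samples.append(ca.SampleRecord(f"s{i:02d}", cohort, 0.99, 0.1,
                                           0.0, 0, (0.0,) * 3))
        calls = []
        for _ in range(120):
            sid = f"s{rng.integers(30):02d}"
            chrom = "chr1" if rng.random() < 0.5 else "chr2"
            i0 = int(rng.integers(0, 95))
            i1 = min(99, i0 + int(rng.integers(1, 20)))
            cn = int(rng.choice([0, 1, 3, 4]))
            calls.append(ca.CnvCall(sid, chrom, (i0 + 1) * 10_000,
                                    (i1 + 1) * 10_000, cn, i1 - i0 + 1))
        counts = count_carriers(calls, small_map, samples)
        cohort_of = {s.sample_id: s.cohort for s in samples}
        for _, row in counts.sample(40, random_state=1).iterrows():
            for typ, states in (("del", {0, 1}), ("dup", {3, 4})):
                carriers = {c.sample_id for c in calls
                            if c.copy_state in states
                            and c.chrom == row["chrom"]
                            and c.start_pos <= row["pos"] <= c.end_pos}
                a = sum(1 for s in carriers if cohort_of[s] == "case")
                b = len(carriers) - a
                assert row[f"{typ}_case"] == a
                assert row[f"{typ}_control"] == b


class TestPerProbeAssociation:
    def test_enrichment_direction_and_p(self, small_map, small_samples):
        calls = ([ca.CnvCall(f"case{i:04d}", "chr1", 110_000, 210_000, 1, 11)
                  for i in range(5)]
                 + [ca.CnvCall("ctrl0000", "chr1", 110_000, 210_000, 1, 11)])
        counts = count_carriers(calls, small_map, small_samples)
        stats = per_probe_association(counts)
        row = stats[(stats["type"] == "del") & (stats["chrom"] == "chr1")
                    & (stats["pos"] == 150_000)]
        assert row["enriched_in"].item() == "case"
        assert row["p"].item() == pytest.approx(
            fisher_exact_two_sided(5, 1, 20, 20))

    def test_no_carriers_gives_p_one_neither(self, small_map, small_samples):
        stats = per_probe_association(
            count_carriers([], small_map, small_samples))
        assert (stats["p"] == 1.0).all()
        assert (stats["enriched_in"] == "neither").all()

    def test_equal_frequencies_are_neither(self, small_map, small_samples):
        calls = [ca.CnvCall("case0000", "chr1", 110_000, 210_000, 1, 11),
                 ca.CnvCall("ctrl0000", "chr1", 110_000, 210_000, 1, 11)]
        stats = per_probe_association(
            count_carriers(calls, small_map, small_samples))
        row = stats[(stats["type"] == "del") & (stats["chrom"] == "chr1")
                    & (stats["pos"] == 150_000)]
        assert row["enriched_in"].item() == "neither"
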