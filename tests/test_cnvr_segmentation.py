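"""CNVR collapse: chaining, local minima, carrier floor, test counting."""

import numpy as np
import pandas as pd
import pytest

import cnvassoc as ca
from cnvassoc.cnvr_segmentation import (Region, collapse_cnvrs,
                                        effective_test_count)


def stats_frame(pos, p, a, b, typ="del", chrom="chr1",
                n1=1000, n2=1000) -> pd.DataFrame:
    """Build a probe-stats frame for one chromosome/type."""
    a = np.asarray(a)
    b = np.asarray(b)
    enriched = np.where(a * n2 > b * n1, "case",
                        np.where(a * n2 < b * n1, "control", "neither"))
    return pd.DataFrame({
        "probe_id": [f"{chrom}_{typ}_{i}" for i in range(len(pos))],
        "chrom": chrom, "pos": pos, "type": typ,
        "case_carriers": a, "control_carriers": b,
        "n_cases": n1, "n_controls": n2,
        "p": p, "enriched_in": enriched})


PARAMS = ca.SegmentationParams()


class TestCollapse:
    def test_large_gap_splits_chains(self):
        # 5 significant probes, a 2 Mb gap, then 4 more
        pos = [i * 10_000 for i in range(1, 6)] \
            + [2_050_000 + i * 10_000 for i in range(4)]
        stats = stats_frame(pos, [0.01] * 9, [5] * 9, [0] * 9)
        cnvrs = collapse_cnvrs(stats, PARAMS)
        assert len(cnvrs) == 2
        assert (cnvrs[0].start_pos, cnvrs[0].end_pos) == (10_000, 50_000)

    def test_gap_at_exactly_one_mb_does_not_split(self):
        stats = stats_frame([10_000, 1_010_000], [0.01, 0.01],
                            [5, 5], [0, 0])
        assert len(collapse_cnvrs(stats, PARAMS)) == 1

    def test_low_carrier_peak_dropped(self):
        stats = stats_frame([10_000, 20_000], [0.01, 0.01], [2, 2], [0, 0])
        assert collapse_cnvrs(stats, PARAMS) == []

    def test_carrier_floor_applies_to_enriched_cohort(self):
        # control-enriched chain: 7 control carriers pass the floor
        stats = stats_frame([10_000, 20_000], [0.001, 0.001],
                            [1, 1], [7, 7])
        (c,) = collapse_cnvrs(stats, PARAMS)
        assert c.direction == "control_enriched"
        assert c.enriched_carriers == 7

    def test_best_probe_is_leftmost_minimum(self):
        stats = stats_frame([10_000, 20_000, 30_000],
                            [0.02, 0.001, 0.001], [4, 6, 6], [0, 0, 0])
        (c,) = collapse_cnvrs(stats, PARAMS)
        assert c.best_pos == 20_000
        assert (c.case_carriers, c.control_carriers) == (6, 0)

    def test_directions_segment_separately(self):
        pos = [10_000, 20_000, 30_000, 40_000]
        stats = stats_frame(pos, [0.01] * 4, [5, 5, 0, 0], [0, 0, 5, 5])
        cnvrs = collapse_cnvrs(stats, PARAMS)
        assert {c.direction for c in cnvrs} == {"case_enriched",
                                                "control_enriched"}

    def test_unsorted_input_rejected(self):
        stats = stats_frame([20_000, 10_000], [0.01, 0.01], [5, 5], [0, 0])
        with pytest.raises(ca.ValidationError, match="sorted"):
            collapse_cnvrs(stats, PARAMS)

    def test_idempotent_and_chromosome_order_independent(self):
        s1 = stats_frame([10_000, 20_000], [0.01] * 2, [5] * 2, [0] * 2,
                         chrom="chr1")
        s2 = stats_frame([10_000, 20_000], [0.01] * 2, [5] * 2, [0] * 2,
                         chrom="chr2")
        ab = collapse_cnvrs(pd.concat([s1, s2], ignore_index=True), PARAMS)
        ba = collapse_cnvrs(pd.concat([s2, s1], ignore_index=True), PARAMS)
        key = lambda c: (c.chrom, c.start_pos, c.type, c.direction)
        assert sorted(map(key, ab)) == sorted(map(key, ba))


def brute_force_chains(pos, p, a, b, alpha=0.05, gap=1_000_000,
                       min_carriers=3, n1=1000, n2=1000):
    """Independent oracle: explicit scan over probes of one chrom/type."""
    out = []
    for cohort in ("case", "control"):
        sig = []
        for i in range(len(pos)):
            enr = ("case" if a[i] * n2 > b[i] * n1
                   else "control" if a[i] * n2 < b[i] * n1 else "neither")
            if p[i] < alpha and enr == cohort:
                sig.append(i)
        chain = []
        chains = []
        for i in sig:
            if chain and pos[i] - pos[chain[-1]] > gap:
                chains.append(chain)
                chain = []
            chain.append(i)
        if chain:
            chains.append(chain)
        for chain in chains:
            best = min(chain, key=lambda i: (p[i], pos[i]))
            carriers = a[best] if cohort == "case" else b[best]
            if carriers >= min_carriers:
                out.append((pos[chain[0]], pos[chain[-1]], cohort,
                            pos[best], a[best], b[best]))
    return sorted(out)


def random_vector_matches_oracle(seed, n_probes=60):
    rng = np.random.default_rng(seed)
    pos = np.cumsum(rng.choice([10_000, 400_000, 1_500_000], n_probes,
                               p=[0.7, 0.2, 0.1]))
    p = rng.random(n_probes) ** 2          # enrich small p
    a = rng.integers(0, 9, n_probes)
    b = rng.integers(0, 9, n_probes)
    neq = a == b
    b[neq] = 0                              # avoid "neither" ties mostly
    stats = stats_frame(pos, p, a, b)
    got = sorted((c.start_pos, c.end_pos,
                  "case" if c.direction == "case_enriched" else "control",
                  c.best_pos, c.case_carriers, c.control_carriers)
                 for c in collapse_cnvrs(stats, PARAMS))
    return got == brute_force_chains(pos, p, a, b)


def test_collapse_matches_brute_force_on_random_vectors():
    assert all(random_vector_matches_oracle(s) for s in range(100))


class TestEffectiveTestCount:
    def r(self, chrom, s, e):
        return Region(chrom, s, e)

    def test_disjoint_counts_add(self):
        dels = [self.r("chr1", 1, 10), self.r("chr1", 100, 110),
                self.r("chr2", 1, 10)]
        dups = [self.r("chr3", 1, 10), self.r("chr3", 100, 110)]
        assert effective_test_count(dels, dups) == 5

    def test_zero_regions(self):
        assert effective_test_count([], []) == 0

    def test_overlapping_del_dup_merged(self):
        """101 deletion + 76 duplication regions with 6 overlapping
        del/dup pairs collapse to 171 distinct tests."""
        dels = [self.r("chr1", i * 1000, i * 1000 + 100)
                for i in range(101)]
        dups = [self.r("chr2", i * 1000, i * 1000 + 100)
                for i in range(70)]
        dups += [self.r("chr1", i * 1000 + 50, i * 1000 + 150)
                 for i in range(6)]        # overlap the first 6 deletions
        assert effective_test_count(dels, dups) == 171

    def test_every_significant_probe_in_exactly_one_cnvr(self):
        rng = np.random.default_rng(5)
        pos = np.cumsum(rng.choice([10_000, 1_500_000], 80, p=[0.85, 0.15]))
        p = rng.random(80) ** 2
        a = rng.integers(3, 9, 80)
        stats = stats_frame(pos, p, a, np.zeros(80, dtype=int))
        cnvrs = collapse_cnvrs(stats, PARAMS)
        sig_pos = stats.loc[(stats["p"] < 0.05)
                            & (stats["enriched_in"] == "case"), "pos"]
        for x in sig_pos:
            covering = [c for c in cnvrs
                        if c.start_pos <= x <= c.end_pos]
            assert len(covering) == 1
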