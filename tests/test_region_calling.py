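"""Region calling: run extraction, resistance rule, consensus intersection,
coverage-depth sharing, annotation overlap — all against brute-force per-bp
oracles on toys."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from introscan.ancestry_hmm import AncestryTrack
from introscan.region_calling import (
    GenomicRegion,
    call_regions,
    call_resistant,
    consensus_regions,
    overlap_annotations,
    shared_across_populations,
    total_bp,
)


def make_track(values, bp=None, chrom="chr1", population="p0", method="hmm",
               chrom_lengths=None):
    values = np.asarray(values, dtype=float)
    n = len(values)
    bp = np.asarray(bp) if bp is not None else (np.arange(n) + 1) * 1000
    sites = pd.DataFrame(
        {
            "chrom": [chrom] * n,
            "bp": bp,
            "cM": bp / 1e6,
            "ref": ["A"] * n,
            "alt": ["G"] * n,
        }
    )
    return AncestryTrack(
        sites=sites,
        dosage=2 * values[:, None],
        mean=values,
        individuals=["i0"],
        population=population,
        direction="mexicana",
        method=method,
        chrom_lengths=chrom_lengths,
    )


def coverage_oracle(regions, lo, hi):
    """Per-bp boolean coverage of [lo, hi) by a region list."""
    cov = np.zeros(hi - lo, dtype=int)
    for r in regions:
        s, e = max(r.start, lo), min(r.end, hi)
        if s < e:
            cov[s - lo : e - lo] += 1
    return cov


class TestCallRegions:
    def test_whole_chromosome_above_threshold(self):
        track = make_track([0.6] * 5, chrom_lengths={"chr1": 10_000})
        regions = call_regions(track, 0.5)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (0, 10_000)
        assert regions[0].mean_signal == pytest.approx(0.6)

    def test_hand_track_single_region(self):
        # markers at 1..5 kb; only the run at markers 2-3 (0.6, 0.7) survives
        # min_sites=2; bounds at midpoints to flanking markers
        track = make_track([0.1, 0.6, 0.7, 0.2, 0.55])
        regions = call_regions(track, 0.5, min_sites=2)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end) == ((1000 + 2000) // 2, (3000 + 4000) // 2)
        assert r.mean_signal == pytest.approx(0.65)

    def test_min_sites_suppresses_singletons(self):
        track = make_track([0.1, 0.9, 0.1, 0.9, 0.9, 0.1])
        regions = call_regions(track, 0.5, min_sites=2)
        assert len(regions) == 1 and regions[0].mean_signal == pytest.approx(0.9)

    def test_empty_track(self):
        track = make_track([])
        assert call_regions(track, 0.5) == []

    def test_regions_never_overlap_and_threshold_monotone(self):
        rng = np.random.default_rng(52)
        track = make_track(rng.random(200))
        prev_bp = None
        for thr in (0.3, 0.5, 0.7, 0.9):
            regions = call_regions(track, thr, min_sites=2)
            starts = [r.start for r in regions]
            ends = [r.end for r in regions]
            assert all(e0 <= s1 for e0, s1 in zip(ends, starts[1:]))
            bp = total_bp(regions)
            if prev_bp is not None:
                assert bp <= prev_bp
            prev_bp = bp

    def test_nan_counts_as_subthreshold(self):
        track = make_track([0.9, np.nan, 0.9, 0.9])
        regions = call_regions(track, 0.5, min_sites=2)
        assert len(regions) == 1
        assert regions[0].mean_signal == pytest.approx(0.9)


class TestCallResistant:
    def _tracks(self, per_pop_values, methods=("hmm", "freq")):
        out = {}
        for pop, vals in per_pop_values.items():
            out[pop] = {
                m: make_track(vals, population=pop, method=m) for m in methods
            }
        return out

    def test_all_zero_whole_genome_resistant(self):
        tracks = self._tracks({f"p{i}": [0.0] * 4 for i in range(3)})
        regions = call_resistant(tracks, 0.05, k=3, chrom_lengths={"chr1": 5000})
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (0, 5000)
        assert regions[0].support == 3

    def test_one_high_population_blocks_k_equals_n(self):
        vals = {f"p{i}": [0.0] * 4 for i in range(2)}
        vals["p2"] = [0.5] * 4
        regions = call_resistant(self._tracks(vals), 0.05, k=3)
        assert regions == []

    def test_k_exceeding_populations_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            call_resistant(self._tracks({"p0": [0.0]}), k=2)

    def test_both_methods_required(self):
        vals = [0.0, 0.0, 0.0]
        tracks = {
            "p0": {"hmm": make_track(vals), "freq": make_track([0.3, 0.3, 0.3])},
            "p1": {"hmm": make_track(vals), "freq": make_track(vals)},
        }
        regions = call_resistant(tracks, 0.05, k=2)
        assert regions == []  # p0's frequency scan is not below threshold

    def test_supporting_populations_confirmed_region_wide(self):
        vals = {
            "p0": [0.0, 0.0, 0.0, 0.0],
            "p1": [0.0, 0.0, 0.0, 0.0],
            "p2": [0.0, 0.0, 0.2, 0.0],  # dips out mid-region
        }
        regions = call_resistant(self._tracks(vals), 0.05, k=2)
        assert regions
        for r in regions:
            assert "p2" not in r.populations_supporting or r.end <= 2500


class TestConsensus:
    def test_idempotent_on_identical_lists(self):
        regs = [GenomicRegion("chr1", 0, 100), GenomicRegion("chr1", 200, 300)]
        out = consensus_regions(regs, regs)
        assert [(r.start, r.end) for r in out] == [(0, 100), (200, 300)]
        assert all(r.method == "consensus" for r in out)

    def test_disjoint_lists_empty(self):
        a = [GenomicRegion("chr1", 0, 100)]
        b = [GenomicRegion("chr1", 100, 200)]  # half-open: touching, no overlap
        assert consensus_regions(a, b) == []

    def test_matches_per_bp_intersection_oracle(self):
        rng = np.random.default_rng(53)

        def random_regions(seed):
            rng = np.random.default_rng(seed)
            regs, pos = [], 0
            while pos < 900:
                start = pos + int(rng.integers(1, 60))
                end = start + int(rng.integers(1, 80))
                if end > 1000:
                    break
                regs.append(GenomicRegion("chr1", start, end))
                pos = end
            return regs

        a, b = random_regions(1), random_regions(2)
        out = consensus_regions(a, b)
        cov = (coverage_oracle(a, 0, 1000) > 0) & (coverage_oracle(b, 0, 1000) > 0)
        np.testing.assert_array_equal(coverage_oracle(out, 0, 1000) > 0, cov)
        # consensus is contained in each input's coverage
        out_cov = coverage_oracle(out, 0, 1000) > 0
        assert np.all(out_cov <= (coverage_oracle(a, 0, 1000) > 0))


class TestSharedAcrossPopulations:
    def test_region_in_all_populations(self):
        regs = {f"p{i}": [GenomicRegion("chr1", 100, 200)] for i in range(9)}
        out = shared_across_populations(regs, k=7)
        assert len(out) == 1
        assert (out[0].start, out[0].end, out[0].support) == (100, 200, 9)

    def test_insufficient_support_not_returned(self):
        regs = {f"p{i}": [GenomicRegion("chr1", 100, 200)] for i in range(6)}
        regs.update({f"q{i}": [] for i in range(3)})
        assert shared_across_populations(regs, k=7) == []

    def test_matches_per_bp_depth_oracle(self):
        rng = np.random.default_rng(54)
        regs = {}
        for i in range(5):
            pop_regs = []
            for _ in range(rng.integers(1, 4)):
                s = int(rng.integers(0, 900))
                e = s + int(rng.integers(10, 100))
                pop_regs.append(GenomicRegion("chr1", s, min(e, 1000)))
            regs[f"p{i}"] = pop_regs
        for k in (1, 2, 3, 5):
            out = shared_across_populations(regs, k=k)
            depth = np.zeros(1000, dtype=int)
            for pop_regs in regs.values():
                depth += coverage_oracle(pop_regs, 0, 1000) > 0
            np.testing.assert_array_equal(
                coverage_oracle(out, 0, 1000) > 0, depth >= k
            )

    def test_k1_union_kn_intersection(self):
        regs = {
            "p0": [GenomicRegion("chr1", 0, 50)],
            "p1": [GenomicRegion("chr1", 30, 80)],
        }
        union = shared_across_populations(regs, k=1)
        inter = shared_across_populations(regs, k=2)
        assert [(r.start, r.end) for r in union] == [(0, 80)]
        assert [(r.start, r.end) for r in inter] == [(30, 50)]


class TestOverlapAnnotations:
    def test_containment_touching_and_oracle(self):
        regions = [GenomicRegion("chr1", 0, 10), GenomicRegion("chr1", 10, 20)]
        annots = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr2"],
                "start": [2, 10, 0],
                "end": [5, 20, 100],
                "name": ["inside", "touching_second", "other_chrom"],
            }
        )
        table, summary = overlap_annotations(regions, annots)
        # containment: full annotation length; half-open touching: no overlap
        # with region 1, full with region 2
        got = {(row.annotation, row.region_start): row.overlap_bp
               for row in table.itertuples()}
        assert got[("inside", 0)] == 3
        assert ("touching_second", 0) not in got
        assert got[("touching_second", 10)] == 10
        assert summary["n_regions_with_overlap"] == 2
        assert summary["n_annotations_hit"] == 2

    def test_random_toys_match_bruteforce(self):
        rng = np.random.default_rng(55)
        regions = [
            GenomicRegion("chr1", int(s), int(s) + int(l))
            for s, l in zip(rng.integers(0, 500, 8), rng.integers(5, 50, 8))
        ]
        annots = pd.DataFrame(
            {
                "chrom": ["chr1"] * 10,
                "start": rng.integers(0, 500, 10),
            }
        )
        annots["end"] = annots["start"] + rng.integers(1, 60, 10)
        annots["name"] = [f"g{i}" for i in range(10)]
        table, _ = overlap_annotations(regions, annots)
        expected = []
        for r in regions:
            for row in annots.itertuples():
                ov = min(r.end, row.end) - max(r.start, row.start)
                if ov > 0:
                    expected.append((r.start, row.name, ov))
        got = [(row.region_start, row.annotation, row.overlap_bp)
               for row in table.itertuples()]
        assert sorted(got) == sorted(expected)
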