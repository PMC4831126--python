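"""Region definition: read filtering, peak calling, merging, counting, RPM."""

import numpy as np
import pandas as pd
import pytest

from mbdmeth import (
    GenomicInterval,
    RegionCountMatrix,
    call_regions,
    count_matrix,
    default_config,
    filter_reads,
    merge_region_sets,
    rpm_filter,
    simulate_capture_reads,
    simulate_genome,
)
from mbdmeth.pipeline import match_to_truth


def make_reads(rows):
    """rows: (chrom, start, end, mapq, strand, sample)"""
    return pd.DataFrame(
        [(c, s, e, f"r{i}", q, st, sm) for i, (c, s, e, q, st, sm) in enumerate(rows)],
        columns=["chrom", "start", "end", "name", "mapq", "strand", "sample"],
    )


class TestGenomicInterval:
    def test_validation(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 5)

    def test_overlap_arithmetic(self):
        a = GenomicInterval("c", 100, 300)
        assert a.overlap_len(GenomicInterval("c", 200, 400)) == 100
        assert a.overlap_len(GenomicInterval("c", 300, 400)) == 0
        assert a.overlap_len(GenomicInterval("d", 100, 300)) == 0
        assert len(a) == 200


class TestFilterReads:
    def test_mapq_threshold_is_inclusive_at_37(self):
        reads = make_reads([("c", 0, 36, 36, "+", "s"),
                            ("c", 50, 86, 37, "+", "s"),
                            ("c", 100, 136, 60, "+", "s")])
        out = filter_reads(reads)
        assert list(out["mapq"]) == [37, 60]

    def test_duplicates_collapse_to_one(self):
        reads = make_reads([("c", 10, 46, 40, "+", "s")] * 5)
        assert len(filter_reads(reads)) == 1

    def test_opposite_strands_are_not_duplicates(self):
        reads = make_reads([("c", 10, 46, 40, "+", "s"),
                            ("c", 10, 46, 40, "-", "s")])
        assert len(filter_reads(reads)) == 2

    def test_matches_bruteforce_grouping(self, rng):
        """Dedup key is (sample, chrom, 5' start, strand) — first read wins."""
        for _ in range(50):
            n = int(rng.integers(1, 40))
            starts = rng.integers(0, 20, n)
            strands = rng.choice(["+", "-"], n)
            samples = rng.choice(["a", "b"], n)
            reads = make_reads([
                ("c", int(s), int(s) + 36, 40, st, sm)
                for s, st, sm in zip(starts, strands, samples)
            ])
            seen, expect = set(), []
            for _, row in reads.iterrows():
                fp = row["start"] if row["strand"] == "+" else row["end"] - 1
                key = (row["sample"], row["chrom"], fp, row["strand"])
                if key not in seen:
                    seen.add(key)
                    expect.append(row["name"])
            assert list(filter_reads(reads)["name"]) == expect

    def test_empty_in_empty_out(self):
        assert filter_reads(make_reads([])).empty


class TestCallRegions:
    def test_uniform_background_yields_almost_no_regions(self):
        """Per-window false positives at p<1e-8 are rare: <=1 region/run."""
        for seed in range(20):
            r = np.random.default_rng(seed)
            n = 100_000
            starts = r.integers(0, 5_000_000 - 36, n)
            reads = pd.DataFrame({
                "chrom": r.choice(["c1", "c2"], n), "start": starts,
                "end": starts + 36, "name": "x", "mapq": 40,
                "strand": r.choice(["+", "-"], n), "sample": "s",
            })
            called = call_regions(reads, {"c1": 5_000_000, "c2": 5_000_000})
            assert len(called) <= 1

    def test_enriched_region_recovered_with_high_overlap(self):
        cfg = default_config(seed=7, n_regions=20, depth_per_sample=20_000,
                            background_fraction=0.3)
        genome, truth = simulate_genome(cfg)
        reads = simulate_capture_reads(genome, truth, cfg)
        sub = filter_reads(reads)
        sub = sub[sub["sample"] == "C1"]
        called = call_regions(sub, {c: len(s) for c, s in genome.items()})
        # every truth region with decent coverage should be recovered
        recovered = 0
        for t in truth.regions:
            hit = any(c.overlap_len(t) >= 0.8 * len(t) for c in called)
            recovered += hit
        assert recovered >= 0.95 * len(truth.regions)

    def test_rejects_bad_genome_size(self):
        reads = make_reads([("c", 0, 36, 40, "+", "s")])
        with pytest.raises(ValueError):
            call_regions(reads, {"c": 0})


class TestMerge:
    def test_exactly_half_overlap_not_merged(self):
        out = merge_region_sets([[GenomicInterval("c", 100, 300)],
                                 [GenomicInterval("c", 200, 400)]])
        assert len(out) == 2  # overlap 100 = 50% of shorter, rule is strict >

    def test_identical_regions_merge(self):
        r = GenomicInterval("c", 10, 500)
        assert merge_region_sets([[r], [r]]) == [r]

    def test_short_contained_region_merges_into_long(self):
        out = merge_region_sets([[GenomicInterval("c", 0, 1000)],
                                 [GenomicInterval("c", 900, 960)]])
        assert out == [GenomicInterval("c", 0, 1000)]

    def test_idempotent_and_order_invariant(self, rng):
        for _ in range(30):
            sets = []
            for _s in range(3):
                starts = np.sort(rng.integers(0, 5000, rng.integers(1, 10)))
                sets.append([GenomicInterval("c", int(s), int(s) + int(rng.integers(50, 400)))
                             for s in starts])
            merged = merge_region_sets(sets)
            assert merge_region_sets([merged]) == merged
            assert merge_region_sets(reversed(sets)) == merged


class TestCountMatrix:
    def test_single_read_inside_region(self):
        reads = make_reads([("c", 500, 536, 40, "+", "s")])
        m = count_matrix([GenomicInterval("c", 400, 900)], reads)
        assert m.counts[0, 0] == 1

    def test_no_reads_in_regions_all_zero(self):
        reads = make_reads([("c", 5000, 5036, 40, "+", "s")])
        m = count_matrix([GenomicInterval("c", 0, 100)], reads)
        assert m.counts.sum() == 0
        assert m.library_sizes[0] == 1

    def test_matches_bruteforce_overlap(self, rng):
        for _ in range(30):
            rows = []
            for i in range(20):
                s = int(rng.integers(0, 3000))
                rows.append(("c", s, s + 36, 40,
                             str(rng.choice(["+", "-"])), str(rng.choice(["a", "b"]))))
            reads = make_reads(rows)
            regions = []
            for _j in range(3):
                s = int(rng.integers(0, 3000))
                regions.append(GenomicInterval("c", s, s + int(rng.integers(100, 600))))
            m = count_matrix(regions, reads, samples=["a", "b"])
            for ri, r in enumerate(regions):
                for si, sample in enumerate(["a", "b"]):
                    n = 0
                    for (_, st, en, _q, strand, sm) in rows:
                        if sm != sample:
                            continue
                        fs = st if strand == "+" else en - 250
                        if fs < r.end and fs + 250 > r.start:
                            n += 1
                    assert m.counts[ri, si] == n

    def test_unknown_sample_rejected(self):
        reads = make_reads([("c", 0, 36, 40, "+", "mystery")])
        with pytest.raises(ValueError):
            count_matrix([GenomicInterval("c", 0, 100)], reads, samples=["a"])


class TestRpmFilter:
    def test_boundary_rpm_20_is_kept(self):
        m = RegionCountMatrix([GenomicInterval("c", 0, 100)], ["a", "b"],
                              np.array([[20, 0]]), np.array([1_000_000, 1_000_000]))
        assert len(rpm_filter(m).regions) == 1

    def test_below_floor_everywhere_removed(self):
        m = RegionCountMatrix([GenomicInterval("c", 0, 100)], ["a", "b"],
                              np.array([[19, 19]]), np.array([1_000_000, 1_000_000]))
        assert len(rpm_filter(m).regions) == 0

    def test_small_library_scales_rpm(self):
        # 5 reads in a 200k library is 25 RPM — retained regardless of others
        m = RegionCountMatrix([GenomicInterval("c", 0, 100)], ["a", "b"],
                              np.array([[5, 0]]), np.array([200_000, 1_000_000]))
        out = rpm_filter(m)
        assert len(out.regions) == 1
        assert out.rpm()[0, 0] == pytest.approx(25.0)

    def test_output_regions_subset_of_input(self, rng):
        counts = rng.integers(0, 40, size=(30, 3))
        m = RegionCountMatrix(
            [GenomicInterval("c", i * 1000, i * 1000 + 500) for i in range(30)],
            ["a", "b", "c"], counts, np.array([1e6, 5e5, 2e6]))
        out = rpm_filter(m)
        assert set(out.regions) <= set(m.regions)
        kept = set(out.regions)
        for r, row_rpm in zip(m.regions, m.rpm()):
            if (row_rpm >= 20).any():
                assert r in kept
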