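"""Demultiplexing, conversion-aware alignment, methylation summaries,
and capture-vs-bisulfite concordance."""

import numpy as np
import pandas as pd
import pytest

from mbdmeth import (
    AmpliconSpec,
    bisulfite_align,
    concordance,
    demultiplex,
    quantify_sample,
    simulate_bisulfite_reads,
    summarize_amplicon,
)
from mbdmeth.simulate import cpg_positions, revcomp

# the study's inline 6-mer indexes
INDEXES = ["ACCAAT", "AGAGAT", "AGTCAT", "CAGTCT", "CCGGCT",
           "CGATCT", "CGTACT", "GAGAGT", "GCCGGT"]

AMP = ("ATTCGAGCTACGTTAGGACGATCCGTTAACGTAGCTTAGCGATACCGGTATCGATTGCA"
       "CGTAGTTACGGATCTTACGAGTCAATCGGTAC")


def converted(seq, methylated_positions=()):
    cpgs = set(cpg_positions(seq))
    out = []
    for i, b in enumerate(seq):
        if b == "C" and i not in methylated_positions:
            out.append("T")
        else:
            out.append(b)
    return "".join(out)


class TestDemultiplex:
    TABLE = {f"S{i}": idx for i, idx in enumerate(INDEXES)}

    def test_exact_prefix_match_strips_index(self):
        reads = [("r1", "ACCAAT" + "TTTGGA" * 5)]
        assigned, unassigned = demultiplex(reads, {"P1": "ACCAAT"})
        assert assigned["P1"] == [("r1", "TTTGGA" * 5)]
        assert unassigned == []

    def test_unknown_prefix_goes_to_unassigned(self):
        reads = [("r1", "TTTTTT" + "ACGT" * 8)]
        assigned, unassigned = demultiplex(reads, self.TABLE)
        assert sum(len(v) for v in assigned.values()) == 0
        assert len(unassigned) == 1

    def test_partition_conservation(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 30))
            reads = []
            for i in range(n):
                prefix = str(rng.choice(INDEXES + ["TTTTTT", "AAAAAA"]))
                body = "".join(rng.choice(list("ACGT"), size=30))
                reads.append((f"r{i}", prefix + body))
            assigned, unassigned = demultiplex(reads, self.TABLE)
            # conservation, and each read routed to the right bucket
            assert sum(len(v) for v in assigned.values()) + len(unassigned) == n
            for sample, got in assigned.items():
                idx = self.TABLE[sample]
                expect = [(name, seq[6:]) for name, seq in reads
                          if seq.startswith(idx)]
                assert got == expect

    def test_ambiguous_truncated_table_refused(self):
        with pytest.raises(ValueError):
            demultiplex([], {"a": "ACCAAT", "b": "ACCAGG"}, index_len=4)

    def test_study_indexes_unique_at_six_but_not_five(self):
        table = {f"S{i}": idx for i, idx in enumerate(INDEXES)}
        demultiplex([], table, index_len=6)  # fine
        prefixes5 = [i[:5] for i in INDEXES]
        assert len(set(prefixes5)) == len(prefixes5)  # these 9 happen to be
        # unique at 5 too; ambiguity check still guards arbitrary tables


class TestBisulfiteAlign:
    SPEC = AmpliconSpec("amp", AMP)

    def test_unconverted_read_fully_methylated(self):
        read = converted(AMP, methylated_positions=set(cpg_positions(AMP)))
        aln = bisulfite_align(read, self.SPEC)
        assert aln is not None
        assert aln.offset == 0 and aln.strand == "+"
        assert aln.cpg_calls == {p: True for p in cpg_positions(AMP)}

    def test_fully_converted_read_zero_mismatches(self):
        read = converted(AMP)
        aln = bisulfite_align(read, self.SPEC)
        assert aln is not None
        assert aln.n_mismatch == 0
        assert set(aln.cpg_calls.values()) == {False}

    def test_reverse_complement_read_aligns(self):
        read = revcomp(converted(AMP)[10:50])
        aln = bisulfite_align(read, self.SPEC)
        assert aln is not None
        assert aln.strand == "-"
        assert aln.offset == 10

    def test_garbage_read_rejected(self):
        assert bisulfite_align("G" * 40, self.SPEC) is None

    def test_short_read_rejected(self):
        assert bisulfite_align("ACGTACGTAC", self.SPEC) is None

    def test_placement_matches_bruteforce_all_offsets(self, rng):
        """Best placement equals an exhaustive scan over offsets/strands."""
        conv = converted(AMP, methylated_positions={cpg_positions(AMP)[1]})
        for _ in range(200):
            off = int(rng.integers(0, len(AMP) - 30))
            frag = conv[off:off + 30]
            if rng.random() < 0.5:
                frag = revcomp(frag)
            # inject up to 2 errors
            frag = list(frag)
            for e in rng.integers(0, 30, size=int(rng.integers(0, 3))):
                frag[e] = str(rng.choice([b for b in "ACGT" if b != frag[e]]))
            frag = "".join(frag)
            aln = bisulfite_align(frag, self.SPEC)

            def mism(q, o):
                return sum(
                    1 for j, b in enumerate(q)
                    if b != AMP[o + j] and not (AMP[o + j] == "C" and b == "T")
                )
            best = min(
                (mism(q, o), rank, o)
                for rank, q in enumerate([frag, revcomp(frag)])
                for o in range(len(AMP) - 30 + 1)
            )
            if best[0] > 3:  # 0.1 * 30
                assert aln is None
            else:
                assert aln is not None
                assert (aln.n_mismatch, 0 if aln.strand == "+" else 1,
                        aln.offset) == best


class TestSummarize:
    def test_overall_is_unweighted_mean(self):
        out = summarize_amplicon({3: (2, 8), 10: (8, 2)}, "s", "amp", min_cov=10)
        assert out.per_cpg[3][2] == pytest.approx(0.2)
        assert out.per_cpg[10][2] == pytest.approx(0.8)
        assert out.overall == pytest.approx(0.5)

    def test_all_methylated(self):
        out = summarize_amplicon({0: (20, 0), 5: (15, 0)}, "s", "amp")
        assert out.overall == pytest.approx(1.0)

    def test_low_coverage_cpgs_excluded_and_reported(self):
        out = summarize_amplicon({0: (20, 0), 5: (1, 1)}, "s", "amp", min_cov=10)
        assert out.low_coverage_cpgs == [5]
        assert out.overall == pytest.approx(1.0)

    def test_no_covered_cpg_flagged(self):
        out = summarize_amplicon({0: (1, 0)}, "s", "amp", min_cov=10)
        assert out.overall is None

    def test_matches_bruteforce_tally(self, rng):
        for _ in range(200):
            tallies = {int(p): (int(rng.integers(0, 30)), int(rng.integers(0, 30)))
                       for p in rng.choice(100, size=5, replace=False)}
            out = summarize_amplicon(tallies, "s", "amp", min_cov=10)
            fracs = []
            for p, (m, u) in tallies.items():
                if m + u > 0:
                    assert out.per_cpg[p][2] == pytest.approx(m / (m + u))
                if m + u >= 10:
                    fracs.append(m / (m + u))
            if fracs:
                assert out.overall == pytest.approx(float(np.mean(fracs)))
            else:
                assert out.overall is None


def test_simulated_methylation_recovered_through_alignment():
    probs = {p: 0.3 for p in cpg_positions(AMP)}
    reads = simulate_bisulfite_reads(AMP, probs, 1000, "ACCAAT", seed=4,
                                     error_rate=0.001, read_length=42)
    assigned, unassigned = demultiplex(reads, {"P1": "ACCAAT"})
    assert not unassigned
    summary, rejected = quantify_sample(assigned["P1"], AmpliconSpec("amp", AMP),
                                        "P1")
    assert rejected < 20
    for p, (m, u, frac) in summary.per_cpg.items():
        n = m + u
        if n >= 100:
            assert abs(frac - 0.3) <= 3 * np.sqrt(0.3 * 0.7 / n)


class TestConcordance:
    def frames(self, values):
        rows_bs, rows_mbd = [], []
        for (sample, locus), (bs, rpm) in values.items():
            rows_bs.append({"sample": sample, "locus": locus, "overall": bs})
            rows_mbd.append({"sample": sample, "locus": locus, "rpm": rpm})
        return pd.DataFrame(rows_bs), pd.DataFrame(rows_mbd)

    def test_identical_to_controls_gives_zero_ratios_and_flag(self):
        bs, mbd = self.frames({
            ("C1", "L1"): (0.5, 30), ("C2", "L1"): (0.5, 30),
            ("P1", "L1"): (0.5, 30),
            ("C1", "L2"): (0.8, 60), ("C2", "L2"): (0.8, 60),
            ("P1", "L2"): (0.8, 60),
        })
        paired, r = concordance(bs, mbd, ["C1", "C2"])
        assert np.allclose(paired["bs_log2"], 0)
        assert np.allclose(paired["mbd_log2"], 0)
        assert r is None  # degenerate: correlation undefined, flagged

    def test_halved_methylation_gives_minus_one_on_both_axes(self):
        bs, mbd = self.frames({
            ("C1", "L1"): (0.8, 80), ("C2", "L1"): (0.8, 80),
            ("P1", "L1"): (0.4, 40),
            ("C1", "L2"): (0.6, 50), ("C2", "L2"): (0.6, 50),
            ("P1", "L2"): (0.6, 50),
        })
        paired, r = concordance(bs, mbd, ["C1", "C2"])
        row = paired[paired["locus"] == "L1"].iloc[0]
        assert row["bs_log2"] == pytest.approx(-1.0, abs=0.05)
        assert row["mbd_log2"] == pytest.approx(-1.0, abs=0.05)

    def test_missing_pairing_rejected(self):
        bs, mbd = self.frames({("C1", "L1"): (0.5, 30), ("P1", "L1"): (0.4, 20)})
        mbd = mbd[mbd["sample"] != "P1"]
        with pytest.raises(ValueError):
            concordance(bs, mbd, ["C1"])
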