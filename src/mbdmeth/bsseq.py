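"""Bisulfite-amplicon validation arm.

Reads carry an inline sample index at their 5' end; after demultiplexing
they are aligned, conversion-aware and ungapped, to short amplicon
references.  At each covered CpG a retained C calls methylated and a T
calls unmethylated; per-CpG fractions are averaged into a per-amplicon
level, and patient-vs-control log2 ratios from this assay are compared
with the capture-based (RPM) ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import cpg_positions, revcomp

MIN_COVERAGE = 10
LOG2_EPSILON = 0.01


@dataclass
class AmpliconSpec:
    """One bisulfite PCR product: name, reference, CpG positions."""

    name: str
    sequence: str
    cpg_positions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.cpg_positions:
            self.cpg_positions = cpg_positions(self.sequence)
        for p in self.cpg_positions:
            if self.sequence[p:p + 2] != "CG":
                raise ValueError(f"position {p} of {self.name} is not a CpG")


@dataclass
class AmpliconMethylation:
    """Per-CpG and overall methylation for one (sample, amplicon)."""

    sample_id: str
    amplicon: str
    per_cpg: dict[int, tuple[int, int, float]]  # pos -> (n_meth, n_unmeth, fraction)
    overall: float | None  # None when no CpG reaches min coverage
    low_coverage_cpgs: list[int]


def demultiplex(
    reads: Iterable[tuple[str, str]],
    index_table: Mapping[str, str],
    index_len: int | None = None,
) -> tuple[dict[str, list[tuple[str, str]]], list[tuple[str, str]]]:
    """Assign reads to samples by exact prefix match on the inline index.

    ``index_len`` defaults to the full index length; truncated prefixes
    must stay pairwise distinct or the table is refused.  Matched
    prefixes are stripped.  Returns (per-sample reads, unassigned).
    """
    if index_len is None:
        lens = {len(v) for v in index_table.values()}
        if len(lens) != 1:
            raise ValueError("indexes have unequal lengths; pass index_len")
        index_len = lens.pop()
    prefix_to_sample: dict[str, str] = {}
    for sample, idx in index_table.items():
        prefix = idx[:index_len].upper()
        if prefix in prefix_to_sample:
            raise ValueError(
                f"ambiguous index table: prefix {prefix!r} maps to both "
                f"{prefix_to_sample[prefix]!r} and {sample!r}"
            )
        prefix_to_sample[prefix] = sample
    assigned: dict[str, list[tuple[str, str]]] = {s: [] for s in index_table}
    unassigned: list[tuple[str, str]] = []
    for name, seq in reads:
        sample = prefix_to_sample.get(seq[:index_len].upper())
        if sample is None:
            unassigned.append((name, seq))
        else:
            assigned[sample].append((name, seq[index_len:]))
    return assigned, unassigned


@dataclass
class BisulfiteAlignment:
    offset: int
    strand: str  # '+' read matches the converted reference, '-' its revcomp
    n_mismatch: int
    cpg_calls: dict[int, bool]  # reference CpG position -> methylated


def bisulfite_align(
    read: str,
    amplicon: AmpliconSpec,
    max_mismatch_frac: float = 0.1,
    min_read_len: int = 20,
) -> BisulfiteAlignment | None:
    """Conversion-aware ungapped placement of one read on one amplicon.

    The read (or its reverse complement) is compared at every offset
    against the reference; positions where the reference has C and the
    read T are conversion events, not mismatches.  The best placement
    under the mismatch budget wins (ties: fewer mismatches, then + before
    -, then smaller offset).  At each covered CpG, C calls methylated and
    T unmethylated; any other base gives no call.  Returns None when no
    placement is acceptable.
    """
    read = read.upper()
    if len(read) < min_read_len:
        return None
    ref = np.frombuffer(amplicon.sequence.encode(), dtype="S1")
    n_off = len(amplicon.sequence) - len(read) + 1
    if n_off < 1:
        return None
    ref_c = ref == b"C"
    windows = np.lib.stride_tricks.sliding_window_view(ref, len(read))
    ref_c_win = np.lib.stride_tricks.sliding_window_view(ref_c, len(read))

    best: tuple[int, int, int] | None = None  # (mismatches, strand_rank, offset)
    best_seq = ""
    for rank, seq in enumerate((read, revcomp(read))):
        q = np.frombuffer(seq.encode(), dtype="S1")
        mism = ((windows != q) & ~(ref_c_win & (q == b"T"))).sum(axis=1)
        o = int(np.argmin(mism))
        cand = (int(mism[o]), rank, o)
        if best is None or cand < best:
            best = cand
            best_seq = seq
    assert best is not None
    n_mism, rank, offset = best
    if n_mism > max_mismatch_frac * len(read):
        return None
    calls: dict[int, bool] = {}
    for p in amplicon.cpg_positions:
        if offset <= p < offset + len(read):
            base = best_seq[p - offset]
            if base == "C":
                calls[p] = True
            elif base == "T":
                calls[p] = False
    return BisulfiteAlignment(offset, "+" if rank == 0 else "-", n_mism, calls)


def quantify_sample(
    reads: Iterable[tuple[str, str]],
    amplicon: AmpliconSpec,
    sample_id: str,
    max_mismatch_frac: float = 0.1,
    min_cov: int = MIN_COVERAGE,
) -> tuple[AmpliconMethylation, int]:
    """Align a sample's reads to one amplicon and summarize.

    Returns the methylation summary and the number of rejected reads.
    """
    tallies: dict[int, list[int]] = {p: [0, 0] for p in amplicon.cpg_positions}
    rejected = 0
    for _, seq in reads:
        aln = bisulfite_align(seq, amplicon, max_mismatch_frac)
        if aln is None:
            rejected += 1
            continue
        for pos, methylated in aln.cpg_calls.items():
            tallies[pos][0 if methylated else 1] += 1
    return summarize_amplicon(tallies, sample_id, amplicon.name, min_cov), rejected


def summarize_amplicon(
    tallies: Mapping[int, Sequence[int]],
    sample_id: str,
    amplicon_name: str,
    min_cov: int = MIN_COVERAGE,
) -> AmpliconMethylation:
    """Per-CpG methylated fractions and their unweighted mean.

    ``tallies`` maps CpG position to (n_methylated, n_unmethylated).
    CpGs with coverage below ``min_cov`` are excluded from the overall
    mean and reported; with no covered CpG the overall level is None.
    """
    per_cpg: dict[int, tuple[int, int, float]] = {}
    fractions = []
    low = []
    for pos in sorted(tallies):
        m, u = int(tallies[pos][0]), int(tallies[pos][1])
        frac = m / (m + u) if (m + u) > 0 else float("nan")
        per_cpg[pos] = (m, u, frac)
        if m + u >= min_cov:
            fractions.append(frac)
        else:
            low.append(pos)
    overall = float(np.mean(fractions)) if fractions else None
    return AmpliconMethylation(sample_id, amplicon_name, per_cpg, overall, low)


def concordance(
    bs_levels: pd.DataFrame,
    mbd_rpm: pd.DataFrame,
    control_ids: Sequence[str],
    epsilon: float = LOG2_EPSILON,
) -> tuple[pd.DataFrame, float | None]:
    """Pair bisulfite and capture log2 ratios versus controls per
    (individual, locus) and report their Pearson correlation.

    Both frames need columns sample/locus plus ``overall`` (bisulfite
    methylated fraction) or ``rpm``.  For each non-control individual and
    locus: ratio = log2((value + eps) / (control mean + eps)).  With zero
    variance on either axis the correlation is undefined and returned as
    None (flagged, not NaN).
    """
    for df, col in ((bs_levels, "overall"), (mbd_rpm, "rpm")):
        if not {"sample", "locus", col}.issubset(df.columns):
            raise ValueError(f"frame must have sample/locus/{col} columns")
    bs_c = (bs_levels[bs_levels["sample"].isin(control_ids)]
            .groupby("locus")["overall"].mean())
    mbd_c = (mbd_rpm[mbd_rpm["sample"].isin(control_ids)]
             .groupby("locus")["rpm"].mean())
    if (bs_c <= 0).any() or (mbd_c <= 0).any():
        raise ValueError("control group means must be > 0")
    bs = bs_levels[~bs_levels["sample"].isin(control_ids)].copy()
    mbd = mbd_rpm[~mbd_rpm["sample"].isin(control_ids)].copy()
    bs["bs_log2"] = np.log2((bs["overall"] + epsilon)
                            / (bs["locus"].map(bs_c) + epsilon))
    mbd["mbd_log2"] = np.log2((mbd["rpm"] + epsilon)
                              / (mbd["locus"].map(mbd_c) + epsilon))
    paired = bs[["sample", "locus", "bs_log2"]].merge(
        mbd[["sample", "locus", "mbd_log2"]], on=["sample", "locus"],
        how="outer", indicator=True,
    )
    if (paired["_merge"] != "both").any():
        raise ValueError("bisulfite and capture tables do not pair up")
    paired = paired.drop(columns="_merge")
    x = paired["bs_log2"].to_numpy()
    y = paired["mbd_log2"].to_numpy()
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        return paired, None
    r = float(stats.pearsonr(x, y).statistic)
    return paired, r
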