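"""Region definition from methyl-capture reads.

Pipeline stage order: filter reads (mapping quality + duplicates), call
methylated regions per sample with a Poisson enrichment test, merge region
sets across samples (>50% reciprocal-of-shorter overlap), count
non-redundant reads per merged region, and drop regions below the
reads-per-million floor.

The peak caller is a deliberate simplification of a capture peak caller:
reads are extended to the fragment length from their 5' end, coverage is
evaluated in fixed windows, and a window is significant when the Poisson
upper tail under the larger of the genome-wide and local (10 kb) rates
falls below the threshold.  Adjacent significant windows are joined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval

#: default thresholds: mapq floor, peak p-value, fragment size, RPM floor
MIN_MAPQ = 37
PEAK_P = 1e-8
FRAGMENT_EXTENSION = 250
MIN_RPM = 20.0


@dataclass
class RegionCountMatrix:
    """Merged regions x samples non-redundant read counts."""

    regions: list[GenomicInterval]
    samples: list[str]
    counts: np.ndarray  # (R, S) ints
    library_sizes: np.ndarray  # (S,) filtered read totals

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.library_sizes = np.asarray(self.library_sizes)
        if self.counts.shape != (len(self.regions), len(self.samples)):
            raise ValueError("counts shape does not match regions x samples")
        if np.any(self.library_sizes <= 0):
            raise ValueError("library sizes must be > 0")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def rpm(self) -> np.ndarray:
        """Reads per million: counts * 1e6 / library size."""
        return self.counts * 1e6 / self.library_sizes[np.newaxis, :]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.samples)
        df.insert(0, "chrom", [r.chrom for r in self.regions])
        df.insert(1, "start", [r.start for r in self.regions])
        df.insert(2, "end", [r.end for r in self.regions])
        return df

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#library_sizes\t" + "\t".join(
                f"{s}={int(n)}" for s, n in zip(self.samples, self.library_sizes)
            ) + "\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "RegionCountMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n")
            if not header.startswith("#library_sizes\t"):
                raise ValueError("missing library-size header line")
            sizes = dict(item.split("=") for item in header.split("\t")[1:])
            df = pd.read_csv(fh, sep="\t")
        samples = [c for c in df.columns if c not in ("chrom", "start", "end")]
        regions = [GenomicInterval(c, int(s), int(e))
                   for c, s, e in zip(df["chrom"], df["start"], df["end"])]
        return cls(regions, samples, df[samples].to_numpy(),
                   np.array([float(sizes[s]) for s in samples]))


def five_prime_start(start: np.ndarray, end: np.ndarray, strand: np.ndarray
                     ) -> np.ndarray:
    """Position of the 5' base of each read (start on +, end-1 on -)."""
    return np.where(np.asarray(strand) == "+", start, np.asarray(end) - 1)


def filter_reads(reads: pd.DataFrame, min_mapq: int = MIN_MAPQ) -> pd.DataFrame:
    """Drop low-quality reads and collapse duplicates.

    A duplicate shares (sample, chrom, 5' start, strand) with an earlier
    read; exactly one representative is retained, in input order.
    """
    if reads.empty:
        return reads.copy()
    kept = reads[reads["mapq"] >= min_mapq].copy()
    kept["_fp"] = five_prime_start(kept["start"].to_numpy(),
                                   kept["end"].to_numpy(),
                                   kept["strand"].to_numpy())
    kept = kept.drop_duplicates(subset=["sample", "chrom", "_fp", "strand"],
                                keep="first")
    return kept.drop(columns="_fp").reset_index(drop=True)


def _extended_fragments(reads: pd.DataFrame, ext: int
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Fragment [start, end) obtained by extending each read to ``ext``
    bases from its 5' end along its strand."""
    start = reads["start"].to_numpy()
    end = reads["end"].to_numpy()
    plus = reads["strand"].to_numpy() == "+"
    fs = np.where(plus, start, end - ext)
    return fs, fs + ext


def call_regions(
    reads: pd.DataFrame,
    genome_sizes: dict[str, int],
    p_threshold: float = PEAK_P,
    fragment_extension: int = FRAGMENT_EXTENSION,
    window: int = 250,
    local_span: int = 10_000,
) -> list[GenomicInterval]:
    """Call enriched (methylated) regions from one sample's filtered reads.

    Windows are significant when the Poisson upper-tail probability of the
    observed extended-fragment count, under lambda = max(genome-wide rate,
    local 10 kb rate), is below ``p_threshold``.
    """
    if reads.empty:
        raise ValueError("need at least one read")
    total_genome = sum(genome_sizes.values())
    if total_genome <= 0 or any(v <= 0 for v in genome_sizes.values()):
        raise ValueError("genome sizes must be positive")

    fs, fe = _extended_fragments(reads, fragment_extension)
    chroms = reads["chrom"].to_numpy()
    n_total = len(reads)
    # expected fragments overlapping a window under uniform placement
    span = window + fragment_extension
    lam_bg = n_total * span / total_genome

    out: list[GenomicInterval] = []
    for chrom in sorted(genome_sizes):
        clen = genome_sizes[chrom]
        mask = chroms == chrom
        if not mask.any():
            continue
        s_sorted = np.sort(fs[mask])
        e_sorted = np.sort(fe[mask])

        n_win = int(np.ceil(clen / window))
        ws = np.arange(n_win) * window
        we = np.minimum(ws + window, clen)

        def overlap_counts(a: np.ndarray, b: np.ndarray) -> np.ndarray:
            # fragments with start < b and end > a
            return (np.searchsorted(s_sorted, b, side="left")
                    - np.searchsorted(e_sorted, a, side="right"))

        k = overlap_counts(ws, we)
        centers = (ws + we) // 2
        ls = np.maximum(0, centers - local_span // 2)
        le = np.minimum(clen, centers + local_span // 2)
        k_local = overlap_counts(ls, le)
        lam_local = k_local * span / (local_span + fragment_extension)
        lam = np.maximum(lam_bg, lam_local)
        pvals = stats.poisson.sf(k - 1, lam)
        sig = (pvals < p_threshold) & (k > 0)

        # join runs of adjacent significant windows
        idx = np.flatnonzero(sig)
        if idx.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > 1)
        run_starts = np.concatenate([[0], breaks + 1])
        run_ends = np.concatenate([breaks, [idx.size - 1]])
        for a, b in zip(run_starts, run_ends):
            out.append(GenomicInterval(chrom, int(ws[idx[a]]), int(we[idx[b]])))
    return sorted(out)


def merge_region_sets(
    per_sample_regions: Iterable[Iterable[GenomicInterval]],
    min_overlap_frac: float = 0.5,
) -> list[GenomicInterval]:
    """Merge regions across samples when they overlap by more than
    ``min_overlap_frac`` of the SHORTER region.

    Single-linkage: connected components of the pairwise merge relation
    are collapsed to their union span, and the procedure repeats on the
    new spans until nothing changes.  Output is sorted and independent of
    input order.
    """
    pool = sorted(set(r for rs in per_sample_regions for r in rs))
    while True:
        parent = list(range(len(pool)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        # sweep over sorted intervals, testing each against the still-open
        # earlier intervals on the same contig
        active: list[int] = []
        for i, r in enumerate(pool):
            active = [j for j in active
                      if pool[j].chrom == r.chrom and pool[j].end > r.start]
            for j in active:
                ov = pool[j].overlap_len(r)
                if ov > min_overlap_frac * min(len(pool[j]), len(r)):
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[ri] = rj
            active.append(i)

        components: dict[int, GenomicInterval] = {}
        for i, r in enumerate(pool):
            root = find(i)
            cur = components.get(root)
            components[root] = r if cur is None else cur.union_span(r)
        merged = sorted(set(components.values()))
        if merged == pool:
            return pool
        pool = merged


def count_matrix(
    regions: Sequence[GenomicInterval],
    reads: pd.DataFrame,
    samples: Sequence[str] | None = None,
    fragment_extension: int = FRAGMENT_EXTENSION,
) -> RegionCountMatrix:
    """Count, per merged region and sample, the filtered reads whose
    extended fragment overlaps the region by at least one base.

    A fragment overlapping two regions counts in both.  Library size is
    the sample's total filtered read count.
    """
    present = list(pd.unique(reads["sample"]))
    if samples is None:
        samples = sorted(present)
    else:
        unknown = set(present) - set(samples)
        if unknown:
            raise ValueError(f"reads contain unknown sample ids: {sorted(unknown)}")
        samples = list(samples)
    lib = reads["sample"].value_counts()
    library_sizes = np.array([int(lib.get(s, 0)) for s in samples])

    counts = np.zeros((len(regions), len(samples)), dtype=int)
    fs_all, fe_all = _extended_fragments(reads, fragment_extension)
    chrom_all = reads["chrom"].to_numpy()
    sample_all = reads["sample"].to_numpy()
    r_chrom = np.array([r.chrom for r in regions])
    r_start = np.array([r.start for r in regions], dtype=int)
    r_end = np.array([r.end for r in regions], dtype=int)
    for si, s in enumerate(samples):
        smask = sample_all == s
        for chrom in np.unique(r_chrom):
            cmask = smask & (chrom_all == chrom)
            s_sorted = np.sort(fs_all[cmask])
            e_sorted = np.sort(fe_all[cmask])
            rmask = r_chrom == chrom
            counts[rmask, si] = (
                np.searchsorted(s_sorted, r_end[rmask], side="left")
                - np.searchsorted(e_sorted, r_start[rmask], side="right")
            )
    return RegionCountMatrix(list(regions), samples, counts, library_sizes)


def rpm_filter(matrix: RegionCountMatrix, min_rpm: float = MIN_RPM
               ) -> RegionCountMatrix:
    """Keep regions reaching ``min_rpm`` reads per million in at least one
    sample (boundary value kept)."""
    keep = (matrix.rpm() >= min_rpm).any(axis=1)
    return RegionCountMatrix(
        [r for r, k in zip(matrix.regions, keep) if k],
        matrix.samples,
        matrix.counts[keep],
        matrix.library_sizes,
    )
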