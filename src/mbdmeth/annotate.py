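"""Region annotation: ZFP57 motif counting, allele-specific-methylation
dataset overlap, CpG-island detection and transcript-relative mapping.

The ZFP57 zinc-finger protein recognizes the methylated hexamer TGCCGC;
enrichment of this motif in hypomethylated regions is the signature of
regions that lose methylation when ZFP57 is defective.  Motifs are
counted on both strands by default (the protein binds a methylated
duplex), with a flag to restrict to the forward strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .simulate import revcomp

ZFP57_MOTIF = "TGCCGC"


def count_motif(sequence: str, motif: str = ZFP57_MOTIF,
                both_strands: bool = True) -> int:
    """Occurrences of ``motif`` in ``sequence`` (overlap-aware scan).

    When ``both_strands`` is set, forward occurrences of the reverse
    complement are added.  ``N`` never matches.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    seq = sequence.upper()
    motif = motif.upper()

    def scan(m: str) -> int:
        n = 0
        i = seq.find(m)
        while i != -1:
            n += 1
            i = seq.find(m, i + 1)
        return n

    total = scan(motif)
    if both_strands:
        rc = revcomp(motif)
        if rc != motif:  # palindromes would double-count
            total += scan(rc)
    return total


def motif_distribution(
    regions: Sequence[GenomicInterval],
    genome: Mapping[str, str],
    motif: str = ZFP57_MOTIF,
    both_strands: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-region motif counts and their integer histogram.

    Returns ``(counts, histogram)`` where ``histogram[k]`` is the number
    of regions containing exactly ``k`` motifs.
    """
    counts = np.empty(len(regions), dtype=int)
    for i, r in enumerate(regions):
        if r.chrom not in genome or r.end > len(genome[r.chrom]):
            raise ValueError(f"region {r} outside the genome")
        counts[i] = count_motif(genome[r.chrom][r.start:r.end], motif, both_strands)
    hist = np.bincount(counts) if counts.size else np.zeros(1, dtype=int)
    return counts, hist


def fraction_at_least(counts: Sequence[int], k: int = 2) -> float:
    """Percentage of values >= k ("two or more"), full precision."""
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("empty count vector")
    return 100.0 * float(np.count_nonzero(counts >= k)) / counts.size


@dataclass(frozen=True)
class AMRScore:
    region: GenomicInterval
    n_datasets: int


def amr_overlap(
    regions: Sequence[GenomicInterval],
    amr_datasets: Sequence[Sequence[GenomicInterval]],
    threshold: int = 5,
) -> tuple[list[AMRScore], float]:
    """Score each region by the number of allele-specific-methylation
    datasets overlapping it (>= 1 bp, dataset-level indicator), and report
    the percentage of regions with a score strictly above ``threshold``
    ("more than 5 data sets").
    """
    scores = np.zeros(len(regions), dtype=int)
    for dataset in amr_datasets:
        by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in {iv.chrom for iv in dataset}:
            ivs = [iv for iv in dataset if iv.chrom == chrom]
            by_chrom[chrom] = (
                np.sort(np.array([iv.start for iv in ivs])),
                np.sort(np.array([iv.end for iv in ivs])),
            )
        for i, r in enumerate(regions):
            if r.chrom not in by_chrom:
                continue
            starts, ends = by_chrom[r.chrom]
            n_olap = (np.searchsorted(starts, r.end, side="left")
                      - np.searchsorted(ends, r.start, side="right"))
            if n_olap > 0:
                scores[i] += 1
    pct = fraction_above(scores, threshold) if len(regions) else 0.0
    return [AMRScore(r, int(s)) for r, s in zip(regions, scores)], pct


def fraction_above(scores: Sequence[int], threshold: int = 5) -> float:
    """Percentage of scores strictly greater than ``threshold``."""
    scores = np.asarray(scores)
    if scores.size == 0:
        raise ValueError("empty score vector")
    return 100.0 * float(np.count_nonzero(scores > threshold)) / scores.size


def detect_cpg_islands(
    genome: Mapping[str, str],
    min_len: int = 200,
    gc_min: float = 0.50,
    oe_min: float = 0.60,
) -> list[GenomicInterval]:
    """CpG islands by the classic sliding-window criteria.

    Every 200 bp window with GC fraction >= ``gc_min`` and observed /
    expected CpG ratio >= ``oe_min`` qualifies; overlapping qualifying
    windows are merged into maximal islands.  O/E = n_CG * L / (n_C * n_G).
    """
    win = min_len
    islands: list[GenomicInterval] = []
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        L = len(seq)
        if L < win:
            continue
        arr = np.frombuffer(seq.encode(), dtype="S1")
        is_c = (arr == b"C").astype(int)
        is_g = (arr == b"G").astype(int)
        is_cg = np.zeros(L, dtype=int)
        is_cg[:-1] = (arr[:-1] == b"C") & (arr[1:] == b"G")

        def wsum(x: np.ndarray, width: int) -> np.ndarray:
            c = np.concatenate([[0], np.cumsum(x)])
            return c[width:] - c[:-width]

        n_c = wsum(is_c, win)
        n_g = wsum(is_g, win)
        # CG dinucleotides fully inside the window: starts in [i, i+win-1)
        n_cg = wsum(is_cg, win - 1)[: L - win + 1] if L >= win else np.array([])
        gc = (n_c + n_g) / win
        with np.errstate(divide="ignore", invalid="ignore"):
            oe = np.where((n_c > 0) & (n_g > 0), n_cg * win / (n_c * n_g), 0.0)
        ok = np.flatnonzero((gc >= gc_min) & (oe >= oe_min))
        if ok.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(ok) > win)
        run_starts = np.concatenate([[0], breaks + 1])
        run_ends = np.concatenate([breaks, [ok.size - 1]])
        for a, b in zip(run_starts, run_ends):
            islands.append(GenomicInterval(chrom, int(ok[a]), int(ok[b]) + win))
    return sorted(islands)


def map_to_transcripts(
    regions: Sequence[GenomicInterval],
    transcripts: pd.DataFrame,
    proximal_bp: int = 1000,
) -> pd.DataFrame:
    """Map region centers to the nearest transcript 5' end.

    ``transcripts`` needs chrom/start/end/strand columns; the 5' end is
    ``start`` on + and ``end - 1`` on -.  ``tss_proximal`` is inclusive at
    ``proximal_bp`` (1 kb: "more than 1 kb away" is strictly greater).
    Regions on contigs without transcripts get NaN distance and False
    flags, with ``defined`` False.
    """
    required = {"chrom", "start", "end", "strand"}
    if not required.issubset(transcripts.columns):
        raise ValueError(f"transcripts need columns {sorted(required)}")
    five = np.where(transcripts["strand"].to_numpy() == "+",
                    transcripts["start"].to_numpy(),
                    transcripts["end"].to_numpy() - 1)
    t_chrom = transcripts["chrom"].to_numpy()
    t_start = transcripts["start"].to_numpy()
    t_end = transcripts["end"].to_numpy()
    rows = []
    for r in regions:
        mask = t_chrom == r.chrom
        center = r.center
        if not mask.any():
            rows.append((r.chrom, r.start, r.end, center, np.nan,
                         False, False, False))
            continue
        d = np.abs(five[mask] - center)
        within = bool(np.any((t_start[mask] <= center) & (center < t_end[mask])))
        dist = int(d.min())
        rows.append((r.chrom, r.start, r.end, center, dist, within,
                     dist <= proximal_bp, True))
    return pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "center", "distance_to_5prime",
        "within_transcript", "tss_proximal", "defined",
    ])
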