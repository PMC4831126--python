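"""Synthetic cohorts for methyl-capture differential-methylation analysis.

The generators in this module produce the inputs the rest of the pipeline
consumes — a toy genome, aligned capture reads per sample, and indexed
bisulfite amplicon reads — together with the ground truth needed for
parameter-recovery tests.

The statistical structure mirrors what the analysis assumes:

* each "methylated region" captures reads in proportion to a baseline
  weight times a per-sample methylation multiplier (1 = normal,
  0.5 = partial loss, 0 = total loss, >1 = gain);
* per-region read counts are negative binomial with
  ``var = mean + phi * mean**2`` (``phi = 0`` gives Poisson);
* a configurable fraction of extra reads is uniform background, a
  fraction of reads carries sub-threshold mapping quality, and a
  fraction is duplicated — so that read filtering and peak calling are
  exercised, not bypassed;
* designated differentially methylated regions carry deliberately
  inserted copies of the ZFP57 recognition motif TGCCGC.

The default cohort has four patients, three heterozygotes and five
controls, with three regions totally hypomethylated in every patient —
the structure of a multilocus imprinting-defect study.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .intervals import GenomicInterval

MOTIF = "TGCCGC"
MOTIF_RC = "GCGGCA"

PATIENT = "patient"
HETEROZYGOTE = "heterozygote"
CONTROL = "control"

@dataclass(frozen=True)
class Effect:
    """A methylation change at one region in a set of samples.

    multiplier 0 = total loss, 0.5 = partial loss, >1 = gain.
    """

    region_index: int
    samples: tuple[str, ...]
    multiplier: float

    def __post_init__(self) -> None:
        if self.multiplier < 0:
            raise ValueError("multiplier must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_contigs: int = 2
    contig_length: int = 200_000
    n_regions: int = 60
    region_length_mean: int = 600
    motif_rate: float = 4.0  # expected TGCCGC insertions per designated DMR
    background_motif_rate: float = 0.0  # same, for non-DMR regions
    cohort: tuple[tuple[str, str], ...] = field(default_factory=lambda: default_cohort())
    depth_per_sample: int = 40_000
    dispersion: float = 0.1  # NB overdispersion phi, var = mu + phi mu^2
    effects: tuple[Effect, ...] = ()
    read_length: int = 36
    fragment_length: int = 250
    background_fraction: float = 0.30  # extra uniform reads, as fraction of depth
    low_mapq_fraction: float = 0.05  # reads emitted with mapq < 37
    duplicate_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion phi must be >= 0")
        groups = {g for _, g in self.cohort}
        bad = groups - {PATIENT, HETEROZYGOTE, CONTROL}
        if bad:
            raise ValueError(f"unknown cohort groups: {bad}")
        ids = [s for s, _ in self.cohort]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in cohort")
        for eff in self.effects:
            if not (0 <= eff.region_index < self.n_regions):
                raise ValueError("effect region_index out of range")
            for s in eff.samples:
                if s not in ids:
                    raise ValueError(f"effect names unknown sample {s!r}")

    @property
    def sample_ids(self) -> list[str]:
        return [s for s, _ in self.cohort]

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s, g in self.cohort if g == group]

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["cohort"] = [list(p) for p in d["cohort"]]
        d["effects"] = [
            {"region_index": e["region_index"], "samples": list(e["samples"]),
             "multiplier": e["multiplier"]}
            for e in d["effects"]
        ]
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationConfig":
        d = yaml.safe_load(text)
        d["cohort"] = tuple((s, g) for s, g in d.get("cohort", []))
        d["effects"] = tuple(
            Effect(e["region_index"], tuple(e["samples"]), e["multiplier"])
            for e in d.get("effects", ())
        )
        return cls(**d)


def default_cohort() -> tuple[tuple[str, str], ...]:
    """Four patients, three heterozygous relatives, five unrelated controls."""
    cohort = [(f"P{i}", PATIENT) for i in range(1, 5)]
    cohort += [(f"H{i}", HETEROZYGOTE) for i in range(1, 4)]
    cohort += [(f"C{i}", CONTROL) for i in range(1, 6)]
    return tuple(cohort)


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The study-shaped default scenario.

    Three regions lose methylation completely in all four patients, and each
    patient additionally carries a few private partial losses; heterozygotes
    are methylated normally.  DMRs carry inserted TGCCGC motifs.
    """
    cohort = default_cohort()
    patients = tuple(s for s, g in cohort if g == PATIENT)
    n_regions = int(overrides.get("n_regions", 60))
    if n_regions < 12:
        raise ValueError("the default scenario needs at least 12 regions")
    # spread the designated DMRs across the region list
    slots = np.linspace(0, n_regions - 1, 10).astype(int).tolist()
    effects = [Effect(i, patients, 0.0) for i in slots[:3]]
    # private partial losses and one private gain
    for region, pat in zip(slots[3:9], ["P1", "P1", "P2", "P2", "P3", "P4"]):
        effects.append(Effect(region, (pat,), 0.5))
    effects.append(Effect(slots[9], ("P2",), 2.0))
    cfg = dict(seed=seed, effects=tuple(effects))
    cfg.update(overrides)
    return SimulationConfig(**cfg)


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside simulated data."""

    regions: list[GenomicInterval]
    baseline_weight: np.ndarray  # (R,) relative capture propensity > 0
    samples: list[str]
    methylation_multiplier: np.ndarray  # (R, S)
    inserted_motif_counts: np.ndarray  # (R,) ints
    dmr_indices: list[int]  # regions designated as DMRs (targets of effects)

    def multiplier_frame(self) -> pd.DataFrame:
        idx = [f"{r.chrom}:{r.start}-{r.end}" for r in self.regions]
        return pd.DataFrame(self.methylation_multiplier, index=idx, columns=self.samples)


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_seq(rng: np.random.Generator, n: int, p: Sequence[float]) -> np.ndarray:
    return rng.choice(_BASES, size=n, p=np.asarray(p, dtype=float))


def _deplete_cpg(rng: np.random.Generator, seq: np.ndarray, keep_prob: float = 0.1) -> None:
    """Convert most CG dinucleotides to CA in place (background sequence)."""
    is_c = seq[:-1] == b"C"
    is_g = seq[1:] == b"G"
    cg = np.flatnonzero(is_c & is_g)
    drop = cg[rng.random(cg.size) >= keep_prob]
    seq[drop + 1] = b"A"


def scan_motif(seq: str, motif: str) -> list[int]:
    """Offsets of every (possibly overlapping) occurrence of motif in seq."""
    out = []
    i = seq.find(motif)
    while i != -1:
        out.append(i)
        i = seq.find(motif, i + 1)
    return out


def _scrub_motifs(rng: np.random.Generator, region: np.ndarray,
                  keep: Sequence[tuple[int, int]] = ()) -> None:
    """Destroy accidental TGCCGC / GCGGCA matches in place.

    ``keep`` lists [start, end) spans that must not be touched (deliberate
    insertions).  Mutates one base inside each offending window, outside any
    kept span, and repeats until the only matches left are the kept ones.
    """
    kept_starts = {s for s, _ in keep}
    for _ in range(200):
        text = region.tobytes().decode()
        bad = [o for o in scan_motif(text, MOTIF) if o not in kept_starts]
        bad += scan_motif(text, MOTIF_RC)
        bad = [o for o in bad
               if not any(s <= o and o + 6 <= e for s, e in keep)]
        if not bad:
            return
        for o in bad:
            candidates = [p for p in range(o, o + 6)
                          if not any(s <= p < e for s, e in keep)]
            p = candidates[rng.integers(len(candidates))]
            cur = region[p]
            repl = rng.choice(_BASES)
            while repl == cur:
                repl = rng.choice(_BASES)
            region[p] = repl
    raise RuntimeError("could not scrub accidental motif matches")


def _place_regions(rng: np.random.Generator, cfg: SimulationConfig
                   ) -> tuple[list[GenomicInterval], list[int]]:
    """Non-overlapping region intervals, round-robin across contigs."""
    per_contig = cfg.n_regions // cfg.n_contigs
    counts = [per_contig] * cfg.n_contigs
    for i in range(cfg.n_regions - per_contig * cfg.n_contigs):
        counts[i] += 1
    if cfg.contig_length < 10 * cfg.region_length_mean * cfg.n_regions / cfg.n_contigs:
        raise ValueError(
            "contig_length too small for the requested region packing "
            "(need >= 10 * region_length_mean * n_regions / n_contigs)"
        )
    min_gap = 2 * cfg.fragment_length
    regions: list[GenomicInterval] = []
    lengths_all: list[int] = []
    for c, n_here in enumerate(counts):
        if n_here == 0:
            continue
        lengths = np.maximum(200, rng.poisson(cfg.region_length_mean, n_here))
        free = cfg.contig_length - int(lengths.sum()) - (n_here + 1) * min_gap
        if free < 0:
            raise ValueError("infeasible packing of non-overlapping regions")
        # gaps between/around regions: min_gap plus a random share of the slack
        extra = rng.multinomial(free, np.full(n_here + 1, 1.0 / (n_here + 1)))
        pos = 0
        for j in range(n_here):
            pos += min_gap + int(extra[j])
            regions.append(GenomicInterval(f"contig{c + 1}", pos, pos + int(lengths[j])))
            pos += int(lengths[j])
        lengths_all.extend(int(x) for x in lengths)
    return regions, lengths_all


def simulate_genome(config: SimulationConfig
                    ) -> tuple[dict[str, str], SimulationTruth]:
    """Build a toy genome and the truth skeleton for it.

    The background is CpG-depleted; regions are GC-rich CpG islands so
    island detection has signal to find.  Regions named in
    ``config.effects`` are the designated DMRs and receive
    ``Poisson(motif_rate)`` exact TGCCGC insertions; other regions receive
    ``Poisson(background_motif_rate)``.  The recorded motif count equals a
    brute-force scan of the emitted region sequence: accidental matches
    (either strand) are scrubbed before insertion.
    """
    rng = np.random.default_rng(config.seed)
    regions, _ = _place_regions(rng, config)
    dmr_indices = sorted({e.region_index for e in config.effects})
    dmr_set = set(dmr_indices)

    contigs: dict[str, np.ndarray] = {}
    for c in range(config.n_contigs):
        seq = _random_seq(rng, config.contig_length, [0.3, 0.2, 0.2, 0.3])
        _deplete_cpg(rng, seq)
        contigs[f"contig{c + 1}"] = seq

    motif_arr = np.frombuffer(MOTIF.encode(), dtype="S1")
    inserted = np.zeros(len(regions), dtype=int)
    for i, r in enumerate(regions):
        L = len(r)
        block = _random_seq(rng, L, [0.15, 0.35, 0.35, 0.15])
        rate = config.motif_rate if i in dmr_set else config.background_motif_rate
        k = int(rng.poisson(rate)) if rate > 0 else 0
        k = min(k, L // 12)  # cannot pack more without overlap
        spans: list[tuple[int, int]] = []
        if k:
            # non-overlapping starts with pairwise gap >= 7: sample in the
            # gap-reduced space and shift back
            room = L - 6 - 7 * (k - 1)
            if room < k:
                raise RuntimeError("could not place motif insertions")
            base = np.sort(rng.choice(room, size=k, replace=False))
            starts = base + 7 * np.arange(k)
            spans = [(int(s), int(s) + 6) for s in starts]
            for s, _e in spans:
                block[s:s + 6] = motif_arr
        _scrub_motifs(rng, block, keep=spans)
        inserted[i] = k
        contigs[r.chrom][r.start:r.end] = block

    genome = {name: arr.tobytes().decode() for name, arr in contigs.items()}

    samples = config.sample_ids
    mult = np.ones((len(regions), len(samples)))
    seen: set[tuple[int, str]] = set()
    for eff in config.effects:
        for s in eff.samples:
            key = (eff.region_index, s)
            if key in seen:
                raise ValueError(f"duplicate effect for region {key}")
            seen.add(key)
            mult[eff.region_index, samples.index(s)] = eff.multiplier

    weights = rng.uniform(0.5, 1.5, size=len(regions))
    truth = SimulationTruth(
        regions=regions,
        baseline_weight=weights,
        samples=samples,
        methylation_multiplier=mult,
        inserted_motif_counts=inserted,
        dmr_indices=dmr_indices,
    )
    return genome, truth


# ---------------------------------------------------------------------------
# capture-read simulation
# ---------------------------------------------------------------------------


def sample_nb_counts(rng: np.random.Generator, mean: np.ndarray, phi: float
                     ) -> np.ndarray:
    """Negative binomial counts with var = mean + phi * mean**2 (gamma-Poisson)."""
    if phi < 0:
        raise ValueError("phi must be >= 0")
    mean = np.asarray(mean, dtype=float)
    if phi == 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / phi, scale=phi * mean)
    return rng.poisson(lam)


def simulate_capture_reads(genome: Mapping[str, str], truth: SimulationTruth,
                           config: SimulationConfig) -> pd.DataFrame:
    """Aligned single-end capture reads for every sample in the cohort.

    Returns a BED6+1-shaped frame: chrom, start, end, name, mapq, strand,
    sample.  In-region counts follow NB(depth * weight * multiplier / sum
    weights, phi); background reads are uniform over the genome; a fraction
    of reads gets mapq below 37 and a fraction is duplicated, to exercise
    the read filter.
    """
    if config.depth_per_sample <= 0:
        raise ValueError("depth_per_sample must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    contig_names = list(genome)
    contig_len = np.array([len(genome[c]) for c in contig_names])
    region_chrom_idx = np.array(
        [contig_names.index(r.chrom) for r in truth.regions]
    )
    r_start = np.array([r.start for r in truth.regions])
    r_len = np.array([len(r) for r in truth.regions])
    w = truth.baseline_weight
    wsum = w.sum()
    ext = config.fragment_length
    rl = config.read_length
    half = ext // 2

    acc: dict[str, list[np.ndarray]] = {k: [] for k in
                                        ("cidx", "start", "end", "mapq", "plus", "sidx")}
    for si, sample in enumerate(truth.samples):
        mu = config.depth_per_sample * w * truth.methylation_multiplier[:, si] / wsum
        counts = sample_nb_counts(rng, mu, config.dispersion)
        rep = np.repeat(np.arange(len(truth.regions)), counts)
        mids = r_start[rep] + np.floor(rng.random(rep.size) * r_len[rep]).astype(int)
        f0 = mids - half
        cidx = region_chrom_idx[rep]

        n_bg = rng.poisson(config.background_fraction * config.depth_per_sample)
        bg_c = rng.choice(len(contig_names), size=n_bg, p=contig_len / contig_len.sum())
        bg_f0 = np.floor(rng.random(n_bg) * (contig_len[bg_c] - ext)).astype(int)
        f0 = np.concatenate([f0, bg_f0])
        cidx = np.concatenate([cidx, bg_c])
        f0 = np.clip(f0, 0, contig_len[cidx] - ext)

        strand_plus = rng.random(f0.size) < 0.5
        start = np.where(strand_plus, f0, f0 + ext - rl)
        end = start + rl
        mapq = np.full(f0.size, 37)
        low = rng.random(f0.size) < config.low_mapq_fraction
        mapq[low] = rng.integers(0, 37, size=int(low.sum()))

        n_dup = int(round(config.duplicate_fraction * f0.size))
        if n_dup:
            didx = rng.integers(0, f0.size, size=n_dup)
            start = np.concatenate([start, start[didx]])
            end = np.concatenate([end, end[didx]])
            cidx = np.concatenate([cidx, cidx[didx]])
            strand_plus = np.concatenate([strand_plus, strand_plus[didx]])
            mapq = np.concatenate([mapq, mapq[didx]])

        acc["cidx"].append(cidx)
        acc["start"].append(start)
        acc["end"].append(end)
        acc["mapq"].append(mapq)
        acc["plus"].append(strand_plus)
        acc["sidx"].append(np.full(start.size, si))

    cidx = np.concatenate(acc["cidx"])
    plus = np.concatenate(acc["plus"])
    sidx = np.concatenate(acc["sidx"])
    out = pd.DataFrame({
        "chrom": pd.Categorical.from_codes(cidx, categories=contig_names),
        "start": np.concatenate(acc["start"]),
        "end": np.concatenate(acc["end"]),
        "name": np.arange(cidx.size),
        "mapq": np.concatenate(acc["mapq"]),
        "strand": pd.Categorical.from_codes((~plus).astype(int),
                                            categories=["+", "-"]),
        "sample": pd.Categorical.from_codes(sidx, categories=truth.samples),
    })
    return out


# ---------------------------------------------------------------------------
# bisulfite amplicon simulation
# ---------------------------------------------------------------------------


def cpg_positions(sequence: str) -> list[int]:
    """Offsets of the C of every CpG on the forward strand."""
    seq = sequence.upper()
    return [i for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G"]


_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def simulate_bisulfite_reads(
    amplicon_seq: str,
    cpg_methylation: Mapping[int, float],
    n_reads: int,
    index: str,
    seed: int,
    error_rate: float = 0.001,
    read_length: int = 36,
    index_table: Mapping[str, str] | None = None,
) -> list[tuple[str, str]]:
    """Indexed bisulfite reads from one amplicon for one sample.

    Each read is the sample index followed by a fragment of the
    bisulfite-converted amplicon (either strand of the PCR product).
    Unmethylated cytosines convert to T; CpG cytosines are retained as C
    per read with the given per-CpG methylation probability; non-CpG C
    always converts.  Uniform substitution errors at ``error_rate``.

    Returns (read_id, sequence) pairs.
    """
    seq = amplicon_seq.upper()
    cpgs = cpg_positions(seq)
    missing = [p for p in cpgs if p not in cpg_methylation]
    if missing:
        raise ValueError(f"methylation probability missing for CpG at {missing}")
    if index_table is not None and index not in index_table.values():
        raise ValueError(f"index {index!r} not in the configured index table")
    rng = np.random.default_rng(seed)
    frag_len = read_length - len(index)
    if frag_len < 1:
        raise ValueError("read_length must exceed index length")
    if len(seq) < frag_len:
        raise ValueError("amplicon shorter than the read fragment")
    arr = np.frombuffer(seq.encode(), dtype="S1")
    is_c = arr == b"C"
    cpg_mask = np.zeros(len(seq), dtype=bool)
    probs = np.zeros(len(seq))
    for p in cpgs:
        cpg_mask[p] = True
        probs[p] = cpg_methylation[p]

    reads = []
    for i in range(n_reads):
        conv = arr.copy()
        meth = rng.random(len(seq)) < probs
        to_t = is_c & ~(cpg_mask & meth)
        conv[to_t] = b"T"
        offset = int(rng.integers(0, len(seq) - frag_len + 1))
        frag = conv[offset:offset + frag_len].tobytes().decode()
        if rng.random() < 0.5:
            frag = revcomp(frag)
        if error_rate > 0:
            frag_arr = list(frag)
            errs = np.flatnonzero(rng.random(frag_len) < error_rate)
            for e in errs:
                choices = [b for b in "ACGT" if b != frag_arr[e]]
                frag_arr[e] = choices[rng.integers(3)]
            frag = "".join(frag_arr)
        reads.append((f"bs{i}", index + frag))
    return reads
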