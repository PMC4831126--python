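"""End-to-end orchestration of the capture analysis on one cohort.

Glue only — every step is a public function of the stage modules.  Runs:
read filtering, per-sample region calling, cross-sample merging,
non-redundant counting, the RPM floor, the per-patient NB exact test
with BH adjustment, and cross-patient sharing.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import diffmeth, regions as rg, shared, simulate
from .intervals import GenomicInterval


@dataclass
class CohortResult:
    config: simulate.SimulationConfig
    truth: simulate.SimulationTruth
    genome: dict[str, str]
    matrix: rg.RegionCountMatrix
    per_patient: dict[str, pd.DataFrame]
    shared_report: pd.DataFrame


def analyze_reads(
    reads: pd.DataFrame,
    genome_sizes: dict[str, int],
    patients: list[str],
    controls: list[str],
    others: list[str] | None = None,
    alpha: float = diffmeth.ALPHA,
    min_rpm: float = rg.MIN_RPM,
) -> tuple[rg.RegionCountMatrix, dict[str, pd.DataFrame], pd.DataFrame]:
    """Full capture analysis from aligned reads to shared-region report.

    ``others`` (e.g. heterozygotes) contribute reads to region calling and
    counting but are not tested against the controls here.
    """
    all_samples = patients + (others or []) + controls
    filtered = rg.filter_reads(reads)
    per_sample_regions = []
    for s in all_samples:
        sub = filtered[filtered["sample"] == s]
        if len(sub):
            per_sample_regions.append(rg.call_regions(sub, genome_sizes))
    universe = rg.merge_region_sets(per_sample_regions)
    matrix = rg.count_matrix(universe, filtered, samples=all_samples)
    matrix = rg.rpm_filter(matrix, min_rpm)

    eff = diffmeth.normalize_libraries(matrix)
    phi = diffmeth.estimate_dispersion(matrix, controls, eff).phi
    per_patient = {
        p: diffmeth.test_patient(matrix, p, controls, phi=phi,
                                 effective_sizes=eff, alpha=alpha)
        for p in patients
    }
    report = shared.build_shared(per_patient, matrix.regions)
    return matrix, per_patient, report


def run_cohort(config: simulate.SimulationConfig) -> CohortResult:
    """Simulate a cohort under ``config`` and run the whole analysis."""
    genome, truth = simulate.simulate_genome(config)
    reads = simulate.simulate_capture_reads(genome, truth, config)
    genome_sizes = {c: len(s) for c, s in genome.items()}
    matrix, per_patient, report = analyze_reads(
        reads,
        genome_sizes,
        patients=config.samples_in_group(simulate.PATIENT),
        controls=config.samples_in_group(simulate.CONTROL),
        others=config.samples_in_group(simulate.HETEROZYGOTE),
    )
    return CohortResult(config, truth, genome, matrix, per_patient, report)


#: the study's inline sample indexes (6-mers)
VALIDATION_INDEXES = ("ACCAAT", "AGAGAT", "AGTCAT", "CAGTCT", "CCGGCT",
                      "CGATCT", "CGTACT", "GAGAGT", "GCCGGT")


def simulate_validation_scenario(
    seed: int,
    n_amplicons: int = 8,
    n_patients: int = 3,
    n_controls: int = 3,
    reads_per_sample: int = 300,
    capture_depth: float = 200.0,
    phi: float = 0.1,
    amplicon_length: int = 90,
):
    """Build the bisulfite-validation arm on synthetic amplicons.

    Emulates verifying a set of capture-detected loci by amplicon
    bisulfite sequencing: ``n_amplicons`` loci with control methylation
    levels drawn in [0.25, 0.88], per-patient multipliers mixing total
    loss, partial loss and normal methylation.  Both assays are driven by
    the same truth: bisulfite reads are simulated, demultiplexed and
    quantified through the aligner; capture RPM values are NB draws
    around ``capture_depth`` scaled by the same methylation level.

    Returns (bs_levels, mbd_rpm, control_ids, truth_multipliers).
    """
    import numpy as np

    from .bsseq import AmpliconSpec, demultiplex, quantify_sample
    from .simulate import (cpg_positions, sample_nb_counts,
                           simulate_bisulfite_reads)

    rng = np.random.default_rng(seed)
    samples = [f"P{i + 1}" for i in range(n_patients)] + \
              [f"C{i + 1}" for i in range(n_controls)]
    controls = samples[n_patients:]
    index_table = {s: VALIDATION_INDEXES[i] for i, s in enumerate(samples)}

    bases = np.array(list("ACGT"))
    rows_bs, rows_mbd = [], []
    truth = {}
    for a in range(n_amplicons):
        while True:
            seq = "".join(rng.choice(bases, size=amplicon_length,
                                     p=[0.2, 0.3, 0.3, 0.2]))
            if len(cpg_positions(seq)) >= 3:
                break
        spec = AmpliconSpec(f"amp{a}", seq)
        baseline = float(rng.uniform(0.25, 0.88))
        for s in samples:
            if s in controls:
                mult = 1.0
            else:
                mult = float(rng.choice([0.1, 0.5, 1.0], p=[0.3, 0.4, 0.3]))
            truth[(s, spec.name)] = baseline * mult
            level = min(1.0, baseline * mult)
            probs = {p: level for p in spec.cpg_positions}
            reads = simulate_bisulfite_reads(
                seq, probs, reads_per_sample, index_table[s],
                seed=int(rng.integers(2**31)), error_rate=0.001,
                read_length=42,
            )
            assigned, _ = demultiplex(reads, index_table)
            summary, _ = quantify_sample(assigned[s], spec, s)
            rows_bs.append({"sample": s, "locus": spec.name,
                            "overall": summary.overall})
            rpm = float(sample_nb_counts(
                rng, np.array([capture_depth * baseline * mult]), phi)[0])
            rows_mbd.append({"sample": s, "locus": spec.name, "rpm": rpm})
    return (pd.DataFrame(rows_bs), pd.DataFrame(rows_mbd), controls, truth)


def match_to_truth(called: GenomicInterval, truth_regions,
                   min_frac: float = 0.5) -> int | None:
    """Index of the truth region that ``called`` overlaps by more than
    ``min_frac`` of the truth region's length, or None."""
    for i, t in enumerate(truth_regions):
        if called.overlap_len(t) > min_frac * len(t):
            return i
    return None
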