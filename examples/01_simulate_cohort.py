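"""Simulate a study-shaped cohort and inspect its ground truth.

Builds the default scenario — 4 patients, 3 heterozygous relatives,
5 controls; 60 methylated regions on a 2-contig toy genome; 3 regions
totally hypomethylated in every patient — and writes the genome, aligned
capture reads and truth tables to ./example_output/.
"""

from pathlib import Path

from mbdmeth import default_config, simulate_capture_reads, simulate_genome
from mbdmeth.io import write_fasta, write_reads_bed

out = Path("example_output")
out.mkdir(exist_ok=True)

cfg = default_config(seed=1)
genome, truth = simulate_genome(cfg)
reads = simulate_capture_reads(genome, truth, cfg)

write_fasta(genome, out / "genome.fa")
write_reads_bed(reads, out / "reads.bed")
(out / "sim_config.yaml").write_text(cfg.to_yaml())
truth.multiplier_frame().to_csv(out / "truth_multipliers.tsv", sep="\t")

print(f"contigs: { {c: len(s) for c, s in genome.items()} }")
print(f"regions: {len(truth.regions)}  designated DMRs: {truth.dmr_indices}")
print(f"aligned reads: {len(reads)} across {len(truth.samples)} samples")
total_loss = (truth.methylation_multiplier == 0).any(axis=1)
print(f"regions with total loss in some sample: {int(total_loss.sum())}")
print("motif insertions in DMRs:",
      truth.inserted_motif_counts[truth.dmr_indices].tolist())
# The multiplier table is the ground truth the analysis must recover:
# 1 = normal methylation, 0.5 = partial loss, 0 = total loss, 2 = gain.
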