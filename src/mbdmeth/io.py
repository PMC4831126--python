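"""Plain-text I/O: FASTA, FASTQ, BED and TSV round-trips.

Standard formats go through Biopython; BED-shaped tables through pandas.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval

READ_BED_COLUMNS = ["chrom", "start", "end", "name", "mapq", "strand", "sample"]


def write_fasta(genome: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: Iterable[tuple[str, str]], path) -> None:
    """Write (id, sequence) pairs with uniform placeholder qualities."""
    records = []
    for name, seq in reads:
        rec = SeqRecord(Seq(seq), id=name, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(seq)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def write_reads_bed(reads: pd.DataFrame, path) -> None:
    """BED6+1: chrom, start, end, name, mapq (score column), strand, sample."""
    reads[READ_BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_reads_bed(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", names=READ_BED_COLUMNS)


def write_regions_bed(regions: Sequence[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


def read_regions_bed(path) -> list[GenomicInterval]:
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                     names=["chrom", "start", "end"])
    return [GenomicInterval(c, int(s), int(e))
            for c, s, e in zip(df["chrom"], df["start"], df["end"])]
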