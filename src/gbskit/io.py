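"""File-format adapters: FASTA, VCF v4.2, BED and the plain TSV side tables.

FASTA goes through Biopython's SeqIO; VCF parsing goes through cyvcf2.
VCF *emission* is a small text writer covering the v4.2 subset the
synthetic generator produces (GT calls; float INFO keys QD, FS, MQ).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from gbskit.digest import Fragment
from gbskit.variant_filter import MISSING, VariantRecord


def read_fasta(path: str | Path) -> dict[str, str]:
    """Chromosome name -> uppercase sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    """Write sequences wrapped at 60 columns."""
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


_GT_OF_DOSE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(
    path: str | Path,
    records: Iterable[VariantRecord],
    samples: Sequence[str],
    contigs: Mapping[str, int] | None = None,
) -> None:
    """Emit records as VCF v4.2 with GT calls and QD/FS/MQ INFO floats.

    Contig header lines are derived from the records when not supplied.
    """
    records = list(records)
    if contigs is None:
        bounds: dict[str, int] = {}
        for rec in records:
            end = rec.pos + len(rec.ref)
            bounds[rec.chromosome] = max(bounds.get(rec.chromosome, 0), end + 1000)
        contigs = bounds
    lines = [
        "##fileformat=VCFv4.2",
        "##source=gbskit",
        '##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">',
        '##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand bias (phred)">',
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    if contigs:
        for name, length in contigs.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    for rec in records:
        info = rec.info_raw
        if info is None:
            parts = []
            for key, value in (("QD", rec.qd), ("FS", rec.fs), ("MQ", rec.mq)):
                if value is not None:
                    parts.append(f"{key}={value:.4g}")
            info = ";".join(parts) if parts else "."
        gts = "\t".join(_GT_OF_DOSE[int(d)] for d in rec.genotypes)
        lines.append(
            f"{rec.chromosome}\t{rec.pos}\t{rec.record_id}\t{rec.ref}\t"
            f"{','.join(rec.alt)}\t.\t.\t{info}\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> tuple[list[VariantRecord], list[str]]:
    """Parse a VCF into :class:`~gbskit.variant_filter.VariantRecord` objects.

    Genotypes are normalized to unphased alternate-allele doses; a genotype
    with any missing allele becomes missing as a whole.
    """
    from cyvcf2 import VCF  # deferred: import cost and htslib warnings

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records = []
    for v in vcf:
        doses = np.empty(len(samples), dtype=np.int8)
        for i, gt in enumerate(v.genotypes):
            alleles = gt[:-1]  # last element is the phased flag
            if any(a < 0 for a in alleles):
                doses[i] = MISSING
            else:
                doses[i] = sum(1 for a in alleles if a > 0)
        def _info(key: str) -> float | None:
            val = v.INFO.get(key)
            return float(val) if val is not None else None

        records.append(
            VariantRecord(
                chromosome=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alt=tuple(v.ALT),
                qd=_info("QD"),
                fs=_info("FS"),
                mq=_info("MQ"),
                genotypes=doses,
                record_id=v.ID or ".",
            )
        )
    return records, samples


def write_bed(path: str | Path, fragments: Iterable[Fragment]) -> None:
    """BED6 with the fragment length as name, score 0, strand '.'."""
    with open(path, "w") as fh:
        for f in fragments:
            fh.write(f"{f.chromosome}\t{f.start}\t{f.end}\t{f.length}\t0\t.\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read the first three BED columns as (chromosome, start, end) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            out.append((chrom, int(start), int(end)))
    return out


def write_labels(path: str | Path, labels: Mapping[str, str]) -> None:
    """Plain two-column TSV: sample_id <TAB> population."""
    with open(path, "w") as fh:
        for sample, pop in labels.items():
            fh.write(f"{sample}\t{pop}\n")


def read_labels(path: str | Path) -> dict[str, str]:
    labels = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            sample, pop = line.split("\t")[:2]
            labels[sample] = pop
    return labels


def write_q_matrix(path: str | Path, q: pd.DataFrame) -> None:
    """Samples x populations ancestry table, tab-separated."""
    q.to_csv(path, sep="\t", index_label="sample", float_format="%.6f")


def read_q_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample")
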