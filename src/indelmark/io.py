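"""Readers/writers for the plain-text formats the pipeline exchanges.

Variants travel as VCF 4.2, references as FASTA, regions as BED (0-based
half-open on disk, converted to 1-based inclusive in memory), and tables as
TSV with ``NA`` for missing cells.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_vcf(calls: Iterable, path: str | Path, contig_lengths: Mapping[str, int] | None = None) -> None:
    """Write VariantCall records as a single-sample VCF 4.2 text file.

    DP and MQ go to INFO; zygosity is encoded in the sample GT (1/1 for
    homozygous variant, 0/1 for heterozygous, ./. otherwise).
    """
    calls = list(calls)
    contigs = dict(contig_lengths or {})
    for call in calls:
        contigs.setdefault(call.chrom, 0)
    gt_map = {"hom": "1/1", "het": "0/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contigs.items():
            if length:
                fh.write(f"##contig=<ID={name},length={length}>\n")
            else:
                fh.write(f"##contig=<ID={name}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Raw read depth">\n')
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE\n")
        for call in sorted(calls, key=lambda c: (c.chrom, c.pos)):
            info_parts = []
            if call.depth is not None:
                info_parts.append(f"DP={call.depth}")
            if call.mapping_quality is not None:
                info_parts.append(f"MQ={call.mapping_quality:g}")
            info = ";".join(info_parts) or "."
            gt = gt_map.get(call.genotype, "./.")
            fh.write(
                f"{call.chrom}\t{call.pos}\t.\t{call.ref}\t{','.join(call.alts)}\t.\tPASS\t{info}\tGT\t{gt}\n"
            )


def write_bed(regions: Iterable[tuple[str, int, int]], path: str | Path, one_based: bool = True) -> None:
    """Write (chrom, start, end) regions as BED.

    With ``one_based=True`` the inputs are 1-based inclusive intervals and
    are converted to BED's 0-based half-open convention.
    """
    with open(path, "w") as fh:
        for chrom, start, end in regions:
            if one_based:
                start, end = start - 1, end
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_bed(path: str | Path) -> dict[str, tuple[int, int]]:
    """Read BED regions into {chrom: (start, end)} with 1-based inclusive bounds."""
    regions: dict[str, tuple[int, int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            regions[chrom] = (int(start) + 1, int(end))
    return regions


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep="NA")


def read_tsv(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, na_values=["NA"])


def read_pairwise_table(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parse a mixed pairwise-comparison table into count and percent matrices.

    The on-disk layout mirrors the classic marker-panel report: polymorphic
    marker counts above the diagonal, integer percentages (cells suffixed
    with ``%``) below it, and an empty diagonal.  Both returned matrices are
    symmetrized, with NaN on the diagonal.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    names = list(raw.columns)
    counts = pd.DataFrame(float("nan"), index=names, columns=names)
    percents = pd.DataFrame(float("nan"), index=names, columns=names)
    for i, row_name in enumerate(raw.index):
        for j, col_name in enumerate(names):
            cell = raw.iloc[i, j]
            if pd.isna(cell) or str(cell).strip() == "":
                continue
            cell = str(cell).strip()
            if cell.endswith("%"):
                value = float(cell[:-1])
                percents.loc[row_name, col_name] = value
                percents.loc[col_name, row_name] = value
            else:
                value = float(cell)
                counts.loc[row_name, col_name] = value
                counts.loc[col_name, row_name] = value
    return counts, percents
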