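"""Readers and writers for the plain-text formats the pipeline consumes.

BED3/BED6/narrowPeak, a gene-model TSV (``gene_id  symbol  chrom  strand
start  end``), and FASTA. Coordinates are kept 0-based half-open end to end.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GeneModel, GenomicInterval, Peak

GENE_TABLE_COLUMNS = ["gene_id", "symbol", "chrom", "strand", "start", "end"]


class BedParseError(ValueError):
    """Raised for a malformed BED line; message names the file and line."""


def _is_skippable(line: str) -> bool:
    s = line.strip()
    return not s or s.startswith(("#", "track", "browser"))


def read_bed(
    path: Union[str, os.PathLike],
    cell_line: Optional[str] = None,
    replicate: Optional[str] = None,
) -> list[Union[GenomicInterval, Peak]]:
    """Parse a BED3/BED6/narrowPeak file.

    Three-column lines become :class:`GenomicInterval`; lines with extra
    columns become :class:`Peak` (narrowPeak column 10 is the summit offset
    from ``start``; -1 means no summit). ``cell_line``/``replicate`` labels
    are attached to every returned peak.
    """
    out: list[Union[GenomicInterval, Peak]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_skippable(line):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            try:
                iv = GenomicInterval(chrom, start, end, strand)
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
            if len(fields) == 3:
                out.append(iv)
                continue
            name = fields[3] if len(fields) >= 4 and fields[3] != "." else None
            score: Optional[float] = None
            if len(fields) >= 5 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: non-numeric score") from exc
            summit: Optional[int] = None
            if len(fields) >= 10:  # narrowPeak: column 10 = summit offset
                try:
                    offset = int(fields[9])
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: non-integer summit offset") from exc
                if offset >= 0:
                    summit = start + offset
                    if summit >= end:
                        raise BedParseError(f"{path}:{lineno}: summit offset beyond peak end")
            out.append(
                Peak(iv, cell_line=cell_line, replicate=replicate,
                     summit=summit, score=score, name=name)
            )
    return out


def write_bed(
    records: Iterable[Union[GenomicInterval, Peak]], path: Union[str, os.PathLike]
) -> None:
    """Write intervals as BED3 and peaks as narrowPeak (summit preserved)."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, Peak):
                iv = rec.interval
                offset = rec.summit - iv.start if rec.summit is not None else -1
                score = f"{rec.score:g}" if rec.score is not None else "0"
                name = rec.name or "."
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}"
                    f"\t0\t-1\t-1\t{offset}\n"
                )
            else:
                fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\n")


def read_gene_table(path: Union[str, os.PathLike]) -> list[GeneModel]:
    """Read the gene-model TSV (header: gene_id, symbol, chrom, strand, start, end)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: gene table missing columns {missing}")
    genes = []
    for row in df.itertuples(index=False):
        symbol = None if pd.isna(row.symbol) else str(row.symbol)
        genes.append(
            GeneModel(
                gene_id=str(row.gene_id),
                interval=GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand),
                symbol=symbol,
            )
        )
    return genes


def write_gene_table(genes: Sequence[GeneModel], path: Union[str, os.PathLike]) -> None:
    df = pd.DataFrame(
        [
            (g.gene_id, g.symbol or "", g.chrom, g.strand, g.interval.start, g.interval.end)
            for g in genes
        ],
        columns=GENE_TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_fasta(path: Union[str, os.PathLike]) -> dict[str, str]:
    """Read a FASTA file into ``{record id: uppercase sequence}``."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: Union[str, os.PathLike]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")
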