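"""Readers and writers for the standard formats the pipeline touches.

FASTA goes through Biopython; FASTQ is streamed by a minimal 4-line reader
so truncation and length-mismatch errors can name the offending record.
GFF3 is converted from 1-based closed to the package-internal 0-based
half-open convention on the way in and back on the way out.
"""
from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator, Sequence, Union

import pandas as pd
from Bio import SeqIO

from .types import AnnotationFeature, FeatureClass, GenomeSequence, RawRead, UniqueRead

# GFF3/BED type strings recognised as first-class feature classes; anything
# else falls back to biological_region.
_GFF_TYPE_MAP = {
    "mirna": FeatureClass.MIRNA,
    "rrna": FeatureClass.RRNA,
    "trna": FeatureClass.TRNA,
    "snrna": FeatureClass.SNRNA,
    "snorna": FeatureClass.SNORNA,
    "repeat": FeatureClass.REPEAT,
    "repeat_region": FeatureClass.REPEAT,
    "transposable_element": FeatureClass.REPEAT,
    "cds": FeatureClass.CDS,
    "utr5": FeatureClass.UTR5,
    "five_prime_utr": FeatureClass.UTR5,
    "utr3": FeatureClass.UTR3,
    "three_prime_utr": FeatureClass.UTR3,
    "intron": FeatureClass.INTRON,
    "gene_up": FeatureClass.GENE_UP,
    "gene_down": FeatureClass.GENE_DOWN,
    "biological_region": FeatureClass.BIOLOGICAL_REGION,
}


def _open_text(path: Union[str, Path], mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: Union[str, Path], source_tag: str = "nuclear") -> list[GenomeSequence]:
    """Read a (multi-)FASTA file into GenomeSequence records.

    Sequences are uppercased; the header token before the first whitespace
    becomes the chromosome id.
    """
    path = Path(path)
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ValueError(
                    f"{path}: line {lineno}: sequence line before any FASTA header"
                )
            break
    with _open_text(path) as fh:
        records = [
            GenomeSequence(rec.id, str(rec.seq).upper(), source_tag)
            for rec in SeqIO.parse(fh, "fasta")
        ]
    return records


def write_fasta(records: Iterable[GenomeSequence], path: Union[str, Path]) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.chrom_id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_fastq(path: Union[str, Path]) -> Iterator[RawRead]:
    """Lazily stream 4-line FASTQ records (gzip transparently handled)."""
    with _open_text(path) as fh:
        record_index = 0
        while True:
            header = fh.readline()
            if not header:
                return
            header = header.rstrip("\n")
            if not header:
                continue
            if not header.startswith("@"):
                raise ValueError(
                    f"record {record_index}: header does not start with '@': "
                    f"{header[:40]!r}"
                )
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline()
            if not qual:
                raise ValueError(f"truncated FASTQ record at index {record_index}")
            qual = qual.rstrip("\n")
            if len(seq) != len(qual):
                raise ValueError(
                    f"record {record_index}: sequence/quality length mismatch "
                    f"({len(seq)} vs {len(qual)})"
                )
            yield RawRead(seq.upper(), qual, header[1:].split()[0] if header[1:] else "")
            record_index += 1


def write_fastq(reads: Iterable[RawRead], path: Union[str, Path]) -> None:
    with _open_text(path, "wt") as fh:
        for read in reads:
            qual = read.quality if read.quality is not None else "I" * len(read.sequence)
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{qual}\n")


def write_collapsed_fasta(reads: Iterable[UniqueRead], path: Union[str, Path]) -> None:
    """Export collapsed reads as ``>seq{i}_x{count}`` FASTA."""
    with _open_text(path, "wt") as fh:
        for i, read in enumerate(reads, start=1):
            fh.write(f">seq{i}_x{read.count}\n{read.insert}\n")


def _feature_class_for(type_str: str) -> FeatureClass:
    return _GFF_TYPE_MAP.get(type_str.lower(), FeatureClass.BIOLOGICAL_REGION)


def read_annotation(path: Union[str, Path], format: str = "gff3") -> list[AnnotationFeature]:
    """Read GFF3 or BED6 annotation into 0-based half-open features.

    GFF3's 1-based closed coordinates are converted; BED is already
    0-based half-open and passes through. Unknown feature types map to
    ``biological_region``.
    """
    if format not in ("gff3", "bed"):
        raise ValueError(f"unknown annotation format {format!r}")
    features: list[AnnotationFeature] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if format == "gff3":
                if len(fields) < 8:
                    raise ValueError(f"line {lineno}: GFF3 needs >= 8 columns")
                chrom, _source, ftype, start1, end1, _score, strand = fields[:7]
                start, end = int(start1) - 1, int(end1)
                name = ""
                if len(fields) >= 9:
                    for kv in fields[8].split(";"):
                        if kv.startswith(("ID=", "Name=")):
                            name = kv.split("=", 1)[1]
                            break
                fclass = _feature_class_for(ftype)
            else:
                if len(fields) < 3:
                    raise ValueError(f"line {lineno}: BED needs >= 3 columns")
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 else ""
                strand = fields[5] if len(fields) > 5 else "."
                fclass = _feature_class_for(name) if name else FeatureClass.BIOLOGICAL_REGION
            if end < start:
                raise ValueError(f"line {lineno}: end < start ({end} < {start})")
            if strand not in ("+", "-", "."):
                strand = "."
            features.append(
                AnnotationFeature(chrom, start, end, strand, fclass, name)
            )
    return features


def write_annotation_gff3(
    features: Iterable[AnnotationFeature], path: Union[str, Path]
) -> None:
    """Write features as GFF3 (converting back to 1-based closed)."""
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                "\t".join(
                    [
                        f.chrom_id,
                        "srnacompare",
                        f.feature_class.value,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        f"ID={f.name}" if f.name else ".",
                    ]
                )
                + "\n"
            )


def write_report(
    table: Union[pd.DataFrame, Sequence[Sequence]], path: Union[str, Path]
) -> None:
    """Write a rectangular table as TSV, floats at 6 significant digits.

    Accepts a DataFrame or a list of rows whose first row is the header;
    ragged rows raise before anything is written.
    """
    if not isinstance(table, pd.DataFrame):
        rows = [list(r) for r in table]
        if not rows:
            raise ValueError("table must at least contain a header row")
        width = len(rows[0])
        for i, row in enumerate(rows):
            if len(row) != width:
                raise ValueError(f"ragged table: row {i} has {len(row)} != {width} cells")
        table = pd.DataFrame(rows[1:], columns=rows[0])
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
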