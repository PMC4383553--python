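"""Readers and writers for the external formats the pipeline touches.

FASTA I/O goes through Biopython. GFF3 uses 1-based inclusive coordinates on
disk and BED uses 0-based half-open; both are converted to the internal
0-based half-open convention at this boundary and nowhere else. All tabular
writers emit a ``#`` header comment naming the tool version and, when given,
a configuration hash.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import Gene, Interval, __version__, logger


def _header_comment(config_hash: str | None = None) -> str:
    tag = f"# retromod v{__version__}"
    if config_hash:
        tag += f" config={config_hash}"
    return tag + "\n"


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_sequences(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: uppercase sequence} mapping.

    Raises ``ValueError`` naming the offending record on duplicate names or
    empty sequences.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate sequence name: {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence record: {rec.id!r}")
        out[rec.id] = seq
    if not out:
        raise ValueError(f"no FASTA records found in {path}")
    return out


def write_sequences(path: str | os.PathLike, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Gene annotation: GFF3 and BED12
# ---------------------------------------------------------------------------


def read_annotation(path: str | os.PathLike, dialect: str = "gff3") -> list[Gene]:
    """Read gene models; introns are derived later from exon gaps.

    ``dialect`` is ``gff3`` (1-based inclusive) or ``bed12`` (0-based
    half-open, one transcript per line).
    """
    if dialect == "gff3":
        return _read_gff3(path)
    if dialect == "bed12":
        return _read_bed12(path)
    raise ValueError(f"unknown annotation dialect: {dialect!r}")


def _read_gff3(path: str | os.PathLike) -> list[Gene]:
    exons: dict[str, list[tuple[str, str, int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(fields)}")
            chrom, _, ftype, start, end, _, strand, _, attrs = fields
            if ftype != "exon":
                continue
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            parent = attr.get("Parent") or attr.get("ID")
            if parent is None:
                raise ValueError(f"{path}:{lineno}: exon without Parent attribute")
            # GFF3 is 1-based inclusive; internal is 0-based half-open.
            exons.setdefault(parent, []).append((chrom, strand, int(start) - 1, int(end)))
    return _assemble_genes(exons)


def _read_bed12(path: str | os.PathLike) -> list[Gene]:
    exons: dict[str, list[tuple[str, str, int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 BED columns, got {len(fields)}")
            chrom, start, _end, name, _, strand = fields[:6]
            start = int(start)
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != len(starts) or len(sizes) != int(fields[9]):
                raise ValueError(f"{path}:{lineno}: blockCount/blockSizes/blockStarts disagree")
            for sz, st in zip(sizes, starts):
                exons.setdefault(name, []).append((chrom, strand, start + st, start + st + sz))
    return _assemble_genes(exons)


def _assemble_genes(exons: dict[str, list[tuple[str, str, int, int]]]) -> list[Gene]:
    genes = []
    for gene_id, rows in exons.items():
        chroms = {r[0] for r in rows}
        strands = {r[1] for r in rows}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(f"{gene_id}: exons on multiple chromosomes or strands")
        # Gene.__post_init__ rejects overlapping / out-of-order exons.
        genes.append(Gene(gene_id, chroms.pop(), strands.pop(), [(s, e) for _, _, s, e in rows]))
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def write_annotation(
    path: str | os.PathLike,
    genes: list[Gene],
    dialect: str = "gff3",
    config_hash: str | None = None,
) -> None:
    with open(path, "w") as fh:
        if dialect == "gff3":
            fh.write("##gff-version 3\n")
            fh.write(_header_comment(config_hash))
            for g in genes:
                fh.write(
                    f"{g.chrom}\tretromod\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}\n"
                )
                for i, (s, e) in enumerate(g.exons):
                    fh.write(
                        f"{g.chrom}\tretromod\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                        f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                    )
        elif dialect == "bed12":
            fh.write(_header_comment(config_hash))
            for g in genes:
                sizes = ",".join(str(e - s) for s, e in g.exons)
                starts = ",".join(str(s - g.start) for s, _ in g.exons)
                fh.write(
                    f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                    f"{g.start}\t{g.end}\t0\t{len(g.exons)}\t{sizes}\t{starts}\n"
                )
        else:
            raise ValueError(f"unknown annotation dialect: {dialect!r}")


# ---------------------------------------------------------------------------
# Repeat tables (simplified 6-column RepeatMasker-style TSV)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RepeatRecord:
    """One repeat annotation row, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str
    repeat_name: str
    repeat_family: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.repeat_name}: start must be < end")
        if self.strand not in "+-":
            raise ValueError(f"{self.repeat_name}: strand must be + or -")


REPEAT_COLUMNS = ("chrom", "start", "end", "strand", "repeat_name", "repeat_family")


def read_repeat_table(
    path: str | os.PathLike, family_filter: set[str] | None = None
) -> list[RepeatRecord]:
    """Read the simplified repeat TSV, keeping rows whose family is in
    ``family_filter`` (empty/None keeps everything)."""
    records: list[RepeatRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields == list(REPEAT_COLUMNS):
                continue
            if len(fields) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
            try:
                rec = RepeatRecord(
                    fields[0], int(fields[1]), int(fields[2]), fields[3], fields[4], fields[5]
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if not family_filter or rec.repeat_family in family_filter:
                records.append(rec)
    return records


def write_repeat_table(
    path: str | os.PathLike, records: list[RepeatRecord], config_hash: str | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(config_hash))
        fh.write("\t".join(REPEAT_COLUMNS) + "\n")
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.strand}\t{r.repeat_name}\t{r.repeat_family}\n")


# ---------------------------------------------------------------------------
# BED6 and generic TSV tables
# ---------------------------------------------------------------------------


def write_bed6(
    path: str | os.PathLike,
    rows: list[tuple[str, int, int, str, float, str]],
    config_hash: str | None = None,
) -> None:
    """Write (chrom, start, end, name, score, strand) rows as BED6."""
    with open(path, "w") as fh:
        fh.write(_header_comment(config_hash))
        for chrom, start, end, name, score, strand in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a TSV table, skipping ``#`` header comments."""
    return pd.read_csv(path, sep="\t", comment="#")


def write_table(
    path: str | os.PathLike, table: pd.DataFrame, config_hash: str | None = None
) -> None:
    buf = io.StringIO()
    table.to_csv(buf, sep="\t", index=False)
    with open(path, "w") as fh:
        fh.write(_header_comment(config_hash))
        fh.write(buf.getvalue())
    logger.debug("wrote %d rows to %s", len(table), path)
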