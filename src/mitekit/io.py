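"""Readers and writers for the standard formats the pipeline consumes.

All internal coordinates are 0-based half-open.  GFF3 is converted at the
boundary (1-based inclusive on disk); BED is emitted natively 0-based
half-open.  FASTA sequences are upper-cased on input and any character
outside ACGTN is collapsed to N.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from ._seq import normalize
from .errors import FormatError, ValidationError

__all__ = [
    "GenomeSequence",
    "GeneModel",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "write_bed",
]


@dataclass(frozen=True)
class GenomeSequence:
    """One FASTA record: identifier plus an ACGTN nucleotide string."""

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class GeneModel:
    """A gene with exon structure; coordinates 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start {self.start} >= end {self.end}")
        if self.strand not in "+-":
            raise ValidationError(
                f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")
        if not self.exons:
            self.exons = [(self.start, self.end)]
        self.exons.sort()
        prev_end = None
        for a, b in self.exons:
            if a >= b:
                raise ValidationError(
                    f"gene {self.gene_id}: empty exon ({a}, {b})")
            if a < self.start or b > self.end:
                raise ValidationError(
                    f"gene {self.gene_id}: exon ({a}, {b}) outside gene span "
                    f"[{self.start}, {self.end})")
            if prev_end is not None and a < prev_end:
                raise ValidationError(
                    f"gene {self.gene_id}: overlapping exons at ({a}, {b})")
            prev_end = b

    @property
    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return out


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Parse a FASTA file into :class:`GenomeSequence` records.

    Sequences are normalised (upper case, non-ACGT -> N).  Raises
    :class:`FormatError` naming the line number on a malformed header or an
    empty file.
    """
    records: list[GenomeSequence] = []
    header: str | None = None
    chunks: list[str] = []
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            n_lines += 1
            if line.startswith(">"):
                if header is not None:
                    records.append(GenomeSequence(header, normalize("".join(chunks))))
                header = line[1:].split()[0] if len(line) > 1 else ""
                if not header:
                    raise FormatError(f"{path}: empty FASTA header at line {lineno}")
                chunks = []
            else:
                if header is None:
                    raise FormatError(
                        f"{path}: expected '>' header at line {lineno}, got sequence data")
                chunks.append(line)
    if n_lines == 0:
        raise FormatError(f"{path}: empty FASTA file (line 1)")
    if header is not None:
        records.append(GenomeSequence(header, normalize("".join(chunks))))
    return records


def write_fasta(records: Iterable[GenomeSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def _gff_attrs(field9: str) -> dict[str, str]:
    out = {}
    for item in field9.strip().split(";"):
        if not item:
            continue
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene/exon features from a GFF3 file.

    Exon ``Parent`` attributes are resolved through mRNA records when
    present.  Genes without exon rows get a single exon spanning the gene.
    An exon outside its parent gene span raises :class:`ValidationError`.
    """
    genes: dict[str, dict] = {}
    mrna_parent: dict[str, str] = {}
    pending_exons: list[tuple[int, str, int, int]] = []  # lineno, parent, start, end
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"{path}: expected 9 tab-separated fields at line {lineno}")
            chrom, _src, ftype, start_s, end_s, _score, strand, _frame, attrs_s = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(
                    f"{path}: non-integer coordinates at line {lineno}") from None
            start, end = start1 - 1, end1  # 1-based inclusive -> 0-based half-open
            attrs = _gff_attrs(attrs_s)
            if ftype == "gene":
                gid = attrs.get("ID", f"gene_line{lineno}")
                genes[gid] = {
                    "gene_id": gid, "chrom": chrom, "start": start, "end": end,
                    "strand": strand if strand in "+-" else "+", "exons": [],
                }
            elif ftype in ("mRNA", "transcript"):
                tid = attrs.get("ID")
                parent = attrs.get("Parent")
                if tid and parent:
                    mrna_parent[tid] = parent
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if parent is None:
                    raise FormatError(
                        f"{path}: exon without Parent attribute at line {lineno}")
                pending_exons.append((lineno, parent, start, end))
    for lineno, parent, start, end in pending_exons:
        gid = mrna_parent.get(parent, parent)
        if gid not in genes:
            raise ValidationError(
                f"{path}: exon at line {lineno} references unknown parent {parent!r}")
        g = genes[gid]
        if start < g["start"] or end > g["end"]:
            raise ValidationError(
                f"{path}: exon at line {lineno} ({start + 1}..{end}) lies outside "
                f"gene {gid} span ({g['start'] + 1}..{g['end']})")
        g["exons"].append((start, end))
    models = [GeneModel(**g) for g in genes.values()]
    models.sort(key=lambda g: (g.chrom, g.start, g.end, g.gene_id))
    return models


def write_gff3(genes: Sequence[GeneModel], path: str | Path, source: str = "mitekit") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.end, g.gene_id)):
            fh.write("\t".join([
                g.chrom, source, "gene", str(g.start + 1), str(g.end), ".",
                g.strand, ".", f"ID={g.gene_id}",
            ]) + "\n")
            mrna_id = g.gene_id + ".t1"
            fh.write("\t".join([
                g.chrom, source, "mRNA", str(g.start + 1), str(g.end), ".",
                g.strand, ".", f"ID={mrna_id};Parent={g.gene_id}",
            ]) + "\n")
            for i, (a, b) in enumerate(g.exons, start=1):
                fh.write("\t".join([
                    g.chrom, source, "exon", str(a + 1), str(b), ".",
                    g.strand, ".", f"ID={mrna_id}.exon{i};Parent={mrna_id}",
                ]) + "\n")


def write_bed(intervals: Iterable, path: str | Path) -> None:
    """Write BED6 lines.

    Each item must expose chrom/start/end plus either a family_id or name,
    an optional identity (emitted in per-mille as the score) and an
    optional strand.
    """
    with open(path, "w") as fh:
        for iv in intervals:
            name = getattr(iv, "family_id", None) or getattr(iv, "name", ".")
            identity = getattr(iv, "identity", None)
            score = str(int(round(identity * 1000))) if identity is not None else "0"
            strand = getattr(iv, "strand", "+")
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{strand}\n")
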