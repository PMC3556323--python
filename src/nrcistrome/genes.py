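"""Gene models and annotation I/O (BED12 and minimal GTF).

A :class:`GeneModel` is one transcript: strand-resolved TSS, CDS bounds and
ordered disjoint exons, all in 0-based half-open coordinates.  The TSS of a
minus-strand transcript is ``tx_end - 1`` (its last base under half-open
coordinates), symmetric with the plus strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .intervals import GenomicInterval


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r} for {self.gene_id}")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"{self.gene_id}: tx_start must be < tx_end")
        if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
            raise ValueError(f"{self.gene_id}: CDS must lie within the transcript")
        prev_end = self.tx_start - 1
        for ex in self.exons:
            if ex.chrom != self.chrom:
                raise ValueError(f"{self.gene_id}: exon on wrong chromosome")
            if ex.start < self.tx_start or ex.end > self.tx_end:
                raise ValueError(f"{self.gene_id}: exon outside transcript bounds")
            if ex.start <= prev_end:
                raise ValueError(f"{self.gene_id}: exons must be sorted and disjoint")
            prev_end = ex.end - 1

    @property
    def tss(self) -> int:
        """Strand-resolved transcription start site (a single bp)."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def tx_interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.tx_start, self.tx_end)

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start))
        return tuple(out)

    @property
    def coding(self) -> bool:
        return self.cds_end > self.cds_start


def _parse_bed12_line(fields: list[str]) -> GeneModel:
    chrom = fields[0]
    start, end = int(fields[1]), int(fields[2])
    name = fields[3]
    strand = fields[5]
    cds_start, cds_end = int(fields[6]), int(fields[7])
    n_blocks = int(fields[9])
    sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
    offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
    if len(sizes) != n_blocks or len(offsets) != n_blocks:
        raise ValueError("blockCount disagrees with blockSizes/blockStarts")
    exons = tuple(
        GenomicInterval(chrom, start + off, start + off + size)
        for off, size in zip(offsets, sizes)
    )
    return GeneModel(name, chrom, strand, start, end, cds_start, cds_end, exons)


def parse_gene_models(path: str | Path, dialect: str | None = None) -> list[GeneModel]:
    """Parse gene models from BED12 or GTF.

    ``dialect`` is ``"bed12"`` or ``"gtf"``; by default it is inferred from
    the file suffix (.gtf/.gff -> GTF, otherwise BED12).  Malformed lines
    raise ``ValueError`` naming the line number.
    """
    path = Path(path)
    if dialect is None:
        dialect = "gtf" if path.suffix.lower() in (".gtf", ".gff") else "bed12"
    if dialect == "bed12":
        return _parse_bed12(path)
    if dialect == "gtf":
        return _parse_gtf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _parse_bed12(path: Path) -> list[GeneModel]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 BED fields")
            try:
                out.append(_parse_bed12_line(fields))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def _gtf_attributes(raw: str) -> dict[str, str]:
    attrs = {}
    for item in raw.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        key, _, value = item.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def _parse_gtf(path: Path) -> list[GeneModel]:
    """Minimal GTF reader: exon and CDS features grouped by transcript_id.

    GTF 1-based closed coordinates are converted to 0-based half-open.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF fields")
            chrom, _, feature, start, end, _, strand, _, attr_raw = fields[:9]
            if feature not in ("exon", "CDS"):
                continue
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
            attrs = _gtf_attributes(attr_raw)
            tid = attrs.get("transcript_id")
            if tid is None:
                raise ValueError(f"{path}:{lineno}: missing transcript_id attribute")
            try:
                s, e = int(start) - 1, int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad coordinates") from exc
            prev = meta.setdefault(tid, (chrom, strand))
            if prev != (chrom, strand):
                raise ValueError(f"{path}:{lineno}: inconsistent chrom/strand for {tid}")
            (exons if feature == "exon" else cds).setdefault(tid, []).append((s, e))
    out = []
    for tid, (chrom, strand) in meta.items():
        ex = sorted(exons.get(tid, []))
        if not ex:
            raise ValueError(f"transcript {tid} has no exon features")
        tx_start, tx_end = ex[0][0], ex[-1][1]
        cd = sorted(cds.get(tid, []))
        cds_start = cd[0][0] if cd else tx_start
        cds_end = cd[-1][1] if cd else tx_start  # non-coding: empty CDS
        out.append(
            GeneModel(
                tid,
                chrom,
                strand,
                tx_start,
                tx_end,
                cds_start,
                cds_end,
                tuple(GenomicInterval(chrom, s, e) for s, e in ex),
            )
        )
    out.sort(key=lambda g: (g.chrom, g.tx_start, g.gene_id))
    return out


def write_bed12(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(len(e)) for e in g.exons) + ","
            offsets = ",".join(str(e.start - g.tx_start) for e in g.exons) + ","
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        g.chrom,
                        g.tx_start,
                        g.tx_end,
                        g.gene_id,
                        0,
                        g.strand,
                        g.cds_start,
                        g.cds_end,
                        0,
                        len(g.exons),
                        sizes,
                        offsets,
                    )
                )
                + "\n"
            )
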