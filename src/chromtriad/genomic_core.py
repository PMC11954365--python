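"""Coordinate conventions, interval algebra, and plain-text genomic I/O.

All coordinates are 0-based half-open (BED convention): an interval
``[start, end)`` covers bases ``start .. end-1``.  Chromosome names are
matched strictly ("chr1" and "1" are different chromosomes); no dialect
coercion is ever attempted, so mixed naming surfaces as an explicit error
rather than silently empty overlaps.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence


class BedFormatError(ValueError):
    """A BED-like record that cannot be parsed."""


class ChromosomeMismatchError(ValueError):
    """An interval refers to a chromosome unknown to the genome definition."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic span ``[start, end)`` on a named chromosome.

    ``strand`` is one of ``'+'``, ``'-'`` or ``'.'`` (unstranded).  Strand is
    carried through all operations but ignored by overlap arithmetic: peaks
    are unstranded objects.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of + - . , got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Floor midpoint, itself a valid base of the interval."""
        return (self.start + self.end) // 2

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class Peak:
    """A called peak: an interval with signal score and replicate provenance.

    ``support`` counts the distinct replicates contributing to the peak; raw
    single-replicate calls have support 1, consensus peaks ≥ 2.
    """

    interval: GenomicInterval
    score: float = 0.0
    sample_id: str = ""
    replicate_id: str = ""
    support: int = 1

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError(f"score must be >= 0, got {self.score}")
        if self.support < 1:
            raise ValueError(f"support must be >= 1, got {self.support}")

    # convenience pass-throughs used everywhere downstream
    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def midpoint(self) -> int:
        return self.interval.midpoint


@dataclass(frozen=True)
class GeneModel:
    """Minimal gene annotation: span, TSS, exons and optional 5'UTR."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    gene_span: GenomicInterval
    exons: tuple[GenomicInterval, ...] = ()
    utr5: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if not self.gene_span.contains(self.tss):
            raise ValueError(
                f"{self.gene_id}: TSS {self.tss} outside gene span "
                f"[{self.gene_span.start}, {self.gene_span.end})"
            )
        exons = tuple(sorted(self.exons))
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for ex in exons:
            if ex.start < self.gene_span.start or ex.end > self.gene_span.end:
                raise ValueError(f"{self.gene_id}: exon outside gene span")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"{self.gene_id}: overlapping exons")
            prev_end = ex.end

    @property
    def exonic_length(self) -> int:
        return sum(ex.length for ex in self.exons) or self.gene_span.length


@dataclass(frozen=True)
class GenomeDef:
    """Chromosome sizes; every interval in a dataset must lie within them."""

    chrom_sizes: dict[str, int]

    def __post_init__(self) -> None:
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive size")

    @property
    def total_size(self) -> int:
        return sum(self.chrom_sizes.values())

    def check(self, iv: GenomicInterval) -> None:
        if iv.chrom not in self.chrom_sizes:
            raise ChromosomeMismatchError(
                f"chromosome {iv.chrom!r} not in genome definition "
                f"(known: {sorted(self.chrom_sizes)}); chromosome names are "
                "matched strictly and never coerced"
            )
        if iv.end > self.chrom_sizes[iv.chrom]:
            raise ValueError(
                f"interval [{iv.start}, {iv.end}) exceeds {iv.chrom} "
                f"length {self.chrom_sizes[iv.chrom]}"
            )


# ---------------------------------------------------------------------------
# interval algebra
# ---------------------------------------------------------------------------

def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals (0 on different chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def overlap_fraction(a: GenomicInterval, b: GenomicInterval) -> float:
    """Overlap length divided by the length of the *shorter* interval.

    Anchoring the fraction on the shorter interval makes the measure
    symmetric and is the most permissive reading of a "minimum 50% overlap"
    rule; containment therefore always scores 1.0.
    """
    ov = overlap_length(a, b)
    if ov == 0:
        return 0.0
    return ov / min(a.length, b.length)


def merge_cluster(intervals: Sequence[GenomicInterval]) -> GenomicInterval:
    """Convex hull ``[min(starts), max(ends))`` of intervals on one chromosome."""
    if not intervals:
        raise ValueError("merge_cluster of an empty collection is undefined")
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) > 1:
        raise ValueError(f"intervals span multiple chromosomes: {sorted(chroms)}")
    return GenomicInterval(
        intervals[0].chrom,
        min(iv.start for iv in intervals),
        max(iv.end for iv in intervals),
    )


# ---------------------------------------------------------------------------
# readers / writers (BED3-BED6, chrom sizes, BED12 genes)
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[Peak]:
    """Read a BED3-BED6 file into Peaks, sorted by (chrom, start, end).

    Column 4 (name) maps to ``sample_id``, column 5 to ``score``; further
    columns are ignored.  Coordinates are preserved verbatim.
    """
    peaks: list[Peak] = []
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedFormatError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedFormatError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if end <= start:
                raise BedFormatError(
                    f"{path}:{lineno}: end ({end}) must exceed start ({start})"
                )
            name = fields[3] if len(fields) >= 4 and fields[3] != "." else ""
            score = 0.0
            if len(fields) >= 5 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedFormatError(
                        f"{path}:{lineno}: non-numeric score {fields[4]!r}"
                    ) from exc
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            peaks.append(
                Peak(
                    interval=GenomicInterval(fields[0], start, end, strand),
                    score=score,
                    sample_id=name,
                )
            )
    peaks.sort(key=lambda p: (p.chrom, p.start, p.end))
    return peaks


def write_bed(
    peaks: Iterable[Peak], path: str | Path, with_support: bool = False
) -> None:
    """Write Peaks as BED6 (+ optional support column), sorted canonically."""
    rows = sorted(peaks, key=lambda p: (p.chrom, p.start, p.end))
    with Path(path).open("w") as fh:
        for p in rows:
            cols = [
                p.chrom,
                str(p.start),
                str(p.end),
                p.sample_id or ".",
                format(p.score, "g"),
                p.interval.strand,
            ]
            if with_support:
                cols.append(str(p.support))
            fh.write("\t".join(cols) + "\n")


def read_chrom_sizes(path: str | Path) -> GenomeDef:
    """Two-column TSV: chromosome name, length."""
    sizes: dict[str, int] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise BedFormatError(f"{path}:{lineno}: expected 2 columns")
            sizes[fields[0]] = int(fields[1])
    return GenomeDef(chrom_sizes=sizes)


def write_chrom_sizes(genome: GenomeDef, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for chrom in sorted(genome.chrom_sizes):
            fh.write(f"{chrom}\t{genome.chrom_sizes[chrom]}\n")


def read_bed12_genes(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED12.

    Dialect: ``thickStart``/``thickEnd`` delimit the CDS; the 5'UTR is the
    strand-aware span between the transcript edge and the CDS start; the TSS
    is ``start`` on '+' and ``end-1`` on '-'.
    """
    genes: list[GeneModel] = []
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise BedFormatError(f"{path}:{lineno}: expected 12 BED12 columns")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            gene_id, strand = f[3], f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise BedFormatError(f"{path}:{lineno}: block count mismatch")
            exons = tuple(
                GenomicInterval(chrom, start + off, start + off + sz, strand)
                for off, sz in zip(offsets, sizes)
            )
            span = GenomicInterval(chrom, start, end, strand)
            tss = start if strand == "+" else end - 1
            utr5 = None
            if strand == "+" and thick_start > start:
                utr5 = GenomicInterval(chrom, start, thick_start, strand)
            elif strand == "-" and thick_end < end:
                utr5 = GenomicInterval(chrom, thick_end, end, strand)
            genes.append(
                GeneModel(
                    gene_id=gene_id, chrom=chrom, strand=strand, tss=tss,
                    gene_span=span, exons=exons, utr5=utr5,
                )
            )
    return genes


def write_bed12_genes(genes: Iterable[GeneModel], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.gene_span.start)):
            span = g.gene_span
            exons = g.exons or (span,)
            if g.utr5 is None:
                thick_start, thick_end = span.start, span.end
            elif g.strand == "+":
                thick_start, thick_end = g.utr5.end, span.end
            else:
                thick_start, thick_end = span.start, g.utr5.start
            sizes = ",".join(str(ex.length) for ex in exons)
            offsets = ",".join(str(ex.start - span.start) for ex in exons)
            fh.write(
                "\t".join(
                    [
                        g.chrom, str(span.start), str(span.end), g.gene_id,
                        "0", g.strand, str(thick_start), str(thick_end),
                        "0", str(len(exons)), sizes, offsets,
                    ]
                )
                + "\n"
            )


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with Path(path).open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
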