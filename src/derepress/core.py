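"""Genomic interval types, annotation I/O, and shared interval arithmetic.

All internal coordinates are 0-based half-open; conversions happen only at
I/O boundaries (GFF3 is 1-based inclusive on disk). Strand is carried but
ignored by every downstream statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("derepress")

_VALID_STRANDS = {"+", "-", "."}


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise AnnotationError("chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid interval [{self.start}, {self.end}): require 0 <= start < end"
            )
        if self.strand not in _VALID_STRANDS:
            raise AnnotationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """Half-open overlap: true iff same chromosome and the spans intersect.

    Abutting intervals ([0,10) vs [10,20)) do not overlap.
    """
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


@dataclass
class GeneAnnotationSet:
    """Named, stranded gene intervals plus chromosome lengths.

    ``chrom_lengths`` is required for any sampling operation; lengths
    inferred from the data (max end per chromosome) trigger a logged
    warning because random-region draws then under-cover the chromosome.
    """

    genes: list[tuple[str, GenomicInterval]] = field(default_factory=list)
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for gene_id, iv in self.genes:
            if gene_id in seen:
                raise AnnotationError(f"duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            length = self.chrom_lengths.get(iv.chrom)
            if length is not None and iv.end > length:
                raise AnnotationError(
                    f"gene {gene_id!r} extends past end of {iv.chrom} ({iv.end} > {length})"
                )

    def __len__(self) -> int:
        return len(self.genes)

    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.genes]

    def interval_of(self, gene_id: str) -> GenomicInterval:
        for g, iv in self.genes:
            if g == gene_id:
                return iv
        raise KeyError(gene_id)

    def genes_on(self, chrom: str) -> list[tuple[str, GenomicInterval]]:
        return [(g, iv) for g, iv in self.genes if iv.chrom == chrom]

    def starts_on(self, chrom: str) -> np.ndarray:
        """Gene start coordinates on a chromosome, in annotation order."""
        return np.array([iv.start for _, iv in self.genes_on(chrom)], dtype=np.int64)

    def chromosomes(self) -> list[str]:
        out: list[str] = []
        for _, iv in self.genes:
            if iv.chrom not in out:
                out.append(iv.chrom)
        return out

    def subset(self, gene_ids: Iterable[str]) -> "GeneAnnotationSet":
        wanted = set(gene_ids)
        return GeneAnnotationSet(
            genes=[(g, iv) for g, iv in self.genes if g in wanted],
            chrom_lengths=dict(self.chrom_lengths),
        )


@dataclass
class RepeatAnnotationSet:
    """Repeat elements as (family_name, interval) pairs; no merging."""

    elements: list[tuple[str, GenomicInterval]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for fam, _ in self.elements:
            if not fam:
                raise AnnotationError("repeat family name must be non-empty")

    def __len__(self) -> int:
        return len(self.elements)

    def families(self) -> list[str]:
        out: list[str] = []
        for fam, _ in self.elements:
            if fam not in out:
                out.append(fam)
        return out

    def of_family(self, family: str) -> list[GenomicInterval]:
        return [iv for fam, iv in self.elements if fam == family]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a UCSC-style two-column chrom.sizes TSV."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise AnnotationError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            try:
                sizes[fields[0]] = int(fields[1])
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: bad length {fields[1]!r}") from exc
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def _parse_bed_line(fields: Sequence[str], path: str | Path, lineno: int):
    if len(fields) < 3:
        raise AnnotationError(f"{path}:{lineno}: BED needs >= 3 columns, got {len(fields)}")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise AnnotationError(f"{path}:{lineno}: non-integer coordinate") from exc
    if start >= end:
        raise AnnotationError(f"{path}:{lineno}: start >= end ({start} >= {end})")
    name = fields[3] if len(fields) > 3 else f"feature_{lineno}"
    strand = fields[5] if len(fields) > 5 and fields[5] in _VALID_STRANDS else "."
    return name, GenomicInterval(chrom, start, end, strand)


def _iter_data_lines(path: str | Path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


_GFF_GENE_TYPES = {"gene", "protein_coding_gene", "pseudogene"}


def _gff3_records(path: str | Path):
    for lineno, fields in _iter_data_lines(path):
        if len(fields) != 9:
            raise AnnotationError(f"{path}:{lineno}: GFF3 needs 9 columns, got {len(fields)}")
        chrom, _source, ftype, start_s, end_s, _score, strand, _frame, attrs = fields
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError as exc:
            raise AnnotationError(f"{path}:{lineno}: non-integer coordinate") from exc
        # GFF3 is 1-based inclusive on disk -> 0-based half-open in memory
        if start1 < 1 or end1 < start1:
            raise AnnotationError(f"{path}:{lineno}: invalid GFF3 span {start1}..{end1}")
        attr_map = dict(
            kv.split("=", 1) for kv in attrs.split(";") if kv and "=" in kv
        )
        name = attr_map.get("ID") or attr_map.get("Name") or f"feature_{lineno}"
        strand = strand if strand in _VALID_STRANDS else "."
        yield ftype, name, GenomicInterval(chrom, start1 - 1, end1, strand)


def read_gene_annotation(
    path: str | Path,
    format: str = "BED",
    chrom_sizes: str | Path | dict[str, int] | None = None,
) -> GeneAnnotationSet:
    """Read gene annotation from BED (0-based half-open) or GFF3 (1-based).

    ``chrom_sizes`` may be a path to a chrom.sizes file or a dict; when
    absent, chromosome lengths are inferred from the maximum feature end
    (logged as a warning, because sampling operations need true lengths).
    """
    fmt = format.upper()
    genes: list[tuple[str, GenomicInterval]] = []
    if fmt == "BED":
        for lineno, fields in _iter_data_lines(path):
            genes.append(_parse_bed_line(fields, path, lineno))
    elif fmt == "GFF3":
        for ftype, name, iv in _gff3_records(path):
            if ftype in _GFF_GENE_TYPES:
                genes.append((name, iv))
    else:
        raise ValueError(f"unknown gene annotation format {format!r}")

    if chrom_sizes is None:
        sizes: dict[str, int] = {}
        for _, iv in genes:
            sizes[iv.chrom] = max(sizes.get(iv.chrom, 0), iv.end)
        if genes:
            logger.warning(
                "chrom_lengths inferred from max feature end; provide a chrom.sizes "
                "file for correct random sampling"
            )
    elif isinstance(chrom_sizes, dict):
        sizes = dict(chrom_sizes)
    else:
        sizes = read_chrom_sizes(chrom_sizes)
    return GeneAnnotationSet(genes=genes, chrom_lengths=sizes)


def write_gene_annotation(annotation: GeneAnnotationSet, path: str | Path) -> None:
    """Write genes as 6-column BED (score column written as 0)."""
    with open(path, "w") as fh:
        for gene_id, iv in annotation.genes:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{gene_id}\t0\t{iv.strand}\n")


_RMSK_REQUIRED = ("genoName", "genoStart", "genoEnd", "repName")


def read_repeat_annotation(path: str | Path, format: str = "rmsk") -> RepeatAnnotationSet:
    """Read repeats from a UCSC rmsk-style TSV (header row) or BED+name.

    The rmsk dialect must provide genoName/genoStart/genoEnd/repName
    columns; repName becomes the family name.
    """
    fmt = format.lower()
    elements: list[tuple[str, GenomicInterval]] = []
    if fmt == "rmsk":
        with open(path) as fh:
            header_line = fh.readline().rstrip("\n")
        header = [c.lstrip("#") for c in header_line.split("\t")]
        missing = [c for c in _RMSK_REQUIRED if c not in header]
        if missing:
            raise AnnotationError(f"{path}: rmsk table missing columns {missing}")
        idx = {c: header.index(c) for c in _RMSK_REQUIRED}
        with open(path) as fh:
            next(fh)
            for lineno, line in enumerate(fh, 2):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                try:
                    iv = GenomicInterval(
                        fields[idx["genoName"]],
                        int(fields[idx["genoStart"]]),
                        int(fields[idx["genoEnd"]]),
                    )
                except (IndexError, ValueError) as exc:
                    raise AnnotationError(f"{path}:{lineno}: malformed rmsk row") from exc
                elements.append((fields[idx["repName"]], iv))
    elif fmt == "bed":
        for lineno, fields in _iter_data_lines(path):
            name, iv = _parse_bed_line(fields, path, lineno)
            elements.append((name, iv))
    else:
        raise ValueError(f"unknown repeat annotation format {format!r}")
    return RepeatAnnotationSet(elements=elements)


def write_repeat_annotation(repeats: RepeatAnnotationSet, path: str | Path) -> None:
    """Write repeats as 4-column BED with the family name in column 4."""
    with open(path, "w") as fh:
        for fam, iv in repeats.elements:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{fam}\n")


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------


def gene_density(
    annotation: GeneAnnotationSet, chrom: str, window_bp: int
) -> list[tuple[GenomicInterval, int]]:
    """Count genes in tiling windows [0,w), [w,2w), ... along a chromosome.

    A gene is counted in the window containing its start, so the window
    counts sum to the number of genes on the chromosome.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if chrom not in annotation.chrom_lengths:
        raise KeyError(f"unknown chromosome {chrom!r}")
    length = annotation.chrom_lengths[chrom]
    n_windows = int(np.ceil(length / window_bp))
    starts = annotation.starts_on(chrom)
    counts = np.bincount(starts // window_bp, minlength=n_windows) if starts.size else np.zeros(
        n_windows, dtype=np.int64
    )
    out = []
    for i in range(n_windows):
        lo = i * window_bp
        hi = min((i + 1) * window_bp, length)
        out.append((GenomicInterval(chrom, lo, hi), int(counts[i])))
    return out
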