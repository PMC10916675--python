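"""Genomic data model, standard-format I/O, interval algebra and feature annotation.

All coordinates are 0-based half-open (BED convention). ``GenomicInterval``,
``GeneModel`` and ``GenomeDescription`` are the shared currency of the whole
package; every other module builds on the operations here.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "GenomeDescription",
    "read_bed",
    "write_bed",
    "read_gene_table",
    "write_gene_table",
    "make_promoters",
    "overlap_query",
    "merge_intervals",
    "coverage_fraction",
    "annotate_feature_class",
    "bin_genome",
]

_STRANDS = {"+", "-", "."}

FEATURE_CLASSES = ("promoter", "exon", "intron", "intergenic")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on a named chromosome.

    ``strand`` is ``'+'``, ``'-'`` or ``'.'`` (unstranded). ``name`` and
    ``score`` are optional BED-style annotations.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return self.start + (self.end - self.start) // 2

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class GeneModel:
    """A gene with transcript span and exon blocks.

    The TSS is ``tx_start`` for ``+`` genes and ``tx_end`` for ``-`` genes.
    Exons are 0-based half-open, sorted, pairwise disjoint and contained in
    ``[tx_start, tx_end)``.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if not (0 <= self.tx_start < self.tx_end):
            raise ValueError(f"gene {self.gene_id}: invalid transcript span")
        prev_end = self.tx_start
        for s, e in self.exons:
            if s < prev_end or e > self.tx_end or s >= e:
                raise ValueError(
                    f"gene {self.gene_id}: exons must be sorted, disjoint and "
                    "contained in the transcript span"
                )
            prev_end = e

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end


class GenomeDescription:
    """Ordered chromosome names with lengths in bases."""

    def __init__(self, lengths: Mapping[str, int] | Sequence[tuple[str, int]]):
        items = list(lengths.items()) if isinstance(lengths, Mapping) else list(lengths)
        names = [n for n, _ in items]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in items:
            if length <= 0:
                raise ValueError(f"chromosome {name}: length must be > 0")
        self._lengths: dict[str, int] = dict(items)

    @property
    def chroms(self) -> list[str]:
        return list(self._lengths)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def __getitem__(self, chrom: str) -> int:
        return self._lengths[chrom]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GenomeDescription) and self._lengths == other._lengths

    def items(self):
        return self._lengths.items()

    @property
    def total_length(self) -> int:
        return sum(self._lengths.values())

    @classmethod
    def read_chrom_sizes(cls, path: str | Path) -> "GenomeDescription":
        items = []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated fields")
            items.append((fields[0], int(fields[1])))
        return cls(items)

    def write_chrom_sizes(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(f"{name}\t{length}\n" for name, length in self._lengths.items())
        )


# ---------------------------------------------------------------------------
# BED and gene-table I/O
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 into validated intervals, preserving input order."""
    out: list[GenomicInterval] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("track", "browser", "#")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated fields")
        try:
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed BED line") from exc
        name = fields[3] if len(fields) > 3 and fields[3] != "." else None
        score = None
        if len(fields) > 4 and fields[4] != ".":
            score = float(fields[4])
        strand = fields[5] if len(fields) > 5 else "."
        try:
            out.append(GenomicInterval(chrom, start, end, strand, name, score))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            score = f"{iv.score:g}" if iv.score is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


_GENE_COLUMNS = ("gene_id", "chrom", "strand", "tx_start", "tx_end", "exon_starts", "exon_ends")


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read the tab-separated gene annotation dialect used across the package.

    Columns: gene_id, chrom, strand, tx_start, tx_end, comma-separated exon
    starts and ends. All coordinates are 0-based half-open.
    """
    genes: list[GeneModel] = []
    lines = Path(path).read_text().splitlines()
    start_at = 1 if lines and lines[0].startswith("gene_id") else 0
    for lineno, line in enumerate(lines[start_at:], start=start_at + 1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 5:
            raise ValueError(f"{path}:{lineno}: expected >=5 tab-separated fields")
        exon_starts = exon_ends = []
        if len(fields) >= 7 and fields[5].strip(","):
            exon_starts = [int(x) for x in fields[5].strip(",").split(",")]
            exon_ends = [int(x) for x in fields[6].strip(",").split(",")]
        try:
            genes.append(
                GeneModel(
                    gene_id=fields[0],
                    chrom=fields[1],
                    strand=fields[2],
                    tx_start=int(fields[3]),
                    tx_end=int(fields[4]),
                    exons=tuple(zip(exon_starts, exon_ends)),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_COLUMNS) + "\n")
        for g in genes:
            starts = ",".join(str(s) for s, _ in g.exons)
            ends = ",".join(str(e) for _, e in g.exons)
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tx_start}\t{g.tx_end}\t{starts}\t{ends}\n"
            )


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def make_promoters(
    genes: Iterable[GeneModel],
    genome: GenomeDescription,
    upstream: int = 2000,
    downstream: int = 2000,
) -> list[GenomicInterval]:
    """Strand-aware promoter windows around each TSS, clipped to chromosome bounds.

    The default window is the field-standard −2 kb / +2 kb around the TSS; for
    ``-`` genes the window is reflected so "upstream" follows transcription.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream must be >= 0")
    out = []
    for g in genes:
        if g.chrom not in genome:
            raise KeyError(f"gene {g.gene_id}: chromosome {g.chrom} not in genome")
        if g.strand == "+":
            lo, hi = g.tss - upstream, g.tss + downstream
        else:
            lo, hi = g.tss - downstream, g.tss + upstream
        lo = max(0, lo)
        hi = min(genome[g.chrom], hi)
        out.append(GenomicInterval(g.chrom, lo, hi, g.strand, name=g.gene_id))
    return out


def _trees_by_chrom(intervals: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for idx, iv in enumerate(intervals):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, idx)
    return trees


def overlap_query(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[tuple[GenomicInterval, GenomicInterval, int]]:
    """All pairs (x in a, y in b) sharing at least one base, with overlap length.

    Half-open semantics: abutting intervals do not overlap.
    """
    trees = _trees_by_chrom(b)
    pairs = []
    for x in a:
        tree = trees.get(x.chrom)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(x.start, x.end), key=lambda h: h.data):
            y = b[hit.data]
            pairs.append((x, y, min(x.end, y.end) - max(x.start, y.start)))
    return pairs


def merge_intervals(spans: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or abutting (start, end) spans into a disjoint union."""
    merged: list[list[int]] = []
    for s, e in sorted(spans):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def coverage_fraction(
    target: GenomicInterval, cover: Iterable[GenomicInterval]
) -> float:
    """Fraction of target bases covered by the union of cover intervals.

    Cover intervals on other chromosomes are ignored; overlapping cover pieces
    are merged before measuring, so the result is in [0, 1].
    """
    spans = [
        (max(target.start, c.start), min(target.end, c.end))
        for c in cover
        if c.chrom == target.chrom and c.start < target.end and c.end > target.start
    ]
    covered = sum(e - s for s, e in merge_intervals(spans))
    return covered / len(target)


def annotate_feature_class(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    genome: GenomeDescription,
    promoter_window: int = 2000,
) -> tuple[list[str], dict[str, float]]:
    """Assign each peak one genomic feature class and report class proportions.

    A peak's class is decided by where its midpoint lies, with precedence
    promoter > exon > intron > intergenic. Promoter windows extend
    ``promoter_window`` bases on each side of every TSS. Proportions sum to 1
    for a nonempty peak set.
    """
    promoters = _trees_by_chrom(
        make_promoters(genes, genome, promoter_window, promoter_window)
    )
    exon_ivs = [
        GenomicInterval(g.chrom, s, e) for g in genes for s, e in g.exons
    ]
    exons = _trees_by_chrom(exon_ivs)
    bodies = _trees_by_chrom(
        [GenomicInterval(g.chrom, g.tx_start, g.tx_end) for g in genes]
    )

    def _hits(trees: dict[str, IntervalTree], chrom: str, pos: int) -> bool:
        tree = trees.get(chrom)
        return bool(tree and tree.overlap(pos, pos + 1))

    classes = []
    for p in peaks:
        mid = p.midpoint
        if _hits(promoters, p.chrom, mid):
            cls = "promoter"
        elif _hits(exons, p.chrom, mid):
            cls = "exon"
        elif _hits(bodies, p.chrom, mid):
            cls = "intron"
        else:
            cls = "intergenic"
        classes.append(cls)
    n = len(classes)
    proportions = {
        c: (classes.count(c) / n if n else 0.0) for c in FEATURE_CLASSES
    }
    return classes, proportions


def bin_genome(genome: GenomeDescription, bin_size: int) -> list[GenomicInterval]:
    """Tile each chromosome with fixed-size bins; the last bin may be shorter."""
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    bins = []
    for chrom, length in genome.items():
        for start in range(0, length, bin_size):
            bins.append(GenomicInterval(chrom, start, min(start + bin_size, length)))
    return bins


def intervals_to_arrays(
    intervals: Sequence[GenomicInterval],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Group intervals by chromosome into (starts, ends) arrays (internal helper)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return {
        c: (np.array([s for s, _ in v]), np.array([e for _, e in v]))
        for c, v in by_chrom.items()
    }
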