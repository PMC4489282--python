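"""Genomic interval containers, interval arithmetic, and format readers.

All coordinates are 0-based half-open (BED convention). Any 1-based input
dialect must be converted at the reader boundary. Chromosome names are
opaque strings: ``"chr1"`` and ``"1"`` never alias.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from intervaltree import IntervalTree

__all__ = [
    "GenomicRegion",
    "RegionCollection",
    "GeneEntry",
    "GeneAnnotation",
    "read_bed",
    "write_bed",
    "read_gene_annotation",
    "overlap_fraction",
    "merge_intervals",
]


@dataclass(frozen=True)
class GenomicRegion:
    """A half-open genomic interval ``[start, end)`` with a unique id."""

    chrom: str
    start: int
    end: int
    region_id: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start for {self.region_id}: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"start >= end for {self.region_id}: [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def intersects(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end

    def overlap_bp(self, other: "GenomicRegion") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class RegionCollection:
    """An ordered set of :class:`GenomicRegion` with an interval index.

    Parameters
    ----------
    regions
        Regions in the order they should be kept (typically file order or
        sorted genomic order). Region ids must be unique.
    genome_tag
        Genome build label, e.g. ``"hg19"`` or ``"toy1"``. Collections from
        different builds refuse to interoperate.
    scores
        Optional per-region numeric score keyed by region_id (e.g. a
        narrowPeak signalValue).
    """

    def __init__(
        self,
        regions: Iterable[GenomicRegion],
        genome_tag: str = "unknown",
        scores: dict[str, float] | None = None,
    ):
        self.regions: list[GenomicRegion] = list(regions)
        self.genome_tag = genome_tag
        self.scores = scores
        self._by_id: dict[str, GenomicRegion] = {}
        for r in self.regions:
            if r.region_id in self._by_id:
                raise ValueError(f"duplicate region_id {r.region_id!r}")
            self._by_id[r.region_id] = r
        self._trees: dict[str, IntervalTree] | None = None

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[GenomicRegion]:
        return iter(self.regions)

    def __contains__(self, region_id: str) -> bool:
        return region_id in self._by_id

    def __getitem__(self, region_id: str) -> GenomicRegion:
        return self._by_id[region_id]

    @property
    def ids(self) -> list[str]:
        return [r.region_id for r in self.regions]

    # -- index --------------------------------------------------------------
    def _index(self) -> dict[str, IntervalTree]:
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for r in self.regions:
                trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r)
            self._trees = trees
        return self._trees

    def overlapping(self, chrom: str, start: int, end: int) -> list[GenomicRegion]:
        """All regions intersecting ``chrom:[start, end)`` by >= 1 bp."""
        tree = self._index().get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        hits.sort(key=lambda r: (r.start, r.end, r.region_id))
        return hits

    def sorted(self) -> "RegionCollection":
        """A copy sorted by (chrom, start, end)."""
        regs = sorted(self.regions, key=lambda r: (r.chrom, r.start, r.end))
        return RegionCollection(regs, self.genome_tag, self.scores)

    def score_of(self, region_id: str) -> float:
        if self.scores is None:
            raise ValueError("collection carries no scores")
        return self.scores[region_id]


def merge_intervals(
    intervals: Iterable[tuple[int, int]], book_ended: bool = True
) -> list[tuple[int, int]]:
    """Coalesce intervals on one chromosome; book-ended intervals merge."""
    ivs = sorted(intervals)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and (s < out[-1][1] or (book_ended and s == out[-1][1])):
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def overlap_fraction(query: GenomicRegion, others: RegionCollection) -> float:
    """Fraction of *query* covered by the union of regions in *others*.

    The numerator is the length of the union of the intersections of the
    query with every region in ``others`` (double-covered bases count once);
    the denominator is the query length.
    """
    hits = others.overlapping(query.chrom, query.start, query.end)
    if not hits:
        return 0.0
    clipped = [
        (max(query.start, h.start), min(query.end, h.end)) for h in hits
    ]
    covered = sum(e - s for s, e in merge_intervals(clipped))
    return covered / len(query)


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------

def read_bed(
    path: str | Path,
    with_score: bool = False,
    score_col: int = 5,
    genome_tag: str = "unknown",
) -> RegionCollection:
    """Read a BED file (BED3/BED6/narrowPeak/broadPeak) into a collection.

    Coordinates are kept exactly as written (BED is already 0-based
    half-open). Region ids come from the name column when present and not
    ``"."``; otherwise ``chrom:start-end`` is generated (de-duplicated with a
    ``_2``, ``_3`` ... suffix for repeated identical intervals).

    Parameters
    ----------
    with_score
        Also read a numeric score per region. ``score_col`` is the 1-based
        column holding it: 5 for BED5/BED6 scores, 7 for the ENCODE
        narrowPeak/broadPeak signalValue.
    """
    path = Path(path)
    regions: list[GenomicRegion] = []
    scores: dict[str, float] = {}
    seen: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: malformed line {lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: malformed line {lineno}: {exc}") from None
            if start >= end:
                raise ValueError(f"{path}: start >= end at line {lineno}")
            if len(fields) >= 4 and fields[3] not in (".", ""):
                rid = fields[3]
            else:
                rid = f"{chrom}:{start}-{end}"
            if rid in seen:
                seen[rid] += 1
                rid = f"{rid}_{seen[rid]}"
            else:
                seen[rid] = 1
            if with_score:
                if len(fields) < score_col:
                    raise ValueError(
                        f"{path}: line {lineno}: missing score column {score_col}"
                    )
                try:
                    scores[rid] = float(fields[score_col - 1])
                except ValueError:
                    raise ValueError(
                        f"{path}: line {lineno}: non-numeric score "
                        f"{fields[score_col - 1]!r}"
                    ) from None
            regions.append(GenomicRegion(chrom, start, end, rid))
    return RegionCollection(regions, genome_tag, scores if with_score else None)


def write_bed(
    collection: RegionCollection,
    path: str | Path,
    track_line: str | None = None,
) -> None:
    """Write BED (tab-separated, no header unless *track_line* given).

    Emits BED4 (chrom, start, end, name), or BED5 with the score column when
    the collection carries scores. Round-trips coordinates bit-exactly.
    """
    with open(path, "w") as fh:
        if track_line is not None:
            fh.write(track_line.rstrip("\n") + "\n")
        for r in collection:
            cols = [r.chrom, str(r.start), str(r.end), r.region_id]
            if collection.scores is not None:
                cols.append(repr(collection.scores[r.region_id]))
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

@dataclass
class GeneEntry:
    chrom: str
    strand: str
    tss: int
    introns: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r}")
        for s, e in self.introns:
            if not (0 <= s < e):
                raise ValueError(f"invalid intron interval [{s}, {e})")


class GeneAnnotation:
    """Gene symbol -> (chrom, strand, TSS, introns) lookup."""

    def __init__(self, entries: dict[str, GeneEntry]):
        self.entries = entries

    def __contains__(self, gene: str) -> bool:
        return gene in self.entries

    def __getitem__(self, gene: str) -> GeneEntry:
        return self.entries[gene]

    def __len__(self) -> int:
        return len(self.entries)

    def genes(self) -> list[str]:
        return list(self.entries)


def _read_tss_table(path: Path) -> GeneAnnotation:
    entries: dict[str, GeneEntry] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "gene" and lineno == 1:  # optional header
                continue
            if len(fields) < 4:
                raise ValueError(f"{path}: line {lineno}: need gene, chrom, strand, tss")
            gene, chrom, strand, tss = fields[0], fields[1], fields[2], fields[3]
            if gene in entries:
                raise ValueError(f"{path}: duplicate gene {gene!r} at line {lineno}")
            entries[gene] = GeneEntry(chrom, strand, int(tss))
    return GeneAnnotation(entries)


def _read_gtf_lite(path: Path) -> GeneAnnotation:
    # gene_id attribute required; TSS = 5'-most transcript start respecting
    # strand; introns = gaps between consecutive exons of the union-exon model.
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ValueError(f"{path}: line {lineno}: fewer than 9 GTF columns")
            chrom, feature, start, end, strand, attrs = f[0], f[2], f[3], f[4], f[6], f[8]
            if feature != "exon":
                continue
            if strand not in ("+", "-"):
                raise ValueError(f"{path}: line {lineno}: unknown strand {strand!r}")
            gene = None
            for attr in attrs.split(";"):
                attr = attr.strip()
                if attr.startswith("gene_id"):
                    gene = attr.split(None, 1)[1].strip('" ')
            if gene is None:
                raise ValueError(f"{path}: line {lineno}: missing gene_id attribute")
            if gene in meta and meta[gene] != (chrom, strand):
                raise ValueError(f"{path}: gene {gene!r} on multiple chrom/strand")
            meta[gene] = (chrom, strand)
            # GTF is 1-based inclusive -> convert at the boundary
            exons.setdefault(gene, []).append((int(start) - 1, int(end)))
    entries: dict[str, GeneEntry] = {}
    for gene, ivs in exons.items():
        chrom, strand = meta[gene]
        union = merge_intervals(ivs)
        tss = union[0][0] if strand == "+" else union[-1][1] - 1
        introns = [
            (a_end, b_start)
            for (_, a_end), (b_start, _) in itertools.pairwise(union)
            if b_start > a_end
        ]
        entries[gene] = GeneEntry(chrom, strand, tss, introns)
    return GeneAnnotation(entries)


def read_gene_annotation(path: str | Path, dialect: str = "tss_table") -> GeneAnnotation:
    """Read gene annotation from a TSS table (TSV) or a minimal GTF.

    ``tss_table``: tab-separated ``gene  chrom  strand  tss`` with 0-based
    TSS positions. ``gtf_lite``: GTF exon lines (1-based inclusive,
    converted here) with a ``gene_id`` attribute; TSS and introns are derived
    from the union-exon model.
    """
    path = Path(path)
    if dialect == "tss_table":
        return _read_tss_table(path)
    if dialect == "gtf_lite":
        return _read_gtf_lite(path)
    raise ValueError(f"unknown dialect {dialect!r}")
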