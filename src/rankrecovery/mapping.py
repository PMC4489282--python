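"""Map user input (region sets or gene lists) to a foreground of CRR ids.

Region/peak input selects every CRR covered by the input peaks above a
fraction-of-overlap threshold (default 0.4: at least 40% of a CRR's bases
must lie under input peaks). Gene input collects all CRRs intersecting
each gene's regulatory search space — a window around the TSS, or a
strand-aware upstream window plus all introns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .regions import (
    GeneAnnotation,
    GenomicRegion,
    RegionCollection,
    merge_intervals,
)

__all__ = [
    "ForegroundSet",
    "GeneWindowSpec",
    "map_regions_to_crrs",
    "map_genes_to_crrs",
]


@dataclass
class ForegroundSet:
    """The query of the enrichment analysis.

    crr_ids
        CRR ids selected by the mapping (subset of the CRR universe).
    provenance
        Per selected CRR, the input items (peak ids or gene symbols) that
        contributed it.
    unmapped
        Input items that selected no CRR.
    report
        Long-format overlap table (input item, CRR, overlap bp, fraction).
    """

    crr_ids: list[str]
    provenance: dict[str, list[str]] = field(default_factory=dict)
    unmapped: list[str] = field(default_factory=list)
    report: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for rid in self.crr_ids:
            if not self.provenance.get(rid):
                raise ValueError(f"foreground CRR {rid!r} has no provenance")

    def __len__(self) -> int:
        return len(self.crr_ids)


@dataclass
class GeneWindowSpec:
    """Regulatory search space per gene.

    ``around_tss``: [tss - upstream_bp, tss + downstream_bp) with upstream/
    downstream reflected for minus-strand genes. The human/mouse default of
    a 20 kb space around the TSS is upstream_bp = downstream_bp = 10000.
    ``upstream_plus_introns``: the strand-aware upstream window plus all
    intron intervals (the fly default: 5 kb upstream and all introns).
    """

    mode: str = "around_tss"
    upstream_bp: int = 10_000
    downstream_bp: int = 10_000

    def __post_init__(self) -> None:
        if self.mode not in ("around_tss", "upstream_plus_introns"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.upstream_bp < 0 or self.downstream_bp < 0:
            raise ValueError("window sizes must be >= 0")

    @classmethod
    def fly_default(cls) -> "GeneWindowSpec":
        return cls("upstream_plus_introns", 5_000, 0)


def map_regions_to_crrs(
    input_regions: RegionCollection,
    crrs: RegionCollection,
    min_fraction: float = 0.4,
) -> ForegroundSet:
    """Select CRRs whose input-covered fraction reaches *min_fraction*.

    The fraction is of the CRR's own length (the CRR is the query of
    :func:`~rankrecovery.regions.overlap_fraction`); the threshold is
    inclusive. Input peaks intersecting no selected CRR are reported as
    unmapped. A per-pair overlap table accompanies the result.
    """
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError(f"min_fraction must be in [0, 1], got {min_fraction}")
    rows: list[tuple[str, str, int, float]] = []
    selected: list[str] = []
    provenance: dict[str, list[str]] = {}
    mapped_inputs: set[str] = set()
    for crr in crrs:
        peaks = input_regions.overlapping(crr.chrom, crr.start, crr.end)
        if not peaks:
            continue
        clipped = [(max(crr.start, p.start), min(crr.end, p.end)) for p in peaks]
        covered = sum(e - s for s, e in merge_intervals(clipped))
        fraction = covered / len(crr)
        for p in peaks:
            rows.append((p.region_id, crr.region_id, crr.overlap_bp(p), fraction))
        if fraction >= min_fraction:
            selected.append(crr.region_id)
            provenance[crr.region_id] = [p.region_id for p in peaks]
            mapped_inputs.update(p.region_id for p in peaks)
    unmapped = [p.region_id for p in input_regions if p.region_id not in mapped_inputs]
    report = pd.DataFrame(
        rows, columns=["input_id", "crr_id", "overlap_bp", "crr_fraction"]
    )
    return ForegroundSet(selected, provenance, unmapped, report)


def _gene_space(
    entry, window: GeneWindowSpec
) -> list[tuple[int, int]]:
    """Search-space intervals for one gene, strand-reflected."""
    if entry.strand == "+":
        up_start, up_end = entry.tss - window.upstream_bp, entry.tss
        down_start, down_end = entry.tss, entry.tss + window.downstream_bp
    else:
        up_start, up_end = entry.tss + 1, entry.tss + 1 + window.upstream_bp
        down_start, down_end = entry.tss + 1 - window.downstream_bp, entry.tss + 1
    if window.mode == "around_tss":
        ivs = [(min(up_start, down_start), max(up_end, down_end))]
    else:
        ivs = [(up_start, up_end)] + list(entry.introns)
    return [(max(0, s), e) for s, e in ivs if e > max(0, s)]


def map_genes_to_crrs(
    genes: list[str],
    annotation: GeneAnnotation,
    window: GeneWindowSpec,
    crrs: RegionCollection,
) -> ForegroundSet:
    """Collect all CRRs in the regulatory neighbourhood of each gene.

    A CRR joins the foreground when it intersects a gene's search space by
    at least 1 bp (the fraction-of-overlap threshold applies to peak input
    only). Genes absent from the annotation, or whose space contains no
    CRR, are listed as unmapped; an entirely unmapped input is an error.
    """
    genes = [g.strip() for g in genes if g.strip()]
    if not genes:
        raise ValueError("empty gene list")
    selected: list[str] = []
    provenance: dict[str, list[str]] = {}
    unmapped: list[str] = []
    rows: list[tuple[str, str, int]] = []
    for gene in genes:
        if gene not in annotation:
            unmapped.append(gene)
            continue
        entry = annotation[gene]
        hit_any = False
        for s, e in _gene_space(entry, window):
            for crr in crrs.overlapping(entry.chrom, s, e):
                hit_any = True
                ov = min(crr.end, e) - max(crr.start, s)
                rows.append((gene, crr.region_id, ov))
                if crr.region_id not in provenance:
                    selected.append(crr.region_id)
                    provenance[crr.region_id] = []
                if gene not in provenance[crr.region_id]:
                    provenance[crr.region_id].append(gene)
        if not hit_any:
            unmapped.append(gene)
    if not selected:
        raise ValueError(
            f"no input gene mapped to any CRR (unmapped: {unmapped})"
        )
    report = pd.DataFrame(rows, columns=["gene", "crr_id", "overlap_bp"])
    return ForegroundSet(selected, provenance, unmapped, report)
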