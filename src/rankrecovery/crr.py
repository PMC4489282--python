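"""Candidate-regulatory-region (CRR) database construction.

Heterogeneous feature region sets (open chromatin, promoters, conserved
elements, curated enhancers, ...) are merged into contiguous intervals;
intervals dominated by insulators or coding exons are removed; remaining
intervals are split around insulator/exon bases; short fragments are
dropped; and the survivors are extended toward a target size in directions
that avoid insulators and exons. The result is the fixed region universe
that scoring, ranking, and recovery all operate on.
"""

from __future__ import annotations

from dataclasses import dataclass

from .regions import GenomicRegion, RegionCollection, merge_intervals, overlap_fraction

__all__ = [
    "CrrBuildConfig",
    "merge_feature_sets",
    "apply_exclusions",
    "extend_to_target",
    "build_crr_database",
]


@dataclass
class CrrBuildConfig:
    """Thresholds of the CRR build.

    insulator_fraction
        Remove a merged region when at least this fraction of it is covered
        by insulator elements (default 0.2).
    exon_fraction
        Remove a merged region when at least this fraction of it is covered
        by coding exons (default 0.8).
    min_size
        Fragments shorter than this (bp) are dropped after splitting
        (default 30).
    target_size
        Regions shorter than this are extended toward it where insulators,
        exons, and chromosome bounds permit (default 1000).
    """

    insulator_fraction: float = 0.2
    exon_fraction: float = 0.8
    min_size: int = 30
    target_size: int = 1000

    def __post_init__(self) -> None:
        for name in ("insulator_fraction", "exon_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.min_size >= self.target_size:
            raise ValueError("min_size must be < target_size")


def _check_same_genome(*collections: RegionCollection) -> str:
    tags = {c.genome_tag for c in collections if len(c) > 0}
    if len(tags) > 1:
        raise ValueError(f"mixed genome tags: {sorted(tags)}")
    return tags.pop() if tags else "unknown"


def _fresh_ids(intervals: list[tuple[str, int, int]], prefix: str) -> list[GenomicRegion]:
    out: list[GenomicRegion] = []
    seen: dict[str, int] = {}
    for chrom, s, e in intervals:
        rid = f"{chrom}:{s}-{e}"
        if rid in seen:  # identical intervals possible after extension
            seen[rid] += 1
            rid = f"{rid}_{seen[rid]}"
        else:
            seen[rid] = 1
        out.append(GenomicRegion(chrom, s, e, rid))
    return out


def merge_feature_sets(feature_sets: list[RegionCollection]) -> RegionCollection:
    """Union all feature intervals; overlapping or book-ended intervals
    coalesce. Output is sorted by (chrom, start) with fresh ids."""
    tag = _check_same_genome(*feature_sets)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for coll in feature_sets:
        for r in coll:
            by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    out: list[tuple[str, int, int]] = []
    for chrom in sorted(by_chrom):
        for s, e in merge_intervals(by_chrom[chrom]):
            out.append((chrom, s, e))
    return RegionCollection(_fresh_ids(out, "crr"), tag)


def _masked_subtract(
    region: GenomicRegion, mask: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Sub-intervals of *region* containing no masked base."""
    pieces: list[tuple[int, int]] = []
    pos = region.start
    for ms, me in mask:
        ms, me = max(ms, region.start), min(me, region.end)
        if ms >= me:
            continue
        if ms > pos:
            pieces.append((pos, ms))
        pos = max(pos, me)
    if pos < region.end:
        pieces.append((pos, region.end))
    return pieces


def apply_exclusions(
    merged: RegionCollection,
    insulators: RegionCollection,
    exons: RegionCollection,
    config: CrrBuildConfig | None = None,
) -> RegionCollection:
    """Remove insulator/exon-dominated regions, then excise residual
    insulator/exon bases.

    Step 1 drops a region when its insulator-covered fraction is at least
    ``insulator_fraction`` or its exon-covered fraction is at least
    ``exon_fraction``. Step 2 splits survivors at the boundaries of any
    remaining insulator or exon overlap, keeping only clean sub-intervals.
    Step 3 drops fragments shorter than ``min_size``.
    """
    config = config or CrrBuildConfig()
    tag = _check_same_genome(merged, insulators, exons)
    out: list[tuple[str, int, int]] = []
    for region in merged:
        ins_frac = overlap_fraction(region, insulators)
        ex_frac = overlap_fraction(region, exons)
        if ins_frac >= config.insulator_fraction or ex_frac >= config.exon_fraction:
            continue
        hits = insulators.overlapping(region.chrom, region.start, region.end)
        hits += exons.overlapping(region.chrom, region.start, region.end)
        mask = merge_intervals([(h.start, h.end) for h in hits])
        for s, e in _masked_subtract(region, mask):
            if e - s >= config.min_size:
                out.append((region.chrom, s, e))
    out.sort()
    return RegionCollection(_fresh_ids(out, "crr"), tag)


def extend_to_target(
    regions: RegionCollection,
    forbidden: RegionCollection,
    config: CrrBuildConfig | None = None,
    chrom_sizes: dict[str, int] | None = None,
) -> RegionCollection:
    """Grow each region shorter than ``target_size`` toward it.

    Growth is symmetric when both flanks are free; a blocked flank's share
    goes to the free flank; each flank stops at the nearest forbidden
    interval and at chromosome bounds. No output base overlaps *forbidden*.
    Regions already at or above the target are unchanged. Extension never
    re-merges regions that come to touch (post-extension overlap is
    permitted).
    """
    config = config or CrrBuildConfig()
    tag = _check_same_genome(regions, forbidden)
    out: list[tuple[str, int, int]] = []
    for region in regions:
        length = len(region)
        if length >= config.target_size:
            out.append((region.chrom, region.start, region.end))
            continue
        chrom_end = (
            chrom_sizes[region.chrom]
            if chrom_sizes is not None and region.chrom in chrom_sizes
            else None
        )
        # Nearest forbidden base on each side bounds the free flanks.
        left_bound = 0
        right_bound = chrom_end
        window = 2 * config.target_size
        near = forbidden.overlapping(
            region.chrom,
            max(0, region.start - window),
            region.end + window,
        )
        for h in near:
            if h.end <= region.start:
                left_bound = max(left_bound, h.end)
            elif h.start >= region.end:
                right_bound = (
                    h.start if right_bound is None else min(right_bound, h.start)
                )
        free_left = region.start - left_bound
        free_right = (
            float("inf") if right_bound is None else right_bound - region.end
        )
        deficit = config.target_size - length
        want_l = deficit // 2
        want_r = deficit - want_l
        grow_l = min(want_l, free_left)
        grow_r = min(want_r, free_right)
        rem = deficit - grow_l - grow_r
        if rem > 0:
            extra_l = min(rem, free_left - grow_l)
            grow_l += extra_l
            rem -= extra_l
        if rem > 0:
            grow_r += min(rem, free_right - grow_r)
        out.append((region.chrom, region.start - grow_l, int(region.end + grow_r)))
    return RegionCollection(_fresh_ids(out, "crr"), tag)


def build_crr_database(
    feature_sets: list[RegionCollection],
    insulators: RegionCollection,
    exons: RegionCollection,
    config: CrrBuildConfig | None = None,
    chrom_sizes: dict[str, int] | None = None,
) -> RegionCollection:
    """merge -> exclude/split/size-filter -> extend; the full CRR build."""
    config = config or CrrBuildConfig()
    merged = merge_feature_sets(feature_sets)
    kept = apply_exclusions(merged, insulators, exons, config)
    forbidden_ivs: list[tuple[str, int, int]] = []
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for coll in (insulators, exons):
        for r in coll:
            by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    for chrom in sorted(by_chrom):
        for s, e in merge_intervals(by_chrom[chrom]):
            forbidden_ivs.append((chrom, s, e))
    forbidden = RegionCollection(
        _fresh_ids(forbidden_ivs, "forbidden"),
        _check_same_genome(insulators, exons) if (len(insulators) or len(exons)) else "unknown",
    )
    if len(forbidden) and len(kept):
        # keep genome tags compatible for the extension step
        forbidden.genome_tag = kept.genome_tag
    return extend_to_target(kept, forbidden, config, chrom_sizes)
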