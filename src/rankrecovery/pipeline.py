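"""End-to-end convenience wiring: fixture bundle -> databases -> foreground
-> enrichment -> report files. Used by the CLI, the test-suite, and any
scripted analysis that starts from in-memory objects."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .annotate import closest_genes, cluster_motifs
from .mapping import ForegroundSet, map_regions_to_crrs
from .recovery import (
    EnrichmentParams,
    LeadingEdge,
    EnrichmentScore,
    run_enrichment,
)
from .regions import RegionCollection
from .report import EnrichmentReport, build_report, write_report, write_sif, write_target_bed
from .scoring import (
    RankingDatabase,
    build_ranking_database,
    rank_motif_across_genomes,
    score_track_peaks,
)
from .simulate import FixtureBundle

__all__ = ["CaseResult", "build_case_databases", "analyze_case"]


@dataclass
class CaseResult:
    foreground: ForegroundSet
    motif_db: RankingDatabase
    track_db: RankingDatabase
    results: list[tuple[EnrichmentScore, LeadingEdge]]
    report: EnrichmentReport


def build_case_databases(
    bundle: FixtureBundle, seed: int
) -> tuple[RankingDatabase, RankingDatabase]:
    """Score and rank every motif (cross-genome, order-statistics
    aggregated) and every track of a fixture bundle."""
    motif_rankings = [
        rank_motif_across_genomes(bundle.crrs, bundle.genomes, pwm, seed)
        for pwm in bundle.pwms
    ]
    motif_db = RankingDatabase(bundle.crrs.ids, motif_rankings, "motifs", seed)
    track_scores = {
        tid: (score_track_peaks(bundle.crrs, track), "track")
        for tid, track in bundle.tracks.items()
    }
    track_db = build_ranking_database(
        bundle.crrs, track_scores, seed, "open_chromatin"
    )
    return motif_db, track_db


def analyze_case(
    bundle: FixtureBundle,
    seed: int,
    out_dir: str | Path | None = None,
    params: EnrichmentParams | None = None,
    min_fraction: float = 0.4,
) -> CaseResult:
    """Run the full analysis of a fixture bundle's region-mode foreground.

    When *out_dir* is given, writes the report TSV (+ metadata sidecar),
    one target BED per enriched feature, and the SIF network.
    """
    params = params or EnrichmentParams(auc_fraction=bundle.auc_fraction)
    motif_db, track_db = build_case_databases(bundle, seed)
    foreground = map_regions_to_crrs(bundle.foreground_peaks, bundle.crrs, min_fraction)
    results = run_enrichment([motif_db, track_db], foreground, params)
    enriched_motif_ids = {
        es.feature_id for es, _ in results if es.feature_type == "motif"
    }
    enriched_pwms = [p for p in bundle.pwms if p.motif_id in enriched_motif_ids]
    nes_by_motif = {
        es.feature_id: es.nes for es, _ in results if es.feature_type == "motif"
    }
    clusters = (
        cluster_motifs(enriched_pwms, nes_by_motif) if enriched_pwms else []
    )
    report = build_report(
        results,
        clusters,
        metadata={
            "seed": seed,
            "auc_fraction": params.auc_fraction,
            "nes_threshold": params.nes_threshold,
            "quick": params.quick,
            "min_fraction": min_fraction,
            "motif_db_checksum": motif_db.checksum(),
        },
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_report(report, out / "report.tsv")
        target_union: list[str] = []
        for es, le in results:
            write_target_bed(le, bundle.crrs, out / f"targets_{es.feature_id}.bed")
            target_union.extend(t for t in le.target_ids if t not in target_union)
        targets = RegionCollection(
            [bundle.crrs[t] for t in sorted(target_union)], bundle.crrs.genome_tag
        )
        genes = closest_genes(targets, bundle.annotation)
        write_sif(report, genes, out / "network.sif")
    return CaseResult(foreground, motif_db, track_db, results, report)
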