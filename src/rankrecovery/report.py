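"""Report assembly and writers: TSV report, target BEDs, SIF network,
recovery-curve plots. All writers are deterministic given the analysis
result and seed metadata."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotate import MotifCluster, Motif2TFEdge, motif2tf_lookup
from .recovery import EnrichmentScore, LeadingEdge
from .regions import RegionCollection

__all__ = [
    "ReportRow",
    "EnrichmentReport",
    "build_report",
    "write_report",
    "write_target_bed",
    "write_sif",
    "plot_recovery_curves",
]


@dataclass
class ReportRow:
    feature_id: str
    feature_type: str
    nes: float
    auc: float
    cluster_rank: int | None
    within_rank: int | None
    tfs: list[str]
    le_rank: int
    target_ids: list[str]

    @property
    def rank_label(self) -> str:
        """Two-part motif rank: cluster rank, then member rank in brackets."""
        if self.cluster_rank is None:
            return "-"
        return f"{self.cluster_rank} ({self.within_rank})"


@dataclass
class EnrichmentReport:
    rows: list[ReportRow]
    metadata: dict = field(default_factory=dict)


def build_report(
    results: list[tuple[EnrichmentScore, LeadingEdge]],
    clusters: list[MotifCluster] | None = None,
    tf_table: list[Motif2TFEdge] | None = None,
    metadata: dict | None = None,
) -> EnrichmentReport:
    """Assemble enriched features, cluster ranks, and TF candidates into
    one report, sorted by NES descending within feature type."""
    cluster_info: dict[str, tuple[int, int]] = {}
    if clusters:
        for c in clusters:
            for m in c.members:
                cluster_info[m] = (c.cluster_rank, c.within_ranks[m])
    rows: list[ReportRow] = []
    for es, le in results:
        cr, wr = cluster_info.get(es.feature_id, (None, None))
        tfs = (
            [tf for tf, _ in motif2tf_lookup(es.feature_id, tf_table)]
            if tf_table is not None and es.feature_type == "motif"
            else []
        )
        rows.append(
            ReportRow(
                es.feature_id,
                es.feature_type,
                es.nes,
                es.auc,
                cr,
                wr,
                tfs,
                le.le_rank,
                list(le.target_ids),
            )
        )
    type_order = {"motif": 0, "track": 1, "combined": 2}
    rows.sort(
        key=lambda r: (type_order.get(r.feature_type, 3), -r.nes, r.feature_id)
    )
    return EnrichmentReport(rows, metadata or {})


def write_report(report: EnrichmentReport, path: str | Path) -> None:
    """Write the report TSV plus a JSON metadata sidecar (parameters and
    seeds), byte-identical across reruns with the same inputs."""
    path = Path(path)
    header = [
        "rank",
        "feature_id",
        "feature_type",
        "nes",
        "auc",
        "candidate_tfs",
        "leading_edge_rank",
        "n_targets",
        "target_ids",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in report.rows:
            fh.write(
                "\t".join(
                    [
                        row.rank_label,
                        row.feature_id,
                        row.feature_type,
                        f"{row.nes:.6f}",
                        f"{row.auc:.6f}",
                        ",".join(row.tfs) or "-",
                        str(row.le_rank),
                        str(len(row.target_ids)),
                        ",".join(row.target_ids) or "-",
                    ]
                )
                + "\n"
            )
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(report.metadata, indent=2, sort_keys=True) + "\n")


def write_target_bed(
    le: LeadingEdge,
    crrs: RegionCollection,
    path: str | Path,
    track_line: bool = False,
) -> None:
    """BED6 of the leading-edge target regions, in genomic order.

    Score = rank of the target among the leading edge scaled to 0-1000
    (best first); strand ".". Optional UCSC custom-track header.
    """
    missing = [t for t in le.target_ids if t not in crrs]
    if missing:
        raise ValueError(f"target ids not in the CRR collection: {missing[:3]}")
    if not le.target_ids:
        warnings.warn(f"empty leading edge for {le.feature_id}; writing empty BED")
    n = len(le.target_ids)
    scores = {
        tid: int(round(1000 * (n - i) / n)) if n else 0
        for i, tid in enumerate(le.target_ids)
    }
    regions = sorted(
        (crrs[t] for t in le.target_ids), key=lambda r: (r.chrom, r.start, r.end)
    )
    with open(path, "w") as fh:
        if track_line:
            fh.write(f'track name="{le.feature_id}_targets"\n')
        for r in regions:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}"
                f"\t{scores[r.region_id]}\t.\n"
            )


def write_sif(
    report: EnrichmentReport,
    gene_assignments: dict[str, str | None],
    path: str | Path,
) -> None:
    """Simple Interaction File: ``feature targets region`` for every
    (enriched feature, leading-edge region) pair and ``region nearest
    gene`` for every assigned region."""
    lines: list[str] = []
    regions_seen: list[str] = []
    for row in report.rows:
        for tid in row.target_ids:
            lines.append(f"{row.feature_id} targets {tid}")
            if tid not in regions_seen:
                regions_seen.append(tid)
    for tid in regions_seen:
        gene = gene_assignments.get(tid)
        if gene is not None:
            lines.append(f"{tid} nearest {gene}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def plot_recovery_curves(
    curves: dict[str, np.ndarray],
    mean_curve: np.ndarray,
    sd_curve: np.ndarray,
    path: str | Path,
    title: str = "Recovery",
) -> None:
    """Recovery curves against the database mean + 2 SD null band."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    x = np.arange(1, len(mean_curve) + 1)
    ax.plot(x, mean_curve, color="grey", label="database mean")
    ax.plot(
        x, mean_curve + 2 * sd_curve, color="grey", linestyle="--", label="mean + 2 SD"
    )
    for fid, rc in curves.items():
        ax.plot(x[: len(rc)], rc, label=fid)
    ax.set_xlabel("rank")
    ax.set_ylabel("recovered foreground regions")
    ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
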