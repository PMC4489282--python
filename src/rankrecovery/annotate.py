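"""Post-enrichment interpretation.

Enriched motifs are linked to candidate transcription factors through an
evidence-typed motif-TF table (direct annotation > orthology > motif
similarity), grouped into clusters of similar matrices (sum-of-squared-
distances metric, average-linkage tree, Calinski-Harabasz choice of k),
and leading-edge target regions are assigned their closest gene. Two
analyses can be compared motif-by-motif or cluster-by-cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .pwm import PWM
from .regions import GeneAnnotation, RegionCollection

__all__ = [
    "Motif2TFEdge",
    "MotifCluster",
    "ssd_distance",
    "cluster_motifs",
    "read_motif2tf_table",
    "motif2tf_lookup",
    "closest_genes",
    "compare_reports",
]

_EVIDENCE_ORDER = {"direct": 0, "orthology": 1, "similarity": 2}


@dataclass
class Motif2TFEdge:
    motif_id: str
    tf: str
    evidence: str  # direct | orthology | similarity
    species: str = ""
    similarity_score: float | None = None

    def __post_init__(self) -> None:
        if self.evidence not in _EVIDENCE_ORDER:
            raise ValueError(f"unknown evidence type {self.evidence!r}")


@dataclass
class MotifCluster:
    cluster_id: str
    members: list[str]
    cluster_rank: int
    within_ranks: dict[str, int]


# ---------------------------------------------------------------------------
# Motif similarity and clustering
# ---------------------------------------------------------------------------

def _ssd_at_offset(a: np.ndarray, b: np.ndarray, offset: int, bg: np.ndarray) -> float:
    """Mean per-column SSD for b shifted by *offset* relative to a.

    Columns covered by only one motif compare against the background, so
    length mismatches are penalized proportionally.
    """
    la, lb = len(a), len(b)
    span_start = min(0, offset)
    span_end = max(la, offset + lb)
    total = 0.0
    ncols = 0
    for pos in range(span_start, span_end):
        col_a = a[pos] if 0 <= pos < la else None
        col_b = b[pos - offset] if 0 <= pos - offset < lb else None
        if col_a is None:
            col_a = bg
        if col_b is None:
            col_b = bg
        total += float(np.sum((col_a - col_b) ** 2))
        ncols += 1
    return total / ncols


def ssd_distance(a: PWM, b: PWM) -> float:
    """Sum-of-squared-distances dissimilarity between two motifs.

    Minimum over all ungapped offsets and both orientations (b as given
    and reverse-complemented) of the mean per-aligned-column sum of squared
    probability differences; columns without a partner compare against the
    background distribution. Symmetric; 0 for identical motifs and for a
    motif against its own reverse complement.
    """
    bg = (a.background + b.background) / 2.0
    best = np.inf
    for mat_b in (b.matrix, b.reverse_complement().matrix):
        for offset in range(-(len(mat_b) - 1), len(a.matrix)):
            best = min(best, _ssd_at_offset(a.matrix, mat_b, offset, bg))
    return best


def _distance_matrix(pwms: list[PWM]) -> np.ndarray:
    n = len(pwms)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = ssd_distance(pwms[i], pwms[j])
    return d


def _calinski_harabasz(d2: np.ndarray, labels: np.ndarray) -> float:
    """Calinski-Harabasz index from a squared-distance matrix alone.

    Uses the identity SSW = sum over clusters of (1/(2 n_c)) * sum of
    within-cluster pairwise squared distances; SSB = SST - SSW.
    """
    n = len(labels)
    ks = np.unique(labels)
    k = len(ks)
    sst = d2.sum() / (2 * n)
    ssw = 0.0
    for c in ks:
        idx = np.flatnonzero(labels == c)
        ssw += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    ssb = sst - ssw
    if k == 1 or n == k:
        return 0.0
    if ssw <= 1e-15:  # perfectly tight clusters
        return np.inf if ssb > 1e-15 else 0.0
    return (ssb / (k - 1)) / (ssw / (n - k))


def cluster_motifs(
    pwms: list[PWM], nes_by_motif: dict[str, float], k_max: int = 10
) -> list[MotifCluster]:
    """Group similar enriched motifs; rank clusters by best member NES.

    Average-linkage hierarchical clustering on the pairwise SSD matrix;
    the number of clusters maximizes the Calinski-Harabasz index over
    k = 2..min(k_max, n-1). A single cluster is returned when n <= 2 or
    when the motifs show no scatter to partition.
    """
    if not pwms:
        raise ValueError("no motifs to cluster")
    n = len(pwms)
    if n == 1:
        labels = np.array([1])
    else:
        d = _distance_matrix(pwms)
        if n <= 2 or d.max() <= 1e-12:
            labels = np.ones(n, dtype=int)
        else:
            z = linkage(squareform(d, checks=False), method="average")
            d2 = d**2
            best_k, best_ch = 1, 0.0
            for k in range(2, min(k_max, n - 1) + 1):
                lab = fcluster(z, t=k, criterion="maxclust")
                ch = _calinski_harabasz(d2, lab)
                if ch > best_ch:
                    best_k, best_ch = k, ch
            labels = (
                fcluster(z, t=best_k, criterion="maxclust")
                if best_k > 1
                else np.ones(n, dtype=int)
            )

    # Global NES ranks (1 = best) drive cluster and within-cluster ranks.
    order = sorted(pwms, key=lambda p: (-nes_by_motif.get(p.motif_id, 0.0), p.motif_id))
    global_rank = {p.motif_id: i + 1 for i, p in enumerate(order)}
    groups: dict[int, list[str]] = {}
    for pwm, lab in zip(pwms, labels):
        groups.setdefault(int(lab), []).append(pwm.motif_id)
    clusters: list[MotifCluster] = []
    for lab, members in groups.items():
        members_sorted = sorted(members, key=lambda m: global_rank[m])
        clusters.append(
            MotifCluster(
                cluster_id=f"c{lab}",
                members=members_sorted,
                cluster_rank=min(global_rank[m] for m in members),
                within_ranks={m: i + 1 for i, m in enumerate(members_sorted)},
            )
        )
    clusters.sort(key=lambda c: c.cluster_rank)
    for i, cluster in enumerate(clusters, start=1):
        cluster.cluster_id = f"c{i}"
        cluster.cluster_rank = i
    return clusters


# ---------------------------------------------------------------------------
# Motif -> TF lookup
# ---------------------------------------------------------------------------

def read_motif2tf_table(path: str | Path) -> list[Motif2TFEdge]:
    """TSV with columns motif_id, tf, evidence, species, score."""
    edges: list[Motif2TFEdge] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if f[0] == "motif_id" and lineno == 1:
                continue
            if len(f) < 3:
                raise ValueError(f"{path}: line {lineno}: need >= 3 columns")
            score = float(f[4]) if len(f) > 4 and f[4] not in ("", "NA") else None
            edges.append(
                Motif2TFEdge(f[0], f[1], f[2], f[3] if len(f) > 3 else "", score)
            )
    return edges


def motif2tf_lookup(
    motif_id: str,
    table: list[Motif2TFEdge],
    evidence: set[str] | None = None,
    species: set[str] | None = None,
) -> list[tuple[str, str]]:
    """Candidate TFs for a motif, as (tf, best evidence) pairs.

    Edges failing the evidence/species filters are dropped; duplicates keep
    the strongest evidence (direct > orthology > similarity). Unknown
    motifs yield an empty list.
    """
    best: dict[str, str] = {}
    for edge in table:
        if edge.motif_id != motif_id:
            continue
        if evidence is not None and edge.evidence not in evidence:
            continue
        if species is not None and edge.species not in species:
            continue
        prev = best.get(edge.tf)
        if prev is None or _EVIDENCE_ORDER[edge.evidence] < _EVIDENCE_ORDER[prev]:
            best[edge.tf] = edge.evidence
    return sorted(best.items(), key=lambda kv: (_EVIDENCE_ORDER[kv[1]], kv[0]))


# ---------------------------------------------------------------------------
# Closest genes
# ---------------------------------------------------------------------------

def closest_genes(
    targets: RegionCollection, annotation: GeneAnnotation
) -> dict[str, str | None]:
    """Per target region, the gene with the nearest TSS on its chromosome.

    Distance is |region midpoint - TSS|; ties take the lexicographically
    smallest symbol; chromosomes without genes yield None.
    """
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for gene in sorted(annotation.genes()):
        e = annotation[gene]
        by_chrom.setdefault(e.chrom, []).append((e.tss, gene))
    out: dict[str, str | None] = {}
    for region in targets:
        candidates = by_chrom.get(region.chrom)
        if not candidates:
            out[region.region_id] = None
            continue
        mid = region.midpoint
        out[region.region_id] = min(
            candidates, key=lambda tg: (abs(mid - tg[0]), tg[1])
        )[1]
    return out


# ---------------------------------------------------------------------------
# Cross-analysis comparison
# ---------------------------------------------------------------------------

def compare_reports(
    a: dict[str, float],
    b: dict[str, float],
    clusters_a: list[MotifCluster] | None = None,
    clusters_b: list[MotifCluster] | None = None,
) -> pd.DataFrame:
    """Compare two enrichment results (feature_id -> NES maps).

    Rows carry both NES values where present and a status of ``common``,
    ``a_only``, or ``b_only``. When cluster assignments are supplied, a
    ``cluster_common`` flag marks features whose cluster shares at least
    one member motif with some cluster of the other analysis.
    """
    def cluster_of(fid: str, clusters: list[MotifCluster] | None) -> set[str]:
        if clusters is None:
            return set()
        for c in clusters:
            if fid in c.members:
                return set(c.members)
        return set()

    rows = []
    for fid in sorted(set(a) | set(b)):
        in_a, in_b = fid in a, fid in b
        status = "common" if (in_a and in_b) else ("a_only" if in_a else "b_only")
        cluster_common = status == "common"
        if not cluster_common:
            own = cluster_of(fid, clusters_a if in_a else clusters_b)
            other = b if in_a else a
            other_clusters = clusters_b if in_a else clusters_a
            shared = own & set(other)
            if not shared and other_clusters is not None:
                shared = own & {m for c in other_clusters for m in c.members}
            cluster_common = bool(shared)
        rows.append(
            {
                "feature_id": fid,
                "nes_a": a.get(fid, np.nan),
                "nes_b": b.get(fid, np.nan),
                "status": status,
                "cluster_common": cluster_common,
            }
        )
    return pd.DataFrame(rows)
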