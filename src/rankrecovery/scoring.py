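"""Scoring CRRs by motifs and tracks, ranking, and rank aggregation.

This is the "offline" half of the pipeline. Every feature (a motif or an
experimental track) induces one total ordering of all CRRs from strongest
to weakest signal; the collection of orderings is the ranking database the
"online" recovery analysis consumes.

Motif scores are cis-regulatory-module (CRM) scores: the best total
log-odds of a set of non-overlapping motif hits within the region,
considering both strands, counting only hits with positive log-odds. For
cross-species scoring, each genome is ranked separately and the per-genome
rank ratios of a region are aggregated into one statistic with the joint
cumulative distribution of uniform order statistics.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pwm import PWM
from .regions import RegionCollection

__all__ = [
    "GenomeSequences",
    "FeatureRanking",
    "RankingDatabase",
    "crm_score",
    "score_motif_over_regions",
    "score_track_peaks",
    "score_track_coverage",
    "scores_to_ranking",
    "aggregate_rankings",
    "aggregate_ratio_matrix",
    "build_ranking_database",
    "read_fasta",
    "read_ortholog_table",
]

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


# ---------------------------------------------------------------------------
# Sequence plumbing
# ---------------------------------------------------------------------------

@dataclass
class GenomeSequences:
    """One genome assembly: chromosome name -> sequence string.

    ``orthologs`` maps base-genome region_ids to (chrom, start, end) in this
    assembly; ``None`` marks the base genome itself (regions score at their
    own coordinates). Missing ids mean no ortholog.
    """

    tag: str
    sequences: dict[str, str]
    orthologs: dict[str, tuple[str, int, int]] | None = None

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self.sequences.get(chrom)
        if seq is None:
            raise KeyError(f"{self.tag}: no chromosome {chrom!r}")
        if start < 0 or end > len(seq):
            raise ValueError(
                f"{self.tag}: {chrom}:{start}-{end} outside sequence bounds "
                f"(length {len(seq)})"
            )
        return seq[start:end]


def read_fasta(path: str | Path, tag: str = "unknown") -> GenomeSequences:
    from Bio import SeqIO

    seqs = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }
    return GenomeSequences(tag, seqs)


def read_ortholog_table(path: str | Path) -> dict[str, tuple[str, int, int]]:
    """TSV of region_id, chrom, start, end (0-based half-open)."""
    table: dict[str, tuple[str, int, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if f[0] == "region_id" and lineno == 1:
                continue
            if len(f) < 4:
                raise ValueError(f"{path}: line {lineno}: need 4 columns")
            table[f[0]] = (f[1], int(f[2]), int(f[3]))
    return table


# ---------------------------------------------------------------------------
# CRM scoring
# ---------------------------------------------------------------------------

def _encode(sequence: str) -> np.ndarray:
    seq = sequence.upper()
    try:
        return np.array([_BASE_CODE[b] for b in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid character {exc.args[0]!r} in sequence") from None


def _window_scores(code: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Sum of per-position log-odds for every window start (vectorized)."""
    L = len(log_odds)
    W = len(code) - L + 1
    out = np.zeros(W)
    for j in range(L):
        out += log_odds[j, code[j : j + W]]
    return out


def crm_score(sequence: str, pwm: PWM) -> float:
    """Best total log-odds of non-overlapping positive motif hits.

    Every window on either strand whose summed log2(p_motif/p_background)
    is positive is a candidate hit; the score is the maximum achievable sum
    over any set of non-overlapping hits (weighted interval scheduling).
    ``N`` bases contribute log-odds 0. Sequences shorter than the motif
    score 0.
    """
    if len(sequence) < 1:
        raise ValueError("empty sequence")
    code = _encode(sequence)
    L = len(pwm)
    if len(code) < L:
        return 0.0
    fwd = _window_scores(code, pwm.log_odds())
    rev = _window_scores(code, pwm.reverse_complement().log_odds())
    # Both strands occupy the same bases at a given offset: only the better
    # strand can ever be part of an optimal non-overlapping set.
    w = np.maximum(fwd, rev)
    W = len(w)
    best = np.zeros(W + L)  # best[i] = optimum using windows starting >= i
    for i in range(W - 1, -1, -1):
        take = w[i] + best[i + L] if w[i] > 0 else -math.inf
        best[i] = max(best[i + 1], take)
    return float(best[0])


def score_motif_over_regions(
    crrs: RegionCollection,
    genomes: list[GenomeSequences],
    pwm: PWM,
) -> list[dict[str, float]]:
    """Per genome, a CRM score per region (missing ortholog -> absent).

    The first entries of *genomes* with ``orthologs=None`` score regions at
    their own coordinates; others look the region up in their ortholog
    table and skip regions without an entry (absent, not zero).
    """
    out: list[dict[str, float]] = []
    for genome in genomes:
        scores: dict[str, float] = {}
        for region in crrs:
            if genome.orthologs is None:
                loc = (region.chrom, region.start, region.end)
            else:
                if region.region_id not in genome.orthologs:
                    continue
                loc = genome.orthologs[region.region_id]
            scores[region.region_id] = crm_score(genome.fetch(*loc), pwm)
        out.append(scores)
    return out


# ---------------------------------------------------------------------------
# Track scoring
# ---------------------------------------------------------------------------

def score_track_peaks(
    crrs: RegionCollection, scored_peaks: RegionCollection
) -> dict[str, float]:
    """Per region, the maximum signal of peaks intersecting it by >= 1 bp
    (no peak -> 0)."""
    if scored_peaks.scores is None:
        raise ValueError("peaks carry no scores (read with with_score=True)")
    if any(v < 0 for v in scored_peaks.scores.values()):
        warnings.warn("negative signal values present; kept as-is")
    out: dict[str, float] = {}
    for region in crrs:
        hits = scored_peaks.overlapping(region.chrom, region.start, region.end)
        out[region.region_id] = (
            max(scored_peaks.scores[h.region_id] for h in hits) if hits else 0.0
        )
    return out


def score_track_coverage(
    crrs: RegionCollection,
    coverage: dict[str, np.ndarray],
    aggregate: str = "max",
) -> dict[str, float]:
    """Per region, max (default) or mean of a per-base signal."""
    if aggregate not in ("max", "mean"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    out: dict[str, float] = {}
    for region in crrs:
        sig = coverage.get(region.chrom)
        if sig is None:
            warnings.warn(f"no coverage for chromosome {region.chrom!r}; score 0")
            out[region.region_id] = 0.0
            continue
        window = np.asarray(sig[region.start : region.end], dtype=float)
        out[region.region_id] = float(
            window.max() if aggregate == "max" else window.mean()
        )
    return out


# ---------------------------------------------------------------------------
# Rankings
# ---------------------------------------------------------------------------

@dataclass
class FeatureRanking:
    """One total ordering of all CRRs for one feature (rank 1 = strongest)."""

    feature_id: str
    feature_type: str  # motif | track | combined
    order: list[str]
    _ranks: dict[str, int] | None = field(default=None, repr=False, compare=False)

    def ranks(self) -> dict[str, int]:
        """region_id -> 1-based rank."""
        if self._ranks is None:
            self._ranks = {rid: i + 1 for i, rid in enumerate(self.order)}
        return self._ranks

    def __len__(self) -> int:
        return len(self.order)


def _tie_rng(seed: int, feature_id: str) -> np.random.Generator:
    key = zlib.crc32(f"{seed}:{feature_id}".encode()) & 0x7FFFFFFF
    return np.random.default_rng(key)


def scores_to_ranking(
    scores: dict[str, float],
    crr_ids: list[str],
    feature_id: str,
    feature_type: str = "motif",
    seed: int = 0,
) -> FeatureRanking:
    """Descending-score total order over the whole CRR universe.

    Ties break by a deterministic pseudo-random shuffle seeded by
    ``(seed, feature_id)``; regions with absent scores (missing keys or
    NaN) rank after all scored regions, shuffled among themselves.
    """
    unknown = set(scores) - set(crr_ids)
    if unknown:
        raise ValueError(f"scores for ids outside the CRR universe: {sorted(unknown)[:3]}")
    n = len(crr_ids)
    vals = np.full(n, np.nan)
    for i, rid in enumerate(crr_ids):
        v = scores.get(rid)
        if v is not None:
            vals[i] = v
    present = ~np.isnan(vals)
    tiebreak = _tie_rng(seed, feature_id).permutation(n)
    sort_vals = np.where(present, vals, -np.inf)
    idx = np.lexsort((tiebreak, -sort_vals))
    order = [crr_ids[i] for i in idx]
    return FeatureRanking(feature_id, feature_type, order)


# ---------------------------------------------------------------------------
# Order-statistics aggregation
# ---------------------------------------------------------------------------

def aggregate_rankings(ratios: "np.ndarray | list[float]") -> float:
    """Joint CDF of uniform order statistics at the sorted rank ratios.

    Given N per-genome rank ratios r_i in (0, 1], returns
    Q = P(U_(1) <= b_1, ..., U_(N) <= b_N) for N iid uniform(0,1) variables,
    with b the ratios sorted ascending. Smaller Q = stronger combined
    support. N=1 returns the ratio itself; all-ones returns 1.
    """
    r = np.atleast_1d(np.asarray(ratios, dtype=float))
    if r.ndim != 1 or len(r) < 1:
        raise ValueError("need >= 1 ratio")
    if np.any((r <= 0) | (r > 1)):
        raise ValueError("ratios must lie in (0, 1]")
    return float(aggregate_ratio_matrix(r[None, :])[0])


def aggregate_ratio_matrix(ratios: np.ndarray) -> np.ndarray:
    """Vectorized :func:`aggregate_rankings` over rows of an (M, N) matrix."""
    b = np.sort(np.asarray(ratios, dtype=float), axis=1)
    m, n = b.shape
    # Alternating recursion for P(U_(k) <= b_k for all k):
    #   c_0 = 1;  c_k = sum_{j=1..k} (-1)^{j+1} c_{k-j} b_{k-j+1}^j / j!
    #   Q = n! * c_n
    c = [np.ones(m)]
    for k in range(1, n + 1):
        acc = np.zeros(m)
        for j in range(1, k + 1):
            term = c[k - j] * b[:, k - j] ** j / math.factorial(j)
            acc += term if j % 2 == 1 else -term
        c.append(acc)
    return math.factorial(n) * c[n]


# ---------------------------------------------------------------------------
# Ranking database
# ---------------------------------------------------------------------------

class RankingDatabase:
    """All feature rankings over one CRR universe.

    ``rankings`` is an ordered mapping feature_id -> :class:`FeatureRanking`;
    every ranking is a permutation of exactly ``crr_ids``.
    """

    def __init__(
        self,
        crr_ids: list[str],
        rankings: list[FeatureRanking],
        db_label: str = "user",
        seed: int = 0,
    ):
        self.crr_ids = list(crr_ids)
        self.db_label = db_label
        self.seed = seed
        universe = set(self.crr_ids)
        self.rankings: dict[str, FeatureRanking] = {}
        for fr in rankings:
            if fr.feature_id in self.rankings:
                raise ValueError(f"duplicate feature_id {fr.feature_id!r}")
            if set(fr.order) != universe or len(fr.order) != len(self.crr_ids):
                raise ValueError(
                    f"ranking {fr.feature_id!r} is not a permutation of the universe"
                )
            self.rankings[fr.feature_id] = fr

    def __len__(self) -> int:
        return len(self.rankings)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.rankings)

    def checksum(self) -> str:
        return hashlib.md5("\n".join(self.crr_ids).encode()).hexdigest()

    # -- persistence: TSV rank matrix + JSON sidecar -----------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        mat = pd.DataFrame(
            {fid: pd.Series(fr.ranks()) for fid, fr in self.rankings.items()}
        ).loc[self.crr_ids]
        mat.index.name = "region_id"
        mat.to_csv(directory / "rankings.tsv", sep="\t")
        meta = {
            "db_label": self.db_label,
            "seed": self.seed,
            "crr_checksum": self.checksum(),
            "features": [
                {"feature_id": fid, "feature_type": fr.feature_type}
                for fid, fr in self.rankings.items()
            ],
        }
        (directory / "metadata.json").write_text(json.dumps(meta, indent=2) + "\n")

    @classmethod
    def load(
        cls, directory: str | Path, crrs: RegionCollection | None = None
    ) -> "RankingDatabase":
        directory = Path(directory)
        meta = json.loads((directory / "metadata.json").read_text())
        mat = pd.read_csv(directory / "rankings.tsv", sep="\t", index_col="region_id")
        crr_ids = [str(i) for i in mat.index]
        db = object.__new__(cls)
        db.crr_ids = crr_ids
        db.db_label = meta["db_label"]
        db.seed = meta["seed"]
        db.rankings = {}
        types = {f["feature_id"]: f["feature_type"] for f in meta["features"]}
        for fid in mat.columns:
            ranks = mat[fid].to_numpy()
            order = [crr_ids[i] for i in np.argsort(ranks, kind="stable")]
            db.rankings[fid] = FeatureRanking(fid, types[fid], order)
        if meta["crr_checksum"] != db.checksum():
            raise ValueError("metadata checksum does not match the stored universe")
        if crrs is not None and set(crr_ids) != set(crrs.ids):
            raise ValueError("stored CRR universe does not match the supplied CRRs")
        return db


def build_ranking_database(
    crrs: RegionCollection,
    feature_scores: dict[str, tuple[dict[str, float], str]],
    seed: int = 0,
    db_label: str = "user",
) -> RankingDatabase:
    """Rank every feature's score vector over the CRR universe.

    *feature_scores* maps feature_id -> (scores by region_id, feature_type).
    Motif features scored across several genomes should be aggregated first
    (see :func:`rank_motif_across_genomes`).
    """
    rankings = [
        scores_to_ranking(scores, crrs.ids, fid, ftype, seed)
        for fid, (scores, ftype) in feature_scores.items()
    ]
    return RankingDatabase(crrs.ids, rankings, db_label, seed)


def rank_motif_across_genomes(
    crrs: RegionCollection,
    genomes: list[GenomeSequences],
    pwm: PWM,
    seed: int = 0,
) -> FeatureRanking:
    """Score a motif in every genome, rank per genome, aggregate.

    Each genome's scores are ranked separately; a region's rank ratio in a
    genome is rank/N_regions. Missing orthologs impute ratio 1.0
    (uninformative) so N stays constant per region. The aggregated Q values
    are re-ranked ascending (small Q = strong) into the final ordering.
    """
    per_genome = score_motif_over_regions(crrs, genomes, pwm)
    n = len(crrs)
    ids = crrs.ids
    ratio_mat = np.ones((n, len(genomes)))
    for g, scores in enumerate(per_genome):
        ranking = scores_to_ranking(
            scores, ids, f"{pwm.motif_id}@{genomes[g].tag}", "motif", seed
        )
        ranks = ranking.ranks()
        for i, rid in enumerate(ids):
            if rid in scores:
                ratio_mat[i, g] = ranks[rid] / n
    q = aggregate_ratio_matrix(ratio_mat)
    neg_q = {rid: -q[i] for i, rid in enumerate(ids)}
    return scores_to_ranking(neg_q, ids, pwm.motif_id, "motif", seed)
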