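"""Independent brute-force oracles used by the test-suite.

Each oracle recomputes a quantity by a deliberately different route than
the library (per-base masks, exhaustive enumeration, plain-Python loops)
so that agreement is evidence, not tautology.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

# ---------------------------------------------------------------------------
# Per-base CRR-build oracle
# ---------------------------------------------------------------------------

def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean array, as half-open intervals."""
    out = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(mask)))
    return out


def crr_build_oracle(
    feature_sets,
    insulators,
    exons,
    config,
    chrom_sizes: dict[str, int],
) -> list[tuple[str, int, int]]:
    """Mark every base kept/excluded, then segment, filter, and extend."""
    out: list[tuple[str, int, int]] = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        feat = np.zeros(size, dtype=bool)
        ins = np.zeros(size, dtype=bool)
        exo = np.zeros(size, dtype=bool)
        for coll in feature_sets:
            for r in coll:
                if r.chrom == chrom:
                    feat[r.start : r.end] = True
        for r in insulators:
            if r.chrom == chrom:
                ins[r.start : r.end] = True
        for r in exons:
            if r.chrom == chrom:
                exo[r.start : r.end] = True
        bad = ins | exo
        kept_pieces: list[tuple[int, int]] = []
        for s, e in _runs(feat):  # merged regions (book-ended by construction)
            length = e - s
            if ins[s:e].sum() / length >= config.insulator_fraction:
                continue
            if exo[s:e].sum() / length >= config.exon_fraction:
                continue
            for ps, pe in _runs(~bad[s:e]):
                if pe - ps >= config.min_size:
                    kept_pieces.append((s + ps, s + pe))
        for s, e in kept_pieces:
            deficit = config.target_size - (e - s)
            if deficit <= 0:
                out.append((chrom, s, e))
                continue
            free_left = 0
            i = s - 1
            while i >= 0 and not bad[i]:
                free_left += 1
                i -= 1
            free_right = 0
            i = e
            while i < size and not bad[i]:
                free_right += 1
                i += 1
            want_l = deficit // 2
            want_r = deficit - want_l
            gl, gr = min(want_l, free_left), min(want_r, free_right)
            rem = deficit - gl - gr
            extra = min(rem, free_left - gl)
            gl += extra
            rem -= extra
            gr += min(rem, free_right - gr)
            out.append((chrom, s - gl, e + gr))
    out.sort()
    return out


# ---------------------------------------------------------------------------
# Exhaustive CRM-score oracle
# ---------------------------------------------------------------------------

def crm_score_oracle(sequence: str, pwm) -> float:
    """Enumerate all non-overlapping subsets of positive hits on both
    strands (memoized recursion over hit list)."""
    seq = sequence.upper()
    L = len(pwm)
    if len(seq) < L:
        return 0.0
    code = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
    lo_f = [
        [math.log2(pwm.matrix[j, b] / pwm.background[b]) for b in range(4)] + [0.0]
        for j in range(L)
    ]
    rc = pwm.reverse_complement()
    lo_r = [
        [math.log2(rc.matrix[j, b] / rc.background[b]) for b in range(4)] + [0.0]
        for j in range(L)
    ]
    hits: list[tuple[int, float]] = []
    for i in range(len(seq) - L + 1):
        for lo in (lo_f, lo_r):
            w = sum(lo[j][code[seq[i + j]]] for j in range(L))
            if w > 0:
                hits.append((i, w))
    hits.sort()

    @lru_cache(maxsize=None)
    def best(k: int) -> float:
        if k >= len(hits):
            return 0.0
        start, w = hits[k]
        nxt = k + 1
        while nxt < len(hits) and hits[nxt][0] < start + L:
            nxt += 1
        return max(best(k + 1), w + best(nxt))

    return best(0)


# ---------------------------------------------------------------------------
# Plain-loop recovery-analysis oracle
# ---------------------------------------------------------------------------

def recovery_oracle(
    orders: dict[str, list[str]],
    foreground: set[str],
    T_auc: int,
    T_le: int | None = None,
):
    """Recompute curves, AUCs, NES, mean/sd curves, and leading edges with
    plain Python loops and the statistics module."""
    import statistics

    T_le = T_le if T_le is not None else T_auc
    T = max(T_auc, T_le)
    F = len(foreground)
    curves: dict[str, list[int]] = {}
    for fid, order in orders.items():
        curves[fid] = [
            sum(1 for rid in order[:x] if rid in foreground) for x in range(1, T + 1)
        ]
    aucs = {
        fid: sum(rc[x] for x in range(T_auc)) / (T_auc * F)
        for fid, rc in curves.items()
    }
    mu = statistics.fmean(aucs.values())
    sigma = statistics.pstdev(aucs.values())
    nes = {
        fid: ((a - mu) / sigma if sigma > 0 else 0.0) for fid, a in aucs.items()
    }
    mean_curve = [
        statistics.fmean(curves[fid][x] for fid in curves) for x in range(T)
    ]
    sd_curve = [
        statistics.pstdev(curves[fid][x] for fid in curves) for x in range(T)
    ]
    les = {}
    for fid, rc in curves.items():
        diffs = [
            rc[x] - (mean_curve[x] + 2 * sd_curve[x]) for x in range(T_le)
        ]
        best_x, best_d = 1, diffs[0]
        for x in range(1, T_le):
            if diffs[x] > best_d:
                best_x, best_d = x + 1, diffs[x]
        targets = sorted(
            (rid for rid in foreground if orders[fid].index(rid) + 1 <= best_x),
            key=lambda rid: orders[fid].index(rid),
        )
        les[fid] = (best_x, targets, best_d > 0)
    return curves, aucs, nes, mean_curve, sd_curve, les


# ---------------------------------------------------------------------------
# Brute-force motif-distance oracle
# ---------------------------------------------------------------------------

def ssd_oracle(a, b) -> float:
    """Pad-into-a-common-frame enumeration of offsets/orientations."""
    bg = (a.background + b.background) / 2.0
    best = math.inf
    for mat_b in (b.matrix, b.reverse_complement().matrix):
        la, lb = len(a.matrix), len(mat_b)
        for offset in range(-lb + 1, la):
            lo = min(0, offset)
            hi = max(la, offset + lb)
            frame_a = np.tile(bg, (hi - lo, 1))
            frame_b = np.tile(bg, (hi - lo, 1))
            frame_a[-lo : -lo + la] = a.matrix
            frame_b[offset - lo : offset - lo + lb] = mat_b
            best = min(best, float(np.mean(np.sum((frame_a - frame_b) ** 2, axis=1))))
    return best
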