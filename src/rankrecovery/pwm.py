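"""Position weight matrices: container, converters, and readers.

A PWM is an L x 4 per-position probability matrix over (A, C, G, T) with a
background nucleotide distribution. Count matrices (Cluster-Buster text
format, JASPAR-style) are converted to probabilities with a pseudocount.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["PWM", "read_pwms", "read_pwms_cb", "read_pwms_jaspar"]

ALPHABET = "ACGT"
_COMPLEMENT = np.array([3, 2, 1, 0])  # A<->T, C<->G
DEFAULT_PSEUDOCOUNT = 0.001
UNIFORM = np.full(4, 0.25)


@dataclass
class PWM:
    motif_id: str
    matrix: np.ndarray  # (L, 4) probabilities over A, C, G, T
    background: np.ndarray = field(default_factory=lambda: UNIFORM.copy())
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or len(self.matrix) < 1:
            raise ValueError(f"{self.motif_id}: matrix must be L x 4 with L >= 1")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"{self.motif_id}: matrix rows must sum to 1")
        if np.any(self.matrix <= 0):
            raise ValueError(f"{self.motif_id}: matrix entries must be > 0 "
                             "(apply a pseudocount when converting counts)")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError(f"{self.motif_id}: background must sum to 1")

    def __len__(self) -> int:
        return len(self.matrix)

    @classmethod
    def from_counts(
        cls,
        motif_id: str,
        counts: np.ndarray,
        background: np.ndarray | None = None,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
    ) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        if np.any(counts < 0):
            raise ValueError(f"{motif_id}: negative counts")
        probs = counts + pseudocount
        probs /= probs.sum(axis=1, keepdims=True)
        bg = UNIFORM.copy() if background is None else np.asarray(background, float)
        return cls(motif_id, probs, bg, pseudocount)

    def reverse_complement(self) -> "PWM":
        mat = self.matrix[::-1, _COMPLEMENT]
        bg = self.background[_COMPLEMENT]
        return PWM(self.motif_id, mat, bg, self.pseudocount)

    def log_odds(self) -> np.ndarray:
        """(L, 5) log2(p/bg) with a trailing zero column for N bases."""
        lo = np.log2(self.matrix / self.background)
        return np.hstack([lo, np.zeros((len(self), 1))])

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_pwms_cb(
    path: str | Path,
    background: np.ndarray | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[PWM]:
    """Cluster-Buster text format: ``>name`` header, one ``A C G T`` count
    row per motif position."""
    pwms: list[PWM] = []
    name: str | None = None
    rows: list[list[float]] = []

    def flush() -> None:
        if name is not None:
            if not rows:
                raise ValueError(f"motif {name!r} has no count rows")
            pwms.append(PWM.from_counts(name, np.array(rows), background, pseudocount))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0]
                rows = []
            else:
                vals = [float(x) for x in line.split()]
                if len(vals) != 4:
                    raise ValueError(f"motif {name!r}: expected 4 counts per row")
                rows.append(vals)
    flush()
    return pwms


def read_pwms_jaspar(
    path: str | Path,
    background: np.ndarray | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[PWM]:
    """JASPAR-style count matrices: ``>ID name`` header then four rows
    ``A [ 1 2 3 ]`` ... ``T [ ... ]`` (brackets optional)."""
    pwms: list[PWM] = []
    name: str | None = None
    per_base: dict[str, list[float]] = {}

    def flush() -> None:
        if name is None:
            return
        missing = [b for b in ALPHABET if b not in per_base]
        if missing:
            raise ValueError(f"motif {name!r}: missing rows for {missing}")
        counts = np.array([per_base[b] for b in ALPHABET]).T  # (L, 4)
        pwms.append(PWM.from_counts(name, counts, background, pseudocount))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0]
                per_base = {}
            else:
                base, rest = line[0].upper(), line[1:]
                if base not in ALPHABET:
                    raise ValueError(f"motif {name!r}: unexpected row {line!r}")
                rest = rest.replace("[", " ").replace("]", " ")
                per_base[base] = [float(x) for x in rest.split()]
    flush()
    return pwms


def read_pwms(path: str | Path, **kwargs) -> list[PWM]:
    """Auto-detect Cluster-Buster vs JASPAR count format."""
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith((">", "#")):
                continue
            first = line[0].upper()
            if first in ALPHABET and not line.split()[0].replace(".", "").isdigit():
                return read_pwms_jaspar(path, **kwargs)
            return read_pwms_cb(path, **kwargs)
    return []


def write_pwms_cb(pwms: list[PWM], path: str | Path, scale: int = 100) -> None:
    """Write motifs in Cluster-Buster count format (probabilities x scale)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id}\n")
            for row in pwm.matrix:
                fh.write("\t".join(f"{v * scale:.4f}" for v in row) + "\n")
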