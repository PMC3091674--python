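"""Position-specific scoring matrices and promoter scanning.

Builds log-odds weight matrices from nucleotide frequency matrices,
scans promoter sequences for high-scoring windows on both strands,
reports per-promoter maxima, and calibrates score thresholds so that a
configured fraction of a promoter universe is called.

The weight of nucleotide ``nuc`` at motif position ``j`` is

    W(nuc, j) = log2( (f(nuc, j) + eps) / p(nuc) )

where ``f`` is the relative frequency in the motif, ``p`` the background
frequency of the nucleotide in intergenic DNA, and ``eps`` a small
pseudocount guarding against zero frequencies.  A window of sequence
scores the sum of the weights of its nucleotides; the per-promoter score
is the maximum over all windows on both strands.

.. note::
   The default background uses the composition as printed in the source
   material for yeast intergenic regions, ``p_G = p_C = 0.34`` and
   ``p_A = p_T = 0.16``.  Yeast intergenic DNA is in fact AT-rich, so
   this looks like a transposition of A/T and G/C; the printed values
   are kept as the default rather than silently corrected, and the
   background is configurable.  Fixed score thresholds depend on the
   logarithm base; the fraction-of-universe calibration
   (:func:`calibrate_threshold`) is the primary, base-independent
   mechanism.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

NUCLEOTIDES = "ACGT"
_NUC_INDEX = {c: i for i, c in enumerate(NUCLEOTIDES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Background frequencies as printed for yeast intergenic regions
#: (see module note on the apparent A/T vs G/C transposition).
DEFAULT_BACKGROUND = {"A": 0.16, "C": 0.34, "G": 0.34, "T": 0.16}


@dataclasses.dataclass(frozen=True)
class FrequencyMatrix:
    """Per-position nucleotide frequencies of a motif.

    ``matrix`` has shape (4, length) with rows ordered A, C, G, T and
    columns summing to 1.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != 4 or m.shape[1] < 1:
            raise ValueError("frequency matrix must have shape (4, length>=1)")
        if np.any(m < 0):
            raise ValueError("frequencies must be non-negative")
        colsums = m.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > 1e-9):
            raise ValueError("frequency matrix columns must sum to 1")
        object.__setattr__(self, "matrix", m)

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @classmethod
    def from_counts(cls, counts: np.ndarray) -> "FrequencyMatrix":
        """Normalize a 4 x L count (or frequency) matrix column-wise."""
        c = np.asarray(counts, dtype=float)
        totals = c.sum(axis=0)
        if np.any(totals <= 0):
            raise ValueError("every column needs a positive total count")
        return cls(c / totals)

    @property
    def consensus(self) -> str:
        return "".join(NUCLEOTIDES[i] for i in self.matrix.argmax(axis=0))


@dataclasses.dataclass(frozen=True)
class Pssm:
    """Log-odds weight matrix with its background and pseudocount."""

    weights: np.ndarray          # (4, length), rows A, C, G, T
    background: dict[str, float]
    epsilon: float

    @property
    def length(self) -> int:
        return self.weights.shape[1]

    @property
    def max_score(self) -> float:
        """Best achievable window score (consensus score)."""
        return float(self.weights.max(axis=0).sum())


def build_pssm(
    freq: FrequencyMatrix,
    background: dict[str, float] | None = None,
    epsilon: float = 0.01,
) -> Pssm:
    """Convert a frequency matrix into a log2-odds weight matrix.

    Raises if any ``f + epsilon`` is zero (demand ``epsilon > 0`` for
    motifs with absent nucleotides) or the background is not a positive
    distribution.
    """
    bg = dict(DEFAULT_BACKGROUND if background is None else background)
    p = np.array([bg[c] for c in NUCLEOTIDES], dtype=float)
    if np.any(p <= 0):
        raise ValueError("background frequencies must be positive")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("background frequencies must sum to 1")
    f = freq.matrix + epsilon
    if np.any(f <= 0):
        raise ValueError("f + epsilon is zero; a pseudocount epsilon > 0 is required")
    weights = np.log2(f / p[:, None])
    return Pssm(weights=weights, background=bg, epsilon=epsilon)


def _encode(sequence: str) -> np.ndarray:
    seq = sequence.upper()
    idx = np.full(len(seq), 4, dtype=np.int64)  # 4 == N / unknown
    for c, i in _NUC_INDEX.items():
        idx[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(c)] = i
    return idx


def reverse_complement(sequence: str) -> str:
    return sequence.upper().translate(_COMPLEMENT)[::-1]


def _window_scores(idx: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Scores of all windows of an encoded sequence; N-containing windows -inf."""
    length = weights.shape[1]
    n_win = idx.size - length + 1
    if n_win <= 0:
        return np.empty(0, dtype=float)
    # pad the weight matrix with a -inf row so that any window touching
    # an N scores -inf and can never be maximal
    padded = np.vstack([weights, np.full(length, -np.inf)])
    scores = np.zeros(n_win, dtype=float)
    for j in range(length):
        scores += padded[idx[j : j + n_win], j]
    return scores


@dataclasses.dataclass
class ScanResult:
    """All window scores of one promoter plus the per-promoter maximum.

    ``forward`` and ``reverse`` hold one score per window start in
    forward-strand coordinates (left edge of the window, 0-based,
    half-open ``[start, start+len)``).  ``max_score`` is NaN when the
    sequence is shorter than the motif or every window contains an N.
    """

    forward: np.ndarray
    reverse: np.ndarray
    max_score: float
    best_start: int | None
    best_strand: str | None


def scan(sequence: str, pssm: Pssm, both_strands: bool = True) -> ScanResult:
    """Score every window of ``sequence`` against ``pssm``.

    The reverse strand is scanned by scoring the reverse complement and
    mapping window starts back to forward coordinates.
    """
    idx = _encode(sequence)
    fwd = _window_scores(idx, pssm.weights)
    if both_strands and fwd.size:
        rc_scores = _window_scores(_encode(reverse_complement(sequence)), pssm.weights)
        rev = rc_scores[::-1]  # rc window i <-> forward start L-len-i
    else:
        rev = np.full(fwd.size if both_strands else 0, -np.inf)

    best: float = -np.inf
    best_start: int | None = None
    best_strand: str | None = None
    for strand, arr in (("+", fwd), ("-", rev)):
        if arr.size and np.max(arr) > best:
            best = float(np.max(arr))
            best_start = int(np.argmax(arr))
            best_strand = strand
    if not np.isfinite(best):
        return ScanResult(fwd, rev, float("nan"), None, None)
    return ScanResult(fwd, rev, best, best_start, best_strand)


def scan_promoters(
    promoters: dict[str, str], pssm: Pssm, both_strands: bool = True
) -> pd.DataFrame:
    """Per-promoter maximum scores for a set of sequences.

    Returns a frame indexed by promoter id with columns ``max_score``,
    ``best_start`` and ``strand``.
    """
    rows = []
    for name, seq in promoters.items():
        res = scan(seq, pssm, both_strands=both_strands)
        rows.append((name, res.max_score, res.best_start, res.best_strand))
    return pd.DataFrame(
        rows, columns=["promoter", "max_score", "best_start", "strand"]
    ).set_index("promoter")


def calibrate_threshold(max_scores, fraction: float) -> float:
    """Smallest observed score whose strict exceedance fraction is <= ``fraction``.

    A promoter is called when its maximum score is strictly greater than
    the threshold, so the called fraction of the calibration universe is
    at most ``fraction`` (typically just below it: with N distinct
    scores and fraction f the called fraction is ceil-adjusted to about
    f - 1/N).  ``fraction=1`` returns a value below the minimum score so
    every promoter passes.
    """
    scores = np.asarray(max_scores, dtype=float)
    scores = scores[~np.isnan(scores)]
    if scores.size == 0:
        raise ValueError("empty score universe; nothing to calibrate on")
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    if fraction >= 1.0:
        return float(scores.min() - 1.0)
    candidates = np.unique(scores)  # ascending
    n = scores.size
    # strict exceedance counts for each candidate value
    exceed = n - np.searchsorted(np.sort(scores), candidates, side="right")
    ok = exceed / n <= fraction
    first = int(np.argmax(ok))  # candidates are ascending; exceed is non-increasing
    return float(candidates[first])


def call_sites(max_scores: pd.Series, threshold: float) -> pd.Series:
    """Site call per promoter: maximum window score strictly above threshold."""
    return max_scores > threshold


# ---------------------------------------------------------------------------
# PFM file format: 4 whitespace-delimited rows labelled A, C, G, T, one
# column per motif position; entries may be counts and are normalized on load.
# ---------------------------------------------------------------------------

def read_pfm(path: str | Path) -> FrequencyMatrix:
    rows: dict[str, list[float]] = {}
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts or parts[0].startswith("#"):
            continue
        label = parts[0].upper().rstrip(":")
        if label not in _NUC_INDEX:
            raise ValueError(f"unexpected row label {parts[0]!r} in PFM file")
        rows[label] = [float(x) for x in parts[1:]]
    missing = set(NUCLEOTIDES) - set(rows)
    if missing:
        raise ValueError(f"PFM file lacks rows for {sorted(missing)}")
    lengths = {len(v) for v in rows.values()}
    if len(lengths) != 1:
        raise ValueError("PFM rows have unequal lengths")
    counts = np.array([rows[c] for c in NUCLEOTIDES], dtype=float)
    return FrequencyMatrix.from_counts(counts)


def write_pfm(freq: FrequencyMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, c in enumerate(NUCLEOTIDES):
            fh.write(c + "\t" + "\t".join(f"{v:.6f}" for v in freq.matrix[i]) + "\n")
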