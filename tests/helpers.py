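"""Independent oracles shared across test modules.

Everything here is deliberately naive (pure-Python enumeration, direct
formulas) and independent of the library code paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_ORDER = "ACGT"


def brute_revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq.upper()))


def brute_window_scores(seq: str, weights: np.ndarray) -> list[float]:
    """Score every forward window by explicit per-position lookup."""
    L = weights.shape[1]
    seq = seq.upper()
    out = []
    for i in range(len(seq) - L + 1):
        total = 0.0
        for j in range(L):
            c = seq[i + j]
            if c not in _ORDER:
                total = -math.inf
                break
            total += weights[_ORDER.index(c), j]
        out.append(total)
    return out


def brute_scan_max(seq: str, weights: np.ndarray, both_strands: bool = True):
    """(max score, per-strand window score lists) by exhaustive enumeration."""
    fwd = brute_window_scores(seq, weights)
    L = weights.shape[1]
    rev = []
    if both_strands:
        rc = brute_window_scores(brute_revcomp(seq), weights)
        # rc window i starts at forward coordinate len(seq) - L - i
        rev = list(reversed(rc))
    candidates = [s for s in fwd + rev if s != -math.inf]
    best = max(candidates) if candidates else math.nan
    return best, fwd, rev

def brute_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment by the textbook formula."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def brute_hypergeom_tail(universe: int, size_a: int, size_b: int, k: int) -> float:
    """P(X >= k) for the hypergeometric overlap, by direct combinatorics."""
    total = 0.0
    denom = math.comb(universe, size_b)
    for x in range(k, min(size_a, size_b) + 1):
        total += math.comb(size_a, x) * math.comb(universe - size_a, size_b - x) / denom
    return total


def brute_t_two_sided_p(t: float, df: int, grid: int = 400_000) -> float:
    """Two-sided t-test p-value by numerical integration of the t density."""
    # integrate the density from 0 to |t|; p = 1 - 2 * integral
    x = np.linspace(0.0, abs(t), grid)
    dens = (
        math.gamma((df + 1) / 2)
        / (math.sqrt(df * math.pi) * math.gamma(df / 2))
        * (1 + x**2 / df) ** (-(df + 1) / 2)
    )
    return float(1.0 - 2.0 * np.trapezoid(dens, x))


def random_dna(rng: np.random.Generator, n: int, p=None, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=n, p=p))


def all_kmers(k: int):
    return ("".join(t) for t in itertools.product(_ORDER, repeat=k))
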