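"""ChIP target calling with a mirrored-null FDR, and target-set statistics.

Per-promoter averaged log2 binding ratios are standardized to Z scores.
Under the assumption that the null (unbound) part of the Z distribution
is symmetric around zero, the negative tail estimates the number of
false positives in the positive tail, giving for a cutoff ``c``

    FDR(c) = #{Z <= -c} / max(1, #{Z >= c})

The returned threshold is the smallest observed cutoff whose estimated
FDR is at or below the requested level; promoters with Z at or above it
are called targets.  Because every observed |Z| is a candidate, the
scan reaches into the extreme tail, where a single top-ranked positive
score trivially satisfies any level; called sets under a pure null are
therefore tiny (almost always 0-2 extreme promoters) rather than
strictly empty.

Targets of an activator and a repressor are classified into
activator-only / common / repressor-only groups; overlaps are scored
with the hypergeometric upper tail and motif presence with a simple
fold enrichment.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats


def zscores(values) -> pd.Series:
    """Standardize (x - mean)/sd with the sample sd (n-1 denominator).

    Missing values are excluded from the mean/sd and reported with a
    warning; their Z is NaN.  Fewer than 3 usable values or a zero sd
    is an error.
    """
    x = pd.Series(values, dtype=float)
    finite = x.dropna()
    n_missing = len(x) - len(finite)
    if n_missing:
        warnings.warn(f"{n_missing} missing values excluded from Z scoring")
    if len(finite) < 3:
        raise ValueError(f"need at least 3 non-missing values, got {len(finite)}")
    sd = float(finite.std(ddof=1))
    if sd == 0:
        raise ValueError("constant input: standard deviation is zero")
    return (x - finite.mean()) / sd


@dataclasses.dataclass
class MirroredFdrResult:
    threshold: float            # +inf when no cutoff attains the level
    alpha: float
    n_called: int
    fdr_at_threshold: float
    called: pd.Series           # boolean, Z >= threshold


def mirrored_fdr_threshold(z, alpha: float = 0.05) -> MirroredFdrResult:
    """Smallest observed |Z| cutoff with mirrored-null FDR <= alpha.

    Candidates are the observed positive |Z| values; the estimate is
    capped at 1 and its denominator floored at 1.  Returns +inf (empty
    called set) when no candidate qualifies, e.g. for a perfectly
    mirrored distribution.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    zs = pd.Series(z, dtype=float)
    vals = zs.dropna().to_numpy()
    candidates = np.unique(np.abs(vals[vals != 0]))
    if candidates.size == 0 or not np.any(vals > 0):
        warnings.warn("no positive Z values; returning +inf threshold")
        return MirroredFdrResult(np.inf, alpha, 0, np.nan, zs >= np.inf)
    sorted_vals = np.sort(vals)
    n = sorted_vals.size
    # #{Z >= c} and #{Z <= -c} for every candidate c, via one sort
    n_pos = n - np.searchsorted(sorted_vals, candidates, side="left")
    n_neg = np.searchsorted(sorted_vals, -candidates, side="right")
    fdr = np.minimum(n_neg / np.maximum(n_pos, 1), 1.0)
    ok = fdr <= alpha
    if not ok.any():
        return MirroredFdrResult(np.inf, alpha, 0, np.nan, zs >= np.inf)
    i = int(np.argmax(ok))  # candidates ascending -> smallest qualifying cutoff
    thr = float(candidates[i])
    called = zs >= thr
    return MirroredFdrResult(thr, alpha, int(called.sum()), float(fdr[i]), called)


def build_binding_table(
    ratios: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, dict[str, MirroredFdrResult]]:
    """Per-factor Z scores and called flags from averaged binding ratios.

    ``ratios``: promoter-indexed frame, one column per factor.  Returns
    (table, per-factor FDR results); the table carries, per factor,
    ``<f>_ratio``, ``<f>_z``, ``<f>_called`` plus the threshold used.
    """
    out = pd.DataFrame(index=ratios.index)
    results: dict[str, MirroredFdrResult] = {}
    for factor in ratios.columns:
        z = zscores(ratios[factor])
        res = mirrored_fdr_threshold(z, alpha)
        out[f"{factor}_ratio"] = ratios[factor]
        out[f"{factor}_z"] = z
        out[f"{factor}_called"] = res.called
        out.attrs[f"{factor}_threshold"] = res.threshold
        results[factor] = res
    return out, results


@dataclasses.dataclass(frozen=True)
class TargetGroups:
    """Disjoint activator-only / common / repressor-only promoter sets."""

    activator_only: frozenset
    common: frozenset
    repressor_only: frozenset

    def label_of(self, promoter) -> str | None:
        if promoter in self.common:
            return "common"
        if promoter in self.activator_only:
            return "activator_only"
        if promoter in self.repressor_only:
            return "repressor_only"
        return None

    def as_series(self) -> pd.Series:
        data = {}
        for name in ("activator_only", "common", "repressor_only"):
            for p in getattr(self, name):
                data[p] = name
        return pd.Series(data, name="group")


def classify_groups(targets_activator, targets_repressor) -> TargetGroups:
    """Split two called target sets into only/common/only groups."""
    a, b = frozenset(targets_activator), frozenset(targets_repressor)
    return TargetGroups(
        activator_only=a - b, common=a & b, repressor_only=b - a
    )


def overlap_pvalue(set_a, set_b, universe_size: int) -> float:
    """Hypergeometric upper-tail P(X >= |A & B|) over a shared universe."""
    a, b = set(set_a), set(set_b)
    if len(a) > universe_size or len(b) > universe_size:
        raise ValueError("set larger than the universe")
    k = len(a & b)
    if k > min(len(a), len(b)):
        raise ValueError("overlap exceeds the smaller set")  # unreachable from sets
    return float(stats.hypergeom.sf(k - 1, universe_size, len(a), len(b)))


def motif_fold_enrichment(group_set, universe_set, site_calls) -> float:
    """(fraction of group promoters with a site) / (same over the universe).

    ``site_calls``: mapping or boolean Series over the universe.
    """
    calls = pd.Series(site_calls).astype(bool)
    universe = list(universe_set)
    group = list(group_set)
    if not universe or not group:
        raise ValueError("empty group or universe")
    frac_universe = calls.reindex(universe).fillna(False).mean()
    if frac_universe == 0:
        raise ValueError("no promoter in the universe has a site; fold undefined")
    frac_group = calls.reindex(group).fillna(False).mean()
    return float(frac_group / frac_universe)
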