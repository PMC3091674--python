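"""Feed-forward-loop dissection: direct vs indirect late-meiosis repression.

Middle-meiosis genes are activated by Ndt80 and re-repressed late.  The
repressor Sum1 can act on a target directly (binding its promoter) and
indirectly (repressing *NDT80* itself), forming a coherent type-2
feed-forward loop.  Comparing late-phase repression between the
wild type and a strain whose *NDT80* escapes Sum1 control (estradiol
inducible, "ER") separates the two paths.

Per gene, the repression fold between the designated middle and late
timepoints is

    R = 2^(x(middle) - x(late))        (x: log2 expression)

with R > 1 meaning late repression.  The weight of the indirect path is

    W = clamp(1 - ln(R_mutant) / ln(R_wt), 0, 1)

so W = 0 when the ER mutant represses exactly like the wild type (the
indirect path is dispensable) and W = 1 when the mutant shows no
repression at all (everything flows through NDT80 down-regulation).  W
is a ratio of logarithms, hence independent of the log base, continuous
and non-increasing in R_mutant, and only defined where the wild type
actually represses (R_wt > 1).

.. note::
   The exact printed form of the weight equation in the source study is
   not recoverable (it appears only as an image); the form above is a
   reconstruction satisfying every stated property.  Equivalently,
   R_mutant = R_wt^(1-W).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

#: reason codes for missing W
W_OK = "ok"
W_NO_WT_REPRESSION = "wt_not_repressed"      # R_wt <= 1
W_MISSING_INPUT = "missing_input"


@dataclasses.dataclass(frozen=True)
class StrainTimepointMap:
    """Designated (middle, late) timepoint labels per strain."""

    middle_late: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        for strain, (mid, late) in self.middle_late.items():
            if float(mid) >= float(late):
                raise ValueError(
                    f"{strain}: middle timepoint {mid} must precede late {late}"
                )

    def middle(self, strain: str) -> str:
        return self.middle_late[strain][0]

    def late(self, strain: str) -> str:
        return self.middle_late[strain][1]


def repression_fold(
    expr: pd.DataFrame, middle_label, late_label
) -> pd.Series:
    """Per-gene linear repression fold R = 2^(x_middle - x_late).

    Missing values at either timepoint leave R missing for that gene.
    """
    for label in (middle_label, late_label):
        if label not in expr.columns:
            raise KeyError(f"timepoint {label!r} not in expression matrix")
    r = np.power(2.0, expr[middle_label] - expr[late_label])
    r.name = "R"
    return r


def select_repressed_targets(targets, r_wt: pd.Series, cutoff: float = 1.3) -> list:
    """Targets whose wild-type repression fold is at least ``cutoff``."""
    r = r_wt.reindex(list(targets))
    return list(r.index[r >= cutoff])


def indirect_weight(r_wt, r_mutant) -> pd.Series:
    """W = clamp(1 - ln(R_mutant)/ln(R_wt), 0, 1), elementwise.

    NaN (reason: no wild-type repression) where R_wt <= 1; mutant folds
    must be positive where defined.
    """
    rw = pd.Series(r_wt, dtype=float)
    rm = pd.Series(r_mutant, dtype=float).reindex(rw.index)
    if np.any(rm.dropna() <= 0) or np.any(rw.dropna() <= 0):
        raise ValueError("repression folds must be positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        w = 1.0 - np.log(rm) / np.log(rw)
    w = w.clip(0.0, 1.0)
    w[rw <= 1.0] = np.nan
    w.name = "W"
    return w


def w_reason(r_wt, r_mutant) -> pd.Series:
    """Reason codes accompanying :func:`indirect_weight`."""
    rw = pd.Series(r_wt, dtype=float)
    rm = pd.Series(r_mutant, dtype=float).reindex(rw.index)
    reason = pd.Series(W_OK, index=rw.index, name="w_flag")
    reason[rw <= 1.0] = W_NO_WT_REPRESSION
    reason[rw.isna() | rm.isna()] = W_MISSING_INPUT
    return reason


def build_repression_records(
    folds: dict[str, pd.Series],
    groups: pd.Series,
    repressed_cutoff: float = 1.3,
) -> pd.DataFrame:
    """Assemble the per-gene record table.

    ``folds``: repression folds per strain, keys ``wt``, ``er``,
    ``sum1d``; ``groups``: gene -> group label.  W is computed for genes
    in activator-bound groups (activator_only or common) whose wild-type
    fold passes ``repressed_cutoff``.
    """
    genes = folds["wt"].index
    rec = pd.DataFrame(index=genes)
    rec["group"] = groups.reindex(genes)
    rec["R_wt"] = folds["wt"]
    rec["R_er"] = folds["er"].reindex(genes)
    rec["R_sumdel"] = folds["sum1d"].reindex(genes)
    activator_bound = rec["group"].isin(["activator_only", "common"])
    repressed = rec["R_wt"] >= repressed_cutoff
    eligible = activator_bound & repressed
    w = indirect_weight(rec.loc[eligible, "R_wt"], rec.loc[eligible, "R_er"])
    rec["W"] = w.reindex(genes)
    rec["w_flag"] = w_reason(rec["R_wt"], rec["R_er"])
    rec.loc[~eligible, "w_flag"] = "not_selected"
    rec.index.name = "gene"
    return rec


@dataclasses.dataclass
class GroupComparison:
    n: int
    mean_a: float                # mean linear fold, first condition
    mean_b: float
    statistic: float | None      # paired t on per-gene log2 fold differences
    df: int | None
    p: float | None
    mean_log2_diff: float        # mean of log2(R_a) - log2(R_b)
    test: str
    degenerate: bool = False


def compare_groups(
    r_a: pd.Series, r_b: pd.Series, test: str = "t"
) -> GroupComparison:
    """Paired comparison of repression folds between two conditions.

    Runs a two-sided paired test on log2(R_a) - log2(R_b) over the genes
    defined in both series: Student t by default, Wilcoxon signed-rank
    with ``test="wilcoxon"``.  All-zero differences are degenerate (the
    statistic is undefined); p is then missing and flagged.
    """
    paired = pd.concat([r_a, r_b], axis=1, keys=["a", "b"]).dropna()
    n = len(paired)
    if n < 3:
        raise ValueError(f"need >= 3 paired observations, got {n}")
    diffs = np.log2(paired["a"]) - np.log2(paired["b"])
    mean_a, mean_b = float(paired["a"].mean()), float(paired["b"].mean())
    if np.allclose(diffs, 0.0):
        return GroupComparison(
            n, mean_a, mean_b, None, None, None, 0.0, test, degenerate=True
        )
    if test == "t":
        res = stats.ttest_1samp(diffs, 0.0)
        return GroupComparison(
            n, mean_a, mean_b, float(res.statistic), n - 1, float(res.pvalue),
            float(diffs.mean()), "t",
        )
    if test == "wilcoxon":
        res = stats.wilcoxon(diffs)
        return GroupComparison(
            n, mean_a, mean_b, float(res.statistic), None, float(res.pvalue),
            float(diffs.mean()), "wilcoxon",
        )
    raise ValueError("test must be 't' or 'wilcoxon'")


def summarize_groups(records: pd.DataFrame) -> pd.DataFrame:
    """Per-group means of R in each background plus WT-vs-ER paired tests."""
    rows = []
    for group, sub in records.groupby("group"):
        row = {
            "group": group,
            "n": len(sub),
            "mean_R_wt": sub["R_wt"].mean(),
            "mean_R_er": sub["R_er"].mean(),
            "mean_R_sumdel": sub["R_sumdel"].mean(),
            "mean_W": sub["W"].mean(),
        }
        both = sub[["R_wt", "R_er"]].dropna()
        if len(both) >= 3:
            cmp = compare_groups(both["R_wt"], both["R_er"])
            row["t_wt_vs_er"] = cmp.statistic
            row["p_wt_vs_er"] = cmp.p
        else:
            row["t_wt_vs_er"] = np.nan
            row["p_wt_vs_er"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")
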