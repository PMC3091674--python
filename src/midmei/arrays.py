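"""Two-channel spot tables: lowess (MA) normalization and averaging.

Two-colour microarrays report a sample and a reference intensity per
spot.  Intensity-dependent dye bias is removed by robust local linear
regression of ``M = log2(sample/reference)`` on the mean log intensity
``A = 0.5 * log2(sample * reference)`` per array; the fitted trend is
subtracted from ``M``.  Dye-swapped arrays have their ``M`` sign-flipped
before fitting.  Features are printed as duplicate spots: the feature
value on an array is the mean of its surviving (unflagged) spots, a
single surviving spot stands alone, and a feature with no surviving
spots is missing.  Replicate arrays are then averaged per feature.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

#: Documented spot-table dialect (TSV with this header).
SPOT_COLUMNS = [
    "array_id",
    "spot_id",
    "feature_id",
    "f_sample",
    "f_reference",
    "flag",
    "dye_swapped",
]

DEFAULT_SPAN = 0.3
DEFAULT_ITERATIONS = 3


def _check_spot_table(spots: pd.DataFrame) -> None:
    missing = [c for c in SPOT_COLUMNS if c not in spots.columns]
    if missing:
        raise ValueError(f"spot table lacks columns {missing}")


def lowess_normalize(
    spots: pd.DataFrame,
    span: float = DEFAULT_SPAN,
    iterations: int = DEFAULT_ITERATIONS,
    delta: float | None = None,
) -> pd.DataFrame:
    """Lowess-correct the log-ratios of every array in a spot table.

    Returns a copy with added columns ``a`` (mean log2 intensity) and
    ``m`` (corrected log2 ratio; NaN for flagged spots).  Fitting uses
    only unflagged spots; flagged spots are carried through unscored.
    Arrays marked ``dye_swapped`` have M sign-flipped before fitting, so
    toggling the flag on an array negates its normalized values exactly.

    ``delta`` is the lowess interpolation distance along A (points
    closer than this share a fit); defaults to 1% of the A range of
    each array, the customary speed/accuracy trade-off.  Pass 0 to fit
    at every point.
    """
    _check_spot_table(spots)
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    out = spots.copy()
    out["a"] = np.nan
    out["m"] = np.nan
    min_spots = max(4, math.ceil(2.0 / span))
    for _, group in out.groupby("array_id", sort=False):
        keep = ~group["flag"].astype(bool)
        sub = group[keep]
        if len(sub) < min_spots:
            raise ValueError(
                f"array {group['array_id'].iloc[0]!r} has {len(sub)} usable spots; "
                f"lowess with span {span} needs at least {min_spots}"
            )
        fs = sub["f_sample"].to_numpy(dtype=float)
        fr = sub["f_reference"].to_numpy(dtype=float)
        if np.any(fs <= 0) or np.any(fr <= 0):
            raise ValueError("channel intensities of retained spots must be positive")
        m = np.log2(fs / fr)
        if bool(sub["dye_swapped"].iloc[0]):
            m = -m
        a = 0.5 * np.log2(fs * fr)
        d = 0.01 * float(np.ptp(a)) if delta is None else delta
        fit = _sm_lowess(
            m, a, frac=span, it=iterations, delta=d, return_sorted=False
        )
        out.loc[sub.index, "a"] = a
        out.loc[sub.index, "m"] = m - fit
    return out


def average_spots(normalized: pd.DataFrame) -> pd.DataFrame:
    """Feature-level values per array: mean of surviving duplicate spots.

    Expects the output of :func:`lowess_normalize`.  Returns a feature x
    array frame; a feature whose spots were all flagged on an array is
    NaN there (missingness is data, not an error).
    """
    if "m" not in normalized.columns:
        raise ValueError("run lowess_normalize first (column 'm' missing)")
    ok = normalized[~normalized["flag"].astype(bool)]
    table = ok.pivot_table(
        index="feature_id", columns="array_id", values="m", aggfunc="mean"
    )
    # re-introduce features that were flagged away everywhere
    all_features = pd.Index(normalized["feature_id"].unique(), name="feature_id")
    return table.reindex(all_features)


def average_replicates(
    per_array: pd.DataFrame, array_groups: dict[str, str] | None = None
) -> pd.DataFrame:
    """Average replicate arrays per feature.

    ``array_groups`` maps array id to a group label (e.g. the timepoint
    it measures); arrays sharing a label are averaged, NaN-aware, so a
    feature missing on one replicate keeps its other replicate's value.
    Without a grouping, all arrays are treated as replicates of one
    condition.
    """
    if array_groups is None:
        return per_array.mean(axis=1, skipna=True).to_frame("value")
    labels = pd.Series({a: array_groups[a] for a in per_array.columns})
    return per_array.T.groupby(labels).mean().T


def filter_and_average(
    spots: pd.DataFrame, array_groups: dict[str, str] | None = None
) -> pd.DataFrame:
    """Normalized spot table -> feature x condition matrix (convenience)."""
    return average_replicates(average_spots(spots), array_groups)


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_spot_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _check_spot_table(df)
    df["flag"] = df["flag"].astype(bool)
    df["dye_swapped"] = df["dye_swapped"].astype(bool)
    return df


def write_spot_table(spots: pd.DataFrame, path: str | Path) -> None:
    _check_spot_table(spots)
    spots.to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Gene x timepoint log2-ratio matrix from TSV (first column: gene)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene"
    return df


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")
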