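"""Deconvolution of asynchronous meiotic expression time courses.

A sporulating culture is asynchronous: cells enter the meiotic program
at staggered times, so the expression measured at hour ``t`` mixes cells
occupying different meiotic stages.  The observed profile of gene ``g``
is modelled as a linear mixture

    x_g(t) = sum_s C(t, s) * e_g(s) + noise

where ``C`` is the timepoint x stage composition of the culture and
``e_g`` the synchronous (per-stage) expression profile.  ``C`` is
estimated from DAPI nuclear staging counts (mononucleate /binucleate /
tetranucleate cells per timepoint), either directly as the three
category fractions or by fitting a progression model: cells start the
program at a Normal(mean, sd) time offset and then traverse stages of
fixed duration, which lets the three coarse categories be expanded into
any configured number of sub-stages.  The inversion solves a ridge
least-squares problem per gene, sharing one factorization of
``C'C + lambda*I`` across genes.

Profiles are log2 ratios and may be negative, so no non-negativity
constraint is imposed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclasses.dataclass(frozen=True)
class StageModel:
    """Progression model: fixed-duration stages entered after a random start.

    A cell with start offset T0 is in stage 0 before T0 and in stage
    ``min(n_stages-1, floor((t-T0)/duration) + 1)`` afterwards; the last
    stage is absorbing.  ``dapi_boundaries = (b1, b2)`` maps stages to
    DAPI categories: mononucleate = stages < b1 (pre-MI), binucleate =
    b1 <= stage < b2 (post-MI), tetranucleate = stages >= b2 (post-MII).
    """

    n_stages: int = 8
    stage_duration: float = 1.25  # hours
    dapi_boundaries: tuple[int, int] = (4, 6)

    def __post_init__(self) -> None:
        if self.n_stages < 1:
            raise ValueError("need at least one stage")
        if self.stage_duration <= 0:
            raise ValueError("stage durations must be positive")
        b1, b2 = self.dapi_boundaries
        if not (0 < b1 < b2 <= self.n_stages):
            raise ValueError("dapi boundaries must satisfy 0 < b1 < b2 <= n_stages")


def _cdf_start(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """P(T0 <= x); degenerates to a step function when sd == 0."""
    if sd == 0:
        return (np.asarray(x, dtype=float) >= mean).astype(float)
    return stats.norm.cdf(x, loc=mean, scale=sd)


def composition_matrix(
    times, start_mean: float, start_sd: float, model: StageModel
) -> np.ndarray:
    """Exact timepoint x stage occupancy probabilities under the model.

    Stage s >= 1 is entered at T0 + (s-1)*duration, so occupancies are
    differences of the start-time CDF at shifted arguments; rows
    telescope to 1 exactly.
    """
    t = np.asarray(times, dtype=float)
    S, d = model.n_stages, model.stage_duration
    if S == 1:
        return np.ones((t.size, 1))
    # P(stage >= s) for s = 1..S-1
    entered = np.stack(
        [_cdf_start(t - (s - 1) * d, start_mean, start_sd) for s in range(1, S)],
        axis=1,
    )
    C = np.empty((t.size, S))
    C[:, 0] = 1.0 - entered[:, 0]
    C[:, 1 : S - 1] = entered[:, :-1] - entered[:, 1:]
    C[:, S - 1] = entered[:, -1]
    return C


def dapi_fractions(
    times, start_mean: float, start_sd: float, model: StageModel
) -> np.ndarray:
    """Expected mono/bi/tetra fractions per timepoint (columns sum to 1)."""
    t = np.asarray(times, dtype=float)
    b1, b2 = model.dapi_boundaries
    d = model.stage_duration
    p_bi_plus = _cdf_start(t - (b1 - 1) * d, start_mean, start_sd)
    p_tetra = _cdf_start(t - (b2 - 1) * d, start_mean, start_sd)
    return np.stack([1.0 - p_bi_plus, p_bi_plus - p_tetra, p_tetra], axis=1)


@dataclasses.dataclass
class StageComposition:
    """Timepoint x stage mixing proportions plus any fitted parameters."""

    matrix: pd.DataFrame          # rows: timepoints, columns: stages; rows sum to 1
    start_mean: float | None = None
    start_sd: float | None = None
    residual: float | None = None

    @property
    def values(self) -> np.ndarray:
        return self.matrix.to_numpy(dtype=float)


def composition_from_counts(
    dapi: pd.DataFrame,
    model: StageModel | None = None,
    mode: str = "direct",
) -> StageComposition:
    """DAPI category counts -> stage composition.

    ``dapi`` needs columns ``hour``, ``mono``, ``bi``, ``tetra``.

    direct mode
        Three stages; each row is simply counts/total.
    model mode
        Fits the Normal start-offset parameters (mean, sd) of ``model``
        to the category fractions by least squares and expands to the
        model's configured sub-stages through the progression CDF.
    """
    for col in ("hour", "mono", "bi", "tetra"):
        if col not in dapi.columns:
            raise ValueError(f"DAPI table lacks column {col!r}")
    counts = dapi[["mono", "bi", "tetra"]].to_numpy(dtype=float)
    if np.any(counts < 0):
        raise ValueError("DAPI counts must be non-negative")
    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        bad = dapi["hour"].to_numpy()[totals == 0]
        raise ValueError(f"all-zero DAPI counts at hours {bad.tolist()}")
    hours = dapi["hour"].to_numpy(dtype=float)
    fractions = counts / totals[:, None]

    if mode == "direct":
        matrix = pd.DataFrame(
            fractions, index=hours, columns=["mono", "bi", "tetra"]
        )
        matrix.index.name = "hour"
        return StageComposition(matrix=matrix)
    if mode != "model":
        raise ValueError("mode must be 'direct' or 'model'")

    model = model or StageModel()

    def resid(theta):
        mean, log_sd = theta
        pred = dapi_fractions(hours, mean, np.exp(log_sd), model)
        return (pred - fractions).ravel()

    # initial guess: start mean near where half the culture is past MI
    past_mi = fractions[:, 1] + fractions[:, 2]
    if np.any(past_mi >= 0.5):
        t_half = hours[np.argmax(past_mi >= 0.5)]
    else:
        t_half = hours[-1]
    b1 = model.dapi_boundaries[0]
    theta0 = np.array([t_half - (b1 - 1) * model.stage_duration, np.log(1.5)])
    sol = optimize.least_squares(resid, theta0, method="lm", max_nfev=2000)
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    if not sol.success or rms > 0.25:
        raise RuntimeError(
            f"progression-model fit failed to converge (status {sol.status}, "
            f"rms residual {rms:.3f}); per-timepoint residuals: "
            f"{np.round(sol.fun.reshape(-1, 3), 3).tolist()}"
        )
    mean, sd = float(sol.x[0]), float(np.exp(sol.x[1]))
    C = composition_matrix(hours, mean, sd, model)
    matrix = pd.DataFrame(
        C, index=hours, columns=[f"stage{s}" for s in range(model.n_stages)]
    )
    matrix.index.name = "hour"
    return StageComposition(matrix=matrix, start_mean=mean, start_sd=sd, residual=rms)


def _solve_block(C: np.ndarray, X: np.ndarray, ridge: float) -> np.ndarray:
    """argmin_e ||x - C e||^2 + ridge ||e||^2 for every column of X."""
    S = C.shape[1]
    gram = C.T @ C + ridge * np.eye(S)
    if ridge == 0:
        if C.shape[0] < S or np.linalg.matrix_rank(gram) < S:
            raise np.linalg.LinAlgError("rank deficient")
    return np.linalg.solve(gram, C.T @ X)


def deconvolve(
    expr: pd.DataFrame,
    composition: StageComposition | pd.DataFrame | np.ndarray,
    ridge: float = 1e-3,
) -> pd.DataFrame:
    """Invert the mixing model: gene x timepoint -> gene x stage profiles.

    One factorization of ``C'C + ridge*I`` is shared by all genes;
    genes with missing timepoints drop those rows from their own system
    (re-solved per missing pattern).  With ``ridge=0`` a rank-deficient
    system (e.g. more stages than informative timepoints) raises with
    instructions to use ``ridge > 0``.
    """
    if isinstance(composition, StageComposition):
        C = composition.values
        stage_names = list(composition.matrix.columns)
    else:
        C = np.asarray(composition, dtype=float)
        stage_names = [f"stage{s}" for s in range(C.shape[1])]
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    X = expr.to_numpy(dtype=float)
    if X.shape[1] != C.shape[0]:
        raise ValueError(
            f"expression has {X.shape[1]} timepoints but composition has "
            f"{C.shape[0]} rows"
        )
    S = C.shape[1]
    E = np.full((X.shape[0], S), np.nan)
    finite = np.isfinite(X)

    def solve_rows(rows: np.ndarray, cols: np.ndarray) -> None:
        try:
            E[rows] = _solve_block(C[cols], X[np.ix_(rows, cols)].T, ridge).T
        except np.linalg.LinAlgError:
            raise ValueError(
                f"C'C is rank deficient with ridge=0 ({int(cols.sum())} usable "
                f"timepoints for {S} stages); set ridge > 0"
            ) from None

    complete = finite.all(axis=1)
    if complete.any():
        solve_rows(np.flatnonzero(complete), np.ones(X.shape[1], dtype=bool))
    if not complete.all():
        patterns: dict[bytes, list[int]] = {}
        for i in np.flatnonzero(~complete):
            patterns.setdefault(finite[i].tobytes(), []).append(i)
        for key, rows in patterns.items():
            cols = np.frombuffer(key, dtype=bool)
            solve_rows(np.asarray(rows), cols)
    return pd.DataFrame(E, index=expr.index, columns=stage_names)


def mix(profiles: pd.DataFrame, composition, timepoint_labels=None) -> pd.DataFrame:
    """Forward model: stage profiles x composition -> observed matrix."""
    C = (
        composition.values
        if isinstance(composition, StageComposition)
        else np.asarray(composition, dtype=float)
    )
    X = profiles.to_numpy(dtype=float) @ C.T
    cols = timepoint_labels if timepoint_labels is not None else range(C.shape[0])
    return pd.DataFrame(X, index=profiles.index, columns=cols)


def read_dapi(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df


def write_dapi(dapi: pd.DataFrame, path) -> None:
    dapi.to_csv(path, sep="\t", index=False)
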