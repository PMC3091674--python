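"""Synthetic middle/late-meiosis studies with known ground truth.

Generates everything the analysis consumes — expression time courses in
three genetic backgrounds (wild type, *sum1*-deleted, estradiol-induced
*NDT80* "ER"), DAPI staging counts, ChIP binding ratios for an activator
and a repressor, and promoter sequences with planted binding sites —
from one seed, together with the ground truth needed to score every
downstream stage.

Gene classes and their temporal archetypes (log2 vs a vegetative
reference, piecewise linear over stages):

``activator_only``, ``common``
    transient middle pulse: rise, plateau at the gene's amplitude,
    fall back to baseline by the last stages (re-repression).
``middle_repressed``
    mirror image: a middle-stage dip.
``late_independent``
    rises only in the final stages (activator/repressor independent).
``repressor_only``, ``background``
    flat; repressor-only promoters are distinguished by ChIP signal and
    a planted repressor site, not by a middle-meiosis expression
    pattern.

Genetic backgrounds transform the activator-bound classes
(``activator_only`` + ``common``):

sum1del
    no late repression: post-peak stage values are clamped at the pulse
    level (running maximum), and all target amplitudes are damped by
    ``sum1del_amplitude_factor`` (overall expression of targets is low
    in this background).
ER
    the indirect repression path (Sum1 repressing *NDT80*) is severed;
    a gene with planted indirect weight ``W`` retains only the direct
    fraction of its repression, so its post-peak values become
    ``W * v_middle + (1 - W) * v_wt`` and its stage-level repression
    fold is exactly ``R_wt ** (1 - W)``.  By default activator-only
    targets carry W = 1 (no direct repressor binding: repression is
    entirely indirect) and common targets W = 0 (direct repression
    intact), the mechanistic reading of the feed-forward loop; both are
    configurable intervals.

Cells enter the program at Normal(start_time_mean, start_time_sd) hours
and then traverse fixed-duration stages; observed expression mixes the
stage profiles with the resulting composition.  All randomness flows
from ``seed`` through named per-purpose generators, so each data type
can be regenerated independently and reproducibly.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import motifs
from .arrays import SPOT_COLUMNS
from .deconvolution import StageComposition, StageModel, composition_matrix

GENE_CLASSES = (
    "activator_only",
    "common",
    "repressor_only",
    "late_independent",
    "middle_repressed",
    "background",
)
ACTIVATOR_BOUND = ("activator_only", "common")
STRAINS = ("wt", "sum1d", "er")

_STREAMS = {
    "expression": 1,
    "observation": 2,
    "chip": 3,
    "sequence": 4,
    "composition": 5,
    "spots": 6,
}


def _default_group_sizes() -> dict[str, int]:
    return {
        "activator_only": 80,
        "common": 40,
        "repressor_only": 120,
        "late_independent": 80,
        "middle_repressed": 50,
        "background": 1630,
    }


def _default_timepoints() -> dict[str, list[float]]:
    # WT sampled through late meiosis; the deletion strain later (its
    # cultures are staged the same way); the ER strain on the same
    # absolute schedule as the WT middle/late reference hours so the two
    # backgrounds are compared at identical culture stages.
    return {
        "wt": [2.5, 5, 7.5, 10, 11, 12, 13, 14, 15, 16, 17, 18],
        "sum1d": [10, 17, 21],
        "er": [8, 14, 18],
    }


def _default_middle_late() -> dict[str, tuple[float, float]]:
    return {"wt": (14, 18), "sum1d": (17, 21), "er": (14, 18)}


@dataclasses.dataclass
class SimulationConfig:
    """All knobs of the synthetic study; defaults define the reference study."""

    n_genes: int = 2000
    n_stages: int = 8
    group_sizes: dict[str, int] = dataclasses.field(default_factory=_default_group_sizes)
    timepoints_hours: dict[str, list[float]] = dataclasses.field(
        default_factory=_default_timepoints
    )
    middle_late: dict[str, tuple[float, float]] = dataclasses.field(
        default_factory=_default_middle_late
    )
    pulse_amplitude: float = 5.0          # log2 units at the pulse peak
    amplitude_jitter: tuple[float, float] = (0.8, 1.2)  # per-gene multiplier range
    sum1del_amplitude_factor: float = 0.6
    noise_sd: float = 0.2                 # log2 units, stage and observation level
    chip_signal_shift: float = 4.0        # enrichment of bound promoters (Z scale)
    chip_noise_sd: float = 0.8            # per-replicate ChIP ratio noise
    chip_null_family: str = "normal"      # normal | laplace | logistic (symmetric)
    dapi_cells_per_timepoint: int = 200
    start_time_mean: float = 9.0          # hours
    start_time_sd: float = 1.0            # hours
    stage_duration_hours: float = 1.25
    dapi_boundaries: tuple[int, int] = (4, 6)
    promoter_length: int = 500
    planted_site_rate: dict[str, float] = dataclasses.field(
        default_factory=lambda: {
            "activator_only": 0.8,
            "common": 0.8,
            "repressor_only": 0.8,
        }
    )
    w_true_range: dict[str, tuple[float, float]] = dataclasses.field(
        default_factory=lambda: {"activator_only": (1.0, 1.0), "common": (0.0, 0.0)}
    )
    promoter_background: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"A": 0.34, "C": 0.16, "G": 0.16, "T": 0.34}
    )
    dye_bias: tuple[float, float] = (0.3, 0.2)  # linear, quadratic coefficient
    spot_noise_factor: float = 2.0        # spot sd = factor * noise_sd
    spot_flag_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("invalid config: need at least one gene")
        if self.n_stages < 1:
            raise ValueError("invalid config: need at least one stage")
        unknown = set(self.group_sizes) - set(GENE_CLASSES)
        if unknown:
            raise ValueError(f"invalid config: unknown gene classes {sorted(unknown)}")
        if sum(self.group_sizes.values()) != self.n_genes:
            raise ValueError(
                f"invalid config: group sizes sum to {sum(self.group_sizes.values())}, "
                f"expected n_genes={self.n_genes}"
            )
        for name in ("noise_sd", "chip_noise_sd", "start_time_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"invalid config: {name} must be >= 0")
        for strain, tps in self.timepoints_hours.items():
            if np.any(np.diff(tps) <= 0):
                raise ValueError(
                    f"invalid config: timepoints for {strain!r} must be strictly increasing"
                )
        if self.stage_duration_hours <= 0:
            raise ValueError("invalid config: stage durations must be positive")
        if not np.isfinite([self.start_time_mean, self.start_time_sd]).all():
            raise ValueError("invalid config: start-time parameters must be finite")

    @property
    def stage_model(self) -> StageModel:
        return StageModel(
            n_stages=self.n_stages,
            stage_duration=self.stage_duration_hours,
            dapi_boundaries=self.dapi_boundaries,
        )

    def rng(self, stream: str, extra: int = 0) -> np.random.Generator:
        """Named per-purpose generator derived from the single seed."""
        return np.random.default_rng([self.seed, _STREAMS[stream], extra])


@dataclasses.dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    classes: pd.Series                    # gene -> class label
    amplitudes: pd.Series                 # gene -> pulse amplitude (log2 units)
    archetypes: pd.DataFrame              # noiseless WT stage profiles
    stage_profiles: pd.DataFrame          # emitted (noisy) WT stage profiles
    w_true: pd.Series                     # gene -> planted indirect weight (NaN elsewhere)
    middle_stage: int
    late_stage: int
    peak_last_stage: int
    compositions: dict[str, StageComposition]
    site_positions: pd.DataFrame | None = None

    @property
    def r_wt_true(self) -> pd.Series:
        """Stage-level WT repression folds from the noiseless archetypes."""
        mid = self.archetypes.iloc[:, self.middle_stage]
        late = self.archetypes.iloc[:, self.late_stage]
        return np.power(2.0, mid - late)

    def targets_of(self, factor: str) -> list:
        groups = (
            ACTIVATOR_BOUND if factor == "activator" else ("repressor_only", "common")
        )
        return list(self.classes.index[self.classes.isin(groups)])


# ---------------------------------------------------------------------------
# stage archetypes
# ---------------------------------------------------------------------------

def _pulse_shape(n_stages: int) -> np.ndarray:
    """Rise / plateau / fall, unit peak; anchors are stage fractions."""
    frac = np.arange(n_stages) / max(n_stages - 1, 1)
    return np.interp(frac, [0.0, 0.2, 0.42, 0.72, 0.86, 1.0], [0, 0, 1, 1, 0.4, 0])


def _ramp_shape(n_stages: int) -> np.ndarray:
    frac = np.arange(n_stages) / max(n_stages - 1, 1)
    return np.interp(frac, [0.0, 0.7, 1.0], [0, 0, 1])


def class_archetypes(n_stages: int) -> dict[str, np.ndarray]:
    pulse = _pulse_shape(n_stages)
    return {
        "activator_only": pulse,
        "common": pulse,
        "repressor_only": np.zeros(n_stages),
        "late_independent": _ramp_shape(n_stages),
        "middle_repressed": -pulse,
        "background": np.zeros(n_stages),
    }


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def simulate_stage_profiles(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-gene synchronous (stage-wise) WT profiles plus ground truth.

    Profiles are archetype * per-gene amplitude plus Normal(0, noise_sd)
    stage noise.  Deterministic for a given config (same seed twice
    gives bit-identical matrices).
    """
    config.validate()
    rng = config.rng("expression")
    S = config.n_stages
    shapes = class_archetypes(S)
    genes, classes = [], []
    ids = _gene_ids(config.n_genes)
    pos = 0
    for cls in GENE_CLASSES:
        size = config.group_sizes.get(cls, 0)
        genes.extend(ids[pos : pos + size])
        classes.extend([cls] * size)
        pos += size
    classes = pd.Series(classes, index=genes, name="class")

    lo, hi = config.amplitude_jitter
    amplitudes = pd.Series(
        config.pulse_amplitude * rng.uniform(lo, hi, size=config.n_genes),
        index=genes,
        name="amplitude",
    )
    arche = np.stack([shapes[c] for c in classes]) * amplitudes.to_numpy()[:, None]
    noise = rng.normal(0.0, config.noise_sd, size=arche.shape) if config.noise_sd else 0.0
    stage_cols = [f"stage{s}" for s in range(S)]
    archetypes = pd.DataFrame(arche, index=genes, columns=stage_cols)
    profiles = pd.DataFrame(arche + noise, index=genes, columns=stage_cols)

    w_true = pd.Series(np.nan, index=genes, name="w_true")
    for cls, (wlo, whi) in config.w_true_range.items():
        members = classes.index[classes == cls]
        w_true[members] = rng.uniform(wlo, whi, size=len(members))

    pulse = shapes["activator_only"]
    peak_last = int(np.flatnonzero(pulse == pulse.max())[-1]) if pulse.max() > 0 else 0
    middle_stage = min(peak_last, int(round(0.5 * (S - 1))))
    truth = GroundTruth(
        classes=classes,
        amplitudes=amplitudes,
        archetypes=archetypes,
        stage_profiles=profiles,
        w_true=w_true,
        middle_stage=middle_stage,
        late_stage=S - 1,
        peak_last_stage=peak_last,
        compositions={},
    )
    return profiles, truth


# ---------------------------------------------------------------------------
# culture composition and DAPI staging
# ---------------------------------------------------------------------------

def simulate_composition(
    config: SimulationConfig, strain: str = "wt"
) -> tuple[StageComposition, pd.DataFrame]:
    """True stage composition at the strain's timepoints plus DAPI counts.

    The composition is the exact occupancy probability of the
    progression model (rows sum to 1); DAPI counts are a multinomial
    draw of ``dapi_cells_per_timepoint`` cells per timepoint, coarsened
    to mononucleate / binucleate / tetranucleate via the stage-category
    boundaries.
    """
    times = np.asarray(config.timepoints_hours[strain], dtype=float)
    model = config.stage_model
    C = composition_matrix(times, config.start_time_mean, config.start_time_sd, model)
    matrix = pd.DataFrame(
        C, index=times, columns=[f"stage{s}" for s in range(model.n_stages)]
    )
    matrix.index.name = "hour"
    comp = StageComposition(
        matrix=matrix, start_mean=config.start_time_mean, start_sd=config.start_time_sd
    )
    rng = config.rng("composition", _STREAMS_STRAIN[strain])
    b1, b2 = model.dapi_boundaries
    counts = np.stack(
        [rng.multinomial(config.dapi_cells_per_timepoint, row) for row in C]
    )
    dapi = pd.DataFrame(
        {
            "hour": times,
            "mono": counts[:, :b1].sum(axis=1),
            "bi": counts[:, b1:b2].sum(axis=1),
            "tetra": counts[:, b2:].sum(axis=1),
        }
    )
    return comp, dapi


_STREAMS_STRAIN = {"wt": 0, "sum1d": 1, "er": 2}


# ---------------------------------------------------------------------------
# strain transformations and observed expression
# ---------------------------------------------------------------------------

def strain_stage_profiles(
    stage_profiles: pd.DataFrame,
    strain: str,
    config: SimulationConfig,
    truth: GroundTruth,
) -> pd.DataFrame:
    """Apply the genetic-background transformation to WT stage profiles."""
    if strain == "wt":
        return stage_profiles.copy()
    X = stage_profiles.copy()
    targets = truth.classes.index[truth.classes.isin(ACTIVATOR_BOUND)]
    targets = [g for g in targets if g in X.index]
    if strain == "sum1d":
        vals = X.loc[targets].to_numpy()
        X.loc[targets] = np.maximum.accumulate(vals, axis=1) * config.sum1del_amplitude_factor
        return X
    if strain == "er":
        w = truth.w_true.reindex(targets).fillna(0.0).to_numpy()[:, None]
        vals = X.loc[targets].to_numpy()
        v_mid = vals[:, truth.middle_stage][:, None]
        post = slice(truth.peak_last_stage + 1, None)
        vals[:, post] = w * v_mid + (1.0 - w) * vals[:, post]
        X.loc[targets] = vals
        return X
    raise ValueError(f"unknown strain {strain!r}")


def mix_observed_expression(
    stage_profiles: pd.DataFrame,
    composition: StageComposition | np.ndarray,
    strain: str,
    config: SimulationConfig,
    truth: GroundTruth | None = None,
) -> pd.DataFrame:
    """Observed gene x timepoint matrix for a strain.

    Applies the strain transformation (which needs ``truth`` except for
    the wild type), mixes stage profiles with the composition, and adds
    Normal(0, noise_sd) observation noise.
    """
    if strain != "wt" and truth is None:
        raise ValueError(f"strain {strain!r} requires the ground truth")
    profiles = (
        stage_profiles if strain == "wt" else strain_stage_profiles(
            stage_profiles, strain, config, truth
        )
    )
    C = (
        composition.values
        if isinstance(composition, StageComposition)
        else np.asarray(composition, dtype=float)
    )
    if C.shape[1] != profiles.shape[1]:
        raise ValueError(
            f"composition has {C.shape[1]} stages but profiles have {profiles.shape[1]}"
        )
    base = profiles.to_numpy() @ C.T
    rng = config.rng("observation", _STREAMS_STRAIN[strain])
    if config.noise_sd:
        base = base + rng.normal(0.0, config.noise_sd, size=base.shape)
    if isinstance(composition, StageComposition):
        labels = [_fmt_hour(h) for h in composition.matrix.index]
    else:
        labels = [str(i) for i in range(C.shape[0])]
    return pd.DataFrame(base, index=stage_profiles.index, columns=labels)


def _fmt_hour(h: float) -> str:
    return f"{float(h):g}"


# ---------------------------------------------------------------------------
# ChIP ratios
# ---------------------------------------------------------------------------

def _symmetric_noise(
    rng: np.random.Generator, family: str, scale: float, size
) -> np.ndarray:
    if scale == 0:
        return np.zeros(size)
    if family == "normal":
        return rng.normal(0.0, scale, size)
    if family == "laplace":
        return rng.laplace(0.0, scale / np.sqrt(2.0), size)
    if family == "logistic":
        return rng.logistic(0.0, scale * np.sqrt(3.0) / np.pi, size)
    raise ValueError(f"unknown null family {family!r}")


def simulate_chip(config: SimulationConfig, truth: GroundTruth) -> pd.DataFrame:
    """Duplicate ChIP binding ratios per promoter for both factors.

    Non-target promoters draw from a symmetric-about-zero null; bound
    promoters are shifted by ``chip_signal_shift``.  Columns:
    ``{factor}_rep{1,2}`` for factors ``activator`` and ``repressor``.
    """
    rng = config.rng("chip")
    promoters = list(truth.classes.index)
    out = pd.DataFrame(index=pd.Index(promoters, name="promoter"))
    for factor in ("activator", "repressor"):
        bound = truth.classes.isin(
            ACTIVATOR_BOUND if factor == "activator" else ("repressor_only", "common")
        ).to_numpy()
        shift = np.where(bound, config.chip_signal_shift, 0.0)
        for rep in (1, 2):
            noise = _symmetric_noise(
                rng, config.chip_null_family, config.chip_noise_sd, len(promoters)
            )
            out[f"{factor}_rep{rep}"] = shift + noise
    return out


def average_chip_replicates(chip: pd.DataFrame) -> pd.DataFrame:
    """Mean the duplicate arrays per factor (``<factor>_rep*`` columns)."""
    factors = sorted({c.rsplit("_rep", 1)[0] for c in chip.columns})
    return pd.DataFrame(
        {f: chip[[c for c in chip.columns if c.startswith(f + "_rep")]].mean(axis=1)
         for f in factors},
        index=chip.index,
    )


# ---------------------------------------------------------------------------
# promoters with planted sites
# ---------------------------------------------------------------------------

#: Synthetic stand-in frequency matrices (rows A, C, G, T).  The
#: activator motif mimics the middle sporulation element (MSE,
#: gNCACAAAA/T core) and the repressor motif its overlapping variant
#: (MSE*); the study's own matrices came from a de novo discovery tool
#: and are not printed, so these are synthetic constructions with the
#: uneven per-column information content of real motifs (a few
#: near-invariant core positions flanked by degenerate ones).
_ACTIVATOR_PFM = [
    # G    N    C    A    C    A    A    A    A/T
    [0.20, 0.30, 0.10, 0.85, 0.08, 0.95, 0.95, 0.90, 0.50],
    [0.15, 0.20, 0.70, 0.05, 0.80, 0.02, 0.01, 0.03, 0.07],
    [0.55, 0.20, 0.05, 0.06, 0.04, 0.02, 0.02, 0.02, 0.08],
    [0.10, 0.30, 0.15, 0.04, 0.08, 0.01, 0.02, 0.05, 0.35],
]
_REPRESSOR_PFM = [
    # T    G    C    A    C    A    A    A    T    W
    [0.15, 0.10, 0.08, 0.90, 0.06, 0.92, 0.90, 0.85, 0.20, 0.35],
    [0.10, 0.10, 0.75, 0.04, 0.85, 0.03, 0.05, 0.06, 0.10, 0.15],
    [0.15, 0.65, 0.07, 0.03, 0.04, 0.03, 0.02, 0.04, 0.15, 0.15],
    [0.60, 0.15, 0.10, 0.03, 0.05, 0.02, 0.03, 0.05, 0.55, 0.35],
]


def default_pfms() -> tuple[motifs.FrequencyMatrix, motifs.FrequencyMatrix]:
    """Synthetic stand-in frequency matrices for the two binding sites."""
    return (
        motifs.FrequencyMatrix(np.array(_ACTIVATOR_PFM)),
        motifs.FrequencyMatrix(np.array(_REPRESSOR_PFM)),
    )


def _sample_site(rng: np.random.Generator, pfm: motifs.FrequencyMatrix) -> str:
    cols = pfm.matrix.T
    return "".join(
        motifs.NUCLEOTIDES[rng.choice(4, p=col / col.sum())] for col in cols
    )


def plant_promoters(
    config: SimulationConfig,
    truth: GroundTruth,
    pfm_activator: motifs.FrequencyMatrix | None = None,
    pfm_repressor: motifs.FrequencyMatrix | None = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random-background promoters with class-dependent planted sites.

    Activator-only promoters receive (with probability
    ``planted_site_rate``) a site sampled from the activator matrix,
    repressor-only promoters one from the repressor matrix, and common
    promoters one of each (in disjoint halves of the promoter).  Site
    positions and strands are recorded and attached to the truth.
    """
    if pfm_activator is None or pfm_repressor is None:
        default_a, default_r = default_pfms()
        pfm_activator = pfm_activator or default_a
        pfm_repressor = pfm_repressor or default_r
    rng = config.rng("sequence")
    bg = config.promoter_background
    p = np.array([bg[c] for c in motifs.NUCLEOTIDES], dtype=float)
    p = p / p.sum()
    L = config.promoter_length
    promoters: dict[str, str] = {}
    records = []
    for gene, cls in truth.classes.items():
        seq = list(rng.choice(list(motifs.NUCLEOTIDES), size=L, p=p))
        rate = config.planted_site_rate.get(cls, 0.0)
        wanted = []
        if cls in ("activator_only", "common") and rng.random() < rate:
            wanted.append(("activator", pfm_activator))
        if cls in ("repressor_only", "common") and rng.random() < rate:
            wanted.append(("repressor", pfm_repressor))
        halves = rng.permutation(len(wanted)) if len(wanted) > 1 else [0]
        for (factor, pfm), half in zip(wanted, halves):
            site = _sample_site(rng, pfm)
            lo = half * (L // 2)
            hi = (half + 1) * (L // 2) - len(site) if len(wanted) > 1 else L - len(site)
            start = int(rng.integers(lo, max(lo + 1, hi)))
            strand = "+" if rng.random() < 0.5 else "-"
            placed = site if strand == "+" else motifs.reverse_complement(site)
            seq[start : start + len(site)] = list(placed)
            records.append((gene, factor, start, strand, site))
        promoters[gene] = "".join(seq)
    sites = pd.DataFrame(
        records, columns=["promoter", "factor", "start", "strand", "site"]
    )
    truth.site_positions = sites
    return promoters, sites


# ---------------------------------------------------------------------------
# spot-table mode (two-channel arrays consumed by the arrays module)
# ---------------------------------------------------------------------------

def make_spot_tables(
    base_expression: pd.DataFrame, strain: str, config: SimulationConfig
) -> pd.DataFrame:
    """Two-channel duplicate-spotted arrays encoding an expression matrix.

    For every timepoint two replicate arrays are produced (the second
    dye-swapped) with two spots per gene.  Each spot's physical log
    ratio is the gene's value plus a smooth intensity-dependent dye bias
    (removed downstream by lowess) plus spot noise of
    ``spot_noise_factor * noise_sd`` (so the mean of the four spots has
    roughly ``noise_sd`` noise); a small fraction of spots is flagged as
    poor quality.
    """
    rng = config.rng("spots", _STREAMS_STRAIN[strain])
    c1, c2 = config.dye_bias
    rows = []
    genes = list(base_expression.index)
    n = len(genes)
    spot_sd = config.spot_noise_factor * config.noise_sd
    for label in base_expression.columns:
        m_true = base_expression[label].to_numpy(dtype=float)
        for rep, swapped in ((1, False), (2, True)):
            array_id = f"{strain}_t{label}_r{rep}"
            for spot in (1, 2):
                a = rng.uniform(7.0, 13.0, size=n)
                u = (a - 10.0) / 3.0
                bias = c1 * u + c2 * u * u
                m_phys = m_true + rng.normal(0.0, spot_sd, size=n)
                if swapped:
                    m_phys = -m_phys
                m_phys = m_phys + bias
                fs = np.power(2.0, a + m_phys / 2.0)
                fr = np.power(2.0, a - m_phys / 2.0)
                flags = rng.random(n) < config.spot_flag_rate
                for i, gene in enumerate(genes):
                    rows.append(
                        (array_id, f"{array_id}_s{spot}_{gene}", gene,
                         fs[i], fr[i], flags[i], swapped)
                    )
    return pd.DataFrame(rows, columns=SPOT_COLUMNS)


def spot_array_groups(spots: pd.DataFrame) -> dict[str, str]:
    """Map array ids back to their timepoint label (``strain_tLABEL_rN``)."""
    groups = {}
    for array_id in spots["array_id"].unique():
        groups[array_id] = array_id.rsplit("_r", 1)[0].split("_t", 1)[1]
    return groups


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SyntheticStudy:
    config: SimulationConfig
    truth: GroundTruth
    dapi: dict[str, pd.DataFrame]
    expression: dict[str, pd.DataFrame]       # observed matrices per strain
    spots: dict[str, pd.DataFrame]            # spot tables per strain
    chip: pd.DataFrame
    promoters: dict[str, str]
    pfms: tuple[motifs.FrequencyMatrix, motifs.FrequencyMatrix]


def simulate_study(config: SimulationConfig, spot_tables: bool = True) -> SyntheticStudy:
    """Generate a complete synthetic study (all strains and data types)."""
    profiles, truth = simulate_stage_profiles(config)
    dapi: dict[str, pd.DataFrame] = {}
    expression: dict[str, pd.DataFrame] = {}
    spots: dict[str, pd.DataFrame] = {}
    for strain in STRAINS:
        comp, counts = simulate_composition(config, strain)
        truth.compositions[strain] = comp
        dapi[strain] = counts
        expression[strain] = mix_observed_expression(
            profiles, comp, strain, config, truth
        )
        if spot_tables:
            transformed = strain_stage_profiles(profiles, strain, config, truth)
            base = pd.DataFrame(
                transformed.to_numpy() @ comp.values.T,
                index=profiles.index,
                columns=[_fmt_hour(h) for h in comp.matrix.index],
            )
            spots[strain] = make_spot_tables(base, strain, config)
    chip = simulate_chip(config, truth)
    pfm_a, pfm_r = default_pfms()
    promoters, _ = plant_promoters(config, truth, pfm_a, pfm_r)
    return SyntheticStudy(
        config=config,
        truth=truth,
        dapi=dapi,
        expression=expression,
        spots=spots,
        chip=chip,
        promoters=promoters,
        pfms=(pfm_a, pfm_r),
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float, np.integer, np.floating)):
        return repr(float(v)) if isinstance(v, (float, np.floating)) else str(int(v))
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def config_to_toml(config: SimulationConfig) -> str:
    """Resolved config as TOML (dict-valued fields become sections)."""
    simple, sections = [], []
    for f in dataclasses.fields(config):
        v = getattr(config, f.name)
        if isinstance(v, dict):
            body = "\n".join(
                f'"{k}" = {_toml_value(val)}' for k, val in v.items()
            )
            sections.append(f"[{f.name}]\n{body}")
        else:
            simple.append(f"{f.name} = {_toml_value(v)}")
    return "\n".join(simple) + "\n\n" + "\n\n".join(sections) + "\n"


def config_from_toml(text: str) -> SimulationConfig:
    import tomllib

    data = tomllib.loads(text)
    fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    kwargs = {}
    for key, value in data.items():
        if key not in fields:
            raise ValueError(f"unknown config key {key!r}")
        kwargs[key] = value
    for tup_field in ("amplitude_jitter", "dapi_boundaries", "dye_bias"):
        if tup_field in kwargs:
            kwargs[tup_field] = tuple(kwargs[tup_field])
    if "middle_late" in kwargs:
        kwargs["middle_late"] = {
            k: tuple(v) for k, v in kwargs["middle_late"].items()
        }
    if "w_true_range" in kwargs:
        kwargs["w_true_range"] = {
            k: tuple(v) for k, v in kwargs["w_true_range"].items()
        }
    return SimulationConfig(**kwargs)


def config_digest(config: SimulationConfig) -> str:
    return hashlib.sha256(config_to_toml(config).encode()).hexdigest()[:16]


def write_fasta(promoters: dict[str, str], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in promoters.items()]
    seqio_write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio.SeqIO import parse

    return {rec.id: str(rec.seq) for rec in parse(str(path), "fasta")}


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """Write every study artifact as plain text; returns name -> path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def save(name: str, writer) -> None:
        paths[name] = out / name
        writer(paths[name])

    for strain in STRAINS:
        expr = study.expression[strain]
        save(f"expression_{strain}.tsv", lambda p, e=expr: e.to_csv(p, sep="\t", index_label="gene"))
        counts = study.dapi[strain]
        save(f"dapi_{strain}.tsv", lambda p, d=counts: d.to_csv(p, sep="\t", index=False))
        comp = study.truth.compositions[strain].matrix
        save(f"composition_{strain}.tsv", lambda p, c=comp: c.to_csv(p, sep="\t"))
        if strain in study.spots:
            spots = study.spots[strain]
            save(f"spots_{strain}.tsv", lambda p, s=spots: s.to_csv(p, sep="\t", index=False))
    save("chip.tsv", lambda p: study.chip.to_csv(p, sep="\t"))
    save("promoters.fasta", lambda p: write_fasta(study.promoters, p))
    save("truth_genes.tsv", lambda p: pd.DataFrame(
        {
            "class": study.truth.classes,
            "amplitude": study.truth.amplitudes,
            "w_true": study.truth.w_true,
        }
    ).to_csv(p, sep="\t", index_label="gene"))
    save("truth_stage_profiles.tsv", lambda p: study.truth.stage_profiles.to_csv(
        p, sep="\t", index_label="gene"
    ))
    if study.truth.site_positions is not None:
        save("truth_sites.tsv", lambda p: study.truth.site_positions.to_csv(
            p, sep="\t", index=False
        ))
    save("pfm_activator.txt", lambda p: motifs.write_pfm(study.pfms[0], p))
    save("pfm_repressor.txt", lambda p: motifs.write_pfm(study.pfms[1], p))
    save("config.toml", lambda p: Path(p).write_text(config_to_toml(study.config)))
    return paths
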