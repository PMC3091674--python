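"""End-to-end orchestration of the middle/late-meiosis analysis.

Chains the stages in dependency order — simulate (or load), normalize,
deconvolve, call ChIP targets, scan promoters, cluster, quantify the
feed-forward loop — under a single config and seed, logging stage
timings to stderr and emitting a machine-readable run manifest.  Stage
outputs are pure functions of (inputs, config, seed): two runs with the
same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, arrays, binding, clustering, ffl, motifs
from .deconvolution import composition_from_counts, deconvolve
from .synthetic_data import (
    SimulationConfig,
    SyntheticStudy,
    average_chip_replicates,
    config_digest,
    config_to_toml,
    simulate_study,
    spot_array_groups,
    write_study,
    _fmt_hour,
    _toml_value,
)

log = logging.getLogger("midmei")


@dataclasses.dataclass
class AnalysisConfig:
    """Parameters of the analysis stages (simulation aside)."""

    fdr_alpha: float = 0.05
    motif_fraction: float = 0.05
    ridge: float = 1e-3
    composition_mode: str = "model"   # "model" (fit progression) or "direct" (3 stages)
    min_range: float = 3.0            # log2 range cutoff for clustering selection;
                                      # scaled to the generator's pulse amplitude
    k: int = 10
    restarts: int = 20
    repressed_cutoff: float = 1.3
    lowess_span: float = 0.3
    lowess_iterations: int = 3
    use_spot_tables: bool = True


@dataclasses.dataclass
class PipelineConfig:
    simulation: SimulationConfig = dataclasses.field(default_factory=SimulationConfig)
    analysis: AnalysisConfig = dataclasses.field(default_factory=AnalysisConfig)


def pipeline_config_to_toml(config: PipelineConfig) -> str:
    sim_toml = config_to_toml(config.simulation)
    # nest the simulation sections under [simulation.*]
    sim_lines = []
    in_section = False
    for line in sim_toml.splitlines():
        if line.startswith("["):
            sim_lines.append(f"[simulation.{line[1:-1]}]")
            in_section = True
        else:
            sim_lines.append(line)
    header = "[simulation]\n" if not sim_toml.startswith("[") else ""
    analysis_lines = [
        f"{f.name} = {_toml_value(getattr(config.analysis, f.name))}"
        for f in dataclasses.fields(config.analysis)
    ]
    return (
        "[analysis]\n" + "\n".join(analysis_lines) + "\n\n" + header
        + "\n".join(sim_lines) + "\n"
    )


def pipeline_config_from_toml(text: str) -> PipelineConfig:
    import tomllib

    from .synthetic_data import config_from_toml

    data = tomllib.loads(text)
    analysis = AnalysisConfig(**data.get("analysis", {}))
    sim_data = data.get("simulation", {})
    # re-serialize the simulation table through the flat loader
    sim = config_from_toml_dict(sim_data)
    return PipelineConfig(simulation=sim, analysis=analysis)


def config_from_toml_dict(data: dict) -> SimulationConfig:
    fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    kwargs = {k: v for k, v in data.items() if k in fields}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown simulation config keys {sorted(unknown)}")
    for tup_field in ("amplitude_jitter", "dapi_boundaries", "dye_bias"):
        if tup_field in kwargs:
            kwargs[tup_field] = tuple(kwargs[tup_field])
    for map_field in ("middle_late", "w_true_range"):
        if map_field in kwargs:
            kwargs[map_field] = {k: tuple(v) for k, v in kwargs[map_field].items()}
    return SimulationConfig(**kwargs)


@dataclasses.dataclass
class MotifStageResult:
    thresholds: dict[str, float]
    scores: dict[str, pd.DataFrame]       # per factor: max_score/best_start/strand/called
    fold_enrichment: pd.DataFrame         # group x factor folds


@dataclasses.dataclass
class PipelineResult:
    config: PipelineConfig
    study: SyntheticStudy
    expression: dict[str, pd.DataFrame]   # normalized gene x timepoint matrices
    chip_ratios: pd.DataFrame             # promoter x factor averaged ratios
    composition: object                   # StageComposition used for deconvolution
    stage_profiles: pd.DataFrame          # deconvolved WT profiles
    binding_table: pd.DataFrame
    fdr_results: dict
    groups: binding.TargetGroups
    group_overlap_p: float
    motif: MotifStageResult
    clusters: clustering.ClusterResult
    records: pd.DataFrame                 # per-gene repression records
    group_summary: pd.DataFrame
    manifest: dict


def _timed(name: str, manifest: dict):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is None:
                log.info("stage %s: done in %.2fs", name, dt)
                manifest.setdefault("stages", {}).setdefault(name, {})["seconds"] = round(dt, 3)
            else:
                log.error("stage %s: FAILED after %.2fs", name, dt)
            return False

    return _Timer()


def _sorted_time_columns(df: pd.DataFrame) -> pd.DataFrame:
    return df[sorted(df.columns, key=float)]


def run_study(
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
    seed: int | None = None,
) -> PipelineResult:
    """Run the full pipeline on a synthetic study.

    Any stage failure propagates with the failing stage named in the
    log.  With ``outdir`` set, every stage output is written as TSV and
    a JSON run manifest is saved.
    """
    config = config or PipelineConfig()
    if seed is not None:
        config = dataclasses.replace(
            config, simulation=dataclasses.replace(config.simulation, seed=seed)
        )
    sim = config.simulation
    ana = config.analysis
    manifest: dict = {
        "version": __version__,
        "seed": sim.seed,
        "config_digest": config_digest(sim),
    }

    with _timed("simulate", manifest):
        study = simulate_study(sim, spot_tables=ana.use_spot_tables)

    with _timed("normalize", manifest):
        expression: dict[str, pd.DataFrame] = {}
        for strain in study.expression:
            if ana.use_spot_tables:
                norm = arrays.lowess_normalize(
                    study.spots[strain],
                    span=ana.lowess_span,
                    iterations=ana.lowess_iterations,
                )
                mat = arrays.filter_and_average(norm, spot_array_groups(study.spots[strain]))
                expression[strain] = _sorted_time_columns(mat).reindex(
                    study.expression[strain].index
                )
            else:
                expression[strain] = study.expression[strain]
        chip_ratios = average_chip_replicates(study.chip)

    with _timed("deconvolve", manifest):
        comp = composition_from_counts(
            study.dapi["wt"], model=sim.stage_model, mode=ana.composition_mode
        )
        stage_profiles = deconvolve(expression["wt"], comp, ridge=ana.ridge)

    with _timed("call_targets", manifest):
        binding_table, fdr_results = binding.build_binding_table(
            chip_ratios, alpha=ana.fdr_alpha
        )
        called_a = set(binding_table.index[binding_table["activator_called"]])
        called_r = set(binding_table.index[binding_table["repressor_called"]])
        groups = binding.classify_groups(called_a, called_r)
        group_overlap_p = binding.overlap_pvalue(called_a, called_r, sim.n_genes)

    with _timed("scan", manifest):
        thresholds: dict[str, float] = {}
        scores: dict[str, pd.DataFrame] = {}
        group_sets = {
            "activator_only": groups.activator_only,
            "common": groups.common,
            "repressor_only": groups.repressor_only,
        }
        universe = list(study.promoters)
        fold_rows = {}
        for factor, pfm in zip(("activator", "repressor"), study.pfms):
            pssm = motifs.build_pssm(pfm)
            table = motifs.scan_promoters(study.promoters, pssm)
            thr = motifs.calibrate_threshold(table["max_score"], ana.motif_fraction)
            table["called"] = motifs.call_sites(table["max_score"], thr)
            thresholds[factor] = thr
            scores[factor] = table
            folds = {}
            for gname, gset in group_sets.items():
                folds[gname] = (
                    binding.motif_fold_enrichment(gset, universe, table["called"])
                    if gset
                    else np.nan
                )
            fold_rows[factor] = folds
        motif_result = MotifStageResult(
            thresholds=thresholds,
            scores=scores,
            fold_enrichment=pd.DataFrame(fold_rows),
        )

    with _timed("cluster", manifest):
        selected = clustering.select_variable_genes(stage_profiles, ana.min_range)
        clusters = clustering.kmeans_correlation(
            stage_profiles.loc[selected], k=ana.k, seed=sim.seed, restarts=ana.restarts
        )

    with _timed("ffl", manifest):
        folds = {}
        for strain in ("wt", "er", "sum1d"):
            mid, late = sim.middle_late[strain]
            folds[strain] = ffl.repression_fold(
                expression[strain], _fmt_hour(mid), _fmt_hour(late)
            )
        records = ffl.build_repression_records(
            folds, groups.as_series(), repressed_cutoff=ana.repressed_cutoff
        )
        grouped = records.dropna(subset=["group"])
        group_summary = ffl.summarize_groups(grouped)

    result = PipelineResult(
        config=config,
        study=study,
        expression=expression,
        chip_ratios=chip_ratios,
        composition=comp,
        stage_profiles=stage_profiles,
        binding_table=binding_table,
        fdr_results=fdr_results,
        groups=groups,
        group_overlap_p=group_overlap_p,
        motif=motif_result,
        clusters=clusters,
        records=records,
        group_summary=group_summary,
        manifest=manifest,
    )
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = result.manifest
    files = manifest.setdefault("outputs", {})

    def save(name: str, df: pd.DataFrame, **kwargs) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", **kwargs)
        files[name] = {"path": str(path), "rows": int(len(df))}

    write_study(result.study, outdir / "study")
    files["study"] = {"path": str(outdir / "study"), "rows": result.config.simulation.n_genes}
    for strain, mat in result.expression.items():
        save(f"normalized_{strain}.tsv", mat, index_label="gene")
    save("chip_ratios.tsv", result.chip_ratios, index_label="promoter")
    save("composition_fit.tsv", result.composition.matrix)
    save("stage_profiles_wt.tsv", result.stage_profiles, index_label="gene")
    save("binding_table.tsv", result.binding_table, index_label="promoter")
    save("target_groups.tsv", result.groups.as_series().to_frame(), index_label="promoter")
    for factor, table in result.motif.scores.items():
        save(f"motif_scores_{factor}.tsv", table)
    save("motif_fold_enrichment.tsv", result.motif.fold_enrichment, index_label="group")
    save("clusters.tsv", result.clusters.labels.to_frame(), index_label="gene")
    save("repression_records.tsv", result.records, index_label="gene")
    save("group_summary.tsv", result.group_summary)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# scoring helpers against the ground truth (used by tests and reports)
# ---------------------------------------------------------------------------

def classification_accuracy(result: PipelineResult) -> float:
    """Fraction of planted bound promoters assigned to their true group."""
    truth = result.study.truth.classes
    planted = truth[truth.isin(["activator_only", "common", "repressor_only"])]
    assigned = result.groups.as_series().reindex(planted.index)
    return float((assigned == planted).mean())


def ffl_pattern_holds(result: PipelineResult, alpha: float = 0.05) -> dict:
    """The qualitative feed-forward-loop contrast of the dissection.

    activator-only targets: repression significantly reduced in the ER
    background (paired p < alpha with R_er < R_wt); common targets: not
    significantly reduced; both groups de-repressed (mean R within
    [0.8, 1.25]) in the deletion strain.
    """
    summary = result.group_summary
    out = {"activator_reduced": False, "common_not_reduced": True, "sum1d_derepressed": False}
    if "activator_only" in summary.index:
        row = summary.loc["activator_only"]
        out["activator_reduced"] = bool(
            row["p_wt_vs_er"] < alpha and row["mean_R_wt"] > row["mean_R_er"]
        )
    if "common" in summary.index:
        row = summary.loc["common"]
        reduced = bool(row["p_wt_vs_er"] < alpha and row["mean_R_wt"] > row["mean_R_er"])
        out["common_not_reduced"] = not reduced
    both_ok = []
    for g in ("activator_only", "common"):
        if g in summary.index:
            both_ok.append(0.8 <= summary.loc[g, "mean_R_sumdel"] <= 1.25)
    out["sum1d_derepressed"] = bool(both_ok) and all(both_ok)
    out["holds"] = all(
        out[k] for k in ("activator_reduced", "common_not_reduced", "sum1d_derepressed")
    )
    return out
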