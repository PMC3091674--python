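"""The synthetic-study generator: archetypes, composition, mixing, ChIP, promoters."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from midmei import motifs
from midmei.deconvolution import deconvolve
from midmei.synthetic_data import (
    SimulationConfig,
    class_archetypes,
    config_from_toml,
    config_to_toml,
    default_pfms,
    mix_observed_expression,
    plant_promoters,
    simulate_chip,
    simulate_composition,
    simulate_stage_profiles,
    simulate_study,
    write_fasta,
    read_fasta,
)


def small_config(**overrides):
    defaults = dict(
        n_genes=120,
        group_sizes={
            "activator_only": 20, "common": 15, "repressor_only": 20,
            "late_independent": 15, "middle_repressed": 10, "background": 40,
        },
        seed=0,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    def test_group_sizes_must_sum_to_n_genes(self):
        with pytest.raises(ValueError, match="group sizes"):
            small_config(n_genes=121)

    def test_zero_genes_rejected(self):
        with pytest.raises(ValueError, match="invalid config"):
            SimulationConfig(n_genes=0, group_sizes={})

    def test_zero_stages_rejected(self):
        with pytest.raises(ValueError, match="invalid config"):
            small_config(n_stages=0)

    def test_non_increasing_timepoints_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            small_config(
                timepoints_hours={"wt": [2, 2, 3], "sum1d": [1, 2], "er": [1, 2]}
            )

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="noise_sd"):
            small_config(noise_sd=-0.1)

    def test_toml_roundtrip(self):
        config = small_config(seed=9, noise_sd=0.3)
        again = config_from_toml(config_to_toml(config))
        assert again == config


class TestStageProfiles:
    def test_noiseless_pulse_spans_exactly_the_amplitude(self):
        config = small_config(noise_sd=0.0, pulse_amplitude=3.0, amplitude_jitter=(1.0, 1.0))
        profiles, truth = simulate_stage_profiles(config)
        common = truth.classes.index[truth.classes == "common"]
        spans = profiles.loc[common].max(axis=1) - profiles.loc[common].min(axis=1)
        assert np.allclose(spans, 3.0)
        # and the maximum sits at the middle stages (the pulse plateau)
        peaks = profiles.loc[common].to_numpy().argmax(axis=1)
        assert set(peaks) <= set(range(2, truth.peak_last_stage + 1))

    def test_class_shapes(self):
        config = small_config(noise_sd=0.0, amplitude_jitter=(1.0, 1.0))
        profiles, truth = simulate_stage_profiles(config)
        late = profiles.columns[-1]
        ramp = truth.classes.index[truth.classes == "late_independent"]
        assert (profiles.loc[ramp, late] > 0).all()
        assert np.allclose(profiles.loc[ramp].iloc[:, :3], 0.0)
        dip = truth.classes.index[truth.classes == "middle_repressed"]
        assert (profiles.loc[dip].min(axis=1) < 0).all()
        flat = truth.classes.index[truth.classes == "background"]
        assert np.allclose(profiles.loc[flat], 0.0)

    def test_same_seed_bit_identical(self):
        a, _ = simulate_stage_profiles(small_config(seed=7))
        b, _ = simulate_stage_profiles(small_config(seed=7))
        pd.testing.assert_frame_equal(a, b)

    def test_class_means_match_archetype_means(self):
        # per-class emitted means vs the generative archetype formulas,
        # within 3 * noise_sd / sqrt(class size)
        config = SimulationConfig(
            n_genes=500,
            group_sizes={
                "activator_only": 100, "common": 100, "repressor_only": 50,
                "late_independent": 100, "middle_repressed": 100, "background": 50,
            },
            amplitude_jitter=(1.0, 1.0),
            seed=13,
        )
        profiles, truth = simulate_stage_profiles(config)
        shapes = class_archetypes(config.n_stages)
        for cls, size in config.group_sizes.items():
            members = truth.classes.index[truth.classes == cls]
            expected = shapes[cls] * config.pulse_amplitude
            # 4 sigma of the class mean: the check is a max over
            # 6 classes x 8 stages, so the per-entry bound needs head
            # room beyond 3 sigma
            tol = 4 * config.noise_sd / np.sqrt(size)
            assert np.allclose(
                profiles.loc[members].mean(axis=0), expected, atol=tol
            ), cls

    def test_invalid_config_raises(self):
        with pytest.raises(ValueError):
            simulate_stage_profiles(small_config(n_stages=0))


class TestComposition:
    def test_rows_sum_to_one_and_dapi_sums_to_cell_count(self):
        comp, dapi = simulate_composition(small_config(), "wt")
        assert np.allclose(comp.values.sum(axis=1), 1.0, atol=1e-12)
        assert (dapi[["mono", "bi", "tetra"]].sum(axis=1) == 200).all()

    def test_synchronous_culture_is_one_hot(self):
        comp, _ = simulate_composition(small_config(start_time_sd=0.0), "wt")
        assert np.all(comp.values.max(axis=1) == 1.0)

    def test_category_fractions_match_cdf_integration_oracle(self):
        # empirical DAPI fractions over 50 seeds vs the Normal-CDF
        # expectation, within multinomial error of the pooled counts
        config = small_config()
        totals = np.zeros((len(config.timepoints_hours["wt"]), 3))
        n_seeds = 50
        for seed in range(n_seeds):
            _, dapi = simulate_composition(small_config(seed=seed), "wt")
            totals += dapi[["mono", "bi", "tetra"]].to_numpy()
        pooled = totals / totals.sum(axis=1, keepdims=True)
        from midmei.deconvolution import dapi_fractions

        expected = dapi_fractions(
            config.timepoints_hours["wt"],
            config.start_time_mean,
            config.start_time_sd,
            config.stage_model,
        )
        n = 200 * n_seeds
        se = np.sqrt(np.maximum(expected * (1 - expected), 1e-4) / n)
        assert np.all(np.abs(pooled - expected) < 5 * se)


class TestMixing:
    def test_identity_composition_reproduces_profiles(self):
        config = small_config(noise_sd=0.0)
        profiles, truth = simulate_stage_profiles(config)
        observed = mix_observed_expression(
            profiles, np.eye(config.n_stages), "wt", config, truth
        )
        assert np.allclose(observed.to_numpy(), profiles.to_numpy())

    def test_sum1del_late_equals_middle(self):
        config = small_config(noise_sd=0.0)
        profiles, truth = simulate_stage_profiles(config)
        observed = mix_observed_expression(
            profiles, np.eye(config.n_stages), "sum1d", config, truth
        )
        targets = truth.classes.index[truth.classes == "common"]
        mid = observed.columns[truth.middle_stage]
        late = observed.columns[-1]
        assert np.allclose(observed.loc[targets, mid], observed.loc[targets, late])

    def test_er_with_full_indirect_weight_abolishes_repression(self):
        config = small_config(
            noise_sd=0.0, w_true_range={"activator_only": (1.0, 1.0), "common": (1.0, 1.0)}
        )
        profiles, truth = simulate_stage_profiles(config)
        observed = mix_observed_expression(
            profiles, np.eye(config.n_stages), "er", config, truth
        )
        targets = truth.classes.index[truth.classes.isin(["activator_only", "common"])]
        mid = observed.columns[truth.middle_stage]
        late = observed.columns[-1]
        folds = 2.0 ** (observed.loc[targets, mid] - observed.loc[targets, late])
        assert np.allclose(folds, 1.0)

    def test_shape_mismatch_rejected(self):
        config = small_config()
        profiles, truth = simulate_stage_profiles(config)
        with pytest.raises(ValueError, match="stages"):
            mix_observed_expression(profiles, np.eye(3), "wt", config, truth)

    def test_noiseless_round_trip_through_deconvolution(self):
        config = small_config(noise_sd=0.0)
        profiles, truth = simulate_stage_profiles(config)
        observed = mix_observed_expression(
            profiles, np.eye(config.n_stages), "wt", config, truth
        )
        back = deconvolve(observed, np.eye(config.n_stages), ridge=0.0)
        assert np.allclose(back.to_numpy(), profiles.to_numpy(), atol=1e-10)


class TestChip:
    def test_null_study_target_and_background_indistinguishable(self):
        config = small_config(chip_signal_shift=0.0, seed=21)
        _, truth = simulate_stage_profiles(config)
        chip = simulate_chip(config, truth)
        bound = truth.classes.isin(["activator_only", "common"]).to_numpy()
        stat = stats.ks_2samp(
            chip.loc[bound, "activator_rep1"], chip.loc[~bound, "activator_rep1"]
        )
        assert stat.pvalue > 0.01

    def test_replicates_positively_correlated_with_signal(self):
        config = small_config(chip_signal_shift=4.0, chip_noise_sd=0.8)
        _, truth = simulate_stage_profiles(config)
        chip = simulate_chip(config, truth)
        r = np.corrcoef(chip["activator_rep1"], chip["activator_rep2"])[0, 1]
        assert r > 0.0

    def test_planted_targets_exceed_mirrored_threshold(self):
        # strong shift, small noise: planted targets are always called
        from midmei import binding
        from midmei.synthetic_data import average_chip_replicates

        hits = []
        for seed in range(20):
            config = small_config(chip_signal_shift=5.0, chip_noise_sd=0.5, seed=seed)
            _, truth = simulate_stage_profiles(config)
            ratios = average_chip_replicates(simulate_chip(config, truth))
            z = binding.zscores(ratios["activator"])
            res = binding.mirrored_fdr_threshold(z, 0.05)
            targets = truth.targets_of("activator")
            hits.append(res.called.loc[targets].all())
        assert np.mean(hits) >= 0.95

    def test_symmetric_null_families(self):
        for family in ("normal", "laplace", "logistic"):
            config = small_config(chip_null_family=family, seed=2)
            _, truth = simulate_stage_profiles(config)
            chip = simulate_chip(config, truth)
            assert np.isfinite(chip.to_numpy()).all()
        with pytest.raises(ValueError, match="family"):
            config = small_config(chip_null_family="cauchy", seed=2)
            _, truth = simulate_stage_profiles(config)
            simulate_chip(config, truth)


class TestPromoters:
    def test_consensus_site_scores_at_least_consensus_score(self):
        pfm_a, _ = default_pfms()
        pssm = motifs.build_pssm(pfm_a)
        rng = np.random.default_rng(0)
        bg = "".join(rng.choice(list("ACGT"), size=200))
        consensus = "".join(
            motifs.NUCLEOTIDES[i] for i in pssm.weights.argmax(axis=0)
        )
        seq = bg[:90] + consensus + bg[90 + len(consensus):]
        res = motifs.scan(seq, pssm)
        assert res.max_score >= pssm.max_score - 1e-9

    def test_sites_recorded_in_truth(self):
        config = small_config(planted_site_rate={
            "activator_only": 1.0, "common": 1.0, "repressor_only": 1.0
        })
        _, truth = simulate_stage_profiles(config)
        promoters, sites = plant_promoters(config, truth)
        pfm_a, pfm_r = default_pfms()
        assert truth.site_positions is sites
        # every recorded site is recoverable from the sequence
        for _, row in sites.iterrows():
            seq = promoters[row.promoter]
            window = seq[row.start : row.start + len(row.site)]
            expected = row.site if row.strand == "+" else motifs.reverse_complement(row.site)
            assert window == expected
        # common promoters got one site per factor
        common = truth.classes.index[truth.classes == "common"]
        per_factor = sites.groupby(["promoter", "factor"]).size()
        for p in common:
            assert per_factor.get((p, "activator"), 0) == 1
            assert per_factor.get((p, "repressor"), 0) == 1

    def test_common_group_fold_enrichment_above_one(self):
        from midmei import binding

        folds_common, folds_background = [], []
        for seed in range(6):
            # a universe large enough for the 5% calibration to resolve
            config = SimulationConfig(
                n_genes=600,
                group_sizes={
                    "activator_only": 60, "common": 40, "repressor_only": 60,
                    "late_independent": 40, "middle_repressed": 40,
                    "background": 360,
                },
                seed=seed,
            )
            _, truth = simulate_stage_profiles(config)
            promoters, _ = plant_promoters(config, truth)
            pssm = motifs.build_pssm(default_pfms()[0])
            table = motifs.scan_promoters(promoters, pssm)
            thr = motifs.calibrate_threshold(table["max_score"], 0.05)
            calls = motifs.call_sites(table["max_score"], thr)
            universe = list(promoters)
            common = truth.classes.index[truth.classes == "common"]
            background = truth.classes.index[truth.classes == "background"]
            folds_common.append(
                binding.motif_fold_enrichment(common, universe, calls)
            )
            folds_background.append(
                binding.motif_fold_enrichment(background, universe, calls)
            )
        # the calibrated threshold fixes the universe fraction, so the
        # planted classes are enriched while the background is pushed
        # at or slightly below one
        assert np.mean(folds_common) > 1.0
        assert np.mean(folds_background) < 1.1
        assert np.mean(folds_common) > 2 * np.mean(folds_background)

    def test_fasta_text_deterministic(self, tmp_path):
        texts = []
        for _ in range(2):
            config = small_config(seed=4)
            _, truth = simulate_stage_profiles(config)
            promoters, _ = plant_promoters(config, truth)
            path = tmp_path / "p.fasta"
            write_fasta(promoters, path)
            texts.append(path.read_text())
        assert texts[0] == texts[1]
        assert read_fasta(tmp_path / "p.fasta") == promoters


def test_full_study_is_deterministic():
    s1 = simulate_study(small_config(seed=3), spot_tables=False)
    s2 = simulate_study(small_config(seed=3), spot_tables=False)
    for strain in s1.expression:
        pd.testing.assert_frame_equal(s1.expression[strain], s2.expression[strain])
    pd.testing.assert_frame_equal(s1.chip, s2.chip)
    assert s1.promoters == s2.promoters
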