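"""PSSM construction, scanning and threshold calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import helpers
from midmei import motifs


@pytest.fixture
def uniform_freq():
    return motifs.FrequencyMatrix(np.full((4, 5), 0.25))


def pfm_random(rng: np.random.Generator, length: int) -> motifs.FrequencyMatrix:
    m = rng.dirichlet(np.ones(4), size=length).T
    return motifs.FrequencyMatrix(m)


class TestBuildPssm:
    def test_background_equal_frequencies_give_zero_weights(self):
        freq = motifs.FrequencyMatrix(
            np.array([[0.16, 0.16], [0.34, 0.34], [0.34, 0.34], [0.16, 0.16]])
        )
        pssm = motifs.build_pssm(freq, epsilon=0.0)
        assert np.allclose(pssm.weights, 0.0)

    def test_hand_computed_weight(self):
        # f(A) = 1 against p_A = 0.16 with no pseudocount; a vanishing
        # residual mass keeps the other cells non-zero (an exact zero
        # with epsilon = 0 is rejected by contract)
        tiny = 1e-12
        freq = motifs.FrequencyMatrix(
            np.array([[1.0 - 3 * tiny], [tiny], [tiny], [tiny]])
        )
        pssm = motifs.build_pssm(freq, epsilon=0.0)
        assert pssm.weights[0, 0] == pytest.approx(np.log2(1 / 0.16), abs=1e-9)

    def test_printed_default_background(self):
        # intergenic background as printed: G/C heavy, configurable
        assert motifs.DEFAULT_BACKGROUND["G"] == 0.34
        assert motifs.DEFAULT_BACKGROUND["C"] == 0.34
        assert motifs.DEFAULT_BACKGROUND["A"] == 0.16

    def test_zero_frequency_without_pseudocount_rejected(self):
        freq = motifs.FrequencyMatrix(np.array([[1.0], [0.0], [0.0], [0.0]]))
        with pytest.raises(ValueError, match="pseudocount"):
            motifs.build_pssm(freq, epsilon=0.0)
        # epsilon > 0 succeeds
        motifs.build_pssm(freq, epsilon=0.01)

    def test_invalid_frequency_matrix_rejected(self):
        with pytest.raises(ValueError):
            motifs.FrequencyMatrix(np.full((4, 3), 0.3))


class TestScan:
    def test_zero_pssm_scores_zero(self, uniform_freq):
        pssm = motifs.Pssm(np.zeros((4, 3)), motifs.DEFAULT_BACKGROUND, 0.0)
        res = motifs.scan("ACGTACGT", pssm)
        assert np.allclose(res.forward, 0.0)
        assert res.max_score == 0.0

    def test_sequence_shorter_than_motif(self):
        pssm = motifs.Pssm(np.zeros((4, 6)), motifs.DEFAULT_BACKGROUND, 0.0)
        res = motifs.scan("ACG", pssm)
        assert res.forward.size == 0
        assert np.isnan(res.max_score)
        assert res.best_start is None

    def test_empty_sequence_is_not_an_error(self):
        pssm = motifs.Pssm(np.zeros((4, 2)), motifs.DEFAULT_BACKGROUND, 0.0)
        assert np.isnan(motifs.scan("", pssm).max_score)

    def test_n_windows_never_maximal(self):
        rng = np.random.default_rng(7)
        pssm = motifs.build_pssm(pfm_random(rng, 4))
        res = motifs.scan("ANGT" + "ACGT" * 3, pssm)
        assert np.isinf(res.forward[0]) and res.forward[0] < 0
        assert np.isfinite(res.max_score)

    def test_all_n_sequence_has_no_max(self):
        pssm = motifs.Pssm(np.zeros((4, 2)), motifs.DEFAULT_BACKGROUND, 0.0)
        assert np.isnan(motifs.scan("NNNNN", pssm).max_score)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(11)
        pssm = motifs.build_pssm(pfm_random(rng, 7))
        for _ in range(50):
            seq = helpers.random_dna(rng, 60)
            res = motifs.scan(seq, pssm)
            best, fwd, rev = helpers.brute_scan_max(seq, pssm.weights)
            assert np.allclose(res.forward, fwd, atol=1e-9)
            assert np.allclose(res.reverse, rev, atol=1e-9)
            assert res.max_score == pytest.approx(best, abs=1e-9)

    def test_strand_symmetry(self):
        rng = np.random.default_rng(3)
        pssm = motifs.build_pssm(pfm_random(rng, 6))
        seq = helpers.random_dna(rng, 80)
        a = motifs.scan(seq, pssm).max_score
        b = motifs.scan(helpers.brute_revcomp(seq), pssm).max_score
        assert a == pytest.approx(b, abs=1e-9)

    def test_window_score_independent_of_position(self):
        rng = np.random.default_rng(5)
        pssm = motifs.build_pssm(pfm_random(rng, 5))
        core = "ACGTA"
        left = motifs.scan(core + "T" * 20, pssm).forward[0]
        right = motifs.scan("T" * 20 + core, pssm).forward[20]
        assert left == pytest.approx(right, abs=1e-12)

    def test_consensus_achieves_max_possible_score(self):
        # the consensus w.r.t. the weights (background-adjusted) attains
        # the best achievable window score exactly
        rng = np.random.default_rng(9)
        freq = pfm_random(rng, 8)
        pssm = motifs.build_pssm(freq)
        consensus = "".join(
            motifs.NUCLEOTIDES[i] for i in pssm.weights.argmax(axis=0)
        )
        res = motifs.scan(consensus, pssm, both_strands=False)
        assert res.max_score == pytest.approx(pssm.max_score, abs=1e-9)
        # and with a uniform background the frequency consensus agrees
        uni = motifs.build_pssm(freq, background=dict.fromkeys("ACGT", 0.25))
        res_uni = motifs.scan(freq.consensus, uni, both_strands=False)
        assert res_uni.max_score == pytest.approx(uni.max_score, abs=1e-9)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        seq=st.text(alphabet="ACGTN", min_size=0, max_size=200),
        length=st.integers(min_value=1, max_value=12),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    def test_brute_force_equivalence_property(self, seq, length, seed):
        pssm = motifs.build_pssm(pfm_random(np.random.default_rng(seed), length))
        res = motifs.scan(seq, pssm)
        best, fwd, rev = helpers.brute_scan_max(seq, pssm.weights)
        assert np.allclose(res.forward, fwd, atol=1e-9)
        assert np.allclose(res.reverse, rev, atol=1e-9)
        if np.isnan(best):
            assert np.isnan(res.max_score)
        else:
            assert res.max_score == pytest.approx(best, abs=1e-9)


class TestCalibration:
    def test_counting_example(self):
        thr = motifs.calibrate_threshold(np.arange(1.0, 101.0), 0.05)
        assert thr == 95.0  # exactly {96..100} exceed

    def test_fraction_one_passes_everything(self):
        scores = np.array([3.0, 5.0, 9.0])
        thr = motifs.calibrate_threshold(scores, 1.0)
        assert thr < scores.min()
        assert (scores > thr).all()

    def test_monotone_in_fraction(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=500)
        thresholds = [
            motifs.calibrate_threshold(scores, f) for f in (0.5, 0.2, 0.1, 0.05, 0.01)
        ]
        assert all(b >= a for a, b in zip(thresholds, thresholds[1:]))

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            motifs.calibrate_threshold([], 0.05)

    def test_called_fraction_never_exceeds_target(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=997)
        for f in (0.3, 0.05, 0.01):
            thr = motifs.calibrate_threshold(scores, f)
            assert (scores > thr).mean() <= f


class TestPfmIO:
    def test_roundtrip_and_count_normalization(self, tmp_path):
        path = tmp_path / "m.pfm"
        path.write_text(
            "A\t8\t0\t1\nC\t1\t9\t1\nG\t1\t1\t7\nT\t0\t0\t1\n"
        )
        freq = motifs.read_pfm(path)
        assert freq.matrix[:, 0] == pytest.approx([0.8, 0.1, 0.1, 0.0])
        out = tmp_path / "round.pfm"
        motifs.write_pfm(freq, out)
        again = motifs.read_pfm(out)
        assert np.allclose(freq.matrix, again.matrix, atol=1e-6)

    def test_missing_row_rejected(self, tmp_path):
        path = tmp_path / "bad.pfm"
        path.write_text("A\t1\t1\nC\t1\t1\nG\t1\t1\n")
        with pytest.raises(ValueError, match="lacks rows"):
            motifs.read_pfm(path)
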