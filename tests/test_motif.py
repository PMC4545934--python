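"""Unit tests for PFM parsing, PWM construction and scoring."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pwmscale import (
    BACKGROUND_PRESETS,
    PFM,
    BackgroundModel,
    ParameterError,
    ParseError,
    build_pwm,
    filter_pfms,
    information_content,
    parse_pfms,
    reverse_complement,
    scale_weights,
    score_window,
    shift_weights,
)
from pwmscale.motif import write_pwm_tsv

UNIFORM = BACKGROUND_PRESETS["uniform"]


class TestBackground:
    def test_presets_match_organism_frequencies(self):
        fly = BACKGROUND_PRESETS["fly"]
        assert (fly.freq_a, fly.freq_c, fly.freq_g, fly.freq_t) == (
            0.28, 0.22, 0.22, 0.28)
        yeast = BACKGROUND_PRESETS["yeast"]
        assert yeast.freq_a == yeast.freq_t == 0.31
        assert yeast.freq_c == yeast.freq_g == 0.19
        vert = BACKGROUND_PRESETS["vertebrate"]
        assert vert.freq_a == 0.29 and vert.freq_g == 0.21

    @pytest.mark.parametrize("freqs", [(0.5, 0.5, 0.0, 0.0),
                                       (0.3, 0.3, 0.3, 0.3)])
    def test_invalid_frequencies_rejected(self, freqs):
        with pytest.raises(ParameterError):
            BackgroundModel(*freqs)


class TestParsing:
    def test_jaspar_block_direct_transcription(self):
        text = ">M1 TF1\nA [ 8 0 ]\nC [ 0 8 ]\nG [ 0 0 ]\nT [ 0 0 ]\n"
        (pfm,) = parse_pfms(text)
        assert pfm.motif_id == "M1" and pfm.tf_name == "TF1"
        assert pfm.length == 2
        np.testing.assert_array_equal(
            pfm.counts, [[8, 0], [0, 8], [0, 0], [0, 0]])

    def test_row_order_normalized_to_acgt(self):
        text = ">M2\nT [ 1 0 ]\nG [ 2 0 ]\nC [ 3 0 ]\nA [ 4 1 ]\n"
        (pfm,) = parse_pfms(text)
        np.testing.assert_array_equal(
            pfm.counts, [[4, 1], [3, 0], [2, 0], [1, 0]])

    def test_bare_matrix_rows_assumed_acgt(self):
        (pfm,) = parse_pfms("8 0\n0 8\n0 0\n1 0\n")
        np.testing.assert_array_equal(
            pfm.counts, [[8, 0], [0, 8], [0, 0], [1, 0]])

    def test_three_row_block_is_parse_error(self):
        with pytest.raises(ParseError, match="expected 4 rows"):
            parse_pfms(">M3\nA [ 8 ]\nC [ 0 ]\nG [ 0 ]\n")

    def test_ragged_columns_error_names_block(self):
        with pytest.raises(ParseError, match="M4"):
            parse_pfms(">M4\nA [ 8 0 ]\nC [ 0 ]\nG [ 0 0 ]\nT [ 0 0 ]\n")

    def test_negative_count_rejected_with_line_number(self):
        with pytest.raises(ParseError, match="line 3"):
            parse_pfms(">M5\nA [ 8 ]\nC [ -1 ]\nG [ 0 ]\nT [ 0 ]\n")

    def test_multiple_blocks_and_default_n_sequences(self):
        text = (">M6\nA [ 10 2 ]\nC [ 0 8 ]\nG [ 0 0 ]\nT [ 0 0 ]\n"
                "\n4 0\n0 4\n0 0\n0 0\n")
        pfms = parse_pfms(text)
        assert len(pfms) == 2
        assert pfms[0].n_sequences == 10  # max column sum, rounded
        assert pfms[1].n_sequences == 4

    def test_n_sequences_metadata_override(self):
        text = ">M7 TF ; n_sequences=55\nA [ 8 ]\nC [ 0 ]\nG [ 0 ]\nT [ 0 ]\n"
        (pfm,) = parse_pfms(text)
        assert pfm.n_sequences == 55

    def test_parse_from_handle(self):
        handle = io.StringIO("1 2\n3 4\n5 6\n7 8\n")
        (pfm,) = parse_pfms(handle)
        assert pfm.counts[3, 1] == 8


class TestFilter:
    def make(self, n, length, mid):
        counts = np.ones((4, length)) * n / 4
        return PFM(counts=counts, n_sequences=n, motif_id=mid)

    def test_boundaries_follow_less_than_semantics(self):
        pfms = [self.make(29, 10, "few_sites"),
                self.make(30, 6, "boundary_ok"),
                self.make(100, 5, "too_short")]
        kept = filter_pfms(pfms)
        assert [p.motif_id for p in kept] == ["boundary_ok"]

    def test_order_preserved_and_empty_allowed(self):
        pfms = [self.make(50, 8, "b"), self.make(40, 9, "a")]
        assert [p.motif_id for p in filter_pfms(pfms)] == ["b", "a"]
        assert filter_pfms([self.make(5, 8, "x")]) == []


class TestBuildPwm:
    def test_background_matching_column_has_zero_weights(self, uniform_bg):
        pfm = PFM(counts=np.full((4, 1), 2.0), n_sequences=8)
        pwm = build_pwm(pfm, uniform_bg)  # v = (2+0.25)/9 = 0.25 = f
        np.testing.assert_allclose(pwm.weights, 0.0, atol=1e-12)
        assert pwm.s_max == 0.0

    def test_sharp_column_weights(self, single_a_column_pfm, uniform_bg):
        pwm = build_pwm(single_a_column_pfm, uniform_bg)
        assert pwm.weights[0, 0] == pytest.approx(
            math.log2((8.25 / 9) / 0.25), abs=1e-9)
        assert pwm.weights[0, 0] == pytest.approx(1.87447, abs=1e-5)
        np.testing.assert_allclose(pwm.weights[1:, 0], math.log2(1 / 9),
                                   atol=1e-12)
        assert pwm.weights[1, 0] == pytest.approx(-3.16993, abs=1e-5)

    def test_small_pseudocount_limit(self, single_a_column_pfm, uniform_bg):
        pwm = build_pwm(single_a_column_pfm, uniform_bg, pseudocount=1e-4)
        assert pwm.weights[0, 0] == pytest.approx(2.0, abs=1e-4)
        assert pwm.weights[1, 0] < -10

    def test_nonpositive_pseudocount_rejected(self, single_a_column_pfm,
                                              uniform_bg):
        with pytest.raises(ParameterError):
            build_pwm(single_a_column_pfm, uniform_bg, pseudocount=0)

    def test_s_max_is_sum_of_column_maxima(self, a6_pwm):
        assert a6_pwm.s_max == pytest.approx(
            a6_pwm.weights.max(axis=0).sum())


class TestInformationContent:
    def test_uniform_column_contributes_zero(self, uniform_bg):
        pfm = PFM(counts=np.full((4, 1), 2.0), n_sequences=8)
        assert information_content(pfm, uniform_bg) == pytest.approx(0.0,
                                                                     abs=1e-12)

    def test_sharp_column_value(self, single_a_column_pfm, uniform_bg):
        got = information_content(single_a_column_pfm, uniform_bg)
        expected = (8.25 / 9) * math.log2((8.25 / 9) / 0.25) + \
            3 * (0.25 / 9) * math.log2((0.25 / 9) / 0.25)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(1.45410, abs=1e-5)

    def test_mu_to_zero_limit_two_bits_per_specified_column(self, uniform_bg):
        pfm = PFM(counts=np.array([[1.0], [0], [0], [0]]), n_sequences=1)
        got = information_content(pfm, uniform_bg, pseudocount=1e-9)
        assert got == pytest.approx(2.0, abs=1e-6)

    def test_invariant_under_column_permutation_and_revcomp(self, uniform_bg):
        rng = np.random.default_rng(11)
        counts = rng.integers(0, 20, size=(4, 7)).astype(float) + 0.5
        pfm = PFM(counts=counts, n_sequences=40)
        base = information_content(pfm, uniform_bg)
        perm = PFM(counts=counts[:, rng.permutation(7)], n_sequences=40)
        rc = PFM(counts=counts[::-1, ::-1].copy(), n_sequences=40)
        assert information_content(perm, uniform_bg) == pytest.approx(base)
        assert information_content(rc, uniform_bg) == pytest.approx(base)

    def test_nonnegative_on_random_pfms(self, uniform_bg):
        rng = np.random.default_rng(5)
        for _ in range(20):
            counts = rng.integers(0, 30, size=(4, 9)).astype(float) + 0.1
            pfm = PFM(counts=counts, n_sequences=30)
            assert information_content(pfm, uniform_bg) >= 0


class TestScoreWindow:
    def test_zero_pwm_scores_zero(self, uniform_bg):
        pfm = PFM(counts=np.full((4, 2), 2.0), n_sequences=8)
        pwm = build_pwm(pfm, uniform_bg)
        assert score_window(pwm, "ACGT", 1) == pytest.approx(0.0, abs=1e-12)

    def test_consensus_window_attains_s_max(self, uniform_bg):
        counts = np.zeros((4, 2))
        counts[0] = 8.0
        pwm = build_pwm(PFM(counts=counts, n_sequences=8), uniform_bg)
        assert score_window(pwm, "AA", 0) == pytest.approx(pwm.s_max)
        assert score_window(pwm, "AA", 0) == pytest.approx(3.74894, abs=1e-4)

    def test_non_acgt_window_is_unscorable_not_an_exception(self, uniform_bg):
        counts = np.zeros((4, 2))
        counts[0] = 8.0
        pwm = build_pwm(PFM(counts=counts, n_sequences=8), uniform_bg)
        assert math.isnan(score_window(pwm, "AN", 0))

    def test_window_outside_sequence_raises(self, a6_pwm):
        with pytest.raises(ParameterError):
            score_window(a6_pwm, "ACGT", 2)

    def test_maximum_over_all_kmers_is_s_max_at_argmax_sequence(self,
                                                                uniform_bg):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 20, size=(4, 4)).astype(float) + 0.2
        pwm = build_pwm(PFM(counts=counts, n_sequences=20), uniform_bg)
        from itertools import product
        best = max(
            score_window(pwm, "".join(w), 0)
            for w in product("ACGT", repeat=4))
        assert best == pytest.approx(pwm.s_max, abs=1e-9)
        assert score_window(pwm, pwm.consensus(), 0) == pytest.approx(
            pwm.s_max)


class TestReverseComplement:
    def test_single_column_maps_a_to_t(self, single_a_column_pfm, uniform_bg):
        pwm = build_pwm(single_a_column_pfm, uniform_bg)
        rc = reverse_complement(pwm)
        np.testing.assert_array_equal(rc.weights[3], pwm.weights[0])
        np.testing.assert_array_equal(rc.weights[0], pwm.weights[3])

    def test_involution_is_bitwise(self, uniform_bg):
        rng = np.random.default_rng(9)
        counts = rng.integers(0, 15, size=(4, 6)).astype(float) + 0.3
        pwm = build_pwm(PFM(counts=counts, n_sequences=15), uniform_bg)
        back = reverse_complement(reverse_complement(pwm))
        np.testing.assert_array_equal(back.weights, pwm.weights)

    def test_palindrome_fixed_point_and_invariants(self, uniform_bg):
        counts = np.array([[8, 0, 0, 0], [0, 8, 0, 0],
                           [0, 0, 8, 0], [0, 0, 0, 8]], dtype=float)
        pwm = build_pwm(PFM(counts=counts, n_sequences=8), uniform_bg)
        rc = reverse_complement(pwm)
        np.testing.assert_array_equal(rc.weights, pwm.weights)
        assert rc.s_max == pwm.s_max
        assert rc.information_content == pwm.information_content


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_shift_property_preserves_score_differences(seed):
    """Adding per-column constants shifts every score and s_max alike,
    leaving S_max - S_j unchanged for every window."""
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, 25, size=(4, 5)).astype(float) + 0.25
    pwm = build_pwm(PFM(counts=counts, n_sequences=25), UNIFORM)
    shifts = rng.normal(size=5)
    shifted = shift_weights(pwm, shifts)
    window = "".join("ACGT"[i] for i in rng.integers(0, 4, size=5))
    s0 = score_window(pwm, window, 0)
    s1 = score_window(shifted, window, 0)
    assert s1 - s0 == pytest.approx(shifts.sum(), abs=1e-9)
    assert shifted.s_max - pwm.s_max == pytest.approx(shifts.sum(), abs=1e-9)
    assert (shifted.s_max - s1) == pytest.approx(pwm.s_max - s0, abs=1e-9)


def test_scale_weights_validates_factor(a6_pwm):
    with pytest.raises(ParameterError):
        scale_weights(a6_pwm, -1.0)
    scaled = scale_weights(a6_pwm, 2.0)
    assert scaled.s_max == pytest.approx(2 * a6_pwm.s_max)
    assert scaled.information_content == a6_pwm.information_content


def test_pwm_tsv_serialization_round_readable(tmp_path, a6_pwm):
    path = tmp_path / "pwm.tsv"
    write_pwm_tsv(a6_pwm, str(path))
    text = path.read_text()
    assert "# s_max_bits" in text and "# information_content_bits" in text
    assert text.count("\n") == 5 + 1 + 4  # meta + header + 4 base rows
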