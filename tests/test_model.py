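"""Motif model scoring: logistic terms, noisy-OR, affinity map."""

import numpy as np
import pytest
from scipy.special import expit

from rbpmotif import (
    AffinityMap,
    MotifModel,
    plum_alphabet,
    predict_affinity,
    profile_from_external,
    score_sequence,
    sequence_term,
    single_letter_alphabet,
    structure_term,
    window_probability,
)
from rbpmotif.model import window_probabilities

from conftest import random_rna


def make_model(width=4, theta=None, gamma=None, b_seq=0.0, b_str=0.0, alphabet=None,
               mean_context=False):
    alphabet = alphabet or plum_alphabet()
    theta = np.zeros((4, width)) if theta is None else np.asarray(theta, float)
    gamma = np.zeros(len(alphabet)) if gamma is None else np.asarray(gamma, float)
    return MotifModel(width=width, theta=theta, gamma=gamma, b_seq=b_seq,
                      b_str=b_str, alphabet=alphabet, mean_context=mean_context)


def uniform_profile(n, alphabet=None):
    alphabet = alphabet or plum_alphabet()
    vals = np.full((len(alphabet), n), 1.0 / len(alphabet))
    return profile_from_external(vals, alphabet)


def random_model(rng, width, alphabet=None):
    alphabet = alphabet or plum_alphabet()
    return make_model(
        width,
        theta=rng.normal(0, 1.5, size=(4, width)),
        gamma=rng.normal(0, 1.5, size=len(alphabet)),
        b_seq=rng.normal(),
        b_str=rng.normal(),
        alphabet=alphabet,
    )


def random_profile(rng, n, alphabet=None):
    alphabet = alphabet or plum_alphabet()
    raw = rng.dirichlet(np.ones(len(alphabet)), size=n).T
    return profile_from_external(raw, alphabet)


class TestSequenceTerm:
    def test_zero_parameters_give_half(self):
        m = make_model(4)
        assert sequence_term("ACGU", m) == 0.5

    def test_closed_form_example(self):
        theta = np.zeros((4, 2))
        theta[0, 0] = 1.0  # A at position 1
        theta[3, 1] = 1.0  # U at position 2
        m = make_model(2, theta=theta, b_seq=-1.0)
        assert sequence_term("AU", m) == pytest.approx(expit(1.0), abs=1e-6)
        assert sequence_term("AU", m) == pytest.approx(0.731059, abs=1e-6)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            w = int(rng.integers(4, 9))
            m = random_model(rng, w)
            kmer = random_rna(rng, w)
            direct = m.b_seq + sum(
                m.theta["ACGU".index(c), j] for j, c in enumerate(kmer)
            )
            assert sequence_term(kmer, m) == pytest.approx(
                1.0 / (1.0 + np.exp(-direct)), rel=1e-12
            )

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            sequence_term("ACG", make_model(4))


class TestStructureTerm:
    def test_single_letter_alphabet_is_constant(self):
        alpha = single_letter_alphabet()
        m = make_model(3, gamma=[0.7], b_str=0.2, alphabet=alpha)
        for _ in range(5):
            prof = np.ones((1, 3))
            assert structure_term(prof, m) == pytest.approx(expit(0.2 + 3 * 0.7))

    def test_pure_context_closed_form(self):
        alpha = plum_alphabet()
        gamma = np.zeros(4)
        gamma[alpha.index("L")] = 2.0
        m = make_model(3, gamma=gamma, alphabet=alpha)
        prof = np.zeros((4, 3))
        prof[alpha.index("L")] = 1.0
        assert structure_term(prof, m) == pytest.approx(expit(6.0), abs=1e-6)
        assert structure_term(prof, m) == pytest.approx(0.997527, abs=1e-6)

    def test_mixed_profile_hand_weighted_sum(self):
        alpha = plum_alphabet()
        gamma = np.zeros(4)
        gamma[alpha.index("P")] = -1.0
        gamma[alpha.index("L")] = 1.0
        m = make_model(2, gamma=gamma, alphabet=alpha)
        prof = np.zeros((4, 2))
        prof[alpha.index("P")] = 0.5
        prof[alpha.index("L")] = 0.5
        assert structure_term(prof, m) == 0.5

    def test_mean_convention_divides_by_width(self):
        alpha = plum_alphabet()
        gamma = np.zeros(4)
        gamma[alpha.index("L")] = 2.0
        m = make_model(4, gamma=gamma, alphabet=alpha, mean_context=True)
        prof = np.zeros((4, 4))
        prof[alpha.index("L")] = 1.0
        assert structure_term(prof, m) == pytest.approx(expit(2.0))

    def test_alphabet_mismatch(self):
        m = make_model(3)
        with pytest.raises(ValueError):
            structure_term(np.ones((1, 3)), m)


class TestWindowProbability:
    def test_product_structure(self):
        # choose parameters so the two terms are 0.8 and 0.5
        alpha = plum_alphabet()
        theta = np.zeros((4, 2))
        m = make_model(2, theta=theta, b_seq=float(np.log(4)), alphabet=alpha)
        prof = np.zeros((4, 2))
        prof[alpha.index("U")] = 1.0
        assert sequence_term("AC", m) == pytest.approx(0.8)
        assert structure_term(prof, m) == 0.5
        assert window_probability("AC", prof, m) == pytest.approx(0.4)

    def test_saturated_context_reduces_to_sequence_term(self):
        m = make_model(3, b_str=40.0)
        prof = np.zeros((4, 3))
        prof[0] = 1.0
        assert window_probability("ACG", prof, m) == pytest.approx(
            sequence_term("ACG", m), rel=1e-12
        )

    def test_disfavored_context_kills_binding(self):
        alpha = plum_alphabet()
        gamma = np.full(4, 0.0)
        gamma[alpha.index("P")] = -60.0
        m = make_model(3, theta=np.full((4, 3), 5.0), gamma=gamma, alphabet=alpha)
        prof = np.zeros((4, 3))
        prof[alpha.index("P")] = 1.0
        assert window_probability("AAA", prof, m) < 1e-12


class TestScoreSequence:
    def test_noisy_or_limits(self):
        m = make_model(4, theta=np.full((4, 4), -50.0), b_seq=-50.0)
        prof = uniform_profile(10)
        assert score_sequence("ACGUACGUAC", prof, m) == pytest.approx(0.0, abs=1e-12)
        m1 = make_model(4, theta=np.full((4, 4), 50.0), b_seq=50.0, b_str=50.0)
        assert score_sequence("ACGUACGUAC", prof, m1) == pytest.approx(1.0, abs=1e-9)

    def test_two_windows_at_half(self):
        # width = n-1 gives exactly two windows; tune to p = 0.5 each
        alpha = plum_alphabet()
        m = make_model(4, alphabet=alpha, b_str=40.0)  # sequence term 0.5, context ~1
        prof = uniform_profile(5)
        assert score_sequence("ACGUA", prof, m) == pytest.approx(0.75, rel=1e-9)

    def test_matches_per_window_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            m = random_model(rng, int(rng.integers(4, 9)))
            seq = random_rna(rng, 35)
            prof = random_profile(rng, 35)
            p = [
                window_probability(seq[i : i + m.width],
                                   prof.values[:, i : i + m.width], m)
                for i in range(35 - m.width + 1)
            ]
            brute = 1.0 - np.prod([1.0 - pi for pi in p])
            assert score_sequence(seq, prof, m) == pytest.approx(brute, abs=1e-12)

    def test_non_acgu_windows_contribute_zero(self):
        rng = np.random.default_rng(1)
        m = random_model(rng, 4)
        seq = "ACGUACGUACGU"
        prof = random_profile(rng, len(seq))
        base = score_sequence(seq, prof, m)
        seq_n = seq[:5] + "N" + seq[6:]
        p = window_probabilities(seq_n, prof, m)
        assert np.all(p[2:6] == 0.0)
        # remaining windows unchanged
        p0 = window_probabilities(seq, prof, m)
        assert np.allclose(p[:2], p0[:2]) and np.allclose(p[6:], p0[6:])
        assert score_sequence(seq_n, prof, m) <= base + 1e-12

    def test_too_short_sequence_errors(self):
        m = make_model(6)
        with pytest.raises(ValueError, match="shorter"):
            score_sequence("ACGUA", uniform_profile(5), m)

    def test_single_letter_reduction_to_sequence_only(self):
        """gamma=0 and saturated context bias give a pure noisy-OR PWM model."""
        rng = np.random.default_rng(5)
        alpha = single_letter_alphabet()
        theta = rng.normal(size=(4, 4))
        m = make_model(4, theta=theta, gamma=[0.0], b_str=50.0, alphabet=alpha)
        seq = random_rna(rng, 20)
        prof = profile_from_external(np.ones((1, 20)), alpha)
        p_seq = [sequence_term(seq[i : i + 4], m) for i in range(17)]
        expected = 1.0 - np.prod([1 - p for p in p_seq])
        assert score_sequence(seq, prof, m) == pytest.approx(expected, rel=1e-9)

    def test_context_specific_and_dsrna_representations(self):
        """The parameterization can express a loop-specific binder and a
        sequence-indifferent dsRNA binder."""
        rng = np.random.default_rng(8)
        alpha = plum_alphabet()
        # loop-specific: negative gamma except L
        gamma = np.full(4, -8.0)
        gamma[alpha.index("L")] = 4.0
        m_loop = make_model(4, theta=rng.normal(size=(4, 4)), gamma=gamma, alphabet=alpha)
        loop_prof = np.zeros((4, 4)); loop_prof[alpha.index("L")] = 1.0
        pair_prof = np.zeros((4, 4)); pair_prof[alpha.index("P")] = 1.0
        kmer = "ACGU"
        assert window_probability(kmer, loop_prof, m_loop) > 100 * window_probability(
            kmer, pair_prof, m_loop
        )
        # dsRNA binder: constant theta columns, large positive paired gamma
        gamma2 = np.full(4, -4.0)
        gamma2[alpha.index("P")] = 4.0
        m_ds = make_model(4, theta=np.full((4, 4), 0.3), gamma=gamma2, alphabet=alpha)
        assert window_probability("ACGU", pair_prof, m_ds) == pytest.approx(
            window_probability("GGGG", pair_prof, m_ds), rel=1e-12
        )
        assert window_probability("ACGU", pair_prof, m_ds) > window_probability(
            "ACGU", loop_prof, m_ds
        )


class TestAffinityMap:
    def test_trivial_lines(self):
        amap = AffinityMap(slope=2.0, intercept=-1.0)
        assert amap(0.0) == -1.0
        assert amap(0.75) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            AffinityMap(slope=0.0, intercept=0.0)

    def test_predict_affinity_monotone_in_score(self):
        rng = np.random.default_rng(2)
        m = random_model(rng, 4)
        amap = AffinityMap(slope=1.7, intercept=0.3)
        seqs = [random_rna(rng, 20) for _ in range(10)]
        profs = [random_profile(rng, 20) for _ in range(10)]
        scores = [score_sequence(s, p, m) for s, p in zip(seqs, profs)]
        preds = [predict_affinity(s, p, m, amap) for s, p in zip(seqs, profs)]
        order = np.argsort(scores)
        assert np.all(np.diff(np.array(preds)[order]) >= -1e-12)


class TestModelValidation:
    def test_shape_checks(self):
        with pytest.raises(ValueError):
            MotifModel(width=4, theta=np.zeros((4, 3)), gamma=np.zeros(4),
                       b_seq=0, b_str=0)
        with pytest.raises(ValueError):
            MotifModel(width=4, theta=np.zeros((4, 4)), gamma=np.zeros(3),
                       b_seq=0, b_str=0)
        with pytest.raises(ValueError):
            MotifModel(width=4, theta=np.full((4, 4), np.nan), gamma=np.zeros(4),
                       b_seq=0, b_str=0)
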