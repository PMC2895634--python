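"""Joint sequence + structural-context binding model.

A motif of width w is scored on a window by the product of two logistic
terms: a PWM-driven sequence term sigma(b_seq + sum_j theta[base_j, j]) and a
context term sigma(b_str + sum_j sum_a gamma[a] * pi[a, j]) driven by the
window's annotation profile slice pi.  A whole sequence is scored by noisy-OR
over its windows, N = 1 - prod_i (1 - p_i): the probability that at least one
window is bound.  Predicted affinity is an affine function of N with positive
slope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .alphabet import AnnotationAlphabet, plum_alphabet
from .structure import BASES, AnnotationProfile, encode

logger = logging.getLogger(__name__)

#: windows whose sequence-term logit exceeds this are clamped so that
#: 1 - p stays representable; keeps the noisy-OR log-domain product finite.
_P_MAX = 1.0 - 1e-12


@dataclass
class MotifModel:
    """Width-w binding model: PWM theta, context preferences gamma, biases.

    ``theta`` has shape (4, w), rows ordered A, C, G, U.  ``gamma`` has one
    entry per alphabet letter, shared across motif positions.  When
    ``mean_context`` is True the context logit averages over positions instead
    of summing (the two differ only by a rescaling of gamma at fixed width,
    but matter when comparing widths); the default is the sum.
    """

    width: int
    theta: np.ndarray
    gamma: np.ndarray
    b_seq: float
    b_str: float
    alphabet: AnnotationAlphabet = field(default_factory=plum_alphabet)
    mean_context: bool = False

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.width < 1:
            raise ValueError("width must be positive")
        if self.theta.shape != (4, self.width):
            raise ValueError(
                f"theta must be 4 x {self.width}, got {self.theta.shape}"
            )
        if self.gamma.shape != (len(self.alphabet),):
            raise ValueError(
                f"gamma must have {len(self.alphabet)} entries, got {self.gamma.shape}"
            )
        for name, arr in (("theta", self.theta), ("gamma", self.gamma)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
        if not (np.isfinite(self.b_seq) and np.isfinite(self.b_str)):
            raise ValueError("bias terms must be finite")

    @property
    def context_scale(self) -> float:
        """Multiplier applied to gamma in the context logit (w or 1)."""
        return 1.0 if self.mean_context else float(self.width)

    def context_weights(self) -> np.ndarray:
        """Per-position weight of the profile columns in the context logit."""
        return np.full(self.width, 1.0 / self.width if self.mean_context else 1.0)


@dataclass(frozen=True)
class AffinityMap:
    """Affine map from noisy-OR score N to predicted affinity."""

    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("slope must be positive")

    def __call__(self, n_score):
        return self.slope * np.asarray(n_score, dtype=float) + self.intercept


def sequence_term(kmer: str, model: MotifModel) -> float:
    """PWM logistic term for one k-mer in the ideal structural context."""
    codes = encode(kmer)
    if codes.size != model.width:
        raise ValueError(f"kmer length {codes.size} != width {model.width}")
    logit = model.b_seq + float(model.theta[codes, np.arange(model.width)].sum())
    return float(expit(logit))


def structure_term(window_profile: np.ndarray, model: MotifModel) -> float:
    """Context logistic term for one |A| x w profile slice."""
    pi = np.asarray(window_profile, dtype=float)
    if pi.shape != (len(model.alphabet), model.width):
        raise ValueError(
            f"window profile must be {len(model.alphabet)} x {model.width}, "
            f"got {pi.shape}"
        )
    logit = model.b_str + float(model.gamma @ (pi @ model.context_weights()))
    return float(expit(logit))


def pure_context_term(model: MotifModel, letter: str) -> float:
    """Context term of a hypothetical window entirely in context ``letter``."""
    g = model.gamma[model.alphabet.index(letter)]
    return float(expit(model.b_str + model.context_scale * g))


def window_probability(kmer: str, window_profile: np.ndarray, model: MotifModel) -> float:
    """Probability that the RBP binds this window: sequence x context term."""
    return sequence_term(kmer, model) * structure_term(window_profile, model)


def window_probabilities(
    seq: str, profile: AnnotationProfile, model: MotifModel
) -> np.ndarray:
    """Vector of binding probabilities for every width-w window of ``seq``.

    Windows containing a character outside ACGU contribute probability 0.
    """
    w = model.width
    n = len(seq)
    if n < w:
        raise ValueError(f"sequence of length {n} shorter than motif width {w}")
    if profile.alphabet.letters != model.alphabet.letters:
        raise ValueError(
            f"profile alphabet {profile.alphabet.name} does not match "
            f"model alphabet {model.alphabet.name}"
        )
    if profile.n != n:
        raise ValueError(f"profile length {profile.n} != sequence length {n}")
    codes = np.empty(n, dtype=np.int64)
    unknown = np.zeros(n, dtype=bool)
    for i, ch in enumerate(seq.upper()):
        ch = "U" if ch == "T" else ch
        if ch in BASES:
            codes[i] = BASES.index(ch)
        else:
            codes[i] = 0
            unknown[i] = True
    if unknown.any():
        logger.warning(
            "sequence contains %d non-ACGU characters; affected windows "
            "contribute probability 0",
            int(unknown.sum()),
        )
    n_win = n - w + 1
    offs = np.arange(w)
    win_codes = codes[np.arange(n_win)[:, None] + offs]
    x_seq = model.b_seq + model.theta[win_codes, offs].sum(axis=1)
    cw = model.context_weights()
    # windowed profile sums, weighted per position
    pw = np.stack(
        [profile.values[:, i : i + n_win] * cw[i] for i in range(w)]
    ).sum(axis=0)
    x_str = model.b_str + model.gamma @ pw
    p = expit(x_seq) * expit(x_str)
    valid = ~(unknown[np.arange(n_win)[:, None] + offs].any(axis=1))
    return np.where(valid, p, 0.0)


def score_sequence(seq: str, profile: AnnotationProfile, model: MotifModel) -> float:
    """Noisy-OR score N = 1 - prod_i (1 - p_i), accumulated in log domain."""
    p = np.minimum(window_probabilities(seq, profile, model), _P_MAX)
    return float(-np.expm1(np.log1p(-p).sum()))


def predict_affinity(
    seq: str, profile: AnnotationProfile, model: MotifModel, affinity_map: AffinityMap
) -> float:
    """Predicted affinity slope*N + intercept."""
    return float(affinity_map(score_sequence(seq, profile, model)))
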