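"""Interpretive outputs of a fitted model.

Three views: per-letter relative context-preference ratios (how much each
structural context scales binding relative to the best one), a per-position
preferred-context track derived from the top-scoring windows of a test set,
and a position-frequency matrix suitable for logo rendering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import MotifModel, pure_context_term, window_probabilities
from .records import RnaRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContextPreferenceReport:
    """Per-letter context term ratios relative to the preferred context."""

    letters: tuple[str, ...]
    gamma: tuple[float, ...]
    pure_terms: tuple[float, ...]
    ratios: tuple[float, ...]
    best_letter: str
    convention: str  # "sum" or "mean" context aggregation


def context_preference_ratios(model: MotifModel) -> ContextPreferenceReport:
    """Ratio of each letter's pure-context term to the best letter's.

    The pure-context term for letter a is the context term of a hypothetical
    window with probability one for a at every motif position.  The best
    letter's ratio is 1 by construction; all ratios lie in (0, 1].
    """
    letters = model.alphabet.letters
    terms = np.array([pure_context_term(model, a) for a in letters])
    best = int(np.argmax(terms))
    ratios = terms / terms[best]
    return ContextPreferenceReport(
        letters=letters,
        gamma=tuple(float(g) for g in model.gamma),
        pure_terms=tuple(float(t) for t in terms),
        ratios=tuple(float(r) for r in ratios),
        best_letter=letters[best],
        convention="mean" if model.mean_context else "sum",
    )


def preferred_context_track(
    model: MotifModel,
    records: Sequence[RnaRecord],
    top_n: int = 20,
) -> str:
    """Preferred context letter at each motif position, from top test windows.

    Ranks every width-w window of the supplied records by its binding
    probability, averages the annotation-profile slices of the ``top_n`` best
    windows, and reports the argmax letter per position (ties resolved toward
    the earlier letter in alphabet order; ranking ties toward the earlier
    record/window).
    """
    w = model.width
    entries = []  # (-p, record_index, window_start)
    for t, r in enumerate(records):
        if r.profile is None:
            raise ValueError(f"record {r.id} has no annotation profile")
        p = window_probabilities(r.seq, r.profile, model)
        for i, pi in enumerate(p):
            entries.append((-pi, t, i))
    entries.sort()
    if len(entries) < top_n:
        logger.warning(
            "only %d windows available; preferred-context track uses all of them",
            len(entries),
        )
    chosen = entries[:top_n]
    acc = np.zeros((len(model.alphabet), w))
    for _, t, i in chosen:
        acc += records[t].profile.values[:, i : i + w]
    acc /= len(chosen)
    return "".join(model.alphabet.letters[int(np.argmax(acc[:, j]))] for j in range(w))


def pfm_for_logo(model: MotifModel) -> np.ndarray:
    """Rescale the PWM to a 4 x w position frequency matrix (columns sum to 1).

    The PWM is uniformly rescaled by c > 0 chosen so the optimal site's
    sequence term becomes 0.5 (its rescaled logit is 0, the bias absorbing the
    shift); each rescaled column is then converted to frequencies with a
    softmax.  An all-zero PWM yields the uniform matrix.
    """
    theta = model.theta
    opt = float(theta.max(axis=0).sum())
    if opt == 0.0:
        if np.allclose(theta, 0.0):
            logger.info("all-zero PWM; emitting uniform frequencies")
        return np.full_like(theta, 0.25)
    if model.b_seq < 0:
        c = -model.b_seq / opt
        if c <= 0:  # pragma: no cover - opt<0 with negative bias
            c = 1.0
    else:
        # bias cannot be cancelled by a positive scale; keep the raw scale
        c = 1.0
    scaled = c * theta
    scaled = scaled - scaled.max(axis=0, keepdims=True)
    expd = np.exp(scaled)
    return expd / expd.sum(axis=0, keepdims=True)
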