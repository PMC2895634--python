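"""Evaluation protocol: labeling, AUC-PR, cross-validation, bootstrap, baselines.

Records are labeled "positive" when their measured affinity falls in the right
tail of the training distribution and "negative" when it falls below the
median; everything else is "other" and excluded from scoring.  Classification
accuracy is summarized by the area under the precision-recall curve, computed
as average precision (mean of precision at each positive's rank, with expected
precision inside tied-score blocks).  Significance of AUC-PR differences
between scorers is assessed with Wilcoxon's signed-rank test over bootstrap
resamples of the test set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .alphabet import single_letter_alphabet
from .records import RnaRecord
from .structure import BASES
from . import training as tr

logger = logging.getLogger(__name__)

POSITIVE, NEGATIVE, OTHER = "positive", "negative", "other"


@dataclass(frozen=True)
class PositiveRule:
    """How the right-tail 'positive' cutoff is chosen.

    kind 'quantile': positives are records at or above the given affinity
    quantile (default 0.995, i.e. the top 0.5%).  kind 'count': the top-k
    records.  kind 'threshold': an absolute affinity cutoff.
    """

    kind: str = "quantile"
    value: float = 0.995

    def cutoff(self, affinities: np.ndarray) -> float:
        n = affinities.size
        if self.kind == "threshold":
            return float(self.value)
        if self.kind == "count":
            k = int(self.value)
        elif self.kind == "quantile":
            k = max(1, int(round(n * (1.0 - self.value))))
        else:
            raise ValueError(f"unknown positive rule kind {self.kind!r}")
        if k >= n:
            raise ValueError("positive rule would label every record positive")
        return float(np.sort(affinities)[::-1][k - 1])


@dataclass
class LabeledSet:
    """Records plus their positive/negative/other labels."""

    records: list[RnaRecord]
    labels: list[str]
    positive_cutoff: float
    median_affinity: float

    def subset(self, label: str) -> list[RnaRecord]:
        return [r for r, lab in zip(self.records, self.labels) if lab == label]

    @property
    def n_positive(self) -> int:
        return self.labels.count(POSITIVE)

    @property
    def n_negative(self) -> int:
        return self.labels.count(NEGATIVE)

    def scored_subset(self):
        """(records, is_positive) over the positive+negative records only."""
        keep = [
            (r, lab == POSITIVE)
            for r, lab in zip(self.records, self.labels)
            if lab in (POSITIVE, NEGATIVE)
        ]
        return [r for r, _ in keep], np.array([p for _, p in keep], dtype=bool)


def label_records(
    records: Sequence[RnaRecord],
    positive_rule: PositiveRule | None = None,
) -> LabeledSet:
    """Assign positive/negative/other labels from measured affinities.

    Positives are at or above the rule's cutoff (ties inclusive); negatives
    are strictly below the median affinity.  The cutoff must exceed the
    median, otherwise the two rules would overlap.
    """
    positive_rule = positive_rule or PositiveRule()
    if len(records) < 3:
        raise ValueError("need at least 3 records to label")
    aff = np.array([r.affinity for r in records], dtype=float)
    if np.any(np.isnan(aff)):
        raise ValueError("records with missing affinity cannot be labeled")
    if np.ptp(aff) == 0:
        raise ValueError("degenerate affinity distribution (all values equal)")
    cutoff = positive_rule.cutoff(aff)
    med = float(np.median(aff))
    if cutoff <= med:
        raise ValueError(
            f"positive cutoff {cutoff:.6g} does not exceed the median "
            f"{med:.6g}; positive and negative rules would overlap"
        )
    labels = [
        POSITIVE if a >= cutoff else (NEGATIVE if a < med else OTHER) for a in aff
    ]
    return LabeledSet(
        records=list(records),
        labels=labels,
        positive_cutoff=cutoff,
        median_affinity=med,
    )


@dataclass(frozen=True)
class PRResult:
    """Area under the precision-recall curve plus the curve itself."""

    auc_pr: float
    curve: tuple[tuple[float, float], ...]
    n_pos: int
    n_neg: int


def average_precision(scores, is_positive) -> PRResult:
    """AUC-PR as average precision with grouped ties.

    Items are ranked by descending score.  AP is the mean over positives of
    the precision at that positive's rank; within a block of tied scores the
    positives are treated as evenly interleaved, so precision is evaluated at
    fractional depths n_prev + (j/p) * b for the j-th of p positives in a
    block of b items.  Random scores therefore give AP equal to the positive
    fraction in expectation (exactly, when all scores tie).
    """
    scores = np.asarray(scores, dtype=float)
    is_positive = np.asarray(is_positive, dtype=bool)
    n_pos = int(is_positive.sum())
    n_neg = int((~is_positive).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("average precision needs at least one of each class")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    p_sorted = is_positive[order]
    ap = 0.0
    curve = [(0.0, 1.0)]
    i = 0
    n = scores.size
    tp_prev = 0.0
    n_prev = 0.0
    while i < n:
        j = i
        while j < n and s_sorted[j] == s_sorted[i]:
            j += 1
        b = j - i
        p = int(p_sorted[i:j].sum())
        if p > 0:
            for k in range(1, p + 1):
                depth = n_prev + (k / p) * b
                ap += (tp_prev + k) / depth
        tp_prev += p
        n_prev += b
        curve.append((tp_prev / n_pos, tp_prev / n_prev))
        i = j
    return PRResult(
        auc_pr=ap / n_pos,
        curve=tuple(curve),
        n_pos=n_pos,
        n_neg=n_neg,
    )


@dataclass
class FoldResult:
    """One cross-validation fold: the selected model and its test AUC-PR."""

    selected: tr.FitResult
    test_pr: PRResult
    test_scores: np.ndarray
    test_is_positive: np.ndarray


@dataclass
class CrossfoldResult:
    folds: list[FoldResult]

    @property
    def mean_test_auc_pr(self) -> float:
        return float(np.mean([f.test_pr.auc_pr for f in self.folds]))


def _run_fold(
    train: Sequence[RnaRecord],
    test: Sequence[RnaRecord],
    config: tr.TrainingConfig,
    positive_rule: PositiveRule | None,
    alphabet=None,
) -> FoldResult:
    train_labeled = label_records(train, positive_rule)
    results = tr.fit_scan(train, config, alphabet=alphabet)
    selected = tr.select_model(results, train_labeled.records, train_labeled.labels)
    test_labeled = label_records(test, positive_rule)
    recs, is_pos = test_labeled.scored_subset()
    scores = tr.score_records(recs, selected.model)
    pr = average_precision(scores, is_pos)
    return FoldResult(
        selected=selected, test_pr=pr, test_scores=scores, test_is_positive=is_pos
    )


def crossfold(
    pool_a: Sequence[RnaRecord],
    pool_b: Sequence[RnaRecord],
    config: tr.TrainingConfig,
    positive_rule: PositiveRule | None = None,
    alphabet=None,
) -> CrossfoldResult:
    """Two-fold cross-validation: train on one designed half-pool, test on the
    other, then swap.  Labels and model selection use only the training fold;
    test AUC-PR is computed on the test fold's positives and negatives.
    """
    ids_a = {r.id for r in pool_a}
    overlap = [r.id for r in pool_b if r.id in ids_a]
    if overlap:
        raise ValueError(f"pools are not disjoint; shared ids include {overlap[:3]}")
    folds = [
        _run_fold(pool_a, pool_b, config, positive_rule, alphabet),
        _run_fold(pool_b, pool_a, config, positive_rule, alphabet),
    ]
    return CrossfoldResult(folds=folds)


@dataclass
class BootstrapComparison:
    """Pairwise bootstrap comparison of two scorers on one labeled test set."""

    name_a: str
    name_b: str
    wins_a: int
    wins_b: int
    wilcoxon_p: float
    ci_low: float
    ci_high: float
    mean_auc_a: float
    mean_auc_b: float
    auc_a: np.ndarray = field(repr=False, default=None)
    auc_b: np.ndarray = field(repr=False, default=None)


def bootstrap_compare(
    is_positive,
    scorers: dict[str, np.ndarray],
    n_boot: int = 1000,
    seed: int = 0,
    retry_cap: int = 100,
) -> list[BootstrapComparison]:
    """Bootstrap AUC-PR comparison between scorers on one labeled test set.

    ``scorers`` maps a name to a per-record score vector.  Records are
    resampled with replacement ``n_boot`` times; replicates missing a class
    are redrawn (logged) up to ``retry_cap`` attempts each.  For each pair of
    scorers, reports win/loss counts, Wilcoxon's signed-rank p-value over the
    paired replicate AUC-PRs, and the 2.5/97.5 percentile CI of the AUC-PR
    difference.  Bit-reproducible for a fixed seed.
    """
    if len(scorers) < 2:
        raise ValueError("need at least two scorers to compare")
    is_positive = np.asarray(is_positive, dtype=bool)
    n = is_positive.size
    names = list(scorers)
    mats = {k: np.asarray(v, dtype=float) for k, v in scorers.items()}
    for k, v in mats.items():
        if v.shape != (n,):
            raise ValueError(f"scorer {k!r} has {v.shape[0]} scores for {n} records")
    rng = np.random.default_rng(seed)
    aucs = {k: np.empty(n_boot) for k in names}
    n_retries = 0
    for b in range(n_boot):
        for attempt in range(retry_cap):
            idx = rng.integers(0, n, size=n)
            pos = is_positive[idx]
            if pos.any() and (~pos).any():
                break
            n_retries += 1
        else:
            raise RuntimeError(
                f"could not draw a two-class bootstrap replicate in {retry_cap} tries"
            )
        for k in names:
            aucs[k][b] = average_precision(mats[k][idx], pos).auc_pr
    if n_retries:
        logger.info("redrew %d one-class bootstrap replicates", n_retries)
    out = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, bname = names[i], names[j]
            diff = aucs[a] - aucs[bname]
            wins_a = int((diff > 0).sum())
            wins_b = int((diff < 0).sum())
            if np.allclose(diff, 0.0):
                p = 1.0
            else:
                p = float(stats.wilcoxon(aucs[a], aucs[bname]).pvalue)
            lo, hi = np.percentile(diff, [2.5, 97.5])
            out.append(
                BootstrapComparison(
                    name_a=a,
                    name_b=bname,
                    wins_a=wins_a,
                    wins_b=wins_b,
                    wilcoxon_p=p,
                    ci_low=float(lo),
                    ci_high=float(hi),
                    mean_auc_a=float(aucs[a].mean()),
                    mean_auc_b=float(aucs[bname].mean()),
                    auc_a=aucs[a],
                    auc_b=aucs[bname],
                )
            )
    return out


@dataclass
class AblationResult:
    """Full-alphabet vs single-letter (structure-naive) comparison."""

    full: FoldResult
    naive: FoldResult

    @property
    def auc_gain(self) -> float:
        return self.full.test_pr.auc_pr - self.naive.test_pr.auc_pr


def ablation_single_letter(
    train: Sequence[RnaRecord],
    test: Sequence[RnaRecord],
    config: tr.TrainingConfig,
    positive_rule: PositiveRule | None = None,
) -> AblationResult:
    """Train the model and its structure-naive variant under one protocol.

    The naive variant collapses every context letter into one, so its context
    term is a per-width constant and only the PWM carries signal.  Both
    variants share widths, restarts, seeds and the selection rule; both are
    evaluated on the same test positives/negatives.
    """
    full = _run_fold(train, test, config, positive_rule)
    naive_alpha = single_letter_alphabet()
    collapse = lambda recs: [
        r.with_profile(r.profile.collapse_to(naive_alpha)) for r in recs
    ]
    naive = _run_fold(
        collapse(train), collapse(test), config, positive_rule, alphabet=naive_alpha
    )
    return AblationResult(full=full, naive=naive)


# ---------------------------------------------------------------------------
# fully-specified k-mer baseline
# ---------------------------------------------------------------------------

def _kmer_codes(seq: str, k: int) -> np.ndarray:
    """Integer code of every k-mer window; -1 where a window has non-ACGU."""
    s = seq.upper().replace("T", "U")
    codes = np.array([BASES.index(c) if c in BASES else -1 for c in s], dtype=np.int64)
    n_win = len(s) - k + 1
    if n_win < 1:
        raise ValueError(f"sequence of length {len(s)} shorter than k={k}")
    win = codes[np.arange(n_win)[:, None] + np.arange(k)]
    bad = (win < 0).any(axis=1)
    vals = (win * (4 ** np.arange(k - 1, -1, -1))).sum(axis=1)
    vals[bad] = -1
    return vals


def kmer_baseline_train(
    records: Sequence[RnaRecord],
    k: int = 7,
    trim_fraction: float = 0.05,
) -> np.ndarray:
    """Affinity table over all 4^k k-mers from (weakly structured) records.

    Each k-mer's affinity is the trimmed mean (``trim_fraction`` cut from each
    tail) of the affinities of the training sequences containing it; a
    sequence counts once per k-mer it contains.  K-mers never observed get the
    global median affinity (their count is logged).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    per_kmer: dict[int, list[float]] = {}
    all_aff = []
    for r in records:
        if r.affinity is None:
            raise ValueError(f"record {r.id} has no affinity")
        all_aff.append(r.affinity)
        for code in set(int(c) for c in _kmer_codes(r.seq, k) if c >= 0):
            per_kmer.setdefault(code, []).append(r.affinity)
    table = np.full(4**k, float(np.median(all_aff)))
    for code, vals in per_kmer.items():
        table[code] = stats.trim_mean(vals, trim_fraction)
    n_unseen = 4**k - len(per_kmer)
    if n_unseen:
        logger.info(
            "%d of %d %d-mers unseen in training; assigned the global median",
            n_unseen, 4**k, k,
        )
    return table


def kmer_baseline_score(seq: str, table: np.ndarray, k: int = 7) -> float:
    """Mean of the table affinities over every k-mer window of ``seq``."""
    codes = _kmer_codes(seq, k)
    codes = codes[codes >= 0]
    if codes.size == 0:
        raise ValueError("sequence has no ACGU-only window of length k")
    return float(table[codes].mean())
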