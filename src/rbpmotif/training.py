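"""Model fitting: regularized least squares via box-constrained quasi-Newton.

The fitted quantity is the squared error between measured affinities y_t and
predicted affinities slope * N_t + intercept, where N_t is the noisy-OR score
of record t, plus a ridge penalty lambda * (||theta||^2 + ||gamma||^2 +
b_seq^2 + b_str^2) that removes the shift indeterminacy between PWM columns
and the sequence bias.  The slope and intercept of the affinity line are not
penalized.  Optimization uses L-BFGS-B with the slope bounded below by a small
positive constant so predicted affinity increases with the score.

The scan protocol mirrors standard practice for this family of models: widths
are fitted in ascending order with several random restarts each; for widths
above the minimum, two restarts are seeded from the previous width's best PWM
padded with a zero column on the left and on the right, and the rest are drawn
uniformly from [-init_range, +init_range].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .alphabet import AnnotationAlphabet, plum_alphabet
from .model import AffinityMap, MotifModel, _P_MAX
from .records import GROUP_WEAK, RnaRecord

logger = logging.getLogger(__name__)

SUBSET_FULL = "full"
SUBSET_WEAK = "weak"


@dataclass
class TrainingConfig:
    """Knobs of the fitting protocol; defaults follow the standard scan."""

    widths: tuple[int, ...] = tuple(range(4, 13))
    restarts_per_width: int = 10
    lambda_reg: float = 0.01
    init_range: float = 0.05
    slope_lower_bound: float = 1e-6
    gtol: float = 1e-6
    maxiter: int = 500
    base_seed: int = 0
    subsets: tuple[str, ...] = (SUBSET_FULL, SUBSET_WEAK)
    mean_context: bool = False

    def __post_init__(self) -> None:
        self.widths = tuple(sorted(self.widths))
        if self.restarts_per_width < 1:
            raise ValueError("restarts_per_width must be >= 1")
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be >= 0")
        if self.slope_lower_bound <= 0:
            raise ValueError("slope_lower_bound must be positive")
        for s in self.subsets:
            if s not in (SUBSET_FULL, SUBSET_WEAK):
                raise ValueError(f"unknown subset {s!r}")

    def restart_seed(self, width: int, restart: int) -> int:
        """Auditable per-restart seed."""
        return self.base_seed + width * 1000 + restart


@dataclass
class FitResult:
    """Outcome of one fit (or the best of several restarts)."""

    model: MotifModel
    affinity_map: AffinityMap
    objective: float
    converged: bool
    width: int
    restart: int
    subset: str
    seed: int
    train_auc_pr: Optional[float] = None


class Batch:
    """Vectorized view of (sequence, profile, affinity) data at one width.

    Flattens every valid width-w window of every record into index arrays so
    the objective and gradient are a handful of NumPy operations.  Windows
    containing non-ACGU characters are dropped (they contribute probability 0
    and no gradient).
    """

    def __init__(
        self,
        records: Sequence[RnaRecord],
        width: int,
        alphabet: AnnotationAlphabet,
        mean_context: bool = False,
        require_affinity: bool = True,
    ):
        from .structure import BASES

        if not records:
            raise ValueError("no records supplied")
        too_short = [r.id for r in records if len(r.seq) < width]
        if too_short:
            raise ValueError(
                f"motif width {width} exceeds sequence length for records: "
                f"{too_short[:5]}{'...' if len(too_short) > 5 else ''}"
            )
        self.width = width
        self.alphabet = alphabet
        self.n_letters = len(alphabet)
        self.n_records = len(records)
        w = width
        offs = np.arange(w)
        cw = np.full(w, 1.0 / w) if mean_context else np.ones(w)
        idx_chunks, pw_chunks, rec_chunks = [], [], []
        y = np.empty(len(records))
        for t, r in enumerate(records):
            if require_affinity:
                if r.affinity is None:
                    raise ValueError(f"record {r.id} has no affinity")
                y[t] = r.affinity
            if r.profile is None:
                raise ValueError(f"record {r.id} has no annotation profile")
            if r.profile.alphabet.letters != alphabet.letters:
                raise ValueError(
                    f"record {r.id} profile alphabet {r.profile.alphabet.name} "
                    f"!= batch alphabet {alphabet.name}"
                )
            seq = r.seq.upper().replace("T", "U")
            codes = np.array(
                [BASES.index(c) if c in BASES else -1 for c in seq], dtype=np.int64
            )
            n_win = len(seq) - w + 1
            win = np.arange(n_win)[:, None] + offs
            wc = codes[win]
            valid = ~(wc < 0).any(axis=1)
            if not valid.all():
                logger.warning(
                    "record %s: %d windows skipped (non-ACGU)", r.id,
                    int((~valid).sum()),
                )
            wc = wc[valid]
            idx_chunks.append(wc * w + offs)
            pv = r.profile.values
            pw = np.zeros((n_win, self.n_letters))
            for j in range(w):
                pw += pv[:, j : j + n_win].T * cw[j]
            pw_chunks.append(pw[valid])
            rec_chunks.append(np.full(int(valid.sum()), t, dtype=np.int64))
        self.y = y if require_affinity else None
        self.idx = np.concatenate(idx_chunks)
        self.pw = np.concatenate(pw_chunks)
        self.rec = np.concatenate(rec_chunks)
        self.n_theta = 4 * w

    # -- parameter packing ------------------------------------------------
    def pack(self, model: MotifModel, affinity_map: AffinityMap) -> np.ndarray:
        return np.concatenate(
            [
                model.theta.ravel(),
                model.gamma,
                [model.b_seq, model.b_str, affinity_map.slope, affinity_map.intercept],
            ]
        )

    def unpack(self, x: np.ndarray, mean_context: bool = False):
        w = self.width
        theta = x[: 4 * w].reshape(4, w)
        gamma = x[4 * w : 4 * w + self.n_letters]
        b_seq, b_str, slope, intercept = x[4 * w + self.n_letters :]
        model = MotifModel(
            width=w,
            theta=theta.copy(),
            gamma=gamma.copy(),
            b_seq=float(b_seq),
            b_str=float(b_str),
            alphabet=self.alphabet,
            mean_context=mean_context,
        )
        return model, AffinityMap(slope=float(max(slope, 1e-300)), intercept=float(intercept))

    # -- forward and backward passes --------------------------------------
    def scores(self, x: np.ndarray) -> np.ndarray:
        """Noisy-OR score N_t for every record at parameter vector x."""
        nt, nl = self.n_theta, self.n_letters
        theta_flat = x[:nt]
        gamma = x[nt : nt + nl]
        b_seq, b_str = x[nt + nl], x[nt + nl + 1]
        xs = b_seq + theta_flat[self.idx].sum(axis=1)
        xt = b_str + self.pw @ gamma
        p = np.minimum(expit(xs) * expit(xt), _P_MAX)
        s = np.bincount(self.rec, weights=np.log1p(-p), minlength=self.n_records)
        return -np.expm1(s)

    def value_and_grad(self, x: np.ndarray, lam: float):
        nt, nl = self.n_theta, self.n_letters
        theta_flat = x[:nt]
        gamma = x[nt : nt + nl]
        b_seq, b_str, slope, intercept = x[nt + nl :]
        xs = b_seq + theta_flat[self.idx].sum(axis=1)
        xt = b_str + self.pw @ gamma
        ps = expit(xs)
        pt = expit(xt)
        p = np.minimum(ps * pt, _P_MAX)
        l1p = np.log1p(-p)
        s = np.bincount(self.rec, weights=l1p, minlength=self.n_records)
        n_score = -np.expm1(s)
        r = slope * n_score + intercept - self.y
        reg = theta_flat @ theta_flat + gamma @ gamma + b_seq**2 + b_str**2
        f = float(r @ r + lam * reg)
        # backward
        g_n = 2.0 * slope * r
        # d N_t / d p_i = prod_{k != i} (1 - p_k) = exp(S_t - log(1-p_i))
        gp = g_n[self.rec] * np.exp(s[self.rec] - l1p)
        gxs = gp * pt * ps * (1.0 - ps)
        gxt = gp * ps * pt * (1.0 - pt)
        g = np.empty_like(x)
        g[:nt] = np.bincount(
            self.idx.ravel(),
            weights=np.repeat(gxs, self.width),
            minlength=nt,
        ) + 2.0 * lam * theta_flat
        g[nt : nt + nl] = self.pw.T @ gxt + 2.0 * lam * gamma
        g[nt + nl] = gxs.sum() + 2.0 * lam * b_seq
        g[nt + nl + 1] = gxt.sum() + 2.0 * lam * b_str
        g[nt + nl + 2] = 2.0 * (r @ n_score)
        g[nt + nl + 3] = 2.0 * r.sum()
        return f, g


def objective(
    x: np.ndarray,
    batch: Batch,
    lambda_reg: float,
) -> float:
    """Regularized least-squares objective at packed parameter vector ``x``."""
    f, _ = batch.value_and_grad(np.asarray(x, dtype=float), lambda_reg)
    return f


def gradient(x: np.ndarray, batch: Batch, lambda_reg: float) -> np.ndarray:
    """Analytic gradient of :func:`objective` with respect to ``x``."""
    _, g = batch.value_and_grad(np.asarray(x, dtype=float), lambda_reg)
    return g


def initial_parameter_sets(
    width: int,
    previous_best_theta: Optional[np.ndarray],
    restarts: int,
    init_range: float,
    seed: int,
    n_letters: int,
    slope_lower_bound: float = 1e-6,
) -> list[np.ndarray]:
    """Packed initializations for one width.

    When a previous width's best PWM is available, the first two
    initializations reuse it padded with a zero column on the left and right;
    every other entry (and all entries of the remaining restarts) is sampled
    uniformly from [-init_range, +init_range], with the slope clamped up to
    the lower bound.
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    rng = np.random.default_rng(seed)
    n_params = 4 * width + n_letters + 4
    inits = []
    for k in range(restarts):
        x = rng.uniform(-init_range, init_range, size=n_params)
        if previous_best_theta is not None and k < 2:
            prev = np.asarray(previous_best_theta, dtype=float)
            if prev.shape != (4, width - 1):
                raise ValueError(
                    f"previous theta has shape {prev.shape}, expected (4, {width - 1})"
                )
            zero = np.zeros((4, 1))
            padded = np.hstack([zero, prev]) if k == 0 else np.hstack([prev, zero])
            x[: 4 * width] = padded.ravel()
        x[-2] = max(x[-2], slope_lower_bound)  # slope
        inits.append(x)
    return inits


def fit_single(
    data: Sequence[RnaRecord] | Batch,
    width: int,
    init_params: np.ndarray,
    config: TrainingConfig,
    restart: int = 0,
    subset: str = SUBSET_FULL,
    seed: int = 0,
    alphabet: Optional[AnnotationAlphabet] = None,
) -> FitResult:
    """One box-constrained quasi-Newton run from a given initialization.

    The slope is constrained to [slope_lower_bound, +inf); all other
    parameters are unbounded.  Optimizer failure is reported via the
    ``converged`` flag, never raised.
    """
    if isinstance(data, Batch):
        batch = data
    else:
        alphabet = alphabet or (data[0].profile.alphabet if data[0].profile else plum_alphabet())
        batch = Batch(data, width, alphabet, mean_context=config.mean_context)
    x0 = np.asarray(init_params, dtype=float).copy()
    x0[-2] = max(x0[-2], config.slope_lower_bound)
    n_params = x0.size
    bounds = [(None, None)] * n_params
    bounds[-2] = (config.slope_lower_bound, None)
    converged = True
    try:
        res = minimize(
            batch.value_and_grad,
            x0,
            args=(config.lambda_reg,),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": config.maxiter, "gtol": config.gtol},
        )
        x_best, f_best = res.x, float(res.fun)
        converged = bool(res.success)
    except Exception as exc:  # pragma: no cover - optimizer pathologies
        logger.warning("optimizer failure at width %d restart %d: %s", width, restart, exc)
        x_best, _ = x0, None
        f_best, _ = batch.value_and_grad(x0, config.lambda_reg)
        converged = False
    f0, _ = batch.value_and_grad(x0, config.lambda_reg)
    if f_best > f0:  # descent contract: never return worse than the init
        x_best, f_best = x0, f0
    model, amap = batch.unpack(x_best, mean_context=config.mean_context)
    return FitResult(
        model=model,
        affinity_map=amap,
        objective=f_best,
        converged=converged,
        width=width,
        restart=restart,
        subset=subset,
        seed=seed,
    )


def _subset_records(records: Sequence[RnaRecord], subset: str) -> list[RnaRecord]:
    if subset == SUBSET_FULL:
        return list(records)
    filtered = [r for r in records if r.group == GROUP_WEAK]
    if not filtered:
        raise ValueError(
            "subset 'weak' requested but no records carry the "
            f"{GROUP_WEAK!r} group tag"
        )
    return filtered


def fit_scan(
    records: Sequence[RnaRecord],
    config: TrainingConfig,
    alphabet: Optional[AnnotationAlphabet] = None,
) -> list[FitResult]:
    """Best-of-restarts fit for every width x training-subset combination.

    Widths are processed in ascending order; each subset's best PWM at width w
    seeds two of the restarts at width w+1 (zero-column padding).
    """
    alphabet = alphabet or (
        records[0].profile.alphabet if records and records[0].profile else plum_alphabet()
    )
    results: list[FitResult] = []
    for subset in config.subsets:
        sub = _subset_records(records, subset)
        prev_theta: Optional[np.ndarray] = None
        for width in config.widths:
            try:
                batch = Batch(sub, width, alphabet, mean_context=config.mean_context)
            except ValueError as exc:
                logger.warning("width %d subset %s skipped: %s", width, subset, exc)
                continue
            inits = initial_parameter_sets(
                width,
                prev_theta,
                config.restarts_per_width,
                config.init_range,
                config.restart_seed(width, 0),
                len(alphabet),
                config.slope_lower_bound,
            )
            best: Optional[FitResult] = None
            for k, x0 in enumerate(inits):
                fit = fit_single(
                    batch,
                    width,
                    x0,
                    config,
                    restart=k,
                    subset=subset,
                    seed=config.restart_seed(width, k),
                )
                logger.debug(
                    "width %d subset %s restart %d: objective %.6g",
                    width, subset, k, fit.objective,
                )
                if best is None or fit.objective < best.objective:
                    best = fit
            if best is None:  # pragma: no cover
                logger.warning("all restarts failed at width %d subset %s", width, subset)
                continue
            results.append(best)
            prev_theta = best.model.theta
    return results


def score_records(
    records: Sequence[RnaRecord], model: MotifModel
) -> np.ndarray:
    """Noisy-OR scores of many records under one model (vectorized)."""
    batch = Batch(
        records,
        model.width,
        model.alphabet,
        mean_context=model.mean_context,
        require_affinity=False,
    )
    x = batch.pack(model, AffinityMap(slope=1.0, intercept=0.0))
    return batch.scores(x)


def select_model(
    results: Sequence[FitResult],
    labeled_records: Sequence[RnaRecord],
    labels: Sequence[str],
) -> FitResult:
    """Pick the candidate with the best training AUC-PR.

    ``labeled_records``/``labels`` are the training-set records annotated
    "positive"/"negative" (others ignored).  Ties break toward the smaller
    width, then the full training subset.
    """
    from .evaluation import average_precision

    if not results:
        raise ValueError("no fit results to select from")
    keep = [
        (r, lab)
        for r, lab in zip(labeled_records, labels)
        if lab in ("positive", "negative")
    ]
    if not keep:
        raise ValueError("no positive/negative records for model selection")
    recs = [r for r, _ in keep]
    is_pos = np.array([lab == "positive" for _, lab in keep])
    scored: list[FitResult] = []
    for res in results:
        scores = score_records(recs, res.model)
        pr = average_precision(scores, is_pos)
        scored.append(replace(res, train_auc_pr=pr.auc_pr))
    scored.sort(
        key=lambda r: (
            -r.train_auc_pr,
            r.width,
            0 if r.subset == SUBSET_FULL else 1,
        )
    )
    return scored[0]
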