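"""Objective, gradient, optimizer and the width-scan protocol."""

import numpy as np
import pytest

from rbpmotif import (
    AffinityMap,
    PoolDesign,
    RnaRecord,
    TrainingConfig,
    default_ground_truth,
    fit_scan,
    fit_single,
    initial_parameter_sets,
    make_pool,
    plum_alphabet,
    score_records,
    score_sequence,
    select_model,
)
from rbpmotif.training import Batch, gradient, objective

from conftest import random_rna
from test_model import random_model, random_profile


def synthetic_records(rng, n, length=30, alphabet=None):
    alphabet = alphabet or plum_alphabet()
    out = []
    for i in range(n):
        seq = random_rna(rng, length)
        prof = random_profile(rng, length, alphabet)
        out.append(
            RnaRecord(id=f"r{i}", seq=seq, affinity=float(rng.normal()), profile=prof)
        )
    return out


def straight_line_objective(x, records, width, lam, alphabet):
    """Independent re-implementation: per-record python loop, no batching."""
    batch = Batch(records, width, alphabet)  # only for unpack
    model, amap = batch.unpack(x)
    total = 0.0
    for r in records:
        n = score_sequence(r.seq, r.profile, model)
        total += (amap.slope * n + amap.intercept - r.affinity) ** 2
    theta, gamma = model.theta, model.gamma
    total += lam * (
        float((theta**2).sum()) + float((gamma**2).sum())
        + model.b_seq**2 + model.b_str**2
    )
    return total


class TestObjective:
    def test_perfect_fit_is_zero(self):
        rng = np.random.default_rng(0)
        recs = synthetic_records(rng, 10)
        batch = Batch(recs, 4, plum_alphabet())
        model = random_model(rng, 4)
        amap = AffinityMap(slope=1.3, intercept=0.2)
        x = batch.pack(model, amap)
        # set affinities to the model's own predictions
        preds = amap(batch.scores(x))
        for r, p in zip(recs, preds):
            r.affinity = float(p)
        batch2 = Batch(recs, 4, plum_alphabet())
        assert objective(x, batch2, 0.0) == pytest.approx(0.0, abs=1e-18)

    def test_single_record_squared_residual(self):
        rng = np.random.default_rng(1)
        recs = synthetic_records(rng, 1)
        batch = Batch(recs, 4, plum_alphabet())
        model = random_model(rng, 4)
        amap = AffinityMap(slope=1.0, intercept=0.0)
        x = batch.pack(model, amap)
        pred = float(amap(batch.scores(x))[0])
        recs[0].affinity = pred - 2.0
        batch = Batch(recs, 4, plum_alphabet())
        assert objective(x, batch, 0.0) == pytest.approx(4.0, rel=1e-10)

    def test_matches_straight_line_reimplementation(self):
        rng = np.random.default_rng(2)
        recs = synthetic_records(rng, 50)
        alpha = plum_alphabet()
        batch = Batch(recs, 5, alpha)
        for _ in range(5):
            x = rng.uniform(-1, 1, size=4 * 5 + 4 + 4)
            x[-2] = abs(x[-2]) + 0.1
            assert objective(x, batch, 0.01) == pytest.approx(
                straight_line_objective(x, recs, 5, 0.01, alpha), rel=1e-9
            )

    def test_width_longer_than_sequence_lists_records(self):
        recs = [RnaRecord(id="short1", seq="ACGU", affinity=0.0,
                          profile=random_profile(np.random.default_rng(0), 4))]
        with pytest.raises(ValueError, match="short1"):
            Batch(recs, 6, plum_alphabet())


class TestGradient:
    def test_penalty_gradient_quadratic(self):
        rng = np.random.default_rng(3)
        recs = synthetic_records(rng, 5)
        batch = Batch(recs, 4, plum_alphabet())
        lam = 0.25
        x = np.zeros(4 * 4 + 4 + 4)
        x[-2] = 1.0  # slope
        x[0] = 3.0  # one theta entry
        g_with = gradient(x, batch, lam)
        g_without = gradient(x, batch, 0.0)
        assert g_with[0] - g_without[0] == pytest.approx(2 * lam * 3.0, rel=1e-9)

    def test_matches_central_finite_differences(self):
        rng = np.random.default_rng(4)
        recs = synthetic_records(rng, 30)
        batch = Batch(recs, 5, plum_alphabet())
        h = 1e-6
        for _ in range(5):
            x = rng.uniform(-0.8, 0.8, size=4 * 5 + 4 + 4)
            x[-2] = abs(x[-2]) + 0.1
            g = gradient(x, batch, 0.01)
            for i in rng.choice(x.size, size=8, replace=False):
                xp, xm = x.copy(), x.copy()
                xp[i] += h
                xm[i] -= h
                fd = (objective(xp, batch, 0.01) - objective(xm, batch, 0.01)) / (2 * h)
                assert abs(fd - g[i]) / max(abs(fd), abs(g[i]), 1e-8) < 1e-4

    def test_zero_gradient_at_perfect_fit(self):
        rng = np.random.default_rng(5)
        recs = synthetic_records(rng, 10)
        batch = Batch(recs, 4, plum_alphabet())
        model = random_model(rng, 4)
        amap = AffinityMap(slope=1.0, intercept=0.0)
        x = batch.pack(model, amap)
        preds = amap(batch.scores(x))
        for r, p in zip(recs, preds):
            r.affinity = float(p)
        batch = Batch(recs, 4, plum_alphabet())
        g = gradient(x, batch, 0.0)
        assert np.max(np.abs(g)) < 1e-10


class TestColumnShiftDegeneracy:
    def test_unpenalized_invariance_and_penalized_preference(self):
        """Adding c to one PWM column and subtracting c from b_seq leaves all
        scores unchanged; the ridge penalty prefers the centered version."""
        rng = np.random.default_rng(6)
        recs = synthetic_records(rng, 20)
        batch = Batch(recs, 4, plum_alphabet())
        x = rng.uniform(-0.5, 0.5, size=4 * 4 + 4 + 4)
        x[-2] = 1.0
        c = 0.7
        x_shift = x.copy()
        x_shift[0 * 4 + 2] += c  # theta[A, col 2]
        x_shift[1 * 4 + 2] += c
        x_shift[2 * 4 + 2] += c
        x_shift[3 * 4 + 2] += c
        x_shift[4 * 4 + 4] -= c  # b_seq
        assert objective(x, batch, 0.0) == pytest.approx(
            objective(x_shift, batch, 0.0), rel=1e-10
        )
        assert objective(x_shift, batch, 0.01) > objective(x, batch, 0.01)


class TestInitialParameterSets:
    def test_minimum_width_all_random_within_range(self):
        inits = initial_parameter_sets(4, None, 10, 0.05, seed=1, n_letters=4)
        assert len(inits) == 10
        for x in inits:
            assert x.size == 4 * 4 + 4 + 4
            assert np.all(np.abs(x[:-2]) <= 0.05)
            assert x[-2] >= 1e-6  # slope clamped positive

    def test_padding_parent_left_and_right(self):
        parent = np.arange(12, dtype=float).reshape(4, 3)
        inits = initial_parameter_sets(4, parent, 5, 0.05, seed=2, n_letters=4)
        t0 = inits[0][: 4 * 4].reshape(4, 4)
        t1 = inits[1][: 4 * 4].reshape(4, 4)
        assert np.array_equal(t0[:, 1:], parent) and np.all(t0[:, 0] == 0.0)
        assert np.array_equal(t1[:, :3], parent) and np.all(t1[:, 3] == 0.0)
        # the rest are fully random
        assert np.all(np.abs(inits[2][: 4 * 4]) <= 0.05)

    def test_same_seed_identical(self):
        a = initial_parameter_sets(5, None, 4, 0.05, seed=9, n_letters=4)
        b = initial_parameter_sets(5, None, 4, 0.05, seed=9, n_letters=4)
        for xa, xb in zip(a, b):
            assert np.array_equal(xa, xb)


class TestFitSingle:
    def test_descent_contract(self):
        rng = np.random.default_rng(7)
        recs = synthetic_records(rng, 30)
        cfg = TrainingConfig(widths=(4,), restarts_per_width=1, subsets=("full",))
        x0 = initial_parameter_sets(4, None, 1, 0.05, seed=3, n_letters=4)[0]
        batch = Batch(recs, 4, plum_alphabet())
        fit = fit_single(batch, 4, x0, cfg)
        f0 = objective(x0, batch, cfg.lambda_reg)
        assert fit.objective <= f0 + 1e-12
        assert fit.affinity_map.slope >= cfg.slope_lower_bound

    def test_init_at_optimum_stays_near(self):
        rng = np.random.default_rng(8)
        recs = synthetic_records(rng, 15)
        model = random_model(rng, 4)
        amap = AffinityMap(slope=1.0, intercept=0.1)
        batch = Batch(recs, 4, plum_alphabet())
        x_star = batch.pack(model, amap)
        preds = amap(batch.scores(x_star))
        for r, p in zip(recs, preds):
            r.affinity = float(p)
        batch = Batch(recs, 4, plum_alphabet())
        cfg = TrainingConfig(widths=(4,), restarts_per_width=1, lambda_reg=0.0,
                             subsets=("full",))
        fit = fit_single(batch, 4, x_star, cfg)
        assert fit.objective <= objective(x_star, batch, 0.0) + 1e-12

    def test_noiseless_generative_recovery(self):
        """Fitting noise-free data from a known model recovers its ranking."""
        design = PoolDesign(n_stemloop=120, n_weak=120)
        truth = default_ground_truth(noise_sd=0.0)
        recs, _ = make_pool(design, truth, seed=77, n_samples=200)
        cfg = TrainingConfig(widths=(6,), restarts_per_width=3, base_seed=5,
                             subsets=("full",))
        results = fit_scan(recs, cfg)
        best = min(results, key=lambda r: r.objective)
        fitted = best.affinity_map(score_records(recs, best.model))
        y = np.array([r.affinity for r in recs])
        assert np.corrcoef(fitted, y)[0, 1] > 0.99


class TestFitScan:
    def test_counts_and_best_of_restarts(self):
        rng = np.random.default_rng(9)
        recs = synthetic_records(rng, 25)
        for r in recs[:12]:
            r.group = "weakly-structured"
        for r in recs[12:]:
            r.group = "stem-loop"
        cfg = TrainingConfig(widths=(4, 5), restarts_per_width=2, base_seed=11)
        results = fit_scan(recs, cfg)
        assert len(results) == 4  # 2 widths x 2 subsets
        assert {(r.width, r.subset) for r in results} == {
            (4, "full"), (5, "full"), (4, "weak"), (5, "weak")
        }
        # determinism of the whole scan
        results2 = fit_scan(recs, cfg)
        for a, b in zip(results, results2):
            assert a.objective == b.objective
            assert np.array_equal(a.model.theta, b.model.theta)


class TestSelectModel:
    def _labeled(self, rng, n=30):
        recs = synthetic_records(rng, n)
        truth = random_model(rng, 5)
        scores = score_records(recs, truth)
        order = np.argsort(-scores)
        labels = ["other"] * n
        for i in order[:5]:
            labels[i] = "positive"
        for i in order[-10:]:
            labels[i] = "negative"
        return recs, labels, truth

    def test_single_candidate_returned(self):
        rng = np.random.default_rng(10)
        recs, labels, truth = self._labeled(rng)
        from rbpmotif.training import FitResult
        res = FitResult(model=truth, affinity_map=AffinityMap(1.0, 0.0),
                        objective=1.0, converged=True, width=5, restart=0,
                        subset="full", seed=0)
        out = select_model([res], recs, labels)
        assert out.model is res.model
        assert out.train_auc_pr == pytest.approx(1.0)

    def test_better_auc_wins_and_ties_break_small_width(self):
        rng = np.random.default_rng(11)
        recs, labels, truth = self._labeled(rng)
        from rbpmotif.training import FitResult
        good = FitResult(model=truth, affinity_map=AffinityMap(1.0, 0.0),
                         objective=9.9, converged=True, width=5, restart=0,
                         subset="full", seed=0)
        bad = FitResult(model=random_model(rng, 6), affinity_map=AffinityMap(1.0, 0.0),
                        objective=0.1, converged=True, width=6, restart=0,
                        subset="full", seed=0)
        assert select_model([bad, good], recs, labels).width == 5
        # exact AUC tie (identical scorer): the smaller declared width wins,
        # and at equal width the full subset beats the weak subset
        tie_wide = FitResult(model=truth, affinity_map=AffinityMap(1.0, 0.0),
                             objective=0.1, converged=True, width=6, restart=0,
                             subset="full", seed=0)
        assert select_model([tie_wide, good], recs, labels).width == 5
        tie_weak = FitResult(model=truth, affinity_map=AffinityMap(1.0, 0.0),
                             objective=0.1, converged=True, width=5, restart=0,
                             subset="weak", seed=0)
        assert select_model([tie_weak, good], recs, labels).subset == "full"

    def test_empty_results_error(self):
        with pytest.raises(ValueError):
            select_model([], [], [])
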