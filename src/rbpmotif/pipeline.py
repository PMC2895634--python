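"""Reproducible end-to-end runs: simulate, annotate, train, score, evaluate,
report.

:func:`run_pipeline` is the library's smoke path.  Every stage writes
plain-text outputs under one directory, plus a machine-readable provenance
record (configuration echo, package version, seeds) sufficient to rerun the
whole thing identically.  Outputs are byte-deterministic for a fixed base
seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from . import evaluation as ev
from . import io as rio
from . import pools
from . import reporting
from . import training as tr

logger = logging.getLogger(__name__)


def run_pipeline(
    out_dir,
    base_seed: int = 0,
    design: Optional[pools.PoolDesign] = None,
    truth: Optional[pools.GroundTruth] = None,
    config: Optional[tr.TrainingConfig] = None,
    positive_rule: Optional[ev.PositiveRule] = None,
    n_samples: int = 1000,
    n_boot: int = 200,
) -> dict:
    """Simulate a pool, fit the scan on Set A, evaluate on Set B, report.

    Returns a summary dict (also echoed into ``provenance.json``).  All
    randomness derives from ``base_seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = design or pools.PoolDesign(n_stemloop=300, n_weak=300)
    truth = truth or pools.default_ground_truth()
    config = config or tr.TrainingConfig(
        widths=(5, 6, 7), restarts_per_width=3, base_seed=base_seed + 100
    )
    positive_rule = positive_rule or ev.PositiveRule("quantile", 0.99)

    # simulate + annotate
    records, manifest = pools.make_pool(
        design, truth, seed=base_seed, n_samples=n_samples
    )
    rio.write_fasta(out / "pool.fasta", records)
    rio.write_affinity_table(out / "affinities.tsv", records)
    rio.write_profiles(out / "profiles.txt", records)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")

    set_a, set_b = pools.split_sets(records, seed=base_seed + 10)

    # train on Set A
    train_labeled = ev.label_records(set_a, positive_rule)
    results = tr.fit_scan(set_a, config)
    selected = tr.select_model(results, train_labeled.records, train_labeled.labels)
    models_dir = out / "models"
    models_dir.mkdir(exist_ok=True)
    selection_rows = []
    train_recs, train_is_pos = train_labeled.scored_subset()
    for res in sorted(results, key=lambda r: (r.width, r.subset)):
        rio.write_model(
            models_dir / f"model_w{res.width}_{res.subset}.txt",
            res.model,
            res.affinity_map,
        )
        scores = tr.score_records(train_recs, res.model)
        pr = ev.average_precision(scores, train_is_pos)
        selection_rows.append(
            {
                "width": res.width,
                "subset": res.subset,
                "objective": res.objective,
                "train_auc_pr": pr.auc_pr,
                "selected": res.width == selected.width and res.subset == selected.subset,
            }
        )
    rio.write_reports(
        out / "selection.tsv",
        ["width", "subset", "objective", "train_auc_pr", "selected"],
        selection_rows,
    )
    rio.write_model(out / "selected_model.txt", selected.model, selected.affinity_map)

    # score Set B
    n_scores = tr.score_records(set_b, selected.model)
    predicted = selected.affinity_map(n_scores)
    rio.write_scores(
        out / "scores.tsv",
        ["id", "score", "predicted_affinity"],
        [
            {"id": r.id, "score": float(s), "predicted_affinity": float(p)}
            for r, s, p in zip(set_b, n_scores, predicted)
        ],
    )

    # evaluate on Set B positives/negatives: fitted model vs 7-mer baseline
    test_labeled = ev.label_records(set_b, positive_rule)
    recs, is_pos = test_labeled.scored_subset()
    model_scores = tr.score_records(recs, selected.model)
    weak_train = [r for r in set_a if r.group == pools.GROUP_WEAK]
    table = ev.kmer_baseline_train(weak_train, k=7)
    kmer_scores = np.array([ev.kmer_baseline_score(r.seq, table, k=7) for r in recs])
    comparisons = ev.bootstrap_compare(
        is_pos,
        {"motif_model": model_scores, "kmer_baseline": kmer_scores},
        n_boot=n_boot,
        seed=base_seed + 20,
    )
    eval_rows = []
    for cmp_ in comparisons:
        eval_rows.append(
            {
                "scorer_a": cmp_.name_a,
                "scorer_b": cmp_.name_b,
                "auc_pr_a": ev.average_precision(model_scores, is_pos).auc_pr,
                "auc_pr_b": ev.average_precision(kmer_scores, is_pos).auc_pr,
                "mean_boot_auc_a": cmp_.mean_auc_a,
                "mean_boot_auc_b": cmp_.mean_auc_b,
                "wins_a": cmp_.wins_a,
                "wins_b": cmp_.wins_b,
                "wilcoxon_p": cmp_.wilcoxon_p,
                "ci_low": cmp_.ci_low,
                "ci_high": cmp_.ci_high,
            }
        )
    rio.write_reports(
        out / "evaluation.tsv",
        [
            "scorer_a", "scorer_b", "auc_pr_a", "auc_pr_b",
            "mean_boot_auc_a", "mean_boot_auc_b", "wins_a", "wins_b",
            "wilcoxon_p", "ci_low", "ci_high",
        ],
        eval_rows,
    )

    # report
    ctx = reporting.context_preference_ratios(selected.model)
    rio.write_reports(
        out / "context_report.tsv",
        ["letter", "gamma", "pure_context_term", "ratio"],
        [
            {
                "letter": letter,
                "gamma": g,
                "pure_context_term": t,
                "ratio": rr,
            }
            for letter, g, t, rr in zip(ctx.letters, ctx.gamma, ctx.pure_terms, ctx.ratios)
        ],
    )
    track = reporting.preferred_context_track(selected.model, recs)
    pfm = reporting.pfm_for_logo(selected.model)
    rio.write_pfm_meme(out / "pfm_meme.txt", pfm)
    rio.write_table(
        out / "pfm.tsv",
        ["base"] + [f"pos{j + 1}" for j in range(pfm.shape[1])],
        [
            {"base": b, **{f"pos{j + 1}": float(pfm[bi, j]) for j in range(pfm.shape[1])}}
            for bi, b in enumerate("ACGU")
        ],
    )
    (out / "preferred_context.txt").write_text(track + "\n")

    summary = {
        "package_version": __version__,
        "base_seed": base_seed,
        "design": asdict(design),
        "training_config": asdict(config),
        "positive_rule": asdict(positive_rule),
        "n_samples": n_samples,
        "n_boot": n_boot,
        "selected_width": selected.width,
        "selected_subset": selected.subset,
        "selected_objective": selected.objective,
        "test_auc_pr": ev.average_precision(model_scores, is_pos).auc_pr,
        "best_context_letter": ctx.best_letter,
        "preferred_context_track": track,
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return summary
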