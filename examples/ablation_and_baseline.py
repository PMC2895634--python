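"""Quantify what structural context adds: ablation and the 7-mer baseline.

On a pool whose affinities depend on a hairpin-loop motif, compares the full
structure-aware model against (a) its single-letter (structure-naive) variant
trained under the identical protocol and (b) a fully specified 7-mer lookup
model trained on the weakly structured sequences, with bootstrap confidence
intervals for the AUC-PR difference.  Takes a minute or two.
"""

import numpy as np

from rbpmotif import (
    GROUP_WEAK,
    PoolDesign,
    PositiveRule,
    TrainingConfig,
    bootstrap_compare,
    default_ground_truth,
    kmer_baseline_score,
    kmer_baseline_train,
    make_pool,
    score_records,
    split_sets,
)
from rbpmotif.evaluation import ablation_single_letter

truth = default_ground_truth()
records, _ = make_pool(PoolDesign(n_stemloop=600, n_weak=600), truth, seed=9,
                       n_samples=400)
train, test = split_sets(records, seed=10)
config = TrainingConfig(widths=(5, 6, 7), restarts_per_width=3, base_seed=11,
                        subsets=("full",))
rule = PositiveRule("quantile", 0.995)

res = ablation_single_letter(train, test, config, rule)
print(f"structure-aware model: test AUC-PR {res.full.test_pr.auc_pr:.3f}")
print(f"single-letter ablation: test AUC-PR {res.naive.test_pr.auc_pr:.3f}")
print(f"gain from modeling context: {res.auc_gain:+.3f}\n")

# 7-mer baseline trained on the weakly structured training sequences
from rbpmotif import label_records

table = kmer_baseline_train([r for r in train if r.group == GROUP_WEAK], k=7)
labeled = label_records(test, rule)
recs, is_pos = labeled.scored_subset()
model_scores = score_records(recs, res.full.selected.model)
kmer_scores = np.array([kmer_baseline_score(r.seq, table, k=7) for r in recs])
cmp_ = bootstrap_compare(
    is_pos, {"motif_model": model_scores, "kmer_baseline": kmer_scores},
    n_boot=500, seed=12,
)[0]
print("motif model vs 7-mer baseline over 500 bootstrap resamples:")
print(f"  wins {cmp_.wins_a} / losses {cmp_.wins_b}; "
      f"Wilcoxon signed-rank p = {cmp_.wilcoxon_p:.3g}")
print(f"  95% CI of AUC-PR difference: [{cmp_.ci_low:+.3f}, {cmp_.ci_high:+.3f}]")
print(
  "\nA CI excluding 0 means the structure-aware model separates bound from"
  "\nunbound test sequences better than a pure k-mer affinity lookup."
)
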