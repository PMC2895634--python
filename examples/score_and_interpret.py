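"""Score sequences under a hand-built sequence+context motif model.

Builds a loop-preferring binder for the consensus UGCAUG, scores the same
k-mer presented in a hairpin loop versus a paired stem, and prints the
relative context-preference ratios the model implies.
"""

import numpy as np

from rbpmotif import (
    MotifModel,
    annotation_profile,
    context_preference_ratios,
    plum_alphabet,
    score_sequence,
)

alpha = plum_alphabet()
theta = np.full((4, 6), -2.0)
for j, b in enumerate("UGCAUG"):
    theta["ACGU".index(b), j] = 2.0
gamma = np.array([-2.0, 2.0, -1.0, -1.0])  # P, L, U, M: loop strongly preferred
model = MotifModel(width=6, theta=theta, gamma=gamma, b_seq=-4.0, b_str=0.0,
                   alphabet=alpha)

in_loop = "GGCGGCGGGCUGCAUGAAGCCCGCCGCC"     # consensus inside the hairpin loop
in_stem = "GGUGCAUGGGAAAACCCAUGCACCAAAA"     # consensus inside the stem
for name, seq in [("loop-presented", in_loop), ("stem-presented", in_stem)]:
    prof = annotation_profile(seq, n_samples=1000, seed=2)
    n = score_sequence(seq, prof, model)
    print(f"{name}: noisy-OR score N = {n:.4f}")
print(
    "The same consensus scores near 1 in its preferred loop context and near"
    "\n0 when the ensemble pairs it into a stem: context licenses binding.\n"
)

report = context_preference_ratios(model)
print("relative context preference (ratio to best context):")
for letter, ratio in zip(report.letters, report.ratios):
    print(f"  {letter}: {ratio:.4f}")
print(f"preferred context: {report.best_letter} (ratio 1 by construction)")
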