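# Methods

`rbpmotif` learns the joint sequence and secondary-structure-context binding
preferences of an RNA-binding protein (RBP) from per-sequence binding
affinities, in the style of discriminative motif finding on in-vitro
affinity-selection pools.  This note records the model, the numerical and
design choices, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Structural context annotation

A base's binding relevance depends on the secondary-structure context it sits
in, and a short RNA rarely has a single structure.  We therefore annotate
every base with a probability distribution over context letters, estimated
from the Boltzmann ensemble:

- **Alphabet.** Default letters P (paired), L (hairpin loop), U (external /
  unstructured), M (miscellaneous: bulge, internal loop or multiloop).
  Paired bases are P regardless of helix type.  Unpaired bases are classified
  by the loop that directly contains them: no enclosing pair → U; enclosing
  loop with no inner helix → L; one inner helix with unpaired bases on one
  side → bulge (M), on both sides → internal loop (M); two or more inner
  helices → multiloop (M).  Bases outside every pair are always U; we do not
  distinguish exterior bases adjacent to stems from free tails.  A
  single-letter alphabet (all categories → one letter) is supported and used
  for the structure-naive ablation.
- **Ensemble.** A self-contained simplified-thermodynamic model: only the six
  canonical pairs, with pseudo-energies GC −3, AU −2, GU −1 (arbitrary
  units), a stacking bonus of −1 for a pair directly enclosing another, a
  minimum hairpin of 3 unpaired bases, inverse temperature β = 1.  Lonely
  pairs are allowed; dangling ends, coaxial stacking and pseudoknots are not
  modeled.  These defaults produce non-trivial ensembles at pool scale
  (29–38 nt) without fitting real thermodynamics; all values are
  configurable.  Because the motif model consumes only annotation profiles,
  any Boltzmann-consistent annotator can be substituted — profiles can also
  be built from externally sampled dot-bracket structures or supplied as
  probability tables.
- **Computation.** An inside dynamic program computes the partition function
  over all legal nested structures exactly; structures are drawn by
  stochastic traceback (exact Boltzmann sampling, internal
  xorshift128+ generator, bit-reproducible per seed).  The annotation
  profile is the empirical letter frequency per base over `n_samples`
  structures (default 1000).  Weights are unscaled `float64`; with |E| up to
  roughly 50 at pool lengths this is far from overflow, but sequences beyond
  a few hundred bases would need rescaling and are out of scope.
- **Oracles.** For sequences up to 16 nt an exhaustive enumerator lists every
  structure with its weight; tests verify the DP total, the sampler's
  empirical law (TV distance and chi-squared), and the loop taxonomy against
  independent reimplementations.

## Motif model

A motif of width w has a 4×w real PWM Θ, one context parameter γ_a per
alphabet letter (shared across positions), and biases b_seq, b_str.  For a
window (k-mer) starting at position i of sequence s with profile slice π:

- sequence term  p_seq = σ(b_seq + Σ_j Θ[s_{i+j}, j]),
- context term   p_str = σ(b_str + Σ_j Σ_a γ_a · π[a, j]),
- window probability  p_i = p_seq · p_str,

with σ the logistic function.  The whole sequence scores
N = 1 − Π_i (1 − p_i) (noisy-OR: the probability that at least one window is
bound), accumulated in the log domain.  Predicted affinity is slope·N +
intercept with slope > 0.  A strongly disfavored context drives p_str → 0
and vetoes binding regardless of sequence; a saturated context bias recovers
a pure sequence PWM model.

Two conventions exist for the context logit: summing the per-position
contributions (a pure-context-a window has logit b_str + w·γ_a) or averaging
them.  They differ only by rescaling γ at fixed width but matter when
comparing widths.  We default to the **sum** and expose the mean as a flag
(`mean_context`); reports record which was used.

Windows containing a non-ACGU character contribute probability 0 (with a
logged warning) instead of failing the record.  Scanning is single-stranded
5′→3′ only; coordinates are 0-based internally.

## Fitting

Parameters (Θ, γ, b_seq, b_str, slope, intercept) minimize

  Σ_t (slope·N_t + intercept − y_t)² + λ (‖Θ‖² + ‖γ‖² + b_seq² + b_str²)

by L-BFGS-B with an analytic gradient; the slope is box-constrained to
[1e−6, ∞).  The ridge term breaks the shift degeneracy between PWM columns
and b_seq (tests assert the penalized objective prefers the centered
representative).  λ defaults to 0.01; the slope and intercept are left
unpenalized so the affinity scale is not shrunk — both choices are
documented defaults, configurable.  Binary-label (bound/unbound, y = ±1)
training is the same objective.  Stopping: projected-gradient tolerance
1e−6 or 500 iterations.

The width scan fits each width in 4..12 (ascending) with 10 restarts.  For
widths above the minimum, two restarts reuse the previous width's best PWM
padded with a zero column on the left or right; all other initial entries
are uniform in [−0.05, 0.05] (slope clamped positive).  Restart seeds are
`base_seed + 1000·width + restart` for auditability.  Models are fitted on
the full training set and on the weakly structured subset; the single
reported model is the candidate with the highest training AUC-PR on the
training positives/negatives, ties broken toward smaller width, then the
full subset.  On easy synthetic pools several widths often reach a training
AUC-PR of 1.0, so the tie-break (compactness) decides.

## Evaluation

- **Labels.** Positives are the right tail of the measured-affinity
  distribution — default the top 0.5 % of the training set (the assay used
  per-protein manual cutoffs; count and absolute-threshold rules are
  supported), ties at the cutoff included.  Negatives are records strictly
  below the median affinity; the rest are "other" and excluded from scoring.
- **AUC-PR** is computed as average precision: the mean over positives of
  the precision at that positive's rank, descending scores.  Within a block
  of tied scores positives are treated as evenly interleaved (precision
  evaluated at fractional depths), so all-tied scores give exactly the
  positive fraction.  No trapezoidal PR interpolation.
- **Cross-validation** follows the designed-pool Set A / Set B protocol:
  train on one half (labels and model selection from that half only), test
  on the other half's positives/negatives, swap, report the mean.
- **Significance.** Test records are resampled with replacement (1000
  bootstrap replicates by default; one-class replicates are redrawn);
  scorers are compared by win/loss counts, Wilcoxon's signed-rank test on
  the paired replicate AUC-PRs, and the 2.5/97.5 percentile CI of the
  difference.  Resampling is at the record level.
- **Ablation.** The structure-naive variant collapses the alphabet to one
  letter (its context term is a per-width constant) and is trained under the
  identical protocol.
- **7-mer baseline.** Every 7-mer's affinity is the trimmed mean (5 % per
  tail) of the affinities of weakly structured training sequences containing
  it; unobserved 7-mers get the global median (count logged).  A sequence
  scores the mean of its windows' table values.

## Synthetic pools

The generator emulates a designed affinity-selection pool at desk scale
(default 2000 stem-loops + 2000 weakly structured sequences; the real pool
has ~213k members with 64-fold 7-mer coverage):

- **Stem-loops:** random flanks around a 10-bp Watson–Crick stem closing a
  loop; loop lengths cycle over 3–7 so each is represented; total length
  29–38 nt.  No two pool sequences share a substring longer than 12 nt
  (tracked globally, regenerated on violation).
- **Weakly structured:** candidates drawn from a GC-depleted composition
  (A/C-rich, p = 0.3/0.4/0.1/0.2) — mirroring that the real weak group was
  *designed* for high folding free energy — then accepted only if the mean
  per-base pairing probability from the built-in annotator (100 samples) is
  below 0.3, with up to 6 repair rounds mutating the most-paired positions
  toward A/C first.  Plain-uniform candidates almost never pass under the
  default energies, hence the designed proposals.
- **Planting and affinities:** a ground-truth model (default: consensus
  UGCAUG, +2/−2 PWM contrast, γ = +2 for L, −2 for P, −1 elsewhere,
  b_seq = −4, identity affinity line) is planted into hairpin loops of 10 %
  of stem-loops and anywhere into 25 % of weak sequences; affinities are the
  truth's predictions plus Gaussian noise (default sd 0.1 ≈ 10 % of the
  affinity range).  Planted loops have length 8 (the designed pool also
  carried length-8 loops) with the motif at a random offset: loop-spanning
  13-mers have little entropy because the 3′ stem mirrors the 5′ stem, and
  denser or fixed-offset planting makes the 12-nt shared-substring
  constraint unsatisfiable.  The optional `fixed_prefix` flag reproduces the
  transcription-initiation prefix artifact (unpaired 5′-AGA/AGG on every
  member) for confound studies; it is off by default.
- **Manifest.** Design, truth parameters and seeds are recorded; a manifest
  regenerates a pool bit-exactly.

What a green test establishes — and does not: the generator's affinities
come from the same model family that is being fitted, so recovery tests
verify the estimation machinery, not the model's adequacy for real
microarray data; the noise is i.i.d. Gaussian (no intensity-dependent
variance, probe effects or missing data); group membership correlates with
base composition (weak sequences are A/C-rich), which a sequence-only model
can partially exploit — the ablation comparisons measure the *additional*
value of context on top of that.

## Determinism

Every stochastic step (sampling, initialization, pool synthesis, splitting,
bootstrap) is driven by explicit integer seeds; the end-to-end pipeline
writes byte-identical outputs for a fixed base seed.  Model files print 10
significant digits; tables print 6 decimals.

## Shape of the package

The package is a library: the importable API plus `examples/` scripts are
the interface, and `rbpmotif.pipeline.run_pipeline` provides the end-to-end
simulate → annotate → train → score → evaluate → report path with a
provenance record.  No shell CLI is installed; the expected user drives the
analysis from Python.

## Limitations

- The folding model is a caricature of real thermodynamics; profiles are
  exchangeable with richer folders via the external-profile adapter, and
  conclusions about real RBPs should use one.
- One motif per model; no dinucleotide sequence terms; γ is shared across
  motif positions (no per-position context preferences).
- Acceptance-scale experiments reduce pool size / widths / restarts /
  folding samples where noted in the test docstrings to stay within a desk
  time budget.
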