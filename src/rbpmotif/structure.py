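"""Secondary-structure ensembles and per-base context annotation profiles.

The motif model does not consume structures directly: it consumes, for every
base of a sequence, a probability distribution over structural-context letters
(the *annotation profile*), estimated as empirical annotation frequencies over
a large sample of structures drawn from the Boltzmann ensemble.

This module provides a self-contained simplified-thermodynamic ensemble: only
the six canonical pairs are allowed, each with a configurable pseudo-energy,
plus an optional stacking bonus; hairpin loops must enclose at least
``min_hairpin`` unpaired bases; pseudoknots, dangling ends and coaxial stacks
are not modeled.  Any richer external folding program can be substituted via
:func:`profile_from_external`, which accepts sampled dot-bracket strings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _fold
from .alphabet import CATEGORIES, AnnotationAlphabet, plum_alphabet

BASES = "ACGU"
_CODE = {b: i for i, b in enumerate(BASES)}
#: canonical pair kinds, stored with both orientations
CANONICAL_PAIRS = ("AU", "UA", "GC", "CG", "GU", "UG")

ENUMERATION_GUARD = 16


class InvalidSequenceError(ValueError):
    """Sequence contains characters outside A, C, G, U (after T->U mapping)."""


def encode(seq: str) -> np.ndarray:
    """Map an RNA string to integer codes A=0, C=1, G=2, U=3 (T -> U)."""
    out = np.empty(len(seq), dtype=np.int64)
    for i, ch in enumerate(seq.upper()):
        if ch == "T":
            ch = "U"
        code = _CODE.get(ch)
        if code is None:
            raise InvalidSequenceError(
                f"illegal character {ch!r} at position {i + 1} in sequence"
            )
        out[i] = code
    return out


@dataclass(frozen=True)
class EnergyModel:
    """Simplified pseudo-thermodynamic model of the Boltzmann ensemble.

    Parameters
    ----------
    pair_scores
        Pseudo-energy per canonical pair kind (more negative = more stable).
        Keys may name either orientation ("AU" covers "UA" unless both given).
    stack_bonus
        Extra energy added when a pair is stacked directly on another
        (pairs (i, j) and (i+1, j-1) both present).
    min_hairpin
        Minimum number of unpaired bases enclosed by any pair (>= 3).
    beta
        Inverse-temperature scale; structure weight is exp(-beta * E).
    """

    pair_scores: dict[str, float] = field(
        default_factory=lambda: {"GC": -3.0, "AU": -2.0, "GU": -1.0}
    )
    stack_bonus: float = -1.0
    min_hairpin: int = 3
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.min_hairpin < 3:
            raise ValueError("min_hairpin must be >= 3")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        for key in self.pair_scores:
            k = key.upper().replace("T", "U")
            if k not in CANONICAL_PAIRS:
                raise ValueError(f"non-canonical pair kind in pair_scores: {key!r}")

    def pair_energy(self, a: str, b: str) -> float | None:
        """Energy of the pair (a, b), or None if the pair is forbidden."""
        for key in (a + b, b + a):
            if key in self.pair_scores:
                return self.pair_scores[key]
        return None

    def pair_weight_matrix(self) -> np.ndarray:
        """4x4 Boltzmann pair weights exp(-beta*E); 0 for forbidden pairs."""
        w = np.zeros((4, 4))
        for i, a in enumerate(BASES):
            for j, b in enumerate(BASES):
                e = self.pair_energy(a, b)
                if e is not None:
                    w[i, j] = math.exp(-self.beta * e)
        return w

    @property
    def stack_multiplier(self) -> float:
        return math.exp(-self.beta * self.stack_bonus)


@dataclass(frozen=True)
class SecondaryStructure:
    """One secondary structure as a pairing involution plus dot-bracket."""

    partner: tuple[int, ...]
    dotbracket: str

    @property
    def n(self) -> int:
        return len(self.partner)

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return [(i, j) for i, j in enumerate(self.partner) if j > i]

    @classmethod
    def from_partner(cls, partner) -> "SecondaryStructure":
        db = "".join(
            "." if p < 0 else ("(" if p > i else ")") for i, p in enumerate(partner)
        )
        return cls(partner=tuple(int(p) for p in partner), dotbracket=db)

    @classmethod
    def from_dotbracket(cls, db: str) -> "SecondaryStructure":
        partner = [-1] * len(db)
        stack: list[int] = []
        for i, ch in enumerate(db):
            if ch == "(":
                stack.append(i)
            elif ch == ")":
                if not stack:
                    raise ValueError(f"unbalanced ')' at position {i + 1}")
                j = stack.pop()
                partner[i] = j
                partner[j] = i
            elif ch != ".":
                raise ValueError(f"illegal dot-bracket character {ch!r}")
        if stack:
            raise ValueError(f"unbalanced '(' at position {stack[-1] + 1}")
        return cls(partner=tuple(partner), dotbracket=db)


def structure_energy(structure: SecondaryStructure, seq: str, model: EnergyModel) -> float:
    """Total pseudo-energy: pair terms plus stacking bonuses."""
    e = 0.0
    partner = structure.partner
    for i, j in structure.pairs:
        pe = model.pair_energy(seq[i], seq[j])
        if pe is None:
            raise ValueError(f"forbidden pair {seq[i]}{seq[j]} at ({i}, {j})")
        e += pe
        if i + 1 < j - 1 and partner[i + 1] == j - 1:
            e += model.stack_bonus
    return e


@dataclass(frozen=True)
class PartitionTables:
    """Inside tables of the partition-function DP for one sequence."""

    seq: str
    codes: np.ndarray
    z: np.ndarray
    zb: np.ndarray
    model: EnergyModel

    @property
    def total_weight(self) -> float:
        n = len(self.seq)
        return float(self.z[0, n - 1]) if n > 1 else 1.0


def compute_partition(seq: str, model: EnergyModel | None = None) -> PartitionTables:
    """Fill the inside DP over all legal non-crossing structures of ``seq``.

    The total weight ``z[0, n-1]`` equals the sum of exp(-beta*E(s)) over every
    legal structure s (the empty structure has E=0 and weight 1).
    """
    model = model or EnergyModel()
    codes = encode(seq)
    if codes.size == 0:
        raise InvalidSequenceError("empty sequence")
    z, zb = _fold.fill_partition(
        codes, model.pair_weight_matrix(), model.stack_multiplier, model.min_hairpin
    )
    return PartitionTables(seq=seq, codes=codes, z=z, zb=zb, model=model)


def _legal_pairs(codes: np.ndarray, model: EnergyModel) -> list[tuple[int, int]]:
    w = model.pair_weight_matrix()
    n = codes.size
    return [
        (i, j)
        for i in range(n)
        for j in range(i + model.min_hairpin + 1, n)
        if w[codes[i], codes[j]] > 0
    ]


def enumerate_structures(
    seq: str, model: EnergyModel | None = None
) -> list[tuple[SecondaryStructure, float]]:
    """Exhaustively enumerate every legal structure with its Boltzmann weight.

    Intended as a small-n oracle for the DP and the sampler; refuses sequences
    longer than ``ENUMERATION_GUARD`` bases.
    """
    model = model or EnergyModel()
    codes = encode(seq)
    n = codes.size
    if n > ENUMERATION_GUARD:
        raise ValueError(
            f"enumerate_structures refuses length {n} > {ENUMERATION_GUARD}"
        )
    out: list[tuple[SecondaryStructure, float]] = []

    def rec(i: int, j: int, partner: list[int]):
        # yield all structures on [i, j] given choices made outside
        if i >= j:
            yield partner
            return
        # i unpaired
        yield from rec(i + 1, j, partner)
        for k in range(i + model.min_hairpin + 1, j + 1):
            if model.pair_energy(seq[i], seq[k]) is None:
                continue
            partner[i], partner[k] = k, i
            for inner in rec(i + 1, k - 1, partner):
                yield from rec(k + 1, j, inner)
            partner[i], partner[k] = -1, -1

    seen = set()
    for p in rec(0, n - 1, [-1] * n):
        s = SecondaryStructure.from_partner(p)
        if s.dotbracket in seen:  # pragma: no cover - recursion yields uniquely
            continue
        seen.add(s.dotbracket)
        out.append((s, math.exp(-model.beta * structure_energy(s, seq, model))))
    return out


def sample_structures(
    seq: str,
    tables: PartitionTables,
    n_samples: int,
    seed: int,
) -> list[SecondaryStructure]:
    """Draw i.i.d. structures from the exact Boltzmann distribution.

    Stochastic traceback of the inside tables; bit-reproducible given ``seed``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if tables.seq != seq:
        raise ValueError("tables were computed for a different sequence")
    model = tables.model
    partners = _fold.sample_partners(
        tables.codes,
        model.pair_weight_matrix(),
        model.stack_multiplier,
        model.min_hairpin,
        tables.z,
        tables.zb,
        n_samples,
        seed,
    )
    return [SecondaryStructure.from_partner(row) for row in partners]


def classify_contexts(
    structure: SecondaryStructure, alphabet: AnnotationAlphabet | None = None
) -> str:
    """Annotate every position of one structure with its context letter.

    Paired bases get the paired letter.  Each unpaired base is classified by
    the loop containing it: no enclosing pair -> external; enclosing loop with
    no inner helix -> hairpin loop; one inner helix with unpaired bases on one
    side -> bulge, on both sides -> internal loop; two or more inner helices ->
    multiloop.
    """
    alphabet = alphabet or plum_alphabet()
    partner = np.asarray(structure.partner, dtype=np.int64)
    cats = np.full(partner.shape[0], -1, dtype=np.int64)
    _fold.classify_partner(partner, cats)
    return "".join(alphabet.category_map[CATEGORIES[c]] for c in cats)


@dataclass(frozen=True)
class AnnotationProfile:
    """Per-base distribution over context letters (|A| x n matrix)."""

    alphabet: AnnotationAlphabet
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != len(self.alphabet):
            raise ValueError(
                f"profile must be {len(self.alphabet)} x n, got shape {v.shape}"
            )
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise ValueError("profile entries must lie in [0, 1]")
        colsums = v.sum(axis=0)
        if v.shape[1] and np.max(np.abs(colsums - 1.0)) > 1e-9:
            raise ValueError("profile columns must sum to 1 within 1e-9")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[1]

    def collapse_to(self, alphabet: AnnotationAlphabet) -> "AnnotationProfile":
        """Re-express the profile in a coarser alphabet (e.g. single letter).

        Only valid when the target alphabet merges letters of this profile's
        alphabet, i.e. each category's letter here maps to one target letter.
        """
        mapping = {}
        for cat in CATEGORIES:
            src = self.alphabet.category_map[cat]
            dst = alphabet.category_map[cat]
            if src in mapping and mapping[src] != dst:
                raise ValueError("alphabets are not nested; cannot collapse")
            mapping[src] = dst
        out = np.zeros((len(alphabet), self.n))
        for src, dst in mapping.items():
            out[alphabet.index(dst)] += self.values[self.alphabet.index(src)]
        return AnnotationProfile(alphabet=alphabet, values=out)


def annotation_profile(
    seq: str,
    model: EnergyModel | None = None,
    alphabet: AnnotationAlphabet | None = None,
    n_samples: int = 1000,
    seed: int = 0,
    tables: PartitionTables | None = None,
) -> AnnotationProfile:
    """Estimate the annotation profile as empirical frequencies over samples.

    ``values[a, i]`` is the fraction of the ``n_samples`` Boltzmann samples in
    which base i carries annotation letter a; columns sum to 1 exactly
    (integer counts divided by ``n_samples``).  The default of 1000 samples
    matches common practice for ensemble annotation.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    model = model or EnergyModel()
    alphabet = alphabet or plum_alphabet()
    if tables is None:
        tables = compute_partition(seq, model)
    partners = _fold.sample_partners(
        tables.codes,
        model.pair_weight_matrix(),
        model.stack_multiplier,
        model.min_hairpin,
        tables.z,
        tables.zb,
        n_samples,
        seed,
    )
    counts = _fold.profile_counts(partners)
    values = np.zeros((len(alphabet), len(seq)))
    for ci, cat in enumerate(CATEGORIES):
        values[alphabet.row_of(cat)] += counts[ci]
    return AnnotationProfile(alphabet=alphabet, values=values / n_samples)


def profile_from_external(
    structures,
    alphabet: AnnotationAlphabet | None = None,
) -> AnnotationProfile:
    """Build a profile from external folding output.

    ``structures`` is either a list of same-length dot-bracket strings (e.g.
    samples from another folding program) or a pre-normalized |A| x n
    probability table.  Dot-brackets are annotated with the same context rules
    as the built-in sampler.
    """
    alphabet = alphabet or plum_alphabet()
    if isinstance(structures, np.ndarray) or (
        structures and not isinstance(structures[0], str)
    ):
        table = np.asarray(structures, dtype=float)
        colsums = table.sum(axis=0)
        bad = np.nonzero(np.abs(colsums - 1.0) > 1e-6)[0]
        if bad.size:
            raise ValueError(
                f"profile column {bad[0] + 1} sums to {colsums[bad[0]]:.8f}, not 1"
            )
        return AnnotationProfile(alphabet=alphabet, values=table)
    if not structures:
        raise ValueError("no structures supplied")
    n = len(structures[0])
    counts = np.zeros((len(alphabet), n))
    for lineno, db in enumerate(structures, start=1):
        if len(db) != n:
            raise ValueError(
                f"dot-bracket line {lineno} has length {len(db)}, expected {n}"
            )
        try:
            s = SecondaryStructure.from_dotbracket(db)
        except ValueError as exc:
            raise ValueError(f"dot-bracket line {lineno}: {exc}") from exc
        letters = classify_contexts(s, alphabet)
        for i, letter in enumerate(letters):
            counts[alphabet.index(letter), i] += 1
    return AnnotationProfile(alphabet=alphabet, values=counts / len(structures))


def mean_paired_probability(profile: AnnotationProfile) -> float:
    """Mean probability mass on the paired letter across positions."""
    return float(profile.values[profile.alphabet.row_of("paired")].mean())
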