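"""Synthetic RNAcompete-style pools with known ground-truth affinities.

The generator emulates the designed-pool layout used by in-vitro binding
assays: short (29-38 nt) RNAs split into a *stem-loop* group (a 10-bp
Watson-Crick stem closing a loop of 3-7 nt, with random flanks) and a
*weakly structured* group (random sequences accepted only when their ensemble
pairing probability is low), with no two pool members sharing a substring
longer than 12 nt.  A ground-truth motif model assigns each member an
affinity (plus Gaussian noise), optionally after planting the motif consensus
into hairpin loops and/or weak sequences, so that parameter-recovery and
ablation experiments have a known answer.

Scale note: the real assay pool has ~213k sequences with 64-fold 7-mer
coverage; the default here is a desk-scale 2000+2000 pool.  Every knob is a
config field and the manifest records enough to regenerate a pool bit-exactly.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .alphabet import AnnotationAlphabet, plum_alphabet  # noqa: F401
from .model import AffinityMap, MotifModel
from .records import GROUP_STEMLOOP, GROUP_WEAK, RnaRecord
from .structure import (
    BASES,
    EnergyModel,
    annotation_profile,
    mean_paired_probability,
)

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}


@dataclass
class PoolDesign:
    """Layout of the synthetic pool (defaults mirror the assay's design)."""

    n_stemloop: int = 2000
    n_weak: int = 2000
    min_length: int = 29
    max_length: int = 38
    stem_length: int = 10
    min_loop: int = 3
    max_loop: int = 7
    max_shared_substring: int = 12
    weak_pairing_threshold: float = 0.3
    weak_check_samples: int = 100
    #: candidate base composition (A, C, G, U) for the weak group; GC-depleted
    #: so that proposals resemble the assay's high-folding-free-energy designs
    weak_base_probs: tuple[float, float, float, float] = (0.3, 0.4, 0.1, 0.2)
    #: design-repair iterations: mutate the most-paired positions toward A/C
    #: when a candidate fails the ensemble pairing check
    weak_repair_rounds: int = 6
    fixed_prefix: str = ""  # e.g. "AGA" to emulate the T7-initiation artifact

    def __post_init__(self) -> None:
        if self.min_loop < 3:
            raise ValueError("loops must allow the minimum hairpin size (3)")
        if self.min_length < 2 * self.stem_length + self.max_loop:
            raise ValueError("min_length cannot accommodate stem + loop")


@dataclass
class GroundTruth:
    """Generative model of affinities, recorded verbatim in the manifest."""

    model: MotifModel
    affinity_map: AffinityMap
    noise_sd: float = 0.1
    #: stem-loop planting is kept sparse: every planted loop consumes one of
    #: the few distinct loop-spanning 13-mers compatible with a complementary
    #: stem, and the pool's shared-substring cap must remain satisfiable
    plant_stemloop_fraction: float = 0.1
    plant_weak_fraction: float = 0.25

    @property
    def consensus(self) -> str:
        return "".join(BASES[b] for b in np.argmax(self.model.theta, axis=0))


def default_ground_truth(
    alphabet: Optional[AnnotationAlphabet] = None,
    width: int = 6,
    consensus: str = "UGCAUG",
    preferred_letter: str = "L",
    noise_sd: float = 0.1,
) -> GroundTruth:
    """A planted-motif truth: strong PWM, hairpin-loop context preference.

    The PWM gives the consensus base +2 and every other base -2 per column
    (sequence-term logits: consensus +8, one mismatch +4, two mismatches 0).
    Gamma is +2 for the preferred letter, -2 for paired, -1 elsewhere, so a
    consensus site is licensed in the preferred context and suppressed in the
    others; the affinity map is the identity line and noise_sd defaults to
    ~10% of the resulting affinity range.
    """
    alphabet = alphabet or plum_alphabet()
    consensus = consensus.upper().replace("T", "U")
    if len(consensus) != width:
        raise ValueError("consensus length must equal width")
    theta = np.full((4, width), -2.0)
    for j, b in enumerate(consensus):
        theta[BASES.index(b), j] = 2.0
    gamma = np.full(len(alphabet), -1.0)
    gamma[alphabet.index(preferred_letter)] = 2.0
    if "P" in alphabet.letters and preferred_letter != "P":
        gamma[alphabet.index("P")] = -2.0
    model = MotifModel(
        width=width,
        theta=theta,
        gamma=gamma,
        b_seq=-4.0,
        b_str=0.0,
        alphabet=alphabet,
    )
    return GroundTruth(
        model=model,
        affinity_map=AffinityMap(slope=1.0, intercept=0.0),
        noise_sd=noise_sd,
    )


def context_free_ground_truth(
    alphabet: Optional[AnnotationAlphabet] = None,
    width: int = 6,
    consensus: str = "UGCAUG",
    noise_sd: float = 0.1,
) -> GroundTruth:
    """A structure-indifferent truth (gamma = 0, large positive context bias).

    Affinities depend on sequence only; used for the ablation null experiment.
    """
    truth = default_ground_truth(alphabet, width, consensus, noise_sd=noise_sd)
    model = truth.model
    model.gamma = np.zeros(len(model.alphabet))
    model.b_str = 20.0
    return replace(truth, model=model)


class _SubstringRegistry:
    """Rejects sequences sharing a substring longer than the configured cap."""

    def __init__(self, max_shared: int):
        self.k = max_shared + 1
        self.seen: set[str] = set()

    def kmers(self, seq: str):
        return {seq[i : i + self.k] for i in range(len(seq) - self.k + 1)}

    def conflicts(self, seq: str) -> bool:
        return any(km in self.seen for km in self.kmers(seq))

    def add(self, seq: str) -> None:
        self.seen |= self.kmers(seq)


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _apply_prefix(seq: str, prefix: str) -> str:
    return (prefix + seq[len(prefix):]) if prefix else seq


def make_stemloop_pool(
    design: PoolDesign,
    seed: int = 0,
    plant: Optional[str] = None,
    plant_fraction: float = 0.0,
    registry: Optional[_SubstringRegistry] = None,
    max_attempts: int = 200,
) -> list[RnaRecord]:
    """Generate the stem-loop group: flanks + 10-bp stem + loop + stem'.

    Loop lengths cycle through the configured range so every length is
    represented.  Planted records use an extended loop (length >= motif
    width + 2, at least max_loop + 1, mirroring the designed pool's length-8
    loops) and carry ``plant`` at a random offset inside the loop: loops
    spanning a planted site have little sequence entropy (the 3' stem is the
    complement of the 5' stem), so the extra loop bases and the random offset
    are needed for the shared-substring cap to stay satisfiable.  Uniqueness
    is enforced against ``registry`` (a fresh one if not given), regenerating
    on violation.
    """
    rng = np.random.default_rng(seed)
    registry = registry or _SubstringRegistry(design.max_shared_substring)
    loop_lengths = list(range(design.min_loop, design.max_loop + 1))
    n_plant = int(round(design.n_stemloop * plant_fraction)) if plant else 0
    records = []
    for i in range(design.n_stemloop):
        planted = i < n_plant
        if planted:
            loop_len = max(design.max_loop + 1, len(plant) + 2)
        else:
            loop_len = loop_lengths[i % len(loop_lengths)]
        for attempt in range(max_attempts):
            total = int(
                rng.integers(
                    max(design.min_length, 2 * design.stem_length + loop_len),
                    design.max_length + 1,
                )
            )
            flank_total = total - 2 * design.stem_length - loop_len
            left = int(rng.integers(0, flank_total + 1))
            stem5 = _random_bases(rng, design.stem_length)
            stem3 = "".join(_COMPLEMENT[b] for b in reversed(stem5))
            if planted:
                off = int(rng.integers(0, loop_len - len(plant) + 1))
                loop = (
                    _random_bases(rng, off)
                    + plant
                    + _random_bases(rng, loop_len - len(plant) - off)
                )
            else:
                loop = _random_bases(rng, loop_len)
            seq = (
                _random_bases(rng, left)
                + stem5
                + loop
                + stem3
                + _random_bases(rng, flank_total - left)
            )
            seq = _apply_prefix(seq, design.fixed_prefix)
            if not registry.conflicts(seq):
                registry.add(seq)
                break
        else:
            raise RuntimeError(
                f"could not generate stem-loop {i} without sharing a "
                f">{design.max_shared_substring}-nt substring; reduce n_stemloop"
            )
        records.append(
            RnaRecord(id=f"SL{i:05d}", seq=seq, group=GROUP_STEMLOOP)
        )
    return records


def make_weak_pool(
    design: PoolDesign,
    seed: int = 0,
    plant: Optional[str] = None,
    plant_fraction: float = 0.0,
    registry: Optional[_SubstringRegistry] = None,
    energy_model: Optional[EnergyModel] = None,
    max_attempts: int = 400,
) -> list[RnaRecord]:
    """Generate the weakly structured group by design + ensemble check.

    Candidates are proposed from a GC-depleted composition (the assay's weak
    group was likewise *designed* for high folding free energy, not sampled
    uniformly) and, when a candidate fails the check, its most-paired
    positions are mutated toward A/C for a few repair rounds.  A sequence is
    accepted only when its mean per-base pairing probability, estimated with
    the built-in annotator at a reduced sample count, is below the design
    threshold.  Planted records carry ``plant`` at a random interior position
    (overwriting, so length is preserved); planted bases are never mutated.
    """
    rng = np.random.default_rng(seed)
    registry = registry or _SubstringRegistry(design.max_shared_substring)
    energy_model = energy_model or EnergyModel()
    n_plant = int(round(design.n_weak * plant_fraction)) if plant else 0
    base_probs = np.asarray(design.weak_base_probs, dtype=float)
    base_probs = base_probs / base_probs.sum()
    records = []
    attempts = 0
    accepted = 0
    paired_row = plum_alphabet().index("P")  # internal check uses PLUM
    for i in range(design.n_weak):
        planted = i < n_plant
        for attempt in range(max_attempts):
            attempts += 1
            if attempts >= 200 and accepted / attempts < 0.01:
                raise RuntimeError(
                    "weak-pool acceptance rate below 1%; raise "
                    "weak_pairing_threshold or loosen the design"
                )
            total = int(rng.integers(design.min_length, design.max_length + 1))
            chars = [BASES[j] for j in rng.choice(4, size=total, p=base_probs)]
            protected = set(range(len(design.fixed_prefix)))
            if planted:
                lo = len(design.fixed_prefix)
                pos = int(rng.integers(lo, total - len(plant) + 1))
                chars[pos : pos + len(plant)] = list(plant)
                protected |= set(range(pos, pos + len(plant)))
            chars[: len(design.fixed_prefix)] = list(design.fixed_prefix)
            seq = "".join(chars)
            ok = False
            for rep in range(design.weak_repair_rounds):
                prof = annotation_profile(
                    seq,
                    energy_model,
                    n_samples=design.weak_check_samples,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                if mean_paired_probability(prof) < design.weak_pairing_threshold:
                    ok = True
                    break
                paired_p = prof.values[paired_row]
                worst = np.argsort(-paired_p)
                mutated = 0
                chars = list(seq)
                for pos2 in worst:
                    if int(pos2) in protected or paired_p[pos2] < 0.5:
                        continue
                    chars[pos2] = "A" if rng.integers(0, 2) == 0 else "C"
                    mutated += 1
                    if mutated >= 4:
                        break
                if mutated == 0:
                    break
                seq = "".join(chars)
            if not ok or registry.conflicts(seq):
                continue
            registry.add(seq)
            accepted += 1
            break
        else:
            raise RuntimeError(
                f"could not generate weak sequence {i} in {max_attempts} attempts; "
                "raise weak_pairing_threshold"
            )
        records.append(RnaRecord(id=f"WK{i:05d}", seq=seq, group=GROUP_WEAK))
    return records


def kmer_coverage(records: Sequence[RnaRecord], k: int = 7) -> dict[str, int]:
    """Number of sequences containing each observed k-mer (coverage report)."""
    counts: dict[str, int] = {}
    for r in records:
        seen = {r.seq[i : i + k] for i in range(len(r.seq) - k + 1)}
        for km in seen:
            counts[km] = counts.get(km, 0) + 1
    return counts


def annotate_pool(
    records: Sequence[RnaRecord],
    energy_model: Optional[EnergyModel] = None,
    alphabet: Optional[AnnotationAlphabet] = None,
    n_samples: int = 1000,
    seed: int = 0,
) -> list[RnaRecord]:
    """Attach annotation profiles to every record (deterministic per seed)."""
    energy_model = energy_model or EnergyModel()
    alphabet = alphabet or plum_alphabet()
    out = []
    for i, r in enumerate(records):
        prof = annotation_profile(
            r.seq,
            energy_model,
            alphabet,
            n_samples=n_samples,
            seed=(seed + 7919 * i) % (2**31 - 1),
        )
        out.append(r.with_profile(prof))
    return out


def assign_affinities(
    records: Sequence[RnaRecord],
    truth: GroundTruth,
    seed: int = 0,
) -> tuple[list[RnaRecord], dict]:
    """Score each record under the true model and add Gaussian noise.

    Returns the records with affinities plus a manifest fragment recording the
    truth and seed (enough to regenerate the affinities exactly).
    """
    from .training import score_records

    for r in records:
        if r.profile is None:
            raise ValueError(f"record {r.id} has no annotation profile")
    n_scores = score_records(records, truth.model)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, truth.noise_sd, size=len(records)) if truth.noise_sd > 0 \
        else np.zeros(len(records))
    y = truth.affinity_map(n_scores) + noise
    out = [r.with_affinity(float(v)) for r, v in zip(records, y)]
    manifest = {
        "truth": {
            "width": truth.model.width,
            "theta": truth.model.theta.tolist(),
            "gamma": truth.model.gamma.tolist(),
            "b_seq": truth.model.b_seq,
            "b_str": truth.model.b_str,
            "alphabet": truth.model.alphabet.name,
            "slope": truth.affinity_map.slope,
            "intercept": truth.affinity_map.intercept,
            "noise_sd": truth.noise_sd,
            "consensus": truth.consensus,
        },
        "affinity_seed": seed,
    }
    return out, manifest


def split_sets(
    records: Sequence[RnaRecord], seed: int = 0
) -> tuple[list[RnaRecord], list[RnaRecord]]:
    """Stratified half split by group tag into Set A and Set B."""
    rng = np.random.default_rng(seed)
    groups: dict[str, list[RnaRecord]] = {}
    for r in records:
        groups.setdefault(r.group or "", []).append(r)
    set_a: list[RnaRecord] = []
    set_b: list[RnaRecord] = []
    for key in sorted(groups):
        members = groups[key]
        if len(members) < 2:
            raise ValueError(f"group {key!r} has fewer than 2 records; cannot split")
        order = rng.permutation(len(members))
        half = len(members) // 2
        set_a.extend(members[i] for i in sorted(order[:half]))
        set_b.extend(members[i] for i in sorted(order[half:]))
    return set_a, set_b


def make_pool(
    design: PoolDesign,
    truth: GroundTruth,
    seed: int = 0,
    n_samples: int = 1000,
    energy_model: Optional[EnergyModel] = None,
) -> tuple[list[RnaRecord], dict]:
    """End-to-end pool synthesis: sequences, profiles, affinities, manifest."""
    energy_model = energy_model or EnergyModel()
    registry = _SubstringRegistry(design.max_shared_substring)
    stemloops = make_stemloop_pool(
        design,
        seed=seed + 1,
        plant=truth.consensus,
        plant_fraction=truth.plant_stemloop_fraction,
        registry=registry,
    )
    weaks = make_weak_pool(
        design,
        seed=seed + 2,
        plant=truth.consensus,
        plant_fraction=truth.plant_weak_fraction,
        registry=registry,
        energy_model=energy_model,
    )
    records = stemloops + weaks
    records = annotate_pool(
        records,
        energy_model,
        truth.model.alphabet,
        n_samples=n_samples,
        seed=seed + 3,
    )
    records, manifest = assign_affinities(records, truth, seed=seed + 4)
    manifest.update(
        {
            "design": asdict(design),
            "pool_seed": seed,
            "n_samples": n_samples,
            "n_records": len(records),
        }
    )
    return records, manifest
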