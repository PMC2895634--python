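"""Shared fixtures and independent oracles for the test suite.

The oracle implementations here are deliberately naive (exhaustive recursion,
per-window loops) and independent of the package's vectorized/DP code paths.
"""

from __future__ import annotations

import numpy as np
import pytest

from rbpmotif import (
    EnergyModel,
    PoolDesign,
    TrainingConfig,
    default_ground_truth,
    make_pool,
    split_sets,
)

BASES = "ACGU"


# ---------------------------------------------------------------------------
# independent folding oracles
# ---------------------------------------------------------------------------

def can_pair(a: str, b: str) -> bool:
    return a + b in ("AU", "UA", "GC", "CG", "GU", "UG")


def count_structures(seq: str, min_hairpin: int = 3) -> int:
    """Independent recursive counter of legal non-crossing structures."""

    from functools import lru_cache

    @lru_cache(maxsize=None)
    def c(i: int, j: int) -> int:
        if j - i < min_hairpin + 1:
            return 1
        total = c(i + 1, j)
        for k in range(i + min_hairpin + 1, j + 1):
            if can_pair(seq[i], seq[k]):
                inner = c(i + 1, k - 1)
                rest = c(k + 1, j) if k + 1 <= j else 1
                total += inner * rest
        return total

    return c(0, len(seq) - 1)


def enumerate_partner_lists(seq: str, min_hairpin: int = 3):
    """Yield every legal structure as a partner list (independent recursion)."""
    n = len(seq)

    def rec(positions):
        if not positions:
            yield []
            return
        i = positions[0]
        # i unpaired
        for rest in rec(positions[1:]):
            yield rest
        for idx in range(1, len(positions)):
            j = positions[idx]
            if j - i <= min_hairpin or not can_pair(seq[i], seq[j]):
                continue
            inside = [p for p in positions[1:idx]]
            outside = positions[idx + 1:]
            for a in rec(inside):
                for b in rec(outside):
                    yield [(i, j)] + a + b

    for pairs in rec(list(range(n))):
        partner = [-1] * n
        for i, j in pairs:
            partner[i], partner[j] = j, i
        yield partner


def oracle_energy(partner, seq: str, model: EnergyModel) -> float:
    e = 0.0
    for i, j in ((i, p) for i, p in enumerate(partner) if p > i):
        e += model.pair_scores[_pair_key(seq[i], seq[j], model)]
        if i + 1 < j - 1 and partner[i + 1] == j - 1:
            e += model.stack_bonus
    return e


def _pair_key(a: str, b: str, model: EnergyModel) -> str:
    for key in (a + b, b + a):
        if key in model.pair_scores:
            return key
    raise AssertionError(f"non-canonical pair {a}{b}")


def oracle_loop_categories(partner) -> list[str]:
    """Independent loop decomposition: structural category per position.

    For every unpaired position, finds its nearest enclosing pair by direct
    scanning, then classifies that loop by counting its direct inner helices
    and which sides carry unpaired bases.  Categories match
    rbpmotif.alphabet.CATEGORIES names.
    """
    n = len(partner)
    out = []
    for i in range(n):
        if partner[i] >= 0:
            out.append("paired")
            continue
        enclosing = None
        best_span = None
        for p in range(n):
            q = partner[p]
            if q > p and p < i < q:
                if best_span is None or q - p < best_span:
                    best_span = q - p
                    enclosing = (p, q)
        if enclosing is None:
            out.append("external")
            continue
        p, q = enclosing
        children = []
        unpaired = []
        t = p + 1
        while t < q:
            if partner[t] > t:
                children.append((t, partner[t]))
                t = partner[t] + 1
            else:
                unpaired.append(t)
                t += 1
        if len(children) == 0:
            out.append("hairpin_loop")
        elif len(children) >= 2:
            out.append("multiloop")
        else:
            (c1, c2) = children[0]
            left = [u for u in unpaired if u < c1]
            right = [u for u in unpaired if u > c2]
            out.append("internal_loop" if (left and right) else "bulge")
    return out


def oracle_loop_contexts(partner) -> str:
    """PLUM letters from :func:`oracle_loop_categories`."""
    mapping = {
        "paired": "P",
        "hairpin_loop": "L",
        "external": "U",
        "bulge": "M",
        "internal_loop": "M",
        "multiloop": "M",
    }
    return "".join(mapping[c] for c in oracle_loop_categories(partner))


def random_rna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


# ---------------------------------------------------------------------------
# shared synthetic pool (session-scoped: several test modules reuse it)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_pool():
    """A 300+300 planted-motif pool with profiles and affinities."""
    design = PoolDesign(n_stemloop=300, n_weak=300)
    truth = default_ground_truth()
    records, manifest = make_pool(design, truth, seed=101, n_samples=250)
    return records, truth, manifest


@pytest.fixture(scope="session")
def small_pool_split(small_pool):
    records, truth, _ = small_pool
    set_a, set_b = split_sets(records, seed=7)
    return set_a, set_b, truth


@pytest.fixture
def quick_config():
    return TrainingConfig(
        widths=(5, 6, 7), restarts_per_width=3, base_seed=23, subsets=("full",)
    )
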