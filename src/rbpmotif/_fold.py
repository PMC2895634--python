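"""Numba kernels for the secondary-structure partition function and sampler.

Everything here works on integer-coded sequences (A=0, C=1, G=2, U=3) and a
4x4 matrix of Boltzmann pair weights.  The dynamic program uses inclusive
intervals [i, j]; empty intervals have weight 1.  ``zb[i, j]`` is the summed
weight of all structures on [i, j] in which (i, j) is a pair, including the
pair's own energy and a stacking bonus when (i+1, j-1) is also paired.

The traceback uses an internal xorshift128+ generator so that sampling is
bit-reproducible for a given seed regardless of the NumPy/Numba version.
"""

from __future__ import annotations

import numpy as np
from numba import njit

UNPAIRED = -1

# loop-context category codes (order matches alphabet.CATEGORIES)
CAT_PAIRED = 0
CAT_HAIRPIN = 1
CAT_EXTERNAL = 2
CAT_BULGE = 3
CAT_INTERNAL = 4
CAT_MULTI = 5


@njit(cache=True)
def _xorshift128p(state):
    s1 = state[0]
    s0 = state[1]
    state[0] = s0
    s1 ^= (s1 << np.uint64(23)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    s1 ^= s1 >> np.uint64(17)
    s1 ^= s0
    s1 ^= s0 >> np.uint64(26)
    state[1] = s1
    return (state[0] + state[1]) & np.uint64(0xFFFFFFFFFFFFFFFF)


@njit(cache=True)
def _uniform(state):
    # 53-bit mantissa uniform in [0, 1)
    return (_xorshift128p(state) >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True)
def seed_state(seed):
    # splitmix64 expansion of a small seed into a non-zero 128-bit state
    state = np.empty(2, dtype=np.uint64)
    x = np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15)
    for k in range(2):
        z = x
        z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        z = z ^ (z >> np.uint64(31))
        state[k] = z
        x = x + np.uint64(0x9E3779B97F4A7C15)
    if state[0] == np.uint64(0) and state[1] == np.uint64(0):
        state[0] = np.uint64(1)
    return state


@njit(cache=True)
def fill_partition(codes, pair_w, stack_mult, min_hairpin):
    """Inside fill. Returns (z, zb); total weight is z[0, n-1]."""
    n = codes.shape[0]
    z = np.ones((n, n))
    zb = np.zeros((n, n))
    for span in range(2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span - 1
            q = pair_w[codes[i], codes[j]]
            if q > 0.0 and j - i - 1 >= min_hairpin:
                interior = 1.0 if j - 1 < i + 1 else z[i + 1, j - 1]
                stacked = 0.0 if j - 1 < i + 1 else zb[i + 1, j - 1]
                zb[i, j] = q * (interior + (stack_mult - 1.0) * stacked)
            total = z[i + 1, j] if i + 1 <= j else 1.0
            for k in range(i + min_hairpin + 1, j + 1):
                if zb[i, k] > 0.0:
                    rest = z[k + 1, j] if k + 1 <= j else 1.0
                    total += zb[i, k] * rest
            z[i, j] = total
    return z, zb


# traceback task modes
_FREE = 0          # sample structure on [i, j]
_EXCL = 1          # sample on [i, j] excluding the full pair (i, j)
_INTERIOR = 2      # (i, j) already paired; sample its interior


@njit(cache=True)
def _traceback(codes, pair_w, stack_mult, min_hairpin, z, zb, state, partner):
    n = codes.shape[0]
    partner[:] = UNPAIRED
    stack = np.empty((4 * n + 8, 3), dtype=np.int64)
    top = 0
    stack[top, 0] = 0
    stack[top, 1] = n - 1
    stack[top, 2] = _FREE
    top += 1
    while top > 0:
        top -= 1
        i = stack[top, 0]
        j = stack[top, 1]
        mode = stack[top, 2]
        if mode == _INTERIOR:
            a, b = i + 1, j - 1
            if b < a:
                continue
            interior = z[a, b]
            stacked = zb[a, b]
            total = interior + (stack_mult - 1.0) * stacked
            u = _uniform(state) * total
            if u < stack_mult * stacked:
                partner[a] = b
                partner[b] = a
                stack[top, 0] = a
                stack[top, 1] = b
                stack[top, 2] = _INTERIOR
                top += 1
            else:
                stack[top, 0] = a
                stack[top, 1] = b
                stack[top, 2] = _EXCL
                top += 1
            continue
        # interval sampling; `mode` EXCL forbids the single pair (i, j)
        excl = mode == _EXCL
        while i < j:
            w_total = z[i, j] - (zb[i, j] if excl else 0.0)
            u = _uniform(state) * w_total
            w_un = z[i + 1, j] if i + 1 <= j else 1.0
            if u < w_un:
                i += 1
                excl = False
                continue
            u -= w_un
            k_hi = j - 1 if excl else j
            chosen = -1
            for k in range(i + min_hairpin + 1, k_hi + 1):
                if zb[i, k] <= 0.0:
                    continue
                rest = z[k + 1, j] if k + 1 <= j else 1.0
                w = zb[i, k] * rest
                if u < w:
                    chosen = k
                    break
                u -= w
            if chosen < 0:
                # numerical remainder: take the last legal k
                for k in range(k_hi, i + min_hairpin, -1):
                    if zb[i, k] > 0.0:
                        chosen = k
                        break
            partner[i] = chosen
            partner[chosen] = i
            stack[top, 0] = i
            stack[top, 1] = chosen
            stack[top, 2] = _INTERIOR
            top += 1
            i = chosen + 1
            excl = False


@njit(cache=True)
def sample_partners(codes, pair_w, stack_mult, min_hairpin, z, zb, n_samples, seed):
    """Draw ``n_samples`` structures; returns (n_samples, n) partner matrix."""
    n = codes.shape[0]
    state = seed_state(seed)
    out = np.empty((n_samples, n), dtype=np.int64)
    row = np.empty(n, dtype=np.int64)
    for s in range(n_samples):
        _traceback(codes, pair_w, stack_mult, min_hairpin, z, zb, state, row)
        out[s, :] = row
    return out


@njit(cache=True)
def classify_partner(partner, cats):
    """Assign a structural-category code to every position of one structure."""
    n = partner.shape[0]
    for i in range(n):
        if partner[i] >= 0:
            cats[i] = CAT_PAIRED
    # external bases: walk the top level
    i = 0
    while i < n:
        if partner[i] > i:
            i = partner[i] + 1
        elif partner[i] < 0:
            cats[i] = CAT_EXTERNAL
            i += 1
        else:  # pragma: no cover - closing partner at top level is impossible
            i += 1
    # loops: for each pair (p, q), classify unpaired bases directly inside
    for p in range(n):
        q = partner[p]
        if q <= p:
            continue
        n_children = 0
        child_start = -1
        child_end = -1
        n_unpaired = 0
        t = p + 1
        while t < q:
            if partner[t] > t:
                n_children += 1
                if n_children == 1:
                    child_start = t
                    child_end = partner[t]
                t = partner[t] + 1
            else:
                n_unpaired += 1
                t += 1
        if n_unpaired == 0:
            continue
        if n_children == 0:
            cat = CAT_HAIRPIN
        elif n_children == 1:
            left = child_start - p - 1
            right = q - child_end - 1
            cat = CAT_INTERNAL if (left > 0 and right > 0) else CAT_BULGE
        else:
            cat = CAT_MULTI
        t = p + 1
        while t < q:
            if partner[t] > t:
                t = partner[t] + 1
            else:
                cats[t] = cat
                t += 1
    return cats


@njit(cache=True)
def profile_counts(partners, n_categories=6):
    """Per-position counts of each structural category over sampled structures."""
    n_samples, n = partners.shape
    counts = np.zeros((n_categories, n), dtype=np.int64)
    cats = np.empty(n, dtype=np.int64)
    for s in range(n_samples):
        cats[:] = -1
        classify_partner(partners[s], cats)
        for i in range(n):
            counts[cats[i], i] += 1
    return counts
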