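"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by the most literal method available
(full dynamic-programming matrices, explicit base sets, cumulative sums) so
they share no code path with the implementations they check.
"""

import numpy as np
from numba import njit


@njit
def full_smith_waterman(q, t, match, mismatch, gap_open, gap_extend):
    """Unrestricted full-matrix affine-gap local alignment score."""
    n, m = q.shape[0], t.shape[0]
    NEG = -(10**9)
    H = np.zeros((n + 1, m + 1), np.int64)
    E = np.full((n + 1, m + 1), NEG, np.int64)
    F = np.full((n + 1, m + 1), NEG, np.int64)
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if (q[i - 1] == t[j - 1] and q[i - 1] < 4) else mismatch
            E[i, j] = max(H[i, j - 1] + gap_open + gap_extend, E[i, j - 1] + gap_extend)
            F[i, j] = max(H[i - 1, j] + gap_open + gap_extend, F[i - 1, j] + gap_extend)
            h = max(0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
            H[i, j] = h
            if h > best:
                best = h
    return best


def n50_by_cumsum(lengths, fraction=0.5):
    """Descending sort, cumulative sum, first crossing."""
    lens = sorted(lengths, reverse=True)
    total = sum(lens)
    running = 0
    for l in lens:
        running += l
        if running >= fraction * total:
            return l
    raise AssertionError("unreachable")


def union_by_base_set(intervals):
    """Total covered length via an explicit set of integer positions."""
    bases = set()
    for s, e in intervals:
        bases.update(range(s, e))
    return len(bases)


def mutated_substring(rng, target, min_len=50, max_len=200):
    """A substring of `target` carrying planted substitutions and indels at
    the high-identity densities the seed-and-extend paradigm is defined for
    (seeds must exist between adjacent mutations); returns the query string."""
    m = len(target)
    s0 = int(rng.integers(0, max(1, m - min_len)))
    e0 = int(rng.integers(s0 + min_len, min(m, s0 + max_len) + 1))
    q = list(target[s0:e0])
    n_subs = int(rng.integers(0, max(2, len(q) // 15)))
    for _ in range(n_subs):
        p = int(rng.integers(0, len(q)))
        q[p] = "ACGT"[int(rng.integers(0, 4))]
    for _ in range(int(rng.integers(0, 3))):
        p = int(rng.integers(0, len(q)))
        if rng.random() < 0.5 and len(q) > min_len + 2:
            del q[p]
        else:
            q.insert(p, "ACGT"[int(rng.integers(0, 4))])
    return "".join(q)
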