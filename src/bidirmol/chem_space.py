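"""Counting the string spaces reachable by uni- vs bidirectional growers.

A seed of N tokens inside a window of M positions over an alphabet of L
tokens can be completed by a unidirectional model in exactly ``L**(M-N)``
ways (all completions on one side), while a bidirectional model also
chooses where the seed sits, giving the dominant term
``L**(M-N) * (M - N + 1)`` — positions times completions — before
correcting for strings that contain the seed more than once.  Rather than
a closed-form correction series, the exact count of length-M strings
containing the pattern at least once is computed with a
Knuth-Morris-Pratt failure-function automaton dynamic programme
(``O(M * N * L)``), which brute-force enumeration confirms on small
instances.  All arithmetic uses arbitrary-precision integers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "SpaceQuery",
    "SpaceCounts",
    "uni_count",
    "bi_dominant_count",
    "bi_exact_count",
    "brute_force_count",
    "check_aperiodicity",
    "space_counts",
]


@dataclass(frozen=True)
class SpaceQuery:
    """Alphabet size L, window length M, constraint length N."""

    L: int
    M: int
    N: int
    pattern: tuple | None = None

    def __post_init__(self):
        if not (1 <= self.N <= self.M):
            raise ValueError("need 1 <= N <= M")
        if self.L < 1:
            raise ValueError("alphabet must be non-empty")
        if self.pattern is not None and len(self.pattern) != self.N:
            raise ValueError("pattern length differs from N")


@dataclass(frozen=True)
class SpaceCounts:
    uni: int
    bi_dominant: int
    bi_exact: int | None = None


def uni_count(q: SpaceQuery) -> int:
    """|D_uni| = L**(M-N): one-sided completions of the constraint."""
    return q.L ** (q.M - q.N)


def bi_dominant_count(q: SpaceQuery) -> int:
    """First (dominant) term of |D_bi|: L**(M-N) * (M-N+1)."""
    return q.L ** (q.M - q.N) * (q.M - q.N + 1)


def _kmp_failure(pattern: Sequence) -> list[int]:
    fail = [0] * len(pattern)
    k = 0
    for i in range(1, len(pattern)):
        while k and pattern[i] != pattern[k]:
            k = fail[k - 1]
        if pattern[i] == pattern[k]:
            k += 1
        fail[i] = k
    return fail


def bi_exact_count(pattern: Sequence, alphabet: Sequence, m: int) -> int:
    """Exact number of length-m strings over ``alphabet`` containing
    ``pattern`` as a contiguous substring at least once."""
    pattern = list(pattern)
    alphabet = list(alphabet)
    n, L = len(pattern), len(alphabet)
    if n == 0:
        raise ValueError("empty pattern")
    if len(set(alphabet)) != L:
        raise ValueError("alphabet has repeats")
    if any(tok not in alphabet for tok in pattern):
        raise ValueError("pattern tokens must come from the alphabet")
    if n > m:
        return 0
    fail = _kmp_failure(pattern)
    # delta[state][symbol] -> next match length, for states 0..n-1
    delta = []
    for state in range(n):
        row = {}
        for sym in alphabet:
            k = state
            while k and pattern[k] != sym:
                k = fail[k - 1]
            row[sym] = k + 1 if pattern[k] == sym else 0
        delta.append(row)
    # count strings that always stay below the accepting state
    counts = [0] * n
    counts[0] = 1
    for _ in range(m):
        nxt = [0] * n
        for state in range(n):
            c = counts[state]
            if not c:
                continue
            for sym in alphabet:
                to = delta[state][sym]
                if to < n:
                    nxt[to] += c
        counts = nxt
    return L ** m - sum(counts)


def brute_force_count(pattern: Sequence, alphabet: Sequence, m: int) -> int:
    """Exhaustive enumeration oracle (use only for tiny instances)."""
    from itertools import product

    pattern = tuple(pattern)
    n = len(pattern)
    hits = 0
    for s in product(tuple(alphabet), repeat=m):
        if any(s[i:i + n] == pattern for i in range(m - n + 1)):
            hits += 1
    return hits


def check_aperiodicity(pattern: Sequence) -> bool:
    """True iff no proper divisor period tiles the pattern exactly
    (ABCABC is periodic; ABCABCA is aperiodic)."""
    pattern = list(pattern)
    n = len(pattern)
    if n == 0:
        raise ValueError("empty pattern")
    for p in range(1, n):
        if n % p == 0 and pattern == pattern[:p] * (n // p):
            return False
    return True


def space_counts(pattern: Sequence, alphabet: Sequence, m: int) -> SpaceCounts:
    """All three counts for an explicit pattern and alphabet."""
    q = SpaceQuery(L=len(alphabet), M=m, N=len(pattern),
                   pattern=tuple(pattern))
    return SpaceCounts(
        uni=uni_count(q),
        bi_dominant=bi_dominant_count(q),
        bi_exact=bi_exact_count(pattern, alphabet, m),
    )
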