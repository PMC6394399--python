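"""Literal classical-BWT construction on the lifted sequence; test oracle.

A panel of H haplotypes over n sites is embedded ("lifted") into a single
sequence X of length 2Hn over an enlarged ordered alphabet

    p_0 < p_1 < ... < p_{n-2} < p_{n-1}^0 < ... < p_{n-1}^{H-1} < 0 < 1 (< 2 ...)

by inserting the position symbol p_j after every allele x_i[j]; the final
position symbol of haplotype j is the distinct symbol p_{n-1}^j, which fixes
the initial ordering of the cyclic shifts.  Sorting all 2Hn cyclic shifts of
X naively and reading off the last column yields the classical BWT, whose
first Hn characters coincide with the PBWT of the panel.  This module exists
purely as a correctness oracle at test scale (O((Hn)^2 log Hn) sorting); no
attempt is made at efficient suffix sorting.

Symbols are represented as ordered integer triples: position symbols
``(0, i, 0)`` (``(0, n-1, j)`` for the H specialized final symbols) and
allele symbols ``(1, a, 0)``.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass

import numpy as np

from .panel_io import HaplotypePanel

__all__ = [
    "LiftedSequence",
    "BWTTable",
    "lift",
    "build_bwt_naive",
    "bwt_search",
    "lift_pattern",
    "pos_symbol",
    "allele_symbol",
]

Symbol = tuple[int, int, int]


def pos_symbol(i: int, j: int = 0) -> Symbol:
    """Position symbol p_i; pass j to select the specialized p_{n-1}^j."""
    return (0, i, j)


def allele_symbol(a: int) -> Symbol:
    return (1, a, 0)


@dataclass
class LiftedSequence:
    symbols: list  # length 2Hn, alternating allele / position symbols
    H: int
    n: int


@dataclass
class BWTTable:
    """Sorted cyclic shifts of a lifted sequence, with C/rank support."""

    pi: list  # sorting permutation of the 2Hn cyclic shifts
    last_column: list  # BWT(X)
    _sorted_symbols: list  # distinct symbols of X, ascending
    _cum_counts: list  # cum_counts[t] = total count of symbols < sorted[t]
    _prefix: dict  # symbol -> (N+1)-array of prefix counts in last_column

    @property
    def N(self) -> int:
        return len(self.last_column)

    def C(self, a: Symbol) -> int:
        """Number of symbols in X strictly less than ``a`` (any ``a``)."""
        t = bisect_left(self._sorted_symbols, a)
        if t == len(self._sorted_symbols):
            return self.N
        base = self._cum_counts[t]
        return base

    def R(self, a: Symbol, i: int) -> int:
        """Occurrences of ``a`` in last_column[0, i); 0 for absent symbols."""
        arr = self._prefix.get(a)
        return 0 if arr is None else int(arr[i])


def lift(panel: HaplotypePanel) -> LiftedSequence:
    """Interleave allele and position symbols: haplotype j contributes
    x_j[0] p_0 x_j[1] p_1 ... x_j[n-1] p_{n-1}^j."""
    H, n = panel.H, panel.n
    symbols: list[Symbol] = []
    for j in range(H):
        for i in range(n):
            symbols.append(allele_symbol(int(panel.alleles[j, i])))
            symbols.append(pos_symbol(i, j) if i == n - 1 else pos_symbol(i))
    return LiftedSequence(symbols=symbols, H=H, n=n)


def build_bwt_naive(X: LiftedSequence) -> BWTTable:
    """Sort all cyclic shifts of X lexicographically; extract the last column
    and build the C / rank tables.  Test scale only."""
    symbols = X.symbols
    N = len(symbols)
    order = sorted(set(symbols))
    enc = {s: t for t, s in enumerate(order)}
    codes = [enc[s] for s in symbols]
    if len(order) < 256:
        doubled = bytes(codes) * 2
        pi = sorted(range(N), key=lambda k: doubled[k : k + N])
    else:  # pragma: no cover - alphabets this large never arise at test scale
        doubled_list = codes * 2
        pi = sorted(range(N), key=lambda k: doubled_list[k : k + N])
    last_column = [symbols[(k - 1) % N] for k in pi]

    counts: dict[Symbol, int] = {}
    for s in symbols:
        counts[s] = counts.get(s, 0) + 1
    cum = []
    total = 0
    for s in order:
        cum.append(total)
        total += counts[s]

    prefix: dict[Symbol, np.ndarray] = {}
    for s in order:
        arr = np.zeros(N + 1, dtype=np.int64)
        for t, c in enumerate(last_column):
            arr[t + 1] = arr[t] + (1 if c == s else 0)
        prefix[s] = arr
    return BWTTable(
        pi=pi,
        last_column=last_column,
        _sorted_symbols=order,
        _cum_counts=cum,
        _prefix=prefix,
    )


def bwt_search(w: list, table: BWTTable) -> tuple[int, int]:
    """Generic backward BWT search: returns (s, e) with M_k[0, |w|) = w
    exactly for k in [s, e).  An empty interval signals no match."""
    s, e = 0, table.N
    i = len(w)
    while s < e and i > 0:  # w[i, |w|) matches M_k[0, |w|-i) for k in [s, e)
        i -= 1
        a = w[i]
        s = table.C(a) + table.R(a, s)
        e = table.C(a) + table.R(a, e)
    return s, e


def lift_pattern(w, i: int, n: int) -> list:
    """Lift an allele pattern anchored at sites [i, i+|w|) into the symbol
    alphabet: p_{i-1} w[0] p_i w[1] ... w[-1] (no leading symbol when i=0).

    Searching the lifted pattern in the classical BWT visits the same row
    intervals as the positional search; note a single-character pattern with
    i=0 has no position anchor and matches rotations at every locus.
    """
    out: list[Symbol] = []
    if i > 0:
        out.append(pos_symbol(i - 1))
    for t, a in enumerate(w):
        out.append(allele_symbol(int(a)))
        if t < len(w) - 1:
            out.append(pos_symbol(i + t))
    return out
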