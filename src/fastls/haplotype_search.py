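"""Exact subsequence search in a haplotype panel via the PBWT.

The search scans the pattern right to left, refining a sorted-row interval
with one LF step per site.  Matching is anchored: the pattern ``w`` is
compared against panel sites [anchor - |w|, anchor), the default anchor
being |w| (prefix search).  If the interval empties before the pattern is
exhausted, the last nonempty interval is returned together with the
leftmost site actually matched — the longest matched proper suffix of the
pattern.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np

from .pbwt_core import PBWTIndex

__all__ = ["MatchInterval", "search_prefix"]


class MatchInterval(NamedTuple):
    """Half-open row range [s, e) in the PBWT block at the leftmost matched
    site ``i``; s == e signals no match at all."""

    s: int
    e: int
    i: int


def search_prefix(
    index: PBWTIndex,
    w: Sequence[int],
    anchor: int | None = None,
) -> tuple[MatchInterval, list[int]]:
    """Match ``w`` against panel sites [anchor - |w|, anchor).

    Returns the match interval and the panel row ids it covers, recovered
    through the sorting permutation at the stopping site.  For a full match
    the rows are exactly the haplotypes whose subsequence at the anchored
    sites equals ``w``; for a partial match they carry the longest matched
    suffix ``w[i* - lo:]`` where ``i*`` is the reported leftmost site.
    """
    j = len(w) if anchor is None else int(anchor)
    lo = j - len(w)
    if lo < 0 or j > index.n:
        raise ValueError("pattern does not fit the panel at the given anchor")
    w = [int(a) for a in w]
    if any(not 0 <= a < index.alphabet_size for a in w):
        raise ValueError("pattern alleles outside the panel alphabet")
    s, e = 0, index.H
    i = j
    while i > lo:
        a = w[i - 1 - lo]
        ns = index._lf(s, a, i - 1)
        ne = index._lf(e, a, i - 1)
        if ns == ne:
            break
        s, e = ns, ne
        i -= 1
    interval = MatchInterval(s=s, e=e, i=i)
    rows = [int(r) for r in index.perms[i][s:e]]
    return interval, rows
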