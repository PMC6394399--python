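"""Positional Burrows-Wheeler transform index with LF/FL rank support.

The index stores, for each site i, the permutation a^i that sorts panel rows
by their allele suffix starting at site i+1 (back-to-front counting sort),
together with per-site allele frequencies f_i^a and cumulative rank tables
r_i^a(k).  The positional last-to-first mapping

    LF(k, a, i) = r_i^a(k) + sum_{c<a} f_i^c

refines a sorted-row interval by one additional matched allele; FL is its
inverse, recovered by binary search, and walks a single haplotype forward
through the per-site orderings.

Conventions: ``perms`` has n+1 slots; slot t holds a^{t-1}, so slot 0 is the
extra permutation a^{-1} (rows sorted by their full allele sequence) required
by the tracebacks, and slot n is a^{n-1} = identity.  The implicit PBWT block
at site i is x_{a^i_j}[i] = ``alleles[perms[i+1][j], i]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel_io import HaplotypePanel

__all__ = ["PBWTIndex", "build_pbwt", "lf", "fl", "rank"]


@dataclass
class PBWTIndex:
    H: int
    n: int
    alphabet_size: int
    perms: np.ndarray  # (n+1, H); perms[t] = a^{t-1}
    freqs: np.ndarray  # (n, A); f_i^a
    ranks: np.ndarray  # (n, A, H+1); ranks[i, a, k] = r_i^a(k)
    cumfreqs: np.ndarray  # (n, A+1); exclusive prefix sums of freqs
    panel_alleles: np.ndarray = None  # original H x n matrix (for block()/tracebacks)

    def block(self, i: int) -> np.ndarray:
        """Alleles of PBWT block i: x_{a^i_0}[i], ..., x_{a^i_{H-1}}[i]."""
        if not 0 <= i < self.n:
            raise ValueError(f"site {i} out of range [0, {self.n})")
        return self.panel_alleles[self.perms[i + 1], i]

    # unchecked fast paths used by the inner loops
    def _lf(self, k: int, a: int, i: int) -> int:
        return int(self.ranks[i, a, k] + self.cumfreqs[i, a])

    def _fl(self, k: int, i: int) -> tuple[int, int]:
        cf = self.cumfreqs[i]
        a = int(np.searchsorted(cf, k, side="right")) - 1
        ra = self.ranks[i, a]
        off = cf[a]
        lo, hi = 0, self.H
        while lo < hi:  # LF(j,a,i) <= k for j < lo; > k for j >= hi
            mid = (lo + hi) // 2
            if ra[mid] + off <= k:
                lo = mid + 1
            else:
                hi = mid
        return a, lo - 1


def build_pbwt(panel: HaplotypePanel) -> PBWTIndex:
    """Build the PBWT index by stable counting sort per site, back to front.

    Runs in O(Hn) for the binary alphabet (O(Hn|A|) in general).  The output
    includes the extra permutation a^{-1}, stored at slot 0.
    """
    alleles = panel.alleles
    H, n, A = panel.H, panel.n, panel.alphabet_size
    perms = np.empty((n + 1, H), dtype=np.int64)
    freqs = np.zeros((n, A), dtype=np.int64)
    ranks = np.zeros((n, A, H + 1), dtype=np.int64)
    perm = np.arange(H, dtype=np.int64)
    perms[n] = perm
    for i in range(n - 1, -1, -1):
        col = alleles[perm, i]
        parts = []
        for a in range(A):
            mask = col == a
            freqs[i, a] = int(mask.sum())
            np.cumsum(mask, out=ranks[i, a, 1:])
            parts.append(perm[mask])
        perm = np.concatenate(parts)
        perms[i] = perm
    cumfreqs = np.zeros((n, A + 1), dtype=np.int64)
    np.cumsum(freqs, axis=1, out=cumfreqs[:, 1:])
    return PBWTIndex(
        H=H, n=n, alphabet_size=A, perms=perms, freqs=freqs, ranks=ranks,
        cumfreqs=cumfreqs, panel_alleles=alleles,
    )


def _check_site(index: PBWTIndex, i: int) -> None:
    if not 0 <= i < index.n:
        raise ValueError(f"site {i} out of range [0, {index.n})")


def lf(index: PBWTIndex, k: int, a: int, i: int) -> int:
    """Positional last-to-first mapping LF(k, a, i).

    Maps offset ``k`` in PBWT block i to the offset, in block i-1, of the
    first row at or after ``k`` once the matched alleles are extended by
    ``a`` at site i.  Monotone nondecreasing in ``k``; for the binary case
    LF(k,1,i) = f_i^0 + k - r_i^0(k).
    """
    _check_site(index, i)
    if not 0 <= k <= index.H:
        raise ValueError(f"offset {k} out of range [0, {index.H}]")
    if not 0 <= a < index.alphabet_size:
        raise ValueError(f"allele {a} out of range [0, {index.alphabet_size})")
    return index._lf(k, a, i)


def fl(index: PBWTIndex, k: int, i: int) -> tuple[int, int]:
    """First-to-last mapping: inverse of ``lf`` by binary search, O(log H).

    Given a row offset ``k`` in block i-1, returns ``(a, j)`` where ``a`` is
    the allele at site i of the corresponding haplotype and ``j`` its offset
    in block i, i.e. the unique pair with lf(j, a, i) <= k < lf(j+1, a, i)
    and ``a`` determined by the cumulative frequency block containing ``k``.
    """
    _check_site(index, i)
    if not 0 <= k < index.H:
        raise ValueError(f"offset {k} out of range [0, {index.H})")
    return index._fl(k, i)


def rank(index: PBWTIndex, i: int, a: int, k: int) -> int:
    """r_i^a(k): occurrences of allele ``a`` in the first ``k`` entries of
    PBWT block i."""
    _check_site(index, i)
    if not 0 <= k <= index.H:
        raise ValueError(f"offset {k} out of range [0, {index.H}]")
    if not 0 <= a < index.alphabet_size:
        raise ValueError(f"allele {a} out of range [0, {index.alphabet_size})")
    return int(index.ranks[i, a, k])
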