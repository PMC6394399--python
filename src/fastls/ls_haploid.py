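"""Exact haploid Li & Stephens mosaic decoding over a PBWT (branch & bound).

A mosaic path copies the query from a sequence of reference-panel segments;
its score is m*rho + sum of mu_i over mismatching sites, where m counts all
segments (so a perfect single-segment copy scores rho).  The decoder keeps,
per site, a set of states (s, e, score): a PBWT row interval grouping all
path suffixes that share the same matched segment, plus the accumulated
suffix score.  Branch-and-bound pruning keeps the set a *full suffix set* —
guaranteed to contain a suffix of some optimal path — while discarding:

* extensions scoring >= (current minimum) + rho, since recombining out of a
  minimum-score state is at least as good; and
* recombinations whenever some minimum-score state extends with a matching
  allele, since the recombination can be postponed for free; otherwise a
  single recombination state per site suffices.

The resulting live-state count is empirically bounded independent of the
panel size H.  Recombination cost must be constant along the sequence (the
postponement argument needs it); the mutation cost may vary per site.

Scores are floats; equality comparisons (minimum-state detection, traceback
matching) use a 1e-9 relative tolerance, which is exact for integer-scaled
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .panel_io import HaplotypePanel, QueryHaplotype
from .pbwt_core import PBWTIndex

__all__ = [
    "ScoreParams",
    "HaploidState",
    "TracebackRecord",
    "MosaicPath",
    "score_path",
    "fastls_haploid",
    "traceback_haploid",
    "dedupe_states",
    "InvalidPathError",
    "InternalConsistencyError",
]

_EQ_TOL = 1e-9


def _eq(a: float, b: float) -> bool:
    return abs(a - b) <= _EQ_TOL * max(1.0, abs(a), abs(b))


class InvalidPathError(ValueError):
    """A mosaic path that does not describe contiguous panel segments."""


class InternalConsistencyError(RuntimeError):
    """Traceback walk failed to reproduce the forward-pass score."""


@dataclass(frozen=True)
class ScoreParams:
    """Recombination score rho and mutation score mu (scalar or per-site).

    These are negated log odds of the underlying copying-model
    probabilities: rho = -log(p_rho/(1 - n*p_rho)), mu = -log(p_mu/(1-3*p_mu));
    integer-scaled values keep all score arithmetic exact.
    """

    rho: float
    mu: float | np.ndarray

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ValueError("rho must be nonnegative")
        mu = np.asarray(self.mu, dtype=float)
        if mu.ndim > 1 or np.any(mu < 0):
            raise ValueError("mu must be a nonnegative scalar or 1-D vector")
        object.__setattr__(self, "mu", mu if mu.ndim else float(mu))

    @property
    def mu_is_scalar(self) -> bool:
        return np.ndim(self.mu) == 0

    def mu_vector(self, n: int) -> np.ndarray:
        if self.mu_is_scalar:
            return np.full(n, float(self.mu))
        mu = np.asarray(self.mu, dtype=float)
        if mu.size != n:
            raise ValueError(f"per-site mu has length {mu.size}, expected {n}")
        return mu


class HaploidState(NamedTuple):
    """A group of path suffixes: PBWT interval [s, e) and suffix score."""

    s: int
    e: int
    score: float


class TracebackRecord(NamedTuple):
    """Recombination opportunity recorded during the forward pass."""

    locus: int
    idx: int
    score: float


@dataclass
class MosaicPath:
    """Decoded mosaic: (start_locus, panel_row) segments, starts ascending."""

    segments: list

    @property
    def n_parts(self) -> int:
        return len(self.segments)

    def row_at(self, i: int) -> int:
        row = None
        for start, r in self.segments:
            if start > i:
                break
            row = r
        return row

    def alleles(self, panel: HaplotypePanel) -> np.ndarray:
        """Per-site copied alleles implied by the path."""
        out = np.empty(panel.n, dtype=np.int64)
        starts = [s for s, _ in self.segments] + [panel.n]
        for t, (start, row) in enumerate(self.segments):
            out[start : starts[t + 1]] = panel.alleles[row, start : starts[t + 1]]
        return out


def _validate_path(panel: HaplotypePanel, path: MosaicPath) -> None:
    if not path.segments or path.segments[0][0] != 0:
        raise InvalidPathError("first segment must start at locus 0")
    prev = -1
    for start, row in path.segments:
        if not 0 <= start < panel.n:
            raise InvalidPathError(f"segment start {start} outside [0, {panel.n})")
        if start <= prev:
            raise InvalidPathError("segment starts must be strictly increasing")
        if not 0 <= row < panel.H:
            raise InvalidPathError(f"panel row {row} outside [0, {panel.H})")
        prev = start


def score_path(
    panel: HaplotypePanel,
    x: QueryHaplotype,
    path: MosaicPath,
    params: ScoreParams,
) -> float:
    """Path score m*rho + sum(mu_i over mismatching sites)."""
    if x.n != panel.n:
        raise InvalidPathError("query length must equal panel site count")
    _validate_path(panel, path)
    mu = params.mu_vector(panel.n)
    mism = path.alleles(panel) != x.alleles
    return path.n_parts * params.rho + float(mu[mism].sum())


def dedupe_states(states: list) -> list:
    """Drop exact duplicates and dominated states.

    A state (s, e, score) is dominated by (s', e', score') when the latter
    has a containing interval (s' <= s, e' >= e) and no worse score; its
    extensions can never improve on the dominating state's, so removing it
    leaves every later minimum unchanged.
    """
    out = []
    for t, (s, e, sc) in enumerate(states):
        dominated = False
        for u, (s2, e2, sc2) in enumerate(states):
            if u == t:
                continue
            if s2 <= s and e2 >= e and sc2 <= sc:
                if (s2, e2, sc2) != (s, e, sc) or u < t:
                    dominated = True
                    break
        if not dominated:
            out.append(states[t])
    return out


def fastls_haploid(
    index: PBWTIndex,
    x: QueryHaplotype,
    params: ScoreParams,
    *,
    dedupe: bool = True,
    state_counts: Optional[list] = None,
) -> tuple[float, int, list]:
    """Minimum mosaic-path score for a haploid query, with traceback data.

    Returns ``(gm, gm_idx, traceback)`` where ``gm`` is the exact minimum of
    :func:`score_path` over all mosaic paths, ``gm_idx`` the offset (in the
    final PBWT block) of a minimum-score state, and ``traceback`` the list
    of recombination records consumed by :func:`traceback_haploid`.

    ``dedupe`` toggles the redundant-state removal pass (scores are
    invariant to it); ``state_counts``, if given a list, receives the live
    state count after each site for scaling diagnostics.
    """
    if index.alphabet_size != 2:
        raise ValueError("the Li & Stephens decoder requires a binary panel")
    H, n = index.H, index.n
    if n < 1:
        raise ValueError("panel must contain at least one site")
    if x.n != n:
        raise ValueError("query length must equal panel site count")
    if params.rho <= 0:
        raise ValueError(
            "fastls_haploid requires rho > 0 (pruning postpones recombinations "
            "at cost rho; a zero cost admits no bound)"
        )
    rho = float(params.rho)
    mu = params.mu_vector(n)
    xq = np.asarray(x.alleles)
    if xq.min() < 0 or xq.max() > 1:
        raise ValueError("query alleles must be 0/1")
    lf_ = index._lf

    st: list[tuple[int, int, float]] = [(0, H, 0.0)]
    gm = 0.0
    traceback: list[TracebackRecord] = [TracebackRecord(n - 1, -1, -1.0)]
    dedupe_base = 1
    for i in range(n - 1, -1, -1):
        a = int(xq[i])
        b = 1 - a
        mui = float(mu[i])
        st2: list[tuple[int, int, float]] = []
        gm2 = gm + mui
        extended = False
        gm_rep = -1  # offset of the first minimum-score incoming state
        for (s, e, score) in st:
            if gm_rep < 0 and _eq(score, gm):
                gm_rep = s
            if score < gm + rho:
                s2 = lf_(s, a, i)
                e2 = lf_(e, a, i)
                if s2 < e2:
                    st2.append((s2, e2, score))
                    if score < gm2:
                        gm2 = score
                    if _eq(score, gm):
                        extended = True
            if score + mui < gm2 + rho:
                s2 = lf_(s, b, i)
                e2 = lf_(e, b, i)
                if s2 < e2:
                    st2.append((s2, e2, score + mui))
        if not extended:
            s2 = lf_(0, a, i)
            e2 = lf_(H, a, i)
            if s2 < e2:
                # impossible at the first site: the initial state spans all
                # rows, so a nonempty match extension also marks `extended`
                assert i < n - 1, "recombination state on the first iteration"
                st2.append((s2, e2, gm + rho))
                if gm + rho < gm2:
                    gm2 = gm + rho
                traceback.append(TracebackRecord(i, gm_rep, gm + rho))
        gm, st = gm2, st2
        if dedupe and (
            (n - 1 - i) % 32 == 31 or len(st) > 4 * dedupe_base
        ):
            st = dedupe_states(st)
            dedupe_base = max(1, len(st))
        if state_counts is not None:
            state_counts.append(len(st))
    best = min(score for _, _, score in st)
    assert _eq(best, gm)
    gm_idx = min(s for s, _, score in st if _eq(score, gm))
    return gm + rho, gm_idx, traceback


def traceback_haploid(
    index: PBWTIndex,
    x: QueryHaplotype,
    params: ScoreParams,
    gm: float,
    gm_idx: int,
    traceback: list,
) -> MosaicPath:
    """Recover a minimum-scoring mosaic path by a forward FL walk.

    Starting from a minimum-score row, the walk advances one site at a time
    through the per-site orderings, deducting mu_i at mismatches; a recorded
    recombination is followed greedily whenever the remaining score matches
    its record.  The result always rescores to ``gm``.
    """
    rho = float(params.rho)
    mu = params.mu_vector(index.n)
    xq = np.asarray(x.alleles)
    g = gm - rho  # internal suffix-score scale (first segment's rho excluded)
    i = 0
    idx = gm_idx
    segments = [(0, int(index.perms[0][idx]))]
    for rec in reversed(traceback):
        while i <= rec.locus:
            a, idx = index._fl(idx, i)
            if a != xq[i]:
                g -= mu[i]
            i += 1
        if _eq(g, rec.score):
            idx = rec.idx
            g -= rho
            segments.append((i, int(index.perms[i][idx])))
    if not _eq(g, 0.0):
        raise InternalConsistencyError(
            f"traceback finished with residual score {g!r}, expected 0"
        )
    return MosaicPath(segments=segments)
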