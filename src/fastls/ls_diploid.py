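"""Exact diploid Li & Stephens: best pair of mosaic paths for a genotype.

A genotype sequence g (values 0/1/2 per site) is explained by an unordered
pair of mosaic paths {alpha, beta}; the pair score is

    s(alpha, beta) = rho*m(alpha) + rho*m(beta) + mu * sum_i |alpha_i + beta_i - g_i|

with m counting all segments of each path.  The decoder generalizes the
haploid branch-and-bound: states are pairs of PBWT intervals plus a suffix
score, extensions range over allele pairs (a1, a2), and pruning compares
each candidate against the global minimum (bound + 2*rho) and against the
per-group minima lm[(s, e)] (bound + rho) — recombining one or both paths
out of a minimum-score pair is at least as good as keeping a worse pair.
Single recombinations are only considered when the kept extension is
genotype-compatible (a1 + a2 = 1 at heterozygous sites; the recombining
allele equal to g_i/2 at homozygous sites) and no minimum-score partner
already extends; one double recombination per site suffices.

Only a scalar mutation score is supported: the pruning argument has not
been extended to position-dependent mu for pairs, so per-site mu is
rejected at the API boundary.
"""

from __future__ import annotations

from typing import NamedTuple, Optional

import numpy as np

from .panel_io import HaplotypePanel, QueryGenotype
from .pbwt_core import PBWTIndex
from .ls_haploid import (
    InternalConsistencyError,
    MosaicPath,
    ScoreParams,
    _eq,
    _validate_path,
)

__all__ = [
    "DiploidState",
    "DiploidTracebackRecord",
    "score_pair",
    "fastls_diploid",
    "traceback_diploid",
]

_INF = float("inf")


class DiploidState(NamedTuple):
    """Two PBWT intervals (unordered pair semantics) and a suffix score."""

    s1: int
    e1: int
    s2: int
    e2: int
    score: float


class DiploidTracebackRecord(NamedTuple):
    """Recorded recombination: [start, end) bounds the non-recombining
    path's rows; end == -1 encodes a double recombination."""

    locus: int
    start: int
    end: int
    idx: int
    score: float


def score_pair(
    panel: HaplotypePanel,
    g: QueryGenotype,
    alpha: MosaicPath,
    beta: MosaicPath,
    params: ScoreParams,
) -> float:
    """rho*m(alpha) + rho*m(beta) + mu * sum |alpha_i + beta_i - g_i|."""
    if g.n != panel.n:
        raise ValueError("genotype length must equal panel site count")
    if not params.mu_is_scalar:
        raise ValueError("the diploid model supports a scalar mu only")
    _validate_path(panel, alpha)
    _validate_path(panel, beta)
    dosage = alpha.alleles(panel) + beta.alleles(panel)
    k = int(np.abs(dosage - g.genotypes).sum())
    return (alpha.n_parts + beta.n_parts) * params.rho + k * float(params.mu)


def _consider_recomb(c: int, a1: int, a2: int, j: int) -> bool:
    """Is a single recombination with recombining-path allele (a1,a2)[j]
    worth considering at a site with genotype c?"""
    if c == 1:
        return a1 + a2 == 1
    return (a1, a2)[j] == c // 2


def _dedupe_pairs(states: list) -> list:
    """Drop exact duplicate pair states (compared as unordered pairs)."""
    seen = set()
    out = []
    for st in states:
        s1, e1, s2, e2, score = st
        key = (min((s1, e1), (s2, e2)), max((s1, e1), (s2, e2)), score)
        if key not in seen:
            seen.add(key)
            out.append(st)
    return out


def fastls_diploid(
    index: PBWTIndex,
    g: QueryGenotype,
    params: ScoreParams,
    *,
    canonicalize: bool = True,
    dedupe: bool = True,
    state_counts: Optional[list] = None,
) -> tuple[float, int, int, list]:
    """Minimum pair score for a genotype query, with traceback data.

    Returns ``(gm, gm_idx1, gm_idx2, traceback)``: the exact minimum of
    :func:`score_pair` over all unordered pairs of mosaic paths, offsets of
    a minimum-score pair state in the final PBWT block, and the
    recombination records for :func:`traceback_diploid`.

    ``canonicalize`` stores each pair with its intervals in lexicographic
    order (scores are invariant to it); ``dedupe`` removes exact duplicate
    pair states periodically.
    """
    if index.alphabet_size != 2:
        raise ValueError("the Li & Stephens decoder requires a binary panel")
    if not params.mu_is_scalar:
        raise ValueError("the diploid model supports a scalar mu only")
    H, n = index.H, index.n
    if g.n != n:
        raise ValueError("genotype length must equal panel site count")
    if params.rho <= 0:
        raise ValueError("fastls_diploid requires rho > 0")
    rho = float(params.rho)
    mu = float(params.mu)
    gq = np.asarray(g.genotypes)
    lf_ = index._lf

    st: list[tuple[int, int, int, int, float]] = [(0, H, 0, H, 0.0)]
    gm = 0.0
    lm: dict[tuple[int, int], float] = {(0, H): 0.0}
    traceback: list[DiploidTracebackRecord] = [
        DiploidTracebackRecord(n - 1, -1, -1, -1, -1.0)
    ]
    dedupe_base = 1

    for i in range(n - 1, -1, -1):
        c = int(gq[i])
        st2: list[tuple[int, int, int, int, float]] = []
        gm2 = gm + 2 * mu
        lm2: dict[tuple[int, int], float] = {}
        extended: set[tuple[int, int, int]] = set()
        double_recomb = False

        # regular pair extensions
        for (s1, e1, s2, e2, score) in st:
            prune_old = score >= min(
                lm.get((s1, e1), _INF) + rho,
                lm.get((s2, e2), _INF) + rho,
                gm + 2 * rho,
            )
            for a1 in (0, 1):
                for a2 in (0, 1):
                    if s1 == s2 and e1 == e2 and a1 > a2:
                        continue
                    if prune_old:
                        continue
                    score2 = score + mu * abs(a1 + a2 - c)
                    sp1 = lf_(s1, a1, i)
                    ep1 = lf_(e1, a1, i)
                    sp2 = lf_(s2, a2, i)
                    ep2 = lf_(e2, a2, i)
                    if sp1 == ep1 or sp2 == ep2:
                        continue
                    if score2 >= min(
                        lm2.get((sp1, ep1), _INF) + rho,
                        lm2.get((sp2, ep2), _INF) + rho,
                        gm2 + 2 * rho,
                    ):
                        continue
                    if canonicalize and (sp2, ep2) < (sp1, ep1):
                        st2.append((sp2, ep2, sp1, ep1, score2))
                    else:
                        st2.append((sp1, ep1, sp2, ep2, score2))
                    lm2[(sp1, ep1)] = min(score2, lm2.get((sp1, ep1), _INF))
                    lm2[(sp2, ep2)] = min(score2, lm2.get((sp2, ep2), _INF))
                    if score2 < gm2:
                        gm2 = score2
                    for j in (0, 1):  # j = recombining path of the pair
                        other = ((s1, e1), (s2, e2))[1 - j]
                        if _consider_recomb(c, a1, a2, j) and _eq(
                            score, lm.get(other, _INF)
                        ):
                            extended.add(other + ((a1, a2)[1 - j],))

        # single and double recombinations
        for (s1, e1, s2, e2, score) in st:
            ivs = ((s1, e1), (s2, e2))
            for a1 in (0, 1):
                for a2 in (0, 1):
                    for j in (0, 1):
                        ar = (a1, a2)[j]
                        ax = (a1, a2)[1 - j]
                        sr_in, er_in = ivs[j]
                        sx, ex = ivs[1 - j]
                        score2 = score + rho + mu * abs(ar + ax - c)
                        spr = lf_(0, ar, i)
                        epr = lf_(H, ar, i)
                        spx = lf_(sx, ax, i)
                        epx = lf_(ex, ax, i)
                        if (
                            not _consider_recomb(c, a1, a2, j)
                            or spr == epr
                            or score > lm.get((sx, ex), _INF)
                            or (sx, ex, ax) in extended
                            or score2
                            >= min(
                                lm2.get((spx, epx), _INF) + rho,
                                lm2.get((spr, epr), _INF) + rho,
                                gm2 + 2 * rho,
                            )
                        ):
                            continue
                        if spx < epx:
                            if canonicalize and (spr, epr) < (spx, epx):
                                st2.append((spr, epr, spx, epx, score2))
                            else:
                                st2.append((spx, epx, spr, epr, score2))
                            lm2[(spx, epx)] = min(score2, lm2.get((spx, epx), _INF))
                            lm2[(spr, epr)] = min(score2, lm2.get((spr, epr), _INF))
                            if score2 < gm2:
                                gm2 = score2
                            extended.add((sx, ex, ax))
                            traceback.append(
                                DiploidTracebackRecord(i, sx, ex, sr_in, score + rho)
                            )
                        if (
                            c != 1
                            and ar + ax == c
                            and not double_recomb
                            and _eq(score, gm)
                            and (sr_in, er_in, ar) not in extended
                        ):
                            if score + 2 * rho < lm2.get((spr, epr), _INF) + rho:
                                st2.append((spr, epr, spr, epr, score + 2 * rho))
                                lm2[(spr, epr)] = min(
                                    score + 2 * rho, lm2.get((spr, epr), _INF)
                                )
                                if score + 2 * rho < gm2:
                                    gm2 = score + 2 * rho
                                traceback.append(
                                    DiploidTracebackRecord(
                                        i, sx, -1, sr_in, score + 2 * rho
                                    )
                                )
                                double_recomb = True

        gm, lm, st = gm2, lm2, st2
        if dedupe and ((n - 1 - i) % 32 == 31 or len(st) > 4 * dedupe_base):
            st = _dedupe_pairs(st)
            dedupe_base = max(1, len(st))
        if state_counts is not None:
            state_counts.append(len(st))

    best = min(score for *_, score in st)
    assert _eq(best, gm)
    gm_idx1, gm_idx2 = min(
        (s1, s2) for (s1, e1, s2, e2, score) in st if _eq(score, gm)
    )
    return gm + 2 * rho, gm_idx1, gm_idx2, traceback


def traceback_diploid(
    index: PBWTIndex,
    g: QueryGenotype,
    params: ScoreParams,
    gm: float,
    gm_idx1: int,
    gm_idx2: int,
    traceback: list,
) -> tuple[MosaicPath, MosaicPath]:
    """Recover a minimum-scoring pair of mosaic paths by a dual FL walk.

    A recorded single recombination is followed when the remaining score
    matches and the non-recombining walker index lies inside the recorded
    interval; a double recombination (end == -1) resets both walkers and
    only needs the scores to agree.  The reconstructed pair always rescores
    to ``gm``.
    """
    rho = float(params.rho)
    mu = float(params.mu)
    gq = np.asarray(g.genotypes)
    gi = gm - 2 * rho
    i = 0
    idx1, idx2 = gm_idx1, gm_idx2
    path1 = [(0, int(index.perms[0][idx1]))]
    path2 = [(0, int(index.perms[0][idx2]))]
    for rec in reversed(traceback):
        while i <= rec.locus:
            a1, idx1 = index._fl(idx1, i)
            a2, idx2 = index._fl(idx2, i)
            gi -= mu * abs(a1 + a2 - int(gq[i]))
            i += 1
        if _eq(gi, rec.score):
            if rec.end == -1:  # double recombination
                idx1, idx2 = rec.start, rec.idx
                path1.append((i, int(index.perms[i][idx1])))
                path2.append((i, int(index.perms[i][idx2])))
                gi -= 2 * rho
            elif rec.start <= idx1 < rec.end:  # path 2 recombines
                idx2 = rec.idx
                path2.append((i, int(index.perms[i][idx2])))
                gi -= rho
            elif rec.start <= idx2 < rec.end:  # path 1 recombines
                idx1 = rec.idx
                path1.append((i, int(index.perms[i][idx1])))
                gi -= rho
    if not _eq(gi, 0.0):
        raise InternalConsistencyError(
            f"diploid traceback finished with residual score {gi!r}, expected 0"
        )
    return MosaicPath(segments=path1), MosaicPath(segments=path2)
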