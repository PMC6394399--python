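"""Dynamic-programming and exhaustive oracles for the Li & Stephens model.

``viterbi_haploid`` is the textbook O(Hn) DP over copied rows:

    V_0(h) = rho + mu_0 * [x_0 != x_h[0]]
    V_i(h) = mu_i * [x_i != x_h[i]] + min(V_{i-1}(h), rho + min_h' V_{i-1}(h'))

(the first segment costs rho, so m counts every part of the mosaic).
``viterbi_diploid`` is the O(H^2 n) DP over ordered row pairs with per-site
cost mu * |x_{h1}[i] + x_{h2}[i] - g_i| and transitions costing 0 / rho /
2*rho for zero, one or two switches; unordered-pair semantics is recovered
at readout.  ``enumerate_paths_min`` checks both DPs by brute enumeration
of per-site copying assignments on tiny instances, counting parts as
maximal constant runs.  These serve as independent references for the
branch-and-bound decoders and are not built for speed.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from .panel_io import HaplotypePanel, QueryGenotype, QueryHaplotype
from .ls_haploid import MosaicPath, ScoreParams

__all__ = ["viterbi_haploid", "viterbi_diploid", "enumerate_paths_min"]


def viterbi_haploid(
    panel: HaplotypePanel,
    x: QueryHaplotype,
    params: ScoreParams,
) -> tuple[float, MosaicPath]:
    """Exact minimum of the mosaic path score by standard Viterbi DP."""
    if x.n != panel.n:
        raise ValueError("query length must equal panel site count")
    H, n = panel.H, panel.n
    rho = float(params.rho)
    mu = params.mu_vector(n)
    mism = panel.alleles != x.alleles[None, :]
    V = rho + mu[0] * mism[:, 0]
    switched = np.zeros((n, H), dtype=bool)
    best_prev = np.zeros(n, dtype=np.int64)
    for i in range(1, n):
        j = int(V.argmin())
        rec = rho + V[j]
        take = rec < V  # strict: ties prefer staying (no redundant switch)
        switched[i] = take
        best_prev[i] = j
        V = np.where(take, rec, V) + mu[i] * mism[:, i]
    h = int(V.argmin())
    score = float(V[h])
    segments = []
    cur = h
    for i in range(n - 1, 0, -1):
        if switched[i, cur]:
            segments.append((i, cur))
            cur = int(best_prev[i])
    segments.append((0, cur))
    segments.reverse()
    return score, MosaicPath(segments=segments)


def viterbi_diploid(
    panel: HaplotypePanel,
    g: QueryGenotype,
    params: ScoreParams,
) -> tuple[float, tuple[MosaicPath, MosaicPath]]:
    """Exact minimum pair score by Viterbi DP over ordered row pairs."""
    if g.n != panel.n:
        raise ValueError("genotype length must equal panel site count")
    if not params.mu_is_scalar:
        raise ValueError("the diploid model supports a scalar mu only")
    H, n = panel.H, panel.n
    rho = float(params.rho)
    mu = float(params.mu)
    A = panel.alleles
    gq = np.asarray(g.genotypes)

    def cost(i: int) -> np.ndarray:
        return mu * np.abs(A[:, i][:, None] + A[:, i][None, :] - gq[i])

    layers = [2 * rho + cost(0)]
    for i in range(1, n):
        V = layers[-1]
        row_min = V.min(axis=1)  # best partner for fixed h1 (switch path 2)
        col_min = V.min(axis=0)
        glob = float(V.min())
        newV = np.minimum(
            np.minimum(V, rho + row_min[:, None]),
            np.minimum(rho + col_min[None, :], 2 * rho + glob),
        ) + cost(i)
        layers.append(newV)

    flat = int(layers[-1].argmin())
    h1, h2 = divmod(flat, H)
    score = float(layers[-1][h1, h2])
    segs1: list = []
    segs2: list = []
    for i in range(n - 1, 0, -1):
        V = layers[i - 1]
        base = layers[i][h1, h2] - cost(i)[h1, h2]
        if np.isclose(base, V[h1, h2]):
            continue
        if np.isclose(base, rho + V[h1].min()):
            nh2 = int(V[h1].argmin())
            segs2.append((i, h2))
            h2 = nh2
        elif np.isclose(base, rho + V[:, h2].min()):
            nh1 = int(V[:, h2].argmin())
            segs1.append((i, h1))
            h1 = nh1
        else:
            flat = int(V.argmin())
            segs1.append((i, h1))
            segs2.append((i, h2))
            h1, h2 = divmod(flat, H)
    segs1.append((0, h1))
    segs2.append((0, h2))
    segs1.reverse()
    segs2.reverse()
    return score, (MosaicPath(segments=segs1), MosaicPath(segments=segs2))


def enumerate_paths_min(
    panel: HaplotypePanel,
    query,
    params: ScoreParams,
    diploid: bool = False,
) -> float:
    """Global minimum score by explicit enumeration of per-site copying
    assignments; parts are maximal constant runs.  Guarded to tiny sizes."""
    H, n = panel.H, panel.n
    rho = float(params.rho)
    if diploid:
        if H > 3 or n > 4:
            raise ValueError("diploid enumeration guarded to H <= 3, n <= 4")
        mu = float(params.mu)
        gq = np.asarray(query.genotypes)
        assigns = list(product(range(H), repeat=n))
        costs = {}
        for h in assigns:
            runs = 1 + sum(h[i] != h[i - 1] for i in range(1, n))
            costs[h] = runs * rho
        best = np.inf
        A = panel.alleles
        for ha in assigns:
            da = np.array([A[ha[i], i] for i in range(n)])
            for hb in assigns:
                db = np.array([A[hb[i], i] for i in range(n)])
                sc = costs[ha] + costs[hb] + mu * np.abs(da + db - gq).sum()
                if sc < best:
                    best = float(sc)
        return best
    if H > 4 or n > 5:
        raise ValueError("haploid enumeration guarded to H <= 4, n <= 5")
    mu = params.mu_vector(n)
    xq = np.asarray(query.alleles)
    best = np.inf
    for h in product(range(H), repeat=n):
        runs = 1 + sum(h[i] != h[i - 1] for i in range(1, n))
        mismatch = sum(
            mu[i] for i in range(n) if panel.alleles[h[i], i] != xq[i]
        )
        sc = runs * rho + mismatch
        if sc < best:
            best = float(sc)
    return best
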