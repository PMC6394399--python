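import numpy as np
import pytest

from fastls import (
    HaplotypePanel,
    MosaicPath,
    QueryHaplotype,
    ScoreParams,
    build_pbwt,
    dedupe_states,
    fastls_haploid,
    score_path,
    traceback_haploid,
    viterbi_haploid,
)
from fastls.ls_haploid import InvalidPathError
from conftest import random_panel, random_query

PARAM_GRID = [  # covers mu < 2*rho, mu = 2*rho, mu > 2*rho
    (2.0, 1.0),
    (2.0, 4.0),
    (1.0, 3.0),
    (3.0, 2.0),
]


def _random_instance(rng, max_h=30, max_n=60):
    panel = random_panel(rng, max_h, max_n)
    if rng.random() < 0.5:
        x = random_query(rng, panel.n)
    else:  # noisy copy of a panel row: realistic mosaic-like query
        x = QueryHaplotype(
            np.where(
                rng.random(panel.n) < 0.1,
                1 - panel.alleles[int(rng.integers(panel.H))],
                panel.alleles[int(rng.integers(panel.H))],
            )
        )
    k = int(rng.integers(len(PARAM_GRID)))
    rho, mu = PARAM_GRID[k]
    if rng.random() < 0.25:  # per-site mutation scores
        mu = rng.integers(0, 6, panel.n).astype(float)
    return panel, x, ScoreParams(rho=rho, mu=mu)


class TestScorePath:
    def test_exact_copy_costs_rho(self):
        panel = HaplotypePanel(np.array([[0, 1, 0], [1, 1, 1]]))
        x = QueryHaplotype(np.array([0, 1, 0]))
        params = ScoreParams(rho=1.0, mu=4.0)
        assert score_path(panel, x, MosaicPath([(0, 0)]), params) == 1.0

    def test_single_mismatch_adds_mu(self):
        panel = HaplotypePanel(np.array([[0, 1, 0], [1, 1, 1]]))
        x = QueryHaplotype(np.array([0, 0, 0]))
        params = ScoreParams(rho=1.0, mu=4.0)
        assert score_path(panel, x, MosaicPath([(0, 0)]), params) == 5.0

    def test_two_segments_cost_two_rho(self):
        panel = HaplotypePanel(np.array([[0, 0, 0], [1, 1, 1]]))
        x = QueryHaplotype(np.array([0, 0, 1]))
        params = ScoreParams(rho=1.0, mu=4.0)
        assert score_path(panel, x, MosaicPath([(0, 0), (2, 1)]), params) == 2.0

    def test_per_site_mu_sums_over_mismatches(self):
        panel = HaplotypePanel(np.array([[0, 0, 0]]))
        x = QueryHaplotype(np.array([1, 0, 1]))
        params = ScoreParams(rho=1.0, mu=np.array([5.0, 7.0, 11.0]))
        assert score_path(panel, x, MosaicPath([(0, 0)]), params) == 1 + 5 + 11

    @pytest.mark.parametrize(
        "segments",
        [[(1, 0)], [(0, 0), (0, 0)], [(0, 5)], [], [(0, 0), (3, 0)]],
    )
    def test_invalid_paths_rejected(self, segments):
        panel = HaplotypePanel(np.array([[0, 1, 0], [1, 1, 1]]))
        x = QueryHaplotype(np.array([0, 1, 0]))
        with pytest.raises(InvalidPathError):
            score_path(panel, x, MosaicPath(segments), ScoreParams(1.0, 1.0))


class TestFastlsHaploid:
    def test_exact_match_costs_rho(self):
        idx = build_pbwt(HaplotypePanel(np.array([[0, 1, 0], [1, 1, 1]])))
        gm, _, _ = fastls_haploid(
            idx, QueryHaplotype(np.array([0, 1, 0])), ScoreParams(1.0, 4.0)
        )
        assert gm == 1.0

    def test_forced_recombination_beats_mismatch(self):
        idx = build_pbwt(HaplotypePanel(np.array([[0, 0, 0], [1, 1, 1]])))
        gm, _, _ = fastls_haploid(
            idx, QueryHaplotype(np.array([0, 0, 1])), ScoreParams(1.0, 4.0)
        )
        assert gm == 2.0  # two segments, zero mismatches, vs rho + mu = 5

    def test_agrees_with_viterbi_on_random_instances(self, rng):
        for _ in range(200):
            panel, x, params = _random_instance(rng)
            idx = build_pbwt(panel)
            gm, gm_idx, tb = fastls_haploid(idx, x, params)
            v, _ = viterbi_haploid(panel, x, params)
            assert gm == pytest.approx(v, abs=1e-9)
            path = traceback_haploid(idx, x, params, gm, gm_idx, tb)
            assert score_path(panel, x, path, params) == pytest.approx(gm)

    def test_monomorphic_site_against_query_is_handled(self):
        # column 1 is monomorphic 0 while the query carries 1 there
        panel = HaplotypePanel(np.array([[0, 0, 0], [1, 0, 1]]))
        x = QueryHaplotype(np.array([0, 1, 0]))
        params = ScoreParams(rho=1.0, mu=2.0)
        idx = build_pbwt(panel)
        gm, gm_idx, tb = fastls_haploid(idx, x, params)
        v, _ = viterbi_haploid(panel, x, params)
        assert gm == v == 3.0  # copy row 0 throughout, one mismatch

    def test_mu_at_least_two_rho_restricts_to_exact_mosaics(self, rng):
        # with mu >= 2*rho any mismatch can be replaced by two switches, so
        # the optimum over exact-match mosaics (mu -> inf) already attains it
        for _ in range(30):
            panel, x, _ = _random_instance(rng, max_h=15, max_n=25)
            # guarantee an exact mosaic exists at every site
            if not np.all(
                (panel.alleles == x.alleles[None, :]).any(axis=0)
            ):
                continue
            params = ScoreParams(rho=1.0, mu=2.0)
            idx = build_pbwt(panel)
            gm, _, _ = fastls_haploid(idx, x, params)
            exact_only, _ = viterbi_haploid(
                panel, x, ScoreParams(rho=1.0, mu=1e9)
            )
            assert exact_only == pytest.approx(gm)

    def test_rho_zero_rejected(self):
        idx = build_pbwt(HaplotypePanel(np.array([[0, 1]])))
        with pytest.raises(ValueError):
            fastls_haploid(
                idx, QueryHaplotype(np.array([0, 1])), ScoreParams(0.0, 1.0)
            )

    def test_traceback_exact_match_is_single_segment(self):
        panel = HaplotypePanel(np.array([[0, 1, 0], [1, 1, 1]]))
        idx = build_pbwt(panel)
        x = QueryHaplotype(np.array([1, 1, 1]))
        params = ScoreParams(1.0, 4.0)
        gm, gm_idx, tb = fastls_haploid(idx, x, params)
        path = traceback_haploid(idx, x, params, gm, gm_idx, tb)
        assert path.segments == [(0, 1)]

    def test_traceback_forced_recombination_switch_locus(self):
        panel = HaplotypePanel(np.array([[0, 0, 0], [1, 1, 1]]))
        idx = build_pbwt(panel)
        x = QueryHaplotype(np.array([0, 0, 1]))
        params = ScoreParams(1.0, 4.0)
        gm, gm_idx, tb = fastls_haploid(idx, x, params)
        path = traceback_haploid(idx, x, params, gm, gm_idx, tb)
        assert path.segments == [(0, 0), (2, 1)]
        assert score_path(panel, x, path, params) == 2.0

    def test_optimum_not_beaten_by_random_mosaics(self, rng):
        panel, x, params = _random_instance(rng, max_h=12, max_n=20)
        idx = build_pbwt(panel)
        gm, _, _ = fastls_haploid(idx, x, params)
        for _ in range(1000):
            m = int(rng.integers(1, 5))
            starts = sorted(
                {0, *rng.integers(1, panel.n, m - 1).tolist()}
            ) if panel.n > 1 else [0]
            segs = [(s, int(rng.integers(panel.H))) for s in starts]
            assert gm <= score_path(panel, x, MosaicPath(segs), params) + 1e-9


class TestDedupe:
    def test_identical_states_collapse(self):
        assert dedupe_states([(2, 5, 3.0), (2, 5, 3.0)]) == [(2, 5, 3.0)]

    def test_dominated_state_removed(self):
        assert dedupe_states([(2, 5, 3.0), (2, 5, 7.0)]) == [(2, 5, 3.0)]
        assert dedupe_states([(3, 4, 5.0), (2, 5, 3.0)]) == [(2, 5, 3.0)]

    def test_incomparable_states_kept(self):
        states = [(0, 3, 5.0), (1, 4, 2.0)]
        assert dedupe_states(states) == states

    def test_scores_invariant_to_dedupe(self, rng):
        for _ in range(100):
            panel, x, params = _random_instance(rng, max_h=20, max_n=40)
            idx = build_pbwt(panel)
            gm_on, *_ = fastls_haploid(idx, x, params, dedupe=True)
            gm_off, *_ = fastls_haploid(idx, x, params, dedupe=False)
            assert gm_on == gm_off
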