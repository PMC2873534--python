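import numpy as np
import pytest

import cnapeel as cp
from cnapeel.peeloff import (
    PeelState,
    _gr_envelope,
    arm_peel,
    find_peak,
    limited_peel,
    limited_residual,
    standard_peel,
)
from cnapeel.significance import build_null
from conftest import make_matrix


class TestFindPeak:
    def test_minimum_q_wins(self):
        q = np.array([0.5, 0.01, 0.5])
        assert find_peak(q, np.ones(3)) == 1

    def test_nothing_significant_returns_none(self):
        assert find_peak(np.full(4, 0.3), np.ones(4)) is None
        assert find_peak(np.full(4, 0.25), np.ones(4)) is None  # threshold is strict

    def test_tie_broken_by_gscore_then_position(self):
        q = np.array([0.01, 0.01])
        assert find_peak(q, np.array([3.0, 5.0])) == 1
        assert find_peak(q, np.array([5.0, 5.0])) == 0


class TestResidualEnvelope:
    def test_instant_dip_accepted_at_s1(self):
        g = np.array([1.0, 0.4, 1.0, 1.0])
        np.testing.assert_allclose(_gr_envelope(g, 1), [1.0, 0.4, 0.4, 0.4])

    def test_transient_dip_masked_at_s2(self):
        g = np.array([1.0, 0.4, 1.0, 1.0])
        np.testing.assert_allclose(_gr_envelope(g, 2), [1.0, 1.0, 1.0, 1.0])

    def test_s0_behaves_like_s1(self):
        g = np.array([1.0, 0.4, 1.0, 0.8])
        np.testing.assert_allclose(_gr_envelope(g, 0), _gr_envelope(g, 1))

    def test_flat_run_has_no_reduction(self):
        for s in (0, 1, 3, 10):
            np.testing.assert_allclose(_gr_envelope(np.full(5, 0.7), s), 0.7)

    def test_sustained_drop_accepted_at_any_s(self):
        g = np.array([1.0, 0.3, 0.3, 0.3, 0.3])
        np.testing.assert_allclose(_gr_envelope(g, 3), [1.0, 0.3, 0.3, 0.3, 0.3])

    def test_envelope_is_monotone_and_bounded(self):
        rng = np.random.default_rng(0)
        g = np.abs(rng.normal(0.5, 0.3, 50))
        for s in (1, 4, 9):
            env = _gr_envelope(g, s)
            assert (np.diff(env) <= 1e-15).all()
            assert env[0] == g[0]

    def test_envelope_grows_with_s(self):
        rng = np.random.default_rng(1)
        g = np.abs(rng.normal(0.5, 0.3, 50))
        prev = _gr_envelope(g, 1)
        for s in (2, 5, 12):
            cur = _gr_envelope(g, s)
            assert (cur >= prev - 1e-15).all()
            prev = cur

    def test_negative_s_rejected(self):
        with pytest.raises(Exception):
            _gr_envelope(np.ones(3), -1)


def _state(contrib, grid, variant="standard", s=2, g_thres=np.inf, peel_mode="zero"):
    contrib = np.asarray(contrib, dtype=float)
    return PeelState(
        working=contrib.copy(), original=contrib, grid=grid,
        samples=tuple(f"S{j}" for j in range(contrib.shape[1])),
        direction="amp", variant=variant, null=build_null(np.maximum(contrib, 0)),
        s=s, g_thres=g_thres, peel_mode=peel_mode,
    )


def _region(grid, first, last, pm=None):
    pm = first if pm is None else pm
    return cp.PeakRegion(
        direction="amp", chrom=str(grid.chrom[pm]), first=first, last=last,
        start=int(grid.pos[first]), end=int(grid.pos[last]), peak_marker=pm,
        q_value=0.01, order=1, variant="standard",
    )


class TestStandardPeel:
    def test_whole_chromosome_run_zeroed(self, small_grid):
        contrib = np.full((10, 1), 0.5)
        st = _state(contrib, small_grid)
        standard_peel(st, _region(small_grid, 4, 4))
        assert not st.working.any()

    def test_sample_without_peak_untouched(self, small_grid):
        contrib = np.zeros((10, 2))
        contrib[2:5, 0] = 0.5   # carries the peak
        contrib[6:9, 1] = 0.7   # aberrant elsewhere only
        st = _state(contrib, small_grid)
        standard_peel(st, _region(small_grid, 3, 3))
        assert not st.working[:, 0].any()
        np.testing.assert_array_equal(st.working[:, 1], contrib[:, 1])

    def test_second_disjoint_run_survives(self, small_grid):
        contrib = np.zeros((10, 1))
        contrib[1:4, 0] = 0.5
        contrib[6:9, 0] = 0.5
        st = _state(contrib, small_grid)
        standard_peel(st, _region(small_grid, 2, 2))
        assert not st.working[1:4].any()
        assert st.working[6:9, 0].sum() == pytest.approx(1.5)

    def test_runs_do_not_cross_chromosomes(self, two_chrom_grid):
        contrib = np.full((20, 1), 0.5)
        st = _state(contrib, two_chrom_grid)
        standard_peel(st, _region(two_chrom_grid, 9, 9))
        assert not st.working[:10].any()
        assert st.working[10:].sum() == pytest.approx(5.0)


class TestArmPeel:
    def test_q_arm_zeroed_p_arm_kept(self, two_chrom_grid, two_chrom_arms):
        m = make_matrix(np.full((20, 1), 0.5), two_chrom_grid)
        m = cp.assign_arms(m, two_chrom_arms)
        contrib = np.full((20, 1), 0.5)
        st = _state(contrib, m.grid)
        arm_peel(st, _region(m.grid, 7, 7))  # q arm of chromosome 1
        assert not st.working[5:10].any()          # q arm gone
        assert st.working[0:5].sum() == pytest.approx(2.5)   # p arm intact
        assert st.working[10:].sum() == pytest.approx(5.0)   # chromosome 2 intact


class TestLimitedPeel:
    def test_no_secondary_signal_equals_standard(self, small_grid):
        contrib = np.zeros((10, 2))
        contrib[2:8, 0] = 0.5
        contrib[2:8, 1] = 0.5
        a = _state(contrib, small_grid, g_thres=0.01)
        b = _state(contrib, small_grid)
        region = _region(small_grid, 4, 5, pm=4)
        limited_peel(a, region)
        standard_peel(b, region)
        np.testing.assert_array_equal(a.working, b.working)

    def test_abort_preserves_second_peak(self, small_grid):
        # plateau 0.5 with a stronger sub-region at markers 7-8
        contrib = np.zeros((10, 2))
        contrib[1:9, :] = 0.5
        contrib[7:9, :] = 1.5
        st = _state(contrib, small_grid, s=1, g_thres=1.0)
        limited_peel(st, _region(small_grid, 2, 3, pm=2))
        # sum G_n at marker 7 is 2.0 >= 1.0: abort there, leave 7-8 intact
        assert not st.working[1:7].any()
        np.testing.assert_array_equal(st.working[7:9], contrib[7:9])

    def test_infinite_threshold_never_aborts(self, small_grid):
        contrib = np.zeros((10, 2))
        contrib[1:9, :] = 0.5
        contrib[7:9, :] = 1.5
        a = _state(contrib, small_grid, g_thres=np.inf)
        b = _state(contrib, small_grid)
        region = _region(small_grid, 2, 3, pm=2)
        limited_peel(a, region)
        standard_peel(b, region)
        np.testing.assert_array_equal(a.working, b.working)

    def test_subtract_mode_leaves_independent_component(self, small_grid):
        contrib = np.zeros((10, 1))
        contrib[1:9, 0] = 0.5
        contrib[7:9, 0] = 1.5
        st = _state(contrib, small_grid, s=1, g_thres=np.inf, peel_mode="subtract")
        limited_peel(st, _region(small_grid, 2, 3, pm=2))
        # G_r stays at the 0.5 level; the extra 1.0 at markers 7-8 remains
        np.testing.assert_allclose(st.working[7:9, 0], 1.0)
        assert not st.working[1:7].any()

    def test_residual_decomposition_identity(self, small_grid):
        rng = np.random.default_rng(4)
        contrib = np.zeros((10, 3))
        contrib[1:9, :] = np.abs(rng.normal(0.5, 0.2, (8, 3)))
        st = _state(contrib, small_grid, s=2)
        region = _region(small_grid, 3, 3)
        for j in range(3):
            dec = limited_residual(st, region, j, side="right")
            g = st.working[dec.markers, j]
            np.testing.assert_allclose(dec.g_r + dec.g_n, np.maximum(g, dec.g_r))
            assert (np.diff(dec.g_r) <= 1e-15).all()
            assert (dec.g_r >= 0).all() and (dec.g_n >= 0).all()

    def test_peel_never_increases_contributions(self, small_grid):
        rng = np.random.default_rng(5)
        contrib = np.abs(rng.normal(0.3, 0.3, (10, 3)))
        contrib[4, :] = 1.0
        st = _state(contrib, small_grid, s=1, g_thres=0.5)
        limited_peel(st, _region(small_grid, 4, 4))
        assert (st.working <= st.original + 1e-15).all()
        assert st.working.sum() < st.original.sum()


class TestRunVariant:
    def test_two_peak_fixture_standard_vs_limited(self):
        mat, arms, truth = cp.two_peak_fixture(0)
        params = cp.ScoreParams(direction="amp")
        std = cp.run_variant(mat, arms, params, variant="standard", seed=1)
        lim = cp.run_variant(mat, arms, params, variant="limited", s=2, seed=1)
        assert [(p.first, p.last) for p in std.peaks] == [truth[0]]
        assert [(p.first, p.last) for p in lim.peaks] == truth

    def test_peaks_do_not_overlap_within_direction(self):
        spec = cp.random_cohort_spec(7)
        mat, _ = cp.simulate(spec)
        arms = cp.arm_table_for(spec)
        res = cp.run_variant(mat, arms, cp.ScoreParams(direction="amp"),
                             variant="limited", seed=7)
        for i, a in enumerate(res.peaks):
            for b in res.peaks[i + 1:]:
                assert not a.overlaps(b)

    def test_discovery_order_and_significance(self):
        spec = cp.random_cohort_spec(3)
        mat, _ = cp.simulate(spec)
        arms = cp.arm_table_for(spec)
        res = cp.run_variant(mat, arms, cp.ScoreParams(direction="del"),
                             variant="standard", seed=3)
        assert [p.order for p in res.peaks] == list(range(1, len(res.peaks) + 1))
        assert all(p.q_value < 0.25 for p in res.peaks)

    def test_limited_peaks_cover_standard_peaks(self):
        spec = cp.random_cohort_spec(11)
        mat, _ = cp.simulate(spec)
        arms = cp.arm_table_for(spec)
        params = cp.ScoreParams(direction="amp")
        std = cp.run_variant(mat, arms, params, variant="standard", seed=11)
        lim = cp.run_variant(mat, arms, params, variant="limited", seed=11)
        assert std.peaks  # cohort plants amplifications, so this is non-vacuous
        for sp in std.peaks:
            assert any(sp.overlaps(lp) for lp in lim.peaks)

    def test_unknown_variant_rejected(self):
        mat, arms, _ = cp.two_peak_fixture(0)
        with pytest.raises(Exception, match="variant"):
            cp.run_variant(mat, arms, cp.ScoreParams(), variant="bogus")
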