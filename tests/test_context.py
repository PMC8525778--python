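"""Paired intact/scrambled runs, IRPC, time constants, virtual areas."""

import numpy as np
import pytest

from reservoir_events.context import (
    PairedRun,
    TimeConstantTable,
    alignment_time,
    construct_forget_independence,
    diff_trajectory,
    forgetting_time,
    irpc,
    make_virtual_areas,
    run_paired,
    time_constants,
)
from reservoir_events.dynamics import HalfLifeTimes, IntegratorParams, Trajectory
from reservoir_events.synthetic import (
    EmbeddingSequence,
    gaussian_abcd_pair,
    gen_gaussian_stream,
    make_intact_scrambled,
)


class TestRunPaired:
    def test_identical_middles_give_identical_trajectories(self, integrator):
        a = gen_gaussian_stream(5, 20, 0)
        b = gen_gaussian_stream(4, 20, 1)
        d = gen_gaussian_stream(3, 20, 2)
        run = run_paired(integrator, make_intact_scrambled(a, b, b, d))
        assert np.array_equal(run.traj_intact.states, run.traj_scrambled.states)
        assert np.all(diff_trajectory(run) == 0)

    def test_difference_zero_before_forgetting_transition(
            self, small_reservoir, abcd_pair):
        run = run_paired(small_reservoir, abcd_pair)
        d = diff_trajectory(run)
        assert np.all(d[:run.t_forget] == 0)       # bit-identical shared prefix
        assert np.any(d[run.t_forget] != 0)

    def test_integrator_post_construction_geometric_decay(self, abcd_pair):
        p = IntegratorParams(alpha=0.05, D=20)
        run = run_paired(p, abcd_pair)
        d = diff_trajectory(run)
        # after inputs re-align, the two integrators differ only in their
        # pasts: the difference contracts by exactly (1 - alpha) per step
        seg = d[run.t_construct:]
        assert np.allclose(seg[1:], 0.95 * seg[:-1], atol=1e-10)

    def test_transition_ordering_enforced(self, integrator):
        t = Trajectory(np.zeros((10, 20)), "integrator")
        with pytest.raises(ValueError, match="t_forget"):
            PairedRun(t, t, t_forget=5, t_construct=3)


class TestIrpc:
    def test_self_correlation_diagonal_is_one(self, rng):
        traj = Trajectory(rng.standard_normal((12, 30)), "reservoir")
        R = irpc(traj, traj)
        assert np.allclose(np.diag(R), 1.0)
        assert R.shape == (12, 12)

    def test_hand_computed_entries(self):
        # 3 units so one degree of freedom survives pattern centering
        A = np.array([[1.0, 2.0, 4.0], [0.0, 1.0, -1.0]])
        B = np.array([[2.0, 4.0, 8.0], [1.0, 1.0, 1.0]])
        ta = Trajectory(A, "reservoir")
        tb = Trajectory(B, "reservoir")
        # temporal means: A -> [.5, 1.5, 1.5], B -> [1.5, 2.5, 4.5]
        Ac = A - A.mean(axis=0)
        Bc = B - B.mean(axis=0)
        expected = np.corrcoef(Ac[0], Bc[0])[0, 1]
        assert np.isclose(irpc(ta, tb)[0, 0], expected)

    def test_constant_pattern_flagged_nan(self, rng):
        A = rng.standard_normal((6, 5))
        B = rng.standard_normal((6, 5))
        # a row equal to the mean of the others is the temporal mean of
        # the full matrix, so it vanishes after centering
        B[2] = B[[0, 1, 3, 4, 5]].mean(axis=0)
        R = irpc(Trajectory(A, "r"), Trajectory(B, "r"))
        assert np.all(np.isnan(R[:, 2]))
        assert np.all(np.isfinite(R[:, [0, 1, 3, 4, 5]]))

    def test_unit_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="unit counts"):
            irpc(Trajectory(rng.standard_normal((4, 3)), "r"),
                 Trajectory(rng.standard_normal((4, 5)), "r"))


class TestTimeConstants:
    def test_integrator_alignment_time_closed_form(self, abcd_pair):
        # (1-a)^s <= 1/2 first at s = ceil(log .5 / log .95) = 14
        p = IntegratorParams(alpha=0.05, D=20)
        run = run_paired(p, abcd_pair)
        res = alignment_time(diff_trajectory(run), run.t_construct)
        assert np.all(res.times[res.defined()] == 14)
        # integrator degeneracy: zero variance across units
        assert np.var(res.times[res.defined()]) == 0.0

    def test_zero_initial_difference_undefined(self):
        diff = np.zeros((30, 3))
        diff[10:, 1] = np.linspace(1, 0, 20)
        res = alignment_time(diff, 10)
        assert res.undefined[0] and res.undefined[2]
        assert not res.undefined[1]

    def test_never_halving_censored(self):
        diff = np.ones((30, 1))
        res = alignment_time(diff, 5, window=10)
        assert res.censored[0] and res.times[0] == 10

    def test_forgetting_rise_detected(self):
        # step rise at the transition: half-plateau reached immediately
        diff = np.zeros((40, 2))
        diff[10:, :] = 1.0
        res = forgetting_time(diff, 10, window=20)
        assert np.all(res.times == 1)

    def test_all_zero_forgetting_window_undefined(self):
        res = forgetting_time(np.zeros((40, 3)), 10, window=20)
        assert np.all(res.undefined)

    def test_reservoir_has_diverse_construct_times(
            self, small_reservoir, abcd_pair):
        run = run_paired(small_reservoir, abcd_pair)
        tab = time_constants(run)
        t = tab.construct.times[tab.construct.defined()]
        assert np.subtract(*np.percentile(t, [75, 25])) > 0

    def test_window_validation(self):
        with pytest.raises(ValueError, match="window"):
            alignment_time(np.zeros((10, 2)), 5, window=0)
        with pytest.raises(ValueError, match="window"):
            forgetting_time(np.zeros((10, 2)), 5, window=0)


class TestVirtualAreas:
    @staticmethod
    def _table(n, rng):
        c = HalfLifeTimes(times=rng.permutation(n).astype(float),
                          undefined=np.zeros(n, bool),
                          censored=np.zeros(n, bool))
        f = HalfLifeTimes(times=rng.integers(1, 5, n).astype(float),
                          undefined=np.zeros(n, bool),
                          censored=np.zeros(n, bool))
        return TimeConstantTable(construct=c, forget=f)

    def test_fast_slow_scheme(self, rng):
        tab = self._table(1000, rng)
        areas = make_virtual_areas(tab, "fast_slow_100")
        assert [a.label for a in areas] == ["fast", "slow"]
        assert all(len(a.unit_ids) == 100 for a in areas)
        assert not set(areas[0].unit_ids) & set(areas[1].unit_ids)
        # ranks map to construction-time order
        ct = tab.construct.times
        assert ct[areas[0].unit_ids].max() < ct[areas[1].unit_ids].min()

    def test_five_by_200_partition_and_ordering(self, rng):
        tab = self._table(1000, rng)
        areas = make_virtual_areas(tab, "five_by_200")
        ids = np.concatenate([a.unit_ids for a in areas])
        assert np.array_equal(np.sort(ids), np.arange(1000))
        means = [tab.construct.times[a.unit_ids].mean() for a in areas]
        assert np.all(np.diff(means) > 0)

    def test_scheme_too_large_rejected(self, rng):
        with pytest.raises(ValueError, match="rank"):
            make_virtual_areas(self._table(500, rng), "fast_slow_100")

    def test_sort_order_is_permutation_with_undefined_last(self, rng):
        tab = self._table(20, rng)
        tab.construct.times[3] = np.nan
        tab.construct.undefined[3] = True
        order = tab.sort_order
        assert sorted(order) == list(range(20))
        assert order[-1] == 3


class TestIndependence:
    def test_perfect_correlation(self, rng):
        t = rng.permutation(20).astype(float)
        flags = np.zeros(20, bool)
        tab = TimeConstantTable(
            construct=HalfLifeTimes(t, flags.copy(), flags.copy()),
            forget=HalfLifeTimes(t.copy(), flags.copy(), flags.copy()))
        rho, _ = construct_forget_independence(tab)
        assert np.isclose(rho, 1.0)

    def test_hand_ranked_example(self):
        # construct [1,2,3,4,5], forget [2,1,4,3,5]: Spearman rho = 0.7
        flags = np.zeros(10, bool)
        c = np.array([1, 2, 3, 4, 5, 1, 2, 3, 4, 5], float)
        f = np.array([2, 1, 4, 3, 5, 2, 1, 4, 3, 5], float)
        tab = TimeConstantTable(
            construct=HalfLifeTimes(c, flags.copy(), flags.copy()),
            forget=HalfLifeTimes(f, flags.copy(), flags.copy()))
        rho, _ = construct_forget_independence(tab)
        from scipy.stats import spearmanr
        assert np.isclose(rho, spearmanr(c, f).statistic)

    def test_too_few_defined_pairs_rejected(self, rng):
        t = rng.permutation(8).astype(float)
        flags = np.zeros(8, bool)
        tab = TimeConstantTable(
            construct=HalfLifeTimes(t, flags.copy(), flags.copy()),
            forget=HalfLifeTimes(t.copy(), flags.copy(), flags.copy()))
        with pytest.raises(ValueError, match="need >= 10"):
            construct_forget_independence(tab)


def test_asymmetry_on_gaussian_pairs(small_reservoir):
    """Construction is slower than forgetting for reservoir pairs."""
    med_f, med_c = [], []
    for seed in range(3):
        pair = gaussian_abcd_pair(30, 60, 30, 20, seed=seed)
        run = run_paired(small_reservoir, pair)
        tab = time_constants(run)
        med_f.append(np.nanmedian(tab.forget.times))
        med_c.append(np.nanmedian(tab.construct.times))
    assert np.median(med_f) < np.median(med_c)
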