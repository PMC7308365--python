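"""Experiment harness: sweeps, critical fits, expansion, regime labels."""

import numpy as np
import pytest

from nichesim import ModelParams, Trajectory, init_full, run, spawn_seeds
from nichesim.experiments import (
    Protocol,
    RegimeLabel,
    classify_regime,
    estimate_critical_point,
    fit_order_parameter_exponent,
    range_expansion,
    relaxation_profile,
    sweep_phase_diagram,
    transect,
)


def make_trajectory(t, p_nc, p_ex, e=0.01):
    """Hand-built competition trajectory for classifier tests."""
    t = np.asarray(t, dtype=float)
    p_nc = np.asarray(p_nc, dtype=float)
    p_ex = np.asarray(p_ex, dtype=float)
    p_vac = np.full_like(t, 0.1)
    p_minus = 1.0 - p_nc - p_ex - p_vac
    return Trajectory(
        times=t, p_minus=p_minus, p_vac=p_vac, p_nc=p_nc, p_ex=p_ex,
        absorbed=bool(p_nc[-1] + p_ex[-1] == 0), absorbed_at=-1.0,
        seed=0, params=ModelParams(delta=0.1, e=e, c=0.4, competition=True),
    )


class TestSweep:
    def test_rejects_empty_grid(self):
        with pytest.raises(ValueError):
            sweep_phase_diagram([], [0.1], ModelParams(delta=0.1), Protocol())

    def test_small_sweep_reproducible_and_monotone(self, warm_kernel):
        proto = Protocol(L=32, t_transient=80.0, t_avg=40.0, sample_dt=2.0, seed=5)
        params = ModelParams(delta=0.1, alpha=1.0)
        c_grid = [0.2, 0.4]
        e_grid = [0.005, 0.05, 0.6]
        a = sweep_phase_diagram(c_grid, e_grid, params, proto)
        b = sweep_phase_diagram(c_grid, e_grid, params, proto)
        assert np.array_equal(a.mean_occupancy, b.mean_occupancy)
        # deep subcritical cell persists; e >> 1 kills everything
        assert a.mean_occupancy[0, 1] > 0.3
        assert a.mean_occupancy[2, 0] == 0.0
        assert a.mean_occupancy[2, 1] == 0.0
        # column-wise occupancy decreases with destruction rate
        for j in range(len(c_grid)):
            col = a.mean_occupancy[:, j]
            assert col[0] > col[1] > col[2] or col[1] == col[2] == 0.0

    def test_competition_sweep_relative_occupancy(self, warm_kernel):
        proto = Protocol(L=24, t_transient=40.0, t_avg=20.0, sample_dt=2.0, seed=9)
        params = ModelParams(delta=0.1, alpha=1.0, competition=True)
        pd_ = sweep_phase_diagram([0.4], [0.02, 1.5], params, proto)
        rel = pd_.relative_occupancy
        assert rel.shape == (2, 1)
        tot = pd_.mean_occupancy + pd_.mean_occupancy_ex
        assert np.isnan(rel[tot == 0]).all()
        ok = tot > 0
        assert ((rel[ok] >= 0) & (rel[ok] <= 1)).all()


class TestCriticalPoint:
    def test_invalid_bracket_raises(self, warm_kernel):
        proto = Protocol(L=16, t_max=60.0, replicates=2, seed=1)
        with pytest.raises(ValueError):
            # both ends deep supercritical: bottom is not surviving
            estimate_critical_point("delta", ModelParams(delta=0.1), (3.0, 5.0), proto)

    def test_small_lattice_bracket_contains_known_threshold(self, warm_kernel):
        # coarse, small-L estimate: wide interval but it must bracket the
        # established r*=1 contact-process value 0.6065
        proto = Protocol(L=32, t_max=400.0, replicates=6, seed=2)
        fit = estimate_critical_point(
            "delta", ModelParams(delta=0.1), (0.45, 0.85), proto, tol=0.05
        )
        assert fit.k_name == "delta"
        assert fit.bracket[0] - 0.1 < 0.6065 < fit.bracket[1] + 0.1
        assert abs(fit.k_crit - 0.6065) < 0.15


class TestSurvivalRefinement:
    def test_crossing_sits_between_surviving_and_extinct_candidates(self, warm_kernel):
        from nichesim.experiments import refine_critical_point_by_survival

        # 0.3 is deep subcritical (all replicates survive), 1.0 deep
        # supercritical (none do); the interpolated 50% survival crossing
        # must land between the last majority-surviving candidate and the
        # next one
        proto = Protocol(L=32, t_max=400.0, sample_dt=2.0, replicates=6, seed=8)
        fit = refine_critical_point_by_survival(
            ModelParams(delta=0.1), "delta", np.array([0.3, 0.58, 1.0]), proto
        )
        assert 0.58 <= fit.k_crit < 1.0

    def test_all_supercritical_candidates_raise(self, warm_kernel):
        from nichesim.experiments import refine_critical_point_by_survival

        proto = Protocol(L=16, t_max=300.0, sample_dt=2.0, replicates=4, seed=9)
        with pytest.raises(ValueError):
            refine_critical_point_by_survival(
                ModelParams(delta=0.1), "delta", np.array([2.0, 3.0]), proto
            )


class TestExponentFit:
    def test_exact_power_law_recovery(self):
        k_crit = 0.6
        dk = np.geomspace(0.005, 0.05, 8)
        occ = 1.7 * dk**0.58
        fit = fit_order_parameter_exponent(k_crit - dk, occ, k_crit)
        assert fit.exponent == pytest.approx(0.58, abs=1e-6)
        assert fit.stderr == pytest.approx(0.0, abs=1e-6)
        assert fit.n_points == 8

    def test_slope_invariant_under_occupancy_rescaling(self):
        k_crit = 0.6
        dk = np.geomspace(0.01, 0.1, 6)
        occ = 0.9 * dk**0.7
        a = fit_order_parameter_exponent(k_crit - dk, occ, k_crit)
        b = fit_order_parameter_exponent(k_crit - dk, 37.0 * occ, k_crit)
        assert a.exponent == pytest.approx(b.exponent, abs=1e-9)

    def test_rejects_supercritical_points_and_sparse_data(self):
        with pytest.raises(ValueError):
            fit_order_parameter_exponent([0.7], [0.1], 0.6)
        with pytest.raises(ValueError):
            fit_order_parameter_exponent([0.5, 0.55], [0.1, 0.05], 0.6)


class TestRelaxation:
    def test_profiles_separate_sub_and_supercritical(self, warm_kernel):
        proto = Protocol(L=32, t_max=150.0, sample_dt=1.0, replicates=3, seed=3)
        curves = relaxation_profile(
            ModelParams(delta=0.1), "delta",
            {"sub": 0.3, "super": 1.2}, proto,
        )
        t, sub = curves["sub"]
        _, sup = curves["super"]
        assert sub[-1] > 0.2  # plateau at quasi-stationary occupancy
        assert sup[-1] == 0.0  # fast decay to extinction
        # supercritical decay is exponential-like: log-linear fit slope < 0
        mask = sup > 0
        rate = np.polyfit(t[mask][:50], np.log(sup[mask][:50]), 1)[0]
        assert rate < -0.01


class TestRangeExpansion:
    def test_wider_construction_expands_faster(self, warm_kernel):
        params = ModelParams(delta=0.1, e=0.01, c=0.4, alpha=1.0)
        proto = Protocol(L=48, t_max=900.0, sample_dt=2.0, seed=12)
        res = range_expansion(params, [1, 10], proto, establishment_retries=6)
        assert set(res) == {1, 10}
        r1, r10 = res[1], res[10]
        assert r1.survived and r10.survived
        assert r10.t_saturation < r1.t_saturation
        # mosaic extent is (noisy but) expanding: late extent >> early extent
        assert r10.mosaic_extent[-1] >= 20
        assert r1.occupied_fraction[0] == pytest.approx(1 / 48**2)

    def test_supercritical_founder_dies(self, warm_kernel):
        # delta above the discounted CP threshold: expansion must fail
        params = ModelParams(delta=0.5, e=0.01, c=0.4, alpha=1.0)
        proto = Protocol(L=32, t_max=400.0, sample_dt=5.0, seed=4)
        res = range_expansion(params, [1], proto)
        assert not res[1].survived
        assert np.isnan(res[1].t_saturation)
        assert res[1].occupied_fraction[-1] == 0.0


class TestSpatialInvariants:
    def test_ips_threshold_below_meanfield_across_strategies(self, warm_kernel):
        # spatial crowding shrinks persistence for every allocation tested
        from nichesim import mf_ecrit

        for i, c in enumerate((0.2, 0.6)):
            mfa = mf_ecrit(c, 0.0, 1.0)
            proto = Protocol(L=48, t_max=600.0, replicates=6, seed=71 + i)
            fit = estimate_critical_point(
                "e", ModelParams(delta=0.0, c=c, alpha=1.0), (0.02, mfa + 0.08),
                proto, tol=0.02,
            )
            assert fit.k_crit < mfa

    def test_clustering_near_threshold_disappears_with_wide_construction(
        self, warm_kernel
    ):
        # near e_crit the r=1 metapopulation fragments into many small
        # clusters; with r=10 the clustering signal is gone (mass sits in a
        # dominant component and components are fewer)
        from nichesim import CellState, connected_clusters

        stats = {}
        for r in (1, 10):
            ncl, lfrac = [], []
            for s in spawn_seeds(900 + r, 8):
                p = ModelParams(delta=0.0, e=0.088, c=0.4, alpha=1.0, r_con=r)
                tr = run(p, init_full(64), 1000.0, sample_dt=100.0, seed=s,
                         keep_final_grid=True)
                if tr.absorbed:
                    continue
                cs = connected_clusters(tr.final_grid, {CellState.NC})
                ncl.append(cs.n_clusters)
                lfrac.append(cs.largest_fraction)
            stats[r] = (ncl, lfrac)
        ncl1, lfrac1 = stats[1]
        ncl10, lfrac10 = stats[10]
        assert len(ncl1) >= 5 and len(ncl10) >= 5
        # fragmented but alive at r=1
        assert all(n > 1 for n in ncl1)
        assert all(f < 0.5 for f in lfrac1)
        # r=10 survivors concentrate occupancy in fewer, dominant components
        assert np.median(lfrac10) > np.median(lfrac1)
        assert np.median(ncl10) < np.median(ncl1)


class TestRegimeClassifier:
    T = np.arange(0.0, 1001.0, 1.0)

    def test_coexistence(self):
        n = len(self.T)
        tr = make_trajectory(self.T, np.full(n, 0.3), np.full(n, 0.2))
        assert classify_regime(tr) is RegimeLabel.COEXISTENCE

    def test_nc_monopoly(self):
        n = len(self.T)
        ex = np.where(self.T < 200, 0.2, 0.0)
        tr = make_trajectory(self.T, np.full(n, 0.4), ex)
        assert classify_regime(tr) is RegimeLabel.NC_MONOPOLY

    def test_ecological_suicide(self):
        nc = np.where(self.T < 300, 0.2, 0.0)
        ex = np.where(self.T < 700, 0.3, 0.0)
        tr = make_trajectory(self.T, nc, ex)
        assert classify_regime(tr) is RegimeLabel.ECOLOGICAL_SUICIDE

    def test_competitive_exclusion_without_disturbance(self):
        n = len(self.T)
        nc = np.where(self.T < 400, 0.1, 0.0)
        tr = make_trajectory(self.T, nc, np.full(n, 0.5), e=0.0)
        assert classify_regime(tr) is RegimeLabel.COMPETITIVE_EXCLUSION

    def test_trivial_extinction(self):
        # exploiter collapses first, NC follows: the landscape was lethal
        nc = np.where(self.T < 500, 0.05, 0.0)
        ex = np.where(self.T < 200, 0.05, 0.0)
        tr = make_trajectory(self.T, nc, ex)
        assert classify_regime(tr) is RegimeLabel.TRIVIAL_EXTINCTION

    def test_ambiguous_lingering_transient(self):
        n = len(self.T)
        nc = np.where(self.T < 900, 0.004, 0.0)
        tr = make_trajectory(self.T, nc, np.full(n, 0.3))
        assert classify_regime(tr) is RegimeLabel.AMBIGUOUS


class TestTransect:
    def test_extraction_shape_and_content(self):
        snaps = np.arange(3 * 5 * 5).reshape(3, 5, 5) % 3 - 1
        m = transect(snaps, 2)
        assert m.shape == (3, 5)
        assert np.array_equal(m, snaps[:, 2, :])

    def test_row_out_of_range(self):
        with pytest.raises(ValueError):
            transect(np.zeros((2, 4, 4)), 4)

    def test_constant_destroyed_run(self, warm_kernel):
        from nichesim import CellState, LandscapeGrid, run

        grid = LandscapeGrid.filled(8, CellState.DESTROYED)
        tr = run(ModelParams(delta=0.1, e=0.3, c=0.5), grid, t_max=5.0,
                 sample_dt=1.0, seed=0, snapshot_stride=1)
        m = transect(tr.snapshots, 3)
        assert (m == -1).all()
        assert m.shape == (6, 8)
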