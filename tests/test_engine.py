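import numpy as np
import pytest

from lignosim.engine import (AbsorbingState, TimeCourse, average_runs,
                             draw_event, run, step)
from lignosim.engine import test_sample_scan as scan_objectives
from lignosim.kinetics import EnzymePool, ParameterSet, effective_enzymes
from lignosim.substrate import StructureConfig, build_microfibril


def _first_crossing(tc: TimeCourse, level: float) -> float:
    idx = np.argmax(tc.conversion >= level)
    if tc.conversion[idx] < level:
        return np.inf
    return tc.times[idx]


def _bgl_only_state(n_cellobiose=1):
    cfg = StructureConfig(cellulose_rings=(1,), cellulose_dp=4)
    state = build_microfibril(cfg, seed=0)
    state.fragments[0].clear()  # no cellulose channels left
    for c in state.chains:
        c.present[:] = False
        c.bond_intact[:] = False
    state.free_cellobiose = n_cellobiose
    state.initial_glucose = 2 * n_cellobiose
    return state


class TestDraw:
    def test_waiting_time_exponential_mean(self):
        # single BGL channel with propensity 2/h -> mean waiting time 0.5 h
        state = _bgl_only_state()
        params = ParameterSet(K_BGL=2.0, n_BGL0=1.0, omega_BGL_glc=0.0)
        pool = EnzymePool.from_params(params)
        effective_enzymes(pool, 0, 0, params)
        rng = np.random.default_rng(0)
        n = 10_000
        dts = np.array([draw_event(state, pool, params, rng)[0]
                        for _ in range(n)])
        se = 0.5 / np.sqrt(n)
        assert abs(dts.mean() - 0.5) < 3 * se

    def test_categorical_selection(self):
        # BGL propensity 1, EG propensity 3 -> EG frequency 0.75
        cfg = StructureConfig(cellulose_rings=(1,), cellulose_dp=10)
        state = build_microfibril(cfg, seed=0)
        state.free_cellobiose = 1
        state.initial_glucose += 2
        params = ParameterSet(K_BGL=1.0, n_BGL0=1.0, K_EG=0.6, n_EG0=1.0,
                              K_CBHA=0.0, K_XYL=0.0, X_cellulose=0.0,
                              r_cellulose=1.0, omega_EG_glc=0.0,
                              omega_BGL_glc=0.0)
        pool = EnzymePool.from_params(params)
        effective_enzymes(pool, 0, 0, params)
        rng = np.random.default_rng(1)
        n = 10_000
        kinds = [draw_event(state, pool, params, rng)[1][0] for _ in range(n)]
        freq = sum(k == "EG_cut" for k in kinds) / n
        se = np.sqrt(0.75 * 0.25 / n)
        assert abs(freq - 0.75) < 3 * se

    def test_absorbing_state(self):
        state = _bgl_only_state(n_cellobiose=0)
        params = ParameterSet()
        pool = EnzymePool.from_params(params)
        with pytest.raises(AbsorbingState):
            draw_event(state, pool, params, np.random.default_rng(0))


class TestRun:
    def test_cbh_bgl_complete_conversion(self):
        cfg = StructureConfig(cellulose_rings=(1,), cellulose_dp=4)
        params = ParameterSet(K_EG=0.0, K_XYL=0.0, K_CBHA=1000.0,
                              K_CBHD=1000.0, K_BGL=1000.0,
                              n_CBH0=1.0, n_BGL0=1.0,
                              X_cellulose=0.0, r_cellulose=1.0, L_adh=0.0,
                              omega_CBH_glc=0.0, omega_BGL_glc=0.0,
                              omega_CBH_cbs=0.0)
        tc = run(params, cfg, t_max=10.0, seed=3, validate=True)
        assert tc.conversion[-1] == pytest.approx(100.0)

    def test_conversion_monotone_and_bounded(self, amorphous_params,
                                             small_fibril_config):
        tc = run(amorphous_params, small_fibril_config, seed=11)
        assert np.all(np.diff(tc.conversion) >= 0)
        assert tc.conversion.min() >= 0 and tc.conversion.max() <= 100

    def test_deterministic_under_seed(self, amorphous_params,
                                      small_fibril_config):
        a = run(amorphous_params, small_fibril_config, seed=5)
        b = run(amorphous_params, small_fibril_config, seed=5)
        np.testing.assert_array_equal(a.conversion, b.conversion)

    def test_crystallinity_slowdown_factor(self):
        # digestion-limited CBH: t50 scales roughly with 1/r when X=1
        cfg = StructureConfig(cellulose_rings=(1,), cellulose_dp=20)
        base = ParameterSet(K_EG=0.0, K_XYL=0.0, K_CBHA=1e6, K_CBHD=1000.0,
                            K_BGL=1e6, n_CBH0=1.0, n_BGL0=5.0,
                            X_cellulose=0.0, r_cellulose=1.0, L_adh=0.0,
                            omega_CBH_glc=0.0, omega_BGL_glc=0.0,
                            omega_CBH_cbs=0.0)
        r = 1e-3
        crys = base.replace(X_cellulose=1.0, r_cellulose=r)
        grid_a = np.linspace(0.0, 1.0, 2001)
        grid_c = np.linspace(0.0, 50.0, 2001)
        t_am = [_first_crossing(run(base, cfg, t_max=1.0, grid=grid_a, seed=s),
                                50.0) for s in range(20)]
        t_cr = [_first_crossing(run(crys, cfg, t_max=50.0, grid=grid_c,
                                    seed=100 + s), 50.0) for s in range(20)]
        ratio = np.mean(t_cr) / np.mean(t_am)
        assert (1 / r) / 2 < ratio < (1 / r) * 2

    def test_inhibition_slows_completion(self):
        cfg = StructureConfig(cellulose_rings=(1,), cellulose_dp=10)
        free = ParameterSet(K_EG=10.0, K_CBHA=10.0, K_CBHD=10.0, K_BGL=10.0,
                            K_XYL=0.0, n_EG0=1.0, n_CBH0=1.0, n_BGL0=1.0,
                            X_cellulose=0.0, r_cellulose=1.0, L_adh=0.0,
                            omega_EG_glc=0.0, omega_CBH_glc=0.0,
                            omega_BGL_glc=0.0, omega_EG_cbs=0.0,
                            omega_CBH_cbs=0.0)
        inhibited = free.replace(omega_EG_glc=1.0, omega_CBH_glc=1.0,
                                 omega_BGL_glc=1.0, omega_EG_cbs=1.0,
                                 omega_CBH_cbs=1.0)
        grid = np.linspace(0.0, 40.0, 4001)
        t_free = [_first_crossing(run(free, cfg, t_max=40.0, grid=grid, seed=s),
                                  100.0) for s in range(50)]
        t_inh = [_first_crossing(run(inhibited, cfg, t_max=40.0, grid=grid,
                                     seed=s), 100.0) for s in range(50)]
        assert np.mean(t_inh) > np.mean(t_free)

    def test_r_one_layout_invariance(self, small_fibril_config):
        params = ParameterSet(X_cellulose=0.5, r_cellulose=1.0,
                              X_hemicellulose=0.0, r_hemicellulose=1.0)
        a = run(params, small_fibril_config, seed=9, layout="random")
        b = run(params, small_fibril_config, seed=9, layout="contiguous_blocks")
        np.testing.assert_array_equal(a.conversion, b.conversion)

    def test_two_phase_amorphous_first(self):
        # EG-dominant cocktail: the amorphous/crystalline choice is made by
        # EG, which strongly prefers amorphous bonds at r << 1
        cfg = StructureConfig(cellulose_rings=(2,), cellulose_dp=40)
        params = ParameterSet(K_EG=500.0, K_CBHA=100.0, K_CBHD=20.0,
                              K_BGL=500.0, n_EG0=5.0, n_CBH0=2.0, n_BGL0=5.0,
                              X_cellulose=0.5, r_cellulose=1e-3, L_adh=0.0,
                              omega_EG_glc=0.0, omega_CBH_glc=0.0,
                              omega_BGL_glc=0.0, omega_EG_cbs=0.0,
                              omega_CBH_cbs=0.0)
        fractions = []
        for s in range(10):
            tc, rec = run(params, cfg, t_max=72.0, seed=s, record_events=True)
            t50 = _first_crossing(tc, 50.0)
            cuts = [c for (t, kind, _, c) in rec.events
                    if t < t50 and c is not None]
            if cuts:
                fractions.append(np.mean(cuts))
        assert fractions and np.mean(fractions) < params.X_cellulose

    def test_mass_conservation_layered(self, layered_config):
        params = ParameterSet(L_adh=5.0)
        run(params, layered_config, t_max=24.0, seed=2, validate=True)

    def test_grid_validation(self, amorphous_params, bare_chain_config):
        with pytest.raises(ValueError):
            run(amorphous_params, bare_chain_config, t_max=10.0,
                grid=np.array([0.0, 20.0]))
        with pytest.raises(ValueError):
            run(amorphous_params, bare_chain_config, t_max=-1.0)


class TestAverageRuns:
    def test_single_rep_equals_run(self, amorphous_params, small_fibril_config):
        single = run(amorphous_params, small_fibril_config, seed=4)
        avg = average_runs(amorphous_params, small_fibril_config,
                           n_rep=1, seed=4)
        np.testing.assert_array_equal(single.conversion, avg.conversion)

    def test_mean_of_identical_runs(self, amorphous_params,
                                    small_fibril_config):
        a = run(amorphous_params, small_fibril_config, seed=6)
        b = run(amorphous_params, small_fibril_config, seed=6)
        mean = np.mean([a.conversion, b.conversion], axis=0)
        np.testing.assert_allclose(mean, a.conversion)

    def test_replicate_seeds_recorded(self, amorphous_params,
                                      small_fibril_config):
        avg = average_runs(amorphous_params, small_fibril_config,
                           n_rep=3, seed=10)
        assert avg.seeds == (10, 11, 12)
        assert avg.replicates == 3

    def test_variance_shrinks_with_replicates(self, small_fibril_config):
        params = ParameterSet(K_EG=20.0, K_CBHA=20.0, K_CBHD=5.0,
                              K_BGL=20.0, n_EG0=1.0, n_CBH0=1.0, n_BGL0=1.0,
                              X_cellulose=0.0, r_cellulose=1.0, L_adh=0.0,
                              omega_EG_glc=0.0, omega_CBH_glc=0.0,
                              omega_BGL_glc=0.0, omega_EG_cbs=0.0,
                              omega_CBH_cbs=0.0)
        grid = np.arange(0.0, 4.0 + 1e-9, 0.5)

        def mid_values(n_rep, n_groups=30):
            # conversion at t = 1.5 h, well before saturation
            return [average_runs(params, small_fibril_config, n_rep=n_rep,
                                 t_max=4.0, grid=grid,
                                 seed=1000 * g).conversion[3]
                    for g in range(n_groups)]

        v1 = np.var(mid_values(1))
        v4 = np.var(mid_values(4))
        assert v4 < v1 / 2  # expect ~ v1 / 4

    def test_invalid_reps(self, amorphous_params, small_fibril_config):
        with pytest.raises(ValueError):
            average_runs(amorphous_params, small_fibril_config, n_rep=0)


class TestScan:
    def test_self_match_is_close(self, amorphous_params, small_fibril_config):
        grid = np.arange(0.0, 24.0 + 1e-9, 1.0)
        ref = average_runs(amorphous_params, small_fibril_config, n_rep=2,
                           t_max=24.0, grid=grid, seed=77)
        table = scan_objectives([amorphous_params], ref, small_fibril_config,
                                n_rep=2, seed=77, t_max=24.0)
        assert table.loc[0, "Y"] == 0.0
        assert table.loc[0, "sign_class"] == "close"

    def test_cbh_rate_shifts_class(self, small_fibril_config):
        gen = ParameterSet(K_EG=10.0, K_CBHA=100.0, K_CBHD=1.0, K_BGL=100.0,
                           n_EG0=1.0, n_CBH0=2.0, n_BGL0=2.0,
                           X_cellulose=0.0, r_cellulose=1.0, L_adh=0.0,
                           omega_EG_glc=0.0, omega_CBH_glc=0.0,
                           omega_BGL_glc=0.0, omega_EG_cbs=0.0,
                           omega_CBH_cbs=0.0)
        grid = np.arange(0.0, 72.0 + 1e-9, 1.0)
        ref = average_runs(gen, small_fibril_config, n_rep=3, grid=grid,
                           seed=21)
        table = scan_objectives(
            [gen.replace(K_CBHD=100.0), gen.replace(K_CBHD=0.01)],
            ref, small_fibril_config, n_rep=3, seed=99)
        assert table.loc[0, "sign_class"] == "above"
        assert table.loc[1, "sign_class"] == "below"


class TestStepApi:
    def test_step_applies_event(self):
        state = _bgl_only_state(n_cellobiose=2)
        params = ParameterSet(K_BGL=5.0, n_BGL0=1.0, omega_BGL_glc=0.0,
                              omega_EG_glc=0.0, omega_CBH_glc=0.0)
        pool = EnzymePool.from_params(params)
        dt, event = step(state, pool, params, np.random.default_rng(0))
        assert dt > 0
        assert event[0] == "BGL_split"
        assert state.free_glucose == 2
        assert state.free_cellobiose == 1
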