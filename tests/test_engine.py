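"""Engine correctness: determinism, exactness, ledgers, state-machine legality."""

import numpy as np
import pytest
from scipy import linalg, stats

from ddrsim import _kernel as K
from ddrsim.engine import (
    EngineError,
    advance,
    initialize_state,
    simulate_cell,
    simulate_population,
)
from ddrsim.protocols import Protocol, single_dose
from tests.conftest import zeroed_overlay


class TestDeterminism:
    def test_identical_seeds_give_bit_identical_trajectories(self, mrc5):
        a = simulate_cell(mrc5, single_dose(20.0), 900.0, seed=42)
        b = simulate_cell(mrc5, single_dose(20.0), 900.0, seed=42)
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(a.focus_episodes, b.focus_episodes, equal_nan=True)
        assert np.array_equal(a.break_episodes, b.break_episodes, equal_nan=True)

    def test_different_seeds_differ(self, mrc5):
        a = simulate_cell(mrc5, None, 600.0, seed=1)
        b = simulate_cell(mrc5, None, 600.0, seed=2)
        assert not np.array_equal(a.data, b.data)

    def test_population_n1_equals_single_cell(self, mrc5):
        pop = simulate_population(mrc5, None, 300.0, n=1, base_seed=7)
        single = simulate_cell(mrc5, None, 300.0, seed=7)
        assert np.array_equal(pop[0].data, single.data)


class TestDegenerateRuns:
    def test_all_rates_zero_leaves_state_unchanged(self, mrc5):
        model = mrc5.with_overrides(zeroed_overlay(mrc5))
        state = initialize_state(model, seed=3)
        pools0 = state.pools.copy()
        advance(state, model, 500.0)
        assert state.clock == 500.0
        assert np.array_equal(state.pools, pools0)
        assert state.foci_count == 0

    def test_duration_zero_gives_single_record(self, mrc5):
        tr = simulate_cell(mrc5, None, 0.0, seed=0)
        assert tr.data.shape[0] == 1
        assert tr.times[0] == 0.0

    def test_advance_backwards_rejected(self, mrc5):
        state = initialize_state(mrc5, seed=0)
        advance(state, mrc5, 10.0)
        with pytest.raises(EngineError):
            advance(state, mrc5, 5.0)


BD_RATE_IN, BD_RATE_OUT = 2.0, 0.1  # stationary mean 20


@pytest.fixture(scope="module")
def bd_model(mrc5):
    return mrc5.with_overrides(
        {
            **zeroed_overlay(mrc5, keep={"k_ros_prod_norm", "k_ros_dec"}),
            "k_ros_prod_norm": BD_RATE_IN,
            "k_ros_dec": BD_RATE_OUT,
            "init_ros": 20.0,
        }
    )


@pytest.fixture(scope="module")
def irradiated_state(mrc5):
    state = initialize_state(mrc5, seed=11)
    state.ev_time, state.ev_kind, state.ev_value = single_dose(20.0).timed_events(5220.0)
    return state


@pytest.fixture(scope="module")
def heavy_run(mrc5):
    return simulate_cell(mrc5, single_dose(20.0), 3000.0, seed=5)


@pytest.fixture(scope="module")
def ros10_run(mrc5):
    return simulate_cell(mrc5, Protocol(ros_multiplier=10.0), 1800.0, seed=14)


class TestBirthDeathOracle:
    """ROS alone is a birth-death process: stationary law is Poisson."""

    RATE_IN, RATE_OUT = BD_RATE_IN, BD_RATE_OUT

    def test_stationary_mean_and_variance_match_poisson(self, bd_model):
        n_rep, t_end = 250, 150.0
        final = np.array(
            [
                simulate_cell(bd_model, None, t_end, seed=500 + i,
                              sample_every=t_end).column("ros")[-1]
                for i in range(n_rep)
            ]
        )
        mean_target = self.RATE_IN / self.RATE_OUT
        se_mean = np.sqrt(mean_target / n_rep)
        assert abs(final.mean() - mean_target) < 3 * se_mean
        var = final.var(ddof=1)
        se_var = mean_target * np.sqrt(2.0 / (n_rep - 1))
        assert abs(var - mean_target) < 3 * se_var

    def test_transient_distribution_matches_master_equation(self, bd_model):
        """Chi-square of 4000 SSA replicates vs the exact transient law."""
        model = bd_model.with_overrides({"init_ros": 0.0})
        t_end, n_rep, cap = 30.0, 4000, 60
        # master equation: generator on {0..cap}
        Q = np.zeros((cap + 1, cap + 1))
        for n in range(cap + 1):
            if n < cap:
                Q[n, n + 1] = self.RATE_IN
            if n > 0:
                Q[n, n - 1] = self.RATE_OUT * n
            Q[n, n] = -Q[n].sum()
        p0 = np.zeros(cap + 1)
        p0[0] = 1.0
        p_t = p0 @ linalg.expm(Q * t_end)
        samples = np.array(
            [
                simulate_cell(model, None, t_end, seed=9000 + i,
                              sample_every=t_end).column("ros")[-1]
                for i in range(n_rep)
            ],
            dtype=int,
        )
        # pool the tail so all expected counts are >= 5
        edges = [0, 1, 2, 3, 4, 5, 6, 7, 8, 10, cap + 1]
        obs = np.array([((samples >= a) & (samples < b)).sum()
                        for a, b in zip(edges, edges[1:])])
        exp = np.array([p_t[a:b].sum() for a, b in zip(edges, edges[1:])]) * n_rep
        stat, p = stats.chisquare(obs, exp * obs.sum() / exp.sum())
        assert p > 0.01, (obs, exp.round(1))


class TestConservationAndLegality:
    def test_repair_factor_ledgers_hold_throughout(self, mrc5, irradiated_state):
        state = irradiated_state
        init = {
            "ku": mrc5.parameters["init_ku"].value,
            "pk": mrc5.parameters["init_pk"].value,
            "liIV": mrc5.parameters["init_liIV"].value,
            "parp": mrc5.parameters["init_parp"].value,
            "liIII": mrc5.parameters["init_liIII"].value,
            "atm": mrc5.parameters["init_atm"].value,
        }
        for until in np.linspace(500, 5220, 10):
            advance(state, mrc5, float(until))
            totals = state.factor_totals()
            for key, expected in init.items():
                assert totals[key] == pytest.approx(expected), (key, until)

    def test_site_state_machine_legality(self, irradiated_state):
        state = irradiated_state
        assert set(np.unique(state.site)) <= {0, 1, 2}
        assert set(np.unique(state.h2x)) <= {0, 1, 2, 3}
        assert set(np.unique(state.bnd)) <= set(range(11))
        # intact sites carry no repair factors and no ATM-bound p-H2AX
        ok = state.site == K.S_OK
        assert np.all(state.bnd[ok] == K.B_NONE)
        assert not np.any(state.h2x[ok] == K.H_PA)

    def test_pool_counts_never_negative(self, irradiated_state):
        assert np.all(irradiated_state.pools >= 0)


class TestEventLogSemantics:
    def test_ligation_requires_formed_focus(self, heavy_run):
        """Every ligation instant falls inside a focus episode on its site."""
        tr = heavy_run
        ligations = tr.break_episodes[np.isfinite(tr.break_episodes[:, 2])]
        assert len(ligations) > 10  # the check must actually exercise repair
        for site, _, t_lig, _ in ligations:
            eps = tr.focus_episodes[tr.focus_episodes[:, 0] == site]
            t_res = np.where(np.isnan(eps[:, 2]), np.inf, eps[:, 2])
            assert np.any((eps[:, 1] <= t_lig) & (t_lig <= t_res)), (site, t_lig)

    def test_focus_can_resolve_while_break_persists(self, heavy_run):
        tr = heavy_run
        found = False
        for site, t_break, t_lig, _ in tr.break_episodes:
            t_lig = np.inf if np.isnan(t_lig) else t_lig
            eps = tr.focus_episodes[tr.focus_episodes[:, 0] == site]
            for _, t_form, t_res in eps:
                if t_break <= t_form and np.isfinite(t_res) and t_res < t_lig:
                    found = True
        assert found

    def test_focus_can_outlive_repaired_break(self, heavy_run):
        tr = heavy_run
        found = False
        for site, t_break, t_lig, _ in tr.break_episodes:
            if not np.isfinite(t_lig):
                continue
            eps = tr.focus_episodes[tr.focus_episodes[:, 0] == site]
            for _, t_form, t_res in eps:
                t_res = np.inf if np.isnan(t_res) else t_res
                if t_form <= t_lig < t_res:
                    found = True
        assert found

    def test_foci_count_bounded_by_site_count(self, heavy_run):
        foci = heavy_run.column("foci")
        assert foci.min() >= 0 and foci.max() <= 50


class TestSenescenceCounter:
    def test_counter_bounded(self, ros10_run):
        sen_int = ros10_run.column("sen_int")
        assert sen_int.min() >= 1 and sen_int.max() <= 10

    def test_switch_is_irreversible(self, ros10_run):
        sen_state = ros10_run.column("sen_state")
        assert np.all(np.diff(sen_state) >= 0)

    def test_switch_time_consistent_with_samples(self, ros10_run):
        tr = ros10_run
        if np.isfinite(tr.sen_switch_time):
            t = tr.times
            assert np.all(tr.column("sen_state")[t < tr.sen_switch_time] == 0)
            assert np.all(tr.column("sen_state")[t > tr.sen_switch_time + 5] == 1)

    def test_post_senescence_depletion_of_ku_and_parp(self, mrc5):
        """After the switch, Ku and PARP totals decay toward their floors."""
        model = mrc5
        state = None
        for seed in range(21, 29):  # a senescent replicate occurs w.h.p.
            state = initialize_state(model, seed=seed)
            state.mods[1] = 10.0  # 10x background ROS
            advance(state, model, 3600.0)
            if state.senescent:
                break
        assert state is not None and state.senescent
        assert state.pools[K.PI["deg_ku"]] > 0
        assert state.pools[K.PI["deg_parp"]] > 0
        alive_ku = state.factor_totals()["ku"] - state.pools[K.PI["deg_ku"]]
        assert alive_ku >= model.parameters["ku_floor"].value - 1
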