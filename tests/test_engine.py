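"""Event rules, rate formulas and the stochastic drivers."""

import math

import numpy as np
import pytest

from gturcsim import (
    CLOSED,
    OPEN,
    SimConfig,
    SimResult,
    baseline_params,
    growth_speed,
    run_ensemble,
    run_simulation,
)
from gturcsim.engine import (
    ASSOCIATION,
    CLOSURE,
    DISSOCIATION,
    AbsorbingStateError,
    CensoredTrajectoryError,
    Event,
    apply_event,
    effective_params,
    event_rates,
    next_event,
    spawn_seeds,
)
from conftest import make_state


def rates_by_kind(events):
    out = {}
    for ev in events:
        out.setdefault(ev.kind, []).append(ev)
    return out


class TestEventRates:
    def test_association_rate_is_kon_times_molar_concentration(self, baseline):
        cfg = SimConfig(concentration=10.5)
        events = rates_by_kind(event_rates(make_state([]), baseline, cfg))
        assoc = events[ASSOCIATION]
        assert len(assoc) == 13
        assert all(ev.rate == pytest.approx(1.3e6 * 10.5e-6) for ev in assoc)
        assert assoc[0].rate == pytest.approx(13.65)

    def test_single_open_dimer_off_rate(self, baseline):
        cfg = SimConfig(concentration=10.5)
        events = rates_by_kind(event_rates(make_state([4]), baseline, cfg))
        (dis,) = events[DISSOCIATION]
        assert dis.rate == pytest.approx(1.3e6 * math.exp(-7.92))
        assert dis.rate == pytest.approx(4.7e2, rel=0.01)

    def test_closure_rate_from_prospective_bonds(self, baseline):
        cfg = SimConfig(concentration=10.5)
        ev = rates_by_kind(event_rates(make_state([3, 4, 5, 6]), baseline, cfg))
        (closure,) = ev[CLOSURE]
        assert closure.rate == pytest.approx(0.01 * math.exp(-(10 - 3 * 6.5)))
        assert closure.rate == pytest.approx(1.3e2, rel=0.03)
        ev0 = rates_by_kind(event_rates(make_state([]), baseline, cfg))
        assert ev0[CLOSURE][0].rate == pytest.approx(0.01 * math.exp(-10.0))

    def test_closure_rate_reduces_to_prefactor_without_barrier(self):
        params = baseline_params().replace(dG_conf=0.0)
        cfg = SimConfig(concentration=10.5)
        ev = rates_by_kind(event_rates(make_state([]), params, cfg))
        assert ev[CLOSURE][0].rate == pytest.approx(params.k_conf)

    def test_closed_state_has_no_closure_channel(self, baseline):
        cfg = SimConfig(concentration=10.5)
        st = make_state([4], conformation=CLOSED)
        assert CLOSURE not in rates_by_kind(event_rates(st, baseline, cfg))

    def test_all_mode_gives_every_dimer_a_channel(self, baseline):
        cfg = SimConfig(concentration=10.5, dissociation="all")
        st = make_state({3: 4})
        dis = rates_by_kind(event_rates(st, baseline, cfg))[DISSOCIATION]
        assert [(ev.pf, ev.layer) for ev in dis] == [(3, 1), (3, 2), (3, 3), (3, 4)]
        cfg_t = SimConfig(concentration=10.5, dissociation="terminal")
        dis_t = rates_by_kind(event_rates(st, baseline, cfg_t))[DISSOCIATION]
        assert [(ev.pf, ev.layer) for ev in dis_t] == [(3, 4)]


class _FixedRng:
    def __init__(self, values):
        self.values = list(values)

    def random(self):
        return self.values.pop(0)


class TestNextEvent:
    def test_waiting_time_formula(self):
        ev = Event(ASSOCIATION, pf=0, layer=1, rate=2.0)
        chosen, dt = next_event([ev], _FixedRng([math.exp(-1.0)]))
        assert chosen is ev
        assert dt == pytest.approx(0.5)

    def test_selection_probability_matches_rate_ratio(self):
        rng = np.random.default_rng(123)
        k1, k2 = 3.0, 7.0
        wins = 0
        n = 100_000
        for _ in range(n):
            ev, _ = next_event(
                [Event(ASSOCIATION, rate=k1), Event(DISSOCIATION, rate=k2)], rng
            )
            wins += ev.kind == ASSOCIATION
        p = k1 / (k1 + k2)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(wins / n - p) < 4 * se

    def test_all_zero_rates_signal_absorbing_state(self):
        with pytest.raises(AbsorbingStateError):
            next_event([Event(ASSOCIATION, rate=0.0)], np.random.default_rng(0))
        with pytest.raises(AbsorbingStateError):
            next_event([], np.random.default_rng(0))


class TestApplyEvent:
    def test_dissociation_cascades_above(self):
        st = make_state({3: 5})
        apply_event(st, Event(DISSOCIATION, pf=3, layer=2, waiting_time=0.1))
        assert st.heights[3] == 1
        assert st.t == pytest.approx(0.1)

    def test_first_association_binds_gamma_site(self):
        st = make_state([])
        apply_event(st, Event(ASSOCIATION, pf=0, layer=1, waiting_time=0.0))
        assert st.heights[0] == 1

    def test_closure_flips_conformation_only(self):
        st = make_state([3, 4])
        heights = st.heights.copy()
        apply_event(st, Event(CLOSURE, waiting_time=0.2))
        assert st.conformation == CLOSED
        assert (st.heights == heights).all()

    @pytest.mark.parametrize(
        "state_kw,event",
        [
            (dict(occupied=[]), Event(DISSOCIATION, pf=0, layer=1)),
            (dict(occupied=[0]), Event(ASSOCIATION, pf=0, layer=1)),
            (dict(occupied=[0], conformation=CLOSED), Event(CLOSURE)),
        ],
    )
    def test_inconsistent_events_are_internal_errors(self, state_kw, event):
        with pytest.raises(RuntimeError):
            apply_event(make_state(**state_kw), event)


class TestRunSimulation:
    def test_zero_concentration_never_nucleates(self, baseline):
        cfg = SimConfig(concentration=0.0, t_max=50.0, rng_seed=1, trace_dt=10.0)
        r = run_simulation(baseline, cfg, engine="python")
        assert r.censored
        assert r.final_heights.sum() == 0

    def test_zero_closure_prefactor_censors_gturc_mode(self):
        params = baseline_params().replace(k_conf=0.0)
        cfg = SimConfig(concentration=28.0, t_max=5.0, rng_seed=2)
        for engine in ("python", "numba"):
            assert run_simulation(params, cfg, engine=engine).censored

    @pytest.mark.parametrize("engine", ["python", "numba"])
    def test_fixed_seed_is_bit_reproducible(self, baseline, engine):
        cfg = SimConfig(concentration=21.0, t_max=100.0, rng_seed=7, stop_after_nucleation=True)
        a = run_simulation(baseline, cfg, engine=engine)
        b = run_simulation(baseline, cfg, engine=engine)
        assert a.nucleation_time == b.nucleation_time
        assert a.n_events == b.n_events
        if a.closure_snapshot is not None:
            assert (a.closure_snapshot == b.closure_snapshot).all()

    def test_seed_mode_overrides_gamma_bond_and_starts_closed(self, baseline):
        cfg = SimConfig(mode="seed")
        eff = effective_params(baseline, cfg)
        assert eff.dG_long_gamma == baseline.dG_long_ab
        from gturcsim.engine import initial_state

        assert initial_state(cfg).conformation == CLOSED

    def test_seed_mode_records_time_to_50nm(self, baseline):
        cfg = SimConfig(
            mode="seed", concentration=7.0, t_max=200.0, rng_seed=5,
            stop_after_nucleation=True, trace_dt=None,
        )
        r = run_simulation(baseline, cfg, engine="numba")
        assert not r.censored
        assert 0 < r.nucleation_time < 200.0

    def test_python_and_numba_agree_in_distribution(self, baseline):
        """The first-reaction reference and the direct-method kernel sample
        the same nucleation-time law (KS test, alpha = 0.01)."""
        from scipy import stats

        cfg = SimConfig(concentration=28.0, t_max=200.0, stop_after_nucleation=True)
        t_py = [
            run_simulation(baseline, cfg.replace(rng_seed=int(s)), engine="python").nucleation_time
            for s in range(60)
        ]
        t_nb = [
            run_simulation(baseline, cfg.replace(rng_seed=int(s) + 1000), engine="numba").nucleation_time
            for s in range(200)
        ]
        t_py = [t for t in t_py if t is not None]
        t_nb = [t for t in t_nb if t is not None]
        assert stats.ks_2samp(t_py, t_nb).pvalue > 0.01


class TestEnsemble:
    def test_all_censored_gives_flat_zero_curve(self, baseline):
        cfg = SimConfig(concentration=0.0, t_max=10.0)
        ens = run_ensemble(baseline, cfg, n_sims=5, master_seed=3, engine="numba")
        _, p = ens.p_curve(dt=1.0)
        assert (p == 0).all()

    def test_single_nucleation_steps_to_one(self, baseline):
        cfg = SimConfig(concentration=28.0, t_max=200.0, stop_after_nucleation=True)
        ens = run_ensemble(baseline, cfg, n_sims=1, master_seed=4)
        t0 = ens.results[0].nucleation_time
        grid, p = ens.p_curve(dt=0.5)
        assert (p[grid < t0] == 0).all()
        assert (p[grid >= t0 + 0.5] == 1).all()

    def test_identical_master_seed_reproduces_ensemble(self, baseline):
        cfg = SimConfig(concentration=14.0, t_max=100.0, stop_after_nucleation=True)
        a = run_ensemble(baseline, cfg, n_sims=20, master_seed=9)
        b = run_ensemble(baseline, cfg, n_sims=20, master_seed=9)
        assert np.array_equal(a.nucleation_times(), b.nucleation_times())

    def test_seed_derivation_is_deterministic_and_in_range(self):
        s1 = spawn_seeds(42, 100)
        s2 = spawn_seeds(42, 100)
        assert np.array_equal(s1, s2)
        assert (s1 >= 0).all() and (s1 < 2**31).all()
        assert len(np.unique(s1)) == 100

    def test_conservation_of_dimers(self, baseline):
        """Dimers added minus removed equals the final occupancy."""
        from gturcsim.engine import ASSOCIATION, DISSOCIATION, initial_state
        from gturcsim.engine import event_rates as rates, next_event as nxt, apply_event as apply
        from gturcsim.engine import effective_params

        cfg = SimConfig(concentration=21.0, t_max=2.0, rng_seed=11)
        state = initial_state(cfg)
        rng = np.random.default_rng(11)
        added = removed = 0
        p = effective_params(baseline, cfg)
        for _ in range(500):
            ev, dt = nxt(rates(state, p, cfg), rng)
            before = state.total_dimers
            apply(state, ev, dt)
            delta = state.total_dimers - before
            if ev.kind == ASSOCIATION:
                added += delta
            elif ev.kind == DISSOCIATION:
                removed -= delta
            assert added - removed == state.total_dimers


class TestGrowthSpeed:
    def test_linear_trace_slope(self):
        t = np.linspace(0, 10, 21)
        trace = np.column_stack([t, np.zeros_like(t), 2 * t])
        r = SimResult(nucleation_time=0.0, t_end=10.0, rng_seed=0, mode="seed", trace=trace)
        assert growth_speed(r) == pytest.approx(2.0)

    def test_censored_gturc_trajectory_rejected(self):
        t = np.linspace(0, 10, 11)
        trace = np.column_stack([t, np.zeros_like(t), t])
        r = SimResult(nucleation_time=None, t_end=10.0, rng_seed=0, mode="gturc", trace=trace)
        with pytest.raises(CensoredTrajectoryError):
            growth_speed(r)

    def test_speed_increases_linearly_with_concentration(self, baseline):
        """Replicates the growth-speed calibration protocol: seed-mode
        ensembles across concentrations; mean speeds are nearly linear in C."""
        from scipy import stats

        cfg = SimConfig(mode="seed", t_max=60.0, length_max=1e5, trace_dt=0.5)
        means = []
        concs = [6.0, 10.0, 14.0, 18.0]
        for i, c in enumerate(concs):
            ens = run_ensemble(baseline, cfg.replace(concentration=c), n_sims=8, master_seed=30 + i)
            means.append(np.mean([growth_speed(r) for r in ens.results]))
        assert all(b > a for a, b in zip(means, means[1:]))
        res = stats.linregress(concs, means)
        assert res.rvalue**2 > 0.98

    def test_no_net_polymerization_below_threshold(self, baseline):
        """Below the polymerization threshold the template gains no
        appreciable length (speeds are orders of magnitude under the
        growing regime)."""
        cfg = SimConfig(mode="seed", concentration=1.0, t_max=100.0, trace_dt=1.0)
        ens = run_ensemble(baseline, cfg, n_sims=6, master_seed=31)
        mean_speed = np.mean([growth_speed(r) for r in ens.results])
        assert mean_speed < 0.1  # nm/s; compare ~20 nm/s at 10 uM
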