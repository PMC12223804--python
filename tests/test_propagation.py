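"""Toy dynamics against their oracles; state classification; recycling."""

import numpy as np
import pytest
from scipy import integrate, stats

from mablwe import (ConfigError, Interval, StateDef, classify_state,
                    make_toy_system, propagate_ensemble, recycle_walkers)
from mablwe.systems import DoubleWell1D, MarkovChainPropagator

from conftest import make_ensemble


class TestMarkovChain:
    def test_identity_chain_is_frozen(self, rng):
        prop = MarkovChainPropagator(np.eye(3))
        e = make_ensemble([0.5, 0.5], coords=np.array([[1.0], [2.0]]))
        e.walkers[0].payload, e.walkers[1].payload = 1, 2
        propagate_ensemble(e, prop, rng)
        assert [w.payload for w in e.walkers] == [1, 2]
        np.testing.assert_array_equal(e.coords_matrix(), [[1.0], [2.0]])

    def test_propagation_never_touches_weights_or_count(self, rng):
        sys_ = make_toy_system("markov_chain")
        e = sys_.initial_ensemble(10)
        before = e.weights().copy()
        for _ in range(20):
            propagate_ensemble(e, sys_.propagator, rng)
        np.testing.assert_array_equal(e.weights(), before)
        assert len(e) == 10

    def test_empirical_frequencies_match_matrix(self, rng):
        """Chi-square goodness of fit of observed transitions vs each row of
        the 3-state fixture chain, 1e5 total steps."""
        sys_ = make_toy_system("markov_chain")
        T = sys_.propagator.T
        n_walk, n_steps = 1000, 100
        states = np.zeros(n_walk, dtype=int)
        counts = np.zeros((3, 3))
        for _ in range(n_steps):
            new, _ = sys_.propagator.advance(list(states), 1.0, rng)
            new = np.asarray(new)
            for s, t in zip(states, new):
                counts[s, t] += 1
            states = new
        for i in range(3):
            expected = counts[i].sum() * T[i]
            keep = expected > 0
            _, p = stats.chisquare(counts[i][keep], expected[keep])
            assert p > 0.01

    def test_non_stochastic_matrix_rejected(self):
        with pytest.raises(ConfigError):
            make_toy_system("markov_chain",
                            {"transition_matrix": [[0.9, 0.2], [0.1, 0.9]]})


class TestDoubleWell:
    def test_barrierless_limit_is_free_diffusion(self, rng):
        """With h = 0 the mean-square displacement grows as 2 D t, D = kT/gamma."""
        free = DoubleWell1D(barrier_height=0.0, steps_per_tau=100)  # t = 0.1/tau
        x = [0.0] * 4000
        x, _ = free.advance(x, 1.0, rng)
        msd1 = np.mean(np.square(x))
        x, _ = free.advance(x, 1.0, rng)
        msd2 = np.mean(np.square(x))
        assert msd1 == pytest.approx(0.2, rel=0.05)
        assert msd2 == pytest.approx(0.4, rel=0.05)

    def test_equilibrium_matches_boltzmann(self, rng):
        """Long unresampled sampling of a tilted double well reproduces the
        Boltzmann ratio of the two wells within 5%."""
        dw = DoubleWell1D(barrier_height=1.5, tilt=0.5, steps_per_tau=200)
        Z = lambda a, b: integrate.quad(lambda x: np.exp(-dw.potential(x)), a, b)[0]
        exact = Z(0, 4) / Z(-4, 0)
        x = list(rng.uniform(-1.5, 1.5, 600))
        for _ in range(120):                      # equilibration: 24 time units
            x, _ = dw.advance(x, 1.0, rng)
        pos = neg = 0
        for _ in range(60):                       # time-averaged occupancies
            x, _ = dw.advance(x, 1.0, rng)
            arr = np.asarray(x)
            pos += (arr > 0).sum()
            neg += (arr < 0).sum()
        assert pos / neg == pytest.approx(exact, rel=0.05)

    def test_low_temperature_needs_resampling(self, rng):
        """An 8 kT barrier is not crossed by one unresampled trajectory in
        1e4 steps; the weighted-ensemble demo crosses it (premise of the
        whole approach)."""
        dw = DoubleWell1D(barrier_height=8.0, steps_per_tau=100)
        x = [-1.0]
        for _ in range(100):  # 1e4 steps
            x, _ = dw.advance(x, 1.0, rng)
            assert x[0] < 0.8


class TestStates:
    DEFS = (
        StateDef("bound", (Interval("distance", hi=2.0),)),
        StateDef("encounter", (Interval("rmsd", lo=10.0, hi=13.0),
                               Interval("distance", hi=6.0))),
        StateDef("unbound", (Interval("distance", lo=8.0),)),
    )
    NAMES = ("rmsd", "energy", "distance")

    def test_direct_predicates(self):
        assert classify_state([5.0, 0.0, 9.0], self.DEFS, self.NAMES) == "unbound"
        assert classify_state([5.0, 0.0, 1.0], self.DEFS, self.NAMES) == "bound"
        assert classify_state([5.0, 0.0, 5.0], self.DEFS, self.NAMES) is None

    def test_closed_boundary_is_inside(self):
        assert classify_state([5.0, 0.0, 2.0], self.DEFS, self.NAMES) == "bound"
        assert classify_state([5.0, 0.0, 8.0], self.DEFS, self.NAMES) == "unbound"

    def test_trap_region_is_encounter(self):
        assert classify_state([11.0, 0.0, 4.5], self.DEFS, self.NAMES) == "encounter"

    def test_declaration_order_wins(self):
        # a point matching both bound and encounter returns the first
        assert classify_state([11.0, 0.0, 1.5], self.DEFS, self.NAMES) == "bound"

    def test_unknown_coordinate_is_config_error(self):
        with pytest.raises(ConfigError):
            classify_state([1.0], self.DEFS, ("other",))


class TestRecycling:
    def test_noop_when_nobody_in_target(self):
        e = make_ensemble([0.5, 0.5], coords=np.array([[1.0], [2.0]]))
        target = StateDef("unbound", (Interval("x", lo=8.0),))
        _, flux = recycle_walkers(e, target, 0.0, [0.0], ("x",))
        assert flux == 0.0
        np.testing.assert_array_equal(e.coords_matrix(), [[1.0], [2.0]])

    def test_recycled_weight_is_summed_and_conserved(self):
        e = make_ensemble([0.01, 0.02, 0.97],
                          coords=np.array([[9.0], [8.5], [1.0]]))
        target = StateDef("unbound", (Interval("x", lo=8.0),))
        _, flux = recycle_walkers(e, target, -1.0, [0.0], ("x",))
        assert flux == pytest.approx(0.03)
        assert e.total_weight == pytest.approx(1.0, abs=1e-15)
        np.testing.assert_array_equal(e.coords_matrix(), [[0.0], [0.0], [1.0]])
        assert e.walkers[0].payload == -1.0


class TestToyFactory:
    def test_unknown_kind(self):
        with pytest.raises(ConfigError):
            make_toy_system("lattice")

    def test_surrogate_recommended_spec_uses_printed_ranges(self):
        sys_ = make_toy_system("surrogate_unbinding_2d")
        by_name = {c.name: c for c in sys_.score_spec.coordinates}
        assert (by_name["rmsd"].q_init, by_name["rmsd"].q_target) == (0.0, 25.0)
        assert by_name["rmsd"].region_scalings == ((10.0, 13.0, 0.8),)
        assert (by_name["energy"].q_init, by_name["energy"].q_target) == (350.0, -200.0)
        assert (by_name["distance"].q_init, by_name["distance"].q_target) == (0.0, 10.0)

    def test_surrogate_energy_observable_shape(self):
        """Energy-like coordinate: bound value 350, repulsive bump (> 0) just
        before the exit, approaching -200 when unbound."""
        prop = make_toy_system("surrogate_unbinding_2d").propagator
        assert prop.energy_observable(0.0) == pytest.approx(350.0)
        assert prop.energy_observable(prop.bump_d) > 0.0
        assert prop.energy_observable(20.0) == pytest.approx(-200.0, abs=1.0)

    def test_initial_ensemble_weight_exact(self):
        e = make_toy_system("double_well_1d").initial_ensemble(7)
        assert e.total_weight == pytest.approx(1.0, abs=1e-15)
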