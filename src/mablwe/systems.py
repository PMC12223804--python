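"""Built-in toy systems with exact or analytically known ground truth.

These are desk-scale stand-ins for a receptor-ligand MD system, chosen so
every statistical property of the resamplers can be checked against an
independent oracle:

* ``markov_chain`` — a discrete-state chain; the exact time-dependent
  distribution is a matrix power and mean first-passage times come from the
  fundamental matrix.
* ``double_well_1d`` — overdamped Langevin dynamics in U(x) = h(x^2-1)^2
  (optionally tilted), integrated by Euler-Maruyama; equilibrium well
  occupancies follow the Boltzmann distribution and the barrierless limit is
  free diffusion.
* ``surrogate_unbinding_2d`` — a two-dimensional landscape emulating charged-
  ligand unbinding.  A "distance"-like coordinate d runs from a bound well
  over a Gaussian barrier to the unbound region; an "rmsd"-like coordinate r
  lives in a bistable channel whose main track rises with d into a range
  where the exit over the barrier is sealed, while a metastable low-rmsd
  corridor — reachable only by backward motion along r — carries the true
  unbinding path.  A third, derived "energy"-like coordinate decreases
  smoothly with separation but has a repulsive (positive) bump just before
  the exit channel.  Together these exercise the three-coordinate progress
  score, the 0.8 region-scaling window and the backward-progress lesson
  without any molecular dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .ensemble import Ensemble, ROOT_PARENT, Walker
from .exceptions import ConfigError
from .progress import CoordinateSpec, ScoreSpec
from .propagation import Interval, StateDef

TOY_KINDS = ("markov_chain", "double_well_1d", "surrogate_unbinding_2d")


# ---------------------------------------------------------------------------
# propagators

class MarkovChainPropagator:
    """Discrete-state Markov chain; payload is the state index.

    One resampling interval tau corresponds to ``steps_per_tau`` chain steps
    (default 1, so the exact n-iteration distribution is ``p0 @ T**n``).
    """

    def __init__(self, transition_matrix, steps_per_tau: int = 1):
        T = np.asarray(transition_matrix, dtype=float)
        if T.ndim != 2 or T.shape[0] != T.shape[1]:
            raise ConfigError("transition matrix must be square")
        if np.any(T < 0) or not np.allclose(T.sum(axis=1), 1.0, atol=1e-12):
            raise ConfigError("transition matrix rows must be nonnegative and sum to 1")
        self.T = T
        self.cum = np.cumsum(T, axis=1)
        self.steps_per_tau = int(steps_per_tau)
        self.coordinate_names = ("state",)

    def advance(self, payloads, tau, rng):
        states = np.asarray(payloads, dtype=int)
        for _ in range(self.steps_per_tau):
            u = rng.random(states.shape[0])
            states = np.array([int(np.searchsorted(self.cum[s], x, side="right"))
                               for s, x in zip(states, u)])
            states = np.minimum(states, self.T.shape[0] - 1)
        return list(int(s) for s in states), states[:, None].astype(float)


class DoubleWell1D:
    """Overdamped Langevin particle in U(x) = h (x^2 - 1)^2 + tilt * x.

    Euler-Maruyama stepping: dx = -U'(x) dt / gamma + sqrt(2 kT dt / gamma) xi.
    ``h`` is the barrier height in units of kT (for tilt = 0); the two minima
    sit near x = -1 (reactant) and x = +1 (product).  Payload is the position.
    """

    def __init__(self, barrier_height: float = 5.0, tilt: float = 0.0,
                 kT: float = 1.0, friction: float = 1.0,
                 dt: float = 1e-3, steps_per_tau: int = 10):
        if dt <= 0 or friction <= 0 or kT <= 0:
            raise ConfigError("dt, friction and kT must be positive")
        self.h, self.tilt, self.kT = float(barrier_height), float(tilt), float(kT)
        self.friction, self.dt = float(friction), float(dt)
        self.steps_per_tau = int(steps_per_tau)
        self.coordinate_names = ("x",)

    def potential(self, x):
        return self.h * (x ** 2 - 1.0) ** 2 + self.tilt * x

    def force(self, x):
        return -(4.0 * self.h * x * (x ** 2 - 1.0) + self.tilt)

    def advance(self, payloads, tau, rng):
        x = np.asarray(payloads, dtype=float)
        a = self.dt / self.friction
        noise = np.sqrt(2.0 * self.kT * self.dt / self.friction)
        for _ in range(self.steps_per_tau):
            x = x + a * self.force(x) + noise * rng.standard_normal(x.shape)
        return [float(v) for v in x], x[:, None].copy()


class SurrogateUnbinding2D:
    """Two-dimensional surrogate-unbinding landscape; payload is (d, r).

    ``d`` is the separation-distance-like coordinate: a shallow bound well
    near ``well_d``, a Gaussian barrier of height ``barrier_height`` (kT)
    centred at ``barrier_d``, and the unbound region beyond.  ``r`` is the
    rmsd-like coordinate living in a *bistable* channel: the main track
    r = track_slope * d rises steadily with separation, but an exit block
    seals the barrier passage for r above ``block_r_onset`` — and the track
    has climbed past that onset by the time it reaches the barrier, so
    following apparent rmsd progress dead-ends in a crowd of encounter-
    complex-like states pressed against the closed gate.  The only way over
    the barrier is a metastable low-r corridor valley at ``corridor_r`` that
    bifurcates off the track at ``corridor_onset_d``, slightly uphill
    (``corridor_offset`` kT): reaching it requires backward motion along r.
    The two valleys are combined smoothly as a log-sum of Gaussians, so the
    dynamics is an ordinary overdamped Langevin process on a smooth surface.

    The derived energy-like observable is

        E(d) = e_unbound + (e_bound - e_unbound) exp(-d/2)
               + bump * exp(-(d - bump_d)^2 / (2 bump_w^2)),

    positive just before the exit channel (repulsive springboard) and
    approaching ``e_unbound`` < 0 at large separation.
    """

    def __init__(self, barrier_height: float = 6.0, barrier_d: float = 5.2,
                 barrier_w: float = 1.2, well_d: float = 1.5,
                 well_k: float = 0.05,
                 track_slope: float = 2.8, track_k: float = 1.0,
                 corridor_r: float = 9.6, corridor_k: float = 1.5,
                 corridor_offset: float = 1.5, corridor_onset_d: float = 3.8,
                 corridor_onset_k: float = 6.0,
                 block_height: float = 12.0, block_r_onset: float = 10.0,
                 block_r_width: float = 0.5, block_d_width: float = 1.0,
                 e_bound: float = 350.0, e_unbound: float = -200.0,
                 bump: float = 250.0, bump_d: float = 6.5, bump_w: float = 0.5,
                 kT: float = 1.0, friction: float = 1.0,
                 dt: float = 5e-3, steps_per_tau: int = 20):
        self.h, self.bd, self.bw = (float(barrier_height), float(barrier_d),
                                    float(barrier_w))
        self.wd, self.wk = float(well_d), float(well_k)
        self.slope, self.kt_ = float(track_slope), float(track_k)
        self.cr, self.ck = float(corridor_r), float(corridor_k)
        self.coff, self.cod = float(corridor_offset), float(corridor_onset_d)
        self.cok = float(corridor_onset_k)
        self.bh, self.br0, self.brw = (float(block_height), float(block_r_onset),
                                       float(block_r_width))
        self.bdw = float(block_d_width)
        self.e_bound, self.e_unbound = float(e_bound), float(e_unbound)
        self.bump, self.bump_d, self.bump_w = float(bump), float(bump_d), float(bump_w)
        self.kT, self.friction, self.dt = float(kT), float(friction), float(dt)
        self.steps_per_tau = int(steps_per_tau)
        self.coordinate_names = ("rmsd", "energy", "distance")

    # potential pieces -----------------------------------------------------
    def _corridor_penalty(self, d):
        """Extra free energy of the corridor valley; large before the onset."""
        gap = np.maximum(self.cod - d, 0.0)
        return self.coff + self.cok * gap ** 2

    def _channel_parts(self, d, r):
        """Log-weights of the track and corridor valleys (kT units)."""
        a_track = -0.5 * self.kt_ * (r - self.slope * d) ** 2
        a_corr = -0.5 * self.ck * (r - self.cr) ** 2 - self._corridor_penalty(d)
        return a_track, a_corr

    def _block_parts(self, d, r):
        # saturating in r: seals the passage above the onset without exerting
        # force on configurations far above it
        excess = np.clip((r - self.br0) / self.brw, 0.0, 1.0)
        gate = np.exp(-((d - self.bd) ** 2) / (2.0 * self.bdw ** 2))
        return excess, gate

    def potential(self, d, r):
        barrier = self.h * np.exp(-((d - self.bd) ** 2) / (2 * self.bw ** 2))
        well = self.wk * (d - self.wd) ** 2
        a_track, a_corr = self._channel_parts(d, r)
        m = np.maximum(a_track, a_corr)
        channel = -(m + np.log(np.exp(a_track - m) + np.exp(a_corr - m)))
        excess, gate = self._block_parts(d, r)
        block = self.bh * gate * excess ** 2
        return well + barrier + channel + block

    def _grad(self, d, r):
        a_track, a_corr = self._channel_parts(d, r)
        m = np.maximum(a_track, a_corr)
        wt = np.exp(a_track - m)
        wc = np.exp(a_corr - m)
        norm = wt + wc
        # d(-logsumexp)/dx = -(wt * da_t/dx + wc * da_c/dx) / norm
        dat_dr = -self.kt_ * (r - self.slope * d)
        dac_dr = -self.ck * (r - self.cr)
        dat_dd = self.kt_ * (r - self.slope * d) * self.slope
        gap = np.maximum(self.cod - d, 0.0)
        dac_dd = 2.0 * self.cok * gap            # -d(penalty)/dd
        dch_dr = -(wt * dat_dr + wc * dac_dr) / norm
        dch_dd = -(wt * dat_dd + wc * dac_dd) / norm
        excess, gate = self._block_parts(d, r)
        dU_dd = (-self.h * (d - self.bd) / self.bw ** 2
                 * np.exp(-((d - self.bd) ** 2) / (2 * self.bw ** 2))
                 + 2.0 * self.wk * (d - self.wd)
                 + dch_dd
                 - self.bh * gate * (d - self.bd) / self.bdw ** 2 * excess ** 2)
        dU_dr = (dch_dr
                 + self.bh * gate * 2.0 * excess * (excess < 1.0) / self.brw)
        return dU_dd, dU_dr

    def energy_observable(self, d):
        return (self.e_unbound
                + (self.e_bound - self.e_unbound) * np.exp(-d / 2.0)
                + self.bump * np.exp(-(d - self.bump_d) ** 2 / (2 * self.bump_w ** 2)))

    def advance(self, payloads, tau, rng):
        pts = np.asarray(payloads, dtype=float).reshape(-1, 2)
        d, r = pts[:, 0].copy(), pts[:, 1].copy()
        a = self.dt / self.friction
        noise = np.sqrt(2.0 * self.kT * self.dt / self.friction)
        for _ in range(self.steps_per_tau):
            gd, gr = self._grad(d, r)
            d = d - a * gd + noise * rng.standard_normal(d.shape)
            r = r - a * gr + noise * rng.standard_normal(r.shape)
            d = np.maximum(d, 0.0)     # reflective floor: separation >= 0
            r = np.maximum(r, 0.0)
        coords = np.column_stack([r, self.energy_observable(d), d])
        return [(float(x), float(y)) for x, y in zip(d, r)], coords


# ---------------------------------------------------------------------------
# fixture factory

@dataclass
class ToySystem:
    """A ready-to-run toy system: dynamics, states, and a recommended score."""

    kind: str
    propagator: Any
    states: tuple[StateDef, ...]
    score_spec: ScoreSpec
    source_payload: Any
    source_coords: np.ndarray
    parameters: dict = field(default_factory=dict)

    def initial_ensemble(self, walker_count: int, tau: float = 1.0) -> Ensemble:
        w = 1.0 / walker_count
        walkers = [Walker(id=i, parent_id=ROOT_PARENT, weight=w,
                          coords=np.array(self.source_coords, copy=True),
                          payload=_copy(self.source_payload))
                   for i in range(walker_count)]
        # absorb the division residual so the sum is exactly 1
        walkers[-1].weight = 1.0 - w * (walker_count - 1)
        return Ensemble(iteration=0, walkers=walkers, tau=tau)


def _copy(x):
    import copy
    return copy.deepcopy(x)


DEFAULT_CHAIN_3STATE = np.array([[0.90, 0.10, 0.00],
                                 [0.10, 0.80, 0.10],
                                 [0.00, 0.10, 0.90]])


def make_toy_system(kind: str, parameters: dict | None = None) -> ToySystem:
    """Build one of the built-in toy systems with a recommended score spec."""
    params = dict(parameters or {})
    if kind == "markov_chain":
        T = np.asarray(params.pop("transition_matrix", DEFAULT_CHAIN_3STATE),
                       dtype=float)
        prop = MarkovChainPropagator(T, steps_per_tau=params.pop("steps_per_tau", 1))
        n = T.shape[0]
        spec = ScoreSpec((CoordinateSpec("state", q_init=0.0, q_target=float(n - 1)),))
        states = (
            StateDef("bound", (Interval("state", hi=0.5),)),
            StateDef("unbound", (Interval("state", lo=n - 1.5),)),
        )
        return ToySystem(kind, prop, states, spec,
                         source_payload=0, source_coords=np.array([0.0]),
                         parameters={"transition_matrix": T.tolist(),
                                     "steps_per_tau": prop.steps_per_tau})
    if kind == "double_well_1d":
        prop = DoubleWell1D(**params)
        spec = ScoreSpec((CoordinateSpec("x", q_init=-1.0, q_target=1.0),))
        states = (
            StateDef("reactant", (Interval("x", hi=-0.8),)),
            StateDef("product", (Interval("x", lo=0.8),)),
        )
        return ToySystem(kind, prop, states, spec,
                         source_payload=-1.0, source_coords=np.array([-1.0]),
                         parameters={"barrier_height": prop.h, "tilt": prop.tilt,
                                     "kT": prop.kT, "dt": prop.dt,
                                     "friction": prop.friction,
                                     "steps_per_tau": prop.steps_per_tau})
    if kind == "surrogate_unbinding_2d":
        region = params.pop("rmsd_region_scaling", ((10.0, 13.0, 0.8),))
        prop = SurrogateUnbinding2D(**params)
        d0 = prop.wd
        r0 = prop.slope * d0
        spec = ScoreSpec((
            CoordinateSpec("rmsd", q_init=0.0, q_target=25.0,
                           region_scalings=tuple(region) if region else ()),
            CoordinateSpec("energy", q_init=prop.e_bound, q_target=prop.e_unbound),
            CoordinateSpec("distance", q_init=0.0, q_target=10.0),
        ))
        states = (
            StateDef("bound", (Interval("distance", hi=2.0),)),
            StateDef("encounter", (Interval("rmsd", lo=10.0, hi=13.0),
                                   Interval("distance", hi=6.0),)),
            StateDef("unbound", (Interval("distance", lo=8.0),)),
        )
        coords0 = np.array([r0, float(prop.energy_observable(d0)), d0])
        return ToySystem(kind, prop, states, spec,
                         source_payload=(d0, r0), source_coords=coords0,
                         parameters={"barrier_height": prop.h,
                                     "track_slope": prop.slope,
                                     "corridor_r": prop.cr,
                                     "corridor_offset": prop.coff,
                                     "rmsd_region_scaling": [list(w) for w in (region or ())],
                                     "dt": prop.dt, "kT": prop.kT,
                                     "steps_per_tau": prop.steps_per_tau})
    raise ConfigError(f"unknown toy system kind {kind!r}; choose from {TOY_KINDS}")
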