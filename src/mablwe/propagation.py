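"""Dynamics contract, state classification and walker recycling.

A *propagator* stands in for the MD engine: it advances every walker's opaque
payload by one resampling interval tau and refreshes the walker's progress
coordinates from the payload.  Propagation never touches statistical weights
— trajectory weights are a property of the resampling bookkeeping, not of the
dynamics.

States (bound / unbound / encounter-complex / ...) are defined as interval
predicates on named coordinates; they need not partition coordinate space.
Optional *recycling* resets walkers that reach a target state back to a
source configuration while keeping their weight, recording the recycled
weight as flux — the steady-state flux into the target equals the rate of
the transition (Hill relation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Protocol, Sequence, runtime_checkable

import numpy as np

from .ensemble import Ensemble
from .exceptions import ConfigError, PropagationError


@runtime_checkable
class Propagator(Protocol):
    """Contract every dynamics backend satisfies."""

    coordinate_names: tuple[str, ...]

    def advance(self, payloads: list[Any], tau: float,
                rng: np.random.Generator) -> tuple[list[Any], np.ndarray]:
        """Advance payloads by tau; return (new payloads, (n, M) coords)."""
        ...


@dataclass(frozen=True)
class Interval:
    """Closed/open interval condition on one named coordinate."""

    coordinate: str
    lo: float = -np.inf
    hi: float = np.inf
    closed_lo: bool = True
    closed_hi: bool = True

    def contains(self, v: float) -> bool:
        above = v >= self.lo if self.closed_lo else v > self.lo
        below = v <= self.hi if self.closed_hi else v < self.hi
        return above and below


@dataclass(frozen=True)
class StateDef:
    """A named state: the conjunction of interval conditions on coordinates."""

    name: str
    conditions: tuple[Interval, ...]

    def matches(self, coords: Sequence[float], names: Sequence[str]) -> bool:
        lookup = dict(zip(names, coords))
        for c in self.conditions:
            if c.coordinate not in lookup:
                raise ConfigError(
                    f"state {self.name!r} references unknown coordinate "
                    f"{c.coordinate!r} (have {list(names)})")
            if not c.contains(lookup[c.coordinate]):
                return False
        return True


def classify_state(coords: Sequence[float], defs: Sequence[StateDef],
                   names: Sequence[str]) -> str | None:
    """First matching state in declaration order, or None."""
    for sd in defs:
        if sd.matches(coords, names):
            return sd.name
    return None


def propagate_ensemble(e: Ensemble, p: Propagator,
                       rng: np.random.Generator) -> Ensemble:
    """Advance every walker by exactly tau, in place; weights untouched."""
    payloads = [w.payload for w in e.walkers]
    try:
        new_payloads, coords = p.advance(payloads, e.tau, rng)
    except (TypeError, KeyError, IndexError) as err:
        raise PropagationError(f"payload incompatible with propagator: {err}")
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.shape[0] != len(e):
        raise PropagationError("propagator returned wrong number of walkers")
    for w, pay, c in zip(e.walkers, new_payloads, coords):
        w.payload = pay
        w.coords = np.array(c, dtype=float)
    return e


def recycle_walkers(e: Ensemble, target: StateDef, source_payload: Any,
                    source_coords: Sequence[float],
                    names: Sequence[str]) -> tuple[Ensemble, float]:
    """Reset every walker in the target state to the source, keeping its weight.

    Returns the ensemble (modified in place) and the total recycled weight,
    i.e. the probability flux that arrived in the target this iteration.
    """
    recycled = 0.0
    src = np.asarray(source_coords, dtype=float)
    for w in e.walkers:
        if target.matches(w.coords, names):
            recycled += w.weight
            w.payload = _copy_payload(source_payload)
            w.coords = np.array(src, copy=True)
    return e, recycled


def _copy_payload(payload: Any) -> Any:
    import copy
    return copy.deepcopy(payload)
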