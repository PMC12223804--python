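"""The binless progress score used to rank walkers for splitting and merging.

Each walker's score combines, multiplicatively,

* per-coordinate normalized progress ``1 - |q - q_t| / |q_i - q_t|`` on a
  0-to-1 scale between a user-chosen initial value ``q_i`` and target value
  ``q_t``,
* a per-coordinate scaling factor ``C_m`` tuning that coordinate's influence,
* optional *region scalings*: multiplicative penalties applied while a
  coordinate sits inside a window, used to de-emphasize regions where
  trajectories get trapped and backward motion is needed, and
* a weight-balance ("soft threshold") term, by default ``1/(-ln P)`` where
  ``P`` is the walker's statistical weight.  The balance term is increasing in
  ``P``, so low-weight walkers are disfavored for further splitting and
  favored for merging, which curbs oversplitting at the leading edge.

The score only *ranks* walkers; weights are never touched here, so the
initial/target values, scalings, and windows can all be adjusted on the fly
without biasing the ensemble.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

BALANCE_MODES = ("inverse_neg_log", "one_minus_log", "none")

#: upper bound on the 1/(-ln P) balance term; P = 1 (the very first iteration)
#: would otherwise diverge.
DEFAULT_BALANCE_CAP = 1e3


@dataclass(frozen=True)
class CoordinateSpec:
    """Progress definition for one coordinate.

    ``region_scalings`` is a list of ``(lo, hi, factor)`` windows; while the
    coordinate's value lies in ``[lo, hi]`` the walker's score is multiplied
    by ``factor`` (in (0, 1]).
    """

    name: str
    q_init: float
    q_target: float
    scale: float = 1.0
    region_scalings: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self):
        if self.q_init == self.q_target:
            raise ValueError(f"{self.name}: q_init must differ from q_target")
        if not self.scale > 0:
            raise ValueError(f"{self.name}: scale C_m must be positive")
        object.__setattr__(self, "region_scalings",
                           tuple(tuple(w) for w in self.region_scalings))
        for lo, hi, f in self.region_scalings:
            if not lo < hi:
                raise ValueError(f"{self.name}: region window needs lo < hi")
            if not 0 < f <= 1:
                raise ValueError(f"{self.name}: region factor must be in (0,1]")


@dataclass(frozen=True)
class ScoreSpec:
    """Full score definition over M coordinates plus the balance term."""

    coordinates: tuple[CoordinateSpec, ...]
    balance: str = "inverse_neg_log"
    balance_cap: float = DEFAULT_BALANCE_CAP
    clamp_progress: bool = True

    def __post_init__(self):
        object.__setattr__(self, "coordinates", tuple(self.coordinates))
        if len(self.coordinates) < 1:
            raise ValueError("at least one coordinate is required")
        if self.balance not in BALANCE_MODES:
            raise ValueError(f"unknown balance mode {self.balance!r}")
        if not self.balance_cap > 0:
            raise ValueError("balance_cap must be positive")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.coordinates)


def coordinate_progress(q: float, cs: CoordinateSpec, *, clamp: bool = True) -> float:
    """Normalized progress of one coordinate: 1 at target, 0 at the initial value.

    Computed as ``1 - |q - q_target| / |q_init - q_target|``; with ``clamp``
    the result is held in [0, 1] so overshoot past the target or backtracking
    behind the initial value cannot produce scores outside the ranking scale.
    """
    if not math.isfinite(q):
        raise ValueError(f"{cs.name}: coordinate value must be finite, got {q}")
    p = 1.0 - abs(q - cs.q_target) / abs(cs.q_init - cs.q_target)
    if clamp:
        p = min(1.0, max(0.0, p))
    return p


def balance_term(P: float, spec: ScoreSpec) -> float:
    """Weight-balance factor of the score for a walker of weight ``P``."""
    if not 0.0 < P <= 1.0:
        raise ValueError(f"weight must be in (0, 1], got {P}")
    if spec.balance == "none":
        return 1.0
    if spec.balance == "one_minus_log":
        return 1.0 - math.log(P)
    neg_log = -math.log(P)
    if neg_log <= 1.0 / spec.balance_cap:
        return spec.balance_cap
    return 1.0 / neg_log


def region_factor(q: float, cs: CoordinateSpec) -> float:
    """Product of all region-scaling factors whose window contains ``q``."""
    f = 1.0
    for lo, hi, factor in cs.region_scalings:
        if lo <= q <= hi:
            f *= factor
    return f


def compute_score(coords: Sequence[float], P: float, spec: ScoreSpec) -> float:
    """Progress score S of a walker with coordinate values ``coords`` and weight ``P``.

    ``S = [prod_m C_m * progress_m] * balance(P) * prod(region factors)``.
    S is 0 whenever any coordinate sits at (or, with clamping, behind) its
    initial value, and multiplying all ``C_m`` by a common constant rescales
    every S identically, leaving the rank order unchanged.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (len(spec.coordinates),):
        raise ValueError(
            f"expected {len(spec.coordinates)} coordinate values, got {coords.shape}")
    s = 1.0
    for q, cs in zip(coords, spec.coordinates):
        s *= cs.scale * coordinate_progress(float(q), cs, clamp=spec.clamp_progress)
        s *= region_factor(float(q), cs)
    return s * balance_term(P, spec)


def score_ensemble(e, spec: ScoreSpec) -> np.ndarray:
    """Vector of scores for every walker in an ensemble."""
    return np.array([compute_score(w.coords, w.weight, spec) for w in e.walkers])


def update_spec(spec: ScoreSpec, coordinate: str, **changes) -> ScoreSpec:
    """Return a new spec with one coordinate's fields changed.

    Progress definitions may be adjusted mid-run: walker weights are
    independent of the score, so re-targeting a coordinate or adding a region
    window only changes future split/merge rankings, never the statistics.
    """
    found = False
    new_coords = []
    for cs in spec.coordinates:
        if cs.name == coordinate:
            cs = replace(cs, **changes)
            found = True
        new_coords.append(cs)
    if not found:
        raise ValueError(f"no coordinate named {coordinate!r}")
    return replace(spec, coordinates=tuple(new_coords))
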