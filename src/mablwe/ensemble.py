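"""Walker/ensemble data model and statistically exact split/merge primitives.

A *walker* is one weighted trajectory segment: a statistical weight, a vector
of progress-coordinate values, an opaque propagator payload (e.g. a phase-space
point), and a lineage pointer to its parent in the previous iteration.  An
*ensemble* is the set of walkers alive at one iteration; its weights always sum
to one.

The two primitives every resampler must go through are :func:`split_walker`
(replicate a trajectory, dividing its weight among the children) and
:func:`merge_walkers` (terminate redundant trajectories, with the survivor
chosen probabilistically by weight).  Used correctly these leave the weighted
ensemble statistically unbiased, which is why all resampling variants in this
package are built on top of them rather than manipulating weights directly.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Any, Sequence

import numpy as np

from .exceptions import ConservationError, LookupError_

#: parent_id sentinel for walkers present at iteration 0
ROOT_PARENT = -1

#: default tolerance on |sum(weights) - 1|
CONSERVATION_TOL = 1e-12


@dataclass
class Walker:
    """One weighted trajectory segment.

    Parameters
    ----------
    id : int
        Unique within its iteration.
    parent_id : int
        Id of the parent walker in the previous iteration, or
        :data:`ROOT_PARENT` at iteration 0.
    weight : float
        Statistical weight, in (0, 1].
    coords : ndarray
        Current values of the M progress coordinates.
    payload : object
        Opaque propagator state (full phase-space point for Langevin systems,
        a state index for Markov chains).
    """

    id: int
    parent_id: int
    weight: float
    coords: np.ndarray
    payload: Any = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not (self.weight > 0.0):
            raise ValueError(f"walker weight must be positive, got {self.weight}")
        if self.weight > 1.0 + 1e-9:  # slack for fp noise accumulated by merges
            raise ValueError(f"walker weight must be <= 1, got {self.weight}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("walker coords must be finite")

    def clone(self, **changes: Any) -> "Walker":
        """Copy with independent coords/payload, applying field overrides."""
        w = replace(self, **changes)
        w.coords = np.array(self.coords if "coords" not in changes else w.coords,
                            dtype=float, copy=True)
        if "payload" not in changes:
            w.payload = copy.deepcopy(self.payload)
        return w


@dataclass
class Ensemble:
    """The walkers alive at one iteration.

    Invariants: weights sum to 1 (tolerance 1e-12), ids are unique, and there
    is at least one walker.
    """

    iteration: int
    walkers: list[Walker]
    tau: float = 1.0
    _next_id: int = field(default=-1, repr=False)

    def __post_init__(self) -> None:
        if not self.walkers:
            raise ValueError("ensemble must contain at least one walker")
        ids = [w.id for w in self.walkers]
        if len(set(ids)) != len(ids):
            raise ValueError("walker ids must be unique within an iteration")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self._next_id < 0:
            self._next_id = max(ids) + 1

    def __len__(self) -> int:
        return len(self.walkers)

    def __iter__(self):
        return iter(self.walkers)

    @property
    def total_weight(self) -> float:
        import math
        return math.fsum(w.weight for w in self.walkers)

    def fresh_id(self) -> int:
        """Next unused walker id within this iteration."""
        i = self._next_id
        self._next_id += 1
        return i

    def weights(self) -> np.ndarray:
        return np.array([w.weight for w in self.walkers])

    def coords_matrix(self) -> np.ndarray:
        """(n_walkers, M) array of progress-coordinate values."""
        return np.vstack([w.coords for w in self.walkers])


def split_walker(w: Walker, k: int = 2, *, id_source=None) -> list[Walker]:
    """Split a walker into ``k`` children, dividing its weight among them.

    Each child carries weight ``w.weight / k`` (the last child absorbs the
    one-ulp division residual so the sum is bit-exact), the parent's coords and
    payload, and ``parent_id = w.id``.

    Parameters
    ----------
    id_source : callable, optional
        Zero-argument callable returning fresh walker ids (typically
        ``Ensemble.fresh_id``).  Defaults to ids ``0..k-1``.
    """
    if k < 2:
        raise ValueError(f"split requires k >= 2, got {k}")
    if not (w.weight > 0.0):
        raise ValueError("cannot split a walker with nonpositive weight")
    share = w.weight / k
    new_id = id_source if id_source is not None else iter(range(k)).__next__
    children = []
    for j in range(k):
        wt = share if j < k - 1 else w.weight - share * (k - 1)
        children.append(
            Walker(id=new_id(), parent_id=w.id, weight=wt,
                   coords=np.array(w.coords, copy=True),
                   payload=copy.deepcopy(w.payload))
        )
    return children


def merge_walkers(ws: Sequence[Walker], rng: np.random.Generator) -> Walker:
    """Merge >= 2 walkers into one, conserving their total weight.

    The survivor is one of the inputs, chosen with probability proportional to
    its weight; it keeps its own coords and payload and inherits the summed
    weight.  Choosing the survivor any other way (e.g. by progress) biases the
    ensemble — see the rule-violating resampler mode for a demonstration.
    """
    if len(ws) < 2:
        raise ValueError("merge requires at least 2 walkers")
    weights = np.array([w.weight for w in ws], dtype=float)
    if np.any(weights <= 0):
        raise ValueError("all merge candidates must have positive weight")
    total = float(weights.sum())
    idx = int(rng.choice(len(ws), p=weights / total))
    return ws[idx].clone(weight=total)


def assert_conservation(e: Ensemble, tol: float = CONSERVATION_TOL,
                        *, iteration: int | None = None) -> None:
    """Raise :class:`ConservationError` unless |sum(weights) - 1| <= tol."""
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    s = e.total_weight
    if abs(s - 1.0) > tol:
        raise ConservationError(s, iteration if iteration is not None else e.iteration)


def trace_lineage(rec, walker_id: int, iteration: int):
    """Trace a walker's ancestor chain back to iteration 0.

    Parameters
    ----------
    rec : RunRecord
        Per-iteration history with ids/parents/coords/weights arrays.

    Returns
    -------
    list of (iteration, walker_id, coords, weight)
        Ordered from iteration 0 to ``iteration``; consecutive entries differ
        by exactly one iteration.
    """
    chain = []
    it, wid = iteration, walker_id
    while it >= 0:
        snap = rec.iteration_data(it)
        ids = snap["ids"]
        hits = np.flatnonzero(ids == wid)
        if hits.size != 1:
            raise LookupError_(f"walker id {wid} not found at iteration {it}")
        j = int(hits[0])
        chain.append((it, wid, np.array(snap["coords"][j]), float(snap["weights"][j])))
        parent = int(snap["parents"][j])
        if it == 0:
            if parent != ROOT_PARENT:
                raise LookupError_(
                    f"iteration-0 walker {wid} has non-root parent {parent}")
            break
        wid = parent
        it -= 1
    chain.reverse()
    return chain
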