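"""Per-iteration run history: the archive-backed record of a WE simulation.

One :class:`RunRecord` stores, for every completed iteration, the walker ids,
their parent ids in the previous iteration, weights, coordinate values,
progress scores and the resampling events that produced the *next* iteration,
plus the recycled-flux series and a config snapshot.  Everything an analysis
needs can be re-derived from the record alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .exceptions import LookupError_

SCHEMA_VERSION = 1


@dataclass
class FluxSeries:
    """Recycled weight per iteration (probability flux into the target state)."""

    values: np.ndarray
    tau: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("flux entries must be nonnegative")

    def __len__(self):
        return len(self.values)

    def cumulative_mean(self) -> np.ndarray:
        n = np.arange(1, len(self.values) + 1)
        return np.cumsum(self.values) / n


class RunRecord:
    """In-memory run archive; append-only during a simulation."""

    def __init__(self, config: dict | None = None, seed: int | None = None,
                 coordinate_names: tuple[str, ...] = (), tau: float = 1.0):
        self.config = dict(config or {})
        self.seed = seed
        self.coordinate_names = tuple(coordinate_names)
        self.tau = float(tau)
        self.iterations: list[dict] = []
        self.flux: list[float] = []
        self.spec_changes: list[tuple[int, dict]] = []
        self.truncated = False

    # -- building ----------------------------------------------------------
    def append_iteration(self, ids, parents, weights, coords, scores=None,
                         events=None, flux: float = 0.0) -> None:
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        snap = {
            "ids": np.asarray(ids, dtype=int),
            "parents": np.asarray(parents, dtype=int),
            "weights": np.asarray(weights, dtype=float),
            "coords": coords,
            "scores": (np.asarray(scores, dtype=float) if scores is not None
                       else np.full(len(coords), np.nan)),
            "events": list(events or []),
        }
        n = len(snap["ids"])
        if not all(len(snap[k]) == n for k in ("parents", "weights", "coords")):
            raise ValueError("iteration arrays must have equal length")
        self.iterations.append(snap)
        self.flux.append(float(flux))

    def log_spec_change(self, iteration: int, changes: dict) -> None:
        self.spec_changes.append((iteration, dict(changes)))

    # -- access ------------------------------------------------------------
    @property
    def n_iterations(self) -> int:
        return len(self.iterations)

    def iteration_data(self, k: int) -> dict:
        if not 0 <= k < len(self.iterations):
            raise LookupError_(f"no iteration {k} in record "
                               f"({len(self.iterations)} recorded)")
        return self.iterations[k]

    def coordinate_index(self, name: str) -> int:
        try:
            return self.coordinate_names.index(name)
        except ValueError:
            raise LookupError_(
                f"unknown coordinate {name!r}; record has {self.coordinate_names}")

    def flux_series(self) -> FluxSeries:
        return FluxSeries(np.asarray(self.flux), tau=self.tau)

    def walker_counts(self) -> np.ndarray:
        return np.array([len(s["ids"]) for s in self.iterations])

    def weight_sums(self) -> np.ndarray:
        return np.array([s["weights"].sum() for s in self.iterations])

    def config_json(self) -> str:
        return json.dumps(self.config, sort_keys=True)

    def __eq__(self, other) -> bool:
        if not isinstance(other, RunRecord):
            return NotImplemented
        if (self.config != other.config or self.seed != other.seed
                or self.coordinate_names != other.coordinate_names
                or self.tau != other.tau
                or len(self.iterations) != len(other.iterations)
                or self.flux != other.flux):
            return False
        for a, b in zip(self.iterations, other.iterations):
            for k in ("ids", "parents", "weights", "coords", "scores"):
                if not np.array_equal(a[k], b[k], equal_nan=True):
                    return False
            if a["events"] != b["events"]:
                return False
        return True
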