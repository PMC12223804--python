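"""Observables and exact oracles for validating WE runs.

The Markov-chain helpers (:func:`exact_markov`, :func:`mfpt`) are brute-force
references — matrix powers and the fundamental matrix — against which the
weighted ensemble's statistics can be compared exactly.  The remaining
functions compute the observables used throughout: weighted coordinate
histograms, the first-event aggregate simulation time (the efficiency metric:
total walker-tau spent until any trajectory first reaches the target state),
the Hill-relation rate estimate from recycled flux, and the per-bin weight
profile used to audit merge-rule violations (under correct resampling the
maximum walker weight decays toward the target across a barrier; a
score-based merge survivor collapses that decay).
"""

from __future__ import annotations

import numpy as np

from .propagation import StateDef
from .record import FluxSeries, RunRecord


# ---------------------------------------------------------------------------
# exact Markov oracles

def _check_stochastic(T: np.ndarray) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(T < 0) or np.max(np.abs(T.sum(axis=1) - 1.0)) > 1e-12:
        raise ValueError("rows of the transition matrix must sum to 1")
    return T


def exact_markov(T, p0, n: int) -> np.ndarray:
    """Distribution after n steps: p0 advanced by the n-th matrix power."""
    T = _check_stochastic(T)
    p0 = np.asarray(p0, dtype=float)
    if abs(p0.sum() - 1.0) > 1e-9:
        raise ValueError("p0 must sum to 1")
    return p0 @ np.linalg.matrix_power(T, n)


def mfpt(T, source: int, target: int) -> float:
    """Mean first-passage time (in steps) from source to target.

    Computed from the fundamental matrix N = (I - Q)^-1 of the chain with the
    target state made absorbing; the MFPT is the source row sum of N.
    """
    T = _check_stochastic(T)
    keep = [i for i in range(T.shape[0]) if i != target]
    Q = T[np.ix_(keep, keep)]
    N = np.linalg.inv(np.eye(len(keep)) - Q)
    times = N.sum(axis=1)
    return float(times[keep.index(source)])


def stationary_distribution(T) -> np.ndarray:
    """Stationary distribution of an ergodic chain (left eigenvector for 1)."""
    T = _check_stochastic(T)
    vals, vecs = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# observables on run records

def weighted_histogram(rec: RunRecord, coordinates, bins,
                       iteration_range: tuple[int, int] | None = None,
                       log: bool = False):
    """Weighted 1-D or 2-D histogram averaged over an iteration range.

    Bin mass is the summed walker weight falling in the bin, averaged over the
    iterations in ``iteration_range`` (half-open; default: all).  Without
    recycling the total mass is the (averaged) total weight, i.e. 1.  With
    ``log=True`` the probabilities are log10-transformed with a floor at
    1e-300.

    Returns ``(hist, edges)`` for one coordinate or ``(hist, xedges, yedges)``
    for two.
    """
    names = [coordinates] if isinstance(coordinates, str) else list(coordinates)
    if len(names) not in (1, 2):
        raise ValueError("one or two coordinate names required")
    idx = [rec.coordinate_index(n) for n in names]
    lo, hi = iteration_range if iteration_range is not None else (0, rec.n_iterations)
    if not 0 <= lo < hi <= rec.n_iterations:
        raise ValueError(f"bad iteration range ({lo}, {hi})")

    hist = None
    for k in range(lo, hi):
        snap = rec.iteration_data(k)
        w = snap["weights"]
        if len(names) == 1:
            h, edges = np.histogram(snap["coords"][:, idx[0]], bins=bins, weights=w)
            out_edges = (edges,)
        else:
            h, xe, ye = np.histogram2d(snap["coords"][:, idx[0]],
                                       snap["coords"][:, idx[1]],
                                       bins=bins, weights=w)
            out_edges = (xe, ye)
        hist = h if hist is None else hist + h
        bins = out_edges if len(out_edges) > 1 else out_edges[0]
    hist = hist / (hi - lo)
    if log:
        hist = np.log10(np.maximum(hist, 1e-300))
    return (hist, *out_edges)


def first_event_iteration(rec: RunRecord, target: StateDef) -> int | None:
    """0-based index of the earliest iteration at which any walker is in target."""
    for k in range(rec.n_iterations):
        snap = rec.iteration_data(k)
        for coords in snap["coords"]:
            if target.matches(coords, rec.coordinate_names):
                return k
    return None


def first_event_aggregate_time(rec: RunRecord, target: StateDef) -> float | None:
    """Total sampling cost (walkers x tau summed over iterations) until the
    first trajectory reaches the target state; None if no event occurred.

    Every propagated walker-tau is counted from the first iteration on,
    whether or not it belongs to the successful lineage: this is the total
    aggregate simulation time the run spent to produce its first event.
    """
    k = first_event_iteration(rec, target)
    if k is None:
        return None
    counts = rec.walker_counts()[: k + 1]
    return float(counts.sum() * rec.tau)


def flux_rate_estimate(flux: FluxSeries, burn_in: int = 0,
                       block: int = 10, n_boot: int = 1000,
                       rng: np.random.Generator | None = None
                       ) -> tuple[float, float]:
    """Hill-relation rate: mean recycled weight per unit time after burn-in.

    Returns ``(rate, standard_error)``; the error is a block bootstrap over
    contiguous blocks of iterations (default 10), which respects the serial
    correlation of the flux series.
    """
    if burn_in >= len(flux):
        raise ValueError("burn_in must leave at least one iteration")
    v = flux.values[burn_in:]
    rate = float(v.mean() / flux.tau)
    if np.all(v == 0):
        return 0.0, 0.0
    rng = rng if rng is not None else np.random.default_rng(0)
    nblocks = max(1, len(v) // block)
    blocks = [v[i * block:(i + 1) * block] for i in range(nblocks)]
    means = np.empty(n_boot)
    for b in range(n_boot):
        pick = rng.integers(0, nblocks, nblocks)
        means[b] = np.concatenate([blocks[j] for j in pick]).mean()
    se = float(means.std(ddof=1) / flux.tau)
    return rate, se


def weight_profile(rec: RunRecord, coordinate: str, bins,
                   iteration_range: tuple[int, int] | None = None):
    """Per-bin (mean, min, max) walker weight along one coordinate.

    Aggregated over the iteration range; bins never visited hold NaN.  The
    diagnostic for merge-rule violations: under correct resampling across a
    barrier the max weight near the target is orders of magnitude below the
    max weight near the source, while a score-based merge survivor lets heavy
    weights "bee-line" to the target and the gap collapses.
    """
    j = rec.coordinate_index(coordinate)
    lo, hi = iteration_range if iteration_range is not None else (0, rec.n_iterations)
    edges = np.asarray(bins, dtype=float) if not np.isscalar(bins) else None
    values, weights = [], []
    for k in range(lo, hi):
        snap = rec.iteration_data(k)
        values.append(snap["coords"][:, j])
        weights.append(snap["weights"])
    v = np.concatenate(values)
    w = np.concatenate(weights)
    if edges is None:
        edges = np.histogram_bin_edges(v, bins=bins)
    nb = len(edges) - 1
    which = np.clip(np.searchsorted(edges, v, side="right") - 1, 0, nb - 1)
    mean = np.full(nb, np.nan)
    wmin = np.full(nb, np.nan)
    wmax = np.full(nb, np.nan)
    for b in range(nb):
        inb = (which == b) & (v >= edges[0]) & (v <= edges[-1])
        sel = w[inb]
        if sel.size:
            mean[b], wmin[b], wmax[b] = sel.mean(), sel.min(), sel.max()
    return {"edges": edges, "mean": mean, "min": wmin, "max": wmax}
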