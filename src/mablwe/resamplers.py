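"""Weighted-ensemble resampling procedures.

Four statistically correct resamplers are provided:

* :func:`mabl_resample` — the binless scheme: rank every walker by its progress
  score, split the top N, and remove N walkers by weight-proportional merging,
  keeping the trajectory count fixed.
* :func:`mab_assignments` / :func:`mab_layout` — minimal adaptive binning:
  bins evenly spaced between the lagging and leading edges of sampled
  progress, plus dedicated leading-edge, lagging-edge and bottleneck bins,
  recomputed every iteration.
* multi-MAB — independent MAB schemes nested inside user-defined outer
  regions of coordinate space, limiting oversplitting of leading walkers.
* fixed bins — static boundaries with a target walker count per bin.

All of them conserve total weight exactly because they only ever call the
split/merge primitives.  :func:`violating_merge_resample` is an intentionally
*biased* variant (merge survivor chosen by best score instead of by weight)
kept only to demonstrate the statistical damage of breaking the
survivor-selection rule; it refuses to run without an explicit opt-in flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np

from .ensemble import Ensemble, Walker, merge_walkers, split_walker
from .exceptions import ConfigError
from .progress import ScoreSpec, score_ensemble


# ---------------------------------------------------------------------------
# configs

@dataclass(frozen=True)
class MABLConfig:
    """Binless resampler parameters.

    ``n_split_merge`` (N) is the number of walkers split and the number
    merged away each iteration; it cannot exceed half the walker count, since
    a walker cannot be both split and merged in one step.  ~10-20% of the
    walker count is a good default range.
    """

    n_split_merge: int
    walker_count: int
    merge_policy: str = "absorb_up"   # or "pairwise_bottom"
    split_children: int = 2
    tie_break: str = "by_weight_then_id"

    def __post_init__(self):
        if self.n_split_merge < 0:
            raise ConfigError("N must be >= 0")
        if 2 * self.n_split_merge > self.walker_count:
            raise ConfigError(
                f"N={self.n_split_merge} exceeds 50% of {self.walker_count} walkers: "
                "a walker cannot be both split and merged in one resampling step")
        if self.merge_policy not in ("absorb_up", "pairwise_bottom"):
            raise ConfigError(f"unknown merge policy {self.merge_policy!r}")
        if self.split_children < 2:
            raise ConfigError("split_children must be >= 2")


@dataclass(frozen=True)
class MABConfig:
    """Adaptive-binning parameters for one (possibly multi-dimensional) scheme."""

    bins_per_dim: tuple[int, ...]
    direction: tuple[int, ...]
    bottleneck_enabled: bool = True

    def __post_init__(self):
        object.__setattr__(self, "bins_per_dim", tuple(self.bins_per_dim))
        object.__setattr__(self, "direction", tuple(self.direction))
        if len(self.bins_per_dim) != len(self.direction):
            raise ConfigError("bins_per_dim and direction must have equal length")
        if any(b < 1 for b in self.bins_per_dim):
            raise ConfigError("each dimension needs at least one bin")
        if any(d not in (-1, 1) for d in self.direction):
            raise ConfigError("direction entries must be +1 or -1")


@dataclass(frozen=True)
class MultiMABConfig:
    """Outer-region grid with a separate MAB scheme nested in each used region.

    ``outer_boundaries`` gives, per dimension, a strictly increasing boundary
    list (±inf allowed); cells are half-open ``[lo, hi)``.  Each scheme is
    registered by a *placement key*: a coordinate vector falling inside the
    outer cell the scheme should govern.
    """

    outer_boundaries: tuple[tuple[float, ...], ...]
    schemes: tuple[tuple[tuple[float, ...], MABConfig], ...]

    def __post_init__(self):
        object.__setattr__(self, "outer_boundaries",
                           tuple(tuple(map(float, b)) for b in self.outer_boundaries))
        object.__setattr__(self, "schemes",
                           tuple((tuple(map(float, k)), c) for k, c in self.schemes))
        for b in self.outer_boundaries:
            if len(b) < 2 or any(x >= y for x, y in zip(b, b[1:])):
                raise ConfigError("outer boundaries must be strictly increasing")
        cells = [outer_cell(np.asarray(k), self.outer_boundaries) for k, _ in self.schemes]
        if len(set(cells)) != len(cells):
            raise ConfigError("two schemes placed in the same outer cell")

    def scheme_for_cell(self, cell: tuple[int, ...]) -> MABConfig:
        for key, cfg in self.schemes:
            if outer_cell(np.asarray(key), self.outer_boundaries) == cell:
                return cfg
        raise ConfigError(f"no MAB scheme registered for outer cell {cell}")


@dataclass(frozen=True)
class FixedBinConfig:
    """Static bin boundaries per dimension with a target count per bin."""

    boundaries: tuple[tuple[float, ...], ...]
    target_per_bin: int = 4

    def __post_init__(self):
        object.__setattr__(self, "boundaries",
                           tuple(tuple(map(float, b)) for b in self.boundaries))
        if self.target_per_bin < 1:
            raise ConfigError("target_per_bin must be >= 1")
        for b in self.boundaries:
            if len(b) < 2 or any(x >= y for x, y in zip(b, b[1:])):
                raise ConfigError("bin boundaries must be strictly increasing")


# ---------------------------------------------------------------------------
# shared plumbing

def rank_walkers(e: Ensemble, scores: np.ndarray) -> list[int]:
    """Indices of walkers sorted best-first.

    Descending score, ties broken by descending weight then ascending id, so
    reruns are deterministic.
    """
    return sorted(range(len(e)),
                  key=lambda i: (-scores[i], -e.walkers[i].weight, e.walkers[i].id))


def _next_ensemble(e: Ensemble, walkers: list[Walker]) -> Ensemble:
    """Renumber ``walkers`` 0..n-1 as the starting ensemble of iteration+1.

    Each output walker's ``parent_id`` is the id of its source walker in
    iteration ``e.iteration`` (already set by split/merge bookkeeping).
    """
    out = [w.clone(id=i) for i, w in enumerate(walkers)]
    return Ensemble(iteration=e.iteration + 1, walkers=out, tau=e.tau)


def passthrough_resample(e: Ensemble) -> tuple[Ensemble, list[dict]]:
    """No-op resampler: every walker continues unchanged into the next iteration."""
    kept = [w.clone(parent_id=w.id) for w in e.walkers]
    return _next_ensemble(e, kept), []


# ---------------------------------------------------------------------------
# MABL

def mabl_resample(e: Ensemble, spec: ScoreSpec, cfg: MABLConfig,
                  rng: np.random.Generator, *,
                  survivor_rule: str = "by_weight") -> tuple[Ensemble, list[dict]]:
    """One binless resampling step: rank by score, split top N, merge bottom N away.

    Under the default ``absorb_up`` policy each of the bottom-N walkers is
    merged with the lowest-ranked not-yet-consumed walker above the bottom-N
    cutoff (never a split walker); when that pool is exhausted the remaining
    bottom walkers are absorbed into the previous merge survivor.  Exactly N
    walkers are removed, so the output count always equals the input count.

    Returns the next iteration's ensemble plus a list of resampling-event
    records (splits: parent and children ids; merges: survivor, absorbed ids
    and pre-merge weights).
    """
    n = len(e)
    if n != cfg.walker_count:
        raise ConfigError(f"ensemble has {n} walkers, config expects {cfg.walker_count}")
    N = cfg.n_split_merge
    if 2 * N > n:
        raise ConfigError("N exceeds half the walker count")
    if N == 0:
        return passthrough_resample(e)

    scores = score_ensemble(e, spec)
    order = rank_walkers(e, scores)
    split_set = order[:N]
    bottom = order[n - N:]
    events: list[dict] = []
    out: list[Walker] = []

    # split the top N, children carry parent_id = source id
    for i in split_set:
        w = e.walkers[i]
        kids = split_walker(w, cfg.split_children, id_source=e.fresh_id)
        events.append({"type": "split", "parent": w.id,
                       "children": [k.id for k in kids], "weight": w.weight})
        out.extend(kids)

    # merge the bottom N away
    merge_groups: list[list[Walker]] = []
    if cfg.merge_policy == "absorb_up":
        pool = [e.walkers[i] for i in order[N:n - N]]  # neither split nor bottom
        for i in reversed(bottom):           # worst rank first
            b = e.walkers[i]
            if pool:
                partner = pool.pop()         # lowest-ranked above the cutoff
                merge_groups.append([b, partner])
            elif merge_groups:
                merge_groups[-1].append(b)   # chain onto the previous group
            else:
                # n == 2N: no unconsumed walker exists outside the split and
                # bottom sets, so absorb into a child of the lowest-ranked split
                merge_groups.append([b, out.pop()])
    else:  # pairwise_bottom: merge the bottom 2N pairwise (needs 3N <= n)
        if 3 * N > n:
            raise ConfigError("pairwise_bottom requires N <= count/3")
        tail = [e.walkers[i] for i in order[n - 2 * N:]]
        for j in range(N):
            merge_groups.append([tail[2 * j], tail[2 * j + 1]])

    orig_ids = {w.id for w in e.walkers}
    consumed = set()
    for group in merge_groups:
        consumed.update(w.id for w in group)
        surv = _select_survivor(group, rng, survivor_rule, e, spec)
        events.append({"type": "merge", "survivor": surv.id,
                       "absorbed": [w.id for w in group if w.id != surv.id],
                       "pre_weights": [w.weight for w in group]})
        # a split child drafted as partner (n == 2N) keeps its split lineage
        parent = surv.id if surv.id in orig_ids else surv.parent_id
        out.append(surv.clone(parent_id=parent))

    # everyone else continues unchanged
    for w in e.walkers:
        if w.id not in consumed and w.id not in {e.walkers[i].id for i in split_set}:
            out.append(w.clone(parent_id=w.id))

    return _next_ensemble(e, out), events


def _select_survivor(group: list[Walker], rng, rule: str, e, spec) -> Walker:
    if rule == "by_weight":
        return merge_walkers(group, rng)
    if rule == "by_score":  # biased demonstration mode
        scores = [(_score_of(w, spec), w.weight, -w.id) for w in group]
        best = max(range(len(group)), key=lambda j: scores[j])
        total = sum(w.weight for w in group)
        return group[best].clone(weight=total)
    raise ConfigError(f"unknown survivor rule {rule!r}")


def _score_of(w: Walker, spec: ScoreSpec) -> float:
    from .progress import compute_score
    return compute_score(w.coords, w.weight, spec)


def violating_merge_resample(e: Ensemble, spec: ScoreSpec, cfg: MABLConfig,
                             rng: np.random.Generator, *,
                             allow_biased: bool = False) -> tuple[Ensemble, list[dict]]:
    """MABL with the merge survivor chosen by *score* instead of by weight.

    This breaks the rule that the survivor must be selected probabilistically
    by weight: a higher-weight walker can be terminated and its weight handed
    to a lower-weight, higher-progress survivor, letting heavy weights make an
    unphysical "bee-line" to the target state.  Provided only to reproduce
    that pathology in controlled tests; refuses to run without
    ``allow_biased=True``.
    """
    if not allow_biased:
        raise ConfigError(
            "violating_merge_resample is statistically biased; "
            "pass allow_biased=True to run it deliberately")
    return mabl_resample(e, spec, cfg, rng, survivor_rule="by_score")


# ---------------------------------------------------------------------------
# MAB layout

@dataclass
class MabDimLayout:
    """Adaptive bin layout along one dimension for one iteration."""

    edges: np.ndarray                 # ascending interior bin edges (real space)
    direction: int
    leading_value: float
    lagging_value: float
    bottleneck_value: float | None    # position of the bottleneck walker, if any

    def interior_index(self, x: float) -> int:
        j = int(np.searchsorted(self.edges, x, side="right")) - 1
        return min(max(j, 0), len(self.edges) - 2)


def mab_layout(positions: Sequence[float], weights: Sequence[float],
               cfg: MABConfig, dim: int) -> MabDimLayout:
    """Adaptive bin layout along dimension ``dim`` of a MAB scheme.

    Interior bins are evenly spaced between the lagging and the leading edge
    of sampled progress (direction-aware); the walkers *at* the two edges get
    dedicated bins, as does the bottleneck walker: the one sitting just before
    the steepest drop in −ln(weight) between adjacent occupied interior bins
    along the progress direction.  With all walkers at one point the layout
    degenerates to a single interior bin.
    """
    x = np.asarray(positions, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one walker")
    d = cfg.direction[dim]
    nbins = cfg.bins_per_dim[dim]
    signed = d * x
    lead_i = int(np.argmax(signed))
    lag_i = int(np.argmin(signed))
    lo, hi = min(x[lead_i], x[lag_i]), max(x[lead_i], x[lag_i])
    if lo == hi:
        edges = np.array([lo - 0.5, lo + 0.5])
        return MabDimLayout(edges, d, x[lead_i], x[lag_i], None)
    edges = np.linspace(lo, hi, nbins + 1)

    layout = MabDimLayout(edges, d, float(x[lead_i]), float(x[lag_i]), None)
    if cfg.bottleneck_enabled and nbins >= 2:
        layout.bottleneck_value = _bottleneck_position(x, w, layout)
    return layout


def _bottleneck_position(x: np.ndarray, w: np.ndarray,
                         layout: MabDimLayout) -> float | None:
    """Position of the max-weight walker just before the sharpest weight drop."""
    nbins = len(layout.edges) - 1
    best_w = np.full(nbins, np.nan)
    best_pos = np.full(nbins, np.nan)
    for xi, wi in zip(x, w):
        b = layout.interior_index(xi)
        if np.isnan(best_w[b]) or wi > best_w[b]:
            best_w[b], best_pos[b] = wi, xi
    occupied = [b for b in range(nbins) if not np.isnan(best_w[b])]
    if layout.direction < 0:
        occupied = occupied[::-1]          # traverse along progress direction
    best_drop, best = 0.0, None
    for b, nxt in zip(occupied, occupied[1:]):
        drop = (-np.log(best_w[nxt])) - (-np.log(best_w[b]))
        if drop > best_drop:
            best_drop, best = drop, float(best_pos[b])
    return best


def outer_cell(coords: np.ndarray, boundaries: tuple[tuple[float, ...], ...]
               ) -> tuple[int, ...]:
    """Half-open outer-grid cell index of a coordinate vector, per dimension."""
    cell = []
    for v, b in zip(coords, boundaries):
        edges = np.asarray(b)
        j = int(np.searchsorted(edges, v, side="right")) - 1
        if j < 0 or j >= len(edges) - 1:
            raise ConfigError(f"coordinate value {v} outside outer grid {b}")
        cell.append(j)
    return tuple(cell)


def mab_assignments(coords: np.ndarray, weights: np.ndarray,
                    cfg: MABConfig) -> list[Hashable]:
    """Bin label per walker under one MAB scheme over all dimensions.

    Special bins take precedence (bottleneck, then leading edge, then lagging
    edge, first dimension wins); otherwise the label is the tuple of interior
    bin indices.
    """
    coords = np.atleast_2d(coords)
    n, ndim = coords.shape
    layouts = [mab_layout(coords[:, m], weights, cfg, m) for m in range(ndim)]
    labels: list[Hashable] = []
    for i in range(n):
        special: Hashable | None = None
        for m, lay in enumerate(layouts):
            v = coords[i, m]
            if lay.bottleneck_value is not None and v == lay.bottleneck_value:
                special = ("bottleneck", m)
                break
        if special is None:
            for m, lay in enumerate(layouts):
                if coords[i, m] == lay.leading_value:
                    special = ("lead", m)
                    break
                if coords[i, m] == lay.lagging_value:
                    special = ("lag", m)
                    break
        labels.append(special if special is not None else
                      tuple(lay.interior_index(coords[i, m])
                            for m, lay in enumerate(layouts)))
    return labels


def multi_mab_assign(coords: np.ndarray, cfg: MultiMABConfig,
                     current_layouts: dict | None = None
                     ) -> tuple[tuple[int, ...], Hashable]:
    """Outer cell and nested-MAB bin of a single coordinate vector.

    ``current_layouts`` maps outer cells to per-dimension
    :class:`MabDimLayout` lists computed from the walkers currently in that
    cell; without it only the outer cell is resolved (inner label ``None``).
    """
    coords = np.asarray(coords, dtype=float)
    cell = outer_cell(coords, cfg.outer_boundaries)
    cfg.scheme_for_cell(cell)  # raises if the cell has no scheme
    if not current_layouts or cell not in current_layouts:
        return cell, None
    layouts = current_layouts[cell]
    inner = tuple(lay.interior_index(coords[m]) for m, lay in enumerate(layouts))
    return cell, inner


def multi_mab_assignments(coords: np.ndarray, weights: np.ndarray,
                          cfg: MultiMABConfig) -> list[Hashable]:
    """Per-walker bin labels under the multi-MAB scheme: (outer cell, inner label)."""
    coords = np.atleast_2d(coords)
    cells = [outer_cell(coords[i], cfg.outer_boundaries) for i in range(len(coords))]
    labels: list[Hashable] = [None] * len(coords)
    for cell in sorted(set(cells)):
        idx = [i for i, c in enumerate(cells) if c == cell]
        sub_cfg = cfg.scheme_for_cell(cell)
        sub_labels = mab_assignments(coords[idx], weights[idx], sub_cfg)
        for i, lab in zip(idx, sub_labels):
            labels[i] = (cell, lab)
    return labels


def fixed_bin_assignments(coords: np.ndarray, cfg: FixedBinConfig) -> list[Hashable]:
    """Per-walker static-grid bin labels (half-open cells)."""
    coords = np.atleast_2d(coords)
    return [outer_cell(coords[i], cfg.boundaries) for i in range(len(coords))]


# ---------------------------------------------------------------------------
# binned resampling (shared by MAB, multi-MAB and fixed bins)

def binned_resample(e: Ensemble, assignment: Sequence[Hashable],
                    target_per_bin: int, rng: np.random.Generator
                    ) -> tuple[Ensemble, list[dict]]:
    """Bring every occupied bin to the target walker count by split/merge.

    Underpopulated bins split their largest-weight walkers first (halving the
    largest weight reduces weight variance fastest); overpopulated bins merge
    their two smallest-weight walkers repeatedly, the survivor chosen by
    weight.  Per-bin — hence global — weight is conserved exactly.
    """
    if len(assignment) != len(e):
        raise ValueError("one bin label per walker required")
    bins: dict[Hashable, list[Walker]] = {}
    for w, lab in zip(e.walkers, assignment):
        bins.setdefault(lab, []).append(w)

    events: list[dict] = []
    out: list[Walker] = []
    for lab in bins:
        members = [w.clone(parent_id=w.id) for w in bins[lab]]
        while len(members) < target_per_bin:
            members.sort(key=lambda w: (-w.weight, w.parent_id))
            w = members.pop(0)
            kids = split_walker(
                _as_source(w), 2, id_source=e.fresh_id)
            events.append({"type": "split", "parent": w.parent_id,
                           "children": [k.id for k in kids], "weight": w.weight,
                           "bin": repr(lab)})
            members = kids_with_parent(kids, w.parent_id) + members
        while len(members) > target_per_bin:
            members.sort(key=lambda w: (w.weight, w.parent_id))
            a, b = members.pop(0), members.pop(0)
            surv = merge_walkers([a, b], rng)
            absorbed = b.parent_id if surv.parent_id == a.parent_id else a.parent_id
            events.append({"type": "merge", "survivor": surv.parent_id,
                           "absorbed": [absorbed],
                           "pre_weights": [a.weight, b.weight], "bin": repr(lab)})
            members.append(surv)
        out.extend(members)
    return _next_ensemble(e, out), events


def _as_source(w: Walker) -> Walker:
    """Treat an in-progress output walker as a split source keeping its lineage."""
    return w.clone(id=w.parent_id)


def kids_with_parent(kids: list[Walker], parent: int) -> list[Walker]:
    return [k.clone(parent_id=parent) for k in kids]
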