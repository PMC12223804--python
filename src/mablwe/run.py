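"""Run orchestration: the propagate -> recycle -> score -> resample loop.

One call to :func:`run_simulation` executes the configured number of WE
iterations and returns a :class:`~mablwe.record.RunRecord`.  Total weight is
checked after every propagation and every resampling step; a violation aborts
the run with the iteration index.  Given (config, seed) the run is
bit-reproducible: a single seeded generator drives every stochastic choice
(propagation noise first, then merge-survivor draws) in a fixed order.
"""

from __future__ import annotations

import logging

import numpy as np

from .config import (RunConfig, build_resampler_config, build_score_spec,
                     build_states, build_system)
from .ensemble import assert_conservation
from .exceptions import ConfigError
from .progress import score_ensemble
from .propagation import propagate_ensemble, recycle_walkers
from .record import RunRecord
from .resamplers import (binned_resample, fixed_bin_assignments,
                         mab_assignments, mabl_resample, multi_mab_assignments,
                         passthrough_resample, violating_merge_resample)

log = logging.getLogger("mablwe")


def run_simulation(cfg: RunConfig, seed: int | None = None) -> RunRecord:
    """Run a WE simulation as configured; returns the per-iteration record."""
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    system = build_system(cfg)
    spec = build_score_spec(cfg, system)
    states = build_states(cfg, system)
    rcfg = build_resampler_config(cfg)
    names = system.propagator.coordinate_names

    target = None
    if cfg.recycling:
        by_name = {s.name: s for s in states}
        if cfg.recycle_target not in by_name:
            raise ConfigError(f"recycle target {cfg.recycle_target!r} not among "
                              f"states {sorted(by_name)}")
        target = by_name[cfg.recycle_target]

    e = system.initial_ensemble(cfg.walker_count, tau=cfg.tau)
    rec = RunRecord(config=cfg.raw, seed=seed, coordinate_names=names, tau=cfg.tau)
    log.info("run start: system=%s resampler=%s walkers=%d iterations=%d seed=%d",
             cfg.system_kind, cfg.resampler_type, cfg.walker_count,
             cfg.iterations, seed)

    for k in range(cfg.iterations):
        propagate_ensemble(e, system.propagator, rng)
        assert_conservation(e, iteration=k)

        flux = 0.0
        if target is not None:
            e, flux = recycle_walkers(e, target, system.source_payload,
                                      system.source_coords, names)
            assert_conservation(e, iteration=k)

        scores = score_ensemble(e, spec)
        rec_ids = [w.id for w in e.walkers]
        rec_parents = [w.parent_id for w in e.walkers]
        rec_weights = [w.weight for w in e.walkers]
        rec_coords = e.coords_matrix()

        e, events = _resample(e, spec, cfg, rcfg, rng)
        assert_conservation(e, iteration=k)

        rec.append_iteration(rec_ids, rec_parents, rec_weights, rec_coords,
                             scores=scores, events=events, flux=flux)
        log.debug("iteration %d: %d walkers, weight sum %.15f, flux %.3e",
                  k, len(rec_ids), float(np.sum(rec_weights)), flux)
    return rec


def _resample(e, spec, cfg: RunConfig, rcfg, rng):
    t = cfg.resampler_type
    if t == "none" or rcfg is None:
        return passthrough_resample(e)
    if t == "mabl":
        return mabl_resample(e, spec, rcfg, rng)
    if t == "violating_demo":
        mcfg, allow = rcfg
        return violating_merge_resample(e, spec, mcfg, rng, allow_biased=allow)
    coords = e.coords_matrix()
    weights = e.weights()
    if t == "mab":
        mab_cfg, target = rcfg
        labels = mab_assignments(coords, weights, mab_cfg)
    elif t == "multimab":
        mm_cfg, target = rcfg
        labels = multi_mab_assignments(coords, weights, mm_cfg)
    elif t == "fixedbin":
        labels = fixed_bin_assignments(coords, rcfg)
        target = rcfg.target_per_bin
    else:
        raise ConfigError(f"unhandled resampler type {t!r}")
    return binned_resample(e, labels, target, rng)
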