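"""Run configuration: YAML schema, validation, and object construction.

A run config fully determines a simulation together with the seed: the toy
system, the progress-score definition, the resampler and its parameters,
state definitions, walker count, tau, and iteration count.  Unknown keys are
rejected so typos fail loudly before any walker moves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .exceptions import ConfigError
from .progress import BALANCE_MODES, CoordinateSpec, DEFAULT_BALANCE_CAP, ScoreSpec
from .propagation import Interval, StateDef
from .resamplers import (FixedBinConfig, MABConfig, MABLConfig, MultiMABConfig)
from .systems import TOY_KINDS, ToySystem, make_toy_system

_TOP_KEYS = {"system", "score", "resampler", "states", "walker_count", "tau",
             "iterations", "seed", "recycling", "output"}
RESAMPLER_TYPES = ("mabl", "mab", "multimab", "fixedbin", "violating_demo", "none")


@dataclass
class RunConfig:
    """Validated run configuration."""

    raw: dict
    system_kind: str
    system_parameters: dict
    resampler_type: str
    resampler_params: dict
    walker_count: int
    tau: float
    iterations: int
    seed: int
    recycling: bool = False
    recycle_target: str = "unbound"
    score_overrides: dict | None = None
    state_overrides: list | None = None
    output: str | None = None


def _reject_unknown(d: dict, allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")


def load_config(source) -> RunConfig:
    """Parse and validate a config from a YAML path, YAML text, or dict."""
    if isinstance(source, dict):
        data = source
    else:
        text = source
        if "\n" not in str(source):
            try:
                with open(source) as fh:
                    text = fh.read()
            except OSError as err:
                raise ConfigError(f"cannot read config: {err}")
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError("config must be a mapping")
    _reject_unknown(data, _TOP_KEYS, "config")

    for key in ("system", "resampler", "walker_count", "iterations", "seed"):
        if key not in data:
            raise ConfigError(f"config is missing required key {key!r}")

    system = data["system"]
    _reject_unknown(system, {"kind", "parameters"}, "system block")
    kind = system.get("kind")
    if kind not in TOY_KINDS:
        raise ConfigError(f"system.kind must be one of {TOY_KINDS}, got {kind!r}")

    res = dict(data["resampler"])
    rtype = res.pop("type", None)
    if rtype not in RESAMPLER_TYPES:
        raise ConfigError(f"resampler.type must be one of {RESAMPLER_TYPES}, "
                          f"got {rtype!r}")

    walker_count = int(data["walker_count"])
    iterations = int(data["iterations"])
    if walker_count < 1 or iterations < 0:
        raise ConfigError("walker_count must be >= 1 and iterations >= 0")
    tau = float(data.get("tau", 1.0))
    if tau <= 0:
        raise ConfigError("tau must be positive")

    recycling = data.get("recycling", {"enabled": False})
    if isinstance(recycling, bool):
        recycling = {"enabled": recycling}
    _reject_unknown(recycling, {"enabled", "target"}, "recycling block")

    cfg = RunConfig(
        raw=data,
        system_kind=kind,
        system_parameters=dict(system.get("parameters") or {}),
        resampler_type=rtype,
        resampler_params=res,
        walker_count=walker_count,
        tau=tau,
        iterations=iterations,
        seed=int(data["seed"]),
        recycling=bool(recycling.get("enabled", False)),
        recycle_target=str(recycling.get("target", "unbound")),
        score_overrides=data.get("score"),
        state_overrides=data.get("states"),
        output=data.get("output"),
    )
    # construct everything once so structural errors surface at validate time
    build_system(cfg)
    build_score_spec(cfg)
    build_resampler_config(cfg)
    return cfg


def build_system(cfg: RunConfig) -> ToySystem:
    return make_toy_system(cfg.system_kind, cfg.system_parameters)


def build_score_spec(cfg: RunConfig, system: ToySystem | None = None) -> ScoreSpec:
    system = system or build_system(cfg)
    if not cfg.score_overrides:
        return system.score_spec
    blk = dict(cfg.score_overrides)
    _reject_unknown(blk, {"coordinates", "balance", "balance_cap", "clamp"},
                    "score block")
    balance = blk.get("balance", "inverse_neg_log")
    if balance not in BALANCE_MODES:
        raise ConfigError(f"score.balance must be one of {BALANCE_MODES}")
    coords = []
    for c in blk.get("coordinates", []):
        _reject_unknown(c, {"name", "initial", "target", "scale", "regions"},
                        f"score coordinate {c.get('name')!r}")
        coords.append(CoordinateSpec(
            name=c["name"], q_init=float(c["initial"]), q_target=float(c["target"]),
            scale=float(c.get("scale", 1.0)),
            region_scalings=tuple(tuple(map(float, w)) for w in c.get("regions", []))))
    if not coords:
        coords = list(system.score_spec.coordinates)
    names = {c.name for c in coords}
    if not names <= set(system.propagator.coordinate_names):
        raise ConfigError(f"score coordinates {sorted(names)} not all provided by "
                          f"the {cfg.system_kind} system "
                          f"({system.propagator.coordinate_names})")
    # keep coordinate order aligned with the propagator output
    order = {n: i for i, n in enumerate(system.propagator.coordinate_names)}
    coords.sort(key=lambda c: order[c.name])
    return ScoreSpec(tuple(coords), balance=balance,
                     balance_cap=float(blk.get("balance_cap", DEFAULT_BALANCE_CAP)),
                     clamp_progress=bool(blk.get("clamp", True)))


def build_states(cfg: RunConfig, system: ToySystem | None = None
                 ) -> tuple[StateDef, ...]:
    system = system or build_system(cfg)
    if not cfg.state_overrides:
        return system.states
    defs = []
    for s in cfg.state_overrides:
        _reject_unknown(s, {"name", "conditions"}, f"state {s.get('name')!r}")
        conds = []
        for c in s.get("conditions", []):
            _reject_unknown(c, {"coordinate", "lo", "hi", "closed_lo", "closed_hi"},
                            "state condition")
            conds.append(Interval(
                coordinate=c["coordinate"],
                lo=float(c.get("lo", -np.inf)), hi=float(c.get("hi", np.inf)),
                closed_lo=bool(c.get("closed_lo", True)),
                closed_hi=bool(c.get("closed_hi", True))))
        defs.append(StateDef(s["name"], tuple(conds)))
    return tuple(defs)


def build_resampler_config(cfg: RunConfig):
    """Per-type parameter object for the configured resampler."""
    p = dict(cfg.resampler_params)
    t = cfg.resampler_type
    if t in ("mabl", "violating_demo"):
        _reject_unknown(p, {"n_split_merge", "merge_policy", "split_children",
                            "allow_biased"}, f"{t} resampler block")
        allow = bool(p.pop("allow_biased", False))
        mcfg = MABLConfig(n_split_merge=int(p.get("n_split_merge", 0)),
                          walker_count=cfg.walker_count,
                          merge_policy=p.get("merge_policy", "absorb_up"),
                          split_children=int(p.get("split_children", 2)))
        if t == "violating_demo" and not allow:
            raise ConfigError("violating_demo is a deliberately biased mode; "
                              "set allow_biased: true to run it")
        return (mcfg, allow) if t == "violating_demo" else mcfg
    if t == "mab":
        _reject_unknown(p, {"bins_per_dim", "direction", "bottleneck",
                            "target_per_bin"}, "mab resampler block")
        return (MABConfig(bins_per_dim=tuple(p["bins_per_dim"]),
                          direction=tuple(p.get("direction",
                                                [1] * len(p["bins_per_dim"]))),
                          bottleneck_enabled=bool(p.get("bottleneck", True))),
                int(p.get("target_per_bin", 4)))
    if t == "multimab":
        _reject_unknown(p, {"outer_boundaries", "schemes", "target_per_bin"},
                        "multimab resampler block")
        schemes = []
        for s in p["schemes"]:
            _reject_unknown(s, {"placement", "bins_per_dim", "direction",
                                "bottleneck"}, "multimab scheme")
            schemes.append((tuple(map(float, s["placement"])),
                            MABConfig(bins_per_dim=tuple(s["bins_per_dim"]),
                                      direction=tuple(s.get(
                                          "direction",
                                          [1] * len(s["bins_per_dim"]))),
                                      bottleneck_enabled=bool(
                                          s.get("bottleneck", True)))))
        bounds = tuple(tuple(_parse_boundary(x) for x in b)
                       for b in p["outer_boundaries"])
        return (MultiMABConfig(outer_boundaries=bounds, schemes=tuple(schemes)),
                int(p.get("target_per_bin", 4)))
    if t == "fixedbin":
        _reject_unknown(p, {"boundaries", "target_per_bin"}, "fixedbin block")
        bounds = tuple(tuple(_parse_boundary(x) for x in b)
                       for b in p["boundaries"])
        return FixedBinConfig(boundaries=bounds,
                              target_per_bin=int(p.get("target_per_bin", 4)))
    if t == "none":
        if p:
            raise ConfigError("resampler type 'none' takes no parameters")
        return None
    raise ConfigError(f"unhandled resampler type {t!r}")


def _parse_boundary(x) -> float:
    """Boundary entries may be numbers or the strings 'inf' / '-inf'."""
    if isinstance(x, str):
        s = x.strip().lower().strip("'\"")
        if s in ("inf", "+inf", "infinity"):
            return np.inf
        if s == "-inf":
            return -np.inf
        raise ConfigError(f"bad boundary value {x!r}")
    return float(x)
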