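"""Built-in demonstration runs with their oracle comparisons.

Each demo builds a small config, runs it, and reports the numbers that make
the run checkable at a glance: the Markov-chain demo compares the weighted
state distribution with the exact matrix-power oracle; the double-well demo
reports the first barrier-crossing event; the surrogate-unbinding demo
reports the first-event aggregate time.
"""

from __future__ import annotations

import numpy as np

from .analysis import exact_markov, first_event_aggregate_time
from .archive import write_archive
from .config import build_states, load_config
from .run import run_simulation
from .systems import DEFAULT_CHAIN_3STATE


def markov3_config(resampler: str = "mabl", seed: int = 1,
                   iterations: int = 50, walker_count: int = 20) -> dict:
    res: dict = {"type": resampler}
    if resampler == "mabl":
        res["n_split_merge"] = 3
    elif resampler in ("mab",):
        res.update({"bins_per_dim": [3], "direction": [1], "target_per_bin": 4})
    elif resampler == "fixedbin":
        res.update({"boundaries": [[-0.5, 0.5, 1.5, 2.5]], "target_per_bin": 4})
    elif resampler == "multimab":
        res.update({"outer_boundaries": [[-0.5, 1.0, 2.5]],
                    "schemes": [{"placement": [0.0], "bins_per_dim": [2],
                                 "direction": [1]},
                                {"placement": [2.0], "bins_per_dim": [2],
                                 "direction": [1]}],
                    "target_per_bin": 4})
    return {
        "system": {"kind": "markov_chain"},
        "resampler": res,
        "walker_count": walker_count,
        "tau": 1.0,
        "iterations": iterations,
        "seed": seed,
    }


def doublewell_config(resampler: str = "mabl", seed: int = 1,
                      iterations: int = 300, walker_count: int = 20) -> dict:
    res: dict = {"type": resampler}
    if resampler == "mabl":
        res["n_split_merge"] = 3
    elif resampler == "mab":
        res.update({"bins_per_dim": [8], "direction": [1], "target_per_bin": 4})
    elif resampler == "fixedbin":
        res.update({"boundaries": [[-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0]],
                    "target_per_bin": 4})
    elif resampler == "multimab":
        res.update({"outer_boundaries": [[-3.0, 0.0, 3.0]],
                    "schemes": [{"placement": [-1.0], "bins_per_dim": [4],
                                 "direction": [1]},
                                {"placement": [1.0], "bins_per_dim": [4],
                                 "direction": [1]}],
                    "target_per_bin": 4})
    return {
        "system": {"kind": "double_well_1d",
                   "parameters": {"barrier_height": 5.0, "steps_per_tau": 10}},
        "resampler": res,
        "walker_count": walker_count,
        "tau": 1.0,
        "iterations": iterations,
        "seed": seed,
    }


def unbind2d_config(resampler: str = "mabl", seed: int = 1,
                    iterations: int = 400, walker_count: int = 40,
                    region_scaling: bool = True) -> dict:
    """The production-shaped surrogate-unbinding run: 40 walkers, N = 5,
    three-coordinate progress score, 0.8 scaling window on the rmsd-like
    coordinate in [10, 13]."""
    res: dict = {"type": resampler}
    if resampler == "mabl":
        res["n_split_merge"] = 5
    elif resampler == "mab":
        res.update({"bins_per_dim": [5, 1, 5], "direction": [1, -1, 1],
                    "target_per_bin": 4})
    elif resampler == "fixedbin":
        res.update({"boundaries": [[0.0, 2.5, 5.0, 7.5, 10.0, 13.0, "inf"],
                                   ["-inf"] + [float(x) for x in
                                               range(-200, 351, 25)] + ["inf"],
                                   [0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0,
                                    8.0, "inf"]],
                    "target_per_bin": 4})
    elif resampler == "multimab":
        # a scheme in every outer cell: unlike a buried-ligand system, the
        # surrogate landscape can visit any energy/rmsd combination
        schemes = []
        for r_ in (3.0, 9.0, 12.0):
            for e_ in (0.0, 55.0):
                for d_ in (3.0, 8.0):
                    schemes.append({"placement": [r_, e_, d_],
                                    "bins_per_dim": [5, 1, 5],
                                    "direction": [1, -1, 1]})
        res.update({"outer_boundaries": [[0.0, 7.5, 10.5, "inf"],
                                         ["-inf", 10.0, "inf"],
                                         [0.0, 6.0, "inf"]],
                    "schemes": schemes,
                    "target_per_bin": 4})
    params: dict = {}
    if not region_scaling:
        params["rmsd_region_scaling"] = []
    return {
        "system": {"kind": "surrogate_unbinding_2d", "parameters": params},
        "resampler": res,
        "walker_count": walker_count,
        "tau": 1.0,
        "iterations": iterations,
        "seed": seed,
    }


_BUILDERS = {"markov3": markov3_config, "doublewell": doublewell_config,
             "unbind2d": unbind2d_config}


def run_demo(which: str, resampler: str = "mabl", seed: int = 1,
             iterations: int | None = None, output_path=None) -> str:
    kwargs = {"resampler": resampler, "seed": seed}
    if iterations is not None:
        kwargs["iterations"] = iterations
    cfg = load_config(_BUILDERS[which](**kwargs))
    rec = run_simulation(cfg)
    if output_path:
        write_archive(rec, output_path)
    lines = [f"{which} demo: {rec.n_iterations} iterations, "
             f"{resampler} resampler, seed {seed}",
             f"max |weight sum - 1| = "
             f"{np.abs(rec.weight_sums() - 1).max():.2e}"]

    if which == "markov3":
        n = rec.n_iterations
        n_rep = 30
        occ = np.zeros((n_rep, 3))
        for r in range(n_rep):
            rep = rec if r == 0 else run_simulation(
                load_config(_BUILDERS[which](resampler=resampler,
                                             seed=seed + r,
                                             iterations=n)))
            snap = rep.iteration_data(n - 1)
            for s, w in zip(snap["coords"][:, 0].astype(int), snap["weights"]):
                occ[r, int(s)] += w
        mean = occ.mean(axis=0)
        se = occ.std(axis=0, ddof=1) / np.sqrt(n_rep)
        exact = exact_markov(DEFAULT_CHAIN_3STATE, [1.0, 0.0, 0.0], n)
        lines.append(f"weighted occupancy, mean over {n_rep} replicates:")
        lines.append("state  WE mean +/- SE      exact (matrix power)")
        for s in range(3):
            lines.append(f"  {s}    {mean[s]:.4f} +/- {se[s]:.4f}    {exact[s]:.4f}")
        dev = np.abs(mean - exact) / se
        lines.append(f"max |deviation| = {dev.max():.2f} SE")
    else:
        states = {s.name: s for s in build_states(cfg)}
        target = states["product" if which == "doublewell" else "unbound"]
        t = first_event_aggregate_time(rec, target)
        if t is None:
            lines.append(f"no {target.name!r} event within the budget "
                         f"({rec.n_iterations} iterations)")
        else:
            lines.append(f"first {target.name!r} event: aggregate time "
                         f"{t:.0f} walker-tau units")
    return "\n".join(lines)
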