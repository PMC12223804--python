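"""HDF5 run archive: schema-versioned, per-iteration, lineage-complete.

Layout::

    /meta                 attrs: schema_version, seed, tau, coordinate_names,
                          config (JSON text), spec_changes (JSON)
    /iterations/<k>       datasets: ids, parents, weights, coords, scores
                          attrs: events (JSON)
    /flux                 recycled weight per iteration

Reads of an archive written by a newer schema fail loudly; a truncated
archive (e.g. a run killed mid-write) is recovered up to the last complete
iteration and flagged on the returned record.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .exceptions import ArchiveFormatError
from .record import RunRecord, SCHEMA_VERSION

_ITER_KEYS = ("ids", "parents", "weights", "coords", "scores")


def write_archive(rec: RunRecord, path) -> None:
    """Write a run record to an HDF5 archive (overwrites)."""
    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        meta.attrs["schema_version"] = SCHEMA_VERSION
        meta.attrs["seed"] = -1 if rec.seed is None else int(rec.seed)
        meta.attrs["tau"] = rec.tau
        meta.attrs["coordinate_names"] = json.dumps(list(rec.coordinate_names))
        meta.attrs["config"] = rec.config_json()
        meta.attrs["spec_changes"] = json.dumps(rec.spec_changes)
        its = f.create_group("iterations")
        for k, snap in enumerate(rec.iterations):
            g = its.create_group(f"{k:06d}")
            for key in _ITER_KEYS:
                g.create_dataset(key, data=np.asarray(snap[key]))
            g.attrs["events"] = json.dumps(snap["events"])
        f.create_dataset("flux", data=np.asarray(rec.flux, dtype=float))


def read_archive(path) -> RunRecord:
    """Read an archive back into a :class:`RunRecord`.

    Incomplete trailing iterations are dropped and ``record.truncated`` set.
    """
    with h5py.File(path, "r") as f:
        if "meta" not in f:
            raise ArchiveFormatError(f"{path}: not a run archive (no /meta)")
        meta = f["meta"]
        version = int(meta.attrs.get("schema_version", -1))
        if version > SCHEMA_VERSION or version < 1:
            raise ArchiveFormatError(
                f"{path}: archive schema v{version} not supported "
                f"(this build reads up to v{SCHEMA_VERSION})")
        seed = int(meta.attrs["seed"])
        rec = RunRecord(
            config=json.loads(meta.attrs["config"]),
            seed=None if seed == -1 else seed,
            coordinate_names=tuple(json.loads(meta.attrs["coordinate_names"])),
            tau=float(meta.attrs["tau"]),
        )
        rec.spec_changes = [(int(i), dict(c)) for i, c in
                            json.loads(meta.attrs.get("spec_changes", "[]"))]
        flux = list(np.asarray(f["flux"])) if "flux" in f else []
        its = f.get("iterations")
        keys = sorted(its.keys()) if its is not None else []
        for pos, key in enumerate(keys):
            if int(key) != pos:          # gap: stop at the last contiguous one
                rec.truncated = True
                break
            g = its[key]
            if not all(dk in g for dk in _ITER_KEYS):
                rec.truncated = True     # incomplete trailing write
                break
            rec.append_iteration(
                ids=np.asarray(g["ids"]), parents=np.asarray(g["parents"]),
                weights=np.asarray(g["weights"]), coords=np.asarray(g["coords"]),
                scores=np.asarray(g["scores"]),
                events=json.loads(g.attrs.get("events", "[]")),
                flux=flux[pos] if pos < len(flux) else 0.0)
    return rec
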