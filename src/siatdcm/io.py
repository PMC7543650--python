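"""File formats: behavior CSV, cross-spectra HDF5, result JSON, config YAML.

JSON is used for every human-diffable report (posteriors, model selection,
PEB, classifier); HDF5 only for the large complex cross-spectral arrays.
All writers are paired with validating readers that raise
:class:`SchemaError` naming the offending field or row.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import cmc_forward as cmc
from .dcm_inversion import Posterior
from .errors import SchemaError

__all__ = [
    "write_behavior_csv",
    "read_behavior_csv",
    "write_csd_h5",
    "read_csd_h5",
    "write_posterior_json",
    "read_posterior_json",
    "write_json",
    "read_json",
    "load_config",
]

BEHAVIOR_COLUMNS = [
    "subject_id",
    "group",
    "block_index",
    "block_type",
    "condition",
    "trial_index",
    "rt_ms",
    "correct",
]
_VALID_BLOCK_TYPES = {"single", "critical"}
_VALID_CONDITIONS = {"self_life", "self_death", "life", "death", "me", "not_me"}


def write_behavior_csv(tables, path):
    """Concatenate per-subject trial tables into one CSV."""
    df = pd.concat(tables, ignore_index=True)
    missing = [c for c in BEHAVIOR_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"behavior table missing columns: {missing}")
    df.to_csv(path, index=False)


def read_behavior_csv(path):
    """Read and validate a behavior CSV; returns one DataFrame per subject."""
    df = pd.read_csv(path)
    missing = [c for c in BEHAVIOR_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    bad = ~df["block_type"].isin(_VALID_BLOCK_TYPES)
    if bad.any():
        i = int(df.index[bad][0])
        raise SchemaError(
            f"{path}: row {i} has invalid block_type {df.loc[i, 'block_type']!r}"
        )
    bad = ~df["condition"].isin(_VALID_CONDITIONS)
    if bad.any():
        i = int(df.index[bad][0])
        raise SchemaError(
            f"{path}: row {i} has invalid condition {df.loc[i, 'condition']!r}"
        )
    if (df["rt_ms"] <= 0).any() or not np.all(np.isfinite(df["rt_ms"])):
        i = int(df.index[(df["rt_ms"] <= 0) | ~np.isfinite(df["rt_ms"])][0])
        raise SchemaError(f"{path}: row {i} has non-positive rt_ms")
    return [g.reset_index(drop=True) for _, g in df.groupby("subject_id", sort=True)]


def write_csd_h5(datasets, subject_ids, groups, path, seed=None):
    """Write per-subject cross-spectra to HDF5.

    Layout: ``/regions``, ``/freqs``, ``/subjects/<id>/<condition>/csd``
    (complex F x R x R) with a ``group`` attribute per subject and an
    optional file-level ``seed``.
    """
    first = datasets[0]
    with h5py.File(path, "w") as h5:
        h5.create_dataset(
            "regions", data=np.array(first.regions, dtype="S")
        )
        h5.create_dataset("freqs", data=first.freqs)
        if seed is not None:
            h5.attrs["seed"] = int(seed)
        subs = h5.create_group("subjects")
        for cs, sid, grp in zip(datasets, subject_ids, groups):
            g = subs.create_group(str(sid))
            g.attrs["group"] = grp
            for cond, s in cs.spectra.items():
                g.create_group(cond).create_dataset("csd", data=s)


def read_csd_h5(path):
    """Read the HDF5 CSD layout; returns (datasets, subject_ids, groups)."""
    datasets, sids, groups = [], [], []
    with h5py.File(path, "r") as h5:
        for key in ("regions", "freqs", "subjects"):
            if key not in h5:
                raise SchemaError(f"{path}: missing dataset/group '{key}'")
        regions = tuple(r.decode() for r in h5["regions"][()])
        freqs = h5["freqs"][()]
        for sid in sorted(h5["subjects"]):
            g = h5["subjects"][sid]
            spectra = {}
            for cond in g:
                if cond not in cmc.CONDITIONS:
                    raise SchemaError(
                        f"{path}: subject {sid} has invalid condition {cond!r}"
                    )
                spectra[cond] = g[cond]["csd"][()]
            datasets.append(
                cmc.CrossSpectra(freqs=freqs, regions=regions, spectra=spectra)
            )
            sids.append(sid)
            groups.append(g.attrs.get("group", ""))
    return datasets, sids, groups


def write_posterior_json(post: Posterior, path):
    payload = {
        "subject_id": post.subject_id,
        "names": list(post.names),
        "Ep": post.Ep.tolist(),
        "Cp": post.Cp.tolist(),
        "F": post.F,
        "fit_correlations": post.fit_correlations,
        "trace": [float(f) for f in post.trace],
        "log_precisions": (
            post.log_precisions.tolist()
            if post.log_precisions is not None
            else None
        ),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_posterior_json(path) -> Posterior:
    d = json.loads(Path(path).read_text())
    for key in ("names", "Ep", "Cp", "F"):
        if key not in d:
            raise SchemaError(f"{path}: posterior JSON missing field {key!r}")
    return Posterior(
        names=tuple(d["names"]),
        Ep=np.array(d["Ep"]),
        Cp=np.array(d["Cp"]),
        F=float(d["F"]),
        fit_correlations=d.get("fit_correlations", {}),
        trace=d.get("trace", []),
        log_precisions=(
            np.array(d["log_precisions"])
            if d.get("log_precisions") is not None
            else None
        ),
        subject_id=d.get("subject_id", ""),
    )


def write_json(obj, path):
    Path(path).write_text(json.dumps(obj, indent=1, default=_jsonify))


def _jsonify(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, tuple):
        return list(x)
    raise TypeError(f"cannot serialize {type(x)}")


def read_json(path):
    return json.loads(Path(path).read_text())


def load_config(path) -> dict:
    """Read a YAML or JSON pipeline configuration."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        return yaml.safe_load(text)
    return json.loads(text)
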