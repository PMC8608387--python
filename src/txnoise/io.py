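"""Configuration parsing, run manifests and shared file I/O.

Configs are YAML key-value files.  Two kinds exist:

* simulation configs — a ``model`` block (network, maturation, cell-cycle),
  a ``params`` block of mean rates, an optional ``noise`` block mapping
  parameter names to hyper-distributions, plus ``cells``, ``dual_reporter``
  and ``seed``;
* experiment configs — an ``experiment`` id (table2 | table3 | table4 |
  heatmap | generality | figure2) with driver options (replicates, cells,
  rows, grid, ...).

Unknown keys and unknown parameter names are rejected with errors naming the
offending key.  Every CLI run writes a JSON manifest next to its outputs
recording the command, resolved configuration, seed, package version,
timestamps and output paths, so a run can be replayed bit-for-bit
(deterministic stages) or distribution-identically (stochastic stages).

All delimited text uses comma separation, ``.`` decimals, a header row and
UTF-8 with no quoting of numerics.
"""

from __future__ import annotations

import datetime
import json
import os
from importlib import metadata, resources

import numpy as np
import pandas as pd
import yaml

from .distributions import ConfigurationError, NoiseSpec
from .simulator import CellCycleSpec, GeneParams, ModelSpec, canonical_param

__all__ = [
    "noise_spec_from_config", "noise_spec_to_config",
    "parse_config", "default_config_path", "write_manifest",
    "read_count_table",
]

_NOISE_KEYS = {"family", "params"}


def noise_spec_from_config(d: dict) -> NoiseSpec:
    """Build a NoiseSpec from ``{family: ..., params: [...]}``."""
    if not isinstance(d, dict):
        raise ConfigurationError(f"noise spec must be a mapping, got {d!r}")
    unknown = set(d) - _NOISE_KEYS
    if unknown:
        raise ConfigurationError(f"unknown noise-spec keys {sorted(unknown)}")
    try:
        return NoiseSpec(d["family"], tuple(d["params"]))
    except KeyError as e:
        raise ConfigurationError(f"noise spec missing key {e.args[0]!r}") from e


def noise_spec_to_config(spec: NoiseSpec) -> dict:
    return {"family": spec.family, "params": list(spec.params)}


def _check_keys(block: dict, allowed: set[str], where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigurationError(f"unknown key(s) {sorted(unknown)} in {where}")


def _parse_simulation(cfg: dict) -> dict:
    _check_keys(cfg, {"model", "params", "noise", "cells", "dual_reporter",
                      "seed", "t_end", "n_cycles"}, "simulation config")
    model_block = dict(cfg.get("model", {}))
    _check_keys(model_block, {"network", "maturation", "delay", "cell_cycle"},
                "model block")
    cc = model_block.get("cell_cycle")
    if cc is not None:
        _check_keys(dict(cc), {"rate", "replication_shape", "division_shape",
                               "dosage_factor"}, "cell_cycle block")
        cc = CellCycleSpec(**cc)
    delay = model_block.get("delay", 0.0)
    model = ModelSpec(model_block.get("network", "M1"),
                      model_block.get("maturation", "rate"),
                      tuple(delay) if isinstance(delay, list) else delay, cc)
    params = GeneParams.of(**(cfg.get("params") or {}))
    noise = {canonical_param(k): noise_spec_from_config(v)
             for k, v in (cfg.get("noise") or {}).items()}
    return {"kind": "simulate", "model": model, "params": params, "noise": noise,
            "cells": int(cfg.get("cells", 500)),
            "dual_reporter": bool(cfg.get("dual_reporter", False)),
            "seed": cfg.get("seed"), "t_end": cfg.get("t_end"),
            "n_cycles": int(cfg.get("n_cycles", 10))}


_EXPERIMENT_KEYS = {
    "table2": {"replicates", "cells", "seed", "rows"},
    "table3": {"replicates", "cells", "seed", "rows"},
    "table4": {"replicates", "cells", "seed", "rows"},
    "heatmap": {"pair", "mu_values", "lam_range", "dp_range", "n_lam", "n_dp",
                "samples", "KM", "seed"},
    "generality": {"case", "replicates", "cells", "seed", "with_noise", "n_cycles"},
    "figure2": {"n_samples", "seed"},
}


def _parse_experiment(cfg: dict) -> dict:
    exp = cfg["experiment"]
    if exp not in _EXPERIMENT_KEYS:
        raise ConfigurationError(
            f"unknown experiment {exp!r}; expected one of {sorted(_EXPERIMENT_KEYS)}")
    opts = {k: v for k, v in cfg.items() if k != "experiment"}
    _check_keys(opts, _EXPERIMENT_KEYS[exp], f"{exp} config")
    if exp in ("table2", "table3") and "rows" in opts:
        opts["rows"] = [(str(r.get("label", i)),
                         noise_spec_from_config({k: r[k] for k in _NOISE_KEYS}))
                        for i, r in enumerate(opts["rows"])]
    if exp == "table4" and "rows" in opts:
        opts["rows"] = [tuple(float(v) for v in r) for r in opts["rows"]]
    for key in ("mu_values", "lam_range", "dp_range"):
        if key in opts:
            opts[key] = tuple(float(v) for v in opts[key])
    return {"kind": "experiment", "experiment": exp, "options": opts}


def parse_config(path) -> dict:
    """Load and validate a YAML config; returns fully typed structures.

    Simulation configs give ``{"kind": "simulate", model, params, noise, ...}``;
    experiment configs give ``{"kind": "experiment", experiment, options}``.
    """
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"config {path} is not a mapping")
    if "experiment" in cfg:
        return _parse_experiment(cfg)
    return _parse_simulation(cfg)


def default_config_path(name: str):
    """Path of a shipped default config (``table2``, ``heatmap``, ...)."""
    ref = resources.files("txnoise") / "configs" / f"{name}.yaml"
    if not ref.is_file():
        raise ConfigurationError(f"no shipped config named {name!r}")
    return ref


def write_manifest(out_path, command: str, config: dict | None, seed,
                   outputs: list[str], started: str | None = None) -> str:
    """Write the JSON run manifest alongside ``out_path``; returns its path."""
    try:
        version = metadata.version("txnoise")
    except metadata.PackageNotFoundError:  # editable/source tree
        version = "unknown"
    manifest = {
        "command": command,
        "config": config,
        "seed": seed,
        "version": version,
        "started": started,
        "finished": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "outputs": [str(o) for o in outputs],
    }
    mpath = str(out_path) + ".manifest.json"
    tmp = mpath + ".tmp"
    with open(tmp, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    os.replace(tmp, mpath)   # atomic alongside the output
    return mpath


def read_count_table(path, columns: tuple[str, str] | None = None,
                     ) -> tuple[np.ndarray, np.ndarray, tuple[str, str]]:
    """Read a paired count table (delimited text, header naming the species).

    With ``columns=None`` the first two numeric columns are used.  Returns
    (x, y, (name_x, name_y)).
    """
    df = pd.read_csv(path)
    if columns is None:
        num = [c for c in df.columns if np.issubdtype(df[c].dtype, np.number)
               and c.lower() not in ("cell", "index")]
        if len(num) < 2:
            raise ConfigurationError(
                f"{path} needs at least two numeric count columns, found {num}")
        columns = (num[0], num[1])
    for c in columns:
        if c not in df.columns:
            raise ConfigurationError(f"column {c!r} not present in {path}")
    return df[columns[0]].to_numpy(float), df[columns[1]].to_numpy(float), columns
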