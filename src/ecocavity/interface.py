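"""Configuration parsing, result serialization and reproducibility plumbing."""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["RunConfig", "parse_config", "write_results", "read_results"]

_KNOWN_BLOCKS = {"command", "model", "ensemble", "solver", "integrator",
                 "scan", "seed", "out", "tolerances", "n_realizations"}


@dataclasses.dataclass
class RunConfig:
    command: str
    model: dict = dataclasses.field(default_factory=dict)
    ensemble: dict = dataclasses.field(default_factory=dict)
    solver: dict = dataclasses.field(default_factory=dict)
    integrator: dict = dataclasses.field(default_factory=dict)
    scan: dict = dataclasses.field(default_factory=dict)
    tolerances: dict = dataclasses.field(default_factory=dict)
    n_realizations: int = 1
    seed: int | None = None
    out: str | None = None
    seed_generated: bool = False

    def effective(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.effective(), sort_keys=True)


def parse_config(source) -> RunConfig:
    """Parse and validate a run configuration from a mapping or a JSON/YAML
    file path.  Unknown top-level keys are rejected; a missing seed is
    generated (from entropy) and recorded."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
    elif isinstance(source, dict):
        data = dict(source)
    else:
        raise TypeError("parse_config expects a mapping or a path")
    if not isinstance(data, dict):
        raise ValueError("configuration must be a mapping")
    unknown = set(data) - _KNOWN_BLOCKS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    if "command" not in data:
        raise ValueError("missing required field: command")
    model = data.get("model", {})
    if model and "kind" not in model:
        raise ValueError("missing required field: model.kind")
    cfg = RunConfig(
        command=data["command"],
        model=model,
        ensemble=data.get("ensemble", {}),
        solver=data.get("solver", {}),
        integrator=data.get("integrator", {}),
        scan=data.get("scan", {}),
        tolerances=data.get("tolerances", {}),
        n_realizations=int(data.get("n_realizations", 1)),
        seed=data.get("seed"),
        out=data.get("out"),
    )
    if cfg.seed is None:
        cfg.seed = int(np.random.SeedSequence().entropy % (2 ** 31))
        cfg.seed_generated = True
    return cfg


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if dataclasses.is_dataclass(x) and not isinstance(x, type):
        return _jsonable(dataclasses.asdict(x))
    return x


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_results(results, path, metadata: dict | None = None,
                  config: RunConfig | None = None) -> dict:
    """Write a results table (+ JSON metadata) and return a manifest with
    checksums.

    ``results`` may be a DataFrame, a list of row dicts, or a dict of
    columns.  Floating-point formatting is fixed (repr-roundtrip, 17
    significant digits) so identical runs produce byte-identical files.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(results, pd.DataFrame):
        df = results
    elif isinstance(results, list):
        df = pd.DataFrame(results)
    elif isinstance(results, dict):
        df = pd.DataFrame(_jsonable(results))
    else:
        raise TypeError("unsupported results type")
    csv_path = path.with_suffix(".csv")
    df.to_csv(csv_path, index=False, float_format="%.17g")
    meta = {
        "version": _package_version(),
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
        "n_rows": int(len(df)),
        "columns": list(df.columns),
    }
    if metadata:
        meta.update(_jsonable(metadata))
    if config is not None:
        meta["config"] = _jsonable(config.effective())
    meta_path = path.with_suffix(".meta.json")
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    manifest = {
        "files": {
            csv_path.name: _sha256(csv_path),
            meta_path.name: _sha256(meta_path),
        }
    }
    manifest_path = path.with_suffix(".manifest.json")
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def export_system(system, stem, seed: int | None = None) -> dict:
    """Export a sampled system: matrices as CSV, vectors + metadata
    (including the seed that produced it) as JSON.  Returns the manifest."""
    from .systems import GLVSystem

    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    files = {}
    if isinstance(system, GLVSystem):
        mats = {"A": system.A}
        vecs = {"r": system.r, "g": system.g}
    else:
        mats = {"c": system.c}
        if system.d is not None:
            mats["d"] = system.d
        if system.v is not None:
            mats["v"] = system.v
        vecs = {k: v for k, v in (
            ("m", system.m), ("w", system.w), ("e", system.e),
            ("K", system.K), ("r_res", system.r_res),
            ("kappa", system.kappa), ("omega", system.omega)) if v is not None}
        vecs["kind"] = system.kind
    for name, mat in mats.items():
        p = stem.parent / f"{stem.name}.{name}.csv"
        np.savetxt(p, mat, delimiter=",", fmt="%.17g")
        files[p.name] = _sha256(p)
    payload = _jsonable(vecs)
    payload["seed"] = seed
    p = stem.parent / f"{stem.name}.json"
    p.write_text(json.dumps(payload, indent=2, sort_keys=True))
    files[p.name] = _sha256(p)
    return {"files": files}


def read_results(path) -> pd.DataFrame:
    """Read a results table back with lossless float parsing (the default
    pandas parser is not round-trip exact)."""
    path = Path(path)
    if path.suffix != ".csv":
        path = path.with_suffix(".csv")
    return pd.read_csv(path, float_precision="round_trip")


def _package_version() -> str:
    try:
        from importlib.metadata import version

        return version("ecocavity")
    except Exception:
        return "unknown"
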