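"""Configuration loading and run manifests.

A run configuration is a single hierarchical YAML/JSON document with
per-module sections (``electrode``, ``activation``, ``sampler``, ``network``
...), overridable from the command line by dotted keys
(``-o electrode.current_ua=75``).  Every pipeline output directory receives
one ``manifest.json`` — config snapshot, seeds, package version and input
digests — sufficient to re-run the deterministic stages bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .activation import ActivationParams
from .ensemble import PlacementSampler
from .field import FieldSource


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending field."""


DEFAULT_CONFIG: dict[str, Any] = {
    "electrode": {
        "kind": "square_plate",
        "center": [0.0, 0.0, 0.0],
        "edge_a": 150.0,
        "current_ua": 100.0,
        "rho_e_ohm_cm": 300.0,
        "medium_factor": 1.0,
    },
    "activation": {
        "f_threshold_myelinated": 3.0,
        "unmyelinated_multiplier": 20.0,
        "rho_i_ohm_cm": 300.0,
        "node_length_k_um": 1.0,
        "internode_d_um": 100.0,
        "direction_window_um": 10.0,
    },
    "sampler": {
        "planar_distance_R": 0.0,
        "n_rotations": 12,
        "n_depth_shifts": 10,
    },
    "seed": 0,
}


def _deep_update(base: dict, extra: Mapping) -> dict:
    for k, v in extra.items():
        if isinstance(v, Mapping) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
    return base


def load_config(path: str | Path | None = None,
                overrides: Mapping[str, Any] | None = None) -> dict:
    """Merge defaults <- file <- dotted-key overrides."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))   # deep copy
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        _deep_update(cfg, loaded)
    for dotted, value in (overrides or {}).items():
        node = cfg
        *parents, leaf = dotted.split(".")
        for p in parents:
            node = node.setdefault(p, {})
            if not isinstance(node, dict):
                raise ConfigError(f"override {dotted!r}: {p!r} is not a section")
        node[leaf] = value
    return cfg


def parse_override(text: str) -> tuple[str, Any]:
    """``key.path=value`` with YAML-typed values (numbers, bools, lists)."""
    if "=" not in text:
        raise ConfigError(f"override {text!r} must look like key=value")
    key, raw = text.split("=", 1)
    return key.strip(), yaml.safe_load(raw)


def field_source_from(cfg: Mapping) -> FieldSource:
    e = cfg["electrode"]
    try:
        return FieldSource(kind=e["kind"], center=tuple(e["center"]),
                           edge_a=float(e["edge_a"]),
                           current_ua=float(e["current_ua"]),
                           rho_e_ohm_cm=float(e["rho_e_ohm_cm"]),
                           medium_factor=float(e.get("medium_factor", 1.0)))
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"electrode section: {exc}") from exc


def activation_params_from(cfg: Mapping) -> ActivationParams:
    a = cfg["activation"]
    try:
        return ActivationParams(
            f_threshold_myelinated=float(a["f_threshold_myelinated"]),
            unmyelinated_multiplier=float(a["unmyelinated_multiplier"]),
            rho_i_ohm_cm=float(a["rho_i_ohm_cm"]),
            node_length_k_um=float(a["node_length_k_um"]),
            internode_d_um=float(a["internode_d_um"]),
            direction_window_um=float(a["direction_window_um"]))
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"activation section: {exc}") from exc


def sampler_from(cfg: Mapping) -> PlacementSampler:
    s = cfg["sampler"]
    try:
        return PlacementSampler(
            planar_distance_R=float(s["planar_distance_R"]),
            n_rotations=int(s["n_rotations"]),
            n_depth_shifts=int(s["n_depth_shifts"]))
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"sampler section: {exc}") from exc


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: str | Path, config: Mapping,
                   inputs: Mapping[str, str | Path] | None = None,
                   extra: Mapping[str, Any] | None = None) -> Path:
    """Write ``manifest.json`` capturing everything needed to re-run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": dict(config),
        "inputs": {name: file_digest(p) for name, p in (inputs or {}).items()},
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return path
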