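"""YAML run configuration: load, validate, merge with defaults, snapshot.

A run config is a single YAML document with optional sections ``grid``,
``tissues``, ``vessels``, ``electrodes``, ``flow``, ``simulation``,
``train`` and ``eval``.  Unknown sections or keys are rejected so typos
fail loudly.  Every command writes the fully resolved configuration next
to its outputs for reproducibility.
"""

from __future__ import annotations

import dataclasses
import json

import yaml

from .benchmark import BenchmarkConfig
from .forward import SimulationConfig
from .phantom import FlowConfig, GridSpec, PhantomConfig, VesselSpec, default_config

__all__ = ["ConfigError", "load_run_config", "RunConfig", "resolved_snapshot"]


class ConfigError(ValueError):
    pass


_ALLOWED = {
    "scale": None,
    "seed": None,
    "grid": {"nx", "ny", "dx", "dy", "origin"},
    "tissues": None,  # free-form tissue -> conductivity overrides
    "vessels": {"artery", "vein"},
    "electrodes": {"e0_angle_deg"},
    "roi": {"shape", "center"},
    "flow": {"period", "dt", "vein_speed", "peak_speed", "waveform_params"},
    "simulation": {
        "B_values",
        "stenosis_rates",
        "directions",
        "weight_B",
        "train_fraction",
        "coefficient_cap",
    },
    "train": {
        "cae_lr",
        "cae_iterations",
        "cae_channels",
        "cnn_lr",
        "cnn_iterations",
        "bp_lr",
        "bp_iterations",
        "batch_size",
    },
    "eval": {"subset_size", "snr_list", "methods"},
}


@dataclasses.dataclass
class RunConfig:
    phantom: PhantomConfig
    flow: FlowConfig
    simulation: SimulationConfig
    train: BenchmarkConfig
    eval_subset_size: int | None
    snr_list: tuple
    methods: tuple
    seed: int
    raw: dict


def _check_keys(doc: dict) -> None:
    for section, value in doc.items():
        if section not in _ALLOWED:
            raise ConfigError(f"unknown config section {section!r}")
        allowed = _ALLOWED[section]
        if allowed is not None and isinstance(value, dict):
            bad = set(value) - allowed
            if bad:
                raise ConfigError(f"unknown key(s) {sorted(bad)} in section {section!r}")


def load_run_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config (or defaults when ``path`` is None)."""
    doc: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config root must be a mapping")
        doc = loaded
    if overrides:
        doc = {**doc, **{k: v for k, v in overrides.items() if v is not None}}
    _check_keys(doc)

    scale = doc.get("scale", "small")
    seed = int(doc.get("seed", 0))
    try:
        pcfg = default_config(scale)
    except ValueError as err:
        raise ConfigError(str(err)) from err

    if "grid" in doc:
        g = doc["grid"]
        base = pcfg.grid
        pcfg.grid = GridSpec(
            nx=int(g.get("nx", base.nx)),
            ny=int(g.get("ny", base.ny)),
            dx=float(g.get("dx", base.dx)),
            dy=float(g.get("dy", base.dy)),
            origin=tuple(g.get("origin", base.origin)),
        )
    if "tissues" in doc:
        pcfg.conductivity_overrides = dict(doc["tissues"])
    if "vessels" in doc:
        for name in ("artery", "vein"):
            if name in doc["vessels"]:
                v = doc["vessels"][name]
                setattr(pcfg, name, VesselSpec(tuple(v["center"]), float(v["radius"])))
    if "electrodes" in doc:
        pcfg.e0_angle_deg = float(doc["electrodes"].get("e0_angle_deg", pcfg.e0_angle_deg))
    if "roi" in doc:
        r = doc["roi"]
        if "shape" in r:
            pcfg.roi_shape = tuple(int(v) for v in r["shape"])
        if "center" in r:
            pcfg.roi_center = tuple(float(v) for v in r["center"])

    fdoc = doc.get("flow", {})
    try:
        flow = FlowConfig(
            period=float(fdoc.get("period", 0.85)),
            dt=float(fdoc.get("dt", 0.01)),
            vein_speed=float(fdoc.get("vein_speed", 0.08)),
            peak_speed=float(fdoc.get("peak_speed", 1.0)),
            waveform_params=tuple(fdoc.get("waveform_params", (0.45, 0.45, 0.3, 0.3))),
        )
    except ValueError as err:
        raise ConfigError(str(err)) from err

    sdoc = doc.get("simulation", {})
    try:
        sim = SimulationConfig(
            B_values=tuple(sdoc.get("B_values", (0.02, 0.04, 0.06, 0.08, 0.10))),
            stenosis_rates=tuple(sdoc.get("stenosis_rates", [round(i / 10, 1) for i in range(10)])),
            directions=tuple(sdoc.get("directions", ("+x", "-y"))),
            weight_B=float(sdoc.get("weight_B", 0.10)),
            train_fraction=float(sdoc.get("train_fraction", 0.8)),
            seed=seed,
        )
    except ValueError as err:
        raise ConfigError(str(err)) from err

    tdoc = doc.get("train", {})
    train = BenchmarkConfig(seed=seed, scale=scale)
    for key, val in tdoc.items():
        setattr(train, key, type(getattr(train, key))(val))

    edoc = doc.get("eval", {})
    subset = edoc.get("subset_size")
    snr_list = tuple(float(s) for s in edoc.get("snr_list", (60.0, 50.0, 40.0, 30.0, 20.0)))
    methods = tuple(edoc.get("methods", ("tikhonov", "bp", "cae_cnn")))

    return RunConfig(
        phantom=pcfg,
        flow=flow,
        simulation=sim,
        train=train,
        eval_subset_size=subset,
        snr_list=snr_list,
        methods=methods,
        seed=seed,
        raw=doc,
    )


def resolved_snapshot(cfg: RunConfig) -> dict:
    """JSON-serializable snapshot of the resolved configuration."""

    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        if isinstance(obj, dict):
            return {k: enc(v) for k, v in obj.items()}
        return obj

    return {
        "seed": cfg.seed,
        "phantom": enc(cfg.phantom),
        "flow": enc(cfg.flow),
        "simulation": enc(cfg.simulation),
        "train": enc(cfg.train),
        "eval": {
            "subset_size": cfg.eval_subset_size,
            "snr_list": list(cfg.snr_list),
            "methods": list(cfg.methods),
        },
    }


def write_snapshot(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(resolved_snapshot(cfg), fh, indent=2)
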