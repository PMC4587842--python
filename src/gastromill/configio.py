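"""Configuration files, run manifests, and provenance.

Circuit configurations are stored as YAML with the package's unit
conventions (mV, ms, nS, pF, pA; field names carry the unit).  Loading is
strict: unknown keys are rejected with the offending key named, so typos
cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from importlib import resources
from pathlib import Path

import yaml

from . import __version__
from .circuit import (
    CircuitConfig,
    ClampTerm,
    DriveParams,
    IMIParams,
    NeuronParams,
    SimSettings,
    SynapseSpec,
    TerminalParams,
)
from .errors import ConfigError

_HEADER = """\
# gastromill circuit configuration
# units: voltages mV, times ms (durations in s where the key says _s),
#        conductances nS, capacitances pF, currents pA
"""


def _build(cls, data, path=""):
    """Strictly construct a (possibly nested) dataclass from a mapping."""
    if not isinstance(data, dict):
        raise ConfigError(f"{path or cls.__name__}: expected a mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(
            f"{path or cls.__name__}: unknown key(s) {sorted(unknown)}; "
            f"expected keys from {sorted(fields)}"
        )
    kwargs = {}
    for name, value in data.items():
        kwargs[name] = value
    missing = [
        n for n, f in fields.items()
        if n not in kwargs
        and f.default is dataclasses.MISSING
        and f.default_factory is dataclasses.MISSING
    ]
    if missing:
        raise ConfigError(f"{path or cls.__name__}: missing required key(s) {missing}")
    return cls(**kwargs)


def dict_to_config(data: dict) -> CircuitConfig:
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    known = {"lg", "int1", "ab", "mcn1_soma", "terminal", "g_mi_nS", "imi",
             "synapses", "gap_junction_nS", "drives", "sim", "clamps"}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}")
    try:
        cfg = CircuitConfig(
            lg=_build(NeuronParams, data["lg"], "lg"),
            int1=_build(NeuronParams, data["int1"], "int1"),
            ab=_build(NeuronParams, data["ab"], "ab"),
            mcn1_soma=_build(NeuronParams, data["mcn1_soma"], "mcn1_soma"),
            terminal=_build(TerminalParams, data["terminal"], "terminal"),
            g_mi_nS=float(data["g_mi_nS"]),
            imi=_build(IMIParams, data.get("imi", {}), "imi"),
            synapses=[
                _build(SynapseSpec, s, f"synapses[{i}]")
                for i, s in enumerate(data["synapses"])
            ],
            gap_junction_nS=float(data["gap_junction_nS"]),
            drives=_build(DriveParams, data.get("drives", {}), "drives"),
            sim=_build(SimSettings, data.get("sim", {}), "sim"),
            clamps=[
                _build(ClampTerm, c, f"clamps[{i}]")
                for i, c in enumerate(data.get("clamps", []))
            ],
        )
    except KeyError as exc:
        raise ConfigError(f"missing required section {exc.args[0]!r}") from None
    cfg.validate()
    return cfg


def config_to_dict(config: CircuitConfig) -> dict:
    return dataclasses.asdict(config)


def load_config(path) -> CircuitConfig:
    """Load and validate a circuit configuration from YAML."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return dict_to_config(data)


def save_config(config: CircuitConfig, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_HEADER)
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def default_config() -> CircuitConfig:
    """The calibrated default circuit shipped with the package."""
    ref = resources.files("gastromill").joinpath("data/default_circuit.yaml")
    with ref.open() as fh:
        data = yaml.safe_load(fh)
    return dict_to_config(data)


def config_hash(config: CircuitConfig) -> str:
    canon = json.dumps(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


def write_manifest(out_dir, command: str, seed=None, config: CircuitConfig | None = None,
                   outputs=()) -> Path:
    """Write the run manifest for a results directory; returns its path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "package_version": __version__,
        "config_sha256": config_hash(config) if config is not None else None,
        "seed": seed,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "outputs": [str(o) for o in outputs],
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    return path
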