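"""Run configuration (YAML) and reproducibility manifests.

Experiment definitions are human-editable YAML documents with a versioned
schema; unknown keys are rejected so typos fail loudly.  Every run writes a
JSON manifest recording the configuration hash, the master seed and SHA-256
checksums of the output artifacts, so that reruns can be verified
bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .simulation import Condition, DEFAULT_CONDITIONS

__all__ = [
    "ConfigError",
    "RunConfig",
    "parse_config",
    "write_run_manifest",
    "read_manifest",
    "verify_manifest",
]

SCHEMA_VERSION = 1

_KNOWN_KEYS = {
    "schema",
    "bank",
    "bank_seed",
    "n_simulees",
    "test_length",
    "threshold",
    "conditions",
    "checkpoints",
    "seed",
}


class ConfigError(ValueError):
    """Invalid or contradictory run configuration."""


@dataclass(frozen=True)
class RunConfig:
    """Validated experiment configuration with defaults filled in."""

    bank: str | None = None  # path to a bank CSV; None = default synthetic bank
    bank_seed: int = 1
    n_simulees: int = 2000
    test_length: int = 120
    threshold: float | None = 1.0
    conditions: tuple[str, ...] = tuple(c.name for c in DEFAULT_CONDITIONS)
    checkpoints: tuple[int, ...] | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conditions"] = list(self.conditions)
        d["checkpoints"] = list(self.checkpoints) if self.checkpoints is not None else None
        return d


def _parse_threshold(value) -> float | None:
    if value is None or (isinstance(value, str) and value.strip().lower() == "none"):
        return None
    try:
        t = float(value)
    except (TypeError, ValueError):
        raise ConfigError(f"threshold must be a number or 'none', got {value!r}") from None
    if t < 0:
        raise ConfigError("threshold must be nonnegative")
    return t


def parse_config(source) -> RunConfig:
    """Parse a YAML file path, YAML text, or mapping into a :class:`RunConfig`.

    Defaults: test length 120, threshold 1.0 (lenient), seed 0.  Unknown keys
    are rejected with a message listing them.
    """
    if isinstance(source, (str, Path)) and Path(source).exists():
        raw = yaml.safe_load(Path(source).read_text())
    elif isinstance(source, str):
        raw = yaml.safe_load(source)
    else:
        raw = source
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")
    unknown = sorted(set(raw) - _KNOWN_KEYS)
    if unknown:
        raise ConfigError(f"unknown configuration keys: {unknown}")
    schema = raw.get("schema", SCHEMA_VERSION)
    if schema != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema version {schema!r} (expected {SCHEMA_VERSION})")

    n_simulees = int(raw.get("n_simulees", 2000))
    test_length = int(raw.get("test_length", 120))
    seed = int(raw.get("seed", 0))
    if n_simulees < 1:
        raise ConfigError("n_simulees must be >= 1")
    if test_length < 0:
        raise ConfigError("test_length must be >= 0")

    conditions = raw.get("conditions")
    if conditions is None:
        conditions = [c.name for c in DEFAULT_CONDITIONS]
    try:
        conditions = tuple(Condition.parse(c).name for c in conditions)
    except ValueError as exc:
        raise ConfigError(str(exc)) from None

    checkpoints = raw.get("checkpoints")
    if checkpoints is not None:
        checkpoints = tuple(int(c) for c in checkpoints)
        if any(c < 1 or c > test_length for c in checkpoints):
            raise ConfigError("checkpoints must lie in [1, test_length]")

    bank = raw.get("bank")
    if bank is not None:
        bank = str(bank)
        if not Path(bank).exists():
            raise ConfigError(f"bank file not found: {bank}")

    return RunConfig(
        bank=bank,
        bank_seed=int(raw.get("bank_seed", 1)),
        n_simulees=n_simulees,
        test_length=test_length,
        threshold=_parse_threshold(raw.get("threshold", 1.0)),
        conditions=conditions,
        checkpoints=checkpoints,
        seed=seed,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def write_run_manifest(config: dict | RunConfig, outputs, path) -> dict:
    """Write a JSON manifest with config hash, seed, version and output checksums."""
    if isinstance(config, RunConfig):
        config = config.to_dict()
    outputs = [Path(p) for p in outputs]
    for p in outputs:
        if not p.exists():
            raise IOError(f"declared output does not exist: {p}")
    manifest = {
        "schema": SCHEMA_VERSION,
        "package_version": __version__,
        "config": config,
        "config_hash": config_hash(config),
        "seed": config.get("seed"),
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def read_manifest(path) -> dict:
    manifest = json.loads(Path(path).read_text())
    for key in ("schema", "config", "config_hash", "outputs"):
        if key not in manifest:
            raise ConfigError(f"manifest missing required key {key!r}")
    if manifest["config_hash"] != config_hash(manifest["config"]):
        raise ConfigError("manifest config hash does not match its config")
    return manifest


def verify_manifest(path) -> list[str]:
    """Return the names of output files whose checksums no longer match."""
    manifest = read_manifest(path)
    base = Path(path).parent
    bad = []
    for name, digest in manifest["outputs"].items():
        p = base / name
        if not p.exists() or _sha256(p) != digest:
            bad.append(name)
    return bad
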