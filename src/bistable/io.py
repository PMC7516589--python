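"""Config parsing and structured table output for the CLI.

A run configuration is a single flat YAML/JSON document with a
``subcommand`` key; command-line flags override config values.  All
numeric output is written at full float precision (17 significant
digits) so reruns are byte-identical.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "RunConfig",
    "KNOWN_KEYS",
    "parse_config",
    "parse_grid",
    "write_table",
    "write_json",
    "format_float",
]

#: Allowed parameter keys per subcommand; unknown keys are rejected.
KNOWN_KEYS: dict[str, frozenset] = {
    "prob": frozenset({"k", "p"}),
    "povm": frozenset({"k", "theta", "phi", "p"}),
    "causal": frozenset({"k", "p", "as_printed", "conditional"}),
    "polytope": frozenset({"k", "k_grid"}),
    "bellwigner": frozenset(
        {"joint", "k1", "k2", "k3", "grid", "inequality", "marginals_only"}
    ),
    "simulate": frozenset({"k", "p", "n", "seed", "reps"}),
}

_GLOBAL_KEYS = frozenset({"subcommand", "out", "format", "log_level"})


@dataclass(frozen=True)
class RunConfig:
    """A validated run: subcommand name, parameters, output format."""

    subcommand: str
    params: dict = field(default_factory=dict)
    out: str | None = None
    fmt: str = "json"

    def as_dict(self) -> dict:
        doc = {"subcommand": self.subcommand, **self.params}
        if self.out is not None:
            doc["out"] = self.out
        doc["format"] = self.fmt
        return doc


def parse_config(
    path: str | Path | None = None,
    overrides: dict | None = None,
    subcommand: str | None = None,
) -> RunConfig:
    """Build a :class:`RunConfig` from a config file and/or flag overrides.

    ``overrides`` (flag values; ``None`` entries are ignored) take
    precedence over the file.  Unknown keys are rejected with a
    message naming the offending key.
    """
    doc: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if not isinstance(loaded, dict):
            raise ValueError(f"config {path} must be a mapping, got {type(loaded).__name__}")
        doc.update(loaded)
    if overrides:
        doc.update({k: v for k, v in overrides.items() if v is not None})
    if subcommand is not None:
        doc.setdefault("subcommand", subcommand)
    sub = doc.get("subcommand")
    if sub not in KNOWN_KEYS:
        raise ValueError(
            f"unknown or missing subcommand {sub!r}; expected one of {sorted(KNOWN_KEYS)}"
        )
    allowed = KNOWN_KEYS[sub] | _GLOBAL_KEYS
    for key in doc:
        if key not in allowed:
            raise ValueError(f"unknown config key {key!r} for subcommand {sub!r}")
    params = {k: v for k, v in doc.items() if k in KNOWN_KEYS[sub]}
    fmt = doc.get("format", "json")
    if fmt not in ("json", "csv"):
        raise ValueError(f"format must be 'json' or 'csv', got {fmt!r}")
    return RunConfig(subcommand=sub, params=params, out=doc.get("out"), fmt=fmt)


def parse_grid(spec) -> list[float]:
    """Parse a grid spec into a list of floats.

    Accepts ``"start:stop:step"`` (inclusive endpoints, e.g.
    ``"0.5:1.0:0.1"`` gives six points), a comma-separated list, or
    any iterable of numbers.
    """
    if isinstance(spec, (list, tuple)):
        return [float(x) for x in spec]
    text = str(spec)
    if ":" in text:
        parts = text.split(":")
        if len(parts) != 3:
            raise ValueError(f"grid spec must be start:stop:step, got {text!r}")
        start, stop, step = (float(x) for x in parts)
        if step <= 0:
            raise ValueError("grid step must be positive")
        n = int(round((stop - start) / step)) + 1
        if n < 1 or abs(start + (n - 1) * step - stop) > 1e-9:
            raise ValueError(f"grid spec {text!r} does not land on its endpoint")
        return [round(start + i * step, 12) for i in range(n)]
    return [float(x) for x in text.split(",")]


def format_float(x) -> str:
    """Render a float with 17 significant digits (round-trip exact)."""
    if isinstance(x, float):
        return format(x, ".17g")
    return str(x)


def write_table(rows, schema: list[str], destination) -> None:
    """Write rows as CSV with a fixed column order and full precision.

    ``rows`` is an iterable of mappings conforming to ``schema``; an
    empty iterable yields a header-only file.  ``destination`` is a
    path or an open text handle.
    """
    close = False
    if isinstance(destination, (str, Path)):
        handle = open(destination, "w", newline="")
        close = True
    else:
        handle = destination
    try:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(schema)
        for row in rows:
            missing = [c for c in schema if c not in row]
            if missing:
                raise ValueError(f"row is missing columns {missing}")
            writer.writerow([format_float(row[c]) for c in schema])
    finally:
        if close:
            handle.close()


def _jsonify(obj):
    import numpy as np

    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj).__name__}")


def write_json(payload, destination=None) -> str:
    """Serialise ``payload`` (numpy-tolerant) to JSON; optionally write it."""
    text = json.dumps(payload, indent=2, sort_keys=True, default=_jsonify)
    if destination is not None:
        Path(destination).write_text(text + "\n")
    return text
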