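"""Declarative run configuration: YAML with named selections and analysis toggles."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .core import Selection, Topology


@dataclass
class RunConfig:
    """Parsed pipeline configuration.

    ``selections`` maps names to conjunctive selection expressions over the
    atom table (keys: role, element, name, molecule_id, indices);
    ``analyses`` maps analysis names to their parameter dicts.
    """

    trajectory: str
    topology: str | None = None
    box: tuple[float, float, float] | None = None
    window_fraction: float = 0.1
    seed: int = 0
    output: str | None = None
    log_level: str = "INFO"
    selections: dict[str, dict] = field(default_factory=dict)
    analyses: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.window_fraction <= 1:
            raise ValueError("window_fraction must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Path | None = None) -> "RunConfig":
        raw = dict(raw)
        if base is not None:
            for key in ("trajectory", "topology", "output"):
                if raw.get(key) and not Path(raw[key]).is_absolute():
                    raw[key] = str(base / raw[key])
        box = raw.get("box")
        if box is not None:
            raw["box"] = tuple(float(v) for v in box)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "trajectory": self.trajectory, "topology": self.topology,
            "box": list(self.box) if self.box else None,
            "window_fraction": self.window_fraction, "seed": self.seed,
            "output": self.output, "log_level": self.log_level,
            "selections": self.selections, "analyses": self.analyses,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def resolve_selection(topology: Topology, expr: dict | list | str,
                      label: str = "") -> Selection:
    """Resolve a selection expression against the topology.

    Accepts a dict of conjunctive filters, an explicit index list, or the
    name shorthands "all" / a single role name.
    """
    if isinstance(expr, str):
        if expr == "all":
            return Selection(tuple(range(topology.n_atoms)), label or "all")
        return topology.select(role=expr, label=label or expr)
    if isinstance(expr, list):
        return Selection(tuple(int(i) for i in expr), label)
    return topology.select(label=label, **{k: v for k, v in expr.items()})
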