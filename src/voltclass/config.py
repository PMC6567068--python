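"""Experiment configuration: one YAML file drives every pipeline command.

The config names a library spec (builtin or generic), the label scheme, the
model kinds to run, the split plan, the training preset and a master seed.
All randomness downstream derives from that seed, so re-running a command
with the same config reproduces its outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .nn.training import TrainConfig, desk_config, full_config
from .simulate import (
    LibrarySpec,
    collapse_to_4sw,
    explosives_11class_config,
    explosives_3class_config,
    generic_library_spec,
    seawater_library_spec,
)
from .splits import SplitPlan

__all__ = ["ExperimentConfig", "load_config", "resolve_library"]

PRESETS = ("desk", "full")

#: builtin library spec names
BUILTIN_LIBRARIES = ("11-SW", "4-SW", "3-EXP", "11-EXP")


@dataclass(frozen=True)
class ExperimentConfig:
    library: str = "11-SW"  # builtin name or path to a generic-library YAML
    scheme: str | None = None  # defaults to the library's scheme
    models: tuple[str, ...] = ("fcn",)
    preset: str = "desk"
    n_repeats: int | None = None  # None: 5 for desk, 25 for full
    batch_size: int = 16
    lstm_cells: int = 8
    epochs: int | None = None  # None: preset default
    out_dir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"preset must be one of {PRESETS}")

    @property
    def repeats(self) -> int:
        if self.n_repeats is not None:
            return self.n_repeats
        return 5 if self.preset == "desk" else 25

    def train_config(self) -> TrainConfig:
        base = desk_config if self.preset == "desk" else full_config
        kwargs = {"batch_size": self.batch_size, "seed": self.seed}
        if self.epochs is not None:
            kwargs["epochs"] = self.epochs
        return base(**kwargs)

    def split_plan(self, scheme: str) -> SplitPlan:
        return SplitPlan.for_scheme(scheme, n_repeats=self.repeats, seed=self.seed)

    def digest(self) -> str:
        """Short content hash stamped onto every output file."""
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> ExperimentConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "models" in raw and isinstance(raw["models"], list):
        raw["models"] = tuple(raw["models"])
    return ExperimentConfig(**raw)


def resolve_library(name: str) -> LibrarySpec:
    """Map a config's library field to a LibrarySpec.

    Builtin names cover the four study layouts; anything else is read as a
    YAML file holding a generic library description.
    """
    if name == "11-SW":
        return seawater_library_spec()
    if name == "4-SW":
        return collapse_to_4sw(seawater_library_spec())
    if name == "3-EXP":
        return generic_library_spec(explosives_3class_config())
    if name == "11-EXP":
        return generic_library_spec(explosives_11class_config())
    path = Path(name)
    if not path.exists():
        raise FileNotFoundError(
            f"library {name!r} is neither builtin {BUILTIN_LIBRARIES} nor a config file"
        )
    with open(path) as fh:
        return generic_library_spec(yaml.safe_load(fh))
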