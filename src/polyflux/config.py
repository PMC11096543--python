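"""Flat run configuration with documented defaults.

Every numeric decision of the pipeline lives here so a run is fully
described by one small JSON/TOML file plus the master seed; a serialized
copy is written next to every pipeline output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

from .errors import FormatError


@dataclass
class RunConfig:
    # master seed: every random stream in the pipeline derives from it
    seed: int = 0
    # study design
    n_mice: int = 4
    conditions: tuple = ("B6", "TC")
    # condition-B ground-truth multipliers, "*" = default for unlisted reactions
    effect: dict = field(default_factory=lambda: {"*": 1.25})
    # measurement window half-width, in SEMs, around each measured rate
    k: float = 2.0
    # relative half-width of the growth-rate window
    delta: float = 0.05
    # expression-bias strength and flux normalization (None = glucose uptake)
    beta: float = 5.0
    vscale: float | None = None
    # chain settings
    n_draws: int = 1000
    burn_in: int = 10000
    thin: int = 100
    # tolerances
    loop_tol: float = 1e-6
    prune_tol: float = 1e-9
    # culture parameters
    dry_weight_per_cell: float = 30e-12  # grams
    culture_volume: float = 1e-3  # liters
    # noise model of the synthetic generator (relative sd / lognormal sigma)
    conc_noise_sd: float = 0.03
    count_noise_sd: float = 0.05
    expr_noise_sd: float = 0.3
    informative_expression: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["conditions"] = list(self.conditions)
        return d

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        if "conditions" in data:
            data = dict(data, conditions=tuple(data["conditions"]))
        return cls(**data)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = str(path)
        if path.endswith(".toml"):
            import tomllib

            with open(path, "rb") as fh:
                data = tomllib.load(fh)
        else:
            with open(path) as fh:
                data = json.load(fh)
        return cls.from_dict(data)
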