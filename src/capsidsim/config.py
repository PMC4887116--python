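"""Run configuration: defaults < YAML config file < command-line flags."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml

from .engine import SimConfig

__all__ = ["RunConfig", "load_run_config"]


@dataclass
class RunConfig:
    """Full protocol for a simulation run.

    ``effect_code`` (a 4-digit binary RNA-effect combination) and the manual
    ``kon_scale``/``koff_scale`` pair are mutually exclusive ways to scale
    the base rates.
    """

    ruleset: str | None = None
    effect_code: str | None = None
    kon_scale: float | None = None
    koff_scale: float | None = None
    reps: int = 1
    seed: int = 0
    time_limit: float = 100.0
    subunits: int = 90
    concentration_uM: float = 15.6
    out_dir: str = "."

    def __post_init__(self) -> None:
        if self.effect_code is not None and (
            self.kon_scale is not None or self.koff_scale is not None
        ):
            raise ValueError(
                "effect_code and manual kon/koff scalings are mutually exclusive"
            )
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.subunits < 1:
            raise ValueError("subunits must be >= 1")

    def sim_config(self, seed: int | None = None) -> SimConfig:
        return SimConfig(
            n_subunits=self.subunits,
            concentration_uM=self.concentration_uM,
            time_limit=self.time_limit,
            seed=self.seed if seed is None else seed,
        )

    def to_dict(self) -> dict:
        return asdict(self)


def load_run_config(path=None, **overrides) -> RunConfig:
    """Build a :class:`RunConfig` from an optional YAML file plus overrides.

    Overrides with value ``None`` are ignored, so CLI flags that were not
    given fall through to the file and then to the defaults.
    """
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(RunConfig)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        values.update(doc)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**values)
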