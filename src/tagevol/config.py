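"""Run configuration: cost parameters, enabled events and search knobs.

Defaults reproduce the standard cost setting for TAG-cluster inference
(duplications cheap to open, deletions and inversions expensive, extension
cost 1 per gene for every event type).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import TextIO

import yaml

from tagevol.model import CostModel, ModelError
from tagevol.search import SearchParams

__all__ = ["RunConfig"]

_EVENT_KEYS = ("dup", "idup", "del", "inv")


@dataclass
class RunConfig:
    """Everything needed to reproduce a run; serialised into output headers
    for provenance."""

    alpha: dict = field(
        default_factory=lambda: {"dup": 100.0, "idup": 100.0, "del": 500.0, "inv": 500.0}
    )
    beta: dict = field(
        default_factory=lambda: {"dup": 1.0, "idup": 1.0, "del": 1.0, "inv": 1.0}
    )
    enabled: tuple = _EVENT_KEYS
    queue_capacity: int = 300
    depth: int = 1
    max_solutions: int = 256
    extension_cap: int = 10_000
    id_exact_bound: int = 8
    seed: int = 0

    def cost_model(self) -> CostModel:
        return CostModel(
            alpha=dict(self.alpha),
            beta=dict(self.beta),
            enabled=frozenset(self.enabled),
        )

    def search_params(self) -> SearchParams:
        return SearchParams(
            queue_capacity=self.queue_capacity,
            depth=self.depth,
            max_solutions=self.max_solutions,
        )

    def disable(self, *etypes: str) -> "RunConfig":
        bad = set(etypes) - set(_EVENT_KEYS)
        if bad:
            raise ModelError(f"unknown event types {sorted(bad)}")
        enabled = tuple(t for t in self.enabled if t not in etypes)
        if not enabled:
            raise ModelError("at least one event type must stay enabled")
        return RunConfig(**{**asdict(self), "enabled": enabled})

    def to_yaml(self, out: TextIO | str | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if out is not None:
            if hasattr(out, "write"):
                out.write(text)
            else:
                with open(out, "w") as fh:
                    fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source: TextIO | str) -> "RunConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source.read())
        else:
            with open(source) as fh:
                data = yaml.safe_load(fh)
        data = data or {}
        cfg = cls(**data)
        cfg.enabled = tuple(cfg.enabled)
        return cfg
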