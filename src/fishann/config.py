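"""Run configuration: a validated YAML-loadable description of one analysis.

Every default is explicit in the rendered effective configuration, so a run
is reproducible from its logged config plus the seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .activations import ActivationKind
from .pipeline import SearchGrid
from .records import Species
from .training import TrainerConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Configuration for an end-to-end analysis run."""

    species: list[str] = field(default_factory=lambda: [s.value for s in Species])
    seed: int = 0
    noise_cv: float = 0.03
    n_per_dose: int = 10
    hidden_sizes: list[int] = field(default_factory=lambda: list(range(4, 11)))
    activations: list[str] = field(
        default_factory=lambda: ["purelin", "tansig", "logsig"]
    )
    trainers: list[str] = field(default_factory=lambda: ["gda", "rp", "seq"])
    lr0: float = 0.05
    max_epochs: int = 1000
    goal_mse: float = 1e-5
    it_max_s: float = 180.0
    rt_max_s: float = 300.0
    output_dir: str = "fishann_out"

    def __post_init__(self) -> None:
        self.species = [Species(s).value for s in self.species]
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_per_dose < 1:
            raise ValueError("n_per_dose must be >= 1")
        if not self.hidden_sizes or any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden_sizes must be positive")
        for a in self.activations:
            ActivationKind(a)
        for t in self.trainers:
            if t not in ("gda", "rp", "seq"):
                raise ValueError(f"unknown trainer {t!r}")
        if self.it_max_s <= 0 or self.rt_max_s <= 0:
            raise ValueError("dose constraints must be positive")

    def grid(self) -> SearchGrid:
        return SearchGrid(
            hidden_sizes=tuple(self.hidden_sizes),
            activations=tuple(ActivationKind(a) for a in self.activations),
            trainers=tuple(self.trainers),
        )

    def trainer_defaults(self) -> TrainerConfig:
        return TrainerConfig(
            lr0=self.lr0, max_epochs=self.max_epochs, goal_mse=self.goal_mse
        )

    def to_yaml(self) -> str:
        """Render the full effective configuration (all defaults explicit)."""
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        doc = yaml.safe_load(text) or {}
        if not isinstance(doc, dict):
            raise ValueError("config must be a YAML mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)
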