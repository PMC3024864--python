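"""Run configuration: one YAML-round-trippable object, one seed.

A single seed drives every stochastic stage (shuffle nulls, CV splits,
fixture generation) through derived streams, so a run is reproducible from
its config file alone.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from typing import Dict, Optional, Tuple

import yaml

from .ensemble import GridConfig
from .folding import EnergyModel


@dataclass
class RunConfig:
    # folding engine
    pair_energies: Dict[str, float] = field(
        default_factory=lambda: {"GC": -3.0, "AU": -2.0, "GU": -1.0}
    )
    min_hairpin_loop: int = 3
    temperature: float = 310.15
    # shuffle null
    n_shuffles: int = 300
    # selection / ensemble
    m: Optional[int] = 32
    selection_mode: str = "per_fold"
    k: int = 3
    aggregation: str = "mean_distance"
    centroid_on: str = "subset"
    c_exponents: Tuple[int, ...] = (-5, -1, 3, 7, 11, 15)
    gamma_exponents: Tuple[int, ...] = (-15, -11, -7, -3, 1, 3)
    inner_folds: int = 5
    mfei34_swapped: bool = False
    # reproducibility / logging
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        self.c_exponents = tuple(self.c_exponents)
        self.gamma_exponents = tuple(self.gamma_exponents)

    def energy_model(self) -> EnergyModel:
        return EnergyModel(
            pair_energies=dict(self.pair_energies),
            min_hairpin_loop=self.min_hairpin_loop,
            temperature=self.temperature,
        )

    def grid(self) -> GridConfig:
        return GridConfig(
            c_exponents=tuple(self.c_exponents),
            gamma_exponents=tuple(self.gamma_exponents),
            inner_folds=self.inner_folds,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as out:
            yaml.safe_dump(self.as_canonical_dict(), out, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls(**data)

    def as_canonical_dict(self) -> dict:
        data = asdict(self)
        data["c_exponents"] = list(self.c_exponents)
        data["gamma_exponents"] = list(self.gamma_exponents)
        return data

    def config_hash(self) -> str:
        """Stable digest of the canonical YAML rendering (logged per run)."""
        canonical = yaml.safe_dump(self.as_canonical_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]
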