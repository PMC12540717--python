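"""Typed hyperparameter search spaces and unit-box genome decoding.

The differential-evolution engine works on real genomes in [0, 1]^N; each
dimension decodes to an integer range, a categorical level set, or a real
interval.  The default Extra-Trees space:

    n_estimators       integer [10, 100]
    criterion          {gini, entropy}
    min_samples_split  integer [2, 30]
    max_features       integer [2, n_features]
    max_depth          integer [1, 25]
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = ["Dimension", "HyperparamSpace", "Candidate", "decode", "default_et_space"]


@dataclass
class Dimension:
    """One search dimension: integer bounds, categorical levels, or real bounds."""

    name: str
    kind: str  # "integer" | "categorical" | "real"
    bounds: tuple[float, float] | None = None
    levels: tuple | None = None

    def __post_init__(self) -> None:
        if self.kind in ("integer", "real"):
            if self.bounds is None or not self.bounds[0] <= self.bounds[1]:
                raise ValidationError(f"dimension {self.name!r}: invalid bounds {self.bounds}")
        elif self.kind == "categorical":
            if not self.levels:
                raise ValidationError(f"dimension {self.name!r}: empty level set")
        else:
            raise ValidationError(f"dimension {self.name!r}: unknown kind {self.kind!r}")

    def decode(self, g: float):
        g = float(min(max(g, 0.0), 1.0))
        if self.kind == "integer":
            lo, hi = self.bounds
            return int(min(max(round(lo + g * (hi - lo)), lo), hi))
        if self.kind == "real":
            lo, hi = self.bounds
            return float(lo + g * (hi - lo))
        idx = min(int(g * len(self.levels)), len(self.levels) - 1)
        return self.levels[idx]

    def validate(self, value) -> None:
        if self.kind == "integer":
            lo, hi = self.bounds
            if not (float(value) == int(value) and lo <= value <= hi):
                raise ValidationError(
                    f"{self.name}={value!r} outside integer range [{lo:g}, {hi:g}]"
                )
        elif self.kind == "real":
            lo, hi = self.bounds
            if not lo <= value <= hi:
                raise ValidationError(f"{self.name}={value!r} outside [{lo:g}, {hi:g}]")
        elif value not in self.levels:
            raise ValidationError(f"{self.name}={value!r} not among levels {self.levels}")


@dataclass
class HyperparamSpace:
    """Ordered list of dimensions defining the optimizer's box."""

    dimensions: list[Dimension]

    def __post_init__(self) -> None:
        names = [d.name for d in self.dimensions]
        if len(set(names)) != len(names):
            raise ValidationError("dimension names must be unique")

    @property
    def n_dims(self) -> int:
        return len(self.dimensions)

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.dimensions]

    def decode(self, genome: np.ndarray) -> dict:
        genome = np.asarray(genome, dtype=float)
        if genome.size != self.n_dims:
            raise ValidationError(
                f"genome length {genome.size} != {self.n_dims} dimensions"
            )
        return {d.name: d.decode(g) for d, g in zip(self.dimensions, genome)}

    def validate(self, hp: dict) -> None:
        by_name = {d.name: d for d in self.dimensions}
        for key, value in hp.items():
            if key not in by_name:
                raise ValidationError(
                    f"unknown hyperparameter {key!r}; dimensions: {sorted(by_name)}"
                )
            by_name[key].validate(value)


def decode(genome: np.ndarray, space: HyperparamSpace) -> dict:
    """Decode a unit-box genome into a hyperparameter mapping."""
    return space.decode(genome)


@dataclass
class Candidate:
    """One encoded search point: genome, decoded mapping, objective value."""

    genome: np.ndarray
    decoded: dict
    fitness: float = field(default=-np.inf)


def default_et_space(n_features: int = 34) -> HyperparamSpace:
    """The five tunable Extra-Trees dimensions."""
    return HyperparamSpace(
        [
            Dimension("n_estimators", "integer", bounds=(10, 100)),
            Dimension("criterion", "categorical", levels=("gini", "entropy")),
            Dimension("min_samples_split", "integer", bounds=(2, 30)),
            Dimension("max_features", "integer", bounds=(2, n_features)),
            Dimension("max_depth", "integer", bounds=(1, 25)),
        ]
    )
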