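"""Candidate kinetic-parameter vectors with provenance and labels."""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .models import ModelSpec

__all__ = ["ParameterSet", "LOG_BOUNDS"]

#: natural-log coordinate box used for sampling and estimation
LOG_BOUNDS = (-15.0, 5.0)


@dataclass
class ParameterSet:
    """One candidate parameter vector.

    ``log_values`` (natural-log coordinates, aligned with
    ``model.param_names``) is the source of truth; ``values`` is derived as
    ``exp(log_values)`` exactly.
    """

    id: str
    model_id: str
    param_names: tuple[str, ...]
    log_values: np.ndarray
    provenance: str = "random"  # estimated | random | original
    fitness: float | None = None
    label: str = "unclassified"  # positive | negative | excluded | unclassified

    def __post_init__(self):
        self.log_values = np.asarray(self.log_values, dtype=float)
        if self.log_values.shape != (len(self.param_names),):
            raise ValueError("log_values must align with param_names")

    @property
    def values(self) -> dict[str, float]:
        return dict(zip(self.param_names, np.exp(self.log_values)))

    @property
    def vector(self) -> np.ndarray:
        return np.exp(self.log_values)

    @classmethod
    def from_values(cls, model: ModelSpec, values: Mapping[str, float], *,
                    id: str, provenance: str = "original", **kw) -> "ParameterSet":
        vec = model.params_to_vector(values)
        if np.any(vec <= 0):
            raise ValueError("parameter values must be positive")
        return cls(id=id, model_id=model.id, param_names=model.param_names,
                   log_values=np.log(vec), provenance=provenance, **kw)

    def with_label(self, label: str, fitness: float | None = None) -> "ParameterSet":
        return replace(self, label=label,
                       fitness=self.fitness if fitness is None else fitness)
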