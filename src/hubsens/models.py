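"""Signaling-hub network models M1-M4.

The four motifs (reversible reaction, cycle, negative feedback loop,
incoherent feedforward loop) are defined declaratively in YAML data files, one
per model, and loaded into :class:`ModelSpec` objects.  Every reaction is
either mass action or Michaelis-Menten, optionally multiplied by the input
signal ``s(t)`` and/or by a catalytic modifier species; conserved pools
(active + inactive forms) are reduced by explicit substitution
(inactive = total - sum of the other pool members), so the dynamic state only
contains the independent species.

Naming convention: ``Xa``/``Ya`` denote the active forms written X*/Y* in the
figures of this field; the output species is always ``Xa``.

An extension point is provided: :func:`ModelSpec.from_dict` accepts any model
definition following the same schema (see the YAML files for documentation),
which is how the linear toy model used by the test oracles is built.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "MODEL_IDS",
    "ReactionSpec",
    "ModelSpec",
    "CompiledModel",
    "build_model",
    "build_linear_toy",
    "evaluate_rates",
]

MODEL_IDS = ("M1", "M2", "M3", "M4")

LAW_MASS_ACTION = 0
LAW_MICHAELIS_MENTEN = 1
_LAW_CODES = {"mass_action": LAW_MASS_ACTION, "michaelis_menten": LAW_MICHAELIS_MENTEN}


@dataclass(frozen=True)
class ReactionSpec:
    """One named reaction with its rate-law template.

    ``rate = k * [s(t) if signal] * [modifier if any] * f(substrate)`` where
    ``f`` is the identity (mass action) or ``S / (km + S)`` (Michaelis-Menten).
    A mass-action reaction with no substrate is zeroth order (rate ``k`` or
    ``k*s``), which the toy models use.
    """

    label: str
    rate_law: str
    k: str
    stoich: Mapping[str, int]
    km: str | None = None
    substrate: str | None = None
    modifier: str | None = None
    signal: bool = False

    def __post_init__(self):
        if self.rate_law not in _LAW_CODES:
            raise ValueError(f"unknown rate law {self.rate_law!r}")
        if self.rate_law == "michaelis_menten" and (self.km is None or self.substrate is None):
            raise ValueError(f"reaction {self.label}: Michaelis-Menten needs km and substrate")

    def rate(self, state: Mapping[str, float], s: float, params: Mapping[str, float]) -> float:
        """Scalar rate evaluation (readable reference path; kernels are compiled)."""
        v = params[self.k]
        if self.signal:
            v *= s
        if self.modifier is not None:
            v *= max(state[self.modifier], 0.0)
        if self.substrate is not None:
            sub = max(state[self.substrate], 0.0)
            if self.rate_law == "mass_action":
                v *= sub
            else:
                v *= sub / (params[self.km] + sub)
        return v


@dataclass(frozen=True)
class Pool:
    total: float
    members: tuple[str, ...]
    eliminate: str


@dataclass(frozen=True)
class ModelSpec:
    """Fully specified hub model: species, conserved pools, reactions, output."""

    id: str
    name: str
    species: tuple[str, ...]
    output: str
    pools: tuple[Pool, ...]
    initial: Mapping[str, float]
    reactions: tuple[ReactionSpec, ...]
    reference_params: Mapping[str, float]

    # ---- derived structure -------------------------------------------------

    @property
    def reaction_labels(self) -> tuple[str, ...]:
        return tuple(r.label for r in self.reactions)

    @property
    def param_names(self) -> tuple[str, ...]:
        names: list[str] = []
        for r in self.reactions:
            names.append(r.k)
            if r.km is not None:
                names.append(r.km)
        return tuple(names)

    @property
    def rate_constant_names(self) -> tuple[str, ...]:
        """One perturbable rate constant per reaction (Michaelis constants excluded)."""
        return tuple(r.k for r in self.reactions)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def stoichiometry(self) -> np.ndarray:
        """Full stoichiometry matrix v (species x reactions)."""
        v = np.zeros((self.n_species, self.n_reactions))
        idx = {name: i for i, name in enumerate(self.species)}
        for j, r in enumerate(self.reactions):
            for sp, coef in r.stoich.items():
                v[idx[sp], j] = coef
        return v

    def params_to_vector(self, params: Mapping[str, float]) -> np.ndarray:
        return np.array([params[name] for name in self.param_names], dtype=float)

    def vector_to_params(self, vec: Sequence[float]) -> dict[str, float]:
        return dict(zip(self.param_names, map(float, vec)))

    def initial_full(self) -> np.ndarray:
        return np.array([self.initial[sp] for sp in self.species], dtype=float)

    def compile(self) -> "CompiledModel":
        return CompiledModel.from_spec(self)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "ModelSpec":
        reactions = tuple(ReactionSpec(**r) for r in raw["reactions"])
        pools = tuple(
            Pool(total=float(p["total"]), members=tuple(p["members"]), eliminate=p["eliminate"])
            for p in raw.get("pools", [])
        )
        spec = cls(
            id=raw["id"],
            name=raw.get("name", raw["id"]),
            species=tuple(raw["species"]),
            output=raw["output"],
            pools=pools,
            initial={k: float(v) for k, v in raw["initial"].items()},
            reactions=reactions,
            reference_params={k: float(v) for k, v in raw.get("reference_params", {}).items()},
        )
        spec._validate()
        return spec

    def _validate(self) -> None:
        names = set(self.species)
        if self.output not in names:
            raise ValueError(f"{self.id}: output {self.output!r} not a species")
        seen_params: set[str] = set()
        for r in self.reactions:
            for sp in (r.substrate, r.modifier):
                if sp is not None and sp not in names:
                    raise ValueError(f"{self.id}/{r.label}: unknown species {sp!r}")
            for p in (r.k, r.km):
                if p is None:
                    continue
                if p in seen_params:
                    raise ValueError(f"{self.id}: parameter {p!r} used by more than one reaction")
                seen_params.add(p)
        for pool in self.pools:
            if pool.eliminate not in pool.members:
                raise ValueError(f"{self.id}: eliminated species must belong to its pool")
            # activation/deactivation pairs must conserve the pool
            v = self.stoichiometry()
            idx = {name: i for i, name in enumerate(self.species)}
            cons = np.zeros(self.n_species)
            for sp in pool.members:
                cons[idx[sp]] = 1.0
            if np.any(np.abs(cons @ v) > 1e-12):
                raise ValueError(f"{self.id}: stoichiometry does not conserve pool {pool.members}")


@dataclass(frozen=True)
class CompiledModel:
    """Array encoding of a :class:`ModelSpec` consumed by the numba kernels.

    Indices are into the *full* species vector; ``dyn_idx`` lists the
    independent (dynamic) species, and the ``elim_*`` arrays describe how each
    eliminated species is reconstructed from its pool total.
    """

    spec: ModelSpec
    law: np.ndarray
    kidx: np.ndarray
    kmidx: np.ndarray
    subidx: np.ndarray
    modidx: np.ndarray
    sigf: np.ndarray
    stoich_dyn: np.ndarray
    dyn_idx: np.ndarray
    elim_idx: np.ndarray
    elim_total: np.ndarray
    elim_ptr: np.ndarray
    elim_members: np.ndarray
    out_dyn: int
    y0_dyn: np.ndarray
    dyn_species: tuple[str, ...] = field(default=())

    @classmethod
    def from_spec(cls, spec: ModelSpec) -> "CompiledModel":
        sp_idx = {name: i for i, name in enumerate(spec.species)}
        p_idx = {name: i for i, name in enumerate(spec.param_names)}
        n_r = spec.n_reactions
        law = np.zeros(n_r, dtype=np.int64)
        kidx = np.zeros(n_r, dtype=np.int64)
        kmidx = np.full(n_r, -1, dtype=np.int64)
        subidx = np.full(n_r, -1, dtype=np.int64)
        modidx = np.full(n_r, -1, dtype=np.int64)
        sigf = np.zeros(n_r, dtype=np.int64)
        for j, r in enumerate(spec.reactions):
            law[j] = _LAW_CODES[r.rate_law]
            kidx[j] = p_idx[r.k]
            if r.km is not None:
                kmidx[j] = p_idx[r.km]
            if r.substrate is not None:
                subidx[j] = sp_idx[r.substrate]
            if r.modifier is not None:
                modidx[j] = sp_idx[r.modifier]
            sigf[j] = 1 if r.signal else 0

        eliminated = {pool.eliminate for pool in spec.pools}
        dyn_species = tuple(s for s in spec.species if s not in eliminated)
        dyn_idx = np.array([sp_idx[s] for s in dyn_species], dtype=np.int64)
        dyn_pos = {s: i for i, s in enumerate(dyn_species)}

        v_full = spec.stoichiometry()
        stoich_dyn = v_full[dyn_idx, :].copy()

        elim_idx = np.array([sp_idx[p.eliminate] for p in spec.pools], dtype=np.int64)
        elim_total = np.array([p.total for p in spec.pools], dtype=float)
        members: list[int] = []
        ptr = [0]
        for pool in spec.pools:
            for sp in pool.members:
                if sp != pool.eliminate:
                    members.append(dyn_pos[sp])
            ptr.append(len(members))
        elim_ptr = np.array(ptr, dtype=np.int64)
        elim_members = np.array(members, dtype=np.int64)

        y_full0 = spec.initial_full()
        y0_dyn = y_full0[dyn_idx].copy()
        return cls(
            spec=spec, law=law, kidx=kidx, kmidx=kmidx, subidx=subidx, modidx=modidx,
            sigf=sigf, stoich_dyn=stoich_dyn, dyn_idx=dyn_idx, elim_idx=elim_idx,
            elim_total=elim_total, elim_ptr=elim_ptr, elim_members=elim_members,
            out_dyn=dyn_pos[spec.output], y0_dyn=y0_dyn, dyn_species=dyn_species,
        )

    def full_state(self, y_dyn: np.ndarray) -> np.ndarray:
        """Reconstruct the full species vector from the dynamic state."""
        y_full = np.empty(self.spec.n_species)
        y_full[self.dyn_idx] = y_dyn
        for e in range(self.elim_idx.size):
            tot = self.elim_total[e]
            ssum = y_dyn[self.elim_members[self.elim_ptr[e]:self.elim_ptr[e + 1]]].sum()
            y_full[self.elim_idx[e]] = max(tot - ssum, 0.0)
        return y_full


# ---------------------------------------------------------------------------


def build_model(model_id: str) -> ModelSpec:
    """Load one of the four hub models (M1-M4) from its packaged definition.

    Raises ``KeyError`` for an unknown model id.
    """
    if model_id not in MODEL_IDS:
        raise KeyError(f"unknown model id {model_id!r}; expected one of {MODEL_IDS}")
    text = resources.files("hubsens.data.models").joinpath(f"{model_id}.yaml").read_text()
    return ModelSpec.from_dict(yaml.safe_load(text))


def build_linear_toy(k1: float = 2.0, k2: float = 0.05) -> ModelSpec:
    """Linear toy model dXa/dt = k1*s - k2*Xa used by the analytic oracles.

    Production is zeroth order (no conserved pool), so the output integral is
    exactly proportional to ``k1``.
    """
    return ModelSpec.from_dict({
        "id": "TOY",
        "name": "linear toy",
        "species": ["Xa"],
        "output": "Xa",
        "initial": {"Xa": 0.0},
        "reactions": [
            {"label": "A", "rate_law": "mass_action", "k": "k1", "signal": True, "stoich": {"Xa": 1}},
            {"label": "D", "rate_law": "mass_action", "k": "k2", "substrate": "Xa", "stoich": {"Xa": -1}},
        ],
        "reference_params": {"k1": k1, "k2": k2},
    })


def evaluate_rates(model: ModelSpec, state, s: float, params) -> np.ndarray:
    """Evaluate all reaction rates a_j at a full species state.

    Parameters
    ----------
    state:
        Full species vector aligned with ``model.species`` (or a mapping).
    s:
        Input signal concentration.
    params:
        Mapping of parameter name to positive value (or a vector aligned with
        ``model.param_names``).

    Raises ``ValueError`` on negative species values or non-positive
    parameters (domain errors).
    """
    if not isinstance(state, Mapping):
        state = dict(zip(model.species, np.asarray(state, dtype=float)))
    if not isinstance(params, Mapping):
        params = model.vector_to_params(params)
    if any(v < 0 for v in state.values()):
        raise ValueError("species values must be non-negative")
    if any(params[name] <= 0 for name in model.param_names):
        raise ValueError("parameters must be positive")
    return np.array([r.rate(state, s, params) for r in model.reactions], dtype=float)
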