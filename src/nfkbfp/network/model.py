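"""Domain types for tabular reaction-network models.

A model is a closed set of species, parameters and reactions. Concentrations
are in nM and time is in hours throughout; every rate constant is documented
in these units in the model tables. Time-varying inputs (e.g. NEMO-IKK
activity) are declared as parameters of class ``input`` whose table value is
the basal level used when no stimulus is supplied.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

COMPARTMENTS = frozenset({"cytoplasm", "nucleus", "membrane", "none"})
PARAM_CLASSES = frozenset(
    {"expression", "degradation", "binding", "transport", "catalysis", "induction", "input"}
)
RATE_LAWS = frozenset({"mass_action", "constant_source", "activation", "hill_activation"})


class ModelValidationError(ValueError):
    """Raised when a model table or spec violates its schema or references."""


@dataclass(frozen=True)
class Species:
    name: str
    compartment: str = "none"
    initial_amount: float = 0.0

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ModelValidationError(
                f"species {self.name!r}: unknown compartment {self.compartment!r}"
            )
        if not np.isfinite(self.initial_amount) or self.initial_amount < 0:
            raise ModelValidationError(
                f"species {self.name!r}: initial_amount must be finite and >= 0"
            )


@dataclass(frozen=True)
class Parameter:
    name: str
    value: float
    param_class: str

    def __post_init__(self) -> None:
        if self.param_class not in PARAM_CLASSES:
            raise ModelValidationError(
                f"parameter {self.name!r}: unknown class {self.param_class!r}"
            )
        if not np.isfinite(self.value) or self.value < 0:
            raise ModelValidationError(f"parameter {self.name!r}: value must be finite and >= 0")


@dataclass(frozen=True)
class Reaction:
    """One reaction: stoichiometry plus a rate-law template reference.

    ``reactants``/``products`` map species name -> positive integer
    stoichiometry. ``parameter_refs`` is the ordered list of parameter names
    the rate law consumes (mass_action/constant_source/activation take one
    rate constant k; hill_activation takes (k, K, n)). ``modifiers`` are
    species or input names that enter the rate but not the stoichiometry.
    """

    name: str
    reactants: Mapping[str, int] = field(default_factory=dict)
    products: Mapping[str, int] = field(default_factory=dict)
    rate_law: str = "mass_action"
    parameter_refs: Sequence[str] = ()
    modifiers: Sequence[str] = ()

    def __post_init__(self) -> None:
        if self.rate_law not in RATE_LAWS:
            raise ModelValidationError(
                f"reaction {self.name!r}: unknown rate law {self.rate_law!r}"
            )
        for side in (self.reactants, self.products):
            for sp, n in side.items():
                if not (isinstance(n, (int, np.integer)) and n > 0):
                    raise ModelValidationError(
                        f"reaction {self.name!r}: stoichiometry of {sp!r} must be a positive integer"
                    )


@dataclass(frozen=True)
class ModelSpec:
    species: tuple[Species, ...]
    parameters: tuple[Parameter, ...]
    reactions: tuple[Reaction, ...]

    def __post_init__(self) -> None:
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ModelValidationError("duplicate species names")
        pnames = [p.name for p in self.parameters]
        if len(set(pnames)) != len(pnames):
            raise ModelValidationError("duplicate parameter names")
        if set(names) & set(pnames):
            raise ModelValidationError("species and parameter names must be disjoint")
        sset, pset = set(names), set(pnames)
        inputs = {p.name for p in self.parameters if p.param_class == "input"}
        n_rate_params = {"mass_action": 1, "constant_source": 1, "activation": 1, "hill_activation": 3}
        for rx in self.reactions:
            for sp in list(rx.reactants) + list(rx.products):
                if sp not in sset:
                    raise ModelValidationError(
                        f"reaction {rx.name!r}: unresolved species reference {sp!r}"
                    )
            for pn in rx.parameter_refs:
                if pn not in pset:
                    raise ModelValidationError(
                        f"reaction {rx.name!r}: unresolved parameter reference {pn!r}"
                    )
            if len(rx.parameter_refs) != n_rate_params[rx.rate_law]:
                raise ModelValidationError(
                    f"reaction {rx.name!r}: rate law {rx.rate_law!r} takes "
                    f"{n_rate_params[rx.rate_law]} parameter(s), got {len(rx.parameter_refs)}"
                )
            for m in rx.modifiers:
                if m not in sset and m not in inputs:
                    raise ModelValidationError(
                        f"reaction {rx.name!r}: modifier {m!r} is neither a species "
                        "nor an input-class parameter"
                    )
            if rx.rate_law == "hill_activation" and not rx.modifiers:
                raise ModelValidationError(
                    f"reaction {rx.name!r}: hill_activation requires at least one modifier"
                )

    # -- convenience lookups ------------------------------------------------
    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    @property
    def input_names(self) -> list[str]:
        return [p.name for p in self.parameters if p.param_class == "input"]

    def species_index(self, name: str) -> int:
        try:
            return self.species_names.index(name)
        except ValueError:
            raise KeyError(f"unknown species {name!r}") from None

    def parameter(self, name: str) -> Parameter:
        for p in self.parameters:
            if p.name == name:
                return p
        raise KeyError(f"unknown parameter {name!r}")

    def parameter_values(self) -> dict[str, float]:
        return {p.name: p.value for p in self.parameters}

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_amount for s in self.species], dtype=float)

    def with_parameters(self, overrides: Mapping[str, float]) -> "ModelSpec":
        """Return a new spec with the given parameter values replaced."""
        known = {p.name for p in self.parameters}
        missing = set(overrides) - known
        if missing:
            raise KeyError(f"unknown parameters: {sorted(missing)}")
        new = tuple(
            replace(p, value=float(overrides[p.name])) if p.name in overrides else p
            for p in self.parameters
        )
        return ModelSpec(self.species, new, self.reactions)

    def scale_parameters(self, factors: Mapping[str, float]) -> "ModelSpec":
        vals = self.parameter_values()
        return self.with_parameters({k: vals[k] * f for k, f in factors.items()})


@dataclass(frozen=True)
class StimulusProfile:
    """Piecewise-constant stimulus for one named input.

    Segments are contiguous (t_start, t_end, level) pieces in hours; times
    outside the covered range evaluate to the nearest end segment's level.
    """

    input_name: str
    segments: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ModelValidationError("stimulus needs at least one segment")
        prev_end = None
        for t0, t1, level in self.segments:
            if t1 <= t0:
                raise ModelValidationError("stimulus segment must have t_end > t_start")
            if level < 0:
                raise ModelValidationError("stimulus levels must be >= 0")
            if prev_end is not None and not np.isclose(t0, prev_end):
                raise ModelValidationError("stimulus segments must be contiguous")
            prev_end = t1

    @classmethod
    def constant(cls, input_name: str, level: float, t_end: float = np.inf) -> "StimulusProfile":
        return cls(input_name, ((0.0, float(t_end), float(level)),))

    @property
    def is_constant(self) -> bool:
        return len({lvl for _, _, lvl in self.segments}) == 1

    def __call__(self, t: float) -> float:
        starts = [s[0] for s in self.segments]
        i = bisect.bisect_right(starts, t) - 1
        i = min(max(i, 0), len(self.segments) - 1)
        return self.segments[i][2]


class InterpolatedStimulus:
    """Stimulus defined by linear interpolation of a sampled curve.

    Used to feed the active-IKK output of receptor modules into the core
    model as its NEMO-IKK input.
    """

    def __init__(self, input_name: str, times: np.ndarray, values: np.ndarray):
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
        if times.ndim != 1 or times.shape != values.shape:
            raise ValueError("times and values must be matching 1-D arrays")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        self.input_name = input_name
        self.times = times
        self.values = values

    @property
    def is_constant(self) -> bool:
        return bool(np.allclose(self.values, self.values[0]))

    def __call__(self, t: float) -> float:
        return float(np.interp(t, self.times, self.values))


Stimulus = StimulusProfile | InterpolatedStimulus
StimulusMap = Mapping[str, "Stimulus"]


@dataclass(frozen=True)
class Trajectory:
    """Time course of all species for one integration run."""

    times: np.ndarray  # hours, strictly increasing
    states: np.ndarray  # (n_times, n_species), nM
    spec: ModelSpec
    cell_id: int | None = None

    def __post_init__(self) -> None:
        if self.states.shape != (len(self.times), len(self.spec.species)):
            raise ValueError("states shape does not match times x species")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def series(self, species: str) -> np.ndarray:
        return self.states[:, self.spec.species_index(species)]

    def final_state(self) -> np.ndarray:
        return self.states[-1].copy()
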