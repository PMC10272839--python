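"""Compile a ModelSpec into a fast vectorised derivative evaluator.

Every rate law in the closed dialect factors into at most three
concentration-like factors times a rate constant, except Hill activation
which is handled on a separate code path:

* ``mass_action``      k * prod([reactant]^stoich)      (total order <= 3)
* ``constant_source``  k
* ``activation``       k * prod([reactant]) * prod([modifier])
* ``hill_activation``  k * M^n / (K^n + M^n), M = sum of modifiers
  (a Vmax-style law: reactant concentrations set stoichiometry only, not
  the rate — used for induced synthesis and carrier-limited transport)

Factors index into an extended state vector ``xx = [state, 1.0, inputs(t)]``
so the whole rate vector is three gathers and two multiplies; the derivative
is the stoichiometry matrix (species x reactions) times the rate vector.
"""

from __future__ import annotations

from typing import Callable, Mapping

import numpy as np

from .model import ModelSpec, ModelValidationError, Stimulus

MAX_FACTORS = 3


class CompiledModel:
    """A ModelSpec compiled to index arrays for fast RHS evaluation.

    The structure (species, reactions, rate-law wiring) is fixed at compile
    time; parameter values can be swapped cheaply per cell via
    :meth:`set_parameters`, which is what makes population simulation over
    thousands of parameter sets affordable.
    """

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        n_sp = len(spec.species)
        n_rx = len(spec.reactions)
        self.n_species = n_sp
        self.input_names = spec.input_names
        n_in = len(self.input_names)
        # extended vector layout: [species..., ONE, inputs...]
        self._one = n_sp
        input_pos = {name: n_sp + 1 + i for i, name in enumerate(self.input_names)}
        sp_pos = {s.name: i for i, s in enumerate(spec.species)}

        N = np.zeros((n_sp, n_rx))
        factors = np.full((n_rx, MAX_FACTORS), self._one, dtype=np.intp)
        hill_rows: list[int] = []
        hill_mod_idx: list[list[int]] = []
        self._k_refs: list[str] = []
        self._hill_refs: list[tuple[str, str]] = []  # (K, n) per hill row

        def resolve(name: str) -> int:
            return sp_pos[name] if name in sp_pos else input_pos[name]

        for j, rx in enumerate(spec.reactions):
            for sp, st in rx.reactants.items():
                N[sp_pos[sp], j] -= st
            for sp, st in rx.products.items():
                N[sp_pos[sp], j] += st
            self._k_refs.append(rx.parameter_refs[0])
            fac: list[int] = []
            if rx.rate_law in ("mass_action", "activation"):
                for sp, st in rx.reactants.items():
                    fac.extend([sp_pos[sp]] * st)
            if rx.rate_law == "activation":
                fac.extend(resolve(m) for m in rx.modifiers)
            if rx.rate_law == "hill_activation":
                hill_rows.append(j)
                hill_mod_idx.append([resolve(m) for m in rx.modifiers])
                self._hill_refs.append((rx.parameter_refs[1], rx.parameter_refs[2]))
            if len(fac) > MAX_FACTORS:
                raise ModelValidationError(
                    f"reaction {rx.name!r}: rate law order {len(fac)} exceeds the "
                    f"supported maximum of {MAX_FACTORS}"
                )
            factors[j, : len(fac)] = fac

        self._N = N
        self._factors = factors
        self._hill_rows = np.array(hill_rows, dtype=np.intp)
        self._hill_mods = hill_mod_idx
        self._n_ext = n_sp + 1 + n_in
        self.set_parameters(spec.parameter_values())

    def set_parameters(self, values: Mapping[str, float]) -> None:
        """Load a full parameter-value mapping (name -> value)."""
        self._k = np.array([values[r] for r in self._k_refs], dtype=float)
        self._hill_K = np.array([values[K] for K, _ in self._hill_refs], dtype=float)
        self._hill_n = np.array([values[n] for _, n in self._hill_refs], dtype=float)
        self._basal_inputs = np.array(
            [values[name] for name in self.input_names], dtype=float
        )

    def input_levels(self, t: float, stimuli: Mapping[str, Stimulus] | None) -> np.ndarray:
        levels = self._basal_inputs.copy()
        if stimuli:
            for i, name in enumerate(self.input_names):
                stim = stimuli.get(name)
                if stim is not None:
                    levels[i] = stim(t)
        return levels

    def rates(self, state: np.ndarray, input_levels: np.ndarray) -> np.ndarray:
        xx = np.empty(self._n_ext)
        xx[: self.n_species] = np.maximum(state, 0.0)
        xx[self._one] = 1.0
        xx[self.n_species + 1 :] = input_levels
        r = self._k * xx[self._factors[:, 0]] * xx[self._factors[:, 1]] * xx[self._factors[:, 2]]
        if self._hill_rows.size:
            for h, j in enumerate(self._hill_rows):
                M = sum(xx[i] for i in self._hill_mods[h])
                Mn = M ** self._hill_n[h]
                r[j] *= Mn / (self._hill_K[h] ** self._hill_n[h] + Mn)
        return r

    def rhs(self, t: float, state: np.ndarray, stimuli: Mapping[str, Stimulus] | None = None) -> np.ndarray:
        if len(state) != self.n_species:
            raise ValueError(
                f"state has length {len(state)}, model has {self.n_species} species"
            )
        return self._N @ self.rates(state, self.input_levels(t, stimuli))


def assemble_rhs(
    spec: ModelSpec,
) -> Callable[[np.ndarray, float, Mapping[str, Stimulus] | None], np.ndarray]:
    """Return a derivative evaluator ``f(state, t, stimuli) -> d(state)/dt``.

    The evaluator computes, for each species, the sum over reactions of
    (signed stoichiometry x rate). Inputs not covered by ``stimuli`` stay at
    their basal table values.
    """
    compiled = CompiledModel(spec)

    def f(state, t, stimuli=None):
        return compiled.rhs(t, np.asarray(state, dtype=float), stimuli)

    return f
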