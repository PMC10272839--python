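"""Read and write the delimited-text model tables.

Schema (UTF-8, comma-delimited, ``#`` starts a comment line):

``species.csv``     columns: name, compartment, initial_amount
``parameters.csv``  columns: name, value, param_class
``reactions.csv``   columns: name, reactants, products, rate_law, parameters, modifiers

Reactant/product fields are ``+``-separated terms with optional integer
stoichiometry (``2 p50``); empty means none (source/sink). ``parameters``
and ``modifiers`` are ``;``-separated ordered name lists. Unknown columns
are schema errors, never silently ignored.
"""

from __future__ import annotations

import io
import json
from pathlib import Path

import pandas as pd

from .model import ModelSpec, ModelValidationError, Parameter, Reaction, Species

SPECIES_COLS = ["name", "compartment", "initial_amount"]
PARAM_COLS = ["name", "value", "param_class"]
REACTION_COLS = ["name", "reactants", "products", "rate_law", "parameters", "modifiers"]


def _read_csv(path: str | Path, cols: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", skip_blank_lines=True, dtype=str)
    got = list(df.columns)
    if got != cols:
        extra = set(got) - set(cols)
        missing = set(cols) - set(got)
        raise ModelValidationError(
            f"{path}: expected columns {cols}, got {got}"
            + (f" (unknown: {sorted(extra)})" if extra else "")
            + (f" (missing: {sorted(missing)})" if missing else "")
        )
    return df.fillna("")


def _parse_side(text: str, where: str) -> dict[str, int]:
    side: dict[str, int] = {}
    text = text.strip()
    if not text:
        return side
    for term in text.split("+"):
        bits = term.split()
        if len(bits) == 1:
            name, stoich = bits[0], 1
        elif len(bits) == 2:
            try:
                stoich = int(bits[0])
            except ValueError:
                raise ModelValidationError(f"{where}: bad stoichiometry in {term!r}") from None
            name = bits[1]
        else:
            raise ModelValidationError(f"{where}: cannot parse term {term!r}")
        side[name] = side.get(name, 0) + stoich
    return side


def _parse_list(text: str) -> tuple[str, ...]:
    text = text.strip()
    if not text:
        return ()
    return tuple(t.strip() for t in text.split(";") if t.strip())


def load_model_tables(
    species_path: str | Path,
    parameters_path: str | Path,
    reactions_path: str | Path,
) -> ModelSpec:
    """Load and validate the three model tables into a ModelSpec.

    Raises :class:`ModelValidationError` naming the offending row for any
    unresolved reference, negative value or malformed field.
    """
    sdf = _read_csv(species_path, SPECIES_COLS)
    pdf = _read_csv(parameters_path, PARAM_COLS)
    rdf = _read_csv(reactions_path, REACTION_COLS)

    species = []
    for i, row in sdf.iterrows():
        try:
            species.append(
                Species(row["name"].strip(), row["compartment"].strip(), float(row["initial_amount"]))
            )
        except (ValueError, ModelValidationError) as e:
            raise ModelValidationError(f"{species_path} row {i + 1}: {e}") from None
    parameters = []
    for i, row in pdf.iterrows():
        try:
            parameters.append(
                Parameter(row["name"].strip(), float(row["value"]), row["param_class"].strip())
            )
        except (ValueError, ModelValidationError) as e:
            raise ModelValidationError(f"{parameters_path} row {i + 1}: {e}") from None
    reactions = []
    for i, row in rdf.iterrows():
        where = f"{reactions_path} row {i + 1} ({row['name']})"
        reactions.append(
            Reaction(
                name=row["name"].strip(),
                reactants=_parse_side(row["reactants"], where),
                products=_parse_side(row["products"], where),
                rate_law=row["rate_law"].strip(),
                parameter_refs=_parse_list(row["parameters"]),
                modifiers=_parse_list(row["modifiers"]),
            )
        )
    try:
        return ModelSpec(tuple(species), tuple(parameters), tuple(reactions))
    except ModelValidationError as e:
        raise ModelValidationError(f"model tables {reactions_path}: {e}") from None


def write_model_tables(spec: ModelSpec, directory: str | Path) -> None:
    """Write a ModelSpec back out as the three-table text form."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [(s.name, s.compartment, s.initial_amount) for s in spec.species],
        columns=SPECIES_COLS,
    ).to_csv(directory / "species.csv", index=False)
    pd.DataFrame(
        [(p.name, p.value, p.param_class) for p in spec.parameters],
        columns=PARAM_COLS,
    ).to_csv(directory / "parameters.csv", index=False)

    def fmt_side(side):
        return " + ".join(n if k == 1 else f"{k} {n}" for n, k in side.items())

    pd.DataFrame(
        [
            (
                r.name,
                fmt_side(r.reactants),
                fmt_side(r.products),
                r.rate_law,
                ";".join(r.parameter_refs),
                ";".join(r.modifiers),
            )
            for r in spec.reactions
        ],
        columns=REACTION_COLS,
    ).to_csv(directory / "reactions.csv", index=False)


def trajectory_to_long(traj) -> pd.DataFrame:
    """Tidy long-format export: (time, species, cell_id, value)."""
    spec = traj.spec
    n_t, n_s = traj.states.shape
    return pd.DataFrame(
        {
            "time": pd.Series(traj.times).repeat(n_s).to_numpy(),
            "species": spec.species_names * n_t,
            "cell_id": traj.cell_id if traj.cell_id is not None else -1,
            "value": traj.states.ravel(),
        }
    )
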