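"""Virtual DLBCL cell lines.

A virtual line is the core NF-kB model with its per-subunit expression
parameters multiplied by line-specific factors, plus the line's recurrent
mutations applied to the receptor modules. Scaling factors come either
from gene-expression z-scores (factor = 10^z, so an average line is
unchanged and a line one SD above average is scaled 10-fold) or from
calibration against a measured fingerprint (adjusting RelA and RelB
expression until the simulated population's fingerprint medians match).

Scaling is applied to the base parameter values *before* the population
sampling that introduces cell-to-cell variability, and therefore persists
through both the steady-state and time-course phases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core_model import EXPRESSION_PARAMS, build_nfkb_model
from .fingerprint import simulated_fingerprint
from .network import ModelSpec, StimulusProfile
from .population import PopulationConfig, sample_cells, two_phase_simulate
from .receptors import (
    apply_mutation,
    build_bcr_module,
    build_tlr_module,
    get_mutation,
)

#: gene symbol -> subunit whose expression parameters it scales
GENE_TO_SUBUNIT = {
    "RELA": "RelA",
    "REL": "cRel",
    "RELB": "RelB",
    "NFKB1": "p50",
    "NFKB2": "p52",
}


def standardize_library(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-score each gene column across cell lines (population SD, divisor
    n). Raises for zero-variance genes, naming them."""
    if len(matrix) < 2:
        raise ValueError("standardisation needs >= 2 cell lines")
    sd = matrix.std(ddof=0)
    dead = sd[sd == 0]
    if not dead.empty:
        raise ValueError(f"zero-variance gene(s): {list(dead.index)}")
    return (matrix - matrix.mean()) / sd


def expression_scaling(z: float | np.ndarray | pd.DataFrame):
    """Map an expression z-score to a multiplicative parameter factor,
    10^z: an average line (z=0) is unchanged, one SD above average (z=1)
    is scaled 10-fold."""
    arr = np.asarray(z, dtype=float) if not isinstance(z, pd.DataFrame) else z
    if isinstance(arr, np.ndarray) and not np.all(np.isfinite(arr)):
        raise ValueError("z-scores must be finite")
    return 10.0 ** z


@dataclass(frozen=True)
class VirtualCellLine:
    """Name, per-subunit expression scalings, mutations and basal inputs."""

    name: str
    subunit_scalings: Mapping[str, float] = field(default_factory=dict)
    mutations: tuple[str, ...] = ()
    basal_nemo_ikk: float | None = None  # None -> derived from receptor modules
    basal_nik: float | None = None

    def __post_init__(self) -> None:
        for su, f in self.subunit_scalings.items():
            if su not in EXPRESSION_PARAMS:
                raise KeyError(f"unknown subunit {su!r}")
            if f <= 0:
                raise ValueError(f"scaling for {su} must be > 0")
        for m in self.mutations:
            get_mutation(m)  # validates the name


def build_virtual_line(base_spec: ModelSpec, line: VirtualCellLine) -> ModelSpec:
    """Apply the line's expression scalings (and any mutations whose target
    parameter lives in this spec) to a base model."""
    pnames = {p.name for p in base_spec.parameters}
    factors: dict[str, float] = {}
    for su, f in line.subunit_scalings.items():
        for pname in EXPRESSION_PARAMS[su]:
            if pname in pnames:  # receptor specs carry no subunit expression
                factors[pname] = f
    spec = base_spec.scale_parameters(factors) if factors else base_spec
    for mname in line.mutations:
        m = get_mutation(mname)
        if m.target_parameter in pnames:
            spec = apply_mutation(spec, m)
    return spec


@dataclass(frozen=True)
class VirtualLineModels:
    """The full model bundle for one line: scaled core + mutated receptors."""

    line: VirtualCellLine
    core: ModelSpec
    tlr: ModelSpec
    bcr: ModelSpec


def build_virtual_line_models(
    line: VirtualCellLine, core_spec: ModelSpec | None = None
) -> VirtualLineModels:
    core = build_virtual_line(core_spec or build_nfkb_model(), line)
    tlr = build_virtual_line(build_tlr_module().spec, line)
    bcr = build_virtual_line(build_bcr_module().spec, line)
    return VirtualLineModels(line, core, tlr, bcr)


def library_to_lines(library_matrix: pd.DataFrame) -> list[VirtualCellLine]:
    """One virtual line per library row: standardise, then scale each
    subunit's expression by 10^z of its encoding gene."""
    z = standardize_library(library_matrix)
    lines = []
    for name, row in z.iterrows():
        scalings = {
            GENE_TO_SUBUNIT[g]: float(expression_scaling(row[g]))
            for g in row.index
            if g in GENE_TO_SUBUNIT
        }
        lines.append(VirtualCellLine(str(name), scalings))
    return lines


# ---------------------------------------------------------------------------
# population fingerprint simulation and calibration


def simulate_basal_states(
    spec: ModelSpec,
    n_cells: int,
    seed: int,
    basal_nemo_ikk: float | None = None,
) -> np.ndarray:
    """Per-cell basal steady states for a heterogeneous population."""
    basal = None
    if basal_nemo_ikk is not None:
        basal = {"NEMO_IKK": StimulusProfile.constant("NEMO_IKK", basal_nemo_ikk)}
    pop = sample_cells(spec, PopulationConfig(n_cells=n_cells, seed=seed))
    res = two_phase_simulate(pop, basal_input=basal, steady_only=True)
    return res.steady_states


class CalibrationError(RuntimeError):
    pass


def calibrate_to_fingerprint(
    base_spec: ModelSpec,
    targets: Mapping[str, float],
    n_cells: int = 25,
    seed: int = 11,
    tol: float = 0.15,
    log10_bracket: tuple[float, float] = (-1.5, 1.5),
    max_iter: int = 18,
) -> VirtualCellLine:
    """Find expression scalings whose simulated fingerprint medians match
    ``targets`` (per-subunit median z-scores, e.g. {"RelA": 0.8}).

    The candidate population is pooled with a baseline population
    simulated from the unscaled model, fingerprinted, and the candidate's
    per-marker median z compared to the target. The map from log-scaling
    to median z is monotone, so each subunit is solved by deterministic
    1-D bisection (RelA and RelB are the calibrated subunits; others stay
    at base expression).
    """
    unknown = set(targets) - {"RelA", "RelB", "cRel"}
    if unknown:
        raise KeyError(f"calibration targets must be subunits, got {sorted(unknown)}")
    base_states = simulate_basal_states(base_spec, n_cells, seed)

    def median_z(scalings: Mapping[str, float], subunit: str) -> float:
        spec = build_virtual_line(base_spec, VirtualCellLine("cand", scalings))
        states = simulate_basal_states(spec, n_cells, seed)
        fp = simulated_fingerprint({"base": base_states, "cand": states}, base_spec)
        return float(fp.median_by_population().loc["cand", subunit])

    scalings: dict[str, float] = {}
    for subunit in targets:
        lo, hi = log10_bracket
        z_lo = median_z({**scalings, subunit: 10.0 ** lo}, subunit)
        z_hi = median_z({**scalings, subunit: 10.0 ** hi}, subunit)
        t = targets[subunit]
        if not (min(z_lo, z_hi) - tol <= t <= max(z_lo, z_hi) + tol):
            raise CalibrationError(
                f"{subunit}: target {t:+.2f} outside achievable median-z range "
                f"[{min(z_lo, z_hi):+.2f}, {max(z_lo, z_hi):+.2f}]"
            )
        increasing = z_hi >= z_lo
        for _ in range(max_iter):
            mid = (lo + hi) / 2
            z_mid = median_z({**scalings, subunit: 10.0 ** mid}, subunit)
            if abs(z_mid - t) < tol:
                break
            if (z_mid < t) == increasing:
                lo = mid
            else:
                hi = mid
        scalings[subunit] = 10.0 ** ((lo + hi) / 2 if abs(z_mid - t) >= tol else mid)
    return VirtualCellLine("calibrated", scalings)


# ---------------------------------------------------------------------------
# shipped line presets (fingerprint-informed scalings + known lesions)

#: Expression scalings authored to reproduce the measured fingerprint
#: layout: RelA lowest in RIVA, rising through U2932 R2 and HBL1 to U2932
#: R1; RelB low and homogeneous in primary (patient/healthy) B cells;
#: mutations per line as reported for these models (HBL1 MYD88 L265P +
#: CD79B; U2932 TAK1; RIVA wild-type).
PRESET_LINES: dict[str, VirtualCellLine] = {
    "RIVA": VirtualCellLine("RIVA", {"RelA": 0.28, "RelB": 1.2}, ()),
    "U2932_R1": VirtualCellLine("U2932_R1", {"RelA": 3.0, "RelB": 1.0}, ("TAK1_mut",)),
    "U2932_R2": VirtualCellLine("U2932_R2", {"RelA": 0.9, "RelB": 1.0}, ("TAK1_mut",)),
    "HBL1": VirtualCellLine("HBL1", {"RelA": 1.8, "RelB": 0.9}, ("MYD88_L265P", "CD79B_mut")),
    "patient": VirtualCellLine("patient", {"RelA": 0.6, "RelB": 0.25}, ()),
    "healthy": VirtualCellLine("healthy", {"RelA": 0.12, "RelB": 0.12}, ()),
}

#: the four cell-line presets used in the mutation/stimulus experiments
CELL_LINE_PRESETS = ("RIVA", "U2932_R1", "U2932_R2", "HBL1")
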