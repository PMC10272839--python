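"""TLR9 and BCR receptor-proximal cascades feeding NEMO-IKK.

Each module is a small ModelSpec with an active-IKK output species; the two
branches are simulated independently and their active-IKK curves summed to
form the NEMO-IKK input to the core NF-kB model.

Both branches share a three-state IKK cycle (inactive -> active ->
refractory -> inactive, slow recovery). The refractory state is what makes
chronic pathway activation self-limiting: an oncogenic mutation that drives
the cascade tonically parks most IKK in the refractory pool, so the basal
active-IKK level rises only modestly while the stimulus-recruitable
reserve is depleted. That is the mechanism by which MYD88/CD79B/TAK1
mutations blunt the response to a TLR9 (CpG) stimulus without markedly
raising resting NF-kB activity.

Recurrent DLBCL mutations are encoded as parameter perturbations:
MYD88 L265P multiplies the MyD88 self-activation rate, CD79B mutation
raises the basal BCR engagement set-point, and TAK1 mutation multiplies
the TAK1 activation rate in whichever branches carry it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import ReporterSeries
from .network import (
    InterpolatedStimulus,
    ModelSpec,
    Parameter,
    Reaction,
    Species,
    Stimulus,
    StimulusProfile,
    integrate,
    run_to_steady_state,
)

#: nM of summed branch active IKK corresponding to 1.0 on the core model's
#: normalised NEMO-IKK input scale
IKK_SCALE = 32.0


@dataclass(frozen=True)
class ReceptorModule:
    kind: str  # "TLR" or "BCR"
    spec: ModelSpec
    ikk_output_species: str = "IKKa"

    def __post_init__(self) -> None:
        if self.ikk_output_species not in self.spec.species_names:
            raise ValueError(f"IKK output species {self.ikk_output_species!r} missing")


def build_tlr_module() -> ReceptorModule:
    """CpG -> TLR9 engagement -> MyD88 (with self-activation) -> TRAF6 ->
    TAK1 -> active IKK. The CpG ligand level is the module input."""
    sp = [
        Species("TLR9", "membrane", 100.0),
        Species("TLR9a", "membrane", 0.0),
        Species("MyD88i", "cytoplasm", 100.0),
        Species("MyD88a", "cytoplasm", 0.0),
        Species("TRAF6i", "cytoplasm", 100.0),
        Species("TRAF6a", "cytoplasm", 0.0),
        Species("TAK1i", "cytoplasm", 100.0),
        Species("TAK1a", "cytoplasm", 0.0),
        Species("IKKi", "cytoplasm", 100.0),
        Species("IKKa", "cytoplasm", 0.0),
        Species("IKKr", "cytoplasm", 0.0),
    ]
    pars = {
        "CpG": (0.0, "input"),
        "k_syn_tlr9": (10.0, "expression"),
        "k_deg_tlr9": (0.1, "degradation"),
        "k_cpg_bind": (10.0, "binding"),
        "k_cpg_unbind": (0.5, "binding"),
        "k_int_tlr9a": (2.0, "degradation"),
        "k_myd88_act": (0.02, "catalysis"),
        "k_myd88_self": (0.001, "catalysis"),
        "k_myd88_basal": (0.002, "catalysis"),
        "k_myd88_inact": (1.0, "catalysis"),
        "k_traf6_act": (0.03, "catalysis"),
        "k_traf6_inact": (1.0, "catalysis"),
        "k_tak1_act": (0.03, "catalysis"),
        "k_tak1_inact": (1.0, "catalysis"),
        "k_ikk_act": (0.1, "catalysis"),
        "k_ikk_off": (4.0, "catalysis"),
        "k_ikk_rec": (0.04, "catalysis"),
    }
    rx = [
        Reaction("syn_tlr9", {}, {"TLR9": 1}, "constant_source", ("k_syn_tlr9",)),
        Reaction("deg_tlr9", {"TLR9": 1}, {}, "mass_action", ("k_deg_tlr9",)),
        Reaction("bind_cpg", {"TLR9": 1}, {"TLR9a": 1}, "activation", ("k_cpg_bind",), ("CpG",)),
        Reaction("unbind_cpg", {"TLR9a": 1}, {"TLR9": 1}, "mass_action", ("k_cpg_unbind",)),
        Reaction("int_tlr9a", {"TLR9a": 1}, {}, "mass_action", ("k_int_tlr9a",)),
        Reaction("act_myd88", {"MyD88i": 1}, {"MyD88a": 1}, "activation",
                 ("k_myd88_act",), ("TLR9a",)),
        Reaction("self_myd88", {"MyD88i": 1}, {"MyD88a": 1}, "activation",
                 ("k_myd88_self",), ("MyD88a",)),
        Reaction("basal_myd88", {"MyD88i": 1}, {"MyD88a": 1}, "mass_action", ("k_myd88_basal",)),
        Reaction("inact_myd88", {"MyD88a": 1}, {"MyD88i": 1}, "mass_action", ("k_myd88_inact",)),
        Reaction("act_traf6", {"TRAF6i": 1}, {"TRAF6a": 1}, "activation",
                 ("k_traf6_act",), ("MyD88a",)),
        Reaction("inact_traf6", {"TRAF6a": 1}, {"TRAF6i": 1}, "mass_action", ("k_traf6_inact",)),
        Reaction("act_tak1", {"TAK1i": 1}, {"TAK1a": 1}, "activation",
                 ("k_tak1_act",), ("TRAF6a",)),
        Reaction("inact_tak1", {"TAK1a": 1}, {"TAK1i": 1}, "mass_action", ("k_tak1_inact",)),
        Reaction("act_ikk", {"IKKi": 1}, {"IKKa": 1}, "activation", ("k_ikk_act",), ("TAK1a",)),
        Reaction("off_ikk", {"IKKa": 1}, {"IKKr": 1}, "mass_action", ("k_ikk_off",)),
        Reaction("rec_ikk", {"IKKr": 1}, {"IKKi": 1}, "mass_action", ("k_ikk_rec",)),
    ]
    spec = ModelSpec(
        tuple(sp), tuple(Parameter(n, v, c) for n, (v, c) in pars.items()), tuple(rx)
    )
    return ReceptorModule("TLR", spec)


def build_bcr_module() -> ReceptorModule:
    """Chronic/basal BCR engagement (CD79-dependent) -> CARD11-BCL10-MALT1
    -> TAK1 -> active IKK. The basal engagement rate is an input-class
    parameter (the CD79B mutation raises it); there is no acute ligand."""
    sp = [
        Species("BCRe", "membrane", 0.0),
        Species("CBMi", "cytoplasm", 100.0),
        Species("CBMa", "cytoplasm", 0.0),
        Species("TAK1i", "cytoplasm", 100.0),
        Species("TAK1a", "cytoplasm", 0.0),
        Species("IKKi", "cytoplasm", 100.0),
        Species("IKKa", "cytoplasm", 0.0),
        Species("IKKr", "cytoplasm", 0.0),
    ]
    pars = {
        "k_bcr_basal": (1.0, "input"),  # nM/h engagement set-point
        "k_bcr_decay": (1.0, "degradation"),
        "k_cbm_act": (0.005, "catalysis"),
        "k_cbm_inact": (1.0, "catalysis"),
        "k_tak1_act": (0.03, "catalysis"),
        "k_tak1_inact": (1.0, "catalysis"),
        "k_ikk_act": (0.1, "catalysis"),
        "k_ikk_off": (4.0, "catalysis"),
        "k_ikk_rec": (0.04, "catalysis"),
    }
    rx = [
        Reaction("engage_bcr", {}, {"BCRe": 1}, "constant_source", ("k_bcr_basal",)),
        Reaction("decay_bcr", {"BCRe": 1}, {}, "mass_action", ("k_bcr_decay",)),
        Reaction("act_cbm", {"CBMi": 1}, {"CBMa": 1}, "activation", ("k_cbm_act",), ("BCRe",)),
        Reaction("inact_cbm", {"CBMa": 1}, {"CBMi": 1}, "mass_action", ("k_cbm_inact",)),
        Reaction("act_tak1", {"TAK1i": 1}, {"TAK1a": 1}, "activation",
                 ("k_tak1_act",), ("CBMa",)),
        Reaction("inact_tak1", {"TAK1a": 1}, {"TAK1i": 1}, "mass_action", ("k_tak1_inact",)),
        Reaction("act_ikk", {"IKKi": 1}, {"IKKa": 1}, "activation", ("k_ikk_act",), ("TAK1a",)),
        Reaction("off_ikk", {"IKKa": 1}, {"IKKr": 1}, "mass_action", ("k_ikk_off",)),
        Reaction("rec_ikk", {"IKKr": 1}, {"IKKi": 1}, "mass_action", ("k_ikk_rec",)),
    ]
    spec = ModelSpec(
        tuple(sp), tuple(Parameter(n, v, c) for n, (v, c) in pars.items()), tuple(rx)
    )
    return ReceptorModule("BCR", spec)


# ---------------------------------------------------------------------------
# mutations


@dataclass(frozen=True)
class MutationSpec:
    """A recurrent lesion encoded as a single-parameter perturbation.

    ``action`` is ``multiply`` (value *= magnitude) or ``set`` (value =
    magnitude). The target parameter may exist in one or both receptor
    branches; :func:`apply_mutation` changes it wherever present.
    """

    name: str
    target_parameter: str
    action: str  # "multiply" | "set"
    magnitude: float

    def __post_init__(self) -> None:
        if self.action not in ("multiply", "set"):
            raise ValueError(f"unknown action {self.action!r}")
        if self.magnitude <= 0:
            raise ValueError("mutation magnitude must be > 0")


#: default magnitudes are authored so that chronic-activation lesions
#: saturate the stimulus-recruitable IKK reserve without large basal shifts
MUTATIONS: dict[str, MutationSpec] = {
    "MYD88_L265P": MutationSpec("MYD88_L265P", "k_myd88_self", "multiply", 25.0),
    "CD79B_mut": MutationSpec("CD79B_mut", "k_bcr_basal", "set", 20.0),
    "TAK1_mut": MutationSpec("TAK1_mut", "k_tak1_act", "multiply", 12.0),
}


def get_mutation(name: str) -> MutationSpec:
    try:
        return MUTATIONS[name]
    except KeyError:
        raise KeyError(
            f"unknown mutation {name!r}; known: {sorted(MUTATIONS)}"
        ) from None


def apply_mutation(spec: ModelSpec, m: MutationSpec) -> ModelSpec:
    """Return a new spec with only the targeted parameter changed."""
    current = spec.parameter(m.target_parameter).value
    new = current * m.magnitude if m.action == "multiply" else m.magnitude
    return spec.with_parameters({m.target_parameter: new})


# ---------------------------------------------------------------------------
# IKK curves


def ikk_series(
    module_spec: ModelSpec,
    stimulus: dict[str, Stimulus] | None = None,
    t_span: tuple[float, float] = (0.0, 8.0),
    t_eval: np.ndarray | None = None,
    ikk_species: str = "IKKa",
) -> ReporterSeries:
    """Two-phase active-IKK curve: basal steady state, then stimulation."""
    ss = run_to_steady_state(module_spec).state
    traj = integrate(module_spec, ss, stimulus, t_span, t_eval=t_eval)
    return ReporterSeries(traj.times, traj.series(ikk_species), "active IKK (nM)")


def combine_ikk(tlr_out: ReporterSeries, bcr_out: ReporterSeries) -> ReporterSeries:
    """Pointwise sum of the two branches' active-IKK curves."""
    if tlr_out.times.shape != bcr_out.times.shape or not np.allclose(
        tlr_out.times, bcr_out.times
    ):
        raise ValueError("IKK series time grids differ; resample before combining")
    return ReporterSeries(tlr_out.times, tlr_out.values + bcr_out.values, "active IKK (nM)")


def nemo_ikk_input(combined: ReporterSeries, scale: float = IKK_SCALE) -> InterpolatedStimulus:
    """Convert a summed active-IKK curve (nM) to the core model's
    normalised NEMO-IKK input."""
    return InterpolatedStimulus("NEMO_IKK", combined.times, combined.values / scale)


def basal_nemo_ikk_level(
    tlr_spec: ModelSpec, bcr_spec: ModelSpec, scale: float = IKK_SCALE
) -> float:
    """Steady-state combined NEMO-IKK input level (no CpG)."""
    a = run_to_steady_state(tlr_spec).state[tlr_spec.species_index("IKKa")]
    b = run_to_steady_state(bcr_spec).state[bcr_spec.species_index("IKKa")]
    return float((a + b) / scale)
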