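"""The multi-dimer NF-kB core model.

Builds a ModelSpec covering canonical and non-canonical NF-kB signalling
with explicit dimer formation between the five subunits (RelA, RelB, cRel,
p50, p52; p50/p52 arise by processing of their precursors p105/p100):

* per-subunit synthesis (expression-class parameters, the knobs that
  gene-expression scaling and population sampling act on);
* p105 -> p50 processing and NIK-dependent p100 -> p52 processing;
* dimerisation over a configurable dimer set (default: the
  transcriptionally dominant RelA:p50, cRel:p50, RelB:p52 plus the p50:p50
  homodimer that couples the RelA/cRel branches through a shared p50 pool);
* IkBa/IkBe synthesis induced by nuclear canonical dimers (Hill), binding
  of canonical dimers in both compartments, and NEMO-IKK-driven degradation
  of complexed IkB that releases the dimer;
* p100 sequestration of RelB relieved by NIK (the IkBd role of p100);
* carrier-limited nuclear import of free dimers, basal export, and
  constitutive degradation of every protein species.

Inputs: ``NEMO_IKK`` (canonical) and ``NIK`` (non-canonical) activity, on a
normalised scale where the basal table value is the resting level and 1.0
is a saturating stimulus.

The same model ships as authored CSV tables under ``data/core`` together
with a manifest recording counts and the subunit-moiety annotation used by
:func:`total_subunit_abundance`; the tables are written from this builder
and round-trip through the table loader.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import ModelSpec, Parameter, Reaction, Species, Trajectory

SUBUNITS = ("RelA", "RelB", "cRel", "p50", "p52")
PRECURSORS = ("p105", "p100")
#: all 15 unordered pairs of the five subunits
ALL_DIMERS = tuple(
    f"{a}:{b}" for i, a in enumerate(SUBUNITS) for b in SUBUNITS[i:]
)
DEFAULT_DIMERS = ("RelA:p50", "cRel:p50", "RelB:p52", "p50:p50")
#: dimers regulated by IkB binding / NEMO-IKK (canonical)
CANONICAL_DIMERS = ("RelA:p50", "cRel:p50")

#: expression-class parameters per subunit, the targets of 10-fold /
#: z-score scaling experiments
EXPRESSION_PARAMS = {
    "RelA": ("k_syn_rela",),
    "cRel": ("k_syn_crel",),
    "RelB": ("k_syn_relb", "k_ind_relb"),
    "p50": ("k_syn_p105",),
    "p52": ("k_syn_p100",),
}


def canonical_dimer_name(name: str) -> str:
    """Normalise a dimer name to the fixed subunit order of ALL_DIMERS."""
    parts = name.split(":")
    if len(parts) != 2 or any(p not in SUBUNITS for p in parts):
        raise ValueError(f"malformed dimer name {name!r}")
    a, b = sorted(parts, key=SUBUNITS.index)
    return f"{a}:{b}"


def dimer_species_id(dimer: str, nuclear: bool = False) -> str:
    a, b = canonical_dimer_name(dimer).split(":")
    return ("n" if nuclear else "") + a + b


@dataclass(frozen=True)
class CoreModelConfig:
    """Options for the core model build.

    ``dimers`` may be any subset of the 15 possible pairs; pairs outside the
    default set get generic weak association constants. IkB regulation only
    attaches to canonical (RelA/cRel with p50) dimers.
    """

    dimers: tuple[str, ...] = DEFAULT_DIMERS
    relb_induction: bool = True  # canonical dimers induce RelB transcription
    ikb_induction: bool = True
    basal_nemo_ikk: float = 0.05
    basal_nik: float = 0.05

    def __post_init__(self) -> None:
        for d in self.dimers:
            if canonical_dimer_name(d) not in ALL_DIMERS:
                raise ValueError(f"dimer {d!r} outside the implemented set")


# default kinetic constants (nM, hours); authored values, documented in
# docs/methods.md.  "_w" marks the weak generic constants for non-default
# dimer pairs.
DEFAULT_PARAMS: dict[str, tuple[float, str]] = {
    # synthesis (expression)
    "k_syn_rela": (12.0, "expression"),
    "k_syn_crel": (6.0, "expression"),
    "k_syn_relb": (1.5, "expression"),
    "k_syn_p105": (30.0, "expression"),
    "k_syn_p100": (10.0, "expression"),
    "k_syn_ikba": (1.0, "expression"),
    "k_syn_ikbe": (0.3, "expression"),
    # NF-kB-induced synthesis (induction)
    "k_ind_ikba": (360.0, "induction"),
    "k_ind_ikbe": (3.0, "induction"),
    "k_ind_relb": (6.0, "induction"),
    "K_nfkb": (12.0, "induction"),
    "n_nfkb": (4.0, "induction"),
    # processing (catalysis)
    "k_proc_p105": (0.6, "catalysis"),
    "k_proc_p100": (2.0, "catalysis"),
    # IKK-dependent complexed-IkB degradation (catalysis, per input unit/h)
    "k_ikk_ikba": (12.0, "catalysis"),
    "k_ikk_ikbe": (0.05, "catalysis"),
    # basal complexed-IkB turnover releasing the dimer
    "k_turn_ikb": (0.06, "catalysis"),
    # IKK-dependent free-IkB degradation
    "k_ikk_ikba_free": (12.0, "catalysis"),
    "k_ikk_ikbe_free": (0.1, "catalysis"),
    # dimerisation (binding, /nM/h and /h); cRel:p50 binds much tighter
    # than RelA:p50, so the cRel dimer pool is saturated in p50 and
    # insensitive to the free-p50 surge that follows an IKK stimulus
    "k_on_a50": (0.12, "binding"),
    "k_off_a50": (3.0, "binding"),
    "k_on_c50": (1.2, "binding"),
    "k_off_c50": (0.3, "binding"),
    "k_on_b52": (0.12, "binding"),
    "k_off_b52": (3.0, "binding"),
    "k_on_p50_p50": (0.03, "binding"),
    "k_off_p50_p50": (3.0, "binding"),
    "k_on_dimer_w": (0.006, "binding"),
    "k_off_dimer_w": (6.0, "binding"),
    "k_on_p100_relb": (0.06, "binding"),
    "k_off_p100_relb": (0.6, "binding"),
    # IkB-dimer association, cytoplasmic and nuclear capture (binding).
    # RelA:p50 is held mainly by the strongly IKK-sensitive IkBa while
    # cRel:p50 is held mainly by the weakly IKK-sensitive IkBe, which is
    # what makes the stimulated response RelA-dominated.
    "k_b_ikba_a50": (5.0, "binding"),
    "k_b_ikba_c50": (0.005, "binding"),
    "k_b_ikbe_a50": (0.005, "binding"),
    "k_b_ikbe_c50": (0.5, "binding"),
    "k_cap_ikba_a50": (8.0, "binding"),
    "k_cap_ikba_c50": (0.3, "binding"),
    "k_cap_ikbe_a50": (0.3, "binding"),
    "k_cap_ikbe_c50": (8.0, "binding"),
    # carrier-limited nuclear import, per dimer (Vmax nM/h, Km nM);
    # cRel:p50 import runs near saturation, buffering its nuclear level
    # against expression changes and stimulus
    "k_imp_a50": (120.0, "transport"),
    "K_imp_a50": (800.0, "transport"),
    "k_imp_c50": (30.0, "transport"),
    "K_imp_c50": (100.0, "transport"),
    "k_imp_generic": (30.0, "transport"),
    "K_imp_generic": (300.0, "transport"),
    "k_exp_dimer": (0.05, "transport"),
    # degradation
    "k_deg_monomer": (0.12, "degradation"),
    "k_deg_ikb_free": (1.2, "degradation"),
    "k_deg_dimer": (0.02, "degradation"),
    "k_deg_complex": (0.02, "degradation"),
}

MONOMER_SPECIES = {
    "RelA": "RelA",
    "cRel": "cRel",
    "RelB": "RelB",
    "p50": "p50",
    "p52": "p52",
}


def build_nfkb_model(config: CoreModelConfig | None = None) -> ModelSpec:
    """Assemble the core NF-kB ModelSpec for the given configuration."""
    cfg = config or CoreModelConfig()
    dimers = tuple(canonical_dimer_name(d) for d in cfg.dimers)
    if len(set(dimers)) != len(dimers):
        raise ValueError("duplicate dimers in config")

    species: list[Species] = []
    reactions: list[Reaction] = []
    params = dict(DEFAULT_PARAMS)
    params["NEMO_IKK"] = (cfg.basal_nemo_ikk, "input")
    params["NIK"] = (cfg.basal_nik, "input")

    def sp(name: str, compartment: str = "cytoplasm") -> None:
        species.append(Species(name, compartment, 0.0))

    for m in ("RelA", "cRel", "RelB", "p105", "p50", "p100", "p52", "IkBa", "IkBe"):
        sp(m)
    sp("p100_RelB")
    for d in dimers:
        sp(dimer_species_id(d))
        sp(dimer_species_id(d, nuclear=True), "nucleus")
    canonical_present = [d for d in dimers if d in CANONICAL_DIMERS]
    ikb_tags = {"RelA:p50": "a50", "cRel:p50": "c50"}
    for d in canonical_present:
        for ikb in ("IkBa", "IkBe"):
            sp(f"{ikb}_{dimer_species_id(d)}")
    nuclear_canonical = [dimer_species_id(d, nuclear=True) for d in canonical_present]

    rx = reactions.append
    # --- synthesis -------------------------------------------------------
    rx(Reaction("syn_rela", {}, {"RelA": 1}, "constant_source", ("k_syn_rela",)))
    rx(Reaction("syn_crel", {}, {"cRel": 1}, "constant_source", ("k_syn_crel",)))
    rx(Reaction("syn_relb", {}, {"RelB": 1}, "constant_source", ("k_syn_relb",)))
    rx(Reaction("syn_p105", {}, {"p105": 1}, "constant_source", ("k_syn_p105",)))
    rx(Reaction("syn_p100", {}, {"p100": 1}, "constant_source", ("k_syn_p100",)))
    rx(Reaction("syn_ikba", {}, {"IkBa": 1}, "constant_source", ("k_syn_ikba",)))
    rx(Reaction("syn_ikbe", {}, {"IkBe": 1}, "constant_source", ("k_syn_ikbe",)))
    if cfg.ikb_induction and nuclear_canonical:
        # IkBa is predominantly a RelA:p50 target gene, IkBe a cRel target;
        # this wiring lets free IkBa collapse during a canonical stimulus
        # (the RelA:p50 pulse) while IkBe holds cRel:p50 in check.
        ikba_drivers = tuple(d for d in ("nRelAp50",) if d in nuclear_canonical) or tuple(nuclear_canonical)
        ikbe_drivers = tuple(d for d in ("ncRelp50",) if d in nuclear_canonical) or tuple(nuclear_canonical)
        rx(Reaction("ind_ikba", {}, {"IkBa": 1}, "hill_activation",
                    ("k_ind_ikba", "K_nfkb", "n_nfkb"), ikba_drivers))
        rx(Reaction("ind_ikbe", {}, {"IkBe": 1}, "hill_activation",
                    ("k_ind_ikbe", "K_nfkb", "n_nfkb"), ikbe_drivers))
    if cfg.relb_induction and nuclear_canonical:
        rx(Reaction("ind_relb", {}, {"RelB": 1}, "hill_activation",
                    ("k_ind_relb", "K_nfkb", "n_nfkb"), tuple(nuclear_canonical)))

    # --- processing ------------------------------------------------------
    rx(Reaction("proc_p105", {"p105": 1}, {"p50": 1}, "mass_action", ("k_proc_p105",)))
    rx(Reaction("proc_p100", {"p100": 1}, {"p52": 1}, "activation", ("k_proc_p100",), ("NIK",)))
    rx(Reaction("proc_p100_relb", {"p100_RelB": 1}, {"RelB": 1, "p52": 1},
                "activation", ("k_proc_p100",), ("NIK",)))

    # --- dimerisation ----------------------------------------------------
    for d in dimers:
        a, b = d.split(":")
        did = dimer_species_id(d)
        named = {"p50:p50": ("k_on_p50_p50", "k_off_p50_p50"),
                 "RelA:p50": ("k_on_a50", "k_off_a50"),
                 "cRel:p50": ("k_on_c50", "k_off_c50"),
                 "RelB:p52": ("k_on_b52", "k_off_b52")}
        kon, koff = named.get(d, ("k_on_dimer_w", "k_off_dimer_w"))
        reactants = {a: 2} if a == b else {MONOMER_SPECIES[a]: 1, MONOMER_SPECIES[b]: 1}
        tag = did.lower()
        rx(Reaction(f"dim_{tag}_f", reactants, {did: 1}, "mass_action", (kon,)))
        rx(Reaction(f"dim_{tag}_r", {did: 1}, reactants, "mass_action", (koff,)))
    rx(Reaction("seq_relb", {"p100": 1, "RelB": 1}, {"p100_RelB": 1},
                "mass_action", ("k_on_p100_relb",)))
    rx(Reaction("seq_relb_r", {"p100_RelB": 1}, {"p100": 1, "RelB": 1},
                "mass_action", ("k_off_p100_relb",)))

    # --- IkB binding, capture, and IKK-driven release --------------------
    for d in canonical_present:
        did = dimer_species_id(d)
        nid = dimer_species_id(d, nuclear=True)
        tag = ikb_tags[d]
        for ikb, short in (("IkBa", "ikba"), ("IkBe", "ikbe")):
            cplx = f"{ikb}_{did}"
            rx(Reaction(f"bind_{short}_{tag}", {ikb: 1, did: 1}, {cplx: 1},
                        "mass_action", (f"k_b_{short}_{tag}",)))
            rx(Reaction(f"cap_{short}_{tag}", {ikb: 1, nid: 1}, {cplx: 1},
                        "mass_action", (f"k_cap_{short}_{tag}",)))
            rx(Reaction(f"rel_{short}_{tag}", {cplx: 1}, {did: 1},
                        "activation", (f"k_ikk_{short}",), ("NEMO_IKK",)))
            rx(Reaction(f"turn_{short}_{tag}", {cplx: 1}, {did: 1},
                        "mass_action", ("k_turn_ikb",)))
    rx(Reaction("deg_ikba_ikk", {"IkBa": 1}, {}, "activation",
                ("k_ikk_ikba_free",), ("NEMO_IKK",)))
    rx(Reaction("deg_ikbe_ikk", {"IkBe": 1}, {}, "activation",
                ("k_ikk_ikbe_free",), ("NEMO_IKK",)))

    # --- transport -------------------------------------------------------
    import_params = {"RelA:p50": ("k_imp_a50", "K_imp_a50"), "cRel:p50": ("k_imp_c50", "K_imp_c50")}
    for d in dimers:
        did = dimer_species_id(d)
        nid = dimer_species_id(d, nuclear=True)
        tag = did.lower()
        vmax, km = import_params.get(d, ("k_imp_generic", "K_imp_generic"))
        rx(Reaction(f"imp_{tag}", {did: 1}, {nid: 1}, "hill_activation",
                    (vmax, km, "n_imp_one"), (did,)))
        rx(Reaction(f"exp_{tag}", {nid: 1}, {did: 1}, "mass_action", ("k_exp_dimer",)))
    params["n_imp_one"] = (1.0, "transport")

    # --- constitutive degradation ---------------------------------------
    for m in ("RelA", "cRel", "RelB", "p105", "p50", "p100", "p52"):
        rx(Reaction(f"deg_{m.lower()}", {m: 1}, {}, "mass_action", ("k_deg_monomer",)))
    for ikb in ("IkBa", "IkBe"):
        rx(Reaction(f"deg_{ikb.lower()}", {ikb: 1}, {}, "mass_action", ("k_deg_ikb_free",)))
    for d in dimers:
        for nuclear in (False, True):
            sid = dimer_species_id(d, nuclear)
            rx(Reaction(f"deg_{sid.lower()}", {sid: 1}, {}, "mass_action", ("k_deg_dimer",)))
    for d in canonical_present:
        for ikb in ("IkBa", "IkBe"):
            cplx = f"{ikb}_{dimer_species_id(d)}"
            rx(Reaction(f"deg_{cplx.lower()}", {cplx: 1}, {}, "mass_action", ("k_deg_complex",)))
    rx(Reaction("deg_p100_relb", {"p100_RelB": 1}, {}, "mass_action", ("k_deg_complex",)))

    parameters = tuple(Parameter(n, v, c) for n, (v, c) in params.items())
    return ModelSpec(tuple(species), parameters, tuple(reactions))


# ---------------------------------------------------------------------------
# packaged tables


def packaged_data_dir():
    from importlib.resources import files

    return files("nfkbfp") / "data"


def load_packaged_model(which: str = "core") -> ModelSpec:
    """Load one of the shipped model-table sets (core, tlr, bcr)."""
    from .network import load_model_tables

    d = packaged_data_dir() / which
    if not d.is_dir():
        raise FileNotFoundError(f"no packaged model {which!r}")
    return load_model_tables(d / "species.csv", d / "parameters.csv", d / "reactions.csv")


def load_manifest() -> dict:
    import json

    return json.loads((packaged_data_dir() / "manifest.json").read_text())


# ---------------------------------------------------------------------------
# reporters


def subunit_moiety_map(spec: ModelSpec) -> dict[str, dict[str, int]]:
    """Map each subunit to {species: copies of that subunit it contains}.

    Precursors carry one copy of their product subunit (p105 -> p50,
    p100 -> p52), so per-subunit totals are conserved under processing.
    """
    names = set(spec.species_names)
    moieties: dict[str, dict[str, int]] = {s: {} for s in SUBUNITS}

    def add(subunit: str, species: str, k: int = 1) -> None:
        if species in names:
            moieties[subunit][species] = moieties[subunit].get(species, 0) + k

    for su in ("RelA", "cRel", "RelB"):
        add(su, su)
    add("p50", "p50"), add("p50", "p105")
    add("p52", "p52"), add("p52", "p100")
    add("RelB", "p100_RelB"), add("p52", "p100_RelB")
    for d in ALL_DIMERS:
        did = dimer_species_id(d)
        if did not in names:
            continue
        a, b = d.split(":")
        for sid in (did, "n" + did):
            add(a, sid)
            add(b, sid)
        for cplx_prefix in ("IkBa_", "IkBe_"):
            cplx = cplx_prefix + did
            if cplx in names:
                add(a, cplx)
                add(b, cplx)
    return moieties


def total_subunit_abundance(state: np.ndarray, subunit: str, spec: ModelSpec) -> float:
    """Total protein content of one subunit over all species (nM).

    Counts stoichiometry: a homodimer contributes two copies per molecule.
    This is the quantity a fixed/permeabilised total-protein stain sees.
    """
    if subunit in PRECURSORS:
        return float(state[spec.species_index(subunit)])
    if subunit not in SUBUNITS:
        raise KeyError(f"unknown subunit {subunit!r}")
    state = np.asarray(state, dtype=float)
    if state.shape[-1] != len(spec.species):
        raise ValueError("state dimension does not match spec")
    moieties = subunit_moiety_map(spec)[subunit]
    idx = np.array([spec.species_index(s) for s in moieties], dtype=np.intp)
    w = np.array(list(moieties.values()), dtype=float)
    return float(state[..., idx] @ w)


@dataclass(frozen=True)
class ReporterSeries:
    times: np.ndarray
    values: np.ndarray
    reporter: str

    def __post_init__(self) -> None:
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must match")


def nuclear_dimer_series(traj: Trajectory, dimer: str) -> ReporterSeries:
    """Free nuclear concentration of one dimer along a trajectory."""
    sid = dimer_species_id(dimer, nuclear=True)
    if sid not in traj.spec.species_names:
        raise KeyError(f"dimer {dimer!r} not in this model")
    return ReporterSeries(traj.times, traj.series(sid), f"nuclear {canonical_dimer_name(dimer)}")


def total_subunit_series(traj: Trajectory, subunit: str) -> ReporterSeries:
    values = np.array(
        [total_subunit_abundance(traj.states[i], subunit, traj.spec) for i in range(len(traj.times))]
    )
    return ReporterSeries(traj.times, values, f"total {subunit}")
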