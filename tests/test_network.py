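"""Reaction-network layer: table I/O, RHS assembly, integration, steady state."""

import numpy as np
import pandas as pd
import pytest

from nfkbfp.core_model import load_manifest, load_packaged_model
from nfkbfp.network import (
    CompiledModel,
    IntegrationError,
    ModelSpec,
    ModelValidationError,
    Parameter,
    Reaction,
    Species,
    StimulusProfile,
    assemble_rhs,
    constant_input,
    integrate,
    load_model_tables,
    run_to_steady_state,
    write_model_tables,
)

from conftest import make_binding, make_birth_death


# ---------------------------------------------------------------------------
# tables


def _write_minimal(tmp_path, reactions_rows=None, params_rows=None):
    (tmp_path / "species.csv").write_text(
        "name,compartment,initial_amount\nA,cytoplasm,1.0\nB,cytoplasm,0.0\n"
    )
    (tmp_path / "parameters.csv").write_text(
        "name,value,param_class\n" + (params_rows or "k,0.5,catalysis\n")
    )
    (tmp_path / "reactions.csv").write_text(
        "name,reactants,products,rate_law,parameters,modifiers\n"
        + (reactions_rows or "conv,A,B,mass_action,k,\n")
    )
    return (
        tmp_path / "species.csv",
        tmp_path / "parameters.csv",
        tmp_path / "reactions.csv",
    )


class TestModelTables:
    def test_minimal_tables_load(self, tmp_path):
        spec = load_model_tables(*_write_minimal(tmp_path))
        assert len(spec.species) == 2
        assert len(spec.reactions) == 1
        assert len(spec.parameters) == 1

    def test_unresolved_parameter_names_the_row(self, tmp_path):
        paths = _write_minimal(tmp_path, reactions_rows="conv,A,B,mass_action,k_missing,\n")
        with pytest.raises(ModelValidationError, match="k_missing"):
            load_model_tables(*paths)

    def test_negative_value_rejected(self, tmp_path):
        paths = _write_minimal(tmp_path, params_rows="k,-0.5,catalysis\n")
        with pytest.raises(ModelValidationError, match="row 1"):
            load_model_tables(*paths)

    def test_unknown_column_rejected(self, tmp_path):
        paths = _write_minimal(tmp_path)
        extra = paths[0].read_text().replace(
            "name,compartment,initial_amount", "name,compartment,initial_amount,bogus"
        ).replace("A,cytoplasm,1.0", "A,cytoplasm,1.0,7")
        paths[0].write_text(extra)
        with pytest.raises(ModelValidationError, match="bogus"):
            load_model_tables(*paths)

    def test_comments_ignored(self, tmp_path):
        paths = _write_minimal(tmp_path)
        paths[1].write_text("# rate constants\n" + paths[1].read_text())
        assert len(load_model_tables(*paths).parameters) == 1

    def test_roundtrip(self, tmp_path, core_spec):
        write_model_tables(core_spec, tmp_path)
        rt = load_model_tables(
            tmp_path / "species.csv", tmp_path / "parameters.csv", tmp_path / "reactions.csv"
        )
        assert rt == core_spec

    def test_packaged_tables_match_manifest(self):
        man = load_manifest()
        for which in ("core", "tlr", "bcr"):
            spec = load_packaged_model(which)
            assert len(spec.species) == man[which]["n_species"]
            assert len(spec.parameters) == man[which]["n_parameters"]
            assert len(spec.reactions) == man[which]["n_reactions"]


# ---------------------------------------------------------------------------
# RHS assembly


class TestAssembleRhs:
    def test_linear_decay(self):
        spec = ModelSpec(
            (Species("A", "cytoplasm", 2.0),),
            (Parameter("k", 0.5, "degradation"),),
            (Reaction("deg", {"A": 1}, {}, "mass_action", ("k",)),),
        )
        f = assemble_rhs(spec)
        assert f([2.0], 0.0) == pytest.approx([-1.0])

    def test_constant_source_ignores_state(self):
        spec = ModelSpec(
            (Species("A", "cytoplasm", 0.0),),
            (Parameter("k", 3.0, "expression"),),
            (Reaction("syn", {}, {"A": 1}, "constant_source", ("k",)),),
        )
        f = assemble_rhs(spec)
        for a in (0.0, 1.0, 100.0):
            assert f([a], 0.0) == pytest.approx([3.0])

    def test_binding_matches_hand_coded_oracle(self):
        k_on, k_off = 2.0, 0.5
        spec = make_binding(k_on, k_off)
        f = assemble_rhs(spec)
        rng = np.random.default_rng(0)
        for _ in range(10):
            a, b, ab = rng.uniform(0, 10, 3)
            # independent hand mass-action: one term per reaction
            v_on = k_on * a * b
            v_off = k_off * ab
            expected = [-v_on + v_off, -v_on + v_off, v_on - v_off]
            assert f([a, b, ab], 0.0) == pytest.approx(expected)

    def test_state_length_mismatch_raises(self, binding_model):
        f = assemble_rhs(binding_model)
        with pytest.raises(ValueError, match="length"):
            f([1.0, 2.0], 0.0)

    def test_core_rhs_equals_per_reaction_oracle(self, core_spec, core_model):
        """Assembled derivatives equal an independent per-reaction hand
        evaluation (stoichiometry x rate law applied literally)."""
        rng = np.random.default_rng(42)
        names = core_spec.species_names
        values = core_spec.parameter_values()
        inputs = {p.name: p.value for p in core_spec.parameters if p.param_class == "input"}
        for _ in range(5):
            state = rng.uniform(0, 50, len(names))
            lookup = dict(zip(names, state))
            lookup.update(inputs)
            expected = np.zeros(len(names))
            for rx in core_spec.reactions:
                k = values[rx.parameter_refs[0]]
                if rx.rate_law == "constant_source":
                    rate = k
                elif rx.rate_law == "mass_action":
                    rate = k
                    for s, st in rx.reactants.items():
                        rate *= lookup[s] ** st
                elif rx.rate_law == "activation":
                    rate = k
                    for s, st in rx.reactants.items():
                        rate *= lookup[s] ** st
                    for m in rx.modifiers:
                        rate *= lookup[m]
                else:  # hill_activation
                    K, n = values[rx.parameter_refs[1]], values[rx.parameter_refs[2]]
                    M = sum(lookup[m] for m in rx.modifiers)
                    rate = k * M**n / (K**n + M**n)
                for s, st in rx.reactants.items():
                    expected[names.index(s)] -= st * rate
                for s, st in rx.products.items():
                    expected[names.index(s)] += st * rate
            got = core_model.rhs(0.0, state)
            np.testing.assert_allclose(got, expected, rtol=1e-12, atol=1e-12)


# ---------------------------------------------------------------------------
# integration


class TestIntegrate:
    def test_pure_decay_closed_form(self):
        spec = ModelSpec(
            (Species("A", "cytoplasm", 1.0),),
            (Parameter("k", 1.0, "degradation"),),
            (Reaction("deg", {"A": 1}, {}, "mass_action", ("k",)),),
        )
        traj = integrate(spec, [1.0], t_span=(0, 5), rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(traj.series("A"), np.exp(-traj.times), atol=1e-6)

    def test_dimerisation_conserves_monomer_mass(self, binding_model):
        traj = integrate(binding_model, [5.0, 3.0, 0.0], t_span=(0, 10), rtol=1e-9, atol=1e-12)
        total_a = traj.series("A") + traj.series("AB")
        total_b = traj.series("B") + traj.series("AB")
        np.testing.assert_allclose(total_a, 5.0, atol=1e-6)
        np.testing.assert_allclose(total_b, 3.0, atol=1e-6)

    def test_equilibrium_matches_kd(self):
        k_on, k_off = 3.0, 1.2
        spec = make_binding(k_on, k_off, a0=4.0, b0=6.0)
        res = run_to_steady_state(spec)
        a, b, ab = res.state
        kd = k_off / k_on
        # closed form: AB* solves (A0-AB)(B0-AB) = Kd*AB
        from numpy.polynomial import polynomial as P

        roots = np.roots([1.0, -(4.0 + 6.0 + kd), 4.0 * 6.0])
        ab_expected = roots[(roots > 0) & (roots < 4.0)][0]
        assert ab == pytest.approx(ab_expected, rel=1e-4)
        assert a * b / ab == pytest.approx(kd, rel=1e-4)

    def test_negative_initial_state_rejected(self, binding_model):
        with pytest.raises(ValueError):
            integrate(binding_model, [-1.0, 0.0, 0.0])

    def test_trajectories_stay_nonnegative(self, core_model, core_steady):
        stim = {"NEMO_IKK": StimulusProfile("NEMO_IKK", ((0.0, 8.0, 1.0),))}
        traj = integrate(core_model, core_steady, stim, (0, 8))
        assert traj.states.min() >= 0.0


class TestSteadyState:
    def test_birth_death_analytic(self, birth_death):
        res = run_to_steady_state(birth_death)
        assert res.converged
        assert res.state[0] == pytest.approx(2.0 / 0.5, rel=1e-6)

    def test_unique_attractor_from_random_initials(self, birth_death):
        rng = np.random.default_rng(3)
        states = [
            run_to_steady_state(birth_death, initial_state=[x0]).state[0]
            for x0 in rng.uniform(0, 50, 2)
        ]
        assert states[0] == pytest.approx(states[1], abs=1e-4)

    def test_core_steady_state_self_consistent(self, core_model, core_steady):
        """Re-integrating 100 h from the steady state moves nothing by >1%."""
        traj = integrate(core_model, core_steady, None, (0, 100))
        final = traj.final_state()
        scale = np.abs(core_steady) + 1e-6
        assert np.max(np.abs(final - core_steady) / scale) < 0.01

    def test_steady_state_requires_constant_input(self, core_model):
        varying = {"NEMO_IKK": StimulusProfile("NEMO_IKK", ((0, 1, 0.1), (1, 2, 0.9)))}
        with pytest.raises(ValueError, match="constant"):
            run_to_steady_state(core_model, basal_input=varying)


class TestStimulusProfile:
    def test_piecewise_lookup(self):
        s = StimulusProfile("x", ((0.0, 1.0, 0.2), (1.0, 4.0, 0.9)))
        assert s(0.5) == 0.2
        assert s(2.0) == 0.9
        assert s(10.0) == 0.9  # clamped to last segment

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ModelValidationError):
            StimulusProfile("x", ((0.0, 2.0, 0.2), (1.0, 3.0, 0.9)))
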