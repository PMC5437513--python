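"""Unit tests for the reaction network, rate laws and observables."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ferrokin as fk
from ferrokin.model import (
    LABEL_SWAP,
    PLAIN_SPECIES,
    SPECIES,
    ConfigurationError,
    ParameterSet,
    build_model,
    ferroportin_rate,
    mass_action_flux,
    tf_binding_flux,
    tf_total,
    total_iron,
    tf_saturation,
    labeled_iron_mol,
)


# ---------------------------------------------------------------------------
# Elementary rate laws
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("S,Ic,Hep,V,Km,Ki,vol,expected", [
    (0.0, 0.0, 0.0, 1.0, 0.01, 1e-9, 1e-3, 0.0),          # no substrate
    (0.01, 0.0, 0.0, 1.0, 0.01, 1e-9, 1e-3, 5.0e-4),      # hand evaluation
])
def test_ferroportin_rate_values(S, Ic, Hep, V, Km, Ki, vol, expected):
    assert ferroportin_rate(S, Ic, Hep, V, Km, Ki, vol) == pytest.approx(expected)


def test_ferroportin_hepcidin_at_ki_halves_flux():
    base = ferroportin_rate(1e-3, 2e-4, 0.0, 0.5, 0.0159, 2.3e-8, 6.7e-5)
    half = ferroportin_rate(1e-3, 2e-4, 2.3e-8, 0.5, 0.0159, 2.3e-8, 6.7e-5)
    assert half == pytest.approx(base / 2.0, rel=1e-14)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(S=st.floats(1e-9, 1e-2), Ic=st.floats(1e-9, 1e-2),
       Hep=st.floats(0, 1e-6))
def test_ferroportin_rate_nonnegative_and_label_symmetric(S, Ic, Hep):
    v = ferroportin_rate(S, Ic, Hep, 0.2, 0.0159, 1e-9, 3.9e-5)
    v_swapped = ferroportin_rate(Ic, S, Hep, 0.2, 0.0159, 1e-9, 3.9e-5)
    assert v >= 0.0
    # swapping substrate and competing twin gives the companion reaction:
    # both share the same denominator
    assert v / S == pytest.approx(v_swapped / Ic, rel=1e-12)


@pytest.mark.parametrize("k,S,vol,expected", [
    (1.0, 0.0, 1.0, 0.0),
    (1.0, 1.0, 1.0, 1.0),
    (0.0235, 0.01, 7.9e-4, 1.8565e-7),
])
def test_mass_action_flux(k, S, vol, expected):
    assert mass_action_flux(k, S, vol) == pytest.approx(expected, rel=1e-12)


def test_tf_binding_flux_hand_value_and_shared_constant():
    v = tf_binding_flux(1.08e9, 3.3e-8, 1e-6, 1.3e-3)
    assert v == pytest.approx(4.633e-8, rel=1e-3)
    assert tf_binding_flux(1.08e9, 0.0, 1e-6, 1.3e-3) == 0.0
    # the labeled reaction uses the very same constant
    assert tf_binding_flux(1.08e9, 3.3e-8, 1e-6, 1.3e-3) == \
        tf_binding_flux(1.08e9, 3.3e-8, 1e-6, 1.3e-3)


# ---------------------------------------------------------------------------
# Network assembly
# ---------------------------------------------------------------------------

def test_species_sets(params6):
    tracer = build_model(params6, include_tracer=True)
    plain = build_model(params6, include_tracer=False)
    assert tuple(tracer.species) == SPECIES
    assert tuple(plain.species) == PLAIN_SPECIES
    assert not any("*" in s for s in plain.species)
    assert "FeOutside*" not in plain.species


def test_tracer_duplication_reaction_count(params6):
    tracer = build_model(params6, include_tracer=True)
    plain = build_model(params6, include_tracer=False)
    # every iron reaction is mirrored, plus the cross-label Tf bindings
    assert len(tracer.reactions) >= 2 * len(plain.reactions)


def test_rbc_has_no_plasma_import(tracer_model):
    """Red cells acquire all their iron in the marrow, never from plasma."""
    plasma_species = {s for s in SPECIES if s.startswith(("NTBI", "Fe1Tf", "Fe2Tf"))}
    for r in tracer_model.reactions:
        produces_rbc = any(s.startswith("FeRBC") and nu > 0
                           for s, nu in r.stoich.items())
        if produces_rbc:
            assert not any(s in plasma_species for s in r.stoich), r.name


def test_missing_parameter_is_named():
    d = fk.fixture_table2(6).to_dict()
    del d["kInDuo"]
    with pytest.raises(ConfigurationError, match="kInDuo"):
        ParameterSet.from_dict(d)
    with pytest.raises(ConfigurationError, match="bogus"):
        ParameterSet.from_dict({**fk.fixture_table2(6).to_dict(), "bogus": 1.0})


def test_nonpositive_parameter_rejected(params6):
    with pytest.raises(ConfigurationError, match="vDiet"):
        params6.replace(vDiet=0.0)


# ---------------------------------------------------------------------------
# Right-hand side consistency and conservation laws
# ---------------------------------------------------------------------------

def _random_state(model, rng):
    y = rng.uniform(0.0, 1e-4, size=model.n_species)
    y[model.index("Hepcidin")] = rng.uniform(0, 1e-7)
    return y


@pytest.mark.parametrize("include_tracer", [True, False])
def test_compiled_rhs_matches_reaction_bookkeeping(params6, include_tracer, rng):
    """The compiled RHS and the reaction-by-reaction sum agree exactly."""
    model = build_model(params6, include_tracer=include_tracer)
    for _ in range(5):
        y = _random_state(model, rng)
        np.testing.assert_allclose(model.rhs(0.0, y),
                                   model.rhs_reference(0.0, y),
                                   rtol=1e-12, atol=1e-30)


def test_label_swap_commutes_with_rhs(tracer_model, rng):
    """Relabeling all tracer/non-tracer twins commutes with the dynamics.

    The only label-asymmetric process is the dietary influx, which by
    design feeds unlabeled iron only; subtracting that known term, the
    two evaluation orders agree exactly.
    """
    perm = np.array([tracer_model.index(LABEL_SWAP[s])
                     for s in tracer_model.species])
    diet_term = np.zeros(tracer_model.n_species)
    diet_term[tracer_model.index("FeDuo")] = tracer_model.params.vDiet
    diet_term[tracer_model.index("FeDuo*")] = -tracer_model.params.vDiet
    for _ in range(5):
        y = _random_state(tracer_model, rng)
        d_then_swap = tracer_model.rhs(0.0, y)[perm]
        swap_then_d = tracer_model.rhs(0.0, y[perm])
        np.testing.assert_allclose(swap_then_d - d_then_swap, diet_term,
                                   rtol=1e-9, atol=1e-12)


def test_transferrin_conserved_by_stoichiometry(tracer_model, rng):
    """d(total Tf)/dt vanishes identically: Tf is only shuttled."""
    ix = tracer_model.index
    tf_idx = [ix(s) for s in ("Tf", "Fe1Tf", "Fe1Tf*", "Fe2Tf", "Fe2Tf*",
                              "Fe2Tf**")]
    for _ in range(5):
        y = _random_state(tracer_model, rng)
        dydt = tracer_model.rhs(0.0, y)
        contributions = np.abs(dydt[tf_idx]).max()
        assert abs(dydt[tf_idx].sum()) <= 1e-10 * max(contributions, 1e-30)


def test_total_iron_balance_is_diet_influx(tracer_model, rng):
    """d(total iron incl. excreted)/dt telescopes to vDiet * V_duodenum."""
    from ferrokin.model import IRON_CONTENT, SPECIES_COMPARTMENT
    p = tracer_model.params
    expected = p.vDiet * tracer_model.compartments["duodenum"].volume
    for _ in range(5):
        y = _random_state(tracer_model, rng)
        dydt = tracer_model.rhs(0.0, y)
        total = 0.0
        for i, s in enumerate(tracer_model.species):
            vol = (1.0 if SPECIES_COMPARTMENT[s] == "outside"
                   else tracer_model.volume(s))
            total += IRON_CONTENT[s] * dydt[i] * vol
        assert total == pytest.approx(expected, rel=1e-9)


def test_zero_iron_state_only_duodenum_grows(tracer_model):
    """With no iron anywhere and hepcidin at balance, only diet flows."""
    y = np.zeros(tracer_model.n_species)
    p = tracer_model.params
    y[tracer_model.index("Tf")] = p.TfTotal
    y[tracer_model.index("Hepcidin")] = p.kHepSyn / p.kHepDeg
    dydt = tracer_model.rhs(0.0, y)
    duo = tracer_model.index("FeDuo")
    assert dydt[duo] > 0
    mask = np.ones(tracer_model.n_species, bool)
    mask[duo] = False
    np.testing.assert_allclose(dydt[mask], 0.0, atol=1e-25)


def test_rhs_rejects_nonfinite_state(tracer_model):
    y = np.zeros(tracer_model.n_species)
    y[0] = np.nan
    with pytest.raises(FloatingPointError):
        tracer_model.rhs_reference(0.0, y)


# ---------------------------------------------------------------------------
# Observables
# ---------------------------------------------------------------------------

def test_total_iron_examples(tracer_model):
    y = np.zeros(tracer_model.n_species)
    assert total_iron(y, tracer_model) == 0.0
    y[tracer_model.index("FeRBC")] = 0.01
    assert total_iron(y, tracer_model) == pytest.approx(0.4412, rel=1e-3)
    y[:] = 0.0
    y[tracer_model.index("Fe2Tf")] = 1e-5
    # di-ferric transferrin carries two iron ions
    expected = 2 * 1e-5 * 1.3e-3 * 55.845 * 1e3
    assert total_iron(y, tracer_model) == pytest.approx(expected, rel=1e-12)


def test_excreted_iron_excluded_unless_requested(tracer_model):
    y = np.zeros(tracer_model.n_species)
    y[tracer_model.index("FeOutside")] = 1e-6  # amount, mol
    assert total_iron(y, tracer_model) == 0.0
    assert total_iron(y, tracer_model, include_outside=True) == \
        pytest.approx(1e-6 * 55.845 * 1e3)


def test_tf_saturation_examples(tracer_model):
    y = np.zeros(tracer_model.n_species)
    assert tf_saturation(y, tracer_model) == 0.0
    y[tracer_model.index("Fe2Tf")] = tracer_model.params.TfTotal
    assert tf_saturation(y, tracer_model) == pytest.approx(100.0)
    y[:] = 0.0
    y[tracer_model.index("Fe1Tf")] = 1e-5
    y[tracer_model.index("Fe2Tf")] = 1e-5
    assert tf_saturation(y, tracer_model) == pytest.approx(38.76, abs=0.01)


def test_mixed_diferric_counts_one_label(tracer_model):
    y = np.zeros(tracer_model.n_species)
    y[tracer_model.index("Fe2Tf*")] = 1e-6
    y[tracer_model.index("Fe2Tf**")] = 1e-6
    vp = tracer_model.compartments["plasma"].volume
    assert labeled_iron_mol(y, tracer_model) == pytest.approx(3e-6 * vp)


def test_tf_total_helper(tracer_model, rng):
    y = _random_state(tracer_model, rng)
    ix = tracer_model.index
    manual = sum(y[ix(s)] for s in ("Tf", "Fe1Tf", "Fe1Tf*", "Fe2Tf",
                                    "Fe2Tf*", "Fe2Tf**"))
    assert tf_total(y, tracer_model) == pytest.approx(manual, rel=1e-15)
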