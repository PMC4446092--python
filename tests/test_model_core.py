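"""Pointwise kinetics: stoichiometry, conservation, rate scaling, presets."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from minosc import model_core as mc

conc = st.floats(min_value=0.0, max_value=5e3)
rate = st.floats(min_value=0.0, max_value=50.0)


def state(**kw) -> mc.PointState:
    return mc.PointState(**kw)


class TestMembraneReactionRates:
    def test_zero_state_gives_zero_derivatives(self):
        out = mc.membrane_reaction_rates(state(), mc.RateParameters())
        assert all(v == 0 for v in out)

    def test_dimerisation_stoichiometry(self):
        # one membrane monomer at 1 um^-2: two monomers consumed per dimer made
        p = mc.RateParameters(omega_dim=0.002, omega_db=0, omega_edf=0,
                              omega_hydr=0, omega_eb=0, omega_er=0)
        out = mc.membrane_reaction_rates(state(d=1.0), p)
        assert out.d == pytest.approx(-0.004)
        assert out.d2 == pytest.approx(0.002)

    def test_heterotetramer_formation_bilinear_term(self):
        p = mc.RateParameters(omega_edf=22.0, omega_db=0, omega_dim=0,
                              omega_hydr=0, omega_eb=0, omega_er=0)
        out = mc.membrane_reaction_rates(state(d2=2.0, e2=1.0), p)
        assert out.d2e2 == pytest.approx(44.0)
        assert out.d2 == pytest.approx(-44.0)
        assert out.e2 == pytest.approx(-44.0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            mc.membrane_reaction_rates(state(d=-1.0), mc.RateParameters())

    def test_vectorised_over_arrays(self):
        p = mc.RateParameters()
        s = state(d=np.array([0.0, 1.0, 2.0]))
        out = mc.membrane_reaction_rates(s, p)
        assert out.d2.shape == (3,)
        assert out.d2[0] == 0.0


class TestExchangeFluxes:
    def test_membrane_binding_drains_cytosolic_minD(self):
        p = mc.RateParameters(omega_db=4.0)
        out = mc.exchange_fluxes(state(D=1389.0), p)
        assert out.minD == pytest.approx(-5556.0)

    def test_mine_release_rate(self):
        p = mc.RateParameters(omega_er=30.0, omega_eb=0.07)
        out = mc.exchange_fluxes(state(e2=1.0), p)
        assert out.minE == pytest.approx(30.0)

    def test_hydrolysis_releases_two_monomers(self):
        p = mc.RateParameters(omega_hydr=0.12)
        out = mc.exchange_fluxes(state(d2e2=1.0), p)
        assert out.minD == pytest.approx(0.24)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(D=conc, E2=conc, d=conc, d2=conc, e2=conc, d2e2=conc,
       omega_db=rate, omega_edf=rate, omega_dim=rate, omega_hydr=rate,
       omega_eb=rate, omega_er=rate)
def test_reactions_conserve_minD_and_minE(D, E2, d, d2, e2, d2e2, omega_db,
                                          omega_edf, omega_dim, omega_hydr,
                                          omega_eb, omega_er):
    """Membrane monomer-equivalent production is exactly balanced by the
    exchange flux: the reaction network neither creates nor destroys MinD
    monomers or MinE dimers."""
    p = mc.RateParameters(omega_db=omega_db, omega_edf=omega_edf,
                          omega_dim=omega_dim, omega_hydr=omega_hydr,
                          omega_eb=omega_eb, omega_er=omega_er)
    s = state(D=D, E2=E2, d=d, d2=d2, e2=e2, d2e2=d2e2)
    mr = mc.membrane_reaction_rates(s, p)
    ex = mc.exchange_fluxes(s, p)
    minD_membrane = mr.d + 2.0 * mr.d2 + 2.0 * mr.d2e2
    minE_membrane = mr.e2 + mr.d2e2
    scale = max(1.0, abs(minD_membrane), abs(minE_membrane))
    assert minD_membrane + ex.minD == pytest.approx(0.0, abs=1e-9 * scale)
    assert minE_membrane + ex.minE == pytest.approx(0.0, abs=1e-9 * scale)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(D=conc, E2=conc, d=conc, d2=conc, e2=conc, d2e2=conc)
def test_no_species_driven_negative_at_zero(D, E2, d, d2, e2, d2e2):
    """Each species' derivative is non-negative when that species is zero."""
    p = mc.RateParameters()
    base = dict(D=D, E2=E2, d=d, d2=d2, e2=e2, d2e2=d2e2)
    for name in ("d", "d2", "e2", "d2e2"):
        s = state(**{**base, name: 0.0})
        out = mc.membrane_reaction_rates(s, p)
        assert getattr(out, name) >= 0.0


class TestTemperatureScaling:
    def test_unity_at_reference_temperature(self):
        ts = mc.TemperatureScaling()
        assert mc.boltzmann_factor(ts.T0, ts) == pytest.approx(1.0)

    def test_monotone_increasing_in_temperature(self):
        f = [mc.boltzmann_factor(T) for T in (293.15, 305.15, 310.15, 313.15)]
        assert all(a < b for a, b in zip(f, f[1:]))

    def test_closed_form_value(self):
        # eps (T - T0) / (k T T0) evaluated at T = 310.15 K
        expected = np.exp(11.5 * 5.0 / (mc.GAS_CONSTANT_KCAL * 310.15 * 305.15))
        p = mc.RateParameters(omega_hydr=0.12)
        assert mc.boltzmann_scaled_hydr(p, 310.15) == pytest.approx(0.12 * expected)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            mc.boltzmann_factor(0.0)


class TestMinEPartition:
    def test_physiological_ratio_and_fraction(self):
        ratio, frac = mc.mine_equilibrium_partition(mc.RateParameters())
        assert ratio == pytest.approx(430.0, rel=0.005)
        assert frac == pytest.approx(99.75, abs=0.05)

    def test_balanced_rates_split_evenly(self):
        p = mc.RateParameters(omega_er=1.0, omega_eb=1.0)
        _, frac = mc.mine_equilibrium_partition(p)
        assert frac == pytest.approx(50.0)

    def test_zero_binding_keeps_all_cytoplasmic(self):
        p = mc.RateParameters(omega_eb=0.0)
        ratio, frac = mc.mine_equilibrium_partition(p)
        assert np.isinf(ratio)
        assert frac == 100.0


class TestPresets:
    def test_fully_labelled_values(self):
        p = mc.preset("fully_labelled")
        assert (p.omega_db, p.omega_edf, p.omega_dim) == (4.0, 22.0, 0.002)
        assert (p.omega_hydr, p.omega_eb, p.omega_er) == (0.12, 0.07, 30.0)
        assert (p.D_D, p.D_E, p.D_m) == (16.0, 20.0, 0.1)

    def test_presets_differ_in_exactly_two_fields(self):
        a = mc.preset("fully_labelled").to_dict()
        b = mc.preset("partially_labelled").to_dict()
        diff = {k for k in a if a[k] != b[k]}
        assert diff == {"omega_hydr", "D_D"}
        assert b["omega_hydr"] == 0.5 and b["D_D"] == 24.0

    def test_unknown_preset_rejected(self):
        with pytest.raises(KeyError):
            mc.preset("unlabelled")

    def test_yaml_round_trip(self):
        p = mc.preset("partially_labelled")
        assert mc.RateParameters.from_yaml(p.to_yaml()) == p

    def test_unknown_yaml_field_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            mc.RateParameters.from_yaml("omega_zz: 1.0\n")


def test_membrane_diffusion_scaling_is_inverse_anchor_count():
    assert mc.MEMBRANE_DIFFUSION_SCALING == {
        "d": 1.0, "d2": 0.5, "e2": 0.5, "d2e2": 0.25}


def test_concentration_totals_monomer_accounting():
    t = mc.ConcentrationTotals()
    assert t.minE_monomer_total == pytest.approx(972.0)
    assert t.scaled(1 / 3).minD_total == pytest.approx(463.0)
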