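"""Reaction-flux formulas and unit conversions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cristaflux as cf
from cristaflux.kinetics import (KineticParams, SoluteState, ant_flux,
                                 as_flux, surrogate_kinase_rate, load_params,
                                 save_params)
from cristaflux.units import convert_cell_rate_to_area_flux


def make_params(**kw):
    return cf.default_params().replace(**kw)


class TestAntFlux:
    def test_zero_at_thermodynamic_equilibrium(self):
        # ψ=0 and a unit concentration ratio kill the driving term
        p = make_params(psi_m=0.0)
        s = SoluteState(ADP_m=0.5, ATP_m=0.5, ADP_e=0.5, ATP_e=0.5)
        assert ant_flux(s, p) == pytest.approx(0.0, abs=1e-12)

    def test_forward_import_at_resting_state(self):
        # 172 mV with resting concentrations drives ADP import
        p = make_params(f_ADP3_m=1.0, f_ADP3_e=1.0, f_ATP4_m=1.0, f_ATP4_e=1.0)
        s = SoluteState(ADP_m=0.72, ATP_m=0.44, ADP_e=0.037, ATP_e=4.0)
        assert ant_flux(s, p) > 0

    def test_matches_symbolic_oracle(self):
        # frozen from an independent symbolic evaluation of the carrier law
        p = make_params(V_ANT=1000.0, psi_m=172.0, f_P=0.5, T=310.0,
                        f_ADP3_m=0.45, f_ADP3_e=0.45, f_ATP4_m=0.05,
                        f_ATP4_e=0.05)
        s = SoluteState(ADP_m=0.30, ATP_m=0.86, ADP_e=0.037, ATP_e=4.0)
        assert ant_flux(s, p) == pytest.approx(153.357115510, rel=1e-9)

    def test_zero_denominator_species_raises(self):
        p = make_params()
        s = SoluteState(ADP_m=0.3, ATP_m=0.8, ADP_e=0.0, ATP_e=4.0)
        with pytest.raises(ValueError, match="ADP3"):
            ant_flux(s, p)

    @given(a1=st.floats(1e-3, 0.5), a2=st.floats(1e-3, 0.5))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_strictly_increasing_in_external_adp(self, a1, a2):
        if abs(a1 - a2) < 1e-9:
            return
        lo, hi = sorted((a1, a2))
        p = make_params()
        f = lambda a: float(ant_flux(
            SoluteState(ADP_m=0.3, ATP_m=0.86, ADP_e=a, ATP_e=4.0), p))
        assert f(hi) > f(lo)

    def test_sign_change_at_equilibrium_crossing(self):
        # flux changes sign exactly where the bracketed numerator does
        p = make_params()
        u = p.psi_m / p.rt_over_f
        # choose ADP_e so that (ATP_e·ADP_m)/(ADP_e·ATP_m)·e^(−u) = 1
        adp_m, atp_m, atp_e = 0.3, 0.86, 4.0
        a_eq = atp_e * adp_m / atp_m * np.exp(-u)
        for fac, sign in ((1.05, 1), (0.95, -1)):
            s = SoluteState(ADP_m=adp_m, ATP_m=atp_m, ADP_e=a_eq * fac,
                            ATP_e=atp_e)
            assert np.sign(float(ant_flux(s, p))) == sign


class TestAsFlux:
    def test_zero_without_calcium(self):
        p = make_params(Ca_m=0.0)
        s = SoluteState(ADP_m=0.3, ATP_m=0.8, ADP_e=1.0, ATP_e=1.0)
        assert as_flux(s, p) == pytest.approx(0.0, abs=1e-12)

    def test_zero_without_potential(self):
        p = make_params(psi_m=0.0)
        s = SoluteState(ADP_m=0.3, ATP_m=0.8, ADP_e=1.0, ATP_e=1.0)
        assert as_flux(s, p) == pytest.approx(0.0, abs=1e-12)

    def test_reverse_mode_without_matrix_adp(self):
        p = make_params()
        s = SoluteState(ADP_m=0.0, ATP_m=0.8, ADP_e=1.0, ATP_e=1.0)
        assert as_flux(s, p) < 0

    def test_matches_symbolic_oracle(self):
        p = make_params(V_AS=300.0, K_ADP=0.18, K_ATP=4.8, K_Pi=1.0,
                        Pi_m=6.0, psi_m=172.0, K_V_ATP=131.4, Ca_m=2e-4,
                        K_Ca_ATP=1.65e-4)
        s = SoluteState(ADP_m=0.25, ATP_m=0.91, ADP_e=1.0, ATP_e=1.0)
        assert as_flux(s, p) == pytest.approx(90.9262676407, rel=1e-9)

    def test_denominator_grouping_switch_changes_value(self):
        p1 = make_params()
        p2 = make_params(as_flat_denominator=True)
        s = SoluteState(ADP_m=0.25, ATP_m=0.91, ADP_e=1.0, ATP_e=1.0)
        assert float(as_flux(s, p1)) != pytest.approx(float(as_flux(s, p2)))

    @given(a1=st.floats(0.01, 1.0), a2=st.floats(0.01, 1.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_strictly_increasing_in_matrix_adp(self, a1, a2):
        if abs(a1 - a2) < 1e-9:
            return
        lo, hi = sorted((a1, a2))
        p = make_params()
        f = lambda a: float(as_flux(
            SoluteState(ADP_m=a, ATP_m=1.16 - a if a < 1.16 else 0.01,
                        ADP_e=1.0, ATP_e=1.0), p))
        assert f(hi) > f(lo)


class TestSurrogateKinase:
    def test_zero_at_zero_concentrations(self):
        p = make_params()
        assert surrogate_kinase_rate(0.0, 0.0, 1.0, p) == 0.0

    def test_zero_at_tuned_equilibrium(self):
        # with the printed rate constants the reaction vanishes whenever
        # k_f·ATP = ADP·Pi
        p = make_params(k_f=0.009, k_r=1.0)
        atp_e, pi_e = 4.0, 1.0
        adp_e = 0.009 * atp_e / pi_e
        assert surrogate_kinase_rate(atp_e, adp_e, pi_e, p) == pytest.approx(
            0.0, abs=1e-15)

    def test_matches_mass_action_oracle(self):
        p = make_params(k_f=0.009, k_r=1.0)
        assert surrogate_kinase_rate(3.7, 0.05, 2.5, p) == pytest.approx(
            -0.0917, rel=1e-12)


class TestConversion:
    def test_resting_cardiomyocyte_rate(self):
        # 1.3 mM/s per liter of cells, 30% mito volume, 37 μm²/μm³ → ~70
        assert convert_cell_rate_to_area_flux(1.3, 0.30, 37.0) == pytest.approx(
            70.0, rel=0.02)

    def test_zero_rate(self):
        assert convert_cell_rate_to_area_flux(0.0, 0.3, 37.0) == 0.0

    def test_unit_chain_oracle(self):
        # hand-derived: 1 mM/s/L → 602214 molecules/μm³/s → /1000 ms
        assert convert_cell_rate_to_area_flux(1.0, 1.0, 1.0) == pytest.approx(
            602.214, rel=1e-12)

    def test_nonpositive_inputs_raise(self):
        with pytest.raises(ValueError):
            convert_cell_rate_to_area_flux(1.0, 0.0, 37.0)


class TestParams:
    def test_yaml_round_trip(self, tmp_path):
        p = cf.default_params()
        path = tmp_path / "p.yaml"
        save_params(p, path)
        q = load_params(path)
        assert p.to_dict() == q.to_dict()

    @pytest.mark.parametrize("field,value", [
        ("V_ANT", -1.0), ("f_P", 1.5), ("f_ADP3_m", 0.0), ("psi_m", -1.0),
        ("D_ADP", 0.0), ("k_f", -0.1),
    ])
    def test_invalid_parameters_rejected(self, field, value):
        with pytest.raises(ValueError):
            cf.default_params().replace(**{field: value})

    def test_bundled_defaults_carry_printed_values(self):
        p = cf.default_params()
        assert (p.psi_m, p.f_P, p.k_f, p.k_r) == (172.0, 0.5, 0.009, 1.0)
        assert "calibrated" in p.provenance
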