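"""Gradient law, Rule of 2, flux decomposition and census scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cristaflux.analysis import (ADPProfile, FluxCurve, census_score,
                                 decompose_flux, depletion, diffusion_penalty,
                                 fit_quadratic, ibm_correction, mirror_profile,
                                 rule_of_two_check, speed_zone)


def parabola_profile(ADP0=0.02, a=0.05, L=0.9, n=100):
    x = np.linspace(0.004, L - 0.004, n)
    return ADPProfile(x=x, adp=ADP0 - a * x * (L - x), ADP0=ADP0, L_CRIS=L)


class TestDepletion:
    def test_flat_profile_has_zero_depletion(self):
        x = np.linspace(0, 0.9, 50)
        p = ADPProfile(x=x, adp=np.full(50, 0.02), ADP0=0.02, L_CRIS=0.9)
        assert depletion(p) == pytest.approx(0.0, abs=1e-12)

    def test_zero_reference_raises(self):
        x = np.linspace(0, 0.9, 50)
        p = ADPProfile(x=x, adp=np.zeros(50), ADP0=0.0, L_CRIS=0.9)
        with pytest.raises(ValueError):
            depletion(p)

    def test_parabola_depletion_closed_form(self):
        # area depletion of the quadratic law is a·L²/(6·ADP0)
        L, ADP0, a = 0.9, 0.02, 0.05
        x = np.linspace(0, L, 4000)
        p = ADPProfile(x=x, adp=ADP0 - a * x * (L - x), ADP0=ADP0, L_CRIS=L)
        assert depletion(p) == pytest.approx(a * L**2 / (6 * ADP0), rel=1e-3)


class TestQuadraticFit:
    def test_recovers_exact_parabola(self):
        p = parabola_profile()
        fit = fit_quadratic(p)
        assert fit.a == pytest.approx(0.05, abs=1e-10)
        assert fit.R2 == pytest.approx(1.0, abs=1e-12)
        assert fit.k == pytest.approx(0.05 * 0.9 / 0.02)

    def test_too_few_points_raise(self):
        p = ADPProfile(x=np.array([0.0, 0.1, 0.2]),
                       adp=np.array([1.0, 0.9, 1.0]), ADP0=1.0, L_CRIS=0.3)
        with pytest.raises(ValueError):
            fit_quadratic(p)

    def test_mirrored_one_cj_profile_doubles_length(self):
        p = parabola_profile(L=0.9)
        half = ADPProfile(x=p.x[:50], adp=p.adp[:50], ADP0=p.ADP0,
                          L_CRIS=0.45)
        m = mirror_profile(half)
        assert m.L_CRIS == pytest.approx(0.9)
        assert np.all(np.diff(m.x) > 0)


class TestRuleOfTwo:
    def test_identical_profiles_have_zero_deviation(self):
        p = parabola_profile(L=0.45)
        p2 = mirror_profile(p)
        one_cj = ADPProfile(x=p.x, adp=p.adp, ADP0=p.ADP0, L_CRIS=0.45)
        assert rule_of_two_check(one_cj, p2) == pytest.approx(0.0, abs=1e-12)

    def test_mismatched_lengths_rejected(self):
        a = parabola_profile(L=0.3)
        b = parabola_profile(L=0.9)
        with pytest.raises(ValueError, match="Rule-of-2"):
            rule_of_two_check(a, b)


class TestFluxAlgebra:
    def test_penalty_zero_at_max(self):
        assert diffusion_penalty(70.0, 70.0) == 0.0

    def test_decompose_identity_at_jmax(self):
        ledger = (1.0, 3.0, 4.0)
        assert decompose_flux(100.0, ledger, 100.0) == pytest.approx(100.0)

    def test_decompose_recompose_round_trip(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            s_ibm, s_cris = rng.uniform(0.1, 5.0, 2)
            ledger = (s_ibm, s_cris, s_ibm + s_cris)
            j_model, j_max = rng.uniform(10, 100, 2)
            j_cris = decompose_flux(j_model, ledger, j_max)
            recomposed = (s_ibm / (s_ibm + s_cris)) * j_max + \
                         (s_cris / (s_ibm + s_cris)) * j_cris
            assert recomposed == pytest.approx(j_model, rel=1e-12)

    def test_decompose_without_cristae_raises(self):
        with pytest.raises(ValueError):
            decompose_flux(50.0, (1.0, 0.0, 1.0), 100.0)

    @pytest.mark.parametrize("j_cris,frac,rounded", [
        (0.58, 0.92, 0.61), (0.70, 0.92, 0.72), (0.93, 0.92, 0.94)])
    def test_ibm_correction_reference_values(self, j_cris, frac, rounded):
        assert round(ibm_correction(j_cris, frac), 2) == rounded

    def test_ibm_correction_identity_without_ibm(self):
        assert ibm_correction(0.37, 1.0) == pytest.approx(0.37)


class TestSpeedZones:
    @pytest.mark.parametrize("j,zone", [
        (0.95, "fast"), (0.90, "fast"), (0.60, "slow"), (0.75, "moderate"),
        (0.89999, "moderate"), (0.74999, "slow")])
    def test_reference_classifications(self, j, zone):
        assert speed_zone(j) == zone

    @given(st.floats(0.0, 1.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_partition_without_gaps(self, j):
        zone = speed_zone(j)
        assert zone in ("fast", "moderate", "slow")
        assert (zone == "fast") == (j >= 0.9)
        assert (zone == "moderate") == (0.75 <= j < 0.9)


def flat_curves(value=0.8):
    lengths = np.array([0.075, 0.15, 0.45, 0.9])
    mk = lambda name: FluxCurve(topology=name, lengths=lengths,
                                values=np.full(4, value))
    return {n: mk(n) for n in ("no_cj", "one_narrow", "one_wide",
                               "two_narrow", "two_wide")}


class TestCensusScore:
    def census(self, lengths, ends):
        return pd.DataFrame({
            "crista_id": [f"C{i}" for i in range(len(lengths))],
            "length_um": lengths, "n_segments": 1,
            "cjs_per_segment": 2.0, "cj_ends": ends,
        })

    def test_single_crista_equals_curve_value(self):
        curves = flat_curves(0.66)
        c = self.census([0.5], ["one"])
        assert census_score(c, curves) == pytest.approx(0.66)

    def test_weighted_average_oracle_on_one_curve(self):
        lengths = [0.2, 0.5, 1.1]
        curve = FluxCurve(topology="one_narrow",
                          lengths=np.array([0.1, 0.5, 1.2]),
                          values=np.array([0.9, 0.8, 0.6]))
        curves = {"one_narrow": curve}
        c = self.census(lengths, ["one"] * 3)
        expected = sum(L * float(curve(L)) for L in lengths) / sum(lengths)
        assert census_score(c, curves) == pytest.approx(expected, rel=1e-12)

    def test_invariant_to_row_order_and_unit_rescaling(self):
        curves = flat_curves(0.71)
        lengths = [0.4, 0.9, 1.3]
        c = self.census(lengths, ["both", "one", "none"])
        shuffled = c.iloc[[2, 0, 1]].reset_index(drop=True)
        assert census_score(c, curves) == pytest.approx(
            census_score(shuffled, curves))
        nm = self.census([L * 1000 for L in lengths],
                         ["both", "one", "none"])
        assert census_score(nm, curves) == pytest.approx(
            census_score(c, curves))

    def test_empty_census_rejected(self):
        with pytest.raises(ValueError):
            census_score(pd.DataFrame(), flat_curves())

    def test_rule_of_two_curve_evaluates_at_half_length(self):
        base = FluxCurve(topology="one_narrow",
                         lengths=np.array([0.1, 0.5, 1.0]),
                         values=np.array([0.9, 0.8, 0.6]))
        two = FluxCurve(topology="two_narrow", lengths=base.lengths,
                        values=base.values)
        two.rule_of_two_of = "one_narrow"
        assert float(two(1.0)) == pytest.approx(float(base(0.5)))
        # flat clamp outside the sampled range
        assert float(base(5.0)) == pytest.approx(0.6)
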