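"""Steady-state solver behaviour: oracles, invariants, determinism."""

import numpy as np
import pytest

import cristaflux as cf
from cristaflux import analysis
from cristaflux.solver import (ConvergenceError, LinearExchangeMembrane,
                               run_condition_grid, calibrate, evaluate_anchors)
from cristaflux.units import MOLECULES_PER_UM3_PER_MM


class TestEquilibriumAndOracles:
    def test_uniform_fields_at_joint_equilibrium(self, params):
        """With the kinase at its mass-action equilibrium at the boundary
        values and the matrix pool frozen at the translocase reversal
        point, every flux vanishes and the fields stay at the boundary
        values."""
        p = params
        bc = cf.BoundaryConditions(
            ADP_cyt=p.k_f * 4.0 / (p.k_r * p.Pi_e), ATP_cyt=4.0)
        u = p.psi_m / p.rt_over_f
        # matrix ratio that zeroes the translocase driving term
        ratio = np.exp(u) * bc.ADP_cyt / bc.ATP_cyt  # ADP_m/ATP_m at reversal
        adp_m = 1.16 * ratio / (1 + ratio)
        model = cf.build_no_crista_2d(h=0.005)
        res = cf.solve_steady_state(model, p, bc,
                                    fixed_matrix=(adp_m, 1.16 - adp_m))
        ext = ~np.isnan(res.ADP_e)
        assert np.allclose(res.ADP_e[ext], bc.ADP_cyt, rtol=1e-6)
        assert np.allclose(res.ATP_e[ext], bc.ATP_cyt, rtol=1e-6)
        assert np.allclose(res.face_J_ant, 0.0, atol=1e-6)

    def test_dead_end_channel_matches_cosh_solution(self, params):
        """A linearized membrane exchange in a dead-end channel must follow
        the closed-form catenary profile within 1%."""
        g, A_eq, L, w = 2.0e4, 0.005, 0.3, 0.02
        p = params.replace(k_f=0.0, k_r=0.0, D_ADP=0.1, D_ATP=0.1)
        bc = cf.BoundaryConditions(ADP_cyt=0.037, ATP_cyt=4.0)
        model = cf.build_uniform_2d(L, "one_end", domain_w=0.04, h=0.002)
        res = cf.solve_steady_state(
            model, p, bc, membrane=LinearExchangeMembrane(g, A_eq),
            fixed_matrix=(0.72, 0.44))
        prof = analysis.midline_profile(res, 1)
        beta = g / MOLECULES_PER_UM3_PER_MM  # μm/ms
        kappa = np.sqrt(2 * beta / (w * p.D_ADP))
        shape = (np.cosh(kappa * (L - prof.x))
                 + beta / (kappa * p.D_ADP) * np.sinh(kappa * (L - prof.x)))
        C = (prof.adp[0] - A_eq) / shape[0]
        analytic = A_eq + C * shape
        assert np.max(np.abs(prof.adp - analytic)) / prof.ADP0 < 0.01


class TestInvariants:
    def test_matrix_adenine_conserved(self, small_solve):
        res, _, _ = small_solve
        assert res.ADP_m + res.ATP_m == pytest.approx(1.16, abs=1e-12)

    def test_sum_field_uniform_with_equal_diffusivities(self, small_solve):
        res, _, bc = small_solve
        total = res.ADP_e + res.ATP_e
        ext = ~np.isnan(total)
        assert np.max(np.abs(total[ext] - (bc.ADP_cyt + bc.ATP_cyt))) < 1e-6

    def test_flux_balance_residual_small(self, small_solve):
        res, _, _ = small_solve
        assert res.converged
        assert res.residual < 1e-6
        assert res.J_ANT_total == pytest.approx(res.J_AS_total, rel=1e-5)

    def test_both_ends_profile_mirror_symmetric(self, small_solve):
        res, model, _ = small_solve
        prof = analysis.midline_profile(res, (model.n_cristae + 1) // 2)
        assert np.allclose(prof.adp, prof.adp[::-1], rtol=1e-4)

    def test_deterministic_rerun_bit_identical(self, params):
        bc = cf.BoundaryConditions(ADP_cyt=0.037)
        runs = []
        for _ in range(2):
            model = cf.build_uniform_2d(0.16, "one_end", domain_w=0.08,
                                        h=0.005)
            runs.append(cf.solve_steady_state(model, params, bc))
        assert runs[0].ADP_m == runs[1].ADP_m
        a0, a1 = runs[0].ADP_e, runs[1].ADP_e
        assert np.array_equal(a0[~np.isnan(a0)], a1[~np.isnan(a1)])

    def test_grid_refinement_changes_flux_below_2pct(self, params):
        bc = cf.BoundaryConditions(ADP_cyt=0.037)
        js = []
        for h in (0.004, 0.002):
            model = cf.build_uniform_2d(0.32, "one_end", h=h)
            js.append(cf.solve_steady_state(model, params, bc).j_AS)
        assert abs(js[1] - js[0]) / js[1] < 0.02


class TestMonotonicity:
    def test_flux_decreases_with_crista_length(self, grid_df):
        for cfg in ("one_end", "both_ends"):
            for adp, sub in grid_df[grid_df.cj_config == cfg].groupby("ADP_cyt"):
                j = sub.sort_values("L_CRIS").J_AS.to_numpy()
                assert np.all(np.diff(j) < 0), (cfg, adp)

    def test_flux_increases_with_cytosolic_adp(self, grid_df):
        for (cfg, L), sub in grid_df[grid_df.cj_config != "no_crista"].groupby(
                ["cj_config", "L_CRIS"]):
            j = sub.sort_values("ADP_cyt").J_AS.to_numpy()
            assert np.all(np.diff(j) > 0), (cfg, L)

    def test_synthase_flux_near_linear_in_matrix_adp(self, grid_df):
        sub = grid_df[grid_df.cj_config != "no_crista"]
        x, y = sub.ADP_m.to_numpy(), sub.J_AS.to_numpy()
        slope, icpt = np.polyfit(x, y, 1)
        resid = y - (slope * x + icpt)
        r2 = 1 - np.sum(resid**2) / np.sum((y - y.mean())**2)
        assert r2 > 0.98


class TestGridRunner:
    def test_empty_grid_gives_empty_table(self, params):
        df = run_condition_grid(params, lengths=(), with_baseline=False)
        assert len(df) == 0

    def test_full_grid_has_18_conditions(self, grid_df):
        assert (grid_df.cj_config != "no_crista").sum() == 18
        assert grid_df.converged.all()


class TestErrorsAndCalibration:
    def test_nonconvergence_reports_residual_history(self, params):
        model = cf.build_uniform_2d(0.16, "one_end", domain_w=0.08, h=0.005)
        with pytest.raises(ConvergenceError):
            cf.solve_steady_state(model, params,
                                  cf.BoundaryConditions(ADP_cyt=0.0185),
                                  max_iter=1)

    def test_calibrate_is_fixed_point_when_anchors_met(self, params):
        anchors = evaluate_anchors(params, h=0.005)
        keep = {k: anchors[k] for k in
                ("jmax", "depletion_trunk", "depletion_branch")}
        fitted = calibrate(params, anchors=keep, h=0.01, tol=0.05)
        assert fitted is params
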