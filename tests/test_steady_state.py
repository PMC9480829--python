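import numpy as np
import pytest

from slpathway import (
    FeedbackExponents,
    integrate,
    jacobian,
    odes,
    parameter_scan,
    sample_ensemble,
    solve_steady_state,
    steady_state_exists,
)


def _closed_form_ab(p):
    """Independent sequential inversion oracle for the unregulated AB cascade."""
    cisb = p.KM_CCD7 * p.k0 / (p.kcat_CCD7 * p.E_CCD7 - p.k0)
    rev = p.kcat_D27B * p.E_D27 * cisb / (p.KM_D27 + cisb)
    g = p.k0 + rev
    bcar = p.KM_D27 * g / (p.kcat_D27A * p.E_D27 - g)
    ctnl = p.KM_CCD8 * p.k0 / (p.kcat_CCD8 * p.E_CCD8 - p.k0)
    cl = p.KM_MAX1 * p.k0 / (p.Vmax_MAX1 - p.k0)
    return np.array(
        [bcar, cisb, ctnl, cl, p.omega * p.k0 / p.k, (1 - p.omega) * p.k0 / p.k]
    )


class TestClosedFormSteadyState:
    def test_ab_adjusted_levels(self, ab_params, ab_steady):
        expected = _closed_form_ab(ab_params)
        np.testing.assert_allclose(ab_steady.state, expected, rtol=1e-12)
        # the solved levels, to the precision quoted in the derivation
        approx = {
            "BCAR": 3.61e-4, "CISB": 3.16e-8, "CTNL": 5.09e-4,
            "CL": 8.24e-7, "ORO": 5.0e-9, "STR": 5.0e-9,
        }
        conc = ab_steady.concentrations()
        for sp, v in approx.items():
            assert conc[sp] == pytest.approx(v, rel=5e-3)

    def test_ab_bcar_in_experimental_window(self, ab_steady):
        assert 1e-4 <= ab_steady.concentrations()["BCAR"] <= 1e-1

    def test_ac_levels_and_product_asymmetry(self, ac_steady):
        conc = ac_steady.concentrations()
        assert conc["ORO"] == pytest.approx(1.0e-8, rel=1e-3)
        assert conc["STR"] == pytest.approx(9.8e-14, rel=5e-3)
        assert conc["DO"] == pytest.approx(8.2e-7, rel=5e-3)
        assert conc["CLA"] == pytest.approx(8.2e-7, rel=5e-3)
        # ORO sits orders of magnitude above STR in model AC
        assert conc["ORO"] / conc["STR"] > 1e4

    def test_residual_is_stationary(self, ab_params, ab_steady, ac_params, ac_steady):
        assert np.abs(odes(ab_steady.state, ab_params)).max() <= 1e-18
        assert np.abs(odes(ac_steady.state, ac_params)).max() <= 1e-18

    def test_zero_influx_gives_empty_stable_pathway(self, ab_params, ac_params):
        for p in (ab_params.replace(k0=0.0), ac_params.replace(k0=0.0)):
            res = solve_steady_state(p)
            assert res.status == "stable"
            assert np.all(res.state == 0)

    def test_net_fluxes_all_equal_influx(self, ab_params, ab_steady):
        f = ab_steady.fluxes
        k0 = ab_params.k0
        assert f["d27_forward"] - f["d27_reverse"] == pytest.approx(k0, rel=1e-9)
        assert f["ccd7"] == pytest.approx(k0, rel=1e-9)
        assert f["ccd8"] == pytest.approx(k0, rel=1e-9)
        assert f["removal_oro"] + f["removal_str"] == pytest.approx(k0, rel=1e-9)


class TestExistence:
    def test_adjusted_set_exists(self, ab_params):
        exists, limiting = steady_state_exists(ab_params)
        assert exists and limiting is None

    def test_ccd8_is_the_bottleneck(self, ab_params):
        # CCD8 capacity = 0.18 * 1.06e-6 = 1.908e-7 mM/s
        exists, limiting = steady_state_exists(ab_params.replace(k0=2e-7))
        assert not exists
        assert limiting == "ccd8"

    def test_zero_influx_always_exists(self, ab_params):
        assert steady_state_exists(ab_params.replace(k0=0.0))[0]

    def test_scan_flips_exactly_at_capacity_bound(self, ab_params):
        cap = ab_params.Vmax_CCD8  # tightest capacity
        records = parameter_scan(ab_params, "k0", decades=6, points_per_decade=10)
        for rec in records:
            assert rec.result.exists == (rec.value < cap), rec.value

    def test_solver_never_returns_state_beyond_capacity(self, ab_params):
        res = solve_steady_state(ab_params.replace(k0=2e-7))
        assert res.status == "no_steady_state"
        assert res.state is None and res.limiting_step == "ccd8"


class TestIntegration:
    def test_pure_accumulation_without_enzymes(self, ab_params):
        p = ab_params.replace(E_D27=0.0, E_CCD7=0.0, E_CCD8=0.0, Vmax_MAX1=0.0)
        t, Y = integrate(p, t_end=100.0, n_out=11)
        assert Y[-1][0] == pytest.approx(p.k0 * 100.0, rel=1e-9)
        assert np.all(Y[:, 1:] == 0)

    def test_zero_influx_zero_trajectory(self, ac_params):
        _, Y = integrate(ac_params.replace(k0=0.0), t_end=1e4)
        assert np.all(Y == 0)

    def test_converges_to_closed_form(self, ab_params, ab_steady):
        _, Y = integrate(ab_params, t_end=1e7, n_out=5)
        np.testing.assert_allclose(Y[-1], ab_steady.state, rtol=1e-8)

    def test_rejects_bad_inputs(self, ab_params):
        with pytest.raises(ValueError):
            integrate(ab_params, t_end=-1.0)
        with pytest.raises(ValueError):
            integrate(ab_params, init=[-1, 0, 0, 0, 0, 0])


class TestJacobian:
    @pytest.mark.parametrize("model", ["AB", "AC"])
    def test_analytic_matches_finite_difference(
        self, model, ab_params, ab_steady, ac_params, ac_steady
    ):
        p, res = (ab_params, ab_steady) if model == "AB" else (ac_params, ac_steady)
        Ja = jacobian(res.state, p, method="analytic")
        Jf = jacobian(res.state, p, method="finite_difference")
        nz = np.abs(Ja) > 0
        assert np.abs((Ja - Jf)[nz] / Ja[nz]).max() <= 1e-6

    def test_product_rows_structure(self, ab_params, ab_steady):
        # ORO and STR rows: diagonal -k, one coupling via the CL column
        J = ab_steady.jacobian
        for row in (4, 5):
            assert J[row, row] == pytest.approx(-ab_params.k)
            others = [J[row, c] for c in range(6) if c not in (row, 3)]
            assert np.all(np.array(others) == 0)
            assert J[row, 3] > 0

    def test_cascade_is_lower_triangular_except_d27_block(self, ab_steady):
        J = ab_steady.jacobian
        upper = np.triu(J, k=1).copy()
        upper[0, 1] = 0.0  # BCAR <-> CISB reversible isomerase block
        assert np.all(upper == 0)

    def test_feedback_adds_upper_coupling(self, ab_params, ab_steady):
        fb = FeedbackExponents(foro1=-0.5)
        J = jacobian(ab_steady.state, ab_params, fb)
        assert J[0, 4] > 0  # more ORO -> less BCAR consumption


class TestStability:
    def test_adjusted_sets_are_stable(self, ab_steady, ac_steady):
        assert ab_steady.status == "stable"
        assert ac_steady.status == "stable"
        assert ab_steady.max_real_eig < 0

    def test_removal_eigenvalues_equal_minus_k(self, ab_params, ab_steady):
        re_sorted = np.sort(ab_steady.eigenvalues.real)
        assert np.sum(np.isclose(ab_steady.eigenvalues.real, -ab_params.k)) >= 2
        assert re_sorted[0] <= -ab_params.k * (1 - 1e-9)

    def test_slow_mode_approaches_zero_near_capacity(self, ab_params):
        cap = ab_params.Vmax_CCD8
        res = solve_steady_state(ab_params.replace(k0=0.999 * cap))
        # CTNL piles up (~9 mM) and its relaxation rate collapses toward 0-
        assert res.status == "stable"
        assert -1e-8 < res.max_real_eig < 0
        assert res.concentrations()["CTNL"] > 1.0


class TestEnsembleOracleEquivalence:
    @pytest.mark.parametrize("fixture", ["ab_adjusted", "ac_adjusted"])
    def test_closed_form_agrees_with_integration(self, fixture, ab_params, ac_params):
        base = ab_params if fixture == "ab_adjusted" else ac_params
        ens = sample_ensemble(base, half_width_decades=1.0, n=20, seed=42)
        checked = 0
        for m in ens.members:
            if not steady_state_exists(m)[0]:
                continue
            res = solve_steady_state(m)
            assert res.status == "stable"
            t_end = min(40.0 / abs(res.max_real_eig), 1e13)
            _, Y = integrate(m, t_end=t_end, n_out=5)
            nz = res.state > 0
            assert np.abs(Y[-1][nz] / res.state[nz] - 1).max() <= 1e-6
            checked += 1
        assert checked >= 10
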