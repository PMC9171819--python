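"""The C_ij parameterization engine: gradient fits, back-extrapolation,
ratio scaling, the two-chelator solve and its diagnostics."""

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from chbe import cijfit
from chbe.cijfit import (
    ChBESolution,
    DegenerateDesignError,
    DenticityRatios,
    GradientSet,
    MixedDesignError,
    SingularSystemError,
    TIObservation,
    back_extrapolate_zero,
    build_gradient_set,
    contour_line,
    fit_gradient,
    predict_dg,
    read_observations,
    scale_reference_zero,
    solve_cij,
    solve_cij_direct,
    solve_cij_lstsq,
)


def obs_line(c_values, slope, intercept, varied="c_o", fixed=65.9, noise=None):
    out = []
    for i, c in enumerate(c_values):
        dg = intercept + slope * c + (noise[i] if noise is not None else 0.0)
        kw = {"c_o": c, "c_n": fixed} if varied == "c_o" else {"c_o": fixed, "c_n": c}
        out.append(TIObservation("EDTA", "Ca2+", dg_sim=dg, **kw))
    return out


class TestFitGradient:
    def test_exact_line(self):
        obs = obs_line([0, 10, 20, 40], slope=-0.5, intercept=-40.0)
        assert fit_gradient(obs) == pytest.approx(-0.5, abs=1e-12)

    def test_flat_data_zero_slope(self):
        obs = obs_line([0, 10, 20], slope=0.0, intercept=-40.0)
        assert fit_gradient(obs) == pytest.approx(0.0, abs=1e-12)

    def test_nitrogen_scan_detected(self):
        obs = obs_line([0, 30, 60], slope=-0.18, intercept=-40.0, varied="c_n")
        assert fit_gradient(obs) == pytest.approx(-0.18, abs=1e-12)

    def test_noisy_line_matches_normal_equations(self, rng):
        c = np.array([0.0, 15.0, 30.0, 45.0, 60.0, 75.0])
        noise = rng.normal(0, 1.0, size=6)
        obs = obs_line(c, slope=-0.593, intercept=-35.0, noise=noise)
        y = np.array([o.dg_sim for o in obs])
        # closed-form least squares, computed independently of the fit path
        sxx = np.sum((c - c.mean()) ** 2)
        sxy = np.sum((c - c.mean()) * (y - y.mean()))
        assert fit_gradient(obs) == pytest.approx(sxy / sxx, rel=1e-10)

    def test_anchored_variant(self):
        obs = obs_line([10, 20, 40], slope=-0.5, intercept=-40.0)
        slope = fit_gradient(obs, anchor=(34.4, -40.0 - 0.5 * -34.4 * -1))
        # anchor lies on the same exact line, so the slope is unchanged
        assert slope == pytest.approx(-0.5, abs=1e-12)

    def test_design_errors(self):
        with pytest.raises(DegenerateDesignError):
            fit_gradient(obs_line([10, 10, 10], slope=0, intercept=-40))
        mixed = [
            TIObservation("EDTA", "Ca2+", c_o=0, c_n=0, dg_sim=-40),
            TIObservation("EDTA", "Ca2+", c_o=10, c_n=10, dg_sim=-45),
        ]
        with pytest.raises(MixedDesignError):
            fit_gradient(mixed)
        with pytest.raises(ValueError):
            fit_gradient(obs_line([10], slope=0, intercept=-40))

    def test_negative_cij_rejected(self):
        with pytest.raises(ValueError):
            TIObservation("EDTA", "Ca2+", c_o=-1.0, c_n=0.0, dg_sim=-40.0)


def test_build_gradient_set_round_trip():
    """A two-scan design yields a model that reproduces its own inputs."""
    m_o, m_n, z = -0.6, -0.15, -25.0
    c_o_d, c_n_d = 34.4, 65.9
    obs = []
    for c_o in (0.0, 20.0, c_o_d, 50.0):
        obs.append(TIObservation("EDTA", "Ca2+", c_o=c_o, c_n=c_n_d,
                                 dg_sim=z + m_o * c_o + m_n * c_n_d))
    for c_n in (0.0, 30.0, c_n_d, 90.0):
        obs.append(TIObservation("EDTA", "Ca2+", c_o=c_o_d, c_n=c_n,
                                 dg_sim=z + m_o * c_o_d + m_n * c_n))
    g = build_gradient_set(obs, c_o_d, c_n_d)
    assert g.m_o == pytest.approx(m_o, abs=1e-10)
    assert g.m_n == pytest.approx(m_n, abs=1e-10)
    assert g.dg_zero == pytest.approx(z, abs=1e-9)
    assert predict_dg(g, c_o_d, c_n_d) == pytest.approx(g.dg_default, abs=1e-9)


class TestBackExtrapolation:
    def test_zero_gradients_identity(self):
        g = GradientSet("EDTA", "Ca2+", m_o=0.0, m_n=0.0, dg_default=-56.0,
                        c_o_default=34.4, c_n_default=65.9, dg_zero=-56.0)
        assert back_extrapolate_zero(g) == -56.0

    def test_published_inputs_reproduce_printed_refs(self, edta_gradients):
        """Printed one-decimal inputs limit agreement to ~0.1 kJ/mol."""
        printed = {"Ca2+": -24.0, "Mg2+": -21.8, "Y3+": -82.6, "La3+": -79.0}
        for metal, expected in printed.items():
            z = back_extrapolate_zero(edta_gradients[metal])
            assert z == pytest.approx(expected, abs=0.15)

    def test_invariant_of_constructor(self, edta_gradients):
        for g in edta_gradients.values():
            assert g.dg_zero == pytest.approx(
                g.dg_default - g.m_o * g.c_o_default - g.m_n * g.c_n_default,
                abs=1e-12,
            )


class TestScaleReferenceZero:
    def test_unit_ratio_identity(self):
        assert scale_reference_zero(-23.94, -60.8, -60.8) == pytest.approx(-23.94)

    def test_zero_target_annihilates(self):
        assert scale_reference_zero(-23.94, -60.8, 0.0) == 0.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ZeroDivisionError):
            scale_reference_zero(-23.94, 0.0, -37.5)

    def test_ca_ratio_arithmetic(self, edta_gradients):
        z = back_extrapolate_zero(edta_gradients["Ca2+"])
        scaled = scale_reference_zero(z, -60.8, -37.5)
        assert scaled == pytest.approx(z * 37.5 / 60.8, rel=1e-12)
        assert scaled == pytest.approx(-14.77, abs=0.01)


class TestSolve:
    def test_reproduces_published_coefficients(self, cij_reference):
        for metal in cijfit.METALS:
            sol = cijfit.solve_reference(metal)
            ref = cij_reference.loc[metal]
            assert sol.physical
            assert sol.c_o == pytest.approx(ref.c_o_chbe, rel=0.015)
            assert sol.c_n == pytest.approx(ref.c_n_chbe, rel=0.015)

    def test_solution_satisfies_both_equations(self, edta_gradients, exp_dg):
        for metal in cijfit.METALS:
            g = edta_gradients[metal]
            sol = cijfit.solve_reference(metal)
            assert predict_dg(g, sol.c_o, sol.c_n) == pytest.approx(
                exp_dg[(metal, "EDTA")], abs=1e-9
            )
            assert max(abs(r) for r in sol.residuals) < 1e-9
            assert sol.condition_diag > 0

    def test_consistent_zero_inputs_give_zero_solution(self):
        g = GradientSet.from_back_extrapolation(
            "EDTA", "Xx", m_o=-0.6, m_n=-0.2, dg_default=-30.0 - 0.6 * -34.4 - 0.2 * -65.9,
            c_o_default=34.4, c_n_default=65.9,
        )
        # experimental energies equal to the model at (0, 0)
        sol = solve_cij(g, g.dg_zero, g.dg_zero * 0.6)
        assert sol.c_o == pytest.approx(0.0, abs=1e-9)
        assert sol.c_n == pytest.approx(0.0, abs=1e-9)

    def test_equal_ratios_singular(self, edta_gradients):
        with pytest.raises(SingularSystemError):
            solve_cij(edta_gradients["Ca2+"], -60.8, -37.5,
                      DenticityRatios(rho_o=0.5, rho_n=0.5))

    def test_ratio_validation(self):
        with pytest.raises(ValueError):
            DenticityRatios(rho_o=0.0, rho_n=0.5)
        with pytest.raises(ValueError):
            DenticityRatios(rho_o=0.75, rho_n=1.5)

    @given(
        c_o=st.floats(1.0, 200.0),
        c_n=st.floats(1.0, 200.0),
        m_o=st.floats(-2.0, -0.05),
        m_n=st.floats(-0.5, -0.01),
        rho_o=st.floats(0.3, 0.95),
        rho_n_frac=st.floats(0.05, 0.85),
    )
    @settings(max_examples=60, deadline=None)
    def test_parameter_recovery(self, c_o, c_n, m_o, m_n, rho_o, rho_n_frac):
        """Synthetic two-chelator systems generated from known (C_O*, C_N*)
        are recovered exactly by the solve."""
        rho_n = rho_o * rho_n_frac  # keep the system away from singularity
        ratios = DenticityRatios(rho_o=rho_o, rho_n=rho_n)
        g = GradientSet.from_back_extrapolation(
            "EDTA", "Xx", m_o=m_o, m_n=m_n, dg_default=-50.0,
            c_o_default=34.4, c_n_default=65.9,
        )
        z = g.dg_zero
        dg_exp_ref = z + m_o * c_o + m_n * c_n
        assume(abs(dg_exp_ref) > 1.0)
        assume(abs(1 - z / dg_exp_ref) > 0.05)
        rhs = rho_o * m_o * c_o + rho_n * m_n * c_n
        # consistent second-chelator energy under the ratio-scaled model
        dg_exp_other = rhs / (1 - z / dg_exp_ref)
        sol = solve_cij(g, dg_exp_ref, dg_exp_other, ratios)
        assert sol.c_o == pytest.approx(c_o, abs=1e-6)
        assert sol.c_n == pytest.approx(c_n, abs=1e-6)

    def test_direct_solve_flags_nonphysical_metals(self, exp_dg):
        """Solving with each chelator's own gradients (including the positive
        NTA m(N) values) yields negative C_ij for Mg/Y/La: the behaviour
        that motivates the ratio-based scheme."""
        flags = {}
        for metal in cijfit.METALS:
            ge = cijfit.reference_gradient_set(metal, "EDTA")
            gn = cijfit.reference_gradient_set(metal, "NTA")
            sol = solve_cij_direct(
                ge, gn, exp_dg[(metal, "EDTA")], exp_dg[(metal, "NTA")]
            )
            flags[metal] = sol.physical
        assert not flags["Mg2+"]
        assert not flags["Y3+"]
        assert not flags["La3+"]

    def test_lstsq_reduces_to_exact_solve(self, edta_gradients):
        g = edta_gradients["Ca2+"]
        exact = solve_cij(g, -60.8, -37.5)
        ls = solve_cij_lstsq(g, -60.8, [(-37.5, DenticityRatios())])
        assert ls.c_o == pytest.approx(exact.c_o, rel=1e-9)
        assert ls.c_n == pytest.approx(exact.c_n, rel=1e-9)


class TestPredictAndContour:
    def test_round_trip_through_defaults(self, edta_gradients):
        for g in edta_gradients.values():
            assert predict_dg(g, g.c_o_default, g.c_n_default) == pytest.approx(
                g.dg_default, abs=1e-10
            )

    def test_monotone_in_c_o(self, edta_gradients):
        g = edta_gradients["Ca2+"]  # m_o < 0
        vals = [predict_dg(g, c, 65.9) for c in (0, 10, 50, 100)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_contour_self_consistency(self, edta_gradients):
        g = edta_gradients["Ca2+"]
        pts = contour_line(g, -60.8, np.linspace(0, 120, 25))
        for c_o, c_n in pts:
            assert predict_dg(g, c_o, c_n) == pytest.approx(-60.8, abs=1e-9)

    def test_solution_lies_on_experimental_contour(self, edta_gradients):
        sol = cijfit.solve_reference("Ca2+")
        g = edta_gradients["Ca2+"]
        (_, c_n_on_contour), = contour_line(g, -60.8, [sol.c_o])
        assert c_n_on_contour == pytest.approx(sol.c_n, abs=1e-9)

    def test_gradient_rescaling_preserves_contour_energy(self, edta_gradients):
        """Doubling both gradients and halving the C offsets from any contour
        point leaves the predicted energy on target."""
        g = edta_gradients["Ca2+"]
        g2 = GradientSet(g.chelator, g.metal, 2 * g.m_o, 2 * g.m_n,
                         g.dg_default, g.c_o_default, g.c_n_default, g.dg_zero)
        for c_o, c_n in contour_line(g, -60.8, np.linspace(5, 80, 9)):
            assert predict_dg(g2, c_o / 2, c_n / 2) == pytest.approx(-60.8, abs=1e-9)

    def test_degenerate_contour(self):
        g = GradientSet("EDTA", "Xx", m_o=-0.5, m_n=0.0, dg_default=-50.0,
                        c_o_default=34.4, c_n_default=65.9, dg_zero=-30.0)
        with pytest.raises(ValueError):
            contour_line(g, -60.8, [0.0, 10.0])


def test_read_observations_csv_and_json(tmp_path):
    csv = tmp_path / "obs.csv"
    csv.write_text(
        "chelator,metal,c_o,c_n,dg_sim\nEDTA,Ca2+,0,65.9,-41.3\nEDTA,Ca2+,34.4,65.9,-56.0\n"
    )
    obs = read_observations(csv)
    assert len(obs) == 2 and obs[1].c_o == 34.4

    js = tmp_path / "obs.json"
    js.write_text(
        '[{"chelator":"EDTA","metal":"Ca2+","c_o":0,"c_n":65.9,"dg_sim":-41.3}]'
    )
    assert read_observations(js)[0].dg_sim == -41.3

    bad = tmp_path / "bad.csv"
    bad.write_text("a,b\n1,2\n")
    with pytest.raises(ValueError, match="missing columns"):
        read_observations(bad)
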