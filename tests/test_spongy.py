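"""Spongy-layer Kubelka-Munk tests: coefficient mapping, eigenvalues,
boundary matching and equivalence with independent numerical solutions of
the underlying two-point boundary-value problem."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_bvp
from scipy.linalg import expm

from leafoptics import (
    A_SP_FLOOR,
    SpongyParams,
    build_km_matrix,
    km_eigenvalues,
    km_evaluate,
    km_solve,
)

L_CM = 58.6e-4


def _as_matrix(L):
    return np.array(
        [
            [L.L11, 0.0, 0.0, 0.0],
            [0.0, L.L22, 0.0, 0.0],
            [L.L31, L.L32, L.L33, L.L34],
            [L.L41, L.L42, L.L43, L.L44],
        ],
        dtype=float,
    )


def _expm_bvp(L, l, ic_h, is_h, jc_hl, js_hl, x):
    """Independent oracle: numerical two-point solve of the linear depth
    ODE via the matrix exponential, with the two unknown top-boundary
    values eliminated against the bottom-boundary conditions."""
    M = _as_matrix(L)
    E = expm(M * l)
    A = np.array([[E[1, 1], E[1, 3]], [E[3, 1], E[3, 3]]])
    b = np.array(
        [jc_hl - E[1, 0] * ic_h - E[1, 2] * is_h,
         js_hl - E[3, 0] * ic_h - E[3, 2] * is_h]
    )
    jc0, js0 = np.linalg.solve(A, b)
    y0 = np.array([ic_h, jc0, is_h, js0])
    return expm(M * x) @ y0


class TestMatrix:
    def test_coefficient_mapping(self):
        sp = SpongyParams(l=L_CM, a_Sp=20.0, s_Sp=600.0, f=0.5)
        L = build_km_matrix(sp, 0.0, 0.0)
        assert L.L11 == pytest.approx(-620.0)
        assert L.L22 == pytest.approx(+620.0)
        assert L.L31 == pytest.approx(300.0)
        assert L.L32 == pytest.approx(300.0)
        assert L.L33 == pytest.approx(-640.0)
        assert L.L34 == pytest.approx(600.0)
        assert L.L41 == pytest.approx(-300.0)
        assert L.L42 == pytest.approx(-300.0)
        assert L.L43 == pytest.approx(-600.0)
        assert L.L44 == pytest.approx(+640.0)

    def test_no_scattering_decouples(self):
        sp = SpongyParams(l=L_CM, a_Sp=20.0, s_Sp=0.0)
        L = build_km_matrix(sp, 0.3, 0.2)
        assert L.L31 == L.L32 == L.L41 == L.L42 == 0.0
        assert L.L34 == L.L43 == 0.0
        assert L.L33 == pytest.approx(-40.0)

    def test_scattering_gains_balance_collimated_loss(self):
        # light scattered out of I_C reappears split f/(1-f) between the
        # two diffuse flows: L31 - L41 = s_Sp / cos(beta_I1)
        b1 = 0.35
        sp = SpongyParams(l=L_CM, a_Sp=12.0, s_Sp=800.0, f=0.3)
        L = build_km_matrix(sp, b1, 0.1)
        assert L.L31 - L.L41 == pytest.approx(800.0 / math.cos(b1), rel=1e-12)
        # and the collimated decay splits into absorption + that loss
        assert -L.L11 == pytest.approx((12.0 + 800.0) / math.cos(b1), rel=1e-12)

    def test_flux_divergence_identity(self):
        # d(I_C - J_C + I_S - J_S)/dx must equal minus the absorbed power:
        # column sums of the signed matrix reduce to pure-absorption terms
        b1, b2 = 0.3, 0.15
        sp = SpongyParams(l=L_CM, a_Sp=33.0, s_Sp=700.0, f=0.4)
        L = build_km_matrix(sp, b1, b2)
        a = 33.0
        sign = np.array([1.0, -1.0, 1.0, -1.0])
        M = _as_matrix(L)
        col = sign @ M  # coefficients of d(net flux)/dx per flow
        assert col[0] == pytest.approx(-a / math.cos(b1), rel=1e-12)
        assert col[1] == pytest.approx(-a / math.cos(b2), rel=1e-12)
        assert col[2] == pytest.approx(-2 * a, rel=1e-12)
        assert col[3] == pytest.approx(-2 * a, rel=1e-12)

    def test_grazing_angle_rejected(self):
        sp = SpongyParams(l=L_CM, a_Sp=1.0)
        with pytest.raises(ValueError):
            build_km_matrix(sp, math.pi / 2, 0.0)


class TestEigenvalues:
    def test_classical_km_exponent(self):
        sp = SpongyParams(l=L_CM, a_Sp=20.0, s_Sp=600.0, f=0.5)
        L = build_km_matrix(sp, 0.0, 0.0)
        l1, l2, l3, l4 = km_eigenvalues(L)
        assert l1 == pytest.approx(-620.0)
        assert l2 == pytest.approx(+620.0)
        expected = 2.0 * math.sqrt(20.0 * (20.0 + 600.0))
        assert l3 == pytest.approx(expected, rel=1e-12)
        assert l3 == pytest.approx(222.7, abs=0.1)
        assert l4 == pytest.approx(-expected, rel=1e-12)

    def test_no_scattering_block_is_diagonal(self):
        sp = SpongyParams(l=L_CM, a_Sp=20.0, s_Sp=0.0)
        L = build_km_matrix(sp, 0.0, 0.0)
        _, _, l3, l4 = km_eigenvalues(L)
        assert (l3, l4) == (pytest.approx(40.0), pytest.approx(-40.0))

    def test_matches_generic_eigensolver_and_characteristic_equation(self, rng):
        for _ in range(25):
            sp = SpongyParams(
                l=L_CM,
                a_Sp=rng.uniform(0.5, 500),
                s_Sp=rng.uniform(0, 1500),
                f=rng.uniform(0.1, 0.9),
            )
            L = build_km_matrix(sp, rng.uniform(0, 0.7), rng.uniform(0, 0.7))
            lams = np.sort(np.asarray(km_eigenvalues(L), dtype=float))
            generic = np.sort(np.linalg.eigvals(_as_matrix(L)).real)
            assert lams == pytest.approx(generic, rel=1e-9)
            # characteristic-equation residual of the scattered block
            for lam in lams:
                block = np.array(
                    [[L.L33 - lam, L.L34], [L.L43, L.L44 - lam]]
                )
                res = (L.L11 - lam) * (L.L22 - lam) * np.linalg.det(block)
                assert abs(res) <= 1e-9 * max(abs(lam), 1.0) ** 4 + 1e-6


class TestSolve:
    def test_zero_boundaries_zero_solution(self):
        sp = SpongyParams(l=L_CM, a_Sp=20.0, s_Sp=600.0)
        sol = km_solve(0.0, 0.0, 0.0, 0.0, sp)
        for x in (0.0, L_CM / 2, L_CM):
            st = km_evaluate(sol, x)
            assert st.I_C == st.I_S == st.J_C == st.J_S == 0.0

    def test_boundary_recovery(self):
        sp = SpongyParams(l=L_CM, a_Sp=20.0, s_Sp=600.0)
        ich, ish, jchl, jshl = 1000.0, 150.0, 80.0, 40.0
        sol = km_solve(ich, ish, jchl, jshl, sp, beta_I1=0.3, beta_I2=0.2)
        top = km_evaluate(sol, 0.0)
        bottom = km_evaluate(sol, sp.l)
        assert float(top.I_C) == pytest.approx(ich, rel=1e-9)
        assert float(top.I_S) == pytest.approx(ish, rel=1e-9)
        assert float(bottom.J_C) == pytest.approx(jchl, rel=1e-9)
        assert float(bottom.J_S) == pytest.approx(jshl, rel=1e-9)

    def test_scattering_couples_flows(self):
        sp = SpongyParams(l=L_CM, a_Sp=20.0, s_Sp=600.0, f=0.5)
        sol = km_solve(1000.0, 0.0, 0.0, 0.0, sp)
        top = km_evaluate(sol, 0.0)
        bottom = km_evaluate(sol, sp.l)
        assert float(top.J_S) > 0.0  # upward diffuse reflection
        assert float(bottom.I_S) > 0.0  # downward diffuse transmission

    def test_matches_expm_oracle_random_sweep(self, rng):
        worst = 0.0
        for _ in range(60):
            a = rng.uniform(1, 500)
            s = rng.uniform(0, 1500)
            l = rng.uniform(10e-4, 150e-4)
            b1 = math.radians(rng.uniform(0, 40))
            b2 = math.radians(rng.uniform(0, 40))
            sp = SpongyParams(l=l, a_Sp=a, s_Sp=s, f=0.5)
            L = build_km_matrix(sp, b1, b2)
            ich, ish, jchl, jshl = rng.uniform(0, 1000, 4)
            sol = km_solve(ich, ish, jchl, jshl, sp, L)
            for frac in (0.0, 0.31, 0.77, 1.0):
                x = frac * l
                st = km_evaluate(sol, x)
                ana = np.array(
                    [float(st.I_C), float(st.J_C), float(st.I_S), float(st.J_S)]
                )
                num = _expm_bvp(L, l, ich, ish, jchl, jshl, x)
                scale = np.abs(num).max() + 1e-9
                worst = max(worst, float(np.abs(ana - num).max() / scale))
        assert worst < 1e-5

    def test_matches_collocation_bvp_oracle(self):
        # cross-check with an adaptive-collocation integration on a
        # moderately stiff parameter set
        a, s, l = 20.0, 600.0, L_CM
        b1 = b2 = math.radians(23.9)
        sp = SpongyParams(l=l, a_Sp=a, s_Sp=s, f=0.5)
        L = build_km_matrix(sp, b1, b2)
        M = _as_matrix(L)
        ich, ish, jchl, jshl = 1000.0, 100.0, 50.0, 20.0
        res = solve_bvp(
            lambda x, y: M @ y,
            lambda ya, yb: np.array(
                [ya[0] - ich, yb[1] - jchl, ya[2] - ish, yb[3] - jshl]
            ),
            np.linspace(0, l, 101),
            np.ones((4, 101)),
            tol=1e-7,
            max_nodes=200000,
        )
        assert res.success
        sol = km_solve(ich, ish, jchl, jshl, sp, L)
        for frac in (0.0, 0.5, 1.0):
            st = km_evaluate(sol, frac * l)
            ana = np.array([float(st.I_C), float(st.J_C), float(st.I_S), float(st.J_S)])
            num = res.sol(frac * l)
            assert ana == pytest.approx(num, rel=1e-5, abs=1e-4)

    def test_vectorized_over_wavelength(self, rng):
        a = rng.uniform(1, 400, size=30)
        sp = SpongyParams(l=L_CM, a_Sp=a, s_Sp=600.0)
        sol = km_solve(
            np.full(30, 1000.0), np.full(30, 50.0), np.zeros(30), np.zeros(30), sp
        )
        top = km_evaluate(sol, 0.0)
        assert np.asarray(top.J_S).shape == (30,)
        # each wavelength independently matches its scalar solve
        for k in (0, 13, 29):
            spk = SpongyParams(l=L_CM, a_Sp=float(a[k]), s_Sp=600.0)
            solk = km_solve(1000.0, 50.0, 0.0, 0.0, spk)
            assert float(np.asarray(top.J_S)[k]) == pytest.approx(
                float(km_evaluate(solk, 0.0).J_S), rel=1e-12
            )

    def test_upward_diffuse_output_increases_with_scattering_and_thickness(self):
        js_by_s = [
            float(
                km_evaluate(
                    km_solve(
                        1000.0, 0.0, 0.0, 0.0,
                        SpongyParams(l=L_CM, a_Sp=5.0, s_Sp=s),
                    ),
                    0.0,
                ).J_S
            )
            for s in (200.0, 600.0, 1000.0, 1400.0)
        ]
        assert js_by_s == sorted(js_by_s)
        js_by_l = [
            float(
                km_evaluate(
                    km_solve(
                        1000.0, 0.0, 0.0, 0.0,
                        SpongyParams(l=l, a_Sp=5.0, s_Sp=600.0),
                    ),
                    0.0,
                ).J_S
            )
            for l in (20e-4, 60e-4, 120e-4)
        ]
        assert js_by_l == sorted(js_by_l)

    def test_optically_thick_layer_stays_finite(self):
        sp = SpongyParams(l=150e-4, a_Sp=5000.0, s_Sp=1500.0)
        sol = km_solve(1000.0, 100.0, 50.0, 20.0, sp)
        for x in (0.0, sp.l / 2, sp.l):
            st = km_evaluate(sol, x)
            for v in (st.I_C, st.I_S, st.J_C, st.J_S):
                assert np.all(np.isfinite(v))

    def test_absorption_floor_is_continuous(self):
        sp_floor = SpongyParams(l=L_CM, a_Sp=0.0, s_Sp=600.0)  # clamped
        assert float(np.asarray(sp_floor.a_Sp)) == A_SP_FLOOR
        js = [
            float(
                km_evaluate(
                    km_solve(
                        1000.0, 0.0, 0.0, 0.0,
                        SpongyParams(l=L_CM, a_Sp=a, s_Sp=600.0),
                    ),
                    0.0,
                ).J_S
            )
            for a in (0.0, A_SP_FLOOR, 10 * A_SP_FLOOR, 1e-4)
        ]
        assert js[0] == js[1]
        assert js[1] == pytest.approx(js[2], rel=1e-3)
        assert js[2] == pytest.approx(js[3], rel=1e-2)

    def test_out_of_range_depth_rejected(self):
        sp = SpongyParams(l=L_CM, a_Sp=20.0)
        sol = km_solve(1.0, 0.0, 0.0, 0.0, sp)
        with pytest.raises(ValueError):
            km_evaluate(sol, 2 * L_CM)
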