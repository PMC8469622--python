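"""Effective-field terms, Cayley LLG integration and relaxation."""

import numpy as np
import pytest

from cubemag.demag import DemagKernel, demag_field_direct, demag_tensor
from cubemag.geometry import DiscretizedGeometry, build_truncated_cube
from cubemag.materials import K_B, MU0, magnetite
from cubemag.micromag import (ConvergenceError, LLGSolver, MagnetizationState,
                              ThermalFieldParams, uniform_state)

from conftest import macrospin


# --------------------------------------------------------------------- demag
class TestDemag:
    def test_uniform_cube_mean_field_is_minus_Ms_over_3(self, mat):
        n = 12
        mask = np.ones((n, n, n), bool)
        M = np.zeros((n, n, n, 3))
        M[..., 2] = mat.Ms
        H = DemagKernel((n, n, n)).field(M)
        assert H[..., 2].mean() / mat.Ms == pytest.approx(-1 / 3, rel=5e-3)
        assert abs(H[..., 0].mean()) < 1e-6 * mat.Ms

    def test_self_tensor_trace(self):
        N = demag_tensor(0, 0, 0)
        assert float(N["xx"]) == pytest.approx(1 / 3, abs=1e-12)
        assert float(N["xx"] + N["yy"] + N["zz"]) == pytest.approx(1.0,
                                                                   abs=1e-12)

    def test_two_cell_field_equals_direct_sum(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[0, 1, 2] = mask[3, 2, 0] = True
        rng = np.random.default_rng(3)
        M = np.where(mask[..., None], rng.standard_normal((4, 4, 4, 3)) * 4e5,
                     0.0)
        Hf = DemagKernel((4, 4, 4)).field(M)
        Hd = demag_field_direct(M, mask)
        assert np.allclose(Hf[mask], Hd[mask], rtol=1e-12, atol=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_fft_equals_direct_sum_on_random_small_masks(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(2, 6, size=3))
        mask = rng.random(shape) > 0.35
        if not mask.any():
            mask[0, 0, 0] = True
        M = np.where(mask[..., None],
                     rng.standard_normal(shape + (3,)) * 4e5, 0.0)
        Hf = DemagKernel(shape).field(M)
        Hd = demag_field_direct(M, mask)
        scale = np.abs(Hd[mask]).max()
        assert np.abs(Hf[mask] - Hd[mask]).max() < 1e-12 * scale

    def test_linearity_under_sign_flip(self):
        rng = np.random.default_rng(5)
        mask = rng.random((5, 5, 5)) > 0.5
        M = np.where(mask[..., None], rng.standard_normal((5, 5, 5, 3)) * 4e5,
                     0.0)
        K = DemagKernel((5, 5, 5))
        assert np.allclose(K.field(-M), -K.field(M), rtol=0, atol=1e-8)

    def test_magnetostatic_self_energy_nonnegative(self, cube20, mat):
        sol = LLGSolver(cube20, mat)
        rng = np.random.default_rng(11)
        m = rng.standard_normal(cube20.grid_shape + (3,))
        m /= np.linalg.norm(m, axis=-1, keepdims=True)
        m[~cube20.mask] = 0.0
        assert sol.energies(m, np.zeros(3))["E_m"] >= 0.0

    def test_grid_mismatch_raises(self, mat):
        K = DemagKernel((4, 4, 4))
        with pytest.raises(ValueError, match="grid mismatch"):
            K.field(np.zeros((5, 5, 5, 3)))


# ------------------------------------------------------------------ exchange
class TestExchange:
    def test_uniform_magnetization_gives_zero_field(self, cube20, mat):
        sol = LLGSolver(cube20, mat, demag=False)
        m = uniform_state(cube20, [0.3, -0.5, 0.8]).m
        assert np.abs(sol.exchange_field(m)).max() < 1e-6

    @pytest.mark.parametrize("stencil", ["6", "26"])
    def test_spin_spiral_matches_continuum_laplacian(self, mat, stencil):
        # m = (sin qx, 0, cos qx) -> |H_ex| = 2 k_ex q^2 / (mu0 Ms)
        n = 64
        ds = 2.0
        mask = np.ones((n, 3, 3), bool)
        geom = DiscretizedGeometry(ds=ds, mask=mask, origin=np.zeros(3),
                                   particle_id=np.zeros((n, 3, 3), int))
        sol = LLGSolver(geom, mat, demag=False, exchange_stencil=stencil)
        q = 0.1 / (ds * 1e-9)  # q*ds = 0.1, small
        x = np.arange(n) * ds * 1e-9
        m = np.zeros((n, 3, 3, 3))
        m[..., 0] = np.sin(q * x)[:, None, None]
        m[..., 2] = np.cos(q * x)[:, None, None]
        h = sol.exchange_field(m)
        expected = 2 * mat.k_ex * q**2 / (MU0 * mat.Ms)
        mags = np.linalg.norm(h[5:-5, 1, 1], axis=-1)  # interior cells
        assert mags == pytest.approx(expected, rel=0.02)

    def test_single_cell_has_no_exchange(self, macrospin_geom, mat):
        sol = LLGSolver(macrospin_geom, mat, demag=False)
        m = uniform_state(macrospin_geom, [1, 0, 0]).m
        assert np.abs(sol.exchange_field(m)).max() == 0.0

    def test_exchange_energy_nonnegative(self, cube20, mat):
        sol = LLGSolver(cube20, mat, demag=False)
        rng = np.random.default_rng(2)
        m = rng.standard_normal(cube20.grid_shape + (3,))
        m /= np.linalg.norm(m, axis=-1, keepdims=True)
        m[~cube20.mask] = 0.0
        assert sol.energies(m, np.zeros(3))["E_ex"] >= 0.0


# ---------------------------------------------------------------- anisotropy
class TestAnisotropy:
    def test_easy_axis_100_gives_zero_field_and_energy(self, macrospin_geom,
                                                       mat):
        sol = LLGSolver(macrospin_geom, mat, demag=False)
        m = uniform_state(macrospin_geom, [1, 0, 0]).m
        assert np.abs(sol.anisotropy_field(m)).max() < 1e-12
        assert sol.energies(m, np.zeros(3))["E_an"] == pytest.approx(0.0,
                                                                     abs=1e-9)

    def test_111_energy_closed_form(self, macrospin_geom, mat):
        sol = LLGSolver(macrospin_geom, mat, demag=False)
        m = uniform_state(macrospin_geom, [1, 1, 1]).m
        e = sol.energies(m, np.zeros(3))["E_an"]
        assert e == pytest.approx(mat.K1 / 3 + mat.K2 / 27, rel=1e-12)
        assert e == pytest.approx(-4663.0, abs=1.0)  # J/m^3
        # with K1 < 0, <111> is easy: the field is parallel to m (restoring)
        h = sol.anisotropy_field(m)[0, 0, 0]
        mhat = m[0, 0, 0]
        assert h @ mhat > 0
        assert np.linalg.norm(np.cross(h, mhat)) < 1e-9 * np.linalg.norm(h)

    def test_field_is_minus_energy_gradient(self, macrospin_geom, mat):
        """H_an == -(de_an/dm) / (mu0 Ms) at 100 random unit vectors."""
        sol = LLGSolver(macrospin_geom, mat, demag=False)
        K1, K2 = mat.K1, mat.K2

        def e_an(v):
            x2, y2, z2 = v[0] ** 2, v[1] ** 2, v[2] ** 2
            return K1 * (x2 * y2 + y2 * z2 + z2 * x2) + K2 * x2 * y2 * z2

        rng = np.random.default_rng(42)
        eps = 1e-6
        for _ in range(100):
            v = rng.standard_normal(3)
            v /= np.linalg.norm(v)
            m = np.zeros((1, 1, 1, 3))
            m[0, 0, 0] = v
            h = sol.anisotropy_field(m)[0, 0, 0]
            g = np.empty(3)
            for i in range(3):
                vp, vm = v.copy(), v.copy()
                vp[i] += eps
                vm[i] -= eps
                g[i] = (e_an(vp) - e_an(vm)) / (2 * eps)
            expected = -g / (MU0 * mat.Ms)
            assert np.allclose(h, expected, rtol=1e-6,
                               atol=1e-6 * max(np.abs(expected).max(), 1.0))


# ------------------------------------------------------------- thermal field
class TestThermalField:
    def test_zero_temperature_gives_zero_field(self, cube20, mat):
        sol = LLGSolver(cube20, mat, demag=False)
        h = sol.thermal_field(ThermalFieldParams(T=0.0, dt=1e-12), seed=1)
        assert np.abs(h).max() == 0.0

    def test_variance_matches_fluctuation_dissipation(self, mat):
        geom = macrospin(ds=2.0)
        matT = magnetite(thermal=True)
        sol = LLGSolver(geom, matT, demag=False)
        dt = 1e-12
        T = 300.0
        draws = np.array([
            sol.thermal_field(ThermalFieldParams(T=T, dt=dt), seed=9, step=s)
            [0, 0, 0] for s in range(40000)
        ]).ravel()
        var_expected = (2 * matT.alpha * K_B * T
                        / (matT.gamma * MU0 * matT.Ms * (2e-9) ** 3 * dt))
        assert draws.mean() == pytest.approx(0.0,
                                             abs=4 * np.sqrt(var_expected
                                                             / len(draws)))
        assert draws.var() == pytest.approx(var_expected, rel=0.02)

    def test_deterministic_under_seed(self, cube20, mat):
        sol = LLGSolver(cube20, mat, demag=False)
        p = ThermalFieldParams(T=300.0, dt=1e-12)
        a = sol.thermal_field(p, seed=4, step=17)
        b = sol.thermal_field(p, seed=4, step=17)
        c = sol.thermal_field(p, seed=5, step=17)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_negative_temperature_rejected(self):
        with pytest.raises(ValueError):
            ThermalFieldParams(T=-1.0, dt=1e-12)

    def test_macrospin_samples_boltzmann_distribution(self):
        """Long-run orientation histogram of a uniaxial macrospin at fixed T
        matches the Boltzmann distribution (KS test)."""
        from scipy.stats import kstest

        ds = 8.0  # nm; V = 5.12e-25 m^3
        V = (ds * 1e-9) ** 3
        T = 300.0
        Ku = 2.0 * K_B * T / V  # barrier ~ 2 kT: fast mixing, clear structure
        mat = magnetite(thermal=True, K1=0.0, K2=0.0, Ku=Ku,
                        easy_axis=(0, 0, 1), alpha=0.5)
        n_rep = 384
        mask = np.ones((n_rep, 1, 1), bool)
        geom = DiscretizedGeometry(ds=ds, mask=mask, origin=np.zeros(3),
                                   particle_id=np.zeros((n_rep, 1, 1), int))
        sol = LLGSolver(geom, mat, demag=False, exchange_stencil="6")
        sol.cex = 0.0  # independent replicas: decouple the cells
        rng = np.random.default_rng(0)
        m0 = rng.standard_normal((n_rep, 1, 1, 3))
        m0 /= np.linalg.norm(m0, axis=-1, keepdims=True)
        st, _ = sol.run_thermal(MagnetizationState(m0), np.zeros(3), T=T,
                                dt=2e-12, n_steps=4000, seed=123)
        mz = st.m[:, 0, 0, 2]
        sigma = Ku * V / (K_B * T)

        # Boltzmann CDF for u = m_z: p(u) ∝ exp(sigma u^2)
        u = np.linspace(-1, 1, 2001)
        pdf = np.exp(sigma * u**2)
        cdf = np.cumsum(pdf)
        cdf /= cdf[-1]
        res = kstest(mz, lambda x: np.interp(x, u, cdf))
        assert res.pvalue > 0.01


# ------------------------------------------------------------ LLG integrator
class TestLLGIntegration:
    def test_larmor_precession_period(self, macrospin_geom):
        mat = magnetite(alpha=1e-14, K1=0.0, K2=0.0)  # alpha -> 0 limit
        sol = LLGSolver(macrospin_geom, mat, demag=False)
        H = np.array([0.0, 0.0, 1e4])
        st = uniform_state(macrospin_geom, [1, 0, 0])
        period = 2 * np.pi / (mat.gamma * 1e4)
        assert period == pytest.approx(2.843e-9, rel=1e-3)
        dt = period / 2000
        for _ in range(2000):
            h = sol.effective_field(st.m, H)
            st = sol.llg_step(st, h, dt)
        assert st.m[0, 0, 0, 0] == pytest.approx(1.0, abs=1e-5)
        assert st.m[0, 0, 0, 2] == pytest.approx(0.0, abs=1e-9)

    def test_damped_motion_aligns_and_dissipates(self, macrospin_geom):
        mat = magnetite(alpha=0.1, K1=0.0, K2=0.0)
        sol = LLGSolver(macrospin_geom, mat, demag=False)
        H = np.array([0.0, 0.0, 5e4])
        st = uniform_state(macrospin_geom, [1, 0, 0])
        mz_prev, e_prev = 0.0, np.inf
        for k in range(4000):
            h = sol.effective_field(st.m, H)
            st = sol.llg_step(st, h, 1e-12)
            if k % 400 == 0:
                mz = st.m[0, 0, 0, 2]
                e = sol.energies(st.m, H)["E_Z"]
                assert mz >= mz_prev - 1e-12
                assert e <= e_prev + 1e-12
                mz_prev, e_prev = mz, e
        assert st.m[0, 0, 0, 2] > 0.99

    def test_norm_preserved_to_machine_precision(self, cube20, mat):
        sol = LLGSolver(cube20, mat, demag=False)
        st = uniform_state(cube20, [1, 0.2, 0.1])
        rng = np.random.default_rng(8)
        H = rng.standard_normal(3) * 1e4
        for _ in range(10_000):
            h = sol.effective_field(st.m, H)
            st = sol.llg_step(st, h, 1e-12)
        norms = np.linalg.norm(st.m[cube20.mask], axis=-1)
        assert np.abs(norms - 1.0).max() < 1e-12

    def test_energy_conserved_without_damping(self, macrospin_geom):
        # alpha -> 0, static field + anisotropy: total energy is constant
        # (midpoint Cayley trajectory; run_thermal at T = 0 is deterministic)
        mat = magnetite(alpha=1e-14)
        sol = LLGSolver(macrospin_geom, mat, demag=False)
        H = np.array([3e3, -2e3, 5e3])
        st = uniform_state(macrospin_geom, [0.6, 0.8, 0.0])
        e0 = sol.energies(st.m, H)["E_total"]
        st, _ = sol.run_thermal(st, H, T=0.0, dt=5e-13, n_steps=5000, seed=0)
        e1 = sol.energies(st.m, H)["E_total"]
        assert e1 == pytest.approx(e0, rel=1e-4)


# ----------------------------------------------------------------- relaxation
class TestRelax:
    def test_saturated_state_converges_immediately(self, cube20, mat):
        sol = LLGSolver(cube20, mat)
        d = np.array([1.0, 0.0, 0.0])
        st = sol.relax(uniform_state(cube20, d), 1200e3 * d, method="minimize")
        mm = st.m[cube20.mask]
        assert np.mean(mm @ d) > 0.999

    def test_relax_modes_agree_on_macrospin_equilibrium(self, macrospin_geom):
        mat = magnetite(K1=0.0, K2=0.0, Ku=10e3, easy_axis=(0, 0, 1))
        sol = LLGSolver(macrospin_geom, mat, demag=False)
        H = 20e3 * np.array([np.sin(0.4), 0.0, np.cos(0.4)])
        st0 = uniform_state(macrospin_geom, [0.1, 0.0, 1.0])
        m_a = sol.relax(st0.copy(), H, method="minimize").m[0, 0, 0]
        m_b = sol.relax(st0.copy(), H, method="llg").m[0, 0, 0]
        assert np.allclose(m_a, m_b, atol=2e-4)

    def test_nonconvergence_raises_with_residual(self, macrospin_geom, mat):
        sol = LLGSolver(macrospin_geom, mat, demag=False)
        st = uniform_state(macrospin_geom, [0.0, 1.0, 0.0])
        with pytest.raises(ConvergenceError) as exc:
            sol.relax(st, np.array([5e4, 0, 0]), max_steps=3,
                      method="minimize")
        assert exc.value.residual is not None

    def test_axis_relabeling_symmetry(self, mat):
        """x<->y relabeling of a symmetric geometry+field leaves results
        invariant."""
        geom = build_truncated_cube(20.0, 2.5)
        sol = LLGSolver(geom, mat)
        dx = np.array([1.0, 0.0, 0.0])
        dy = np.array([0.0, 1.0, 0.0])
        sx = sol.relax(uniform_state(geom, dx), 50e3 * dx, method="minimize")
        sy = sol.relax(uniform_state(geom, dy), 50e3 * dy, method="minimize")
        mx = sx.m[geom.mask] @ dx
        my = sy.m[geom.mask] @ dy
        assert np.mean(mx) == pytest.approx(np.mean(my), rel=1e-6, abs=1e-8)
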