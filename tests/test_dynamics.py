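"""Time integrators: stability bounds, dispersion, equivariance, couplings."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from cortifield.dynamics import (
    KGParams,
    LimitCycleParams,
    MultilayerParams,
    MultilayerState,
    QuarticParams,
    integrate_kg,
    integrate_limit_cycle,
    integrate_multilayer,
    integrate_quartic,
    integrate_tessellated,
    stable_dt,
)
from cortifield.errors import DivergenceError, StabilityError, SymmetryError
from cortifield.fixtures import discrete_mode_eigenvalue, make_plane_wave
from cortifield.grid_fields import FieldState, GridSpec, IntegrityError
from cortifield.spectra import measure_plane_wave_frequency

from conftest import commensurate_k


class TestStableDt:
    def test_free_field_hits_safety_floor(self, grid16):
        assert stable_dt(KGParams(c=0.0, m=0.0), grid16) == pytest.approx(1.0)

    @pytest.mark.parametrize("h", [1.0, 0.5])
    def test_massless_kg_cfl(self, h):
        # leapfrog + 5-point stencil: dt <= safety * h / (c sqrt(2))
        g = GridSpec(16, 16, dx=h, dy=h)
        assert stable_dt(KGParams(c=1.0, m=0.0), g) == pytest.approx(
            0.5 * h / np.sqrt(2.0)
        )

    def test_doubling_c_halves_dt(self, grid16):
        d1 = stable_dt(KGParams(c=1.0, m=0.0), grid16)
        d2 = stable_dt(KGParams(c=2.0, m=0.0), grid16)
        assert d1 / d2 == pytest.approx(2.0)

    def test_oversized_dt_rejected_before_integrating(self, grid16, kg_params):
        s = make_plane_wave(grid16, 1.0, commensurate_k(grid16), kg_params)
        bad_dt = 2.0 * stable_dt(kg_params, grid16) / 0.5  # above the raw bound
        with pytest.raises(StabilityError):
            integrate_kg(s, kg_params, bad_dt, 10)


class TestKleinGordon:
    def test_zero_field_is_fixed_point(self, grid16, kg_params):
        z = FieldState(grid16, np.zeros(grid16.shape), np.zeros(grid16.shape))
        traj = integrate_kg(z, kg_params, 0.05, 50)
        assert all(np.all(s.phi == 0) and np.all(s.phi_dot == 0) for s in traj.states)

    def test_plane_wave_frequency_matches_discrete_dispersion(self, grid32):
        params = KGParams(c=1.0, m=0.0)
        k = commensurate_k(grid32, 2)
        s = make_plane_wave(grid32, 1.0, k, params)
        dt = stable_dt(params, grid32) / 4
        traj = integrate_kg(s, params, dt, 1200, stride=4)
        omega, _ = measure_plane_wave_frequency(traj, k)
        omega_disc = np.sqrt(discrete_mode_eigenvalue(grid32, k))
        assert omega == pytest.approx(omega_disc, rel=1e-3)
        # continuum limit: within 2% of c*k for k*dx < 0.3
        assert omega == pytest.approx(np.hypot(*k), rel=0.02)

    def test_c_zero_sites_decouple(self, grid16, rng):
        # c = 0 removes both propagation and (m c^2)^2 restoring: phi drifts
        # linearly with phi_dot, sites independent
        phi = rng.standard_normal(grid16.shape) + 0j
        phi_dot = rng.standard_normal(grid16.shape) + 0j
        s = FieldState(grid16, phi, phi_dot)
        traj = integrate_kg(s, KGParams(c=0.0, m=1.0), 0.1, 10)
        expect = phi + 1.0 * phi_dot
        assert np.allclose(traj[-1].phi, expect, atol=1e-12)

    def test_superposition(self, grid16, kg_params, rng):
        def mk():
            return FieldState(
                grid16,
                rng.standard_normal(grid16.shape) + 1j * rng.standard_normal(grid16.shape),
                rng.standard_normal(grid16.shape) + 1j * rng.standard_normal(grid16.shape),
            )

        s1, s2 = mk(), mk()
        a, b = 0.7, -1.3
        combo = FieldState(grid16, a * s1.phi + b * s2.phi,
                           a * s1.phi_dot + b * s2.phi_dot)
        dt = stable_dt(kg_params, grid16) / 4
        t1 = integrate_kg(s1, kg_params, dt, 100)
        t2 = integrate_kg(s2, kg_params, dt, 100)
        tc = integrate_kg(combo, kg_params, dt, 100)
        assert np.allclose(tc[-1].phi, a * t1[-1].phi + b * t2[-1].phi, atol=1e-10)

    def test_halving_dt_quarters_frequency_error(self, grid32):
        # second-order scheme: plane-wave frequency error ~ dt^2
        params = KGParams(c=1.0, m=0.0)
        k = commensurate_k(grid32, 3)
        omega_disc = np.sqrt(discrete_mode_eigenvalue(grid32, k))
        errs = []
        for dt in (0.2, 0.1):
            s = make_plane_wave(grid32, 1.0, k, params)
            traj = integrate_kg(s, params, dt, int(60 / dt), stride=1)
            omega, _ = measure_plane_wave_frequency(traj, k)
            errs.append(abs(omega - omega_disc))
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.3)


class TestQuartic:
    def test_a3_zero_reduces_bitwise_to_kg(self, grid16, rng):
        phi = rng.standard_normal(grid16.shape) + 1j * rng.standard_normal(grid16.shape)
        s = FieldState(grid16, phi, 0.3 * phi)
        q = QuarticParams(c0=0.25, a2=4.0, a3=0.0)
        kg = KGParams(c=2.0, m=np.sqrt(0.25) / 2.0**2)  # m^2 c^4 = 0.25
        dt = 0.05
        tq = integrate_quartic(s, q, dt, 60)
        tk = integrate_kg(s, kg, dt, 60)
        for a, b in zip(tq.states, tk.states):
            assert np.array_equal(a.phi, b.phi)

    def test_plane_wave_dispersion_small_k(self, grid32):
        q = QuarticParams(c0=1.0, a2=1.0, a3=1.0)
        k = commensurate_k(grid32, 1)
        s = make_plane_wave(grid32, 1.0, k, q)
        dt = stable_dt(q, grid32) / 4
        traj = integrate_quartic(s, q, dt, 4000, stride=8)
        omega, _ = measure_plane_wave_frequency(traj, k)
        kk = np.hypot(*k)
        assert omega == pytest.approx(np.sqrt(1 + kk**2 + kk**4), rel=0.01)

    def test_negative_coefficients_rejected(self):
        with pytest.raises(ValueError):
            QuarticParams(c0=1.0, a2=-1.0, a3=0.0)


class TestLimitCycleIntegrator:
    def test_u1_equivariance(self, grid16, lc_params, rng):
        x, _ = grid16.coords()
        phi = 0.9 * np.exp(1j * 0.3 * np.cos(2 * np.pi * x / 16))
        s = FieldState(grid16, phi, 1j * phi)
        alpha = rng.uniform(0, 2 * np.pi)
        rot = FieldState(grid16, np.exp(1j * alpha) * s.phi,
                         np.exp(1j * alpha) * s.phi_dot)
        dt = stable_dt(lc_params, grid16) / 4
        t1 = integrate_limit_cycle(s, lc_params, dt, 150)
        t2 = integrate_limit_cycle(rot, lc_params, dt, 150)
        scale = np.max(np.abs(t1[-1].phi))
        assert np.allclose(t2[-1].phi, np.exp(1j * alpha) * t1[-1].phi,
                           atol=1e-10 * scale)

    def test_homogeneous_matches_ode_oracle(self, lc_params):
        # c1 irrelevant for homogeneous data; compare against a high-order
        # scalar ODE integration of the same complex equation at one site
        g = GridSpec(4, 4)
        phi0, phid0 = 1.05 + 0.0j, 1j * 1.05
        s = FieldState(g, np.full(g.shape, phi0), np.full(g.shape, phid0))
        dt = 2e-3
        T = 6.0
        traj = integrate_limit_cycle(s, lc_params, dt, int(T / dt), stride=50)

        c2, c3 = lc_params.c2, lc_params.c3

        def rhs(t, y):
            phi = y[0] + 1j * y[1]
            phid = y[2] + 1j * y[3]
            acc = -phi - 1j * (c2 * phi + c3 * phi * abs(phi) ** 2)
            return [phid.real, phid.imag, acc.real, acc.imag]

        sol = solve_ivp(rhs, (0, T), [phi0.real, phi0.imag, 0.0, 1.05],
                        rtol=1e-10, atol=1e-12, dense_output=True)
        for st in traj.states[1:]:
            ref = sol.sol(st.t)
            assert st.phi[0, 0] == pytest.approx(ref[0] + 1j * ref[1], abs=2e-4)

    def test_short_window_radius_constancy_on_cycle(self, lc_params):
        # exact on-cycle state: radius constant over ~2 rotations before the
        # breathing instability (seeded at truncation level) becomes visible
        g = GridSpec(8, 8)
        phi = np.ones(g.shape, complex)
        s = FieldState(g, phi, 1j * phi)
        dt = 2 * np.pi / 400
        traj = integrate_limit_cycle(s, lc_params, dt, 800, stride=40)
        radii = np.array([np.abs(st.phi).max() for st in traj.states])
        assert np.max(np.abs(radii - 1.0)) < 5e-3

    def test_blowup_raises_divergence_error_with_time(self, lc_params):
        g = GridSpec(4, 4)
        phi = np.full(g.shape, 30.0 + 0j)
        s = FieldState(g, phi, np.zeros(g.shape))
        with pytest.raises(DivergenceError) as exc:
            integrate_limit_cycle(s, lc_params, 0.05, 20000)
        assert exc.value.t_blowup is not None and exc.value.t_blowup > 0

    def test_no_cycle_parameters_warn(self):
        with pytest.warns(UserWarning, match="limit cycle"):
            LimitCycleParams(c1=1.0, c2=1.0, c3=1.0)


class TestMultilayer:
    def make_state(self, grid, n_layers, rng):
        phi = rng.standard_normal((n_layers,) + grid.shape) \
            + 1j * rng.standard_normal((n_layers,) + grid.shape)
        return MultilayerState(grid, phi, np.zeros_like(phi))

    def test_decoupled_layers_match_kg(self, grid16, rng):
        p = MultilayerParams(np.zeros((2, 2)), A2=1.0)
        ms = self.make_state(grid16, 2, rng)
        dt = stable_dt(p, grid16) / 4
        tm = integrate_multilayer(ms, p, dt, 100)
        kg = KGParams(c=1.0, m=1.0)  # c^2 = A2 = 1, m^2 c^4 = 1
        for i in range(2):
            tk = integrate_kg(ms.layer(i), kg, dt, 100)
            assert np.allclose(tm[-1].phi[i], tk[-1].phi, atol=1e-11)

    def test_direct_vs_diagonalized_agree(self, grid16, rng):
        p = MultilayerParams(np.array([[0.0, 0.4], [0.4, 0.0]]), A2=1.0)
        ms = self.make_state(grid16, 2, rng)
        dt = stable_dt(p, grid16) / 4
        td = integrate_multilayer(ms, p, dt, 200, mode="direct")
        tg = integrate_multilayer(ms, p, dt, 200, mode="diagonalized")
        diff = max(np.max(np.abs(a.phi - b.phi)) for a, b in zip(td.states, tg.states))
        assert diff < 1e-10

    def test_two_layer_energy_beating(self, grid16):
        # homogeneous IC in layer 1 beats between layers at the eigenvalue
        # splitting of I + A1: Omega_beat = sqrt(1+g) - sqrt(1-g)
        gcoup = 0.2
        p = MultilayerParams(np.array([[0.0, gcoup], [gcoup, 0.0]]), A2=1.0)
        phi = np.zeros((2,) + grid16.shape, complex)
        phi[0] = 1.0
        ms = MultilayerState(grid16, phi, np.zeros_like(phi))
        dt = stable_dt(p, grid16) / 8
        beat = 2 * np.pi / (np.sqrt(1 + gcoup) - np.sqrt(1 - gcoup))
        n = int(beat / dt)
        traj = integrate_multilayer(ms, p, dt, n, stride=max(n // 200, 1))
        occ1 = np.array([np.mean(np.abs(s.phi[1]) ** 2) for s in traj.states])
        # layer 2 fills and empties again over one beat period
        assert occ1.max() > 0.5
        assert occ1[-1] < 0.1 * occ1.max()

    def test_non_hermitian_diagonalized_rejected(self, grid16, rng):
        p = MultilayerParams(np.array([[0.0, 1.0], [0.0, 0.0]]))
        ms = self.make_state(grid16, 2, rng)
        with pytest.raises(SymmetryError):
            integrate_multilayer(ms, p, 0.01, 5, mode="diagonalized")

    def test_layer_count_mismatch_rejected(self, grid16, rng):
        p = MultilayerParams(np.zeros((3, 3)))
        ms = self.make_state(grid16, 2, rng)
        with pytest.raises(IntegrityError):
            integrate_multilayer(ms, p, 0.01, 5)


class TestTessellated:
    def tiles(self, grid, n, rng):
        out = []
        for _ in range(n):
            phi = rng.standard_normal(grid.shape) + 1j * rng.standard_normal(grid.shape)
            out.append(FieldState(grid, phi, np.zeros_like(phi)))
        return out

    def test_zero_coupling_matches_local_dynamics(self, rng):
        g = GridSpec(8, 8)
        op = KGParams(c=1.0, m=1.0)
        tiles = self.tiles(g, 3, rng)
        dt = stable_dt(op, g) / 4
        tt = integrate_tessellated(tiles, op, np.zeros((3, 3)), dt, 80)
        for i, tile in enumerate(tiles):
            tk = integrate_kg(tile, op, dt, 80)
            assert np.allclose(tt[-1].phi[i], tk[-1].phi, atol=1e-11)

    def test_eigenvector_span_is_invariant(self, rng):
        g = GridSpec(8, 8)
        op = KGParams(c=1.0, m=1.0)
        G = np.array([[0.0, 0.3, 0.0], [0.3, 0.0, 0.3], [0.0, 0.3, 0.0]])
        w, V = np.linalg.eigh(G)
        v = V[:, -1]
        base = rng.standard_normal(g.shape) + 1j * rng.standard_normal(g.shape)
        tiles = [FieldState(g, v[i] * base, np.zeros_like(base)) for i in range(3)]
        dt = stable_dt(op, g, G=G) / 4
        traj = integrate_tessellated(tiles, op, G, dt, 120)
        for s in traj.states:
            flat = s.phi.reshape(3, -1)
            outside = flat - np.outer(v, v @ flat)
            assert np.linalg.norm(outside) / np.linalg.norm(flat) < 1e-10

    def test_two_tile_mode_beating(self):
        # G = [[0,g],[g,0]]: symmetric/antisymmetric modes split by 2g in
        # omega^2; IC in tile 1 only transfers to tile 2 and back
        g = GridSpec(8, 8)
        op = KGParams(c=1.0, m=1.0)  # homogeneous tiles: only m^2 c^4 = 1 acts
        gc = 0.3
        G = np.array([[0.0, gc], [gc, 0.0]])
        tiles = [
            FieldState(g, np.ones(g.shape, complex), np.zeros(g.shape)),
            FieldState(g, np.zeros(g.shape, complex), np.zeros(g.shape)),
        ]
        dt = stable_dt(op, g, G=G) / 8
        om_s = np.sqrt(1 - gc)  # d2/dt2 = -(m^2 c^4) + G modes: 1 -+ g
        om_a = np.sqrt(1 + gc)
        beat = 2 * np.pi / (om_a - om_s)
        n = int(beat / dt)
        traj = integrate_tessellated(tiles, op, G, dt, n, stride=max(n // 300, 1))
        occ2 = np.array([np.mean(np.abs(s.phi[1]) ** 2) for s in traj.states])
        assert occ2.max() > 0.5
        assert occ2[-1] < 0.1 * occ2.max()

    def test_g_shape_mismatch_rejected(self, rng):
        g = GridSpec(8, 8)
        tiles = self.tiles(g, 2, rng)
        with pytest.raises(IntegrityError):
            integrate_tessellated(tiles, KGParams(), np.zeros((3, 3)), 0.01, 5)

    def test_u1_equivariance_all_linear_integrators(self, grid16, rng):
        # phase-covariance of every right-hand side, random global phase
        alpha = rng.uniform(0, 2 * np.pi)
        rotate = np.exp(1j * alpha)
        phi = rng.standard_normal(grid16.shape) + 1j * rng.standard_normal(grid16.shape)
        s = FieldState(grid16, phi, 0.2j * phi)
        rot = FieldState(grid16, rotate * s.phi, rotate * s.phi_dot)
        for integ, params in [
            (integrate_kg, KGParams(c=1.0, m=0.5)),
            (integrate_quartic, QuarticParams(c0=1.0, a2=1.0, a3=0.5)),
        ]:
            dt = stable_dt(params, grid16) / 4
            t1 = integ(s, params, dt, 60)
            t2 = integ(rot, params, dt, 60)
            assert np.allclose(t2[-1].phi, rotate * t1[-1].phi, atol=1e-11)
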