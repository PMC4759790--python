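import numpy as np
import pytest

from burstswitch.diffusion_approx import km_coefficients
from burstswitch.model_core import ModelParams, find_attractors, transcription_propensity
from burstswitch.wkb import (
    HamiltonianSpec,
    _action_and_grad,
    _burst_rates,
    diffusion_hamiltonian,
    minimize_action,
    pdmp_hamiltonian,
    quasipotential_surface,
)


@pytest.fixture(scope="module")
def one_species():
    # frozen rate a = 4/cycle; x* = a*b/gamma0 = 0.6
    return ModelParams(B=30.0, K=200.0, r=0.0, r0=4.0 / 200.0)


@pytest.fixture(scope="module")
def att_conc(table1, high_x_attractor):
    return high_x_attractor / table1.K


class TestHamiltonians:
    def test_fast_rate_closures_match_propensity(self, table1, threeway):
        for p in (table1, threeway):
            lam, _ = _burst_rates(p)
            lx, ly = lam(1.3, 0.4)
            ax = transcription_propensity(p, N_other=0.4 * p.K, N_self=1.3 * p.K)
            ay = transcription_propensity(p, N_other=1.3 * p.K, N_self=0.4 * p.K)
            assert lx == pytest.approx(p.b * ax, rel=1e-12)
            assert ly == pytest.approx(p.b * ay, rel=1e-12)

    @pytest.mark.parametrize("kind", ["pdmp", "diffusion"])
    def test_zero_momentum_characteristic(self, table1, kind):
        ham = (pdmp_hamiltonian(table1) if kind == "pdmp"
               else diffusion_hamiltonian(km_coefficients(table1)))
        rng = np.random.default_rng(0)
        x, y = rng.uniform(0.0, 4.0, size=(2, 20))
        assert np.allclose(ham.H(x, y, np.zeros(20), np.zeros(20)), 0.0)

    def test_momentum_domain_guard(self, table1):
        ham = pdmp_hamiltonian(table1)
        with pytest.raises(ValueError, match="momentum"):
            ham.check_momentum(np.array([0.5, 1.01]), np.array([0.0, 0.0]))
        ham.check_momentum(0.5, -3.0)  # negative momenta are admissible

    def test_derivatives_consistent(self, table1):
        # analytic dH/dp and dH/dx against finite differences
        for ham in (pdmp_hamiltonian(table1),
                    diffusion_hamiltonian(km_coefficients(table1))):
            rng = np.random.default_rng(1)
            for _ in range(5):
                x, y = rng.uniform(0.2, 3.0, 2)
                px, py = rng.uniform(-0.5, 0.7, 2)
                e = 1e-6
                assert ham.dH_dp(x, y, px, py)[0] == pytest.approx(
                    (ham.H(x, y, px + e, py) - ham.H(x, y, px - e, py)) / (2 * e),
                    rel=1e-4,
                )
                assert ham.dH_dx(x, y, px, py)[1] == pytest.approx(
                    (ham.H(x, y + e, px, py) - ham.H(x, y - e, px, py)) / (2 * e),
                    rel=1e-4, abs=1e-8,
                )

    def test_quadratic_truncation_is_modified_diffusion(self, table1):
        # expanding the burst kernel to second order in p gives the
        # diffusion Hamiltonian with burst second moment 2b^2 (instead
        # of the geometric (2B^2+B)/K^2) and no degradation noise
        p = table1
        ham = pdmp_hamiltonian(p)
        lam, _ = _burst_rates(p)
        rng = np.random.default_rng(2)
        x, y = 1.5, 0.3
        lx, ly = lam(x, y)
        for scale in (1e-2, 1e-3):
            px, py = scale * rng.uniform(-1, 1, 2)
            # Lam*p^2 == (a * 2b^2 / K^0) /(2b) * p^2 termwise
            a_x = lx / p.b
            assert a_x * (2 * p.b**2) / (2 * p.b) == pytest.approx(lx)
            quad = ((lx - p.gamma0 * x) * px + (ly - p.gamma0 * y) * py
                    + lx * px**2 + ly * py**2)
            assert abs(ham.H(x, y, px, py) - quad) < 5.0 * scale**3


class TestMinimizeAction:
    def test_endpoint_at_attractor(self, table1, att_conc):
        ham = pdmp_hamiltonian(table1)
        res = minimize_action(ham, att_conc, att_conc, path_points=32)
        assert res.value == 0.0 and res.converged

    def test_path_points_validation(self, table1, att_conc):
        with pytest.raises(ValueError):
            minimize_action(pdmp_hamiltonian(table1), att_conc,
                            att_conc + 0.5, path_points=8)

    def test_one_species_closed_form(self, one_species):
        # S0(x) = (x - x*) - x* ln(x/x*) from the Gamma stationary law
        ham = pdmp_hamiltonian(one_species)
        xs = 0.6
        for x_end in (1.5, 2.0):
            res = minimize_action(ham, (xs, xs), (x_end, xs), path_points=128)
            exact = (x_end - xs) - xs * np.log(x_end / xs)
            assert res.converged
            assert res.value == pytest.approx(exact, rel=0.01)

    def test_decoupled_two_species_additivity(self, one_species):
        # frozen rates decouple the species: moving both coordinates
        # costs the sum of the 1-species closed forms.  This
        # discriminates the exact alignment recovery (grad_p H || v)
        # from the p || v ray approximation, which underestimates here.
        ham = pdmp_hamiltonian(one_species)
        xs = 0.6
        res = minimize_action(ham, (xs, xs), (2.0, 1.4), path_points=128)
        exact = ((2.0 - xs) - xs * np.log(2.0 / xs)
                 + (1.4 - xs) - xs * np.log(1.4 / xs))
        assert res.value == pytest.approx(exact, rel=0.01)

    def test_gradient_matches_finite_differences(self, table1):
        ham = pdmp_hamiltonian(table1)
        phi = (np.linspace(0, 1, 12)[:, None] * np.array([1.2, -0.8])
               + np.array([0.8, 1.0]))
        S, grad, *_ = _action_and_grad(ham, phi)
        for i in (3, 7):
            for c in (0, 1):
                ph = phi.copy()
                ph[i, c] += 1e-6
                Sp = _action_and_grad(ham, ph)[0]
                ph[i, c] -= 2e-6
                Sm = _action_and_grad(ham, ph)[0]
                assert grad[i, c] == pytest.approx((Sp - Sm) / 2e-6, rel=1e-4,
                                                   abs=1e-8)

    def test_zero_hamiltonian_along_path(self, table1, att_conc):
        ham = pdmp_hamiltonian(table1)
        res = minimize_action(ham, att_conc, (2.8, 0.2), path_points=64)
        mid = 0.5 * (res.path[1:] + res.path[:-1])
        H = ham.H(mid[:, 0], mid[:, 1], res.momenta[:, 0], res.momenta[:, 1])
        assert np.max(np.abs(H)) < 1e-6

    def test_detailed_balance_gradient_system(self):
        # drift -grad U with U = ((x-1)^2 + (y-1)^2)/2 and unit noise:
        # Freidlin-Wentzell action equals 2*(U(end) - U(start))
        def U(x, y):
            return 0.5 * ((x - 1.0) ** 2 + (y - 1.0) ** 2)

        ham = HamiltonianSpec(
            H=lambda x, y, px, py: -(x - 1.0) * px - (y - 1.0) * py
            + 0.5 * (px**2 + py**2),
            dH_dp=lambda x, y, px, py: (-(x - 1.0) + px, -(y - 1.0) + py),
            dH_dx=lambda x, y, px, py: (-px, -py),
            p_bound=np.inf,
            kind="gradient-test",
        )
        end = (1.9, 0.4)
        res = minimize_action(ham, (1.0, 1.0), end, path_points=64)
        assert res.value == pytest.approx(2.0 * U(*end), rel=0.01)

    def test_action_monotone_along_ray(self, table1, att_conc):
        ham = pdmp_hamiltonian(table1)
        direction = np.array([1.0, -0.2])
        vals = []
        for s in (0.3, 0.6, 0.9):
            end = att_conc + s * direction
            vals.append(minimize_action(ham, att_conc, end,
                                        path_points=48).value)
        assert vals[0] < vals[1] < vals[2]

    def test_pdmp_shallower_than_diffusion(self, table1, att_conc):
        # fat exponential tails make the PDMP quasi-potential smaller
        # than the diffusion approximation's at large protein numbers;
        # probe along increasing x with y at its slaved equilibrium
        # value Lam_Y(x)/gamma0
        hp = pdmp_hamiltonian(table1)
        hd = diffusion_hamiltonian(km_coefficients(table1))
        lam, _ = _burst_rates(table1)
        for xe in (2.8, 3.2, 3.5):
            ye = lam(xe, 0.0)[1] / table1.gamma0
            sp = minimize_action(hp, att_conc, (xe, ye), path_points=64).value
            sd = minimize_action(hd, att_conc, (xe, ye), path_points=64).value
            assert 0 < sp < sd

    def test_hessians_agree_near_attractor(self, table1, att_conc):
        # both Hamiltonians share the attractor as zero set; close to it
        # the actions agree up to the second-moment correction
        # (2B^2+B)/(2B^2) and the degradation-noise term
        hp = pdmp_hamiltonian(table1)
        hd = diffusion_hamiltonian(km_coefficients(table1))
        end = att_conc + np.array([0.12, 0.0])
        sp = minimize_action(hp, att_conc, end, path_points=48).value
        sd = minimize_action(hd, att_conc, end, path_points=48).value
        assert sp > 0 and sd > 0
        # correction factors stay within ~20% at Table-1 parameters
        assert sp / sd == pytest.approx(1.0, abs=0.25)


class TestQuasipotentialSurface:
    def test_small_surface_properties(self, table1, att_conc):
        ham = pdmp_hamiltonian(table1)
        xs = np.linspace(0.4, 3.0, 5)
        field = quasipotential_surface(ham, att_conc, xs, xs, path_points=36,
                                       max_outer=4)
        assert np.nanmin(field.S0) >= 0.0
        # minimum at the grid cell nearest the attractor
        i, j = np.unravel_index(np.nanargmin(field.S0), field.S0.shape)
        ia = np.argmin(np.abs(xs - att_conc[0]))
        ja = np.argmin(np.abs(xs - att_conc[1]))
        assert (i, j) == (ia, ja)
        assert field.S0[i, j] < 0.02

    def test_toggle_symmetry(self, table1, att_conc):
        # S0 from the X-attractor equals the transposed S0 from the
        # mirrored Y-attractor
        ham = pdmp_hamiltonian(table1)
        xs = np.linspace(0.5, 2.5, 4)
        fx = quasipotential_surface(ham, att_conc, xs, xs, path_points=36,
                                    max_outer=4)
        fy = quasipotential_surface(ham, att_conc[::-1], xs, xs,
                                    path_points=36, max_outer=4)
        assert np.allclose(fx.S0, fy.S0.T, rtol=0.05, atol=5e-3)

    def test_wkb_density_modes_match_simulation(self, table1, att_conc):
        # exp(-S0/b) at b = 0.15 puts its modes in the same coarse cells
        # as the simulated shot-noise stationary histogram
        from burstswitch.ssa_simulators import stationary_histogram

        ham = pdmp_hamiltonian(table1)
        xs = np.linspace(0.1, 3.1, 9)
        cell = xs[1] - xs[0]
        field = quasipotential_surface(ham, att_conc, xs, xs, path_points=36,
                                       max_outer=4)
        w = field.wkb_density(table1.b)
        iw, jw = np.unravel_index(np.argmax(w), w.shape)
        h = stationary_histogram("PDMP-SN", table1, 50.0, 20_050.0, seed=30)
        # restrict to this attractor's basin (x > y) and locate the mode
        masses = np.array(h.masses)
        ii, jj = np.meshgrid(*[np.arange(s) for s in masses.shape], indexing="ij")
        masses[ii <= jj] = 0.0
        im, jm = np.unravel_index(np.argmax(masses), masses.shape)
        xm, ym = im / table1.K, jm / table1.K
        assert abs(xs[iw] - xm) <= cell and abs(xs[jw] - ym) <= cell
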