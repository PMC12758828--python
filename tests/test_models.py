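"""Closed-form and numerical velocity/viscosity model behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

import coreplasma as cp
from coreplasma import models as m
from conftest import DP, relerr


NEWT = cp.NewtonianParams(mu=2e-3)
PL = cp.PowerLawParams(K_p=3e-3, n_p=0.9)
CARR = cp.CarreauParams(mu0=10e-3, mu_inf=2e-3, lambda_c=3.31, n_c=0.36)
DPPP = cp.DPPParams(v_max=0.05, k1=0.5, k2=2.0)
CORE = cp.CorePlasmaParams(mu_p=1.5e-3, K_cp=3e-3, n_cp=0.9, delta=5e-6)


# ---------------------------------------------------------------------------
# frozen scalar oracles (independent high-precision substitution)
# ---------------------------------------------------------------------------

def test_newtonian_centerline_value(geom):
    # dP=1e4 Pa, L=1e-2 m, R=25e-6 m, mu=2e-3 Pa*s
    g = cp.ChannelGeometry(radius=25e-6, length=1e-2)
    assert cp.newtonian_velocity(0.0, g, 1e4, NEWT) == pytest.approx(
        7.8125e-2, rel=1e-12
    )


def test_powerlaw_centerline_value():
    g = cp.ChannelGeometry(radius=25e-6, length=1e-2)
    # arbitrary-precision substitution oracle (40-digit evaluation)
    assert cp.powerlaw_velocity(0.0, g, 1e4, PL) == pytest.approx(
        0.12457084957920246, rel=1e-12
    )


def test_carreau_viscosity_value():
    # mu0=10, mu_inf=2 mPa*s, lambda=3.31 s, n=0.36, gamma=100 1/s
    assert cp.carreau_viscosity(100.0, CARR) == pytest.approx(
        2.195163591901917e-3, rel=1e-12
    )


def test_newtonian_quadratic_symmetry(geom):
    u0 = cp.newtonian_velocity(0.0, geom, DP, NEWT)
    assert cp.newtonian_velocity(geom.radius / np.sqrt(2), geom, DP, NEWT) == (
        pytest.approx(u0 / 2, rel=1e-12)
    )


# ---------------------------------------------------------------------------
# no-slip, evenness, monotonicity
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "evaluate",
    [
        lambda r, g: cp.newtonian_velocity(r, g, DP, NEWT),
        lambda r, g: cp.powerlaw_velocity(r, g, DP, PL),
        lambda r, g: m.carreau_velocity(r, g, DP, CARR),
        lambda r, g: cp.dpp_velocity(r, g.radius, DPPP),
        lambda r, g: cp.coreplasma_velocity(r, g, DP, CORE),
    ],
    ids=["newtonian", "powerlaw", "carreau", "dpp", "coreplasma"],
)
def test_no_slip_even_and_monotone(geom, evaluate):
    R = geom.radius
    assert evaluate(R, geom) == pytest.approx(0.0, abs=1e-18)
    grid = np.linspace(0, R, 64)
    u = np.asarray(evaluate(grid, geom))
    assert np.all(np.diff(u) <= 1e-15 * u[0])  # non-increasing in |r|
    assert np.allclose(np.asarray(evaluate(-grid[::-1], geom))[::-1], u)  # even


@pytest.mark.parametrize(
    "call",
    [
        lambda g: cp.newtonian_velocity(g.radius * 1.01, g, DP, NEWT),
        lambda g: cp.coreplasma_velocity(g.radius * 1.5, g, DP, CORE),
    ],
)
def test_outside_tube_is_domain_error(geom, call):
    with pytest.raises(cp.DomainError):
        call(geom)


@pytest.mark.parametrize(
    "bad",
    [
        lambda: cp.NewtonianParams(mu=-1.0),
        lambda: cp.PowerLawParams(K_p=3e-3, n_p=5.0),
        lambda: cp.CarreauParams(mu0=1e-3, mu_inf=2e-3, lambda_c=1.0, n_c=0.5),
        lambda: cp.DPPParams(v_max=0.05, k1=1.5, k2=2.0),
        lambda: cp.CorePlasmaParams(mu_p=1e-3, K_cp=3e-3, n_cp=0.9, delta=-1e-6),
        lambda: cp.ChannelGeometry(radius=1e-2, length=1e-3),
    ],
)
def test_invalid_parameters_rejected(bad):
    with pytest.raises(cp.ValidationError):
        bad()


# ---------------------------------------------------------------------------
# nesting identities
# ---------------------------------------------------------------------------

def test_nesting_identities(geom):
    grid = np.linspace(0, geom.radius, 64)
    u_pl = cp.powerlaw_velocity(grid, geom, DP, PL)
    u_cp0 = cp.coreplasma_velocity(
        grid, geom, DP,
        cp.CorePlasmaParams(mu_p=1.5e-3, K_cp=PL.K_p, n_cp=PL.n_p, delta=0.0),
    )
    assert relerr(u_cp0, u_pl) < 1e-12

    u_n = cp.newtonian_velocity(grid, geom, DP, NEWT)
    u_cp1 = cp.coreplasma_velocity(
        grid, geom, DP,
        cp.CorePlasmaParams(mu_p=NEWT.mu, K_cp=NEWT.mu, n_cp=1.0, delta=8e-6),
    )
    assert relerr(u_cp1, u_n) < 1e-12

    u_pl1 = cp.powerlaw_velocity(grid, geom, DP, cp.PowerLawParams(K_p=NEWT.mu, n_p=1.0))
    assert relerr(u_pl1, u_n) < 1e-12

    u_dpp = cp.dpp_velocity(grid, geom.radius, cp.DPPParams(v_max=0.05, k1=0.0, k2=2.0))
    assert relerr(u_dpp, 0.05 * (1 - (grid / geom.radius) ** 2)) < 1e-12


# ---------------------------------------------------------------------------
# Carreau law and tube-flow solver
# ---------------------------------------------------------------------------

def test_carreau_plateaus():
    assert cp.carreau_viscosity(0.0, CARR) == CARR.mu0
    flat = cp.CarreauParams(mu0=10e-3, mu_inf=2e-3, lambda_c=0.0, n_c=0.36)
    g = np.array([0.0, 1.0, 1e4])
    assert np.all(cp.carreau_viscosity(g, flat) == flat.mu0)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(gamma=st.floats(0, 1e6), lam=st.floats(0, 100), n=st.floats(1e-3, 1.0))
def test_carreau_viscosity_bounded(gamma, lam, n):
    p = cp.CarreauParams(mu0=10e-3, mu_inf=2e-3, lambda_c=lam, n_c=n)
    mu = cp.carreau_viscosity(gamma, p)
    assert p.mu_inf <= mu <= p.mu0


def test_carreau_viscosity_monotone_shear_thinning():
    g = np.linspace(0, 5000, 400)
    mu = cp.carreau_viscosity(g, CARR)
    assert np.all(np.diff(mu) <= 0)


def test_carreau_solver_degenerate_matches_newtonian(geom):
    flat = cp.CarreauParams(mu0=2e-3, mu_inf=2e-3, lambda_c=3.31, n_c=0.36)
    grid = np.linspace(0, geom.radius, 200)
    u_c = m.carreau_velocity(grid, geom, DP, flat)
    u_n = cp.newtonian_velocity(grid, geom, DP, NEWT)
    assert np.max(np.abs(u_c - u_n)) / u_n[0] < 1e-6


def test_carreau_solver_wall_and_grid_convergence(geom):
    prof = cp.carreau_velocity_profile(
        np.linspace(0, geom.radius, 200), geom, DP, CARR
    )
    assert prof.u[-1] == 0.0
    u_fine = m.carreau_velocity(0.0, geom, DP, CARR, num_nodes=4001)
    u_half = m.carreau_velocity(0.0, geom, DP, CARR, num_nodes=2001)
    assert abs(u_fine - u_half) / u_fine < 1e-6


# ---------------------------------------------------------------------------
# core-plasma interface behaviour
# ---------------------------------------------------------------------------

def test_coreplasma_interface_continuity(geom):
    R, L = geom.radius, geom.length
    rc = R - CORE.delta
    # CFL-branch value at the interface, written out independently
    u_cfl = DP * (R**2 - rc**2) / (4 * CORE.mu_p * L)
    eps = 1e-9
    u_below = cp.coreplasma_velocity(rc * (1 - eps), geom, DP, CORE)  # core branch
    u_above = cp.coreplasma_velocity(rc * (1 + eps), geom, DP, CORE)  # CFL branch
    assert abs(u_below - u_above) <= 1e-6 * u_cfl
    assert cp.coreplasma_velocity(rc, geom, DP, CORE) == pytest.approx(u_cfl, rel=1e-12)


def test_coreplasma_shear_stress_continuity_at_interface(geom):
    R, L = geom.radius, geom.length
    rc = R - CORE.delta
    tau = DP * rc / (2 * L)
    g_cfl = DP * rc / (2 * CORE.mu_p * L)
    g_core = (DP * rc / (2 * CORE.K_cp * L)) ** (1 / CORE.n_cp)
    assert CORE.mu_p * g_cfl == pytest.approx(tau, rel=1e-12)
    assert CORE.K_cp * g_core**CORE.n_cp == pytest.approx(tau, rel=1e-12)


def test_coreplasma_shear_rate_centerline_and_wall(geom):
    assert cp.coreplasma_shear_rate(0.0, geom, DP, CORE) == 0.0
    p1 = cp.CorePlasmaParams(mu_p=2e-3, K_cp=2e-3, n_cp=1.0, delta=5e-6)
    # Newtonian wall shear dP*R/(2*mu*L) = 18000*25e-6/(2*2e-3*1e-2)
    assert cp.coreplasma_shear_rate(geom.radius, geom, DP, p1) == pytest.approx(
        11250.0, rel=1e-12
    )


def test_stress_linearity_all_models(geom):
    """tau(r) reconstructed from each constitutive law equals dP*r/(2L)."""
    R, L = geom.radius, geom.length
    grid = np.linspace(R / 64, R, 64)
    tau_expected = DP * grid / (2 * L)

    g_n = np.asarray(m.evaluate_shear_rate(NEWT, grid, geom, DP))
    assert relerr(NEWT.mu * g_n, tau_expected) < 1e-8

    g_p = np.asarray(m.evaluate_shear_rate(PL, grid, geom, DP))
    assert relerr(PL.K_p * g_p**PL.n_p, tau_expected) < 1e-8

    g_c = np.asarray(m.evaluate_shear_rate(CARR, grid, geom, DP))
    assert relerr(cp.carreau_viscosity(g_c, CARR) * g_c, tau_expected) < 1e-8

    g_cp = np.asarray(m.evaluate_shear_rate(CORE, grid, geom, DP))
    rc = R - CORE.delta
    tau_cp = np.where(
        grid >= rc, CORE.mu_p * g_cp, CORE.K_cp * g_cp**CORE.n_cp
    )
    assert relerr(tau_cp, tau_expected) < 1e-8


# ---------------------------------------------------------------------------
# apparent viscosity and flow rates
# ---------------------------------------------------------------------------

def test_apparent_viscosity_round_trip():
    g = cp.ChannelGeometry(radius=25e-6, length=1e-2)
    q = np.pi * 1e4 * (25e-6) ** 4 / (8 * 2e-3 * 1e-2)
    assert cp.apparent_viscosity(q, 1e4, g) == pytest.approx(2e-3, rel=1e-12)
    assert cp.apparent_viscosity(2 * q, 1e4, g) == pytest.approx(1e-3, rel=1e-12)
    with pytest.raises(cp.ValidationError):
        cp.apparent_viscosity(-q, 1e4, g)


def test_apparent_viscosity_quadrature_closure(geom):
    """Integrate a Newtonian profile numerically, invert Poiseuille, get mu."""
    q, _ = integrate.quad(
        lambda r: 2 * np.pi * r * cp.newtonian_velocity(r, geom, DP, NEWT),
        0, geom.radius, epsrel=1e-12,
    )
    assert cp.apparent_viscosity(q, DP, geom) == pytest.approx(NEWT.mu, rel=1e-6)


def test_volumetric_flow_closed_forms(geom):
    q_closed = cp.volumetric_flow(NEWT, geom, DP)
    q_quad, _ = integrate.quad(
        lambda r: 2 * np.pi * r * cp.newtonian_velocity(r, geom, DP, NEWT),
        0, geom.radius, epsrel=1e-12,
    )
    assert abs(q_closed - q_quad) / q_closed < 1e-8

    q_pl1 = cp.volumetric_flow(cp.PowerLawParams(K_p=NEWT.mu, n_p=1.0), geom, DP)
    assert q_pl1 == pytest.approx(q_closed, rel=1e-12)

    # core-plasma with delta=0 reduces to the power-law closed form
    q_cp = cp.volumetric_flow(
        cp.CorePlasmaParams(mu_p=1.5e-3, K_cp=PL.K_p, n_cp=PL.n_p, delta=0.0),
        geom, DP,
    )
    q_pl = cp.volumetric_flow(PL, geom, DP)
    assert q_cp == pytest.approx(q_pl, rel=1e-8)
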