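"""Poroelastic solver verification: strain measures, patch tests, storage,
Darcy recovery, Terzaghi consolidation, assembly oracle and the fixator."""
import numpy as np
import pytest

from ossify.fem import (CalibrationError, CallusModel, FixatorCurve, LoadCase,
                        PoroelasticSystem, StimulusConstants, calibrate_fixator,
                        compute_stimulus, default_fixator_base_curve,
                        fluid_speed, octahedral_shear_strain, M4NS_TO_MM4NS)
from ossify.materials import ElementMaterial
from ossify.oracles import TerzaghiProblem, make_fixture_mesh, terzaghi_pressure


def uniform_material(mesh, E=3.0, nu=0.3, k=1e-14, poro=0.8):
    ne = mesh.n_elements
    return ElementMaterial(np.full(ne, E), np.full(ne, nu),
                           np.full(ne, k), np.full(ne, poro))


# ---------------------------------------------------------------------------
# octahedral shear strain and stimulus
# ---------------------------------------------------------------------------

def voigt(T):
    return np.array([[T[0, 0], T[1, 1], T[2, 2],
                      2 * T[0, 1], 2 * T[1, 2], 2 * T[0, 2]]])


def test_octahedral_shear_strain_hydrostatic_is_zero():
    assert octahedral_shear_strain(voigt(0.01 * np.eye(3)))[0] == pytest.approx(0.0, abs=1e-15)


def test_octahedral_shear_strain_uniaxial():
    eps = 0.02
    g = octahedral_shear_strain(np.array([[eps, 0, 0, 0, 0, 0]]))[0]
    assert g == pytest.approx(2 * np.sqrt(2) / 3 * eps, rel=1e-12)


def test_octahedral_shear_strain_rotation_invariant(rng):
    T = rng.normal(size=(3, 3)) * 0.01
    T = 0.5 * (T + T.T)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    Tr = q @ T @ q.T
    assert octahedral_shear_strain(voigt(T))[0] == \
        pytest.approx(octahedral_shear_strain(voigt(Tr))[0], rel=1e-9)


def test_stimulus_formula_and_linearity():
    c = StimulusConstants()
    assert compute_stimulus(np.array([0.0]), np.array([0.0]), c).S[0] == 0.0
    assert compute_stimulus(np.array([0.0375]), np.array([0.0]), c).S[0] == pytest.approx(1.0)
    assert compute_stimulus(np.array([0.0]), np.array([3.0]), c).S[0] == pytest.approx(1.0)
    s1 = compute_stimulus(np.array([0.01]), np.array([1.0]), c).S
    s2 = compute_stimulus(np.array([0.02]), np.array([2.0]), c).S
    assert s2[0] == pytest.approx(2 * s1[0], rel=1e-14)
    with pytest.raises(ValueError):
        compute_stimulus(np.array([-0.01]), np.array([0.0]), c)


# ---------------------------------------------------------------------------
# patch tests and single-element physics
# ---------------------------------------------------------------------------

def test_affine_patch_on_distorted_hex():
    """A linear displacement field is reproduced exactly on a distorted element."""
    mesh = make_fixture_mesh("single_hex", distort=7)
    sys = PoroelasticSystem(mesh)
    A = np.array([[0.004, 0.001, 0.0], [0.001, -0.002, 0.0015],
                  [0.0, 0.0015, -0.006]])
    dofs, vals = [], []
    for n, x in enumerate(mesh.nodes):
        u = A @ x
        for c in range(3):
            dofs.append(4 * n + c)
            vals.append(u[c])
    x = sys.solve_static_drained(uniform_material(mesh),
                                 fixed_dofs=np.array(dofs),
                                 fixed_vals=np.array(vals))
    strain = sys.element_strain(x)[0]
    expected = np.array([A[0, 0], A[1, 1], A[2, 2],
                         2 * A[0, 1], 2 * A[1, 2], 2 * A[0, 2]])
    np.testing.assert_allclose(strain, expected, atol=1e-12)


def test_uniaxial_drained_compression_matches_modulus(single_hex):
    """Uniaxial stress on a unit cube: reaction = E * A * strain exactly."""
    E, eps = 3.0, 0.01
    sys = PoroelasticSystem(single_hex)
    bottom = single_hex.node_sets["bottom_fixed_face"]
    top = single_hex.node_sets["top_load_face"]
    dofs = [4 * n + 2 for n in bottom] + [4 * n + 2 for n in top]
    vals = [0.0] * len(bottom) + [-eps] * len(top)
    # pin rigid in-plane modes without constraining lateral contraction
    dofs += [0, 1, 4 * 1 + 1]       # node 0: ux, uy; node 1 (on x-axis): uy
    vals += [0.0, 0.0, 0.0]
    mat = uniform_material(single_hex, E=E)
    x = sys.solve_static_drained(mat, fixed_dofs=np.array(dofs),
                                 fixed_vals=np.array(vals))
    Ksp, _, _ = sys.matrices(mat)
    reaction = (Ksp @ x)[[4 * n + 2 for n in top]].sum()
    assert reaction == pytest.approx(-E * eps, rel=1e-10)
    strain = sys.element_strain(x)[0]
    assert strain[2] == pytest.approx(-eps, rel=1e-12)
    assert strain[0] == pytest.approx(0.3 * eps, rel=1e-10)   # Poisson expansion


def test_undrained_pressure_carries_volumetric_strain(single_hex):
    """Confined compression, no drainage: p = -eps_vol / storage."""
    sys = PoroelasticSystem(single_hex)
    eps = 0.001
    dofs, vals = [], []
    for n, x in enumerate(single_hex.nodes):
        dofs += [4 * n + 0, 4 * n + 1]
        vals += [0.0, 0.0]
        if abs(x[2]) < 1e-12:
            dofs.append(4 * n + 2); vals.append(0.0)
        elif abs(x[2] - 1.0) < 1e-12:
            dofs.append(4 * n + 2); vals.append(-eps)
    mat = uniform_material(single_hex, k=1e-17)   # effectively impermeable
    sol = sys.solve_transient(mat, dt=1e-3, n_steps=1,
                              fixed_dofs=np.array(dofs), fixed_vals=np.array(vals),
                              ramp=lambda t: 1.0)
    p = sol.states[-1][3::4].mean()
    storage = 0.8 / 2300.0
    assert p == pytest.approx(eps / storage, rel=0.01)


def test_zero_load_gives_zero_response(single_hex):
    sys = PoroelasticSystem(single_hex)
    dofs = np.array([4 * n + 2 for n in single_hex.node_sets["bottom_fixed_face"]])
    sol = sys.solve_transient(uniform_material(single_hex), dt=0.1, n_steps=3,
                              fixed_dofs=dofs, fixed_vals=np.zeros(dofs.size))
    assert np.allclose(sol.states[-1], 0.0, atol=1e-15)


# ---------------------------------------------------------------------------
# Darcy velocity recovery
# ---------------------------------------------------------------------------

def test_pressure_gradient_and_darcy_speed(column10):
    sys = PoroelasticSystem(column10)
    G = 0.05   # MPa/mm along z
    x = np.zeros(sys.ndof)
    x[3::4] = G * column10.nodes[:, 2]
    grad = sys.element_pressure_gradient(x)
    np.testing.assert_allclose(grad[:, 2], G, rtol=1e-12)
    np.testing.assert_allclose(grad[:, :2], 0.0, atol=1e-12)
    k = 1e-14
    v_umps = fluid_speed(grad, np.full(column10.n_elements, k))
    assert v_umps[0] == pytest.approx(k * 1e12 * G * 1e3, rel=1e-12)
    # impermeable limit: vanishing permeability gives vanishing speed
    assert fluid_speed(grad, np.full(column10.n_elements, 1e-30)).max() < 1e-10
    # uniform pressure: no flow
    x[3::4] = 0.123
    assert np.allclose(sys.element_pressure_gradient(x), 0.0, atol=1e-12)


# ---------------------------------------------------------------------------
# Terzaghi consolidation
# ---------------------------------------------------------------------------

def run_terzaghi_column(n_elem=50, height=10.0, E=3.0, nu=0.3, k=1e-14,
                        poro=0.8, sigma0=0.1, n_steps=200):
    mesh = make_fixture_mesh("column", n=n_elem, height=height)
    sys = PoroelasticSystem(mesh)
    E_oed = E * (1 - nu) / ((1 + nu) * (1 - 2 * nu))
    storage = poro / 2300.0
    problem = TerzaghiProblem(column_height=height, drained_stiffness=E_oed,
                              permeability=k, applied_stress=sigma0,
                              storage=storage)
    cv = problem.consolidation_coefficient
    T = height ** 2 / cv
    dofs, vals = [], []
    for n, xyz in enumerate(mesh.nodes):
        dofs += [4 * n + 0, 4 * n + 1]
        vals += [0.0, 0.0]
        if abs(xyz[2]) < 1e-12:
            dofs.append(4 * n + 2); vals.append(0.0)
    top = mesh.node_sets["drainage_boundary"]
    for n in top:
        dofs.append(4 * n + 3); vals.append(0.0)
    fdofs = np.array([4 * n + 2 for n in top])
    fvals = np.full(fdofs.size, -sigma0 / fdofs.size)
    mat = uniform_material(mesh, E=E, nu=nu, k=k, poro=poro)
    dt = T / n_steps
    sol = sys.solve_transient(mat, dt=dt, n_steps=n_steps,
                              fixed_dofs=np.array(dofs), fixed_vals=np.array(vals),
                              force_dofs=fdofs, force_vals=fvals,
                              ramp=lambda t: 1.0)
    z_c = mesh.element_centroid[:, 2]
    return mesh, sys, sol, problem, T, z_c


@pytest.mark.parametrize("t_frac", [0.1, 0.5, 1.0])
def test_terzaghi_pore_pressure_within_2pct(t_frac):
    mesh, sys, sol, problem, T, z_c = run_terzaghi_column(n_elem=50)
    n_steps = len(sol.states) - 1
    step = int(round(t_frac * n_steps))
    x = sol.states[step]
    t = sol.times[step]
    p_fem = np.array([x[3::4][mesh.hex_conn[e]].mean()
                      for e in range(mesh.n_elements)])
    p_ref = np.array([terzaghi_pressure(problem, problem.column_height - z, t)
                      for z in z_c])
    err = np.linalg.norm(p_fem - p_ref) / np.linalg.norm(p_ref)
    assert err < 0.02


# ---------------------------------------------------------------------------
# assembly oracle: independent dense quadrature on an affine 2-element mesh
# ---------------------------------------------------------------------------

def _reference_hex_matrices(coords, E, nu, k_mm, storage):
    """3x3x3 Gauss integration with finite-difference shape gradients,
    written independently of the production assembly."""
    signs = [(-1, -1, -1), (1, -1, -1), (1, 1, -1), (-1, 1, -1),
             (-1, -1, 1), (1, -1, 1), (1, 1, 1), (-1, 1, 1)]

    def N(xi):
        return np.array([(1 + xi[0] * s[0]) * (1 + xi[1] * s[1])
                         * (1 + xi[2] * s[2]) / 8 for s in signs])

    def dN(xi, h=1e-6):
        out = np.zeros((8, 3))
        for a in range(3):
            e = np.zeros(3); e[a] = h
            out[:, a] = (N(xi + e) - N(xi - e)) / (2 * h)
        return out

    gl, wl = np.polynomial.legendre.leggauss(3)
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = lam * np.outer([1, 1, 1, 0, 0, 0], [1, 1, 1, 0, 0, 0]) \
        + mu * np.diag([2, 2, 2, 1, 1, 1])
    K = np.zeros((24, 24)); Q = np.zeros((24, 8))
    H = np.zeros((8, 8)); M = np.zeros((8, 8))
    for i, xi1 in enumerate(gl):
        for j, xi2 in enumerate(gl):
            for l, xi3 in enumerate(gl):
                xi = np.array([xi1, xi2, xi3])
                w = wl[i] * wl[j] * wl[l]
                dNxi = dN(xi)
                J = dNxi.T @ coords
                detJ = np.linalg.det(J)
                dNx = dNxi @ np.linalg.inv(J).T
                B = np.zeros((6, 24))
                for a in range(8):
                    B[0, 3 * a] = dNx[a, 0]
                    B[1, 3 * a + 1] = dNx[a, 1]
                    B[2, 3 * a + 2] = dNx[a, 2]
                    B[3, 3 * a] = dNx[a, 1]; B[3, 3 * a + 1] = dNx[a, 0]
                    B[4, 3 * a + 1] = dNx[a, 2]; B[4, 3 * a + 2] = dNx[a, 1]
                    B[5, 3 * a] = dNx[a, 2]; B[5, 3 * a + 2] = dNx[a, 0]
                Bvol = B[0] + B[1] + B[2]
                Nv = N(xi)
                K += w * detJ * B.T @ D @ B
                Q += w * detJ * np.outer(Bvol, Nv)
                H += w * detJ * k_mm * dNx @ dNx.T
                M += w * detJ * storage * np.outer(Nv, Nv)
    return K, Q, H, M


def test_assembled_matrices_match_dense_quadrature_oracle():
    mesh = make_fixture_mesh("column", n=2, height=2.0)
    E, nu, k, poro = 7.0, 0.33, 2e-14, 0.6
    sys = PoroelasticSystem(mesh)
    mat = uniform_material(mesh, E=E, nu=nu, k=k, poro=poro)
    Ksp, Hsp, Ssp = sys.matrices(mat)
    nd = sys.ndof
    Kref = np.zeros((nd, nd)); Qref = np.zeros((nd, nd))
    Href = np.zeros((nd, nd)); Mref = np.zeros((nd, nd))
    for conn in mesh.hex_conn:
        coords = mesh.nodes[conn]
        Ke, Qe, He, Me = _reference_hex_matrices(
            coords, E, nu, k * M4NS_TO_MM4NS, poro / 2300.0)
        ud = np.array([4 * n + c for n in conn for c in range(3)])
        pd = np.array([4 * n + 3 for n in conn])
        Kref[np.ix_(ud, ud)] += Ke
        Qref[np.ix_(ud, pd)] += Qe
        Href[np.ix_(pd, pd)] += He
        Mref[np.ix_(pd, pd)] += Me
    np.testing.assert_allclose(Ksp.toarray(), Kref, atol=1e-8 * np.abs(Kref).max())
    np.testing.assert_allclose(sys.Qsp.toarray(), Qref, atol=1e-8 * np.abs(Qref).max())
    np.testing.assert_allclose(Hsp.toarray(), Href, atol=1e-8 * np.abs(Href).max())
    np.testing.assert_allclose(Ssp.toarray(), Mref, atol=1e-8 * np.abs(Mref).max())


# ---------------------------------------------------------------------------
# fixator curve, load balance and calibration
# ---------------------------------------------------------------------------

def test_fixator_curve_validation():
    with pytest.raises(ValueError):
        FixatorCurve(np.array([0.0, 1.0, 0.5]), np.array([0.0, 1.0, 2.0]))
    with pytest.raises(ValueError):
        FixatorCurve(np.array([0.0, 1.0]), np.array([10.0, 20.0]))
    with pytest.raises(ValueError):
        FixatorCurve(np.array([0.0, 1.0, 2.0]), np.array([0.0, 5.0, 3.0]))


def test_fixator_force_interpolation_and_extrapolation():
    c = FixatorCurve(np.array([0.0, 1.0, 2.0]), np.array([0.0, 100.0, 300.0]))
    assert c.force(0.5) == pytest.approx(50.0)
    assert c.force(1.5) == pytest.approx(200.0)
    assert c.force(3.0) == pytest.approx(500.0)    # last slope extrapolated
    assert c.scaled(2.0).force(0.5) == pytest.approx(100.0)


@pytest.fixture(scope="module")
def callus_model(request):
    from ossify.geometry import GeometryParams, build_geometry
    from ossify.mesh import generate_mesh
    geom = build_geometry(GeometryParams())
    mesh = generate_mesh(geom, target_h=1.6, n_theta=4)
    return CallusModel(mesh, n_steps=4, load=LoadCase(500.0, 4.0, 4.0))


def test_ifm_decreases_with_tissue_stiffness(callus_model):
    fix = default_fixator_base_curve()
    soft = callus_model.solve_daily_load(uniform_material(callus_model.mesh, E=3.0), fix)
    stiff = callus_model.solve_daily_load(
        uniform_material(callus_model.mesh, E=4000.0, k=3.7e-13), fix)
    assert soft.ifm > 0
    assert stiff.ifm < 0.1 * soft.ifm


def test_rigid_fixator_limit(callus_model):
    rigid = default_fixator_base_curve().scaled(1e9)
    sol = callus_model.solve_daily_load(uniform_material(callus_model.mesh), rigid)
    assert sol.ifm == pytest.approx(0.0, abs=1e-6)


def test_fixator_calibration_hits_target(callus_model):
    mat = uniform_material(callus_model.mesh)
    unit = callus_model.unit_response(mat)
    tissue_only_ifm = unit.ifm_unit * callus_model.load.axial_load / unit.k_t
    target = 0.5 * tissue_only_ifm
    curve = calibrate_fixator(target, callus_model, mat)
    sol = callus_model.solve_daily_load(mat, curve)
    assert sol.ifm == pytest.approx(target, rel=0.01)
    with pytest.raises(CalibrationError):
        calibrate_fixator(0.0, callus_model, mat)
    with pytest.raises(CalibrationError):
        calibrate_fixator(2.0 * tissue_only_ifm, callus_model, mat)
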