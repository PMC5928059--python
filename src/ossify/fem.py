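"""Biphasic poroelastic finite elements for the daily load event.

The tissue is a fluid-saturated porous solid (Biot consolidation, u-p form):
linear isotropic elasticity for the drained skeleton, Darcy flow for the pore
fluid, full Biot coupling (alpha = 1) and a small storage term n/K_f from
fluid compressibility (grains incompressible).  Displacements and pressure
are interpolated with the same trilinear basis, as in ABAQUS' C3D8P family,
and integrated with backward Euler in time.

Unit system: mm - N - MPa - s.  Permeability is stored in m^4/(N s) and
converted internally (1 m^4/Ns = 1e12 mm^4/Ns); fluid speed is reported in
um/s, the unit of the stimulus constant b.

The external fixator is a nonlinear axial spring in parallel with the tissue
column between the loaded bone end and the (restrained) mirror image of the
model.  Because the FE problem is linear for a given material state, the
daily solve is done once under a unit prescribed end displacement; the
actual amplitude follows from the scalar load balance between tissue
reaction and fixator force, and all fields scale linearly.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.optimize import brentq
from scipy.sparse.linalg import splu

from .materials import ElementMaterial
from .mesh import Mesh

__all__ = [
    "StimulusConstants", "StimulusField", "FixatorCurve", "LoadCase",
    "PoroelasticSystem", "CallusModel", "DailySolution",
    "octahedral_shear_strain", "compute_stimulus", "fluid_speed",
    "calibrate_fixator",
    "CalibrationError", "SolverError", "default_fixator_base_curve",
]

M4NS_TO_MM4NS = 1e12     # permeability m^4/(N s) -> mm^4/(N s)
MMPS_TO_UMPS = 1e3       # mm/s -> um/s


class SolverError(RuntimeError):
    pass


class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class StimulusConstants:
    """Empirical constants of the mechanoregulatory stimulus S = gamma/a + v/b."""

    a: float = 0.0375    # dimensionless strain (3.75 %)
    b: float = 3.0       # fluid speed, um/s

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("stimulus constants must be positive")


@dataclass(frozen=True)
class StimulusField:
    gamma: np.ndarray    # octahedral shear strain, per element
    v: np.ndarray        # fluid speed, um/s
    S: np.ndarray        # gamma/a + v/b


@dataclass(frozen=True)
class LoadCase:
    axial_load: float = 500.0          # N
    load_ramp_duration: float = 1.0    # s
    analysis_duration: float = 1.0     # s

    def __post_init__(self):
        if self.axial_load <= 0 or self.load_ramp_duration <= 0 \
                or self.analysis_duration <= 0:
            raise ValueError("load case values must be positive")


@dataclass(frozen=True)
class FixatorCurve:
    """Piecewise-linear axial force-displacement law of the external fixator.

    Displacements are the relative axial motion of the two bone ends of the
    *full* model (twice the half-model end displacement); the last segment's
    slope is extrapolated beyond the final breakpoint.
    """

    displacements: np.ndarray   # mm, strictly increasing, starting at 0
    forces: np.ndarray          # N, non-decreasing, starting at 0
    case: str = "A"

    def __post_init__(self):
        d = np.asarray(self.displacements, dtype=float)
        f = np.asarray(self.forces, dtype=float)
        object.__setattr__(self, "displacements", d)
        object.__setattr__(self, "forces", f)
        if d.shape != f.shape or d.ndim != 1 or d.size < 2:
            raise ValueError("curve needs matching 1-d breakpoint arrays (>= 2 points)")
        if d[0] != 0 or f[0] != 0:
            raise ValueError("fixator curve must pass through (0, 0)")
        if np.any(np.diff(d) <= 0):
            raise ValueError("breakpoint displacements must be strictly increasing")
        if np.any(np.diff(f) < 0):
            raise ValueError("breakpoint forces must be non-decreasing")

    def force(self, d: float) -> float:
        d = float(d)
        if d <= self.displacements[-1]:
            return float(np.interp(d, self.displacements, self.forces))
        slope = (self.forces[-1] - self.forces[-2]) / \
                (self.displacements[-1] - self.displacements[-2])
        return float(self.forces[-1] + slope * (d - self.displacements[-1]))

    def scaled(self, s: float) -> "FixatorCurve":
        return FixatorCurve(self.displacements.copy(), s * self.forces, self.case)


def default_fixator_base_curve(case: str = "A") -> FixatorCurve:
    """Normalised stiffening base shape; calibration scales the force axis."""
    return FixatorCurve(
        np.array([0.0, 0.5, 1.0, 2.0, 4.0]),
        np.array([0.0, 100.0, 250.0, 700.0, 1800.0]),
        case,
    )


def octahedral_shear_strain(strain_voigt: np.ndarray) -> np.ndarray:
    """gamma = (2/3) sqrt((e1-e2)^2 + (e2-e3)^2 + (e3-e1)^2) from principal strains.

    ``strain_voigt`` is (ne, 6) with engineering shears
    (exx, eyy, ezz, gxy, gyz, gzx).
    """
    e = np.atleast_2d(strain_voigt)
    T = np.empty((e.shape[0], 3, 3))
    T[:, 0, 0], T[:, 1, 1], T[:, 2, 2] = e[:, 0], e[:, 1], e[:, 2]
    T[:, 0, 1] = T[:, 1, 0] = e[:, 3] / 2
    T[:, 1, 2] = T[:, 2, 1] = e[:, 4] / 2
    T[:, 0, 2] = T[:, 2, 0] = e[:, 5] / 2
    p = np.linalg.eigvalsh(T)
    return (2.0 / 3.0) * np.sqrt((p[:, 0] - p[:, 1]) ** 2
                                 + (p[:, 1] - p[:, 2]) ** 2
                                 + (p[:, 2] - p[:, 0]) ** 2)


def fluid_speed(pressure_gradient: np.ndarray,
                permeability: np.ndarray) -> np.ndarray:
    """Darcy velocity magnitude |k grad p| in um/s.

    ``pressure_gradient`` is (ne, 3) in MPa/mm; ``permeability`` per element
    in m^4/(N s).
    """
    k_mm = np.asarray(permeability, dtype=float) * M4NS_TO_MM4NS
    return k_mm * np.linalg.norm(np.atleast_2d(pressure_gradient), axis=1) \
        * MMPS_TO_UMPS


def compute_stimulus(gamma: np.ndarray, v: np.ndarray,
                     constants: StimulusConstants = StimulusConstants()) -> StimulusField:
    """Elementwise biophysical stimulus S = gamma/a + v/b (v in um/s)."""
    gamma = np.asarray(gamma, dtype=float)
    v = np.asarray(v, dtype=float)
    if gamma.shape != v.shape:
        raise ValueError("gamma and v must have the same shape")
    if np.any(gamma < 0) or np.any(v < 0):
        raise ValueError("gamma and v must be non-negative")
    return StimulusField(gamma, v, gamma / constants.a + v / constants.b)


# ---------------------------------------------------------------------------
# discrete system
# ---------------------------------------------------------------------------

class _BlockData:
    """Precomputed element integrals for one element type block."""

    def __init__(self, etype, conn: np.ndarray, nodes: np.ndarray):
        from .elements import mapped_gradients
        self.conn = conn
        ne, nn = conn.shape
        coords = nodes[conn]
        dNdx, detJw, dNdx_c, N_c = mapped_gradients(etype, coords)
        ng = etype.gauss_points.shape[0]
        # strain-displacement matrices, engineering shear convention
        B = np.zeros((ne, ng, 6, 3 * nn))
        ii = np.arange(nn)
        B[:, :, 0, 3 * ii + 0] = dNdx[:, :, :, 0]
        B[:, :, 1, 3 * ii + 1] = dNdx[:, :, :, 1]
        B[:, :, 2, 3 * ii + 2] = dNdx[:, :, :, 2]
        B[:, :, 3, 3 * ii + 0] = dNdx[:, :, :, 1]
        B[:, :, 3, 3 * ii + 1] = dNdx[:, :, :, 0]
        B[:, :, 4, 3 * ii + 1] = dNdx[:, :, :, 2]
        B[:, :, 4, 3 * ii + 2] = dNdx[:, :, :, 1]
        B[:, :, 5, 3 * ii + 0] = dNdx[:, :, :, 2]
        B[:, :, 5, 3 * ii + 2] = dNdx[:, :, :, 0]
        Bvol = B[:, :, 0:3, :].sum(axis=2)                      # (ne, ng, 3nn)
        D2 = np.diag([2.0, 2.0, 2.0, 1.0, 1.0, 1.0])
        # K_e = lam * K1 + mu * K2
        self.K1 = np.einsum("egi,egj,eg->eij", Bvol, Bvol, detJw, optimize=True)
        BD2 = np.einsum("ab,egbj->egaj", D2, B)
        self.K2 = np.einsum("egai,egaj,eg->eij", B, BD2, detJw, optimize=True)
        N = etype.N                                             # (ng, nn)
        self.Q = np.einsum("egi,gj,eg->eij", Bvol, N, detJw, optimize=True)
        self.Hu = np.einsum("egia,egja,eg->eij", dNdx, dNdx, detJw, optimize=True)
        self.M = np.einsum("gi,gj,eg->eij", N, N, detJw, optimize=True)
        # centroid operators for strain / pressure gradient recovery
        Bc = np.zeros((ne, 6, 3 * nn))
        Bc[:, 0, 3 * ii + 0] = dNdx_c[:, :, 0]
        Bc[:, 1, 3 * ii + 1] = dNdx_c[:, :, 1]
        Bc[:, 2, 3 * ii + 2] = dNdx_c[:, :, 2]
        Bc[:, 3, 3 * ii + 0] = dNdx_c[:, :, 1]
        Bc[:, 3, 3 * ii + 1] = dNdx_c[:, :, 0]
        Bc[:, 4, 3 * ii + 1] = dNdx_c[:, :, 2]
        Bc[:, 4, 3 * ii + 2] = dNdx_c[:, :, 1]
        Bc[:, 5, 3 * ii + 0] = dNdx_c[:, :, 2]
        Bc[:, 5, 3 * ii + 2] = dNdx_c[:, :, 0]
        self.Bc = Bc
        self.dNdx_c = dNdx_c
        # global dof maps
        self.udofs = (4 * conn[:, :, None] + np.arange(3)[None, None, :]).reshape(ne, 3 * nn)
        self.pdofs = 4 * conn + 3


@dataclass
class TransientSolution:
    """States (including the initial one) of a backward-Euler consolidation solve."""

    states: np.ndarray            # (n_steps + 1, ndof)
    times: np.ndarray             # (n_steps + 1,)
    Ksp: sp.csr_matrix
    Qsp: sp.csr_matrix

    def reaction(self, x: np.ndarray, dofs: np.ndarray) -> float:
        """Total internal force (K u - Q p) transmitted through the given dofs."""
        r = self.Ksp @ x - self.Qsp @ x
        return float(r[dofs].sum())


class PoroelasticSystem:
    """Assembled u-p Biot system on a labelled mesh.

    The sparsity pattern and all geometric element integrals are computed
    once; per-material assembly is a vectorised scatter of element data.
    """

    def __init__(self, mesh: Mesh, fluid_bulk_modulus: float = 2300.0):
        self.mesh = mesh
        self.ndof = 4 * mesh.n_nodes
        self.fluid_bulk_modulus = fluid_bulk_modulus
        self.blocks = [_BlockData(etype, conn, mesh.nodes)
                       for etype, conn in mesh.cell_blocks if len(conn)]
        # constant coupling matrix Q (geometry only, alpha = 1)
        self.Qsp = self._scatter([(b.Q, b.udofs, b.pdofs) for b in self.blocks])

    def _scatter(self, triples) -> sp.csr_matrix:
        rows, cols, data = [], [], []
        for mat_e, rdofs, cdofs in triples:
            ne, nr, nc = mat_e.shape
            rows.append(np.repeat(rdofs, nc, axis=1).ravel())
            cols.append(np.tile(cdofs, (1, nr)).ravel())
            data.append(mat_e.ravel())
        A = sp.coo_matrix((np.concatenate(data),
                           (np.concatenate(rows), np.concatenate(cols))),
                          shape=(self.ndof, self.ndof))
        return A.tocsr()

    def matrices(self, mat: ElementMaterial):
        """(K, H, S) sparse matrices for the given element materials."""
        E = np.asarray(mat.youngs_modulus, dtype=float)
        nu = np.asarray(mat.poisson_ratio, dtype=float)
        k_mm = np.asarray(mat.permeability, dtype=float) * M4NS_TO_MM4NS
        stor = np.asarray(mat.porosity, dtype=float) / self.fluid_bulk_modulus
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        kt, ht, st = [], [], []
        off = 0
        for b in self.blocks:
            ne = b.conn.shape[0]
            sl = slice(off, off + ne)
            kt.append((lam[sl, None, None] * b.K1 + mu[sl, None, None] * b.K2,
                       b.udofs, b.udofs))
            ht.append((k_mm[sl, None, None] * b.Hu, b.pdofs, b.pdofs))
            st.append((stor[sl, None, None] * b.M, b.pdofs, b.pdofs))
            off += ne
        return self._scatter(kt), self._scatter(ht), self._scatter(st)

    # -- field recovery -----------------------------------------------------
    def element_strain(self, x: np.ndarray) -> np.ndarray:
        """Centroid small-strain tensors in Voigt form, (ne, 6)."""
        out = []
        for b in self.blocks:
            out.append(np.einsum("eij,ej->ei", b.Bc, x[b.udofs]))
        return np.concatenate(out)

    def element_pressure_gradient(self, x: np.ndarray) -> np.ndarray:
        """Centroid grad(p), (ne, 3), MPa/mm."""
        out = []
        for b in self.blocks:
            out.append(np.einsum("ena,en->ea", b.dNdx_c, x[b.pdofs]))
        return np.concatenate(out)

    # -- solvers ------------------------------------------------------------
    def solve_transient(self, mat: ElementMaterial, *, dt: float, n_steps: int,
                        fixed_dofs: np.ndarray, fixed_vals: np.ndarray,
                        force_dofs: np.ndarray | None = None,
                        force_vals: np.ndarray | None = None,
                        ramp=None) -> TransientSolution:
        """Backward-Euler consolidation from a stress-free initial state.

        ``fixed_vals``/``force_vals`` are the full-amplitude values; ``ramp``
        maps time to the load factor (default: linear ramp over the run).
        """
        if ramp is None:
            total = dt * n_steps
            ramp = lambda t: t / total
        Ksp, Hsp, Ssp = self.matrices(mat)
        A = (Ksp - self.Qsp - self.Qsp.T - Ssp - dt * Hsp).tocsr()
        free = np.ones(self.ndof, dtype=bool)
        free[fixed_dofs] = False
        free_idx = np.flatnonzero(free)
        A_ff = A[free_idx][:, free_idx].tocsc()
        A_fc = A[free_idx][:, fixed_dofs]
        try:
            lu = splu(A_ff)
        except RuntimeError as exc:  # pragma: no cover - defensive
            raise SolverError(f"singular poroelastic system: {exc}") from exc
        CT = (self.Qsp.T + Ssp).tocsr()   # flow-equation history operator
        x = np.zeros(self.ndof)
        states = [x.copy()]
        times = [0.0]
        for n in range(1, n_steps + 1):
            t = n * dt
            fac = float(ramp(t))
            b = -(CT @ x)
            if force_dofs is not None:
                b[force_dofs] += fac * force_vals
            xc = fac * fixed_vals
            rhs = b[free_idx] - A_fc @ xc
            xf = lu.solve(rhs)
            if not np.all(np.isfinite(xf)):
                raise SolverError(f"non-finite solution at step {n}")
            x = np.zeros(self.ndof)
            x[free_idx] = xf
            x[fixed_dofs] = xc
            states.append(x)
            times.append(t)
        return TransientSolution(np.asarray(states), np.asarray(times), Ksp, self.Qsp)

    def solve_static_drained(self, mat: ElementMaterial, *,
                             fixed_dofs: np.ndarray, fixed_vals: np.ndarray,
                             force_dofs: np.ndarray | None = None,
                             force_vals: np.ndarray | None = None) -> np.ndarray:
        """Fully drained (p = 0 everywhere) elastic solve; returns the state."""
        pdofs = 4 * np.arange(self.mesh.n_nodes) + 3
        fixed = np.concatenate([np.asarray(fixed_dofs, dtype=np.int64), pdofs])
        vals = np.concatenate([np.asarray(fixed_vals, dtype=float),
                               np.zeros(pdofs.size)])
        # deduplicate (pressure dofs may already be constrained)
        fixed, keep = np.unique(fixed, return_index=True)
        vals = vals[keep]
        Ksp, _, _ = self.matrices(mat)
        free = np.ones(self.ndof, dtype=bool)
        free[fixed] = False
        free_idx = np.flatnonzero(free)
        A_ff = Ksp[free_idx][:, free_idx].tocsc()
        b = np.zeros(self.ndof)
        if force_dofs is not None:
            b[force_dofs] += force_vals
        rhs = b[free_idx] - Ksp[free_idx][:, fixed] @ vals
        x = np.zeros(self.ndof)
        x[free_idx] = splu(A_ff).solve(rhs)
        x[fixed] = vals
        return x


# ---------------------------------------------------------------------------
# callus daily load event
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DailySolution:
    """Peak-load response of one daily load event."""

    ifm: float                 # mm, both fragments
    u_top: float               # mm, half-model end displacement
    tissue_stiffness: float    # N/mm at the loaded end, peak of ramp
    fixator_force: float       # N carried by the fixator at peak
    gamma: np.ndarray          # per element
    v: np.ndarray              # per element, um/s (peak over the ramp)
    strain_voigt: np.ndarray   # per element, at peak


@dataclass
class _UnitResponse:
    k_t: float
    ifm_unit: float
    gamma_unit: np.ndarray
    v_unit: np.ndarray
    strain_unit: np.ndarray


class CallusModel:
    """Daily poroelastic solve of the callus with the parallel fixator spring.

    Boundary conditions: the loaded bone end face moves rigidly and only
    axially (high bending/torsional fixator stiffness); the mid-gap mirror
    plane is fixed axially; pore fluid drains freely through the periosteal
    callus surface and nowhere else.
    """

    def __init__(self, mesh: Mesh, *, n_steps: int = 6,
                 load: LoadCase = LoadCase(), fluid_bulk_modulus: float = 2300.0):
        self.mesh = mesh
        self.load = load
        self.n_steps = n_steps
        self.system = PoroelasticSystem(mesh, fluid_bulk_modulus)
        top = mesh.node_sets["top_load_face"]
        sym = mesh.node_sets["symmetry_plane"]
        drain = mesh.node_sets["drainage_boundary"]
        fixed: dict[int, float] = {}
        for n in sym:
            fixed[4 * n + 2] = 0.0
        for n in drain:
            fixed[4 * n + 3] = 0.0
        for n in top:
            fixed[4 * n + 0] = 0.0
            fixed[4 * n + 1] = 0.0
            fixed[4 * n + 2] = 1.0     # unit axial end displacement
        self.fixed_dofs = np.fromiter(fixed.keys(), dtype=np.int64)
        self.fixed_vals = np.fromiter(fixed.values(), dtype=float)
        self.top_uz_dofs = 4 * np.asarray(top, dtype=np.int64) + 2
        self.fragment_end_nodes = self._fragment_end_nodes()
        self.fragment_uz = 4 * self.fragment_end_nodes + 2

    def _fragment_end_nodes(self) -> np.ndarray:
        from .geometry import Region
        reg = self.mesh.element_region
        nodes = set()
        off = 0
        for etype, conn in self.mesh.cell_blocks:
            for i, row in enumerate(conn):
                if reg[off + i] == Region.CORTICAL:
                    nodes.update(int(n) for n in row)
            off += len(conn)
        nodes = np.asarray(sorted(nodes), dtype=np.int64)
        z = self.mesh.nodes[nodes, 2]
        zmin = z.min()
        return nodes[np.abs(z - zmin) < 1e-9 + 1e-9 * abs(zmin)]

    def unit_response(self, mat: ElementMaterial) -> _UnitResponse:
        """Transient solve under a unit (1 mm) ramped end displacement."""
        dt = self.load.load_ramp_duration / self.n_steps
        sol = self.system.solve_transient(
            mat, dt=dt, n_steps=self.n_steps,
            fixed_dofs=self.fixed_dofs, fixed_vals=self.fixed_vals)
        v_peak = np.zeros(self.mesh.n_elements)
        for x in sol.states[1:]:
            g = self.system.element_pressure_gradient(x)
            v_peak = np.maximum(v_peak, fluid_speed(g, mat.permeability))
        x_end = sol.states[-1]
        strain = self.system.element_strain(x_end)
        gamma = octahedral_shear_strain(strain)
        k_t = sol.reaction(x_end, self.top_uz_dofs)
        ifm_unit = 2.0 * float(x_end[self.fragment_uz].mean())
        return _UnitResponse(k_t, ifm_unit, gamma, v_peak, strain)

    def solve_daily_load(self, mat: ElementMaterial,
                         fixator: FixatorCurve) -> DailySolution:
        """Share the axial load between tissue and fixator; scale unit fields."""
        unit = self.unit_response(mat)
        u_top = _solve_balance(fixator, unit.k_t, self.load.axial_load)
        return DailySolution(
            ifm=unit.ifm_unit * u_top,
            u_top=u_top,
            tissue_stiffness=unit.k_t,
            fixator_force=fixator.force(2.0 * u_top),
            gamma=unit.gamma_unit * u_top,
            v=unit.v_unit * u_top,
            strain_voigt=unit.strain_unit * u_top,
        )

    def compute_ifm(self, solution: DailySolution) -> float:
        """Axial relative displacement of the two fragment end faces, mm."""
        return solution.ifm


def _solve_balance(fixator: FixatorCurve, k_t: float, load: float,
                   tol: float = 1e-10) -> float:
    """Newton/bracketed solve of k_t*u + F_fix(2u) = load for the half-model
    end displacement u (monotone increasing residual)."""
    if k_t <= 0:
        raise SolverError("non-positive tissue stiffness")
    g = lambda u: k_t * u + fixator.force(2.0 * u) - load
    hi = load / k_t           # tissue-only displacement bounds the root
    if g(hi) < 0:             # numerically flat fixator
        return hi
    return float(brentq(g, 0.0, hi, xtol=tol, rtol=1e-14))


def calibrate_fixator(target_ifm: float, model: CallusModel,
                      mat: ElementMaterial,
                      base_curve: FixatorCurve | None = None,
                      rel_tol: float = 1e-4) -> FixatorCurve:
    """Scale the base fixator curve so the day-1 solve reproduces ``target_ifm``.

    Deterministic bisection on the force scale factor.  Raises
    CalibrationError if the target is outside the reachable range (zero, or
    larger than what the tissue alone permits).
    """
    if base_curve is None:
        base_curve = default_fixator_base_curve()
    if target_ifm <= 0:
        raise CalibrationError("target IFM must be positive (rigid fixator limit)")
    unit = model.unit_response(mat)
    load = model.load.axial_load

    def ifm_of(s: float) -> float:
        u = _solve_balance(base_curve.scaled(s), unit.k_t, load)
        return unit.ifm_unit * u

    s_lo, s_hi = 0.0, 1.0
    if ifm_of(s_lo) < target_ifm:
        raise CalibrationError(
            f"target {target_ifm} mm unreachable: tissue alone gives "
            f"{ifm_of(s_lo):.4f} mm at {load} N")
    for _ in range(80):
        if ifm_of(s_hi) < target_ifm:
            break
        s_hi *= 4.0
    else:  # pragma: no cover
        raise CalibrationError("could not bracket the fixator scale factor")
    for _ in range(200):
        s_mid = 0.5 * (s_lo + s_hi)
        if ifm_of(s_mid) > target_ifm:
            s_lo = s_mid
        else:
            s_hi = s_mid
        if (s_hi - s_lo) <= rel_tol * 1e-2 * max(s_hi, 1e-30):
            break
    s = 0.5 * (s_lo + s_hi)
    curve = base_curve.scaled(s)
    achieved = ifm_of(s)
    if abs(achieved - target_ifm) > 0.01 * target_ifm:
        raise CalibrationError(
            f"calibration missed target: {achieved:.5f} vs {target_ifm}")
    return curve
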