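"""Closed-form and brute-force oracles plus tiny fixture meshes.

Everything here exists to verify the numerical layers independently:
Terzaghi's one-dimensional consolidation series for the poroelastic solver,
a dense-grid centroid for the exact Mamdani defuzzifier, and deterministic
code-generated meshes for unit tests.  Nothing in this module is used by the
simulation itself.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .elements import HEX8, element_volumes
from .fuzzy import FuzzyController, INPUT_ORDER, OUTPUT_ORDER, rule_activation
from .geometry import Region
from .mesh import Mesh, face_adjacency

__all__ = ["TerzaghiProblem", "terzaghi_pressure", "fuzzy_oracle",
           "make_fixture_mesh"]


@dataclass(frozen=True)
class TerzaghiProblem:
    """1D consolidation of a laterally confined column, drained at the top.

    ``drained_stiffness`` is the oedometric (confined) modulus of the
    skeleton; ``storage`` the specific storage coefficient (1/MPa), zero for
    incompressible constituents.  Units mm / MPa / m^4 N^-1 s^-1 / s.
    """

    column_height: float
    drained_stiffness: float
    permeability: float
    applied_stress: float
    evaluation_times: tuple = ()
    evaluation_depths: tuple = ()
    storage: float = 0.0

    def __post_init__(self):
        if min(self.column_height, self.drained_stiffness, self.permeability,
               self.applied_stress) <= 0:
            raise ValueError("Terzaghi problem parameters must be positive")
        for z in self.evaluation_depths:
            if not 0 <= z <= self.column_height:
                raise ValueError("evaluation depth outside the column")

    @property
    def consolidation_coefficient(self) -> float:
        """c_v in mm^2/s."""
        k_mm = self.permeability * 1e12
        return k_mm / (1.0 / self.drained_stiffness + self.storage)

    @property
    def initial_pressure(self) -> float:
        """Undrained pore pressure immediately after load application."""
        return self.applied_stress / (1.0 + self.storage * self.drained_stiffness)


def terzaghi_pressure(problem: TerzaghiProblem, depth: float, time: float) -> float:
    """Pore pressure (MPa) at ``depth`` below the drained surface.

    Classical Fourier series, truncated once the next term changes the sum
    by less than 1e-12 (absolute, in units of the initial pressure).
    """
    H = problem.column_height
    p0 = problem.initial_pressure
    if time <= 0:
        return p0 if 0 < depth <= H else (0.0 if depth == 0 else p0)
    Tv = problem.consolidation_coefficient * time / H ** 2
    Z = depth / H
    total = 0.0
    for m in range(10000):
        M = np.pi * (2 * m + 1) / 2.0
        term = (2.0 / M) * np.sin(M * Z) * np.exp(-M * M * Tv)
        total += term
        if abs(term) < 1e-12 and m >= 2:
            break
    return p0 * total


def fuzzy_oracle(inputs: dict[str, float], controller: FuzzyController,
                 n_grid: int = 10001) -> dict[str, float]:
    """Brute-force Mamdani inference on a dense output grid.

    Recomputes fuzzification and rule activation, then aggregates the
    clipped consequents on ``n_grid`` samples per output universe and takes
    the discrete centroid -- an independent check of the exact
    piecewise-linear centroid used by the controller.
    """
    fuzz = {name: controller.inputs[name].fuzzify(np.asarray([inputs[name]]))
            for name in INPUT_ORDER}
    acts = [float(np.asarray(rule_activation(r, fuzz)).ravel()[0])
            for r in controller.rules]
    out = {}
    for oname in OUTPUT_ORDER:
        var = controller.outputs[oname]
        ys = np.linspace(*var.universe, n_grid)
        agg = np.zeros_like(ys)
        for r, a in zip(controller.rules, acts):
            term = r.consequents.get(oname)
            if term is None or a <= 0:
                continue
            agg = np.maximum(agg, np.minimum(a, var.terms[term](ys)))
        area = np.trapezoid(agg, ys)
        out[oname] = float(np.trapezoid(agg * ys, ys) / area) if area > 1e-12 else 0.0
    return out


def _hex_mesh(nodes: np.ndarray, conn: np.ndarray, regions: np.ndarray,
              drain_nodes: np.ndarray, z_top: float) -> Mesh:
    wedge = np.empty((0, 6), dtype=np.int64)
    indptr, indices, _ = face_adjacency([(HEX8, conn)])
    vol = element_volumes(HEX8, nodes[conn])
    top = np.flatnonzero(np.abs(nodes[:, 2] - z_top) < 1e-12)
    bot = np.flatnonzero(np.abs(nodes[:, 2]) < 1e-12)
    node_sets = {
        "top_load_face": top, "bottom_fixed_face": bot, "symmetry_plane": bot,
        "periosteal_surface": drain_nodes, "drainage_boundary": drain_nodes,
    }
    return Mesh(nodes=nodes, hex_conn=conn, wedge_conn=wedge,
                element_region=regions.astype(np.int8), element_volume=vol,
                adj_indptr=indptr, adj_indices=indices, node_sets=node_sets,
                periosteal_elements=np.empty(0, dtype=np.int64),
                medullary_elements=np.flatnonzero(regions == Region.MEDULLARY),
                element_centroid=nodes[conn].mean(axis=1))


def _box_nodes(nx: int, ny: int, nz: int, lx: float, ly: float, lz: float):
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    zs = np.linspace(0, lz, nz + 1)
    nid = {}
    nodes = []
    for k, z in enumerate(zs):
        for j, y in enumerate(ys):
            for i, x in enumerate(xs):
                nid[(i, j, k)] = len(nodes)
                nodes.append((x, y, z))
    conn = []
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                conn.append((nid[(i, j, k)], nid[(i + 1, j, k)],
                             nid[(i + 1, j + 1, k)], nid[(i, j + 1, k)],
                             nid[(i, j, k + 1)], nid[(i + 1, j, k + 1)],
                             nid[(i + 1, j + 1, k + 1)], nid[(i, j + 1, k + 1)]))
    return np.asarray(nodes, dtype=float), np.asarray(conn, dtype=np.int64)


def make_fixture_mesh(kind: str, **params) -> Mesh:
    """Deterministic tiny meshes for unit tests.

    single_hex : one hexahedron (size lx/ly/lz, default unit cube).
    column     : n stacked unit-section hexes, drainage tagged on top.
    two_region : two face-sharing hexes, one cortical + one soft (gap).
    """
    if kind == "single_hex":
        lx = params.get("lx", 1.0)
        ly = params.get("ly", 1.0)
        lz = params.get("lz", 1.0)
        nodes, conn = _box_nodes(1, 1, 1, lx, ly, lz)
        if "distort" in params:
            # jitter interior geometry for patch tests; boundary tags are by z
            rng = np.random.default_rng(params["distort"])
            nodes = nodes + 0.12 * min(lx, ly, lz) * rng.uniform(-1, 1, nodes.shape)
        reg = np.array([Region.GAP])
        return _hex_mesh(nodes, conn, reg, drain_nodes=np.arange(4, 8),
                         z_top=nodes[:, 2].max())
    if kind == "column":
        n = params.get("n", 10)
        height = params.get("height", 10.0)
        nodes, conn = _box_nodes(1, 1, n, 1.0, 1.0, height)
        reg = np.full(n, Region.GAP)
        drain = np.flatnonzero(np.abs(nodes[:, 2] - height) < 1e-12)
        return _hex_mesh(nodes, conn, reg, drain_nodes=drain, z_top=height)
    if kind == "two_region":
        nodes, conn = _box_nodes(1, 1, 2, 1.0, 1.0, 2.0)
        reg = np.array([Region.CORTICAL, Region.GAP])
        drain = np.flatnonzero(np.abs(nodes[:, 2] - 2.0) < 1e-12)
        return _hex_mesh(nodes, conn, reg, drain_nodes=drain, z_top=2.0)
    raise ValueError(f"unknown fixture kind {kind!r}")
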