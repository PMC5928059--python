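"""Structured hex/wedge meshing of the revolved callus geometry.

The (r, z) plane is gridded with coordinate lines snapped to every region
interface (cortex radii, fragment end face, callus axial extent); cells whose
centroid lies inside the model are revolved through ``n_theta`` sectors.
Cells touching the axis become 6-node wedges, all others 8-node hexahedra —
the same element mix used for this class of callus models.  Meshing is fully
deterministic: identical inputs give identical node ordering and connectivity.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .elements import HEX8, WEDGE6, element_volumes
from .geometry import Geometry, Region

__all__ = ["Mesh", "MeshError", "generate_mesh", "face_adjacency"]


class MeshError(RuntimeError):
    pass


@dataclass
class Mesh:
    """Labelled finite-element mesh.  Elements are indexed hexahedra first,
    then wedges; ``element_region`` / ``element_volume`` follow that order."""

    nodes: np.ndarray                 # (nn, 3) mm
    hex_conn: np.ndarray              # (nh, 8)
    wedge_conn: np.ndarray            # (nw, 6)
    element_region: np.ndarray        # (ne,) Region codes
    element_volume: np.ndarray        # (ne,) mm^3
    adj_indptr: np.ndarray            # CSR face adjacency
    adj_indices: np.ndarray
    node_sets: dict[str, np.ndarray]  # named boundary node sets
    periosteal_elements: np.ndarray   # soft elements with an outer boundary face
    medullary_elements: np.ndarray    # elements in the marrow canal
    element_centroid: np.ndarray = field(default=None)  # (ne, 3)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.hex_conn.shape[0] + self.wedge_conn.shape[0]

    @property
    def cell_blocks(self):
        """[(element type, connectivity)] in global element order."""
        return [(HEX8, self.hex_conn), (WEDGE6, self.wedge_conn)]

    def neighbors(self, e: int) -> np.ndarray:
        return self.adj_indices[self.adj_indptr[e]:self.adj_indptr[e + 1]]

    def adjacency_list(self) -> list[np.ndarray]:
        return [self.neighbors(e) for e in range(self.n_elements)]

    def soft_elements(self) -> np.ndarray:
        """Elements subject to tissue differentiation (everything non-cortical)."""
        return np.flatnonzero(self.element_region != Region.CORTICAL)

    def validate(self) -> None:
        """Assert the structural mesh invariants; raises MeshError on failure."""
        if np.any(self.element_volume <= 0):
            raise MeshError("non-positive element volume")
        total = self.element_volume.sum()
        per_region = sum(self.element_volume[self.element_region == r].sum()
                         for r in Region)
        if abs(per_region - total) > 1e-9 * total:
            raise MeshError("region volumes do not partition the mesh volume")
        for e in range(self.n_elements):
            nb = self.neighbors(e)
            if e in nb:
                raise MeshError(f"self-adjacency at element {e}")
            for j in nb:
                if e not in self.neighbors(int(j)):
                    raise MeshError(f"asymmetric adjacency {e} <-> {j}")


def _segment_lines(breakpoints: list[float], h: float) -> np.ndarray:
    """Coordinate lines covering each [b_i, b_i+1] with cells of size <= h."""
    pts = [breakpoints[0]]
    for a, b in zip(breakpoints[:-1], breakpoints[1:]):
        n = max(1, int(np.ceil((b - a) / h - 1e-9)))
        pts.extend(np.linspace(a, b, n + 1)[1:])
    return np.asarray(pts)


def face_adjacency(cell_blocks) -> tuple[np.ndarray, np.ndarray, list]:
    """Face-sharing adjacency for a list of (element type, connectivity) blocks.

    Returns CSR (indptr, indices) over global element ids plus the list of
    boundary faces as (element id, node tuple).  A face shared by more than
    two elements is a meshing error.
    """
    face_map: dict[tuple, list[int]] = {}
    face_nodes: dict[tuple, tuple] = {}
    eid = 0
    for etype, conn in cell_blocks:
        for row in conn:
            for f in etype.faces:
                nodes = tuple(int(row[i]) for i in f)
                key = tuple(sorted(nodes))
                face_map.setdefault(key, []).append(eid)
                face_nodes[key] = nodes
            eid += 1
    n_elem = eid
    neigh: list[list[int]] = [[] for _ in range(n_elem)]
    boundary = []
    for key, elems in face_map.items():
        if len(elems) == 1:
            boundary.append((elems[0], face_nodes[key]))
        elif len(elems) == 2:
            a, b = elems
            neigh[a].append(b)
            neigh[b].append(a)
        else:
            raise MeshError(f"face {key} shared by {len(elems)} elements")
    indptr = np.zeros(n_elem + 1, dtype=np.int64)
    for e in range(n_elem):
        neigh[e] = sorted(set(neigh[e]))
        indptr[e + 1] = indptr[e] + len(neigh[e])
    indices = np.fromiter((j for lst in neigh for j in lst), dtype=np.int64,
                          count=int(indptr[-1]))
    return indptr, indices, boundary


def generate_mesh(geometry: Geometry, target_h: float = 0.9, n_theta: int = 8) -> Mesh:
    """Mesh the revolved geometry with element size control ``target_h`` (mm).

    Smaller ``target_h`` monotonically increases the element count.  ``n_theta``
    is the number of angular sectors of the full revolution (>= 3).
    """
    if n_theta < 3:
        raise MeshError("n_theta must be >= 3")
    if target_h <= 0:
        raise MeshError("target_h must be positive")
    p = geometry.params
    # _segment_lines always places at least one cell per breakpoint interval,
    # so the gap half-height is resolved by >= 1 element at any target_h.
    r_lines = _segment_lines(
        [0.0, p.cortex_inner_radius, p.cortex_outer_radius, p.callus_max_radius], target_h)
    z_breaks = [0.0, p.gap_half_height, p.callus_axial_extent, geometry.z_top]
    z_breaks = sorted(set(z_breaks))
    z_lines = _segment_lines(z_breaks, target_h)

    theta = 2.0 * np.pi * np.arange(n_theta) / n_theta

    # --- select 2D cells and classify their region ---------------------------
    cells2d = []  # (ir, iz, region)
    for iz in range(len(z_lines) - 1):
        zc = 0.5 * (z_lines[iz] + z_lines[iz + 1])
        for ir in range(len(r_lines) - 1):
            rc = 0.5 * (r_lines[ir] + r_lines[ir + 1])
            reg = geometry.region_of(rc, zc)
            if reg is not None:
                cells2d.append((ir, iz, reg))
    if not cells2d:
        raise MeshError("no cells selected; resolution too coarse for geometry")

    # --- node numbering ------------------------------------------------------
    node_id: dict[tuple[int, int, int], int] = {}
    coords: list[tuple[float, float, float]] = []

    def nid(ir: int, j: int, iz: int) -> int:
        key = (0, 0, iz) if ir == 0 else (ir, j % n_theta, iz)
        i = node_id.get(key)
        if i is None:
            i = len(coords)
            node_id[key] = i
            if ir == 0:
                coords.append((0.0, 0.0, float(z_lines[iz])))
            else:
                r = float(r_lines[ir])
                t = theta[key[1]]
                coords.append((r * np.cos(t), r * np.sin(t), float(z_lines[iz])))
        return i

    hexes, wedges, reg_hex, reg_wedge = [], [], [], []
    for ir, iz, reg in cells2d:
        for j in range(n_theta):
            if ir == 0:
                wedges.append((nid(0, 0, iz), nid(1, j, iz), nid(1, j + 1, iz),
                               nid(0, 0, iz + 1), nid(1, j, iz + 1), nid(1, j + 1, iz + 1)))
                reg_wedge.append(reg)
            else:
                hexes.append((nid(ir, j, iz), nid(ir + 1, j, iz),
                              nid(ir + 1, j + 1, iz), nid(ir, j + 1, iz),
                              nid(ir, j, iz + 1), nid(ir + 1, j, iz + 1),
                              nid(ir + 1, j + 1, iz + 1), nid(ir, j + 1, iz + 1)))
                reg_hex.append(reg)

    nodes = np.asarray(coords, dtype=float)
    hex_conn = np.asarray(hexes, dtype=np.int64).reshape(-1, 8)
    wedge_conn = np.asarray(wedges, dtype=np.int64).reshape(-1, 6)
    region = np.asarray(reg_hex + reg_wedge, dtype=np.int8)

    vol = np.concatenate([
        element_volumes(HEX8, nodes[hex_conn]) if len(hex_conn) else np.empty(0),
        element_volumes(WEDGE6, nodes[wedge_conn]) if len(wedge_conn) else np.empty(0),
    ])
    centroid = np.concatenate([
        nodes[hex_conn].mean(axis=1) if len(hex_conn) else np.empty((0, 3)),
        nodes[wedge_conn].mean(axis=1) if len(wedge_conn) else np.empty((0, 3)),
    ])

    indptr, indices, boundary = face_adjacency(
        [(HEX8, hex_conn), (WEDGE6, wedge_conn)])

    # --- boundary tagging ----------------------------------------------------
    z_top = geometry.z_top
    tol = 1e-9 * max(z_top, p.callus_max_radius)
    top_nodes = np.flatnonzero(np.abs(nodes[:, 2] - z_top) < tol)
    sym_nodes = np.flatnonzero(np.abs(nodes[:, 2]) < tol)
    peri_nodes, drain_nodes, peri_elems = set(), set(), set()
    for e, fnodes in boundary:
        zs = nodes[list(fnodes), 2]
        if np.all(np.abs(zs) < tol) or np.all(np.abs(zs - z_top) < tol):
            continue  # symmetry plane or loaded end, not a lateral surface
        peri_nodes.update(fnodes)
        if region[e] != Region.CORTICAL:
            drain_nodes.update(fnodes)
            peri_elems.add(e)
    node_sets = {
        "top_load_face": top_nodes,
        "bottom_fixed_face": sym_nodes,   # mid-gap mirror plane of the half model
        "symmetry_plane": sym_nodes,
        "periosteal_surface": np.asarray(sorted(peri_nodes), dtype=np.int64),
        "drainage_boundary": np.asarray(sorted(drain_nodes), dtype=np.int64),
    }
    mesh = Mesh(
        nodes=nodes, hex_conn=hex_conn, wedge_conn=wedge_conn,
        element_region=region, element_volume=vol,
        adj_indptr=indptr, adj_indices=indices, node_sets=node_sets,
        periosteal_elements=np.asarray(sorted(peri_elems), dtype=np.int64),
        medullary_elements=np.flatnonzero(region == Region.MEDULLARY),
        element_centroid=centroid,
    )
    mesh.validate()
    return mesh
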