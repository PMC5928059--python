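"""Reference-element tables for trilinear hexahedra and linear wedges.

Both element types carry displacement and pore pressure at the corner
nodes (equal-order interpolation, as in ABAQUS C3D8P/C3D6P).  This module
only knows about reference coordinates, shape functions, quadrature and
face topology; geometric mapping is done vectorised in :mod:`ossify.fem`.
"""
from __future__ import annotations

import numpy as np

__all__ = ["HEX8", "WEDGE6", "ElementType", "mapped_gradients", "element_volumes"]


class ElementType:
    """Shape functions and quadrature for one reference element."""

    def __init__(self, name: str, n_nodes: int, vtk_id: int,
                 gauss_points: np.ndarray, gauss_weights: np.ndarray,
                 faces: tuple[tuple[int, ...], ...]):
        self.name = name
        self.n_nodes = n_nodes
        self.vtk_id = vtk_id
        self.gauss_points = gauss_points          # (ng, 3)
        self.gauss_weights = gauss_weights        # (ng,)
        self.faces = faces                        # local node ids per face
        self.N = self.shape(gauss_points)         # (ng, nn)
        self.dN = self.shape_grad(gauss_points)   # (ng, nn, 3)
        c = self.centroid_ref()[None, :]
        self.N_c = self.shape(c)[0]               # (nn,)
        self.dN_c = self.shape_grad(c)[0]         # (nn, 3)

    # --- overridden per type -------------------------------------------------
    def shape(self, xi: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def shape_grad(self, xi: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def centroid_ref(self) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class _Hex8(ElementType):
    _signs = np.array([(-1, -1, -1), (1, -1, -1), (1, 1, -1), (-1, 1, -1),
                       (-1, -1, 1), (1, -1, 1), (1, 1, 1), (-1, 1, 1)], dtype=float)

    def __init__(self):
        g = 1.0 / np.sqrt(3.0)
        pts = np.array([(sx * g, sy * g, sz * g) for sx, sy, sz in self._signs])
        w = np.ones(8)
        faces = ((0, 3, 2, 1), (4, 5, 6, 7),
                 (0, 1, 5, 4), (1, 2, 6, 5), (2, 3, 7, 6), (3, 0, 4, 7))
        super().__init__("hexahedron", 8, 12, pts, w, faces)

    def shape(self, xi):
        s = self._signs
        return 0.125 * ((1 + xi[:, None, 0] * s[:, 0])
                        * (1 + xi[:, None, 1] * s[:, 1])
                        * (1 + xi[:, None, 2] * s[:, 2]))

    def shape_grad(self, xi):
        s = self._signs
        npts = xi.shape[0]
        dN = np.empty((npts, 8, 3))
        fx = 1 + xi[:, None, 0] * s[:, 0]
        fy = 1 + xi[:, None, 1] * s[:, 1]
        fz = 1 + xi[:, None, 2] * s[:, 2]
        dN[:, :, 0] = 0.125 * s[:, 0] * fy * fz
        dN[:, :, 1] = 0.125 * s[:, 1] * fx * fz
        dN[:, :, 2] = 0.125 * s[:, 2] * fx * fy
        return dN

    def centroid_ref(self):
        return np.zeros(3)


class _Wedge6(ElementType):
    """Triangular prism: area coordinates (L1, L2) x axial xi3 in [-1, 1]."""

    def __init__(self):
        tri = np.array([(1 / 6, 1 / 6), (2 / 3, 1 / 6), (1 / 6, 2 / 3)])
        g = 1.0 / np.sqrt(3.0)
        pts = np.array([(a, b, z) for z in (-g, g) for a, b in tri])
        w = np.full(6, 1.0 / 6.0)
        faces = ((0, 2, 1), (3, 4, 5),
                 (0, 1, 4, 3), (1, 2, 5, 4), (2, 0, 3, 5))
        super().__init__("wedge", 6, 13, pts, w, faces)

    def shape(self, xi):
        l1, l2, z = xi[:, 0], xi[:, 1], xi[:, 2]
        l0 = 1 - l1 - l2
        lo, hi = (1 - z) / 2, (1 + z) / 2
        return np.stack([l0 * lo, l1 * lo, l2 * lo, l0 * hi, l1 * hi, l2 * hi], axis=1)

    def shape_grad(self, xi):
        l1, l2, z = xi[:, 0], xi[:, 1], xi[:, 2]
        l0 = 1 - l1 - l2
        lo, hi = (1 - z) / 2, (1 + z) / 2
        dN = np.empty((xi.shape[0], 6, 3))
        dN[:, 0] = np.stack([-lo, -lo, -l0 / 2], axis=1)
        dN[:, 1] = np.stack([lo, np.zeros_like(lo), -l1 / 2], axis=1)
        dN[:, 2] = np.stack([np.zeros_like(lo), lo, -l2 / 2], axis=1)
        dN[:, 3] = np.stack([-hi, -hi, l0 / 2], axis=1)
        dN[:, 4] = np.stack([hi, np.zeros_like(hi), l1 / 2], axis=1)
        dN[:, 5] = np.stack([np.zeros_like(hi), hi, l2 / 2], axis=1)
        return dN

    def centroid_ref(self):
        return np.array([1 / 3, 1 / 3, 0.0])


HEX8 = _Hex8()
WEDGE6 = _Wedge6()


def mapped_gradients(etype: ElementType, coords: np.ndarray):
    """Map reference gradients to physical space for a batch of elements.

    Parameters
    ----------
    coords : (ne, nn, 3) nodal coordinates.

    Returns
    -------
    dNdx : (ne, ng, nn, 3) physical shape-function gradients.
    detJw : (ne, ng) Jacobian determinant times quadrature weight.
    dNdx_c, N_c : centroid gradients (ne, nn, 3) and shape values (nn,).
    """
    dN = etype.dN                                        # (ng, nn, 3)
    J = np.einsum("gna,enb->egab", dN, coords)           # (ne, ng, 3, 3)
    detJ = np.linalg.det(J)
    if np.any(detJ <= 0):
        raise ValueError("non-positive Jacobian in element mapping")
    Jinv = np.linalg.inv(J)
    # J[a,b] = dx_b/dxi_a, so dN/dx_a = Jinv[a,b] dN/dxi_b
    dNdx = np.einsum("egab,gnb->egna", Jinv, dN)
    detJw = detJ * etype.gauss_weights[None, :]
    Jc = np.einsum("na,enb->eab", etype.dN_c, coords)
    dNdx_c = np.einsum("eab,nb->ena", np.linalg.inv(Jc), etype.dN_c)
    return dNdx, detJw, dNdx_c, etype.N_c


def element_volumes(etype: ElementType, coords: np.ndarray) -> np.ndarray:
    """Exact (quadrature) volumes of a batch of elements, mm^3."""
    _, detJw, _, _ = mapped_gradients(etype, coords)
    return detJw.sum(axis=1)
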