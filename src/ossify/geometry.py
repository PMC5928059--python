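"""Parametric half-symmetry geometry of an osteotomised long bone with callus.

The model is axisymmetric about the bone axis (z) and mirror-symmetric about
the transverse mid-gap plane, so only the upper half is described: it spans
z in [0, gap_half_height + bone_segment_length], with z = 0 the symmetry
plane through the middle of the fracture gap.

Regions
-------
gap        interfragmentary tissue, |z| < gap_half_height, r < cortex outer
cortical   the bone fragment annulus above the gap
medullary  the marrow canal above the fragment end face
callus     the external (periosteal) callus spindle enveloping the cortex

The external callus profile is a documented free choice: an elliptical arc
from the periosteal surface at the callus axial extent, bulging to
``callus_max_radius`` at the symmetry plane (the largest callus diameter is
reached over the gap, as observed in healing calluses).
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

__all__ = ["Region", "GeometryParams", "Geometry", "build_geometry", "ParameterError"]


class ParameterError(ValueError):
    """Raised when geometry parameters violate a constraint."""


class Region(IntEnum):
    CORTICAL = 0
    CALLUS = 1
    GAP = 2
    MEDULLARY = 3


SOFT_REGIONS = (Region.CALLUS, Region.GAP, Region.MEDULLARY)


@dataclass(frozen=True)
class GeometryParams:
    """All lengths in mm.  Defaults give the stable-fixation (2.1 mm gap) case."""

    cortex_outer_radius: float = 5.0
    cortex_inner_radius: float = 2.5
    gap_half_height: float = 1.05
    callus_max_radius: float = 8.0      # max callus diameter 16 mm
    bone_segment_length: float = 15.0
    callus_axial_extent: float = 11.0

    def __post_init__(self):
        f = self
        checks = [
            (f.cortex_inner_radius > 0, "cortex_inner_radius must be > 0"),
            (f.cortex_outer_radius > f.cortex_inner_radius,
             "cortex_outer_radius must exceed cortex_inner_radius"),
            (f.callus_max_radius > f.cortex_outer_radius,
             "callus_max_radius must exceed cortex_outer_radius"),
            (f.gap_half_height > 0, "gap_half_height must be > 0"),
            (f.bone_segment_length > 0, "bone_segment_length must be > 0"),
            (f.callus_axial_extent > f.gap_half_height,
             "callus_axial_extent must exceed gap_half_height"),
            (f.callus_axial_extent <= f.gap_half_height + f.bone_segment_length,
             "callus_axial_extent must not exceed the modelled bone length"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ParameterError(msg)
        for name, v in vars(f).items():
            if not np.isfinite(v) or v <= 0:
                raise ParameterError(f"{name} must be finite and positive")


@dataclass(frozen=True)
class Geometry:
    """Region description produced by :func:`build_geometry`."""

    params: GeometryParams

    @property
    def z_top(self) -> float:
        p = self.params
        return p.gap_half_height + p.bone_segment_length

    def callus_profile_radius(self, z) -> np.ndarray:
        """Outer callus radius at height z (elliptical spindle profile)."""
        p = self.params
        z = np.asarray(z, dtype=float)
        frac = np.clip(1.0 - (z / p.callus_axial_extent) ** 2, 0.0, None)
        return p.cortex_outer_radius + (p.callus_max_radius - p.cortex_outer_radius) * np.sqrt(frac)

    def region_of(self, r: float, z: float) -> Region | None:
        """Region containing the point (r, z), or None if outside the model."""
        p = self.params
        if r < 0 or z < 0 or z > self.z_top:
            return None
        if z < p.gap_half_height:
            if r < p.cortex_outer_radius:
                return Region.GAP
            return Region.CALLUS if r <= self.callus_profile_radius(z) else None
        if r < p.cortex_inner_radius:
            return Region.MEDULLARY
        if r < p.cortex_outer_radius:
            return Region.CORTICAL
        return Region.CALLUS if r <= self.callus_profile_radius(z) else None


def build_geometry(params: GeometryParams) -> Geometry:
    """Validate parameters and return the region description.

    The dataclass already enforces the invariants; this exists as the
    explicit construction step so callers get a parameter error before any
    meshing is attempted.
    """
    return Geometry(params)
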