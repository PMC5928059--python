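"""Tissue property table and mixture-rule homogenisation.

Each callus element holds volume fractions of connective tissue, cartilage
and woven bone (summing to one) plus a perfusion level.  Element-level
poroelastic constants are obtained from the pure-tissue table by a cubic
rule of mixtures for the Young's modulus (after the experimental
stiffness-density relationship of Carter & Hayes) and linear rules for
Poisson's ratio, permeability and porosity.  Cortical bone never remodels
and bypasses mixing.

Units: Young's modulus MPa, permeability m^4/(N s), porosity and
concentrations dimensionless.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "TissueProperties", "TissueLibrary", "TissueState", "ElementMaterial",
    "StateError", "mix_youngs_modulus", "mix_linear", "element_material",
]

_EQ6_TOL = 1e-9


class StateError(ValueError):
    """Tissue concentrations violate the unit-sum constraint or bounds."""


@dataclass(frozen=True)
class TissueProperties:
    youngs_modulus: float      # MPa
    poisson_ratio: float
    permeability: float        # m^4/(N s)
    porosity: float

    def __post_init__(self):
        if not (self.youngs_modulus > 0):
            raise ValueError("youngs_modulus must be > 0")
        if not (0 < self.poisson_ratio < 0.5):
            raise ValueError("poisson_ratio must be in (0, 0.5)")
        if not (self.permeability > 0):
            raise ValueError("permeability must be > 0")
        if not (0 < self.porosity < 1):
            raise ValueError("porosity must be in (0, 1)")


@dataclass(frozen=True)
class TissueLibrary:
    """Pure-tissue poroelastic constants (granulation/connective tissue,
    cartilage, woven bone, cortical bone)."""

    connective: TissueProperties = TissueProperties(3.0, 0.30, 1e-14, 0.8)
    cartilage: TissueProperties = TissueProperties(200.0, 0.45, 5e-15, 0.8)
    woven_bone: TissueProperties = TissueProperties(4000.0, 0.36, 3.7e-13, 0.8)
    cortical_bone: TissueProperties = TissueProperties(10000.0, 0.36, 1e-17, 0.04)

    def soft(self, attr: str) -> np.ndarray:
        """(connective, cartilage, woven bone) values of one property."""
        return np.array([getattr(self.connective, attr),
                         getattr(self.cartilage, attr),
                         getattr(self.woven_bone, attr)])

    def to_dict(self) -> dict:
        return {k: asdict(v) for k, v in vars(self).items()}

    @classmethod
    def from_dict(cls, d: dict) -> "TissueLibrary":
        return cls(**{k: TissueProperties(**v) for k, v in d.items()})


@dataclass
class TissueState:
    """Per-element tissue composition.  All fields are arrays of equal length
    (scalar states are promoted to length-1 arrays)."""

    c_conn: np.ndarray
    c_cart: np.ndarray
    c_bone: np.ndarray
    perfusion: np.ndarray

    def __post_init__(self):
        for name in ("c_conn", "c_cart", "c_bone", "perfusion"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))

    def validate(self) -> None:
        for name in ("c_conn", "c_cart", "c_bone", "perfusion"):
            v = getattr(self, name)
            if np.any(v < -_EQ6_TOL) or np.any(v > 1 + _EQ6_TOL):
                raise StateError(f"{name} outside [0, 1]")
        s = self.c_conn + self.c_cart + self.c_bone
        if np.any(np.abs(s - 1.0) > _EQ6_TOL):
            raise StateError("concentrations must sum to 1")

    def __len__(self) -> int:
        return self.c_conn.shape[0]


@dataclass(frozen=True)
class ElementMaterial:
    """Homogenised poroelastic constants, arrays over elements."""

    youngs_modulus: np.ndarray
    poisson_ratio: np.ndarray
    permeability: np.ndarray
    porosity: np.ndarray


def _fractions(state: TissueState) -> np.ndarray:
    state.validate()
    return np.stack([state.c_conn, state.c_cart, state.c_bone])


def mix_youngs_modulus(state: TissueState, lib: TissueLibrary) -> np.ndarray:
    """Cubic rule of mixtures: E = sum_t E_t * c_t^3 (MPa)."""
    c = _fractions(state)
    return lib.soft("youngs_modulus") @ (c ** 3)


def mix_linear(state: TissueState, lib: TissueLibrary, which: str) -> np.ndarray:
    """Linear rule of mixtures for 'poisson', 'permeability' or 'porosity'."""
    attr = {"poisson": "poisson_ratio", "permeability": "permeability",
            "porosity": "porosity"}.get(which)
    if attr is None:
        raise ValueError(f"unknown property {which!r}")
    return lib.soft(attr) @ _fractions(state)


def element_material(state: TissueState, lib: TissueLibrary,
                     cortical_mask: np.ndarray | None = None) -> ElementMaterial:
    """Per-element constants from the mixture rules.

    Elements flagged in ``cortical_mask`` bypass mixing and take the
    cortical-bone row unchanged.
    """
    E = mix_youngs_modulus(state, lib)
    nu = mix_linear(state, lib, "poisson")
    k = mix_linear(state, lib, "permeability")
    n = mix_linear(state, lib, "porosity")
    if cortical_mask is not None:
        cb = lib.cortical_bone
        m = np.asarray(cortical_mask, dtype=bool)
        E = np.where(m, cb.youngs_modulus, E)
        nu = np.where(m, cb.poisson_ratio, nu)
        k = np.where(m, cb.permeability, k)
        n = np.where(m, cb.porosity, n)
    return ElementMaterial(E, nu, k, n)
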