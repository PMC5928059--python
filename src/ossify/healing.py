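"""Day-by-day coupled simulation of secondary fracture healing.

Each simulated day: (i) homogenise element materials from the current tissue
fractions, (ii) solve the poroelastic daily load event and evaluate the
biophysical stimulus per element, (iii) run the fuzzy controller on every
non-cortical element with its local stimulus, perfusion/tissue state and
face-neighbour maxima, (iv) apply the daily concentration changes with the
unit-sum constraint (connective tissue is the slack fraction), (v) re-impose
the perfusion source boundaries, and (vi) record IFM and fields.

The loop is fully deterministic for a given configuration.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fem import (CallusModel, FixatorCurve, LoadCase, StimulusConstants,
                  StimulusField, calibrate_fixator, compute_stimulus,
                  default_fixator_base_curve)
from .fuzzy import FuzzyController, default_controller
from .geometry import GeometryParams, Region, build_geometry
from .materials import TissueLibrary, TissueState, element_material
from .mesh import Mesh, generate_mesh

__all__ = [
    "SimulationConfig", "HealingHistory", "HealingSimulator",
    "initialize_state", "apply_perfusion_boundaries", "neighbor_max",
    "run_simulation", "healing_day_stimulus", "ifm_minimum_day",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one fixation case.

    Case A is the stable fixation (2.1 mm gap, 0.25 mm nominal day-1 IFM),
    case B the unstable one (3.1 mm gap, 1.25 mm).  ``rate_delta`` is the
    global per-day output scale of the fuzzy controller; ``rng_seed`` only
    seeds auxiliary stochastic fixtures -- the core loop is deterministic.
    """

    case: str = "A"
    gap_size: float = 2.1                   # mm
    nominal_ifm: float = 0.25               # mm, day-1 target after calibration
    days: int = 70
    load: LoadCase = LoadCase(500.0, 8.0, 8.0)
    stimulus_constants: StimulusConstants = StimulusConstants()
    boundary_perfusion: float = 0.30
    medullary_revascularisation_day: int = 10
    rate_delta: float = 0.09
    s_medium: float = 4.0
    s_destruction: float = 23.0
    s_destruction_width: float | None = 10.0
    s_max: float = 50.0
    conc_low_foot: float = 0.4
    stimulus_smoothing_radius: float = 1.5   # mm; 0 disables smoothing
    neighborhood_radius: float = 1.3         # mm; 0 falls back to face adjacency
    physiological_s: float = 1.2            # healing band: max callus S <= this
    sustain_days: int = 3                   # ... for this many consecutive days
    mesh_target_h: float = 0.9              # mm
    n_theta: int = 8
    n_time_steps: int = 6
    rng_seed: int = 0
    geometry: GeometryParams | None = None
    tissue_library: TissueLibrary = TissueLibrary()

    def __post_init__(self):
        if self.days < 1:
            raise ValueError("days must be >= 1")
        if not 0.0 <= self.boundary_perfusion <= 1.0:
            raise ValueError("boundary_perfusion must be in [0, 1]")
        if self.gap_size <= 0 or self.nominal_ifm <= 0:
            raise ValueError("gap_size and nominal_ifm must be positive")

    @staticmethod
    def for_case(case: str, **overrides) -> "SimulationConfig":
        presets = {"A": dict(case="A", gap_size=2.1, nominal_ifm=0.25),
                   "B": dict(case="B", gap_size=3.1, nominal_ifm=1.25)}
        if case not in presets:
            raise ValueError(f"unknown case {case!r} (use 'A' or 'B')")
        kw = presets[case] | overrides
        return SimulationConfig(**kw)

    def geometry_params(self) -> GeometryParams:
        if self.geometry is not None:
            return self.geometry
        return GeometryParams(gap_half_height=self.gap_size / 2.0)

    def controller(self) -> FuzzyController:
        return default_controller(delta=self.rate_delta, s_medium=self.s_medium,
                                  s_destr=self.s_destruction, s_max=self.s_max,
                                  destr_width=self.s_destruction_width,
                                  conc_low_foot=self.conc_low_foot)


@dataclass
class HealingHistory:
    """Day-indexed record of the simulation."""

    days: list[int] = field(default_factory=list)
    ifm: list[float] = field(default_factory=list)              # mm
    max_callus_S: list[float] = field(default_factory=list)
    mean_c_bone: list[float] = field(default_factory=list)
    mean_c_cart: list[float] = field(default_factory=list)
    mean_perfusion: list[float] = field(default_factory=list)
    states: list[TissueState] = field(default_factory=list)
    stimuli: list[StimulusField] = field(default_factory=list)
    n_elements: int = 0

    def record(self, day: int, ifm: float, stim: StimulusField,
               s_eff: np.ndarray, state: TissueState, soft: np.ndarray) -> None:
        self.days.append(day)
        self.ifm.append(float(ifm))
        self.max_callus_S.append(float(s_eff[soft].max()))
        self.mean_c_bone.append(float(state.c_bone[soft].mean()))
        self.mean_c_cart.append(float(state.c_cart[soft].mean()))
        self.mean_perfusion.append(float(state.perfusion[soft].mean()))
        self.states.append(replace(state, c_conn=state.c_conn.copy(),
                                   c_cart=state.c_cart.copy(),
                                   c_bone=state.c_bone.copy(),
                                   perfusion=state.perfusion.copy()))
        self.stimuli.append(stim)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "day": self.days, "ifm_mm": self.ifm, "max_S": self.max_callus_S,
            "mean_c_bone": self.mean_c_bone, "mean_c_cart": self.mean_c_cart,
            "mean_perfusion": self.mean_perfusion,
        })


def initialize_state(mesh: Mesh, config: SimulationConfig) -> TissueState:
    """Connective-tissue-filled callus with zero perfusion except the
    peripheral (periosteal) source elements; cortical elements are pure bone
    and never updated."""
    ne = mesh.n_elements
    cort = mesh.element_region == Region.CORTICAL
    state = TissueState(
        c_conn=np.where(cort, 0.0, 1.0),
        c_cart=np.zeros(ne),
        c_bone=np.where(cort, 1.0, 0.0),
        perfusion=np.zeros(ne),
    )
    state.perfusion[mesh.periosteal_elements] = config.boundary_perfusion
    state.validate()
    return state


def apply_perfusion_boundaries(state: TissueState, day: int,
                               config: SimulationConfig, mesh: Mesh) -> TissueState:
    """Impose the perfusion sources as floors (a source, not a cap):
    peripheral callus every day; the medullary channel from the
    revascularisation day onward."""
    p = state.perfusion
    pe = mesh.periosteal_elements
    p[pe] = np.maximum(p[pe], config.boundary_perfusion)
    if day >= config.medullary_revascularisation_day:
        me = mesh.medullary_elements
        p[me] = np.maximum(p[me], config.boundary_perfusion)
    return state


def neighbor_max(field_values: np.ndarray, indptr: np.ndarray,
                 indices: np.ndarray) -> np.ndarray:
    """Per element, the maximum of ``field_values`` over face-adjacent
    elements (the element itself excluded); elements without neighbours
    return 0."""
    field_values = np.asarray(field_values, dtype=float)
    out = np.zeros(indptr.size - 1)
    gathered = field_values[indices]
    counts = np.diff(indptr)
    nonempty = counts > 0
    if gathered.size:
        segmax = np.maximum.reduceat(gathered, indptr[:-1][nonempty])
        out[nonempty] = segmax
    return out


def radius_neighborhood(centroids: np.ndarray, radius: float,
                        include_self: bool = False):
    """CSR (indptr, indices) of elements whose centroids lie within
    ``radius`` mm of each element's centroid.

    A metric neighbourhood keeps the physics mesh-independent: fields that
    propagate element-to-element (perfusion, the adjacent-bone signal) then
    advance at a fixed speed in millimetres per day rather than one element
    layer per day.
    """
    from scipy.spatial import cKDTree
    tree = cKDTree(centroids)
    lists = tree.query_ball_point(centroids, r=radius)
    indptr = np.zeros(len(lists) + 1, dtype=np.int64)
    idx = []
    for i, lst in enumerate(lists):
        nb = sorted(j for j in lst if include_self or j != i)
        idx.extend(nb)
        indptr[i + 1] = indptr[i] + len(nb)
    return indptr, np.asarray(idx, dtype=np.int64)


def _weighted_average(values: np.ndarray, volumes: np.ndarray,
                      indptr: np.ndarray, indices: np.ndarray) -> np.ndarray:
    """Volume-weighted neighbourhood mean (CSR must include self)."""
    num = np.add.reduceat(np.append((volumes * values)[indices], 0.0), indptr[:-1])
    den = np.add.reduceat(np.append(volumes[indices], 0.0), indptr[:-1])
    empty = np.diff(indptr) == 0
    num[empty] = values[empty] * volumes[empty]
    den[empty] = volumes[empty]
    return num / den


def smooth_stimulus(S: np.ndarray, mesh: Mesh, radius: float = 1.5) -> np.ndarray:
    """Volume-weighted averaging of the element stimulus over a metric
    neighbourhood of ``radius`` mm.

    Differentiating cells integrate their mechanical environment over a
    finite volume rather than a single element, so the stimulus driving the
    controller (and the healing-day metrics) is the local average; this also
    keeps single-element stress concentrations at re-entrant corners from
    dominating the field, and its support does not shrink with mesh
    refinement.
    """
    S = np.asarray(S, dtype=float)
    indptr, indices = radius_neighborhood(mesh.element_centroid, radius,
                                          include_self=True)
    return _weighted_average(S, mesh.element_volume, indptr, indices)


class HealingSimulator:
    """Holds the mesh, FE model, controller and calibrated fixator for one
    case and advances the coupled loop day by day."""

    def __init__(self, config: SimulationConfig,
                 fixator: FixatorCurve | None = None):
        self.config = config
        geometry = build_geometry(config.geometry_params())
        self.mesh = generate_mesh(geometry, target_h=config.mesh_target_h,
                                  n_theta=config.n_theta)
        self.model = CallusModel(self.mesh, n_steps=config.n_time_steps,
                                 load=config.load)
        self.controller = config.controller()
        self.lib = config.tissue_library
        self.cortical_mask = self.mesh.element_region == Region.CORTICAL
        self.soft = self.mesh.soft_elements()
        cen = self.mesh.element_centroid
        if config.neighborhood_radius > 0:
            self.nbr_indptr, self.nbr_indices = radius_neighborhood(
                cen, config.neighborhood_radius)
        else:
            self.nbr_indptr, self.nbr_indices = \
                self.mesh.adj_indptr, self.mesh.adj_indices
        if config.stimulus_smoothing_radius > 0:
            self.sm_indptr, self.sm_indices = radius_neighborhood(
                cen, config.stimulus_smoothing_radius, include_self=True)
        else:
            self.sm_indptr = self.sm_indices = None
        if fixator is None:
            fixator = self.calibrate()
        self.fixator = fixator

    def calibrate(self) -> FixatorCurve:
        """Scale the base fixator curve to the case's nominal day-1 IFM."""
        state = initialize_state(self.mesh, self.config)
        mat = element_material(state, self.lib, self.cortical_mask)
        base = default_fixator_base_curve(self.config.case)
        return calibrate_fixator(self.config.nominal_ifm, self.model, mat, base)

    def step_day(self, state: TissueState, day: int):
        """One coupled iteration; mutates and returns (state, stimulus, ifm)."""
        cfg = self.config
        mat = element_material(state, self.lib, self.cortical_mask)
        sol = self.model.solve_daily_load(mat, self.fixator)
        stim = compute_stimulus(sol.gamma, sol.v, cfg.stimulus_constants)
        if self.sm_indptr is not None:
            s_eff = _weighted_average(stim.S, self.mesh.element_volume,
                                      self.sm_indptr, self.sm_indices)
        else:
            s_eff = stim.S

        soft = self.soft
        ad_perf = neighbor_max(state.perfusion, self.nbr_indptr, self.nbr_indices)
        ad_bone = neighbor_max(state.c_bone, self.nbr_indptr, self.nbr_indices)
        inputs = np.column_stack([
            s_eff[soft], state.perfusion[soft], ad_perf[soft],
            state.c_cart[soft], state.c_bone[soft], ad_bone[soft],
        ])
        delta = self.controller.infer_batch(inputs)

        state.perfusion[soft] = np.clip(state.perfusion[soft] + delta[:, 0], 0.0, 1.0)
        cart = np.clip(state.c_cart[soft] + delta[:, 1], 0.0, 1.0)
        bone = np.clip(state.c_bone[soft] + delta[:, 2], 0.0, 1.0)
        total = cart + bone
        over = total > 1.0
        scale = np.where(over, 1.0 / np.maximum(total, 1e-300), 1.0)
        cart *= scale
        bone *= scale
        state.c_cart[soft] = cart
        state.c_bone[soft] = bone
        state.c_conn[soft] = np.clip(1.0 - cart - bone, 0.0, 1.0)
        apply_perfusion_boundaries(state, day, cfg, self.mesh)
        state.validate()
        return state, stim, s_eff, sol.ifm

    def run(self) -> HealingHistory:
        state = initialize_state(self.mesh, self.config)
        history = HealingHistory(n_elements=self.mesh.n_elements)
        for day in range(1, self.config.days + 1):
            try:
                state, stim, s_eff, ifm = self.step_day(state, day)
            except Exception as exc:
                raise RuntimeError(f"healing loop failed on day {day}") from exc
            history.record(day, ifm, stim, s_eff, state, self.soft)
        return history


def run_simulation(config: SimulationConfig) -> HealingHistory:
    """Initialise, calibrate the fixator and run the full daily loop."""
    return HealingSimulator(config).run()


def healing_day_stimulus(history: HealingHistory, physiological_s: float = 1.0,
                         sustain_days: int = 3) -> int | None:
    """First day at which the peak callus stimulus enters and stays within
    the physiological band for ``sustain_days`` consecutive days (or to the
    end of the record, whichever is shorter).  None if never reached."""
    s = np.asarray(history.max_callus_S)
    days = history.days
    n = s.size
    for i in range(n):
        j = min(n, i + sustain_days)
        if np.all(s[i:j] <= physiological_s):
            return days[i]
    return None


def ifm_minimum_day(history: HealingHistory, rel_tol: float = 0.05) -> int:
    """First day at which the IFM is within ``rel_tol`` of its final value."""
    ifm = np.asarray(history.ifm)
    if ifm.size < 1:
        raise ValueError("empty history")
    final = ifm[-1]
    tol = rel_tol * abs(final) if final != 0 else rel_tol * ifm.max()
    hit = np.abs(ifm - final) <= tol
    return history.days[int(np.argmax(hit))]
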