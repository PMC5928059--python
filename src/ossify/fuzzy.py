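"""Mamdani fuzzy controller for tissue differentiation in the callus.

Six crisp inputs per element -- biophysical stimulus S, own perfusion,
highest perfusion among face neighbours, own cartilage and bone
concentration, highest bone concentration among face neighbours -- are
mapped through 14 linguistic if-then rules to daily changes of perfusion,
cartilage and bone concentration.  Inference is classical Mamdani:
trapezoidal membership, "and" = min, negation = complement, implication =
min-clip, aggregation = max, centroid defuzzification.  The centroid is
integrated exactly on the piecewise-linear aggregate (no sampling grid), so
outputs are deterministic and resolution-free.

The rule base encodes angiogenesis (1-3), intramembranous ossification (4),
chondrogenesis (5-8), endochondral ossification (9-12), tissue destruction
under overload (13) and a default "no change" rule (14).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Trapezoid", "FuzzyVariable", "FuzzyRule", "FuzzyController",
    "membership", "fuzzify", "rule_activation", "transcribe_rule_table",
    "default_controller", "ConfigurationError",
    "INPUT_ORDER", "OUTPUT_ORDER",
]

INPUT_ORDER = ("S", "c_perfusion", "c_adPerfusion",
               "c_cartilage", "c_bone", "c_adbone")
OUTPUT_ORDER = ("dc_perfusion", "dc_cartilage", "dc_bone")


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class Trapezoid:
    """Trapezoidal membership function with feet (a, d) and shoulders (b, c)."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self):
        if not (self.a <= self.b <= self.c <= self.d):
            raise ConfigurationError(
                f"trapezoid abscissae must be non-decreasing: {self}")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        if self.b > self.a:
            rising = (x > self.a) & (x < self.b)
            out = np.where(rising, (x - self.a) / (self.b - self.a), out)
        out = np.where((x >= self.b) & (x <= self.c), 1.0, out)
        if self.d > self.c:
            falling = (x > self.c) & (x < self.d)
            out = np.where(falling, (self.d - x) / (self.d - self.c), out)
        return out if out.ndim else float(out)

    def scalar(self, x: float) -> float:
        """Pure-Python membership evaluation (hot path of the defuzzifier)."""
        if x <= self.a or x >= self.d:
            # feet are exclusive except for degenerate vertical flanks
            if x < self.a or x > self.d:
                return 0.0
            if x == self.a and self.a == self.b:
                return 1.0
            if x == self.d and self.c == self.d:
                return 1.0
            return 0.0
        if x < self.b:
            return (x - self.a) / (self.b - self.a)
        if x <= self.c:
            return 1.0
        return (self.d - x) / (self.d - self.c)

    def aslist(self):
        return [self.a, self.b, self.c, self.d]


def membership(x: float, t: Trapezoid) -> float:
    """Degree of membership of x in the trapezoidal set t."""
    return float(t(float(x)))


@dataclass(frozen=True)
class FuzzyVariable:
    name: str
    universe: tuple[float, float]
    terms: dict[str, Trapezoid]

    def __post_init__(self):
        lo, hi = self.universe
        if not lo < hi:
            raise ConfigurationError(f"{self.name}: empty universe")
        xs = np.linspace(lo, hi, 513)
        cover = np.zeros_like(xs)
        for t in self.terms.values():
            cover = np.maximum(cover, t(xs))
        if np.any(cover <= 0):
            raise ConfigurationError(
                f"{self.name}: terms do not cover the universe (completeness)")

    def clamp(self, value):
        return np.clip(value, *self.universe)

    def fuzzify(self, value):
        """Term -> degree map; value is clamped to the universe first."""
        v = self.clamp(value)
        return {name: t(v) for name, t in self.terms.items()}


def fuzzify(value, var: FuzzyVariable):
    return var.fuzzify(value)


@dataclass(frozen=True)
class FuzzyRule:
    """Antecedents map input name -> (term, negated); consequents map output
    name -> term.  Inputs absent from the map do not participate."""

    antecedents: dict[str, tuple[str, bool]]
    consequents: dict[str, str]

    def __post_init__(self):
        if not self.antecedents or not self.consequents:
            raise ConfigurationError("rule needs >= 1 antecedent and consequent")


def rule_activation(rule: FuzzyRule, fuzzified: dict[str, dict[str, float]]):
    """min over antecedent degrees; 'Not T' evaluates as 1 - degree(T)."""
    act = None
    for var, (term, negated) in rule.antecedents.items():
        try:
            deg = fuzzified[var][term]
        except KeyError as exc:
            raise ConfigurationError(f"unknown term {var}.{term}") from exc
        deg = 1.0 - deg if negated else deg
        act = deg if act is None else np.minimum(act, deg)
    return act


def _parse_term(cell: str) -> tuple[str, bool] | None:
    cell = cell.strip()
    if cell in ("-", "—", ""):
        return None
    neg = cell.lower().startswith("not ")
    term = cell[4:] if neg else cell
    return term.strip().lower(), neg


def transcribe_rule_table() -> list[FuzzyRule]:
    """The 14-rule tissue-differentiation table, one row per rule.

    Cell order: S, c_perfusion, c_adPerfusion, c_cartilage, c_bone, c_adbone
    then the consequents dc_perfusion, dc_cartilage, dc_bone; '—' means the
    variable does not participate.
    """
    rows = [
        # 1-3: angiogenesis
        ("Not destruction", "Low", "Not low", "—", "—", "—", "Increase", "—", "—"),
        ("Not destruction", "Medium", "High", "—", "—", "—", "Increase", "—", "—"),
        ("Not destruction", "High", "—", "—", "—", "—", "Increase", "—", "—"),
        # 4: intramembranous ossification
        ("Low", "High", "—", "Low", "—", "High", "—", "—", "Increase"),
        # 5-8: chondrogenesis
        ("High", "—", "—", "Low", "Not high", "—", "—", "Increase", "—"),
        ("Low", "—", "—", "Low", "Not high", "—", "—", "Increase", "—"),
        ("Medium", "—", "—", "Not low", "—", "—", "—", "Increase", "—"),
        ("Low", "—", "—", "Not low", "—", "—", "—", "Increase", "—"),
        # 9-12: endochondral ossification
        ("Low", "Not low", "—", "Not low", "—", "Not low", "—", "Decrease", "Increase"),
        ("Medium", "Not low", "—", "Not low", "—", "Not low", "—", "Decrease", "Increase"),
        ("Low", "Not low", "—", "Not low", "—", "High", "—", "Decrease", "Increase"),
        ("Low", "Not low", "—", "Low", "High", "High", "—", "Decrease", "Increase"),
        # 13: overload destruction; 14: default
        ("Destruction", "—", "—", "—", "—", "—", "Decrease", "Decrease", "Decrease"),
        ("Not destruction", "—", "—", "—", "—", "—", "Stay", "Stay", "Stay"),
    ]
    rules = []
    for row in rows:
        ante = {}
        for var, cell in zip(INPUT_ORDER, row[:6]):
            parsed = _parse_term(cell)
            if parsed is not None:
                ante[var] = parsed
        cons = {}
        for var, cell in zip(OUTPUT_ORDER, row[6:]):
            parsed = _parse_term(cell)
            if parsed is not None:
                cons[var] = parsed[0]
        rules.append(FuzzyRule(ante, cons))
    return rules


# ---------------------------------------------------------------------------
# exact centroid of the clipped-max aggregate
# ---------------------------------------------------------------------------

def _aggregate_area_moment(terms: list[Trapezoid], alphas: list[float]):
    """Area and first moment of max_t min(alpha_t, trap_t) by exact
    piecewise-linear integration."""
    active = [(t, a) for t, a in zip(terms, alphas) if a > 1e-15]
    if not active:
        return 0.0, 0.0
    xs: set[float] = set()
    for t, a in active:
        xs.update((t.a, t.b, t.c, t.d))
        if t.b > t.a:
            xs.add(t.a + a * (t.b - t.a))
        if t.d > t.c:
            xs.add(t.d - a * (t.d - t.c))
    grid = sorted(xs)

    def val(t: Trapezoid, a: float, x: float) -> float:
        return min(a, t.scalar(x))

    area = moment = 0.0
    for x0, x1 in zip(grid[:-1], grid[1:]):
        if x1 - x0 <= 0:
            continue
        v0 = [val(t, a, x0) for t, a in active]
        v1 = [val(t, a, x1) for t, a in active]
        cuts = {x0, x1}
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                d0, d1 = v0[i] - v0[j], v1[i] - v1[j]
                if d0 * d1 < 0:   # segments cross inside the interval
                    cuts.add(x0 + (x1 - x0) * d0 / (d0 - d1))
        sub = sorted(cuts)
        for y0, y1 in zip(sub[:-1], sub[1:]):
            h = y1 - y0
            if h <= 0:
                continue
            w0 = y0 - x0
            m0 = max(min(a, v0[k] + (v1[k] - v0[k]) * w0 / (x1 - x0))
                     for k, (t, a) in enumerate(active))
            w1 = y1 - x0
            m1 = max(min(a, v0[k] + (v1[k] - v0[k]) * w1 / (x1 - x0))
                     for k, (t, a) in enumerate(active))
            area += h * (m0 + m1) / 2.0
            moment += h * ((2 * y0 + y1) * m0 + (y0 + 2 * y1) * m1) / 6.0
    return area, moment


@dataclass(frozen=True)
class FuzzyController:
    """Six-input / three-output Mamdani system with the 14-rule base."""

    inputs: dict[str, FuzzyVariable]
    outputs: dict[str, FuzzyVariable]
    rules: list[FuzzyRule] = field(default_factory=transcribe_rule_table)

    def __post_init__(self):
        missing = set(INPUT_ORDER) - set(self.inputs)
        if missing:
            raise ConfigurationError(f"missing input variables: {missing}")
        missing = set(OUTPUT_ORDER) - set(self.outputs)
        if missing:
            raise ConfigurationError(f"missing output variables: {missing}")
        for r in self.rules:
            for var, (term, _) in r.antecedents.items():
                if term not in self.inputs[var].terms:
                    raise ConfigurationError(f"rule references unknown {var}.{term}")
            for var, term in r.consequents.items():
                if term not in self.outputs[var].terms:
                    raise ConfigurationError(f"rule references unknown {var}.{term}")

    # -- scalar interface ----------------------------------------------------
    def infer(self, inputs: dict[str, float]) -> dict[str, float]:
        """Crisp outputs for one element's crisp inputs."""
        arr = np.array([[inputs[k] for k in INPUT_ORDER]])
        out = self.infer_batch(arr)
        return {k: float(out[0, i]) for i, k in enumerate(OUTPUT_ORDER)}

    # -- vectorised interface ------------------------------------------------
    def infer_batch(self, inputs: np.ndarray) -> np.ndarray:
        """(n, 6) crisp inputs in INPUT_ORDER -> (n, 3) outputs in OUTPUT_ORDER."""
        inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
        n = inputs.shape[0]
        fuzz = {}
        for i, name in enumerate(INPUT_ORDER):
            fuzz[name] = self.inputs[name].fuzzify(inputs[:, i])
        acts = np.stack([rule_activation(r, fuzz) * np.ones(n)
                         for r in self.rules])            # (n_rules, n)
        out = np.empty((n, len(OUTPUT_ORDER)))
        for oi, oname in enumerate(OUTPUT_ORDER):
            var = self.outputs[oname]
            term_names = list(var.terms)
            traps = [var.terms[t] for t in term_names]
            # per-term clip level: max activation over rules firing that term
            clip = np.zeros((len(term_names), n))
            for r, act in zip(self.rules, acts):
                term = r.consequents.get(oname)
                if term is not None:
                    ti = term_names.index(term)
                    clip[ti] = np.maximum(clip[ti], act)
            for e in range(n):
                area, moment = _aggregate_area_moment(traps, list(clip[:, e]))
                out[e, oi] = moment / area if area > 1e-14 else 0.0
        return out


# ---------------------------------------------------------------------------
# default membership functions
# ---------------------------------------------------------------------------

def concentration_terms(low_foot: float = 0.3) -> dict[str, Trapezoid]:
    """Shared term set for perfusion and tissue concentrations on [0, 1].

    ``low_foot`` is where 'low' membership vanishes; it sets the cartilage
    level at which chondrogenesis (rules 5-6, antecedent 'cartilage low')
    saturates, hence the stiffness a purely chondral callus can reach.
    'high' overlaps down to 0.25 so the angiogenesis chain of rules 1-3
    self-accelerates once an element passes the 'low' ceiling."""
    if not 0.25 < low_foot <= 0.65:
        raise ConfigurationError("low_foot must lie in (0.25, 0.65]")
    return {
        "low": Trapezoid(0.0, 0.0, 0.1, low_foot),
        "medium": Trapezoid(0.1, low_foot, 0.55, 0.75),
        "high": Trapezoid(0.25, 0.65, 1.0, 1.0),
    }


def stimulus_terms(s_medium: float = 4.0, s_destr: float = 23.0,
                   s_max: float = 50.0,
                   destr_width: float | None = None) -> dict[str, Trapezoid]:
    """Mechanoregulatory stimulus bands with overlapping flanks.

    Low S favours bone formation, medium S endochondral activity, high S
    fibrous tissue / chondrogenesis only, and beyond ``s_destr`` tissue
    destruction.  ``s_medium`` is the medium/high boundary and ``s_destr``
    the centre of the destruction onset, whose flank spans ``destr_width``
    (default 20 % of the onset) -- a broad flank grades overload damage in
    proportion to local severity instead of switching at a sharp threshold.
    All breakpoints are element-level calibrated quantities: centroid-sampled
    stimulus values carry the stress concentrations of the fragment-corner
    elements, which sit well above the nominal-gap-strain scale of the
    classical shear/flow diagrams."""
    w = 0.2 * s_destr if destr_width is None else destr_width
    d_lo, d_hi = s_destr - w / 2, s_destr + w / 2
    return {
        "low": Trapezoid(0.0, 0.0, 0.8, 1.2),
        "medium": Trapezoid(0.8, 1.2, 0.9 * s_medium, 1.1 * s_medium),
        "high": Trapezoid(0.9 * s_medium, 1.1 * s_medium, d_lo, d_hi),
        "destruction": Trapezoid(d_lo, d_hi, s_max, s_max),
    }


def change_terms(delta: float) -> dict[str, Trapezoid]:
    """Daily-change terms on [-delta, delta], 'stay' centred at zero."""
    return {
        "decrease": Trapezoid(-delta, -delta, -0.6 * delta, -0.2 * delta),
        "stay": Trapezoid(-0.5 * delta, -0.1 * delta, 0.1 * delta, 0.5 * delta),
        "increase": Trapezoid(0.2 * delta, 0.6 * delta, delta, delta),
    }


def default_controller(delta: float = 0.09, s_medium: float = 4.0,
                       s_destr: float = 23.0, s_max: float = 50.0,
                       destr_width: float | None = 10.0,
                       conc_low_foot: float = 0.4) -> FuzzyController:
    """Controller with the documented default membership calibration.

    ``delta`` is the global per-day rate scale of all three outputs (the one
    free rate knob of the model); ``s_medium`` / ``s_destr`` the medium/high
    boundary and destruction onset of the stimulus bands.
    """
    # perfusion keeps its 'low' foot at the 30 % boundary-source level so a
    # perfused neighbour reads fully 'not low'; the tissue concentrations
    # use the (possibly raised) chondrogenesis ceiling
    perf = concentration_terms(0.3)
    conc = concentration_terms(conc_low_foot)
    inputs = {"S": FuzzyVariable("S", (0.0, s_max),
                                 stimulus_terms(s_medium, s_destr, s_max,
                                                destr_width))}
    for name in ("c_perfusion", "c_adPerfusion"):
        inputs[name] = FuzzyVariable(name, (0.0, 1.0), dict(perf))
    for name in ("c_cartilage", "c_bone", "c_adbone"):
        inputs[name] = FuzzyVariable(name, (0.0, 1.0), dict(conc))
    outputs = {name: FuzzyVariable(name, (-delta, delta), change_terms(delta))
               for name in OUTPUT_ORDER}
    return FuzzyController(inputs, outputs, transcribe_rule_table())
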