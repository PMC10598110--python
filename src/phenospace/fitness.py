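"""Fitness characteristics, measurable aggregate classes and calibration.

Three groups of operations live here:

* phenotype fitness characteristics under the non-selecting condition --
  the protein burden (total steady-state protein N + P) and the relative
  growth rates derived from it;
* aggregate phenotype classes -- the experimentally distinguishable
  grouping of the clock repertoire into constitutive (#6, #8),
  super-repressed (#3, #11) and oscillatory (#7) N-gene expression states,
  with fractions renormalized over the classified phenotypes;
* calibration of the two free mutation-kernel parameters (size scale
  ``lambda``, directional bias ``delta``) against mutant-class proportions
  measured at time zero, patterned on the LAC repressor tolerance data.

The time-zero mutant-class model treats the donor region's tolerance width
``w`` along the mutated parameter as the escape barrier: a single mutation
converts the phenotype beyond the entropy-increasing boundary with
probability ``exp(-w / (lambda*delta))`` and beyond the entropy-decreasing
boundary with probability ``exp(-w * delta / lambda)``; the remainder is
tolerant (wild type).  This survival form is exactly invertible, which the
two-parameter fit exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import math

import numpy as np
from scipy.optimize import brentq, root

from .design_space import DesignSpace
from .mutation import MutationModel, TransitionMatrix
from .population import FitnessProfile, PopulationState, equilibrium

__all__ = [
    "PRINTED_MU",
    "CLOCK_CLASSES",
    "AggregateClasses",
    "BurdenTable",
    "ToleranceData",
    "MutantClassDistribution",
    "FitFailureError",
    "protein_burden",
    "fitness_profile",
    "aggregate_distribution",
    "time_zero_distribution",
    "fit_bias_parameters",
    "selection_for_fraction",
]

#: Published relative growth rates (non-selecting condition, protein-burden
#: spectrum, relative to phenotype #7).  These are inputs of the framework,
#: not derived quantities.
PRINTED_MU: dict[int, float] = {
    1: 0.999997573,
    3: 1.000000322,
    5: 0.999997527,
    6: 0.999997357,
    7: 1.0,
    8: 0.999999693,
    11: 1.000000412,
    15: 1.000000115,
    16: 0.99999976,
}


class FitFailureError(RuntimeError):
    """The bias-parameter fit found no admissible root."""


@dataclass(frozen=True)
class AggregateClasses:
    """Disjoint measurable classes over the phenotype repertoire."""

    mapping: dict[str, frozenset[int]]

    def __post_init__(self):
        seen: set[int] = set()
        for name, members in self.mapping.items():
            if seen & members:
                raise ValueError(f"class {name} overlaps another class")
            seen |= members
        object.__setattr__(
            self, "mapping", {k: frozenset(v) for k, v in self.mapping.items()}
        )

    @property
    def classified(self) -> frozenset[int]:
        out: frozenset[int] = frozenset()
        for members in self.mapping.values():
            out |= members
        return out

    def class_of(self, number: int) -> str | None:
        for name, members in self.mapping.items():
            if number in members:
                return name
        return None


CLOCK_CLASSES = AggregateClasses(
    mapping={
        "oscillatory": frozenset({7}),
        "constitutive": frozenset({6, 8}),
        "super_repressed": frozenset({3, 11}),
    }
)


@dataclass(frozen=True)
class BurdenTable:
    burden: dict[int, float]

    def __post_init__(self):
        if any(v <= 0 for v in self.burden.values()):
            raise ValueError("protein burden must be positive")

    @property
    def log10(self) -> dict[int, float]:
        return {i: math.log10(v) for i, v in self.burden.items()}


@dataclass(frozen=True)
class ToleranceData:
    """Mutant-class proportions at time zero (e.g. LAC repressor scanning)."""

    tolerant: float
    entropy_increasing: float
    entropy_decreasing: float
    source: str = ""

    def __post_init__(self):
        vals = (self.tolerant, self.entropy_increasing, self.entropy_decreasing)
        if any(v < 0 for v in vals):
            raise ValueError("proportions must be nonnegative")
        if abs(sum(vals) - 1.0) > 1e-6:
            raise ValueError(f"proportions sum to {sum(vals):g}, not 1")


#: LAC repressor tolerance proportions used to fix lambda and delta.
LAC_TOLERANCE = ToleranceData(0.67, 0.31, 0.02, source="LAC repressor substitutions")


@dataclass(frozen=True)
class MutantClassDistribution:
    tolerant: float
    entropy_increasing: float
    entropy_decreasing: float
    up_class: str | None
    down_class: str | None
    barrier_width: float

    def by_class(self, wild_class: str = "oscillatory") -> dict[str, float]:
        out = {wild_class: self.tolerant}
        if self.up_class:
            out[self.up_class] = out.get(self.up_class, 0.0) + self.entropy_increasing
        if self.down_class:
            out[self.down_class] = out.get(self.down_class, 0.0) + self.entropy_decreasing
        return out


def protein_burden(space: DesignSpace) -> BurdenTable:
    """Total protein (N + P) at each phenotype centroid's steady state."""
    return BurdenTable(
        burden={
            num: reg.steady_state["N"] + reg.steady_state["P"]
            for num, reg in space.regions.items()
        }
    )


def fitness_profile(
    mode: str,
    numbers=tuple(sorted(PRINTED_MU)),
    space: DesignSpace | None = None,
    burden_cost: float = 1e-5,
    selected: int = 7,
    mu_star: float = 1.0,
) -> FitnessProfile:
    """Relative growth rates under the non-selecting condition.

    ``neutral``: all equal.  ``burden_printed``: the published nine values.
    ``burden_model``: ``mu_i = 1 - c (B_i - B_k)/B_k`` from the computed
    burden table, with ``c`` scaled so the largest cost stays below ~1e-5
    (growth-rate differences at the edge of experimental resolution).
    """
    if mode == "neutral":
        mu = {i: 1.0 for i in numbers}
    elif mode == "burden_printed":
        mu = dict(PRINTED_MU)
    elif mode == "burden_model":
        if space is None:
            raise ValueError("burden_model mode needs a design space")
        table = protein_burden(space).burden
        ref = table[selected]
        rel = {i: (b - ref) / ref for i, b in table.items()}
        top = max(abs(v) for v in rel.values())
        c = burden_cost / top if top else 0.0
        mu = {i: 1.0 - c * v for i, v in rel.items()}
    else:
        raise ValueError(f"unknown fitness mode {mode!r}")
    return FitnessProfile(mu=mu, selected=selected, mu_star=mu_star)


def aggregate_distribution(
    state: PopulationState, classes: AggregateClasses = CLOCK_CLASSES
) -> dict[str, float]:
    """Class fractions of a population state, renormalized over classified phenotypes."""
    sums = {
        name: sum(state.R.get(i, 0.0) for i in members)
        for name, members in classes.mapping.items()
    }
    total = sum(sums.values())
    if total <= 0:
        raise ValueError("no classified phenotype carries any frequency")
    return {name: v / total for name, v in sums.items()}


def _section_through_centroid(
    space: DesignSpace, number: int, parameter: str
) -> tuple[float, float, float]:
    """(low, high, centroid coordinate) of the region along ``parameter``
    on the axis line through its centroid."""
    free = space.slice.free_parameters
    if parameter not in free:
        raise ValueError(f"{parameter!r} is not a mutable free parameter")
    region = space.regions[number]
    qi = free.index(parameter)
    oi = 1 - qi
    t0 = region.centroid[free[oi]]
    lo, hi = space.slice.bounds(parameter)
    for coeffs, b in region.constraints:
        cq, co = coeffs[qi], coeffs[oi]
        rem = b - co * t0
        if cq > 1e-12:
            hi = min(hi, rem / cq)
        elif cq < -1e-12:
            lo = max(lo, rem / cq)
        elif co * t0 > b + 1e-9:
            raise RuntimeError(f"centroid of region {number} violates its own constraints")
    return lo, hi, region.centroid[parameter]


def time_zero_distribution(
    space: DesignSpace,
    model: MutationModel,
    donor: int,
    parameter: str,
    classes: AggregateClasses = CLOCK_CLASSES,
) -> MutantClassDistribution:
    """Mutant-class distribution for single mutations of one parameter.

    The donor region's tolerance width along the parameter is the escape
    barrier; landing beyond the entropy-increasing (resp. -decreasing)
    boundary converts to the class of the neighboring regions there.  A
    boundary that coincides with the Pi-box edge cannot be escaped.
    """
    lo, hi, x0 = _section_through_centroid(space, donor, parameter)
    width = hi - lo
    box_lo, box_hi = space.slice.bounds(parameter)
    free = space.slice.free_parameters
    other = next(p for p in free if p != parameter)
    t0 = space.regions[donor].centroid[other]
    sign = model.entropy_direction.get(parameter, +1)

    def neighbor(beyond: float) -> int | None:
        if beyond < box_lo or beyond > box_hi:
            return None
        return space.classify_point({parameter: beyond, other: t0})

    eps = 1e-6
    up_n = neighbor(hi + eps)
    down_n = neighbor(lo - eps)
    p_up = math.exp(-width / model.scale_for(parameter, +sign)) if up_n else 0.0
    p_down = math.exp(-width / model.scale_for(parameter, -sign)) if down_n else 0.0
    if p_up + p_down >= 1.0:
        raise RuntimeError("escape probabilities exceed 1; barrier too narrow for this kernel")
    return MutantClassDistribution(
        tolerant=1.0 - p_up - p_down,
        entropy_increasing=p_up,
        entropy_decreasing=p_down,
        up_class=classes.class_of(up_n) if up_n else None,
        down_class=classes.class_of(down_n) if down_n else None,
        barrier_width=width,
    )


def fit_bias_parameters(
    data: ToleranceData,
    space: DesignSpace,
    donor: int,
    parameter: str,
    lam_bounds: tuple[float, float] = (1e-3, 10.0),
    delta_bounds: tuple[float, float] = (1.0, 50.0),
) -> tuple[float, float]:
    """Fit (lambda, delta) so the time-zero class distribution matches ``data``.

    The survival form is closed-form invertible --
    ``lambda*delta = w / -ln(p_up)`` and ``lambda/delta = w / -ln(p_down)``
    -- and the result is polished by 2-D root finding on the forward model.
    """
    if not (0 < data.entropy_increasing < 1 and 0 < data.entropy_decreasing < 1):
        raise FitFailureError("crossing proportions must lie strictly in (0, 1)")
    lo, hi, _ = _section_through_centroid(space, donor, parameter)
    w = hi - lo
    s_up = w / -math.log(data.entropy_increasing)
    s_dn = w / -math.log(data.entropy_decreasing)
    lam = math.sqrt(s_up * s_dn)
    delta = math.sqrt(s_up / s_dn)

    def residual(x):
        lam_, delta_ = math.exp(x[0]), math.exp(x[1])
        mdl = MutationModel(lam=lam_, delta=max(delta_, 1.0), m=1e-7)
        dist = time_zero_distribution(space, mdl, donor, parameter)
        return [
            dist.entropy_increasing - data.entropy_increasing,
            dist.entropy_decreasing - data.entropy_decreasing,
        ]

    if delta >= 1.0:
        sol = root(residual, [math.log(lam), math.log(delta)], tol=1e-12)
        if sol.success and max(abs(r) for r in sol.fun) < 1e-8:
            lam, delta = math.exp(sol.x[0]), math.exp(sol.x[1])
    if not (lam_bounds[0] <= lam <= lam_bounds[1]) or not (
        delta_bounds[0] - 1e-9 <= delta <= delta_bounds[1]
    ):
        raise FitFailureError(
            f"fitted (lambda, delta) = ({lam:.4g}, {delta:.4g}) outside admissible bounds"
        )
    return lam, max(delta, 1.0)


def selection_for_fraction(
    target_fraction: float,
    tm: TransitionMatrix,
    base_fitness: FitnessProfile,
    m: float,
    classes: AggregateClasses = CLOCK_CLASSES,
    target_class: str = "oscillatory",
    mu_star_bounds: tuple[float, float] = (1.0, 2.0),
    tol: float = 1e-4,
) -> float:
    """Selecting-condition growth advantage mu_k* that yields a target
    equilibrium fraction of the selected class (bisection; the fraction is
    monotone increasing in mu_k*)."""
    if not 0 < target_fraction < 1:
        raise ValueError("target fraction must lie in (0, 1)")

    def fraction(mu_star: float) -> float:
        prof = FitnessProfile(
            mu=base_fitness.mu, selected=base_fitness.selected, mu_star=mu_star
        )
        eq = equilibrium(tm, prof, m)
        return aggregate_distribution(eq, classes)[target_class]

    lo, hi = mu_star_bounds
    f_lo, f_hi = fraction(lo), fraction(hi)
    if not f_lo < f_hi:
        raise RuntimeError("class fraction is not increasing in mu_k* on the bracket")
    if target_fraction <= f_lo:
        return lo
    if target_fraction > f_hi:
        raise ValueError(
            f"target fraction {target_fraction:g} unreachable below mu_k* = {hi:g}"
        )
    mu = brentq(lambda x: fraction(x) - target_fraction, lo, hi, xtol=1e-12)
    if abs(fraction(mu) - target_fraction) > tol:
        raise RuntimeError("bisection failed to reach the target fraction")
    return float(mu)
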