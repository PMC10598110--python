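"""Phenotype design space: enumerate feasible dominance signatures as polytopes.

Every candidate signature defines an S-system whose steady state is affine
in the free log-parameters.  Substituting that steady state into each
dominance condition (dominant term >= every sibling term of the same sign)
yields linear inequalities in the free log-parameters.  Within a bounding
Pi-box the feasible signatures tile the slice with convex polygons: the
qualitatively distinct phenotypes of the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog
from shapely.geometry import Polygon, box as shapely_box

from .model import (
    AffineForm,
    DegeneratePhenotypeError,
    EigenSpectrum,
    GMASystem,
    Signature,
    SSystem,
    SteadyState,
    _log_param_forms,
    eigenvalues_at,
    extract_ssystem,
    solve_steady_state,
    solve_steady_state_affine,
    term_log_affine,
)

__all__ = [
    "SliceSpec",
    "PhenotypeRegion",
    "DesignSpace",
    "BoundaryExpression",
    "NoSharedBoundaryError",
    "TilingError",
    "default_clock_slice",
    "validate_region",
    "build_design_space",
    "boundary_expression",
]

AREA_TOL = 1e-9
GEOM_TOL = 1e-9


class NoSharedBoundaryError(ValueError):
    """The two regions do not share an edge."""


class TilingError(RuntimeError):
    """The regions fail to tile the Pi-box within tolerance."""


@dataclass(frozen=True)
class SliceSpec:
    """A 2-D slice of log-parameter space bounded by a Pi-box.

    ``center`` holds log10 values of the free parameters at the box center;
    each free parameter spans ``center +/- width/2`` decades.
    """

    free_parameters: tuple[str, str]
    fixed_parameters: dict[str, float]
    center: dict[str, float]
    width: float = 6.0

    def __post_init__(self):
        if not self.width > 0:
            raise ValueError("Pi-box width must be positive")
        object.__setattr__(self, "free_parameters", tuple(self.free_parameters))

    def bounds(self, name: str) -> tuple[float, float]:
        c = self.center[name]
        return (c - self.width / 2.0, c + self.width / 2.0)

    @property
    def box(self) -> Polygon:
        (x0, x1), (y0, y1) = (self.bounds(p) for p in self.free_parameters)
        return shapely_box(x0, y0, x1, y1)

    def parameter_values(self, point: dict[str, float]) -> dict[str, float]:
        """Full parameter map with free parameters set from log10 coordinates."""
        vals = dict(self.fixed_parameters)
        vals.update({p: 10.0 ** point[p] for p in self.free_parameters})
        return vals


def default_clock_slice(system: GMASystem, width: float = 6.0) -> SliceSpec:
    """The published slice: free (K_P, K_N), box centered on the #7 centroid."""
    free = ("K_P", "K_N")
    fixed = {k: v for k, v in system.parameters.items() if k not in free}
    center = {p: math.log10(system.parameters[p]) for p in free}
    return SliceSpec(free_parameters=free, fixed_parameters=fixed, center=center, width=width)


@dataclass(frozen=True)
class PhenotypeRegion:
    """A feasible phenotype: signature, polygon, tolerances and local analysis."""

    signature: Signature
    #: inequalities a . x <= b over x = log10 free parameters, as
    #: ((coeff per free parameter ...), b)
    constraints: tuple[tuple[tuple[float, ...], float], ...]
    polygon: Polygon
    tolerances: dict[str, tuple[float, float]]
    centroid: dict[str, float]
    barycenter: dict[str, float]
    ssystem: SSystem
    steady_state_forms: dict[str, AffineForm]
    steady_state: SteadyState
    eigen: EigenSpectrum
    zero_area: bool = False

    @property
    def number(self) -> int:
        return self.signature.label

    @property
    def area(self) -> float:
        return self.polygon.area

    @property
    def vertices(self) -> tuple[tuple[float, float], ...]:
        xy = np.asarray(self.polygon.exterior.coords)[:-1]
        return tuple(map(tuple, xy))


@dataclass(frozen=True)
class DesignSpace:
    slice: SliceSpec
    regions: dict[int, PhenotypeRegion] = field(default_factory=dict)

    @property
    def numbers(self) -> tuple[int, ...]:
        return tuple(sorted(self.regions))

    @property
    def total_area(self) -> float:
        return sum(r.area for r in self.regions.values())

    def region(self, number: int) -> PhenotypeRegion:
        return self.regions[number]

    def classify_point(self, point: dict[str, float]) -> int:
        """Phenotype number of a point (ties to the lowest number)."""
        x = [point[p] for p in self.slice.free_parameters]
        for num in self.numbers:
            ok = all(
                sum(a * xi for a, xi in zip(coeffs, x)) <= b + GEOM_TOL
                for coeffs, b in self.regions[num].constraints
            )
            if ok:
                return num
        raise ValueError(f"point {point} not inside any region")


def _dominance_constraints(
    system: GMASystem,
    signature: Signature,
    ssys: SSystem,
    slice_spec: SliceSpec,
) -> list[AffineForm]:
    """Affine forms f(x) >= 0 expressing dominance at the region's steady state."""
    free = slice_spec.free_parameters
    all_params = {**slice_spec.fixed_parameters, **{p: 1.0 for p in free}}
    var_logs = solve_steady_state_affine(ssys, all_params, free=free)
    param_logs = _log_param_forms(all_params, free)
    # auxiliary variables evaluated with their dominant solution
    for aux, term in ssys.auxiliary_solutions.items():
        var_logs[aux] = term_log_affine(term, var_logs, param_logs)
    out: list[AffineForm] = []
    for (pi, ni), eq in zip(signature.pairs, system.equations):
        for terms, idx in ((eq.positive_terms, pi), (eq.negative_terms, ni)):
            dom = term_log_affine(terms[idx - 1], var_logs, param_logs)
            for k, other in enumerate(terms, start=1):
                if k == idx:
                    continue
                out.append(dom - term_log_affine(other, var_logs, param_logs))
    return out


def _halfplane_polygon(
    forms: list[AffineForm], slice_spec: SliceSpec
) -> tuple[Polygon, list[tuple[tuple[float, ...], float]]]:
    """Intersect f(x) >= 0 half-planes with the Pi-box."""
    free = slice_spec.free_parameters
    poly = slice_spec.box
    constraints = []
    big = 10.0 * (abs(slice_spec.width) + max(abs(c) for c in slice_spec.center.values()) + 10)
    for f in forms:
        a = np.array([f.coeffs.get(p, 0.0) for p in free])
        norm = np.linalg.norm(a)
        if norm < GEOM_TOL:
            if f.const < -GEOM_TOL:
                return Polygon(), constraints  # constant condition violated
            continue
        # f >= 0  <=>  (-a/|a|) . x <= const/|a|
        constraints.append((tuple(-a / norm), f.const / norm))
        # half-plane as a large polygon: points with a.x + const >= 0
        n = a / norm
        c0 = f.const / norm
        # line: n.x = -c0 ; keep side where n.x >= -c0
        p0 = -c0 * n
        t = np.array([-n[1], n[0]])
        pts = [
            p0 + big * t,
            p0 - big * t,
            p0 - big * t + big * n,
            p0 + big * t + big * n,
        ]
        poly = poly.intersection(Polygon(pts))
        if poly.is_empty:
            return Polygon(), constraints
    return poly, constraints


def _lp_feasible(constraints, slice_spec: SliceSpec) -> bool:
    free = slice_spec.free_parameters
    A = [list(coeffs) for coeffs, _ in constraints]
    b = [rhs for _, rhs in constraints]
    bounds = [slice_spec.bounds(p) for p in free]
    if not A:
        return True
    res = linprog(c=[0.0] * len(free), A_ub=A, b_ub=b, bounds=bounds, method="highs")
    return bool(res.success)


def validate_region(
    system: GMASystem,
    signature: Signature,
    slice_spec: SliceSpec,
    centroid_mode: str = "tolerance_midpoint",
) -> PhenotypeRegion | None:
    """Build the phenotype region for ``signature``, or None if infeasible.

    Feasibility is decided by half-plane intersection inside the Pi-box
    (linear programming is used to distinguish genuinely empty regions from
    lower-dimensional ones, which are retained with area 0 and flagged).
    """
    signature.validate(system)
    try:
        ssys = extract_ssystem(system, signature)
        forms = _dominance_constraints(system, signature, ssys, slice_spec)
    except DegeneratePhenotypeError:
        return None
    poly, constraints = _halfplane_polygon(forms, slice_spec)
    zero_area = False
    if poly.is_empty or poly.area < AREA_TOL:
        if not _lp_feasible(constraints, slice_spec):
            return None
        zero_area = True

    free = slice_spec.free_parameters
    if zero_area:
        # represent by the LP analytic center proxy: midpoint of box clipped bounds
        tol = {p: slice_spec.bounds(p) for p in free}
    else:
        minx, miny, maxx, maxy = poly.bounds
        tol = {free[0]: (minx, maxx), free[1]: (miny, maxy)}
    centroid = {p: 0.5 * (lo + hi) for p, (lo, hi) in tol.items()}
    if not zero_area:
        bc = poly.centroid
        barycenter = {free[0]: bc.x, free[1]: bc.y}
    else:
        barycenter = dict(centroid)
    ref = centroid if centroid_mode == "tolerance_midpoint" else barycenter
    params = slice_spec.parameter_values(ref)
    state = solve_steady_state(ssys, params)
    eigen = eigenvalues_at(ssys, params, state)
    var_forms = solve_steady_state_affine(
        ssys, {**slice_spec.fixed_parameters, **{p: 1.0 for p in free}}, free=free
    )
    return PhenotypeRegion(
        signature=signature,
        constraints=tuple(constraints),
        polygon=poly,
        tolerances=tol,
        centroid=centroid,
        barycenter=barycenter,
        ssystem=ssys,
        steady_state_forms=var_forms,
        steady_state=state,
        eigen=eigen,
        zero_area=zero_area,
    )


def build_design_space(
    system: GMASystem,
    slice_spec: SliceSpec,
    centroid_mode: str = "tolerance_midpoint",
    check_tiling: bool = True,
) -> DesignSpace:
    """Enumerate all candidate signatures and assemble the feasible tiling."""
    regions: dict[int, PhenotypeRegion] = {}
    for sig in system.candidate_signatures():
        region = validate_region(system, sig, slice_spec, centroid_mode=centroid_mode)
        if region is not None:
            regions[sig.label] = region
    space = DesignSpace(slice=slice_spec, regions=regions)
    if check_tiling:
        total = space.total_area
        expected = slice_spec.width**2
        if abs(total - expected) > 1e-3 * expected:
            raise TilingError(f"regions cover {total:g} of {expected:g} square decades")
        nums = space.numbers
        for i, a in enumerate(nums):
            pa = regions[a].polygon
            for b in nums[i + 1 :]:
                inter = pa.intersection(regions[b].polygon).area
                if inter > 1e-6 * expected:
                    raise TilingError(f"regions {a} and {b} overlap by {inter:g}")
    return space


@dataclass(frozen=True)
class BoundaryExpression:
    """Monomial boundary: prod(param ** exponent) = threshold on the shared edge."""

    exponents: dict[str, float]
    threshold: float
    lower_side: int  # phenotype number on the side where the monomial is smaller
    upper_side: int

    def __str__(self) -> str:
        mono = "*".join(
            f"{p}^{e:g}" if e != 1 else p for p, e in self.exponents.items() if e != 0
        )
        return f"{mono} = {self.threshold:.6g}"

    def evaluate(self, values: dict[str, float]) -> float:
        out = 1.0
        for p, e in self.exponents.items():
            out *= values[p] ** e
        return out


def boundary_expression(space: DesignSpace, a: int, b: int) -> BoundaryExpression:
    """The single dominance condition defining the edge shared by regions a and b."""
    ra, rb = space.regions[a], space.regions[b]
    # a buffered intersection is robust to floating-point slivers between
    # adjacent polygons; its area ~ 2*eps*edge_length for a shared edge
    eps = 1e-6
    inter = ra.polygon.buffer(eps).intersection(rb.polygon.buffer(eps))
    edge_length = inter.area / (4.0 * eps)
    if edge_length < 1e-3:
        raise NoSharedBoundaryError(f"regions {a} and {b} share no boundary edge")
    mid = inter.centroid
    free = space.slice.free_parameters
    x = np.array([mid.x, mid.y])
    best = None
    for coeffs, rhs in ra.constraints:
        resid = abs(np.dot(coeffs, x) - rhs)
        if best is None or resid < best[0]:
            best = (resid, np.asarray(coeffs), rhs)
    resid, coeffs, rhs = best
    if resid > 1e-6:
        raise NoSharedBoundaryError(
            f"no single constraint of region {a} supports the shared edge (residual {resid:g})"
        )
    # constraint is coeffs . x <= rhs with x = log10 params; rescale to unit
    # leading exponent for a readable monomial
    nz = [c for c in coeffs if abs(c) > GEOM_TOL]
    scale = 1.0 / min(abs(c) for c in nz)
    if coeffs[np.argmax(np.abs(coeffs))] < 0:
        scale = -scale
    coeffs = coeffs * scale
    rhs = rhs * scale
    exponents = {p: float(c) for p, c in zip(free, coeffs)}
    monomial_at = lambda region: sum(
        exponents[p] * region.centroid[p] for p in free
    )
    lo, hi = (a, b) if monomial_at(ra) < monomial_at(rb) else (b, a)
    return BoundaryExpression(
        exponents=exponents, threshold=10.0**rhs, lower_side=lo, upper_side=hi
    )
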