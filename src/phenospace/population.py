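"""Mutation–selection dynamics of phenotype frequencies.

The population is an exponentially growing collection of asexual haploid
cells, one phenotype per cell.  With relative growth rates
``mu_i = gamma_i / gamma_k`` (reference phenotype ``k``) and time measured
in generations of the reference (``tau = gamma_k t``), the relative
frequencies ``R_i`` obey a replicator–mutator system:

    dR_i/dtau = sum_{j!=i} m k_ji mu_j R_j  -  m mu_i R_i sum_{j!=i} k_ij
                + (mu_i - mubar) R_i,          mubar = sum_j mu_j R_j

where under a selecting condition the selected phenotype's ``mu_k`` is
replaced by ``mu_k*`` (selection coefficient ``mu_k* - 1``).  The sum of
all rates vanishes identically, so ``sum R_i = 1`` is conserved.

The equilibrium of this system is an eigenproblem: column sums of
``A = m k^T diag(g) + diag(g (1 - m c))`` (with ``g`` the effective growth
rates and ``c_i = sum_{j!=i} k_ij``) equal ``g``, so the stationary
distribution is the Perron eigenvector of ``A`` and its eigenvalue is the
equilibrium mean fitness.  This route resolves frequencies spanning many
orders of magnitude that defeat naive root finding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .mutation import TransitionMatrix

__all__ = [
    "FitnessProfile",
    "PopulationState",
    "AbsolutePopulation",
    "RankChange",
    "frequency_rate",
    "equilibrium",
    "integrate_frequencies",
    "rate_contributions",
    "grow_absolute",
]

RESIDUAL_TOL = 1e-14


@dataclass(frozen=True)
class FitnessProfile:
    """Relative growth rates with an optional selecting condition.

    ``mu`` are growth rates relative to the reference (selected) phenotype
    ``selected`` under the NON-selecting condition (``mu[selected] == 1``);
    ``mu_star`` is the reference phenotype's relative growth rate under the
    selecting condition, so the selection coefficient is ``mu_star - 1``.
    """

    mu: dict[int, float]
    selected: int = 7
    mu_star: float = 1.0

    def __post_init__(self):
        if any(v <= 0 for v in self.mu.values()):
            raise ValueError("growth rates must be positive")
        if self.selected in self.mu and abs(self.mu[self.selected] - 1.0) > 1e-12:
            raise ValueError("reference phenotype must have mu = 1")

    def effective(self, numbers: tuple[int, ...]) -> np.ndarray:
        g = np.array([self.mu[i] for i in numbers], dtype=float)
        if self.selected in numbers:
            g[numbers.index(self.selected)] = self.mu_star
        return g

    @property
    def selection_coefficient(self) -> float:
        return self.mu_star - 1.0

    @classmethod
    def neutral(cls, numbers, selected: int = 7, mu_star: float = 1.0):
        return cls(mu={i: 1.0 for i in numbers}, selected=selected, mu_star=mu_star)


@dataclass(frozen=True)
class PopulationState:
    R: dict[int, float]
    tau: float = 0.0

    def __post_init__(self):
        vals = np.array(list(self.R.values()))
        if np.any(vals < -1e-12):
            raise ValueError("negative frequencies")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {vals.sum():.12g}, not 1")

    def vector(self, numbers) -> np.ndarray:
        return np.array([self.R[i] for i in numbers], dtype=float)

    @classmethod
    def from_vector(cls, numbers, vec, tau: float = 0.0):
        vec = np.maximum(np.asarray(vec, dtype=float), 0.0)
        vec = vec / vec.sum()
        return cls(R=dict(zip(numbers, vec.tolist())), tau=tau)

    @classmethod
    def point_mass(cls, numbers, at: int):
        return cls(R={i: (1.0 if i == at else 0.0) for i in numbers})


@dataclass(frozen=True)
class AbsolutePopulation:
    N: dict[int, float]
    gamma: dict[int, float]
    tau: float

    @property
    def total(self) -> float:
        return float(sum(self.N.values()))

    def frequencies(self) -> PopulationState:
        t = self.total
        return PopulationState(R={i: v / t for i, v in self.N.items()}, tau=self.tau)


@dataclass(frozen=True)
class RankChange:
    tau: float
    pair: tuple[int, int]


def _rhs(R: np.ndarray, kof: np.ndarray, c: np.ndarray, g: np.ndarray, m: float) -> np.ndarray:
    influx = m * (kof.T @ (g * R))
    outflux = m * g * c * R
    return influx - outflux + g * R - R * float(g @ R)




def frequency_rate(
    state: PopulationState, tm: TransitionMatrix, fitness: FitnessProfile, m: float
) -> dict[int, float]:
    """dR/dtau at a state; the components sum to zero to machine precision."""
    nums = tm.numbers
    kof = tm.k_offdiag
    rate = _rhs(state.vector(nums), kof, kof.sum(axis=1), fitness.effective(nums), m)
    return dict(zip(nums, rate.tolist()))


def _growth_mutation_matrix(kof, c, g, m):
    return m * kof.T * g[None, :] + np.diag(g * (1.0 - m * c))


class _LinearPropagator:
    """Evaluate ``expm(A t) v`` for many t via one eigendecomposition.

    The frequency dynamics are projectively linear: if ``dN/dt = A N`` with
    the growth-mutation matrix ``A`` (whose column sums are the growth
    rates), then ``R = N / sum(N)`` obeys the replicator-mutator equations
    exactly.  The spectrum of ``A`` is shifted by its largest real part so
    that no mode overflows even over ~1e10 generations.
    """

    def __init__(self, A: np.ndarray):
        w, X = np.linalg.eig(A)
        cond = np.linalg.cond(X)
        if not np.isfinite(cond) or cond > 1e10:
            raise RuntimeError("growth-mutation matrix is too defective to diagonalize")
        self.shift = w.real.max()
        self.w = w - self.shift
        self.X = X
        self.Xinv = np.linalg.inv(X)

    def propagate(self, v: np.ndarray, ts: np.ndarray) -> np.ndarray:
        """Columns are expm(A t) v, rescaled by exp(shift * t)."""
        coeff = self.Xinv @ v.astype(complex)
        modes = np.exp(np.outer(self.w, ts)) * coeff[:, None]
        out = (self.X @ modes).real
        return np.maximum(out, 0.0)


def _perron(A: np.ndarray) -> np.ndarray:
    w, X = np.linalg.eig(A)
    R = np.abs(X[:, np.argmax(w.real)].real)
    R /= R.sum()
    B = A + (np.abs(w).max() + 1.0) * np.eye(A.shape[0])
    for _ in range(500):
        R = B @ R
        R /= R.sum()
    return R


def _newton_polish(R, kof, c, g, m, iters: int = 8):
    n = len(R)
    for _ in range(iters):
        F = _rhs(R, kof, c, g, m)
        F[-1] = R.sum() - 1.0
        gbar = float(g @ R)
        J = m * kof.T * g[None, :] + np.diag(g - m * g * c - gbar) - np.outer(R, g)
        J[-1, :] = 1.0
        try:
            step = np.linalg.solve(J, F)
        except np.linalg.LinAlgError:
            break
        Rn = R - step
        if np.any(Rn <= 0):
            break
        R = Rn
        if np.abs(F).max() < 1e-18:
            break
    return R


def equilibrium(
    tm: TransitionMatrix,
    fitness: FitnessProfile,
    m: float,
    mode: str = "numeric",
) -> PopulationState:
    """Stationary phenotype-frequency distribution.

    ``analytic`` is valid only in the no-size-scale, no-bias, all-neutral
    idealization, where the distribution equals the normalized phenotype
    volumes (read off the volume-limit kernel rows).  ``numeric`` solves
    the general case via the Perron eigenvector of the growth–mutation
    matrix, refined by Newton iteration.
    """
    nums = tm.numbers
    kof = tm.k_offdiag
    c = kof.sum(axis=1)
    g = fitness.effective(nums)
    if mode == "analytic":
        if not (tm.model.volume_limit and np.ptp(g) == 0.0):
            raise ValueError("analytic mode requires the neutral volume-limit idealization")
        return PopulationState.from_vector(nums, tm.k[0])
    if mode != "numeric":
        raise ValueError(f"unknown mode {mode!r}")
    if np.ptp(g) == 0.0:
        # strictly neutral: linear master equation, independent of m
        Q = kof.T - np.diag(c)
        A = np.vstack([Q, np.ones(len(nums))])
        b = np.zeros(len(nums) + 1)
        b[-1] = 1.0
        R, *_ = np.linalg.lstsq(A, b, rcond=None)
        R = np.maximum(R, 0.0)
        R /= R.sum()
    else:
        R = _perron(_growth_mutation_matrix(kof, c, g, m))
        R = _newton_polish(R, kof, c, g, m)
    resid = np.abs(_rhs(R, kof, c, g, m)).max()
    scale = max(m, np.ptp(g)) if np.ptp(g) else m
    if resid > max(RESIDUAL_TOL, 1e-10 * scale):
        raise RuntimeError(f"equilibrium residual {resid:g} did not converge")
    return PopulationState.from_vector(nums, R)


def integrate_frequencies(
    initial: PopulationState,
    tm: TransitionMatrix,
    fitness: FitnessProfile,
    m: float,
    horizon: float,
    points_per_decade: int = 400,
    t_start: float = 1.0,
) -> tuple[pd.DataFrame, list[RankChange]]:
    """Integrate R(tau) with log-spaced dense output and rank-change detection.

    Rank changes (crossings of any pair of frequencies) are located on the
    log grid and refined by bisection to 3 significant figures.
    """
    nums = tm.numbers
    kof = tm.k_offdiag
    c = kof.sum(axis=1)
    g = fitness.effective(nums)
    n_dec = max(1, int(np.ceil(np.log10(horizon / t_start))))
    ts = np.concatenate([[0.0], np.geomspace(t_start, horizon, points_per_decade * n_dec)])
    prop = _LinearPropagator(_growth_mutation_matrix(kof, c, g, m))
    R0 = initial.vector(nums)
    y = prop.propagate(R0, ts)
    y /= y.sum(axis=0, keepdims=True)
    if not np.all(np.isfinite(y)):
        raise RuntimeError("frequency propagation produced non-finite values")
    frame = pd.DataFrame(y.T, columns=list(nums))
    frame.insert(0, "tau", ts)

    # crossings are bracketed on the log grid and refined by bisection on
    # the exact propagator, resolving the crossing time to 3 significant figures
    def diff_at(t: float, a: int, b: int) -> float:
        v = prop.propagate(R0, np.array([t]))[:, 0]
        v = v / v.sum()
        return float(v[a] - v[b])

    events: list[RankChange] = []
    for a in range(len(nums)):
        for b in range(a + 1, len(nums)):
            diff = y[a] - y[b]
            sign = np.sign(diff)
            for idx in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
                lo, hi = max(ts[idx], 1e-12), ts[idx + 1]
                flo = diff[idx]
                while hi / lo > 1.001:
                    mid = math.sqrt(lo * hi)
                    if flo * diff_at(mid, a, b) <= 0:
                        hi = mid
                    else:
                        lo, flo = mid, diff_at(mid, a, b)
                events.append(
                    RankChange(tau=float(math.sqrt(lo * hi)), pair=(nums[a], nums[b]))
                )
    events.sort(key=lambda e: e.tau)
    return frame, events


def rate_contributions(
    state: PopulationState, tm: TransitionMatrix, fitness: FitnessProfile, m: float
) -> tuple[float, float, float]:
    """Mutation, mutation-x-selection and selection contributions for the
    selected phenotype; their sum equals its net frequency rate exactly."""
    nums = tm.numbers
    kof = tm.k_offdiag
    g0 = np.array([fitness.mu[i] for i in nums], dtype=float)  # non-selecting
    R = state.vector(nums)
    ki = nums.index(fitness.selected)
    s = fitness.selection_coefficient
    influx = m * float(kof[:, ki] @ (g0 * R))
    outflux = m * g0[ki] * R[ki] * float(kof[ki].sum())
    mutation = influx - outflux + (g0[ki] - float(g0 @ R)) * R[ki]
    mut_x_sel = -s * m * float(kof[ki].sum()) * R[ki]
    selection = s * (1.0 - R[ki]) * R[ki]
    return mutation, mut_x_sel, selection


def grow_absolute(
    founder: int,
    tm: TransitionMatrix,
    fitness: FitnessProfile,
    m: float,
    target_total: float,
) -> AbsolutePopulation:
    """Deterministic expected phenotype counts during exponential growth.

    Integrates the absolute-number equations from a single founder cell
    until the total reaches ``target_total``.  Time is in generations of
    the reference phenotype; mutation terms conserve the total, so only
    net growth changes it.
    """
    if target_total < 1:
        raise ValueError("target_total must be >= 1 cell")
    nums = tm.numbers
    kof = tm.k_offdiag
    c = kof.sum(axis=1)
    g = fitness.effective(nums)

    prop = _LinearPropagator(_growth_mutation_matrix(kof, c, g, m))
    N0 = np.zeros(len(nums))
    N0[nums.index(founder)] = 1.0

    def log_total(t: float) -> float:
        # propagator rescales by exp(shift * t); restore it in log space
        v = prop.propagate(N0, np.array([t]))[:, 0]
        return math.log(v.sum()) + prop.shift * t

    target_log = math.log(target_total)
    hi = 2.0 * target_log / g.min() + 10.0
    if log_total(hi) < target_log:
        raise RuntimeError("growth horizon too short to reach the target population")
    tau = brentq(lambda t: log_total(t) - target_log, 0.0, hi, xtol=1e-10)
    N = prop.propagate(N0, np.array([tau]))[:, 0]
    N *= target_total / N.sum()
    return AbsolutePopulation(
        N=dict(zip(nums, N.tolist())), gamma=dict(zip(nums, g.tolist())), tau=tau
    )
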