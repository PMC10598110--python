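"""Phenotype-specific mutation rate constants.

Four geometric factors determine the probability that a single-parameter
mutation converts a donor phenotype i into a recipient phenotype j:

* reachability -- an axis-parallel line (varying only the mutated
  parameter) through a point of the donor region must intersect the
  recipient region inside the Pi-box;
* distance -- the separation ``s`` of the phenotype centroids along the
  mutated parameter, in decades;
* size scale -- mutation magnitudes fall off exponentially with scale
  ``lambda`` (decades);
* directional bias -- changes toward weaker binding (larger dissociation
  constant) increase configurational entropy and are more probable: the
  effective scale is ``lambda*delta`` uphill in entropy and
  ``lambda/delta`` downhill.

The raw kernel sums independent parameter paths,
``K_ij = sum_q exp(-s_q / scale_q)``, and the self term (a mutation that
fails to leave the donor region -- robustness) contributes one unit per
mutable parameter.  Normalizing ``K_ij * V_j`` over each donor row gives
transition probabilities ``k_ij``; the phenotype-specific mutation rate
constant is ``m_ij = m * k_ij`` with ``m`` the general per-locus rate.

In the idealized no-size-scale limit (``lambda = inf`` with ``delta = 1``)
the kernel degenerates to the pure volume factor ``k_ij = V_j / sum(V)``
over the whole repertoire, which makes the strictly neutral equilibrium
equal to the normalized phenotype volumes analytically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design_space import DesignSpace

__all__ = ["MutationModel", "TransitionMatrix", "reachable", "kernel_matrix",
           "transition_probabilities", "build_transition_matrix"]

OVERLAP_TOL = 1e-9


@dataclass(frozen=True)
class MutationModel:
    """Size scale, directional bias and general mutation rate."""

    lam: float = 0.6  # decades
    delta: float = 1.85  # dimensionless, >= 1
    pi: float = 6.0  # Pi-box width, decades
    m: float = 1e-7  # mutations / locus / generation
    mutable_parameters: tuple[str, ...] = ("K_P", "K_N")
    #: +1 if increasing the parameter increases entropy (weaker binding)
    entropy_direction: dict[str, int] = field(
        default_factory=lambda: {"K_P": +1, "K_N": +1}
    )

    def __post_init__(self):
        if not self.lam > 0:
            raise ValueError("size scale lambda must be positive")
        if not self.delta >= 1:
            raise ValueError("directional bias delta must be >= 1")
        if not 0 < self.m < 1:
            raise ValueError("general mutation rate m must lie in (0, 1)")
        object.__setattr__(self, "mutable_parameters", tuple(self.mutable_parameters))

    @property
    def volume_limit(self) -> bool:
        """True in the idealized no-size-scale, no-bias regime."""
        return math.isinf(self.lam) and self.delta == 1.0

    def scale_for(self, parameter: str, direction: float) -> float:
        """Effective decay scale for a move of given sign in ``parameter``."""
        if direction == 0:
            return self.lam
        entropic = direction * self.entropy_direction.get(parameter, +1) > 0
        return self.lam * self.delta if entropic else self.lam / self.delta


@dataclass(frozen=True)
class TransitionMatrix:
    """Raw kernels K, transition probabilities k and rates m_ij over the repertoire."""

    numbers: tuple[int, ...]
    K: np.ndarray
    k: np.ndarray
    m_ij: np.ndarray
    reachability: dict[str, np.ndarray]  # parameter -> boolean adjacency
    model: MutationModel

    def index(self, number: int) -> int:
        return self.numbers.index(number)

    @property
    def k_offdiag(self) -> np.ndarray:
        out = self.k.copy()
        np.fill_diagonal(out, 0.0)
        return out

    def frame(self, which: str = "k") -> pd.DataFrame:
        data = getattr(self, which)
        return pd.DataFrame(data, index=list(self.numbers), columns=list(self.numbers))


def _projection_interval(space: DesignSpace, number: int, parameter: str):
    return space.regions[number].tolerances[parameter]


def reachable(space: DesignSpace, donor: int, parameter: str) -> set[int]:
    """Recipients reachable from ``donor`` by mutating only ``parameter``.

    A recipient is reachable iff some axis-parallel line through the donor
    region intersects it, i.e. the two regions' projections onto the
    *other* free parameter overlap with positive length.  The donor itself
    is excluded (robustness is handled by the kernel's self term).
    """
    if parameter not in space.slice.free_parameters:
        raise ValueError(f"{parameter!r} is not a free parameter of the slice")
    other = next(p for p in space.slice.free_parameters if p != parameter)
    lo_d, hi_d = _projection_interval(space, donor, other)
    out = set()
    for num in space.numbers:
        if num == donor:
            continue
        lo, hi = _projection_interval(space, num, other)
        if min(hi, hi_d) - max(lo, lo_d) > OVERLAP_TOL:
            out.add(num)
    return out


def kernel_matrix(space: DesignSpace, model: MutationModel) -> TransitionMatrix:
    """Raw kernel K_ij (distance/size-scale/bias factors, volume not yet applied)."""
    nums = space.numbers
    n = len(nums)
    K = np.zeros((n, n))
    reach = {
        q: np.zeros((n, n), dtype=bool) for q in model.mutable_parameters
    }
    for q in model.mutable_parameters:
        for a, i in enumerate(nums):
            for j in reachable(space, i, q):
                reach[q][a, nums.index(j)] = True
    if model.volume_limit:
        K[:] = 1.0
    else:
        for a, i in enumerate(nums):
            ci = space.regions[i].centroid
            for b, j in enumerate(nums):
                if i == j:
                    K[a, b] = float(len(model.mutable_parameters))
                    continue
                cj = space.regions[j].centroid
                tot = 0.0
                for q in model.mutable_parameters:
                    if not reach[q][a, b]:
                        continue
                    step = cj[q] - ci[q]
                    tot += math.exp(-abs(step) / model.scale_for(q, step))
                K[a, b] = tot
    return TransitionMatrix(
        numbers=nums, K=K, k=np.zeros_like(K), m_ij=np.zeros_like(K),
        reachability=reach, model=model,
    )


def transition_probabilities(space: DesignSpace, tm: TransitionMatrix) -> TransitionMatrix:
    """Volume-weighted row normalization: k_ij = K_ij V_j / sum_j' K_ij' V_j'.

    The normalization runs over the reachable recipients *including* the
    donor's own self term, so that mutations which fail to change the
    phenotype carry their share of the probability; rows of k sum to 1.
    """
    V = np.array([space.regions[i].area for i in tm.numbers])
    KV = tm.K * V[None, :]
    row = KV.sum(axis=1)
    if np.any(row <= 0):
        bad = [tm.numbers[i] for i in np.nonzero(row <= 0)[0]]
        raise RuntimeError(f"donor(s) {bad} have no reachable recipients")
    k = KV / row[:, None]
    return TransitionMatrix(
        numbers=tm.numbers, K=tm.K, k=k, m_ij=tm.model.m * k,
        reachability=tm.reachability, model=tm.model,
    )


def build_transition_matrix(space: DesignSpace, model: MutationModel) -> TransitionMatrix:
    """Convenience: kernel followed by volume-weighted normalization."""
    return transition_probabilities(space, kernel_matrix(space, model))
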