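"""Earth mover's distance between 1-D distribution signatures.

A distribution is summarized as a *signature*: a small set of cluster
representatives with nonnegative weights.  The distance between two
signatures is the minimum total transport work (flow times ground
distance) normalized by the total flow — the classical transportation
problem.  The solver is an exact linear program, so it handles unequal
total masses; for normalized equal-mass 1-D signatures the result
coincides with the 1-D Wasserstein distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog


@dataclass
class Signature:
    """Weighted-cluster representation of a 1-D distribution."""

    representatives: np.ndarray  # cluster centers, same units as the data
    weights: np.ndarray  # nonnegative, positive sum

    def __post_init__(self) -> None:
        self.representatives = np.asarray(self.representatives, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.representatives.size == 0:
            raise ValueError("signature needs at least one cluster")
        if self.representatives.shape != self.weights.shape:
            raise ValueError("representatives and weights must align")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        if self.weights.sum() <= 0:
            raise ValueError("total signature weight must be positive")
        if not np.all(np.isfinite(self.representatives)):
            raise ValueError("representatives must be finite")

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())


@dataclass
class FlowPlan:
    """Optimal transport flows and the ground-distance matrix behind an EMD."""

    flows: np.ndarray  # m x n nonnegative
    ground: np.ndarray  # m x n distances |p_i - q_j|

    @property
    def work(self) -> float:
        return float(np.sum(self.flows * self.ground))

    @property
    def total_flow(self) -> float:
        return float(self.flows.sum())


def build_signature(values: np.ndarray, k: int = 10) -> Signature:
    """Summarize a 1-D sample as an equal-width histogram signature.

    The range [min, max] is cut into ``k`` equal-width bins; empty bins
    are dropped, each remaining cluster is represented by the mean of its
    members and weighted by the member fraction, so weights sum to 1.
    A degenerate sample (all values equal) yields a single unit-weight
    cluster.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("cannot build a signature from an empty sample")
    if k < 1:
        raise ValueError("k must be >= 1")
    lo, hi = values.min(), values.max()
    if lo == hi:
        return Signature(np.array([lo]), np.array([1.0]))
    edges = np.linspace(lo, hi, k + 1)
    # right-inclusive last bin so the maximum is counted
    idx = np.clip(np.digitize(values, edges[1:-1], right=False), 0, k - 1)
    reps, weights = [], []
    for b in range(k):
        members = values[idx == b]
        if members.size:
            reps.append(members.mean())
            weights.append(members.size / values.size)
    return Signature(np.asarray(reps), np.asarray(weights))


def earth_movers_distance(
    p: Signature, q: Signature, return_plan: bool = False
) -> float | tuple[float, FlowPlan]:
    """Exact EMD between two signatures via the transportation LP.

    Minimizes total work ``sum_ij f_ij d_ij`` over flows f subject to
    nonnegativity, row sums bounded by the source weights, column sums
    bounded by the sink weights, and total flow equal to the smaller of
    the two total masses; the returned distance is the optimal work
    divided by the total flow.  The ground distance is ``|p_i - q_j|``.
    """
    reps_p, w_p = p.representatives, p.weights
    reps_q, w_q = q.representatives, q.weights
    m, n = reps_p.size, reps_q.size
    ground = np.abs(reps_p[:, None] - reps_q[None, :])
    total = min(w_p.sum(), w_q.sum())

    c = ground.ravel()
    # row-sum constraints: sum_j f_ij <= w_p[i]
    a_ub = np.zeros((m + n, m * n))
    for i in range(m):
        a_ub[i, i * n : (i + 1) * n] = 1.0
    for j in range(n):
        a_ub[m + j, j::n] = 1.0
    b_ub = np.concatenate([w_p, w_q])
    a_eq = np.ones((1, m * n))
    b_eq = np.array([total])

    res = linprog(
        c, A_ub=a_ub, b_ub=b_ub, A_eq=a_eq, b_eq=b_eq,
        bounds=(0, None), method="highs",
    )
    if not res.success:  # pragma: no cover - LP is always feasible here
        raise RuntimeError(f"transportation LP failed: {res.message}")
    flows = res.x.reshape(m, n)
    emd = float(res.fun / total)
    if return_plan:
        return emd, FlowPlan(flows=flows, ground=ground)
    return emd
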