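"""Fuzzy c-means clustering and rule-base initialization.

FCM minimizes ``sum_ik u_ik^m ||x_k - c_i||^2`` by alternating membership and
center updates.  It is used to pick the rule count (via the fuzzy partition
coefficient) and to seed the premise parameters of an
:class:`~anfiswo.anfis.ANFISModel`: cluster centers become membership centers,
membership-weighted standard deviations become widths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from anfiswo.anfis import ANFISModel, SIGMA_MIN

__all__ = [
    "FCMResult",
    "fcm_cluster",
    "select_rule_count",
    "partition_coefficient",
    "init_anfis_from_fcm",
]

logger = logging.getLogger(__name__)

#: below this total membership mass a cluster is treated as degenerate
EPS_WEIGHT = 1e-12


@dataclass(frozen=True)
class FCMResult:
    """Outcome of one fuzzy c-means run.

    ``centers`` is ``c x d``; ``membership`` is ``N x c`` with rows summing
    to 1; ``objective_trace`` is the nonincreasing per-iteration objective.
    """

    centers: np.ndarray
    membership: np.ndarray
    fuzzifier: float
    objective_trace: np.ndarray
    c: int


def _distances_sq(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances, N x c."""
    diff = X[:, None, :] - centers[None, :, :]
    return np.sum(diff * diff, axis=2)


def _memberships(d2: np.ndarray, m: float) -> np.ndarray:
    """Membership update from squared distances; coincident points get
    uniform membership over the tied clusters."""
    zero = d2 <= 0.0
    any_zero = zero.any(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d2 ** (-1.0 / (m - 1.0))
        u = inv / inv.sum(axis=1, keepdims=True)
    if any_zero.any():
        rows = np.flatnonzero(any_zero)
        u[rows] = zero[rows] / zero[rows].sum(axis=1, keepdims=True)
    return u


def fcm_cluster(
    X: np.ndarray,
    c: int,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 200,
    seed: int = 0,
) -> FCMResult:
    """Run fuzzy c-means on the rows of ``X``.

    Stops when the max absolute membership change drops below ``tol`` or
    after ``max_iter`` iterations.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    n = X.shape[0]
    if not 1 <= c <= n:
        raise ValueError(f"need 1 <= c <= N, got c={c}, N={n}")
    if not m > 1:
        raise ValueError(f"fuzzifier must be > 1, got {m}")

    rng = np.random.default_rng(seed)
    u = rng.random((n, c))
    u /= u.sum(axis=1, keepdims=True)

    trace = []
    for _ in range(max_iter):
        um = u ** m
        centers = (um.T @ X) / um.sum(axis=0)[:, None]
        d2 = _distances_sq(X, centers)
        trace.append(float(np.sum(um * d2)))
        u_new = _memberships(d2, m)
        shift = float(np.max(np.abs(u_new - u)))
        u = u_new
        if shift < tol:
            break

    um = u ** m
    centers = (um.T @ X) / um.sum(axis=0)[:, None]
    return FCMResult(
        centers=centers,
        membership=u,
        fuzzifier=m,
        objective_trace=np.asarray(trace),
        c=c,
    )


def partition_coefficient(result: FCMResult) -> float:
    """Fuzzy partition coefficient: mean of squared memberships (1/c .. 1)."""
    return float(np.mean(np.sum(result.membership ** 2, axis=1)))


def select_rule_count(
    X: np.ndarray,
    c_candidates: list[int],
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 200,
    seed: int = 0,
) -> int:
    """Pick the candidate cluster count maximizing the partition coefficient.

    Ties (within 1e-12) break toward the smaller count.
    """
    if not c_candidates:
        raise ValueError("candidate list is empty")
    best_c, best_pc = None, -np.inf
    for c in sorted(c_candidates):
        pc = partition_coefficient(fcm_cluster(X, c, m=m, tol=tol, max_iter=max_iter, seed=seed))
        if pc > best_pc + 1e-12:
            best_c, best_pc = c, pc
    return best_c


def init_anfis_from_fcm(result: FCMResult, X: np.ndarray) -> ANFISModel:
    """Seed a rule base from a clustering of the same ``X``.

    Rule i gets center row i and, per input column, the membership-weighted
    standard deviation about that center, floored at SIGMA_MIN.  Consequents
    start at zero.
    """
    X = np.asarray(X, dtype=float)
    c, d = result.centers.shape
    if X.shape[0] != result.membership.shape[0]:
        raise ValueError("X row count does not match the clustering result")
    widths = np.empty((c, d))
    for i in range(c):
        w = result.membership[:, i]
        total = w.sum()
        if total <= EPS_WEIGHT:
            logger.warning("degenerate cluster %d: widths floored at SIGMA_MIN", i)
            widths[i] = SIGMA_MIN
            continue
        var = (w[:, None] * (X - result.centers[i]) ** 2).sum(axis=0) / total
        widths[i] = np.maximum(np.sqrt(var), SIGMA_MIN)
    return ANFISModel(
        centers=result.centers.copy(),
        widths=widths,
        coeffs=np.zeros((c, d)),
        bias=np.zeros(c),
    )
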