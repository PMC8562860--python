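"""Tolerance-driven selection between the stQSSA and the k-state slQSSA.

For a fixed dissociation constant ``K_d`` and a relative-error tolerance
``epsilon``, a :class:`ReductionPolicy` certifies a total-copy-number
threshold: totals below it use the L-state slQSSA, totals at or above it
use the stQSSA, and either choice keeps the worst-case relative error
(maximized over the partner total) within the tolerance on the
certification grid.

Certification is by exhaustive exact-error scan on a log-dense integer
grid of totals (every integer up to ``DENSE_TOTAL_LIMIT``, then at least
40 points per decade).  Above the analytic ceiling
``1 / (K_d * epsilon**2)`` the stQSSA is certified by the error bound
``R_A <= 2 F_A S_A < 1 / sqrt(A_T K_d) <= epsilon`` (the Fano factor is
sub-Poissonian and the sensitivity peaks at ``1/sqrt(4 A_T K_d)``), so no
scan is needed there.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from stoqssa.binding import (
    BindingPair,
    Method,
    QssaEstimate,
    SpeciesRole,
    exact_mean,
    slqssa,
    slqssa_unbound,
    stqssa_unbound,
)

__all__ = [
    "ReductionPolicy",
    "NoValidPolicyError",
    "partner_grid",
    "max_error_over_partner",
    "find_policy",
    "choose_estimate",
]

#: totals up to this bound are scanned at every integer
DENSE_TOTAL_LIMIT = 256
#: log-grid density above the dense range
POINTS_PER_DECADE = 40
#: number of log-spaced partner points over (0, 4*total]
PARTNER_LOG_POINTS = 25


class NoValidPolicyError(RuntimeError):
    """No L <= L_max certifies the sub-threshold totals; reports the gap."""

    def __init__(self, message: str, failing_totals: list[int]):
        super().__init__(message)
        self.failing_totals = failing_totals


def partner_grid(total: int, K_d: float) -> np.ndarray:
    """Partner totals ``B_T`` scanned when maximizing the error for a total.

    A coarse log-spaced grid over ``[0, 4*total]`` union a dense integer
    window of half-width ``max(10, 5*K_d)`` around ``B_T = total - K_d``,
    where the sensitivity ``S_A`` (and hence the stQSSA error) peaks.
    """
    pts = {0, 1, int(4 * total)}
    if total >= 1:
        pts.update(
            int(round(x))
            for x in np.geomspace(1.0, max(4.0 * total, 1.0), PARTNER_LOG_POINTS)
        )
    half = int(max(10, math.ceil(5.0 * K_d)))
    center = int(round(total - K_d))
    lo, hi = max(0, center - half), center + half
    pts.update(range(lo, hi + 1))
    return np.array(sorted(p for p in pts if p >= 0), dtype=np.int64)


def _estimator_value(total: int, b_t: int, K_d: float, method) -> float:
    """Evaluate ``method`` ('stqssa' or ('slqssa', k)) at (total, b_t, K_d)."""
    if method == "stqssa":
        return stqssa_unbound(float(total), float(b_t), K_d)
    if isinstance(method, tuple) and method[0] == "slqssa":
        return slqssa_unbound(total, b_t, K_d, method[1])
    raise ValueError(f"unknown method spec {method!r}")


def max_error_over_partner(total: int, K_d: float, method) -> float:
    """Worst-case relative error of an estimator over the partner scan.

    ``method`` is ``"stqssa"`` or ``("slqssa", k)``.  The exact mean is
    strictly positive for any ``total >= 1`` and ``K_d > 0``, so the
    relative error is always defined on the scan.
    """
    if total < 1:
        raise ValueError("total must be >= 1")
    worst = 0.0
    for b_t in partner_grid(total, K_d):
        ex = exact_mean(BindingPair(total, int(b_t), K_d)).value
        est = _estimator_value(total, int(b_t), K_d, method)
        err = abs(est - ex) / ex
        if err > worst:
            worst = err
    return worst


def _total_grid(t_max: int) -> list[int]:
    """Every integer up to DENSE_TOTAL_LIMIT, then >= 40 per decade."""
    totals = list(range(1, min(t_max, DENSE_TOTAL_LIMIT) + 1))
    if t_max > DENSE_TOTAL_LIMIT:
        n_dec = math.log10(t_max / DENSE_TOTAL_LIMIT)
        n_pts = max(2, int(math.ceil(POINTS_PER_DECADE * n_dec)))
        extra = np.geomspace(DENSE_TOTAL_LIMIT, t_max, n_pts + 1)
        totals.extend(sorted({int(round(x)) for x in extra} - set(totals)))
    return totals


@dataclass
class ReductionPolicy:
    """A certified stQSSA/slQSSA switching rule for one binding pair.

    Totals strictly below ``threshold_total`` use the ``L``-state slQSSA;
    totals at or above it use the stQSSA (ties go to the cheaper closed
    form).  ``scan_grid`` records the totals on which the guarantee was
    certified by exact-error evaluation.
    """

    K_d: float
    epsilon: float
    L: int
    threshold_total: int
    scan_grid: list[int] = field(default_factory=list, repr=False)
    analytic_ceiling: int | None = None

    def to_file(self, path: str | Path) -> None:
        payload = {
            "K_d": self.K_d,
            "epsilon": self.epsilon,
            "L": self.L,
            "threshold_total": self.threshold_total,
            "analytic_ceiling": self.analytic_ceiling,
            "scan_grid": {
                "description": (
                    f"every integer total <= {DENSE_TOTAL_LIMIT}, then "
                    f">= {POINTS_PER_DECADE} log-spaced points per decade"
                ),
                "totals": self.scan_grid,
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_file(cls, path: str | Path) -> "ReductionPolicy":
        d = json.loads(Path(path).read_text())
        return cls(
            K_d=d["K_d"],
            epsilon=d["epsilon"],
            L=d["L"],
            threshold_total=d["threshold_total"],
            scan_grid=d.get("scan_grid", {}).get("totals", []),
            analytic_ceiling=d.get("analytic_ceiling"),
        )


def analytic_stqssa_ceiling(K_d: float, epsilon: float) -> int:
    """Smallest total above which ``2*S_A <= epsilon`` holds for any partner.

    From ``R_A <= 2 F_A S_A < 2 S_A <= 1/sqrt(A_T K_d)``: totals at or
    above ``1/(K_d epsilon^2)`` need no scan.
    """
    return int(math.ceil(1.0 / (K_d * epsilon * epsilon)))


def find_policy(
    K_d: float, epsilon: float, L_max: int = 10
) -> ReductionPolicy:
    """Certify a switching threshold and slQSSA state count for (K_d, eps).

    Scans totals upward on the certification grid, finds the smallest
    threshold ``T*`` such that the stQSSA's worst-case error is within
    ``epsilon`` for every scanned total >= ``T*`` (totals above the
    analytic ceiling are certified by the sensitivity bound), then the
    smallest ``L <= L_max`` whose slQSSA certifies every scanned total
    below ``T*``.
    """
    if not (0.0 < epsilon < 1.0):
        raise ValueError("epsilon must be in (0, 1)")
    if K_d <= 0:
        raise ValueError("K_d must be positive")
    ceiling = analytic_stqssa_ceiling(K_d, epsilon)
    grid = _total_grid(ceiling)
    stq_err = {t: max_error_over_partner(t, K_d, "stqssa") for t in grid}
    # smallest grid total from which every scanned total upward passes
    threshold = ceiling
    for t in reversed(grid):
        if stq_err[t] <= epsilon:
            threshold = t
        else:
            break
    below = [t for t in grid if t < threshold]
    chosen_l = None
    failing: list[int] = []
    for L in range(2, L_max + 1):
        failing = [
            t
            for t in below
            if max_error_over_partner(t, K_d, ("slqssa", L)) > epsilon
        ]
        if not failing:
            chosen_l = L
            break
    if chosen_l is None:
        raise NoValidPolicyError(
            f"no slQSSA with L <= {L_max} meets epsilon={epsilon} for totals "
            f"below {threshold} (residual totals: {failing[:10]}...)",
            failing,
        )
    return ReductionPolicy(
        K_d=K_d,
        epsilon=epsilon,
        L=chosen_l,
        threshold_total=threshold,
        scan_grid=grid,
        analytic_ceiling=ceiling,
    )


def choose_estimate(pair: BindingPair, policy: ReductionPolicy) -> QssaEstimate:
    """Adaptive estimate of the unbound count under a certified policy."""
    if not math.isclose(pair.K_d, policy.K_d, rel_tol=1e-9):
        raise ValueError(
            f"policy certified for K_d={policy.K_d}, pair has K_d={pair.K_d}"
        )
    if pair.A_T < policy.threshold_total:
        return slqssa(pair, policy.L)
    return QssaEstimate(
        stqssa_unbound(pair.A_T, pair.B_T, pair.K_d),
        Method.STQSSA,
        SpeciesRole.UNBOUND_A,
    )
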