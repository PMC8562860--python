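"""Stationary statistics of a rapid reversible binding motif and its QSSAs.

The motif is the elementary reaction pair

    A + B  <-->  C        (binding k_f/Omega, unbinding k_b)

with conserved totals ``A_T = A + C`` and ``B_T = B + C``.  Conditioned on
the totals, the unbound count ``A`` has an exact stationary law under the
chemical master equation, supported on ``[A_0, A_T]`` with
``A_0 = max(0, A_T - B_T)``:

    pi(l)  ∝  K_d**(l - A_0) / ( l! * (A_T - l)! * (B_T - A_T + l)! )

where ``K_d = k_b * Omega / k_f`` is the dimensionless dissociation
constant.  The stationary conditional mean ``<A>`` is the stochastic QSSA:
the exact quantity a reduced model should use as a propensity.  Because
evaluating it is O(support), two closed-form approximations are standard:

* the stochastic total QSSA (stQSSA), i.e. the deterministic Morrison
  equation evaluated on dimensionless counts -- accurate unless the two
  species tightly bind at ~1:1 molar ratio; and
* the k-state low-state QSSA (slQSSA), the mean of the law truncated to
  the k lowest reachable states -- accurate under tight binding where the
  unbound count barely leaves those states.

This module provides the exact law, both approximations, the
Michaelis-Menten-type standard QSSA for the complex, and the diagnostics
(Fano factor, relative sensitivity, relative error) that control the
stQSSA's error through the bound  F_A*S_A <= R_A <= 2*F_A*S_A.

All combinatorial weights are handled in log space via ``gammaln`` and
normalized with log-sum-exp, so totals up to 1e6 and beyond are fine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "BindingPair",
    "StationaryDistribution",
    "QssaEstimate",
    "Method",
    "SpeciesRole",
    "UndefinedValueError",
    "exact_stationary_distribution",
    "exact_mean",
    "tqssa",
    "stqssa",
    "slqssa",
    "sqssa_complex",
    "relative_sensitivity",
    "fano_factor",
    "relative_error",
]

# log-weight drop below the running maximum at which tails are negligible;
# exp(-46) ~ 1e-20, far below double round-off on any normalized sum
_LOG_TAIL_CUTOFF = 46.0
# supports smaller than this are always evaluated in full
_FULL_SUPPORT_LIMIT = 4096


class UndefinedValueError(ValueError):
    """A requested statistic is undefined for this input (e.g. zero mean)."""


class Method(str, Enum):
    EXACT = "exact"
    STQSSA = "stQSSA"
    SLQSSA = "slQSSA"
    SQSSA = "sQSSA"


class SpeciesRole(str, Enum):
    UNBOUND_A = "unbound_A"
    UNBOUND_B = "unbound_B"
    COMPLEX_C = "complex_C"


@dataclass(frozen=True)
class BindingPair:
    """A reversible binding motif in dimensionless (copy-number) form.

    Parameters
    ----------
    A_T, B_T
        Total copy numbers (unbound + complexed) of the two partners;
        non-negative integers.  Near-integer floats are accepted and
        rounded (tolerance 1e-9) since callers often pass results of
        float arithmetic.
    K_d
        Dimensionless dissociation constant ``k_b * Omega / k_f``;
        positive and finite.  Small values mean tight binding.
    """

    A_T: int
    B_T: int
    K_d: float

    def __post_init__(self) -> None:
        for name in ("A_T", "B_T"):
            raw = getattr(self, name)
            if not np.isfinite(raw):
                raise ValueError(f"{name} must be finite, got {raw!r}")
            rounded = round(float(raw))
            if abs(float(raw) - rounded) > 1e-9:
                raise ValueError(f"{name} must be an integer, got {raw!r}")
            if rounded < 0:
                raise ValueError(f"{name} must be non-negative, got {raw!r}")
            object.__setattr__(self, name, int(rounded))
        kd = float(self.K_d)
        if not np.isfinite(kd) or kd <= 0.0:
            raise ValueError(f"K_d must be positive and finite, got {self.K_d!r}")
        object.__setattr__(self, "K_d", kd)

    @classmethod
    def from_rates(
        cls, A_T: int, B_T: int, kf_over_omega: float, kb: float
    ) -> "BindingPair":
        """Build a pair from the elementary rates ``k_f/Omega`` and ``k_b``."""
        if kf_over_omega <= 0 or kb <= 0:
            raise ValueError("rate constants must be positive")
        return cls(A_T, B_T, kb / kf_over_omega)

    @property
    def A_0(self) -> int:
        """Lowest reachable unbound-A count, ``max(0, A_T - B_T)``."""
        return max(0, self.A_T - self.B_T)

    def swapped(self) -> "BindingPair":
        """The same motif viewed from the partner's side (A and B swapped)."""
        return BindingPair(self.B_T, self.A_T, self.K_d)


def _log_weights(pair: BindingPair, lo: int, hi: int) -> np.ndarray:
    """Unnormalized log pi(l) for l in [lo, hi] (inclusive, vectorized)."""
    l = np.arange(lo, hi + 1, dtype=np.float64)
    return (
        (l - pair.A_0) * math.log(pair.K_d)
        - gammaln(l + 1.0)
        - gammaln(pair.A_T - l + 1.0)
        - gammaln(pair.B_T - pair.A_T + l + 1.0)
    )


def _mass_window(pair: BindingPair) -> tuple[int, int]:
    """A sub-support window [lo, hi] carrying all but ~1e-20 of the mass.

    The law is log-concave with mode near the stQSSA value, so start
    around it and grow until the boundary log-weights have dropped by
    ``_LOG_TAIL_CUTOFF`` relative to the window maximum.
    """
    a0, at = pair.A_0, pair.A_T
    if at - a0 <= _FULL_SUPPORT_LIMIT:
        return a0, at
    center = int(round(stqssa_unbound(pair.A_T, pair.B_T, pair.K_d)))
    center = min(max(center, a0), at)
    half = int(50 + 40 * math.sqrt(max(center - a0, center, 1)))
    lo, hi = max(a0, center - half), min(at, center + half)
    while True:
        lw = _log_weights(pair, lo, hi)
        peak = lw.max()
        ok_lo = lo == a0 or lw[0] < peak - _LOG_TAIL_CUTOFF
        ok_hi = hi == at or lw[-1] < peak - _LOG_TAIL_CUTOFF
        if ok_lo and ok_hi:
            return lo, hi
        span = hi - lo + 1
        if not ok_lo:
            lo = max(a0, lo - span)
        if not ok_hi:
            hi = min(at, hi + span)


@dataclass
class StationaryDistribution:
    """Exact stationary law of the unbound-A count on ``[A_0, A_T]``."""

    pair: BindingPair
    support: np.ndarray = field(repr=False)
    log_probabilities: np.ndarray = field(repr=False)
    probabilities: np.ndarray = field(repr=False)

    def pmf(self, l: int) -> float:
        """P(A = l); exactly 0 outside ``[A_0, A_T]``."""
        if l < self.support[0] or l > self.support[-1]:
            return 0.0
        return float(self.probabilities[int(l) - int(self.support[0])])

    def mean(self) -> float:
        return float(np.dot(self.support.astype(float), self.probabilities))

    def second_moment(self) -> float:
        return float(np.dot(self.support.astype(float) ** 2, self.probabilities))

    def variance(self) -> float:
        m = self.mean()
        # accumulate around the mean to avoid cancellation at large counts
        d = self.support.astype(float) - m
        return float(np.dot(d * d, self.probabilities))


@dataclass(frozen=True)
class QssaEstimate:
    """A scalar quasi-steady-state value tagged by method and species role."""

    value: float
    method: Method
    species_role: SpeciesRole = SpeciesRole.UNBOUND_A
    k: int | None = None  # slQSSA truncation size, when applicable

    def __post_init__(self) -> None:
        if not np.isfinite(self.value) or self.value < -1e-9:
            raise ValueError(f"estimate must be finite and >= 0, got {self.value!r}")


def exact_stationary_distribution(pair: BindingPair) -> StationaryDistribution:
    """The normalized stationary law of the unbound count A.

    Weights ``pi(l) ∝ K_d**(l - A_0) / (l!(A_T-l)!(B_T-A_T+l)!)`` are
    evaluated in log space on the full support and normalized with
    log-sum-exp, so the result is finite for totals of 1e6 and more.
    """
    lw = _log_weights(pair, pair.A_0, pair.A_T)
    logp = lw - logsumexp(lw)
    return StationaryDistribution(
        pair=pair,
        support=np.arange(pair.A_0, pair.A_T + 1),
        log_probabilities=logp,
        probabilities=np.exp(logp),
    )


def _window_moments(pair: BindingPair) -> tuple[float, float]:
    """(mean, variance) of the exact law, via the adaptive mass window."""
    lo, hi = _mass_window(pair)
    lw = _log_weights(pair, lo, hi)
    p = np.exp(lw - logsumexp(lw))
    l = np.arange(lo, hi + 1, dtype=np.float64)
    m = float(np.dot(l, p))
    d = l - m
    return m, float(np.dot(d * d, p))


def exact_mean(pair: BindingPair) -> QssaEstimate:
    """The stochastic QSSA for A: the exact stationary conditional mean."""
    m, _ = _window_moments(pair)
    return QssaEstimate(m, Method.EXACT, SpeciesRole.UNBOUND_A)


def exact_mean_complex(pair: BindingPair) -> QssaEstimate:
    """``<C> = A_T - <A>`` by conservation."""
    return QssaEstimate(
        pair.A_T - exact_mean(pair).value, Method.EXACT, SpeciesRole.COMPLEX_C
    )


def exact_mean_partner(pair: BindingPair) -> QssaEstimate:
    """``<B> = B_T - A_T + <A>`` by conservation."""
    return QssaEstimate(
        pair.B_T - pair.A_T + exact_mean(pair).value,
        Method.EXACT,
        SpeciesRole.UNBOUND_B,
    )


def exact_variance(pair: BindingPair) -> float:
    """Var(A) under the exact stationary law."""
    return _window_moments(pair)[1]


def tqssa(A_T: float, B_T: float, K_d: float) -> tuple[float, float, float]:
    """Deterministic total-QSSA (Morrison) values ``(A_tq, B_tq, C_tq)``.

    Totals may be real: this is the deterministic formula, shared with the
    stQSSA which evaluates it on dimensionless copy numbers.  The
    tight-binding branch ``A_T - B_T - K_d < 0`` is computed as
    ``2*A_T*K_d / (sqrt(disc) - (A_T - B_T - K_d))`` to avoid cancellation
    between nearly equal terms.
    """
    for name, v in (("A_T", A_T), ("B_T", B_T), ("K_d", K_d)):
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")
    if A_T < 0 or B_T < 0 or K_d <= 0:
        raise ValueError("totals must be >= 0 and K_d > 0")
    b = A_T - B_T - K_d
    disc = b * b + 4.0 * A_T * K_d
    root = math.sqrt(disc)
    if b >= 0.0:
        a_tq = 0.5 * (b + root)
    else:
        a_tq = (2.0 * A_T * K_d) / (root - b)
    c_tq = A_T - a_tq
    b_tq = B_T - c_tq
    # clip tiny negative round-off
    return max(a_tq, 0.0), max(b_tq, 0.0), max(c_tq, 0.0)


def stqssa_unbound(A_T: float, B_T: float, K_d: float) -> float:
    """Scalar stQSSA for the unbound species A (fast path, no dataclass)."""
    return tqssa(A_T, B_T, K_d)[0]


def stqssa(pair: BindingPair | None = None, **kw) -> tuple[QssaEstimate, ...]:
    """stQSSA estimates ``(A_tq, B_tq, C_tq)`` for a pair.

    Accepts either a :class:`BindingPair` or keywords ``A_T, B_T, K_d``
    (reals allowed, since the formula is the deterministic tQSSA).
    """
    if pair is not None:
        a_t, b_t, k_d = float(pair.A_T), float(pair.B_T), pair.K_d
    else:
        a_t, b_t, k_d = float(kw["A_T"]), float(kw["B_T"]), float(kw["K_d"])
    a, b, c = tqssa(a_t, b_t, k_d)
    return (
        QssaEstimate(a, Method.STQSSA, SpeciesRole.UNBOUND_A),
        QssaEstimate(b, Method.STQSSA, SpeciesRole.UNBOUND_B),
        QssaEstimate(c, Method.STQSSA, SpeciesRole.COMPLEX_C),
    )


def slqssa(pair: BindingPair, k: int) -> QssaEstimate:
    """k-state low-state QSSA: mean of the law truncated to the k lowest states.

    The truncated support is ``[A_0, min(A_0 + k - 1, A_T)]``; once it
    covers the full support the value equals the exact mean.  ``k >= 2``.
    """
    if k < 2:
        raise ValueError(f"slQSSA needs k >= 2, got {k}")
    hi = min(pair.A_0 + k - 1, pair.A_T)
    lw = _log_weights(pair, pair.A_0, hi)
    p = np.exp(lw - logsumexp(lw))
    l = np.arange(pair.A_0, hi + 1, dtype=np.float64)
    return QssaEstimate(float(np.dot(l, p)), Method.SLQSSA, SpeciesRole.UNBOUND_A, k=k)


def slqssa_unbound(A_T: int, B_T: int, K_d: float, k: int) -> float:
    """Scalar k-state slQSSA for the unbound species (convenience)."""
    return slqssa(BindingPair(A_T, B_T, K_d), k).value


def slqssa_two_state(pair: BindingPair) -> QssaEstimate:
    """Closed-form two-state slQSSA (the k = 2 special case).

    Piecewise in the sign of ``A_T - B_T``::

        A_T >= B_T:  (A_T - B_T + 1)(A_T - B_T + B_T K_d) / (A_T - B_T + B_T K_d + 1)
        A_T <  B_T:  A_T K_d / (B_T - A_T + A_T K_d + 1)
    """
    a_t, b_t, kd = pair.A_T, pair.B_T, pair.K_d
    if a_t >= b_t:
        num = (a_t - b_t + 1.0) * (a_t - b_t + b_t * kd)
        val = num / (a_t - b_t + b_t * kd + 1.0)
    else:
        val = a_t * kd / (b_t - a_t + a_t * kd + 1.0)
    return QssaEstimate(val, Method.SLQSSA, SpeciesRole.UNBOUND_A, k=2)


def sqssa_complex(A_T: float, B: float, K_d: float) -> QssaEstimate:
    """Standard (Michaelis-Menten-type) QSSA for the complex.

    ``C_sq = A_T * B / (B + K_d)``; valid in the low-partner regime
    ``B_T + K_d >> A_T``.
    """
    if A_T < 0 or B < 0 or K_d <= 0:
        raise ValueError("need A_T >= 0, B >= 0, K_d > 0")
    return QssaEstimate(
        A_T * B / (B + K_d), Method.SQSSA, SpeciesRole.COMPLEX_C
    )


def relative_sensitivity(pair: BindingPair) -> float:
    """Relative sensitivity of the stQSSA w.r.t. the partner total.

    ``S_A = 1 / sqrt((A_T - B_T - K_d)^2 + 4 A_T K_d)``; it peaks at
    ``B_T = A_T - K_d`` with value ``1 / sqrt(4 A_T K_d)`` and, with the
    Fano factor, bounds the stQSSA's relative error.
    """
    b = pair.A_T - pair.B_T - pair.K_d
    return 1.0 / math.sqrt(b * b + 4.0 * pair.A_T * pair.K_d)


def fano_factor(dist: StationaryDistribution | BindingPair) -> float:
    """``Var(A) / <A>`` of the exact stationary law (sub-Poissonian: < 1)."""
    if isinstance(dist, BindingPair):
        m, v = _window_moments(dist)
    else:
        m, v = dist.mean(), dist.variance()
    if m <= 0.0:
        raise UndefinedValueError("Fano factor undefined: mean is zero")
    return v / m


def relative_error(estimate: QssaEstimate, exact: QssaEstimate) -> float:
    """``|estimate - exact| / exact`` for two estimates of the same quantity."""
    if estimate.species_role != exact.species_role:
        raise ValueError(
            f"role mismatch: {estimate.species_role} vs {exact.species_role}"
        )
    if exact.value <= 0.0:
        raise UndefinedValueError(
            "relative error undefined at exact value 0 (not-applicable)"
        )
    return abs(estimate.value - exact.value) / exact.value
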