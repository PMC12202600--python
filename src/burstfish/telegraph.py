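"""Stationary distributions of the random telegraph model and its polyploid extension.

The telegraph model is a two-state promoter switching between an inactive (OFF)
and an active (ON) state with activation rate ``lam`` and deactivation rate
``gam``. While ON, mRNA is transcribed at rate ``mu``; every mRNA molecule is
degraded at rate ``delta``. At stationarity the joint law of the promoter state
``X`` and the mRNA copy number ``Y`` of a single allele is available in closed
form through Kummer's confluent hypergeometric function ``M(a, b, x)``.

For a polyploid cell carrying ``K`` statistically identical, independent
alleles, the probability of observing ``k`` active alleles together with a
*total* mRNA count ``m`` is a binomial coefficient times self-convolutions of
the two partial mass functions (ON-joint ``p`` and OFF-joint ``q``).

Everything in this module is also checkable against a brute-force stationary
solution of the truncated chemical master equation (:func:`cme_stationary_oracle`),
which serves as the independent ground truth in the test-suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import special

__all__ = [
    "TelegraphParams",
    "NormalizedParams",
    "CellObservation",
    "PmfTruncation",
    "KummerError",
    "TruncationError",
    "active_fraction",
    "kummer_m",
    "partial_pmf_on",
    "partial_pmf_off",
    "marginal_pmf",
    "marginal_pmf_direct",
    "default_truncation",
    "polyploid_joint_pmf",
    "cme_stationary_oracle",
]

_MIN_RATE = 1e-12
_M_MAX_CAP = 2000


class KummerError(ArithmeticError):
    """Kummer function evaluation failed to produce a finite value."""


class TruncationError(ValueError):
    """The truncated pmf leaves more probability mass in the tail than allowed."""


@dataclass(frozen=True)
class TelegraphParams:
    """The five inferred parameters of the bursting model.

    Parameters
    ----------
    lam : float
        Promoter activation rate (1/h).
    gam : float
        Promoter deactivation rate (1/h).
    mu : float
        Transcription rate while the promoter is ON (RNA/h).
    delta : float
        mRNA degradation rate (1/h).
    beta : float
        Variance of the nascent-RNA fluorescence intensity at an active
        transcription site (mature-RNA-equivalents squared).
    """

    lam: float
    gam: float
    mu: float
    delta: float
    beta: float

    def __post_init__(self) -> None:
        for name in ("lam", "gam", "mu", "delta", "beta"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive and finite, got {v!r}")
        # Both promoter states must be reachable; callers wanting a limit pass
        # a small-but-positive rate instead.
        if self.lam < _MIN_RATE or self.gam < _MIN_RATE:
            raise ValueError("lam and gam must exceed 1e-12 (both states reachable)")

    def normalized(self) -> "NormalizedParams":
        return NormalizedParams(
            a=self.lam / self.delta,
            b=(self.lam + self.gam) / self.delta,
            rho=self.mu / self.delta,
        )

    def as_array(self) -> np.ndarray:
        return np.array([self.lam, self.gam, self.mu, self.delta, self.beta])

    @staticmethod
    def from_array(theta: np.ndarray) -> "TelegraphParams":
        lam, gam, mu, delta, beta = (float(v) for v in theta)
        return TelegraphParams(lam, gam, mu, delta, beta)


@dataclass(frozen=True)
class NormalizedParams:
    """Degradation-normalized parameters: a = lam/delta, b = (lam+gam)/delta, rho = mu/delta."""

    a: float
    b: float
    rho: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > self.a and self.rho > 0):
            raise ValueError("require a > 0, b > a, rho > 0")


@dataclass(frozen=True)
class CellObservation:
    """One cell's observed (total alleles, active TSs, total mature mRNA count)."""

    cell_id: str
    K: int
    k: int
    m: int

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not (0 <= self.k <= self.K):
            raise ValueError("require 0 <= k <= K")
        if self.m < 0:
            raise ValueError("m must be >= 0")


@dataclass(frozen=True)
class PmfTruncation:
    """Truncation policy for the infinite count support."""

    m_max: int
    tail_tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.m_max < 1:
            raise ValueError("m_max must be >= 1")
        if not (0 < self.tail_tol <= 1e-6):
            raise ValueError("tail_tol must lie in (0, 1e-6]")


def active_fraction(params: TelegraphParams) -> float:
    """Stationary probability f = lam/(lam+gam) that a promoter is ON."""
    return params.lam / (params.lam + params.gam)


def kummer_m(a: float, b: float, x: float) -> float:
    """Kummer's confluent hypergeometric function M(a, b, x).

    For negative arguments the Kummer transformation
    ``M(a, b, x) = e^x M(b - a, b, -x)`` is applied so that the underlying
    series has all-positive terms (every in-model call has argument
    ``-mu/delta < 0``, where the direct series suffers catastrophic
    cancellation).
    """
    if b <= 0 and float(b).is_integer():
        raise ValueError("b must not be a non-positive integer")
    if x < 0:
        val = math.exp(x) * float(special.hyp1f1(b - a, b, -x))
    else:
        val = float(special.hyp1f1(a, b, x))
    if not np.isfinite(val):
        raise KummerError(f"M({a}, {b}, {x}) did not evaluate to a finite value: {val}")
    return val


def _log_hyp1f1_series(a: float, b_arr: np.ndarray, x: float) -> np.ndarray:
    """log M(a, b, x) by log-domain summation of the all-positive series (x > 0)."""
    if x > 1e5:
        raise KummerError(f"hyp1f1 argument {x} beyond the series budget")
    n_terms = int(x + 20.0 * math.sqrt(x) + 60)
    j = np.arange(n_terms, dtype=float)
    log_num = special.gammaln(a + j) - special.gammaln(a) + j * np.log(x) - special.gammaln(j + 1)
    b_col = np.atleast_1d(b_arr)[:, None]
    log_terms = log_num[None, :] - (special.gammaln(b_col + j[None, :]) - special.gammaln(b_col))
    return special.logsumexp(log_terms, axis=1)


def _log_hyp1f1_pos(a: float, b_arr: np.ndarray, x: float) -> np.ndarray:
    """log M(a, b, x) for x >= 0, scalar a, vector b (all-positive series).

    scipy's hyp1f1 is used where it stays finite; entries that overflow
    (x beyond ~700) fall back to log-domain series summation.
    """
    if x > 1e4:
        # far beyond the truncation budget; also keeps scipy's hyp1f1 out of
        # its slow/non-terminating large-argument regime
        raise KummerError(f"hyp1f1 argument {x} beyond the evaluation budget")
    b_arr = np.atleast_1d(np.asarray(b_arr, dtype=float))
    with np.errstate(over="ignore"):
        vals = special.hyp1f1(a, b_arr, x)
    vals = np.atleast_1d(vals)
    bad = ~np.isfinite(vals) | (vals <= 0)
    out = np.empty_like(vals)
    out[~bad] = np.log(vals[~bad])
    if bad.any():
        out[bad] = _log_hyp1f1_series(a, b_arr[bad], x)
    if not np.all(np.isfinite(out)):
        raise KummerError("hyp1f1 produced a non-finite value even in log domain")
    return out


def _log_partial_pmfs(params: TelegraphParams, m_max: int) -> tuple[np.ndarray, np.ndarray]:
    """Log of the partial mass functions p(m) = P(ON, m) and q(m) = P(OFF, m).

    Assembled from log-gamma differences; the Kummer factors are evaluated at
    positive argument via the Kummer transformation:

        p(m) = G(b)G(m+a+1)/[G(a)G(m+b+1)] * M(m+a+1, m+b+1, -rho) * rho^m/m!
        q(m) = (b-a) * G(b)G(m+a)/[G(a)G(m+b+1)] * M(m+a, m+b+1, -rho) * rho^m/m!

    with M(m+a+1, m+b+1, -rho) = e^-rho M(b-a,   m+b+1, rho)
    and  M(m+a,   m+b+1, -rho) = e^-rho M(b-a+1, m+b+1, rho).
    """
    n = params.normalized()
    a, b, rho = n.a, n.b, n.rho
    m = np.arange(m_max + 1, dtype=float)
    base = (
        special.gammaln(b)
        - special.gammaln(a)
        - special.gammaln(m + b + 1)
        + m * np.log(rho)
        - special.gammaln(m + 1)
        - rho
    )
    log_p = base + special.gammaln(m + a + 1) + _log_hyp1f1_pos(b - a, m + b + 1, rho)
    log_q = (
        base
        + math.log(b - a)
        + special.gammaln(m + a)
        + _log_hyp1f1_pos(b - a + 1, m + b + 1, rho)
    )
    return log_p, log_q


@lru_cache(maxsize=64)
def _stationary_arrays(params: TelegraphParams, tail_tol: float) -> tuple[np.ndarray, np.ndarray, int]:
    """(p, q, m_max) with m_max adaptively chosen so the joint tail mass < tail_tol."""
    n = params.normalized()
    mean = active_fraction(params) * n.rho
    m_max = max(16, int(math.ceil(mean + 12.0 * math.sqrt(mean + 1.0) + 0.5 * n.rho)))
    while True:
        m_max = min(m_max, _M_MAX_CAP)
        log_p, log_q = _log_partial_pmfs(params, m_max)
        p, q = np.exp(log_p), np.exp(log_q)
        tail = 1.0 - (p.sum() + q.sum())
        if tail < tail_tol:
            return p, q, m_max
        if m_max >= _M_MAX_CAP:
            raise TruncationError(
                f"tail mass {tail:.3e} above tolerance {tail_tol:.1e} at m_max={m_max}"
            )
        m_max *= 2


def default_truncation(params: TelegraphParams, tail_tol: float = 1e-10) -> PmfTruncation:
    """Smallest power-of-two-grown truncation with joint tail mass below ``tail_tol``."""
    _, _, m_max = _stationary_arrays(params, tail_tol)
    return PmfTruncation(m_max=m_max, tail_tol=tail_tol)


def _pmfs_for(params: TelegraphParams, trunc: PmfTruncation | None) -> tuple[np.ndarray, np.ndarray]:
    if trunc is None:
        p, q, _ = _stationary_arrays(params, 1e-10)
        return p, q
    log_p, log_q = _log_partial_pmfs(params, trunc.m_max)
    p, q = np.exp(log_p), np.exp(log_q)
    tail = 1.0 - (p.sum() + q.sum())
    if tail >= trunc.tail_tol:
        raise TruncationError(
            f"tail mass {tail:.3e} above tolerance {trunc.tail_tol:.1e} at m_max={trunc.m_max}"
        )
    return p, q


def partial_pmf_on(params: TelegraphParams, trunc: PmfTruncation | None = None) -> np.ndarray:
    """Sub-probability vector p(m) = P(X=ON, Y=m), m = 0..m_max; sums to f."""
    return _pmfs_for(params, trunc)[0]


def partial_pmf_off(params: TelegraphParams, trunc: PmfTruncation | None = None) -> np.ndarray:
    """Sub-probability vector q(m) = P(X=OFF, Y=m), m = 0..m_max; sums to 1-f."""
    return _pmfs_for(params, trunc)[1]


def marginal_pmf(params: TelegraphParams, trunc: PmfTruncation | None = None) -> np.ndarray:
    """Marginal stationary count law P(m) = p(m) + q(m) (the beta-Poisson distribution)."""
    p, q = _pmfs_for(params, trunc)
    return p + q


def marginal_pmf_direct(params: TelegraphParams, m_max: int) -> np.ndarray:
    """Beta-Poisson marginal via the independent closed form.

    P(m) = (a)_m/(b)_m * rho^m/m! * M(a+m, b+m, -rho).  This route does not
    pass through the partial mass functions and is used as a cross-check.
    """
    n = params.normalized()
    a, b, rho = n.a, n.b, n.rho
    m = np.arange(m_max + 1, dtype=float)
    log_P = (
        special.gammaln(a + m)
        - special.gammaln(a)
        - special.gammaln(b + m)
        + special.gammaln(b)
        + m * np.log(rho)
        - special.gammaln(m + 1)
        - rho
        + _log_hyp1f1_pos(b - a, b + m, rho)
    )
    return np.exp(log_P)


def polyploid_joint_pmf(
    params: TelegraphParams,
    K: int,
    trunc: PmfTruncation | None = None,
    full_support: bool = False,
) -> np.ndarray:
    """Joint stationary law of (k active alleles, total mRNA m) for K alleles.

    Entry ``(k, m)`` is ``C(K, k) * (p^{*k} conv q^{*(K-k)})(m)`` where ``*k``
    denotes k-fold self-convolution (the 0-fold convolution is a unit mass at
    m = 0). With ``full_support`` the returned matrix spans m = 0..K*m_max
    (the exact support of the convolved truncated arrays); otherwise it is cut
    at m_max columns.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    p, q = _pmfs_for(params, trunc)
    m_max = len(p) - 1
    if K * (m_max + 1) > 5_000_000:
        raise TruncationError(f"K*m_max = {K * m_max} exceeds the convolution array budget")

    def convpow(x: np.ndarray, n: int) -> np.ndarray:
        out = np.ones(1)
        for _ in range(n):
            out = np.convolve(out, x)
        return out

    width = K * m_max + 1 if full_support else m_max + 1
    joint = np.zeros((K + 1, width))
    for k in range(K + 1):
        row = np.convolve(convpow(p, k), convpow(q, K - k))
        joint[k, : min(width, len(row))] = row[:width]
        joint[k] *= math.comb(K, k)
    return joint


def _build_generator(params: TelegraphParams, K: int, m_max: int) -> np.ndarray:
    """Dense generator of the aggregated (k, m) chain on the truncated state space.

    For K exchangeable alleles the pair (number of ON alleles, total RNA) is
    itself Markov: activation k->k+1 at rate (K-k)*lam, deactivation k->k-1 at
    rate k*gam, birth m->m+1 at rate k*mu, death m->m-1 at rate m*delta.
    Births out of m = m_max are suppressed (truncation).
    """
    n_m = m_max + 1
    n_states = (K + 1) * n_m
    Q = np.zeros((n_states, n_states))
    idx = lambda k, m: k * n_m + m  # noqa: E731
    for k in range(K + 1):
        for m in range(n_m):
            i = idx(k, m)
            if k < K:
                Q[i, idx(k + 1, m)] += (K - k) * params.lam
            if k > 0:
                Q[i, idx(k - 1, m)] += k * params.gam
            if m < m_max:
                Q[i, idx(k, m + 1)] += k * params.mu
            if m > 0:
                Q[i, idx(k, m - 1)] += m * params.delta
            Q[i, i] = -Q[i].sum()
    return Q


def cme_stationary_oracle(
    params: TelegraphParams, K: int, m_max: int, residual_tol: float = 1e-10
) -> np.ndarray:
    """Brute-force stationary law of the truncated K-allele chemical master equation.

    Solves pi @ Q = 0 with sum(pi) = 1 as a dense linear system and returns the
    distribution reshaped to a (K+1, m_max+1) matrix over (k, m). Independent
    of every closed form above, hence usable as ground truth.
    """
    if K < 1 or m_max < 1:
        raise ValueError("require K >= 1 and m_max >= 1")
    if (K + 1) * (m_max + 1) > 5000:
        raise ValueError("state space too large for the dense oracle solve")
    Q = _build_generator(params, K, m_max)
    n = Q.shape[0]
    A = Q.T.copy()
    A[-1, :] = 1.0  # replace one balance equation by the normalization
    rhs = np.zeros(n)
    rhs[-1] = 1.0
    try:
        pi = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(f"stationary solve failed: {err}") from err
    scale = max(abs(params.lam) * K, abs(params.gam) * K, params.mu * K, params.delta * m_max)
    residual = np.abs(pi @ Q).max() / scale
    if not np.isfinite(residual) or residual > residual_tol:
        raise np.linalg.LinAlgError(f"balance-equation residual {residual:.2e} above {residual_tol:.0e}")
    return pi.reshape(K + 1, m_max + 1)
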