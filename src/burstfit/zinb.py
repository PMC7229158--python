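"""Steady-state count distribution of the three-state bursting promoter.

A promoter switching between a deep inactive state C, a primed inactive
state B and an active state A (transcribing at rate K, mRNA decaying at
rate delta) has, when C<->B switching is slow compared with B<->A, a
steady-state mRNA copy-number distribution well approximated by a
zero-inflated negative binomial (ZINB):

    P(0) = omega + (1 - omega) * (1 - p)**r
    P(n) = (1 - omega) * C(n + r - 1, n) * (1 - p)**r * p**n,   n > 0

where omega is the stationary fraction of time (and of cells) in the deep
inactive state, r = lambda/delta is the burst frequency and
p/(1 - p) = K/nu is the mean burst size.  All rates are expressed in units
of the mRNA decay rate delta.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "ZINBParams",
    "BurstModelParams",
    "BurstKinetics",
    "zinb_log_pmf",
    "zinb_pmf_vector",
    "zinb_moments",
    "zinb_tail_length",
    "mechanistic_to_statistical",
    "mechanistic_to_statistical_literal",
    "statistical_to_kinetics",
]

#: Hard cap on the support length used by summation oracles.
TAIL_CAP = 10**6


class ParameterError(ValueError):
    """Raised when a parameter lies outside its mathematical domain."""


@dataclass(frozen=True)
class ZINBParams:
    """Statistical parameters (omega, r, p) of the ZINB steady state.

    omega : fraction of cells in the deep inactive state, in [0, 1]
    r     : negative-binomial shape = burst frequency lambda/delta, > 0
    p     : negative-binomial success parameter of the p**n term, in (0, 1)
    """

    omega: float
    r: float
    p: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.omega <= 1.0):
            raise ParameterError(f"omega must lie in [0, 1], got {self.omega}")
        if not (self.r > 0.0):
            raise ParameterError(f"r must be positive, got {self.r}")
        if not (0.0 < self.p < 1.0):
            raise ParameterError(f"p must lie in (0, 1), got {self.p}")

    def as_array(self) -> np.ndarray:
        return np.array([self.omega, self.r, self.p])


@dataclass(frozen=True)
class BurstModelParams:
    """Mechanistic rates of the three-state promoter model.

    All rates are in units of the mRNA decay rate ``delta`` (default 1):
    alpha (C->B), beta (B->C), lam (B->A), nu (A->B), K (transcription in A).
    ``delta`` is kept explicit so simulated time stays interpretable.
    """

    alpha: float
    beta: float
    lam: float
    nu: float
    K: float
    delta: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "lam", "nu", "K"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if not (self.delta > 0):
            raise ParameterError("delta must be positive")


@dataclass(frozen=True)
class BurstKinetics:
    """Burst kinetics: frequency lambda/delta, size K/nu, deep-inactive omega."""

    burst_frequency: float
    burst_size: float
    omega: float


def _validate_count(n) -> None:
    if np.any(np.asarray(n) < 0):
        raise ValueError("counts must be non-negative")


def zinb_log_pmf(params: ZINBParams, n) -> np.ndarray | float:
    """Log-probability of observing ``n`` mRNAs under the ZINB model.

    Evaluated in log space via log-gamma so that counts up to at least 1e4
    neither overflow nor underflow.  ``n`` may be a scalar or array of
    non-negative integers.  Accepts the degenerate boundary omega = 1
    (all mass at zero), in which case positive counts get -inf.
    """
    _validate_count(n)
    n_arr = np.asarray(n, dtype=np.int64)
    scalar = n_arr.ndim == 0
    n_arr = np.atleast_1d(n_arr)

    omega, r, p = params.omega, params.r, params.p
    log1m_p = math.log1p(-p)
    out = np.empty(n_arr.shape, dtype=float)

    zero = n_arr == 0
    # P(0) = omega + (1 - omega) (1 - p)^r, assembled stably in log space
    log_nb0 = r * log1m_p
    if omega == 0.0:
        out[zero] = log_nb0
    elif omega == 1.0:
        out[zero] = 0.0
    else:
        out[zero] = np.logaddexp(math.log(omega), math.log1p(-omega) + log_nb0)

    pos = ~zero
    if np.any(pos):
        if omega == 1.0:
            out[pos] = -np.inf
        else:
            npos = n_arr[pos].astype(float)
            log_coeff = gammaln(npos + r) - gammaln(r) - gammaln(npos + 1.0)
            out[pos] = (
                math.log1p(-omega)
                + log_coeff
                + r * log1m_p
                + npos * math.log(p)
            )
    return float(out[0]) if scalar else out


def zinb_pmf_vector(params: ZINBParams, n_max: int) -> np.ndarray:
    """Tabulate P(n) for n = 0..n_max."""
    if n_max < 0:
        raise ValueError("n_max must be non-negative")
    return np.exp(zinb_log_pmf(params, np.arange(n_max + 1)))


def zinb_tail_length(params: ZINBParams, tail_mass: float = 1e-12) -> int:
    """Smallest N with cumulative mass >= 1 - tail_mass, capped at TAIL_CAP.

    Used by summation oracles; raises if the cap is hit before the tail
    bound is reached.
    """
    omega, r, p = params.omega, params.r, params.p
    if omega == 1.0:
        return 0
    # the tail beyond N is (1-omega) * P(NB(r, p) > N); the survival
    # function avoids the cancellation a naive pmf summation would incur
    from scipy.stats import nbinom

    dist = nbinom(r, 1.0 - p)
    # start from a moment-based guess, then extend geometrically
    b = p / (1.0 - p)
    n = max(16, int(10 * r * b))
    while n <= TAIL_CAP:
        if (1.0 - omega) * dist.sf(n) < tail_mass:
            return n
        n *= 2
    raise RuntimeError(f"tail bound {tail_mass} not reached below cap {TAIL_CAP}")


def zinb_moments(params: ZINBParams) -> tuple[float, float]:
    """Closed-form (mean, variance) of the ZINB distribution.

    With b = p/(1-p):
        mean = (1 - omega) r b
        var  = (1 - omega) r b (1 + b) + omega (1 - omega) (r b)^2
    """
    omega, r, p = params.omega, params.r, params.p
    b = p / (1.0 - p)
    rb = r * b
    mean = (1.0 - omega) * rb
    var = (1.0 - omega) * rb * (1.0 + b) + omega * (1.0 - omega) * rb**2
    return mean, var


def mechanistic_to_statistical(rates: BurstModelParams) -> ZINBParams:
    """Map three-state rates to ZINB parameters.

    omega = beta/(alpha+beta); r = lam/delta; p = K/(nu+K), so that the
    mean burst size p/(1-p) equals K/nu and the model mean is
    (1-omega) * (lam/delta) * (K/nu).
    """
    if rates.alpha + rates.beta == 0:
        raise ParameterError("alpha = beta = 0: deep-inactive occupancy undefined")
    if rates.nu + rates.K == 0:
        raise ParameterError("nu = K = 0: p undefined")
    omega = rates.beta / (rates.alpha + rates.beta)
    r = rates.lam / rates.delta
    p = rates.K / (rates.nu + rates.K)
    return ZINBParams(omega=omega, r=r, p=p)


def mechanistic_to_statistical_literal(rates: BurstModelParams) -> ZINBParams:
    """Alternative convention with p = nu/(nu+K).

    Under this reading the mean burst size is (1-p)/p rather than p/(1-p);
    provided for sensitivity checks against the default convention.
    """
    if rates.alpha + rates.beta == 0:
        raise ParameterError("alpha = beta = 0: deep-inactive occupancy undefined")
    if rates.nu + rates.K == 0:
        raise ParameterError("nu = K = 0: p undefined")
    omega = rates.beta / (rates.alpha + rates.beta)
    r = rates.lam / rates.delta
    p = rates.nu / (rates.nu + rates.K)
    return ZINBParams(omega=omega, r=r, p=p)


def statistical_to_kinetics(params: ZINBParams) -> BurstKinetics:
    """Burst frequency (= r), burst size (= p/(1-p)) and omega."""
    if params.p >= 1.0:
        raise ParameterError("p = 1 implies infinite burst size")
    return BurstKinetics(
        burst_frequency=params.r,
        burst_size=params.p / (1.0 - params.p),
        omega=params.omega,
    )
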