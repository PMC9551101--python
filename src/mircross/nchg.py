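"""Hypergeometric and Fisher's noncentral hypergeometric distributions.

This is the statistical kernel of the package.  The central hypergeometric
distribution models the overlap of two gene sets drawn from a common
universe (the classical two-colour urn); Fisher's noncentral variant adds
an odds parameter ``omega`` that biases the draw toward the "success"
colour, which downstream code uses to weight gene overlaps by target
prediction scores.

Two numeric paths are provided:

* a production path in log-space floating point, stable for population
  sizes into the tens of thousands;
* an exact path over rational numbers (:mod:`fractions`), intended as an
  independent oracle for small populations (``N`` up to a few hundred) —
  tests cross-check the floating-point path against it.

All tail probabilities are the *upper* tail ``P(X >= k)``: every consumer
of this module asks an enrichment question, never a depletion one.
A pmf evaluated outside the support returns 0 rather than raising, so tail
sums are total functions of ``k``.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb, exp, log

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import hypergeom as _scipy_hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "HypergeomParams",
    "NoncentralParams",
    "PValueVector",
    "hypergeom_pmf",
    "hypergeom_cdf",
    "hypergeom_sf",
    "fnch_pmf",
    "fnch_sf",
    "bh_adjust",
    "hypergeom_pmf_exact",
    "hypergeom_sf_exact",
    "fnch_pmf_exact",
    "fnch_sf_exact",
]


@dataclass(frozen=True)
class HypergeomParams:
    """Urn parameters for a two-colour draw without replacement.

    N
        Population size (e.g. genes in the background universe).
    K
        Number of "success" items in the population (e.g. disease genes).
    n
        Draw size (e.g. a miRNA's predicted target count).
    k
        Observed overlap between the draw and the success items.
    """

    N: int
    K: int
    n: int
    k: int

    def __post_init__(self) -> None:
        if not (0 <= self.K <= self.N):
            raise ValueError(f"require 0 <= K <= N, got K={self.K}, N={self.N}")
        if not (0 <= self.n <= self.N):
            raise ValueError(f"require 0 <= n <= N, got n={self.n}, N={self.N}")

    @property
    def support_min(self) -> int:
        return max(0, self.n + self.K - self.N)

    @property
    def support_max(self) -> int:
        return min(self.n, self.K)

    def in_support(self) -> bool:
        return self.support_min <= self.k <= self.support_max


@dataclass(frozen=True)
class NoncentralParams:
    """Fisher's noncentral urn: central parameters plus an odds ``omega``.

    ``omega > 1`` biases the draw toward success items, ``omega = 1``
    recovers the central hypergeometric distribution exactly.
    """

    base: HypergeomParams
    omega: float

    def __post_init__(self) -> None:
        if not self.omega > 0:
            raise ValueError(f"omega must be > 0, got {self.omega}")


@dataclass(frozen=True)
class PValueVector:
    """Raw p-values paired with their BH step-up adjusted counterparts."""

    raw: tuple[float, ...]
    adjusted: tuple[float, ...]


# ---------------------------------------------------------------------------
# central hypergeometric (delegates to scipy; exact path below)
# ---------------------------------------------------------------------------

def hypergeom_pmf(p: HypergeomParams) -> float:
    """P(X = k) for the central hypergeometric urn; 0 outside the support."""
    if not p.in_support():
        return 0.0
    return float(_scipy_hypergeom.pmf(p.k, p.N, p.K, p.n))


def hypergeom_cdf(p: HypergeomParams) -> float:
    """P(X <= k)."""
    if p.k < p.support_min:
        return 0.0
    if p.k >= p.support_max:
        return 1.0
    return float(_scipy_hypergeom.cdf(p.k, p.N, p.K, p.n))


def hypergeom_sf(p: HypergeomParams) -> float:
    """Upper tail P(X >= k); equals 1 at the support minimum."""
    if p.k <= p.support_min:
        return 1.0
    if p.k > p.support_max:
        return 0.0
    # scipy's sf is P(X > k), so shift by one.
    return float(_scipy_hypergeom.sf(p.k - 1, p.N, p.K, p.n))


# ---------------------------------------------------------------------------
# Fisher's noncentral hypergeometric, log-space
# ---------------------------------------------------------------------------

def _log_binom(a: int, b: np.ndarray) -> np.ndarray:
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def _fnch_log_weights(p: NoncentralParams) -> tuple[np.ndarray, np.ndarray]:
    """Unnormalised log weights over the support of the noncentral urn."""
    base = p.base
    j = np.arange(base.support_min, base.support_max + 1)
    lw = (
        _log_binom(base.K, j)
        + _log_binom(base.N - base.K, base.n - j)
        + j * log(p.omega)
    )
    return j, lw


def fnch_pmf(p: NoncentralParams) -> float:
    """Fisher's noncentral hypergeometric mass at ``k``.

    C(K,k) C(N-K,n-k) omega^k, normalised over the support.  Accumulated
    in log-space so the normalising sum is stable for large populations.
    """
    base = p.base
    if not base.in_support():
        return 0.0
    j, lw = _fnch_log_weights(p)
    return float(exp(lw[j == base.k][0] - logsumexp(lw)))


def fnch_sf(p: NoncentralParams) -> float:
    """Upper tail P(X >= k) of Fisher's noncentral distribution."""
    base = p.base
    if base.k <= base.support_min:
        return 1.0
    if base.k > base.support_max:
        return 0.0
    j, lw = _fnch_log_weights(p)
    return float(exp(logsumexp(lw[j >= base.k]) - logsumexp(lw)))


# ---------------------------------------------------------------------------
# exact rational oracle (small N)
# ---------------------------------------------------------------------------

def hypergeom_pmf_exact(p: HypergeomParams) -> Fraction:
    if not p.in_support():
        return Fraction(0)
    return Fraction(comb(p.K, p.k) * comb(p.N - p.K, p.n - p.k), comb(p.N, p.n))


def hypergeom_sf_exact(p: HypergeomParams) -> Fraction:
    total = Fraction(0)
    for j in range(max(p.k, p.support_min), p.support_max + 1):
        total += hypergeom_pmf_exact(HypergeomParams(p.N, p.K, p.n, j))
    if p.k <= p.support_min:
        return Fraction(1)
    return total


def _fnch_exact_weights(base: HypergeomParams, omega: Fraction) -> dict[int, Fraction]:
    return {
        j: comb(base.K, j) * comb(base.N - base.K, base.n - j) * omega**j
        for j in range(base.support_min, base.support_max + 1)
    }


def fnch_pmf_exact(p: NoncentralParams) -> Fraction:
    """Exact rational noncentral mass; ``omega`` is coerced via Fraction.

    Floats are converted to their exact binary value, so the oracle
    computes the distribution for precisely the omega the float path saw.
    """
    base = p.base
    if not base.in_support():
        return Fraction(0)
    omega = Fraction(p.omega)
    w = _fnch_exact_weights(base, omega)
    return w[base.k] / sum(w.values())


def fnch_sf_exact(p: NoncentralParams) -> Fraction:
    base = p.base
    if base.k <= base.support_min:
        return Fraction(1)
    if base.k > base.support_max:
        return Fraction(0)
    omega = Fraction(p.omega)
    w = _fnch_exact_weights(base, omega)
    upper = sum(v for j, v in w.items() if j >= base.k)
    return upper / sum(w.values())


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_adjust(raw) -> PValueVector:
    """Benjamini-Hochberg step-up adjustment, order-preserving.

    Raises ``ValueError`` for p-values outside [0, 1].
    """
    arr = np.asarray(list(raw), dtype=float)
    if arr.size == 0:
        return PValueVector(raw=(), adjusted=())
    if np.any(np.isnan(arr)) or np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("p-values must lie in [0, 1]")
    adjusted = multipletests(arr, method="fdr_bh")[1]
    return PValueVector(raw=tuple(arr.tolist()), adjusted=tuple(adjusted.tolist()))
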