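"""Hybrid head/tail degree-distribution models and their maximum likelihood.

A candidate degree model keeps the empirical relative frequencies for the
low-degree "head" (degrees ``k <= k_c``) and a parametric decay function
``F(k)`` for the tail::

    Pr(k) = A_k                       for k = 1, ..., k_c
    Pr(k) = c * F(k)                  for k > k_c

with ``c`` fixed by normalization, ``c = (1 - sum_i A_i) / sum_{k>k_c} F(k)``.
Six tail families are implemented:

========  ====================================  ==========================
family    F(k)                                  shape parameters
========  ====================================  ==========================
EXP       exp(-alpha*k)                         alpha > 0
POW       alpha^beta * (k+alpha)^-beta          alpha > 0, beta > 1
LGN       Phi_c((ln k - mu)/s)                  mu real, s > 0
WBL       exp(-alpha * k^beta)                  alpha > 0, beta > 0
TPW       alpha^beta (k+alpha)^-beta e^-gamma k alpha > 0, beta > 0, gamma > 0
GWB       exp[alpha(gamma^beta - (k+gamma)^beta)]  alpha, beta > 0,
                                                    gamma > -(k_c+1)
========  ====================================  ==========================

``Phi_c`` is the complementary standard normal distribution function.  The
head probabilities are maximized in closed form (``A_k = n_k / N``); the tail
shape parameters are maximized numerically.  All log-likelihoods are in nats.

For GWB with ``gamma <= 0`` the constant factor ``exp(alpha*gamma^beta)`` is
undefined in real arithmetic; being k-independent it cancels in the
normalized pmf, so it is dropped on that branch (the tail is then simply
``exp(-alpha*(k+gamma)^beta)`` on the support ``k + gamma > 0``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
from scipy import integrate, optimize, special, stats

from .graph_core import DegreeHistogram

__all__ = [
    "FAMILIES",
    "DegreeModelSpec",
    "TailModelFit",
    "tail_function",
    "log_tail_function",
    "log_tail_sum",
    "build_pmf",
    "head_mle",
    "log_likelihood",
    "entropy_bound",
    "fit_tail_mle",
    "ols_tail_diagnostic",
]

FAMILIES = ("EXP", "POW", "LGN", "WBL", "TPW", "GWB")

_N_SHAPE = {"EXP": 1, "POW": 2, "LGN": 2, "WBL": 2, "TPW": 3, "GWB": 3}

#: relative remainder at which infinite tail sums are truncated
TAIL_SUM_RTOL = 1e-12
#: mass left outside the finite pmf support chosen automatically (kept at
#: half the documented 1e-9 normalization contract to leave numeric margin)
PMF_SUPPORT_TOL = 5e-10
#: hard cap on the pmf/tail-sum support, to bound memory on pathological shapes
MAX_SUPPORT = 50_000_000

# ---------------------------------------------------------------------------
# Model specification


@dataclass
class DegreeModelSpec:
    """One hybrid degree model: family tag, cutoff, head and tail shape.

    ``head`` holds ``A_1 .. A_{k_c}``; ``shape`` maps parameter names to
    values (``alpha``/``beta``/``gamma``, or ``mu``/``s`` for LGN).
    ``support_max`` truncates sampling; ``None`` means "choose automatically
    so that the truncated mass is below ``PMF_SUPPORT_TOL``".
    """

    family: str
    k_c: int = 0
    head: np.ndarray = field(default_factory=lambda: np.zeros(0))
    shape: dict[str, float] = field(default_factory=dict)
    support_max: int | None = None

    def __post_init__(self) -> None:
        self.head = np.asarray(self.head, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.k_c < 0:
            raise ValueError("k_c must be nonnegative")
        if self.head.size != self.k_c:
            raise ValueError(
                f"head must have length k_c={self.k_c}, got {self.head.size}")
        if self.head.size and (self.head.min() < 0 or self.head.max() > 1):
            raise ValueError("head probabilities must lie in [0, 1]")
        if self.head.sum() > 1 + 1e-12:
            raise ValueError("head probabilities sum to more than 1")
        s = self.shape
        fam = self.family
        if fam == "LGN":
            if s.get("s", 0.0) <= 0:
                raise ValueError("LGN requires s > 0")
        else:
            if s.get("alpha", 0.0) <= 0:
                raise ValueError(f"{fam} requires alpha > 0")
            if fam != "EXP" and s.get("beta", 0.0) <= 0:
                raise ValueError(f"{fam} requires beta > 0")
        if fam == "POW" and s["beta"] <= 1:
            raise ValueError("POW tail requires beta > 1 for summability")
        if fam == "TPW" and s.get("gamma", 0.0) <= 0:
            raise ValueError("TPW requires gamma > 0")
        if fam == "GWB" and s["gamma"] <= -(self.k_c + 1):
            raise ValueError("GWB requires gamma > -(k_c + 1)")

    @property
    def head_mass(self) -> float:
        return float(self.head.sum())


# ---------------------------------------------------------------------------
# Tail functions (linear and log space)


def log_tail_function(family: str, shape: dict[str, float],
                      k: np.ndarray | float) -> np.ndarray:
    """``ln F(k)`` for the given family, vectorized over ``k``."""
    k = np.asarray(k, dtype=float)
    if family == "EXP":
        return -shape["alpha"] * k
    if family == "POW":
        a, b = shape["alpha"], shape["beta"]
        return b * math.log(a) - b * np.log(k + a)
    if family == "LGN":
        mu, s = shape["mu"], shape["s"]
        with np.errstate(divide="ignore"):
            z = (np.log(k) - mu) / s
        return stats.norm.logsf(z)
    if family == "WBL":
        a, b = shape["alpha"], shape["beta"]
        return -a * np.power(k, b)
    if family == "TPW":
        a, b, g = shape["alpha"], shape["beta"], shape["gamma"]
        return b * math.log(a) - b * np.log(k + a) - g * k
    if family == "GWB":
        a, b, g = shape["alpha"], shape["beta"], shape["gamma"]
        if np.any(k + g <= 0):
            raise ValueError("GWB is undefined where k + gamma <= 0")
        if g > 0:
            # alpha*(g^b - (k+g)^b) = -alpha*g^b*expm1(b*log1p(k/g)),
            # robust when g >> k (the direct difference cancels)
            return -a * g ** b * np.expm1(b * np.log1p(k / g))
        return -a * np.power(k + g, b)
    raise ValueError(f"unknown family {family!r}")


def tail_function(family: str, shape: dict[str, float],
                  k: np.ndarray | float) -> np.ndarray:
    """``F(k)`` itself (see module docstring for the six families)."""
    return np.exp(log_tail_function(family, shape, k))


# -- infinite tail sums -----------------------------------------------------


def _log_remainder_bound(family: str, shape: dict[str, float], K: int) -> float:
    """Upper bound on ``ln sum_{k >= K} F(k)`` (monotone-tail bounds)."""
    if K > MAX_SUPPORT:
        return -np.inf
    if family == "EXP":
        a = shape["alpha"]
        return -a * K - math.log(-math.expm1(-a))
    if family == "POW":
        a, b = shape["alpha"], shape["beta"]
        # exact via Hurwitz zeta: sum_{k>=K} (k+a)^-b = zeta(b, K+a)
        return b * math.log(a) + math.log(special.zeta(b, K + a))
    if family == "TPW":
        a, b, g = shape["alpha"], shape["beta"], shape["gamma"]
        # geometric domination: F(k+1)/F(k) <= e^-gamma for beta > 0
        logF = b * math.log(a) - b * math.log(K + a) - g * K
        return logF - math.log(-math.expm1(-g))
    if family in ("WBL", "GWB"):
        a, b = shape["alpha"], shape["beta"]
        g = shape.get("gamma", 0.0) if family == "GWB" else 0.0
        # sum_{k>=K} f(k) <= f(K) + int_K^inf f  (f decreasing)
        lf = float(log_tail_function(family, shape, float(K)))
        return float(np.logaddexp(
            lf, _log_integral_tail(family, shape, float(K))))
    if family == "LGN":
        mu, s = shape["mu"], shape["s"]
        X = max(K - 1, 1)
        z = (math.log(X) - mu) / s
        val = math.exp(mu + 0.5 * s * s) * stats.norm.sf(z - s) - X * stats.norm.sf(z)
        if val <= 0:
            # cancellation: fall back to a crude but safe N-term bound
            return float(log_tail_function(family, shape, K)) + math.log(1e6)
        return math.log(val)
    raise ValueError(f"unknown family {family!r}")


#: log-slope below which the tail sum switches to the Euler-Maclaurin form
_EM_SLOPE = 0.01


def _log_slope(family: str, shape: dict[str, float], k: float) -> float:
    """``-d ln F / dk`` at k (the local decay rate of the tail)."""
    if family in ("WBL", "GWB"):
        a, b = shape["alpha"], shape["beta"]
        g = shape.get("gamma", 0.0)
        return a * b * (k + g) ** (b - 1.0)
    if family == "TPW":
        a, b, g = shape["alpha"], shape["beta"], shape["gamma"]
        return b / (k + a) + g
    if family == "LGN":
        mu, s = shape["mu"], shape["s"]
        z = (math.log(k) - mu) / s
        sf = stats.norm.sf(z)
        if sf <= 0:
            return np.inf
        return stats.norm.pdf(z) / (s * k * sf)
    raise ValueError(family)


def _log_integral_by_quad(family: str, shape: dict[str, float],
                          K: float) -> float:
    """``ln int_K^inf F(x) dx`` as F(K) * integral of the decaying ratio,
    rescaled by the local log-slope so the integrand has O(1) extent."""
    lf_K = float(log_tail_function(family, shape, K))
    s0 = _log_slope(family, shape, K)
    if not np.isfinite(s0) or s0 <= 0:
        return np.nan
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, _ = integrate.quad(
            lambda u: math.exp(float(log_tail_function(family, shape,
                                                       K + u / s0)) - lf_K),
            0.0, np.inf, limit=200)
    if val <= 0 or not np.isfinite(val):
        return -np.inf
    return lf_K - math.log(s0) + math.log(val)


def _log_integral_tail(family: str, shape: dict[str, float],
                       K: float) -> float:
    """``ln int_K^inf F(x) dx`` in closed form, or -inf on underflow."""
    if family in ("WBL", "GWB"):
        a, b = shape["alpha"], shape["beta"]
        g = shape.get("gamma", 0.0) if family == "GWB" else 0.0
        x = a * (K + g) ** b
        if g > 0 and x >= 600.0:
            # the closed form would cancel huge exp(alpha*g^b) factors
            # against an underflowing incomplete gamma; integrate the
            # well-scaled ratio F(K+t)/F(K) instead
            return _log_integral_by_quad(family, shape, K)
        const = a * g ** b if g > 0 else 0.0
        q = special.gammaincc(1.0 / b, x)
        if q <= 0 or not np.isfinite(q):
            return -np.inf
        return (const + special.gammaln(1.0 / b) - math.log(b)
                - math.log(a) / b + math.log(q))
    if family == "TPW":
        a, b, g = shape["alpha"], shape["beta"], shape["gamma"]
        if b >= 1:
            # no closed form for the incomplete gamma of nonpositive order;
            # integrate the ratio F(K+t)/F(K) (smooth, <= 1, decaying)
            lf = b * math.log(a) - b * math.log(K + a) - g * K
            val, _ = integrate.quad(
                lambda t: math.exp(-b * math.log1p(t / (K + a)) - g * t),
                0.0, np.inf)
            return -np.inf if val <= 0 else lf + math.log(val)
        q = special.gammaincc(1.0 - b, g * (K + a))
        if q <= 0 or not np.isfinite(q):
            return -np.inf
        return (b * math.log(a) + g * a + (b - 1.0) * math.log(g)
                + special.gammaln(1.0 - b) + math.log(q))
    if family == "LGN":
        mu, s = shape["mu"], shape["s"]
        z = (math.log(K) - mu) / s
        t1 = mu + 0.5 * s * s + stats.norm.logsf(z - s)
        t2 = math.log(K) + stats.norm.logsf(z)
        if t1 <= t2:
            return np.nan  # cancellation; caller keeps summing
        diff = -math.expm1(t2 - t1)
        if diff <= 0:
            return np.nan
        return t1 + math.log(diff)
    raise ValueError(family)


def _log_remainder_em(family: str, shape: dict[str, float],
                      K: int) -> float | None:
    """Euler-Maclaurin value of ``ln sum_{k >= K} F(k)`` where the tail is
    slowly varying (log-slope below ``_EM_SLOPE``), else None.

    sum_{k>=K} F(k) = int_K^inf F + F(K)/2 - F'(K)/12 + O(F''')
    with relative error ~ slope^4/720 at the switch threshold.
    """
    s = _log_slope(family, shape, K)
    if not (0.0 <= s < _EM_SLOPE):
        return None
    I = _log_integral_tail(family, shape, float(K))
    if math.isnan(I):
        return None  # closed form unavailable or cancelled
    lf = float(log_tail_function(family, shape, float(K)))
    corr = lf + math.log(0.5 + s / 12.0)  # F/2 - F'/12, F' = -s*F
    return float(np.logaddexp(I, corr))


def _block_logsumexp(logs: np.ndarray) -> float:
    m = float(logs.max())
    if not np.isfinite(m):
        return -np.inf
    return m + math.log(float(np.exp(logs - m).sum()))


def log_tail_sum(family: str, shape: dict[str, float], k_start: int) -> float:
    """``ln sum_{k >= k_start} F(k)`` to ``TAIL_SUM_RTOL`` relative accuracy.

    Closed forms are used where available (geometric for EXP, Hurwitz zeta
    for POW); otherwise blocks are summed in log space, switching to an
    Euler-Maclaurin integral form once the tail is slowly varying, or
    stopping when the analytic remainder bound is negligible.
    """
    if k_start < 1:
        raise ValueError("tail support starts at degree 1")
    if family == "EXP":
        a = shape["alpha"]
        return -a * k_start - math.log(-math.expm1(-a))
    if family == "POW":
        a, b = shape["alpha"], shape["beta"]
        return b * math.log(a) + math.log(special.zeta(b, k_start + a))
    if family == "GWB" and shape["gamma"] <= 0 and k_start + shape["gamma"] <= 0:
        raise ValueError("GWB tail support requires k_start + gamma > 0")
    total = -np.inf
    k = k_start
    block = 512
    log_rtol = math.log(TAIL_SUM_RTOL)
    while True:
        rem = _log_remainder_em(family, shape, k)
        if rem is not None:
            return float(np.logaddexp(total, rem))
        ks = np.arange(k, k + block, dtype=float)
        total = float(np.logaddexp(total, _block_logsumexp(
            log_tail_function(family, shape, ks))))
        k += block
        bound = _log_remainder_bound(family, shape, k)
        if bound <= total + log_rtol:
            return total
        if k > MAX_SUPPORT:
            # pathological shape: absorb the bound so the sum is never
            # underestimated (only makes such parameters less likely)
            return float(np.logaddexp(total, bound))
        block = min(block * 2, 1 << 18)


# ---------------------------------------------------------------------------
# The hybrid pmf


def _log_tail_diff(family: str, shape: dict[str, float],
                   ks: np.ndarray) -> np.ndarray:
    """``ln[F(k) - F(k+1)]`` for the survival-difference discretization."""
    lf = log_tail_function(family, shape, ks)
    lf1 = log_tail_function(family, shape, ks + 1.0)
    with np.errstate(divide="ignore"):
        return lf + np.log(-np.expm1(np.minimum(lf1 - lf, -1e-300)))


def build_pmf(spec: DegreeModelSpec, discretization: str = "pmf") -> np.ndarray:
    """Probability vector over degrees ``1 .. support_max``.

    ``Pr(k) = A_k`` for the head and ``c*F(k)`` beyond the cutoff, with the
    normalizing ``c`` computed against the *infinite* tail sum.  When the
    spec does not fix ``support_max`` the support is extended until the
    truncated mass is below ``PMF_SUPPORT_TOL``, so the returned vector sums
    to 1 within that tolerance.

    ``discretization="survival"`` reads ``F`` as a survival function
    instead, ``Pr(k) ∝ F(k) - F(k+1)``; the tail then normalizes in closed
    form by telescoping (``Σ = F(k_c+1)``).  The two readings coincide for
    EXP and converge for slowly varying tails.
    """
    spec.validate()
    if discretization not in ("pmf", "survival"):
        raise ValueError(f"unknown discretization {discretization!r}")
    tail_mass = 1.0 - spec.head_mass
    if tail_mass < -1e-12:
        raise ValueError("head mass exceeds 1")
    k_lo = spec.k_c + 1
    if tail_mass <= 0:
        return spec.head.copy()
    if discretization == "survival":
        log_c = (math.log(tail_mass)
                 - float(log_tail_function(spec.family, spec.shape,
                                           float(k_lo))))
        return _build_pmf_tail(spec, log_c, k_lo,
                               lambda ks: _log_tail_diff(spec.family,
                                                         spec.shape, ks))
    log_c = math.log(tail_mass) - log_tail_sum(spec.family, spec.shape, k_lo)
    return _build_pmf_tail(spec, log_c, k_lo,
                           lambda ks: log_tail_function(spec.family,
                                                        spec.shape, ks))


def _build_pmf_tail(spec: DegreeModelSpec, log_c: float, k_lo: int,
                    log_prob_fn) -> np.ndarray:
    if spec.support_max is not None:
        # explicit truncation: condition on k <= support_max so the vector
        # is a proper (sampling) distribution even when the tail is long
        K = int(spec.support_max)
        if K < k_lo:
            raise ValueError("support_max must reach past the cutoff")
        ks = np.arange(k_lo, K + 1, dtype=float)
        tail = np.exp(log_c + log_prob_fn(ks))
        pmf = np.concatenate([spec.head, tail])
        return pmf / pmf.sum()

    # grow the support until the mass left out is negligible
    chunks = [spec.head]
    acc = spec.head_mass
    k = k_lo
    block = 4096
    while True:
        ks = np.arange(k, k + block, dtype=float)
        probs = np.exp(log_c + log_prob_fn(ks))
        csum = np.cumsum(probs)
        if acc + csum[-1] >= 1.0 - PMF_SUPPORT_TOL:
            stop = int(np.searchsorted(acc + csum, 1.0 - PMF_SUPPORT_TOL)) + 1
            chunks.append(probs[:stop])
            break
        chunks.append(probs)
        acc += float(csum[-1])
        k += block
        if k > MAX_SUPPORT:
            raise ValueError("pmf support exceeds the hard cap; "
                             "tail decays too slowly")
        block = min(block * 2, 1 << 21)
    return np.concatenate(chunks)


# ---------------------------------------------------------------------------
# Likelihood pieces


def head_mle(hist: DegreeHistogram, k_c: int) -> np.ndarray:
    """Maximum-likelihood head: observed relative frequencies ``n_k / N``."""
    if k_c < 0:
        raise ValueError("k_c must be nonnegative")
    A = np.zeros(k_c)
    for k in range(1, k_c + 1):
        A[k - 1] = hist.counts.get(k, 0) / hist.N
    return A


def entropy_bound(hist: DegreeHistogram) -> float:
    """The maximal attainable log-likelihood, ``-N*H`` (saturated model)."""
    return -hist.N * hist.H


def log_likelihood(spec: DegreeModelSpec, hist: DegreeHistogram) -> float:
    """Multiplicity-form log-likelihood ``sum_k n_k ln Pr(k)``.

    Head cells with ``n_k = 0`` contribute zero (``0*ln 0 := 0``).  An
    observed degree with zero model probability yields ``-inf`` (invalid
    fit).
    """
    ks, ns = hist.arrays()
    in_head = ks <= spec.k_c
    total = 0.0
    if in_head.any():
        A = np.zeros(spec.k_c + 1)
        A[1:] = spec.head
        ak = A[ks[in_head]]
        nk = ns[in_head]
        if np.any((nk > 0) & (ak <= 0)):
            return -np.inf
        total += float(np.sum(nk * np.log(np.where(ak > 0, ak, 1.0))))
    tail_ks = ks[~in_head]
    if tail_ks.size:
        tail_mass = 1.0 - spec.head_mass
        if tail_mass <= 0:
            return -np.inf
        if spec.family == "GWB" and tail_ks[0] + spec.shape["gamma"] <= 0:
            return -np.inf
        log_c = (math.log(tail_mass)
                 - log_tail_sum(spec.family, spec.shape, spec.k_c + 1))
        logF = log_tail_function(spec.family, spec.shape, tail_ks.astype(float))
        total += float(np.sum(ns[~in_head] * (log_c + logF)))
    return total


# ---------------------------------------------------------------------------
# Tail MLE


@dataclass
class TailModelFit:
    """One fitted hybrid model with its information-criterion scores."""

    spec: DegreeModelSpec
    logL: float
    K: int
    aicc: float
    bic: float
    converged: bool
    n_obs: int

    @property
    def family(self) -> str:
        return self.spec.family

    @property
    def k_c(self) -> int:
        return self.spec.k_c

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "k_c": self.k_c,
            "shape": dict(self.spec.shape),
            "logL": self.logL,
            "K": self.K,
            "aicc": self.aicc,
            "bic": self.bic,
            "converged": self.converged,
            "n_obs": self.n_obs,
        }


# transformed (unconstrained) coordinates per family -------------------------

def _to_shape(family: str, theta: np.ndarray, k_c: int) -> dict[str, float]:
    t = np.asarray(theta, dtype=float)
    if family == "EXP":
        return {"alpha": math.exp(t[0])}
    if family == "POW":
        return {"alpha": math.exp(t[0]), "beta": 1.0 + math.exp(t[1])}
    if family == "LGN":
        return {"mu": float(t[0]), "s": math.exp(t[1])}
    if family == "WBL":
        return {"alpha": math.exp(t[0]), "beta": math.exp(t[1])}
    if family == "TPW":
        return {"alpha": math.exp(t[0]), "beta": math.exp(t[1]),
                "gamma": math.exp(t[2])}
    if family == "GWB":
        return {"alpha": math.exp(t[0]), "beta": math.exp(t[1]),
                "gamma": (k_c + 1) * math.expm1(t[2])}
    raise ValueError(family)


def _from_shape(family: str, shape: dict[str, float], k_c: int) -> np.ndarray:
    if family == "EXP":
        return np.array([math.log(shape["alpha"])])
    if family == "POW":
        return np.array([math.log(shape["alpha"]),
                         math.log(shape["beta"] - 1.0)])
    if family == "LGN":
        return np.array([shape["mu"], math.log(shape["s"])])
    if family == "WBL":
        return np.array([math.log(shape["alpha"]), math.log(shape["beta"])])
    if family == "TPW":
        return np.array([math.log(shape["alpha"]), math.log(shape["beta"]),
                         math.log(shape["gamma"])])
    if family == "GWB":
        return np.array([math.log(shape["alpha"]), math.log(shape["beta"]),
                         math.log1p(shape["gamma"] / (k_c + 1))])
    raise ValueError(family)


def _start_grid(family: str, k_c: int) -> list[np.ndarray]:
    """Fixed 5-point-per-parameter start grid in transformed coordinates."""
    ln = np.log
    if family == "EXP":
        axes = [ln([0.003, 0.02, 0.1, 0.5, 2.0])]
    elif family == "POW":
        axes = [ln([0.5, 2.0, 10.0, 50.0, 250.0]),
                ln(np.array([1.1, 1.5, 2.0, 3.0, 5.0]) - 1.0)]
    elif family == "LGN":
        axes = [np.array([0.0, 1.0, 2.5, 4.0, 6.0]),
                ln([0.3, 0.7, 1.2, 2.0, 3.0])]
    elif family == "WBL":
        axes = [ln([0.005, 0.05, 0.3, 1.5, 8.0]),
                ln([0.08, 0.2, 0.4, 0.7, 1.0])]
    elif family == "TPW":
        axes = [ln([0.5, 2.0, 10.0, 50.0, 250.0]),
                ln([0.3, 0.8, 1.5, 2.5, 4.0]),
                ln([1e-4, 1e-3, 1e-2, 0.1, 1.0])]
    elif family == "GWB":
        axes = [ln([0.005, 0.05, 0.3, 1.5, 8.0]),
                ln([0.08, 0.2, 0.4, 0.7, 1.0]),
                np.log1p(np.array([-0.5, 0.0, 2.0, 29.0, 299.0]))]
    else:
        raise ValueError(family)
    grids = np.meshgrid(*axes, indexing="ij")
    return [np.array(p) for p in zip(*(g.ravel() for g in grids))]


_NESTED_IN = {"WBL": "EXP", "GWB": "WBL", "TPW": "POW"}


def _nested_start(family: str, hist: DegreeHistogram, k_c: int) -> np.ndarray | None:
    """Warm start at the optimum of the nested subfamily (enforces that the
    richer family's maximized likelihood never falls below the poorer one)."""
    sub = _NESTED_IN.get(family)
    if sub is None:
        return None
    sub_fit = fit_tail_mle(hist, sub, k_c, _nested=False)
    if not sub_fit.converged:
        return None
    s = sub_fit.spec.shape
    if family == "WBL":  # EXP is WBL with beta = 1
        shape = {"alpha": s["alpha"], "beta": 1.0}
    elif family == "GWB":  # WBL is GWB with gamma = 0
        shape = {"alpha": s["alpha"], "beta": s["beta"], "gamma": 1e-12}
    else:  # TPW -> POW with gamma -> 0
        shape = {"alpha": s["alpha"], "beta": s["beta"], "gamma": 1e-12}
    return _from_shape(family, shape, k_c)


def fit_tail_mle(hist: DegreeHistogram, family: str, k_c: int,
                 extra_starts: Sequence[dict] | None = None,
                 n_polish: int = 3, _nested: bool = True) -> TailModelFit:
    """Maximum-likelihood hybrid fit for one family at a fixed cutoff.

    The head is the closed-form empirical MLE; the tail shape is optimized
    by bounded quasi-Newton (L-BFGS-B) in transformed unconstrained
    coordinates.  The objective is evaluated on a fixed 5-point-per-parameter
    start grid (deterministic) and polished from the ``n_polish`` best grid
    points; warm starts from the nested subfamily optimum (EXP ⊂ WBL ⊂ GWB,
    POW ⊂ TPW) and any caller-supplied ``extra_starts`` (shape dicts) are
    added.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    ks, ns = hist.arrays()
    tail_sel = ks > k_c
    tail_ks = ks[tail_sel].astype(float)
    tail_ns = ns[tail_sel].astype(float)
    if tail_ks.size == 0:
        raise ValueError(f"no observations above k_c={k_c}")
    head = head_mle(hist, k_c)
    n_tail = float(tail_ns.sum())
    # constant pieces of logL: head cells + the tail-mass factor
    head_ns = ns[~tail_sel].astype(float)
    const = float(np.sum(head_ns * np.log(head_ns / hist.N)))
    const += n_tail * math.log(n_tail / hist.N)
    k_lo = k_c + 1
    # Gibbs bound on the shape part: no tail can beat the empirical tail
    # frequencies (guards against numeric pathologies in extreme corners)
    gibbs = float(np.sum(tail_ns * np.log(tail_ns / n_tail)))

    def neg_tail_shape_ll(theta: np.ndarray) -> float:
        shape = _to_shape(family, theta, k_c)
        if family == "GWB" and tail_ks[0] + shape["gamma"] <= 0:
            return np.inf
        try:
            with np.errstate(over="ignore", under="ignore"):
                lts = log_tail_sum(family, shape, k_lo)
                logF = log_tail_function(family, shape, tail_ks)
        except (ValueError, OverflowError, FloatingPointError):
            return np.inf
        val = float(np.sum(tail_ns * logF) - n_tail * lts)
        if not np.isfinite(val) or val > gibbs + 1e-6:
            return np.inf
        return -val

    starts = _start_grid(family, k_c)
    grid_vals = np.array([neg_tail_shape_ll(s) for s in starts])
    order = np.argsort(grid_vals)
    chosen = [starts[i] for i in order[:n_polish] if np.isfinite(grid_vals[i])]
    if _nested:
        ws = _nested_start(family, hist, k_c)
        if ws is not None:
            chosen.append(ws)
    for s in (extra_starts or []):
        try:
            chosen.append(_from_shape(family, s, k_c))
        except (ValueError, KeyError):
            pass

    best_theta = None
    best_val = np.inf
    converged = False
    for x0 in chosen:
        v0 = neg_tail_shape_ll(x0)
        if v0 < best_val:
            best_val, best_theta = v0, np.asarray(x0, dtype=float)
        try:
            res = optimize.minimize(neg_tail_shape_ll, x0, method="L-BFGS-B")
        except (ValueError, OverflowError):
            continue
        if np.isfinite(res.fun) and res.fun < best_val:
            best_val, best_theta = float(res.fun), res.x
        if res.success and np.isfinite(res.fun):
            converged = True
    if best_theta is None or not np.isfinite(best_val):
        spec = DegreeModelSpec(family, k_c, head,
                               _to_shape(family, starts[0], k_c))
        return TailModelFit(spec, -np.inf, _count_parameters(family, k_c),
                            np.inf, np.inf, False, hist.N)

    shape = _to_shape(family, best_theta, k_c)
    spec = DegreeModelSpec(family, k_c, head, shape)
    logL = const - best_val if np.isfinite(best_val) else -np.inf
    K = _count_parameters(family, k_c)
    from .model_selection import aicc as _aicc, bic as _bic
    a = _aicc(logL, K, hist.N) if hist.N > K + 1 else np.inf
    b = _bic(logL, K, hist.N)
    return TailModelFit(spec, logL, K, a, b, converged, hist.N)


def _count_parameters(family: str, k_c: int) -> int:
    return k_c + _N_SHAPE[family]


# ---------------------------------------------------------------------------
# Diagnostic stretched-exponential OLS (never used for selection)


class StretchedExpOLS(NamedTuple):
    slope: float
    exponent: float
    intercept: float
    r_squared: float


def ols_tail_diagnostic(hist: DegreeHistogram, k_threshold: int,
                        beta_grid: np.ndarray | None = None) -> StretchedExpOLS:
    """Least-squares line of ``ln Pr(k)`` against ``k^beta`` over a beta grid.

    A quick visual-fit analogue: the best-R² stretched-exponential exponent
    for the empirical tail.  Purely diagnostic — OLS on log-frequencies has
    no inferential power for model selection.
    """
    ks, ns = hist.arrays()
    sel = ks > k_threshold
    ks, ns = ks[sel].astype(float), ns[sel]
    if ks.size < 10:
        raise ValueError("need at least 10 distinct degrees above threshold")
    logp = np.log(ns / hist.N)
    if beta_grid is None:
        beta_grid = np.linspace(0.05, 1.5, 30)
    best = None
    for b in beta_grid:
        x = np.power(ks, b)
        res = stats.linregress(x, logp)
        r2 = res.rvalue ** 2
        if best is None or r2 > best.r_squared:
            best = StretchedExpOLS(float(res.slope), float(b),
                                   float(res.intercept), float(r2))
    return best
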