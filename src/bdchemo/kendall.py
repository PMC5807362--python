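"""Linear birth-death (Kendall) process: exact probabilities, moments, simulation.

A cell population in which every cell independently divides at rate ``lam``
and dies at rate ``mu`` is a linear birth-death process: a community of size
``k`` has aggregate birth and death rates ``k*lam`` and ``k*mu``.  This module
provides the exact transition probability, the closed-form mean/variance of
the count at a fixed follow-up time, the Gaussian moment-matched likelihood
used for inference, and an exact Gillespie simulator that serves as the
ground-truth oracle for everything else.

Follow-up duration convention: chemo-sensitivity assays use a single fixed
follow-up time, so the rates are interpreted per entire experiment duration
and ``t`` defaults to 1 throughout the modelling layer.  The low-level
functions still accept an explicit ``t`` for validation work.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "BDPParams",
    "MomentPair",
    "alpha_beta",
    "transition_probability",
    "moments",
    "dose_moments",
    "experiment_loglik",
    "simulate_bdp",
    "simulate_bdp_batch",
]

# below this |lam - mu|, the removable singularities in alpha/beta and the
# variance are evaluated by their analytic limits
_EQUAL_RATE_TOL = 1e-8


@dataclass(frozen=True)
class BDPParams:
    """Per-cell birth and death rates (per unit follow-up duration)."""

    birth_rate: float
    death_rate: float

    def __post_init__(self) -> None:
        lam, mu = float(self.birth_rate), float(self.death_rate)
        if not (np.isfinite(lam) and np.isfinite(mu)):
            raise ValueError("rates must be finite")
        if lam < 0 or mu < 0:
            raise ValueError(f"rates must be non-negative, got ({lam}, {mu})")


@dataclass(frozen=True)
class MomentPair:
    """Mean and variance of the population count at follow-up."""

    mean: float
    variance: float


def alpha_beta(params: BDPParams, t: float = 1.0) -> tuple[float, float]:
    """Extinction/expansion probabilities of the single-cell offspring law.

    For one founding cell, ``alpha`` is the probability of extinction by time
    ``t`` and ``beta`` governs the geometric tail of the survivor count:

        alpha(t) = mu (e^{(lam-mu)t} - 1) / (lam e^{(lam-mu)t} - mu)
        beta(t)  = lam (e^{(lam-mu)t} - 1) / (lam e^{(lam-mu)t} - mu)

    At ``lam == mu`` both reduce to the analytic limit ``lam t / (1 + lam t)``.
    """
    if t < 0:
        raise ValueError(f"elapsed time must be non-negative, got {t}")
    lam, mu = params.birth_rate, params.death_rate
    if t == 0 or (lam == 0 and mu == 0):
        return 0.0, 0.0
    delta = lam - mu
    if abs(delta) < _EQUAL_RATE_TOL:
        # removable singularity; first-order expansion keeps continuity
        rate = 0.5 * (lam + mu)
        common = rate * t / (1.0 + rate * t)
        return common, common
    expm = np.expm1(delta * t)  # e^{delta t} - 1
    denom = lam * (expm + 1.0) - mu
    alpha = mu * expm / denom
    beta = lam * expm / denom
    # clip tiny negative round-off
    return float(min(max(alpha, 0.0), 1.0)), float(min(max(beta, 0.0), 1.0))


def transition_probability(
    a: int, b: int, params: BDPParams, t: float = 1.0
) -> float:
    """Exact transition probability P(N(t) = b | N(0) = a).

    Evaluated in log space with log-gamma binomial coefficients:

        P_ab(t) = sum_{j=0}^{min(a,b)} C(a,j) C(a+b-j-1, a-1)
                  alpha^{a-j} beta^{b-j} (1-alpha-beta)^j

    This is the validation path, not the inference path: the combinatorial
    sum is impractical at assay scale, which is why inference uses the
    moment-matched Gaussian instead.  ``a == 0`` is treated as absorbing.
    """
    if a < 0 or b < 0:
        raise ValueError("counts must be non-negative")
    if a == 0:
        return 1.0 if b == 0 else 0.0
    alpha, beta = alpha_beta(params, t)
    if b == 0:
        return float(alpha**a)
    # Equivalent all-positive form (avoids the alternating-sign cancellation
    # of the direct combinatorial sum): condition on j, the number of the a
    # founding cells whose lineage survives to time t.  Each survives with
    # probability 1 - alpha; j surviving lineages contribute a negative
    # binomial total, C(b-1, j-1) (1-beta)^j beta^(b-j).
    js = np.arange(1, min(a, b) + 1)
    log_terms = (
        gammaln(a + 1) - gammaln(js + 1) - gammaln(a - js + 1)
        + _log_pow(alpha, a - js)
        + _log_pow(1.0 - alpha, js)
        + gammaln(b) - gammaln(js) - gammaln(b - js + 1)
        + _log_pow(1.0 - beta, js)
        + _log_pow(beta, b - js)
    )
    out = float(np.exp(logsumexp(log_terms)))
    if not np.isfinite(out):
        raise FloatingPointError(
            f"transition probability overflowed for a={a}, b={b}"
        )
    return min(max(out, 0.0), 1.0)


def _log_pow(base: float, exponent):
    """log(base**exponent) elementwise, with 0**0 = 1 (contribution 0)."""
    exponent = np.asarray(exponent)
    if base > 0:
        return exponent * np.log(base)
    return np.where(exponent == 0, 0.0, -np.inf)


def moments(n0: float, params: BDPParams, t: float = 1.0) -> MomentPair:
    """Mean and variance of N(t) given N(0) = n0.

        m_t = n0 e^{(lam-mu)t}
        v_t = n0 (lam+mu)/(lam-mu) e^{(lam-mu)t} (e^{(lam-mu)t} - 1)

    with the analytic limit v_t = n0 (lam+mu) t on the lam == mu line.
    """
    if n0 <= 0:
        raise ValueError(f"initial count must be positive, got {n0}")
    if t < 0:
        raise ValueError(f"elapsed time must be non-negative, got {t}")
    lam, mu = params.birth_rate, params.death_rate
    delta = lam - mu
    m = n0 * np.exp(delta * t)
    if abs(delta) < _EQUAL_RATE_TOL:
        v = n0 * (lam + mu) * t
    else:
        v = n0 * (lam + mu) / delta * np.exp(delta * t) * np.expm1(delta * t)
    return MomentPair(float(m), float(max(v, 0.0)))


def dose_moments(n0, lam, mu):
    """Vectorised mean/variance with the follow-up duration absorbed (t = 1).

    ``lam`` and ``mu`` may be arrays (one entry per dose); returns arrays
    ``(m, v)`` of the same shape.  Handles the lam == mu line elementwise.
    """
    lam = np.asarray(lam, dtype=float)
    mu = np.asarray(mu, dtype=float)
    n0 = np.asarray(n0, dtype=float)
    delta = lam - mu
    with np.errstate(over="ignore", invalid="ignore"):
        m = n0 * np.exp(delta)
        near = np.abs(delta) < _EQUAL_RATE_TOL
        safe_delta = np.where(near, 1.0, delta)
        v_generic = n0 * (lam + mu) / safe_delta * np.exp(delta) * np.expm1(delta)
        v_limit = n0 * (lam + mu)
        v = np.where(near, v_limit, v_generic)
    return m, np.maximum(v, 0.0)


def experiment_loglik(z, n0, x, background, lam_by_dose, mu_by_dose, theta, sigma2):
    """Gaussian moment-matched log-likelihood of one experiment.

    The measured count is modelled as the process count plus additive assay
    noise, X = N + eps with eps ~ Normal(theta, sigma2), giving

        sum_i log phi(x_i | m(n0_i, z_i) + theta, v(n0_i, z_i) + sigma2)
      + sum_j log phi(e_j | theta, sigma2)

    Parameters
    ----------
    z, n0, x : arrays over wells (log10 M dose, known initial count, measured
        count).  Replicate wells repeat the same z.
    background : array of compound-free noise measurements e_1..e_q.
    lam_by_dose, mu_by_dose : dict mapping each distinct dose to its rates,
        or arrays aligned with ``z``.
    """
    if sigma2 <= 0:
        raise ValueError(f"noise variance must be positive, got {sigma2}")
    z = np.asarray(z, dtype=float)
    n0 = np.asarray(n0, dtype=float)
    x = np.asarray(x, dtype=float)
    if isinstance(lam_by_dose, dict):
        try:
            lam = np.array([lam_by_dose[zi] for zi in z])
            mu = np.array([mu_by_dose[zi] for zi in z])
        except KeyError as err:
            raise ValueError(f"no rate entry for dose {err.args[0]}") from err
    else:
        lam = np.asarray(lam_by_dose, dtype=float)
        mu = np.asarray(mu_by_dose, dtype=float)
        if lam.shape != z.shape or mu.shape != z.shape:
            raise ValueError("rate arrays must align with the well doses")
    m, v = dose_moments(n0, lam, mu)
    total_var = v + sigma2
    resid = x - m - theta
    ll = -0.5 * np.sum(np.log(2 * np.pi * total_var) + resid**2 / total_var)
    e = np.asarray(background, dtype=float)
    if e.size:
        ll += -0.5 * np.sum(np.log(2 * np.pi * sigma2) + (e - theta) ** 2 / sigma2)
    return float(ll)


def simulate_bdp(
    n0: int, params: BDPParams, t: float = 1.0, rng=None, cap: int = 10_000_000
) -> int:
    """Exact Gillespie simulation of one trajectory; returns the final count."""
    rng = np.random.default_rng(rng)
    return int(simulate_bdp_batch(n0, params, t, size=1, rng=rng, cap=cap)[0])


def simulate_bdp_batch(
    n0: int,
    params: BDPParams,
    t: float = 1.0,
    size: int = 1,
    rng=None,
    cap: int = 10_000_000,
):
    """Vectorised exact Gillespie simulation of ``size`` independent runs.

    Event-driven: while a run has k > 0 cells and time remains, the waiting
    time to the next event is Exponential(k (lam+mu)) and the event is a
    birth with probability lam/(lam+mu).  Returns an int64 array of final
    counts.  Raises OverflowError if any run exceeds ``cap`` cells.
    """
    if n0 < 0:
        raise ValueError("initial count must be non-negative")
    rng = np.random.default_rng(rng)
    lam, mu = params.birth_rate, params.death_rate
    k = np.full(size, int(n0), dtype=np.int64)
    if n0 == 0 or t == 0 or (lam == 0 and mu == 0):
        return k
    total = lam + mu
    p_birth = lam / total
    clock = np.zeros(size)
    active = np.ones(size, dtype=bool)
    while True:
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        ki = k[idx]
        wait = rng.exponential(1.0, size=idx.size) / (ki * total)
        clock_i = clock[idx] + wait
        fired = clock_i < t
        clock[idx] = clock_i
        hit = idx[fired]
        if hit.size:
            births = rng.random(hit.size) < p_birth
            k[hit] += np.where(births, 1, -1)
        active[idx[~fired]] = False
        dead = k[idx] == 0
        active[idx[dead]] = False
        if np.any(k[idx] > cap):
            raise OverflowError(
                f"population exceeded cap={cap} during simulation"
            )
    return k
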