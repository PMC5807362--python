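"""Posterior reportables: dose-response curves, GI50/TGI/LC50, rate changes.

All summary concentrations follow the standard screening definitions.  With
net growth g(z) = m(n0, z) - n0 and control growth g_c taken at a reference
dose (default: the smallest tested concentration),

* GI50 -- smallest z where g(z) = 0.5 * g_c (half growth inhibition),
* TGI  -- smallest z where m(z) = n0 (total growth inhibition),
* LC50 -- smallest z where m(z) = 0.5 * n0 (half the initial population killed).

Uncertainty is propagated by solving the crossing per posterior draw; the
point estimate is the crossing of the posterior-mean curve.  Draws whose
curve never reaches the threshold inside the tested range are censored and
reported as such rather than extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gp import gp_conditional
from .kendall import dose_moments

__all__ = [
    "DensePosterior",
    "CurveSummary",
    "SummaryStat",
    "first_crossing",
    "predict_rates",
    "curve_summary",
    "summary_concentration",
    "rate_percent_change",
]


def first_crossing(z, y, level):
    """Smallest z where the piecewise-linear curve (z, y) crosses ``level``.

    Returns ``(z_star, n_crossings)``; ``z_star`` is None when the curve
    never attains the level.  Curves may be non-monotone (the GP imposes no
    shape constraint), hence the smallest-crossing rule plus a count of all
    crossings.
    """
    z = np.asarray(z, dtype=float)
    y = np.asarray(y, dtype=float)
    d = y - level
    hits = []
    for i in range(len(z) - 1):
        if d[i] == 0.0:
            hits.append(z[i])
        elif d[i] * d[i + 1] < 0.0:
            frac = d[i] / (d[i] - d[i + 1])
            hits.append(z[i] + frac * (z[i + 1] - z[i]))
    if d[-1] == 0.0:
        hits.append(z[-1])
    if not hits:
        return None, 0
    return float(hits[0]), len(hits)


@dataclass
class DensePosterior:
    """Per-draw birth/death rate curves on a dense log10-concentration grid."""

    z: np.ndarray          # dense grid, includes every tested dose
    lam: np.ndarray        # (n_draws, len(z))
    mu: np.ndarray
    doses: np.ndarray      # the tested doses

    @property
    def n_draws(self) -> int:
        return self.lam.shape[0]

    def mean_curves(self, n0_ref: float):
        m, _ = dose_moments(n0_ref, self.lam, self.mu)
        return m


def predict_rates(draws, z_dense=None, n_grid: int = 100, rng=None) -> DensePosterior:
    """Extend posterior draws from the tested doses to a dense grid.

    For each retained draw, the log rates on the dense grid are sampled from
    the exact GP conditional given that draw's latent values and
    hyperparameters, so dense-grid uncertainty bands are full posterior
    bands, not plug-in interpolations.
    """
    rng = np.random.default_rng(rng)
    doses = np.asarray(draws.doses, dtype=float)
    if z_dense is None:
        z_dense = np.union1d(np.linspace(doses[0], doses[-1], n_grid), doses)
    else:
        z_dense = np.union1d(np.asarray(z_dense, dtype=float), doses)
    n = draws.n_draws
    lam = np.empty((n, z_dense.size))
    mu = np.empty((n, z_dense.size))
    obs_idx = np.searchsorted(z_dense, doses)
    new_mask = np.ones(z_dense.size, dtype=bool)
    new_mask[obs_idx] = False
    z_new = z_dense[new_mask]
    for i in range(n):
        for phi_obs, alpha, tau2, l2, out in (
            (draws.phi_lam[i], draws.alpha_lam[i], draws.tau2_lam[i], draws.l2_lam[i], lam),
            (draws.phi_mu[i], draws.alpha_mu[i], draws.tau2_mu[i], draws.l2_mu[i], mu),
        ):
            full = np.empty(z_dense.size)
            full[obs_idx] = phi_obs
            if z_new.size:
                mean, cov = gp_conditional(doses, phi_obs, z_new, alpha, tau2, l2)
                # sample the conditional; eigen floor guards tiny negatives
                w, V = np.linalg.eigh(cov)
                w = np.clip(w, 0.0, None)
                full[new_mask] = mean + V @ (np.sqrt(w) * rng.standard_normal(w.size))
            out[i] = np.exp(full)
    return DensePosterior(z_dense, lam, mu, doses)


@dataclass
class CurveSummary:
    """Pointwise posterior mean and 95% equal-quantile CI of m, lambda, mu."""

    z: np.ndarray
    m_mean: np.ndarray
    m_lo: np.ndarray
    m_hi: np.ndarray
    lam_mean: np.ndarray
    lam_lo: np.ndarray
    lam_hi: np.ndarray
    mu_mean: np.ndarray
    mu_lo: np.ndarray
    mu_hi: np.ndarray
    n0_ref: float = 1000.0


def curve_summary(dense: DensePosterior, n0_ref: float) -> CurveSummary:
    """Summarise the Kendall-process mean and rate curves over draws."""
    if dense.n_draws < 1:
        raise ValueError("no posterior draws")
    m = dense.mean_curves(n0_ref)
    q = lambda a: np.percentile(a, [2.5, 97.5], axis=0)
    m_lo, m_hi = q(m)
    lam_lo, lam_hi = q(dense.lam)
    mu_lo, mu_hi = q(dense.mu)
    return CurveSummary(
        dense.z,
        m.mean(axis=0), m_lo, m_hi,
        dense.lam.mean(axis=0), lam_lo, lam_hi,
        dense.mu.mean(axis=0), mu_lo, mu_hi,
        n0_ref,
    )


@dataclass
class SummaryStat:
    """A potency concentration with posterior uncertainty and censoring info.

    Concentrations are molar.  ``posterior_mean`` is the crossing of the
    posterior-mean curve; the CI is the 2.5/97.5 percentile of per-draw
    crossings.  ``censor`` refers to the point estimate; draws with no
    in-range crossing are tallied in ``fraction_censored``.
    """

    kind: str
    posterior_mean: float
    ci_low: float
    ci_high: float
    censor: str = "none"                 # none | below_range | above_range
    fraction_censored: float = 0.0
    fraction_multiple_crossings: float = 0.0
    n_draws: int = 0

    @property
    def log10_mean(self) -> float:
        return float(np.log10(self.posterior_mean))


_KINDS = ("GI50", "TGI", "LC50")


def _threshold_level(kind, m_curve, n0_ref, control_idx):
    """Target level of m(z) for a given summary kind; None if undefined."""
    if kind == "TGI":
        return n0_ref
    if kind == "LC50":
        return 0.5 * n0_ref
    g_c = m_curve[control_idx] - n0_ref
    if g_c <= 0:
        return None  # control population not growing: GI50 undefined
    return n0_ref + 0.5 * g_c


def _censor_side(m_curve, level):
    # never attains the level: above_range if the curve stays above it
    return "above_range" if m_curve.min() > level else "below_range"


def summary_concentration(
    dense: DensePosterior,
    kind: str,
    n0_ref: float,
    control_policy: str = "min_dose",
    control_value: float | None = None,
) -> SummaryStat:
    """GI50/TGI/LC50 posterior summary from per-draw crossings.

    ``control_policy`` resolves the reference for GI50's control growth:
    "min_dose" (default, always available) uses the smallest tested
    concentration; "zero_dose" requires ``control_value`` = the mean count
    of dedicated untreated wells.
    """
    if kind not in _KINDS:
        raise ValueError(f"kind must be one of {_KINDS}")
    z = dense.z
    m = dense.mean_curves(n0_ref)
    if control_policy == "min_dose":
        control_idx = int(np.searchsorted(z, dense.doses[0]))
        control_of = lambda curve: curve[control_idx]
    elif control_policy == "zero_dose":
        if control_value is None:
            raise ValueError("zero_dose policy requires control_value")
        control_of = lambda curve: control_value
        control_idx = None
    else:
        raise ValueError(f"unknown control_policy {control_policy!r}")

    def level_of(curve):
        if kind == "TGI":
            return n0_ref
        if kind == "LC50":
            return 0.5 * n0_ref
        g_c = control_of(curve) - n0_ref
        return None if g_c <= 0 else n0_ref + 0.5 * g_c

    crossings = []
    n_censored = 0
    n_multi = 0
    for i in range(dense.n_draws):
        level = level_of(m[i])
        if level is None:
            n_censored += 1
            continue
        z_star, k = first_crossing(z, m[i], level)
        if z_star is None:
            n_censored += 1
            continue
        if k > 1:
            n_multi += 1
        crossings.append(z_star)

    mean_curve = m.mean(axis=0)
    level = level_of(mean_curve)
    if level is None:
        point, censor = z[-1], "above_range"
    else:
        point, _ = first_crossing(z, mean_curve, level)
        if point is None:
            point = z[-1] if mean_curve.min() > level else z[0]
            censor = _censor_side(mean_curve, level)
        else:
            censor = "none"
    if crossings:
        lo, hi = np.percentile(crossings, [2.5, 97.5])
    else:
        lo = hi = point
    return SummaryStat(
        kind=kind,
        posterior_mean=float(10.0**point),
        ci_low=float(10.0**lo),
        ci_high=float(10.0**hi),
        censor=censor,
        fraction_censored=n_censored / dense.n_draws,
        fraction_multiple_crossings=n_multi / dense.n_draws,
        n_draws=dense.n_draws,
    )


def rate_percent_change(draws) -> tuple[float, float]:
    """Percent change of posterior-mean rates between extreme tested doses.

    Returns (delta_lambda_pct, delta_mu_pct), each
    100 * (rbar(z_max) - rbar(z_min)) / rbar(z_min).
    """
    lam = np.exp(draws.phi_lam)
    mu = np.exp(draws.phi_mu)
    lam_bar = lam.mean(axis=0)
    mu_bar = mu.mean(axis=0)
    d_lam = 100.0 * (lam_bar[-1] - lam_bar[0]) / lam_bar[0]
    d_mu = 100.0 * (mu_bar[-1] - mu_bar[0]) / mu_bar[0]
    return float(d_lam), float(d_mu)
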