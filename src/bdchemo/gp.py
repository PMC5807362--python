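"""Gaussian-process priors on log birth/death rate curves.

The log rates phi_lam(z) = log lambda(z) and phi_mu(z) = log mu(z) carry
independent GP priors with constant mean alpha and squared-exponential
covariance

    K(z, z') = tau2 * exp(-(z - z')^2 / l2),

where tau2 is the marginal variance and l2 the squared length-scale on the
log10-concentration axis.  Hyperpriors: alpha ~ Normal(0, s_a2),
tau2 ~ Inverse-Gamma(a1, b1), l2 ~ Gamma(a2, b2), theta flat, and
p(sigma2) proportional to 1/sigma2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import linalg, stats

__all__ = [
    "GPHyper",
    "HyperPriorConfig",
    "LatentRates",
    "kernel_matrix",
    "log_hyperprior",
    "sample_hyper_prior",
    "sample_latent_prior",
    "gp_conditional",
]


@dataclass
class GPHyper:
    """Hyperparameters of the two GPs plus the background-noise model."""

    alpha_lam: float = 0.0
    alpha_mu: float = 0.0
    tau2_lam: float = 1.0
    tau2_mu: float = 1.0
    l2_lam: float = 1.0
    l2_mu: float = 1.0
    theta: float = 0.0
    sigma2: float = 1.0

    def validate(self) -> None:
        for name in ("tau2_lam", "tau2_mu", "l2_lam", "l2_mu", "sigma2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class HyperPriorConfig:
    """Shape/rate constants of the hyperprior hierarchy.

    ``s_a2_*`` are the prior variances of the GP means; ``a1/b1`` shape/rate
    of the Inverse-Gamma on tau2; ``a2/b2`` shape/rate of the Gamma on l2.
    theta and sigma2 carry improper flat and log-uniform priors with no
    constants to configure.

    Defaults are weakly informative on the scale of the problem rather than
    arbitrarily diffuse: per-cell rates over one assay duration live within
    a few e-folds of 1, so the GP mean prior sd is 2 (alpha within +-6
    covers rates from ~0.002 to ~400), the kernel variance has prior mean 1
    (IG(2,1)), and the squared length-scale has prior mean 4 (Gamma(2,0.5)),
    a sensible correlation length for dose ranges spanning ~5 decades.
    Heavier-tailed choices let the latent curves wander to physically
    impossible rate scales, which manifests as a spurious "all rates near
    zero, noise variance inflated" mode when replicates are few.
    """

    s_a2_lam: float = 4.0
    s_a2_mu: float = 4.0
    a1_lam: float = 2.0
    b1_lam: float = 1.0
    a1_mu: float = 2.0
    b1_mu: float = 1.0
    a2_lam: float = 2.0
    b2_lam: float = 0.5
    a2_mu: float = 2.0
    b2_mu: float = 0.5

    def __post_init__(self) -> None:
        for name, val in asdict(self).items():
            if val <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @classmethod
    def from_dict(cls, d: dict | None) -> "HyperPriorConfig":
        return cls(**(d or {}))


@dataclass
class LatentRates:
    """Log birth/death rate vectors on a dose grid (the GP finite marginal)."""

    grid: np.ndarray
    phi_lam: np.ndarray
    phi_mu: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.phi_lam = np.asarray(self.phi_lam, dtype=float)
        self.phi_mu = np.asarray(self.phi_mu, dtype=float)
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("dose grid must be strictly increasing")
        if not (np.all(np.isfinite(self.phi_lam)) and np.all(np.isfinite(self.phi_mu))):
            raise ValueError("log-rate vectors must be finite")

    @property
    def lam(self) -> np.ndarray:
        return np.exp(self.phi_lam)

    @property
    def mu(self) -> np.ndarray:
        return np.exp(self.phi_mu)


def kernel_matrix(z, tau2: float, l2: float, jitter: float | None = None):
    """Squared-exponential covariance matrix on the grid ``z``.

    The diagonal is tau2 + jitter; jitter defaults to 1e-6 * tau2, large
    enough that the factorisation virtually never fails even for long
    length-scales (a kernel that needs data-dependent jitter escalation
    would make the MCMC density evaluation asymmetric between current and
    proposed states, biasing length-scale updates).  Returns the covariance
    matrix; use :func:`chol_kernel` when the factor is needed too.
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    if z.size == 0:
        raise ValueError("grid must be non-empty")
    if tau2 <= 0 or l2 <= 0:
        raise ValueError("tau2 and l2 must be strictly positive")
    d = z[:, None] - z[None, :]
    K = tau2 * np.exp(-(d**2) / l2)
    if jitter is None:
        jitter = 1e-6 * tau2
    K[np.diag_indices_from(K)] += jitter
    return K


def chol_kernel(z, tau2: float, l2: float):
    """Kernel matrix together with its lower Cholesky factor.

    Escalates jitter x10 up to three times before raising.
    """
    jitter = 1e-6 * tau2
    for _ in range(4):
        K = kernel_matrix(z, tau2, l2, jitter=jitter)
        try:
            return K, linalg.cholesky(K, lower=True, check_finite=False)
        except linalg.LinAlgError:
            jitter *= 10.0
    raise linalg.LinAlgError(
        f"kernel matrix not positive definite after jitter escalation to {jitter:g}"
    )


def log_hyperprior(h: GPHyper, cfg: HyperPriorConfig) -> float:
    """Joint log hyperprior density, up to the improper constants.

    Returns -inf for out-of-support values (rejection semantics).
    """
    if min(h.tau2_lam, h.tau2_mu, h.l2_lam, h.l2_mu, h.sigma2) <= 0:
        return -np.inf
    lp = 0.0
    lp += stats.norm.logpdf(h.alpha_lam, 0.0, np.sqrt(cfg.s_a2_lam))
    lp += stats.norm.logpdf(h.alpha_mu, 0.0, np.sqrt(cfg.s_a2_mu))
    lp += stats.invgamma.logpdf(h.tau2_lam, cfg.a1_lam, scale=cfg.b1_lam)
    lp += stats.invgamma.logpdf(h.tau2_mu, cfg.a1_mu, scale=cfg.b1_mu)
    lp += stats.gamma.logpdf(h.l2_lam, cfg.a2_lam, scale=1.0 / cfg.b2_lam)
    lp += stats.gamma.logpdf(h.l2_mu, cfg.a2_mu, scale=1.0 / cfg.b2_mu)
    # theta: flat, contributes 0; sigma2: p propto 1/sigma2
    lp += -np.log(h.sigma2)
    return float(lp)


def sample_hyper_prior(cfg: HyperPriorConfig, rng=None, theta: float = 0.0, sigma2: float = 1.0) -> GPHyper:
    """Draw the proper-prior hyperparameters from their priors.

    theta and sigma2 carry improper priors and cannot be sampled; they are
    set to the supplied values (validation workflows pin them).
    """
    rng = np.random.default_rng(rng)
    return GPHyper(
        alpha_lam=float(rng.normal(0.0, np.sqrt(cfg.s_a2_lam))),
        alpha_mu=float(rng.normal(0.0, np.sqrt(cfg.s_a2_mu))),
        tau2_lam=float(cfg.b1_lam / rng.gamma(cfg.a1_lam)),
        tau2_mu=float(cfg.b1_mu / rng.gamma(cfg.a1_mu)),
        l2_lam=float(rng.gamma(cfg.a2_lam) / cfg.b2_lam),
        l2_mu=float(rng.gamma(cfg.a2_mu) / cfg.b2_mu),
        theta=theta,
        sigma2=sigma2,
    )


def sample_latent_prior(h: GPHyper, z, rng=None) -> LatentRates:
    """Draw (phi_lam, phi_mu) from their independent GP prior marginals."""
    h.validate()
    rng = np.random.default_rng(rng)
    z = np.atleast_1d(np.asarray(z, dtype=float))
    _, L_lam = chol_kernel(z, h.tau2_lam, h.l2_lam)
    _, L_mu = chol_kernel(z, h.tau2_mu, h.l2_mu)
    phi_lam = h.alpha_lam + L_lam @ rng.standard_normal(z.size)
    phi_mu = h.alpha_mu + L_mu @ rng.standard_normal(z.size)
    return LatentRates(z, phi_lam, phi_mu)


def gp_conditional(z_obs, phi_obs, z_new, alpha: float, tau2: float, l2: float):
    """Mean and covariance of the GP at ``z_new`` given values at ``z_obs``.

    Standard Gaussian conditioning of the joint finite marginal; used to
    extend posterior draws from the tested doses to a dense prediction grid.
    """
    z_obs = np.atleast_1d(np.asarray(z_obs, dtype=float))
    z_new = np.atleast_1d(np.asarray(z_new, dtype=float))
    phi_obs = np.atleast_1d(np.asarray(phi_obs, dtype=float))
    _, L = chol_kernel(z_obs, tau2, l2)
    k_cross = tau2 * np.exp(-((z_new[:, None] - z_obs[None, :]) ** 2) / l2)
    # solve K_obs^{-1} via the Cholesky factor
    w = linalg.cho_solve((L, True), phi_obs - alpha)
    mean = alpha + k_cross @ w
    v = linalg.solve_triangular(L, k_cross.T, lower=True)
    K_new = kernel_matrix(z_new, tau2, l2)
    cov = K_new - v.T @ v
    return mean, cov
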