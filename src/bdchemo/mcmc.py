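"""Metropolis-within-Gibbs sampler for the birth-death GP model.

Target posterior (one experiment):

    p(phi_lam, phi_mu, alpha_., tau2_., l2_., theta, sigma2 | D)
      propto  L(D | exp(phi_lam), exp(phi_mu), theta, sigma2)
              x MVN(phi_lam | alpha_lam 1, K_lam) MVN(phi_mu | alpha_mu 1, K_mu)
              x hyperpriors,

with L the moment-matched Gaussian likelihood and K the squared-exponential
kernels on the tested doses.  The latents live only at the distinct tested
doses during sampling; dense prediction grids are filled in afterwards by
exact GP conditioning per retained draw (distributionally identical to
carrying the dense grid through the chain, and much cheaper).

Update blocks per sweep:

1. phi_lam, phi_mu -- preconditioned Crank-Nicolson (pCN) proposals.  The
   proposal ``phi' = alpha + rho (phi - alpha) + sqrt(1-rho^2) L eps``
   preserves the GP prior exactly, so the Metropolis ratio reduces to the
   likelihood ratio; detailed balance w.r.t. the posterior holds.
2. Rate-shift moves (lam, mu) -> (lam + c, mu + c), global and single-dose:
   they fix the mean curve while moving the variance-identified turnover
   direction, which pCN alone crosses slowly (the posterior can be bimodal
   there when replicates are few).
3. alpha_lam, alpha_mu -- conjugate Normal draws.
4. tau2_lam, tau2_mu -- conjugate Inverse-Gamma draws (K = tau2 R).
5. l2_lam, l2_mu -- random-walk Metropolis on the log scale.
6. theta -- conjugate Normal draw (flat prior); sigma2 -- log-scale
   random-walk Metropolis (its 1/sigma2 prior cancels the log Jacobian).

Proposal scales adapt toward standard target acceptance rates (0.23 for the
vector blocks, 0.44 for scalars) during burn-in only, then freeze, so the
retained chain has the correct stationary distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg

from .gp import GPHyper, HyperPriorConfig, chol_kernel
from .io import Experiment
from .kendall import dose_moments

try:  # hot path: one scalar likelihood per Metropolis proposal
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _njit = lambda *a, **k: (lambda f: f)


@_njit(cache=False)
def _well_loglik_kernel(phi_lam, phi_mu, dose_idx, n0, x, e, theta, sigma2):
    ll = 0.0
    log2pi = 1.8378770664093453
    for i in range(x.size):
        j = dose_idx[i]
        lam = np.exp(phi_lam[j])
        mu = np.exp(phi_mu[j])
        delta = lam - mu
        ed = np.exp(delta)
        m = n0[i] * ed
        if abs(delta) < 1e-8:
            v = n0[i] * (lam + mu)
        else:
            v = n0[i] * (lam + mu) / delta * ed * np.expm1(delta)
        tot = (v if v > 0.0 else 0.0) + sigma2
        r = x[i] - m - theta
        ll += -0.5 * (np.log(tot) + log2pi + r * r / tot)
    for i in range(e.size):
        r = e[i] - theta
        ll += -0.5 * (np.log(sigma2) + log2pi + r * r / sigma2)
    return ll

__all__ = [
    "MCMCConfig",
    "PosteriorDraws",
    "run_mcmc",
    "diagnostics",
    "simulate_from_likelihood",
    "geweke_forward",
    "geweke_successive",
]


@dataclass
class MCMCConfig:
    n_iter: int = 20_000
    n_burn: int = 10_000
    thin: int = 10
    seed: int = 0
    step_phi: float = 0.15      # pCN step in (0, 1]
    step_l2: float = 0.6        # log-scale RW sd
    step_sigma2: float = 0.6
    step_shift: float = 0.2     # rate-shift move sd (per-cell rate units)
    adapt: bool = True
    prior_only: bool = False    # likelihood disabled (prior-recovery mode)
    n_chains: int = 3           # independent chains, pooled in the output

    def __post_init__(self) -> None:
        if not self.n_iter > self.n_burn >= 0:
            raise ValueError("need n_iter > n_burn >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not (0 < self.step_phi <= 1) or self.step_l2 <= 0 or self.step_sigma2 <= 0:
            raise ValueError("proposal scales must be positive (step_phi <= 1)")
        if self.step_shift <= 0 or self.n_chains < 1:
            raise ValueError("step_shift must be positive and n_chains >= 1")


@dataclass
class PosteriorDraws:
    """Retained MCMC draws plus acceptance bookkeeping."""

    doses: np.ndarray
    phi_lam: np.ndarray     # (n_draws, n_doses)
    phi_mu: np.ndarray
    alpha_lam: np.ndarray
    alpha_mu: np.ndarray
    tau2_lam: np.ndarray
    tau2_mu: np.ndarray
    l2_lam: np.ndarray
    l2_mu: np.ndarray
    theta: np.ndarray
    sigma2: np.ndarray
    acceptance: dict = field(default_factory=dict)
    config: MCMCConfig | None = None

    @property
    def n_draws(self) -> int:
        return self.phi_lam.shape[0]

    @property
    def lam(self) -> np.ndarray:
        return np.exp(self.phi_lam)

    @property
    def mu(self) -> np.ndarray:
        return np.exp(self.phi_mu)

    _SCALARS = ("alpha_lam", "alpha_mu", "tau2_lam", "tau2_mu",
                "l2_lam", "l2_mu", "theta", "sigma2")

    def to_dataframe(self) -> pd.DataFrame:
        cols = {}
        for j, z in enumerate(self.doses):
            cols[f"phi_lam_{j}"] = self.phi_lam[:, j]
        for j, z in enumerate(self.doses):
            cols[f"phi_mu_{j}"] = self.phi_mu[:, j]
        for name in self._SCALARS:
            cols[name] = getattr(self, name)
        return pd.DataFrame(cols)

    def save(self, draws_csv, manifest_json=None) -> None:
        self.to_dataframe().to_csv(draws_csv, index=False, float_format="%.17g")
        if manifest_json is not None:
            manifest = {
                "doses": self.doses.tolist(),
                "acceptance": self.acceptance,
                "config": asdict(self.config) if self.config else None,
            }
            Path(manifest_json).write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, draws_csv, manifest_json) -> "PosteriorDraws":
        df = pd.read_csv(draws_csv, float_precision="round_trip")
        manifest = json.loads(Path(manifest_json).read_text())
        doses = np.asarray(manifest["doses"], dtype=float)
        d = len(doses)
        return cls(
            doses,
            df[[f"phi_lam_{j}" for j in range(d)]].to_numpy(),
            df[[f"phi_mu_{j}" for j in range(d)]].to_numpy(),
            *[df[name].to_numpy() for name in cls._SCALARS],
            acceptance=manifest.get("acceptance", {}),
            config=MCMCConfig(**manifest["config"]) if manifest.get("config") else None,
        )


class _State:
    """Mutable sampler state with cached kernel factors and likelihood."""

    def __init__(self, doses, dose_idx, exp, h: GPHyper, phi_lam, phi_mu, prior_only):
        self.doses = doses
        self.dose_idx = dose_idx
        self.exp = exp
        self.h = h
        self.phi = {"lam": phi_lam.copy(), "mu": phi_mu.copy()}
        self.prior_only = prior_only
        # cached per-block kernel factors: lower Cholesky L, log|L|, K^-1
        self.L = {}
        self.logdet = {}
        self.Kinv = {}
        for blk in ("lam", "mu"):
            self._refresh_chol(blk)
        self.loglik = self._loglik(self.phi["lam"], self.phi["mu"], h.theta, h.sigma2)

    def _refresh_chol(self, blk):
        tau2 = getattr(self.h, f"tau2_{blk}")
        l2 = getattr(self.h, f"l2_{blk}")
        _, L = chol_kernel(self.doses, tau2, l2)
        self._set_chol(blk, L)

    def _set_chol(self, blk, L):
        self.L[blk] = L
        self.logdet[blk] = float(np.sum(np.log(np.diag(L))))
        self.Kinv[blk] = linalg.cho_solve((L, True), np.eye(L.shape[0]), check_finite=False)

    def _rescale_chol(self, blk, ratio):
        """K -> ratio * K after a conjugate kernel-variance draw."""
        s = np.sqrt(ratio)
        self.L[blk] = self.L[blk] * s
        self.logdet[blk] += self.L[blk].shape[0] * np.log(s)
        self.Kinv[blk] = self.Kinv[blk] / ratio

    def gp_logpdf(self, blk, phi, alpha):
        r = phi - alpha
        d = r.size
        return float(
            -0.5 * r @ self.Kinv[blk] @ r - self.logdet[blk] - 0.5 * d * np.log(2 * np.pi)
        )

    def _loglik(self, phi_lam, phi_mu, theta, sigma2):
        if self.prior_only:
            return 0.0
        with np.errstate(over="ignore", invalid="ignore"):
            ll = _well_loglik_kernel(
                phi_lam, phi_mu, self.dose_idx, self.exp.n0, self.exp.x,
                self.exp.background, theta, sigma2,
            )
        return float(ll) if np.isfinite(ll) else -np.inf


def _init_state(exp: Experiment, hp: HyperPriorConfig, prior_only: bool) -> _State:
    """Per-dose method-of-moments initialisation.

    Growth rate from the mean count ratio; lambda+mu from the replicate
    variance (the variance identity at t=1); theta/sigma2 from the
    background wells.
    """
    doses = exp.doses
    dose_idx = exp.dose_index()
    d = len(doses)
    theta0 = float(np.mean(exp.background))
    sigma20 = float(max(np.var(exp.background, ddof=1), 1e-6))
    # per-dose method-of-moments start: delta from the mean count ratio,
    # lam+mu from the replicate variance.  The variance estimates are
    # chi^2-noisy with few replicates, which usefully disperses independent
    # chains across the quiescence/turnover posterior modes.
    phi_lam = np.empty(d)
    phi_mu = np.empty(d)
    for i, zi in enumerate(doses):
        sel = exp.z == zi
        n0_i = float(np.mean(exp.n0[sel]))
        m_hat = max(float(np.mean(exp.x[sel])) - theta0, 1e-3 * n0_i)
        delta = float(np.clip(np.log(m_hat / n0_i), -3.0, 3.0))
        if np.sum(sel) >= 2:
            v_hat = max(float(np.var(exp.x[sel], ddof=1)) - sigma20, 1e-6)
        else:
            v_hat = n0_i  # single well: nothing to go on, neutral guess
        if abs(delta) < 1e-3:
            s = v_hat / n0_i
        else:
            s = v_hat * delta / (n0_i * np.exp(delta) * np.expm1(delta))
        s = float(np.clip(s, abs(delta) + 0.02, 10.0))
        phi_lam[i] = np.log(max((s + delta) / 2.0, 1e-2))
        phi_mu[i] = np.log(max((s - delta) / 2.0, 1e-2))
    h = GPHyper(
        alpha_lam=float(np.mean(phi_lam)), alpha_mu=float(np.mean(phi_mu)),
        tau2_lam=1.0, tau2_mu=1.0,
        l2_lam=max(((doses[-1] - doses[0]) / 2.0) ** 2, 0.1),
        l2_mu=max(((doses[-1] - doses[0]) / 2.0) ** 2, 0.1),
        theta=theta0, sigma2=sigma20,
    )
    return _State(doses, dose_idx, exp, h, phi_lam, phi_mu, prior_only)


def run_mcmc(
    exp: Experiment,
    cfg: MCMCConfig | None = None,
    hp: HyperPriorConfig | None = None,
    fix_noise: tuple[float, float] | None = None,
    init: dict | None = None,
) -> PosteriorDraws:
    """Draw from the joint posterior of latent rate curves and hyperparameters.

    Runs ``cfg.n_chains`` independent chains (seeds derived from ``cfg.seed``)
    and pools the retained draws; with few replicates the posterior can be
    bimodal (quiescence vs turnover) and pooled chains represent both basins
    far more reliably than one.  ``fix_noise=(theta, sigma2)`` pins the noise
    parameters (used by the prior-recovery and joint-distribution sampler
    checks, where the improper noise priors cannot be simulated from).
    ``init`` optionally overrides initial state entries (phi_lam, phi_mu, or
    GPHyper fields).  Fixed seed gives bit-identical draws.
    """
    cfg = cfg or MCMCConfig()
    hp = hp or HyperPriorConfig()
    chains = [
        _run_single_chain(exp, cfg, hp, fix_noise, init, chain_id=c)
        for c in range(cfg.n_chains)
    ]
    if len(chains) == 1:
        return chains[0]
    first = chains[0]
    pooled_acc = {
        k: (float(np.mean([ch.acceptance[k] for ch in chains]))
            if first.acceptance[k] is not None else None)
        for k in first.acceptance
    }
    return PosteriorDraws(
        first.doses,
        np.vstack([ch.phi_lam for ch in chains]),
        np.vstack([ch.phi_mu for ch in chains]),
        *[np.concatenate([getattr(ch, n) for ch in chains])
          for n in PosteriorDraws._SCALARS],
        acceptance=pooled_acc, config=cfg,
    )


def _run_single_chain(
    exp: Experiment,
    cfg: MCMCConfig,
    hp: HyperPriorConfig,
    fix_noise,
    init,
    chain_id: int = 0,
) -> PosteriorDraws:
    root = np.random.default_rng([cfg.seed, chain_id])
    streams = root.spawn(6)
    rng_lam, rng_mu, rng_alpha, rng_scale, rng_noise, rng_shift = streams

    st = _init_state(exp, hp, cfg.prior_only)
    if init:
        for key, val in init.items():
            if key in ("phi_lam", "phi_mu"):
                st.phi[key.split("_")[1]] = np.asarray(val, dtype=float).copy()
            else:
                setattr(st.h, key, float(val))
        for blk in ("lam", "mu"):
            st._refresh_chol(blk)
        st.loglik = st._loglik(st.phi["lam"], st.phi["mu"], st.h.theta, st.h.sigma2)
    if fix_noise is not None:
        st.h.theta, st.h.sigma2 = map(float, fix_noise)
        st.loglik = st._loglik(st.phi["lam"], st.phi["mu"], st.h.theta, st.h.sigma2)
    if not np.isfinite(st.loglik):
        raise RuntimeError(
            "non-finite log-posterior at initialization; state: "
            f"h={st.h}, phi_lam={st.phi['lam']}, phi_mu={st.phi['mu']}"
        )

    steps = {"lam": cfg.step_phi, "mu": cfg.step_phi,
             "l2_lam": cfg.step_l2, "l2_mu": cfg.step_l2,
             "sigma2": cfg.step_sigma2, "shift": cfg.step_shift,
             "shift1": cfg.step_shift}
    acc = {k: 0 for k in steps}
    tries = {k: 0 for k in steps}
    acc_win = {k: 0 for k in steps}
    win = 50

    n_keep = (cfg.n_iter - cfg.n_burn) // cfg.thin
    d = len(st.doses)
    out = {
        "phi_lam": np.empty((n_keep, d)), "phi_mu": np.empty((n_keep, d)),
        **{k: np.empty(n_keep) for k in PosteriorDraws._SCALARS},
    }
    kept = 0

    for it in range(cfg.n_iter):
        in_burn = it < cfg.n_burn
        # -- pCN updates of the latent log-rate vectors -------------------
        for blk, rng in (("lam", rng_lam), ("mu", rng_mu)):
            s = steps[blk]
            rho = np.sqrt(1.0 - s * s)
            alpha = getattr(st.h, f"alpha_{blk}")
            phi = st.phi[blk]
            prop = alpha + rho * (phi - alpha) + s * (st.L[blk] @ rng.standard_normal(d))
            if blk == "lam":
                ll_new = st._loglik(prop, st.phi["mu"], st.h.theta, st.h.sigma2)
            else:
                ll_new = st._loglik(st.phi["lam"], prop, st.h.theta, st.h.sigma2)
            tries[blk] += 1
            if np.isfinite(ll_new) and np.log(rng.random()) < ll_new - st.loglik:
                st.phi[blk] = prop
                st.loglik = ll_new
                acc[blk] += 1
                acc_win[blk] += 1

        # -- rate-shift moves: (lam, mu) -> (lam + c, mu + c) ---------------
        # preserve the mean curve (lam - mu fixed) while moving the
        # variance-identified turnover direction, which pCN alone mixes
        # slowly; the posterior is bimodal in this direction (quiescence vs
        # turnover) when replicates are few.  One global shift across all
        # doses plus a single-dose shift; deterministic-map Metropolis with
        # the phi-space Jacobian.
        if not cfg.prior_only:
            for key, rng in (("shift", rng_shift), ("shift1", rng_shift)):
                lam_cur = np.exp(st.phi["lam"])
                mu_cur = np.exp(st.phi["mu"])
                mask = np.ones(d, dtype=bool)
                if key == "shift1":
                    mask = np.zeros(d, dtype=bool)
                    mask[rng.integers(d)] = True
                # occasional 5x-scale proposals jump between the quiescence
                # and turnover modes that small steps cross only slowly
                scale = steps[key] * (5.0 if rng.random() < 0.1 else 1.0)
                c = scale * rng.standard_normal()
                tries[key] += 1
                low = min(lam_cur[mask].min(), mu_cur[mask].min())
                if c <= -low:
                    continue
                phi_lam_p = st.phi["lam"].copy()
                phi_mu_p = st.phi["mu"].copy()
                phi_lam_p[mask] = np.log(lam_cur[mask] + c)
                phi_mu_p[mask] = np.log(mu_cur[mask] + c)
                ll_new = st._loglik(phi_lam_p, phi_mu_p, st.h.theta, st.h.sigma2)
                lp_new = ll_new \
                    + st.gp_logpdf("lam", phi_lam_p, st.h.alpha_lam) \
                    + st.gp_logpdf("mu", phi_mu_p, st.h.alpha_mu)
                lp_cur = st.loglik \
                    + st.gp_logpdf("lam", st.phi["lam"], st.h.alpha_lam) \
                    + st.gp_logpdf("mu", st.phi["mu"], st.h.alpha_mu)
                log_jac = np.sum(st.phi["lam"][mask] - phi_lam_p[mask]) \
                    + np.sum(st.phi["mu"][mask] - phi_mu_p[mask])
                if np.isfinite(lp_new) and np.log(rng.random()) < lp_new - lp_cur + log_jac:
                    st.phi["lam"] = phi_lam_p
                    st.phi["mu"] = phi_mu_p
                    st.loglik = ll_new
                    acc[key] += 1
                    acc_win[key] += 1

        # -- conjugate draws: GP means and variances ----------------------
        for blk in ("lam", "mu"):
            phi = st.phi[blk]
            Kinv = st.Kinv[blk]
            s_a2 = getattr(hp, f"s_a2_{blk}")
            Kinv_one = Kinv.sum(axis=1)
            post_var = 1.0 / (Kinv_one.sum() + 1.0 / s_a2)
            post_mean = post_var * float(Kinv_one @ phi)
            alpha_new = post_mean + np.sqrt(post_var) * rng_alpha.standard_normal()
            setattr(st.h, f"alpha_{blk}", float(alpha_new))

            # K = tau2 * R with R the unit-variance kernel; quadratic form in R
            tau2_old = getattr(st.h, f"tau2_{blk}")
            r = phi - alpha_new
            quad_R = float(r @ Kinv @ r) * tau2_old
            a_post = getattr(hp, f"a1_{blk}") + 0.5 * d
            b_post = getattr(hp, f"b1_{blk}") + 0.5 * quad_R
            tau2_new = b_post / rng_alpha.gamma(a_post)
            setattr(st.h, f"tau2_{blk}", float(tau2_new))
            st._rescale_chol(blk, tau2_new / tau2_old)

        # -- log-RW Metropolis on the squared length-scales ----------------
        for blk, rng in (("l2_lam", rng_scale), ("l2_mu", rng_scale)):
            short = blk.split("_")[1]
            l2_cur = getattr(st.h, blk)
            alpha = getattr(st.h, f"alpha_{short}")
            tau2 = getattr(st.h, f"tau2_{short}")
            phi = st.phi[short]
            a2 = getattr(hp, f"a2_{short}")
            b2 = getattr(hp, f"b2_{short}")
            l2_prop = float(np.exp(np.log(l2_cur) + steps[blk] * rng.standard_normal()))
            try:
                _, L_prop = chol_kernel(st.doses, tau2, l2_prop)
            except linalg.LinAlgError:
                tries[blk] += 1
                continue
            r = linalg.solve_triangular(L_prop, phi - alpha, lower=True, check_finite=False)
            mvn_prop = -0.5 * float(r @ r) - float(np.sum(np.log(np.diag(L_prop))))
            mvn_cur = st.gp_logpdf(short, phi, alpha)  # constant term cancels
            lp_cur = mvn_cur + (a2 - 1) * np.log(l2_cur) - b2 * l2_cur + np.log(l2_cur) \
                - (-0.5 * d * np.log(2 * np.pi))
            lp_prop = mvn_prop + (a2 - 1) * np.log(l2_prop) - b2 * l2_prop + np.log(l2_prop)
            tries[blk] += 1
            if np.isfinite(lp_prop) and np.log(rng.random()) < lp_prop - lp_cur:
                setattr(st.h, blk, l2_prop)
                st._set_chol(short, L_prop)
                acc[blk] += 1
                acc_win[blk] += 1

        # -- noise block ---------------------------------------------------
        if fix_noise is None and not cfg.prior_only:
            lam = np.exp(st.phi["lam"])[st.dose_idx]
            mu = np.exp(st.phi["mu"])[st.dose_idx]
            m, v = dose_moments(exp.n0, lam, mu)
            w_wells = 1.0 / (v + st.h.sigma2)
            w_bg = 1.0 / st.h.sigma2
            prec = np.sum(w_wells) + exp.background.size * w_bg
            mean_post = (np.sum(w_wells * (exp.x - m)) + w_bg * np.sum(exp.background)) / prec
            st.h.theta = float(mean_post + np.sqrt(1.0 / prec) * rng_noise.standard_normal())

            # sigma2: log-RW; the 1/sigma2 prior cancels the log Jacobian
            ll_cur = st._loglik(st.phi["lam"], st.phi["mu"], st.h.theta, st.h.sigma2)
            s2_prop = float(np.exp(np.log(st.h.sigma2) + steps["sigma2"] * rng_noise.standard_normal()))
            ll_prop = st._loglik(st.phi["lam"], st.phi["mu"], st.h.theta, s2_prop)
            tries["sigma2"] += 1
            if np.isfinite(ll_prop) and np.log(rng_noise.random()) < ll_prop - ll_cur:
                st.h.sigma2 = s2_prop
                st.loglik = ll_prop
                acc["sigma2"] += 1
                acc_win["sigma2"] += 1
            else:
                st.loglik = ll_cur

        # -- burn-in adaptation -------------------------------------------
        if cfg.adapt and in_burn and (it + 1) % win == 0:
            batch = (it + 1) // win
            gain = min(0.5, 2.0 / np.sqrt(batch))
            for k in steps:
                target = 0.23 if k in ("lam", "mu") else 0.44
                rate = acc_win[k] / win
                steps[k] = float(steps[k] * np.exp(gain * (rate - target)))
                if k in ("lam", "mu"):
                    steps[k] = min(steps[k], 1.0)
                acc_win[k] = 0

        if not in_burn and (it - cfg.n_burn) % cfg.thin == 0 and kept < n_keep:
            out["phi_lam"][kept] = st.phi["lam"]
            out["phi_mu"][kept] = st.phi["mu"]
            for name in PosteriorDraws._SCALARS:
                out[name][kept] = getattr(st.h, name)
            kept += 1

    acceptance = {k: (acc[k] / tries[k] if tries[k] else None) for k in acc}
    return PosteriorDraws(
        st.doses,
        out["phi_lam"][:kept], out["phi_mu"][:kept],
        *[out[name][:kept] for name in PosteriorDraws._SCALARS],
        acceptance=acceptance, config=cfg,
    )


def simulate_from_likelihood(exp: Experiment, phi_lam, phi_mu, theta, sigma2, rng=None) -> Experiment:
    """Resimulate measured counts from the model's Gaussian likelihood.

    Used by the joint-distribution (successive-conditional) sampler check:
    given current latents/hypers, draws a fresh dataset with the same design.
    """
    rng = np.random.default_rng(rng)
    idx = exp.dose_index()
    lam = np.exp(np.asarray(phi_lam))[idx]
    mu = np.exp(np.asarray(phi_mu))[idx]
    m, v = dose_moments(exp.n0, lam, mu)
    x = m + theta + np.sqrt(v + sigma2) * rng.standard_normal(exp.n_wells)
    e = theta + np.sqrt(sigma2) * rng.standard_normal(exp.background.size)
    return Experiment(exp.experiment_id, exp.z, exp.n0, x, e, exp.metadata)


_GEWEKE_FUNCS = ("alpha_lam", "alpha_mu", "log_tau2_lam", "log_tau2_mu",
                 "log_l2_lam", "log_l2_mu", "mean_phi_lam", "mean_phi_mu")


def _geweke_record(out, i, h: GPHyper, phi_lam, phi_mu):
    out["alpha_lam"][i] = h.alpha_lam
    out["alpha_mu"][i] = h.alpha_mu
    out["log_tau2_lam"][i] = np.log(h.tau2_lam)
    out["log_tau2_mu"][i] = np.log(h.tau2_mu)
    out["log_l2_lam"][i] = np.log(h.l2_lam)
    out["log_l2_mu"][i] = np.log(h.l2_mu)
    out["mean_phi_lam"][i] = float(np.mean(phi_lam))
    out["mean_phi_mu"][i] = float(np.mean(phi_mu))


def geweke_forward(exp_template: Experiment, hp: HyperPriorConfig, n: int,
                   theta: float, sigma2: float, seed: int = 0) -> dict:
    """Independent draws of (hypers, latents) from the prior.

    One half of the joint-distribution sampler check; theta/sigma2 are
    pinned (improper priors cannot be forward-simulated).
    """
    from .gp import sample_hyper_prior, sample_latent_prior

    rng = np.random.default_rng(seed)
    doses = exp_template.doses
    out = {k: np.empty(n) for k in _GEWEKE_FUNCS}
    for i in range(n):
        h = sample_hyper_prior(hp, rng, theta=theta, sigma2=sigma2)
        lat = sample_latent_prior(h, doses, rng=rng)
        _geweke_record(out, i, h, lat.phi_lam, lat.phi_mu)
    return out


def geweke_successive(exp_template: Experiment, hp: HyperPriorConfig, n: int,
                      theta: float, sigma2: float, seed: int = 0,
                      sweeps_per_step: int = 2) -> dict:
    """Successive-conditional simulation: alternate parameter sweeps with
    resimulating the data from the likelihood.

    If the transition kernel targets the correct conditionals, the marginal
    law of the parameters along this chain equals the prior, so these draws
    must be statistically indistinguishable from :func:`geweke_forward`.
    """
    from .gp import sample_hyper_prior, sample_latent_prior

    rng = np.random.default_rng(seed)
    h = sample_hyper_prior(hp, rng, theta=theta, sigma2=sigma2)
    lat = sample_latent_prior(h, exp_template.doses, rng=rng)
    phi_lam, phi_mu = lat.phi_lam, lat.phi_mu
    out = {k: np.empty(n) for k in _GEWEKE_FUNCS}
    cfg = MCMCConfig(
        n_iter=sweeps_per_step, n_burn=sweeps_per_step - 1, thin=1,
        adapt=False, n_chains=1, seed=0,
    )
    for i in range(n):
        data = simulate_from_likelihood(exp_template, phi_lam, phi_mu, theta, sigma2, rng)
        cfg.seed = int(rng.integers(2**31 - 1))
        draws = run_mcmc(
            data, cfg, hp, fix_noise=(theta, sigma2),
            init={
                "phi_lam": phi_lam, "phi_mu": phi_mu,
                "alpha_lam": h.alpha_lam, "alpha_mu": h.alpha_mu,
                "tau2_lam": h.tau2_lam, "tau2_mu": h.tau2_mu,
                "l2_lam": h.l2_lam, "l2_mu": h.l2_mu,
            },
        )
        phi_lam = draws.phi_lam[-1]
        phi_mu = draws.phi_mu[-1]
        for name in ("alpha_lam", "alpha_mu", "tau2_lam", "tau2_mu", "l2_lam", "l2_mu"):
            setattr(h, name, float(getattr(draws, name)[-1]))
        _geweke_record(out, i, h, phi_lam, phi_mu)
    return out


def diagnostics(draws: PosteriorDraws, grid_subsample: int = 3) -> dict:
    """Effective sample size and split-Rhat per hyperparameter and a
    subsample of latent grid points; warns (in the report) when Rhat > 1.05.
    """
    import arviz as az

    n = draws.n_draws
    if n < 4:
        raise ValueError("need at least 4 retained draws for diagnostics")
    half = n // 2
    report = {"params": {}, "warnings": []}
    names = list(PosteriorDraws._SCALARS)
    series = {name: getattr(draws, name) for name in names}
    step = max(1, len(draws.doses) // grid_subsample)
    for j in range(0, len(draws.doses), step):
        series[f"phi_lam_{j}"] = draws.phi_lam[:, j]
        series[f"phi_mu_{j}"] = draws.phi_mu[:, j]
    for name, v in series.items():
        v = v[: 2 * half]
        chains = v.reshape(2, half)
        ess = float(az.ess(chains))
        rhat = float(az.rhat(chains))
        report["params"][name] = {"ess": ess, "rhat": rhat}
        if np.isfinite(rhat) and rhat > 1.05:
            report["warnings"].append(f"{name}: split-Rhat {rhat:.3f} > 1.05")
    return report
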