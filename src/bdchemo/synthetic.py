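"""Synthetic chemo-sensitivity experiments with known ground truth.

Emulates the NCI-DREAM assay design: 9 log-spaced doses spanning
z in [-9, -4] log10 M, triplicate wells, one follow-up time, about 10^3
cells seeded per well, plus compound-free background wells.  Final counts
are produced by exact Gillespie simulation of the linear birth-death
process at each well's dose-specific rates, with additive Gaussian assay
noise on top — i.e. data are generated from the mechanistic model itself,
not from its Gaussian approximation, so recovery tests exercise the
approximation too.

Scenario shapes (rates strictly positive over the dose range):

* ``constant``         -- lambda, mu flat (control-like).
* ``birth_inhibition`` -- lambda falls sigmoidally, mu flat.
* ``death_induction``  -- mu rises sigmoidally, lambda flat.
* ``both``             -- lambda halves and mu triples across the range
                          (the typical cytotoxic pattern).
* ``plateau``          -- the net rate drops in two separated steps, giving
                          a mean curve with a plateau around its waist that
                          no single sigmoid can track.
* ``quiescence`` / ``turnover`` -- matched mean curves (lambda = mu) with
  tiny vs large rates; identical means, very different count variances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io import Experiment, write_experiment
from .kendall import BDPParams, simulate_bdp_batch
from .summaries import first_crossing

__all__ = ["ScenarioSpec", "GroundTruth", "generate_experiment", "SCENARIOS"]


def _sig(x):
    return 1.0 / (1.0 + np.exp(-x))


# default shape parameters per scenario; all overridable via shape_params
_DEFAULTS = {
    "constant": dict(lam0=0.9, mu0=0.3),
    "birth_inhibition": dict(lam_hi=0.9, lam_lo=0.2, mu0=0.3, z0=-6.5, width=0.5),
    "death_induction": dict(lam0=0.9, mu_lo=0.3, mu_hi=1.4, z0=-6.5, width=0.5),
    "both": dict(lam_hi=0.9, lam_lo=0.45, mu_lo=0.3, mu_hi=0.9, z0=-6.5, width=0.5),
    "plateau": dict(
        lam0=1.0, mu_base=0.1, step1=0.65, z1=-7.6, step2=1.45, z2=-5.2, width=0.12
    ),
    "quiescence": dict(rate=0.02),
    "turnover": dict(rate=1.0),
}


def _rate_curves(scenario: str, p: dict):
    """Return (lambda(z), mu(z)) callables for a named scenario."""
    if scenario == "constant":
        return (lambda z: np.full_like(np.asarray(z, float), p["lam0"]),
                lambda z: np.full_like(np.asarray(z, float), p["mu0"]))
    if scenario == "birth_inhibition":
        return (
            lambda z: p["lam_lo"] + (p["lam_hi"] - p["lam_lo"]) * _sig((p["z0"] - np.asarray(z, float)) / p["width"]),
            lambda z: np.full_like(np.asarray(z, float), p["mu0"]),
        )
    if scenario == "death_induction":
        return (
            lambda z: np.full_like(np.asarray(z, float), p["lam0"]),
            lambda z: p["mu_lo"] + (p["mu_hi"] - p["mu_lo"]) * _sig((np.asarray(z, float) - p["z0"]) / p["width"]),
        )
    if scenario == "both":
        return (
            lambda z: p["lam_lo"] + (p["lam_hi"] - p["lam_lo"]) * _sig((p["z0"] - np.asarray(z, float)) / p["width"]),
            lambda z: p["mu_lo"] + (p["mu_hi"] - p["mu_lo"]) * _sig((np.asarray(z, float) - p["z0"]) / p["width"]),
        )
    if scenario == "plateau":
        return (
            lambda z: np.full_like(np.asarray(z, float), p["lam0"]),
            lambda z: p["mu_base"]
            + p["step1"] * _sig((np.asarray(z, float) - p["z1"]) / p["width"])
            + p["step2"] * _sig((np.asarray(z, float) - p["z2"]) / p["width"]),
        )
    if scenario in ("quiescence", "turnover"):
        return (lambda z: np.full_like(np.asarray(z, float), p["rate"]),
                lambda z: np.full_like(np.asarray(z, float), p["rate"]))
    raise ValueError(f"unknown scenario {scenario!r}; known: {sorted(_DEFAULTS)}")


SCENARIOS = tuple(sorted(_DEFAULTS))


@dataclass
class ScenarioSpec:
    """Complete specification of one synthetic experiment."""

    scenario: str = "both"
    shape_params: dict = field(default_factory=dict)
    n_doses: int = 9
    z_min: float = -9.0
    z_max: float = -4.0
    replicates: int = 3
    n0: float = 1000.0
    theta: float = 30.0       # background-noise mean (assay offset)
    sigma2: float = 400.0     # background-noise variance (sd 20 counts)
    q_background: int = 6
    seed: int = 0
    experiment_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.scenario not in _DEFAULTS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.q_background < 2:
            raise ValueError("need >= 2 background wells")
        if self.n_doses < 2 or not self.z_max > self.z_min:
            raise ValueError("need >= 2 distinct doses")

    @property
    def doses(self) -> np.ndarray:
        return np.linspace(self.z_min, self.z_max, self.n_doses)

    def curves(self):
        p = {**_DEFAULTS[self.scenario], **self.shape_params}
        return _rate_curves(self.scenario, p)

    @classmethod
    def from_yaml_dict(cls, d: dict) -> "ScenarioSpec":
        return cls(**d)


@dataclass
class GroundTruth:
    """True rates and analytic potency summaries of a generated experiment."""

    z_dense: np.ndarray
    lam: np.ndarray
    mu: np.ndarray
    doses: np.ndarray
    lam_at_doses: np.ndarray
    mu_at_doses: np.ndarray
    gi50_log10M: float | None
    tgi_log10M: float | None
    lc50_log10M: float | None
    theta: float
    sigma2: float
    n0: float

    def to_json(self, path) -> None:
        d = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in asdict(self).items()
        }
        Path(path).write_text(json.dumps(d, indent=1))


def _true_summaries(spec: ScenarioSpec, lam_f, mu_f):
    """GI50/TGI/LC50 solved analytically on the noiseless true mean curve,
    with the min-dose control policy (matching the estimator's convention)."""
    z = np.linspace(spec.z_min, spec.z_max, 400)
    m = spec.n0 * np.exp(lam_f(z) - mu_f(z))
    g_c = m[0] - spec.n0
    out = {}
    levels = {
        "gi50": None if g_c <= 0 else spec.n0 + 0.5 * g_c,
        "tgi": spec.n0,
        "lc50": 0.5 * spec.n0,
    }
    for name, level in levels.items():
        if level is None:
            out[name] = None
            continue
        z_star, _ = first_crossing(z, m, level)
        out[name] = z_star
    return out


def generate_experiment(spec: ScenarioSpec, rng=None) -> tuple[Experiment, GroundTruth]:
    """Simulate one complete experiment plus its ground-truth record."""
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    lam_f, mu_f = spec.curves()
    doses = spec.doses
    lam_d = np.asarray(lam_f(doses), dtype=float)
    mu_d = np.asarray(mu_f(doses), dtype=float)
    if np.any(lam_d <= 0) or np.any(mu_d <= 0):
        raise ValueError("rate curves must be strictly positive over the dose range")
    z_wells, x_wells, n0_wells = [], [], []
    for zi, lami, mui in zip(doses, lam_d, mu_d):
        counts = simulate_bdp_batch(
            int(round(spec.n0)), BDPParams(lami, mui), 1.0,
            size=spec.replicates, rng=rng,
        )
        noise = rng.normal(spec.theta, np.sqrt(spec.sigma2), size=spec.replicates)
        z_wells.extend([zi] * spec.replicates)
        n0_wells.extend([spec.n0] * spec.replicates)
        x_wells.extend(counts + noise)
    background = rng.normal(spec.theta, np.sqrt(spec.sigma2), size=spec.q_background)
    exp = Experiment(
        spec.experiment_id,
        np.array(z_wells), np.array(n0_wells), np.array(x_wells), background,
        metadata={"scenario": spec.scenario, "seed": spec.seed},
    )
    z_dense = np.linspace(spec.z_min, spec.z_max, 200)
    s = _true_summaries(spec, lam_f, mu_f)
    truth = GroundTruth(
        z_dense, np.asarray(lam_f(z_dense)), np.asarray(mu_f(z_dense)),
        doses, lam_d, mu_d,
        s["gi50"], s["tgi"], s["lc50"],
        spec.theta, spec.sigma2, spec.n0,
    )
    return exp, truth


def write_fixture(spec: ScenarioSpec, outdir) -> dict:
    """Materialise one fixture: counts CSV, background CSV, truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exp, truth = generate_experiment(spec)
    stem = outdir / spec.experiment_id
    counts = stem.with_suffix(".counts.csv")
    bg = stem.with_suffix(".background.csv")
    write_experiment(exp, counts, bg)
    truth.to_json(stem.with_suffix(".truth.json"))
    return {"counts": str(counts), "background": str(bg)}
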