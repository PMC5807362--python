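"""Conventional parametric dose-response fits (Gompertz, logistic).

The standard screening analysis fits the final count g(z) at log10
concentration z with a four-parameter sigmoid,

    Gompertz:  g(z) = phi0 + phi1 * exp(-exp(phi2 + phi3 * z))
    logistic:  g(z) = psi0 + psi1 / (1 + exp((z - psi2) / psi3))

by nonlinear least squares, then reads GI50/TGI/LC50 off the fitted curve as
point estimates — no uncertainty.  Provided as the comparison baseline for
the mechanistic model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .io import Experiment
from .summaries import first_crossing

__all__ = ["SigmoidFit", "fit_sigmoid", "sigmoid_summary_concentration"]

_FAMILIES = ("gompertz", "logistic")


def _gompertz(z, p):
    return p[0] + p[1] * np.exp(-np.exp(p[2] + p[3] * z))


def _logistic(z, p):
    return p[0] + p[1] / (1.0 + np.exp((z - p[2]) / p[3]))


_CURVES = {"gompertz": _gompertz, "logistic": _logistic}


@dataclass
class SigmoidFit:
    family: str
    params: np.ndarray
    sse: float
    residual_variance: float
    converged: bool

    def predict(self, z):
        return _CURVES[self.family](np.asarray(z, dtype=float), self.params)


def _starts(family, z, y, rng):
    """Data-driven multi-start grid: asymptote levels from the data range,
    midpoints spread over the tested doses, both slope signs."""
    lo, hi = float(np.min(y)), float(np.max(y))
    span = max(hi - lo, 1.0)
    mids = np.quantile(z, [0.25, 0.5, 0.75])
    starts = []
    if family == "gompertz":
        # g(-inf) ~ phi0 + phi1 (steep decreasing with phi3 > 0)
        for zm in mids:
            for slope in (0.8, 2.0, 5.0):
                for sign in (1.0, -1.0):
                    starts.append([lo, sign * span, -slope * zm, slope])
    else:
        for zm in mids:
            for w in (0.3, 1.0, 2.5):
                for sign in (1.0, -1.0):
                    starts.append([lo, sign * span, zm, w])
    # a few jittered replicates make the search robust to odd scalings
    base = list(starts)
    for s in base[: max(0, 12 - len(base))]:
        starts.append(list(np.asarray(s) * (1 + 0.3 * rng.standard_normal(4))))
    return starts


def fit_sigmoid(exp: Experiment, family: str = "gompertz", seed: int = 0) -> SigmoidFit:
    """Best-of-multi-start nonlinear least-squares sigmoid fit.

    Requires >= 5 distinct doses (four curve parameters plus a residual
    variance).  Never raises on optimisation failure: the convergence flag
    reports honestly.
    """
    if family not in _FAMILIES:
        raise ValueError(f"family must be one of {_FAMILIES}")
    if exp.n_doses < 5:
        raise ValueError("sigmoid fitting needs at least 5 distinct doses")
    z, y = exp.z, exp.x
    f = _CURVES[family]
    rng = np.random.default_rng(seed)
    best = None
    for p0 in _starts(family, z, y, rng):
        try:
            res = least_squares(
                lambda p: f(z, p) - y, p0, method="lm", max_nfev=2000
            )
        except Exception:
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        sse = float(2 * res.cost)
        if best is None or sse < best[0]:
            best = (sse, res.x, res.status > 0)
    if best is None:
        return SigmoidFit(family, np.full(4, np.nan), np.inf, np.inf, False)
    sse, params, ok = best
    dof = max(len(y) - 4, 1)
    return SigmoidFit(family, np.asarray(params), sse, sse / dof, bool(ok))


def sigmoid_summary_concentration(
    fit: SigmoidFit,
    kind: str,
    n0_ref: float,
    z_range: tuple[float, float],
    control_policy: str = "min_dose",
    n_grid: int = 400,
) -> float | None:
    """GI50/TGI/LC50 point estimate (molar) from a fitted sigmoid curve.

    Same threshold definitions as the posterior summaries, solved on the
    parametric curve over the tested range; returns None when the curve
    never crosses the threshold (the censored case the parametric analysis
    silently ignores).
    """
    z = np.linspace(z_range[0], z_range[1], n_grid)
    m = fit.predict(z)
    if kind == "TGI":
        level = n0_ref
    elif kind == "LC50":
        level = 0.5 * n0_ref
    elif kind == "GI50":
        g_c = (m[0] if control_policy == "min_dose" else m.max()) - n0_ref
        if g_c <= 0:
            return None
        level = n0_ref + 0.5 * g_c
    else:
        raise ValueError("kind must be GI50, TGI or LC50")
    z_star, _ = first_crossing(z, m, level)
    return None if z_star is None else float(10.0**z_star)
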