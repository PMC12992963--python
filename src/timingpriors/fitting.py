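"""Least-squares fits of the mean-response curves and derived metrics.

Two nested models are fitted to ``(T_S, TR_bar)`` points:

* the two-prior model — one curve per prior branch (short: 450-1050 ms,
  long: 1200-1800 ms), nominal parameters (mu_short, mu_long, sigma_short,
  sigma_long) with a Weber fraction w shared between branches;
* the one-prior model — a single curve over the full 450-1800 ms range
  with nominal parameters (mu_wide, sigma_wide, w).

A single curve identifies only ``mu`` and the ratio ``r = sigma / w``; the
shared-w constraint of the two-prior model is therefore vacuous at the
curve level and the branches can be fitted independently.  For fixed ``r``
the model is linear in ``mu``, so ``mu`` is profiled in closed form and the
profiled residual sum of squares is minimized over ``log10 r`` by staged
grid refinement with a final parabolic step — exact least squares on the
identified parameters, deterministic, and independent of initial values
(which the identified quantities must be).  Nominal ``sigma`` values are
back-computed from the init's Weber fraction and are *not* identified:
refitting with a different nominal w rescales them without changing the
curve.

Derived metrics: ``TR_bar(M_priors)`` evaluates each branch's curve at the
midpoint of the two prior means (1125 ms; deliberate extrapolation outside
both branches' ranges), and ``mu_hat`` — the acquired prior mean — equals
the fitted ``mu`` (= unity-line crossing).  Fitted ``mu_hat`` outside the
stimulus range [450, 1800] ms is flagged irregular, never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .design import LONG_PRIOR, M_PRIORS, SHORT_PRIOR
from .observer import DegenerateCurveError, predict_from_ratio

__all__ = [
    "DEFAULT_TWO_PRIOR_INIT",
    "DEFAULT_ONE_PRIOR_INIT",
    "BranchFit",
    "TwoPriorFit",
    "OnePriorFit",
    "FitMetrics",
    "BiasCompensation",
    "fit_branch_batch",
    "fit_two_prior",
    "fit_one_prior",
    "eval_metrics",
    "per_participant_metrics",
    "compensate_undershoot",
    "readjust_mu_hat",
]

#: (mu_short, mu_long, sigma_short, sigma_long, w) — the true design values.
DEFAULT_TWO_PRIOR_INIT = (750.0, 1500.0, 237.0, 237.0, 0.15)
#: (mu_wide, sigma_wide, w) — pooled-support moments.
DEFAULT_ONE_PRIOR_INIT = (1125.0, 454.0, 0.15)

_U_LO, _U_HI = 0.0, 7.0  # log10 r search range (r in ms)
_STAGE1_POINTS = 85
_REFINE_POINTS = 17
_REFINE_STAGES = 3
_TINY = 1e-300


def _profile_eval(u: np.ndarray, ts: np.ndarray, y: np.ndarray):
    """Profiled LS pieces at log10-ratio grid ``u``.

    ``u``: (..., G); ``ts``, ``y``: (..., k) broadcastable against u[..., None].
    Returns (mu, rss), each shaped like ``u``.
    """
    r2 = np.power(10.0, 2.0 * u)[..., None]
    a = r2 / (r2 + ts**2)
    b = 1.0 - a
    denom = np.maximum((b**2).sum(axis=-1), _TINY)
    mu = (b * (y - a * ts)).sum(axis=-1) / denom
    resid = a * ts + b * mu[..., None] - y
    return mu, (resid**2).sum(axis=-1)


def fit_branch_batch(
    Y: np.ndarray, ts: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit one curve per row of ``Y`` against the common grid ``ts``.

    Vectorized workhorse behind all fits (and the permutation test).

    Returns ``(mu, r, rss, at_bound)`` arrays of length ``Y.shape[0]``;
    ``at_bound`` marks fits whose optimum sits at the edge of the ratio
    search range (near-degenerate curves).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    ts = np.asarray(ts, dtype=float)
    m = Y.shape[0]

    u = np.linspace(_U_LO, _U_HI, _STAGE1_POINTS)
    _, rss = _profile_eval(u[None, :], ts[None, None, :], Y[:, None, :])
    best = rss.argmin(axis=1)
    at_bound = (best == 0) | (best == u.size - 1)
    u_best = u[best]
    step = u[1] - u[0]

    for _ in range(_REFINE_STAGES):
        local = u_best[:, None] + np.linspace(-step, step, _REFINE_POINTS)[None, :]
        np.clip(local, _U_LO, _U_HI, out=local)
        _, rss = _profile_eval(local, ts[None, None, :], Y[:, None, :])
        idx = rss.argmin(axis=1)
        u_best = local[np.arange(m), idx]
        step = 2.0 * step / (_REFINE_POINTS - 1)

    # parabolic interpolation through the final bracket
    tri = u_best[:, None] + np.array([-step, 0.0, step])[None, :]
    np.clip(tri, _U_LO, _U_HI, out=tri)
    _, rss3 = _profile_eval(tri, ts[None, None, :], Y[:, None, :])
    d2 = rss3[:, 0] - 2.0 * rss3[:, 1] + rss3[:, 2]
    shift = np.where(
        d2 > 0, 0.5 * step * (rss3[:, 0] - rss3[:, 2]) / np.maximum(d2, _TINY), 0.0
    )
    u_final = np.clip(u_best + np.clip(shift, -step, step), _U_LO, _U_HI)

    mu, rss = _profile_eval(u_final[:, None], ts[None, None, :], Y[:, None, :])
    return mu[:, 0], np.power(10.0, u_final), rss[:, 0], at_bound


@dataclass(frozen=True)
class BranchFit:
    """One fitted curve: identified (mu, ratio) plus fit diagnostics."""

    mu: float
    ratio: float
    rss: float
    n_points: int
    converged: bool
    at_bound: bool

    def predict(self, t_s):
        return predict_from_ratio(t_s, self.mu, self.ratio)


def _fit_branch(ts: np.ndarray, y: np.ndarray) -> BranchFit:
    ts = np.asarray(ts, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(ts).size < 2:
        raise ValueError("need at least 2 distinct t_s values per branch")
    if np.max(np.abs(y - ts)) < 1e-9:
        raise DegenerateCurveError(
            "points lie on the unity line: (mu, r) not identifiable"
        )
    mu, r, rss, at_bound = fit_branch_batch(y[None, :], ts)
    converged = bool(np.isfinite(mu[0]) and np.isfinite(rss[0]))
    return BranchFit(
        mu=float(mu[0]),
        ratio=float(r[0]),
        rss=float(rss[0]),
        n_points=ts.size,
        converged=converged,
        at_bound=bool(at_bound[0]),
    )


@dataclass(frozen=True)
class TwoPriorFit:
    """Fit of the two-prior model.

    ``mu_short``/``mu_long`` and the ratios ``r_short``/``r_long`` are
    identified; ``sigma_short``/``sigma_long``/``w`` are nominal values at
    the init's Weber fraction and are not individually identified.
    """

    mu_short: float
    mu_long: float
    sigma_short: float
    sigma_long: float
    w: float
    r_short: float
    r_long: float
    rss: float
    n_points: int
    converged: bool
    init: tuple
    at_bound: bool

    def predict(self, t_s, prior_label: str):
        r = self.r_short if prior_label == "short" else self.r_long
        mu = self.mu_short if prior_label == "short" else self.mu_long
        return predict_from_ratio(t_s, mu, r)


@dataclass(frozen=True)
class OnePriorFit:
    """Fit of the one-prior (generalized) model; same conventions."""

    mu_wide: float
    sigma_wide: float
    w: float
    r_wide: float
    rss: float
    n_points: int
    converged: bool
    init: tuple
    at_bound: bool

    def predict(self, t_s, prior_label: str = "wide"):
        return predict_from_ratio(t_s, self.mu_wide, self.r_wide)


def _branch_points(points: pd.DataFrame, label: str):
    sel = points[points["prior_label"] == label]
    if sel.empty:
        raise ValueError(f"no points for prior branch '{label}'")
    return sel["t_s"].to_numpy(float), sel["t_r_mean"].to_numpy(float)


def fit_two_prior(
    points: pd.DataFrame, init: tuple = DEFAULT_TWO_PRIOR_INIT
) -> TwoPriorFit:
    """Fit both prior branches jointly (shared nominal w).

    ``points`` needs columns prior_label, t_s, t_r_mean with >= 2 distinct
    t_s per branch.  The shared w constrains only the nominal sigmas, so
    the identified per-branch parameters come from independent exact
    branch fits; the total rss is their sum.
    """
    mu_s0, mu_l0, sig_s0, sig_l0, w0 = init
    short = _fit_branch(*_branch_points(points, "short"))
    long_ = _fit_branch(*_branch_points(points, "long"))
    return TwoPriorFit(
        mu_short=short.mu,
        mu_long=long_.mu,
        sigma_short=short.ratio * w0,
        sigma_long=long_.ratio * w0,
        w=w0,
        r_short=short.ratio,
        r_long=long_.ratio,
        rss=short.rss + long_.rss,
        n_points=short.n_points + long_.n_points,
        converged=short.converged and long_.converged,
        init=tuple(init),
        at_bound=short.at_bound or long_.at_bound,
    )


def fit_one_prior(
    points: pd.DataFrame, init: tuple = DEFAULT_ONE_PRIOR_INIT
) -> OnePriorFit:
    """Fit a single generalized-prior curve to all points (both branches)."""
    mu0, sig0, w0 = init
    ts = points["t_s"].to_numpy(float)
    y = points["t_r_mean"].to_numpy(float)
    branch = _fit_branch(ts, y)
    return OnePriorFit(
        mu_wide=branch.mu,
        sigma_wide=branch.ratio * w0,
        w=w0,
        r_wide=branch.ratio,
        rss=branch.rss,
        n_points=branch.n_points,
        converged=branch.converged,
        init=tuple(init),
        at_bound=branch.at_bound,
    )


@dataclass(frozen=True)
class FitMetrics:
    """Prior-acquisition metrics derived from a two-prior fit."""

    m_priors: float
    t_r_at_mpriors_short: float
    t_r_at_mpriors_long: float
    delta_t_r_at_mpriors: float
    mu_hat_short: float
    mu_hat_long: float
    delta_mu_hat: float
    irregular_short: bool
    irregular_long: bool


def eval_metrics(
    fit: TwoPriorFit,
    m_priors: float = M_PRIORS,
    support_range: tuple[float, float] = (
        SHORT_PRIOR.support[0],
        LONG_PRIOR.support[-1],
    ),
) -> FitMetrics:
    """TR_bar(M_priors) per branch, mu_hat per branch, and their deltas.

    Each branch's curve is evaluated at ``m_priors`` (extrapolation beyond
    the branch's own fitted range is the point of the metric).  ``mu_hat``
    is the fitted mu — identically the curve's unity-line crossing.  A
    ``mu_hat`` outside ``support_range`` is flagged irregular.
    """
    if not fit.converged:
        raise ValueError("cannot derive metrics from a non-converged fit")
    lo, hi = support_range
    t_short = float(predict_from_ratio(m_priors, fit.mu_short, fit.r_short))
    t_long = float(predict_from_ratio(m_priors, fit.mu_long, fit.r_long))
    return FitMetrics(
        m_priors=m_priors,
        t_r_at_mpriors_short=t_short,
        t_r_at_mpriors_long=t_long,
        delta_t_r_at_mpriors=t_long - t_short,
        mu_hat_short=fit.mu_short,
        mu_hat_long=fit.mu_long,
        delta_mu_hat=fit.mu_long - fit.mu_short,
        irregular_short=not (lo <= fit.mu_short <= hi),
        irregular_long=not (lo <= fit.mu_long <= hi),
    )


def per_participant_metrics(
    binned: pd.DataFrame, init: tuple = DEFAULT_TWO_PRIOR_INIT
) -> pd.DataFrame:
    """Two-prior metrics per (participant, bin) from individual binned means.

    Individual fits are noisy — mu_hat is frequently irregular at this
    level, which is why mu_hat is reported from grand-average fits — but
    the TR_bar(M_priors) columns feed the individual-level comparisons.
    """
    rows = []
    for (pid, b), grp in binned.groupby(["participant_id", "bin"], observed=True):
        fit = fit_two_prior(grp, init=init)
        m = eval_metrics(fit)
        rows.append(
            {
                "participant_id": pid,
                "bin": b,
                "t_r_at_mpriors_short": m.t_r_at_mpriors_short,
                "t_r_at_mpriors_long": m.t_r_at_mpriors_long,
                "delta_t_r_at_mpriors": m.delta_t_r_at_mpriors,
                "mu_hat_short": m.mu_hat_short,
                "mu_hat_long": m.mu_hat_long,
                "delta_mu_hat": m.delta_mu_hat,
                "irregular_short": m.irregular_short,
                "irregular_long": m.irregular_long,
                "rss": fit.rss,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class BiasCompensation:
    """Constant-bias (undershoot) compensation of grand-averaged means."""

    bias: float
    adjusted: pd.DataFrame
    readjustment_delta: Optional[float] = None


def compensate_undershoot(grand_bin: pd.DataFrame) -> BiasCompensation:
    """Average TR_bar - T_S over a bin's points and subtract it.

    ``grand_bin`` holds one bin's grand-averaged points (t_s, t_r_mean).
    ``bias`` is negative for a systematic undershoot; subtracting it lifts
    the values back toward the unity line.  Refitting is the caller's job.
    """
    bias = float((grand_bin["t_r_mean"] - grand_bin["t_s"]).mean())
    adjusted = grand_bin.copy()
    adjusted["t_r_mean"] = adjusted["t_r_mean"] - bias
    return BiasCompensation(bias=bias, adjusted=adjusted)


def readjust_mu_hat(
    fit_original: TwoPriorFit,
    fit_subtracted: TwoPriorFit,
    support_range: tuple[float, float] = (
        SHORT_PRIOR.support[0],
        LONG_PRIOR.support[-1],
    ),
) -> tuple[float, float]:
    """Re-anchor bias-compensated mu_hat values to the original long fit.

    Bias compensation shifts both branches' mu_hat; the long-prior fit is
    regular with or without compensation, so its pre-compensation value
    anchors the scale: with ``d = mu_long(subtracted) - mu_long(original)``
    the adjusted pair is ``(mu_short(sub) - d, mu_long(sub) - d)``, whose
    long entry equals the original long mu_hat exactly.

    Raises if the long-prior mu_hat is irregular in either fit.
    """
    lo, hi = support_range
    for name, fit in (("original", fit_original), ("subtracted", fit_subtracted)):
        if not fit.converged:
            raise ValueError(f"{name} fit did not converge")
        if not lo <= fit.mu_long <= hi:
            raise ValueError(f"long-prior mu_hat irregular in {name} fit")
    d = fit_subtracted.mu_long - fit_original.mu_long
    return fit_subtracted.mu_short - d, fit_subtracted.mu_long - d
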