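"""Bayesian observer model of interval timing with scalar variability.

The observer reproduces a stimulus interval ``T_S`` by combining the sensed
interval with an acquired prior over intervals.  Sensory noise obeys scalar
variability (Weber's law for time): the SD of the sensed interval grows
linearly with the interval, ``sigma_sensed = w * T_S``.  Under Gaussian
assumptions the mean reproduced interval is a precision-weighted (convex)
combination of the stimulus and the prior mean::

    TR_bar(T_S) = a * T_S + (1 - a) * mu_prior,
    a = sigma_prior**2 / (sigma_prior**2 + (w * T_S)**2)

Because ``a`` falls with ``T_S``, responses regress toward the prior mean
more strongly for longer intervals ("central tendency"), and the
``TR_bar x T_S`` curve crosses the unity line exactly at ``mu_prior``.

Only ``mu_prior`` and the ratio ``r = sigma_prior / w`` are identified by a
single mean-response curve: rescaling ``(sigma, w) -> (c*sigma, c*w)``
leaves the curve unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PriorSpec",
    "ObserverCurveParams",
    "DegenerateCurveError",
    "predict_mean_response",
    "predict_from_ratio",
    "sensory_sd",
    "prior_moments",
    "unity_intersection",
]


class DegenerateCurveError(ValueError):
    """The mean-response curve does not identify the requested quantity."""


def prior_moments(support: Sequence[float]) -> tuple[float, float]:
    """Mean and sample SD (n-1 denominator) of a discrete prior support.

    The (n-1)-denominator convention matches the nominal prior SDs used as
    fitting initial values (237 ms for the five-value short support, 454 ms
    for the pooled ten-value support).

    Raises
    ------
    ValueError
        If fewer than two distinct values are given (the SD is undefined).
    """
    values = np.asarray(support, dtype=float)
    if values.size < 2 or np.unique(values).size < 2:
        raise ValueError("prior support needs at least 2 distinct values")
    return float(values.mean()), float(values.std(ddof=1))


@dataclass(frozen=True)
class PriorSpec:
    """A discrete prior over stimulus intervals (ms)."""

    label: str
    support: tuple[float, ...]
    mu_prior: float = field(init=False)
    sigma_prior: float = field(init=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.support, dtype=float)
        if values.size == 0:
            raise ValueError("empty prior support")
        if np.any(values <= 0):
            raise ValueError("prior support values must be positive")
        if np.any(np.diff(values) <= 0):
            raise ValueError("prior support must be strictly increasing")
        mu, sigma = prior_moments(values)
        object.__setattr__(self, "support", tuple(float(v) for v in values))
        object.__setattr__(self, "mu_prior", mu)
        object.__setattr__(self, "sigma_prior", sigma)


@dataclass(frozen=True)
class ObserverCurveParams:
    """Parameters of one mean-response curve.

    Attributes
    ----------
    mu : float
        Prior mean used by the estimator (ms).
    sigma : float
        Prior SD (ms); only ``sigma / w`` is identified by the curve.
    w : float
        Weber fraction of scalar sensory variability (dimensionless).
    """

    mu: float
    sigma: float
    w: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.w < 0:
            raise ValueError("Weber fraction must be non-negative")

    @property
    def ratio(self) -> float:
        """Identified shrinkage ratio r = sigma / w (ms); inf when w = 0."""
        return self.sigma / self.w if self.w > 0 else np.inf


def sensory_sd(t_s, w):
    """SD of the sensed interval under scalar variability: ``w * t_s``."""
    t_s = np.asarray(t_s, dtype=float)
    if np.any(t_s < 0) or np.any(np.asarray(w) < 0):
        raise ValueError("t_s and w must be non-negative")
    out = w * t_s
    return float(out) if out.ndim == 0 else out

def predict_from_ratio(t_s, mu: float, ratio: float):
    """Mean-response curve parametrized by the identified (mu, r=sigma/w).

    ``ratio=inf`` (w = 0) returns ``t_s`` unchanged (no shrinkage).
    """
    t_s = np.asarray(t_s, dtype=float)
    if np.any(t_s <= 0):
        raise ValueError("t_s must be positive")
    if np.isinf(ratio):
        out = t_s.copy()
    else:
        # stable for extreme ratios: a = r^2 / (r^2 + t^2) = 1 / (1 + (t/r)^2)
        with np.errstate(over="ignore"):
            a = 1.0 / (1.0 + (t_s / ratio) ** 2)
        out = a * t_s + (1.0 - a) * mu
    return float(out) if out.ndim == 0 else out


def predict_mean_response(t_s, params: ObserverCurveParams):
    """Mean reproduced interval for stimulus ``t_s`` (ms).

    Convex combination of ``t_s`` and ``params.mu`` with weights
    ``sigma^2 / (sigma^2 + w^2 t_s^2)`` and its complement; the result
    therefore always lies between ``t_s`` and ``mu``.
    """
    return predict_from_ratio(t_s, params.mu, params.ratio)


def unity_intersection(params: ObserverCurveParams) -> float:
    """Stimulus interval at which the curve crosses the unity line.

    Solving ``predict_mean_response(T_S) = T_S`` gives
    ``(1 - a)(mu - T_S) = 0``; for ``w > 0`` the weight on the prior is
    nonzero, so the unique crossing is ``T_S = mu``.  This is how the
    acquired prior mean is read off a fitted curve.

    Raises
    ------
    DegenerateCurveError
        If ``w = 0``: the curve coincides with the unity line everywhere.
    """
    if params.w == 0:
        raise DegenerateCurveError(
            "w = 0: curve lies on the unity line, intersection undefined"
        )
    return params.mu
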