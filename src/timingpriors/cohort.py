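"""Synthetic participants: Bayesian observers generating trial-level responses.

Each observer holds acquired prior means for the short and long priors, a
per-bin merge fraction ``merge_lambda`` interpolating between two fully
independent priors (0) and one generalized prior centered on the midpoint of
the prior means (1), identified shrinkage ratios ``r = sigma/w`` per prior,
a Weber fraction for sensory sampling, additive motor noise, a constant
timing bias (negative = undershoot), a lapse rate producing erroneous
trials, and a Gaussian lag model for the concomitant motor response (CMR).

A valid trial is generated as::

    t_m ~ Normal(t_s, (w * t_s)^2)           # sensed interval, floored at 1 ms
    est  = a * t_m + (1 - a) * mu_eff,  a = r^2 / (r^2 + t_m^2)
    t_r  = est + Normal(0, sigma_motor^2) + bias

i.e. shrinkage is applied to the *sensed* interval; averaging over t_m
recovers the mean-response curve of :mod:`timingpriors.observer` up to a
small Jensen-type discrepancy (tested at the Monte-Carlo level).

Lapse trials draw one of four error modes — duplicate press, missing or
extra CMR, no response — each individually switchable; they exist to
exercise the preprocessing exclusion rules.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .design import M_PRIORS, ExperimentDesign

__all__ = [
    "ObserverParams",
    "CohortConfig",
    "sample_cohort",
    "simulate_response",
    "simulate_experiment",
    "TRIAL_COLUMNS",
]

#: Column schema of a trial table (one row per participant x trial).
TRIAL_COLUMNS = [
    "participant_id",
    "experiment_label",
    "trial_index",
    "session",
    "bin",
    "prior_label",
    "color",
    "t_s",
    "cmr_required",
    "t_r",
    "n_presses",
    "cmr_pressed",
    "cmr_lag",
]

_SENSED_FLOOR_MS = 1.0


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of one simulated participant.

    ``merge_lambda`` is a per-bin tuple; the effective prior mean for prior
    ``p`` in a bin is ``(1 - lam) * mu_hat_p + lam * M_priors``.
    """

    mu_hat_short: float = 750.0
    mu_hat_long: float = 1500.0
    merge_lambda: tuple[float, ...] = (0.0, 0.0)
    r_short: float = 237.0 / 0.15
    r_long: float = 237.0 / 0.15
    w: float = 0.15
    sigma_motor: float = 50.0
    bias: float = 0.0
    lapse_rate: float = 0.0
    cmr_lag_mean: float = 20.0
    cmr_lag_sd: float = 15.0

    def __post_init__(self) -> None:
        if not all(0.0 <= lam <= 1.0 for lam in self.merge_lambda):
            raise ValueError("merge_lambda entries must lie in [0, 1]")
        if self.sigma_motor < 0 or self.w < 0:
            raise ValueError("sigma_motor and w must be non-negative")
        if not 0.0 <= self.lapse_rate < 1.0:
            raise ValueError("lapse_rate must lie in [0, 1)")

    def effective_mu(self, prior_label: str, bin_index: int) -> float:
        lam = self.merge_lambda[bin_index - 1]
        mu_hat = self.mu_hat_short if prior_label == "short" else self.mu_hat_long
        return (1.0 - lam) * mu_hat + lam * M_PRIORS

    def ratio(self, prior_label: str) -> float:
        return self.r_short if prior_label == "short" else self.r_long


@dataclass(frozen=True)
class CohortConfig:
    """Population distributions from which observers are drawn.

    Each ``(mean, sd)`` pair parametrizes an independent Gaussian across
    participants; draws are clipped to the parameter's valid range.  The
    defaults describe a cohort that has acquired two independent priors at
    the true prior means with literature-scale Weber fractions (w ~ 0.15)
    and moderate motor noise.
    """

    n_participants: int = 20
    mu_hat_short: tuple[float, float] = (750.0, 100.0)
    mu_hat_long: tuple[float, float] = (1500.0, 100.0)
    merge_lambda: tuple[float, ...] = (0.0, 0.0)
    merge_lambda_sd: float = 0.0
    r_short: tuple[float, float] = (237.0 / 0.15, 300.0)
    r_long: tuple[float, float] = (237.0 / 0.15, 300.0)
    w: tuple[float, float] = (0.15, 0.03)
    sigma_motor: tuple[float, float] = (50.0, 15.0)
    bias: tuple[float, float] = (0.0, 0.0)
    lapse_rate: tuple[float, float] = (0.0, 0.0)
    cmr_lag_mean: tuple[float, float] = (20.0, 10.0)
    cmr_lag_sd: tuple[float, float] = (15.0, 5.0)
    # error modes available to lapse trials, each switchable
    error_modes: tuple[str, ...] = (
        "duplicate_press",
        "missing_cmr",
        "extra_cmr",
        "no_response",
    )

    def validate(self) -> None:
        bad = [
            f.name
            for f in fields(self)
            if isinstance(getattr(self, f.name), tuple)
            and f.name not in ("merge_lambda", "error_modes")
            and getattr(self, f.name)[1] < 0
        ]
        if self.merge_lambda_sd < 0:
            bad.append("merge_lambda_sd")
        if self.n_participants < 1:
            bad.append("n_participants")
        if bad:
            raise ValueError(f"negative SD / invalid population parameters: {bad}")


def merged(config: CohortConfig = CohortConfig(), pooled_width: bool = False) -> CohortConfig:
    """A cohort that generalized one prior over both interval sets.

    Only the acquired prior *mean* is merged by default.  With
    ``pooled_width`` the shrinkage ratio is also widened to the pooled
    support's SD (454 ms at w = 0.15); that flattens the curves toward the
    unity line, which makes the inferred prior mean markedly noisier — the
    same ill-conditioning that produces irregular values in real fits.
    """
    out = replace(config, merge_lambda=(1.0, 1.0))
    if pooled_width:
        out = replace(
            out,
            r_short=(454.0 / 0.15, 300.0),
            r_long=(454.0 / 0.15, 300.0),
        )
    return out


def sample_cohort(config: CohortConfig = CohortConfig(), seed: int = 0) -> list[ObserverParams]:
    """Draw ``config.n_participants`` observers; deterministic given seed."""
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_participants

    def draw(pair: tuple[float, float], lo=None, hi=None) -> np.ndarray:
        mean, sd = pair
        x = rng.normal(mean, sd, size=n)
        if lo is not None or hi is not None:
            x = np.clip(x, lo, hi)
        return x

    lam = np.clip(
        np.asarray(config.merge_lambda)[None, :]
        + rng.normal(0.0, config.merge_lambda_sd, size=(n, len(config.merge_lambda))),
        0.0,
        1.0,
    )
    cols = {
        "mu_hat_short": draw(config.mu_hat_short),
        "mu_hat_long": draw(config.mu_hat_long),
        "r_short": draw(config.r_short, lo=1.0),
        "r_long": draw(config.r_long, lo=1.0),
        "w": draw(config.w, lo=0.0),
        "sigma_motor": draw(config.sigma_motor, lo=0.0),
        "bias": draw(config.bias),
        "lapse_rate": draw(config.lapse_rate, lo=0.0, hi=0.99),
        "cmr_lag_mean": draw(config.cmr_lag_mean),
        "cmr_lag_sd": draw(config.cmr_lag_sd, lo=0.0),
    }
    return [
        ObserverParams(
            merge_lambda=tuple(lam[i]),
            **{k: float(v[i]) for k, v in cols.items()},
        )
        for i in range(n)
    ]


def _simulate_valid_block(
    observer: ObserverParams,
    t_s: np.ndarray,
    prior_label: np.ndarray,
    bins: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized valid-trial responses for one observer."""
    t_m = rng.normal(t_s, observer.w * t_s)
    t_m = np.maximum(t_m, _SENSED_FLOOR_MS)
    if observer.w == 0:
        # no sensory noise: the Bayesian weight on the measurement is 1
        est = t_m
    else:
        r = np.where(prior_label == "short", observer.r_short, observer.r_long)
        lam = np.asarray(observer.merge_lambda)[bins - 1]
        mu_hat = np.where(
            prior_label == "short", observer.mu_hat_short, observer.mu_hat_long
        )
        mu_eff = (1.0 - lam) * mu_hat + lam * M_PRIORS
        a = r**2 / (r**2 + t_m**2)
        est = a * t_m + (1.0 - a) * mu_eff
    return est + rng.normal(0.0, observer.sigma_motor, size=t_s.size) + observer.bias


def simulate_response(
    observer: ObserverParams,
    trial: pd.Series | dict,
    bin_index: int,
    rng: np.random.Generator,
    error_modes: Sequence[str] = CohortConfig.error_modes,
) -> dict:
    """Simulate one trial; returns a TrialRecord-shaped dict.

    With probability ``lapse_rate`` the trial is erroneous (one of the
    enabled ``error_modes``); otherwise the response follows the generative
    model in the module docstring.
    """
    t_s = float(trial["t_s"])
    if t_s <= 0:
        raise ValueError("t_s must be positive")
    label = trial["prior_label"]
    cmr_required = bool(trial["cmr_required"])

    record = {
        "prior_label": label,
        "t_s": t_s,
        "cmr_required": cmr_required,
        "n_presses": 1,
        "cmr_pressed": cmr_required,
        "cmr_lag": np.nan,
        "t_r": np.nan,
    }

    lapse = error_modes and rng.random() < observer.lapse_rate
    t_r = float(
        _simulate_valid_block(
            observer,
            np.array([t_s]),
            np.array([label]),
            np.array([bin_index]),
            rng,
        )[0]
    )
    record["t_r"] = t_r
    if lapse:
        mode = error_modes[int(rng.integers(len(error_modes)))]
        # CMR modes only apply where the design makes them erroneous
        if mode == "missing_cmr" and not cmr_required:
            mode = "duplicate_press"
        if mode == "extra_cmr" and cmr_required:
            mode = "duplicate_press"
        if mode == "duplicate_press":
            record["n_presses"] = 2
        elif mode == "missing_cmr":
            record["cmr_pressed"] = False
        elif mode == "extra_cmr":
            record["cmr_pressed"] = True
        elif mode == "no_response":
            record["t_r"] = np.nan
            record["n_presses"] = 0
    if record["cmr_pressed"] and not np.isnan(record["t_r"]):
        record["cmr_lag"] = float(
            rng.normal(observer.cmr_lag_mean, observer.cmr_lag_sd)
        )
    return record


def simulate_experiment(
    designs: ExperimentDesign | Sequence[ExperimentDesign],
    cohort: Sequence[ObserverParams],
    seed: int = 0,
    experiment_label: str = "sim",
    error_modes: Sequence[str] = CohortConfig.error_modes,
) -> pd.DataFrame:
    """Simulate a full cohort; one TrialRecord row per participant x trial.

    ``designs`` may be a single schedule shared by all participants or one
    schedule per participant (e.g. from counterbalanced configs).
    Deterministic given ``seed``.
    """
    if isinstance(designs, ExperimentDesign):
        designs = [designs] * len(cohort)
    if len(designs) != len(cohort):
        raise ValueError("need one design (or one per participant)")

    rng = np.random.default_rng(seed)
    frames = []
    for pid, (observer, design) in enumerate(zip(cohort, designs), start=1):
        trials = design.trials
        t_s = trials["t_s"].to_numpy(float)
        labels = trials["prior_label"].to_numpy()
        bins = trials["bin"].to_numpy(int)
        n = len(trials)

        t_r = _simulate_valid_block(observer, t_s, labels, bins, rng)
        n_presses = np.ones(n, dtype=int)
        cmr_required = trials["cmr_required"].to_numpy(bool).copy()
        cmr_pressed = cmr_required.copy()

        if error_modes and observer.lapse_rate > 0:
            lapse = rng.random(n) < observer.lapse_rate
            modes = rng.integers(len(error_modes), size=n)
            for m, mode in enumerate(error_modes):
                sel = lapse & (modes == m)
                # CMR modes only apply where the design makes them erroneous;
                # elsewhere fall back to a duplicate press
                if mode == "missing_cmr":
                    fallback = sel & ~cmr_required
                    sel = sel & cmr_required
                    n_presses[fallback] = 2
                    cmr_pressed[sel] = False
                elif mode == "extra_cmr":
                    fallback = sel & cmr_required
                    sel = sel & ~cmr_required
                    n_presses[fallback] = 2
                    cmr_pressed[sel] = True
                elif mode == "duplicate_press":
                    n_presses[sel] = 2
                elif mode == "no_response":
                    t_r[sel] = np.nan
                    n_presses[sel] = 0

        cmr_lag = np.full(n, np.nan)
        has_lag = cmr_pressed & ~np.isnan(t_r)
        cmr_lag[has_lag] = rng.normal(
            observer.cmr_lag_mean, observer.cmr_lag_sd, size=int(has_lag.sum())
        )

        frame = trials.copy()
        frame.insert(0, "participant_id", pid)
        frame.insert(1, "experiment_label", experiment_label)
        frame["cmr_required"] = cmr_required
        frame["t_r"] = t_r
        frame["n_presses"] = n_presses
        frame["cmr_pressed"] = cmr_pressed
        frame["cmr_lag"] = cmr_lag
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]
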