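"""Trial schedules for the two-prior coincidence timing task.

The task presents 640 trials (16 sessions of 40).  Each trial draws its
stimulus interval from one of two discrete uniform priors — a short prior
(450, 600, 750, 900, 1050 ms) and a long prior (1200, 1350, 1500, 1650,
1800 ms) — which strictly alternate from trial to trial and are bound to
stimulus colors (green/orange).  A concomitant motor response (CMR) may be
required selectively for one prior.  Analyses split the run into two
320-trial bins with 160 trials per prior in each.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .observer import PriorSpec

__all__ = [
    "SHORT_PRIOR",
    "LONG_PRIOR",
    "M_PRIORS",
    "DesignConfig",
    "ExperimentDesign",
    "generate_schedule",
    "counterbalance_assignments",
]

SHORT_PRIOR = PriorSpec("short", (450.0, 600.0, 750.0, 900.0, 1050.0))
LONG_PRIOR = PriorSpec("long", (1200.0, 1350.0, 1500.0, 1650.0, 1800.0))

#: Midpoint of the two prior means (ms); evaluation point for TR_bar metrics.
M_PRIORS = (SHORT_PRIOR.mu_prior + LONG_PRIOR.mu_prior) / 2.0

SCHEDULE_COLUMNS = [
    "trial_index",
    "session",
    "bin",
    "prior_label",
    "color",
    "t_s",
    "cmr_required",
]


@dataclass(frozen=True)
class DesignConfig:
    """Design parameters for one participant's schedule.

    ``sampling="balanced"`` draws each support value equally often per prior
    per bin (32 times under the defaults), which guarantees the per-``T_S``
    cell counts the preprocessing relies on; ``sampling="iid"`` draws
    uniformly with replacement.
    """

    short_prior: PriorSpec = SHORT_PRIOR
    long_prior: PriorSpec = LONG_PRIOR
    prior_colors: tuple[tuple[str, str], ...] = (
        ("short", "green"),
        ("long", "orange"),
    )
    cmr_prior: Optional[str] = None  # None, "short" or "long"
    n_trials: int = 640
    trials_per_session: int = 40
    n_bins: int = 2
    sampling: str = "balanced"  # "balanced" | "iid"
    first_prior: Optional[str] = None  # None -> chosen by seed

    def prior(self, label: str) -> PriorSpec:
        if label == "short":
            return self.short_prior
        if label == "long":
            return self.long_prior
        raise KeyError(label)

    @property
    def color_of(self) -> dict[str, str]:
        return dict(self.prior_colors)

    def validate(self) -> None:
        errors = []
        if self.n_trials % 2:
            errors.append("n_trials must be even for strict prior alternation")
        if self.n_trials % self.trials_per_session:
            errors.append("n_trials must divide into whole sessions")
        if self.n_trials % (2 * self.n_bins):
            errors.append("bins must contain equal per-prior trial counts")
        if sorted(self.color_of) != ["long", "short"]:
            errors.append("prior_colors must map exactly {short, long}")
        if len(set(self.color_of.values())) != 2:
            errors.append("prior_colors must be a bijection")
        if self.cmr_prior not in (None, "short", "long"):
            errors.append("cmr_prior must be None, 'short' or 'long'")
        if self.sampling not in ("balanced", "iid"):
            errors.append("sampling must be 'balanced' or 'iid'")
        if self.sampling == "balanced":
            per_bin = self.n_trials // (2 * self.n_bins)
            for prior in (self.short_prior, self.long_prior):
                if per_bin % len(prior.support):
                    errors.append(
                        f"balanced mode: {per_bin} trials per bin for prior "
                        f"'{prior.label}' not divisible by its "
                        f"{len(prior.support)} support values"
                    )
        if errors:
            raise ValueError("invalid design config: " + "; ".join(errors))


@dataclass(frozen=True)
class ExperimentDesign:
    """A generated schedule: one row per trial plus counterbalance metadata."""

    trials: pd.DataFrame
    config: DesignConfig
    seed: int

    def to_csv(self, path) -> None:
        """Write the schedule as CSV with metadata comment lines."""
        meta = io.StringIO()
        meta.write(f"# seed: {self.seed}\n")
        meta.write(f"# prior_colors: {self.config.color_of}\n")
        meta.write(f"# cmr_prior: {self.config.cmr_prior}\n")
        meta.write(f"# sampling: {self.config.sampling}\n")
        with open(path, "w") as fh:
            fh.write(meta.getvalue())
            self.trials.to_csv(fh, index=False)


def _bin_of(trial_index: np.ndarray, n_trials: int, n_bins: int) -> np.ndarray:
    per_bin = n_trials // n_bins
    return (trial_index - 1) // per_bin + 1


def generate_schedule(config: DesignConfig = DesignConfig(), seed: int = 0) -> ExperimentDesign:
    """Generate one participant's trial schedule.

    Priors alternate strictly; within each bin every prior contributes
    ``n_trials / (2 * n_bins)`` trials.  In balanced mode the support values
    of each prior are shuffled in equal counts within each (bin, prior)
    stratum; in iid mode each trial's interval is drawn uniformly from the
    labeled prior's support.  Deterministic given ``(config, seed)``.
    """
    config.validate()
    rng = np.random.default_rng(seed)

    first = config.first_prior or ("short" if rng.integers(2) == 0 else "long")
    if first not in ("short", "long"):
        raise ValueError("first_prior must be 'short' or 'long'")
    labels = np.where(
        np.arange(config.n_trials) % 2 == 0,
        first,
        "short" if first == "long" else "long",
    )

    trial_index = np.arange(1, config.n_trials + 1)
    bins = _bin_of(trial_index, config.n_trials, config.n_bins)
    t_s = np.empty(config.n_trials)
    for label in ("short", "long"):
        support = np.asarray(config.prior(label).support)
        for b in range(1, config.n_bins + 1):
            mask = (labels == label) & (bins == b)
            n_cell = int(mask.sum())
            if config.sampling == "balanced":
                reps = np.tile(support, n_cell // support.size)
                t_s[mask] = rng.permutation(reps)
            else:
                t_s[mask] = rng.choice(support, size=n_cell, replace=True)

    color_of = config.color_of
    trials = pd.DataFrame(
        {
            "trial_index": trial_index,
            "session": (trial_index - 1) // config.trials_per_session + 1,
            "bin": bins,
            "prior_label": labels,
            "color": [color_of[lab] for lab in labels],
            "t_s": t_s,
            "cmr_required": labels == config.cmr_prior
            if config.cmr_prior
            else np.zeros(config.n_trials, dtype=bool),
        }
    )
    return ExperimentDesign(trials=trials, config=config, seed=int(seed))


def counterbalance_assignments(
    n_participants: int, base: DesignConfig = DesignConfig(), with_cmr: bool = True
) -> list[DesignConfig]:
    """Per-participant design configs balancing the condition combinations.

    The four combinations cross the prior<->color pairing with which color
    carries the CMR (when ``with_cmr``).  If ``n_participants`` is not a
    multiple of the number of combinations, assignment is maximally balanced
    and a warning is issued.
    """
    pairings = [
        (("short", "green"), ("long", "orange")),
        (("short", "orange"), ("long", "green")),
    ]
    combos: list[DesignConfig] = []
    for pairing in pairings:
        if with_cmr:
            for cmr_color in ("green", "orange"):
                cmr_prior = next(p for p, c in pairing if c == cmr_color)
                combos.append(
                    replace(base, prior_colors=pairing, cmr_prior=cmr_prior)
                )
        else:
            combos.append(replace(base, prior_colors=pairing, cmr_prior=None))
    if n_participants % len(combos):
        warnings.warn(
            f"{n_participants} participants cannot be split evenly over "
            f"{len(combos)} condition combinations; using maximal balance",
            stacklevel=2,
        )
    return [combos[i % len(combos)] for i in range(n_participants)]
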