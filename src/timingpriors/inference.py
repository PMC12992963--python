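"""Permutation test on prior-divergence metrics and AICc model comparison.

Two bespoke procedures:

* **Permutation test** — is the long-minus-short divergence of acquired
  prior means (delta mu_hat, from grand-average fits) larger in a test
  experiment than in a control experiment?  Participants' per-bin
  ``TR_bar x T_S`` profiles are pooled across the two experiments and
  randomly reassigned to the two labels (group sizes preserved); each
  reassignment is grand-averaged, curve-fitted, and scored by the
  difference in delta mu_hat (test minus control).  The p-value is the
  fraction of permutation differences strictly exceeding the observed one,
  reported against a Bonferroni-corrected alpha = 0.05 / 2 (two trial
  bins).  Iterations producing irregular mu_hat values can be removed
  (counted) before computing p.

* **AICc / Akaike weights** — compares the one-prior and two-prior models
  fitted to grand-averaged means, using every participant's binned means
  as residuals (n = participants x 10 per bin) under a Gaussian
  likelihood: ``AICc = n ln(rss / n) + 2K + 2K(K+1) / (n - K - 1)``.  By
  default K counts the residual-variance parameter (K = k + 1, i.e. 6 vs 4
  nominal parameters); the K = k convention is available via a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .design import LONG_PRIOR, SHORT_PRIOR
from .fitting import fit_branch_batch

__all__ = [
    "ModelComparison",
    "PermutationResult",
    "compute_aicc",
    "akaike_weights",
    "compare_models",
    "permutation_test",
]

#: nominal parameter counts: (mu_wide, sigma_wide, w) vs
#: (mu_short, mu_long, sigma_short, sigma_long, w)
K_ONE_PRIOR = 3
K_TWO_PRIOR = 5

_IRREGULAR_MAGNITUDE_MS = 10_000.0
_RANGE_MS = (SHORT_PRIOR.support[0], LONG_PRIOR.support[-1])


def compute_aicc(residuals: Sequence[float], k: int, count_noise_param: bool = True) -> float:
    """Small-sample-corrected AIC from Gaussian residuals.

    ``k`` is the model's nominal parameter count; with
    ``count_noise_param`` (default) the effective count is K = k + 1 for
    the fitted residual variance.
    """
    residuals = np.asarray(residuals, dtype=float)
    n = residuals.size
    K = k + 1 if count_noise_param else k
    if n <= K + 1:
        raise ValueError(f"AICc undefined: n={n} <= K+1={K + 1}")
    rss = float((residuals**2).sum())
    return n * np.log(rss / n) + 2 * K + 2 * K * (K + 1) / (n - K - 1)


def akaike_weights(aicc_values: Sequence[float]) -> np.ndarray:
    """Normalized relative evidence exp(-delta_i / 2) per model.

    Computed after subtracting the minimum AICc for overflow safety;
    always sums to 1.
    """
    aicc = np.asarray(aicc_values, dtype=float)
    if not np.all(np.isfinite(aicc)):
        raise ValueError("AICc values must be finite")
    rel = np.exp(-0.5 * (aicc - aicc.min()))
    return rel / rel.sum()


@dataclass(frozen=True)
class ModelComparison:
    """One-prior vs two-prior evidence for a single trial bin."""

    bin: int
    aicc_one: float
    aicc_two: float
    weight_one: float
    weight_two: float
    n_residuals: int
    k_one: int
    k_two: int
    rss_one: float
    rss_two: float


def compare_models(
    binned: pd.DataFrame,
    bin: int,
    count_noise_param: bool = True,
) -> ModelComparison:
    """Fit both models to a bin's grand average and compare by AICc.

    ``binned`` is the per-participant binned-means table (all bins are
    accepted; only ``bin`` is used).  Residuals are every participant's
    binned mean minus the grand-average-fitted curve at that point.
    """
    from .fitting import fit_one_prior, fit_two_prior
    from .preprocess import grand_average

    sub = binned[binned["bin"] == bin]
    if sub.empty:
        raise ValueError(f"no binned means for bin {bin}")
    grand = grand_average(sub)

    fit2 = fit_two_prior(grand)
    fit1 = fit_one_prior(grand)

    ts = sub["t_s"].to_numpy(float)
    y = sub["t_r_mean"].to_numpy(float)
    labels = sub["prior_label"].to_numpy()
    pred2 = np.where(
        labels == "short",
        np.asarray(fit2.predict(ts, "short")),
        np.asarray(fit2.predict(ts, "long")),
    )
    resid2 = y - pred2
    resid1 = y - np.asarray(fit1.predict(ts))

    aicc1 = compute_aicc(resid1, K_ONE_PRIOR, count_noise_param)
    aicc2 = compute_aicc(resid2, K_TWO_PRIOR, count_noise_param)
    w1, w2 = akaike_weights([aicc1, aicc2])
    return ModelComparison(
        bin=bin,
        aicc_one=aicc1,
        aicc_two=aicc2,
        weight_one=float(w1),
        weight_two=float(w2),
        n_residuals=len(sub),
        k_one=K_ONE_PRIOR,
        k_two=K_TWO_PRIOR,
        rss_one=float((resid1**2).sum()),
        rss_two=float((resid2**2).sum()),
    )


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of the between-experiment permutation test for one bin."""

    observed_diff: float
    n_perm: int
    n_exceed: int
    n_removed_irregular: int
    p_value: float
    alpha_corrected: float
    seed: Optional[int]
    method: str
    diffs: np.ndarray = field(repr=False)


def _profile_matrix(binned: pd.DataFrame, bin: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Participants-by-points matrix of TR_bar profiles for one bin.

    Columns ordered short-prior t_s ascending then long-prior t_s
    ascending; returns (matrix, ts_short, ts_long).
    """
    sub = binned[binned["bin"] == bin]
    if sub.empty:
        raise ValueError(f"no binned means for bin {bin}")
    pieces = []
    grids = {}
    for label in ("short", "long"):
        wide = sub[sub["prior_label"] == label].pivot(
            index="participant_id", columns="t_s", values="t_r_mean"
        )
        wide = wide.sort_index(axis=1)
        if wide.isna().any().any():
            raise ValueError("incomplete TR_bar profiles (missing cells)")
        grids[label] = wide.columns.to_numpy(float)
        pieces.append(wide.to_numpy(float))
    return np.hstack(pieces), grids["short"], grids["long"]


def _delta_mu_hat_batch(
    Y: np.ndarray,
    ts_short: np.ndarray,
    ts_long: np.ndarray,
    bias_compensation: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-row delta mu_hat (long - short) from grand-average profiles.

    ``Y``: (m, 10) rows of grand-averaged TR_bar over the combined grid.
    Returns (delta_mu_hat, mu_hats) with mu_hats shaped (m, 2).
    """
    ts_all = np.concatenate([ts_short, ts_long])
    k_s = ts_short.size

    def fit_rows(rows: np.ndarray) -> np.ndarray:
        mu_s, _, _, _ = fit_branch_batch(rows[:, :k_s], ts_short)
        mu_l, _, _, _ = fit_branch_batch(rows[:, k_s:], ts_long)
        return np.column_stack([mu_s, mu_l])

    if bias_compensation == "never":
        mus = fit_rows(Y)
    elif bias_compensation == "always":
        bias = (Y - ts_all[None, :]).mean(axis=1, keepdims=True)
        mus = fit_rows(Y - bias)
    elif bias_compensation == "auto":
        mus = fit_rows(Y)
        lo, hi = _RANGE_MS
        redo = ~((mus >= lo) & (mus <= hi)).all(axis=1)
        if redo.any():
            bias = (Y[redo] - ts_all[None, :]).mean(axis=1, keepdims=True)
            mus[redo] = fit_rows(Y[redo] - bias)
    else:
        raise ValueError("bias_compensation must be 'never', 'always' or 'auto'")
    return mus[:, 1] - mus[:, 0], mus


def _irregular_mask(mu_hats: np.ndarray, rule: str) -> np.ndarray:
    if rule == "magnitude":
        return (np.abs(mu_hats) > _IRREGULAR_MAGNITUDE_MS).any(axis=1)
    if rule == "range":
        lo, hi = _RANGE_MS
        return ~((mu_hats >= lo) & (mu_hats <= hi)).all(axis=1)
    raise ValueError("irregular_rule must be 'magnitude' or 'range'")


def permutation_test(
    binned_test: pd.DataFrame,
    binned_control: pd.DataFrame,
    bin: int,
    n_perm: int = 10_000,
    seed: Optional[int] = 0,
    bias_compensation: str = "never",
    irregular_rule: str = "magnitude",
    remove_irregular: bool = True,
    alpha: float = 0.05,
    n_comparisons: int = 2,
    method: str = "monte_carlo",
) -> PermutationResult:
    """Test whether delta mu_hat is larger in the test experiment.

    Both groups must have equal participant counts and identical t_s
    grids.  ``method="exhaustive"`` enumerates every size-preserving label
    split (small groups only) instead of Monte-Carlo sampling.
    ``bias_compensation`` ("never" | "always" | "auto") is applied
    identically to the observed and permuted grand averages.  With
    ``remove_irregular``, iterations whose mu_hat values violate
    ``irregular_rule`` ("magnitude": |mu_hat| > 10000 ms; "range": outside
    450-1800 ms) are dropped from both numerator and denominator.
    """
    X_test, ts_s, ts_l = _profile_matrix(binned_test, bin)
    X_ctrl, ts_s2, ts_l2 = _profile_matrix(binned_control, bin)
    if X_test.shape[0] != X_ctrl.shape[0]:
        raise ValueError(
            f"unequal group sizes: {X_test.shape[0]} vs {X_ctrl.shape[0]}"
        )
    if not (np.array_equal(ts_s, ts_s2) and np.array_equal(ts_l, ts_l2)):
        raise ValueError("t_s grids differ between the two experiments")
    n_group = X_test.shape[0]
    pooled = np.vstack([X_test, X_ctrl])
    n_total = 2 * n_group

    obs_delta, obs_mus = _delta_mu_hat_batch(
        np.vstack([X_test.mean(axis=0), X_ctrl.mean(axis=0)]),
        ts_s,
        ts_l,
        bias_compensation,
    )
    observed = float(obs_delta[0] - obs_delta[1])
    if _irregular_mask(obs_mus.reshape(1, -1), irregular_rule)[0]:
        warnings.warn(
            "observed grand-average fit has irregular mu_hat values",
            stacklevel=2,
        )

    if method == "exhaustive":
        splits = list(combinations(range(n_total), n_group))
        assert len(splits) == comb(n_total, n_group)
        test_idx = np.array(splits)
        n_iter = test_idx.shape[0]
    elif method == "monte_carlo":
        rng = np.random.default_rng(seed)
        order = np.argsort(rng.random((n_perm, n_total)), axis=1)
        test_idx = order[:, :n_group]
        n_iter = n_perm
    else:
        raise ValueError("method must be 'monte_carlo' or 'exhaustive'")

    mask = np.zeros((n_iter, n_total), dtype=bool)
    np.put_along_axis(mask, test_idx, True, axis=1)
    Y_test = (mask.astype(float) @ pooled) / n_group
    Y_ctrl = ((~mask).astype(float) @ pooled) / n_group

    d_test, mus_test = _delta_mu_hat_batch(Y_test, ts_s, ts_l, bias_compensation)
    d_ctrl, mus_ctrl = _delta_mu_hat_batch(Y_ctrl, ts_s, ts_l, bias_compensation)
    diffs = d_test - d_ctrl

    irregular = _irregular_mask(
        np.hstack([mus_test, mus_ctrl]), irregular_rule
    )
    if remove_irregular:
        retained = diffs[~irregular]
        n_removed = int(irregular.sum())
    else:
        retained = diffs
        n_removed = 0
    if irregular.sum() > 0.1 * n_iter:
        warnings.warn(
            f"{irregular.sum()}/{n_iter} permutation iterations had "
            "irregular mu_hat values",
            stacklevel=2,
        )
    if retained.size == 0:
        raise ValueError("all permutation iterations were removed as irregular")

    n_exceed = int((retained > observed).sum())
    return PermutationResult(
        observed_diff=observed,
        n_perm=n_iter,
        n_exceed=n_exceed,
        n_removed_irregular=n_removed,
        p_value=n_exceed / retained.size,
        alpha_corrected=alpha / n_comparisons,
        seed=seed if method == "monte_carlo" else None,
        method=method,
        diffs=diffs,
    )
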