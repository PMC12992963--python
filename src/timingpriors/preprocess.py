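"""Trial exclusion rules and binned response means.

Exclusions happen in a fixed two-stage order:

1. *Validity flags* — a trial is erroneous if it has no timing press,
   more than one press of the same button/switch, a missing concomitant
   response where one was required, or an unrequired concomitant response.
2. *Outlier flags* — among valid trials, a response is an outlier if it
   lies strictly outside mean +/- 3 SD computed per (participant, bin, T_S)
   over valid trials; the SD uses the n-1 denominator and boundary values
   are retained (closed interval).  Flagging is single-pass.

Surviving trials are averaged per (participant, bin, prior, T_S) into
binned means, and across participants into grand averages.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "flag_invalid_trials",
    "remove_outliers",
    "compute_binned_means",
    "grand_average",
    "preprocess",
    "exclusion_report",
]

REQUIRED_COLUMNS = [
    "participant_id",
    "trial_index",
    "bin",
    "prior_label",
    "t_s",
    "cmr_required",
    "t_r",
    "n_presses",
    "cmr_pressed",
]

_MIN_GROUP_FOR_SD = 3


def _check_schema(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise KeyError(f"trial table is missing required columns: {missing}")


def flag_invalid_trials(table: pd.DataFrame) -> pd.DataFrame:
    """Add ``valid`` and ``exclusion_reason`` columns; rows are preserved.

    Reasons (first matching wins): ``no_response``, ``multiple_press``,
    ``missing_cmr``, ``extra_cmr``.
    """
    _check_schema(table)
    out = table.copy()
    t_r = out["t_r"].to_numpy(float)
    n_presses = out["n_presses"].to_numpy(int)
    required = out["cmr_required"].to_numpy(bool)
    pressed = out["cmr_pressed"].to_numpy(bool)

    reason = np.full(len(out), "", dtype=object)
    checks = [
        ("no_response", np.isnan(t_r) | (n_presses < 1) | (t_r <= 0)),
        ("multiple_press", n_presses > 1),
        ("missing_cmr", required & ~pressed),
        ("extra_cmr", ~required & pressed),
    ]
    for name, mask in checks:
        reason[(reason == "") & mask] = name
    out["valid"] = reason == ""
    out["exclusion_reason"] = reason
    return out


def remove_outliers(table: pd.DataFrame) -> pd.DataFrame:
    """Add an ``outlier`` column using the +/- 3 SD rule on valid trials.

    Groups (participant, bin, t_s) with fewer than 3 valid trials cannot
    support the SD criterion; they are left unflagged with a warning.
    Idempotent: re-running on its own output changes nothing.
    """
    if "valid" not in table.columns:
        raise KeyError("run flag_invalid_trials before remove_outliers")
    out = table.copy()
    out["outlier"] = False

    small_groups = []
    valid = out[out["valid"]]
    for key, grp in valid.groupby(["participant_id", "bin", "t_s"], sort=False):
        if len(grp) < _MIN_GROUP_FOR_SD:
            small_groups.append(key)
            continue
        values = grp["t_r"].to_numpy(float)
        mean, sd = values.mean(), values.std(ddof=1)
        flag = np.abs(values - mean) > 3.0 * sd  # closed interval retained
        out.loc[grp.index[flag], "outlier"] = True
    if small_groups:
        warnings.warn(
            f"{len(small_groups)} (participant, bin, t_s) cells had fewer "
            f"than {_MIN_GROUP_FOR_SD} valid trials; outlier rule skipped there",
            stacklevel=2,
        )
    return out


def compute_binned_means(table: pd.DataFrame) -> pd.DataFrame:
    """Mean T_R over surviving trials per (participant, bin, prior, T_S).

    Returns columns participant_id, bin, prior_label, t_s, t_r_mean,
    n_used, n_excluded.  An empty cell (all trials excluded) is an error.
    """
    if "outlier" not in table.columns:
        raise KeyError("run flag_invalid_trials and remove_outliers first")
    keep = table["valid"] & ~table["outlier"]
    grouped = table.assign(_keep=keep).groupby(
        ["participant_id", "bin", "prior_label", "t_s"], sort=True, observed=True
    )
    rows = []
    for key, grp in grouped:
        used = grp[grp["_keep"]]
        if used.empty:
            raise ValueError(
                f"all trials excluded in cell (participant, bin, prior, t_s) = {key}"
            )
        rows.append(
            {
                "participant_id": key[0],
                "bin": key[1],
                "prior_label": key[2],
                "t_s": key[3],
                "t_r_mean": used["t_r"].mean(),
                "n_used": len(used),
                "n_excluded": len(grp) - len(used),
            }
        )
    return pd.DataFrame(rows)


def grand_average(binned: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean of per-participant binned means across participants.

    Every participant must contribute every (bin, prior, t_s) cell;
    ragged participation is an error (the per-participant stage should
    already have failed on empty cells).
    """
    counts = binned.groupby(["bin", "prior_label", "t_s"], observed=True)[
        "participant_id"
    ].nunique()
    n_participants = binned["participant_id"].nunique()
    if (counts != n_participants).any():
        raise ValueError("ragged participation: some cells miss participants")
    out = (
        binned.groupby(["bin", "prior_label", "t_s"], sort=True, observed=True)[
            "t_r_mean"
        ]
        .mean()
        .reset_index()
    )
    out["n_participants"] = n_participants
    return out


def preprocess(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full chain: flags -> outliers -> binned means -> grand average."""
    flagged = remove_outliers(flag_invalid_trials(table))
    binned = compute_binned_means(flagged)
    return flagged, binned, grand_average(binned)


def exclusion_report(flagged: pd.DataFrame) -> pd.DataFrame:
    """Per-participant exclusion counts by reason (including outliers)."""
    out = flagged.copy()
    reason = out["exclusion_reason"].astype(str)
    if "outlier" in out.columns:
        reason = reason.mask(out["outlier"] & (reason == ""), "outlier")
    out["reason"] = reason.replace("", "kept")
    tally = (
        out.groupby(["participant_id", "reason"], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    return tally.reset_index()
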