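"""End-to-end orchestration: simulate, preprocess, fit, compare, permute.

Everything here composes the other modules; no science lives in this file.
Tabular outputs are comma-separated text with a header row; fit results
and test outcomes are serialized as key-value text and JSON-compatible
dicts.  A run's configuration is echoed verbatim into its output
directory, and all randomness flows from a single seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortConfig, sample_cohort, simulate_experiment
from .design import DesignConfig, counterbalance_assignments, generate_schedule
from .fitting import (
    BiasCompensation,
    FitMetrics,
    OnePriorFit,
    TwoPriorFit,
    compensate_undershoot,
    eval_metrics,
    fit_one_prior,
    fit_two_prior,
    per_participant_metrics,
    readjust_mu_hat,
)
from .inference import ModelComparison, PermutationResult, compare_models, permutation_test
from .preprocess import exclusion_report, grand_average, preprocess

__all__ = [
    "PipelineConfig",
    "BinAnalysis",
    "AnalysisReport",
    "run_simulation",
    "run_analysis",
    "simulate_trials",
    "write_report",
    "permutation_replicate",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Serializable configuration of a full run."""

    seed: int = 0
    experiment_label: str = "sim"
    with_cmr: bool = True
    design: DesignConfig = field(default_factory=DesignConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    bias_compensation: str = "auto"  # "never" | "always" | "auto"
    n_perm: int = 10_000
    count_noise_param: bool = True
    irregular_rule: str = "magnitude"

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        """Build from a plain mapping; unknown keys raise a named error."""
        raw = dict(raw)
        known = {f.name for f in fields(cls)}
        bad = sorted(set(raw) - known)
        if bad:
            raise ValueError(f"unknown config keys: {bad}")
        for key, sub_cls in (("design", DesignConfig), ("cohort", CohortConfig)):
            if key in raw and isinstance(raw[key], dict):
                sub_known = {f.name for f in fields(sub_cls)}
                sub_bad = sorted(set(raw[key]) - sub_known)
                if sub_bad:
                    raise ValueError(f"unknown {key} config keys: {sub_bad}")
                sub = dict(raw[key])
                for name in sub:
                    if isinstance(sub[name], list):
                        sub[name] = tuple(
                            tuple(v) if isinstance(v, list) else v for v in sub[name]
                        )
                raw[key] = sub_cls(**sub)
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        def plain(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {
                    f.name: plain(getattr(obj, f.name))
                    for f in fields(obj)
                    if f.init
                }
            if isinstance(obj, (tuple, list)):
                return [plain(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        with open(path, "w") as fh:
            yaml.safe_dump(plain(self), fh, sort_keys=False)

    def validate(self) -> None:
        errors = []
        if self.bias_compensation not in ("never", "always", "auto"):
            errors.append("bias_compensation")
        if self.irregular_rule not in ("magnitude", "range"):
            errors.append("irregular_rule")
        if self.n_perm < 1:
            errors.append("n_perm")
        if errors:
            raise ValueError(f"invalid config values for keys: {errors}")
        self.design.validate()
        self.cohort.validate()


def simulate_trials(config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame, list]:
    """Simulate one experiment's cohort under counterbalanced designs.

    Returns (trial table, combined schedule table, cohort parameter list).
    Deterministic given ``config.seed``.
    """
    config.validate()
    n = config.cohort.n_participants
    design_configs = counterbalance_assignments(
        n, base=config.design, with_cmr=config.with_cmr
    )
    designs = [
        generate_schedule(dc, seed=config.seed * 100_003 + i)
        for i, dc in enumerate(design_configs)
    ]
    observers = sample_cohort(config.cohort, seed=config.seed + 1)
    trials = simulate_experiment(
        designs,
        observers,
        seed=config.seed + 2,
        experiment_label=config.experiment_label,
    )
    schedule = pd.concat(
        [d.trials.assign(participant_id=i + 1) for i, d in enumerate(designs)],
        ignore_index=True,
    )
    return trials, schedule, observers


def run_simulation(config: PipelineConfig, outdir) -> dict[str, Path]:
    """Simulate and write schedule.csv, cohort.csv and trials.csv.

    The configuration is echoed to config.yaml alongside.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trials, schedule, observers = simulate_trials(config)
    paths = {
        "schedule": outdir / "schedule.csv",
        "cohort": outdir / "cohort.csv",
        "trials": outdir / "trials.csv",
    }
    schedule.to_csv(paths["schedule"], index=False)
    pd.DataFrame(
        [dataclasses.asdict(o) for o in observers]
    ).to_csv(paths["cohort"], index=False)
    trials.to_csv(paths["trials"], index=False)
    config.to_yaml(outdir / "config.yaml")
    return paths


@dataclass(frozen=True)
class BinAnalysis:
    """All per-bin results: fits, metrics, model comparison, compensation."""

    bin: int
    fit_two: TwoPriorFit
    fit_one: OnePriorFit
    metrics: FitMetrics
    comparison: ModelComparison
    bias: Optional[float] = None
    mu_hat_short_adj: Optional[float] = None
    mu_hat_long_adj: Optional[float] = None


@dataclass(frozen=True)
class AnalysisReport:
    exclusions: pd.DataFrame
    binned: pd.DataFrame
    grand: pd.DataFrame
    per_participant: pd.DataFrame
    bins: tuple[BinAnalysis, ...]
    permutation: dict[int, PermutationResult] = field(default_factory=dict)


def _analyze_bin(
    binned: pd.DataFrame, grand: pd.DataFrame, b: int, config: PipelineConfig
) -> BinAnalysis:
    grand_bin = grand[grand["bin"] == b]
    fit2 = fit_two_prior(grand_bin)
    fit1 = fit_one_prior(grand_bin)
    metrics = eval_metrics(fit2)
    comparison = compare_models(binned, b, config.count_noise_param)

    bias = mu_s_adj = mu_l_adj = None
    wants_comp = config.bias_compensation == "always" or (
        config.bias_compensation == "auto"
        and (metrics.irregular_short or metrics.irregular_long)
    )
    if wants_comp:
        comp: BiasCompensation = compensate_undershoot(grand_bin)
        fit2_sub = fit_two_prior(comp.adjusted)
        bias = comp.bias
        try:
            mu_s_adj, mu_l_adj = readjust_mu_hat(fit2, fit2_sub)
        except ValueError:
            # long-prior mu_hat irregular: report the compensated fit as-is
            mu_s_adj, mu_l_adj = fit2_sub.mu_short, fit2_sub.mu_long
    return BinAnalysis(
        bin=b,
        fit_two=fit2,
        fit_one=fit1,
        metrics=metrics,
        comparison=comparison,
        bias=bias,
        mu_hat_short_adj=mu_s_adj,
        mu_hat_long_adj=mu_l_adj,
    )


def run_analysis(
    trials: pd.DataFrame,
    config: PipelineConfig = PipelineConfig(),
    control_trials: Optional[pd.DataFrame] = None,
) -> AnalysisReport:
    """Preprocess a trial table, fit per bin, compare models, optionally
    run the permutation test against a control experiment's table."""
    config.validate()
    flagged, binned, grand = preprocess(trials)
    report_bins = tuple(
        _analyze_bin(binned, grand, b, config) for b in sorted(grand["bin"].unique())
    )
    permutation: dict[int, PermutationResult] = {}
    if control_trials is not None:
        _, binned_ctrl, _ = preprocess(control_trials)
        for b in sorted(grand["bin"].unique()):
            permutation[b] = permutation_test(
                binned,
                binned_ctrl,
                bin=b,
                n_perm=config.n_perm,
                seed=config.seed + 10 * b,
                bias_compensation=config.bias_compensation,
                irregular_rule=config.irregular_rule,
            )
    return AnalysisReport(
        exclusions=exclusion_report(flagged),
        binned=binned,
        grand=grand,
        per_participant=per_participant_metrics(binned),
        bins=report_bins,
        permutation=permutation,
    )


def write_report(report: AnalysisReport, outdir) -> None:
    """Serialize a report: CSV tables plus key-value JSON for fits/tests."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.exclusions.to_csv(outdir / "exclusions.csv", index=False)
    report.binned.to_csv(outdir / "binned_means.csv", index=False)
    report.grand.to_csv(outdir / "grand_average.csv", index=False)
    report.per_participant.to_csv(outdir / "per_participant_metrics.csv", index=False)

    payload: dict = {"bins": {}, "permutation": {}}
    for ba in report.bins:
        payload["bins"][str(ba.bin)] = {
            "fit_two": dataclasses.asdict(ba.fit_two),
            "fit_one": dataclasses.asdict(ba.fit_one),
            "metrics": dataclasses.asdict(ba.metrics),
            "comparison": dataclasses.asdict(ba.comparison),
            "bias": ba.bias,
            "mu_hat_short_adj": ba.mu_hat_short_adj,
            "mu_hat_long_adj": ba.mu_hat_long_adj,
        }
    for b, perm in report.permutation.items():
        d = dataclasses.asdict(perm)
        d.pop("diffs")
        payload["permutation"][str(b)] = d
        pd.DataFrame({"diff": perm.diffs}).to_csv(
            outdir / f"permutation_diffs_bin{b}.csv", index=False
        )
    with open(outdir / "report.json", "w") as fh:
        json.dump(payload, fh, indent=2, default=float)


def permutation_replicate(
    seed: int,
    effect_mu_shift: float = 0.0,
    n_perm: int = 1000,
    bin: int = 2,
    n_participants: int = 20,
    bias_compensation: str = "never",
) -> PermutationResult:
    """One simulated two-experiment comparison ending in a permutation test.

    Both cohorts share the default generative settings; the test cohort's
    acquired prior means are pushed apart symmetrically by
    ``effect_mu_shift`` (total added delta mu_hat).  Used for type-I-error
    and power studies of the permutation procedure.
    """
    base = CohortConfig(n_participants=n_participants)
    test_cfg = replace(
        base,
        mu_hat_short=(base.mu_hat_short[0] - effect_mu_shift / 2, base.mu_hat_short[1]),
        mu_hat_long=(base.mu_hat_long[0] + effect_mu_shift / 2, base.mu_hat_long[1]),
    )
    cfg_test = PipelineConfig(
        seed=seed * 2 + 1, experiment_label="test", cohort=test_cfg
    )
    cfg_ctrl = PipelineConfig(
        seed=seed * 2 + 2, experiment_label="control", cohort=base, with_cmr=False
    )
    trials_test, _, _ = simulate_trials(cfg_test)
    trials_ctrl, _, _ = simulate_trials(cfg_ctrl)
    _, binned_test, _ = preprocess(trials_test)
    _, binned_ctrl, _ = preprocess(trials_ctrl)
    return permutation_test(
        binned_test,
        binned_ctrl,
        bin=bin,
        n_perm=n_perm,
        seed=seed + 7,
        bias_compensation=bias_compensation,
    )
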